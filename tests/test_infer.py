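import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import oracle_infer, oracle_pair_consistency
from boolinfer.discretise import BinaryMatrix
from boolinfer.infer import (
    BooleanNetwork,
    ConstraintSet,
    SignedEdge,
    StringencyLevel,
    assign_function,
    infer_network,
    network_complexity,
    pair_consistency,
    read_constraints,
    read_network_tsv,
    write_constraints,
    write_network_sif,
    write_network_tsv,
)

binary_series = st.lists(st.integers(0, 1), min_size=2, max_size=12)


class TestStringencyLevel:
    @pytest.mark.parametrize("pct,allowance", [(50, 50), (80, 20), (100, 0)])
    def test_conflicted_allowance_complement(self, pct, allowance):
        assert StringencyLevel(pct).conflicted_allowance == allowance

    @pytest.mark.parametrize("pct", [0, -1, 101])
    def test_out_of_range_rejected(self, pct):
        with pytest.raises(ValueError):
            StringencyLevel(pct)


class TestPairConsistency:
    def test_perfect_activation(self):
        assert pair_consistency([1, 1, 0, 0, 1], [0, 1, 1, 0, 0], "+") == 1.0

    def test_complement_is_zero(self):
        assert pair_consistency([1, 1, 0, 0, 1], [0, 1, 1, 0, 0], "-") == 0.0

    def test_partial_match(self):
        assert pair_consistency([1, 0, 1], [1, 1, 1], "+") == 0.5

    def test_length_mismatch_and_short_series(self):
        with pytest.raises(ValueError):
            pair_consistency([1, 0], [1], "+")
        with pytest.raises(ValueError):
            pair_consistency([1], [1], "+")

    @given(reg=binary_series, tgt=binary_series)
    @settings(max_examples=100, deadline=None)
    def test_signs_sum_to_one_exactly(self, reg, tgt):
        n = min(len(reg), len(tgt))
        reg, tgt = reg[:n], tgt[:n]
        c_act = pair_consistency(reg, tgt, "+")
        c_inh = pair_consistency(reg, tgt, "-")
        assert c_act + c_inh == 1.0

    @given(reg=binary_series, tgt=binary_series)
    @settings(max_examples=60, deadline=None)
    def test_matches_scalar_oracle(self, reg, tgt):
        n = min(len(reg), len(tgt))
        reg, tgt = reg[:n], tgt[:n]
        for sign in "+-":
            assert pair_consistency(reg, tgt, sign) == float(
                oracle_pair_consistency(reg, tgt, sign)
            )


class TestAssignFunction:
    def test_perfect_pair_assigned_at_full_stringency(self):
        e = assign_function([1, 0, 1, 0], [0, 1, 0, 1], StringencyLevel(100))
        assert e is not None and e.sign == "+" and e.consistency == 1.0

    def test_below_threshold_assigns_nothing(self):
        # 3 of 4 transitions match -> 0.75 < 0.80
        e = assign_function([1, 1, 0, 0, 1], [0, 1, 1, 0, 1], StringencyLevel(80))
        assert e is None

    def test_tie_assigns_nothing_even_at_50(self):
        e = assign_function([1, 0, 1], [1, 1, 1], StringencyLevel(50))
        assert e is None

    def test_exactly_at_threshold_passes(self):
        # 4/5 = 0.8 at stringency 80
        e = assign_function([1, 1, 0, 0, 1, 0], [0, 1, 1, 0, 1, 1], StringencyLevel(80))
        assert e is not None and e.consistency == pytest.approx(0.8)

    def test_constant_regulator_flagged_degenerate(self):
        e = assign_function([1, 1, 1, 0], [0, 1, 1, 1], StringencyLevel(100))
        assert e is not None and e.degenerate


class TestInferNetwork:
    def _matrix(self, rows, genes):
        return BinaryMatrix(gene_ids=tuple(genes), states=np.array(rows))

    def test_delayed_copy_gives_two_cycle(self):
        b = self._matrix([[1, 0, 1, 0], [0, 1, 0, 1]], ["A", "B"])
        net = infer_network(b, StringencyLevel(100))
        assert net.signed_keys == {("A", "B", "+"), ("B", "A", "+")}

    def test_conceptual_constraint_bars_regulator(self):
        b = self._matrix([[1, 0, 1, 0], [0, 1, 0, 1]], ["A", "B"])
        cs = ConstraintSet(conceptual=frozenset({"B"}))
        net = infer_network(b, StringencyLevel(100), constraints=cs)
        assert net.signed_keys == {("A", "B", "+")}

    def test_specific_constraint_bars_pair(self):
        b = self._matrix([[1, 0, 1, 0], [0, 1, 0, 1]], ["A", "B"])
        cs = ConstraintSet(specific=frozenset({("A", "B")}))
        net = infer_network(b, StringencyLevel(100), constraints=cs)
        assert net.signed_keys == {("B", "A", "+")}

    def test_constraint_gene_outside_universe_rejected(self):
        b = self._matrix([[1, 0, 1], [0, 1, 0]], ["A", "B"])
        with pytest.raises(ValueError, match="Z"):
            infer_network(b, StringencyLevel(100), ConstraintSet(conceptual=frozenset({"Z"})))

    def test_single_gene_rejected(self):
        b = self._matrix([[1, 0, 1]], ["A"])
        with pytest.raises(ValueError):
            infer_network(b, StringencyLevel(100))

    def test_no_self_edges_ever(self, rng):
        states = rng.integers(0, 2, size=(6, 8))
        net = infer_network(BinaryMatrix(tuple("ABCDEF"), states), StringencyLevel(50))
        assert all(e.regulator != e.target for e in net.edges)

    def test_stringency_monotone_nesting(self, rng):
        states = rng.integers(0, 2, size=(5, 8))
        b = BinaryMatrix(tuple("ABCDE"), states)
        e50 = infer_network(b, StringencyLevel(50)).signed_keys
        e80 = infer_network(b, StringencyLevel(80)).signed_keys
        e100 = infer_network(b, StringencyLevel(100)).signed_keys
        assert e100 <= e80 <= e50

    @pytest.mark.parametrize("stringency", [50.0, 80.0, 100.0])
    def test_agrees_with_brute_force_oracle(self, rng, stringency):
        for _ in range(10):
            k = int(rng.integers(2, 6))
            p = int(rng.integers(4, 9))
            genes = [f"g{i}" for i in range(k)]
            states = rng.integers(0, 2, size=(k, p))
            net = infer_network(BinaryMatrix(tuple(genes), states), StringencyLevel(stringency))
            expected = oracle_infer(genes, states.tolist(), stringency)
            got = {(e.regulator, e.target): (e.sign, e.consistency) for e in net.edges}
            assert set(got) == set(expected)
            for pair, (sign, cons) in expected.items():
                assert got[pair][0] == sign
                assert got[pair][1] == float(cons)


class TestNetworkComplexity:
    def _net(self, genes, keys):
        edges = tuple(SignedEdge(r, t, s, 1.0) for r, t, s in keys)
        return BooleanNetwork(genes=tuple(genes), edges=edges)

    def test_chain(self):
        net = self._net("ABC", [("A", "B", "+"), ("B", "C", "+")])
        assert network_complexity(net) == (3, pytest.approx(2 / 3))

    def test_empty(self):
        assert network_complexity(self._net("ABC", [])) == (0, 0.0)

    def test_isolated_genes_not_counted(self):
        net = self._net("ABCD", [("A", "B", "+")])
        assert network_complexity(net)[0] == 2


class TestConstraintIO:
    def test_two_section_file(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text(
            "# enzymes\n[conceptual]\nPGI1\nTPI\nPGK\nPGM\n"
            "[specific]\nCO\tCCA1\nFT\tCCA1\n"
        )
        cs = read_constraints(p)
        assert cs.conceptual == {"PGI1", "TPI", "PGK", "PGM"}
        assert cs.specific == {("CO", "CCA1"), ("FT", "CCA1")}

    def test_empty_file_is_classical_mode(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text("")
        cs = read_constraints(p)
        assert not cs

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text("[specific]\nA B no-tab\n")
        with pytest.raises(ValueError, match=":2"):
            read_constraints(p)

    def test_self_pair_rejected(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text("[specific]\nA\tA\n")
        with pytest.raises(ValueError, match="self"):
            read_constraints(p)

    def test_round_trip(self, tmp_path):
        cs = ConstraintSet(conceptual=frozenset({"X"}), specific=frozenset({("A", "B")}))
        p = tmp_path / "c.txt"
        write_constraints(cs, p)
        assert read_constraints(p) == cs

    def test_shipped_clock_constraints(self):
        from importlib import resources

        p = resources.files("boolinfer").joinpath("data/clock_constraints.txt")
        cs = read_constraints(str(p))
        assert cs.conceptual == {"PGI1", "TPI", "PGK", "PGM"}
        assert len(cs.specific) == 21  # 3 flowering genes x 7 clock genes


def test_network_tsv_round_trip_and_sif(tmp_path, rng):
    states = rng.integers(0, 2, size=(4, 8))
    net = infer_network(BinaryMatrix(tuple("ABCD"), states), StringencyLevel(80))
    tsv = tmp_path / "net.tsv"
    write_network_tsv(net, tsv)
    again = read_network_tsv(tsv, genes=list("ABCD"))
    assert again.signed_keys == net.signed_keys
    assert {e.key: round(e.consistency, 6) for e in again.edges} == {
        e.key: round(e.consistency, 6) for e in net.edges
    }
    sif = tmp_path / "net.sif"
    write_network_sif(net, sif)
    lines = sif.read_text().strip().splitlines() if net.edges else []
    assert len(lines) == len(net.edges)
    for line in lines:
        assert line.split("\t")[1] in ("activates", "inhibits")
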