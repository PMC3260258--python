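"""Pairwise Boolean function assignment with stringency and prior constraints.

The regulatory model is deliberately minimal: a target's on/off state is a
Boolean function of a single regulator's state one step earlier —
``target[t+1] = reg[t]`` (activation) or ``1 - reg[t]`` (inhibition).  For
every ordered, non-self gene pair both candidate functions are scored by
their consistency: the fraction of the p-1 observed transitions they explain.
A function is assigned only when its consistency reaches the stringency
threshold, so stringency 100 permits zero conflicting transitions
(conflicted allowance = 100 - stringency).

Prior biological knowledge enters as constraints: *conceptual* constraints
bar a gene (typically an enzymatic gene, which acts post-transcriptionally)
from ever being a regulator; *specific* constraints forbid individual
ordered pairs known not to be regulatory.  Constrained pairs are skipped
before assignment, which is what cuts the method's notorious false-positive
load.  Self-regulation is excluded throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import ACTIVATION, INHIBITION
from .discretise import BinaryMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StringencyLevel:
    """Minimum fraction (percent) of transitions a Boolean function must explain."""

    percent: float

    def __post_init__(self) -> None:
        if not (0 < self.percent <= 100):
            raise ValueError(f"stringency percent must be in (0, 100], got {self.percent}")

    @property
    def conflicted_allowance(self) -> float:
        """Percent of transitions allowed to contradict the assigned function."""
        return 100.0 - self.percent


@dataclass(frozen=True)
class SignedEdge:
    """A directed regulator -> target relation with sign and consistency."""

    regulator: str
    target: str
    sign: str  # '+' activation, '-' inhibition
    consistency: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.regulator == self.target:
            raise ValueError("self-regulation is excluded")
        if self.sign not in (ACTIVATION, INHIBITION):
            raise ValueError(f"sign must be '+' or '-', got {self.sign!r}")
        if not (0.0 <= self.consistency <= 1.0):
            raise ValueError("consistency must lie in [0, 1]")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.regulator, self.target, self.sign)


@dataclass
class BooleanNetwork:
    """A set of signed pairwise relations over a gene universe."""

    genes: tuple[str, ...]
    edges: tuple[SignedEdge, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        universe = set(self.genes)
        pairs: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.regulator not in universe or e.target not in universe:
                raise ValueError(f"edge {e.regulator}->{e.target} outside the gene universe")
            if (e.regulator, e.target) in pairs:
                raise ValueError(
                    f"pair {e.regulator}->{e.target} assigned more than one function"
                )
            pairs.add((e.regulator, e.target))

    @property
    def signed_keys(self) -> frozenset[tuple[str, str, str]]:
        return frozenset(e.key for e in self.edges)

    def pair_signs(self) -> dict[tuple[str, str], str]:
        return {(e.regulator, e.target): e.sign for e in self.edges}


@dataclass(frozen=True)
class ConstraintSet:
    """Prior-knowledge restrictions on the inference search space."""

    conceptual: frozenset[str] = frozenset()  # genes barred from being regulators
    specific: frozenset[tuple[str, str]] = frozenset()  # forbidden ordered pairs
    forbid_self: bool = True

    def __post_init__(self) -> None:
        for reg, tgt in self.specific:
            if reg == tgt:
                raise ValueError(f"specific constraint {reg}->{tgt} is a self-pair")

    def allows(self, regulator: str, target: str) -> bool:
        if self.forbid_self and regulator == target:
            return False
        if regulator in self.conceptual:
            return False
        return (regulator, target) not in self.specific

    def __bool__(self) -> bool:
        return bool(self.conceptual or self.specific)


def _transition_counts(reg: np.ndarray, tgt: np.ndarray, delay: int) -> tuple[int, int]:
    """(#transitions explained by activation, total transitions)."""
    reg = np.asarray(reg, dtype=np.int8)
    tgt = np.asarray(tgt, dtype=np.int8)
    if reg.shape != tgt.shape:
        raise ValueError("regulator and target series must have equal length")
    n = reg.size
    if n < delay + 1:
        raise ValueError(f"need at least {delay + 1} timepoints for delay {delay}")
    matches = int(np.sum(tgt[delay:] == reg[: n - delay]))
    return matches, n - delay


def pair_consistency(reg, tgt, sign: str, delay: int = 1) -> float:
    """Fraction of one-step transitions explained by the candidate function.

    Activation checks ``tgt[t+delay] == reg[t]``; inhibition checks the
    complement.  The two consistencies of a pair sum to 1 exactly.
    """
    if sign not in (ACTIVATION, INHIBITION):
        raise ValueError(f"sign must be '+' or '-', got {sign!r}")
    matches, total = _transition_counts(reg, tgt, delay)
    if sign == INHIBITION:
        matches = total - matches
    return matches / total


def assign_function(
    reg,
    tgt,
    stringency: StringencyLevel,
    delay: int = 1,
    regulator: str = "regulator",
    target: str = "target",
) -> SignedEdge | None:
    """Pick activation or inhibition for one pair, or neither.

    The better-scoring sign is assigned iff its consistency reaches the
    stringency threshold and the two signs are not tied (a tie, possible
    only at stringency <= 50, assigns nothing).
    """
    n_act, total = _transition_counts(np.asarray(reg), np.asarray(tgt), delay)
    n_inh = total - n_act
    if n_act == n_inh:
        return None
    if n_act > n_inh:
        sign, n_best = ACTIVATION, n_act
    else:
        sign, n_best = INHIBITION, n_inh
    # integer comparison avoids float threshold edge cases: n/total >= pct/100
    if n_best * 100 < stringency.percent * total:
        return None
    reg_arr = np.asarray(reg, dtype=np.int8)
    tgt_arr = np.asarray(tgt, dtype=np.int8)
    n = reg_arr.size
    degenerate = (
        len(set(reg_arr[: n - delay].tolist())) == 1
        or len(set(tgt_arr[delay:].tolist())) == 1
    )
    return SignedEdge(
        regulator=regulator,
        target=target,
        sign=sign,
        consistency=n_best / total,
        degenerate=degenerate,
    )


def infer_network(
    b: BinaryMatrix,
    stringency: StringencyLevel,
    constraints: ConstraintSet | None = None,
    delay: int = 1,
) -> BooleanNetwork:
    """Assign a Boolean function to every admissible ordered gene pair.

    Without constraints this is the classical Boolean inference; with a
    :class:`ConstraintSet` the barred pairs are skipped before assignment.
    """
    if b.n_genes < 2:
        raise ValueError("network inference needs at least 2 genes")
    universe = set(b.gene_ids)
    if constraints is not None:
        missing = sorted(
            {g for g in constraints.conceptual if g not in universe}
            | {g for pair in constraints.specific for g in pair if g not in universe}
        )
        if missing:
            raise ValueError(f"constraint gene(s) absent from data: {', '.join(missing)}")
    edges: list[SignedEdge] = []
    for i, reg_gene in enumerate(b.gene_ids):
        for j, tgt_gene in enumerate(b.gene_ids):
            if i == j:
                continue
            if constraints is not None and not constraints.allows(reg_gene, tgt_gene):
                continue
            edge = assign_function(
                b.states[i],
                b.states[j],
                stringency,
                delay=delay,
                regulator=reg_gene,
                target=tgt_gene,
            )
            if edge is not None:
                edges.append(edge)
    net = BooleanNetwork(
        genes=tuple(b.gene_ids),
        edges=tuple(edges),
        provenance={
            "discretisation": b.spec.label if b.spec is not None else None,
            "stringency": stringency.percent,
            "constrained": constraints is not None and bool(constraints),
            "delay": delay,
        },
    )
    log.info(
        "inferred %d edges (%s, stringency %g, constraints=%s)",
        len(edges),
        net.provenance["discretisation"],
        stringency.percent,
        net.provenance["constrained"],
    )
    return net


def network_complexity(net: BooleanNetwork) -> tuple[int, float]:
    """(nodes incident to >= 1 edge, edges per such node); (0, 0) if empty."""
    if not net.edges:
        return 0, 0.0
    nodes = {e.regulator for e in net.edges} | {e.target for e in net.edges}
    return len(nodes), len(net.edges) / len(nodes)


def read_constraints(path: str | Path) -> ConstraintSet:
    """Parse a two-section constraint file.

    Format::

        [conceptual]
        PGI1            # one gene per line
        [specific]
        CO<TAB>CCA1     # one forbidden ordered pair per line

    ``#`` starts a comment; an empty file yields an empty (classical-mode)
    constraint set.
    """
    conceptual: set[str] = set()
    specific: set[tuple[str, str]] = set()
    section: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.lower() in ("[conceptual]", "[specific]"):
                section = line.lower().strip("[]")
                continue
            if section == "conceptual":
                if "\t" in line:
                    raise ValueError(f"{path}:{lineno}: unexpected tab in conceptual section")
                conceptual.add(line)
            elif section == "specific":
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 'regulator<TAB>target' in specific section"
                    )
                reg, tgt = (p.strip() for p in parts)
                if reg == tgt:
                    raise ValueError(f"{path}:{lineno}: self-pair {reg}->{tgt} not allowed")
                specific.add((reg, tgt))
            else:
                raise ValueError(
                    f"{path}:{lineno}: content before any [conceptual]/[specific] header"
                )
    return ConstraintSet(conceptual=frozenset(conceptual), specific=frozenset(specific))


def write_constraints(cs: ConstraintSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("[conceptual]\n")
        for g in sorted(cs.conceptual):
            fh.write(f"{g}\n")
        fh.write("[specific]\n")
        for reg, tgt in sorted(cs.specific):
            fh.write(f"{reg}\t{tgt}\n")


_SIGN_WORD = {ACTIVATION: "activates", INHIBITION: "inhibits"}
_WORD_SIGN = {v: k for k, v in _SIGN_WORD.items()}


def write_network_tsv(net: BooleanNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\tsign\tconsistency\tdegenerate\n")
        for e in sorted(net.edges, key=lambda e: (e.regulator, e.target)):
            fh.write(
                f"{e.regulator}\t{e.target}\t{e.sign}\t{e.consistency:.6g}\t"
                f"{str(e.degenerate).lower()}\n"
            )


def read_network_tsv(path: str | Path, genes: list[str] | None = None) -> BooleanNetwork:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    edges = tuple(
        SignedEdge(
            regulator=str(r.regulator),
            target=str(r.target),
            sign=str(r.sign),
            consistency=float(r.consistency),
            degenerate=bool(r.degenerate),
        )
        for r in df.itertuples()
    )
    if genes is None:
        genes = sorted({e.regulator for e in edges} | {e.target for e in edges})
    return BooleanNetwork(genes=tuple(genes), edges=edges)


def write_network_sif(net: BooleanNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in sorted(net.edges, key=lambda e: (e.regulator, e.target)):
            fh.write(f"{e.regulator}\t{_SIGN_WORD[e.sign]}\t{e.target}\n")
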