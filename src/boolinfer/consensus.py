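"""Master Boolean network: merge the solutions of many binarisation varieties.

Because no single binarisation rule is best for every dataset, each variety
yields its own network solution.  The master network is the union of the
signed edges over the N solutions, with each edge weighted by its
*consistency* n_i / N — the fraction of solutions that contain it — which
serves as an edge-confidence score and as a filter criterion for discarding
relations likely found by chance.  A pair may carry both signs as two
distinct entries (the same genes can flip regulatory sign across
conditions or encodings).

Filtering supports both conventions used in practice: an absolute support
count (e.g. present in at least 4 of 24 solutions) or a fraction threshold
(e.g. consistency strictly above 20%); the caller must pick exactly one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .data_io import ACTIVATION, INHIBITION
from .infer import BooleanNetwork

_SIGN_WORD = {ACTIVATION: "activates", INHIBITION: "inhibits"}


@dataclass(frozen=True)
class MasterEdge:
    regulator: str
    target: str
    sign: str
    support_count: int
    consistency: float
    degenerate: bool = False  # true when every supporting solution flagged it


@dataclass
class MasterNetwork:
    genes: tuple[str, ...]
    edges: tuple[MasterEdge, ...]
    n_solutions: int

    def __post_init__(self) -> None:
        if self.n_solutions < 1:
            raise ValueError("a master network needs at least one solution")
        for e in self.edges:
            if not (0 < e.consistency <= 1):
                raise ValueError("retained edges must have consistency in (0, 1]")
            if e.support_count != round(e.consistency * self.n_solutions):
                raise ValueError("support_count inconsistent with consistency")

    @property
    def signed_keys(self) -> frozenset[tuple[str, str, str]]:
        return frozenset((e.regulator, e.target, e.sign) for e in self.edges)


def build_master(
    solutions: list[BooleanNetwork],
    drop_degenerate: bool = False,
) -> MasterNetwork:
    """Union the signed edges of ``solutions``; consistency = support / N.

    All solutions must share one gene universe.  ``drop_degenerate``
    excludes edges flagged as constant-profile artifacts before counting.
    """
    if not solutions:
        raise ValueError("empty solution list")
    universe = set(solutions[0].genes)
    for s in solutions[1:]:
        if set(s.genes) != universe:
            raise ValueError("solutions do not share one gene universe")
    n = len(solutions)
    support: Counter[tuple[str, str, str]] = Counter()
    non_degenerate_seen: set[tuple[str, str, str]] = set()
    for s in solutions:
        for e in s.edges:
            if drop_degenerate and e.degenerate:
                continue
            support[e.key] += 1
            if not e.degenerate:
                non_degenerate_seen.add(e.key)
    edges = tuple(
        MasterEdge(
            regulator=reg,
            target=tgt,
            sign=sign,
            support_count=cnt,
            consistency=cnt / n,
            degenerate=(reg, tgt, sign) not in non_degenerate_seen,
        )
        for (reg, tgt, sign), cnt in sorted(support.items())
    )
    return MasterNetwork(genes=tuple(sorted(universe)), edges=edges, n_solutions=n)


def filter_master(
    m: MasterNetwork,
    min_count: int | None = None,
    min_fraction: float | None = None,
    strict: bool = False,
) -> MasterNetwork:
    """Keep edges with support >= min_count, or consistency >= (> if strict) min_fraction.

    Exactly one of the two thresholds must be given.
    """
    if (min_count is None) == (min_fraction is None):
        raise ValueError("give exactly one of min_count or min_fraction")
    if min_count is not None:
        kept = tuple(e for e in m.edges if e.support_count >= min_count)
    elif strict:
        kept = tuple(e for e in m.edges if e.consistency > min_fraction)
    else:
        kept = tuple(e for e in m.edges if e.consistency >= min_fraction)
    return MasterNetwork(genes=m.genes, edges=kept, n_solutions=m.n_solutions)


def to_graph(m: MasterNetwork) -> nx.MultiDiGraph:
    """Directed multigraph with consistency/support/sign edge attributes."""
    g = nx.MultiDiGraph(n_solutions=m.n_solutions)
    g.add_nodes_from(m.genes)
    for e in m.edges:
        g.add_edge(
            e.regulator,
            e.target,
            key=e.sign,
            sign=e.sign,
            consistency=e.consistency,
            support_count=e.support_count,
            degenerate=e.degenerate,
        )
    return g


def export_network(m: MasterNetwork, fmt: str, path: str | Path) -> None:
    """Write the master network as ``sif``, ``graphml`` or ``tsv``.

    GraphML carries consistency (drives edge thickness in Cytoscape),
    support_count and sign as typed edge attributes.
    """
    path = Path(path)
    if fmt == "sif":
        with open(path, "w") as fh:
            for e in sorted(m.edges, key=lambda e: (e.regulator, e.target, e.sign)):
                fh.write(f"{e.regulator}\t{_SIGN_WORD[e.sign]}\t{e.target}\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("regulator\ttarget\tsign\tconsistency\tsupport_count\tn_solutions\n")
            for e in sorted(m.edges, key=lambda e: (e.regulator, e.target, e.sign)):
                fh.write(
                    f"{e.regulator}\t{e.target}\t{e.sign}\t{e.consistency:.6g}\t"
                    f"{e.support_count}\t{m.n_solutions}\n"
                )
    elif fmt == "graphml":
        nx.write_graphml(to_graph(m), path)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected sif, graphml or tsv)")
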