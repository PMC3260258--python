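"""Expression-matrix and reference-network I/O plus dataset characteristics.

The package works on short gene-expression time series (typically 6-12
timepoints) stored as tab-separated text: one row per gene, a header row of
timepoint labels, the first column holding the gene identifier.  Values are
on a log2 scale, either log-ratios (two-channel arrays, zero-centred) or
normalised intensities (single-channel arrays); the distinction matters
because the sign-of-log2-ratio binarisation is only meaningful for ratios.

Dataset "quality" is summarised by the amplitude: the mean peak-to-trough
distance of the gene profiles.  "Resolution" is simply the number of
timepoints.  Both are bundled by :func:`characterise`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

LOG_RATIO = "log_ratio"
INTENSITY = "intensity"
DATA_KINDS = (LOG_RATIO, INTENSITY)

ACTIVATION = "+"
INHIBITION = "-"
SIGNS = (ACTIVATION, INHIBITION)


@dataclass
class ExpressionMatrix:
    """A genes x timepoints real-valued expression table.

    Parameters
    ----------
    data
        DataFrame indexed by unique gene id, columns are ordered timepoint
        labels, values finite floats (log2 scale).
    data_kind
        Either ``"log_ratio"`` or ``"intensity"``.
    """

    data: pd.DataFrame
    data_kind: str = LOG_RATIO

    def __post_init__(self) -> None:
        if self.data_kind not in DATA_KINDS:
            raise ValueError(f"data_kind must be one of {DATA_KINDS}, got {self.data_kind!r}")
        if self.data.shape[0] < 1:
            raise ValueError("expression matrix needs at least one gene")
        if self.data.shape[1] < 2:
            raise ValueError(
                f"expression matrix needs at least 2 timepoints, got {self.data.shape[1]}"
            )
        dup = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate gene id(s): {', '.join(map(str, dup))}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if not np.isfinite(values).all():
            bad = list(zip(*np.where(~np.isfinite(values))))
            g, t = bad[0]
            raise ValueError(
                f"non-finite value at gene {self.data.index[g]!r}, "
                f"timepoint {self.data.columns[t]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def timepoint_labels(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class DatasetCharacteristics:
    """Resolution (datapoints), size (genes) and quality (amplitude)."""

    datapoints: int
    genes: int
    amplitude: float


@dataclass(frozen=True)
class ReferenceNetwork:
    """Signed directed reference edges over a fixed gene universe.

    Negatives (true non-relations) are all ordered non-self pairs of the
    universe that carry no edge, so the universe must be stated explicitly.
    """

    edges: frozenset[tuple[str, str, str]]  # (regulator, target, sign)
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for reg, tgt, sign in self.edges:
            if reg == tgt:
                raise ValueError(f"self-regulation {reg}->{tgt} is excluded")
            if sign not in SIGNS:
                raise ValueError(f"sign must be '+' or '-', got {sign!r} for {reg}->{tgt}")
            if reg not in self.universe or tgt not in self.universe:
                raise ValueError(f"edge {reg}->{tgt} uses gene(s) outside the universe")

    def pair_signs(self) -> dict[tuple[str, str], str]:
        """Map ordered pair -> sign (a reference pair carries one sign)."""
        out: dict[tuple[str, str], str] = {}
        for reg, tgt, sign in self.edges:
            if (reg, tgt) in out and out[(reg, tgt)] != sign:
                raise ValueError(f"reference lists {reg}->{tgt} with both signs")
            out[(reg, tgt)] = sign
        return out


def read_expression_matrix(
    path: str | Path,
    data_kind: str = LOG_RATIO,
    drop_incomplete_rows: bool = False,
) -> ExpressionMatrix:
    """Load a tab-separated expression matrix.

    Format: header row of timepoint labels, first column gene id.  Rows with
    missing values are rejected unless ``drop_incomplete_rows`` is set.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 timepoint columns, found {df.shape[1]}")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate gene id(s): {', '.join(map(str, dup))}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        g, t = next(zip(*np.where(bad.to_numpy())))
        raise ValueError(
            f"{path}: non-numeric value at gene {df.index[g]!r}, column {df.columns[t]!r}"
        )
    if numeric.isna().to_numpy().any():
        if drop_incomplete_rows:
            numeric = numeric.dropna(axis=0)
            if numeric.shape[0] == 0:
                raise ValueError(f"{path}: every row has missing values")
        else:
            g = numeric.index[numeric.isna().any(axis=1)][0]
            raise ValueError(
                f"{path}: missing value(s) in row {g!r} "
                "(pass drop_incomplete_rows=True to drop such rows)"
            )
    return ExpressionMatrix(numeric.astype(float), data_kind=data_kind)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t")


def select_genes(m: ExpressionMatrix, genes: list[str]) -> ExpressionMatrix:
    """Return the submatrix for ``genes``, rows in the requested order."""
    missing = [g for g in genes if g not in m.data.index]
    if missing:
        raise KeyError(f"gene id(s) not in matrix: {', '.join(missing)}")
    return ExpressionMatrix(m.data.loc[genes].copy(), data_kind=m.data_kind)


def amplitude(m: ExpressionMatrix) -> float:
    """Mean peak-to-trough distance across gene profiles (log2 units).

    amplitude = (1/k) * sum_j (peak_j - trough_j) over the k genes, where
    peak_j and trough_j are the highest and lowest values of gene j.
    """
    v = m.values
    return float(np.mean(v.max(axis=1) - v.min(axis=1)))


def characterise(m: ExpressionMatrix) -> DatasetCharacteristics:
    """Bundle resolution, gene count and amplitude of a dataset."""
    return DatasetCharacteristics(
        datapoints=m.n_timepoints, genes=m.n_genes, amplitude=amplitude(m)
    )


def read_reference_network(path: str | Path, universe: list[str]) -> ReferenceNetwork:
    """Load a signed reference network from TSV rows ``regulator TAB target TAB sign``.

    Lines starting with ``#`` are comments; an empty file yields an empty
    (but valid) reference.  Signs must be ``+`` or ``-``.
    """
    edges: set[tuple[str, str, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            reg, tgt, sign = (p.strip() for p in parts)
            if sign not in SIGNS:
                raise ValueError(f"{path}:{lineno}: sign must be '+' or '-', got {sign!r}")
            if reg == tgt:
                raise ValueError(f"{path}:{lineno}: self-regulation {reg}->{tgt} is excluded")
            edges.add((reg, tgt, sign))
    return ReferenceNetwork(edges=frozenset(edges), universe=frozenset(universe))


def write_reference_network(ref: ReferenceNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for reg, tgt, sign in sorted(ref.edges):
            fh.write(f"{reg}\t{tgt}\t{sign}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; ``#`` comments and blank lines skipped."""
    genes: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes
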