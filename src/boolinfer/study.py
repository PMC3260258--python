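"""Factor-study orchestration: binarisation x constraints x stringency grids.

The central empirical question the package serves is how three protocol
choices — binarisation variety, prior-knowledge constraints, and stringency
of function assignment — shape network-inference performance.
:func:`run_factor_grid` sweeps the full factorial design over one dataset
and reference, returning a tidy DataFrame (one row per setting) from which
the bar-chart figures are regenerated; computation and presentation stay
strictly separated.  :func:`run_master_pipeline` runs the consensus
protocol: infer one network per variety, merge, filter, export.

Shipped protocol presets (YAML): ``clock_protocol`` — 23 varieties (no
sign-of-log2-ratio), stringency 100, consistency strictly above 20%; and
``galactose_protocol`` — 24 varieties, stringency 100, support >= 4 of 24.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .consensus import MasterNetwork, build_master, export_network, filter_master
from .data_io import ExpressionMatrix, ReferenceNetwork
from .discretise import DiscretisationSpec, discretise_matrix, enumerate_variety_panel
from .evaluate import classify_predictions, performance_indexes
from .infer import BooleanNetwork, ConstraintSet, StringencyLevel, infer_network, network_complexity

log = logging.getLogger(__name__)

GRID_COLUMNS = [
    "variety",
    "constrained",
    "stringency",
    "tp",
    "fp_unidentified",
    "fp_wrong",
    "fp",
    "tn",
    "fn",
    "accuracy",
    "precision",
    "sensitivity",
    "specificity",
    "node_count",
    "edges_per_node",
]


def run_factor_grid(
    m: ExpressionMatrix,
    reference: ReferenceNetwork,
    panel: list[DiscretisationSpec] | None = None,
    stringencies: list[float] = (50.0, 80.0, 100.0),
    constraints: ConstraintSet | None = None,
    modes: tuple[bool, ...] = (False, True),
    delay: int = 1,
) -> pd.DataFrame:
    """Evaluate every (variety, constraint mode, stringency) combination.

    ``modes`` selects constraint usage: False = classical (no prior
    knowledge), True = constraint-based.  Row count is
    |panel| x |stringencies| x |modes|; output is deterministic given the
    inputs.
    """
    if panel is None:
        panel = enumerate_variety_panel(include_log_ratio=m.data_kind == "log_ratio")
    if True in modes and constraints is None:
        raise ValueError("constrained mode requested but no ConstraintSet given")
    rows = []
    for spec in panel:
        binary = discretise_matrix(m, spec)
        for constrained in modes:
            cs = constraints if constrained else None
            for s in stringencies:
                net = infer_network(binary, StringencyLevel(s), constraints=cs, delay=delay)
                counts = classify_predictions(net, reference)
                idx = performance_indexes(counts)
                nodes, epn = network_complexity(net)
                rows.append(
                    {
                        "variety": spec.label,
                        "constrained": constrained,
                        "stringency": s,
                        "tp": counts.tp,
                        "fp_unidentified": counts.fp_unidentified,
                        "fp_wrong": counts.fp_wrong,
                        "fp": counts.fp,
                        "tn": counts.tn,
                        "fn": counts.fn,
                        "accuracy": idx.accuracy,
                        "precision": idx.precision,
                        "sensitivity": idx.sensitivity,
                        "specificity": idx.specificity,
                        "node_count": nodes,
                        "edges_per_node": epn,
                    }
                )
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def plot_grid(df: pd.DataFrame, path: str | Path, stringency: float = 100.0) -> None:
    """Four-panel bar chart (accuracy / precision / sensitivity / specificity)
    per binarisation variety at one stringency, split by constraint mode."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = df[df["stringency"] == stringency]
    varieties = list(dict.fromkeys(sub["variety"]))
    fig, axes = plt.subplots(4, 1, figsize=(max(8, 0.45 * len(varieties)), 12), sharex=True)
    for ax, index in zip(axes, ("accuracy", "precision", "sensitivity", "specificity")):
        width = 0.4
        xs = range(len(varieties))
        for off, constrained, label in ((-width / 2, False, "classical"), (width / 2, True, "constrained")):
            part = sub[sub["constrained"] == constrained].set_index("variety")
            if part.empty:
                continue
            vals = [part.loc[v, index] if v in part.index else float("nan") for v in varieties]
            ax.bar([x + off for x in xs], vals, width=width, label=label)
        ax.set_ylabel(index)
        ax.set_ylim(0, 1.05)
    axes[0].legend(loc="upper right")
    axes[-1].set_xticks(range(len(varieties)))
    axes[-1].set_xticklabels(varieties, rotation=90)
    fig.suptitle(f"network performance by binarisation variety (stringency {stringency:g}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_master_pipeline(
    m: ExpressionMatrix,
    panel: list[DiscretisationSpec] | None = None,
    stringency: float = 100.0,
    constraints: ConstraintSet | None = None,
    min_count: int | None = None,
    min_fraction: float | None = None,
    strict: bool = False,
    drop_degenerate: bool = False,
    delay: int = 1,
    export: tuple[str, str | Path] | None = None,
) -> MasterNetwork:
    """Infer one network per variety, merge into a master network, filter.

    ``export`` optionally writes the filtered master as ``(format, path)``.
    """
    if panel is None:
        panel = enumerate_variety_panel(include_log_ratio=m.data_kind == "log_ratio")
    solutions: list[BooleanNetwork] = []
    for spec in panel:
        binary = discretise_matrix(m, spec)
        solutions.append(
            infer_network(binary, StringencyLevel(stringency), constraints=constraints, delay=delay)
        )
    master = build_master(solutions, drop_degenerate=drop_degenerate)
    if min_count is not None or min_fraction is not None:
        master = filter_master(master, min_count=min_count, min_fraction=min_fraction, strict=strict)
    if export is not None:
        fmt, path = export
        export_network(master, fmt, path)
    return master


def load_protocol(name_or_path: str | Path) -> dict:
    """Load a protocol preset: a shipped name (``clock_protocol``,
    ``galactose_protocol``) or a path to a YAML file."""
    p = Path(name_or_path)
    if p.exists():
        text = p.read_text()
    else:
        ref = resources.files("boolinfer").joinpath(f"data/{name_or_path}.yaml")
        if not ref.is_file():
            raise FileNotFoundError(f"no protocol file or shipped preset named {name_or_path!r}")
        text = ref.read_text()
    return yaml.safe_load(text)
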