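"""Binarisation of expression time series: five method families, 24 varieties.

Boolean analysis needs on/off states, and the choice of binarisation rule is
a known source of variation in the inferred network.  The panel implemented
here spans five families:

* ``mean`` — on where the value exceeds the profile mean;
* ``mid_range`` — on above the midpoint of (max + min) / 2;
* ``sign_log_ratio`` — on where a log2-ratio is positive (ratio data only);
* ``max_minus_pct`` — on above max - x% of max, x in {10, ..., 90};
* ``t0_mean_sd`` — a hysteresis rule: on above mean + x*SD, off below
  mean - x*SD, carry the previous state inside the band; the initial state
  is anchored low (``min_t0``), high (``max_t0``) or to the mean
  (``mean_t0``); x in {0, 0.1, 0.3, 0.5}.

Counting the parameterisations gives 1 + 1 + 1 + 9 + 12 = 24 varieties
(23 when the ratio-only rule is excluded for intensity data).

All thresholds are strict: a value exactly at the threshold encodes 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import LOG_RATIO, ExpressionMatrix

log = logging.getLogger(__name__)

MEAN = "mean"
MID_RANGE = "mid_range"
SIGN_LOG_RATIO = "sign_log_ratio"
MAX_MINUS_PCT = "max_minus_pct"
T0_MEAN_SD = "t0_mean_sd"
FAMILIES = (MEAN, MID_RANGE, SIGN_LOG_RATIO, MAX_MINUS_PCT, T0_MEAN_SD)

MIN_T0 = "min_t0"
MEAN_T0 = "mean_t0"
MAX_T0 = "max_t0"
T0_RULES = (MIN_T0, MEAN_T0, MAX_T0)

_T0_SHORT = {MIN_T0: "min", MEAN_T0: "mean", MAX_T0: "max"}


def _fmt(x: float) -> str:
    return f"{x:g}"


@dataclass(frozen=True)
class DiscretisationSpec:
    """One binarisation variety: a family plus its parameter setting."""

    family: str
    x: float | None = None
    t0_rule: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == MAX_MINUS_PCT:
            if self.x is None or not (0 < self.x < 100):
                raise ValueError("max_minus_pct needs x in (0, 100)")
        elif self.family == T0_MEAN_SD:
            if self.x is None or self.x < 0:
                raise ValueError("t0_mean_sd needs x >= 0")
            if self.t0_rule not in T0_RULES:
                raise ValueError(f"t0_rule must be one of {T0_RULES}")
        else:
            if self.x is not None or self.t0_rule is not None:
                raise ValueError(f"{self.family} takes no parameters")

    @property
    def label(self) -> str:
        if self.family == MEAN:
            return "mean"
        if self.family == MID_RANGE:
            return "midrange"
        if self.family == SIGN_LOG_RATIO:
            return "signlog2"
        if self.family == MAX_MINUS_PCT:
            return f"max-{_fmt(self.x)}pct"
        return f"t0{_T0_SHORT[self.t0_rule]}_sd{_fmt(self.x)}"

    def to_dict(self) -> dict:
        d: dict = {"family": self.family}
        if self.x is not None:
            d["x"] = self.x
        if self.t0_rule is not None:
            d["t0_rule"] = self.t0_rule
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DiscretisationSpec":
        return cls(family=d["family"], x=d.get("x"), t0_rule=d.get("t0_rule"))


@dataclass
class BinaryMatrix:
    """A {0,1} genes x timepoints matrix plus the spec that produced it."""

    gene_ids: tuple[str, ...]
    states: np.ndarray  # int8, k x p
    spec: DiscretisationSpec | None = None
    timepoint_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 2:
            raise ValueError("states must be a 2-D matrix")
        if len(self.gene_ids) != self.states.shape[0]:
            raise ValueError("gene_ids length must match the number of rows")
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("states must be 0/1 valued")

    @property
    def n_genes(self) -> int:
        return self.states.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.states.shape[1]

    def row(self, gene: str) -> np.ndarray:
        return self.states[self.gene_ids.index(gene)]


def _check_profile(profile) -> np.ndarray:
    arr = np.asarray(profile, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("profile must be a 1-D series with at least 2 points")
    return arr


def discretise_mean(profile) -> np.ndarray:
    """1 where the value strictly exceeds the profile mean."""
    arr = _check_profile(profile)
    return (arr > arr.mean()).astype(np.int8)


def discretise_midrange(profile) -> np.ndarray:
    """1 strictly above (max + min) / 2."""
    arr = _check_profile(profile)
    mid = (arr.max() + arr.min()) / 2.0
    return (arr > mid).astype(np.int8)


def discretise_sign_log_ratio(profile) -> np.ndarray:
    """1 for positive log2-ratios, 0 otherwise (zero encodes 0)."""
    arr = _check_profile(profile)
    return (arr > 0).astype(np.int8)


def discretise_max_pct(profile, x: float) -> np.ndarray:
    """1 strictly above max - (x/100)*max."""
    if not (0 < x < 100):
        raise ValueError(f"x must be in (0, 100), got {x}")
    arr = _check_profile(profile)
    mx = arr.max()
    if mx <= 0:
        # Formula still applied literally; sensible only for positive-scale data.
        warnings.warn(
            "max_minus_pct applied to a profile with max <= 0; "
            "threshold max*(1 - x/100) may behave unexpectedly",
            stacklevel=2,
        )
    threshold = mx - (x / 100.0) * mx
    return (arr > threshold).astype(np.int8)


def discretise_t0_sd(profile, x: float, t0_rule: str, sd_mode: str = "population") -> np.ndarray:
    """Hysteresis binarisation around mean +/- x*SD with a carry-forward band.

    The state at t0 is set by ``t0_rule``: ``min_t0`` anchors it to 0,
    ``max_t0`` to 1, ``mean_t0`` to (value > mean).  For i >= 1 the value is
    1 above mean + x*SD, 0 below mean - x*SD and otherwise repeats the
    previous state.  SD is the population SD by default (``sd_mode`` accepts
    ``"sample"`` for the n-1 convention).
    """
    if x < 0:
        raise ValueError("x must be >= 0")
    if t0_rule not in T0_RULES:
        raise ValueError(f"t0_rule must be one of {T0_RULES}")
    arr = _check_profile(profile)
    mean = arr.mean()
    ddof = 0 if sd_mode == "population" else 1
    sd = arr.std(ddof=ddof)
    hi = mean + x * sd
    lo = mean - x * sd
    out = np.empty(arr.size, dtype=np.int8)
    if t0_rule == MIN_T0:
        out[0] = 0
    elif t0_rule == MAX_T0:
        out[0] = 1
    else:
        out[0] = 1 if arr[0] > mean else 0
    for i in range(1, arr.size):
        if arr[i] > hi:
            out[i] = 1
        elif arr[i] < lo:
            out[i] = 0
        else:
            out[i] = out[i - 1]
    return out


def discretise_profile(profile, spec: DiscretisationSpec, data_kind: str = LOG_RATIO) -> np.ndarray:
    """Apply one variety to a single profile."""
    if spec.family == MEAN:
        return discretise_mean(profile)
    if spec.family == MID_RANGE:
        return discretise_midrange(profile)
    if spec.family == SIGN_LOG_RATIO:
        if data_kind != LOG_RATIO:
            raise ValueError(
                "sign_log_ratio is limited to the discretisation of log-ratio data"
            )
        return discretise_sign_log_ratio(profile)
    if spec.family == MAX_MINUS_PCT:
        return discretise_max_pct(profile, spec.x)
    return discretise_t0_sd(profile, spec.x, spec.t0_rule)


def discretise_matrix(m: ExpressionMatrix, spec: DiscretisationSpec) -> BinaryMatrix:
    """Binarise every gene profile of ``m`` independently under ``spec``."""
    states = np.vstack(
        [discretise_profile(m.values[i], spec, m.data_kind) for i in range(m.n_genes)]
    )
    return BinaryMatrix(
        gene_ids=tuple(m.gene_ids),
        states=states,
        spec=spec,
        timepoint_labels=tuple(m.timepoint_labels),
    )


def enumerate_variety_panel(include_log_ratio: bool = True) -> list[DiscretisationSpec]:
    """The full binarisation panel in canonical order.

    mean, midrange, [signlog2,] max-10pct ... max-90pct, then the twelve
    hysteresis varieties (t0 rule outer: min, mean, max; x inner: 0, 0.1,
    0.3, 0.5).  24 varieties with the log-ratio rule, 23 without.
    """
    panel = [DiscretisationSpec(MEAN), DiscretisationSpec(MID_RANGE)]
    if include_log_ratio:
        panel.append(DiscretisationSpec(SIGN_LOG_RATIO))
    panel.extend(DiscretisationSpec(MAX_MINUS_PCT, x=float(x)) for x in range(10, 100, 10))
    for rule in T0_RULES:
        panel.extend(DiscretisationSpec(T0_MEAN_SD, x=x, t0_rule=rule) for x in (0.0, 0.1, 0.3, 0.5))
    labels = [s.label for s in panel]
    assert len(labels) == len(set(labels))
    return panel


def panel_to_yaml(panel: list[DiscretisationSpec], path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump([s.to_dict() for s in panel], fh, sort_keys=False)


def panel_from_yaml(path) -> list[DiscretisationSpec]:
    import yaml

    with open(path) as fh:
        return [DiscretisationSpec.from_dict(d) for d in yaml.safe_load(fh)]
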