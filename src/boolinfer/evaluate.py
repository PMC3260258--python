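"""Benchmark an inferred network against a signed reference.

Every ordered non-self gene pair of the universe falls into exactly one of
five cells, so the counts always total k(k-1):

* TP — predicted edge matching a reference edge in pair and sign;
* FP (wrong prediction) — predicted edge whose pair is in the reference
  with the opposite sign;
* FP (unidentified) — predicted edge whose pair is absent from the
  reference; possibly real regulation the reference simply lacks;
* FN — reference edge with no prediction;
* TN — pair absent from both.

The two FP classes are reported separately because they mean different
things: a wrong prediction contradicts curated knowledge, while an
"unidentified" one merely goes beyond it.  A sign-mismatched prediction
counts once, as FP-wrong (its reference edge is not additionally an FN).

The four summary indexes are accuracy = (TP+TN)/(TP+TN+FP+FN),
precision = TP/(TP+FP), sensitivity = TP/(TP+FN) and
specificity = TN/(TN+FP), with FP = both classes pooled.  A zero
denominator yields ``None``, never a silent 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .data_io import ReferenceNetwork
from .infer import BooleanNetwork


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp_unidentified: int
    fp_wrong: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp_unidentified, self.fp_wrong, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def fp(self) -> int:
        return self.fp_unidentified + self.fp_wrong

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class PerformanceIndexes:
    accuracy: float | None
    precision: float | None
    sensitivity: float | None
    specificity: float | None


def classify_predictions(
    inferred: BooleanNetwork,
    reference: ReferenceNetwork,
    ignore_sign: bool = False,
) -> ConfusionCounts:
    """Place every ordered non-self pair into one confusion cell.

    With ``ignore_sign`` a predicted pair present in the reference counts as
    TP regardless of sign (FP-wrong then never occurs).
    """
    if set(inferred.genes) != set(reference.universe):
        raise ValueError("inferred and reference gene universes differ")
    pred = inferred.pair_signs()
    ref = reference.pair_signs()
    tp = fp_u = fp_w = tn = fn = 0
    genes = sorted(reference.universe)
    for reg in genes:
        for tgt in genes:
            if reg == tgt:
                continue
            pair = (reg, tgt)
            if pair in pred:
                if pair in ref:
                    if ignore_sign or pred[pair] == ref[pair]:
                        tp += 1
                    else:
                        fp_w += 1
                else:
                    fp_u += 1
            else:
                if pair in ref:
                    fn += 1
                else:
                    tn += 1
    return ConfusionCounts(tp=tp, fp_unidentified=fp_u, fp_wrong=fp_w, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def performance_indexes(c: ConfusionCounts) -> PerformanceIndexes:
    """Accuracy, precision, sensitivity and specificity from the counts."""
    return PerformanceIndexes(
        accuracy=_ratio(c.tp + c.tn, c.total),
        precision=_ratio(c.tp, c.tp + c.fp),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
    )


def evaluation_report(
    inferred: BooleanNetwork,
    reference: ReferenceNetwork,
    ignore_sign: bool = False,
) -> dict:
    """JSON-ready counts + indexes for one network/reference comparison."""
    c = classify_predictions(inferred, reference, ignore_sign=ignore_sign)
    p = performance_indexes(c)
    return {
        "counts": {
            "tp": c.tp,
            "fp_unidentified": c.fp_unidentified,
            "fp_wrong": c.fp_wrong,
            "fp": c.fp,
            "tn": c.tn,
            "fn": c.fn,
            "total_pairs": c.total,
        },
        "indexes": {
            "accuracy": p.accuracy,
            "precision": p.precision,
            "sensitivity": p.sensitivity,
            "specificity": p.specificity,
        },
    }


def write_pair_table(
    inferred: BooleanNetwork,
    reference: ReferenceNetwork,
    path: str | Path,
) -> None:
    """Audit table: one row per ordered pair with its confusion cell."""
    pred = inferred.pair_signs()
    ref = reference.pair_signs()
    genes = sorted(reference.universe)
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\tpredicted_sign\treference_sign\tcell\n")
        for reg in genes:
            for tgt in genes:
                if reg == tgt:
                    continue
                pair = (reg, tgt)
                ps = pred.get(pair, ".")
                rs = ref.get(pair, ".")
                if ps != ".":
                    if rs == ".":
                        cell = "fp_unidentified"
                    elif ps == rs:
                        cell = "tp"
                    else:
                        cell = "fp_wrong"
                else:
                    cell = "fn" if rs != "." else "tn"
                fh.write(f"{reg}\t{tgt}\t{ps}\t{rs}\t{cell}\n")
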