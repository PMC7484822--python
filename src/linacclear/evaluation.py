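"""ROC-style validation of predicted vs ground-truth collisions.

A collision prediction is useful clinically only if plans it clears are
truly deliverable: the key figure is therefore the negative predictive
value NPV = TN / (TN + FN), alongside overall accuracy
(TP + TN) / total.  Growing the safety margin converts false negatives
into true positives (and some true negatives into false positives), so
accuracy trades off against NPV; margin sweeps quantify that trade-off.

Ground truth at desk scale is the brute-force oracle verdict on rigidly
perturbed ("treatment-day") geometry with zero margin, standing in for a
physical clearance measurement on the machine.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd

from .collision import check_plan, find_violations, union_intervals
from .geometry import (
    AngleInterval,
    LinacClearError,
    MachineGeometry,
    circular_diff_deg,
    effective_radius,
    interval_overlap,
)
from .structures import PlanSpec, StructureSet

__all__ = [
    "UndefinedStatisticError",
    "ROCCounts",
    "classify_case",
    "accuracy",
    "npv",
    "measured_collision",
    "margin_sweep",
    "angle_agreement",
]


class UndefinedStatisticError(LinacClearError, ZeroDivisionError):
    """The requested rate has an empty denominator."""


@dataclass(frozen=True)
class ROCCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def classify_case(calculated: bool, measured: bool) -> str:
    """Confusion category of one case: TP / TN / FP / FN."""
    if calculated and measured:
        return "TP"
    if not calculated and not measured:
        return "TN"
    if calculated and not measured:
        return "FP"
    return "FN"


def _round1(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def accuracy(c: ROCCounts) -> float:
    """Percent correct, (TP + TN) / total * 100, half-up to one decimal."""
    if c.total < 1:
        raise UndefinedStatisticError("accuracy undefined for zero cases")
    return _round1(100.0 * (c.tp + c.tn) / c.total)


def npv(c: ROCCounts) -> float:
    """Negative predictive value, TN / (TN + FN) * 100, half-up to one decimal."""
    if c.tn + c.fn < 1:
        raise UndefinedStatisticError("NPV undefined without negative predictions")
    return _round1(100.0 * c.tn / (c.tn + c.fn))


def measured_collision(
    plan: PlanSpec,
    true_structures: Sequence[StructureSet],
    machine: MachineGeometry,
) -> bool:
    """Ground-truth verdict: zero-margin check of the true (perturbed) geometry."""
    return check_plan(plan, true_structures, machine, margin_mm=0.0).calculated_collision


def margin_sweep(
    cases: Sequence[tuple[PlanSpec, Sequence[StructureSet], bool]],
    machine: MachineGeometry,
    margins_mm: Sequence[float],
    method: str = "union",
) -> pd.DataFrame:
    """Confusion counts, accuracy and NPV of the checker at each margin.

    ``cases`` are ``(plan, planning_structures, measured)`` triples with
    ``measured`` the ground-truth collision outcome supplied by the caller.
    Returns one row per margin with columns
    ``margin_mm, tp, tn, fp, fn, accuracy_pct, npv_pct``.
    """
    if not cases:
        raise LinacClearError("margin_sweep needs at least one case")
    rows = []
    for margin in margins_mm:
        tally = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
        for plan, structures, measured in cases:
            calc = check_plan(
                plan, structures, machine, margin_mm=margin, method=method
            ).calculated_collision
            tally[classify_case(calc, measured)] += 1
        counts = ROCCounts(tp=tally["TP"], tn=tally["TN"], fp=tally["FP"], fn=tally["FN"])
        rows.append(
            {
                "margin_mm": float(margin),
                "tp": counts.tp,
                "tn": counts.tn,
                "fp": counts.fp,
                "fn": counts.fn,
                "accuracy_pct": accuracy(counts),
                "npv_pct": npv(counts),
            }
        )
    return pd.DataFrame(rows)


def angle_agreement(
    calculated_intervals: Sequence[AngleInterval],
    reference_intervals: Sequence[AngleInterval],
) -> tuple[float, float]:
    """Mean and SD of endpoint-wise absolute circular differences in degrees.

    Intervals are paired by sorted start angle; both lists must contain the
    same number of arcs (the comparison is endpoint-for-endpoint).
    """
    calc = sorted(calculated_intervals, key=lambda iv: iv.start_deg)
    ref = sorted(reference_intervals, key=lambda iv: iv.start_deg)
    if len(calc) != len(ref):
        raise LinacClearError(
            f"cannot pair {len(calc)} calculated with {len(ref)} reference intervals"
        )
    diffs = []
    for a, b in zip(calc, ref):
        diffs.append(circular_diff_deg(a.start_deg, b.start_deg))
        diffs.append(circular_diff_deg(a.end_deg, b.end_deg))
    if not diffs:
        return (0.0, 0.0)
    arr = np.asarray(diffs, dtype=float)
    return float(arr.mean()), float(arr.std())
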