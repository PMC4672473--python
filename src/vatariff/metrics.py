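"""Performance metrics: CCC, CSMF accuracy, chance-corrected CSMF accuracy.

Chance-corrected concordance (CCC) rescales per-cause sensitivity so that
random allocation over N causes scores 0 and perfect prediction scores 1::

    CCC_j = (TP_j/(TP_j + FN_j) - 1/N) / (1 - 1/N)

CSMF accuracy rescales total absolute error between true and predicted
cause-specific mortality fractions by its maximum possible value::

    CSMF accuracy = 1 - sum_j |true_j - pred_j| / (2 (1 - min_j true_j))

so 1 is a perfect population prediction and 0 the maximally wrong one
(all predicted mass on the cause with the smallest true fraction).
Random allocation still scores about 0.632 on CSMF accuracy, so the
chance-corrected variant (CCCSMF) subtracts that floor:
``(acc - chance) / (1 - chance)``; it can be negative (worse than
chance).

Indeterminate individual predictions are false negatives for the true
cause: they never match any truth, lowering CCC while (after
redistribution) improving CSMF accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: CSMF accuracy of random allocation over validation-style populations;
#: recomputable via validation.chance_floor.
DEFAULT_CHANCE = 0.632


def ccc(
    truth: Sequence[str],
    predicted: Sequence[str | None],
    n_causes: int,
) -> tuple[pd.Series, float]:
    """Per-cause chance-corrected concordance and their median.

    ``n_causes`` is the length N of the reporting cause list.  Predictions
    that are None or the indeterminate sentinel count as wrong for every
    true cause.  Causes with zero true deaths are excluded from the median
    (logged by the caller's cause list if needed).
    """
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    if n_causes < 2:
        raise ValueError(f"need N >= 2 causes, got {n_causes}")
    t = pd.Series(list(truth))
    p = pd.Series(list(predicted))
    causes = sorted(t.unique())
    out = {}
    for c in causes:
        members = t == c
        tp = int(((p == c) & members).sum())
        fn = int(members.sum()) - tp
        sens = tp / (tp + fn)
        out[c] = (sens - 1.0 / n_causes) / (1.0 - 1.0 / n_causes)
    per_cause = pd.Series(out)
    return per_cause, float(per_cause.median())


def csmf_accuracy(true_csmf: pd.Series, pred_csmf: pd.Series) -> float:
    """CSMF accuracy between two sum-1 cause-fraction vectors."""
    if set(true_csmf.index) != set(pred_csmf.index):
        raise ValueError("true and predicted CSMF cover different causes")
    pred_csmf = pred_csmf.reindex(true_csmf.index)
    for name, v in (("true", true_csmf), ("predicted", pred_csmf)):
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} CSMF sums to {v.sum()}, expected 1")
    denom = 2.0 * (1.0 - float(true_csmf.min()))
    if denom <= 0:
        raise ValueError("degenerate true CSMF: a single cause has all mass")
    acc = 1.0 - float(np.abs(true_csmf - pred_csmf).sum()) / denom
    if -1e-12 < acc < 0:
        acc = 0.0
    if 1 < acc < 1 + 1e-12:
        acc = 1.0
    return acc


def cccsmf(accuracy: float, chance: float = DEFAULT_CHANCE) -> float:
    """Chance-corrected CSMF accuracy; may be negative (worse than chance)."""
    if not 0 < chance < 1:
        raise ValueError(f"chance floor must be in (0, 1), got {chance}")
    return (accuracy - chance) / (1.0 - chance)


@dataclass(frozen=True)
class MetricReport:
    """Distribution of a metric across validation splits."""

    metric: str
    values: np.ndarray
    median: float
    ui: tuple[float, float]  # 2.5 / 97.5 percentile interval
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.ui[0] <= self.median <= self.ui[1]):
            raise ValueError("uncertainty interval must bracket the median")

    def to_row(self) -> dict:
        return {
            "metric": self.metric,
            **dict(self.labels),
            "median": self.median,
            "ui_lo": self.ui[0],
            "ui_hi": self.ui[1],
            "n_splits": len(self.values),
        }


def summarize(
    values: Sequence[float], metric: str = "", **labels: str
) -> MetricReport:
    """Median and 95% percentile interval (linear interpolation) of splits."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no values to summarize")
    lo, hi = np.percentile(arr, [2.5, 97.5])
    return MetricReport(
        metric=metric,
        values=arr,
        median=float(np.median(arr)),
        ui=(float(lo), float(hi)),
        labels=labels,
    )


def reports_frame(reports: Sequence[MetricReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports])
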