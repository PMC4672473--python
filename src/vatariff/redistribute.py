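"""Population-level reallocation of indeterminate deaths.

Each indeterminate death is split across causes using a weight vector
that averages (1) a model-performance weight — the probability that a
training death from a given cause is itself classified indeterminate —
and (2) an external cause-fraction weight (e.g. estimated cause-specific
mortality by age and sex from a burden-of-disease study), then
renormalizes so the weights sum to one.  Assigned deaths contribute one
full death to their cause; the resulting cause-specific mortality
fractions (CSMFs) always sum to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .assign import Assignment, assign_dataset
from .data import Dataset, VARecord
from .tariff import TrainedModel

logger = logging.getLogger(__name__)

WILDCARD = "*"

#: default age-band edges (years) used to key external weight strata
DEFAULT_AGE_BANDS = ((1, "<1"), (5, "1-4"), (15, "5-14"), (50, "15-49"),
                     (float("inf"), "50+"))


def age_group(age: float, bands=DEFAULT_AGE_BANDS) -> str:
    for upper, label in bands:
        if age < upper:
            return label
    return bands[-1][1]


def tariff_indeterminate_weights(
    model: TrainedModel, train: Dataset, rules=None
) -> pd.Series:
    """Per-cause probability of a training death being indeterminate.

    For each cause: the fraction of its gold-standard training deaths the
    model classifies as indeterminate, normalized across causes to sum 1.
    If no training death anywhere is indeterminate, falls back to uniform
    weights (logged).
    """
    assignments = assign_dataset(train, model, rules)
    labels = pd.Series(train.gold_standards(), index=train.ids)
    indet = pd.Series([a.is_indeterminate for a in assignments], index=train.ids)
    causes = list(model.cause_list)
    frac = pd.Series(0.0, index=causes)
    for c in causes:
        members = labels == c
        if members.any():
            frac[c] = indet[members].mean()
    total = frac.sum()
    if total == 0:
        logger.info("no indeterminate training deaths; uniform tariff weights")
        return pd.Series(1.0 / len(causes), index=causes)
    return frac / total


def combine_weights(tariff_w: pd.Series, external_w: pd.Series) -> pd.Series:
    """Elementwise arithmetic mean of two sum-1 weight vectors, renormalized."""
    if set(tariff_w.index) != set(external_w.index):
        raise ValueError("tariff and external weights cover different causes")
    external_w = external_w.reindex(tariff_w.index)
    for name, w in (("tariff", tariff_w), ("external", external_w)):
        if abs(w.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} weights sum to {w.sum()}, expected 1")
    combined = (tariff_w + external_w) / 2.0
    return combined / combined.sum()


@dataclass
class WeightTable:
    """Per-stratum combined redistribution weights.

    Strata are keyed ``(module, sex, age_group)`` with ``*`` wildcards;
    lookup falls back from the exact stratum to progressively coarser
    keys.  Within a stratum the combined weights sum to 1.
    """

    strata: dict[tuple[str, str, str], pd.Series]
    age_bands: tuple = DEFAULT_AGE_BANDS

    def __post_init__(self) -> None:
        for key, w in self.strata.items():
            if (w < -1e-12).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"stratum {key}: weights must be >=0 and sum to 1")

    def combined_for(self, module: str, sex: str, age: float) -> pd.Series:
        g = age_group(age, self.age_bands)
        for key in ((module, sex, g), (module, sex, WILDCARD),
                    (module, WILDCARD, WILDCARD), (WILDCARD, WILDCARD, WILDCARD)):
            if key in self.strata:
                return self.strata[key]
        raise KeyError(f"no weight stratum for module={module} sex={sex} age={age}")

    @classmethod
    def flat(cls, causes: Sequence[str]) -> "WeightTable":
        w = pd.Series(1.0 / len(causes), index=list(causes))
        return cls({(WILDCARD, WILDCARD, WILDCARD): w})

    @classmethod
    def build(
        cls,
        model: TrainedModel,
        train: Dataset,
        external: "dict[tuple[str, str, str], pd.Series] | None" = None,
        rules=None,
    ) -> "WeightTable":
        """Combine model indeterminate-propensity weights with external ones.

        ``external`` maps stratum keys to sum-1 cause weights; when None a
        flat external weight is used for every stratum.
        """
        causes = list(model.cause_list)
        tw = tariff_indeterminate_weights(model, train, rules)
        if external is None:
            external = {(WILDCARD, WILDCARD, WILDCARD):
                        pd.Series(1.0 / len(causes), index=causes)}
        strata = {
            key: combine_weights(tw, ew.reindex(causes).fillna(0.0))
            for key, ew in external.items()
        }
        return cls(strata)


def load_external_weights(
    path: str | Path, causes: Sequence[str]
) -> dict[tuple[str, str, str], pd.Series]:
    """Read stratified external weights from CSV.

    Columns: ``module, sex, age_group, cause_id, weight``; ``*`` is the
    wildcard stratum value.  Each stratum is renormalized to sum 1.
    """
    df = pd.read_csv(path, dtype={"module": str, "sex": str, "age_group": str,
                                  "cause_id": str, "weight": float},
                     keep_default_na=False)
    out: dict[tuple[str, str, str], pd.Series] = {}
    for key, grp in df.groupby(["module", "sex", "age_group"]):
        w = grp.set_index("cause_id")["weight"].reindex(list(causes)).fillna(0.0)
        if w.sum() <= 0:
            raise ValueError(f"stratum {key}: external weights sum to 0")
        out[tuple(key)] = w / w.sum()
    return out


def population_csmf(
    assignments: Sequence[Assignment],
    records: Sequence[VARecord],
    weights: WeightTable,
) -> pd.Series:
    """Cause-specific mortality fractions with indeterminates reallocated.

    Each assigned death adds 1 to its cause; each indeterminate death adds
    its stratum's combined weight to every cause.  Output sums to 1.
    """
    if not assignments:
        raise ValueError("no assignments to aggregate")
    if len(assignments) != len(records):
        raise ValueError("assignments and records must align")
    some_weights = next(iter(weights.strata.values()))
    totals = pd.Series(0.0, index=some_weights.index)
    for a, r in zip(assignments, records):
        if a.is_indeterminate:
            totals = totals.add(
                weights.combined_for(r.module, r.sex, r.age), fill_value=0.0
            )
        else:
            totals[a.cause] += 1.0
    csmf = totals / len(assignments)
    return csmf / csmf.sum()  # exact conservation under float rounding
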