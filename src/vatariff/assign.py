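"""Individual cause assignment: score, rank, restrict, threshold.

A death is scored against every cause (sum of masked tariffs over its
endorsed items) and each score is ranked within that cause's training
pool (1 = best, midranks for ties).  Restriction rules remove
biologically or epidemiologically impossible causes (males with cervical
cancer; malaria in non-endemic sites).  A cause survives only if the
death ranks within the cause-specific rank threshold and its score
exceeds the absolute minimum; the surviving cause with the best rank
wins.  If no cause survives the death is *indeterminate* — deliberately
so: a record with no endorsements carries no information and must not be
attracted to causes whose top items have mostly negative tariffs.
"""

from __future__ import annotations

import math
import operator
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import Dataset, VARecord
from .tariff import TrainedModel

INDETERMINATE = "indeterminate"

#: reason codes attached to every assignment
REASON_ASSIGNED = "assigned"
REASON_ALL_DISALLOWED = "all-disallowed"
REASON_BELOW_ABSOLUTE = "below-absolute"
REASON_BELOW_CAUSE_RANK = "below-cause-rank"

_OPS = {
    "eq": operator.eq,
    "ne": operator.ne,
    "lt": operator.lt,
    "le": operator.le,
    "gt": operator.gt,
    "ge": operator.ge,
}
_NUMERIC_FIELDS = {"age"}
_FIELDS = {"sex", "age", "site"}


@dataclass(frozen=True)
class RestrictionRule:
    """Disallow ``cause_id`` when ``<field> <op> <value>`` holds."""

    cause_id: str
    field: str
    op: str
    value: str

    def __post_init__(self) -> None:
        if self.field not in _FIELDS:
            raise ValueError(f"rule field must be one of {sorted(_FIELDS)}")
        if self.op not in _OPS:
            raise ValueError(f"rule op must be one of {sorted(_OPS)}")

    def matches(self, record: VARecord) -> bool:
        actual = getattr(record, self.field if self.field != "site" else "site")
        if self.field == "age":
            return _OPS[self.op](float(actual), float(self.value))
        return _OPS[self.op](str(actual), str(self.value))


@dataclass(frozen=True)
class RestrictionRules:
    rules: tuple[RestrictionRule, ...] = ()

    @classmethod
    def from_csv(cls, path: str | Path) -> "RestrictionRules":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        return cls(
            tuple(
                RestrictionRule(r.cause_id, r.field, r.op, r.value)
                for r in df.itertuples()
            )
        )

    def disallowed(self, record: VARecord) -> set[str]:
        return {r.cause_id for r in self.rules if r.matches(record)}


def apply_restrictions(
    record: VARecord, causes: Iterable[str], rules: RestrictionRules | None
) -> list[str]:
    """Candidate causes after removing those disallowed for this record."""
    causes = list(causes)
    if rules is None:
        return causes
    banned = rules.disallowed(record)
    return [c for c in causes if c not in banned]


def tariff_score(record: VARecord, model: TrainedModel, cause: str) -> float:
    """Summed tariff score of one record for one cause."""
    if cause not in model.cause_list:
        raise KeyError(f"unknown cause {cause!r}")
    eff = model.effective_tariffs().loc[cause]
    return float(sum(eff[it] for it, v in record.responses.items()
                     if v and it in eff.index))


def rank_in_pool(score: float, pool: np.ndarray) -> int:
    """Rank (1 = best) of a score in a descending-sorted pool.

    rank = 1 + (# strictly greater) + ceil(#equal / 2): midrank for ties,
    rounded up, so a score below every pool element ranks len(pool)+1.
    """
    if len(pool) == 0:
        raise ValueError("empty score pool")
    asc = pool[::-1]
    left = int(np.searchsorted(asc, score, side="left"))
    right = int(np.searchsorted(asc, score, side="right"))
    greater = len(pool) - right
    equal = right - left
    return 1 + greater + math.ceil(equal / 2)


@dataclass(frozen=True)
class Assignment:
    """Outcome for one death: a cause or the indeterminate sentinel."""

    id: str
    cause: str | None  # None == indeterminate
    reason: str
    scores: pd.Series = field(repr=False, default=None)
    ranks: pd.Series = field(repr=False, default=None)

    @property
    def is_indeterminate(self) -> bool:
        return self.cause is None

    @property
    def label(self) -> str:
        return self.cause if self.cause is not None else INDETERMINATE


def _ranks_matrix(S: np.ndarray, model: TrainedModel) -> np.ndarray:
    """Midranks of every score in every cause pool, vectorized."""
    n, C = S.shape
    R = np.empty((n, C))
    for j, cause in enumerate(model.cause_list):
        asc = model.pools[cause][::-1]
        right = np.searchsorted(asc, S[:, j], side="right")
        left = np.searchsorted(asc, S[:, j], side="left")
        greater = len(asc) - right
        equal = right - left
        R[:, j] = 1 + greater + np.ceil(equal / 2)
    return R


def assign_dataset(
    dataset: Dataset,
    model: TrainedModel,
    rules: RestrictionRules | None = None,
) -> list[Assignment]:
    """Assign a cause (or indeterminate) to every record of a dataset."""
    if rules is None:
        rules = model.restrictions  # type: ignore[assignment]
    causes = list(model.cause_list)
    Sdf = model.score_matrix(dataset)
    S = Sdf.to_numpy()
    R = _ranks_matrix(S, model)
    rank_cut = model.config.rank_quantile * model.pool_size
    min_score = model.config.min_score

    out: list[Assignment] = []
    for i, record in enumerate(dataset.records):
        allowed = apply_restrictions(record, causes, rules)
        scores = pd.Series(S[i], index=causes)
        ranks = pd.Series(R[i], index=causes)
        if not allowed:
            out.append(Assignment(record.id, None, REASON_ALL_DISALLOWED,
                                  scores, ranks))
            continue
        above_abs = [c for c in allowed if scores[c] > min_score]
        if not above_abs:
            out.append(Assignment(record.id, None, REASON_BELOW_ABSOLUTE,
                                  scores, ranks))
            continue
        survivors = [c for c in above_abs if ranks[c] <= rank_cut]
        if not survivors:
            out.append(Assignment(record.id, None, REASON_BELOW_CAUSE_RANK,
                                  scores, ranks))
            continue
        # best rank wins; ties break by larger raw score, then item id
        winner = min(survivors, key=lambda c: (ranks[c], -scores[c], c))
        out.append(Assignment(record.id, winner, REASON_ASSIGNED, scores, ranks))
    return out


def assign(
    record: VARecord, model: TrainedModel, rules: RestrictionRules | None = None
) -> Assignment:
    """Assign a single record (convenience wrapper over assign_dataset)."""
    ds = Dataset([record], _single_dictionary(model, record), model.cause_list)
    return assign_dataset(ds, model, rules)[0]


def _single_dictionary(model: TrainedModel, record: VARecord):
    from .data import Item, ItemDictionary

    return ItemDictionary(
        Item(item_id=i, label=i, source="question", hce_dependent=False,
             module=record.module)
        for i in model.item_ids
    )


def assignments_frame(assignments: Sequence[Assignment]) -> pd.DataFrame:
    """Long summary: id, cause, winning score/rank, reason."""
    rows = []
    for a in assignments:
        if a.cause is not None:
            rows.append(
                {"id": a.id, "cause": a.cause, "score": a.scores[a.cause],
                 "rank": a.ranks[a.cause], "reason": a.reason}
            )
        else:
            rows.append(
                {"id": a.id, "cause": INDETERMINATE, "score": np.nan,
                 "rank": np.nan, "reason": a.reason}
            )
    return pd.DataFrame(rows, columns=["id", "cause", "score", "rank", "reason"])
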