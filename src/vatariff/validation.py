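"""Split-based validation with Dirichlet-resampled test compositions.

Performance of a cause-assignment method depends on the cause composition
of the test population, so a single train/test split is not informative.
The protocol here repeats, for each of ``n_splits`` splits: hold out 25%
of the gold-standard deaths (stratified by cause), draw a fresh cause
composition from a symmetric Dirichlet, rebuild the test set by sampling
held-out deaths with replacement to that composition, train on the 75%,
assign causes to the rebuilt test set, and measure median CCC and CSMF
accuracy (after indeterminate redistribution).  The split distributions
give medians and 95% uncertainty intervals that do not depend on the
original cause composition, and the train-side and test-side compositions
are uncorrelated by construction.

``chance_floor`` reproduces the random-allocation CSMF accuracy floor by
assigning causes uniformly at random to simulated populations with
Dirichlet-drawn compositions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd

from .assign import RestrictionRules, assign_dataset
from .data import CauseList, Dataset, strip_hce
from .metrics import MetricReport, ccc, cccsmf, csmf_accuracy, summarize
from .redistribute import WeightTable, population_csmf
from .tariff import TrainConfig, train_model

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    """Validation design: number of splits, train fraction, Dirichlet alpha."""

    n_splits: int = 500
    train_frac: float = 0.75
    alpha: float = 1.0  # symmetric Dirichlet concentration
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError(f"train_frac must be in (0,1), got {self.train_frac}")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")
        if self.alpha <= 0:
            raise ValueError("Dirichlet alpha must be > 0")


def _rng_for(spec: SplitSpec, index: int, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, index, salt]))


def partition_indices(
    dataset: Dataset, spec: SplitSpec, index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Cause-stratified train/test index partition for one split.

    Disjoint, jointly covering, reproducible from (seed, index).  A cause
    with a single record goes to the training side with a warning.
    """
    if index >= spec.n_splits:
        raise IndexError(f"split index {index} >= n_splits {spec.n_splits}")
    rng = _rng_for(spec, index, salt=0)
    labels = np.array(dataset.gold_standards())
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for c in dataset.causes:
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            warnings.warn(
                f"cause {c!r} has {len(idx)} records; it may be absent "
                "from the test side", stacklevel=2,
            )
            train_idx.append(idx)
            continue
        idx = rng.permutation(idx)
        n_train = int(round(spec.train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return (
        np.sort(np.concatenate(train_idx)),
        np.sort(np.concatenate(test_idx)) if test_idx else np.array([], dtype=int),
    )


def make_split(
    dataset: Dataset, spec: SplitSpec, index: int
) -> tuple[Dataset, Dataset]:
    """One train/test split with a Dirichlet-resampled test composition.

    The held-out 25% is resampled with replacement to its original size
    according to a cause composition drawn from the symmetric Dirichlet
    (restricted to causes present on the test side); resampled records get
    fresh ids so the copies remain distinct.
    """
    train_idx, test_idx = partition_indices(dataset, spec, index)
    train = dataset.subset(train_idx)
    rng = _rng_for(spec, index, salt=1)
    labels = np.array(dataset.gold_standards())
    causes = list(dataset.causes)
    p = rng.dirichlet(np.full(len(causes), spec.alpha))
    present = np.array([np.any(labels[test_idx] == c) for c in causes])
    p = np.where(present, p, 0.0)
    p = p / p.sum()
    n_test = len(test_idx)
    counts = rng.multinomial(n_test, p)
    chosen: list[int] = []
    for c, k in zip(causes, counts):
        if k == 0:
            continue
        pool = test_idx[labels[test_idx] == c]
        chosen.extend(rng.choice(pool, size=k, replace=True))
    resampled = []
    for j, i in enumerate(chosen):
        r = dataset.records[i]
        resampled.append(dc_replace(r, id=f"{r.id}#r{j}"))
    test = Dataset(resampled, dataset.dictionary, dataset.causes)
    return train, test


def run_split(
    dataset: Dataset,
    spec: SplitSpec,
    index: int,
    config: TrainConfig,
    hce: bool = True,
    rules: RestrictionRules | None = None,
    external_weights=None,
    chance: float | None = None,
) -> dict[str, float]:
    """Train/assign/score one split; returns the three per-split metrics."""
    from .metrics import DEFAULT_CHANCE

    train, test = make_split(dataset, spec, index)
    if not hce:
        train, test = strip_hce(train), strip_hce(test)
    model = train_model(
        train, config, seed=int(_rng_for(spec, index, salt=2).integers(2**31)),
        restrictions=rules,
    )
    assignments = assign_dataset(test, model, rules)
    truth = test.gold_standards()
    predicted = [a.cause for a in assignments]
    _, ccc_median = ccc(truth, predicted, n_causes=len(dataset.causes))

    weights = WeightTable.build(model, train, external=external_weights, rules=rules)
    pred_csmf = population_csmf(assignments, test.records, weights)
    true_csmf = pd.Series(truth).value_counts(normalize=True).reindex(
        list(dataset.causes), fill_value=0.0
    )
    acc = csmf_accuracy(true_csmf, pred_csmf)
    return {
        "ccc_median": ccc_median,
        "csmf_accuracy": acc,
        "cccsmf_accuracy": cccsmf(acc, chance or DEFAULT_CHANCE),
    }


def run_validation(
    dataset: Dataset,
    spec: SplitSpec | None = None,
    config: TrainConfig | None = None,
    conditions: Sequence[bool] = (True,),
    rules: RestrictionRules | None = None,
    external_weights=None,
    chance: float | None = None,
    progress: bool = False,
) -> dict[str, dict[str, MetricReport]]:
    """Full multi-split validation for one or both HCE conditions.

    ``conditions`` lists HCE flags (True = all items, False = strip HCE
    and text items); both conditions reuse the same partitions.  Returns
    ``{condition_label: {metric: MetricReport}}``.
    """
    spec = spec or SplitSpec()
    config = config or TrainConfig()
    out: dict[str, dict[str, MetricReport]] = {}
    for hce in conditions:
        label = "hce" if hce else "no_hce"
        per_split: dict[str, list[float]] = {
            "ccc_median": [], "csmf_accuracy": [], "cccsmf_accuracy": []
        }
        for i in range(spec.n_splits):
            res = run_split(
                dataset, spec, i, config, hce=hce, rules=rules,
                external_weights=external_weights, chance=chance,
            )
            for k, v in res.items():
                per_split[k].append(v)
            if progress and (i + 1) % 10 == 0:
                logger.info("condition %s: %d/%d splits", label, i + 1, spec.n_splits)
        out[label] = {
            k: summarize(v, metric=k, module=dataset.module, hce=label)
            for k, v in per_split.items()
        }
    return out


def chance_floor(
    causes: CauseList | int,
    n_splits: int = 500,
    n_deaths: int = 1961,
    alpha: float = 1.0,
    seed: int | None = 0,
) -> float:
    """Mean CSMF accuracy of uniformly random cause assignment.

    For each simulated population: draw a true CSMF from the symmetric
    Dirichlet, realize ``n_deaths`` true causes multinomially, predict
    causes uniformly at random, and compute CSMF accuracy; the mean over
    populations is the chance floor used by :func:`metrics.cccsmf`.  The
    default population size matches a 25% validation test side of the
    7,846 adult gold-standard deaths.
    """
    if n_deaths < 1:
        raise ValueError("n_deaths must be >= 1")
    N = len(causes) if not isinstance(causes, int) else causes
    rng = np.random.default_rng(seed)
    P = rng.dirichlet(np.full(N, alpha), size=n_splits)
    T = rng.multinomial(n_deaths, P) / n_deaths
    Q = rng.multinomial(n_deaths, np.full(N, 1.0 / N), size=n_splits) / n_deaths
    acc = 1.0 - np.abs(T - Q).sum(axis=1) / (2.0 * (1.0 - T.min(axis=1)))
    return float(acc.mean())
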