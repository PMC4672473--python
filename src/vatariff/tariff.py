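"""Tariff training: endorsement rates, tariffs, significance, score pools.

The tariff for cause *i* and item *j* standardizes the endorsement rate
(fraction of cause-*i* deaths answering "yes" to item *j*) against the
distribution of that item's endorsement rate across all causes::

    tariff(i, j) = (rate(i, j) - median_over_causes(rate(., j)))
                   / IQR_over_causes(rate(., j))

Quartiles use the exclusive (n+1)-position linear-interpolation convention
(R type 6), under which an item endorsed only for one cause still carries
a positive tariff for that cause; when the across-cause IQR is exactly 0
the item carries no spread information and all its tariffs are set to 0.

Two filters sparsify the matrix: a stratified-bootstrap significance test
(tariffs whose 95% uncertainty interval includes zero are removed) and a
per-cause top-k cut on absolute tariff (k = 40).  Training concludes by
resampling the training deaths with replacement to a uniform cause
distribution, scoring every resampled death against every cause, and
storing the per-cause descending score pools against which new deaths are
ranked.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .data import CauseList, DataError, Dataset

logger = logging.getLogger(__name__)

QUARTILE_METHOD = "weibull"  # exclusive/(n+1) positions, linear interpolation


@dataclass
class TrainConfig:
    """Tunable training parameters.

    bootstrap_b:        bootstrap replicates for the significance test.
    ui_level:           width of the bootstrap uncertainty interval.
    rounding:           tariff rounding granularity (0 disables).
    top_k:              items kept per cause by absolute tariff.
    rank_quantile:      cause-specific rank threshold as a fraction of the
                        uniform pool; a cause is a candidate for a death
                        only if the death ranks within this fraction.
    min_score:          absolute threshold; a cause needs score strictly
                        above this to be a candidate.
    resample_per_cause: uniform-resample size per cause (None = largest
                        observed cause count).
    """

    bootstrap_b: int = 500
    ui_level: float = 0.95
    rounding: float = 0.5
    top_k: int = 40
    rank_quantile: float = 0.18
    min_score: float = 0.0
    resample_per_cause: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class EndorsementMatrix:
    """Cause x item endorsement rates plus per-cause death counts."""

    rates: pd.DataFrame  # index: cause ids, columns: item ids, values in [0,1]
    counts: pd.Series  # per-cause number of training deaths

    @property
    def causes(self) -> list[str]:
        return list(self.rates.index)

    @property
    def items(self) -> list[str]:
        return list(self.rates.columns)


@dataclass
class TariffMatrix:
    """Cause x item tariffs with significance and top-k masks."""

    values: pd.DataFrame
    significant: pd.DataFrame  # boolean, same shape
    top: pd.DataFrame  # boolean, same shape, <= k true per cause row
    rounding: float = 0.5

    def effective(self) -> pd.DataFrame:
        """Tariffs with both masks applied (masked-out entries are 0)."""
        mask = self.significant.to_numpy() & self.top.to_numpy()
        return self.values.where(pd.DataFrame(mask, index=self.values.index,
                                              columns=self.values.columns), 0.0)


def endorsement_matrix(train: Dataset) -> EndorsementMatrix:
    """Per-cause fraction of deaths endorsing each item.

    Every training record must carry a gold-standard cause and every cause
    in the cause list must have at least one death.
    """
    gs = train.gold_standards()
    missing = [r.id for r, g in zip(train.records, gs) if g is None]
    if missing:
        raise DataError(
            f"{len(missing)} training records lack gold-standard causes "
            f"(e.g. {missing[:3]})"
        )
    labels = np.array(gs)
    causes = list(train.causes)
    empty = [c for c in causes if not np.any(labels == c)]
    if empty:
        raise DataError(f"causes with zero training deaths: {empty}")
    X = train.response_matrix()
    rates = np.empty((len(causes), X.shape[1]))
    counts = np.empty(len(causes), dtype=int)
    for i, c in enumerate(causes):
        rows = labels == c
        counts[i] = rows.sum()
        rates[i] = X[rows].mean(axis=0)
    return EndorsementMatrix(
        rates=pd.DataFrame(rates, index=causes, columns=list(train.item_ids)),
        counts=pd.Series(counts, index=causes, name="deaths"),
    )


def tariffs_from_rates(rates: np.ndarray) -> np.ndarray:
    """Unrounded tariffs from an endorsement-rate array.

    The cause axis is ``-2``; leading axes are batch dimensions (used for
    vectorized bootstrap replicates).  Items with zero across-cause IQR
    get tariff 0 for every cause.
    """
    med = np.median(rates, axis=-2, keepdims=True)
    q1, q3 = np.percentile(rates, [25, 75], axis=-2,
                           method=QUARTILE_METHOD, keepdims=True)
    iqr = q3 - q1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (rates - med) / iqr
    return np.where(iqr > 0, t, 0.0)


def round_tariffs(values: np.ndarray, granularity: float) -> np.ndarray:
    if granularity <= 0:
        return values
    return np.round(values / granularity) * granularity


def compute_tariffs(E: EndorsementMatrix, rounding: float = 0.5) -> TariffMatrix:
    """Point-estimate tariff matrix with all-true masks."""
    if len(E.causes) < 2:
        raise DataError("tariffs need >= 2 causes (median/IQR degenerate)")
    values = round_tariffs(tariffs_from_rates(E.rates.to_numpy()), rounding)
    values = pd.DataFrame(values, index=E.rates.index, columns=E.rates.columns)
    true = pd.DataFrame(True, index=values.index, columns=values.columns)
    return TariffMatrix(values=values, significant=true, top=true.copy(),
                        rounding=rounding)


def significance_mask(
    train: Dataset,
    B: int = 500,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Bootstrap significance mask for each (cause, item) tariff.

    Records are resampled with replacement stratified within cause, up to
    each cause's original count; tariffs are recomputed (unrounded) per
    replicate and an entry is retained iff the empirical
    ``[(1-level)/2, 1-(1-level)/2]`` interval of the replicate tariffs has
    strictly same-signed endpoints (excludes zero).
    """
    if B < 2:
        raise ValueError(f"need at least 2 bootstrap replicates, got {B}")
    rng = np.random.default_rng(seed)
    labels = np.array(train.gold_standards())
    causes = list(train.causes)
    X = train.response_matrix().astype(np.float64)
    n_items = X.shape[1]
    # replicate endorsement rates: B x causes x items.  Resampling n_c
    # records with replacement is a multinomial weighting of the rows.
    R = np.empty((B, len(causes), n_items))
    for i, c in enumerate(causes):
        Xc = X[labels == c]
        n_c = Xc.shape[0]
        if n_c == 0:
            raise DataError(f"cause {c!r} has zero training deaths")
        W = rng.multinomial(n_c, np.full(n_c, 1.0 / n_c), size=B)
        R[:, i, :] = (W @ Xc) / n_c
    T = tariffs_from_rates(R)  # B x causes x items
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(T, [100 * alpha, 100 * (1 - alpha)], axis=0)
    mask = ((lo > 0) & (hi > 0)) | ((lo < 0) & (hi < 0))
    return pd.DataFrame(mask, index=causes, columns=list(train.item_ids))


def top_items(T: TariffMatrix, k: int = 40) -> pd.DataFrame:
    """Per-cause mask of the <= k significant items with largest |tariff|.

    Ties at the k-th position break by lexicographic item id (smaller id
    wins), so the mask is deterministic.
    """
    if k < 1:
        raise ValueError(f"top_items k must be >= 1, got {k}")
    items = list(T.values.columns)
    mask = pd.DataFrame(False, index=T.values.index, columns=items)
    for cause in T.values.index:
        sig = T.significant.loc[cause]
        candidates = [it for it in items if sig[it]]
        candidates.sort(key=lambda it: (-abs(T.values.at[cause, it]), it))
        for it in candidates[:k]:
            mask.at[cause, it] = True
    return mask


@dataclass
class TrainedModel:
    """A fitted tariff classifier.

    ``pools[cause]`` holds the descending-sorted tariff scores of every
    record of the uniformly resampled training set scored against that
    cause; a new death's score is ranked against the pool to normalize
    across causes with inherently different tariff magnitudes.
    """

    tariffs: TariffMatrix
    pools: dict[str, np.ndarray]
    cause_list: CauseList
    item_ids: tuple[str, ...]
    config: TrainConfig
    seed: int | None = None
    restrictions: object | None = None  # RestrictionRules, set by callers

    @property
    def pool_size(self) -> int:
        return len(next(iter(self.pools.values())))

    def effective_tariffs(self) -> pd.DataFrame:
        return self.tariffs.effective()

    def score_matrix(self, dataset: Dataset) -> pd.DataFrame:
        """Records x causes summed tariff scores (Eq. of the method)."""
        X = dataset.response_matrix(self.item_ids).astype(np.float64)
        M = self.effective_tariffs().to_numpy()  # causes x items
        S = X @ M.T
        return pd.DataFrame(S, index=dataset.ids, columns=list(self.cause_list))

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.tariffs.values.rename_axis("cause").to_csv(path / "tariffs.csv")
        long = pd.DataFrame(
            {
                "cause": np.repeat(self.tariffs.values.index, len(self.item_ids)),
                "item": list(self.item_ids) * len(self.tariffs.values.index),
                "significant": self.tariffs.significant.to_numpy().astype(int).ravel(),
                "top": self.tariffs.top.to_numpy().astype(int).ravel(),
            }
        )
        long.to_csv(path / "masks.csv", index=False)
        pool_dir = path / "pools"
        pool_dir.mkdir(exist_ok=True)
        for cause, pool in self.pools.items():
            pd.DataFrame({"score": pool}).to_csv(pool_dir / f"{cause}.csv", index=False)
        meta = {
            "config": self.config.to_dict(),
            "seed": self.seed,
            "module": self.cause_list.module,
            "causes": list(self.cause_list),
            "items": list(self.item_ids),
        }
        (path / "model.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path, cause_list: CauseList | None = None) -> "TrainedModel":
        path = Path(path)
        meta = yaml.safe_load((path / "model.yaml").read_text())
        values = pd.read_csv(path / "tariffs.csv", index_col="cause")
        values.index.name = None
        values.columns.name = None
        long = pd.read_csv(path / "masks.csv")
        sig = long.pivot(index="cause", columns="item", values="significant")
        top = long.pivot(index="cause", columns="item", values="top")
        sig = sig.reindex(index=values.index, columns=values.columns).astype(bool)
        top = top.reindex(index=values.index, columns=values.columns).astype(bool)
        sig.index.name = sig.columns.name = None
        top.index.name = top.columns.name = None
        config = TrainConfig(**meta["config"])
        if cause_list is None:
            cause_list = CauseList(
                module=meta["module"], cause_ids=tuple(meta["causes"])
            )
        pools = {
            c: pd.read_csv(path / "pools" / f"{c}.csv")["score"].to_numpy()
            for c in cause_list
        }
        return cls(
            tariffs=TariffMatrix(values=values, significant=sig, top=top,
                                 rounding=config.rounding),
            pools=pools,
            cause_list=cause_list,
            item_ids=tuple(meta["items"]),
            config=config,
            seed=meta.get("seed"),
        )


def train_model(
    train: Dataset,
    config: TrainConfig | None = None,
    seed: int | None = 0,
    blocklist: object | None = None,
    restrictions: object | None = None,
) -> TrainedModel:
    """Full training pipeline.

    endorsement rates -> tariffs -> bootstrap significance -> top-k masks,
    then a uniform-cause resample of the training set is scored against
    every cause to build the rank pools.  ``blocklist`` may carry
    (text-item, cause) pairs whose tariffs are suppressed.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(seed)
    E = endorsement_matrix(train)
    T = compute_tariffs(E, rounding=config.rounding)
    T.significant = significance_mask(
        train, B=config.bootstrap_b, level=config.ui_level, seed=rng
    )
    if blocklist is not None:
        for item, cause in blocklist.cause_pairs():
            if cause in T.significant.index and item in T.significant.columns:
                T.significant.at[cause, item] = False
    T.top = top_items(T, k=config.top_k)

    # uniform resample with replacement: m records per cause
    labels = np.array(train.gold_standards())
    causes = list(train.causes)
    m = config.resample_per_cause or int(E.counts.max())
    chosen: list[np.ndarray] = []
    for c in causes:
        idx = np.flatnonzero(labels == c)
        chosen.append(rng.choice(idx, size=m, replace=True))
    X = train.response_matrix().astype(np.float64)[np.concatenate(chosen)]
    M = T.effective().to_numpy()
    S = X @ M.T  # (n_causes * m) x n_causes
    pools = {
        c: np.sort(S[:, j])[::-1].copy() for j, c in enumerate(causes)
    }
    return TrainedModel(
        tariffs=T,
        pools=pools,
        cause_list=train.causes,
        item_ids=tuple(train.item_ids),
        config=config,
        seed=seed if isinstance(seed, int) else None,
        restrictions=restrictions,
    )
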