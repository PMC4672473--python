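"""Model/Results interface over the tariff pipeline.

``TariffModel`` is constructed from a gold-standard dataset plus
configuration; ``fit`` runs the training pipeline and returns a
``TariffResults`` carrying the tariff matrix, masks, and rank pools, with
``assign``/``predict_csmf`` for new data and a ``summary()`` table.
"""

from __future__ import annotations

from pathlib import Path
import numpy as np
import pandas as pd

from .assign import RestrictionRules, assign_dataset, assignments_frame
from .data import CauseList, Dataset, ItemDictionary, load_dataset
from .redistribute import WeightTable, population_csmf
from .tariff import TrainConfig, TrainedModel, train_model
from .text import Blocklist


class TariffModel:
    """Tariff cause-of-death classifier specification.

    Parameters
    ----------
    dataset : Dataset
        Gold-standard training data (every record labelled).
    config : TrainConfig, optional
        Training and thresholding parameters.
    restrictions : RestrictionRules, optional
        Demographic cause-censoring rules applied at assignment.
    blocklist : Blocklist, optional
        (text item, cause) tariff suppressions from plausibility review.
    """

    def __init__(
        self,
        dataset: Dataset,
        config: TrainConfig | None = None,
        restrictions: RestrictionRules | None = None,
        blocklist: Blocklist | None = None,
    ):
        self.dataset = dataset
        self.config = config or TrainConfig()
        self.restrictions = restrictions
        self.blocklist = blocklist

    @classmethod
    def from_csv(
        cls,
        data_path: str | Path,
        dictionary_path: str | Path,
        causes_path: str | Path,
        restrictions_path: str | Path | None = None,
        blocklist_path: str | Path | None = None,
        config: TrainConfig | None = None,
    ) -> "TariffModel":
        dictionary = ItemDictionary.from_csv(dictionary_path)
        causes = CauseList.from_csv(causes_path)
        dataset = load_dataset(data_path, dictionary, causes)
        rules = (
            RestrictionRules.from_csv(restrictions_path)
            if restrictions_path else None
        )
        blocklist = Blocklist.from_csv(blocklist_path) if blocklist_path else None
        return cls(dataset, config=config, restrictions=rules, blocklist=blocklist)

    def fit(self, seed: int | None = 0) -> "TariffResults":
        trained = train_model(
            self.dataset,
            self.config,
            seed=seed,
            blocklist=self.blocklist,
            restrictions=self.restrictions,
        )
        return TariffResults(self, trained)


class TariffResults:
    """Fitted tariff model: estimates, masks, pools, and prediction."""

    def __init__(self, model: TariffModel, trained: TrainedModel):
        self.model = model
        self.trained = trained

    # -- estimates ----------------------------------------------------------

    @property
    def tariffs(self) -> pd.DataFrame:
        """Rounded tariff values (cause x item), before masking."""
        return self.trained.tariffs.values

    @property
    def significance_(self) -> pd.DataFrame:
        return self.trained.tariffs.significant

    @property
    def top_items_(self) -> pd.DataFrame:
        return self.trained.tariffs.top

    @property
    def params(self) -> pd.DataFrame:
        """Effective tariffs: masked entries are exactly 0."""
        return self.trained.effective_tariffs()

    @property
    def pools(self) -> dict[str, np.ndarray]:
        return self.trained.pools

    # -- prediction ---------------------------------------------------------

    def assign(self, dataset: Dataset) -> pd.DataFrame:
        """Per-record cause assignment (or indeterminate) as a DataFrame."""
        return assignments_frame(
            assign_dataset(dataset, self.trained, self.model.restrictions)
        )

    def predict_csmf(
        self, dataset: Dataset, external_weights=None
    ) -> pd.Series:
        """Population CSMF with indeterminates redistributed."""
        assignments = assign_dataset(dataset, self.trained, self.model.restrictions)
        weights = WeightTable.build(
            self.trained, self.model.dataset,
            external=external_weights, rules=self.model.restrictions,
        )
        return population_csmf(assignments, dataset.records, weights)

    # -- reporting ----------------------------------------------------------

    def summary(self, max_items: int = 5) -> str:
        t = self.trained
        cfg = t.config
        lines = [
            "Tariff cause-of-death model",
            "=" * 60,
            f"module:            {t.cause_list.module}",
            f"causes:            {len(t.cause_list)}",
            f"items:             {len(t.item_ids)}",
            f"training deaths:   {len(self.model.dataset)}",
            f"bootstrap B:       {cfg.bootstrap_b} (UI level {cfg.ui_level})",
            f"tariff rounding:   {cfg.rounding}",
            f"top-k per cause:   {cfg.top_k}",
            f"rank threshold:    {cfg.rank_quantile} x pool "
            f"(pool size {t.pool_size})",
            f"absolute minimum:  score > {cfg.min_score}",
            "-" * 60,
        ]
        eff = self.params
        n_sig = int(self.significance_.to_numpy().sum())
        n_top = int(self.top_items_.to_numpy().sum())
        lines.append(
            f"significant tariffs: {n_sig} / {eff.size}; in top-k masks: {n_top}"
        )
        lines.append("-" * 60)
        for cause in t.cause_list:
            row = eff.loc[cause]
            best = row.reindex(row.abs().sort_values(ascending=False).index)
            best = best[best != 0][:max_items]
            entries = ", ".join(f"{i}={v:+.1f}" for i, v in best.items())
            lines.append(f"{cause}: {entries if entries else '(no items)'}")
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        self.trained.save(path)
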