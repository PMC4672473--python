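"""Tariff computation against a brute-force oracle, masks, and training."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vatariff import (
    DataError,
    GeneratorSpec,
    TrainConfig,
    compute_tariffs,
    endorsement_matrix,
    generate,
    significance_mask,
    top_items,
    train_model,
)
from vatariff.tariff import EndorsementMatrix, TariffMatrix, round_tariffs, tariffs_from_rates


# ---------------------------------------------------------------------------
# independent brute-force oracle (scalar, no numpy percentile machinery)


def quartile_oracle(values, q):
    """Exclusive (n+1)-position quartile with linear interpolation."""
    vals = sorted(values)
    n = len(vals)
    h = q * (n + 1) - 1  # 0-based fractional position
    h = min(max(h, 0.0), n - 1.0)
    lo, hi = math.floor(h), math.ceil(h)
    return vals[lo] + (h - lo) * (vals[hi] - vals[lo])


def oracle_tariffs(rates):
    C, J = rates.shape
    out = np.zeros((C, J))
    for j in range(J):
        col = list(rates[:, j])
        med = statistics.median(col)
        iqr = quartile_oracle(col, 0.75) - quartile_oracle(col, 0.25)
        if iqr > 0:
            for i in range(C):
                out[i, j] = (rates[i, j] - med) / iqr
    return out


def _E(rates, items=None, causes=None):
    rates = np.asarray(rates, dtype=float)
    causes = causes or [f"c{i}" for i in range(rates.shape[0])]
    items = items or [f"q{j}" for j in range(rates.shape[1])]
    return EndorsementMatrix(
        rates=pd.DataFrame(rates, index=causes, columns=items),
        counts=pd.Series(10, index=causes),
    )


# ---------------------------------------------------------------------------


class TestEndorsementMatrix:
    def test_direct_count(self, sep_dataset):
        E = endorsement_matrix(sep_dataset)
        labels = np.array(sep_dataset.gold_standards())
        X = sep_dataset.response_matrix()
        c = "cause_01"
        j = list(sep_dataset.item_ids).index("sig_cause_01_01")
        expected = X[labels == c][:, j].mean()
        assert E.rates.at[c, "sig_cause_01_01"] == pytest.approx(expected)
        assert E.counts[c] == (labels == c).sum()

    def test_rate_is_fraction_of_cause_deaths(self):
        # 10 deaths of one cause, 4 endorsing the item -> rate 0.4
        from vatariff import CauseList, Dataset, Item, ItemDictionary, VARecord

        d = ItemDictionary([Item("q1", "q1", "question", False, "adult")])
        cl = CauseList(module="adult", cause_ids=("a", "b"))
        recs = [
            VARecord(f"a{i}", "adult", "male", 30, "s",
                     {"q1": 1} if i < 4 else {}, gold_standard="a")
            for i in range(10)
        ] + [VARecord("b0", "adult", "male", 30, "s", {}, gold_standard="b")]
        E = endorsement_matrix(Dataset(recs, d, cl))
        assert E.rates.at["a", "q1"] == pytest.approx(0.4)

    def test_cause_with_zero_deaths_is_an_error(self, sep_dataset):
        # drop every record of one cause
        keep = [i for i, r in enumerate(sep_dataset.records)
                if r.gold_standard != "cause_02"]
        with pytest.raises(DataError, match="cause_02"):
            endorsement_matrix(sep_dataset.subset(keep))

    def test_missing_gold_standard_is_an_error(self, sep_dataset):
        from dataclasses import replace

        from vatariff import Dataset

        recs = [replace(sep_dataset.records[0], gold_standard=None)]
        recs += sep_dataset.records[1:]
        with pytest.raises(DataError, match="gold-standard"):
            endorsement_matrix(
                Dataset(recs, sep_dataset.dictionary, sep_dataset.causes)
            )


class TestComputeTariffs:
    def test_identical_rates_give_zero_tariffs(self):
        T = compute_tariffs(_E(np.full((5, 3), 0.3)))
        assert (T.values.to_numpy() == 0).all()

    def test_hand_rates_match_oracle(self):
        rates = np.array([[0.05], [0.10], [0.20], [0.40], [0.80]])
        got = tariffs_from_rates(rates)
        assert np.allclose(got, oracle_tariffs(rates), atol=1e-12)
        # spot check: median 0.2, exclusive quartiles 0.075 / 0.6
        assert got[4, 0] == pytest.approx((0.80 - 0.20) / 0.525, abs=1e-12)

    def test_one_hot_item_gets_positive_tariff_for_its_cause(self):
        # endorsed for a single cause out of 5: exclusive-quartile IQR is
        # (0+1)/2 - 0 = 0.5, so the owning cause gets tariff +2
        rates = np.array([[1.0], [0.0], [0.0], [0.0], [0.0]])
        got = tariffs_from_rates(rates)
        assert got[0, 0] == pytest.approx(2.0)
        assert (got[1:, 0] <= 0).all()

    def test_zero_iqr_defines_tariff_zero(self):
        rates = np.array([[0.3], [0.3], [0.3], [0.3], [0.9]])
        # exclusive quartiles of {.3,.3,.3,.3,.9}: q1=0.3, q3=(0.3+0.9)/2 -> IQR>0
        assert tariffs_from_rates(rates)[4, 0] > 0
        rates = np.array([[0.3], [0.3], [0.3], [0.3], [0.3]])
        assert (tariffs_from_rates(rates) == 0).all()

    def test_oracle_equivalence_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            rates = rng.random((6, 8))
            assert np.allclose(
                tariffs_from_rates(rates), oracle_tariffs(rates), atol=1e-12
            )

    def test_rounding_never_moves_more_than_half_granularity(self):
        rng = np.random.default_rng(7)
        raw = tariffs_from_rates(rng.random((6, 8)))
        for g in (0.5, 0.25, 1.0):
            assert np.all(np.abs(round_tariffs(raw, g) - raw) <= g / 2 + 1e-12)
        assert np.array_equal(round_tariffs(raw, 0.0), raw)

    def test_single_cause_matrix_rejected(self):
        with pytest.raises(DataError):
            compute_tariffs(_E(np.array([[0.5, 0.2]])))

    @given(st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1))
    def test_monotone_evidence(self, r1, r2):
        # raising one cause's rate while it stays the unique maximum
        # (others fixed) never lowers that cause's tariff
        base = np.array([0.1, 0.2, 0.3, 0.4])
        lo, hi = sorted([r1, r2])
        col_lo = np.concatenate([base, [0.5 + lo]])[:, None]
        col_hi = np.concatenate([base, [0.5 + hi]])[:, None]
        assert tariffs_from_rates(col_hi)[4, 0] >= tariffs_from_rates(col_lo)[4, 0]


class TestSignificanceMask:
    def test_perfectly_discriminating_item_retained(self):
        spec = GeneratorSpec(n_causes=5, signature_items=1, background_items=0,
                             hce_items=0, p_sig=1.0, p_bg=0.0, p_drop=0.0,
                             n_per_cause=50, seed=3)
        ds = generate(spec)
        mask = significance_mask(ds, B=100, seed=0)
        for c in ds.causes:
            assert mask.at[c, f"sig_{c}_01"]

    def test_too_few_replicates_rejected(self, sep_dataset):
        with pytest.raises(ValueError):
            significance_mask(sep_dataset, B=1)

    def test_mask_reproducible_for_seed(self, sep_dataset):
        m1 = significance_mask(sep_dataset, B=40, seed=9)
        m2 = significance_mask(sep_dataset, B=40, seed=9)
        assert m1.equals(m2)


class TestTopItems:
    def _matrix(self, values, significant=None):
        idx = ["c0"]
        cols = [f"q{j}" for j in range(len(values))]
        v = pd.DataFrame([values], index=idx, columns=cols, dtype=float)
        s = pd.DataFrame([significant or [True] * len(values)], index=idx,
                         columns=cols)
        return TariffMatrix(values=v, significant=s, top=s.copy())

    def test_fewer_items_than_k_all_retained(self):
        T = self._matrix([1.0, -2.0, 0.5])
        assert top_items(T, k=40).loc["c0"].sum() == 3

    def test_absolute_value_rule(self):
        T = self._matrix([-5.0, 3.0])
        mask = top_items(T, k=1).loc["c0"]
        assert mask["q0"] and not mask["q1"]

    def test_tie_at_boundary_broken_by_item_id(self):
        # three items tied at |2.0| compete for one slot after q0
        T = self._matrix([5.0, 2.0, -2.0, 2.0])
        mask = top_items(T, k=2).loc["c0"]
        assert mask["q0"] and mask["q1"]
        assert not mask["q2"] and not mask["q3"]

    def test_insignificant_items_never_selected(self):
        T = self._matrix([5.0, 1.0], significant=[False, True])
        mask = top_items(T, k=2).loc["c0"]
        assert not mask["q0"] and mask["q1"]

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            top_items(self._matrix([1.0]), k=0)


class TestTrainModel:
    def test_pools_uniform_and_sorted(self, trained_small, sep_dataset):
        sizes = {len(p) for p in trained_small.pools.values()}
        assert len(sizes) == 1
        for pool in trained_small.pools.values():
            assert np.all(np.diff(pool) <= 0)

    def test_separability_of_own_cause_scores(self, trained_small, sep_dataset):
        S = trained_small.score_matrix(sep_dataset)
        labels = pd.Series(sep_dataset.gold_standards(), index=sep_dataset.ids)
        for c in sep_dataset.causes:
            own = S.loc[labels == c, c].median()
            others = S.loc[labels != c, c].median()
            assert own > others

    def test_deterministic_serialization(self, sep_dataset, fast_config, tmp_path):
        m1 = train_model(sep_dataset, fast_config, seed=4)
        m2 = train_model(sep_dataset, fast_config, seed=4)
        m1.save(tmp_path / "a")
        m2.save(tmp_path / "b")
        assert (tmp_path / "a" / "tariffs.csv").read_bytes() == \
               (tmp_path / "b" / "tariffs.csv").read_bytes()
        for c in sep_dataset.causes:
            assert np.array_equal(m1.pools[c], m2.pools[c])

    def test_save_load_roundtrip(self, trained_small, sep_dataset, tmp_path):
        from vatariff import TrainedModel

        trained_small.save(tmp_path / "m")
        back = TrainedModel.load(tmp_path / "m", sep_dataset.causes)
        pd.testing.assert_frame_equal(
            back.tariffs.values, trained_small.tariffs.values
        )
        assert back.item_ids == trained_small.item_ids
        S1 = trained_small.score_matrix(sep_dataset)
        S2 = back.score_matrix(sep_dataset)
        pd.testing.assert_frame_equal(S1, S2)

    def test_blocklisted_cause_pair_suppressed(self, sep_dataset, fast_config):
        from vatariff import Blocklist

        bl = Blocklist(frozenset({("sig_cause_01_01", "cause_01")}))
        m = train_model(sep_dataset, fast_config, seed=4, blocklist=bl)
        assert m.effective_tariffs().at["cause_01", "sig_cause_01_01"] == 0
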