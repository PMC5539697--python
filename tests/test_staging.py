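"""Normalization, smoothing, personal thresholds and the decision rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sleepfusion as sf
from sleepfusion.errors import ConfigurationError, InputError, SchemaError
from sleepfusion.hypnogram import WAKE, NREM, REM
from sleepfusion.staging import (
    EPS_RATIO,
    LikelihoodSeries,
    NormalizationStats,
    PersonalThresholds,
    fit_personal_thresholds,
)


class TestNormalization:
    def test_training_table_becomes_zero_mean_unit_sd(self, rng):
        table = pd.DataFrame(rng.normal(2, 3, size=(200, 5)), columns=list("abcde"))
        stats = NormalizationStats.fit(table)
        norm = sf.normalize(table, stats)
        assert np.allclose(norm.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(norm.std(axis=0, ddof=0), 1.0, atol=1e-12)

    def test_direct_formula_example(self):
        table = pd.DataFrame({"f": [10.0, 20.0]})
        stats = NormalizationStats(names=["f"], mu=np.array([10.0]), sigma=np.array([5.0]))
        assert sf.normalize(table, stats)["f"].tolist() == [0.0, 2.0]

    def test_constant_test_column_stays_constant(self):
        stats = NormalizationStats(names=["f"], mu=np.array([1.0]), sigma=np.array([2.0]))
        out = sf.normalize(pd.DataFrame({"f": [7.0, 7.0, 7.0]}), stats)
        assert out["f"].nunique() == 1

    def test_zero_variance_training_columns_dropped(self, rng):
        table = pd.DataFrame({"a": rng.normal(size=50), "b": np.ones(50)})
        stats = NormalizationStats.fit(table)
        assert stats.names == ["a"]

    def test_unseen_feature_raises_schema_error(self):
        stats = NormalizationStats(names=["f"], mu=np.array([0.0]), sigma=np.array([1.0]))
        with pytest.raises(SchemaError):
            sf.normalize(pd.DataFrame({"g": [1.0]}), stats)


class TestSelectFeatures:
    def _table(self, rng, n=400, p=52):
        cols = [f"f{i}" for i in range(p)]
        x = rng.normal(size=(n, p))
        y = rng.integers(0, 2, n)
        x[:, 0] += 3 * y  # one strongly separating feature
        return pd.DataFrame(x, columns=cols), y

    def test_default_sizes_44_and_35(self, rng):
        table, y = self._table(rng)
        assert len(sf.select_features(table, y, 44)) == 44
        assert len(sf.select_features(table, y, 35)) == 35

    def test_identity_at_k_equals_52(self, rng):
        table, y = self._table(rng)
        assert sf.select_features(table, y, 52) == list(table.columns)

    def test_separating_feature_always_kept(self, rng):
        table, y = self._table(rng)
        assert "f0" in sf.select_features(table, y, 5)

    def test_k_too_large_rejected(self, rng):
        table, y = self._table(rng, p=10)
        with pytest.raises(ConfigurationError):
            sf.select_features(table, y, 11)


class TestSmoothing:
    def test_alpha_zero_is_identity(self, rng):
        p1 = rng.uniform(size=50)
        series = LikelihoodSeries(p0=1 - p1, p1=p1)
        out = sf.smooth(series, alpha=0.0)
        assert np.allclose(out.p1_smooth, p1)

    def test_constant_input_is_fixed_point(self):
        series = LikelihoodSeries(p0=np.full(20, 0.3), p1=np.full(20, 0.7))
        out = sf.smooth(series, alpha=0.9)
        assert np.allclose(out.p1_smooth, 0.7)
        assert np.allclose(out.p0_smooth + out.p1_smooth, 1.0)

    def test_impulse_decays_geometrically(self):
        p1 = np.zeros(30)
        p1[0] = 1.0
        out = sf.smooth(LikelihoodSeries(p0=1 - p1, p1=p1), alpha=0.9)
        expected = 0.9 ** np.arange(30)
        assert np.allclose(out.p1_smooth, expected, atol=1e-12)

    def test_matches_direct_summation_oracle(self, rng):
        """Closed form: p~(i) = (1-a) sum a^k p(i-k) + a^(i-1) p(1)."""
        alpha = 0.9
        p1 = rng.uniform(size=40)
        out = sf.smooth(LikelihoodSeries(p0=1 - p1, p1=p1), alpha=alpha)
        for i in range(40):
            direct = alpha**i * p1[0] + (1 - alpha) * sum(
                alpha**k * p1[i - k] for k in range(i)
            )
            assert out.p1_smooth[i] == pytest.approx(direct, abs=1e-12)

    def test_ratio_floor(self):
        series = LikelihoodSeries(p0=np.array([0.0]), p1=np.array([1.0]))
        out = sf.smooth(series, alpha=0.5)
        assert out.ratio[0] == pytest.approx(1.0 / EPS_RATIO)

    def test_invalid_alpha_rejected(self):
        series = LikelihoodSeries(p0=np.array([0.5]), p1=np.array([0.5]))
        for alpha in (-0.1, 1.0, 2.0):
            with pytest.raises(ConfigurationError):
                sf.smooth(series, alpha=alpha)


class TestPersonalThreshold:
    def test_nearest_rank_hand_example(self):
        assert sf.personal_threshold([1.0, 2.0, 3.0, 4.0], 50) == 2.0

    def test_eta_100_is_maximum(self):
        assert sf.personal_threshold([5.0, 1.0, 9.0], 100) == 9.0

    def test_constant_sequence(self):
        for eta in (0, 33, 50, 100):
            assert sf.personal_threshold([2.5] * 7, eta) == 2.5

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            sf.personal_threshold([], 50)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        ratios=st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=30),
        eta1=st.floats(0, 100),
        eta2=st.floats(0, 100),
    )
    def test_monotone_in_eta(self, ratios, eta1, eta2):
        lo, hi = sorted([eta1, eta2])
        assert sf.personal_threshold(ratios, lo) <= sf.personal_threshold(ratios, hi)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        ratios=st.lists(
            st.floats(0.01, 50, allow_nan=False), min_size=2, max_size=20, unique=True
        ),
        eta=st.floats(0, 100),
    )
    def test_equivariant_under_monotone_rescaling(self, ratios, eta):
        """The threshold is an order statistic: exp() commutes with it."""
        r = np.asarray(ratios)
        assert sf.personal_threshold(np.exp(r), eta) == pytest.approx(
            np.exp(sf.personal_threshold(r, eta))
        )


class TestWakeSleepDecision:
    def _series(self, ratio):
        n = len(ratio)
        s = LikelihoodSeries(p0=np.zeros(n), p1=np.zeros(n))
        s.ratio = np.asarray(ratio, dtype=float)
        return s

    def test_all_below_threshold_all_wake(self):
        sleep = sf.decide_wake_sleep(self._series([0.1] * 10), gamma_ws=1.0)
        assert not sleep.any()

    def test_first_minute_forced_awake(self):
        sleep = sf.decide_wake_sleep(self._series([5.0] * 10), gamma_ws=1.0)
        assert not sleep[0] and not sleep[1]
        assert sleep[2:].all()

    def test_snore_context_rescues_marginal_epoch(self):
        ratio = [0.0, 0.0, 5.0, 5.0, 0.9, 5.0, 5.0]
        se = np.array([0, 0, 0, 0, 3, 0, 0])
        no_sound = sf.decide_wake_sleep(self._series(ratio), 1.0)
        with_sound = sf.decide_wake_sleep(self._series(ratio), 1.0, se=se)
        assert not no_sound[4]
        assert with_sound[4]


class TestSnoreContext:
    def test_zero_se_changes_nothing(self):
        d = np.array([True, False, True, True])
        out = sf.apply_snore_context(d, np.zeros(4))
        assert np.array_equal(out, d)

    def test_isolated_wake_with_snores_flipped(self):
        d = np.array([True, True, False, True, True])
        out = sf.apply_snore_context(d, np.array([0, 0, 5, 0, 0]))
        assert out.all()

    def test_leading_wake_block_unchanged(self):
        d = np.array([False, False, True, True])
        out = sf.apply_snore_context(d, np.array([0, 0, 0, 0]))
        assert np.array_equal(out, d)

    def test_sleep_never_flipped_to_wake(self, rng):
        d = rng.random(50) > 0.4
        se = rng.poisson(2, 50)
        out = sf.apply_snore_context(d, se)
        assert (out | ~d).all()  # wherever d was sleep, out is sleep


class TestRemNremDecision:
    def test_window_biasing_keeps_mid_ratios_nrem(self):
        thr = PersonalThresholds(gamma_ws=1, gamma_rnr1=3.0, gamma_rnr2=1.0)
        ratios = np.full(10, 2.0)  # between the two thresholds
        idx = np.arange(10) + 5
        rem = sf.decide_rem_nrem(ratios, thr, idx, sleep_onset_epoch=5)
        assert not rem.any()

    def test_after_window_gamma2_applies(self):
        thr = PersonalThresholds(gamma_ws=1, gamma_rnr1=3.0, gamma_rnr2=1.0)
        ratios = np.full(10, 2.0)
        idx = np.arange(10) + 500  # far beyond the latency window
        rem = sf.decide_rem_nrem(ratios, thr, idx, sleep_onset_epoch=0)
        assert rem.all()

    def test_empty_sleep_set(self):
        thr = PersonalThresholds(1, 1, 1)
        assert sf.decide_rem_nrem(np.array([]), thr, np.array([]), 0).size == 0

    def test_latency_window_rem_subset_of_post_window_rem(self, rng):
        """Stricter early threshold: REM-in-window implies REM-post-window."""
        ratios = rng.uniform(0, 5, 200)
        idx = np.arange(200)
        thr = fit_personal_thresholds(rng.uniform(0, 5, 200), ratios)
        early = sf.decide_rem_nrem(ratios, thr, idx, sleep_onset_epoch=0)
        late = sf.decide_rem_nrem(ratios, thr, idx, sleep_onset_epoch=-10_000)
        assert (late | ~early).all()

    def test_gamma1_at_least_gamma2(self, rng):
        thr = fit_personal_thresholds(rng.uniform(size=50), rng.uniform(size=50))
        assert thr.gamma_rnr1 >= thr.gamma_rnr2


class TestTrainStager:
    def _toy(self, rng, n=300):
        stages = rng.choice([WAKE, NREM, REM], n, p=[0.3, 0.5, 0.2])
        x = rng.normal(size=(n, 6))
        x[:, 0] += 4 * (stages != WAKE)  # separable wake/sleep
        x[:, 1] += 4 * (stages == REM)  # separable REM/NREM
        cols = [f"f{i}" for i in range(6)]
        return pd.DataFrame(x, columns=cols), stages

    def test_deterministic_under_seed(self, rng):
        table, stages = self._toy(rng)
        a = sf.train_stager(table, stages, k_ws=6, k_rnr=6, n_estimators=30, seed=7)
        b = sf.train_stager(table, stages, k_ws=6, k_rnr=6, n_estimators=30, seed=7)
        assert a.ws_forest.oob_score_ == b.ws_forest.oob_score_
        pa = a.ws_forest.predict_proba(np.zeros((1, 6)))
        pb = b.ws_forest.predict_proba(np.zeros((1, 6)))
        assert np.array_equal(pa, pb)

    def test_separable_toy_reaches_perfect_training_accuracy(self, rng):
        table, stages = self._toy(rng)
        stager = sf.train_stager(table, stages, k_ws=6, k_rnr=6, n_estimators=50, seed=0)
        norm = stager.ws_stats.transform(table)
        pred = stager.ws_forest.predict(norm[stager.ws_features].to_numpy())
        assert (pred == (stages != WAKE)).mean() == 1.0

    def test_single_class_rejected(self, rng):
        table, _ = self._toy(rng)
        with pytest.raises(InputError):
            sf.train_stager(table, np.full(300, NREM))

    def test_likelihoods_sum_to_one(self, rng):
        table, stages = self._toy(rng)
        stager = sf.train_stager(table, stages, k_ws=6, k_rnr=6, n_estimators=30, seed=1)
        series = sf.predict_likelihoods(
            stager.ws_forest, stager.ws_stats, stager.ws_features, table
        )
        assert np.allclose(series.p0 + series.p1, 1.0)
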