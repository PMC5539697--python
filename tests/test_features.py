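"""Feature extraction against independent oracles.

Moments, singular values and covariance eigenvalues are checked against
brute-force formula/eigendecomposition oracles; spectral peaks against a
direct FFT; the WRMEnAD flags against generated radar fixtures.
"""

import numpy as np
import pytest

import sleepfusion as sf
from sleepfusion.errors import InputError
from sleepfusion.features import (
    FEATURE_NAMES,
    STAT_NAMES,
    cycle_intensity,
    detect_snore_events,
    epoch_to_matrix,
    extract_features_table,
    normalize_ci,
)
from sleepfusion.preprocess import BandSignals


class TestStatisticalFeatures:
    def test_returns_14_named_descriptors(self, rng):
        out = sf.statistical_features(rng.normal(size=500))
        assert out.shape == (14,)
        assert len(STAT_NAMES) == 14

    def test_formula_oracle_on_1234(self):
        out = dict(zip(STAT_NAMES, sf.statistical_features([1.0, 2.0, 3.0, 4.0])))
        assert out["min"] == 1 and out["max"] == 4
        assert out["mean"] == pytest.approx(2.5)
        assert out["median"] == pytest.approx(2.5)
        assert out["rms"] == pytest.approx(np.sqrt(7.5))
        assert out["slope"] == pytest.approx(1.0)  # unit increments
        assert out["sd"] == pytest.approx(np.sqrt(1.25))
        assert out["q1"] == pytest.approx(1.75)
        assert out["q3"] == pytest.approx(3.25)
        assert out["iqr"] == pytest.approx(1.5)

    def test_constant_input_degenerate_conventions(self):
        out = dict(zip(STAT_NAMES, sf.statistical_features(np.full(100, 2.0))))
        assert out["sd"] == 0
        assert out["zcr"] == 0
        assert out["n_peaks"] == 0

    def test_peak_features_on_known_sinusoid(self):
        t = np.arange(3000) / 1000.0
        x = np.sin(2 * np.pi * 2.0 * t)  # 2 Hz, 6 full peaks in 3 s
        out = dict(zip(STAT_NAMES, sf.statistical_features(x)))
        assert out["n_peaks"] == 6
        assert out["peak_dist"] == pytest.approx(500, abs=2)
        assert out["peak_amp"] == pytest.approx(1.0, abs=1e-3)


class TestSpectralPeak:
    def test_recovers_tone_within_one_bin(self):
        t = np.arange(30_000) / 1000.0
        x = np.sin(2 * np.pi * 0.25 * t)
        f = sf.spectral_peak(x, 1000, band=(0.1, 0.5))
        assert abs(f - 0.25) <= 1.0 / 30.0

    def test_larger_amplitude_wins(self):
        t = np.arange(30_000) / 1000.0
        x = 2 * np.sin(2 * np.pi * 0.2 * t) + np.sin(2 * np.pi * 0.4 * t)
        assert sf.spectral_peak(x, 1000, band=(0.1, 0.5)) == pytest.approx(0.2, abs=1 / 30)

    def test_deterministic_on_seeded_noise(self, rng):
        x = rng.normal(size=30_000)
        assert sf.spectral_peak(x, 1000) == sf.spectral_peak(x, 1000)


class TestSkewnessKurtosis:
    def test_symmetric_sequence_zero_skew(self):
        skew, _ = sf.skewness_kurtosis(np.array([-1.0, 0.0, 1.0]))
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_kurtosis_near_three(self, rng):
        _, kurt = sf.skewness_kurtosis(rng.normal(size=200_000))
        assert kurt == pytest.approx(3.0, abs=0.05)

    def test_brute_force_moment_oracle_four_points(self):
        x = np.array([0.0, 0.0, 0.0, 1.0])
        mu = x.mean()
        m2 = np.mean((x - mu) ** 2)
        m3 = np.mean((x - mu) ** 3)
        m4 = np.mean((x - mu) ** 4)
        skew, kurt = sf.skewness_kurtosis(x)
        assert skew == pytest.approx(m3 / m2**1.5)
        assert kurt == pytest.approx(m4 / m2**2)
        # closed form for a one-hot four-point sample
        assert skew == pytest.approx(2.0 / np.sqrt(3.0))

    def test_constant_segment_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            skew, kurt = sf.skewness_kurtosis(np.full(10, 3.3))
        assert (skew, kurt) == (0.0, 0.0)


class TestSVDPCA:
    def test_rank_one_matrix(self, rng):
        u = rng.normal(size=8)
        v = rng.normal(size=10)
        s = sf.svd_features(np.outer(u, v))
        assert s[0] > 0
        assert s[1] == pytest.approx(0.0, abs=1e-10)
        assert s[2] == pytest.approx(0.0, abs=1e-10)

    def test_identity_matrix(self):
        assert sf.svd_features(np.eye(3)) == pytest.approx((1.0, 1.0, 1.0))

    def test_svd_matches_eigen_oracle_on_100_random_matrices(self, rng):
        """Singular values equal sqrt eigenvalues of A^T A (independent path)."""
        for _ in range(100):
            a = rng.normal(size=(10, 10))
            expect = np.sqrt(np.sort(np.linalg.eigvalsh(a.T @ a))[::-1][:3])
            assert np.allclose(sf.svd_features(a), expect, atol=1e-8)

    def test_identical_rows_zero_covariance(self):
        a = np.tile(np.arange(5.0), (4, 1))
        assert sf.pca_features(a) == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)

    def test_known_diagonal_covariance_recovered(self, rng):
        cov = np.diag([4.0, 1.0, 0.25])
        x = rng.multivariate_normal(np.zeros(3), cov, size=10_000)
        vals = sf.pca_features(x)
        assert np.allclose(vals, [4.0, 1.0, 0.25], rtol=0.1)

    def test_eigenvalue_sum_equals_covariance_trace(self, rng):
        a = rng.normal(size=(6, 3))
        centered = a - a.mean(axis=0)
        cov = centered.T @ centered / (a.shape[0] - 1)
        assert sum(sf.pca_features(a)) == pytest.approx(np.trace(cov))

    def test_small_matrix_rejected(self):
        with pytest.raises(InputError):
            sf.svd_features(np.ones((2, 5)))
        with pytest.raises(InputError):
            sf.pca_features(np.ones((1, 5)))


class TestExtractEpochFeatures:
    def test_row_has_52_unique_named_features(self, quiet_epoch_bands):
        epoch, bands = quiet_epoch_bands
        row = sf.extract_epoch_features(epoch, bands)
        assert row.shape == (52,)
        assert len(FEATURE_NAMES) == 52
        assert len(set(FEATURE_NAMES)) == 52

    def test_zero_epoch_yields_defined_row(self):
        with pytest.warns(UserWarning):
            row = sf.extract_epoch_features(np.zeros(30_000))
        assert row.shape == (52,)
        assert np.isfinite(row).all()

    def test_svd_values_non_negative_and_sorted(self, quiet_epoch_bands):
        epoch, bands = quiet_epoch_bands
        row = dict(zip(FEATURE_NAMES, sf.extract_epoch_features(epoch, bands)))
        assert row["svd1"] >= row["svd2"] >= row["svd3"] >= 0

    def test_batch_path_matches_scalar_path(self, rng):
        epochs = rng.normal(size=(3, 30_000))
        bands = sf.bandpass_decompose(epochs)
        batch = extract_features_table(epochs, bands)
        for i in range(3):
            row = sf.extract_epoch_features(
                epochs[i],
                BandSignals(bands.movement[i], bands.breathing[i], bands.heartbeat[i]),
            )
            assert np.allclose(row, batch[i], rtol=1e-8, atol=1e-12)

    def test_breathing_peak_recovered_on_synthetic_nrem(self, small_subject):
        """Breathing spectral peak lands in band for occupied epochs."""
        feats = sf.extract_subject_features(small_subject.recording)
        vals = feats.table["spectral_peak_breathing"].to_numpy()
        lo, hi = sf.BandEdges().breathing
        occupied = ~feats.absence_flag.astype(bool)
        assert ((vals[occupied] >= lo) & (vals[occupied] <= hi)).all()


class TestWRMEnAD:
    def test_zero_epoch_is_absence_not_movement(self):
        bands = sf.bandpass_decompose(np.zeros(30_000))
        move, absent = sf.wrmenad(bands, gamma_move=0.1, gamma_abs=1e-6)
        assert (move, absent) == (0, 1)

    def test_flags_on_generated_fixture(self, small_subject):
        """Programmed absence epochs are flagged exactly; movement tracks wake."""
        feats = sf.extract_subject_features(small_subject.recording)
        expected = small_subject.profile.absence_mask(120).astype(int)
        assert np.array_equal(feats.absence_flag, expected)
        stages = small_subject.hypnogram.stages
        occupied = ~expected.astype(bool)
        wake_rate = feats.movement_flag[(stages == sf.WAKE) & occupied].mean()
        sleep_rate = feats.movement_flag[(stages != sf.WAKE) & occupied].mean()
        assert wake_rate > sleep_rate

    def test_movement_burst_fires_flag(self):
        # quiet breathing plus one 20 mm movement burst
        t = np.arange(30_000) / 1000.0
        breathing = 4e-3 * np.sin(2 * np.pi * 0.2 * t)
        burst = np.zeros_like(t)
        burst[10_000:12_000] = 20e-3 * 0.5 * (1 - np.cos(2 * np.pi * np.arange(2000) / 2000))
        lam = sf.RadarModelParams().wavelength
        quiet = np.cos(0.7 + 4 * np.pi * breathing / lam)
        moving = np.cos(0.7 + 4 * np.pi * (breathing + burst) / lam)
        b_quiet = sf.bandpass_decompose(quiet)
        b_moving = sf.bandpass_decompose(moving)
        move_flags, _, _, _ = sf.wrmenad_flags([b_quiet, b_moving, b_quiet, b_quiet])
        assert move_flags.tolist() == [0, 1, 0, 0]


class TestAcousticFeatures:
    def _snore_audio(self, n_bursts, rng, n_sec=30, fs=16_000):
        x = 0.001 * rng.normal(size=n_sec * fs)
        for k in range(n_bursts):
            start = int((2 + 7 * k) * fs)
            dur = int(0.8 * fs)
            t = np.arange(dur) / fs
            x[start : start + dur] += 0.5 * np.sin(2 * np.pi * 150 * t) * np.hanning(dur)
        return x

    def test_silence_counts_zero(self):
        assert detect_snore_events(np.zeros(16_000 * 30)) == 0

    def test_injected_bursts_counted(self, rng):
        x = self._snore_audio(4, rng)
        clean = sf.reduce_noise_audio(x)
        assert detect_snore_events(clean) == 4

    def test_white_noise_yields_zero_after_denoising(self, rng):
        x = 0.1 * rng.normal(size=16_000 * 30)
        clean = sf.reduce_noise_audio(x)
        assert detect_snore_events(clean) == 0

    def test_ci_silence_zero(self):
        assert cycle_intensity(np.zeros(16_000)) == 0.0

    def test_ci_energy_scales_quadratically(self, rng):
        x = rng.normal(size=16_000)
        assert cycle_intensity(2 * x) == pytest.approx(4 * cycle_intensity(x), rel=1e-6)

    def test_louder_epoch_has_larger_ci(self, rng):
        t = np.arange(16_000 * 2) / 16_000.0
        soft = 0.1 * np.sin(2 * np.pi * 300 * t)
        loud = 0.4 * np.sin(2 * np.pi * 300 * t)
        assert cycle_intensity(loud) > cycle_intensity(soft)

    def test_normalize_ci_unit_range(self, rng):
        ci = rng.uniform(0, 5, 100)
        norm = normalize_ci(ci)
        assert norm.max() == pytest.approx(1.0)
        assert (norm >= 0).all()


def test_epoch_matrix_shape():
    assert epoch_to_matrix(np.zeros(30_000)).shape == (30, 1000)
    with pytest.raises(InputError):
        epoch_to_matrix(np.zeros(30_001))
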