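"""Per-epoch feature extraction.

Every 30-s radar epoch yields exactly 52 named features:

* 14 statistical descriptors for each of the movement, breathing and
  heartbeat band signals (42),
* the spectral-peak frequency of the breathing and heartbeat bands (2),
* skewness and kurtosis of the raw epoch (2),
* the three largest singular values of the epoch's 30 x 1000 sub-window
  matrix (3),
* the three largest eigenvalues of that matrix's centralized covariance (3).

The module also computes the WRMEnAD flags (wake-related movement existence
and absence detection) from band-limited epoch energy, and the acoustic
snore-event count (SE) and cycle-intensity (CI) features.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .errors import InputError
from .preprocess import BandEdges, BandSignals, bandpass_decompose
from .simulate import SAMPLE_RATE_HZ

STAT_NAMES: tuple[str, ...] = (
    "min", "max", "mean", "rms", "median", "q1", "q3", "sd", "iqr",
    "n_peaks", "peak_dist", "peak_amp", "zcr", "slope",
)

_BANDS: tuple[str, ...] = ("movement", "breathing", "heartbeat")

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"{band}_{stat}" for band in _BANDS for stat in STAT_NAMES]
    + ["spectral_peak_breathing", "spectral_peak_heartbeat"]
    + ["fskew", "fkurt"]
    + ["svd1", "svd2", "svd3"]
    + ["pca1", "pca2", "pca3"]
)
assert len(FEATURE_NAMES) == 52

#: Peak definition: local maxima with prominence >= this fraction of the
#: segment standard deviation.
PEAK_PROMINENCE_FRAC: float = 0.1


def statistical_features(band_signal: np.ndarray) -> np.ndarray:
    """The 14 statistical descriptors of one band signal, in STAT_NAMES order.

    Peaks are local maxima with prominence >= 0.1 x the segment standard
    deviation; the zero-cross rate counts sign changes of the mean-removed
    signal; the slope is the least-squares line slope per sample.  Degenerate
    (constant) segments yield zeros for the peak and dispersion features.
    """
    x = np.asarray(band_signal, dtype=float)
    if x.size == 0:
        raise InputError("segment is empty")
    sd = float(x.std())
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    n_peaks, peak_dist, peak_amp = _peak_stats(x, sd)
    centered = x - x.mean()
    t = np.arange(x.size, dtype=float)
    denom = ((t - t.mean()) ** 2).sum()
    slope = float(((t - t.mean()) * centered).sum() / denom) if denom > 0 else 0.0
    return np.array(
        [
            x.min(), x.max(), x.mean(), np.sqrt(np.mean(x**2)), med,
            q1, q3, sd, q3 - q1, float(n_peaks), peak_dist, peak_amp,
            float(_zero_cross_count(centered)), slope,
        ]
    )


def _peak_stats(x: np.ndarray, sd: float) -> tuple[int, float, float]:
    if sd > 0:
        peaks, _ = sps.find_peaks(x, prominence=PEAK_PROMINENCE_FRAC * sd)
    else:
        peaks = np.array([], dtype=int)
    n_peaks = int(peaks.size)
    peak_dist = float(np.diff(peaks).mean()) if n_peaks >= 2 else 0.0
    peak_amp = float(x[peaks].mean()) if n_peaks >= 1 else 0.0
    return n_peaks, peak_dist, peak_amp


def _zero_cross_count(centered: np.ndarray) -> int:
    signs = np.sign(centered)
    signs = signs[signs != 0]
    return int(np.count_nonzero(np.diff(signs)))


def spectral_peak(
    band_signal: np.ndarray,
    sample_rate: int = SAMPLE_RATE_HZ,
    band: tuple[float, float] | None = None,
) -> float:
    """Frequency (Hz) of the maximum-magnitude FFT bin, DC excluded.

    When ``band`` is given the search is restricted to that pass-band, which
    is how the breathing and heartbeat spectral features are computed.
    """
    x = np.asarray(band_signal, dtype=float)
    if x.size == 0:
        raise InputError("segment is empty")
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / sample_rate)
    mask = freqs > 0
    if band is not None:
        mask &= (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        return 0.0
    idx = np.flatnonzero(mask)
    return float(freqs[idx[np.argmax(spec[idx])]])


def skewness_kurtosis(epoch: np.ndarray) -> tuple[float, float]:
    """Population skewness and (non-excess) kurtosis of the raw epoch.

    FSKEW = E[((s-mu)/sigma)^3]; FKURT = E[(s-mu)^4] / E[(s-mu)^2]^2.
    A constant segment (sigma = 0) yields (0, 0) with a warning.
    """
    x = np.asarray(epoch, dtype=float)
    if x.size == 0:
        raise InputError("segment is empty")
    centered = x - x.mean()
    m2 = float(np.mean(centered**2))
    if m2 == 0.0:
        warnings.warn("constant segment: skewness/kurtosis set to 0", stacklevel=2)
        return 0.0, 0.0
    m3 = float(np.mean(centered**3))
    m4 = float(np.mean(centered**4))
    return m3 / m2**1.5, m4 / m2**2


def epoch_to_matrix(epoch: np.ndarray, n_rows: int = 30) -> np.ndarray:
    """Reshape a 30-s epoch into its 30 x 1000 sub-window matrix (1-s rows)."""
    x = np.asarray(epoch, dtype=float)
    if x.size % n_rows != 0:
        raise InputError(f"epoch length {x.size} not divisible by {n_rows}")
    return x.reshape(n_rows, -1)


def svd_features(epoch_matrix: np.ndarray) -> tuple[float, float, float]:
    """The three largest singular values of the sub-window matrix, descending."""
    a = np.asarray(epoch_matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] < 3 or a.shape[1] < 3:
        raise InputError("matrix must have at least 3 rows and 3 columns")
    s = np.linalg.svd(a, compute_uv=False)
    return float(s[0]), float(s[1]), float(s[2])


def pca_features(epoch_matrix: np.ndarray) -> tuple[float, float, float]:
    """Three largest eigenvalues of the centralized covariance of the matrix.

    Cov(A) = (A - mu_A)^T (A - mu_A) / (N - 1) with N the number of rows;
    its eigenvalues are computed via the singular values of the centered
    matrix (Cov(A) is rank-deficient, so this is both exact and cheap).
    """
    a = np.asarray(epoch_matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 3:
        raise InputError("matrix must have at least 2 rows and 3 columns")
    centered = a - a.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    eig = np.zeros(3)
    top = (s**2 / (a.shape[0] - 1))[:3]
    eig[: top.size] = top
    return float(eig[0]), float(eig[1]), float(eig[2])


def extract_epoch_features(
    epoch: np.ndarray,
    bands: BandSignals | None = None,
    sample_rate: int = SAMPLE_RATE_HZ,
    band_edges: BandEdges | None = None,
) -> np.ndarray:
    """The full 52-value feature row for one epoch, in FEATURE_NAMES order."""
    band_edges = band_edges or BandEdges()
    if bands is None:
        bands = bandpass_decompose(epoch, band_edges, sample_rate)
    row = np.empty(52)
    k = 0
    for name in _BANDS:
        row[k : k + 14] = statistical_features(getattr(bands, name))
        k += 14
    row[k] = spectral_peak(bands.breathing, sample_rate, band_edges.breathing)
    row[k + 1] = spectral_peak(bands.heartbeat, sample_rate, band_edges.heartbeat)
    k += 2
    row[k], row[k + 1] = skewness_kurtosis(epoch)
    k += 2
    mat = epoch_to_matrix(epoch)
    row[k : k + 3] = svd_features(mat)
    row[k + 3 : k + 6] = pca_features(mat)
    return row


def _statistical_features_batch(mat: np.ndarray) -> np.ndarray:
    """Vectorized 14-descriptor block for a (n_epochs, samples) band matrix."""
    n = mat.shape[0]
    out = np.empty((n, 14))
    out[:, 0] = mat.min(axis=1)
    out[:, 1] = mat.max(axis=1)
    mean = mat.mean(axis=1, dtype=np.float64)
    out[:, 2] = mean
    out[:, 3] = np.sqrt(np.mean(mat**2, axis=1, dtype=np.float64))
    q1, med, q3 = np.percentile(mat, [25, 50, 75], axis=1)
    out[:, 4] = med
    out[:, 5] = q1
    out[:, 6] = q3
    sd = mat.std(axis=1)
    out[:, 7] = sd
    out[:, 8] = q3 - q1
    centered = mat - mean[:, None].astype(mat.dtype)
    t = np.arange(mat.shape[1], dtype=float)
    tc = t - t.mean()
    denom = (tc**2).sum()
    out[:, 13] = centered @ tc / denom
    for i in range(n):
        out[i, 9:12] = _peak_stats(mat[i], float(sd[i]))
        out[i, 12] = _zero_cross_count(centered[i])
    return out


def _spectral_peak_batch(
    mat: np.ndarray, sample_rate: int, band: tuple[float, float]
) -> np.ndarray:
    freqs = np.fft.rfftfreq(mat.shape[1], d=1.0 / sample_rate)
    cols = np.flatnonzero((freqs > 0) & (freqs >= band[0]) & (freqs <= band[1]))
    out = np.empty(mat.shape[0])
    chunk = 64  # bound the (chunk, n_bins) complex spectrum memory
    for lo in range(0, mat.shape[0], chunk):
        spec = np.abs(np.fft.rfft(mat[lo : lo + chunk], axis=1))[:, cols]
        out[lo : lo + chunk] = freqs[cols[np.argmax(spec, axis=1)]]
    return out


def extract_features_table(
    epochs: np.ndarray,
    bands: BandSignals,
    sample_rate: int = SAMPLE_RATE_HZ,
    band_edges: BandEdges | None = None,
) -> np.ndarray:
    """All 52 features for every epoch at once (vectorized fast path).

    ``epochs`` is the (n_epochs, samples) framed channel and ``bands`` holds
    the per-epoch band decompositions as equally shaped matrices.  Produces
    the same values as calling :func:`extract_epoch_features` per epoch.
    """
    band_edges = band_edges or BandEdges()
    n = epochs.shape[0]
    rows = np.empty((n, 52))
    for j, name in enumerate(_BANDS):
        rows[:, j * 14 : (j + 1) * 14] = _statistical_features_batch(
            np.atleast_2d(getattr(bands, name))
        )
    rows[:, 42] = _spectral_peak_batch(
        np.atleast_2d(bands.breathing), sample_rate, band_edges.breathing
    )
    rows[:, 43] = _spectral_peak_batch(
        np.atleast_2d(bands.heartbeat), sample_rate, band_edges.heartbeat
    )
    mean = epochs.mean(axis=1, dtype=np.float64)
    centered = epochs - mean[:, None].astype(epochs.dtype)
    c2 = centered * centered
    m2 = np.mean(c2, axis=1, dtype=np.float64)
    m3 = np.mean(c2 * centered, axis=1, dtype=np.float64)
    m4 = np.mean(c2 * c2, axis=1, dtype=np.float64)
    ok = m2 > 0
    if not ok.all():
        warnings.warn("constant epochs: skewness/kurtosis set to 0", stacklevel=2)
    rows[:, 44] = np.where(ok, m3 / np.where(ok, m2, 1.0) ** 1.5, 0.0)
    rows[:, 45] = np.where(ok, m4 / np.where(ok, m2, 1.0) ** 2, 0.0)
    for i in range(n):
        mat = epoch_to_matrix(epochs[i])
        rows[i, 46:49] = svd_features(mat)
        rows[i, 49:52] = pca_features(mat)
    return rows


# ---------------------------------------------------------------------------
# WRMEnAD: wake-related movement existence and absence detection

ENVELOPE_WINDOW_S: float = 0.5
DEFAULT_MIN_CROSSINGS: int = 2
GAMMA_ABS_FRACTION: float = 0.01  # of the recording's median epoch energy
GAMMA_MOVE_FACTOR: float = 3.0  # x the recording's median envelope


def band_energy(bands: BandSignals) -> float:
    """E(i): mean squared amplitude of the band-limited epoch signal.

    Defined on the summed band energies (movement + breathing + heartbeat)
    so that an empty room — an arbitrary DC level plus slow phase drift —
    sits at the noise floor regardless of the radar phase offset.
    """
    return float(
        np.mean(bands.movement**2) + np.mean(bands.breathing**2)
        + np.mean(bands.heartbeat**2)
    )


def movement_envelope(
    movement_band: np.ndarray, sample_rate: int = SAMPLE_RATE_HZ
) -> np.ndarray:
    """Sliding 0.5-s RMS envelope of the movement-band signal."""
    win = max(1, int(ENVELOPE_WINDOW_S * sample_rate))
    return np.sqrt(uniform_filter1d(np.asarray(movement_band) ** 2, size=win))


def wrmenad(
    bands: BandSignals,
    gamma_move: float,
    gamma_abs: float,
    sample_rate: int = SAMPLE_RATE_HZ,
    min_crossings: int = DEFAULT_MIN_CROSSINGS,
) -> tuple[int, int]:
    """WRMEnAD flags for one epoch given explicit heuristic thresholds.

    The movement flag fires when the 0.5-s RMS envelope of the movement band
    crosses ``gamma_move`` at least ``min_crossings`` times in the epoch
    (a single burst produces one up- and one down-crossing).  The absence
    flag fires when the band-limited epoch energy E(i) falls below
    ``gamma_abs``.
    """
    if gamma_move <= 0 or gamma_abs <= 0:
        raise InputError("thresholds must be positive")
    env = movement_envelope(bands.movement, sample_rate)
    above = env > gamma_move
    crossings = int(np.count_nonzero(np.diff(above)))
    movement_flag = int(crossings >= min_crossings)
    absence_flag = int(band_energy(bands) < gamma_abs)
    return movement_flag, absence_flag


def wrmenad_flags(
    bands: "BandSignals | list[BandSignals]",
    gamma_move: float | None = None,
    gamma_abs: float | None = None,
    sample_rate: int = SAMPLE_RATE_HZ,
    min_crossings: int = DEFAULT_MIN_CROSSINGS,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-epoch WRMEnAD flags with self-calibrating default thresholds.

    ``bands`` is either one BandSignals whose arrays are (n_epochs, samples)
    matrices or a list of per-epoch BandSignals.  gamma_abs defaults to 1%
    of the recording's median epoch energy and gamma_move to 3 x the
    recording's median movement envelope, so the flags are insensitive to
    the absolute signal scale.
    """
    if isinstance(bands, BandSignals):
        move = np.atleast_2d(bands.movement)
        breathe = np.atleast_2d(bands.breathing)
        heart = np.atleast_2d(bands.heartbeat)
    else:
        move = np.stack([b.movement for b in bands])
        breathe = np.stack([b.breathing for b in bands])
        heart = np.stack([b.heartbeat for b in bands])
    energies = (
        np.mean(move**2, axis=1, dtype=np.float64)
        + np.mean(breathe**2, axis=1, dtype=np.float64)
        + np.mean(heart**2, axis=1, dtype=np.float64)
    )
    win = max(1, int(ENVELOPE_WINDOW_S * sample_rate))
    envelopes = np.sqrt(uniform_filter1d(move**2, size=win, axis=-1))
    if gamma_abs is None:
        gamma_abs = max(GAMMA_ABS_FRACTION * float(np.median(energies)), 1e-300)
    if gamma_move is None:
        gamma_move = max(GAMMA_MOVE_FACTOR * float(np.median(envelopes)), 1e-300)
    crossings = np.count_nonzero(np.diff(envelopes > gamma_move, axis=1), axis=1)
    movement = (crossings >= min_crossings).astype(int)
    absence = (energies < gamma_abs).astype(int)
    return movement, absence, gamma_move, gamma_abs


# ---------------------------------------------------------------------------
# acoustic features (operational definitions)

AUDIO_RATE_HZ: int = 16000
SNORE_MIN_S: float = 0.2
SNORE_MAX_S: float = 2.0
SNORE_RECURRENCE_S: float = 10.0
SNORE_DYNAMIC_RANGE: float = 10.0  # burst-to-background energy ratio floor
CI_BAND_HZ: tuple[float, float] = (100.0, 2000.0)


def _short_time_energy(
    x: np.ndarray, sample_rate: int, win_s: float = 0.05
) -> tuple[np.ndarray, float]:
    win = max(1, int(win_s * sample_rate))
    n = x.size // win
    frames = x[: n * win].reshape(n, win)
    return (frames**2).mean(axis=1), win / sample_rate


def detect_snore_events(
    audio_epoch: np.ndarray, sample_rate: int = AUDIO_RATE_HZ
) -> int:
    """Count snore bursts in one 30-s denoised audio epoch.

    Operational definition: short-time-energy (50-ms frames) runs above an
    adaptive threshold (median + 25% of the median-to-max range), lasting
    0.2-2.0 s.  When several bursts are present, only bursts recurring
    within 10 s of a neighbour are kept (snoring is periodic with the
    breathing cycle); a single isolated burst still counts.
    """
    x = np.asarray(audio_epoch, dtype=float)
    if x.size == 0:
        return 0
    energy, dt = _short_time_energy(x, sample_rate)
    if energy.max() < 1e-12:
        return 0
    med = float(np.median(energy))
    # a flat envelope (residual noise) has no distinct bursts: snore bursts
    # stand at least an order of magnitude above the background energy
    if energy.max() < SNORE_DYNAMIC_RANGE * max(med, 1e-12):
        return 0
    thr = med + 0.25 * (float(energy.max()) - med)
    above = energy > thr
    # maximal runs above threshold
    edges = np.diff(np.concatenate(([0], above.astype(int), [0])))
    starts, ends = np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)
    onsets = []
    for s, e in zip(starts, ends):
        dur = (e - s) * dt
        if SNORE_MIN_S <= dur <= SNORE_MAX_S:
            onsets.append(s * dt)
    if len(onsets) <= 1:
        return len(onsets)
    onsets_arr = np.asarray(onsets)
    gaps = np.diff(onsets_arr)
    keep = np.zeros(onsets_arr.size, dtype=bool)
    keep[:-1] |= gaps <= SNORE_RECURRENCE_S
    keep[1:] |= gaps <= SNORE_RECURRENCE_S
    return int(keep.sum())


def cycle_intensity(
    audio_epoch: np.ndarray, sample_rate: int = AUDIO_RATE_HZ
) -> float:
    """Mean acoustic energy of the 100-2000 Hz breathing band of one epoch.

    Pre-normalization value; callers normalize per recording with
    :func:`normalize_ci`.
    """
    x = np.asarray(audio_epoch, dtype=float)
    if x.size == 0:
        return 0.0
    sos = sps.butter(4, CI_BAND_HZ, btype="band", fs=sample_rate, output="sos")
    y = sps.sosfiltfilt(sos, x)
    return float(np.mean(y**2))


def normalize_ci(ci_values: np.ndarray) -> np.ndarray:
    """Normalize per-epoch CI values to [0, 1] within one recording."""
    ci = np.asarray(ci_values, dtype=float)
    top = ci.max()
    return ci / top if top > 0 else ci.copy()
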