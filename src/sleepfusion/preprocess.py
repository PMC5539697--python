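"""Radar channel selection, framing, band decomposition, audio denoising.

The raw quadrature pair is reduced to a single channel by picking the one
with the larger interquartile range (the channel further from the Doppler
null point), the channel is cut into non-overlapping 30-s epochs, and each
epoch is decomposed by three zero-phase Butterworth band-pass filters into
movement, breathing and heartbeat components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, InputError
from .simulate import QuadratureRecording, SAMPLE_RATE_HZ, EPOCH_LEN_S


@dataclass(frozen=True)
class BandEdges:
    """Pass-band edges (Hz) of the three physiological filters.

    Defaults cover 6-30 breaths/min (breathing), 48-120 bpm (heartbeat) and
    abrupt limb transients (movement); all configurable.
    """

    breathing: tuple[float, float] = (0.1, 0.5)
    heartbeat: tuple[float, float] = (0.8, 2.0)
    movement: tuple[float, float] = (2.0, 10.0)
    order: int = 4

    def validate(self, sample_rate: float) -> None:
        for name in ("breathing", "heartbeat", "movement"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo < hi < sample_rate / 2.0):
                raise ConfigurationError(
                    f"band {name}=({lo}, {hi}) must satisfy 0 < low < high < fs/2"
                )


@dataclass
class EpochSeries:
    """Non-overlapping 30-s single-channel epochs at 1000 Hz."""

    data: np.ndarray  # (n_epochs, samples_per_epoch)
    sample_rate: int = SAMPLE_RATE_HZ
    source_channel: str = "I"

    @property
    def n_epochs(self) -> int:
        return int(self.data.shape[0])

    def __iter__(self):
        return iter(self.data)


@dataclass
class BandSignals:
    """Movement / breathing / heartbeat band-pass outputs of one segment."""

    movement: np.ndarray
    breathing: np.ndarray
    heartbeat: np.ndarray


def iqr(x: np.ndarray) -> float:
    """Interquartile range with linear-interpolation (type-7) quantiles."""
    q1, q3 = np.percentile(x, [25, 75])
    return float(q3 - q1)


def select_channel(rec: QuadratureRecording) -> tuple[np.ndarray, str]:
    """Pick the quadrature channel with the larger interquartile range.

    A larger IQR indicates the channel further from the Doppler null point.
    Ties break toward I.
    """
    if len(rec) == 0:
        raise InputError("recording is empty")
    iqr_i, iqr_q = iqr(rec.channel_I), iqr(rec.channel_Q)
    if iqr_q > iqr_i:
        return rec.channel_Q, "Q"
    return rec.channel_I, "I"


def frame_signal(
    x: np.ndarray,
    sample_rate: int = SAMPLE_RATE_HZ,
    epoch_len: float = EPOCH_LEN_S,
    source_channel: str = "I",
) -> EpochSeries:
    """Cut a signal into consecutive non-overlapping 30-s epochs.

    A trailing partial epoch is discarded.
    """
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(float)
    spe = sample_rate * epoch_len
    if abs(spe - round(spe)) > 1e-9:
        raise ConfigurationError("sample_rate * epoch_len must be integral")
    spe = int(round(spe))
    n = x.size // spe
    if n == 0:
        raise InputError(
            f"signal of {x.size} samples is shorter than one epoch ({spe})"
        )
    data = x[: n * spe].reshape(n, spe)
    return EpochSeries(data, sample_rate, source_channel)


def _sos(lo: float, hi: float, fs: float, order: int) -> np.ndarray:
    return sps.butter(order, [lo, hi], btype="band", fs=fs, output="sos")


def bandpass_decompose(
    epoch: np.ndarray,
    bands: BandEdges | None = None,
    sample_rate: int = SAMPLE_RATE_HZ,
) -> BandSignals:
    """Zero-phase band-pass decomposition of one segment (or full signal).

    Forward-backward filtering preserves peak timing for the peak-count
    features; the band-pass removes DC by construction.
    """
    bands = bands or BandEdges()
    bands.validate(sample_rate)
    x = np.asarray(epoch)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(float)
    out = {}
    for name in ("movement", "breathing", "heartbeat"):
        lo, hi = getattr(bands, name)
        y = sps.sosfiltfilt(_sos(lo, hi, sample_rate, bands.order), x, axis=-1)
        # sosfiltfilt computes in float64; return the caller's precision
        out[name] = y.astype(x.dtype, copy=False)
    return BandSignals(**out)


# ---------------------------------------------------------------------------
# audio noise reduction (spectral subtraction)

AUDIO_RATE_HZ: int = 16000
_NFFT: int = 512  # 32-ms windows at 16 kHz
_GATE_FACTOR: float = 2.0
_GATE_PEAKINESS: float = 10.0  # profile max/median ratio separating tonal content


def reduce_noise_audio(
    wav: np.ndarray, sample_rate: int = AUDIO_RATE_HZ
) -> np.ndarray:
    """Stationary-noise reduction: spectral subtraction plus a noise gate.

    The noise magnitude profile is the mean spectrum of the lowest-energy 5%
    of 32-ms windows; it is subtracted from every frame's magnitude (floored
    at zero), frames whose energy sits at the noise-profile level are gated
    to silence, and the signal is resynthesized at equal length.  Pure
    silence maps to silence.
    """
    wav = np.asarray(wav, dtype=float)
    if wav.size == 0:
        raise InputError("audio is empty")
    if wav.size < _NFFT:
        return np.zeros_like(wav)
    stft = sps.ShortTimeFFT(
        sps.windows.hann(_NFFT, sym=False), hop=_NFFT // 2, fs=sample_rate
    )
    S = stft.stft(wav)
    mag, phase = np.abs(S), np.angle(S)
    frame_energy = (mag**2).sum(axis=0)
    k = max(1, int(np.ceil(0.05 * frame_energy.size)))
    quiet = np.argsort(frame_energy)[:k]
    noise_profile = mag[:, quiet].mean(axis=1, keepdims=True)
    clean = np.maximum(mag - noise_profile, 0.0)
    # gate: a frame within a factor ~2 of the stationary-noise energy holds
    # no signal, so zero it to remove the half-wave-rectified noise residue.
    # Gating only applies when the profile is broadband (no bin stands far
    # above the median); a spiky profile means the "quiet" frames carry
    # narrowband signal that must not be gated away.
    prof = noise_profile[1:, 0]
    broadband = prof.max() < _GATE_PEAKINESS * (np.median(prof) + 1e-300)
    if broadband:
        clean[:, frame_energy < _GATE_FACTOR * (noise_profile**2).sum()] = 0.0
    out = stft.istft(clean * np.exp(1j * phase), k1=wav.size)
    return np.asarray(out[: wav.size], dtype=float)
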