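"""Plain-text file formats.

* Radar trace: two-column CSV ``I,Q`` preceded by a ``# sample_rate_hz=...``
  header line; values written with repr precision so the CSV dialect
  round-trips bit-exactly.
* Hypnogram: CSV ``epoch_index,stage`` with stage in {WAKE, NREM, REM}.
* Sound features: CSV ``epoch_index,SE,CI``.
* Optional audio: 16-bit PCM WAV, 16 kHz mono (via scipy).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import InputError
from .hypnogram import Hypnogram, STAGE_NAMES
from .simulate import QuadratureRecording, SoundFeatureSeries


def write_radar_csv(rec: QuadratureRecording, path) -> None:
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write(f"# sample_rate_hz={rec.sample_rate}\n")
        # pandas writes shortest round-trip float reprs; read back with
        # float_precision="round_trip" for a bit-exact cycle
        pd.DataFrame(
            {"I": rec.channel_I.astype(float), "Q": rec.channel_Q.astype(float)}
        ).to_csv(fh, index=False, lineterminator="\n")


def read_radar_csv(path) -> QuadratureRecording:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("# sample_rate_hz="):
            raise InputError(f"{path}: missing '# sample_rate_hz=' header")
        sample_rate = int(header.split("=", 1)[1])
        df = pd.read_csv(fh, float_precision="round_trip")
    if list(df.columns) != ["I", "Q"]:
        raise InputError(f"{path}: expected columns I,Q")
    return QuadratureRecording(
        df["I"].to_numpy(float), df["Q"].to_numpy(float), sample_rate
    )


def write_hypnogram_csv(hyp: Hypnogram, path) -> None:
    with Path(path).open("w", newline="\n") as fh:
        fh.write("epoch_index,stage\n")
        for i, s in enumerate(hyp.stages):
            fh.write(f"{i},{STAGE_NAMES[int(s)]}\n")


def read_hypnogram_csv(path) -> Hypnogram:
    df = pd.read_csv(path)
    if not {"epoch_index", "stage"} <= set(df.columns):
        raise InputError(f"{path}: expected columns epoch_index,stage")
    df = df.sort_values("epoch_index")
    return Hypnogram.from_labels(df["stage"].tolist())


def write_sound_csv(sound: SoundFeatureSeries, path) -> None:
    with Path(path).open("w", newline="\n") as fh:
        fh.write("epoch_index,SE,CI\n")
        for i, (se, ci) in enumerate(zip(sound.SE, sound.CI)):
            fh.write(f"{int(i)},{int(se)},{float(ci)!r}\n")


def read_sound_csv(path) -> SoundFeatureSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"epoch_index", "SE", "CI"} <= set(df.columns):
        raise InputError(f"{path}: expected columns epoch_index,SE,CI")
    df = df.sort_values("epoch_index")
    return SoundFeatureSeries(df["SE"].to_numpy(int), df["CI"].to_numpy(float))


def write_wav(audio: np.ndarray, path, sample_rate: int = 16000) -> None:
    """Write mono float audio in [-1, 1] as 16-bit PCM WAV."""
    clipped = np.clip(np.asarray(audio, dtype=float), -1.0, 1.0)
    wavfile.write(path, sample_rate, (clipped * 32767).astype(np.int16))


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a WAV file back to float audio in [-1, 1]."""
    sample_rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise InputError(f"{path}: expected mono audio")
    if data.dtype == np.int16:
        return data.astype(float) / 32767.0, int(sample_rate)
    return data.astype(float), int(sample_rate)


def write_rule_log_csv(log, path) -> None:
    with Path(path).open("w", newline="\n") as fh:
        fh.write("epoch_index,rule,old,new\n")
        for epoch, rule, old, new in log.entries:
            fh.write(f"{epoch},{rule},{old},{new}\n")
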