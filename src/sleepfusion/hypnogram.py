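"""Hypnogram container: the per-epoch WAKE / NREM / REM stage sequence.

Stages are stored as small integer codes; the canonical string labels used in
files are ``WAKE``, ``NREM`` and ``REM``.  Epochs are 30-s scoring windows,
matching clinical polysomnography practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

WAKE: int = 0
NREM: int = 1
REM: int = 2

STAGE_NAMES: dict[int, str] = {WAKE: "WAKE", NREM: "NREM", REM: "REM"}
STAGE_CODES: dict[str, int] = {v: k for k, v in STAGE_NAMES.items()}

EPOCH_LEN_S: float = 30.0


@dataclass
class Hypnogram:
    """A per-epoch sequence of sleep stages.

    Parameters
    ----------
    stages
        Integer stage codes (``WAKE``/``NREM``/``REM``), one per 30-s epoch.
    epoch_len
        Epoch length in seconds.  Fixed at 30 s to match PSG scoring.
    """

    stages: np.ndarray
    epoch_len: float = EPOCH_LEN_S

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=np.int8)
        if self.stages.size == 0:
            raise InputError("hypnogram must contain at least one epoch")
        if not np.isin(self.stages, list(STAGE_NAMES)).all():
            raise InputError("stage codes must be WAKE, NREM or REM")

    def __len__(self) -> int:
        return int(self.stages.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        return (
            self.epoch_len == other.epoch_len
            and np.array_equal(self.stages, other.stages)
        )

    @property
    def n_epochs(self) -> int:
        return len(self)

    @property
    def labels(self) -> list[str]:
        """Stage names as strings, one per epoch."""
        return [STAGE_NAMES[int(s)] for s in self.stages]

    @property
    def is_sleep(self) -> np.ndarray:
        """Boolean mask of epochs scored as sleep (NREM or REM)."""
        return self.stages != WAKE

    def sleep_onset(self) -> int | None:
        """Index of the first sleep epoch, or ``None`` if always awake."""
        idx = np.flatnonzero(self.stages != WAKE)
        return int(idx[0]) if idx.size else None

    @classmethod
    def from_labels(cls, labels, epoch_len: float = EPOCH_LEN_S) -> "Hypnogram":
        try:
            codes = [STAGE_CODES[str(s).strip().upper()] for s in labels]
        except KeyError as exc:  # pragma: no cover - message only
            raise InputError(f"unknown stage label {exc.args[0]!r}") from exc
        return cls(np.asarray(codes, dtype=np.int8), epoch_len)
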