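"""Final-decision post-processing of the predicted hypnogram.

Three heuristic correction rules, applied in a fixed order, turn the raw
classifier output into the final hypnogram PFIN:

1. WRMEnAD correction — absence epochs become WAKE (reference PSG scores an
   empty bed as wake), and a single sleep epoch sandwiched between two WAKE
   epochs becomes WAKE (nobody sleeps for exactly 30 s).
2. Sound-based wake-period detection — after zeroing the cycle-intensity
   feature on epochs with few snore events and low CI, every maximal run of
   zero-CI epochs whose length lies in [110, 170] epochs (~55-85 min) is
   relabelled WAKE.
3. REM outlier elimination — nearby REM runs (separated by at most
   ``merge_gap`` NREM epochs) merge into one REM period, then any remaining
   REM run shorter than 3 epochs becomes NREM.  WAKE epochs are never
   touched by this rule.

Every mutation is recorded in a rule log ``(epoch, rule, old, new)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .hypnogram import WAKE, NREM, REM, STAGE_NAMES, Hypnogram


@dataclass
class RuleLog:
    """Chronological record of every post-processing label change."""

    entries: list[tuple[int, str, str, str]] = field(default_factory=list)

    def record(self, epoch: int, rule: str, old: int, new: int) -> None:
        self.entries.append((epoch, rule, STAGE_NAMES[old], STAGE_NAMES[new]))

    def count(self, rule: str | None = None) -> int:
        if rule is None:
            return len(self.entries)
        return sum(1 for e in self.entries if e[1] == rule)

    def __len__(self) -> int:
        return len(self.entries)


def _apply(stages: np.ndarray, idx, new: int, rule: str, log: RuleLog | None):
    for i in np.atleast_1d(idx):
        i = int(i)
        if stages[i] != new:
            if log is not None:
                log.record(i, rule, int(stages[i]), new)
            stages[i] = new


def wrmenad_correction(
    stages: np.ndarray,
    absence_flags: np.ndarray | None = None,
    log: RuleLog | None = None,
) -> np.ndarray:
    """Absence epochs -> WAKE, then lone sandwiched sleep epochs -> WAKE.

    The sandwich rule evaluates all epochs against the post-absence labels
    simultaneously; flipping a lone sleep epoch cannot create a new lone
    sleep epoch, so one pass is idempotent.
    """
    out = np.asarray(stages, dtype=np.int8).copy()
    if absence_flags is not None:
        absence_flags = np.asarray(absence_flags)
        if absence_flags.size != out.size:
            raise InputError("flags and stages must have equal length")
        _apply(out, np.flatnonzero(absence_flags.astype(bool)), WAKE,
               "wrmenad_absence", log)
    is_sleep = out != WAKE
    lone = np.zeros_like(is_sleep)
    if out.size >= 3:
        lone[1:-1] = is_sleep[1:-1] & ~is_sleep[:-2] & ~is_sleep[2:]
    _apply(out, np.flatnonzero(lone), WAKE, "wrmenad_sandwich", log)
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean mask as half-open (start, end) pairs."""
    edges = np.diff(np.concatenate(([0], mask.astype(int), [0])))
    return list(zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)))


def sound_wake_detection(
    stages: np.ndarray,
    ci_norm: np.ndarray,
    se: np.ndarray,
    theta_ci: float = 0.05,
    theta_se: int = 1,
    run_bounds: tuple[int, int] = (110, 170),
    log: RuleLog | None = None,
) -> np.ndarray:
    """Relabel long zero-CI runs as WAKE.

    The per-recording-normalized CI value is first zeroed on epochs with
    SE < ``theta_se`` and CI < ``theta_ci`` (eliminating spurious low CI
    during sleep); each maximal run of zero-CI epochs with length inside
    ``run_bounds`` (inclusive) then becomes WAKE.
    """
    out = np.asarray(stages, dtype=np.int8).copy()
    ci = np.asarray(ci_norm, dtype=float).copy()
    se = np.asarray(se)
    if not (ci.size == se.size == out.size):
        raise InputError("stages, CI and SE must have equal length")
    ci[(se < theta_se) & (ci < theta_ci)] = 0.0
    lo, hi = run_bounds
    for start, end in _runs(ci == 0.0):
        if lo <= end - start <= hi:
            _apply(out, np.arange(start, end), WAKE, "sound_wake", log)
    return out


def rem_outlier_elimination(
    stages: np.ndarray,
    merge_gap: int = 2,
    min_run: int = 3,
    log: RuleLog | None = None,
) -> np.ndarray:
    """Merge nearby REM runs, then drop surviving runs shorter than 3 epochs.

    Two REM runs merge when separated by at most ``merge_gap`` epochs that
    are all NREM (the gap epochs become REM); remaining REM runs shorter
    than ``min_run`` become NREM.  WAKE epochs are never altered.
    """
    out = np.asarray(stages, dtype=np.int8).copy()
    runs = _runs(out == REM)
    for (s1, e1), (s2, _) in zip(runs, runs[1:]):
        gap = out[e1:s2]
        if gap.size <= merge_gap and (gap == NREM).all():
            _apply(out, np.arange(e1, s2), REM, "rem_merge", log)
    for start, end in _runs(out == REM):
        if end - start < min_run:
            _apply(out, np.arange(start, end), NREM, "rem_eliminate", log)
    return out


def finalize(
    stages: np.ndarray,
    absence_flags: np.ndarray | None = None,
    ci_norm: np.ndarray | None = None,
    se: np.ndarray | None = None,
    theta_ci: float = 0.05,
    theta_se: int = 1,
    run_bounds: tuple[int, int] = (110, 170),
    merge_gap: int = 2,
    min_run: int = 3,
) -> tuple[Hypnogram, RuleLog]:
    """Apply the full post-decision rule chain in its fixed order.

    WRMEnAD correction, then (when CI/SE are available, i.e. fusion mode)
    sound-based wake detection, then REM outlier elimination.  The chain is
    repeated until no rule fires (the sound rule can occasionally leave a
    fresh lone sleep epoch for the sandwich rule), which makes the whole
    operation idempotent; in practice one pass almost always suffices.
    """
    log = RuleLog()
    out = np.asarray(stages, dtype=np.int8).copy()
    for _ in range(10):
        before = len(log)
        out = wrmenad_correction(out, absence_flags, log)
        if ci_norm is not None and se is not None:
            out = sound_wake_detection(
                out, ci_norm, se, theta_ci, theta_se, run_bounds, log
            )
        out = rem_outlier_elimination(out, merge_gap, min_run, log)
        if len(log) == before:
            break
    return Hypnogram(out), log
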