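"""Evaluation: per-stage accuracy against a reference hypnogram and
Bland-Altman agreement analysis between paired per-subject accuracy series.

Per-stage accuracy is the recall of that stage — the fraction of
reference-stage epochs the prediction also scores as that stage, times 100.
Total accuracy is the overall fraction of correctly scored epochs times 100.
A stage absent from the reference has an undefined denominator and is
reported as missing (NaN), never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .hypnogram import WAKE, NREM, REM, STAGE_NAMES, Hypnogram

TOTAL = "TOTAL"


def _stages(h) -> np.ndarray:
    return h.stages if isinstance(h, Hypnogram) else np.asarray(h, dtype=int)


def stage_accuracy(pred, ref, stage=TOTAL) -> float:
    """Accuracy (%) of one stage, or overall when ``stage`` is ``TOTAL``.

    Stage accuracy is recall: epochs where both reference and prediction
    score the stage, over epochs where the reference scores it.  Returns
    NaN when the reference contains no epoch of the stage.
    """
    p, r = _stages(pred), _stages(ref)
    if p.size != r.size:
        raise InputError("prediction and reference must have equal length")
    if stage == TOTAL:
        return float(np.mean(p == r) * 100.0)
    denom = int(np.count_nonzero(r == stage))
    if denom == 0:
        return float("nan")
    return float(np.count_nonzero((r == stage) & (p == stage)) / denom * 100.0)


def accuracy_report(pred, ref) -> dict[str, float]:
    """Per-stage and total accuracies (%) for one subject."""
    return {
        "accuracy_wake": stage_accuracy(pred, ref, WAKE),
        "accuracy_nrem": stage_accuracy(pred, ref, NREM),
        "accuracy_rem": stage_accuracy(pred, ref, REM),
        "accuracy_total": stage_accuracy(pred, ref, TOTAL),
    }


def chance_levels(pred, ref) -> dict[str, float]:
    """Prevalence-matched chance accuracies (%) under a permutation null.

    If predicted labels were randomly permuted against the reference, the
    expected recall of stage s equals the predicted prevalence of s, and the
    expected total accuracy is sum_s p_ref(s) * p_pred(s).
    """
    p, r = _stages(pred), _stages(ref)
    out: dict[str, float] = {}
    total = 0.0
    for code, name in STAGE_NAMES.items():
        p_pred = float(np.mean(p == code))
        p_ref = float(np.mean(r == code))
        out[f"chance_{name.lower()}"] = p_pred * 100.0
        total += p_pred * p_ref
    out["chance_total"] = total * 100.0
    return out


@dataclass
class BlandAltmanResult:
    """Bias, SD of paired differences and the 1.96-SD limits of agreement."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


def bland_altman(acc_a: np.ndarray, acc_b: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman agreement between two paired per-subject accuracy series.

    Differences d = a - b; bias = mean(d); sd = sample standard deviation of
    d; limits of agreement = bias +/- 1.96 sd.  Pair means (a + b)/2 are
    returned for plotting.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.size != b.size:
        raise InputError("series must be paired (equal length)")
    if a.size < 2:
        raise InputError("Bland-Altman needs at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=(a + b) / 2.0,
        diffs=d,
    )
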