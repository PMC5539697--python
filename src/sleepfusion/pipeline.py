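"""End-to-end orchestration: preprocess -> features -> staging -> post-process.

``extract_subject_features`` turns one subject's radar recording (plus
optional per-epoch sound features) into the per-epoch feature table with
WRMEnAD flags; ``train_from_cohort`` fits the two forests on a labelled
cohort; ``run_pipeline`` classifies one subject and, when a reference
hypnogram is given, evaluates the result.

Two modes exist: ``fusion`` runs everything; ``single-sensor`` skips the
snore context rule and the sound-based wake detection (the radar-only
baseline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import InputError
from .evaluate import accuracy_report, chance_levels
from .features import (
    FEATURE_NAMES,
    extract_features_table,
    normalize_ci,
    wrmenad_flags,
)
from .hypnogram import WAKE, NREM, REM, Hypnogram
from .postprocess import RuleLog, finalize, wrmenad_correction
from .preprocess import bandpass_decompose, frame_signal, select_channel
from .simulate import (
    QuadratureRecording,
    SoundFeatureSeries,
    SubjectRecord,
    simulate_cohort,
)
from .staging import (
    TrainedStager,
    decide_rem_nrem,
    decide_wake_sleep,
    fit_personal_thresholds,
    predict_likelihoods,
    smooth,
    train_stager,
)

logger = logging.getLogger(__name__)

MODES = ("fusion", "single-sensor")


@dataclass
class SubjectFeatures:
    """Per-epoch feature table and auxiliary series for one subject."""

    table: pd.DataFrame  # 52 columns, one row per epoch
    movement_flag: np.ndarray
    absence_flag: np.ndarray
    se: np.ndarray | None
    ci_norm: np.ndarray | None
    channel: str


def extract_subject_features(
    rec: QuadratureRecording,
    sound: SoundFeatureSeries | None = None,
    config: PipelineConfig | None = None,
) -> SubjectFeatures:
    """Channel-select, frame and featurize one radar recording.

    The selected channel is cut into 30-s epochs and each epoch is
    band-decomposed independently (the framed matrix is filtered along its
    last axis in one vectorized call); each epoch yields the 52 radar
    features plus WRMEnAD flags.  Sound features, when present, are aligned
    to the radar epochs and CI is normalized per recording.
    """
    config = config or PipelineConfig()
    channel, label = select_channel(rec)
    epochs = frame_signal(channel, rec.sample_rate, source_channel=label)
    n = epochs.n_epochs

    # filtering the framed (n_epochs, samples) matrix along axis -1 is
    # per-epoch zero-phase filtering, vectorized
    bands = bandpass_decompose(epochs.data, config.bands, rec.sample_rate)
    rows = extract_features_table(
        epochs.data, bands, rec.sample_rate, config.bands
    )
    table = pd.DataFrame(rows, columns=list(FEATURE_NAMES))

    move, absent, gamma_move, gamma_abs = wrmenad_flags(
        bands,
        config.thresholds.gamma_move,
        config.thresholds.gamma_abs,
        rec.sample_rate,
        config.thresholds.min_crossings,
    )
    logger.debug("wrmenad thresholds: move=%.3g abs=%.3g", gamma_move, gamma_abs)

    se = ci = None
    if sound is not None:
        if len(sound) < n:
            raise InputError("sound features shorter than radar recording")
        se = sound.SE[:n].copy()
        ci = normalize_ci(sound.CI[:n])
    return SubjectFeatures(table, move, absent, se, ci, label)


def train_from_cohort(
    records: list[SubjectRecord],
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> TrainedStager:
    """Extract features from every training subject and fit both forests."""
    config = config or PipelineConfig()
    tables, labels = [], []
    for rec in records:
        feats = extract_subject_features(rec.recording, rec.sound, config)
        n = feats.table.shape[0]
        tables.append(feats.table)
        labels.append(rec.hypnogram.stages[:n])
    features = pd.concat(tables, ignore_index=True)
    stages = np.concatenate(labels)
    return train_stager(
        features,
        stages,
        k_ws=config.forest.k_wake_sleep,
        k_rnr=config.forest.k_rem_nrem,
        n_estimators=config.forest.n_estimators,
        seed=seed,
    )


@dataclass
class PipelineResult:
    hypnogram: Hypnogram
    rule_log: RuleLog
    ws_ratio: np.ndarray
    report: dict | None = None
    mode: str = "fusion"


def classify_epochs(
    feats: SubjectFeatures,
    stager: TrainedStager,
    config: PipelineConfig,
    mode: str = "fusion",
) -> tuple[np.ndarray, RuleLog, np.ndarray]:
    """The fixed decision chain for one subject's feature table.

    Order: wake/sleep decision (with snore context in fusion mode) ->
    WRMEnAD correction -> NREM/REM decision with the REM-latency-windowed
    personal thresholds -> sound wake detection (fusion) -> REM outlier
    elimination.
    """
    thr = config.thresholds
    use_sound = mode == "fusion" and feats.se is not None

    ws = predict_likelihoods(
        stager.ws_forest, stager.ws_stats, stager.ws_features, feats.table
    )
    ws = smooth(ws, config.alpha)

    rnr_all = predict_likelihoods(
        stager.rnr_forest, stager.rnr_stats, stager.rnr_features, feats.table
    )
    rnr_all = smooth(rnr_all, config.alpha)

    thresholds = fit_personal_thresholds(
        ws.ratio, rnr_all.ratio, thr.eta, thr.eta_rnr, thr.delta,
        thr.latency_window,
    )

    sleep = decide_wake_sleep(
        ws,
        thresholds.gamma_ws,
        se=feats.se if use_sound else None,
        theta_se=thr.theta_se,
    )
    stages = np.where(sleep, NREM, WAKE).astype(np.int8)

    log = RuleLog()
    stages = wrmenad_correction(stages, feats.absence_flag, log)

    sleep_idx = np.flatnonzero(stages != WAKE)
    if sleep_idx.size:
        onset = int(sleep_idx[0])
        rem = decide_rem_nrem(
            rnr_all.ratio[sleep_idx], thresholds, sleep_idx, onset
        )
        stages[sleep_idx[rem]] = REM

    final, post_log = finalize(
        stages,
        absence_flags=feats.absence_flag,
        ci_norm=feats.ci_norm if use_sound else None,
        se=feats.se if use_sound else None,
        theta_ci=thr.theta_ci,
        theta_se=thr.theta_se_ci,
        run_bounds=thr.run_bounds,
        merge_gap=thr.merge_gap,
        min_run=thr.min_rem_run,
    )
    log.entries.extend(post_log.entries)
    return final.stages, log, ws.ratio


def cohort_experiment(
    n_train: int = 6,
    n_test: int = 4,
    n_epochs: int = 720,
    seed: int = 1,
    config: PipelineConfig | None = None,
    modes: tuple[str, ...] = ("fusion", "single-sensor"),
) -> dict:
    """Simulate a cohort, train on the first subjects, evaluate on the rest.

    For every test subject and mode the per-stage accuracies, the
    prevalence-matched chance levels and whether every programmed absence
    epoch ended up WAKE are recorded; cohort means (NaN-aware) are attached
    per mode.  Feature extraction runs once per test subject and is shared
    across modes.
    """
    config = config or PipelineConfig()
    cohort = simulate_cohort(n_train + n_test, n_epochs, seed=seed)
    stager = train_from_cohort(cohort[:n_train], config, seed=seed)
    out: dict = {mode: {"subjects": []} for mode in modes}
    for rec in cohort[n_train:]:
        feats = extract_subject_features(rec.recording, rec.sound, config)
        ref = rec.hypnogram.stages
        for mode in modes:
            stages, _, _ = classify_epochs(feats, stager, config, mode)
            entry = accuracy_report(stages, ref)
            entry.update(chance_levels(stages, ref))
            entry["absence_all_wake"] = all(
                bool((stages[a:b] == WAKE).all())
                for a, b in rec.profile.absence_intervals
            )
            entry["n_absence_epochs"] = int(
                sum(b - a for a, b in rec.profile.absence_intervals)
            )
            out[mode]["subjects"].append(entry)
    for mode in modes:
        subs = out[mode]["subjects"]
        for key in ("accuracy_wake", "accuracy_nrem", "accuracy_rem", "accuracy_total"):
            out[mode][f"mean_{key.split('_', 1)[1]}"] = float(
                np.nanmean([s[key] for s in subs])
            )
    out["n_train"], out["n_test"], out["n_epochs"] = n_train, n_test, n_epochs
    out["stager"] = stager
    return out


def run_pipeline(
    rec: QuadratureRecording,
    sound: SoundFeatureSeries | None,
    stager: TrainedStager,
    config: PipelineConfig | None = None,
    mode: str = "fusion",
    reference: Hypnogram | None = None,
) -> PipelineResult:
    """Classify one subject end to end; evaluate if a reference is given."""
    if mode not in MODES:
        raise InputError(f"mode must be one of {MODES}")
    config = config or PipelineConfig()
    feats = extract_subject_features(rec, sound, config)
    stages, log, ws_ratio = classify_epochs(feats, stager, config, mode)
    hyp = Hypnogram(stages)
    report = None
    if reference is not None:
        n = min(len(hyp), reference.n_epochs)
        report = accuracy_report(hyp.stages[:n], reference.stages[:n])
    return PipelineResult(hyp, log, ws_ratio, report, mode)
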