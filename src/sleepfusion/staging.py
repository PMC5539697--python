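"""Two-stage random-forest sleep staging.

A wake/sleep forest runs on all epochs and a NREM/REM forest on the epochs
decided as sleep.  Both consume z-score-normalized subsets of the 52 radar
features (44 for wake/sleep, 35 for NREM/REM, ranked by a class-separation
score on training data).  Forest class likelihoods are recursively smoothed,

    p~_c(i) = alpha * p~_c(i-1) + (1 - alpha) * p_c(i),   alpha = 0.9,

and converted to a per-epoch likelihood ratio R = p~_1 / (p~_0 + eps).  The
decision cutoff is *personal*: a percentile of the subject's own ratio
distribution (nearest-rank), so that inter-subject signal-scale differences
do not move the operating point.  A snore-based context rule rescues
misclassified wake epochs inside sleep blocks, and the NREM/REM cutoff is
stricter during the first 50 min after sleep onset (REM latency).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import ConfigurationError, InputError, SchemaError

logger = logging.getLogger(__name__)

EPS_RATIO: float = 1e-6
DEFAULT_ALPHA: float = 0.9
DEFAULT_K_WAKE_SLEEP: int = 44
DEFAULT_K_REM_NREM: int = 35
FIRST_MINUTE_EPOCHS: int = 2  # "awake for the first minute" = 2 x 30 s
DEFAULT_LATENCY_WINDOW: int = 100  # 50 min of 30-s epochs


@dataclass
class NormalizationStats:
    """Per-feature training means and standard deviations (z-scoring).

    Features with zero training variance are dropped from the model and
    logged; ``sigma`` therefore is strictly positive.
    """

    names: list[str]
    mu: np.ndarray
    sigma: np.ndarray

    @classmethod
    def fit(cls, table: pd.DataFrame) -> "NormalizationStats":
        mu = table.mean(axis=0).to_numpy()
        sigma = table.std(axis=0, ddof=0).to_numpy()
        keep = sigma > 0
        dropped = [n for n, k in zip(table.columns, keep) if not k]
        if dropped:
            logger.info("dropping zero-variance features: %s", dropped)
        return cls(
            names=[n for n, k in zip(table.columns, keep) if k],
            mu=mu[keep],
            sigma=sigma[keep],
        )

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        missing = [n for n in self.names if n not in table.columns]
        if missing:
            raise SchemaError(f"feature table lacks columns {missing}")
        sub = table[self.names].to_numpy(dtype=float)
        return pd.DataFrame(
            (sub - self.mu) / self.sigma, columns=self.names, index=table.index
        )


def normalize(table: pd.DataFrame, stats: NormalizationStats) -> pd.DataFrame:
    """Apply training-set z-scoring (F - mu_n) / sigma_n to a feature table."""
    return stats.transform(table)


def select_features(
    table: pd.DataFrame, labels: np.ndarray, k: int
) -> list[str]:
    """Rank features by absolute standardized mean difference; keep top k.

    The score for feature F is |mean(F | class 1) - mean(F | class 0)| over
    the pooled standard deviation, computed on training data.  Ties keep the
    original column order (stable sort).
    """
    if k > table.shape[1]:
        raise ConfigurationError(
            f"cannot select {k} features from {table.shape[1]}"
        )
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise InputError("feature selection needs two classes")
    x = table.to_numpy(dtype=float)
    m1 = x[y == 1].mean(axis=0)
    m0 = x[y == 0].mean(axis=0)
    pooled = np.sqrt(0.5 * (x[y == 1].var(axis=0) + x[y == 0].var(axis=0)))
    score = np.abs(m1 - m0) / (pooled + 1e-12)
    order = np.argsort(-score, kind="stable")[:k]
    return [table.columns[i] for i in sorted(order)]


@dataclass
class LikelihoodSeries:
    """Per-epoch class likelihoods of a binary stager.

    ``p0``/``p1`` are the raw forest vote fractions (p0 + p1 = 1);
    ``p0_smooth``/``p1_smooth`` the recursively smoothed values and ``ratio``
    the smoothed likelihood ratio p~1 / (p~0 + eps).
    """

    p0: np.ndarray
    p1: np.ndarray
    p0_smooth: np.ndarray | None = None
    p1_smooth: np.ndarray | None = None
    ratio: np.ndarray | None = None

    def __len__(self) -> int:
        return int(self.p0.size)


@dataclass
class PersonalThresholds:
    """Personal-adjusted decision thresholds for one recording.

    ``gamma_rnr1`` (inside the REM latency window) is at least
    ``gamma_rnr2`` — stricter REM evidence is required early in the night.
    """

    gamma_ws: float
    gamma_rnr1: float
    gamma_rnr2: float
    eta: float = 30.0
    eta_rnr: float = 75.0
    delta: float = 20.0
    latency_window: int = DEFAULT_LATENCY_WINDOW


@dataclass
class TrainedStager:
    """The two trained forests plus their feature lists and normalizers."""

    ws_forest: RandomForestClassifier
    rnr_forest: RandomForestClassifier
    ws_features: list[str]
    rnr_features: list[str]
    ws_stats: NormalizationStats
    rnr_stats: NormalizationStats
    seed: int = 0
    schema_version: int = 1

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "TrainedStager":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise InputError(f"{path} is not a stager bundle")
        return obj


def train_stager(
    features: pd.DataFrame,
    stages: np.ndarray,
    k_ws: int = DEFAULT_K_WAKE_SLEEP,
    k_rnr: int = DEFAULT_K_REM_NREM,
    n_estimators: int = 500,
    seed: int = 0,
) -> TrainedStager:
    """Train the wake/sleep and NREM/REM forests on a labelled cohort table.

    ``stages`` are integer WAKE/NREM/REM codes.  The wake/sleep forest is
    trained on all epochs (wake vs NREM+REM); the NREM/REM forest on
    sleep-labelled epochs only.  Fully deterministic under ``seed``.
    """
    from .hypnogram import WAKE, REM

    stages = np.asarray(stages).astype(int)
    if features.shape[0] != stages.size:
        raise InputError("features and stages must have equal length")

    y_ws = (stages != WAKE).astype(int)  # 1 = sleep
    if len(np.unique(y_ws)) < 2:
        raise InputError("training set must contain wake and sleep epochs")
    sleep_mask = stages != WAKE
    y_rnr = (stages[sleep_mask] == REM).astype(int)  # 1 = REM
    if len(np.unique(y_rnr)) < 2:
        raise InputError("training set must contain NREM and REM epochs")

    ws_stats = NormalizationStats.fit(features)
    ws_norm = ws_stats.transform(features)
    ws_feats = select_features(ws_norm, y_ws, min(k_ws, ws_norm.shape[1]))
    ws_forest = RandomForestClassifier(
        n_estimators=n_estimators, max_features="sqrt",
        random_state=seed, n_jobs=1, oob_score=True,
    )
    ws_forest.fit(ws_norm[ws_feats].to_numpy(), y_ws)

    sleep_table = features.loc[sleep_mask]
    rnr_stats = NormalizationStats.fit(sleep_table)
    rnr_norm = rnr_stats.transform(sleep_table)
    rnr_feats = select_features(rnr_norm, y_rnr, min(k_rnr, rnr_norm.shape[1]))
    rnr_forest = RandomForestClassifier(
        n_estimators=n_estimators, max_features="sqrt",
        random_state=seed + 1, n_jobs=1, oob_score=True,
    )
    rnr_forest.fit(rnr_norm[rnr_feats].to_numpy(), y_rnr)

    return TrainedStager(
        ws_forest, rnr_forest, ws_feats, rnr_feats, ws_stats, rnr_stats, seed
    )


def predict_likelihoods(
    forest: RandomForestClassifier,
    stats: NormalizationStats,
    feature_names: list[str],
    table: pd.DataFrame,
) -> LikelihoodSeries:
    """Per-epoch (p0, p1) vote fractions of one forest on a feature table."""
    norm = stats.transform(table)
    missing = [n for n in feature_names if n not in norm.columns]
    if missing:
        raise SchemaError(f"feature table lacks columns {missing}")
    proba = forest.predict_proba(norm[feature_names].to_numpy())
    # column order follows forest.classes_ = [0, 1]
    p0 = proba[:, list(forest.classes_).index(0)]
    p1 = proba[:, list(forest.classes_).index(1)]
    return LikelihoodSeries(p0=p0, p1=p1)


def smooth(series: LikelihoodSeries, alpha: float = DEFAULT_ALPHA) -> LikelihoodSeries:
    """First-order recursive likelihood smoothing.

    p~_c(i) = alpha p~_c(i-1) + (1 - alpha) p_c(i), initialized at
    p~_c(1) = p_c(1); the ratio R = p~1 / (p~0 + eps) is recomputed from the
    smoothed values.
    """
    if not 0.0 <= alpha < 1.0:
        raise ConfigurationError("alpha must be in [0, 1)")
    out = {}
    for name in ("p0", "p1"):
        p = getattr(series, name)
        sm = np.empty_like(p, dtype=float)
        sm[0] = p[0]
        for i in range(1, p.size):
            sm[i] = alpha * sm[i - 1] + (1 - alpha) * p[i]
        out[name + "_smooth"] = sm
    ratio = out["p1_smooth"] / (out["p0_smooth"] + EPS_RATIO)
    return LikelihoodSeries(series.p0, series.p1, ratio=ratio, **out)


def personal_threshold(ratios: np.ndarray, eta: float) -> float:
    """Nearest-rank percentile of the ascending-sorted likelihood ratios.

    rank = ceil(eta / 100 * n), clamped to [1, n].
    """
    r = np.sort(np.asarray(ratios, dtype=float))
    if r.size == 0:
        raise InputError("ratio sequence is empty")
    if not 0.0 <= eta <= 100.0:
        raise ConfigurationError("eta must be in [0, 100]")
    rank = min(max(math.ceil(eta / 100.0 * r.size), 1), r.size)
    return float(r[rank - 1])


def apply_snore_context(
    decisions: np.ndarray,
    se: np.ndarray,
    theta_se: int = 2,
    max_gap: int = 2,
) -> np.ndarray:
    """Snore-based context correction of wake/sleep decisions.

    An epoch decided WAKE with SE >= ``theta_se`` whose nearest SLEEP
    neighbours on both sides are at most ``max_gap`` epochs away is
    relabelled SLEEP (people rarely snore while awake).  SLEEP epochs are
    never flipped to WAKE.
    """
    sleep = np.asarray(decisions, dtype=bool).copy()
    se = np.asarray(se)
    if sleep.size != se.size:
        raise InputError("decisions and SE must have equal length")
    idx_sleep = np.flatnonzero(sleep)
    if idx_sleep.size == 0:
        return sleep
    for i in np.flatnonzero(~sleep):
        if se[i] < theta_se:
            continue
        left = idx_sleep[idx_sleep < i]
        right = idx_sleep[idx_sleep > i]
        if (
            left.size and right.size
            and i - left[-1] <= max_gap and right[0] - i <= max_gap
        ):
            sleep[i] = True
    return sleep


def decide_wake_sleep(
    series: LikelihoodSeries,
    gamma_ws: float,
    se: np.ndarray | None = None,
    theta_se: int = 2,
    snore_max_gap: int = 2,
    first_wake_epochs: int = FIRST_MINUTE_EPOCHS,
) -> np.ndarray:
    """Per-epoch wake/sleep decision (True = sleep).

    SLEEP iff R(i) > gamma_ws; the first two epochs are forced WAKE (a
    person is awake for the first minute); when snore counts are supplied
    the context correction is applied afterwards.
    """
    if series.ratio is None:
        raise InputError("series must be smoothed first (missing ratio)")
    sleep = series.ratio > gamma_ws
    sleep[:first_wake_epochs] = False
    if se is not None:
        sleep = apply_snore_context(sleep, se, theta_se, snore_max_gap)
    return sleep


def decide_rem_nrem(
    ratios: np.ndarray,
    thresholds: PersonalThresholds,
    epoch_indices: np.ndarray,
    sleep_onset_epoch: int,
) -> np.ndarray:
    """Per-sleep-epoch NREM/REM decision (True = REM).

    ``ratios`` are the NREM/REM likelihood ratios of the sleep epochs, whose
    absolute positions in the night are ``epoch_indices``.  Within the REM
    latency window after sleep onset the stricter threshold gamma_rnr1
    applies; afterwards gamma_rnr2.
    """
    ratios = np.asarray(ratios, dtype=float)
    epoch_indices = np.asarray(epoch_indices, dtype=int)
    if ratios.size != epoch_indices.size:
        raise InputError("ratios and epoch indices must have equal length")
    if ratios.size == 0:
        return np.zeros(0, dtype=bool)
    in_window = epoch_indices < sleep_onset_epoch + thresholds.latency_window
    rem = np.where(
        in_window, ratios > thresholds.gamma_rnr1, ratios > thresholds.gamma_rnr2
    )
    return rem.astype(bool)


def fit_personal_thresholds(
    ws_ratios: np.ndarray,
    rnr_ratios: np.ndarray,
    eta: float = 30.0,
    eta_rnr: float = 75.0,
    delta: float = 20.0,
    latency_window: int = DEFAULT_LATENCY_WINDOW,
) -> PersonalThresholds:
    """Personal-adjusted thresholds from a recording's own ratio sequences.

    gamma_ws sits at the eta-th percentile of the wake/sleep ratios;
    gamma_rnr2 at the eta_rnr-th percentile of the NREM/REM ratios and
    gamma_rnr1 delta percentile points higher (clamped at 100), weighting
    NREM more heavily inside the REM latency window.
    """
    gamma_ws = personal_threshold(ws_ratios, eta)
    gamma_rnr2 = personal_threshold(rnr_ratios, eta_rnr)
    gamma_rnr1 = personal_threshold(rnr_ratios, min(eta_rnr + delta, 100.0))
    return PersonalThresholds(
        gamma_ws, gamma_rnr1, gamma_rnr2, eta, eta_rnr, delta, latency_window
    )
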