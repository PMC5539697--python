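"""Pipeline configuration: one object (and one YAML file) for every tunable.

Sections mirror the processing stages: band edges, heuristic thresholds,
forest hyperparameters and simulation sizes.  Anything not set in a YAML
file keeps its default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .preprocess import BandEdges


@dataclass
class Thresholds:
    """Heuristic decision parameters.

    eta / eta_rnr / delta are the personal-threshold percentiles (wake/sleep
    cutoff, REM/NREM cutoff and the extra strictness inside the REM latency
    window); theta_se the snore-count floor of the context rule; theta_ci /
    theta_se_ci the CI-elimination cutoffs of the sound wake rule;
    run_bounds the zero-CI run lengths (epochs) relabelled as wake;
    merge_gap the REM merge distance; latency_window the 50-min REM latency
    in epochs; min_crossings the movement-flag envelope crossing count.
    """

    eta: float = 30.0
    eta_rnr: float = 75.0
    delta: float = 20.0
    theta_se: int = 2
    theta_se_ci: int = 1
    theta_ci: float = 0.05
    run_bounds: tuple[int, int] = (110, 170)
    merge_gap: int = 2
    min_rem_run: int = 3
    latency_window: int = 100
    min_crossings: int = 2
    gamma_move: float | None = None  # None = self-calibrating
    gamma_abs: float | None = None


@dataclass
class ForestParams:
    n_estimators: int = 500
    k_wake_sleep: int = 44
    k_rem_nrem: int = 35


@dataclass
class PipelineConfig:
    bands: BandEdges = field(default_factory=BandEdges)
    thresholds: Thresholds = field(default_factory=Thresholds)
    forest: ForestParams = field(default_factory=ForestParams)
    alpha: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ConfigurationError("alpha must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        if "bands" in raw:
            b = raw["bands"]
            cfg.bands = BandEdges(
                breathing=tuple(b.get("breathing", cfg.bands.breathing)),
                heartbeat=tuple(b.get("heartbeat", cfg.bands.heartbeat)),
                movement=tuple(b.get("movement", cfg.bands.movement)),
                order=int(b.get("order", cfg.bands.order)),
            )
        if "thresholds" in raw:
            t = dict(raw["thresholds"])
            if "run_bounds" in t:
                t["run_bounds"] = tuple(t["run_bounds"])
            cfg.thresholds = Thresholds(**{**asdict(cfg.thresholds), **t})
        if "forest" in raw:
            cfg.forest = ForestParams(**{**asdict(cfg.forest), **raw["forest"]})
        cfg.alpha = float(raw.get("alpha", cfg.alpha))
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"]["run_bounds"] = list(d["thresholds"]["run_bounds"])
        for k in ("breathing", "heartbeat", "movement"):
            d["bands"][k] = list(d["bands"][k])
        return d

    def digest(self) -> str:
        """Stable hash of the configuration, for run logs."""
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]
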