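"""Signal-detection observer and whole-session behavioral simulation.

The observer holds a lever and releases it either because it detected the
contrast increment (hit), because its constant-hazard guessing process fired
before detection was possible (false alarm), or not at all (miss).  Detection
probability follows a Weibull function of contrast with a lapse rate, and the
Weibull threshold grows linearly with LED intensity above an onset intensity
(a hinge), which is the generative counterpart of the dose-response fits in
:mod:`optodetect.dose_response`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .timing import SimulationError, TaskConfig, draw_trial_timing

__all__ = [
    "ObserverParams",
    "TrialRecord",
    "Session",
    "SessionConfig",
    "simulate_observer_trial",
    "simulate_session",
    "simulate_spot_sessions",
]


@dataclass(frozen=True)
class ObserverParams:
    """Generative observer parameters.

    alpha0
        Baseline Weibull contrast threshold (% contrast) without inhibition.
    beta
        Weibull slope (dimensionless).
    lapse
        Lapse rate: miss probability on arbitrarily easy trials.
    fa_hazard
        Constant false-alarm hazard (events per second).
    slope_true, i0_true
        Hinge linking LED intensity (mW/mm^2) to percent threshold increase:
        threshold(I) = alpha0 * (1 + max(0, slope_true*(I - i0_true))/100).
    """

    alpha0: float = 12.0
    beta: float = 3.0
    lapse: float = 0.05
    fa_hazard: float = 0.1
    slope_true: float = 295.9
    i0_true: float = 0.112

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse < 1.0:
            raise ValueError("lapse must lie in [0, 1)")
        if self.alpha0 <= 0 or self.beta <= 0:
            raise ValueError("alpha0 and beta must be positive")
        if self.fa_hazard < 0:
            raise ValueError("fa_hazard must be nonnegative")

    def threshold_at(self, intensity: float) -> float:
        """Weibull threshold (% contrast) at a given LED intensity."""
        rise = max(0.0, self.slope_true * (intensity - self.i0_true))
        return self.alpha0 * (1.0 + rise / 100.0)


@dataclass
class TrialRecord:
    trial_type: str  # "ON" | "OFF"
    contrast: float  # % contrast
    intensity: float  # LED intensity, mW/mm^2
    planned_onset_ms: float
    actual_onset_ms: float
    pulse_phase_ms: float
    outcome: str  # "hit" | "miss" | "false_alarm"
    release_ms: float | None
    trial_len_ms: float


@dataclass
class Session:
    """One day's trials plus light-spot metadata."""

    trials: list[TrialRecord]
    spot_id: str = "spot0"
    area_label: str = "V1"
    intensities: tuple[float, ...] = (0.0,)
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(t) for t in self.trials])
        df["spot_id"] = self.spot_id
        df["area_label"] = self.area_label
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **meta) -> "Session":
        cols = [f.name for f in TrialRecord.__dataclass_fields__.values()]
        trials = [
            TrialRecord(**{c: (None if pd.isna(row[c]) else row[c]) for c in cols})
            for _, row in df.iterrows()
        ]
        spot = meta.pop("spot_id", df["spot_id"].iloc[0] if "spot_id" in df else "spot0")
        area = meta.pop(
            "area_label", df["area_label"].iloc[0] if "area_label" in df else "V1"
        )
        intens = meta.pop(
            "intensities", tuple(sorted(df["intensity"].unique()))
        )
        return cls(trials, spot_id=spot, area_label=area, intensities=tuple(intens), metadata=meta)


@dataclass(frozen=True)
class SessionConfig:
    """What one behavioral session presents: contrast set, LED intensity, size."""

    contrasts: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0, 48.0)
    intensity: float = 0.0
    n_trials: int = 384
    spot_id: str = "spot0"
    area_label: str = "V1"
    task: TaskConfig = field(default_factory=TaskConfig)

    def __post_init__(self) -> None:
        if len(self.contrasts) == 0:
            raise ValueError("contrast set must be non-empty")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")


def simulate_observer_trial(
    timing: tuple[float, float, float],
    contrast: float,
    intensity: float,
    params: ObserverParams,
    config: TaskConfig,
    rng: np.random.Generator,
    trial_type: str = "ON",
) -> TrialRecord:
    """Roll one trial's outcome given its timing.

    The false-alarm candidate is exponential with rate ``fa_hazard``; it wins
    if it lands before ``actual_onset + fa_cutoff`` (after that, a release can
    only be a response to the stimulus).  Otherwise the stimulus is detected
    with Weibull probability at the intensity-adjusted threshold; detected
    trials release uniformly within the reaction window past the cutoff.
    """
    if contrast < 0 or intensity < 0:
        raise ValueError("contrast and intensity must be nonnegative")
    planned, phase, actual = timing
    # Only ON trials see the light during the stimulus response.
    eff_intensity = intensity if trial_type == "ON" else 0.0
    alpha_i = params.threshold_at(eff_intensity)

    if params.fa_hazard > 0:
        t_fa = rng.exponential(1000.0 / params.fa_hazard)
    else:
        t_fa = np.inf
    fa_deadline = actual + config.fa_cutoff_ms
    if t_fa < fa_deadline:
        return TrialRecord(
            trial_type, contrast, intensity, planned, actual, phase,
            "false_alarm", t_fa, t_fa,
        )
    p_detect = (1.0 - params.lapse) * (1.0 - np.exp(-((contrast / alpha_i) ** params.beta)))
    if rng.random() < p_detect:
        release = actual + rng.uniform(config.fa_cutoff_ms, config.react_win_ms)
        return TrialRecord(
            trial_type, contrast, intensity, planned, actual, phase,
            "hit", release, release,
        )
    return TrialRecord(
        trial_type, contrast, intensity, planned, actual, phase,
        "miss", None, actual + config.react_win_ms,
    )


def simulate_session(
    session_config: SessionConfig,
    params: ObserverParams,
    rng: np.random.Generator,
) -> Session:
    """Simulate one behavioral session (bit-reproducible for a seeded rng).

    Trial types are ON with probability ``p_on``; contrasts are drawn
    uniformly from the configured set.  Planned onsets that cannot be placed
    for an OFF trial (the OFF grid starts one pulse period into the trial)
    are redrawn in full, mirroring the truncation the task geometry imposes.
    """
    cfg = session_config
    task = cfg.task
    trials: list[TrialRecord] = []
    for _ in range(cfg.n_trials):
        trial_type = "ON" if rng.random() < task.p_on else "OFF"
        contrast = float(rng.choice(cfg.contrasts))
        timing = None
        for _attempt in range(task.retry_budget):
            try:
                timing = draw_trial_timing(task, trial_type, rng)
                break
            except SimulationError:
                continue
        if timing is None:
            raise SimulationError("could not place trial within retry budget")
        trials.append(
            simulate_observer_trial(
                timing, contrast, cfg.intensity, params, task, rng,
                trial_type=trial_type,
            )
        )
    return Session(
        trials,
        spot_id=cfg.spot_id,
        area_label=cfg.area_label,
        intensities=(cfg.intensity,),
    )


def simulate_spot_sessions(
    intensities: Sequence[float],
    n_sessions: int,
    params: ObserverParams,
    rng: np.random.Generator,
    session_config: SessionConfig | None = None,
    spot_id: str = "spot0",
    area_label: str = "V1",
) -> list[Session]:
    """Sessions for one light spot, cycling through the intensity schedule."""
    base = session_config or SessionConfig()
    sessions = []
    for i in range(n_sessions):
        cfg = SessionConfig(
            contrasts=base.contrasts,
            intensity=float(intensities[i % len(intensities)]),
            n_trials=base.n_trials,
            spot_id=spot_id,
            area_label=area_label,
            task=base.task,
        )
        sessions.append(simulate_session(cfg, params, rng))
    return sessions
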