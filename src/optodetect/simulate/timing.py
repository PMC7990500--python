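"""Task timing engine: pulse trains and stimulus-onset scheduling.

The change-detection task runs an optogenetic pulse train on *every* trial
(200 ms on / 1000 ms off by default, i.e. a 1200 ms period) whose phase is
drawn uniformly at random so the train carries no information about stimulus
time.  Stimulus onsets are drawn from a shifted, discretized geometric
distribution (an approximately flat-hazard schedule) and then adjusted
*downward* onto the pulse grid:

* ON trials  -- the stimulus lands ``stim_to_pulse_ms`` (55 ms) before the
  onset of the coincident pulse, so the light arrives just before visually
  evoked spikes reach cortex.
* OFF trials -- the stimulus lands ``off_gap_ms`` (820 ms) after the offset
  of the *preceding* pulse, i.e. late in the inter-pulse gap, 180 ms before
  the next pulse.

Because OFF placement requires a real preceding pulse, the earliest possible
OFF onset is one pulse period into the trial; this makes OFF trials run
longer than ON trials on average, as observed experimentally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TaskConfig",
    "SimulationError",
    "generate_pulse_train",
    "draw_trial_timing",
]


class SimulationError(RuntimeError):
    """Raised when trial geometry cannot be satisfied within the retry budget."""


@dataclass(frozen=True)
class TaskConfig:
    """Timing parameters of the detection task (all durations in ms)."""

    pulse_on_ms: float = 200.0
    pulse_off_ms: float = 1000.0
    stim_to_pulse_ms: float = 55.0
    off_gap_ms: float = 820.0
    min_onset_ms: float = 400.0
    max_hold_ms: float = 4100.0
    onset_mean_ms: float = 1400.0
    react_win_ms: float = 550.0
    fa_cutoff_ms: float = 100.0
    stim_dur_ms: float = 100.0
    p_on: float = 0.5
    retry_budget: int = field(default=100, repr=False)

    @property
    def period_ms(self) -> float:
        return self.pulse_on_ms + self.pulse_off_ms

    def __post_init__(self) -> None:
        if not self.off_gap_ms < self.pulse_off_ms:
            raise ValueError("off_gap_ms must be smaller than pulse_off_ms")
        if not self.fa_cutoff_ms < self.react_win_ms:
            raise ValueError("fa_cutoff_ms must be smaller than react_win_ms")
        if not self.min_onset_ms < self.max_hold_ms:
            raise ValueError("min_onset_ms must be smaller than max_hold_ms")
        if not self.onset_mean_ms > self.min_onset_ms:
            raise ValueError("onset_mean_ms must exceed min_onset_ms")


def generate_pulse_train(
    config: TaskConfig, phase_ms: float, horizon_ms: float
) -> np.ndarray:
    """Pulse (onset, offset) pairs covering ``[0, horizon_ms)``.

    Parameters
    ----------
    phase_ms
        Onset time of the first pulse, must lie in ``[0, period)``.

    Returns
    -------
    ndarray of shape (n_pulses, 2)
        One row per pulse whose onset falls before ``horizon_ms``.
    """
    period = config.period_ms
    if not 0.0 <= phase_ms < period:
        raise ValueError(f"phase_ms must lie in [0, {period}); got {phase_ms}")
    n = int(np.ceil(max(horizon_ms - phase_ms, 0.0) / period))
    onsets = phase_ms + period * np.arange(n)
    onsets = onsets[onsets < horizon_ms]
    return np.column_stack([onsets, onsets + config.pulse_on_ms])


def _draw_planned_onset(config: TaskConfig, rng: np.random.Generator) -> float:
    """Shifted 1 ms-resolution geometric onset, truncated at max_hold_ms."""
    mean_excess = config.onset_mean_ms - config.min_onset_ms
    p = min(1.0, 1.0 / mean_excess)
    planned = config.min_onset_ms + float(rng.geometric(p))
    return min(planned, config.max_hold_ms)


def _adjust_onset(
    planned_ms: float, phase_ms: float, trial_type: str, config: TaskConfig
) -> float | None:
    """Largest admissible grid onset <= planned, or None if no candidate.

    ON grid: pulse onsets minus stim_to_pulse_ms.  OFF grid: pulse offsets
    plus off_gap_ms (a preceding pulse must exist, so k >= 0 in both cases).
    """
    period = config.period_ms
    if trial_type == "ON":
        base = phase_ms - config.stim_to_pulse_ms
    elif trial_type == "OFF":
        base = phase_ms + config.pulse_on_ms + config.off_gap_ms
    else:
        raise ValueError(f"trial_type must be 'ON' or 'OFF'; got {trial_type!r}")
    k = int(np.floor((planned_ms - base) / period))
    if k < 0:
        return None
    candidate = base + k * period
    if candidate < config.min_onset_ms:
        return None
    return candidate


def draw_trial_timing(
    config: TaskConfig,
    trial_type: str,
    rng: np.random.Generator,
    planned_onset_ms: float | None = None,
) -> tuple[float, float, float]:
    """Draw (planned_onset_ms, pulse_phase_ms, actual_onset_ms) for one trial.

    The planned onset is drawn once; the pulse-train phase is redrawn (up to
    the retry budget) until an admissible adjusted onset exists.

    Raises
    ------
    SimulationError
        If no phase yields an admissible onset within the retry budget
        (e.g. an OFF trial whose planned onset precedes the earliest
        possible post-pulse slot).
    """
    planned = (
        _draw_planned_onset(config, rng)
        if planned_onset_ms is None
        else float(planned_onset_ms)
    )
    for _ in range(config.retry_budget):
        phase = float(rng.uniform(0.0, config.period_ms))
        actual = _adjust_onset(planned, phase, trial_type, config)
        if actual is not None:
            return planned, phase, actual
    raise SimulationError(
        f"no admissible {trial_type} onset for planned={planned:.0f} ms "
        f"after {config.retry_budget} phase redraws"
    )
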