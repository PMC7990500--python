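"""Poisson spiking units under optogenetic suppression.

Each simulated unit fires as an inhomogeneous Poisson process: a constant
baseline rate plus a visually evoked logistic rise whose half-max sits at the
unit's visual latency.  From LED onset on, the whole rate is multiplied by a
suppression factor that falls off as a Gaussian both in LED intensity and in
cortical distance from the light-spot center:

    supp(I, d) = 1 - (1 - exp(-I^2 / (2 sigma_I^2))) * exp(-d^2 / (2 sigma_d^2))

so a unit under the spot (d = 0) at intensity I keeps a fraction
``exp(-I^2/(2 sigma_I^2))`` of its rate, and far-away units are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["UnitConfig", "simulate_unit", "suppression_factor"]

SQRT_2LN2 = float(np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class UnitConfig:
    """Generative parameters for one simulated unit.

    Times are in ms from trial start.  Defaults place the LED pulse onset at
    100 ms and the visual stimulus 10 ms later, so the inhibitory-minimum
    window (25 ms after LED onset) closes before visually evoked spikes
    arrive, as in the recording design.
    """

    baseline_hz: float = 5.0
    evoked_hz: float = 25.0
    latency_ms: float = 65.0  # half-max of the visual rise, post-stimulus
    rise_tau_ms: float = 6.0
    sigma_i: float = 0.2 / SQRT_2LN2  # intensity falloff scale -> I50 = 0.2
    sigma_d_mm: float = 0.73 / (2.0 * SQRT_2LN2)  # distance falloff -> FWHM 0.73 mm
    led_on_ms: float = 100.0
    stim_on_ms: float = 110.0
    trial_len_ms: float = 350.0

    def __post_init__(self) -> None:
        if self.baseline_hz < 0 or self.evoked_hz < 0:
            raise ValueError("rates must be nonnegative")


def suppression_factor(config: UnitConfig, intensity: float, distance_mm: float = 0.0) -> float:
    """Multiplicative rate factor in [0, 1] during the LED pulse."""
    g_i = np.exp(-(intensity**2) / (2.0 * config.sigma_i**2))
    g_d = np.exp(-(distance_mm**2) / (2.0 * config.sigma_d_mm**2))
    return float(1.0 - (1.0 - g_i) * g_d)


def _rate(t_ms: np.ndarray, config: UnitConfig, intensity: float, distance_mm: float) -> np.ndarray:
    from scipy.special import expit

    evoked = config.evoked_hz * expit(
        (t_ms - config.stim_on_ms - config.latency_ms) / config.rise_tau_ms
    )
    rate = config.baseline_hz + evoked
    supp = suppression_factor(config, intensity, distance_mm)
    return np.where(t_ms >= config.led_on_ms, rate * supp, rate)


def simulate_unit(
    config: UnitConfig,
    intensities,
    n_trials: int,
    rng: np.random.Generator,
    unit_id: str = "u0",
    distance_mm: float = 0.0,
    area_label: str = "V1",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one unit across LED intensities.

    Returns
    -------
    spikes : DataFrame with columns unit_id, intensity, trial, spike_time_ms
    events : DataFrame with columns intensity, trial, led_on_ms, stim_on_ms,
             trial_len_ms, area_label, distance_mm
    """
    rate_max = config.baseline_hz + config.evoked_hz
    spikes_rows = []
    events_rows = []
    for intensity in np.atleast_1d(np.asarray(intensities, dtype=float)):
        if intensity < 0:
            raise ValueError("intensity must be nonnegative")
        for trial in range(n_trials):
            n_cand = rng.poisson(rate_max * config.trial_len_ms / 1000.0)
            t_cand = np.sort(rng.uniform(0.0, config.trial_len_ms, size=n_cand))
            keep = rng.random(n_cand) < _rate(t_cand, config, intensity, distance_mm) / rate_max
            for t in t_cand[keep]:
                spikes_rows.append((unit_id, intensity, trial, t))
            events_rows.append(
                (unit_id, intensity, trial, config.led_on_ms, config.stim_on_ms,
                 config.trial_len_ms, area_label, distance_mm)
            )
    spikes = pd.DataFrame(
        spikes_rows, columns=["unit_id", "intensity", "trial", "spike_time_ms"]
    )
    events = pd.DataFrame(
        events_rows,
        columns=["unit_id", "intensity", "trial", "led_on_ms", "stim_on_ms",
                 "trial_len_ms", "area_label", "distance_mm"],
    )
    return spikes, events
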