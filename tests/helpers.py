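"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd

from optodetect.simulate.timing import SimulationError, TaskConfig, draw_trial_timing


def censored_constant_hazard_trials(
    seed: int,
    n_trials: int = 5000,
    hazard_per_s: float = 0.1,
    config: TaskConfig | None = None,
) -> pd.DataFrame:
    """Trials whose length equals their at-risk time.

    Premature-release times are exponential with the given hazard; a trial
    ends at the release (a false alarm) or is censored when a false alarm
    stops being possible, at stimulus onset + fa_cutoff.  Because exposure
    and trial length coincide, the session-level hazard estimator is
    unbiased on this process.
    """
    rng = np.random.default_rng(seed)
    cfg = config or TaskConfig()
    rows = []
    while len(rows) < n_trials:
        trial_type = "ON" if rng.random() < cfg.p_on else "OFF"
        try:
            _, phase, onset = draw_trial_timing(cfg, trial_type, rng)
        except SimulationError:
            continue
        censor = onset + cfg.fa_cutoff_ms
        t_fa = rng.exponential(1000.0 / hazard_per_s)
        if t_fa < censor:
            rows.append((trial_type, "false_alarm", t_fa, t_fa, onset, phase))
        else:
            rows.append((trial_type, "miss", np.nan, censor, onset, phase))
    return pd.DataFrame(
        rows,
        columns=[
            "trial_type",
            "outcome",
            "release_ms",
            "trial_len_ms",
            "actual_onset_ms",
            "pulse_phase_ms",
        ],
    )


def weighted_line_fit(x, y, w):
    """Weighted least-squares line; returns (intercept, slope, slope_se, dof)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    X = np.column_stack([np.ones_like(x), x])
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ beta
    dof = len(x) - 2
    s2 = float((w * resid**2).sum()) / dof
    cov = s2 * np.linalg.inv(X.T @ (w[:, None] * X))
    return float(beta[0]), float(beta[1]), float(np.sqrt(cov[1, 1])), dof
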