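"""Signal-detection analysis for a temporally extended detection task.

With stimulus onset times randomized within the trial, the quantity that
plays the role of the false-alarm rate is the false-alarm *hazard*: the
probability per unit time of a premature release given the trial has lasted
that long.  This module estimates that hazard both as a binned curve and as a
per-session scalar, converts it to a windowed false-alarm probability, and
computes d' and the absolute/relative criterion from hit and false-alarm
rates via the usual normal-quantile transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "HazardCurve",
    "SDTStats",
    "hazard_binned",
    "hazard_estimated",
    "hazard_mle",
    "dprime_by_contrast",
    "criteria",
    "rate_correct",
]


@dataclass
class HazardCurve:
    bin_edges_ms: np.ndarray
    hazard_per_s: np.ndarray  # NaN where no trials survive / no exposure
    survivors: np.ndarray  # trials at risk at bin start (or exposure ms when folded)
    events: np.ndarray
    trial_type: str
    align: str


@dataclass
class SDTStats:
    H: float
    FA: float
    dprime: float
    c_abs: float
    c_rel: float
    fa_hazard_est: float


def _risk_times(df: pd.DataFrame, fa_cutoff_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """(time, is_event) per trial; non-FA trials are censored when a false
    alarm stops being possible (stimulus onset + cutoff)."""
    is_fa = (df["outcome"] == "false_alarm").to_numpy()
    t = np.where(
        is_fa,
        df["release_ms"].to_numpy(dtype=float),
        np.minimum(
            df["actual_onset_ms"].to_numpy(dtype=float) + fa_cutoff_ms,
            df["trial_len_ms"].to_numpy(dtype=float),
        ),
    )
    return t, is_fa


def hazard_binned(
    trials: pd.DataFrame,
    bin_ms: float = 1.0,
    align: str = "trial_start",
    period_ms: float = 1200.0,
    fa_cutoff_ms: float = 100.0,
    max_ms: float | None = None,
    trial_type: str | None = None,
) -> HazardCurve:
    """Binned false-alarm hazard, in units of probability per second.

    ``align='trial_start'``: classic life-table estimate — false alarms per
    bin divided by trials surviving to the bin start, scaled by 1000/bin_ms.
    ``align='pulse_onset'``: trial time is folded modulo the pulse period
    relative to the pulse-train phase, and the hazard is events per second of
    at-risk exposure within each folded bin.
    """
    if bin_ms < 1:
        raise ValueError("bin_ms must be >= 1")
    df = trials
    if trial_type is not None:
        df = df[df["trial_type"] == trial_type]
    t, is_fa = _risk_times(df, fa_cutoff_ms)

    if align == "trial_start":
        horizon = max_ms if max_ms is not None else float(np.ceil(t.max()))
        edges = np.arange(0.0, horizon + bin_ms, bin_ms)
        n_bins = len(edges) - 1
        # survivors at each bin start; events per bin
        survivors = np.array([(t >= e).sum() for e in edges[:-1]], dtype=float)
        ev_t = t[is_fa]
        ev_t = ev_t[ev_t < edges[-1]]  # events beyond the horizon are out of range
        ev_idx = np.clip((ev_t // bin_ms).astype(int), 0, n_bins - 1)
        events = np.bincount(ev_idx, minlength=n_bins).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            hazard = np.where(
                survivors > 0, events / survivors * (1000.0 / bin_ms), np.nan
            )
        return HazardCurve(edges, hazard, survivors, events, trial_type or "all", align)

    if align == "pulse_onset":
        phase = df["pulse_phase_ms"].to_numpy(dtype=float)
        edges = np.arange(0.0, period_ms + bin_ms, bin_ms)
        n_bins = len(edges) - 1
        exposure = np.zeros(n_bins)
        events = np.zeros(n_bins)
        # exposure: each trial is at risk on [0, t); fold into period bins.
        full_periods = np.floor(t / period_ms)
        for ph, ti, fp, fa in zip(phase, t, full_periods, is_fa):
            exposure += fp * bin_ms  # a whole period covers every folded bin once
            rem = ti - fp * period_ms
            # folded coordinate of an absolute time x is (x - ph) mod period
            a = (fp * period_ms - ph) % period_ms
            cov = _interval_coverage(a, rem, period_ms, edges)
            exposure += cov
            if fa:
                fb = int(((ti - ph) % period_ms) // bin_ms)
                events[min(fb, n_bins - 1)] += 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            hazard = np.where(exposure > 0, events / (exposure / 1000.0), np.nan)
        return HazardCurve(edges, hazard, exposure, events, trial_type or "all", align)

    raise ValueError("align must be 'trial_start' or 'pulse_onset'")


def _interval_coverage(start: float, length: float, period: float, edges: np.ndarray) -> np.ndarray:
    """Milliseconds of [start, start+length) (mod period) falling in each bin."""
    n_bins = len(edges) - 1
    cov = np.zeros(n_bins)
    remaining = length
    pos = start % period
    while remaining > 1e-9:
        seg = min(remaining, period - pos)
        lo, hi = pos, pos + seg
        i0, i1 = int(lo // (edges[1] - edges[0])), int(np.ceil(hi / (edges[1] - edges[0])))
        for i in range(i0, min(i1, n_bins)):
            cov[i] += max(0.0, min(hi, edges[i + 1]) - max(lo, edges[i]))
        remaining -= seg
        pos = 0.0
    return cov


def hazard_estimated(session, trial_type: str = "OFF") -> float:
    """Session-level scalar hazard (events/s): fraction of trials of the type
    ending in a false alarm, divided by the mean length of all trials of that
    type in seconds."""
    df = session.to_frame() if hasattr(session, "to_frame") else session
    sub = df[df["trial_type"] == trial_type]
    if len(sub) == 0:
        raise ValueError(f"no {trial_type} trials")
    frac_fa = float((sub["outcome"] == "false_alarm").mean())
    mean_len_s = float(sub["trial_len_ms"].mean()) / 1000.0
    return frac_fa / mean_len_s


def hazard_mle(session, trial_type: str = "OFF", fa_cutoff_ms: float = 100.0) -> float:
    """Exposure-based constant-hazard MLE: events per second of at-risk time.

    Unlike :func:`hazard_estimated`, the denominator counts only time during
    which a false alarm was possible (up to the stimulus onset + cutoff), so
    this estimator is unbiased for a constant-hazard release process.
    """
    df = session.to_frame() if hasattr(session, "to_frame") else session
    sub = df[df["trial_type"] == trial_type]
    if len(sub) == 0:
        raise ValueError(f"no {trial_type} trials")
    t, is_fa = _risk_times(sub, fa_cutoff_ms)
    return float(is_fa.sum() / (t.sum() / 1000.0))


def rate_correct(k: float, n: float) -> float:
    """1/(2N) correction for extreme hit/false-alarm proportions."""
    if n <= 0:
        raise ValueError("n must be positive")
    p = k / n
    lo, hi = 1.0 / (2.0 * n), 1.0 - 1.0 / (2.0 * n)
    return float(np.clip(p, lo, hi))


def dprime_by_contrast(
    session,
    react_win_ms: float = 550.0,
    hazard_fn=hazard_estimated,
) -> pd.DataFrame:
    """Per-(trial type, contrast) d' using the hazard-derived FA probability.

    The scalar session hazard is converted to a false-alarm probability over
    the reaction window, FA = min(1 - eps, hazard * react_win_s); hit rates
    get the 1/(2N) extreme-rate correction.
    """
    df = session.to_frame() if hasattr(session, "to_frame") else session
    rows = []
    for t in ("ON", "OFF"):
        sub = df[df["trial_type"] == t]
        if len(sub) == 0:
            continue
        h_est = hazard_fn(sub, trial_type=t) if "trial_type" in sub else np.nan
        fa = min(1.0 - 1e-6, h_est * react_win_ms / 1000.0)
        fa = max(fa, 1e-6)
        done = sub[sub["outcome"].isin(["hit", "miss"])]
        for c, grp in done.groupby("contrast"):
            n = len(grp)
            if n == 0:
                continue
            hit = rate_correct(int((grp["outcome"] == "hit").sum()), n)
            d = float(norm.ppf(hit) - norm.ppf(fa))
            rows.append((t, float(c), hit, fa, d, n, h_est))
    return pd.DataFrame(
        rows, columns=["trial_type", "contrast", "H", "FA", "dprime", "n", "fa_hazard_est"]
    )


def criteria(H: float, FA: float, convention: str = "paper") -> tuple[float, float]:
    """Absolute and relative criterion from hit and false-alarm rates.

    ``convention='paper'`` uses c = (z(H) + z(FA)) / 2; ``'conventional'``
    flips the sign.  The relative criterion c' = c / d' is NaN when d' = 0.
    """
    if not (0.0 < H < 1.0 and 0.0 < FA < 1.0):
        raise ValueError("H and FA must lie strictly inside (0, 1)")
    zh, zf = norm.ppf(H), norm.ppf(FA)
    c_abs = (zh + zf) / 2.0
    if convention == "conventional":
        c_abs = -c_abs
    elif convention != "paper":
        raise ValueError("convention must be 'paper' or 'conventional'")
    d = zh - zf
    c_rel = c_abs / d if d != 0 else np.nan
    return float(c_abs), float(c_rel)
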