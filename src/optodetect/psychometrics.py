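"""Psychometric fitting: joint ON/OFF Weibull, Naka-Rushton on d', session QC.

Hit rate as a function of contrast ``c`` is modelled per trial type ``t`` as

    p_t(c) = (1 - lambda_t) * (1 - exp(-(c / alpha_t) ** beta))

with the lower asymptote fixed at zero, a lapse rate (one minus the upper
asymptote) fitted per trial type, and a single slope ``beta`` shared between
LED ON and OFF trials.  ``alpha_t`` is the threshold: the contrast at which
the curve reaches 63% (1 - 1/e) of the span between its asymptotes.  Fitting
maximizes the binomial likelihood of the per-contrast hit counts, which
weights unequal trial counts correctly.

Sensitivity curves are fitted with a Naka-Rushton function
``d'(c) = d'_max * c**n / (c**n + c50**n)`` whose threshold is ``c50``, the
50% point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit, minimize

__all__ = [
    "PsychometricFit",
    "NakaRushtonFit",
    "QCReport",
    "DegenerateDataError",
    "weibull_hit_rate",
    "fit_weibull",
    "threshold_increase",
    "profile_ci_alpha",
    "fit_naka_rushton",
    "qc_session",
]

_LAPSE_MAX = 0.5
_P_EPS = 1e-9


class DegenerateDataError(ValueError):
    """Hit rates are all 0 or all 1; the psychometric function is unidentifiable."""


@dataclass
class PsychometricFit:
    alpha_on: float
    alpha_off: float
    beta: float  # shared slope (NaN when fitted per type)
    lapse_on: float
    lapse_off: float
    loglik: float
    converged: bool
    n_params: int
    counts: pd.DataFrame = field(repr=False)  # trial_type, contrast, n, k
    beta_on: float = np.nan
    beta_off: float = np.nan

    def hit_rate(self, contrast, trial_type: str = "OFF") -> np.ndarray:
        t = trial_type.upper()
        alpha = self.alpha_on if t == "ON" else self.alpha_off
        lapse = self.lapse_on if t == "ON" else self.lapse_off
        beta = self.beta
        if np.isnan(beta):
            beta = self.beta_on if t == "ON" else self.beta_off
        return weibull_hit_rate(np.asarray(contrast, dtype=float), alpha, beta, lapse)


@dataclass
class NakaRushtonFit:
    dprime_max: float
    c50: float
    n_exp: float
    converged: bool

    def predict(self, contrast) -> np.ndarray:
        c = np.asarray(contrast, dtype=float)
        cn = c**self.n_exp
        return self.dprime_max * cn / (cn + self.c50**self.n_exp)


@dataclass
class QCReport:
    passed: bool
    lapse_on: float
    lapse_off: float
    mean_trials: float
    reasons: list[str]


def weibull_hit_rate(contrast, alpha: float, beta: float, lapse: float) -> np.ndarray:
    c = np.asarray(contrast, dtype=float)
    return (1.0 - lapse) * (1.0 - np.exp(-((c / alpha) ** beta)))


# ---------------------------------------------------------------------------
# data preparation


def _counts_from_session(session) -> pd.DataFrame:
    """Per-(trial_type, contrast) trial and hit counts from completed trials.

    False alarms end before the stimulus can be judged, so only hits and
    misses enter the psychometric function.
    """
    df = session.to_frame() if hasattr(session, "to_frame") else pd.DataFrame(session)
    if len(df) == 0:
        raise ValueError("empty session")
    done = df[df["outcome"].isin(["hit", "miss"])]
    grp = done.groupby(["trial_type", "contrast"], sort=True)
    counts = grp["outcome"].agg(
        n="size", k=lambda s: int((s == "hit").sum())
    ).reset_index()
    return counts


def _prep_arrays(counts: pd.DataFrame) -> dict:
    out = {}
    for t in ("ON", "OFF"):
        sub = counts[counts["trial_type"] == t]
        out[t] = (
            sub["contrast"].to_numpy(dtype=float),
            sub["n"].to_numpy(dtype=float),
            sub["k"].to_numpy(dtype=float),
        )
    return out


def _nll_arrays(arrs: dict, alpha_on, alpha_off, beta_on, beta_off, lapse_on, lapse_off) -> float:
    total = 0.0
    for t, alpha, beta, lapse in (
        ("ON", alpha_on, beta_on, lapse_on),
        ("OFF", alpha_off, beta_off, lapse_off),
    ):
        c, n, k = arrs[t]
        if len(c) == 0:
            continue
        p = weibull_hit_rate(c, alpha, beta, lapse)
        p = np.clip(p, _P_EPS, 1.0 - _P_EPS)
        total -= float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))
    return total


def _nll(counts: pd.DataFrame, alpha_on, alpha_off, beta_on, beta_off, lapse_on, lapse_off) -> float:
    return _nll_arrays(_prep_arrays(counts), alpha_on, alpha_off, beta_on, beta_off, lapse_on, lapse_off)


def _starts(counts: pd.DataFrame) -> list[np.ndarray]:
    """Three deterministic starting points spanning plausible slopes."""
    guesses = []
    for t in ("ON", "OFF"):
        sub = counts[counts["trial_type"] == t]
        if len(sub) == 0:
            guesses.append(np.nan)
            continue
        rate = sub["k"] / sub["n"]
        above = sub["contrast"][rate >= 0.5]
        guesses.append(float(above.min()) if len(above) else float(sub["contrast"].max()))
    a_on = guesses[0] if np.isfinite(guesses[0]) else guesses[1]
    a_off = guesses[1] if np.isfinite(guesses[1]) else guesses[0]
    starts = []
    for beta in (1.5, 3.0, 6.0):
        starts.append(
            np.array([np.log(a_on), np.log(a_off), np.log(beta), 0.05, 0.05])
        )
    return starts


def fit_weibull(session, shared_beta: bool = True) -> PsychometricFit:
    """Joint maximum-likelihood Weibull fit of ON and OFF hit rates.

    Parameters are (alpha_on, alpha_off, beta, lapse_on, lapse_off) with the
    slope shared across trial types by default; ``shared_beta=False`` fits a
    separate slope per type (used for the nested-model sanity check).

    Raises
    ------
    DegenerateDataError
        If observed hit rates are all zero or all one.
    """
    counts = session if isinstance(session, pd.DataFrame) else _counts_from_session(session)
    for t in ("ON", "OFF"):
        if counts[counts["trial_type"] == t]["contrast"].nunique() < 2:
            raise ValueError(f"need >=2 contrast levels with trials for {t} trials")
    k_tot, n_tot = counts["k"].sum(), counts["n"].sum()
    if k_tot == 0 or k_tot == n_tot:
        raise DegenerateDataError("all-zero or all-one hit rates")

    cmin = counts["contrast"][counts["contrast"] > 0].min()
    cmax = counts["contrast"].max()
    la, ua = np.log(cmin / 10.0), np.log(cmax * 10.0)
    bounds_shared = [(la, ua), (la, ua), (np.log(0.2), np.log(20.0)), (0.0, _LAPSE_MAX), (0.0, _LAPSE_MAX)]

    arrs = _prep_arrays(counts)

    def obj_shared(theta):
        a_on, a_off, b = np.exp(theta[:3])
        return _nll_arrays(arrs, a_on, a_off, b, b, theta[3], theta[4])

    def obj_free(theta):
        a_on, a_off, b_on, b_off = np.exp(theta[:4])
        return _nll_arrays(arrs, a_on, a_off, b_on, b_off, theta[4], theta[5])

    best = None
    for start in _starts(counts):
        if shared_beta:
            res = minimize(obj_shared, start, method="L-BFGS-B", bounds=bounds_shared)
        else:
            start6 = np.array([start[0], start[1], start[2], start[2], start[3], start[4]])
            bounds6 = bounds_shared[:2] + [bounds_shared[2]] * 2 + bounds_shared[3:]
            res = minimize(obj_free, start6, method="L-BFGS-B", bounds=bounds6)
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success)
    if not converged:
        warnings.warn("Weibull fit did not converge; returning best point found")
    th = best.x
    if shared_beta:
        return PsychometricFit(
            alpha_on=float(np.exp(th[0])), alpha_off=float(np.exp(th[1])),
            beta=float(np.exp(th[2])), lapse_on=float(th[3]), lapse_off=float(th[4]),
            loglik=-float(best.fun), converged=converged, n_params=5, counts=counts,
        )
    return PsychometricFit(
        alpha_on=float(np.exp(th[0])), alpha_off=float(np.exp(th[1])),
        beta=np.nan, lapse_on=float(th[4]), lapse_off=float(th[5]),
        loglik=-float(best.fun), converged=converged, n_params=6, counts=counts,
        beta_on=float(np.exp(th[2])), beta_off=float(np.exp(th[3])),
    )


def threshold_increase(fit: PsychometricFit) -> float:
    """Percent increase of the ON threshold over the OFF threshold."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    if not fit.alpha_off > 0:
        raise ValueError("alpha_off must be positive")
    return 100.0 * (fit.alpha_on - fit.alpha_off) / fit.alpha_off


def profile_ci_alpha(
    fit: PsychometricFit, trial_type: str = "OFF", level: float = 0.95
) -> tuple[float, float]:
    """Profile-likelihood confidence interval for a threshold.

    Re-optimizes the remaining parameters at fixed alpha and finds where the
    profiled deviance rises by the chi-square(1) quantile.
    """
    from scipy.stats import chi2

    counts = fit.counts
    idx = 0 if trial_type.upper() == "ON" else 1
    thr = chi2.ppf(level, df=1) / 2.0
    nll_hat = -fit.loglik
    cmin = counts["contrast"][counts["contrast"] > 0].min()
    cmax = counts["contrast"].max()
    la, ua = np.log(cmin / 10.0), np.log(cmax * 10.0)
    bounds = [(la, ua), (np.log(0.2), np.log(20.0)), (0.0, _LAPSE_MAX), (0.0, _LAPSE_MAX)]
    mle = np.array([
        np.log(fit.alpha_on), np.log(fit.alpha_off), np.log(fit.beta),
        fit.lapse_on, fit.lapse_off,
    ])
    warm = {"x": np.delete(mle, idx)}
    arrs = _prep_arrays(counts)

    def profile(log_alpha: float) -> float:
        def obj(theta):
            full = np.insert(theta, idx, log_alpha)
            a_on, a_off, b = np.exp(full[:3])
            return _nll_arrays(arrs, a_on, a_off, b, b, full[3], full[4])

        res = minimize(obj, warm["x"], method="L-BFGS-B", bounds=bounds)
        warm["x"] = res.x
        return float(res.fun)

    cache: dict[float, float] = {}

    def excess(log_alpha: float) -> float:
        # Memoize so the bracketing pass and the root finder see identical
        # values despite the warm-started inner optimization.
        key = round(float(log_alpha), 12)
        if key not in cache:
            cache[key] = profile(log_alpha) - nll_hat - thr
        return cache[key]

    center = mle[idx]
    out = []
    for direction in (-1.0, 1.0):
        warm["x"] = np.delete(mle, idx)
        lo, hi = center, center
        step = 0.08 * direction
        found = False
        for _ in range(80):
            hi = hi + step
            if excess(hi) > 0:
                found = True
                break
            lo = hi
        if not found:
            out.append(np.exp(hi))  # bound not reached within search range
            continue
        if lo == center:
            # MLE endpoint: excess is -thr by construction, no need to profile.
            cache[round(float(center), 12)] = -thr
        a, b = (hi, lo) if direction < 0 else (lo, hi)
        root = brentq(excess, a, b, xtol=1e-4)
        out.append(float(np.exp(root)))
    return (min(out), max(out))


def fit_naka_rushton(points) -> NakaRushtonFit:
    """Least-squares Naka-Rushton fit to (contrast, d') points.

    Points with non-finite d' should be excluded by the caller (the SDT layer
    applies the extreme-rate correction before producing them).
    """
    pts = np.asarray(points, dtype=float)
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if len(pts) < 3:
        raise ValueError("need >=3 finite (contrast, d') points")
    c, d = pts[:, 0], pts[:, 1]
    if np.any(c <= 0):
        raise ValueError("contrasts must be positive")

    def model(c, dmax, c50, n):
        cn = c**n
        return dmax * cn / (cn + c50**n)

    p0 = (max(d.max(), 0.5), float(np.median(c)), 2.0)
    try:
        popt, _ = curve_fit(
            model, c, d, p0=p0,
            bounds=([1e-6, 1e-6, 0.1], [np.inf, np.inf, 20.0]),
            maxfev=20000,
        )
        converged = True
    except RuntimeError:
        popt = p0
        converged = False
        warnings.warn("Naka-Rushton fit did not converge")
    return NakaRushtonFit(float(popt[0]), float(popt[1]), float(popt[2]), converged)


def qc_session(
    session,
    fit: PsychometricFit | None = None,
    lapse_max: float = 0.20,
    min_mean_trials: float = 10.0,
) -> QCReport:
    """Session inclusion criteria: low lapse rates and enough trials.

    A session passes when both fitted lapse rates are below ``lapse_max`` and
    the mean number of completed trials per (contrast, trial type) cell is at
    least ``min_mean_trials``.
    """
    counts = _counts_from_session(session) if fit is None else fit.counts
    if fit is None:
        fit = fit_weibull(counts)
    mean_trials = float(counts["n"].mean())
    reasons = []
    if not (fit.lapse_on < lapse_max and fit.lapse_off < lapse_max):
        reasons.append("lapse")
    if mean_trials < min_mean_trials:
        reasons.append("trials")
    return QCReport(
        passed=len(reasons) == 0,
        lapse_on=fit.lapse_on,
        lapse_off=fit.lapse_off,
        mean_trials=mean_trials,
        reasons=reasons,
    )
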