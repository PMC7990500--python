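"""Windowed spike-rate analysis of optogenetic suppression.

For each unit and LED intensity, three mean firing rates are computed over
fixed windows (half-open, in ms):

* ``r_base`` — 40 ms ending 10 ms before LED onset (pre-light baseline);
* ``r_min``  — 25 ms starting 25 ms after LED onset, after inhibition has
  taken hold but before visually evoked spikes arrive;
* ``r_vis``  — 50 ms starting 65 ms after stimulus onset (90 ms for area PM,
  whose visual latency is ~25 ms longer).

Analysis keeps single units with wide waveforms that are visually responsive
(``r_vis >= 1.1 * r_base`` without inhibition).  The normalized visual
response at intensity I is ``(r_vis(I) - r_min(I)) / (r_vis(0) - r_min(0))``
— 1 means no attenuation, 0 full suppression — and its falloff versus LED
intensity (or versus cortical distance, for spatial experiments) is fit with
a unit-amplitude Gaussian ``g(x) = exp(-x^2 / (2 sigma^2))``, from which the
50%-suppression intensity ``I50 = sigma * sqrt(2 ln 2)`` or the spatial FWHM
``= 2.3548 sigma`` follows in closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize_scalar

__all__ = [
    "UnitWindows",
    "SuppressionFit",
    "window_rates",
    "classify_waveform",
    "select_units",
    "normalized_response",
    "fit_suppression",
    "latency_half_max",
]

SQRT_2LN2 = float(np.sqrt(2.0 * np.log(2.0)))

R_BASE_WIN = (-50.0, -10.0)  # relative to LED onset
R_MIN_WIN = (25.0, 50.0)  # relative to LED onset
R_VIS_WIN = (65.0, 115.0)  # relative to stimulus onset
PM_SHIFT_MS = 25.0


@dataclass
class UnitWindows:
    unit_id: str
    intensity: float
    r_base: float
    r_min: float
    r_vis: float
    area_label: str
    n_trials: int


@dataclass
class SuppressionFit:
    sigma: float  # mW/mm^2 (intensity domain) or mm (distance domain)
    domain: str
    i50: float  # sigma * sqrt(2 ln 2); the x at which the fit crosses 0.5
    fwhm: float  # 2 * i50
    ci95: tuple[float, float]  # bootstrap CI on i50 (intensity) / fwhm (distance)
    converged: bool

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.exp(-(x**2) / (2.0 * self.sigma**2))


def _rate_in_window(times: np.ndarray, lo: float, hi: float) -> float:
    """Spikes per second in the half-open window [lo, hi)."""
    n = int(np.count_nonzero((times >= lo) & (times < hi)))
    return n / ((hi - lo) / 1000.0)


def window_rates(
    spike_table: pd.DataFrame,
    events: pd.DataFrame,
    area_label: str | None = None,
) -> pd.DataFrame:
    """Per-(unit, intensity) mean window rates across trials.

    ``spike_table`` has columns unit_id, intensity, trial, spike_time_ms;
    ``events`` has unit_id, intensity, trial, led_on_ms, stim_on_ms,
    trial_len_ms and optionally area_label.  Windows falling outside the
    recorded epoch raise.
    """
    rows = []
    spikes_grp = spike_table.groupby(["unit_id", "intensity", "trial"])
    for (unit, intensity), ev in events.groupby(["unit_id", "intensity"]):
        area = area_label or (ev["area_label"].iloc[0] if "area_label" in ev else "V1")
        vis_shift = PM_SHIFT_MS if area == "PM" else 0.0
        r_b, r_m, r_v = [], [], []
        for _, e in ev.iterrows():
            led, stim, tlen = e["led_on_ms"], e["stim_on_ms"], e["trial_len_ms"]
            wins = (
                (led + R_BASE_WIN[0], led + R_BASE_WIN[1]),
                (led + R_MIN_WIN[0], led + R_MIN_WIN[1]),
                (stim + R_VIS_WIN[0] + vis_shift, stim + R_VIS_WIN[1] + vis_shift),
            )
            for lo, hi in wins:
                if lo < 0 or hi > tlen:
                    raise ValueError(
                        f"analysis window [{lo}, {hi}) outside recorded epoch [0, {tlen})"
                    )
            try:
                t = spikes_grp.get_group((unit, intensity, e["trial"]))[
                    "spike_time_ms"
                ].to_numpy()
            except KeyError:
                t = np.empty(0)
            r_b.append(_rate_in_window(t, *wins[0]))
            r_m.append(_rate_in_window(t, *wins[1]))
            r_v.append(_rate_in_window(t, *wins[2]))
        rows.append(
            (unit, float(intensity), float(np.mean(r_b)), float(np.mean(r_m)),
             float(np.mean(r_v)), area, len(ev))
        )
    return pd.DataFrame(
        rows,
        columns=["unit_id", "intensity", "r_base", "r_min", "r_vis", "area_label", "n_trials"],
    )


def classify_waveform(trough_to_peak_ms: float, cutoff_ms: float = 0.45) -> str:
    """'narrow' (putative basket cell) or 'wide' by trough-to-peak width."""
    return "narrow" if trough_to_peak_ms < cutoff_ms else "wide"


def select_units(
    windows: pd.DataFrame,
    qc: pd.DataFrame,
    responsive_ratio: float = 1.1,
    min_snr: float = 2.5,
) -> list:
    """Units to analyze: single, wide-waveform, SNR above threshold, and
    visually responsive (r_vis >= ratio * r_base at zero intensity).

    ``qc`` columns: unit_id, snr, waveform_class (or trough_to_peak_ms),
    is_single_unit.
    """
    qc = qc.copy()
    if "waveform_class" not in qc and "trough_to_peak_ms" in qc:
        qc["waveform_class"] = qc["trough_to_peak_ms"].map(classify_waveform)
    zero = windows[windows["intensity"] == 0.0].set_index("unit_id")
    kept = []
    for _, row in qc.iterrows():
        u = row["unit_id"]
        if not bool(row.get("is_single_unit", True)):
            continue
        if row["waveform_class"] != "wide":
            continue
        if float(row.get("snr", np.inf)) < min_snr:
            continue
        if u not in zero.index:
            continue
        z = zero.loc[u]
        if z["r_vis"] < responsive_ratio * z["r_base"]:
            continue
        kept.append(u)
    if not kept:
        warnings.warn("no units pass selection")
    return kept


def normalized_response(windows: pd.DataFrame) -> pd.DataFrame:
    """Normalized visual response per unit and intensity.

    Adds a ``norm_response`` column: (r_vis - r_min) at each intensity divided
    by (r_vis - r_min) at zero intensity for the same unit (1 at zero
    intensity by construction).  Units with nonpositive zero-intensity
    denominator are flagged invalid and excluded.
    """
    out = []
    for unit, grp in windows.groupby("unit_id"):
        zero = grp[grp["intensity"] == 0.0]
        if len(zero) == 0:
            warnings.warn(f"unit {unit}: no zero-intensity condition; skipped")
            continue
        denom = float(zero["r_vis"].iloc[0] - zero["r_min"].iloc[0])
        if denom <= 0:
            warnings.warn(f"unit {unit}: nonpositive visual response at 0; flagged invalid")
            continue
        g = grp.copy()
        g["norm_response"] = (g["r_vis"] - g["r_min"]) / denom
        out.append(g)
    if not out:
        return windows.iloc[0:0].assign(norm_response=[])
    return pd.concat(out, ignore_index=True)


def fit_suppression(
    points,
    domain: str = "intensity",
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    groups=None,
) -> SuppressionFit:
    """Least-squares unit-amplitude Gaussian fit of normalized responses.

    ``points`` are (x, normalized response) pairs — x is LED intensity
    (mW/mm^2) or cortical distance (mm).  The curve is anchored at 1 for
    x = 0.  Bootstrap resamples ``groups`` (e.g. unit ids) when given,
    otherwise points.
    """
    pts = np.asarray(points, dtype=float)
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if np.unique(pts[:, 0]).size < 3:
        raise ValueError("need >=3 distinct x values")
    if pts[:, 0].min() > 0.25 * pts[:, 0].max():
        warnings.warn("no x near 0; the unit-amplitude anchor is unconstrained by data")
    x, y = pts[:, 0], pts[:, 1]
    rng = rng or np.random.default_rng(0)

    def fit_sigma(x, y):
        x2 = x**2

        def sse(log_s):
            return float(((np.exp(-x2 / (2.0 * np.exp(2.0 * log_s))) - y) ** 2).sum())

        scale = max(x.max(), 1e-6)
        res = minimize_scalar(
            sse, bounds=(np.log(scale) - 8.0, np.log(scale) + 4.0), method="bounded"
        )
        return float(np.exp(res.x)), bool(res.success)

    sigma, converged = fit_sigma(x, y)
    if not converged:
        warnings.warn("suppression fit did not converge")
    i50 = sigma * SQRT_2LN2
    fwhm = 2.0 * i50

    if n_boot <= 0:
        scale = SQRT_2LN2 if domain == "intensity" else 2.0 * SQRT_2LN2
        return SuppressionFit(
            sigma=sigma, domain=domain, i50=float(i50), fwhm=float(fwhm),
            ci95=(np.nan, np.nan), converged=converged,
        )
    if groups is not None:
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        stat = np.empty(n_boot)
        for b in range(n_boot):
            pick = uniq[rng.integers(0, len(uniq), size=len(uniq))]
            sel = np.concatenate([np.flatnonzero(groups == g) for g in pick])
            s, _ = fit_sigma(x[sel], y[sel])
            stat[b] = s
    else:
        n = len(x)
        stat = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            s, _ = fit_sigma(x[idx], y[idx])
            stat[b] = s
    scale = SQRT_2LN2 if domain == "intensity" else 2.0 * SQRT_2LN2
    ci = (
        float(np.percentile(stat, 2.5)) * scale,
        float(np.percentile(stat, 97.5)) * scale,
    )
    return SuppressionFit(
        sigma=sigma, domain=domain, i50=float(i50), fwhm=float(fwhm),
        ci95=ci, converged=converged,
    )


def latency_half_max(times_ms, rates) -> float:
    """Time to half-max of a rising PSTH via a logistic fit.

    Fits ``r(t) = lo + (hi - lo) / (1 + exp(-(t - t50)/tau))`` and returns
    ``t50`` (ms, same reference as ``times_ms``).  Raises on a non-rising
    PSTH.
    """
    t = np.asarray(times_ms, dtype=float)
    r = np.asarray(rates, dtype=float)
    if len(t) < 5:
        raise ValueError("PSTH too short")
    early = r[: max(2, len(r) // 5)].mean()
    late = r[-max(2, len(r) // 5):].mean()
    if late <= early:
        raise ValueError("PSTH is not rising; latency undefined")

    def model(t, lo, hi, t50, tau):
        return lo + (hi - lo) / (1.0 + np.exp(-(t - t50) / tau))

    half = (early + late) / 2.0
    above = t[r >= half]
    t50_0 = float(above.min()) if len(above) else float(t[len(t) // 2])
    p0 = (early, late, t50_0, max((t[-1] - t[0]) / 20.0, 1.0))
    popt, _ = curve_fit(model, t, r, p0=p0, maxfev=20000)
    if not (popt[1] > popt[0]):
        raise ValueError("fitted PSTH is not rising; latency undefined")
    return float(popt[2])
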