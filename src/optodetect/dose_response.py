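"""Dose-response fitting: threshold increase versus LED intensity.

Per light spot, percent threshold increases from many sessions are fit with a
piecewise-linear hinge ``f(I) = max(0, s * (I - i0))``; the headline summary
is the 100% crossing point ``X100 = i0 + 100/s``, the intensity at which the
fit predicts a doubling of the psychometric threshold.  The study-level
procedure is two-pass: free-slope fits per spot, slopes with tight bootstrap
confidence ratios are averaged into a pooled slope, and every spot is refit
with that slope fixed.  Confidence intervals come from resampling sessions
with replacement.  When the fitted curve never reaches 100% within the tested
intensity range the crossing point is only a lower bound and the upper
confidence limit is unbounded (reported as +inf).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = [
    "HingeFit",
    "LightSpot",
    "fit_hinge",
    "pool_slope",
    "bootstrap_ci",
    "compare_groups",
    "spot_geometry",
    "crossing_heatmap",
]


@dataclass
class HingeFit:
    slope: float  # % threshold increase per mW/mm^2
    i0: float  # onset intensity, mW/mm^2
    x100: float  # crossing point, mW/mm^2 (lower bound when flagged)
    ci95: tuple[float, float]
    slope_ci: tuple[float, float]
    slope_ci_ratio: float
    fixed_slope: bool
    x100_is_lower_bound: bool
    max_tested: float
    n_points: int


@dataclass
class LightSpot:
    spot_id: str
    area_label: str
    center_mm: tuple[float, float]
    contour_mm: np.ndarray = field(repr=False)  # (n, 2) closed polygon
    area_mm2: float
    points: pd.DataFrame | None = None  # per-session (intensity, pct_increase)


def _hinge_sse_grid(I, y, slope, i0_grid):
    """SSE over a grid of onsets at fixed slope, vectorized."""
    r = np.clip(I[None, :] - i0_grid[:, None], 0.0, None)
    resid = slope * r - y[None, :]
    return (resid**2).sum(axis=1)


def _fit_fixed_slope(I, y, slope, n_grid=2001):
    span = float(np.ptp(I)) + 1e-12
    lo = float(I.min()) - (100.0 / slope) - 0.1 * span
    hi = float(I.max())
    grid = np.linspace(lo, hi, n_grid)
    sse = _hinge_sse_grid(I, y, slope, grid)
    # flat optimum plateaus at the right edge for effect-free data;
    # take the smallest onset achieving (near-)minimal error.
    i_best = int(np.flatnonzero(sse <= sse.min() + 1e-12 * (1 + sse.min()))[0])
    # local refinement around the grid winner
    step = grid[1] - grid[0]
    fine = np.linspace(grid[i_best] - step, grid[i_best] + step, 201)
    sse_f = _hinge_sse_grid(I, y, slope, fine)
    j = int(np.flatnonzero(sse_f <= sse_f.min() + 1e-12 * (1 + sse_f.min()))[0])
    return float(fine[j]), float(sse_f[j])


def _free_sse_grid(I, y, grid):
    """Profile SSE over onsets with the slope solved in closed form."""
    r = np.clip(I[None, :] - grid[:, None], 0.0, None)
    rr = (r**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(rr > 0, (y[None, :] * r).sum(axis=1) / np.where(rr > 0, rr, 1.0), 0.0)
    s = np.clip(s, 0.0, None)
    resid = s[:, None] * r - y[None, :]
    return (resid**2).sum(axis=1), s


def _fit_free(I, y, n_grid=801):
    span = float(np.ptp(I)) + 1e-12
    lo = float(I.min()) - span
    hi = float(I.max())
    grid = np.linspace(lo, hi, n_grid)
    vals, _ = _free_sse_grid(I, y, grid)
    i_best = int(np.argmin(vals))
    step = grid[1] - grid[0]
    fine = np.linspace(grid[i_best] - step, grid[i_best] + step, 201)
    vals_f, s_f = _free_sse_grid(I, y, fine)
    j = int(np.argmin(vals_f))
    return float(s_f[j]), float(fine[j]), float(vals_f[j])


def _x100(slope: float, i0: float) -> float:
    if slope <= 0:
        return np.inf
    return i0 + 100.0 / slope


def fit_hinge(
    points,
    slope: float | None = None,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> HingeFit:
    """Least-squares hinge fit of (intensity, percent increase) points.

    ``slope=None`` fits slope and onset freely (slope constrained
    nonnegative); a numeric ``slope`` fixes it and fits only the onset.
    Bootstrap resamples points (sessions) with replacement.
    """
    pts = np.asarray(points, dtype=float)
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if len(pts) < 3:
        raise ValueError("need >=3 points")
    I, y = pts[:, 0], pts[:, 1]
    if np.unique(I).size < 2:
        raise ValueError("all intensities identical; hinge unidentifiable")
    rng = rng or np.random.default_rng(0)
    max_tested = float(I.max())

    if slope is None:
        s_hat, i0_hat, _ = _fit_free(I, y)
    else:
        s_hat = float(slope)
        i0_hat, _ = _fit_fixed_slope(I, y, s_hat)
    x_hat = _x100(s_hat, i0_hat)

    xs = np.empty(n_boot)
    ss = np.empty(n_boot)
    n = len(I)
    drawn = 0
    attempts = 0
    while drawn < n_boot and attempts < 20 * n_boot:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        Ib, yb = I[idx], y[idx]
        if np.unique(Ib).size < 2:
            continue  # statistic undefined on this resample; redraw
        if slope is None:
            sb, i0b, _ = _fit_free(Ib, yb, n_grid=401)
        else:
            sb = s_hat
            i0b, _ = _fit_fixed_slope(Ib, yb, sb, n_grid=1001)
        xb = _x100(sb, i0b)
        # beyond the tested range the data only lower-bound the crossing
        xs[drawn] = np.inf if xb > max_tested else xb
        ss[drawn] = sb
        drawn += 1
    if drawn < n_boot:
        warnings.warn("bootstrap exhausted redraw budget; CI from fewer resamples")
        xs, ss = xs[:drawn], ss[:drawn]
    # Small-sample widened percentile points (expanded interval): with few
    # sessions the raw 2.5/97.5 bootstrap percentiles undercover.
    from scipy import stats as sps

    tail = 100.0 * float(sps.norm.cdf(-sps.t.ppf(0.975, n - 1) * np.sqrt(n / (n - 1.0))))
    with np.errstate(invalid="ignore"):  # percentiles interpolating between +inf
        q_lo = float(np.percentile(xs, tail))
        q_hi = float(np.percentile(xs, 100.0 - tail))
    is_lb = bool(x_hat > max_tested)
    if np.isfinite(q_hi) and not is_lb:
        # basic (reverse-percentile) interval, clamped to a valid range
        lo_x = max(0.0, min(2.0 * x_hat - q_hi, x_hat))
        hi_x = max(2.0 * x_hat - q_lo, x_hat)
    else:
        # resamples (or the fit itself) run past the tested range: the data
        # only lower-bound the crossing point
        is_lb = True
        lo_x = q_lo if np.isfinite(q_lo) else max_tested
        lo_x = min(lo_x, x_hat)
        hi_x = np.inf
    lo_s = float(np.percentile(ss, 2.5))
    hi_s = float(np.percentile(ss, 97.5))
    ratio = hi_s / lo_s if lo_s > 0 else np.inf
    return HingeFit(
        slope=s_hat, i0=i0_hat, x100=float(x_hat),
        ci95=(lo_x, hi_x), slope_ci=(lo_s, hi_s), slope_ci_ratio=float(ratio),
        fixed_slope=slope is not None, x100_is_lower_bound=is_lb,
        max_tested=max_tested, n_points=n,
    )


def pool_slope(fits, max_ci_ratio: float = 9.0) -> float:
    """Mean slope over free-slope fits with bootstrap slope-CI ratio below cutoff."""
    qual = [f.slope for f in fits if np.isfinite(f.slope_ci_ratio) and f.slope_ci_ratio < max_ci_ratio]
    if not qual:
        raise ValueError(
            "no fits qualify for slope pooling (all CI ratios >= "
            f"{max_ci_ratio}); supply a slope manually"
        )
    return float(np.mean(qual))


def bootstrap_ci(
    values,
    statistic=np.mean,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Percentile bootstrap (point, lo, hi) for a statistic of 1-D values."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise ValueError("need >=2 values")
    point = float(statistic(vals))
    stats = np.empty(n_boot)
    drawn = 0
    attempts = 0
    while drawn < n_boot and attempts < 20 * n_boot:
        attempts += 1
        s = statistic(vals[rng.integers(0, len(vals), size=len(vals))])
        if not np.isfinite(s):
            continue
        stats[drawn] = s
        drawn += 1
    stats = stats[:drawn]
    a = 100.0 * (1.0 - level) / 2.0
    return point, float(np.percentile(stats, a)), float(np.percentile(stats, 100.0 - a))


def compare_groups(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney comparison of two small groups.

    Returns (U, p) where U counts (a, b) pairs with a < b (ties count 1/2);
    p is from the exact null distribution for small untied samples and the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    u_less = float((a[:, None] < b[None, :]).sum() + 0.5 * (a[:, None] == b[None, :]).sum())
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 20 and len(b) <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return u_less, float(res.pvalue)


def spot_geometry(intensity_image: np.ndarray, pixel_size_mm: float) -> LightSpot:
    """Light-spot geometry from a surface intensity image.

    The spot boundary is the contour at 50% of the peak (above the image
    floor); the area is the enclosed polygon area and the center is the
    intensity-weighted centroid of above-half-max pixels, in mm.
    """
    from skimage import measure
    from shapely.geometry import Point, Polygon

    img = np.asarray(intensity_image, dtype=float)
    span = float(np.ptp(img))
    if span <= 0:
        raise ValueError("flat image: no spot")
    level = img.min() + 0.5 * span
    contours = measure.find_contours(img, level)
    if not contours:
        raise ValueError("no 50% contour found")
    peak_rc = np.unravel_index(np.argmax(img), img.shape)
    poly = None
    for c in contours:
        p = Polygon(c)
        if p.is_valid and p.contains(Point(peak_rc)):
            poly = p
            contour = c
            break
    if poly is None:
        # fall back to the largest contour
        contour = max(contours, key=len)
        poly = Polygon(contour)
    area_mm2 = float(poly.area) * pixel_size_mm**2
    mask = img >= level
    w = img[mask]
    rr, cc = np.nonzero(mask)
    center = (
        float((rr * w).sum() / w.sum()) * pixel_size_mm,
        float((cc * w).sum() / w.sum()) * pixel_size_mm,
    )
    return LightSpot(
        spot_id="", area_label="", center_mm=center,
        contour_mm=contour * pixel_size_mm, area_mm2=area_mm2,
    )


def crossing_heatmap(
    spots_and_fits,
    grid_mm: float = 0.025,
    bounds: tuple[float, float, float, float] | None = None,
):
    """Pixel-wise mean crossing point over all covering spots.

    Parameters
    ----------
    spots_and_fits
        Iterable of (LightSpot, x100) pairs; each spot's polygon contour
        claims the pixels it covers.

    Returns
    -------
    (x_coords, y_coords, grid) where uncovered pixels are NaN.
    """
    import shapely
    from shapely.geometry import Polygon

    items = list(spots_and_fits)
    if not items:
        raise ValueError("need at least one spot")
    polys = [Polygon(s.contour_mm) for s, _ in items]
    if bounds is None:
        allb = np.array([p.bounds for p in polys])
        bounds = (allb[:, 0].min(), allb[:, 1].min(), allb[:, 2].max(), allb[:, 3].max())
    r = np.arange(bounds[0], bounds[2] + grid_mm, grid_mm)
    c = np.arange(bounds[1], bounds[3] + grid_mm, grid_mm)
    RR, CC = np.meshgrid(r, c, indexing="ij")
    total = np.zeros(RR.shape)
    count = np.zeros(RR.shape)
    for poly, (_, x100) in zip(polys, items):
        inside = shapely.contains_xy(poly, RR.ravel(), CC.ravel()).reshape(RR.shape)
        total[inside] += x100
        count[inside] += 1
    if count.sum() == 0:
        warnings.warn("grid does not cover any spot; empty map")
    with np.errstate(invalid="ignore"):
        grid = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return r, c, grid
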