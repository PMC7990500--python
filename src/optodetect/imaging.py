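"""Widefield calcium-imaging analysis.

Pipeline order is fixed: (1) remove the rank-1 global fluctuation by
discarding the first principal component of the frame stack; (2) take a
frame-by-frame difference Fdiff (an approximate spike deconvolution for slow
indicators); (3) normalize by the pre-stimulus baseline.  Response maps show
``(Fdiff - Fdiff0) / F0`` where Fdiff0 and F0 are averaged over the three
frames (300 ms at 10 Hz) just before each stimulus onset; conventional
``dF/F = (F - F0)/F0`` maps are produced alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = [
    "ResponseMap",
    "RoiResult",
    "remove_global_component",
    "response_maps",
    "roi_response",
    "polygon_mask",
]

F0_EPS = 1e-9


@dataclass
class ResponseMap:
    map: np.ndarray  # (n_response_frames, H, W): (Fdiff - Fdiff0)/F0, stim-averaged
    dff: np.ndarray  # (n_response_frames, H, W): (F - F0)/F0, stim-averaged
    f0: np.ndarray  # (H, W) mean baseline over stimuli
    stim_frames: np.ndarray
    n_baseline: int


@dataclass
class RoiResult:
    responses: pd.DataFrame  # columns: stim_frame, condition, response
    statistic: float | None
    pvalue: float | None


def remove_global_component(movie: np.ndarray) -> np.ndarray:
    """Subtract the projection of the movie onto its first principal component.

    Frames are the observations (pixels the variables); the movie is mean
    centered per pixel, the leading component — which captures frame-wide
    global fluctuation — is removed, and the mean is restored.  Output shape
    equals input shape.
    """
    movie = np.asarray(movie, dtype=float)
    T = movie.shape[0]
    if T < 2:
        raise ValueError("need >=2 frames")
    X = movie.reshape(T, -1)
    mu = X.mean(axis=0)
    Xc = X - mu
    if not np.any(Xc):
        raise ValueError("degenerate movie: zero variance")
    if min(Xc.shape) <= 600:
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        u1, s1, v1 = U[:, 0], s[0], Vt[0]
    else:
        from scipy.sparse.linalg import svds

        u, s, vt = svds(Xc, k=1)
        u1, s1, v1 = u[:, 0], s[0], vt[0]
    Xout = Xc - np.outer(u1 * s1, v1) + mu
    return Xout.reshape(movie.shape)


def response_maps(
    movie: np.ndarray,
    stim_frames,
    n_baseline: int = 3,
    n_response: int = 3,
) -> ResponseMap:
    """Stimulus-averaged frame-difference response maps and dF/F maps.

    Each stimulus contributes maps for ``n_response`` frames starting at its
    onset frame; stimuli without enough flanking frames are skipped with a
    warning.  Pixels whose baseline F0 is near zero are masked (NaN), never
    divided.
    """
    movie = np.asarray(movie, dtype=float)
    stim_frames = np.asarray(stim_frames, dtype=int)
    T = movie.shape[0]
    fdiff = np.diff(movie, axis=0)  # fdiff[t] = F[t+1] - F[t]
    maps, dffs, f0s = [], [], []
    for s in stim_frames:
        # Fdiff over the 3 baseline frames needs n_baseline+1 raw frames.
        if s < n_baseline + 1 or s + n_response > T:
            warnings.warn(f"stimulus at frame {s} too close to movie edge; skipped")
            continue
        f0 = movie[s - n_baseline : s].mean(axis=0)
        fdiff0 = fdiff[s - n_baseline - 1 : s - 1].mean(axis=0)
        f0_safe = np.where(np.abs(f0) > F0_EPS, f0, np.nan)
        maps.append((fdiff[s - 1 : s + n_response - 1] - fdiff0) / f0_safe)
        dffs.append((movie[s : s + n_response] - f0) / f0_safe)
        f0s.append(f0)
    if not maps:
        raise ValueError("no usable stimuli")
    return ResponseMap(
        map=np.mean(maps, axis=0),
        dff=np.mean(dffs, axis=0),
        f0=np.mean(f0s, axis=0),
        stim_frames=stim_frames,
        n_baseline=n_baseline,
    )


def polygon_mask(shape: tuple[int, int], polygon) -> np.ndarray:
    """Boolean pixel mask from (row, col) polygon vertices."""
    from skimage.draw import polygon as sk_polygon

    poly = np.asarray(polygon, dtype=float)
    rr, cc = sk_polygon(poly[:, 0], poly[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def roi_response(
    movie: np.ndarray,
    roi,
    stim_frames,
    conditions=None,
    n_pre: int = 2,
    n_post: int = 2,
) -> RoiResult:
    """Per-trial ROI responses and an across-condition rank comparison.

    The per-trial scalar is the mean ROI fluorescence over ``n_post`` frames
    from stimulus onset, minus the mean over ``n_pre`` frames before onset,
    divided by the pre-stimulus baseline.  If ``conditions`` labels exactly
    two groups they are compared with a two-sided rank-sum test.
    """
    movie = np.asarray(movie, dtype=float)
    T, H, W = movie.shape
    if isinstance(roi, np.ndarray) and roi.dtype == bool:
        mask = roi
    else:
        mask = polygon_mask((H, W), roi)
    if mask.shape != (H, W) or not mask.any():
        raise ValueError("ROI is empty or outside the frame")
    trace = movie[:, mask].mean(axis=1)
    stim_frames = np.asarray(stim_frames, dtype=int)
    conds = (
        np.asarray(conditions)
        if conditions is not None
        else np.array(["all"] * len(stim_frames))
    )
    rows = []
    for s, cond in zip(stim_frames, conds):
        if s < n_pre or s + n_post > T:
            warnings.warn(f"stimulus at frame {s} too close to movie edge; skipped")
            continue
        pre = trace[s - n_pre : s].mean()
        post = trace[s : s + n_post].mean()
        if abs(pre) <= F0_EPS:
            raise ValueError("pre-stimulus baseline is zero in the ROI")
        rows.append((int(s), cond, float((post - pre) / pre)))
    df = pd.DataFrame(rows, columns=["stim_frame", "condition", "response"])
    labels = df["condition"].unique()
    stat = p = None
    if len(labels) == 2:
        a = df[df["condition"] == labels[0]]["response"]
        b = df[df["condition"] == labels[1]]["response"]
        res = mannwhitneyu(a, b, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    return RoiResult(responses=df, statistic=stat, pvalue=p)
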