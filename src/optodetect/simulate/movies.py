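"""Synthetic widefield imaging movies.

A movie is the sum of a static baseline map, a rank-1 "global" fluctuation
(one spatial map times one zero-mean time course, the nuisance the imaging
pipeline removes with PCA), stimulus-locked fluorescence transients localized
to a Gaussian region of interest with slow exponential decay (GCaMP-like),
and i.i.d. pixel noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MovieConfig", "simulate_movie"]


@dataclass(frozen=True)
class MovieConfig:
    n_frames: int = 200
    height: int = 32
    width: int = 32
    frame_rate_hz: float = 10.0
    baseline: float = 100.0
    roi_center: tuple[float, float] = (20.0, 12.0)  # (row, col), pixels
    roi_sigma_px: float = 3.0
    amplitude: float = 2.0  # absolute fluorescence added at ROI center at stim
    decay_frames: float = 10.0  # GCaMP-like decay time constant, frames
    global_amp: float = 0.0  # SD of the rank-1 global time course
    noise_sd: float = 0.0
    stim_every: int = 20  # frames between stimulus onsets
    first_stim: int = 10

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_frames, self.height, self.width)


def _roi_map(config: MovieConfig) -> np.ndarray:
    r = np.arange(config.height)[:, None]
    c = np.arange(config.width)[None, :]
    d2 = (r - config.roi_center[0]) ** 2 + (c - config.roi_center[1]) ** 2
    return np.exp(-d2 / (2.0 * config.roi_sigma_px**2))


def simulate_movie(
    config: MovieConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Return (movie, stim_frames).

    movie : float64 array (n_frames, height, width)
    stim_frames : int array of stimulus-onset frame indices
    """
    T, H, W = config.shape
    movie = np.full((T, H, W), config.baseline, dtype=float)

    if config.global_amp > 0:
        # Smooth random spatial map, unit norm; AR(1) time course, zero mean.
        gmap = rng.standard_normal((H, W))
        from scipy.ndimage import gaussian_filter

        gmap = gaussian_filter(gmap, sigma=4.0)
        gmap /= np.sqrt((gmap**2).mean())
        tc = np.empty(T)
        tc[0] = rng.standard_normal()
        for t in range(1, T):
            tc[t] = 0.9 * tc[t - 1] + np.sqrt(1 - 0.81) * rng.standard_normal()
        tc = (tc - tc.mean()) * config.global_amp
        movie += tc[:, None, None] * gmap[None, :, :]

    stim_frames = np.arange(config.first_stim, T - 4, config.stim_every, dtype=int)
    roi = _roi_map(config)
    kernel = config.amplitude * np.exp(
        -np.arange(T, dtype=float) / config.decay_frames
    )
    for s in stim_frames:
        n = T - s
        movie[s:] += kernel[:n, None, None] * roi[None, :, :]

    if config.noise_sd > 0:
        movie += rng.normal(0.0, config.noise_sd, size=movie.shape)
    return movie, stim_frames
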