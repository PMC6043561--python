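"""Synthetic trajectory generators.

These stand in for the live-imaging track data: every statistic in
:mod:`senoclust.tracks` is exercised on tracks whose ground truth is known
by construction.

* :func:`gen_persistent_tracks` -- constant-speed 2D walkers whose ensemble
  heading autocorrelation converges to the two-tiered exponential
  ``A exp(-t/tau) + B exp(-t/tau0)``. Realized as a two-population mixture
  (a fraction A/(A+B) of walkers decorrelates with the slow constant tau,
  the rest with tau0) plus independent per-frame heading jitter whose
  amplitude is solved from 1 - (A + B), the instantaneous decorrelated
  component implied by A + B < 1.
* :func:`gen_fbm_tracks` -- fractional Brownian motion per axis via exact
  circulant-embedding sampling of fractional Gaussian noise; the ensemble
  MSD exponent is 2H by construction.
* :func:`gen_inward_tracks` -- noisy straight-line drift toward a point,
  for radial-velocity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class WalkParams:
    """Two-tiered persistent walk parameters (times in hours, lengths um)."""

    A: float = 0.14
    tau: float = 4.56
    B: float = 0.64
    tau0: float = 0.38
    speed: float = 30.0
    dt: float = 0.25
    n_tracks: int = 200
    n_frames: int = 500
    #: per-frame heading jitter sd (radians); None solves it from
    #: exp(-sd^2) = A + B, 0 disables jitter
    jitter_sd: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.A < 0 or self.B < 0 or self.A + self.B > 1 + 1e-12:
            raise ValueError("need A, B >= 0 and A + B <= 1")
        if not (self.tau > self.tau0 > 0):
            raise ValueError("need tau > tau0 > 0")
        if self.speed <= 0 or self.dt <= 0:
            raise ValueError("speed and dt must be positive")


@dataclass
class FbmParams:
    """Fractional-Brownian track parameters. MSD exponent = 2H."""

    hurst: float = 0.71
    n_tracks: int = 200
    n_frames: int = 1000
    dt: float = 0.25
    scale: float = 1.0  # increment sd per frame, um
    seed: Optional[int] = None

    def __post_init__(self):
        if not (0 < self.hurst < 1):
            raise ValueError(f"Hurst parameter must be in (0, 1), got {self.hurst}")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _to_table(times: np.ndarray, xy: np.ndarray, z: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Stack (n_tracks, n_frames, 2|3) positions into a tidy track table."""
    n_tracks, n_frames = xy.shape[:2]
    ids = np.repeat(np.arange(n_tracks), n_frames)
    t = np.tile(times, n_tracks)
    flat = xy.reshape(-1, xy.shape[2])
    zcol = np.zeros(len(flat)) if z is None else z.reshape(-1)
    return pd.DataFrame(
        {"cell_id": ids, "time": t, "x": flat[:, 0], "y": flat[:, 1], "z": zcol}
    )


def gen_persistent_tracks(params: WalkParams, rng=None) -> pd.DataFrame:
    """Generate 2D constant-speed walkers with the two-tiered heading
    autocorrelation. Per-frame displacement magnitude is exactly
    ``speed * dt`` (jitter perturbs heading only, never speed)."""
    rng = _rng(rng if rng is not None else params.seed)
    n, m = params.n_tracks, params.n_frames
    ab = params.A + params.B
    n_slow = int(round(n * (params.A / ab))) if ab > 0 else 0
    taus = np.where(np.arange(n) < n_slow, params.tau, params.tau0)

    if params.jitter_sd is None:
        sigma_j = float(np.sqrt(-np.log(ab))) if ab < 1 else 0.0
    else:
        sigma_j = float(params.jitter_sd)

    phi = rng.uniform(0, 2 * np.pi, size=n)[:, None] + np.concatenate(
        [
            np.zeros((n, 1)),
            np.cumsum(
                rng.standard_normal((n, m - 2)) * np.sqrt(2 * params.dt / taus)[:, None],
                axis=1,
            ),
        ],
        axis=1,
    )  # (n, m-1) heading angle per displacement frame
    if sigma_j > 0:
        phi = phi + rng.standard_normal(phi.shape) * sigma_j
    step = params.speed * params.dt
    dx = step * np.cos(phi)
    dy = step * np.sin(phi)
    pos = np.zeros((n, m, 2))
    pos[:, 1:, 0] = np.cumsum(dx, axis=1)
    pos[:, 1:, 1] = np.cumsum(dy, axis=1)
    times = np.arange(m) * params.dt
    return _to_table(times, pos)


def fgn_autocovariance(k, hurst: float):
    """Autocovariance of unit-variance fractional Gaussian noise at lag k:
    0.5 * (|k+1|^2H - 2|k|^2H + |k-1|^2H)."""
    k = np.abs(np.asarray(k, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2)


def _fgn_sample(n: int, hurst: float, rng: np.random.Generator, size: int) -> np.ndarray:
    """Exact stationary fGn sample paths (size, n) with unit step variance,
    by circulant embedding of the fGn covariance."""
    if n == 1:
        return rng.standard_normal((size, 1))
    g = fgn_autocovariance(np.arange(n), hurst)
    c = np.concatenate([g, g[-2:0:-1]])
    m = len(c)  # 2n - 2
    lam = np.fft.fft(c).real
    lam = np.clip(lam, 0.0, None)  # tiny negative eigenvalues -> 0
    half = m // 2
    a = rng.standard_normal((size, m))
    b = rng.standard_normal((size, m))
    w = np.zeros((size, m), dtype=complex)
    w[:, 0] = np.sqrt(lam[0] / m) * a[:, 0]
    w[:, half] = np.sqrt(lam[half] / m) * a[:, half]
    k = np.arange(1, half)
    w[:, k] = np.sqrt(lam[k] / (2 * m)) * (a[:, k] + 1j * b[:, k])
    w[:, m - k] = np.conj(w[:, k])
    return np.fft.fft(w, axis=1).real[:, :n]


def gen_fbm_tracks(params: FbmParams, rng=None) -> pd.DataFrame:
    """Generate 2D fractional-Brownian tracks (independent fBm per axis)."""
    rng = _rng(rng if rng is not None else params.seed)
    n, m = params.n_tracks, params.n_frames
    incs = params.scale * _fgn_sample(m - 1, params.hurst, rng, size=2 * n)
    pos = np.zeros((n, m, 2))
    pos[:, 1:, 0] = np.cumsum(incs[:n], axis=1)
    pos[:, 1:, 1] = np.cumsum(incs[n:], axis=1)
    times = np.arange(m) * params.dt
    return _to_table(times, pos)


def gen_inward_tracks(
    center,
    speed: float,
    n_tracks: int = 50,
    n_frames: int = 40,
    dt: float = 0.25,
    start_radius: float = 100.0,
    noise_sd: float = 0.0,
    speed_sd: float = 0.0,
    rng=None,
) -> pd.DataFrame:
    """Tracks drifting straight toward ``center`` at the given radial speed
    (per-track speeds drawn N(speed, speed_sd)), with optional isotropic
    positional noise."""
    rng = _rng(rng)
    center = np.asarray(center, float)[:2]
    times = np.arange(n_frames) * dt
    pos = np.zeros((n_tracks, n_frames, 2))
    ang = rng.uniform(0, 2 * np.pi, size=n_tracks)
    u = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    speeds = speed + speed_sd * rng.standard_normal(n_tracks)
    for i in range(n_tracks):
        # start far enough out that the track never crosses the center
        r0 = max(start_radius, abs(speeds[i]) * times[-1] + 5.0)
        r = r0 - speeds[i] * times
        pos[i] = center + u[i] * r[:, None]
    if noise_sd > 0:
        pos += rng.standard_normal(pos.shape) * noise_sd
    return _to_table(times, pos)
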