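"""Cell-track motility statistics and cluster metrics.

These are applied identically to simulator output and to synthetic
experimental-style tracks: the ensemble mean-squared displacement and its
anomalous exponent alpha (log-log slope), the heading autocorrelation
<cos theta>(t) and its two-tiered exponential fit
``A exp(-t/tau) + B exp(-t/tau0)`` (the slow constant tau is the reported
directional persistence time), the mean radial approach speed toward the
senescent core, and the geometric cluster criterion on the lattice.

Track tables are tidy DataFrames with columns ``cell_id, time, x, y, z``
(one row per sample, uniform sampling interval within a track).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._kernels import T_BODY, T_CORE, T_TUMOR
from .lattice import CellTable, Lattice

TRACK_COLUMNS = ["cell_id", "time", "x", "y", "z"]


def read_tracks(path) -> pd.DataFrame:
    """Read a track table CSV (header ``cell_id,time,x,y,z``)."""
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track table {path} lacks columns {missing}")
    return validate_tracks(df[TRACK_COLUMNS])


def write_tracks(df: pd.DataFrame, path) -> None:
    df[TRACK_COLUMNS].to_csv(path, index=False)


def validate_tracks(df: pd.DataFrame) -> pd.DataFrame:
    """Check strictly increasing times and no duplicate (id, time) pairs."""
    if df.duplicated(["cell_id", "time"]).any():
        raise ValueError("duplicate (cell_id, time) rows in track table")
    for cid, g in df.groupby("cell_id"):
        t = g["time"].to_numpy()
        if np.any(np.diff(t) <= 0) and not g["time"].is_monotonic_increasing:
            raise ValueError(f"track {cid}: times not strictly increasing")
    return df


def _track_arrays(tracks: pd.DataFrame, dims: Sequence[str]):
    """Per-track (positions, dt) with a uniform-sampling check."""
    out = []
    for cid, g in tracks.groupby("cell_id"):
        g = g.sort_values("time")
        t = g["time"].to_numpy(float)
        if len(t) < 2:
            continue
        dts = np.diff(t)
        dt = dts[0]
        if not np.allclose(dts, dt, rtol=1e-6, atol=1e-9):
            raise ValueError(f"track {cid}: non-uniform sampling interval")
        out.append((g[list(dims)].to_numpy(float), dt))
    return out


@dataclass
class MsdCurve:
    """Ensemble mean-squared displacement vs lag time."""

    lags: np.ndarray  # lag times (time units of the input), lag 0 included
    msd: np.ndarray
    sd: np.ndarray  # per-lag spread across tracks
    n_tracks: int
    dt: float


@dataclass
class PersistenceCurve:
    """Heading autocorrelation <cos theta>(t) vs lag time."""

    lags: np.ndarray
    values: np.ndarray
    sd: np.ndarray
    n_tracks: int
    dt: float
    fit: Optional["TwoExpFit"] = None


@dataclass
class TwoExpFit:
    """Parameters of A exp(-t/tau) + B exp(-t/tau0) with tau > tau0."""

    A: float
    tau: float
    B: float
    tau0: float
    residual_norm: float
    param_sd: np.ndarray = dc_field(default_factory=lambda: np.full(4, np.nan))
    ok: bool = True

    def __call__(self, t):
        t = np.asarray(t, float)
        return self.A * np.exp(-t / self.tau) + self.B * np.exp(-t / self.tau0)


def compute_msd(
    tracks: pd.DataFrame,
    max_lag: Optional[float] = None,
    dims: Sequence[str] = ("x", "y"),
) -> MsdCurve:
    """Time-and-ensemble averaged squared displacement at each lag.

    All overlapping sample pairs contribute; each track's time average is
    then averaged across tracks with equal weight. 2D (x, y) by default to
    match phase-contrast imaging; pass dims=("x","y","z") for 3D.
    """
    arrs = _track_arrays(tracks, dims)
    if not arrs:
        raise ValueError("need at least one track with >= 2 samples")
    dt = arrs[0][1]
    if any(abs(d - dt) > 1e-9 * max(dt, 1) for _, d in arrs):
        raise ValueError("tracks have differing sampling intervals")
    n_max = max(len(p) for p, _ in arrs)
    if max_lag is None:
        k_max = max(1, (n_max - 1) // 4)  # default fit horizon T/4
    else:
        k_max = max(1, int(round(max_lag / dt)))
        k_max = min(k_max, n_max - 1)
    per_track = np.full((len(arrs), k_max + 1), np.nan)
    per_track[:, 0] = 0.0
    for i, (pos, _) in enumerate(arrs):
        n = len(pos)
        for k in range(1, min(k_max, n - 1) + 1):
            d = pos[k:] - pos[:-k]
            per_track[i, k] = np.mean(np.sum(d * d, axis=1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        msd = np.nanmean(per_track, axis=0)
        sd = np.nanstd(per_track, axis=0)
    return MsdCurve(
        lags=np.arange(k_max + 1) * dt,
        msd=msd,
        sd=sd,
        n_tracks=len(arrs),
        dt=dt,
    )


def fit_msd_exponent(
    msd: MsdCurve, fit_range: Optional[tuple] = None
) -> tuple[float, float]:
    """Anomalous exponent alpha: OLS slope of log<d^2> vs log(t).

    ``fit_range`` is a (lo, hi) lag-time interval; the default starts at two
    frames (short-lag noise) and uses all computed lags (the curve itself is
    computed to T/4 by default). Returns (alpha, standard error).
    """
    if fit_range is None:
        fit_range = (2 * msd.dt, msd.lags[-1])
    lo, hi = fit_range
    sel = (msd.lags >= lo - 1e-12) & (msd.lags <= hi + 1e-12)
    t = msd.lags[sel]
    y = msd.msd[sel]
    good = np.isfinite(y) & (y > 0) & (t > 0)
    if good.sum() < np.isfinite(y).sum():
        warnings.warn("excluding non-positive/undefined MSD values from log-log fit")
    t, y = t[good], y[good]
    if len(t) < 5:
        raise ValueError(f"need >= 5 positive MSD lags in fit range, have {len(t)}")
    res = stats.linregress(np.log(t), np.log(y))
    return float(res.slope), float(res.stderr)


def direction_autocorr(
    tracks: pd.DataFrame,
    max_lag: Optional[float] = None,
    heading_step: Optional[float] = None,
    dims: Sequence[str] = ("x", "y"),
) -> PersistenceCurve:
    """Heading autocorrelation: the heading at time s is the unit vector of
    the displacement over [s, s + heading_step]; the curve value at lag t is
    the mean of cos(angle between headings at s and s + t) over cells and s.

    Zero-length displacements leave the heading undefined and the sample is
    skipped. The per-lag sd is the spread of per-cell means (the shading of
    an ensemble plot)."""
    arrs = _track_arrays(tracks, dims)
    if not arrs:
        raise ValueError("need at least one track with >= 2 samples")
    dt = arrs[0][1]
    h = 1 if heading_step is None else max(1, int(round(heading_step / dt)))
    n_max = max(len(p) for p, _ in arrs)
    if max_lag is None:
        k_max = max(1, (n_max - h - 1))
    else:
        k_max = min(int(round(max_lag / dt)), n_max - h - 1)
    per_track = np.full((len(arrs), k_max + 1), np.nan)
    for i, (pos, _) in enumerate(arrs):
        disp = pos[h:] - pos[:-h]
        norm = np.linalg.norm(disp, axis=1)
        ok = norm > 0
        u = np.zeros_like(disp)
        u[ok] = disp[ok] / norm[ok, None]
        n = len(u)
        per_track[i, 0] = 1.0 if ok.any() else np.nan
        for k in range(1, min(k_max, n - 1) + 1):
            valid = ok[k:] & ok[:-k]
            if valid.any():
                per_track[i, k] = np.mean(
                    np.sum(u[k:][valid] * u[:-k][valid], axis=1)
                )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.nanmean(per_track, axis=0)
        sd = np.nanstd(per_track, axis=0)
    return PersistenceCurve(
        lags=np.arange(k_max + 1) * dt,
        values=values,
        sd=sd,
        n_tracks=len(arrs),
        dt=dt,
    )


def _two_exp_residuals(q, t, y):
    A, B, tau0, ratio = q
    tau = tau0 * ratio
    return A * np.exp(-t / tau) + B * np.exp(-t / tau0) - y


def fit_two_exponential(
    curve: PersistenceCurve,
    max_lag: Optional[float] = None,
    starts_tau: Sequence[float] = (2.0, 5.0, 10.0),
    starts_tau0: Sequence[float] = (0.1, 0.5, 1.0),
) -> TwoExpFit:
    """Constrained nonlinear least squares of the two-tiered exponential.

    Constraints: A, B >= 0 and tau >= 2 tau0 > 0 (identifiability).
    Multi-start initialization over a small (tau, tau0) grid with
    A = B = 0.5; the best residual wins. The lag-0 point is excluded: the
    model describes decorrelation for t > 0 while the empirical curve is 1
    at t = 0 by construction (any instantaneous component appears as
    A + B < 1).

    The fit is flagged not-ok (``ok=False``) when the parameter covariance
    is singular or the relative uncertainty of tau exceeds 1.
    """
    sel = curve.lags > 0
    if max_lag is not None:
        sel &= curve.lags <= max_lag
    t = curve.lags[sel]
    y = curve.values[sel]
    good = np.isfinite(y)
    t, y = t[good], y[good]
    if len(t) < 8:
        raise ValueError(f"need >= 8 lag points to fit, have {len(t)}")

    best = None
    for tau in starts_tau:
        for tau0 in starts_tau0:
            if tau < 2 * tau0:
                continue
            q0 = np.array([0.5, 0.5, tau0, tau / tau0])
            try:
                res = optimize.least_squares(
                    _two_exp_residuals,
                    q0,
                    args=(t, y),
                    bounds=([0.0, 0.0, 1e-6, 2.0], [2.0, 2.0, np.inf, 1e6]),
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                    max_nfev=2000,
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        raise RuntimeError("two-exponential fit failed from every start")

    A, B, tau0, ratio = best.x
    tau = tau0 * ratio
    rnorm = float(np.sqrt(2 * best.cost))

    # parameter uncertainties from the Gauss-Newton covariance
    param_sd = np.full(4, np.nan)
    ok = True
    dof = max(len(t) - 4, 1)
    s2 = 2 * best.cost / dof
    JtJ = best.jac.T @ best.jac
    try:
        cov_q = np.linalg.inv(JtJ) * s2
        # delta method for (A, tau, B, tau0) from (A, B, tau0, ratio)
        G = np.array(
            [
                [1.0, 0.0, 0.0, 0.0],
                [0.0, 0.0, ratio, tau0],
                [0.0, 1.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, 0.0],
            ]
        )
        cov = G @ cov_q @ G.T
        param_sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
        if tau <= 0 or not np.isfinite(param_sd[1]) or param_sd[1] > abs(tau):
            ok = False
    except np.linalg.LinAlgError:
        ok = False
    fit = TwoExpFit(
        A=float(A),
        tau=float(tau),
        B=float(B),
        tau0=float(tau0),
        residual_norm=rnorm,
        param_sd=param_sd,
        ok=ok,
    )
    curve.fit = fit
    return fit


def radial_velocity(tracks: pd.DataFrame, center) -> float:
    """Mean inward radial speed toward ``center`` (positive = approaching).

    Per track, the least-squares slope of distance-to-center vs time;
    single-sample tracks are skipped. Units follow the inputs (um per time
    unit). ``center`` may be 2D (x, y) or 3D."""
    center = np.asarray(center, float)
    dims = ("x", "y", "z")[: len(center)]
    speeds = []
    for cid, g in tracks.groupby("cell_id"):
        g = g.sort_values("time")
        if len(g) < 2:
            continue
        pos = g[list(dims)].to_numpy(float)
        r = np.linalg.norm(pos - center, axis=1)
        t = g["time"].to_numpy(float)
        slope = np.polyfit(t, r, 1)[0]
        speeds.append(-slope)
    if not speeds:
        raise ValueError("no track has >= 2 samples")
    return float(np.mean(speeds))


@dataclass
class ClusterMetrics:
    n_cells_on_core: int
    max_stack_height: int  # tallest contiguous tumor z-extent, in sites
    cluster_formed: bool


def cluster_metrics(lattice: Lattice, cells: CellTable) -> ClusterMetrics:
    """Geometric criterion of Fig.-style 3D cluster formation: tumor cells
    whose centroid lies over the senescent core's x-y footprint and above
    the body's median top surface. ``cluster_formed`` requires >= 2 such
    cells."""
    ct = cells.type_code[: cells.n_ids]
    core_ids = np.nonzero(ct == T_CORE)[0]
    if core_ids.size == 0:
        raise ValueError("no senescent core cell present")
    grid = lattice.grid
    types = ct[grid]
    core_cols = np.any(types == T_CORE, axis=2)

    body = types == T_BODY
    body_cols = np.any(body, axis=2)
    if body_cols.any():
        zi = np.arange(grid.shape[2])
        body_top = np.where(body, zi[None, None, :], -1).max(axis=2)
        z_body_top = float(np.median(body_top[body_cols]))
    else:
        z_body_top = 0.0  # no body: anything above the substrate counts

    n_on = 0
    for cid in np.nonzero(ct == T_TUMOR)[0]:
        if not np.any(grid == cid):
            continue
        cen = lattice.centroid(cid) / lattice.spacing
        cx, cy = int(round(cen[0])) % grid.shape[0], int(round(cen[1])) % grid.shape[1]
        if core_cols[cx, cy] and cen[2] > z_body_top:
            n_on += 1

    # tallest contiguous tumor-occupied z-run over the core footprint
    max_stack = 0
    tumor = types == T_TUMOR
    sub = tumor[core_cols]  # (n_cols, Lz)
    for col in sub:
        run = best = 0
        for v in col:
            run = run + 1 if v else 0
            best = max(best, run)
        max_stack = max(max_stack, best)
    return ClusterMetrics(
        n_cells_on_core=n_on,
        max_stack_height=max_stack,
        cluster_formed=n_on >= 2,
    )
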