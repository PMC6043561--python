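"""Tumor-cell replication and the mitotic-rounding adhesion schedule.

Tumor cells replicate on a noisy clock (normal period, mean 5000 s, sd
1000 s, redrawn if non-positive). At division onset t0 the dividing cell's
interface energies with other tumor cells and with the substrate switch to a
time-dependent schedule that relaxes exponentially back to the resting
values (time constants 100 s and 500 s respectively):

    tumor-tumor:   -6  -/+ 110 * exp(-(t - t0) / 100)
    tumor-matrix:  -20 -/+ 110 * exp(-(t - t0) / 500)

The printed form uses the minus sign (adhesion transiently *strengthens*);
the accompanying description says mitotic rounding *weakens* adhesion, which
corresponds to the plus sign. Both are provided via ``rounding_sign``; see
docs/methods.md for why the simulation default is the weakening variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import T_TUMOR
from .lattice import CellTable, Lattice


@dataclass
class CycleParams:
    """Replication-clock and rounding-schedule constants (time in seconds,
    energies in the dimensionless interaction-energy units of J)."""

    tau_r_mean: float = 5000.0
    tau_r_sd: float = 1000.0
    rounding_amplitude: float = 110.0
    rounding_tau_tt: float = 100.0
    rounding_tau_tm: float = 500.0
    resting_J_tt: float = -6.0
    resting_J_tm: float = -20.0
    rounding_sign: str = "as_printed"  # or "weakening"
    #: chemotactic-sensitivity multiplier for cells inside the rounding
    #: window (1.0 = constant sensitivity for all tumor cells)
    mu_rounding_boost: float = 1.0
    #: beyond this many multiples of the slower time constant the schedule
    #: is treated as fully relaxed (resting J used exactly)
    cutoff_factor: float = 10.0

    def __post_init__(self):
        if self.rounding_sign not in ("as_printed", "weakening"):
            raise ValueError(f"unknown rounding_sign {self.rounding_sign!r}")
        if self.tau_r_mean <= 0 or self.tau_r_sd < 0:
            raise ValueError("cycle length mean must be > 0 and sd >= 0")

    @property
    def sign(self) -> float:
        return -1.0 if self.rounding_sign == "as_printed" else 1.0

    @property
    def cutoff(self) -> float:
        return self.cutoff_factor * max(self.rounding_tau_tt, self.rounding_tau_tm)


def draw_cycle_length(params: CycleParams, rng: np.random.Generator) -> float:
    """One cell-cycle duration: normal(mean, sd), redrawn while <= 0."""
    if params.tau_r_sd == 0:
        return params.tau_r_mean
    while True:
        t = rng.normal(params.tau_r_mean, params.tau_r_sd)
        if t > 0:
            return float(t)


def adhesion_at(t: float, t0: float, pair: str, params: CycleParams) -> float:
    """Interaction energy of a rounding tumor cell at time t (onset t0).

    ``pair`` is "tumor-tumor" or "tumor-matrix". Before onset and beyond the
    relaxation cutoff the resting value is returned exactly.
    """
    if pair == "tumor-tumor":
        resting, tau = params.resting_J_tt, params.rounding_tau_tt
    elif pair == "tumor-matrix":
        resting, tau = params.resting_J_tm, params.rounding_tau_tm
    else:
        raise ValueError(f"unknown pair {pair!r}")
    dt = t - t0
    if dt < 0 or dt > params.cutoff:
        return resting
    return resting + params.sign * params.rounding_amplitude * np.exp(-dt / tau)


def rounding_factors(cells: CellTable, params: CycleParams, time: float, n: int):
    """Per-cell amplitude-scaled exponential offsets feeding the kernels.

    Returns (e_tt, e_tm, sign): arrays of 110*exp(-(t-t0)/tau) per cell
    (zero outside the rounding window) and the schedule sign. When two
    rounding cells touch, the kernel applies the larger offset (the more
    recent onset governs the pair).
    """
    e_tt = np.zeros(n)
    e_tm = np.zeros(n)
    m = cells.n_ids
    dt = time - cells.rounding_onset[:m]
    active = (dt >= 0) & (dt <= params.cutoff) & (cells.type_code[:m] == T_TUMOR)
    idx = np.nonzero(active)[0]
    if idx.size:
        a = params.rounding_amplitude
        e_tt[idx] = a * np.exp(-dt[idx] / params.rounding_tau_tt)
        e_tm[idx] = a * np.exp(-dt[idx] / params.rounding_tau_tm)
    return e_tt, e_tm, params.sign


class DivisionDeferred(Exception):
    """Raised when a cell is too small to split this step (< 2 sites)."""


def divide_cell(
    lattice: Lattice,
    cells: CellTable,
    cell_id: int,
    rng: np.random.Generator,
    time: float = 0.0,
    cycle: CycleParams | None = None,
    normal=None,
):
    """Split a tumor cell by a vertical plane through its centroid.

    The plane's normal is horizontal with uniformly random azimuth (division
    axis co-planar with the substrate), unless an explicit 3-vector
    ``normal`` is given. One half keeps the parent id, the other becomes a
    new cell; both daughters inherit the tumor targets, get fresh division
    clocks, rounding onset t0 = time, and generation + 1.

    Returns (kept_id, new_id).
    """
    if cells.type_code[cell_id] != T_TUMOR:
        raise ValueError(f"cell {cell_id} is not tumor-typed; only tumor cells divide")
    sites = np.argwhere(lattice.grid == cell_id)
    if len(sites) < 2:
        raise DivisionDeferred(f"cell {cell_id} has {len(sites)} site(s)")
    if normal is None:
        phi = rng.uniform(0, 2 * np.pi)
        normal = np.array([np.cos(phi), np.sin(phi), 0.0])
    normal = np.asarray(normal, dtype=float)

    # minimum-image displacement from the centroid on the periodic axes
    cen = lattice.centroid(cell_id) / lattice.spacing
    rel = sites.astype(float) - cen
    for ax in (0, 1):
        L = lattice.shape[ax]
        rel[:, ax] -= L * np.round(rel[:, ax] / L)
    side = rel @ normal
    keep = side < 0
    if keep.all() or not keep.any():
        # degenerate plane (all sites on one side): split by median instead
        order = np.argsort(side, kind="stable")
        keep = np.zeros(len(sites), dtype=bool)
        keep[order[: len(sites) // 2]] = True

    parent_gen = int(cells.generation[cell_id])
    new_id = cells.new_cell(
        "tumor",
        target_volume=float(cells.target_volume[cell_id]),
        target_surface=float(cells.target_surface[cell_id]),
        birth_time=time,
        generation=parent_gen + 1,
        born_by_division=True,
    )
    moved = sites[~keep]
    lattice.grid[moved[:, 0], moved[:, 1], moved[:, 2]] = new_id
    lattice.ensure_capacity(cells.n_ids)

    if cycle is None:
        cycle = CycleParams()
    for cid in (cell_id, new_id):
        cells.rounding_onset[cid] = time
        cells.generation[cid] = parent_gen + 1
        cells.birth_time[cid] = time
        cells.born_by_division[cid] = True
        cells.next_division_time[cid] = time + draw_cycle_length(cycle, rng)
    _refresh_local_caches(lattice, (cell_id, new_id))
    return cell_id, new_id


def _refresh_local_caches(lattice: Lattice, ids):
    """Recount volume and surface for the given cells only."""
    grid = lattice.grid
    Lx, Ly, Lz = grid.shape
    for cid in ids:
        sites = np.argwhere(grid == cid)
        lattice.volumes[cid] = len(sites)
        exposed = 0
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            jz = sites[:, 2] + dz
            ok = (jz >= 0) & (jz < Lz)
            jx = (sites[ok, 0] + dx) % Lx
            jy = (sites[ok, 1] + dy) % Ly
            exposed += int(np.sum(grid[jx, jy, jz[ok]] != cid))
        lattice.surfaces[cid] = exposed
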