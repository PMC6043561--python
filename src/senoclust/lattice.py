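"""Cellular Potts lattice, Hamiltonian and Metropolis copy kinetics.

The model follows the classic Glazier-Graner-Hogeweg construction: every
lattice site holds a cell id (0 is the culture medium), a cell is the domain
of sites sharing an id, and the configuration evolves by neighbor-id copy
attempts accepted with the Boltzmann rule ``p_copy``. The Hamiltonian has
three parts:

* elastic constraints ``lambda_V (v - V_t)^2 + lambda_P (P - P_t)^2`` on each
  cell's volume and surface area,
* type-pair interface energies ``J(tau_i, tau_j)`` summed over every
  unlike-cell site pair in the interaction neighborhood,
* a chemotactic bias applied per copy attempt when the extending cell is a
  tumor cell: ``mu * (omega(target) - omega(source))`` — with ``mu < 0``,
  extension up the chemoattractant gradient lowers the energy.

``total_hamiltonian`` is an independent, vectorized-numpy evaluation used as
the brute-force oracle; ``delta_H`` and ``monte_carlo_step`` run the
incremental numba kernels and must agree with the oracle to rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from . import _kernels
from ._kernels import (
    T_BODY,
    T_CORE,
    T_MATRIX,
    T_MEDIUM,
    T_TUMOR,
    neighbor_offsets,
)

TYPE_NAMES = {
    T_MEDIUM: "medium",
    T_CORE: "core",
    T_BODY: "body",
    T_TUMOR: "tumor",
    T_MATRIX: "matrix",
}
TYPE_CODES = {v: k for k, v in TYPE_NAMES.items()}

#: interaction energies printed in the model's parameter table; the
#: body-matrix pair is not listed there and defaults to the core-matrix value
#: so the thin senescent body stays adherent to the substrate.
DEFAULT_J = {
    ("core", "body"): -170.0,
    ("core", "tumor"): -10.0,
    ("core", "medium"): 10.0,
    ("core", "matrix"): -70.0,
    ("body", "medium"): 4.0,
    ("body", "body"): -120.0,
    ("body", "tumor"): -2.0,
    ("tumor", "tumor"): -6.0,
    ("tumor", "medium"): -4.0,
    ("tumor", "matrix"): -20.0,
    ("medium", "matrix"): 10.0,
    ("body", "matrix"): -70.0,
}


def j_matrix(pairs: Optional[dict] = None) -> np.ndarray:
    """Build the symmetric 5x5 type-pair energy matrix from a name-pair map."""
    J = np.zeros((5, 5), dtype=np.float64)
    for (a, b), v in {**DEFAULT_J, **(pairs or {})}.items():
        ia, ib = TYPE_CODES[a], TYPE_CODES[b]
        J[ia, ib] = J[ib, ia] = float(v)
    return J


def sphere_surface(volume: float) -> float:
    """Surface area of the sphere of the given volume."""
    return (36.0 * np.pi) ** (1.0 / 3.0) * volume ** (2.0 / 3.0)


class ConsistencyError(RuntimeError):
    """Lattice state disagrees with the cell records or cached statistics."""


@dataclass
class EnergyParams:
    """Energy functional parameters.

    J is the symmetric type-pair interaction matrix (5x5, indexed by type
    code); lambda_V and lambda_P are the volume and surface elasticities; mu
    the chemotactic sensitivity (negative pulls tumor cells up-gradient); T
    the Metropolis temperature; neighborhood_order selects the interaction /
    copy-candidate neighborhood (2 -> 18 neighbors).
    """

    J: np.ndarray = dc_field(default_factory=j_matrix)
    lambda_V: float = 2.0
    lambda_P: float = 0.1
    mu: float = -350.0
    T: float = 100.0
    neighborhood_order: int = 2

    def __post_init__(self):
        self.J = np.asarray(self.J, dtype=np.float64)
        if self.J.shape != (5, 5) or not np.allclose(self.J, self.J.T):
            raise ValueError("J must be a symmetric 5x5 matrix")
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T}")
        if self.neighborhood_order not in (1, 2):
            raise ValueError("neighborhood_order must be 1 or 2")

    @property
    def offsets(self) -> np.ndarray:
        return neighbor_offsets(self.neighborhood_order)


@dataclass
class CellRecord:
    """Read-only snapshot of one cell's bookkeeping."""

    id: int
    type: str
    target_volume: float
    target_surface: float
    birth_time: float
    next_division_time: float
    rounding_onset: float  # -inf when no rounding has occurred
    generation: int
    born_by_division: bool


class CellTable:
    """Per-cell bookkeeping backed by flat arrays (indexed by cell id).

    Id 0 is always the medium. Types are immutable after creation; only
    tumor cells carry division clocks.
    """

    _GROW = 64

    def __init__(self):
        n = self._GROW
        self.type_code = np.zeros(n, dtype=np.int32)
        self.target_volume = np.zeros(n, dtype=np.float64)
        self.target_surface = np.zeros(n, dtype=np.float64)
        self.birth_time = np.zeros(n, dtype=np.float64)
        self.next_division_time = np.full(n, np.inf)
        self.rounding_onset = np.full(n, -np.inf)
        self.generation = np.zeros(n, dtype=np.int64)
        self.born_by_division = np.zeros(n, dtype=bool)
        self.n_ids = 1  # id 0 = medium

    def _ensure(self, n):
        cap = len(self.type_code)
        if n <= cap:
            return
        new = max(n, cap * 2)
        for name in (
            "type_code",
            "target_volume",
            "target_surface",
            "birth_time",
            "next_division_time",
            "rounding_onset",
            "generation",
            "born_by_division",
        ):
            arr = getattr(self, name)
            grown = np.zeros(new, dtype=arr.dtype)
            if name == "next_division_time":
                grown[:] = np.inf
            elif name == "rounding_onset":
                grown[:] = -np.inf
            grown[: len(arr)] = arr
            setattr(self, name, grown)

    def new_cell(
        self,
        type: str,
        target_volume: float = 0.0,
        target_surface: float = 0.0,
        birth_time: float = 0.0,
        generation: int = 0,
        born_by_division: bool = False,
    ) -> int:
        cid = self.n_ids
        self._ensure(cid + 1)
        self.type_code[cid] = TYPE_CODES[type]
        self.target_volume[cid] = target_volume
        self.target_surface[cid] = target_surface
        self.birth_time[cid] = birth_time
        self.generation[cid] = generation
        self.born_by_division[cid] = born_by_division
        self.n_ids = cid + 1
        return cid

    def record(self, cid: int) -> CellRecord:
        return CellRecord(
            id=cid,
            type=TYPE_NAMES[int(self.type_code[cid])],
            target_volume=float(self.target_volume[cid]),
            target_surface=float(self.target_surface[cid]),
            birth_time=float(self.birth_time[cid]),
            next_division_time=float(self.next_division_time[cid]),
            rounding_onset=float(self.rounding_onset[cid]),
            generation=int(self.generation[cid]),
            born_by_division=bool(self.born_by_division[cid]),
        )

    def ids_of_type(self, type: str) -> np.ndarray:
        code = TYPE_CODES[type]
        ids = np.nonzero(self.type_code[: self.n_ids] == code)[0]
        return ids[ids > 0]

    @property
    def tumor_ids(self) -> np.ndarray:
        return self.ids_of_type("tumor")


class Lattice:
    """3D integer grid of cell ids with cached per-cell volume/surface.

    x and y are periodic; z is bounded. ``freeze_top`` pins the top z-plane
    to medium (the fixed ceiling of the culture chamber in the simulation
    scenario). Volume caches are site counts, surface caches exposed-face
    counts; physical values scale with ``spacing``.
    """

    def __init__(self, shape, spacing: float = 1.0, freeze_top: bool = False):
        self.grid = np.zeros(shape, dtype=np.int32)
        self.spacing = float(spacing)
        self.freeze_top = bool(freeze_top)
        self.volumes = np.zeros(_kernels_cap(1), dtype=np.int64)
        self.surfaces = np.zeros(_kernels_cap(1), dtype=np.int64)
        self.volumes[0] = self.grid.size

    @property
    def shape(self):
        return self.grid.shape

    def sync_caches(self, cells: CellTable):
        """Recompute volume/surface caches from the grid."""
        n = max(cells.n_ids, int(self.grid.max()) + 1)
        self.volumes = np.bincount(self.grid.ravel(), minlength=_kernels_cap(n)).astype(np.int64)
        surf = _kernels.recompute_surfaces(self.grid, n)
        self.surfaces = np.zeros(_kernels_cap(n), dtype=np.int64)
        self.surfaces[:n] = surf

    def ensure_capacity(self, n_ids: int):
        cap = _kernels_cap(n_ids)
        if len(self.volumes) < cap:
            self.volumes = np.concatenate(
                [self.volumes, np.zeros(cap - len(self.volumes), dtype=np.int64)]
            )
            self.surfaces = np.concatenate(
                [self.surfaces, np.zeros(cap - len(self.surfaces), dtype=np.int64)]
            )

    def check_consistency(self, cells: CellTable):
        """Verify every recorded cell occupies >= 1 site and caches match a
        from-scratch recount. Raises ConsistencyError on any mismatch."""
        n = cells.n_ids
        vols = np.bincount(self.grid.ravel(), minlength=n)
        if int(self.grid.max()) >= n:
            raise ConsistencyError("grid holds an id with no cell record")
        missing = np.nonzero(vols[1:n] == 0)[0] + 1
        if missing.size:
            raise ConsistencyError(f"cells absent from lattice: {missing.tolist()}")
        if not np.array_equal(vols[:n], self.volumes[:n]):
            raise ConsistencyError("cached volumes disagree with recount")
        surf = _kernels.recompute_surfaces(self.grid, n)
        if not np.array_equal(surf, self.surfaces[:n]):
            raise ConsistencyError("cached surfaces disagree with recount")

    def centroid(self, cid: int) -> np.ndarray:
        """Periodic-aware centroid (circular mean in x and y), in physical
        units."""
        sites = np.argwhere(self.grid == cid)
        if sites.size == 0:
            raise ConsistencyError(f"cell {cid} has no sites")
        out = np.empty(3)
        for ax in range(3):
            L = self.grid.shape[ax]
            coords = sites[:, ax].astype(float)
            if ax < 2:  # periodic axes
                ang = coords * (2 * np.pi / L)
                mean_ang = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
                out[ax] = (mean_ang * L / (2 * np.pi)) % L
            else:
                out[ax] = coords.mean()
        return out * self.spacing


def _kernels_cap(n: int) -> int:
    return max(n, 64)


def p_copy(delta_h: float, T: float) -> float:
    """Boltzmann acceptance probability of a copy attempt:
    1 if dH < 0, else exp(-dH / T)."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    if delta_h < 0:
        return 1.0
    return float(np.exp(-delta_h / T))


def _mu_array(cells: CellTable, params, cycle, time: float, n: int):
    """Per-cell chemotactic sensitivity: the base mu, optionally boosted for
    cells inside their mitotic-rounding window (cycle.mu_rounding_boost)."""
    mu = np.full(n, params.mu)
    if cycle is not None and getattr(cycle, "mu_rounding_boost", 1.0) != 1.0:
        m = cells.n_ids
        dt = time - cells.rounding_onset[:m]
        active = (
            (dt >= 0)
            & (dt <= cycle.cutoff)
            & (cells.type_code[:m] == TYPE_CODES["tumor"])
        )
        mu[:m][active] *= cycle.mu_rounding_boost
    return mu


def _rounding_arrays(cells: CellTable, cycle, time: float):
    """Per-cell amplitude-scaled rounding offsets for the two dynamic pairs
    (zero outside the rounding window)."""
    n = _kernels_cap(cells.n_ids)
    e_tt = np.zeros(n)
    e_tm = np.zeros(n)
    rsign = -1.0
    if cycle is None:
        return e_tt, e_tm, rsign
    from .cycle import rounding_factors  # local import avoids a cycle

    return rounding_factors(cells, cycle, time, n)


def total_hamiltonian(
    lattice: Lattice,
    cells: CellTable,
    params: EnergyParams,
    field=None,
    time: float = 0.0,
    cycle=None,
) -> float:
    """Full-configuration energy: elastic constraints plus interface energies.

    The chemotactic term is a per-move bias (it has no configuration
    functional) and is therefore excluded here; ``delta_H`` adds it for the
    move under evaluation. Serves as the brute-force oracle for the
    incremental kernels, so it is computed by an independent vectorized
    route (shifted-array sums, each unordered site pair counted once).
    """
    grid = lattice.grid
    n = cells.n_ids
    if int(grid.max()) >= n:
        raise ConsistencyError("grid holds an id with no cell record")
    vols = np.bincount(grid.ravel(), minlength=n)
    if np.any(vols[1:n] == 0):
        raise ConsistencyError("cell in records absent from lattice")
    h = lattice.spacing
    h3, h2 = h**3, h**2

    ctype = cells.type_code[:n]
    constrained = (ctype >= 1) & (ctype <= 3)
    e = 0.0
    dv = vols[:n] * h3 - cells.target_volume[:n]
    surf = _kernels.recompute_surfaces(grid, n)
    dp = surf * h2 - cells.target_surface[:n]
    e += params.lambda_V * np.sum(dv[constrained] ** 2)
    e += params.lambda_P * np.sum(dp[constrained] ** 2)

    e_tt, e_tm, rsign = _rounding_arrays(cells, cycle, time)
    offs = params.offsets
    half = offs[
        (offs[:, 0] > 0)
        | ((offs[:, 0] == 0) & (offs[:, 1] > 0))
        | ((offs[:, 0] == 0) & (offs[:, 1] == 0) & (offs[:, 2] > 0))
    ]
    Lz = grid.shape[2]
    for dx, dy, dz in half:
        if dz >= 0:
            a = grid[:, :, : Lz - dz] if dz else grid
            b = np.roll(np.roll(grid, -dx, axis=0), -dy, axis=1)[:, :, dz:]
        else:
            a = grid[:, :, -dz:]
            b = np.roll(np.roll(grid, -dx, axis=0), -dy, axis=1)[:, :, :dz]
        ida = a.ravel()
        idb = b.ravel()
        diff = ida != idb
        ida = ida[diff]
        idb = idb[diff]
        ta = ctype[ida]
        tb = ctype[idb]
        ej = params.J[ta, tb].copy()
        tt = (ta == T_TUMOR) & (tb == T_TUMOR)
        if tt.any():
            ej[tt] += rsign * np.maximum(e_tt[ida[tt]], e_tt[idb[tt]])
        tm = (ta == T_TUMOR) & (tb == T_MATRIX)
        if tm.any():
            ej[tm] += rsign * e_tm[ida[tm]]
        mt = (ta == T_MATRIX) & (tb == T_TUMOR)
        if mt.any():
            ej[mt] += rsign * e_tm[idb[mt]]
        e += ej.sum()
    return float(e)


def _dummy_field(lattice):
    return np.zeros(lattice.shape, dtype=np.float64)


def delta_H(
    lattice: Lattice,
    cells: CellTable,
    params: EnergyParams,
    field,
    target_site,
    candidate_id: int,
    source_site=None,
    time: float = 0.0,
    cycle=None,
) -> float:
    """Incremental energy change of copying ``candidate_id`` into
    ``target_site`` (local-stencil evaluation, never two full Hamiltonians).

    ``source_site`` is the neighbor site the id is copied from; it only
    matters for the chemotactic term and defaults to the first interaction
    neighbor holding the candidate id.
    """
    ix, iy, iz = (int(v) for v in target_site)
    a = int(lattice.grid[ix, iy, iz])
    if candidate_id == a:
        return 0.0
    offs = params.offsets
    if source_site is None:
        Lx, Ly, Lz = lattice.shape
        for dx, dy, dz in offs:
            jz = iz + dz
            if jz < 0 or jz >= Lz:
                continue
            jx, jy = (ix + dx) % Lx, (iy + dy) % Ly
            if lattice.grid[jx, jy, jz] == candidate_id:
                source_site = (jx, jy, jz)
                break
        else:
            raise ValueError("candidate_id is not the id of any neighbor site")
    sx, sy, sz = (int(v) for v in source_site)
    lattice.ensure_capacity(cells.n_ids)
    e_tt, e_tm, rsign = _rounding_arrays(cells, cycle, time)
    omega = field.omega if field is not None else _dummy_field(lattice)
    h = lattice.spacing
    tv = np.zeros(len(lattice.volumes))
    ts = np.zeros(len(lattice.volumes))
    tv[: cells.n_ids] = cells.target_volume[: cells.n_ids]
    ts[: cells.n_ids] = cells.target_surface[: cells.n_ids]
    ct = np.zeros(len(lattice.volumes), dtype=np.int32)
    ct[: cells.n_ids] = cells.type_code[: cells.n_ids]
    dh, _, _ = _kernels.site_delta_h(
        lattice.grid,
        ct,
        lattice.volumes,
        lattice.surfaces,
        tv,
        ts,
        params.lambda_V,
        params.lambda_P,
        h**3,
        h**2,
        params.J,
        e_tt,
        e_tm,
        rsign,
        _mu_array(cells, params, cycle, time, len(lattice.volumes)),
        omega,
        field is not None,
        ix,
        iy,
        iz,
        sx,
        sy,
        sz,
        int(candidate_id),
        offs,
    )
    return float(dh)


def monte_carlo_step(
    lattice: Lattice,
    cells: CellTable,
    params: EnergyParams,
    field=None,
    rng: Optional[np.random.Generator] = None,
    time: float = 0.0,
    cycle=None,
) -> dict:
    """One MCS: as many copy attempts as lattice sites. Matrix compartments
    are never overwritten or copied, the frozen top plane (if enabled) is
    never a target, and no cell can lose its last site. Returns acceptance
    statistics. Deterministic given (state, rng state)."""
    if rng is None:
        rng = np.random.default_rng()
    lattice.ensure_capacity(cells.n_ids)
    e_tt, e_tm, rsign = _rounding_arrays(cells, cycle, time)
    omega = field.omega if field is not None else _dummy_field(lattice)
    n = len(lattice.volumes)
    tv = np.zeros(n)
    ts = np.zeros(n)
    tv[: cells.n_ids] = cells.target_volume[: cells.n_ids]
    ts[: cells.n_ids] = cells.target_surface[: cells.n_ids]
    ct = np.zeros(n, dtype=np.int32)
    ct[: cells.n_ids] = cells.type_code[: cells.n_ids]
    h = lattice.spacing
    seed = int(rng.integers(0, 2**31 - 1))
    n_acc = _kernels.mcs_sweep(
        lattice.grid,
        ct,
        lattice.volumes,
        lattice.surfaces,
        tv,
        ts,
        params.lambda_V,
        params.lambda_P,
        h**3,
        h**2,
        params.J,
        e_tt,
        e_tm,
        rsign,
        _mu_array(cells, params, cycle, time, n),
        omega,
        field is not None,
        params.T,
        params.offsets,
        lattice.freeze_top,
        seed,
    )
    n_sites = lattice.grid.size
    return {
        "attempts": n_sites,
        "accepted": int(n_acc),
        "acceptance_rate": n_acc / n_sites,
    }
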