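"""Chemoattractant reaction-diffusion field coupled to the lattice.

The senescent core releases a single SASP-like chemoattractant omega which
diffuses, decays and is continuously produced at the core:

    d(omega)/dt = p * [site in core] - d * omega + D * laplacian(omega)

Solved by explicit forward Euler with a 7-point Laplacian on the lattice
grid. One call to :func:`step_field` advances one second (one MCS) of
physical time in ``n_substeps`` substeps chosen from the 3D stability bound
``D * dt / h^2 <= 1/6``. Boundary handling mirrors the lattice: x/y
periodic, the z faces no-flux, and matrix sites hold no field (no-flux
walls).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import _kernels
from ._kernels import T_CORE, T_MATRIX
from .lattice import CellTable, Lattice


class StabilityError(ValueError):
    """Requested time step violates the explicit-scheme stability bound."""


class ScalarField:
    """Non-negative chemoattractant concentration on the lattice grid.

    Parameters
    ----------
    shape : grid shape (must match the lattice).
    p : production rate at core sites (concentration / s).
    d : first-order decay rate (1/s).
    D : diffusion coefficient (um^2/s).
    spacing : lattice spacing (um).
    n_substeps : Euler substeps per second; ``None`` picks the smallest
        count satisfying ``D * dt / spacing^2 <= 1/6``.
    produce_everywhere : test mode applying the source term at every site.
    """

    def __init__(
        self,
        shape,
        p: float = 2.0,
        d: float = 0.02,
        D: float = 2.0,
        spacing: float = 1.0,
        n_substeps: Optional[int] = None,
        produce_everywhere: bool = False,
    ):
        self.omega = np.zeros(shape, dtype=np.float64)
        self.p = float(p)
        self.d = float(d)
        self.D = float(D)
        self.spacing = float(spacing)
        self.produce_everywhere = bool(produce_everywhere)
        h2 = self.spacing**2
        if n_substeps is None:
            n_substeps = max(1, int(np.ceil(6.0 * self.D / h2)))
        self.n_substeps = int(n_substeps)
        if self.D * self.dt_field / h2 > 1.0 / 6.0 + 1e-12:
            raise StabilityError(
                f"D*dt/h^2 = {self.D * self.dt_field / h2:.4f} exceeds the "
                f"3D explicit bound 1/6; increase n_substeps"
            )
        self._buf = np.empty_like(self.omega)

    @property
    def dt_field(self) -> float:
        return 1.0 / self.n_substeps


def _masks(field: ScalarField, lattice: Lattice, cells: Optional[CellTable]):
    if cells is None:
        matrix = np.zeros(lattice.shape, dtype=np.uint8)
        core = np.zeros(lattice.shape, dtype=np.uint8)
    else:
        ct = cells.type_code[: cells.n_ids]
        types = ct[lattice.grid]
        matrix = (types == T_MATRIX).astype(np.uint8)
        core = (types == T_CORE).astype(np.uint8)
    if field.produce_everywhere:
        core = 1 - matrix
    return matrix, core


def step_field(
    field: ScalarField,
    lattice: Lattice,
    cells: Optional[CellTable] = None,
    n_seconds: float = 1.0,
) -> ScalarField:
    """Advance the field by ``n_seconds`` of physical time (default one
    MCS). Production applies at senescent-core sites only (or everywhere in
    the field's test mode); matrix sites are excluded no-flux walls."""
    if field.omega.shape != lattice.shape:
        raise ValueError("field and lattice shapes differ")
    matrix, core = _masks(field, lattice, cells)
    nsub = int(round(n_seconds * field.n_substeps))
    # fast path: matrix occupies exactly the bottom z slab (the usual layout)
    z0 = 0
    Lz = lattice.shape[2]
    while z0 < Lz and matrix[:, :, z0].all():
        z0 += 1
    if z0 < Lz and not matrix[:, :, z0:].any():
        prod_idx = np.flatnonzero(core)
        _kernels.field_sweep_floor(
            field.omega,
            field._buf,
            prod_idx,
            field.p,
            field.d,
            field.D,
            field.spacing**2,
            field.dt_field,
            nsub,
            z0,
        )
    else:
        _kernels.field_sweep(
            field.omega,
            field._buf,
            matrix,
            core,
            field.p,
            field.d,
            field.D,
            field.spacing**2,
            field.dt_field,
            nsub,
        )
    return field


def sample_gradient_pair(field: ScalarField, x, x_prime) -> float:
    """Concentration difference omega(x') - omega(x) between two sites."""
    ix = tuple(int(v) for v in x)
    ip = tuple(int(v) for v in x_prime)
    return float(field.omega[ip] - field.omega[ix])


def equilibrate(
    field: ScalarField,
    lattice: Lattice,
    cells: Optional[CellTable],
    burn_in: float,
) -> ScalarField:
    """Pre-run the field for ``burn_in`` seconds on a frozen lattice so the
    chemotactic gradient is near steady state before cells start moving."""
    if burn_in > 0:
        step_field(field, lattice, cells, n_seconds=burn_in)
    return field
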