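"""Numba kernels for the Metropolis sweep and the reaction-diffusion field.

Conventions shared by every kernel:

* ``grid`` is a C-contiguous int32 array of shape (Lx, Ly, Lz) holding cell
  ids; ``ctype`` maps cell id -> type code.
* x and y are periodic; z is clamped (an out-of-range z neighbor simply does
  not exist: it contributes no interface energy and no exposed surface face).
* volume caches are in lattice-site counts, surface caches in exposed-face
  counts (6-connectivity); physical units enter the energy through ``h3``
  (spacing**3) and ``h2`` (spacing**2).
* ``e_tt``/``e_tm`` are per-cell mitotic-rounding offsets, already scaled by
  the rounding amplitude; ``rsign`` is -1 for the as-printed schedule
  (adhesion strengthens) and +1 for the weakening variant.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# cell type codes
T_MEDIUM = 0
T_CORE = 1
T_BODY = 2
T_TUMOR = 3
T_MATRIX = 4


def neighbor_offsets(order: int) -> np.ndarray:
    """Offsets of the interaction neighborhood (order 1: 6 faces; order 2
    adds the 12 edge diagonals, i.e. all sites within distance sqrt(2))."""
    if order not in (1, 2):
        raise ValueError(f"neighborhood order must be 1 or 2, got {order}")
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                r2 = dx * dx + dy * dy + dz * dz
                if r2 == 0:
                    continue
                if (order == 1 and r2 == 1) or (order == 2 and r2 <= 2):
                    offs.append((dx, dy, dz))
    return np.asarray(offs, dtype=np.int64)


OFFS_6 = neighbor_offsets(1)


@njit(cache=True, inline="always")
def _pair_energy(p, q, ctype, J, e_tt, e_tm, rsign):
    """Interface energy between two sites of distinct cells p and q."""
    tp = ctype[p]
    tq = ctype[q]
    j = J[tp, tq]
    if tp == T_TUMOR and tq == T_TUMOR:
        e = e_tt[p] if e_tt[p] > e_tt[q] else e_tt[q]
        if e > 0.0:
            j += rsign * e
    elif tp == T_TUMOR and tq == T_MATRIX:
        if e_tm[p] > 0.0:
            j += rsign * e_tm[p]
    elif tp == T_MATRIX and tq == T_TUMOR:
        if e_tm[q] > 0.0:
            j += rsign * e_tm[q]
    return j


@njit(cache=True)
def site_delta_h(
    grid,
    ctype,
    volc,
    surfc,
    tvol,
    tsurf,
    lam_v,
    lam_p,
    h3,
    h2,
    J,
    e_tt,
    e_tm,
    rsign,
    mu_cell,
    omega,
    use_field,
    ix,
    iy,
    iz,
    sx,
    sy,
    sz,
    cand,
    offs,
):
    """Incremental energy change of copying cell id ``cand`` (whose source
    site is (sx,sy,sz)) into target site (ix,iy,iz).

    Returns (dH, dsurf_a, dsurf_b): the energy change and the exposed-face
    count changes of the displaced cell a and the extending cell cand.
    """
    Lx, Ly, Lz = grid.shape
    a = grid[ix, iy, iz]
    if a == cand:
        return 0.0, 0, 0

    dh = 0.0
    ta = ctype[a]
    tb = ctype[cand]

    # --- volume elasticity ---------------------------------------------
    if 1 <= ta <= 3:
        dv = volc[a] * h3 - tvol[a]
        dh += lam_v * ((dv - h3) ** 2 - dv * dv)
    if 1 <= tb <= 3:
        dv = volc[cand] * h3 - tvol[cand]
        dh += lam_v * ((dv + h3) ** 2 - dv * dv)

    # --- surface elasticity (6-connectivity) ---------------------------
    n_in = 0
    n_a = 0
    n_b = 0
    for m in range(6):
        jx = ix + OFFS_6[m, 0]
        jy = iy + OFFS_6[m, 1]
        jz = iz + OFFS_6[m, 2]
        if jz < 0 or jz >= Lz:
            continue
        if jx < 0:
            jx += Lx
        elif jx >= Lx:
            jx -= Lx
        if jy < 0:
            jy += Ly
        elif jy >= Ly:
            jy -= Ly
        n_in += 1
        c = grid[jx, jy, jz]
        if c == a:
            n_a += 1
        if c == cand:
            n_b += 1
    dsa = 2 * n_a - n_in
    dsb = n_in - 2 * n_b
    if 1 <= ta <= 3:
        ds = surfc[a] * h2 - tsurf[a]
        dh += lam_p * ((ds + dsa * h2) ** 2 - ds * ds)
    if 1 <= tb <= 3:
        ds = surfc[cand] * h2 - tsurf[cand]
        dh += lam_p * ((ds + dsb * h2) ** 2 - ds * ds)

    # --- interface energies over the interaction neighborhood ----------
    for m in range(offs.shape[0]):
        jx = ix + offs[m, 0]
        jy = iy + offs[m, 1]
        jz = iz + offs[m, 2]
        if jz < 0 or jz >= Lz:
            continue
        if jx < 0:
            jx += Lx
        elif jx >= Lx:
            jx -= Lx
        if jy < 0:
            jy += Ly
        elif jy >= Ly:
            jy -= Ly
        c = grid[jx, jy, jz]
        if c != cand:
            dh += _pair_energy(cand, c, ctype, J, e_tt, e_tm, rsign)
        if c != a:
            dh -= _pair_energy(a, c, ctype, J, e_tt, e_tm, rsign)

    # --- chemotaxis: the extending cell is chemotactic if tumor-typed ---
    if use_field and tb == T_TUMOR:
        dh += mu_cell[cand] * (omega[ix, iy, iz] - omega[sx, sy, sz])

    return dh, dsa, dsb


@njit(cache=True)
def mcs_sweep(
    grid,
    ctype,
    volc,
    surfc,
    tvol,
    tsurf,
    lam_v,
    lam_p,
    h3,
    h2,
    J,
    e_tt,
    e_tm,
    rsign,
    mu_cell,
    omega,
    use_field,
    temp,
    offs,
    freeze_top,
    seed,
):
    """One Monte Carlo step: Lx*Ly*Lz copy attempts with Metropolis
    acceptance, updating volume/surface caches in place.

    Returns the number of accepted copies.
    """
    np.random.seed(seed)
    Lx, Ly, Lz = grid.shape
    n_sites = Lx * Ly * Lz
    n_offs = offs.shape[0]
    n_acc = 0
    for _ in range(n_sites):
        r = int(np.random.random() * n_sites)
        iz = r % Lz
        iy = (r // Lz) % Ly
        ix = r // (Lz * Ly)
        if freeze_top and iz == Lz - 1:
            continue
        a = grid[ix, iy, iz]
        if ctype[a] == T_MATRIX:
            continue
        m = int(np.random.random() * n_offs)
        sz = iz + offs[m, 2]
        if sz < 0 or sz >= Lz:
            continue
        sx = ix + offs[m, 0]
        if sx < 0:
            sx += Lx
        elif sx >= Lx:
            sx -= Lx
        sy = iy + offs[m, 1]
        if sy < 0:
            sy += Ly
        elif sy >= Ly:
            sy -= Ly
        cand = grid[sx, sy, sz]
        if cand == a:
            continue
        if ctype[cand] == T_MATRIX:
            continue
        if a != 0 and volc[a] <= 1:
            continue  # cells never vanish by copy attempts
        dh, dsa, dsb = site_delta_h(
            grid, ctype, volc, surfc, tvol, tsurf, lam_v, lam_p, h3, h2,
            J, e_tt, e_tm, rsign, mu_cell, omega, use_field,
            ix, iy, iz, sx, sy, sz, cand, offs,
        )
        if dh < 0.0 or np.random.random() < np.exp(-dh / temp):
            grid[ix, iy, iz] = cand
            volc[a] -= 1
            volc[cand] += 1
            surfc[a] += dsa
            surfc[cand] += dsb
            n_acc += 1
    return n_acc


@njit(cache=True)
def recompute_surfaces(grid, n_ids):
    """Exposed-face counts per cell id, recomputed from scratch
    (6-connectivity; x/y periodic, z boundaries count no face)."""
    Lx, Ly, Lz = grid.shape
    surf = np.zeros(n_ids, dtype=np.int64)
    for ix in range(Lx):
        for iy in range(Ly):
            for iz in range(Lz):
                a = grid[ix, iy, iz]
                for m in range(6):
                    jz = iz + OFFS_6[m, 2]
                    if jz < 0 or jz >= Lz:
                        continue
                    jx = (ix + OFFS_6[m, 0]) % Lx
                    jy = (iy + OFFS_6[m, 1]) % Ly
                    if grid[jx, jy, jz] != a:
                        surf[a] += 1
    return surf


@njit(cache=True)
def field_sweep_floor(omega, buf, prod_idx, p, d, D, h2, dt, nsub, z0):
    """Fast field path for the common geometry: matrix occupies exactly the
    z < z0 slab, so the field lives on z in [z0, Lz) with no-flux z faces
    and no per-site mask tests. Production is applied at the sparse site
    list ``prod_idx`` (flattened indices)."""
    Lx, Ly, Lz = omega.shape
    k = dt * D / h2
    decay = dt * d
    src = dt * p
    for _ in range(nsub):
        for ix in range(Lx):
            ixp = ix + 1 if ix + 1 < Lx else 0
            ixm = ix - 1 if ix > 0 else Lx - 1
            for iy in range(Ly):
                iyp = iy + 1 if iy + 1 < Ly else 0
                iym = iy - 1 if iy > 0 else Ly - 1
                for iz in range(z0, Lz):
                    w = omega[ix, iy, iz]
                    lap = (
                        omega[ixp, iy, iz]
                        + omega[ixm, iy, iz]
                        + omega[ix, iyp, iz]
                        + omega[ix, iym, iz]
                        - 4.0 * w
                    )
                    if iz + 1 < Lz:
                        lap += omega[ix, iy, iz + 1] - w
                    if iz > z0:
                        lap += omega[ix, iy, iz - 1] - w
                    buf[ix, iy, iz] = w - decay * w + k * lap
        for j in range(prod_idx.shape[0]):
            f = prod_idx[j]
            buf[f // (Ly * Lz), (f // Lz) % Ly, f % Lz] += src
        omega[:, :, z0:] = buf[:, :, z0:]


@njit(cache=True)
def field_sweep(omega, buf, matrix_mask, prod_mask, p, d, D, h2, dt, nsub):
    """Advance the chemoattractant field by ``nsub`` explicit Euler substeps
    of length ``dt`` (7-point Laplacian, x/y periodic, z and matrix no-flux).

    ``prod_mask`` marks sites producing at rate p (the senescent core, or
    every site in test mode). Matrix sites hold no field and exchange none.
    """
    Lx, Ly, Lz = omega.shape
    k = D / h2
    for _ in range(nsub):
        for ix in range(Lx):
            for iy in range(Ly):
                for iz in range(Lz):
                    if matrix_mask[ix, iy, iz]:
                        buf[ix, iy, iz] = omega[ix, iy, iz]
                        continue
                    w = omega[ix, iy, iz]
                    lap = 0.0
                    for m in range(6):
                        jz = iz + OFFS_6[m, 2]
                        if jz < 0 or jz >= Lz:
                            continue
                        jx = (ix + OFFS_6[m, 0]) % Lx
                        jy = (iy + OFFS_6[m, 1]) % Ly
                        if matrix_mask[jx, jy, jz]:
                            continue
                        lap += omega[jx, jy, jz] - w
                    src = p if prod_mask[ix, iy, iz] else 0.0
                    buf[ix, iy, iz] = w + dt * (src - d * w + k * lap)
        omega[:, :, :] = buf
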