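"""Initial lattice geometry: the fried-egg senescent cell and its neighbors.

The canonical layout places, on a one-site-thick frozen substrate (matrix):

* one senescent **core** -- a digitized hemisphere sitting at the grid
  center (target volume 1800 um^3, asperity 0.8);
* the senescent **body** -- a thin annular sheet around the core split into
  equal angular wedges, one evolving cell each (48 wedges of 600 um^3 at
  full scale);
* **tumor** cells -- near-cubic blocks (400 um^3) seeded in a ring just
  outside the body.

Everything else is medium, and the top z-plane is pinned to medium. The
layout scales to reduced grids by configuring fewer body/tumor cells; the
body thickness is auto-selected as the thinnest sheet whose ring of tumor
cells still fits without overlap.

A second layout, "plate", seeds only tumor cells on the substrate (used for
division-statistics runs with no senescent cell).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .lattice import CellTable, Lattice, sphere_surface


class LayoutError(ValueError):
    """The requested layout does not fit the grid."""


@dataclass
class InitConfig:
    grid: Tuple[int, int, int] = (200, 200, 50)
    spacing: float = 1.0
    layout: str = "senescent"  # or "plate"
    n_body: int = 48
    n_tumor: int = 20
    core_volume: float = 1800.0
    body_volume: float = 600.0
    tumor_volume: float = 400.0
    asperity_core: float = 0.8
    asperity_body: float = 0.8
    asperity_tumor: float = 1.4
    body_thickness: Optional[int] = None  # None: thinnest that fits

    def __post_init__(self):
        if self.layout not in ("senescent", "plate"):
            raise ValueError(f"unknown layout {self.layout!r}")


def _target_surface(volume: float, asperity: float) -> float:
    """Target surface = asperity x surface of the equal-volume sphere
    (asperity ~ 1 means sphere-like)."""
    return asperity * sphere_surface(volume)


def _tumor_box_dims(volume_sites: float) -> Tuple[int, int, int]:
    """Near-cubic integer box with site count closest to the target."""
    s = volume_sites ** (1.0 / 3.0)
    best = None
    for sx in range(max(2, int(s) - 1), int(s) + 3):
        for sy in range(max(2, int(s) - 1), int(s) + 3):
            for sz in range(max(2, int(s) - 1), int(s) + 3):
                err = abs(sx * sy * sz - volume_sites)
                if best is None or err < best[0]:
                    best = (err, (sx, sy, sz))
    return best[1]


def _hemisphere_radius(target_sites: int, lz_room: int) -> Tuple[float, np.ndarray]:
    """Radius whose digitized hemisphere (z >= 0 half-ball) site count is
    closest to target; returns (radius, offsets array of shape (k, 3))."""
    best = None
    for r in np.arange(2.0, 40.0, 0.05):
        rr = int(np.ceil(r))
        zs = np.arange(0, min(rr + 1, lz_room))
        xs = np.arange(-rr, rr + 1)
        X, Y, Z = np.meshgrid(xs, xs, zs, indexing="ij")
        inside = X**2 + Y**2 + Z**2 <= r**2
        count = int(inside.sum())
        err = abs(count - target_sites)
        if best is None or err < best[0]:
            offs = np.stack([X[inside], Y[inside], Z[inside]], axis=1)
            best = (err, r, offs)
        if count > 1.5 * target_sites:
            break
    return best[1], best[2]


def _build_senescent(config: InitConfig, h_body: int):
    Lx, Ly, Lz = config.grid
    h3 = config.spacing**3
    lattice = Lattice(config.grid, spacing=config.spacing, freeze_top=True)
    cells = CellTable()
    grid = lattice.grid

    matrix_id = cells.new_cell("matrix")
    grid[:, :, 0] = matrix_id

    cx, cy = (Lx - 1) / 2.0, (Ly - 1) / 2.0
    icx, icy = int(round(cx)), int(round(cy))

    # --- core: digitized hemisphere resting on the substrate ------------
    core_sites_target = int(round(config.core_volume / h3))
    r_core, offs = _hemisphere_radius(core_sites_target, Lz - 2)
    if int(np.ceil(r_core)) + 1 >= Lz - 1:
        raise LayoutError("core does not fit below the frozen top plane")
    core_id = cells.new_cell(
        "core",
        target_volume=config.core_volume,
        target_surface=_target_surface(config.core_volume, config.asperity_core),
    )
    grid[(offs[:, 0] + icx) % Lx, (offs[:, 1] + icy) % Ly, offs[:, 2] + 1] = core_id
    n_core = int(np.sum(grid == core_id))
    if abs(n_core * h3 - config.core_volume) > 0.10 * config.core_volume:
        raise LayoutError("digitized core volume misses its target by > 10%")

    # --- body: annular sheet of equal angular wedges ---------------------
    body_sites = int(round(config.n_body * config.body_volume / h3))
    zs = np.arange(1, 1 + h_body)
    if zs[-1] >= Lz - 1:
        raise LayoutError("body sheet reaches the frozen top plane")
    X, Y, Z = np.meshgrid(np.arange(Lx), np.arange(Ly), zs, indexing="ij")
    free = grid[:, :, zs] == 0
    rho = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2)
    cand = np.argwhere(free)
    cand_rho = rho[free]
    if len(cand) < body_sites:
        raise LayoutError("not enough room for the body sheet")
    order = np.argsort(cand_rho, kind="stable")[:body_sites]
    sel = cand[order]
    sel_x, sel_y, sel_z = sel[:, 0], sel[:, 1], zs[sel[:, 2]]
    r_body_outer = float(cand_rho[order].max())

    angles = np.arctan2(sel_y - cy, sel_x - cx)
    ang_order = np.argsort(angles, kind="stable")
    chunks = np.array_split(ang_order, config.n_body)
    body_ids = []
    for chunk in chunks:
        bid = cells.new_cell(
            "body",
            target_volume=config.body_volume,
            target_surface=_target_surface(config.body_volume, config.asperity_body),
        )
        grid[sel_x[chunk], sel_y[chunk], sel_z[chunk]] = bid
        body_ids.append(bid)

    # --- tumor ring -------------------------------------------------------
    box = _tumor_box_dims(config.tumor_volume / h3)
    if abs(np.prod(box) * h3 - config.tumor_volume) > 0.10 * config.tumor_volume:
        raise LayoutError("no integer box matches the tumor target volume within 10%")
    if box[2] + 1 >= Lz - 1:
        raise LayoutError("tumor cells reach the frozen top plane")
    half_diag = 0.5 * np.hypot(box[0], box[1])
    ring_r = r_body_outer + half_diag + 1.5
    tumor_ids = []
    for k in range(config.n_tumor):
        theta = 2 * np.pi * k / config.n_tumor
        bx = int(round(cx + ring_r * np.cos(theta) - box[0] / 2))
        by = int(round(cy + ring_r * np.sin(theta) - box[1] / 2))
        xs = (np.arange(bx, bx + box[0])) % Lx
        ys = (np.arange(by, by + box[1])) % Ly
        zsl = np.arange(1, 1 + box[2])
        sub = grid[np.ix_(xs, ys, zsl)]
        if np.any(sub != 0):
            raise LayoutError("tumor ring overlaps existing cells")
        tid = cells.new_cell(
            "tumor",
            target_volume=config.tumor_volume,
            target_surface=_target_surface(config.tumor_volume, config.asperity_tumor),
        )
        grid[np.ix_(xs, ys, zsl)] = tid
        tumor_ids.append(tid)

    lattice.sync_caches(cells)
    return lattice, cells


def _build_plate(config: InitConfig):
    """Only tumor cells, on a square arrangement over the substrate."""
    Lx, Ly, Lz = config.grid
    h3 = config.spacing**3
    lattice = Lattice(config.grid, spacing=config.spacing, freeze_top=True)
    cells = CellTable()
    grid = lattice.grid
    matrix_id = cells.new_cell("matrix")
    grid[:, :, 0] = matrix_id

    box = _tumor_box_dims(config.tumor_volume / h3)
    n_side = int(np.ceil(np.sqrt(config.n_tumor)))
    pitch_x = Lx // n_side
    pitch_y = Ly // n_side
    if pitch_x < box[0] + 1 or pitch_y < box[1] + 1 or box[2] + 1 >= Lz - 1:
        raise LayoutError(f"{config.n_tumor} tumor cells do not fit the plate grid")
    placed = 0
    for i in range(n_side):
        for j in range(n_side):
            if placed >= config.n_tumor:
                break
            bx = i * pitch_x + (pitch_x - box[0]) // 2
            by = j * pitch_y + (pitch_y - box[1]) // 2
            tid = cells.new_cell(
                "tumor",
                target_volume=config.tumor_volume,
                target_surface=_target_surface(config.tumor_volume, config.asperity_tumor),
            )
            grid[bx : bx + box[0], by : by + box[1], 1 : 1 + box[2]] = tid
            placed += 1
    lattice.sync_caches(cells)
    return lattice, cells


def gen_initial_lattice(config: InitConfig):
    """Build the initial (Lattice, CellTable) for the configured layout.

    Raises LayoutError if the geometry cannot fit the grid."""
    if config.layout == "plate":
        return _build_plate(config)
    thicknesses = (
        [config.body_thickness]
        if config.body_thickness is not None
        else list(range(2, 13))
    )
    last_err = None
    for h in thicknesses:
        try:
            return _build_senescent(config, h)
        except LayoutError as e:
            last_err = e
    raise LayoutError(f"layout does not fit grid {config.grid}: {last_err}")
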