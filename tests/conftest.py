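import numpy as np
import pytest

from senoclust.lattice import CellTable, EnergyParams, Lattice


def make_random_lattice(seed, shape=(6, 6, 3), n_cells=3):
    """Small random multi-cell lattice for oracle-equivalence and kinetics
    tests: a few irregular blobs of mixed types over medium."""
    r = np.random.default_rng(seed)
    cells = CellTable()
    lat = Lattice(shape)
    types = ["tumor", "body", "core", "tumor", "body"]
    ids = [
        cells.new_cell(types[i % len(types)], target_volume=20.0, target_surface=50.0)
        for i in range(n_cells)
    ]
    for cid in ids:
        n = int(r.integers(5, 15))
        x0, y0, z0 = (int(r.integers(0, s)) for s in shape)
        for _ in range(n):
            dx, dy, dz = (int(v) for v in r.integers(-1, 2, 3))
            lat.grid[
                (x0 + dx) % shape[0],
                (y0 + dy) % shape[1],
                min(max(z0 + dz, 0), shape[2] - 1),
            ] = cid
    for k, cid in enumerate(ids):  # every cell keeps at least one site
        lat.grid[k % shape[0], 0, 0] = cid
    lat.sync_caches(cells)
    return lat, cells


@pytest.fixture
def small_lattice():
    return make_random_lattice(0)


@pytest.fixture
def default_params():
    return EnergyParams()
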