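"""Lattice, Hamiltonian and Metropolis-kinetics unit tests."""

import numpy as np
import pytest

from senoclust.cycle import CycleParams
from senoclust.field import ScalarField
from senoclust.lattice import (
    CellTable,
    ConsistencyError,
    EnergyParams,
    Lattice,
    delta_H,
    j_matrix,
    monte_carlo_step,
    p_copy,
    total_hamiltonian,
)

from conftest import make_random_lattice


class TestPCopy:
    @pytest.mark.parametrize(
        "dh,T,expected",
        [
            (-5.0, 100.0, 1.0),  # favorable moves always accepted
            (0.0, 100.0, 1.0),  # e^0 = 1
            (100.0, 100.0, np.exp(-1.0)),
            (230.0, 100.0, np.exp(-2.3)),
        ],
    )
    def test_boltzmann_rule(self, dh, T, expected):
        assert p_copy(dh, T) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("T", [0.0, -1.0])
    def test_nonpositive_temperature_rejected(self, T):
        with pytest.raises(ValueError):
            p_copy(1.0, T)

    def test_probability_bounds(self):
        rng = np.random.default_rng(0)
        for dh, T in zip(rng.normal(0, 50, 200), rng.uniform(0.1, 200, 200)):
            assert 0.0 <= p_copy(dh, T) <= 1.0


class TestTotalHamiltonian:
    def test_empty_lattice_is_zero(self, default_params):
        lat = Lattice((5, 5, 5))
        cells = CellTable()
        lat.sync_caches(cells)
        assert total_hamiltonian(lat, cells, default_params) == 0.0

    def test_single_cube_interface_energy(self):
        # a 2x2x2 tumor cell surrounded by medium exposes 24 faces; at
        # neighborhood order 1 the interaction term is 24 * J(tumor, medium)
        lat = Lattice((6, 6, 6))
        cells = CellTable()
        cid = cells.new_cell("tumor", target_volume=8.0, target_surface=0.0)
        lat.grid[2:4, 2:4, 2:4] = cid
        lat.sync_caches(cells)
        params = EnergyParams(lambda_V=3.0, lambda_P=0.0, neighborhood_order=1)
        expected = 24 * params.J[3, 0]  # volume term vanishes at v == V_t
        assert total_hamiltonian(lat, cells, params) == pytest.approx(expected)

    def test_order2_adds_diagonal_pairs(self):
        # enumerate unlike pairs by brute force at order 2 on the same cube
        lat = Lattice((6, 6, 6))
        cells = CellTable()
        cid = cells.new_cell("tumor", target_volume=8.0)
        lat.grid[2:4, 2:4, 2:4] = cid
        lat.sync_caches(cells)
        params = EnergyParams(lambda_V=0.0, lambda_P=0.0, neighborhood_order=2)
        count = 0
        offs = params.offsets
        for x in range(6):
            for y in range(6):
                for z in range(6):
                    for dx, dy, dz in offs:
                        z2 = z + dz
                        if not (0 <= z2 < 6):
                            continue
                        if lat.grid[x, y, z] != lat.grid[(x + dx) % 6, (y + dy) % 6, z2]:
                            count += 1
        expected = (count / 2) * params.J[3, 0]
        assert total_hamiltonian(lat, cells, params) == pytest.approx(expected)

    def test_missing_cell_raises(self, default_params):
        lat = Lattice((4, 4, 4))
        cells = CellTable()
        cells.new_cell("tumor", target_volume=1.0)
        lat.sync_caches(cells)
        lat.grid[:] = 0  # cell record exists but occupies no site
        with pytest.raises(ConsistencyError):
            total_hamiltonian(lat, cells, default_params)


class TestDeltaH:
    def test_identical_candidate_is_zero(self, small_lattice, default_params):
        lat, cells = small_lattice
        site = (0, 0, 0)
        cand = int(lat.grid[site])
        assert delta_H(lat, cells, default_params, None, site, cand) == 0.0

    def test_chemotaxis_term_sign(self):
        # with constraints and J zeroed, a tumor cell extending into a site
        # 5 units higher in omega at mu = -2 gives dH = -10
        lat = Lattice((5, 5, 3))
        cells = CellTable()
        cid = cells.new_cell("tumor", target_volume=0.0)
        lat.grid[2, 2, 1] = cid
        lat.sync_caches(cells)
        params = EnergyParams(
            J=np.zeros((5, 5)), lambda_V=0.0, lambda_P=0.0, mu=-2.0
        )
        fld = ScalarField(lat.shape, p=0, d=0, D=1)
        fld.omega[2, 2, 1] = 2.0
        fld.omega[2, 3, 1] = 7.0
        dh = delta_H(
            lat, cells, params, fld, (2, 3, 1), cid, source_site=(2, 2, 1)
        )
        assert dh == pytest.approx(-10.0)

    @pytest.mark.parametrize("with_field", [False, True])
    @pytest.mark.parametrize("with_rounding", [False, True])
    def test_incremental_matches_bruteforce_oracle(self, with_field, with_rounding):
        """Incremental dH equals the difference of two full Hamiltonian
        evaluations on random lattices, to 1e-9."""
        params = EnergyParams()
        cyc = CycleParams()
        worst = 0.0
        n_checked = 0
        for s in range(100):
            lat, cells = make_random_lattice(s)
            fld = None
            if with_field:
                fld = ScalarField(lat.shape, p=0, d=0, D=1)
                fld.omega[:] = np.random.default_rng(s).random(lat.shape) * 10
            if with_rounding:
                tids = cells.tumor_ids
                if len(tids):
                    cells.rounding_onset[tids[0]] = -50.0
            r = np.random.default_rng(1000 + s)
            offs = params.offsets
            for _ in range(10):
                site = tuple(int(r.integers(0, d)) for d in lat.shape)
                o = offs[r.integers(0, len(offs))]
                nb = (
                    (site[0] + o[0]) % lat.shape[0],
                    (site[1] + o[1]) % lat.shape[1],
                    site[2] + o[2],
                )
                if not (0 <= nb[2] < lat.shape[2]):
                    continue
                cand = int(lat.grid[nb])
                if cand == int(lat.grid[site]):
                    continue
                h0 = total_hamiltonian(lat, cells, params, time=0.0, cycle=cyc)
                chemo = 0.0
                if with_field and cells.type_code[cand] == 3:
                    chemo = params.mu * (fld.omega[site] - fld.omega[nb])
                dh = delta_H(
                    lat, cells, params, fld, site, cand,
                    source_site=nb, time=0.0, cycle=cyc,
                )
                saved = int(lat.grid[site])
                lat.grid[site] = cand
                lat2 = Lattice(lat.shape)
                lat2.grid = lat.grid
                h1 = total_hamiltonian(lat2, cells, params, time=0.0, cycle=cyc)
                lat.grid[site] = saved
                worst = max(worst, abs((h1 - h0 + chemo) - dh))
                n_checked += 1
        assert n_checked >= 100
        assert worst < 1e-9


class TestMonteCarloStep:
    def test_zero_temperature_energy_descent(self, default_params):
        lat, cells = make_random_lattice(3)
        params = EnergyParams(T=1e-6)
        rng = np.random.default_rng(0)
        h_prev = total_hamiltonian(lat, cells, params)
        for t in range(30):
            monte_carlo_step(lat, cells, params, rng=rng, time=float(t))
            h = total_hamiltonian(lat, cells, params)
            assert h <= h_prev + 1e-9
            h_prev = h

    def test_volume_relaxes_to_target(self):
        # a single elastic cell below target inflates to V_t and stays
        # within the thermal fluctuation band sqrt(T / (2 lambda_V))
        lat = Lattice((12, 12, 12))
        cells = CellTable()
        cid = cells.new_cell("tumor", target_volume=60.0, target_surface=0.0)
        lat.grid[4:7, 4:7, 4:7] = cid  # 27 sites
        lat.sync_caches(cells)
        params = EnergyParams(J=np.zeros((5, 5)), lambda_V=2.0, lambda_P=0.0)
        rng = np.random.default_rng(1)
        vols = []
        for t in range(250):
            monte_carlo_step(lat, cells, params, rng=rng, time=float(t))
            if t >= 150:
                vols.append(lat.volumes[cid])
        assert abs(np.mean(vols) - 60.0) < 10.0

    def test_determinism_bit_identical(self, default_params):
        grids = []
        for _ in range(2):
            lat, cells = make_random_lattice(5)
            rng = np.random.default_rng(42)
            for t in range(10):
                monte_carlo_step(lat, cells, default_params, rng=rng, time=float(t))
            grids.append(lat.grid.copy())
        assert np.array_equal(grids[0], grids[1])

    def test_caches_match_recount_after_run(self, default_params):
        lat, cells = make_random_lattice(7)
        rng = np.random.default_rng(2)
        for t in range(20):
            monte_carlo_step(lat, cells, default_params, rng=rng, time=float(t))
        lat.check_consistency(cells)  # raises on any mismatch

    def test_matrix_never_overwritten(self):
        lat = Lattice((8, 8, 4))
        cells = CellTable()
        mid = cells.new_cell("matrix")
        lat.grid[:, :, 0] = mid
        tid = cells.new_cell("tumor", target_volume=30.0)
        lat.grid[3:6, 3:6, 1:3] = tid
        lat.sync_caches(cells)
        rng = np.random.default_rng(0)
        params = EnergyParams()
        for t in range(20):
            monte_carlo_step(lat, cells, params, rng=rng, time=float(t))
        assert np.all(lat.grid[:, :, 0] == mid)
        assert not np.any(lat.grid[:, :, 1:] == mid)

    def test_cells_never_vanish(self, default_params):
        lat, cells = make_random_lattice(11)
        rng = np.random.default_rng(3)
        for t in range(50):
            monte_carlo_step(lat, cells, default_params, rng=rng, time=float(t))
        vols = np.bincount(lat.grid.ravel(), minlength=cells.n_ids)
        assert np.all(vols[1 : cells.n_ids] >= 1)


class TestDifferentialAdhesion:
    @staticmethod
    def _pair_energy(type_a, type_b, gap, params):
        lat = Lattice((14, 8, 6))
        cells = CellTable()
        a = cells.new_cell(type_a, target_volume=8.0)
        b = cells.new_cell(type_b, target_volume=8.0)
        lat.grid[2:4, 3:5, 2:4] = a
        x0 = 4 + gap
        lat.grid[x0 : x0 + 2, 3:5, 2:4] = b
        lat.sync_caches(cells)
        return total_hamiltonian(lat, cells, params)

    def test_tumor_separation_balance(self):
        """Breaking a tumor-tumor contact creates two tumor-medium
        interfaces: per broken pair the energy changes by 2 J_tm - J_tt.
        With the published values (-6, -4) that balance is -2: medium
        wetting slightly beats direct tumor-tumor cohesion, so aggregation
        must come from chemotaxis and core adhesion, not J_tt alone."""
        params = EnergyParams(lambda_V=0.0, lambda_P=0.0, neighborhood_order=1)
        contact = self._pair_energy("tumor", "tumor", 0, params)
        apart = self._pair_energy("tumor", "tumor", 3, params)
        n_broken = 4  # 2x2 face between the cubes
        expected = n_broken * (2 * params.J[3, 0] - params.J[3, 3])
        assert (apart - contact) == pytest.approx(expected)

    def test_core_contact_strongly_favored(self):
        # core-tumor contact (-10) beats core-medium + tumor-medium
        # (10 - 4): detaching a tumor cell from the core costs energy,
        # which is what holds the cluster at the core together
        params = EnergyParams(lambda_V=0.0, lambda_P=0.0, neighborhood_order=1)
        contact = self._pair_energy("core", "tumor", 0, params)
        apart = self._pair_energy("core", "tumor", 3, params)
        assert contact < apart

    def test_j_matrix_defaults_symmetric(self):
        J = j_matrix()
        assert np.allclose(J, J.T)
        # spot-check the strongest and weakest published couplings
        assert J[1, 2] == -170.0  # core-body
        assert J[3, 3] == -6.0  # tumor-tumor
        assert J[0, 4] == 10.0  # medium-matrix


class TestEnergyParamsValidation:
    def test_asymmetric_j_rejected(self):
        J = j_matrix()
        J[0, 1] += 1.0
        with pytest.raises(ValueError):
            EnergyParams(J=J)

    def test_bad_temperature_rejected(self):
        with pytest.raises(ValueError):
            EnergyParams(T=0.0)
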