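"""Finite-volume solver: discretisation oracles, conservation and scaling laws."""

import copy

import numpy as np
import pytest

import tdcsim as t
from tdcsim.solver import (SolverConfig, assemble_system, compute_fields,
                           divergence_residual, measure_current,
                           normalize_to_current, plane_current, solve_potential)
from tdcsim.volumes import Grid, ScalarVolume


def _nodes(shape, active_idx, reference_idx):
    class P:
        active_nodes = np.zeros(shape, dtype=bool)
        reference_nodes = np.zeros(shape, dtype=bool)
    P.active_nodes[active_idx] = True
    P.reference_nodes[reference_idx] = True
    return P


def test_uniform_bar_midpoint_half_volt():
    g = Grid((1, 1, 3), (1, 1, 1))
    sig = ScalarVolume(g, np.full(g.shape, 0.4))
    placed = _nodes(g.shape, (0, 0, 0), (0, 0, 2))
    phi, _ = solve_potential(assemble_system(sig, placed))
    assert phi.values[0, 0, 1] == pytest.approx(0.5, abs=1e-12)


def test_matrix_symmetric_diagonally_dominant(rng):
    g = Grid((4, 4, 4), (1, 1, 1))
    sig = ScalarVolume(g, rng.uniform(0.01, 2.0, g.shape))
    placed = _nodes(g.shape, (0, 0, 0), (3, 3, 3))
    sys_ = assemble_system(sig, placed)
    A = sys_.A.toarray()
    assert np.allclose(A, A.T)
    off = np.abs(A).sum(axis=1) - np.abs(np.diag(A))
    assert np.all(np.diag(A) >= off - 1e-12)


def test_iterative_matches_dense_direct_solve(rng):
    """CG on a random-conductivity grid agrees with a dense solve to 1e-10."""
    g = Grid((4, 4, 4), (1, 1, 1))
    sig = ScalarVolume(g, rng.uniform(0.01, 2.0, g.shape))
    placed = _nodes(g.shape, (0, 0, 0), (3, 3, 3))
    sys_ = assemble_system(sig, placed)
    dense = np.linalg.solve(sys_.A.toarray(), sys_.b)
    phi, _ = solve_potential(sys_, SolverConfig(solver_kind="cg",
                                                relative_residual_tolerance=1e-13))
    iterative = phi.values.ravel()[sys_.unknown_index >= 0]
    assert np.max(np.abs(iterative - dense)) < 1e-10


def test_full_face_dirichlet_gives_linear_potential():
    g = Grid((9, 5, 5), (2, 2, 2))
    sig = ScalarVolume(g, np.ones(g.shape))
    placed = _nodes(g.shape, (0, slice(None), slice(None)), (8, slice(None), slice(None)))
    phi, _ = solve_potential(assemble_system(sig, placed))
    x = np.linspace(1, 0, 9)
    expected = np.broadcast_to(x[:, None, None], g.shape)
    assert np.max(np.abs(phi.values - expected)) < 1e-6


def test_disconnected_electrodes_raise():
    g = Grid((1, 1, 5), (1, 1, 1))
    sig = ScalarVolume(g, np.array([1, 1, 0, 1, 1.0]).reshape(1, 1, 5))
    placed = _nodes(g.shape, (0, 0, 0), (0, 0, 4))
    with pytest.raises(ValueError, match="not connected"):
        assemble_system(sig, placed)


def test_nonconvergence_reports_residual(small_head_case):
    sys_ = assemble_system(small_head_case.sigma, small_head_case.placed)
    with pytest.raises(RuntimeError, match="did not converge"):
        solve_potential(sys_, SolverConfig(solver_kind="cg", max_iterations=3))


class TestFields:
    def test_uniform_potential_zero_field(self):
        g = Grid((4, 4, 4), (1, 1, 1))
        sig = ScalarVolume(g, np.ones(g.shape))
        phi = ScalarVolume(g, np.full(g.shape, 0.7))
        E, J = compute_fields(phi, sig)
        assert np.all(E.values == 0) and np.all(J.values == 0)

    def test_linear_potential_constant_field(self):
        g = Grid((7, 3, 3), (2, 2, 2))
        sig = ScalarVolume(g, np.ones(g.shape))
        k = 3.0  # V/m -> phi drops k * 2e-3 V per voxel
        x = g.axis_coords(0) * 1e-3
        phi = ScalarVolume(g, np.broadcast_to(-k * x[:, None, None], g.shape).copy())
        E, _ = compute_fields(phi, sig)
        assert np.allclose(E.values[0], k)
        assert np.allclose(E.values[1:], 0)

    def test_j_over_e_equals_sigma_within_tissue(self, small_head_case):
        grey = small_head_case.placed.volume.mask("brain_grey_matter")
        ampE = small_head_case.E.amplitude()[grey]
        ampJ = small_head_case.J.amplitude()[grey]
        assert np.allclose(ampJ, 0.027512 * ampE, rtol=1e-12)

    def test_air_voxels_carry_zero_field(self, small_head_case):
        air = small_head_case.sigma.values == 0
        assert np.all(small_head_case.E.values[:, air] == 0)


class TestCurrentAndConservation:
    def test_normalization_achieves_target(self, small_head_case):
        assert small_head_case.achieved_mA == pytest.approx(1.0, rel=1e-3)

    def test_active_equals_minus_reference(self, small_head_case):
        c = small_head_case
        Iref = measure_current(c.phi, c.sigma, c.placed.reference_nodes)
        assert Iref * 1e3 == pytest.approx(-c.achieved_mA, rel=1e-3)

    def test_any_separating_plane_carries_full_current(self, small_head_case):
        c = small_head_case
        ny = c.phi.grid.shape[1]
        # montage A pads straddle the midsagittal plane: every y-plane between
        # them must carry the full 1 mA
        currents = [abs(plane_current(c.phi, c.sigma, 1, j)) * 1e3
                    for j in (ny // 2 - 1, ny // 2)]
        for I in currents:
            assert I == pytest.approx(1.0, rel=1e-3)

    def test_divergence_free_off_electrodes(self, small_head_case):
        c = small_head_case
        res = divergence_residual(c.phi, c.sigma)
        pads = c.placed.active_nodes | c.placed.reference_nodes
        interior = (c.sigma.values > 0) & ~pads
        pad_flux = np.abs(res[pads]).max()
        assert np.abs(res[interior]).max() < 1e-9 * pad_flux

    def test_open_circuit_raises(self):
        g = Grid((1, 1, 3), (1, 1, 1))
        sig = ScalarVolume(g, np.ones(g.shape))
        placed = _nodes(g.shape, (0, 0, 0), (0, 0, 2))
        phi = ScalarVolume(g, np.zeros(g.shape))  # no potential difference
        E, J = compute_fields(phi, sig)
        with pytest.raises(RuntimeError, match="open circuit"):
            normalize_to_current(phi, E, J, sig, placed, target_mA=1.0)


class TestScalingLaws:
    def test_field_linear_in_current(self, small_head_case):
        doubled = t.solve_montage(small_head_case.placed, target_mA=2.0)
        assert np.allclose(doubled.E.values, 2 * small_head_case.E.values, rtol=1e-9)

    def test_global_sigma_scaling(self, small_head_case):
        """sigma -> k*sigma leaves J unchanged and scales E by 1/k."""
        c, k = small_head_case, 3.0
        sig2 = ScalarVolume(c.sigma.grid, c.sigma.values * k)
        sys2 = assemble_system(sig2, c.placed)
        phi2, _ = solve_potential(sys2)
        E2, J2 = compute_fields(phi2, sig2)
        phi2, E2, J2, _ = normalize_to_current(phi2, E2, J2, sig2, c.placed)
        assert np.allclose(J2.values, c.J.values, rtol=1e-9,
                           atol=1e-9 * np.abs(c.J.values).max())
        assert np.allclose(E2.values, c.E.values / k, rtol=1e-9,
                           atol=1e-9 * np.abs(c.E.values).max())

    def test_geometric_scaling_inverse_square(self, small_head_case):
        """Shrinking all dimensions by k multiplies |E| by 1/k^2 at fixed current."""
        c, k = small_head_case, 0.5
        placed2 = copy.copy(c.placed)
        vol2 = c.placed.volume.copy()
        vol2.grid = c.placed.volume.grid.scaled(k)
        placed2.volume = vol2
        sig2 = ScalarVolume(vol2.grid, c.sigma.values)
        sys2 = assemble_system(sig2, placed2)
        phi2, _ = solve_potential(sys2)
        E2, J2 = compute_fields(phi2, sig2)
        phi2, E2, J2, _ = normalize_to_current(phi2, E2, J2, sig2, placed2)
        cond = c.sigma.values > 0
        ref = c.E.amplitude()[cond]
        scaled = E2.amplitude()[cond]
        nz = ref > 1e-12 * ref.max()
        assert np.allclose(scaled[nz] / ref[nz], 1 / k**2, rtol=1e-9)

    def test_mirror_symmetric_field(self, small_head_case):
        amp = small_head_case.E.amplitude()
        asym = np.max(np.abs(amp - amp[:, ::-1, :])) / amp.max()
        assert asym < 0.01


def test_tolerance_tightening_stabilises_solution(small_head_case):
    sys_ = assemble_system(small_head_case.sigma, small_head_case.placed)
    phis = {}
    for tol in (1e-6, 1e-10):
        phi, _ = solve_potential(sys_, SolverConfig(solver_kind="cg",
                                                    relative_residual_tolerance=tol))
        phis[tol] = phi.values
    span = np.abs(phis[1e-10]).max()
    assert np.max(np.abs(phis[1e-6] - phis[1e-10])) / span < 1e-5
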