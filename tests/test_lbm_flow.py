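import numpy as np
import pytest

from ripplemat import _kernels, lbm_flow as L
from ripplemat.geometry import RippleGeometry, make_ripple, mirror_porosity
from conftest import open_water

W9 = np.array([4 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 36, 1 / 36, 1 / 36, 1 / 36])


class TestEquilibrium:
    def test_rest_state_gives_lattice_weights(self):
        rho = np.ones((3, 4))
        u = np.zeros((2, 3, 4))
        feq = L.equilibrium(rho, u)
        for i in range(9):
            assert np.allclose(feq[i], W9[i], atol=1e-15)

    @pytest.mark.parametrize("ux,uy", [(0.1, 0.0), (0.03, -0.08), (0.0, 0.0)])
    def test_moment_identities(self, ux, uy):
        rho = np.full((2, 2), 1.3)
        u = np.zeros((2, 2, 2))
        u[0], u[1] = ux, uy
        feq = L.equilibrium(rho, u)
        assert np.max(np.abs(feq.sum(axis=0) - rho)) < 1e-14
        mx = np.tensordot(L.C[:, 0].astype(float), feq, axes=(0, 0))
        my = np.tensordot(L.C[:, 1].astype(float), feq, axes=(0, 0))
        assert np.max(np.abs(mx - rho * ux)) < 1e-14
        assert np.max(np.abs(my - rho * uy)) < 1e-14


class TestCollideStream:
    def test_rest_state_is_fixed_point(self):
        por = open_water(8, 10)
        state = L.initial_state(8, 10)
        bc = L.FlowBoundaryConditions(u_top=0.0)
        out = state
        for _ in range(20):
            out = L.collide_stream(out, 0.8, por, bc)
        assert np.max(np.abs(out.f - state.f)) < 1e-14

    def test_mass_conserved_with_walls_porous_and_vent(self):
        geom = RippleGeometry(wavelength_m=0.12, height_m=0.02,
                              bed_depth_m=0.01, asymmetry=0.3)
        por = make_ripple(geom, 48, 24, 0.6)
        bc = L.FlowBoundaryConditions(u_top=0.05, vent=(3, 6, 0.01))
        state = L.couette_initial_state(24, 48, 0.05)
        m0 = state.f.sum()
        out = state
        for _ in range(50):
            out = L.collide_stream(out, 0.7, por, bc)
        assert abs(out.f.sum() / m0 - 1) < 1e-13

    def test_tau_out_of_range_rejected(self):
        por = open_water(4, 4)
        with pytest.raises(ValueError):
            L.collide_stream(L.initial_state(4, 4), 0.5, por,
                             L.FlowBoundaryConditions())

    def test_divergence_detected(self):
        state = L.initial_state(4, 4)
        state.f[1] += 5.0  # super-sonic momentum
        with pytest.raises(L.DivergenceError):
            state.check()

    def test_numba_kernel_matches_numpy_reference(self):
        geom = RippleGeometry(wavelength_m=0.12, height_m=0.02,
                              bed_depth_m=0.01, asymmetry=0.3)
        por = make_ripple(geom, 48, 20, 0.6)
        bc = L.FlowBoundaryConditions(u_top=0.05, vent=(3, 5, 0.01))
        state = L.couette_initial_state(20, 48, 0.05)
        ref = state
        for _ in range(7):
            ref = L.collide_stream(ref, 0.8, por, bc)
        f = state.f.copy()
        _kernels.run_steps(f, por.ns, 0.8, 0.05, 0.0, 0.0, False,
                           3, 5, 0.01, 0, 0.1, 7)
        assert np.max(np.abs(f - ref.f)) < 1e-13

    def test_numba_kernel_matches_numpy_with_body_force(self):
        por = open_water(12, 8)
        bc = L.FlowBoundaryConditions(u_top=0.0, body_force=(1e-5, 0.0))
        ref = L.initial_state(12, 8)
        for _ in range(5):
            ref = L.collide_stream(ref, 0.9, por, bc)
        f = L.initial_state(12, 8).f
        _kernels.run_steps(f, por.ns, 0.9, 0.0, 1e-5, 0.0, False,
                           0, -1, 0.0, 0, 0.1, 5)
        assert np.max(np.abs(f - ref.f)) < 1e-14


class TestPartialBounceback:
    def test_ns_zero_is_plain_streaming(self):
        rng = np.random.default_rng(4)
        f = rng.uniform(0.1, 0.2, size=(9, 6, 7))
        ns = np.zeros((6, 7))
        out = L.apply_partial_bounceback(f, ns)
        expect = np.empty_like(f)
        for i in range(9):
            expect[i] = np.roll(f[i], shift=(L.C[i, 1], L.C[i, 0]), axis=(0, 1))
        assert np.array_equal(out, expect)

    def test_swap_preserves_node_mass(self):
        rng = np.random.default_rng(5)
        f = rng.uniform(0.1, 0.2, size=(9, 5, 5))
        ns = rng.uniform(0, 1, size=(5, 5))
        h = L.partial_swap(f, ns)
        assert np.max(np.abs(h.sum(axis=0) - f.sum(axis=0))) < 1e-14

    def test_solid_slab_blocks_flow(self):
        por = open_water(16, 8, ns_val=1.0)
        bc = L.FlowBoundaryConditions(u_top=0.0, body_force=(1e-6, 0.0))
        res = L.run_to_steady(0.8, por, bc, tol=1e-12, max_steps=5000)
        open_por = open_water(16, 8, ns_val=0.0)
        ref = L.run_to_steady(0.8, open_por, bc, tol=1e-12, max_steps=50000)
        assert abs(res.u[0].sum()) < 1e-10 * abs(ref.u[0].sum())

    def test_seepage_flux_monotone_in_solid_fraction(self):
        flux = []
        for nsv in (0.25, 0.5, 0.75):
            por = open_water(16, 8, ns_val=nsv)
            bc = L.FlowBoundaryConditions(u_top=0.0, body_force=(1e-6, 0.0))
            res = L.run_to_steady(0.8, por, bc, tol=1e-11, max_steps=60000)
            flux.append(res.u[0].sum())
        assert flux[0] > flux[1] > flux[2] > 0


class TestSteadyFlow:
    def test_null_forcing_stays_at_rest(self):
        por = open_water(16, 8)
        bc = L.FlowBoundaryConditions(u_top=0.0)
        res = L.run_to_steady(0.8, por, bc, tol=1e-12, max_steps=1000)
        assert res.meta["converged"]
        assert np.max(np.abs(res.u)) < 1e-14

    def test_couette_profile(self):
        ny = nx = 32
        por = open_water(ny, nx)
        bc = L.FlowBoundaryConditions(u_top=0.05)
        res = L.run_to_steady(0.8, por, bc, tol=1e-10, max_steps=100000)
        ux = res.u[0].mean(axis=1)
        y = (np.arange(ny) + 0.5) / ny
        exact = 0.05 * y
        err = np.sqrt(np.mean((ux - exact) ** 2) / np.mean(exact**2))
        assert err < 1e-4

    def test_mirror_symmetry_of_ripple_flow(self):
        # reversing the lid and mirroring the geometry left-right must
        # reproduce the mirrored flow field to round-off
        geom = RippleGeometry(wavelength_m=0.12, height_m=0.015,
                              bed_depth_m=0.01, asymmetry=0.5)
        por = make_ripple(geom, 60, 30, 0.6)
        bc = L.FlowBoundaryConditions(u_top=0.04, vent=(10, 12, 0.002))
        state = L.couette_initial_state(30, 60, 0.04)
        res = L.run_to_steady(0.6, por, bc, state=state, tol=0, max_steps=3000)
        por_m = mirror_porosity(por)
        bc_r = L.FlowBoundaryConditions(u_top=-0.04, vent=(60 - 13, 60 - 11, 0.002))
        state_r = L.couette_initial_state(30, 60, -0.04)
        res_r = L.run_to_steady(0.6, por_m, bc_r, state=state_r, tol=0,
                                max_steps=3000)
        mirrored = L.mirror_flow(res_r)
        assert np.max(np.abs(mirrored.f - res.f)) < 1e-10
        u, u_m = res.u, mirrored.u
        assert np.max(np.abs(u_m[0] - u[0])) < 1e-10
        assert np.max(np.abs(u_m[1] - u[1])) < 1e-10

    def test_non_convergence_is_flagged_not_raised(self):
        por = open_water(24, 8)
        bc = L.FlowBoundaryConditions(u_top=0.05)
        res = L.run_to_steady(0.8, por, bc, tol=1e-14, max_steps=300)
        assert res.meta["converged"] is False
        assert res.meta["steps"] == 300
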