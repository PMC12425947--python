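import numpy as np
import pytest

from ripplemat import lbm_flow as L
from ripplemat import scalar_transport as S
from ripplemat.geometry import RippleGeometry, make_ripple
from conftest import open_water


def make_scalar(ny, nx, D=0.1, top=0.0, bottom=1.0, C0=None, **kw):
    C = np.zeros((ny, nx)) if C0 is None else C0
    return S.ScalarField(name="s", C=C, D=D,
                         bc=S.ScalarBC(top=top, bottom=bottom, **kw))


class TestScalarStep:
    def test_steady_profile_linear_between_walls(self):
        ny, nx = 24, 4
        u = np.zeros((2, ny, nx))
        fld = make_scalar(ny, nx, D=0.2)
        for _ in range(8000):
            fld = S.scalar_step(fld, u)
        y = (np.arange(ny) + 0.5) / ny
        exact = 1.0 - y  # bottom=1, top=0, walls half a cell beyond the grid
        assert np.max(np.abs(fld.C - exact[:, None])) < 1e-6

    def test_direct_solve_matches_explicit_fixed_point(self):
        ny, nx = 16, 6
        rng = np.random.default_rng(0)
        u = np.zeros((2, ny, nx))
        fld = make_scalar(ny, nx, D=0.15, C0=rng.uniform(0, 1, (ny, nx)))
        direct = S.solve_steady(fld, u)
        y = (np.arange(ny) + 0.5) / ny
        assert np.max(np.abs(direct.C - (1.0 - y)[:, None])) < 1e-10

    def test_closed_box_conserves_total(self):
        ny, nx = 16, 16
        rng = np.random.default_rng(1)
        fld = make_scalar(ny, nx, D=0.2, C0=rng.uniform(0, 1, (ny, nx)),
                          top_kind="flux", bottom_kind="flux", top=0.0, bottom=0.0)
        u = np.zeros((2, ny, nx))
        total0 = fld.C.sum()
        for _ in range(3000):
            fld = S.scalar_step(fld, u)
        assert abs(fld.C.sum() / total0 - 1) < 1e-12

    def test_cfl_violation_names_the_number(self):
        fld = make_scalar(8, 8, D=0.1)
        u = np.full((2, 8, 8), 1.5)
        with pytest.raises(ValueError, match="CFL"):
            S.scalar_step(fld, u)
        fld2 = make_scalar(8, 8, D=0.5)
        with pytest.raises(ValueError, match="diffusion number"):
            S.scalar_step(fld2, np.zeros((2, 8, 8)))

    def test_gaussian_advects_and_spreads(self):
        # light version of the advection-diffusion oracle (full run in the
        # acceptance suite): centroid speed and variance growth
        ny = nx = 96
        D, u0, steps = 0.05, 0.05, 400
        yy, xx = np.mgrid[0:ny, 0:nx]
        sig0 = 10.0
        C0 = np.exp(-((xx - 32) ** 2 + (yy - 48) ** 2) / (2 * sig0**2))
        fld = make_scalar(ny, nx, D=D, C0=C0)
        u = np.zeros((2, ny, nx))
        u[0] = u0
        for _ in range(steps):
            fld = S.scalar_step(fld, u, periodic_y=True)
        m = fld.C.sum()
        xc = (fld.C * xx).sum() / m
        var_x = (fld.C * (xx - xc) ** 2).sum() / m
        assert abs((xc - 32) / (u0 * steps) - 1) < 0.01
        assert abs((var_x - sig0**2) / (2 * D * steps) - 1) < 0.02


class TestSteadySolve:
    def test_maximum_principle_on_ripple_flow(self):
        geom = RippleGeometry(wavelength_m=0.12, height_m=0.015,
                              bed_depth_m=0.01, asymmetry=0.5)
        por = make_ripple(geom, 60, 30, 0.6)
        bc = L.FlowBoundaryConditions(u_top=0.04, vent=(55, 59, 0.002))
        state = L.couette_initial_state(30, 60, 0.04)
        flow = L.run_to_steady(0.6, por, bc, state=state, tol=1e-6,
                               max_steps=60000)
        fld = S.ScalarField(name="H2S", C=np.zeros((30, 60)), D=0.01,
                            bc=S.ScalarBC(top=0.0, bottom=1.0))
        out = S.solve_steady(fld, flow.u, por)
        assert out.C.min() >= -1e-9
        assert out.C.max() <= 1.0 + 1e-9

    def test_vent_plume_symmetric_without_shear(self):
        # symmetric geometry, u_top = 0: the vent-driven H2S plume must be
        # mirror-symmetric about the vent column
        ny, nx = 32, 49
        por = open_water(ny, nx)
        por.ns[:8, :] = 0.6
        por.bed_profile[:] = 7
        vent = (24, 24, 0.005)
        bc = L.FlowBoundaryConditions(u_top=0.0, vent=vent)
        flow = L.run_to_steady(0.7, por, bc, tol=1e-10, max_steps=60000)
        mask = np.zeros((ny, nx), bool)
        mask[0, 24] = True
        fld = S.ScalarField(name="H2S", C=np.zeros((ny, nx)), D=0.01,
                            bc=S.ScalarBC(top=0.0, bottom_kind="flux", bottom=0.0),
                            source_mask=mask, source_value=1.0)
        out = S.solve_steady(fld, flow.u, por)
        assert np.max(np.abs(out.C - out.C[:, ::-1])) < 1e-8

    def test_flat_bed_no_flow_gives_one_dimensional_profiles(self):
        ny, nx = 20, 10
        u = np.zeros((2, ny, nx))
        o2 = make_scalar(ny, nx, D=0.05, top=1.0, bottom=0.0)
        h2s = make_scalar(ny, nx, D=0.05, top=0.0, bottom=1.0)
        so2, sh2s = (S.solve_steady(f, u) for f in (o2, h2s))
        for s in (so2, sh2s):
            assert np.max(np.abs(s.C - s.C[:, :1])) < 1e-12
        assert np.max(np.abs(so2.C + sh2s.C - 1.0)) < 1e-10


class TestFlowScalarDecoupling:
    def test_temperature_never_feeds_back_on_velocity(self):
        por = open_water(16, 12)
        bc = L.FlowBoundaryConditions(u_top=0.03)
        flow = L.run_to_steady(0.8, por, bc, tol=1e-9, max_steps=50000)
        f_before = flow.f.copy()
        temp = make_scalar(16, 12, D=0.02, top=0.0, bottom=1.0)
        S.run_scalars_to_steady(flow, [temp], None)
        assert np.array_equal(flow.f, f_before)


class TestConvectionGuard:
    def test_zero_gradient_passes(self):
        chk = S.check_no_convection(delta_T=0.0)
        assert chk.rayleigh_proxy == 0.0
        assert chk.passed

    def test_extreme_gradient_fails(self):
        chk = S.check_no_convection(delta_T=2.0e6)  # a million-fold contrast
        assert not chk.passed

    def test_default_configuration_is_subcritical(self):
        chk = S.check_no_convection()
        assert chk.passed
        assert chk.rayleigh_proxy < 1708.0


class TestPenetrationDepth:
    def test_uniform_scalar_penetrates_full_bed(self):
        geom = RippleGeometry(height_m=0.0, bed_depth_m=0.02)
        por = make_ripple(geom, 32, 24, 0.6)
        fld = make_scalar(24, 32, C0=np.ones((24, 32)))
        depth = S.penetration_depth(fld, por)
        assert np.all(depth == por.bed_profile[0] + 1)
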