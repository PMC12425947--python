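"""Shared fixtures.

The reference ripple run (one asymmetric ripple, lattice Re ~ 100 on the
ripple height, vent in the lee trough) is expensive, so it is converged
once per session and shared by the diagnostic and acceptance tests; its
left-right mirror likewise.
"""

from __future__ import annotations

import numpy as np
import pytest

from ripplemat import lbm_flow, scalar_transport
from ripplemat.config import reference_config
from ripplemat.geometry import PorosityField, mirror_porosity
from ripplemat.pipeline import build_geometry, build_scalars, run_flow


def open_water(ny: int, nx: int, ns_val: float = 0.0) -> PorosityField:
    """A channel with uniform solid fraction and no resolved bed."""
    return PorosityField(ns=np.full((ny, nx), ns_val, float),
                         interface_mask=np.zeros((ny, nx), bool),
                         bed_profile=np.full(nx, -1, dtype=np.int64),
                         dx_m=1.0)


@pytest.fixture(scope="session")
def reference_run():
    """Converged reference ripple flow plus steady scalars."""
    cfg = reference_config()
    porosity = build_geometry(cfg)
    flow = run_flow(cfg, porosity)
    assert flow.meta["converged"]
    scalars = scalar_transport.run_scalars_to_steady(
        flow, build_scalars(cfg, porosity), porosity)
    return cfg, porosity, flow, scalars


@pytest.fixture(scope="session")
def mirrored_reference_run(reference_run):
    """The flow-reversal pair of the reference problem.

    Returns (por_m, flow_m, flow_rev): flow_m is the forward run over the
    mirrored geometry (mirrored vent), flow_rev the reversed-lid run over
    the original geometry.  Mirror symmetry of the dynamics demands that
    flow_rev equal the left-right mirror of flow_m.
    """
    cfg, porosity, _, _ = reference_run
    por_m = mirror_porosity(porosity)
    fc = cfg.flow
    nx = fc.nx
    vent_m = (nx - 1 - fc.vent.x1, nx - 1 - fc.vent.x0, fc.vent.w)
    bc_m = lbm_flow.FlowBoundaryConditions(u_top=fc.u_top, vent=vent_m)
    flow_m = lbm_flow.run_to_steady(
        fc.tau, por_m, bc_m,
        state=lbm_flow.couette_initial_state(fc.ny, fc.nx, fc.u_top),
        tol=fc.tol, max_steps=fc.max_steps)
    assert flow_m.meta["converged"]
    vent = (fc.vent.x0, fc.vent.x1, fc.vent.w)
    bc_r = lbm_flow.FlowBoundaryConditions(u_top=-fc.u_top, vent=vent)
    flow_rev = lbm_flow.run_to_steady(
        fc.tau, porosity, bc_r,
        state=lbm_flow.couette_initial_state(fc.ny, fc.nx, -fc.u_top),
        tol=fc.tol, max_steps=fc.max_steps)
    assert flow_rev.meta["converged"]
    return por_m, flow_m, flow_rev
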