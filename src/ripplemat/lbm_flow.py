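"""D2Q9 BGK lattice-Boltzmann solver for shear-driven flow over a porous bed.

Flow is driven by a moving top wall (imposed horizontal velocity,
mass-conserving moving-wall bounce-back), with a no-slip bottom wall and
periodic lateral boundaries.  The ripple and sand bed are porous: the
gray-lattice partial-bounce-back scheme blends streamed and reflected
populations by the per-cell solid fraction ns, giving Darcy-like
resistance without a permeability calibration.  An alternative Brinkman
mode applies a velocity-proportional momentum sink instead.

Lattice convention (x right, y up):

    index:    0      1      2      3      4      5      6      7      8
    c_i:    (0,0)  (1,0)  (0,1) (-1,0) (0,-1)  (1,1) (-1,1) (-1,-1) (1,-1)
    w_i:    4/9    1/9    1/9    1/9    1/9    1/36   1/36   1/36   1/36

Kinematic viscosity in lattice units is nu = (tau - 1/2)/3.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .geometry import CS, CS2, PorosityField

C = np.array(
    [[0, 0], [1, 0], [0, 1], [-1, 0], [0, -1], [1, 1], [-1, 1], [-1, -1], [1, -1]],
    dtype=np.int64,
)
W = np.array([4 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 9, 1 / 36, 1 / 36, 1 / 36, 1 / 36])
OPP = np.array([0, 3, 4, 1, 2, 7, 8, 5, 6], dtype=np.int64)


class DivergenceError(RuntimeError):
    """The solver left its stability envelope (|u| >= c_s or rho <= 0)."""


@dataclass
class FlowBoundaryConditions:
    """Boundary set for the shear-flow problem.

    u_top: imposed horizontal wall velocity at the top lid (lattice units).
    vent: optional (x0, x1, w) bottom segment with imposed upward velocity w,
    applied as a velocity-Dirichlet row (local density preserved).
    periodic_y: fully periodic in y (validation runs only; disables walls).
    """

    u_top: float = 0.0
    vent: tuple[int, int, float] | None = None
    periodic_y: bool = False
    body_force: tuple[float, float] = (0.0, 0.0)
    porous_mode: str = "graylbm"  # or "brinkman"
    brinkman_drag: float = 0.1  # drag rate per unit ns (lattice units)

    def validate(self, nx: int) -> None:
        # u_top may be negative: reversed lid drive (flow-reversal studies)
        if self.vent is not None:
            x0, x1, w = self.vent
            if w < 0:
                raise ValueError("vent velocity must be >= 0 (inflow)")
            if not (0 <= x0 <= x1 < nx):
                raise ValueError(f"vent segment [{x0}, {x1}] outside domain width {nx}")
        if self.porous_mode not in ("graylbm", "brinkman"):
            raise ValueError(f"unknown porous_mode {self.porous_mode!r}")


@dataclass
class FlowState:
    """Distribution functions plus derived macroscopic fields."""

    f: np.ndarray  # (9, ny, nx)
    step: int = 0
    meta: dict = dfield(default_factory=dict)

    @property
    def rho(self) -> np.ndarray:
        return self.f.sum(axis=0)

    @property
    def u(self) -> np.ndarray:
        """(2, ny, nx) velocity; bare first moment (no force shift)."""
        rho = self.rho
        ux = np.tensordot(C[:, 0].astype(float), self.f, axes=(0, 0)) / rho
        uy = np.tensordot(C[:, 1].astype(float), self.f, axes=(0, 0)) / rho
        return np.stack([ux, uy])

    @property
    def p(self) -> np.ndarray:
        """Equation-of-state pressure c_s²·rho."""
        return CS2 * self.rho

    def check(self) -> None:
        rho = self.rho
        if np.any(rho <= 0) or not np.all(np.isfinite(rho)):
            raise DivergenceError(f"non-positive or non-finite density at step {self.step}")
        speed = np.hypot(*self.u)
        if np.any(speed >= CS):
            raise DivergenceError(f"|u| >= c_s at step {self.step}")


def equilibrium(rho: np.ndarray, u: np.ndarray) -> np.ndarray:
    """D2Q9 Maxwellian truncated to second order in velocity.

    rho: (ny, nx); u: (2, ny, nx).  Returns (9, ny, nx).  The zeroth and
    first moments of the result equal rho and rho·u to round-off.
    """
    ux, uy = u[0], u[1]
    usq = ux * ux + uy * uy
    feq = np.empty((9,) + np.shape(rho))
    for i in range(9):
        cu = C[i, 0] * ux + C[i, 1] * uy
        feq[i] = W[i] * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)
    return feq


def initial_state(ny: int, nx: int, u: np.ndarray | None = None) -> FlowState:
    """Unit-density state at rest, or at a prescribed velocity field."""
    rho = np.ones((ny, nx))
    if u is None:
        u = np.zeros((2, ny, nx))
    return FlowState(f=equilibrium(rho, u))


def couette_initial_state(ny: int, nx: int, u_top: float) -> FlowState:
    """Linear shear profile matching the moving lid — cuts the start-up
    transient of ripple runs to the perturbation induced by the bedform."""
    y = (np.arange(ny) + 0.5) / ny
    u = np.zeros((2, ny, nx))
    u[0] = (u_top * y)[:, None]
    return initial_state(ny, nx, u)


def partial_swap(f_post: np.ndarray, ns: np.ndarray) -> np.ndarray:
    """Per-node partial bounce-back: blend each outgoing population with its
    reverse by the swap fraction θ = ns/2, h_i = (1-θ)·f*_i + θ·f*_opp.

    The swap scales the node's post-collision momentum by (1-2θ) = (1-ns):
    a Darcy-like drag that decreases seepage monotonically over the whole
    ns ∈ [0,1] range and kills it exactly at ns = 1.  (A full swap, θ = ns,
    would reverse the seepage direction for ns > 0.5 — a documented defect
    of the naive scheme.)  Node mass is conserved exactly, and at rest the
    swap is the identity, so no spurious density contrast builds across
    the sediment–water interface.
    """
    theta = 0.5 * ns
    return (1.0 - theta)[None] * f_post + theta[None] * f_post[OPP]


def apply_partial_bounceback(f_post: np.ndarray, ns: np.ndarray) -> np.ndarray:
    """Gray-lattice update of post-collision populations (fully periodic):
    partial swap followed by plain streaming.

    ns = 0 reduces to plain streaming; ns = 1 is full on-node bounce-back
    (nothing is transmitted through a solid cell).  Conserves mass exactly
    for any ns field.
    """
    h = partial_swap(f_post, ns)
    out = np.empty_like(f_post)
    for i in range(9):
        out[i] = np.roll(h[i], shift=(C[i, 1], C[i, 0]), axis=(0, 1))
    return out


def _collide(f: np.ndarray, tau: float, bc: FlowBoundaryConditions,
             ns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """BGK collision with optional Guo forcing; returns (f_post, rho)."""
    rho = f.sum(axis=0)
    ux = np.tensordot(C[:, 0].astype(float), f, axes=(0, 0)) / rho
    uy = np.tensordot(C[:, 1].astype(float), f, axes=(0, 0)) / rho
    fx = np.full_like(rho, bc.body_force[0])
    fy = np.full_like(rho, bc.body_force[1])
    if bc.porous_mode == "brinkman":
        # implicit linear drag: u = (m/rho + F_ext/(2 rho)) / (1 + lam/2)
        lam = bc.brinkman_drag * ns
        ux = (ux + fx / (2 * rho)) / (1.0 + 0.5 * lam)
        uy = (uy + fy / (2 * rho)) / (1.0 + 0.5 * lam)
        fx = fx - lam * rho * ux
        fy = fy - lam * rho * uy
    else:
        ux = ux + fx / (2 * rho)
        uy = uy + fy / (2 * rho)
    u = np.stack([ux, uy])
    feq = equilibrium(rho, u)
    f_post = f - (f - feq) / tau
    if np.any(fx) or np.any(fy):
        pref = 1.0 - 0.5 / tau
        for i in range(9):
            cu = C[i, 0] * ux + C[i, 1] * uy
            sx = 3.0 * (C[i, 0] - ux) + 9.0 * cu * C[i, 0]
            sy = 3.0 * (C[i, 1] - uy) + 9.0 * cu * C[i, 1]
            f_post[i] += pref * W[i] * (sx * fx + sy * fy)
    return f_post, rho


def collide_stream(state: FlowState, tau: float, porosity: PorosityField,
                   bc: FlowBoundaryConditions) -> FlowState:
    """One BGK collision + gray streaming step (reference numpy path).

    Walls: no-slip bottom (full bounce-back below row 0), moving lid above
    the top row carrying u_top, both via halfway bounce-back; periodic in x.
    Raises DivergenceError if the post-step state is outside the stability
    envelope.
    """
    if not 0.5 < tau <= 2.0:
        raise ValueError(f"tau must lie in (0.5, 2.0], got {tau}")
    ny, nx = porosity.shape
    bc.validate(nx)
    ns = porosity.ns if bc.porous_mode == "graylbm" else np.zeros_like(porosity.ns)
    f_post, rho = _collide(state.f, tau, bc, porosity.ns)
    h = partial_swap(f_post, ns)
    f_new = np.empty_like(h)
    for i in range(9):
        f_new[i] = np.roll(h[i], shift=(C[i, 1], C[i, 0]), axis=(0, 1))
    if not bc.periodic_y:
        for i in range(9):
            cy = C[i, 1]
            if cy == 1:
                # wrapped row 0 received row ny-1's upward populations: undo,
                # reflect at the moving lid instead (Ladd momentum correction)
                f_new[i][0, :] -= np.roll(h[i][ny - 1, :], C[i, 0])
                corr = 6.0 * W[i] * rho[ny - 1, :] * (C[i, 0] * bc.u_top)
                f_new[OPP[i]][ny - 1, :] += h[i][ny - 1, :] - corr
            elif cy == -1:
                f_new[i][ny - 1, :] -= np.roll(h[i][0, :], C[i, 0])
                f_new[OPP[i]][0, :] += h[i][0, :]
    if bc.vent is not None:
        x0, x1, w = bc.vent
        rho_v = f_new[:, 0, x0 : x1 + 1].sum(axis=0)
        uv = np.zeros((2, 1, x1 - x0 + 1))
        uv[1] = w
        f_new[:, 0 : 1, x0 : x1 + 1] = equilibrium(rho_v[None, :], uv)
    out = FlowState(f=f_new, step=state.step + 1, meta=dict(state.meta))
    out.check()
    return out


def run_to_steady(
    tau: float,
    porosity: PorosityField,
    bc: FlowBoundaryConditions,
    state: FlowState | None = None,
    tol: float = 1e-8,
    max_steps: int = 200_000,
    window: int = 100,
) -> FlowState:
    """Iterate to a steady state (fast numba path).

    Convergence: max per-cell velocity change over a `window`-step interval,
    relative to the current max speed, falls below `tol`.  Non-convergence
    is flagged in ``state.meta['converged']`` rather than raised; divergence
    raises.  Residual history is stored in ``meta['residuals']``.
    """
    from . import _kernels

    ny, nx = porosity.shape
    bc.validate(nx)
    if state is None:
        state = initial_state(ny, nx)
    f = np.ascontiguousarray(state.f.copy())
    vent = bc.vent if bc.vent is not None else (0, -1, 0.0)
    residuals: list[float] = []
    u_prev = state.u
    steps_done = 0
    converged = False
    while steps_done < max_steps:
        n = min(window, max_steps - steps_done)
        _kernels.run_steps(
            f, porosity.ns, tau, bc.u_top,
            bc.body_force[0], bc.body_force[1],
            bc.periodic_y, vent[0], vent[1], vent[2],
            1 if bc.porous_mode == "brinkman" else 0, bc.brinkman_drag, n,
        )
        steps_done += n
        cur = FlowState(f=f, step=state.step + steps_done)
        cur.check()
        u_now = cur.u
        umax = float(np.max(np.hypot(*u_now)))
        if umax < 1e-12:  # unforced rest state: round-off noise only
            resid = 0.0
        else:
            resid = float(np.max(np.hypot(*(u_now - u_prev)))) / umax
        residuals.append(resid)
        u_prev = u_now
        if resid < tol:
            converged = True
            break
    out = FlowState(f=f, step=state.step + steps_done,
                    meta={"converged": converged, "steps": steps_done,
                          "residual": residuals[-1] if residuals else 0.0,
                          "residuals": residuals})
    return out


def mirror_x(arr: np.ndarray) -> np.ndarray:
    """Mirror a (ny, nx) grid left-right."""
    return arr[:, ::-1]


def mirror_flow(state: FlowState) -> FlowState:
    """Left-right mirror of a flow state (x-velocity sign flips)."""
    perm = np.array([0, 3, 2, 1, 4, 6, 5, 8, 7])
    f = state.f[perm][:, :, ::-1].copy()
    return FlowState(f=f, step=state.step, meta=dict(state.meta))
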