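"""Flow-feature diagnostics: streamfunction, separation, eddies, surface
pressure, and sediment–water exchange fluxes.

All functions here are pure post-processing on converged fields: the same
input always yields the same output.  Sign conventions: x increases in the
imposed-flow direction; exchange flux is positive into the sediment.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage

from .geometry import CS2, PorosityField
from .lbm_flow import FlowState
from .scalar_transport import ScalarField


@dataclass
class Eddy:
    center: tuple[int, int]  # (x, y)
    area_cells: int
    circulation_sign: int  # +1 counter-clockwise, -1 clockwise


@dataclass
class FlowDiagnostics:
    psi: np.ndarray
    separation_points: list[tuple[int, str]]
    eddies: list[Eddy]
    surface_pressure: np.ndarray
    stoss_mean_pressure: float
    lee_mean_pressure: float
    exchange_flux: dict = dfield(default_factory=dict)


def streamfunction(u: np.ndarray, geometry: PorosityField | None = None) -> np.ndarray:
    """Streamfunction by columnwise upward integration of u_x from the
    domain bottom, gauged to psi = 0 at the bottom-left cell.

    psi differences between two points equal the volumetric flux across
    any curve connecting them (discretely, for the x-component).
    """
    ux, uy = u[0], u[1]
    # baseline along the bottom row: psi(0, x) = -∫ u_y dx (midpoint rule);
    # zero for wall-bounded flows, needed for general (e.g. rotating) fields
    base = -(np.cumsum(uy[0, :]) - 0.5 * uy[0, :] - 0.5 * uy[0, 0])
    psi = np.cumsum(ux, axis=0) - 0.5 * ux + base[None, :]  # midpoint rule
    return psi - psi[0, 0]


def wall_shear_profile(flow: FlowState, geometry: PorosityField) -> np.ndarray:
    """One-sided estimate of tangential wall shear per column: u_x at the
    first water cell above the local bed (distance 1/2 cell)."""
    ux = flow.u[0]
    ny = ux.shape[0]
    cols = np.arange(ux.shape[1])
    first_fluid = np.clip(geometry.bed_profile + 1, 0, ny - 1)
    return ux[first_fluid, cols]


def detect_separation(
    flow: FlowState, geometry: PorosityField, eps: float = 1e-9
) -> list[tuple[int, str]]:
    """Bed columns where the wall-shear sign flips along +x.

    Positive-to-negative flips are labelled 'separation', the reverse
    'reattachment'.  Periodic in x; an empty list means attached flow.
    """
    shear = wall_shear_profile(flow, geometry)
    sgn = np.where(shear > eps, 1, np.where(shear < -eps, -1, 0))
    # carry last nonzero sign through near-zero cells
    filled = sgn.copy()
    nx = len(filled)
    last = 0
    for x in list(range(nx)) * 2:  # two passes handle a leading zero run
        if sgn[x] != 0:
            last = sgn[x]
        elif last != 0:
            filled[x] = last
    points: list[tuple[int, str]] = []
    for x in range(nx):
        a, b = filled[x - 1], filled[x]
        if a > 0 and b < 0:
            points.append((x, "separation"))
        elif a < 0 and b > 0:
            points.append((x, "reattachment"))
    return points


def _near_bed_mask(geometry: PorosityField, band_cells: int) -> np.ndarray:
    ny, nx = geometry.shape
    rows = np.arange(ny)[:, None]
    bed = geometry.bed_profile[None, :]
    return (rows > bed) & (rows <= bed + band_cells)


def detect_eddies(
    psi: np.ndarray,
    u: np.ndarray,
    geometry: PorosityField,
    min_eddy_area: int = 5,
    u_ref: float = 1.0,
    band_frac: float = 0.25,
) -> list[Eddy]:
    """Recirculation eddies as connected near-bed regions of reversed flow.

    A cell counts as reversed when its u_x opposes the driving velocity
    u_ref within a band of band_frac × ripple height above the local
    interface.  Components smaller than min_eddy_area are discarded; each
    eddy's centre is the interior streamfunction extremum and its rotation
    sense comes from the local vorticity there.
    """
    if min_eddy_area < 1:
        raise ValueError("min_eddy_area must be >= 1")
    ripple_height = int(geometry.bed_profile.max() - geometry.bed_profile.min())
    band = max(2, int(round(band_frac * max(ripple_height, 8))))
    near_bed = _near_bed_mask(geometry, band)
    direction = 1.0 if u_ref >= 0 else -1.0
    reversed_flow = (u[0] * direction < -1e-9) & near_bed & (geometry.ns == 0)
    # periodic-in-x labelling: label, then merge components touching the seam
    labels, nlab = ndimage.label(reversed_flow)
    if nlab and np.any(reversed_flow[:, 0]) and np.any(reversed_flow[:, -1]):
        for y in range(labels.shape[0]):
            a, b = labels[y, 0], labels[y, -1]
            if a and b and a != b:
                labels[labels == b] = a
    eddies: list[Eddy] = []
    vort = _vorticity(u)
    for lab in np.unique(labels):
        if lab == 0:
            continue
        mask = labels == lab
        area = int(mask.sum())
        if area < min_eddy_area:
            continue
        vals = np.where(mask, psi, np.nan)
        # interior extremum: largest |psi - boundary mean| inside the patch
        ref = np.nanmean(vals)
        iy, ix = np.unravel_index(np.nanargmax(np.abs(vals - ref)), psi.shape)
        sign = 1 if vort[iy, ix] > 0 else -1
        eddies.append(Eddy(center=(int(ix), int(iy)), area_cells=area,
                           circulation_sign=sign))
    eddies.sort(key=lambda e: -e.area_cells)
    return eddies


def _vorticity(u: np.ndarray) -> np.ndarray:
    dvdx = 0.5 * (np.roll(u[1], -1, axis=1) - np.roll(u[1], 1, axis=1))
    dudy = np.gradient(u[0], axis=0)
    return dvdx - dudy


def crest_trough_columns(geometry: PorosityField) -> tuple[int, int]:
    """(crest, trough) column indices from the bed profile (plateau centres)."""
    bp = geometry.bed_profile
    if bp.max() == bp.min():  # flat bed: no distinct crest or trough
        return 0, 0
    for target in (bp.max(), bp.min()):
        cols = np.flatnonzero(bp == target)
        # centre of a possibly seam-crossing plateau
        if len(cols) > 1 and cols[-1] - cols[0] > len(bp) // 2:
            shifted = np.where(cols < len(bp) // 2, cols + len(bp), cols)
            c = int(np.median(shifted)) % len(bp)
        else:
            c = int(np.median(cols))
        if target == bp.max():
            crest = c
        else:
            trough = c
    return crest, trough


def _slope_signs(geometry: PorosityField, eps: float = 0.25) -> np.ndarray:
    """+1 on the stoss flank (bed rising along +x), -1 on the lee flank,
    0 on crest/trough plateaus."""
    bp = geometry.bed_profile.astype(float)
    slope = 0.5 * (np.roll(bp, -2) + np.roll(bp, -1) - np.roll(bp, 1) - np.roll(bp, 2)) / 3.0
    return np.where(slope > eps, 1, np.where(slope < -eps, -1, 0))


def surface_pressure_profile(
    flow: FlowState, geometry: PorosityField
) -> tuple[np.ndarray, float, float]:
    """Pressure at the first water cell above the bed per column, as a
    deviation from the domain-mean surface pressure; also stoss-flank and
    lee-flank means (crest/trough plateaus excluded from both)."""
    p = CS2 * flow.rho
    ny, nx = p.shape
    cols = np.arange(nx)
    first_fluid = np.clip(geometry.bed_profile + 1, 0, ny - 1)
    sp = p[first_fluid, cols]
    sp = sp - sp.mean()
    signs = _slope_signs(geometry)
    stoss = float(sp[signs == 1].mean()) if np.any(signs == 1) else float("nan")
    lee = float(sp[signs == -1].mean()) if np.any(signs == -1) else float("nan")
    return sp, stoss, lee


def interfacial_exchange_flux(
    scalar: ScalarField,
    flow: FlowState,
    geometry: PorosityField,
) -> np.ndarray:
    """Normal scalar flux across the sediment–water interface per column,
    positive into the sediment.

    The interface is the horizontal face between the highest sediment cell
    and the water cell above it; the advective part uses the face-centred
    vertical velocity and upwind concentration, the diffusive part the
    face-mean effective diffusivity.
    """
    C_ = scalar.C
    ny, nx = C_.shape
    u = flow.u
    Deff = scalar.D * (1.0 - geometry.ns)
    flux = np.zeros(nx)
    for x in range(nx):
        b = geometry.bed_profile[x]
        if b < 0 or b + 1 >= ny:
            continue
        w = 0.5 * (u[1][b, x] + u[1][b + 1, x])
        c_up = C_[b + 1, x] if w < 0 else C_[b, x]
        d_face = 0.5 * (Deff[b, x] + Deff[b + 1, x])
        f_up = w * c_up - d_face * (C_[b + 1, x] - C_[b, x])  # positive upward
        flux[x] = -f_up
    return flux


def diagnose(
    flow: FlowState,
    geometry: PorosityField,
    scalars: list[ScalarField] | None = None,
    min_eddy_area: int = 5,
    u_ref: float | None = None,
) -> FlowDiagnostics:
    """Full diagnostic bundle for a converged run."""
    u = flow.u
    if u_ref is None:
        u_ref = float(u[0][-1, :].mean()) or 1.0
    psi = streamfunction(u, geometry)
    sep = detect_separation(flow, geometry)
    eddies = detect_eddies(psi, u, geometry, min_eddy_area=min_eddy_area, u_ref=u_ref)
    sp, stoss, lee = surface_pressure_profile(flow, geometry)
    fluxes = {}
    for s in scalars or []:
        fluxes[s.name] = interfacial_exchange_flux(s, flow, geometry)
    return FlowDiagnostics(psi=psi, separation_points=sep, eddies=eddies,
                           surface_pressure=sp, stoss_mean_pressure=stoss,
                           lee_mean_pressure=lee, exchange_flux=fluxes)
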