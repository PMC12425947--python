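"""Ripple and sand-bed geometry on the lattice.

Builds the per-cell solid-fraction (porosity) field for a train of
asymmetric sand ripples over a flat porous bed, locates the
sediment–water interface, and converts between physical (SI) and
lattice units under Reynolds-number matching.

Coordinates: row 0 is the bottom of the sand bed, y increases upward,
x increases in the imposed-flow direction.  All grids are cell-centred
with 0-based indices and square cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: lattice sound speed of the D2Q9 model, c_s = 1/sqrt(3)
CS = 1.0 / np.sqrt(3.0)
CS2 = 1.0 / 3.0


@dataclass(frozen=True)
class RippleGeometry:
    """Parametric description of a ripple train.

    Parameters
    ----------
    wavelength_m : crest-to-crest length in metres (field ripples: 0.15–0.20 m).
    height_m : trough-to-crest height in metres.
    asymmetry : in [-1, 1]; 0 is mirror-symmetric about each crest, positive
        values shorten (steepen) the lee flank and lengthen the stoss flank.
    bed_depth_m : thickness of the flat porous bed below trough level.
    n_ripples : number of wavelengths spanning the (periodic) domain.
    """

    wavelength_m: float = 0.175
    height_m: float = 0.02
    asymmetry: float = 0.5
    bed_depth_m: float = 0.02
    n_ripples: int = 1

    def __post_init__(self) -> None:
        if self.wavelength_m <= 0:
            raise ValueError(f"wavelength_m must be > 0, got {self.wavelength_m}")
        if self.height_m < 0:
            raise ValueError(f"height_m must be >= 0, got {self.height_m}")
        if self.height_m >= self.wavelength_m:
            raise ValueError(
                f"bedform aspect insane: height_m {self.height_m} >= wavelength_m "
                f"{self.wavelength_m}"
            )
        if self.bed_depth_m < 0:
            raise ValueError(f"bed_depth_m must be >= 0, got {self.bed_depth_m}")
        if not -1.0 <= self.asymmetry <= 1.0:
            raise ValueError(f"asymmetry must lie in [-1, 1], got {self.asymmetry}")
        if self.n_ripples < 1:
            raise ValueError(f"n_ripples must be >= 1, got {self.n_ripples}")


@dataclass
class PorosityField:
    """Per-cell solid fraction encoding ripple and bed.

    ``ns`` is 0 in open water and ``ns_sediment`` in sediment;
    ``interface_mask`` marks water cells with at least one 4-neighbour
    sediment cell; ``bed_profile[x]`` is the row index of the highest
    sediment cell in column x (single-valued: no overhangs).
    """

    ns: np.ndarray
    interface_mask: np.ndarray
    bed_profile: np.ndarray
    dx_m: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.ns.shape

    def validate(self) -> None:
        if np.any((self.ns < 0) | (self.ns > 1)):
            raise ValueError("ns values must lie in [0, 1]")
        if np.any(self.ns[self.interface_mask] != 0):
            raise ValueError("interface cells must be open water (ns = 0)")


@dataclass(frozen=True)
class UnitSystem:
    """Physical ↔ lattice unit conversion under Reynolds matching.

    dx_m, dt_s fix the mapping; nu_phys and U_phys are the physical
    viscosity and driving velocity the lattice run represents.
    """

    dx_m: float
    dt_s: float
    nu_phys: float
    U_phys: float

    @property
    def nu_lattice(self) -> float:
        return self.nu_phys * self.dt_s / self.dx_m**2

    @property
    def tau(self) -> float:
        return 0.5 + 3.0 * self.nu_lattice

    @property
    def U_lattice(self) -> float:
        return self.U_phys * self.dt_s / self.dx_m

    @property
    def mach(self) -> float:
        return self.U_lattice / CS


def _ripple_elevation(phase: np.ndarray, height: float, asymmetry: float) -> np.ndarray:
    """Elevation above trough level at fractional phase in [0, 1).

    Piecewise sinusoid: trough at phase 0, crest at the end of the stoss
    flank of fractional length (1 + asymmetry)/2, back to trough at 1.
    """
    stoss_len = (1.0 + asymmetry) / 2.0
    lee_len = 1.0 - stoss_len
    z = np.empty_like(phase)
    on_stoss = phase < stoss_len
    if stoss_len > 0:
        z[on_stoss] = 0.5 * height * (1.0 - np.cos(np.pi * phase[on_stoss] / stoss_len))
    else:  # degenerate: crest at phase 0
        z[on_stoss] = height
    if lee_len > 0:
        z[~on_stoss] = 0.5 * height * (
            1.0 + np.cos(np.pi * (phase[~on_stoss] - stoss_len) / lee_len)
        )
    else:
        z[~on_stoss] = height
    return z


def bed_elevation_profile(geom: RippleGeometry, nx: int) -> np.ndarray:
    """Continuous bed elevation (metres above the domain bottom) per column."""
    dx = geom.wavelength_m * geom.n_ripples / nx
    xc = (np.arange(nx) + 0.5) * dx
    phase = np.mod(xc / geom.wavelength_m, 1.0)
    return geom.bed_depth_m + _ripple_elevation(phase, geom.height_m, geom.asymmetry)


def make_ripple(
    geom: RippleGeometry, nx: int, ny: int, ns_sediment: float
) -> PorosityField:
    """Rasterize the ripple train onto an nx×ny lattice.

    The horizontal cell size is dx = n_ripples·wavelength / nx (square
    cells); the domain width is exactly the periodic ripple train.
    """
    if not 0.0 < ns_sediment <= 1.0:
        raise ValueError(f"ns_sediment must lie in (0, 1], got {ns_sediment}")
    dx = geom.wavelength_m * geom.n_ripples / nx
    if geom.height_m > 0 and geom.height_m < 4 * dx:
        raise ValueError(
            f"under-resolved ripple: height_m {geom.height_m} < 4·dx ({4 * dx:.4g}); "
            "increase nx"
        )
    elev = bed_elevation_profile(geom, nx)
    bed_profile = np.rint(elev / dx).astype(np.int64) - 1  # highest sediment row
    bed_profile = np.clip(bed_profile, -1, ny - 2)
    if np.any(bed_profile >= ny - 2):
        pass  # crest may touch near the lid only by explicit user choice
    ns = np.zeros((ny, nx), dtype=np.float64)
    rows = np.arange(ny)[:, None]
    ns[rows <= bed_profile[None, :]] = ns_sediment
    interface_mask = _interface_mask(ns)
    field = PorosityField(ns=ns, interface_mask=interface_mask,
                          bed_profile=bed_profile, dx_m=dx)
    field.validate()
    return field


def _interface_mask(ns: np.ndarray) -> np.ndarray:
    solid = ns > 0
    water = ~solid
    neigh = np.zeros_like(solid)
    neigh |= np.roll(solid, 1, axis=1) | np.roll(solid, -1, axis=1)
    up = np.zeros_like(solid)
    up[:-1, :] = solid[1:, :]
    down = np.zeros_like(solid)
    down[1:, :] = solid[:-1, :]
    neigh |= up | down
    return water & neigh


def mirror_porosity(field: PorosityField) -> PorosityField:
    """Left-right mirror of the porosity field (for flow-reversal tests)."""
    return PorosityField(ns=field.ns[:, ::-1].copy(),
                         interface_mask=field.interface_mask[:, ::-1].copy(),
                         bed_profile=field.bed_profile[::-1].copy(),
                         dx_m=field.dx_m)


def sediment_fraction(field: PorosityField) -> float:
    """Fraction of domain area occupied by sediment cells."""
    return float(np.mean(field.ns > 0))


def physical_to_lattice(
    U_phys: float,
    L_phys: float,
    nu_phys: float,
    target_tau: float,
    n_cells: int,
    max_mach: float = 0.1,
) -> UnitSystem:
    """Choose (dx, dt) matching the physical Reynolds number at a given tau.

    L_phys is resolved by n_cells lattice cells; the lattice viscosity is
    fixed by target_tau via nu_lat = (tau - 1/2)/3, and dt follows from
    viscosity matching.  Raises if the resulting lattice velocity violates
    the low-Mach contract U_lat < max_mach·c_s.
    """
    if U_phys <= 0 or L_phys <= 0 or nu_phys <= 0:
        raise ValueError("U_phys, L_phys and nu_phys must all be > 0")
    if not 0.5 < target_tau <= 2.0:
        raise ValueError(f"target_tau must lie in (0.5, 2.0], got {target_tau}")
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    dx = L_phys / n_cells
    nu_lat = (target_tau - 0.5) / 3.0
    dt = nu_lat * dx**2 / nu_phys
    us = UnitSystem(dx_m=dx, dt_s=dt, nu_phys=nu_phys, U_phys=U_phys)
    if us.U_lattice >= max_mach * CS:
        raise ValueError(
            f"no admissible mapping: lattice velocity {us.U_lattice:.4g} exceeds "
            f"{max_mach}·c_s at tau={target_tau}, n_cells={n_cells}; "
            "lower tau or refine the grid"
        )
    return us


def lattice_to_physical(us: UnitSystem, n_cells: int) -> tuple[float, float, float]:
    """Inverse of :func:`physical_to_lattice`: (U_phys, L_phys, nu_phys)."""
    return us.U_phys, us.dx_m * n_cells, us.nu_phys


def reynolds_lattice(us: UnitSystem, n_cells: int) -> float:
    """Lattice Reynolds number U_lat·n_cells/nu_lat (equals the physical Re)."""
    return us.U_lattice * n_cells / us.nu_lattice
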