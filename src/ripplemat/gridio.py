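"""Field I/O: the CSV grid dialect and VTK legacy STRUCTURED_POINTS.

CSV grids are row-major (row 0 = domain bottom) with '#'-prefixed header
lines carrying nx, ny and dx_m; values round-trip at full double
precision.  The VTK writer emits ASCII legacy STRUCTURED_POINTS files
loadable by standard VTK readers (one or more scalar fields per file).
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np


class GridFormatError(ValueError):
    """Malformed grid file (dimension mismatch, bad header)."""


def write_field_csv(path, field: np.ndarray, dx_m: float = 1.0,
                    name: str = "field") -> None:
    field = np.asarray(field)
    if field.ndim != 2:
        raise GridFormatError(f"expected a 2-D grid, got shape {field.shape}")
    ny, nx = field.shape
    with open(path, "w") as fh:
        fh.write(f"# name: {name}\n")
        fh.write(f"# nx: {nx}\n# ny: {ny}\n# dx_m: {dx_m!r}\n")
        np.savetxt(fh, field, fmt="%.17g", delimiter=",")


def read_field_csv(path) -> tuple[np.ndarray, dict]:
    meta: dict = {}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            parts = line.split(",")
            if "nx" in meta and len(parts) != int(meta["nx"]):
                raise GridFormatError(
                    f"{path}: line {lineno} has {len(parts)} values, "
                    f"header says nx = {meta['nx']}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise GridFormatError(f"{path}: line {lineno}: {exc}") from exc
    arr = np.array(rows)
    if "ny" in meta and arr.shape[0] != int(meta["ny"]):
        raise GridFormatError(
            f"{path}: {arr.shape[0]} data rows, header says ny = {meta['ny']}"
        )
    if "dx_m" in meta:
        meta["dx_m"] = float(meta["dx_m"])
    for k in ("nx", "ny"):
        if k in meta:
            meta[k] = int(meta[k])
    return arr, meta


def write_vtk_structured_points(
    path, fields: dict, dx_m: float = 1.0, title: str = "ripplemat fields"
) -> None:
    """ASCII VTK legacy STRUCTURED_POINTS with one SCALARS block per field.

    2-D grids are written as nz = 1 volumes; vector fields may be passed
    as a (2, ny, nx) array and are emitted as 3-component VECTORS.
    """
    first = next(iter(fields.values()))
    ny, nx = (first.shape[-2], first.shape[-1])
    buf = io.StringIO()
    buf.write("# vtk DataFile Version 3.0\n")
    buf.write(title + "\n")
    buf.write("ASCII\n")
    buf.write("DATASET STRUCTURED_POINTS\n")
    buf.write(f"DIMENSIONS {nx} {ny} 1\n")
    buf.write("ORIGIN 0 0 0\n")
    buf.write(f"SPACING {dx_m!r} {dx_m!r} {dx_m!r}\n")
    buf.write(f"POINT_DATA {nx * ny}\n")
    for name, arr in fields.items():
        arr = np.asarray(arr)
        if arr.ndim == 3 and arr.shape[0] == 2:
            buf.write(f"VECTORS {name} double\n")
            for y in range(ny):
                for x in range(nx):
                    buf.write(f"{float(arr[0, y, x])!r} {float(arr[1, y, x])!r} 0\n")
        elif arr.ndim == 2:
            buf.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            for y in range(ny):
                for x in range(nx):
                    buf.write(f"{float(arr[y, x])!r}\n")
        else:
            raise GridFormatError(f"field {name!r} has unsupported shape {arr.shape}")
    Path(path).write_text(buf.getvalue())


def read_vtk_structured_points(path) -> tuple[dict, dict]:
    """Minimal reader for files produced by the writer above."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("# vtk DataFile"):
        raise GridFormatError(f"{path}: not a VTK legacy file")
    meta: dict = {}
    fields: dict = {}
    i = 0
    nx = ny = None
    while i < len(lines):
        line = lines[i].strip()
        toks = line.split()
        if line.startswith("DIMENSIONS"):
            nx, ny = int(toks[1]), int(toks[2])
            meta["nx"], meta["ny"] = nx, ny
        elif line.startswith("SPACING"):
            meta["dx_m"] = float(toks[1])
        elif line.startswith("SCALARS"):
            name = toks[1]
            i += 1  # skip LOOKUP_TABLE
            vals = []
            while len(vals) < nx * ny:
                i += 1
                vals.extend(float(t) for t in lines[i].split())
            fields[name] = np.array(vals).reshape(ny, nx)
        elif line.startswith("VECTORS"):
            name = toks[1]
            vals = []
            while len(vals) < nx * ny * 3:
                i += 1
                vals.extend(float(t) for t in lines[i].split())
            arr = np.array(vals).reshape(ny, nx, 3)
            fields[name] = np.moveaxis(arr, 2, 0)[:2]
        i += 1
    if nx is None:
        raise GridFormatError(f"{path}: missing DIMENSIONS")
    return fields, meta
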