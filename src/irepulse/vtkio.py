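"""Legacy-ASCII VTK structured-points export/import for voxel fields.

Writes the voxel grid as a ``STRUCTURED_POINTS`` dataset with point data
arrays (labels, potential, field magnitude) for inspection in ParaView.
The matching reader only parses files written by this module.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_structured_points", "read_structured_points"]


def write_structured_points(
    path,
    spacing_mm: float,
    origin: tuple[float, float, float],
    arrays: dict[str, np.ndarray],
    comment: str = "irepulse voxel field",
) -> None:
    """Write named voxel arrays (all of one 3D shape) as legacy VTK ASCII."""
    if not arrays:
        raise ValueError("need at least one array")
    shapes = {a.shape for a in arrays.values()}
    if len(shapes) != 1:
        raise ValueError("all arrays must share one shape")
    (nx, ny, nz) = shapes.pop()
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(comment.replace("\n", " ")[:255] + "\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin[0]:.6g} {origin[1]:.6g} {origin[2]:.6g}\n")
        fh.write(f"SPACING {spacing_mm:.6g} {spacing_mm:.6g} {spacing_mm:.6g}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in arrays.items():
            flat = np.asarray(arr, dtype=float).ravel(order="F")  # VTK: x fastest
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, flat.reshape(-1, 1), fmt="%.7g")


def read_structured_points(path):
    """Read a file written by :func:`write_structured_points`.

    Returns (arrays, spacing_mm, origin) with arrays of shape (nx, ny, nz).
    """
    lines = Path(path).read_text().splitlines()
    dims = None
    origin = (0.0, 0.0, 0.0)
    spacing = 1.0
    arrays: dict[str, np.ndarray] = {}
    i = 0
    while i < len(lines):
        tok = lines[i].split()
        if not tok:
            i += 1
            continue
        key = tok[0].upper()
        if key == "DIMENSIONS":
            dims = tuple(int(v) for v in tok[1:4])
        elif key == "ORIGIN":
            origin = tuple(float(v) for v in tok[1:4])
        elif key == "SPACING":
            spacing = float(tok[1])
        elif key == "SCALARS":
            name = tok[1]
            n = dims[0] * dims[1] * dims[2]
            vals = []
            j = i + 2  # skip LOOKUP_TABLE line
            while len(vals) < n:
                vals.extend(float(v) for v in lines[j].split())
                j += 1
            arrays[name] = np.asarray(vals).reshape(dims, order="F")
            i = j
            continue
        i += 1
    if dims is None:
        raise ValueError(f"{path} is not a structured-points VTK file")
    return arrays, spacing, origin
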