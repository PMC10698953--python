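"""Format readers/writers: PLY/OBJ meshes, legacy-VTK PolyData with per-vertex
scalars, NIfTI masks, CSV tables.

PLY/OBJ geometry goes through trimesh.  Scalar-bearing surface maps are
written as ASCII legacy VTK PolyData (readable by ParaView and friends); that
format has no maintained pure-Python reader in this stack, so a minimal
parser/writer for the POINTS / POLYGONS / POINT_DATA subset lives here.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .mesh import TriangleMesh, VoxelMask

logger = logging.getLogger(__name__)

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_mask",
    "read_table",
    "write_table",
    "write_vtk",
    "read_vtk",
]


def read_mesh(path: str | Path) -> TriangleMesh:
    """Read a PLY/OBJ/STL (via trimesh) or legacy VTK PolyData mesh."""
    path = Path(path)
    if path.suffix.lower() == ".vtk":
        mesh, _ = read_vtk(path)
        return mesh
    tm = trimesh.load_mesh(str(path), process=False)
    return TriangleMesh.from_trimesh(tm)


def write_mesh(mesh: TriangleMesh, path: str | Path,
               scalars: dict[str, np.ndarray] | None = None) -> Path:
    """Write a mesh; `.vtk` keeps named per-vertex scalar fields."""
    path = Path(path)
    if path.suffix.lower() == ".vtk":
        return write_vtk(mesh, path, scalars or {})
    if scalars:
        raise ValueError("per-vertex scalars require the .vtk format")
    mesh.to_trimesh().export(str(path))
    return path


def write_vtk(mesh: TriangleMesh, path: str | Path,
              scalars: dict[str, np.ndarray] | None = None) -> Path:
    path = Path(path)
    scalars = scalars or {}
    for name, vals in scalars.items():
        if len(vals) != mesh.n_vertices:
            raise ValueError(f"scalar field {name!r} length != n_vertices")
    lines = [
        "# vtk DataFile Version 3.0",
        "kidneymorph surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {mesh.n_vertices} double",
    ]
    lines += [" ".join(f"{x:.17g}" for x in row) for row in mesh.vertices]
    lines.append(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}")
    lines += [f"3 {a} {b} {c}" for a, b, c in mesh.faces]
    if scalars:
        lines.append(f"POINT_DATA {mesh.n_vertices}")
        for name, vals in scalars.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.17g}" for v in np.asarray(vals, float)]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vtk(path: str | Path) -> tuple[TriangleMesh, dict[str, np.ndarray]]:
    """Parse the ASCII legacy VTK PolyData subset written by :func:`write_vtk`."""
    lines = Path(path).read_text().splitlines()
    i, n_pts = 0, None
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    scalars: dict[str, np.ndarray] = {}

    def fail(msg: str) -> None:
        raise ValueError(f"{path}: line {i + 1}: {msg}")

    while i < len(lines):
        tok = lines[i].split()
        if tok and tok[0] == "POINTS":
            n_pts = int(tok[1])
            for j in range(n_pts):
                i += 1
                parts = lines[i].split()
                if len(parts) != 3:
                    fail("expected 3 point coordinates")
                verts.append([float(x) for x in parts])
        elif tok and tok[0] == "POLYGONS":
            n_f = int(tok[1])
            for j in range(n_f):
                i += 1
                parts = lines[i].split()
                if len(parts) != 4 or parts[0] != "3":
                    fail("expected triangle face '3 i j k'")
                idx = [int(x) for x in parts[1:]]
                if min(idx) < 0 or max(idx) >= n_pts:
                    fail("face index out of range")
                faces.append(idx)
        elif tok and tok[0] == "SCALARS":
            name = tok[1]
            i += 1  # LOOKUP_TABLE line
            vals = []
            for j in range(n_pts):
                i += 1
                vals.append(float(lines[i]))
            scalars[name] = np.array(vals)
        i += 1
    if n_pts is None:
        raise ValueError(f"{path}: no POINTS section found")
    return TriangleMesh(np.array(verts), np.array(faces, int)), scalars


def read_mask(path: str | Path) -> VoxelMask:
    """Read a binary NIfTI segmentation; nonzero voxels are foreground."""
    img = nib.load(str(path))
    data = (np.asanyarray(img.dataobj) > 0).astype(np.uint8)
    return VoxelMask(data=data, affine=np.asarray(img.affine))


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path
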