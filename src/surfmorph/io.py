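"""Format round-tripping: NIfTI masks, PLY/VTK meshes, CSV tables.

All writers are deterministic (fixed gzip mtime, canonical float
formatting) so reruns with identical inputs are byte-identical — the
pipeline's manifests rely on this.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .geometry import SurfaceMesh, VoxelMask

__all__ = [
    "read_mask",
    "write_mask",
    "read_mesh",
    "write_mesh",
    "read_table",
    "write_table",
    "write_vtk_polydata",
    "read_vtk_polydata",
]


# ---------------------------------------------------------------------------
# Masks (NIfTI)
# ---------------------------------------------------------------------------

def write_mask(mask: VoxelMask, path: str | Path) -> Path:
    """Write a binary mask as NIfTI; spacing/origin go into the affine.

    ``.nii.gz`` output is gzipped with mtime=0 for reproducible bytes.
    """
    path = Path(path)
    img = nib.Nifti1Image(mask.occupancy.astype(np.uint8), mask.affine)
    if path.name.endswith(".nii.gz"):
        raw = img.to_bytes()
        with open(path, "wb") as fh:
            with gzip.GzipFile(fileobj=fh, mode="wb", mtime=0) as gz:
                gz.write(raw)
    else:
        nib.save(img, str(path))
    return path


def read_mask(path: str | Path) -> VoxelMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    aff = img.affine
    occupancy = np.asarray(img.dataobj) > 0
    spacing = np.linalg.norm(aff[:3, :3], axis=0)
    return VoxelMask(occupancy, spacing, aff[:3, 3])


# ---------------------------------------------------------------------------
# Meshes (PLY binary, VTK legacy polydata)
# ---------------------------------------------------------------------------

def write_mesh(mesh: SurfaceMesh, path: str | Path) -> Path:
    """Write a mesh as binary little-endian PLY (or legacy VTK by suffix)."""
    path = Path(path)
    if path.suffix == ".vtk":
        return write_vtk_polydata(mesh, path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    data = tm.export(file_type="ply", encoding="binary")
    path.write_bytes(data)
    return path


def read_mesh(path: str | Path) -> SurfaceMesh:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".vtk":
        mesh, _ = read_vtk_polydata(path)
        return mesh
    tm = trimesh.load(str(path), file_type="ply", process=False)
    return SurfaceMesh(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=np.int64))


def write_vtk_polydata(
    mesh: SurfaceMesh, path: str | Path, point_data: dict[str, np.ndarray] | None = None
) -> Path:
    """Legacy-ASCII VTK polydata with optional per-vertex scalar arrays."""
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        "surfmorph polydata",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {mesh.n_vertices} float",
    ]
    for v in mesh.vertices:
        lines.append(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
    lines.append(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_vertices}")
        for name, values in point_data.items():
            values = np.asarray(values, dtype=float)
            if len(values) != mesh.n_vertices:
                raise ValueError(f"scalar array {name!r} length mismatch")
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{x:.9g}" for x in values)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vtk_polydata(path: str | Path) -> tuple[SurfaceMesh, dict[str, np.ndarray]]:
    tokens = Path(path).read_text().split("\n")
    i = 0
    verts = faces = None
    scalars: dict[str, np.ndarray] = {}
    n_points = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n_points = int(line.split()[1])
            vals = []
            i += 1
            while len(vals) < 3 * n_points:
                vals.extend(float(x) for x in tokens[i].split())
                i += 1
            verts = np.array(vals).reshape(n_points, 3)
            continue
        if line.startswith("POLYGONS"):
            n_faces = int(line.split()[1])
            fl = []
            i += 1
            for _ in range(n_faces):
                parts = tokens[i].split()
                if int(parts[0]) != 3:
                    raise ValueError(f"non-triangle polygon at line {i + 1} of {path}")
                fl.append([int(p) for p in parts[1:4]])
                i += 1
            faces = np.array(fl, dtype=np.int64)
            continue
        if line.startswith("SCALARS"):
            name = line.split()[1]
            i += 2  # skip LOOKUP_TABLE
            vals = []
            while len(vals) < n_points:
                vals.extend(float(x) for x in tokens[i].split())
                i += 1
            scalars[name] = np.array(vals)
            continue
        i += 1
    if verts is None or faces is None:
        raise ValueError(f"malformed VTK polydata file: {path}")
    return SurfaceMesh(verts, faces), scalars


# ---------------------------------------------------------------------------
# Tables (CSV)
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    df.to_csv(path, index=index)
    return path


def read_table(
    path: str | Path, required: list[str] | None = None, allow_missing: bool = False
) -> pd.DataFrame:
    """Read a CSV table; missing cells are an error unless allowed.

    Complete-case analysis is the package's only missing-data policy, so
    silent imputation is never performed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    if required:
        missing = set(required) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if not allow_missing and df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        rows = df.index[df.isna().any(axis=1)].tolist()[:5]
        raise ValueError(
            f"{path}: missing values in columns {bad} (first rows {rows}); "
            "complete-case analysis only — drop or fill these rows explicitly"
        )
    return df
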