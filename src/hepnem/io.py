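"""Readers and writers for meshes, network skeletons, and density grids.

Formats: PLY (ascii or binary little-endian) with a per-vertex ``uchar
label`` property for labeled cell surfaces, OFF for unlabeled geometry,
JSON for skeletons, multi-page TIFF for voxel grids (voxel size carried in
the image description). Positions are written at 64-bit precision so
round-trips are lossless.
"""

from __future__ import annotations

import json
import struct
import warnings
from pathlib import Path

import numpy as np
import tifffile
import trimesh

from .types import DensityGrid, Label, LabeledSurfaceMesh, NetworkSkeleton

DEFAULT_VOXEL_SIZE = 0.3  # μm


class FormatError(ValueError):
    """Input file does not match the documented schema."""


class MissingLabelError(FormatError):
    """Mesh file lacks the per-vertex label attribute."""


def volumetric_center(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Divergence-theorem centroid of a closed, consistently oriented mesh.

    Decomposes the solid into signed tetrahedra against the coordinate
    origin; robust to the mesh not enclosing the origin.
    """
    v = np.asarray(vertices, dtype=float)
    t = np.asarray(triangles)
    a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    vol = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
    total = vol.sum()
    if abs(total) < 1e-12:
        raise ValueError("mesh has (near) zero enclosed volume")
    centroid = ((a + b + c) / 4.0 * vol[:, None]).sum(axis=0) / total
    return centroid


def is_closed(triangles: np.ndarray) -> bool:
    """True if every edge is shared by exactly two triangles."""
    t = np.asarray(triangles)
    edges = np.sort(
        np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]]), axis=1
    )
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool(np.all(counts == 2))


def _mesh_from_arrays(
    cell_id: str, vertices: np.ndarray, triangles: np.ndarray, labels: np.ndarray
) -> LabeledSurfaceMesh:
    closed = is_closed(triangles)
    if closed:
        center = volumetric_center(vertices, triangles)
    else:
        warnings.warn(
            f"mesh {cell_id!r} is not closed; using vertex centroid as center",
            stacklevel=3,
        )
        center = np.asarray(vertices, dtype=float).mean(axis=0)
    mesh = LabeledSurfaceMesh(
        cell_id=cell_id,
        vertices=vertices,
        triangles=triangles,
        vertex_labels=labels,
        center=center,
        is_closed=closed,
    )
    mesh.validate()
    return mesh


def read_labeled_mesh(path: str | Path) -> LabeledSurfaceMesh:
    """Read a labeled triangle mesh (PLY with ``label``, or OFF).

    OFF files carry no vertex attributes; all vertices read as unlabeled.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in (".ply", ".off"):
        raise FormatError(f"unsupported mesh format {suffix!r} (use .ply or .off)")
    loaded = trimesh.load(path, process=False, force="mesh")
    faces = np.asarray(loaded.faces)
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise FormatError("mesh faces are not all triangles")
    vertices = np.asarray(loaded.vertices, dtype=float)
    if suffix == ".ply":
        raw = loaded.metadata.get("_ply_raw", {})
        vdata = raw.get("vertex", {}).get("data")
        if isinstance(vdata, dict):
            has_label = "label" in vdata
        else:
            has_label = "label" in (
                getattr(getattr(vdata, "dtype", None), "names", None) or ()
            )
        if not has_label:
            raise MissingLabelError(f"{path} has no per-vertex 'label' property")
        labels = np.asarray(vdata["label"]).reshape(-1).astype(np.uint8)
    else:
        labels = np.full(len(vertices), int(Label.UNLABELED), dtype=np.uint8)
    return _mesh_from_arrays(path.stem, vertices, faces, labels)


def write_labeled_mesh(
    mesh: LabeledSurfaceMesh, path: str | Path, binary: bool = True
) -> Path:
    """Write a mesh to PLY (64-bit positions + uchar label) or OFF."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".off":
        trimesh.Trimesh(mesh.vertices, mesh.triangles, process=False).export(path)
        return path
    if suffix != ".ply":
        raise FormatError(f"cannot infer mesh format from {path.name!r}")
    fmt = "binary_little_endian" if binary else "ascii"
    header = "\n".join(
        [
            "ply",
            f"format {fmt} 1.0",
            f"element vertex {len(mesh.vertices)}",
            "property double x",
            "property double y",
            "property double z",
            "property uchar label",
            f"element face {len(mesh.triangles)}",
            "property list uchar int vertex_indices",
            "end_header",
        ]
    )
    if binary:
        buf = bytearray(header.encode() + b"\n")
        for p, l in zip(mesh.vertices, mesh.vertex_labels):
            buf += struct.pack("<3dB", p[0], p[1], p[2], int(l))
        for t in mesh.triangles:
            buf += struct.pack("<B3i", 3, int(t[0]), int(t[1]), int(t[2]))
        path.write_bytes(bytes(buf))
    else:
        lines = [header]
        for p, l in zip(mesh.vertices, mesh.vertex_labels):
            lines.append(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g} {int(l)}")
        for t in mesh.triangles:
            lines.append(f"3 {t[0]} {t[1]} {t[2]}")
        path.write_text("\n".join(lines) + "\n")
    return path


def read_skeleton(path: str | Path) -> NetworkSkeleton:
    """Read a skeleton from JSON: {"nodes": [[x,y,z],...], "segments": [[i,j],...]}."""
    data = json.loads(Path(path).read_text())
    try:
        nodes = np.asarray(data["nodes"], dtype=float).reshape(-1, 3)
        segments = np.asarray(data["segments"], dtype=np.int64).reshape(-1, 2)
    except (KeyError, ValueError) as exc:
        raise FormatError(f"bad skeleton schema in {path}: {exc}") from exc
    skel = NetworkSkeleton(nodes=nodes, segments=segments)
    skel.validate()
    return skel


def write_skeleton(skeleton: NetworkSkeleton, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(
            {
                "nodes": skeleton.nodes.tolist(),
                "segments": skeleton.segments.tolist(),
            }
        )
    )
    return path


def read_density_grid(path: str | Path) -> DensityGrid:
    """Read a voxel grid from multi-page TIFF (pages = z slices).

    Voxel size and origin are taken from a JSON image description
    ``{"voxel_size_um": [sx, sy, sz], "origin_um": [x, y, z]}``; anisotropic
    voxel sizes are rejected, a missing description falls back to the 0.3 μm
    default with a warning.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    if arr.ndim == 2:
        raise FormatError(f"{path} is a 2D image; a 3D stack is required")
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    if "voxel_size_um" in meta:
        vs = np.asarray(meta["voxel_size_um"], dtype=float)
        if not np.allclose(vs, vs[0], rtol=1e-9, atol=0.0):
            raise FormatError(f"anisotropic voxels {vs.tolist()} not supported")
        voxel_size = float(vs[0])
    else:
        warnings.warn(
            f"{path.name}: no voxel-size metadata, assuming "
            f"{DEFAULT_VOXEL_SIZE} μm",
            stacklevel=2,
        )
        voxel_size = DEFAULT_VOXEL_SIZE
    origin = np.asarray(meta.get("origin_um", [0.0, 0.0, 0.0]), dtype=float)
    # pages are (z, y, x); internal layout is (x, y, z)
    grid = DensityGrid(values=arr.T, voxel_size=voxel_size, origin=origin)
    grid.validate()
    return grid


def write_density_grid(grid: DensityGrid, path: str | Path) -> Path:
    path = Path(path)
    desc = json.dumps(
        {
            "voxel_size_um": [grid.voxel_size] * 3,
            "origin_um": grid.origin.tolist(),
        }
    )
    tifffile.imwrite(path, np.ascontiguousarray(grid.values.T), description=desc)
    return path
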