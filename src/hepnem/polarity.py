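"""Per-cell biaxial nematic polarity from labeled surface meshes.

The apical (or basal) membrane pattern of a cell is summarized by a
symmetric traceless nematic tensor built from the cell surface radially
projected onto the unit sphere around the cell's volumetric center:

    N = (3/2) * sum_{i in marker} A_i (n_i ⊗ n_i − I/3) / sum_{i in marker} A_i

where A_i is the solid angle of projected triangle i and n_i the unit
direction of its spherical centroid. Eigen-decomposition yields the bipolar
axis a1 (largest eigenvalue σ1) and the ring axis a2 (smallest eigenvalue
σ2), with σ2 ≤ σ3 ≤ σ1 and σ1+σ2+σ3 = 0. Two antipodal marker caps give
σ1 = 1 (ring axis degenerate); a marker belt gives σ2 = −1/2 (bipolar axis
degenerate). Real hepatocytes sit between these extremes, so both axes are
typically well defined — the pattern is biaxial.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    CellRecord,
    Label,
    LabeledSurfaceMesh,
    NematicTensor,
    PolarityAxes,
    ProjectedTriangleSet,
    canonical_axis,
)

DEGENERACY_TOL = 0.05


class NoMarkerError(ValueError):
    """The requested marker labels no triangle of the mesh."""


class DegenerateProjectionError(ValueError):
    """A vertex coincides with the projection center."""


class FrameDegeneracyError(ValueError):
    """Apical and basal bipolar axes are (anti)parallel; no map frame exists."""


def select_marker_triangles(mesh: LabeledSurfaceMesh, label: Label) -> np.ndarray:
    """Indices of triangles with at least two vertices carrying ``label``."""
    tri_labels = mesh.vertex_labels[mesh.triangles]
    count = (tri_labels == int(label)).sum(axis=1)
    return np.flatnonzero(count >= 2)


def triangle_solid_angles(units: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Signed solid angles of spherical triangles (Van Oosterom–Strackee).

    ``units``: unit vectors of the projected vertices. Positive sign means
    the triangle winds counter-clockwise as seen from outside.
    """
    a = units[triangles[:, 0]]
    b = units[triangles[:, 1]]
    c = units[triangles[:, 2]]
    numer = np.einsum("ij,ij->i", a, np.cross(b, c))
    denom = (
        1.0
        + np.einsum("ij,ij->i", a, b)
        + np.einsum("ij,ij->i", b, c)
        + np.einsum("ij,ij->i", c, a)
    )
    return 2.0 * np.arctan2(numer, denom)


def spherical_projection(
    mesh: LabeledSurfaceMesh, marker: Label = Label.APICAL
) -> ProjectedTriangleSet:
    """Radially project the cell surface onto the unit sphere at its center.

    Assumes the surface is star-convex with respect to the center; triangles
    whose signed solid angle is negative (rays crossing the surface more
    than once) are counted as violations and their areas taken unsigned.
    """
    rel = mesh.vertices - mesh.center
    norms = np.linalg.norm(rel, axis=1)
    if np.any(norms < 1e-9):
        raise DegenerateProjectionError("vertex coincides with the cell center")
    units = rel / norms[:, None]
    signed = triangle_solid_angles(units, mesh.triangles)
    n_violations = int(np.sum(signed < 0))
    areas = np.abs(signed)
    centroid = units[mesh.triangles].sum(axis=1)
    directions = centroid / np.linalg.norm(centroid, axis=1, keepdims=True)
    proj = ProjectedTriangleSet(
        areas=areas,
        directions=directions,
        marker_mask=select_marker_triangles(mesh, marker),
    )
    proj.n_star_convexity_violations = n_violations
    return proj


def nematic_tensor(proj: ProjectedTriangleSet) -> NematicTensor:
    """Area-weighted nematic tensor of the marker triangle directions.

    Normalized by the total marker solid angle, so the idealized pure
    bipolar pattern yields σ1 = 1 regardless of how much of the surface the
    marker covers.
    """
    idx = np.asarray(proj.marker_mask)
    if idx.size == 0:
        raise NoMarkerError("marker labels no triangle; nematic tensor undefined")
    a = proj.areas[idx]
    n = proj.directions[idx]
    outer = np.einsum("i,ij,ik->jk", a, n, n)
    total = a.sum()
    mat = 1.5 * (outer / total - np.eye(3) / 3.0)
    mat = 0.5 * (mat + mat.T)
    mat -= np.trace(mat) / 3.0 * np.eye(3)
    return NematicTensor(matrix=mat)


def polarity_axes(
    tensor: NematicTensor, degeneracy_tol: float = DEGENERACY_TOL
) -> PolarityAxes:
    """Eigen-axes and weights of a nematic tensor, ordered σ2 ≤ σ3 ≤ σ1.

    a1 (bipolar) belongs to the largest eigenvalue, a2 (ring) to the
    smallest; a3 = ±a1×a2. An axis is flagged degenerate when the
    eigenvalue gap that defines it is below ``degeneracy_tol``.
    """
    evals, evecs = np.linalg.eigh(tensor.matrix)  # ascending
    s2, s3, s1 = evals
    a2, a3_raw, a1 = evecs.T
    a1 = canonical_axis(a1)
    a2 = canonical_axis(a2)
    a3 = canonical_axis(np.cross(a1, a2))
    deg1 = bool(s1 - s3 < degeneracy_tol)
    deg2 = bool(s3 - s2 < degeneracy_tol)
    return PolarityAxes(
        a1=a1,
        a2=a2,
        a3=a3,
        sigma1=float(s1),
        sigma2=float(s2),
        sigma3=float(s3),
        degenerate=(deg1, deg2, deg1 or deg2),
    )


def cell_polarity(
    mesh: LabeledSurfaceMesh,
    marker: Label = Label.APICAL,
    degeneracy_tol: float = DEGENERACY_TOL,
) -> PolarityAxes:
    """Convenience chain: projection → nematic tensor → eigen-axes."""
    return polarity_axes(
        nematic_tensor(spherical_projection(mesh, marker)), degeneracy_tol
    )


# ---------------------------------------------------------------------------
# Mollweide map of the apical pattern in the cell's own polarity frame
# ---------------------------------------------------------------------------


def _mollweide_theta(phi: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Solve 2θ + sin 2θ = π sin φ (Newton), the Mollweide auxiliary angle."""
    phi = np.asarray(phi, dtype=float)
    theta = np.array(phi, dtype=float)
    pole = np.abs(np.abs(phi) - np.pi / 2) < 1e-9
    target = np.pi * np.sin(phi)
    for _ in range(50):
        f = 2 * theta + np.sin(2 * theta) - target
        df = 2 + 2 * np.cos(2 * theta)
        step = np.where(df > 1e-12, f / np.maximum(df, 1e-12), 0.0)
        theta = theta - step
        if np.max(np.abs(f)) < tol:
            break
    theta[pole] = np.sign(phi[pole]) * np.pi / 2
    return theta


def mollweide_xy(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Equal-area Mollweide map coordinates; half-width 2√2, half-height √2."""
    theta = _mollweide_theta(np.asarray(lat, dtype=float))
    lon = np.asarray(lon, dtype=float)
    x = 2.0 * np.sqrt(2.0) / np.pi * lon * np.cos(theta)
    y = np.sqrt(2.0) * np.sin(theta)
    return np.column_stack([x, y])


def mollweide_coordinates(
    mesh: LabeledSurfaceMesh,
    apical: PolarityAxes,
    basal: PolarityAxes,
    min_angle_deg: float = 1.0,
) -> np.ndarray:
    """Map the apical vertices into the cell's Mollweide frame.

    The basal bipolar axis b1 is the pole axis, and the apical bipolar axis
    a1 fixes the zero meridian, so the dominant apical patch sits at the map
    center. Returns (k, 2) coordinates for the apical vertices.
    """
    pole = basal.a1 / np.linalg.norm(basal.a1)
    a1 = apical.a1 / np.linalg.norm(apical.a1)
    cosang = abs(float(np.dot(pole, a1)))
    if cosang > np.cos(np.deg2rad(min_angle_deg)):
        raise FrameDegeneracyError(
            "apical and basal bipolar axes are parallel; map frame undefined"
        )
    m1 = a1 - np.dot(a1, pole) * pole
    m1 /= np.linalg.norm(m1)
    m2 = np.cross(pole, m1)
    apical_idx = np.flatnonzero(mesh.vertex_labels == int(Label.APICAL))
    rel = mesh.vertices[apical_idx] - mesh.center
    u = rel / np.linalg.norm(rel, axis=1, keepdims=True)
    lat = np.arcsin(np.clip(u @ pole, -1.0, 1.0))
    lon = np.arctan2(u @ m2, u @ m1)
    return mollweide_xy(lon, lat)


# ---------------------------------------------------------------------------
# Apical–basal axis cross-correlation (four-pair alignment table)
# ---------------------------------------------------------------------------

_PAIRS = (("a1", "b1"), ("a1", "b2"), ("a2", "b1"), ("a2", "b2"))


def _get_axis(cell: CellRecord, name: str) -> Optional[np.ndarray]:
    which = cell.apical_axes if name[0] == "a" else cell.basal_axes
    if which is None:
        return None
    idx = int(name[1]) - 1
    if which.degenerate[idx]:
        return None
    return which.axes[idx]


def axis_cross_correlation(cells: Sequence[CellRecord]) -> pd.DataFrame:
    """Nematic alignment S between apical and basal polarity axes.

    For each of the four pairs (a1,b1), (a1,b2), (a2,b1), (a2,b2), computes
    the alignment parameter over cells where both axes are non-degenerate.
    Rows carry the pooled S, the cell count, and — when cells carry group
    labels (animals / replicates) — the across-group mean and s.d.
    """
    from .alignment import alignment_parameter

    rows = []
    for ea, eb in _PAIRS:
        axes_a, axes_b, groups = [], [], []
        for cell in cells:
            va, vb = _get_axis(cell, ea), _get_axis(cell, eb)
            if va is None or vb is None:
                continue
            axes_a.append(va)
            axes_b.append(vb)
            groups.append(cell.group)
        if not axes_a:
            raise ValueError(
                f"no cells with non-degenerate {ea} and {eb}; cannot correlate"
            )
        axes_a = np.asarray(axes_a)
        axes_b = np.asarray(axes_b)
        row = {
            "pair": f"{ea}-{eb}",
            "S": alignment_parameter(axes_a, axes_b),
            "n_cells": len(axes_a),
        }
        labels = [g for g in groups if g is not None]
        if labels:
            per_group = [
                alignment_parameter(
                    axes_a[[i for i, g in enumerate(groups) if g == lab]],
                    axes_b[[i for i, g in enumerate(groups) if g == lab]],
                )
                for lab in sorted(set(labels))
            ]
            row["group_mean"] = float(np.mean(per_group))
            row["group_sd"] = float(np.std(per_group, ddof=1)) if len(per_group) > 1 else np.nan
            row["n_groups"] = len(per_group)
        rows.append(row)
    return pd.DataFrame(rows).set_index("pair")


def polarity_table(
    records: Iterable[CellRecord],
) -> pd.DataFrame:
    """Flat per-cell table of axes and weights for CSV export."""
    rows = []
    for c in records:
        row = {"cell_id": c.cell_id}
        row.update({f"pos_{k}": float(v) for k, v in zip("xyz", c.position)})
        for prefix, axes in (("a", c.apical_axes), ("b", c.basal_axes)):
            if axes is None:
                continue
            for i, (ax, sig, deg) in enumerate(
                zip(axes.axes, (axes.sigma1, axes.sigma2, axes.sigma3), axes.degenerate),
                start=1,
            ):
                row.update(
                    {f"{prefix}{i}_{k}": float(v) for k, v in zip("xyz", ax)}
                )
                row[f"{prefix}{i}_sigma"] = float(sig)
                row[f"{prefix}{i}_degenerate"] = bool(deg)
        if c.local_sinusoid_axis is not None:
            row.update(
                {f"sinusoid_{k}": float(v) for k, v in zip("xyz", c.local_sinusoid_axis)}
            )
        rows.append(row)
    return pd.DataFrame(rows)
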