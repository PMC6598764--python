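"""Lobule-level reference field from vein geometry.

The central vein (CV) and portal vein (PV) surfaces are turned into point
charges at their triangle centroids, with strength proportional to the
relative triangle area and net charge +1 on the CV and −1 on the PV. The
scalar field

    χ(r) = sum_i q_i / |r − r_i|

is the Green's-function superposition of these charges (equivalently the
steady-state concentration of diffusive transport from CV source to PV
sink, up to an additive constant); χ < 0 near the PV, χ > 0 near the CV.
Its gradient J = ∇χ, normalized to unit length, provides the local CV–PV
reference direction against which polarity and network axes are scored.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from .types import ChargeSet

EXCLUSION_RADIUS = 2.0  # μm
STAGNATION_TOL = 1e-14


class SingularityError(ValueError):
    """An evaluation point lies within the exclusion radius of a charge."""


def _triangle_areas_centers(
    vertices: np.ndarray, triangles: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(vertices, dtype=float)
    t = np.asarray(triangles)
    a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    centers = (a + b + c) / 3.0
    return areas, centers


def build_charges(
    cv_vertices: np.ndarray,
    cv_triangles: np.ndarray,
    pv_vertices: np.ndarray,
    pv_triangles: np.ndarray,
) -> ChargeSet:
    """One charge per vein-mesh triangle, q_i = ±A_i / ΣA (CV +, PV −)."""
    positions, charges, tags = [], [], []
    for verts, tris, sign, tag in (
        (cv_vertices, cv_triangles, +1.0, "CV"),
        (pv_vertices, pv_triangles, -1.0, "PV"),
    ):
        areas, centers = _triangle_areas_centers(verts, tris)
        keep = areas > 1e-12
        if np.any(~keep):
            warnings.warn(
                f"dropping {int(np.sum(~keep))} degenerate triangles on {tag}",
                stacklevel=2,
            )
        areas, centers = areas[keep], centers[keep]
        if areas.size == 0:
            raise ValueError(f"{tag} mesh has no triangle with positive area")
        positions.append(centers)
        charges.append(sign * areas / areas.sum())
        tags.extend([tag] * len(areas))
    charge_set = ChargeSet(
        positions=np.concatenate(positions),
        charges=np.concatenate(charges),
        vein_tags=np.asarray(tags),
    )
    charge_set.validate()
    return charge_set


def _check_exclusion(
    diffs: np.ndarray, dists: np.ndarray, exclusion_radius: float
) -> None:
    bad = dists < exclusion_radius
    if np.any(bad):
        pt, ch = np.argwhere(bad)[0]
        raise SingularityError(
            f"point {pt} is {dists[pt, ch]:.3g} μm from charge {ch} "
            f"(exclusion radius {exclusion_radius} μm)"
        )


def evaluate_chi(
    points: np.ndarray,
    charges: ChargeSet,
    exclusion_radius: float = EXCLUSION_RADIUS,
) -> np.ndarray:
    """χ(r) = Σ q_i / |r − r_i| at each point (1/μm units)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    diffs = points[:, None, :] - charges.positions[None, :, :]
    dists = np.linalg.norm(diffs, axis=2)
    _check_exclusion(diffs, dists, exclusion_radius)
    return (charges.charges[None, :] / dists).sum(axis=1)


def reference_direction(
    points: np.ndarray,
    charges: ChargeSet,
    exclusion_radius: float = EXCLUSION_RADIUS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit reference directions J = ∇χ at each point.

    Returns (directions, magnitudes, valid): ``directions`` are unit
    vectors (NaN where invalid), ``magnitudes`` the raw |∇χ|, and ``valid``
    flags points that are not stagnation points of the field.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    diffs = points[:, None, :] - charges.positions[None, :, :]
    dists = np.linalg.norm(diffs, axis=2)
    _check_exclusion(diffs, dists, exclusion_radius)
    # ∇_r (1/|r−r_i|) = −(r−r_i)/|r−r_i|^3
    grad = -np.einsum("pc,pcd->pd", charges.charges[None, :] / dists**3, diffs)
    mag = np.linalg.norm(grad, axis=1)
    valid = mag > STAGNATION_TOL
    directions = np.full_like(grad, np.nan)
    directions[valid] = grad[valid] / mag[valid, None]
    return directions, mag, valid


def field_line(
    start: np.ndarray,
    charges: ChargeSet,
    step: float = 1.0,
    max_steps: int = 1000,
    stop_radius: float = EXCLUSION_RADIUS,
) -> np.ndarray:
    """Euler-integrated field line of J from ``start`` toward the CV."""
    pts = [np.asarray(start, dtype=float)]
    for _ in range(max_steps):
        d = np.linalg.norm(pts[-1][None, :] - charges.positions, axis=1)
        if d.min() <= stop_radius * 1.5:
            break
        direction, _, valid = reference_direction(
            pts[-1], charges, exclusion_radius=stop_radius
        )
        if not valid[0]:
            break
        nxt = pts[-1] + step * direction[0]
        d_next = np.linalg.norm(nxt[None, :] - charges.positions, axis=1)
        if d_next.min() <= stop_radius * 1.5:
            break
        pts.append(nxt)
    return np.asarray(pts)
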