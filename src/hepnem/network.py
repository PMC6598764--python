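"""Anisotropy of tubular network skeletons (sinusoids, bile canaliculi).

A skeleton is a set of straight segments with lengths l_i and unit
orientations e_i. Its anisotropy is the length-weighted nematic tensor

    N = (3/2) * sum_i l_i (e_i ⊗ e_i − I/3) / sum_i l_i

whose largest-eigenvalue axis is the network's preferred direction. The
local preferred axis around a cell restricts the sum to segments near the
cell (midpoint within a ball of roughly one hepatocyte diameter, segments
clipped to the ball so lengths weight only the part inside).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .types import NematicTensor, NetworkSkeleton, canonical_axis

DEFAULT_RADIUS = 20.0  # μm, approximately one hepatocyte diameter


class NoSegmentsError(ValueError):
    """The selection contains no segments of positive length."""


def nematic_from_orientations(
    orientations: np.ndarray, weights: np.ndarray
) -> NematicTensor:
    orientations = np.asarray(orientations, dtype=float)
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if orientations.shape[0] == 0 or total <= 0:
        raise NoSegmentsError("no segments with positive total length")
    outer = np.einsum("i,ij,ik->jk", weights, orientations, orientations)
    mat = 1.5 * (outer / total - np.eye(3) / 3.0)
    mat = 0.5 * (mat + mat.T)
    mat -= np.trace(mat) / 3.0 * np.eye(3)
    return NematicTensor(matrix=mat)


def skeleton_nematic_tensor(
    skeleton: NetworkSkeleton, segment_indices: Optional[np.ndarray] = None
) -> NematicTensor:
    """Length-weighted nematic tensor of (a subset of) skeleton segments."""
    lengths = skeleton.lengths
    orientations = skeleton.orientations
    if segment_indices is not None:
        lengths = lengths[segment_indices]
        orientations = orientations[segment_indices]
    return nematic_from_orientations(orientations, lengths)


def _clip_to_ball(
    p0: np.ndarray, p1: np.ndarray, center: np.ndarray, radius: float
) -> np.ndarray:
    """Lengths of segment portions inside the ball (vectorized)."""
    d = p1 - p0
    f = p0 - center
    a = np.einsum("ij,ij->i", d, d)
    b = 2.0 * np.einsum("ij,ij->i", f, d)
    c = np.einsum("ij,ij->i", f, f) - radius**2
    disc = b * b - 4 * a * c
    inside = np.zeros(len(p0))
    ok = disc > 0
    sq = np.sqrt(np.where(ok, disc, 0.0))
    t0 = np.clip((-b - sq) / (2 * a), 0.0, 1.0)
    t1 = np.clip((-b + sq) / (2 * a), 0.0, 1.0)
    inside[ok] = ((t1 - t0) * np.sqrt(a))[ok]
    return inside


@dataclass
class LocalAxisResult:
    axis: np.ndarray  # unit, canonical representative
    weight: float  # largest eigenvalue of the local nematic tensor
    n_segments: int
    degenerate: bool  # top two eigenvalues closer than the tolerance


def local_network_axis(
    skeleton: NetworkSkeleton,
    point: np.ndarray,
    radius: float = DEFAULT_RADIUS,
    degeneracy_tol: float = 0.05,
) -> Optional[LocalAxisResult]:
    """Preferred axis of the network within ``radius`` of ``point``.

    Segments whose midpoint falls inside the ball contribute; each is
    clipped to the ball so its weight is the length actually inside.
    Returns None when the neighborhood is empty (the cell is then excluded
    from downstream alignment statistics).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    point = np.asarray(point, dtype=float)
    mid = skeleton.midpoints
    near = np.flatnonzero(np.linalg.norm(mid - point, axis=1) <= radius)
    if near.size == 0:
        return None
    p0 = skeleton.nodes[skeleton.segments[near, 0]]
    p1 = skeleton.nodes[skeleton.segments[near, 1]]
    clipped = _clip_to_ball(p0, p1, point, radius)
    keep = clipped > 1e-12
    if not np.any(keep):
        return None
    tensor = nematic_from_orientations(
        skeleton.orientations[near][keep], clipped[keep]
    )
    evals, evecs = np.linalg.eigh(tensor.matrix)
    return LocalAxisResult(
        axis=canonical_axis(evecs[:, 2]),
        weight=float(evals[2]),
        n_segments=int(keep.sum()),
        degenerate=bool(evals[2] - evals[1] < degeneracy_tol),
    )


def dead_end_count(skeleton: NetworkSkeleton) -> int:
    """Number of degree-1 nodes (dead ends), a simple topology readout."""
    if skeleton.segments.size == 0:
        return 0
    counts = np.bincount(skeleton.segments.ravel(), minlength=len(skeleton.nodes))
    return int(np.sum(counts == 1))
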