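"""Core domain types shared by all analysis stages.

Lengths are micrometers throughout; coordinates are right-handed. Axes of
nematic quantities are sign-free ("two-headed"): the stored representative
of every axis has a non-negative z component (ties broken on y, then x),
but no statistic in the package depends on the representative chosen.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class Label(enum.IntEnum):
    """Membrane identity of a mesh vertex."""

    LATERAL = 0
    APICAL = 1
    BASAL = 2
    UNLABELED = 255


def canonical_axis(v: np.ndarray) -> np.ndarray:
    """Return the canonical sign representative of a nematic axis.

    The representative has non-negative z component; if z is (numerically)
    zero the tie is broken on y, then x.
    """
    v = np.asarray(v, dtype=float)
    for c in (2, 1, 0):
        if abs(v[c]) > 1e-12:
            return v if v[c] > 0 else -v
    return v


@dataclass
class LabeledSurfaceMesh:
    """Triangulated cell surface with per-vertex membrane labels.

    ``center`` is the volumetric center (divergence-theorem centroid) for
    closed meshes, or the vertex centroid when the mesh is open
    (``is_closed`` False).
    """

    cell_id: str
    vertices: np.ndarray  # (n, 3) float, μm
    triangles: np.ndarray  # (m, 3) int
    vertex_labels: np.ndarray  # (n,) uint8, values in Label
    center: np.ndarray  # (3,) float, μm
    is_closed: bool = True

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.vertex_labels = np.asarray(self.vertex_labels, dtype=np.uint8)
        self.center = np.asarray(self.center, dtype=float)

    def validate(self) -> None:
        n = len(self.vertices)
        if n < 4 or len(self.triangles) < 4:
            raise ValueError("mesh needs at least 4 vertices and 4 triangles")
        if self.triangles.min() < 0 or self.triangles.max() >= n:
            raise ValueError("triangle index out of range")
        if len(self.vertex_labels) != n:
            raise ValueError("one label per vertex required")
        valid = {int(l) for l in Label}
        if not set(np.unique(self.vertex_labels)).issubset(valid):
            raise ValueError("vertex label outside the label enum")


@dataclass
class ProjectedTriangleSet:
    """Triangles of a cell surface radially projected onto the unit sphere.

    ``areas`` are solid angles (steradians), ``directions`` unit vectors of
    the spherical-triangle centroids, ``marker_mask`` the indices carrying
    the marker (e.g. apical) identity.
    """

    areas: np.ndarray  # (m,) steradians
    directions: np.ndarray  # (m, 3) unit vectors
    marker_mask: np.ndarray  # (k,) int indices into areas/directions

    @property
    def total_solid_angle(self) -> float:
        return float(self.areas.sum())


@dataclass
class NematicTensor:
    """Symmetric traceless rank-2 orientation tensor."""

    matrix: np.ndarray  # (3, 3)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)

    def validate(self, sym_tol: float = 1e-12, trace_tol: float = 1e-10) -> None:
        m = self.matrix
        if m.shape != (3, 3):
            raise ValueError("nematic tensor must be 3x3")
        if not np.allclose(m, m.T, atol=sym_tol, rtol=0.0):
            raise ValueError("nematic tensor must be symmetric")
        if abs(np.trace(m)) > trace_tol:
            raise ValueError("nematic tensor must be traceless")


@dataclass
class PolarityAxes:
    """Eigen-system of a cell's nematic polarity tensor.

    a1 is the bipolar axis (largest eigenvalue sigma1), a2 the ring axis
    (smallest eigenvalue sigma2), a3 = ±a1×a2 with sigma3 = −sigma1−sigma2;
    the ordering convention is sigma2 ≤ sigma3 ≤ sigma1. ``degenerate``
    marks axes whose defining eigenvalue gap is below the degeneracy
    tolerance (such axes are directions of noise, not of order).
    """

    a1: np.ndarray
    a2: np.ndarray
    a3: np.ndarray
    sigma1: float
    sigma2: float
    sigma3: float
    degenerate: tuple[bool, bool, bool] = (False, False, False)

    @property
    def axes(self) -> np.ndarray:
        return np.stack([self.a1, self.a2, self.a3])

    def validate(self, ortho_tol: float = 1e-8) -> None:
        A = self.axes
        if not np.allclose(A @ A.T, np.eye(3), atol=ortho_tol, rtol=0.0):
            raise ValueError("polarity axes must be orthonormal")
        if not (self.sigma2 <= self.sigma3 + 1e-12 and self.sigma3 <= self.sigma1 + 1e-12):
            raise ValueError("eigenvalue ordering sigma2 <= sigma3 <= sigma1 violated")
        if abs(self.sigma1 + self.sigma2 + self.sigma3) > 1e-10:
            raise ValueError("eigenvalues of a traceless tensor must sum to 0")


@dataclass
class NetworkSkeleton:
    """Line skeleton of a tubular network (sinusoids or bile canaliculi)."""

    nodes: np.ndarray  # (n, 3) μm
    segments: np.ndarray  # (m, 2) int node indices

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.segments = np.asarray(self.segments, dtype=np.int64)
        if self.segments.size == 0:
            self.segments = self.segments.reshape(0, 2)

    @property
    def vectors(self) -> np.ndarray:
        return self.nodes[self.segments[:, 1]] - self.nodes[self.segments[:, 0]]

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)

    @property
    def orientations(self) -> np.ndarray:
        v = self.vectors
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.nodes[self.segments[:, 0]] + self.nodes[self.segments[:, 1]])

    def validate(self) -> None:
        if self.segments.size and (
            self.segments.min() < 0 or self.segments.max() >= len(self.nodes)
        ):
            raise ValueError("segment references a node index out of range")
        if self.segments.size and np.any(self.lengths <= 0):
            raise ValueError("zero-length segment")


@dataclass
class ChargeSet:
    """Signed point charges on the vein surfaces defining the χ field.

    Central-vein (CV) charges sum to +1, portal-vein (PV) charges to −1.
    """

    positions: np.ndarray  # (n, 3) μm
    charges: np.ndarray  # (n,) signed, dimensionless
    vein_tags: np.ndarray  # (n,) str, "CV" or "PV"

    def validate(self, tol: float = 1e-9) -> None:
        cv = self.charges[self.vein_tags == "CV"].sum()
        pv = self.charges[self.vein_tags == "PV"].sum()
        if abs(cv - 1.0) > tol:
            raise ValueError(f"CV charges sum to {cv}, expected +1")
        if abs(pv + 1.0) > tol:
            raise ValueError(f"PV charges sum to {pv}, expected -1")


@dataclass
class DensityGrid:
    """3D voxel density with isotropic voxel size.

    Voxel centers sit at origin + (index + 0.5) * voxel_size.
    """

    values: np.ndarray  # (nx, ny, nz) >= 0
    voxel_size: float = 0.3  # μm
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.origin = np.asarray(self.origin, dtype=float)

    def validate(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("density grid must be 3D")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        if np.any(self.values < 0):
            raise ValueError("densities must be non-negative")


@dataclass
class DensityImage:
    """2D pixel density (a projected DensityGrid plane)."""

    values: np.ndarray  # (n, m)
    pixel_size: float  # μm

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)


@dataclass
class CellRecord:
    """Per-cell analysis record: position, polarity axes, local network axis."""

    cell_id: str
    position: np.ndarray  # (3,) μm
    apical_axes: Optional[PolarityAxes] = None
    basal_axes: Optional[PolarityAxes] = None
    local_sinusoid_axis: Optional[np.ndarray] = None
    group: Optional[str] = None


@dataclass
class CorrelationProfile:
    """Cross-correlation projected onto a line and binned by lag."""

    lags: np.ndarray  # bin centers, μm
    values: np.ndarray  # mean correlation per bin
    bin_size: float = 1.5  # μm

    def validate(self) -> None:
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if not np.allclose(self.lags, -self.lags[::-1], atol=1e-9):
            raise ValueError("lags must be symmetric about 0")
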