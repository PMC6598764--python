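"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh
from scipy.integrate import quad

from hepnem.types import Label, LabeledSurfaceMesh


# ---------------------------------------------------------------------------
# Independent oracles (kept deliberately separate from package internals)
# ---------------------------------------------------------------------------


def watson_order_parameter(kappa: float) -> float:
    """⟨(3/2)cos²θ − 1/2⟩ under the Watson density ∝ exp(κ cos²θ), by quadrature."""
    num = quad(lambda c: c * c * np.exp(kappa * c * c), -1.0, 1.0)[0]
    den = quad(lambda c: np.exp(kappa * c * c), -1.0, 1.0)[0]
    return 1.5 * num / den - 0.5


def lhuilier_solid_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Spherical excess of a triangle with unit-vector corners (l'Huilier)."""

    def side(u, v):
        return 2.0 * np.arcsin(min(1.0, np.linalg.norm(u - v) / 2.0))

    sa, sb, sc = side(b, c), side(c, a), side(a, b)
    s = 0.5 * (sa + sb + sc)
    t = (
        np.tan(s / 2)
        * np.tan((s - sa) / 2)
        * np.tan((s - sb) / 2)
        * np.tan((s - sc) / 2)
    )
    return 4.0 * np.arctan(np.sqrt(max(t, 0.0)))


def band_nematic_oracle(theta_min_deg: float, theta_max_deg: float, n: int = 100000):
    """Brute-force quadrature of the orientation tensor over a polar band."""
    t0, t1 = np.deg2rad([theta_min_deg, theta_max_deg])
    # uniform measure on the sphere: cosθ uniform
    c = np.linspace(np.cos(t1), np.cos(t0), n)
    phi = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    cc, pp = np.meshgrid(c, phi, indexing="ij")
    ss = np.sqrt(1 - cc**2)
    dirs = np.stack([ss * np.cos(pp), ss * np.sin(pp), cc], axis=-1).reshape(-1, 3)
    outer = np.einsum("ij,ik->jk", dirs, dirs) / len(dirs)
    return 1.5 * (outer - np.eye(3) / 3.0)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def welch_pvalue_oracle(a, b) -> float:
    """Textbook Welch t-test (Satterthwaite df), independent of scipy's."""
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    tstat = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return float(2 * tdist.sf(abs(tstat), df))


# ---------------------------------------------------------------------------
# Mesh fixtures
# ---------------------------------------------------------------------------


def labeled_icosphere(
    subdivisions: int = 3,
    radius: float = 1.0,
    labels: np.ndarray | None = None,
    center=(0.0, 0.0, 0.0),
    cell_id: str = "icosphere",
) -> LabeledSurfaceMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    vertices = np.asarray(ico.vertices) + np.asarray(center, float)
    if labels is None:
        labels = np.full(len(vertices), int(Label.UNLABELED), dtype=np.uint8)
    from hepnem.io import volumetric_center

    return LabeledSurfaceMesh(
        cell_id=cell_id,
        vertices=vertices,
        triangles=np.asarray(ico.faces),
        vertex_labels=labels,
        center=volumetric_center(vertices, np.asarray(ico.faces)),
    )


def cap_labeled_sphere(
    axis, cap_cos: float = 0.97, subdivisions: int = 4, radius: float = 1.0
) -> LabeledSurfaceMesh:
    """Icosphere with two antipodal apical caps: |u·axis| > cap_cos."""
    mesh = labeled_icosphere(subdivisions, radius)
    units = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    apical = np.abs(units @ axis) > cap_cos
    labels = np.full(len(units), int(Label.LATERAL), dtype=np.uint8)
    labels[apical] = int(Label.APICAL)
    mesh.vertex_labels = labels
    return mesh


@pytest.fixture
def tetrahedron() -> LabeledSurfaceMesh:
    """Regular tetrahedron with labels (apical, apical, lateral, lateral)."""
    v = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )
    t = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return LabeledSurfaceMesh(
        cell_id="tetra",
        vertices=v,
        triangles=t,
        vertex_labels=np.array([1, 1, 0, 0], dtype=np.uint8),
        center=np.zeros(3),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
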