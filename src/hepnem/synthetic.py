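"""Synthetic lobules with known ground truth.

Generates the inputs every analysis stage consumes — labeled cell-surface
meshes, vein meshes, sinusoid skeletons, and layered density grids — with
the statistical structure the analysis assumes:

* hepatocyte surfaces are radially jittered icospheres; apical membrane
  patches follow bipolar (two antipodal caps), ring (equatorial belt), or
  mixed patterns around per-cell ground-truth axes, with basal membrane on
  the complement;
* the lobule is a box with the central vein (CV) and portal vein (PV) as
  parallel cylinders at opposite ends; cell bipolar axes disperse around
  the local reference direction J with a Watson distribution of
  concentration ``kappa_align`` (the ring axis optionally biased
  perpendicular to J);
* sinusoid skeletons are chains of segments with Watson-distributed
  orientations about J;
* density grids are alternating hepatocyte/sinusoid slabs of period
  ``layer_spacing`` (default 24 μm = 20 μm hepatocyte + 4 μm sinusoid
  diameter) with per-layer phase jitter, bile canaliculi centered inside
  the hepatocyte slabs.

All randomness flows from the single ``seed`` of ``LobuleConfig``.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Optional

import numpy as np
import trimesh
import yaml

from .io import volumetric_center
from .polarity import polarity_axes
from .reference_field import build_charges, reference_direction
from .types import (
    CellRecord,
    ChargeSet,
    DensityGrid,
    Label,
    LabeledSurfaceMesh,
    NematicTensor,
    NetworkSkeleton,
    PolarityAxes,
)


@dataclass
class LobuleConfig:
    """Geometry and statistics of a synthetic lobule.

    Lengths in μm. ``kappa_align`` is the Watson concentration of the true
    bipolar axes about the local reference direction; ``sinusoid_kappa``
    plays the same role for sinusoid segment orientations. The layered
    grids use ``layer_spacing`` = hepatocyte diameter + sinusoid diameter.
    """

    cv_radius: float = 25.0
    pv_radius: float = 20.0
    lobule_extent: tuple[float, float, float] = (300.0, 200.0, 100.0)
    n_cells: int = 300
    cell_radius: float = 10.0
    apical_pattern: str = "mixed"  # pure_bipolar | pure_ring | mixed
    mixing_weight: float = 0.5
    pattern_kappa: float = 40.0
    kappa_align: float = 5.0
    ring_coupling: bool = True
    ring_coupling_kappa: float = 5.0
    basal_complement: bool = True
    sinusoid_kappa: float = 10.0
    n_sinusoid_chains: int = 150
    sinusoid_step: float = 5.0
    sinusoid_chain_segments: int = 8
    layer_spacing: float = 24.0
    sinusoid_width: float = 4.0
    bc_width: float = 2.0
    layer_jitter: float = 0.1
    layer_angle_deg: float = 0.0  # layer normal in the xy-plane
    grid_extent: tuple[float, float, float] = (150.0, 150.0, 60.0)
    voxel_size: float = 0.3
    mesh_subdivisions: int = 4
    seed: int = 0

    def validate(self) -> None:
        if min(self.cv_radius, self.pv_radius, self.cell_radius) <= 0:
            raise ValueError("radii must be positive")
        if min(self.lobule_extent) <= 0 or min(self.grid_extent) <= 0:
            raise ValueError("extents must be positive")
        if self.kappa_align < 0 or self.sinusoid_kappa < 0 or self.pattern_kappa < 0:
            raise ValueError("concentration parameters must be non-negative")
        if not 0.0 <= self.layer_jitter <= 1.0:
            raise ValueError("layer_jitter must be a fraction in [0, 1]")
        if self.layer_spacing <= 2 * self.voxel_size:
            raise ValueError("layer_spacing must exceed two voxels")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LobuleConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("lobule_extent", "grid_extent"):
            if key in data:
                data[key] = tuple(float(v) for v in data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = asdict(self)
        data["lobule_extent"] = list(self.lobule_extent)
        data["grid_extent"] = list(self.grid_extent)
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path


def kd_preset(base: Optional[LobuleConfig] = None, seed: Optional[int] = None) -> LobuleConfig:
    """Disordered ("knock-down-like") preset: tissue-level order reduced,
    per-cell polarity patterns untouched."""
    cfg = base or LobuleConfig()
    kwargs = {"kappa_align": 0.5, "sinusoid_kappa": 0.5, "ring_coupling": False}
    if seed is not None:
        kwargs["seed"] = seed
    return replace(cfg, **kwargs)


# ---------------------------------------------------------------------------
# Axis sampling
# ---------------------------------------------------------------------------


def sample_uniform_axes(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def sample_watson_axes(
    mu: np.ndarray, kappa: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample axial directions from a Watson distribution about ``mu``.

    Density ∝ exp(κ (u·μ)²) on the sphere (κ ≥ 0: bipolar concentration
    about ±μ; κ = 0: uniform). Rejection sampling on cos θ.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    if kappa == 0:
        return sample_uniform_axes(n, rng)
    cs = np.empty(0)
    while cs.size < n:
        batch = max(64, int(2.5 * (n - cs.size) * max(1.0, 2.0 * kappa)))
        c = rng.uniform(-1.0, 1.0, size=batch)
        accept = rng.uniform(size=batch) < np.exp(kappa * (c**2 - 1.0))
        cs = np.concatenate([cs, c[accept]])
    cs = cs[:n]
    phi = rng.uniform(0.0, 2 * np.pi, size=n)
    # orthonormal frame around mu
    helper = np.array([1.0, 0.0, 0.0])
    if abs(mu[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mu, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    s = np.sqrt(np.clip(1.0 - cs**2, 0.0, None))
    return (
        cs[:, None] * mu[None, :]
        + (s * np.cos(phi))[:, None] * e1[None, :]
        + (s * np.sin(phi))[:, None] * e2[None, :]
    )


def _perpendicular_axis(
    a1: np.ndarray,
    reference: np.ndarray,
    kappa: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit axis in the plane normal to a1.

    With κ > 0 the in-plane angle is biased toward the reference
    direction's component in the plane (density ∝ exp(κ (a2·ref)²)) —
    the ring axes then carry orientational order of their own instead of
    being random in the plane, which is what lifts their alignment above
    the uniaxial baseline. With κ = 0 the in-plane angle is uniform.
    """
    helper = np.array([1.0, 0.0, 0.0])
    if abs(a1[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(a1, helper)
    u /= np.linalg.norm(u)
    v = np.cross(a1, u)
    if kappa <= 0:
        phi = rng.uniform(0.0, 2 * np.pi)
        return np.cos(phi) * u + np.sin(phi) * v
    while True:
        phi = rng.uniform(0.0, 2 * np.pi)
        a2 = np.cos(phi) * u + np.sin(phi) * v
        if rng.uniform() < np.exp(kappa * (float(np.dot(a2, reference)) ** 2 - 1.0)):
            return a2


# ---------------------------------------------------------------------------
# Cell meshes
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _base_icosphere(subdivisions: int) -> tuple[np.ndarray, np.ndarray]:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    return np.asarray(ico.vertices, dtype=float), np.asarray(ico.faces, dtype=np.int64)


def _apical_probability(
    units: np.ndarray,
    pattern: str,
    axis: np.ndarray,
    ring_axis: Optional[np.ndarray],
    kappa: float,
    mixing_weight: float,
) -> np.ndarray:
    c_ax = units @ (axis / np.linalg.norm(axis))
    p_bipolar = np.exp(kappa * (c_ax**2 - 1.0))
    if pattern == "pure_bipolar":
        return p_bipolar
    if pattern == "pure_ring":
        # for the pure ring pattern ``axis`` is the ring axis (belt normal)
        return np.exp(-kappa * c_ax**2)
    if pattern == "mixed":
        if ring_axis is None:
            raise ValueError("mixed pattern needs the ring axis")
        c_ring = units @ (ring_axis / np.linalg.norm(ring_axis))
        p_ring = np.exp(-kappa * c_ring**2)
        # caps are widened (κ/4) so both components carry comparable
        # marker mass: a cap of concentration κ holds ~1/κ of the sphere,
        # a belt ~1/sqrt(κ), and equal nominal weights would otherwise
        # leave the bipolar signal (the σ1−σ3 gap) in the noise
        p_caps = np.exp(0.25 * kappa * (c_ax**2 - 1.0))
        return mixing_weight * p_caps + (1.0 - mixing_weight) * p_ring
    raise ValueError(f"unknown apical pattern {pattern!r}")


def _dual_basal_probability(
    units: np.ndarray,
    pattern: str,
    axis: np.ndarray,
    ring_axis: Optional[np.ndarray],
    kappa: float,
    mixing_weight: float,
) -> np.ndarray:
    """Basal pattern dual to the apical one (bipolar ↔ ring roles swapped).

    Apical caps at ±a1 with a belt normal to a2 leave a complement
    concentrated in caps at ±a2 and a belt normal to a1 — the basal
    bipolar axis is the apical ring axis and vice versa, which is the
    mutual-repulsion geometry of apical and basal membrane domains.
    """
    if pattern == "pure_bipolar":
        return _apical_probability(units, "pure_ring", axis, None, kappa, mixing_weight)
    if pattern == "pure_ring":
        return _apical_probability(units, "pure_bipolar", axis, None, kappa, mixing_weight)
    return _apical_probability(units, "mixed", ring_axis, axis, kappa, mixing_weight)


def generate_cell_mesh(
    pattern: str,
    axis: np.ndarray,
    noise_kappa: float = 40.0,
    mesh_subdivisions: int = 4,
    seed: int = 0,
    radius: float = 10.0,
    center: np.ndarray = (0.0, 0.0, 0.0),
    ring_axis: Optional[np.ndarray] = None,
    mixing_weight: float = 0.5,
    radial_jitter: float = 0.05,
    basal_complement: bool = True,
    cell_id: str = "cell",
) -> LabeledSurfaceMesh:
    """Closed star-convex cell mesh with a patterned apical membrane.

    Vertices are labeled apical by Bernoulli draws with probability
    following the pattern (caps about ``axis`` for pure_bipolar, a belt
    normal to ``axis`` for pure_ring, their mixture for mixed with
    ``ring_axis`` as belt normal); larger ``noise_kappa`` gives tighter,
    cleaner patterns. The remaining vertices are basal (or lateral when
    ``basal_complement`` is off). Reproducible from ``seed``.
    """
    if mesh_subdivisions < 1:
        raise ValueError("mesh_subdivisions must be >= 1")
    rng = np.random.default_rng(seed)
    units, faces = _base_icosphere(mesh_subdivisions)
    radii = radius * (1.0 + radial_jitter * rng.uniform(-1.0, 1.0, size=len(units)))
    vertices = units * radii[:, None] + np.asarray(center, dtype=float)
    axis = np.asarray(axis, dtype=float)
    p = _apical_probability(units, pattern, axis, ring_axis, noise_kappa, mixing_weight)
    apical = rng.uniform(size=len(units)) < p
    labels = np.full(len(units), int(Label.LATERAL), dtype=np.uint8)
    labels[apical] = int(Label.APICAL)
    if basal_complement:
        # Basal membrane concentrates on the complement of the apical
        # pattern (where sinusoid contact happens): the dual pattern with
        # bipolar and ring roles swapped, wider than the apical one, on a
        # broad background covering the rest of the surface.
        p_basal = 0.25 + 0.75 * _dual_basal_probability(
            units, pattern, axis, ring_axis, noise_kappa / 4.0, mixing_weight
        )
        basal = (~apical) & (rng.uniform(size=len(units)) < p_basal)
        labels[basal] = int(Label.BASAL)
    mesh = LabeledSurfaceMesh(
        cell_id=cell_id,
        vertices=vertices,
        triangles=faces,
        vertex_labels=labels,
        center=volumetric_center(vertices, faces),
        is_closed=True,
    )
    mesh.validate()
    return mesh


def _ideal_pattern_tensor(
    pattern: str, a1: np.ndarray, a2: np.ndarray, w: float
) -> np.ndarray:
    """Noise-free nematic tensor of the apical pattern in the true frame."""
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    a3 = np.cross(a1, a2)
    bipolar = 1.5 * (np.outer(a1, a1) - np.eye(3) / 3.0)
    ring = 1.5 * ((np.outer(a1, a1) + np.outer(a3, a3)) / 2.0 - np.eye(3) / 3.0)
    if pattern == "pure_bipolar":
        return bipolar
    if pattern == "pure_ring":
        return ring
    return w * bipolar + (1.0 - w) * ring


# ---------------------------------------------------------------------------
# Lobule
# ---------------------------------------------------------------------------


def _cylinder_mesh(
    radius: float,
    height: float,
    center: np.ndarray,
    sections: int = 48,
    max_edge: float = 15.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cylinder tessellated to a bounded edge length.

    The side faces of a plain cylinder span the full height; the surface
    charges derived from triangle centers would then be far too coarse
    vertically for a uniform charge density, so faces are subdivided.
    """
    cyl = trimesh.creation.cylinder(
        radius=radius, height=height, sections=max(sections, 16)
    )
    v, f = trimesh.remesh.subdivide_to_size(
        np.asarray(cyl.vertices, dtype=float),
        np.asarray(cyl.faces, dtype=np.int64),
        max_edge=max_edge,
    )
    return v + np.asarray(center, dtype=float), np.asarray(f, dtype=np.int64)


def _poisson_disk(
    bounds_lo: np.ndarray,
    bounds_hi: np.ndarray,
    n: int,
    min_sep: float,
    rng: np.random.Generator,
    max_tries: int = 200000,
) -> np.ndarray:
    points: list[np.ndarray] = []
    arr = np.empty((0, 3))
    for _ in range(max_tries):
        cand = rng.uniform(bounds_lo, bounds_hi)
        if arr.size == 0 or np.min(np.linalg.norm(arr - cand, axis=1)) >= min_sep:
            points.append(cand)
            arr = np.asarray(points)
            if len(points) == n:
                return arr
    raise RuntimeError(
        f"could not pack {n} cells at separation {min_sep} μm; "
        f"placed {len(points)} — reduce n_cells or enlarge the lobule"
    )


@dataclass
class SyntheticLobule:
    """Everything the analysis pipeline consumes, plus ground truth."""

    config: LobuleConfig
    cell_meshes: list[LabeledSurfaceMesh]
    records: list[CellRecord]  # ground-truth axes and positions
    cv_mesh: tuple[np.ndarray, np.ndarray]
    pv_mesh: tuple[np.ndarray, np.ndarray]
    skeleton: NetworkSkeleton
    charges: ChargeSet
    reference_at_cells: np.ndarray  # J at each cell center


def generate_lobule(config: LobuleConfig, with_meshes: bool = True) -> SyntheticLobule:
    """Generate a full synthetic lobule from a config.

    CV and PV are parallel cylinders (axes along z) at the +x and −x ends
    of the box; cell centers are Poisson-disk sampled between them; true
    bipolar axes follow a Watson distribution about the local J; sinusoid
    chains follow J with concentration ``sinusoid_kappa``. With
    ``with_meshes`` off only ground-truth records are produced (identical
    random stream), for studies that need axis statistics but no surfaces.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lx, ly, lz = config.lobule_extent
    mid = np.array([0.0, ly / 2.0, lz / 2.0])
    pv_center = mid.copy()
    cv_center = mid + np.array([lx, 0.0, 0.0])
    cv_mesh = _cylinder_mesh(config.cv_radius, 2.0 * lz, cv_center, sections=24)
    pv_mesh = _cylinder_mesh(config.pv_radius, 2.0 * lz, pv_center, sections=24)
    charges = build_charges(cv_mesh[0], cv_mesh[1], pv_mesh[0], pv_mesh[1])

    clearance = config.cell_radius * 1.5
    lo = np.array(
        [config.pv_radius + clearance, clearance, clearance]
    )
    hi = np.array(
        [lx - config.cv_radius - clearance, ly - clearance, lz - clearance]
    )
    min_sep = 0.9 * 2.0 * config.cell_radius
    positions = _poisson_disk(lo, hi, config.n_cells, min_sep, rng)

    directions, _, valid = reference_direction(positions, charges)
    if not np.all(valid):
        # stagnation points inside the lobule are a measure-zero accident
        directions[~valid] = np.array([1.0, 0.0, 0.0])

    cell_meshes: list[LabeledSurfaceMesh] = []
    records: list[CellRecord] = []
    seed_pool = rng.integers(0, 2**31 - 1, size=config.n_cells)
    for i, (pos, j_axis) in enumerate(zip(positions, directions)):
        a1 = sample_watson_axes(j_axis, config.kappa_align, 1, rng)[0]
        a2 = _perpendicular_axis(
            a1,
            j_axis,
            config.ring_coupling_kappa if config.ring_coupling else 0.0,
            rng,
        )
        cell_id = f"cell_{i:04d}"
        if with_meshes:
            pattern_axis = a2 if config.apical_pattern == "pure_ring" else a1
            mesh = generate_cell_mesh(
                pattern=config.apical_pattern,
                axis=pattern_axis,
                noise_kappa=config.pattern_kappa,
                mesh_subdivisions=config.mesh_subdivisions,
                seed=int(seed_pool[i]),
                radius=config.cell_radius,
                center=pos,
                ring_axis=a2,
                mixing_weight=config.mixing_weight,
                basal_complement=config.basal_complement,
                cell_id=cell_id,
            )
            cell_meshes.append(mesh)
        truth = polarity_axes(
            NematicTensor(
                _ideal_pattern_tensor(
                    config.apical_pattern, a1, a2, config.mixing_weight
                )
            )
        )
        records.append(CellRecord(cell_id=cell_id, position=pos, apical_axes=truth))

    skeleton = _sinusoid_skeleton(config, charges, lo, hi, rng)
    return SyntheticLobule(
        config=config,
        cell_meshes=cell_meshes,
        records=records,
        cv_mesh=cv_mesh,
        pv_mesh=pv_mesh,
        skeleton=skeleton,
        charges=charges,
        reference_at_cells=directions,
    )


def _sinusoid_skeleton(
    config: LobuleConfig,
    charges: ChargeSet,
    lo: np.ndarray,
    hi: np.ndarray,
    rng: np.random.Generator,
) -> NetworkSkeleton:
    n_chains = config.n_sinusoid_chains
    pos = rng.uniform(lo, hi, size=(n_chains, 3))
    nodes: list[np.ndarray] = [p.copy() for p in pos]
    segments: list[tuple[int, int]] = []
    tail = list(range(n_chains))  # last node index of each chain
    active = np.ones(n_chains, dtype=bool)
    for _ in range(config.sinusoid_chain_segments):
        if not np.any(active):
            break
        j_dir, _, valid = reference_direction(pos[active], charges)
        axes = np.empty((int(active.sum()), 3))
        for k, (j, ok) in enumerate(zip(j_dir, valid)):
            a = (
                sample_watson_axes(j, config.sinusoid_kappa, 1, rng)[0]
                if ok
                else sample_uniform_axes(1, rng)[0]
            )
            # a chain walks forward: keep the axis pointing along J
            if ok and float(np.dot(a, j)) < 0:
                a = -a
            axes[k] = a
        nxt = pos[active] + config.sinusoid_step * axes
        inside = np.all((nxt >= lo) & (nxt <= hi), axis=1)
        for k, ci in enumerate(np.flatnonzero(active)):
            if not inside[k]:
                active[ci] = False
                continue
            nodes.append(nxt[k].copy())
            segments.append((tail[ci], len(nodes) - 1))
            tail[ci] = len(nodes) - 1
            pos[ci] = nxt[k]
    skel = NetworkSkeleton(
        nodes=np.asarray(nodes), segments=np.asarray(segments, dtype=np.int64)
    )
    skel.validate()
    return skel


# ---------------------------------------------------------------------------
# Layered density grids
# ---------------------------------------------------------------------------


@dataclass
class LayeredGrids:
    hepatocyte: DensityGrid
    sinusoid: DensityGrid
    bile_canaliculi: DensityGrid
    layer_normal: np.ndarray  # 2D unit vector in the projected (x, y) plane


def generate_layered_grid(config: LobuleConfig) -> LayeredGrids:
    """Alternating hepatocyte/sinusoid slab grids with per-layer jitter.

    Slabs are perpendicular to the in-plane layer normal (angle
    ``layer_angle_deg`` from x). Each period of ``layer_spacing`` holds one
    sinusoid slab of width ``sinusoid_width`` whose position is jittered by
    ±``layer_jitter``·spacing with an independent phase per layer;
    hepatocyte density is the exact complement, and bile canaliculi form
    thin slabs centered inside the hepatocyte slabs.
    """
    config.validate()
    if config.layer_jitter >= 0.5:
        warnings.warn("layer_jitter >= 0.5: adjacent layers may merge", stacklevel=2)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x1A7E5]))
    gx, gy, gz = config.grid_extent
    vs = config.voxel_size
    nx, ny, nz = (int(round(e / vs)) for e in (gx, gy, gz))
    angle = np.deg2rad(config.layer_angle_deg)
    normal = np.array([np.cos(angle), np.sin(angle)])
    x = (np.arange(nx) + 0.5) * vs
    y = (np.arange(ny) + 0.5) * vs
    t = x[:, None] * normal[0] + y[None, :] * normal[1]

    s = config.layer_spacing
    n_layers = int(np.floor(t.max() / s)) + 3
    jitter = config.layer_jitter * s * rng.uniform(-1.0, 1.0, size=n_layers + 2)
    layer_ids = np.arange(-1, n_layers + 1)
    sin_centers = (layer_ids + 0.5) * s + jitter[layer_ids + 1]
    bc_centers = layer_ids[:-1] * s + s + 0.5 * (
        jitter[layer_ids[:-1] + 1] + jitter[layer_ids[:-1] + 2]
    )

    j = np.floor(t / s).astype(np.int64)
    sinusoid2d = np.zeros_like(t, dtype=bool)
    for k in (-1, 0, 1):
        centers = sin_centers[np.clip(j + k + 1, 0, len(sin_centers) - 1)]
        sinusoid2d |= np.abs(t - centers) < config.sinusoid_width / 2.0
    bc2d = np.zeros_like(t, dtype=bool)
    for k in (-1, 0):
        centers = bc_centers[np.clip(j + k + 1, 0, len(bc_centers) - 1)]
        bc2d |= np.abs(t - centers) < config.bc_width / 2.0

    def _grid(mask2d: np.ndarray) -> DensityGrid:
        values = np.broadcast_to(
            mask2d[:, :, None].astype(np.float32), (nx, ny, nz)
        ).copy()
        return DensityGrid(values=values, voxel_size=vs)

    sin_grid = _grid(sinusoid2d)
    hep_grid = DensityGrid(
        values=(1.0 - sin_grid.values).astype(np.float32), voxel_size=vs
    )
    return LayeredGrids(
        hepatocyte=hep_grid,
        sinusoid=sin_grid,
        bile_canaliculi=_grid(bc2d),
        layer_normal=normal,
    )
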