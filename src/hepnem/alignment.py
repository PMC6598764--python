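"""Tissue-scale nematic order statistics.

The central statistic is the nematic alignment parameter between an
ensemble of axes e_i and paired reference axes g_i:

    S = (1/N) Σ_i [ (3/2)(e_i·g_i)^2 − 1/2 ]  ∈ [−1/2, 1]

S = 1 for perfect parallel alignment, 0 for isotropic relative
orientation, −1/2 for perpendicular alignment. For biaxial objects with
orthonormal axis triads, uniaxial order about the first axis predicts
S2 = −S1/2 (the "trivial baseline"): measured ring-axis alignment above
this baseline is evidence of genuinely biaxial order.

Spatial maps use Gaussian local averaging of per-cell nematic tensors; the
displayed axis at each position is the principal axis of the weighted-mean
tensor. Group comparisons use Welch's unequal-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import CellRecord, canonical_axis

KERNEL_SD = 20.0  # μm, approximately one hepatocyte diameter


def alignment_parameter(axes: np.ndarray, reference_axes: np.ndarray) -> float:
    """Nematic alignment S between paired unit axes; sign-free in both."""
    axes = np.atleast_2d(np.asarray(axes, dtype=float))
    reference_axes = np.atleast_2d(np.asarray(reference_axes, dtype=float))
    if reference_axes.shape[0] == 1 and axes.shape[0] > 1:
        reference_axes = np.broadcast_to(reference_axes, axes.shape)
    if axes.shape != reference_axes.shape:
        raise ValueError("axes and reference axes must pair one-to-one")
    if axes.shape[0] < 1:
        raise ValueError("at least one axis pair required")
    cos = np.einsum("ij,ij->i", axes, reference_axes)
    return float(np.mean(1.5 * cos**2 - 0.5))


def alignment_terms(axes: np.ndarray, reference_axes: np.ndarray) -> np.ndarray:
    """Per-pair terms (3/2)cos²θ − 1/2 (mean of these is S)."""
    cos = np.einsum(
        "ij,ij->i",
        np.atleast_2d(np.asarray(axes, dtype=float)),
        np.atleast_2d(np.asarray(reference_axes, dtype=float)),
    )
    return 1.5 * cos**2 - 0.5


def uniaxial_baseline(s1: float) -> float:
    """Maximum-likelihood prediction for S2 under purely uniaxial order.

    Follows from S1 + S2 + S3 = 0 with S2 and S3 indistinguishable when
    only the first axis carries order: S2 = −S1/2.
    """
    if not -0.5 - 1e-12 <= s1 <= 1.0 + 1e-12:
        raise ValueError(f"S1 = {s1} outside the admissible range [-1/2, 1]")
    return -0.5 * s1


@dataclass
class AveragedAxis:
    axis: np.ndarray
    weight: float  # principal eigenvalue of the weight-normalized mean tensor
    isolated: bool  # no neighbor carried weight; the cell's own axis returned


def local_average_axes(
    positions: np.ndarray,
    axes: np.ndarray,
    kernel_sd: float = KERNEL_SD,
    query_positions: Optional[np.ndarray] = None,
) -> list[AveragedAxis]:
    """Gaussian-kernel local average of nematic axes.

    At each query position x the per-cell axes contribute the tensor
    (3/2)(a⊗a − I/3) with Gaussian weight in their distance to x; the
    returned axis is the principal axis of the weight-normalized mean
    tensor and the weight its principal eigenvalue (a local order
    parameter: 1 when all nearby axes agree).
    """
    positions = np.asarray(positions, dtype=float)
    axes = np.asarray(axes, dtype=float)
    if query_positions is None:
        query_positions = positions
    query_positions = np.asarray(query_positions, dtype=float)
    tensors = 1.5 * (
        np.einsum("ij,ik->ijk", axes, axes) - np.eye(3)[None] / 3.0
    )
    out: list[AveragedAxis] = []
    inv_two_sd2 = 1.0 / (2.0 * kernel_sd**2)
    for iq, x in enumerate(query_positions):
        d2 = np.sum((positions - x) ** 2, axis=1)
        w = np.exp(-d2 * inv_two_sd2)
        total = w.sum()
        if total < 1e-12:
            own = axes[iq] if iq < len(axes) else axes[np.argmin(d2)]
            out.append(AveragedAxis(axis=canonical_axis(own), weight=1.0, isolated=True))
            continue
        mean_tensor = np.einsum("i,ijk->jk", w / total, tensors)
        evals, evecs = np.linalg.eigh(mean_tensor)
        out.append(
            AveragedAxis(
                axis=canonical_axis(evecs[:, 2]),
                weight=float(evals[2]),
                isolated=False,
            )
        )
    return out


def local_average_cell_axes(
    cells: Sequence[CellRecord],
    axis_type: str = "a1",
    kernel_sd: float = KERNEL_SD,
) -> tuple[list[CellRecord], list[AveragedAxis]]:
    """Gaussian local averaging applied to one axis type of CellRecords.

    ``axis_type`` ∈ {a1, a2, b1, b2, sinusoid}. Cells whose requested axis
    is degenerate or absent are dropped from both the kernel sum and the
    output (returned alongside for bookkeeping).
    """
    kept: list[CellRecord] = []
    axes = []
    for c in cells:
        v = _cell_axis(c, axis_type)
        if v is not None:
            kept.append(c)
            axes.append(v)
    if not kept:
        raise ValueError(f"no cell carries a usable {axis_type} axis")
    positions = np.asarray([c.position for c in kept])
    return kept, local_average_axes(positions, np.asarray(axes), kernel_sd)


def _cell_axis(cell: CellRecord, axis_type: str) -> Optional[np.ndarray]:
    if axis_type == "sinusoid":
        return cell.local_sinusoid_axis
    source = cell.apical_axes if axis_type[0] == "a" else cell.basal_axes
    if source is None:
        return None
    idx = int(axis_type[1]) - 1
    if source.degenerate[idx]:
        return None
    return source.axes[idx]


def cell_alignment(
    cells: Sequence[CellRecord],
    reference_axes: np.ndarray,
    axis_type: str = "a1",
) -> tuple[float, int]:
    """S between one axis type of the cells and per-cell reference axes.

    Returns (S, number of cells used); degenerate/absent axes excluded.
    """
    axes, refs = [], []
    for cell, g in zip(cells, np.atleast_2d(reference_axes)):
        v = _cell_axis(cell, axis_type)
        if v is not None and np.all(np.isfinite(g)):
            axes.append(v)
            refs.append(g)
    if not axes:
        raise ValueError(f"no usable {axis_type} axes for alignment")
    return alignment_parameter(np.asarray(axes), np.asarray(refs)), len(axes)


@dataclass
class BiaxialityResult:
    excess: np.ndarray  # per-group S2 − (−S1/2)
    mean_excess: float
    p_value: Optional[float]  # one-sided (excess > 0), paired across groups


def biaxiality_excess(
    per_group_s1: Sequence[float], per_group_s2: Sequence[float]
) -> BiaxialityResult:
    """Ring-axis alignment above the uniaxial baseline, with a paired test.

    The excess per group (animal/replicate) is S2 + S1/2; a one-sided
    paired t-test asks whether it is positive, i.e. whether ring-axis
    order exceeds what bipolar-axis order alone would impose.
    """
    s1 = np.asarray(per_group_s1, dtype=float)
    s2 = np.asarray(per_group_s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("per-group S1 and S2 must pair one-to-one")
    excess = s2 - np.array([uniaxial_baseline(v) for v in s1])
    p = None
    if len(excess) >= 2 and np.std(excess) > 0:
        p = float(stats.ttest_1samp(excess, 0.0, alternative="greater").pvalue)
    return BiaxialityResult(
        excess=excess, mean_excess=float(excess.mean()), p_value=p
    )


def permutation_excess_pvalue(
    excess: np.ndarray, n_permutations: int = 10000, seed: int = 0
) -> float:
    """Sign-flip permutation p-value for mean excess > 0 (cross-check)."""
    rng = np.random.default_rng(seed)
    excess = np.asarray(excess, dtype=float)
    observed = excess.mean()
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, len(excess)))
    null = (signs * excess).mean(axis=1)
    return float((np.sum(null >= observed - 1e-15) + 1) / (n_permutations + 1))


def compare_groups(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("both groups have zero variance; test degenerate")
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
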