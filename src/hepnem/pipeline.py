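"""End-to-end orchestration: polarity → reference field → network →
alignment → layered order, with a machine-readable JSON report.

A "replicate" is one lobule (one animal / one imaging volume): a directory
written by ``hepnem simulate`` (or arranged the same way from real
segmentations), or an in-memory :class:`~hepnem.synthetic.SyntheticLobule`.
Group statistics (mean ± s.d. across replicates, the biaxiality test, and
Welch comparisons between two conditions) are computed only when at least
two replicates are given.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import alignment as al
from . import layered as lo
from . import network as nw
from . import polarity as pol
from . import reference_field as rf
from .io import read_density_grid, read_labeled_mesh, read_skeleton
from .synthetic import LayeredGrids, LobuleConfig, SyntheticLobule, generate_layered_grid, generate_lobule
from .types import CellRecord, Label

REPORT_SCHEMA = {
    "n_cells": int,
    "axis_correlation": dict,
    "alignment": dict,
    "biaxiality": dict,
    "layered": (dict, type(None)),
    "stages_skipped": list,
}


def validate_report(report: dict) -> None:
    """Structural check of a replicate report against the bundled schema."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report[{key!r}] has type {type(report[key]).__name__}")


@dataclass
class ReplicateInputs:
    cell_meshes: list
    cv_mesh: tuple[np.ndarray, np.ndarray]
    pv_mesh: tuple[np.ndarray, np.ndarray]
    skeleton: Optional[object] = None
    grids: Optional[LayeredGrids] = None
    name: str = "replicate"


def load_replicate(path: str | Path) -> ReplicateInputs:
    """Load a replicate directory (layout written by ``hepnem simulate``)."""
    path = Path(path)
    cells = sorted((path / "cells").glob("*.ply"))
    if not cells:
        raise FileNotFoundError(f"no cell meshes under {path / 'cells'}")
    meshes = [read_labeled_mesh(p) for p in cells]
    cv = read_labeled_mesh(path / "cv.ply")
    pv = read_labeled_mesh(path / "pv.ply")
    skeleton = None
    if (path / "sinusoids.json").exists():
        skeleton = read_skeleton(path / "sinusoids.json")
    grids = None
    if (path / "sinusoid.tif").exists():
        cfg_path = path / "config.yaml"
        normal = np.array([1.0, 0.0])
        if cfg_path.exists():
            cfg = LobuleConfig.from_yaml(cfg_path)
            angle = np.deg2rad(cfg.layer_angle_deg)
            normal = np.array([np.cos(angle), np.sin(angle)])
        grids = LayeredGrids(
            hepatocyte=read_density_grid(path / "hepatocyte.tif"),
            sinusoid=read_density_grid(path / "sinusoid.tif"),
            bile_canaliculi=read_density_grid(path / "bc.tif"),
            layer_normal=normal,
        )
    return ReplicateInputs(
        cell_meshes=meshes,
        cv_mesh=(cv.vertices, cv.triangles),
        pv_mesh=(pv.vertices, pv.triangles),
        skeleton=skeleton,
        grids=grids,
        name=path.name,
    )


def _inputs_from_lobule(
    lob: SyntheticLobule, with_grids: bool = True
) -> ReplicateInputs:
    grids = generate_layered_grid(lob.config) if with_grids else None
    return ReplicateInputs(
        cell_meshes=lob.cell_meshes,
        cv_mesh=lob.cv_mesh,
        pv_mesh=lob.pv_mesh,
        skeleton=lob.skeleton,
        grids=grids,
        name=f"synthetic_seed{lob.config.seed}",
    )


def analyze_replicate(
    inputs: Union[ReplicateInputs, SyntheticLobule, str, Path],
    network_radius: float = nw.DEFAULT_RADIUS,
    degeneracy_tol: float = pol.DEGENERACY_TOL,
    n_null: int = lo.DEFAULT_N_NULL,
    seed: int = 0,
    with_grids: bool = True,
) -> tuple[dict, pd.DataFrame]:
    """Run every stage on one replicate.

    Returns the JSON-serializable report and the per-cell table. Stages
    whose inputs are missing are recorded in ``stages_skipped``.
    """
    if isinstance(inputs, (str, Path)):
        inputs = load_replicate(inputs)
    elif isinstance(inputs, SyntheticLobule):
        inputs = _inputs_from_lobule(inputs, with_grids=with_grids)
    skipped: list[str] = []

    # polarity
    records: list[CellRecord] = []
    for mesh in inputs.cell_meshes:
        apical = pol.cell_polarity(mesh, Label.APICAL, degeneracy_tol)
        basal = None
        if np.any(mesh.vertex_labels == int(Label.BASAL)):
            basal = pol.cell_polarity(mesh, Label.BASAL, degeneracy_tol)
        records.append(
            CellRecord(
                cell_id=mesh.cell_id,
                position=mesh.center,
                apical_axes=apical,
                basal_axes=basal,
            )
        )
    positions = np.asarray([r.position for r in records])

    # reference field
    charges = rf.build_charges(*inputs.cv_mesh, *inputs.pv_mesh)
    j_axes, _, valid = rf.reference_direction(positions, charges)

    # network
    if inputs.skeleton is not None:
        for rec in records:
            local = nw.local_network_axis(
                inputs.skeleton, rec.position, radius=network_radius
            )
            if local is not None and not local.degenerate:
                rec.local_sinusoid_axis = local.axis
    else:
        skipped.append("network")

    # alignment
    align: dict[str, dict] = {}
    for axis_type in ("a1", "a2", "sinusoid"):
        try:
            s, n = al.cell_alignment(
                [r for r, v in zip(records, valid) if v], j_axes[valid], axis_type
            )
            align[axis_type] = {"S": s, "n": n}
        except ValueError:
            align[axis_type] = {"S": None, "n": 0}
    s1 = align["a1"]["S"]
    s2 = align["a2"]["S"]
    biax = {
        "S1": s1,
        "S2": s2,
        "S2_uniaxial_baseline": al.uniaxial_baseline(s1) if s1 is not None else None,
        "excess": (s2 - al.uniaxial_baseline(s1))
        if (s1 is not None and s2 is not None)
        else None,
    }

    # apical–basal cross-correlation (needs basal labels)
    if any(r.basal_axes is not None for r in records):
        table = pol.axis_cross_correlation(
            [r for r in records if r.basal_axes is not None]
        )
        axis_corr = {pair: float(row["S"]) for pair, row in table.iterrows()}
    else:
        axis_corr = {}
        skipped.append("axis_correlation")

    # layered order
    layered_report = None
    if inputs.grids is not None:
        g = inputs.grids
        res_sh = lo.layered_analysis(
            g.sinusoid, g.hepatocyte, g.layer_normal, n_null=n_null, seed=seed
        )
        res_sb = lo.layered_analysis(
            g.sinusoid, g.bile_canaliculi, g.layer_normal, n_null=n_null, seed=seed + 7
        )
        layered_report = {
            "period_sinusoid_hepatocyte_um": res_sh.estimate.period,
            "period_sinusoid_bc_um": res_sb.estimate.period,
            "control_period_um": res_sh.control_estimate.period,
            "control_significant": res_sh.control_estimate.significant,
        }
    else:
        skipped.append("layered_order")

    report = {
        "name": inputs.name,
        "n_cells": len(records),
        "axis_correlation": axis_corr,
        "alignment": align,
        "biaxiality": biax,
        "layered": layered_report,
        "stages_skipped": skipped,
    }
    validate_report(report)
    cell_table = pol.polarity_table(records)
    return report, cell_table


def run_full_analysis(
    inputs: Sequence[Union[ReplicateInputs, SyntheticLobule, str, Path]],
    seed: int = 0,
    n_null: int = lo.DEFAULT_N_NULL,
    with_grids: bool = True,
) -> dict:
    """Analyze one or more replicates; add group statistics when n ≥ 2."""
    replicates = []
    for i, inp in enumerate(inputs):
        rep, _ = analyze_replicate(
            inp, seed=seed + i, n_null=n_null, with_grids=with_grids
        )
        replicates.append(rep)
    report: dict = {"replicates": replicates, "n_replicates": len(replicates)}
    if len(replicates) >= 2:
        group: dict = {}
        for axis_type in ("a1", "a2", "sinusoid"):
            vals = [
                r["alignment"][axis_type]["S"]
                for r in replicates
                if r["alignment"][axis_type]["S"] is not None
            ]
            if vals:
                group[axis_type] = {
                    "mean_S": float(np.mean(vals)),
                    "sd_S": float(np.std(vals, ddof=1)),
                    "n": len(vals),
                }
        s1 = [r["biaxiality"]["S1"] for r in replicates]
        s2 = [r["biaxiality"]["S2"] for r in replicates]
        if all(v is not None for v in s1 + s2):
            biax = al.biaxiality_excess(s1, s2)
            group["biaxiality"] = {
                "mean_excess": biax.mean_excess,
                "p_one_sided": biax.p_value,
            }
        report["group"] = group
    return report


def run_synthetic_study(
    config: LobuleConfig,
    n_replicates: int = 1,
    seed: int = 0,
    n_null: int = lo.DEFAULT_N_NULL,
    with_grids: bool = True,
) -> dict:
    """Generate ``n_replicates`` lobules (seeds seed, seed+1, …) and analyze."""
    from dataclasses import replace

    lobs = [
        generate_lobule(replace(config, seed=seed + i)) for i in range(n_replicates)
    ]
    return run_full_analysis(lobs, seed=seed, n_null=n_null, with_grids=with_grids)


def write_replicate(lob: SyntheticLobule, outdir: str | Path, with_grids: bool = True) -> Path:
    """Write a synthetic lobule as a replicate directory.

    Layout: cells/*.ply (labeled), cv.ply, pv.ply, sinusoids.json,
    hepatocyte/sinusoid/bc.tif, truth.csv (ground-truth axes), config.yaml.
    """
    from .io import write_density_grid, write_labeled_mesh, write_skeleton
    from .types import LabeledSurfaceMesh

    outdir = Path(outdir)
    (outdir / "cells").mkdir(parents=True, exist_ok=True)
    for mesh in lob.cell_meshes:
        write_labeled_mesh(mesh, outdir / "cells" / f"{mesh.cell_id}.ply")
    for name, (verts, tris) in (("cv", lob.cv_mesh), ("pv", lob.pv_mesh)):
        vein = LabeledSurfaceMesh(
            cell_id=name,
            vertices=verts,
            triangles=tris,
            vertex_labels=np.full(len(verts), int(Label.UNLABELED), dtype=np.uint8),
            center=verts.mean(axis=0),
        )
        write_labeled_mesh(vein, outdir / f"{name}.ply")
    write_skeleton(lob.skeleton, outdir / "sinusoids.json")
    if with_grids:
        grids = generate_layered_grid(lob.config)
        write_density_grid(grids.hepatocyte, outdir / "hepatocyte.tif")
        write_density_grid(grids.sinusoid, outdir / "sinusoid.tif")
        write_density_grid(grids.bile_canaliculi, outdir / "bc.tif")
    truth_rows = []
    for rec in lob.records:
        row = {"cell_id": rec.cell_id}
        row.update({f"pos_{k}": v for k, v in zip("xyz", rec.position)})
        for i, ax in enumerate(rec.apical_axes.axes, start=1):
            row.update({f"true_a{i}_{k}": v for k, v in zip("xyz", ax)})
        truth_rows.append(row)
    pd.DataFrame(truth_rows).to_csv(outdir / "truth.csv", index=False)
    lob.config.to_yaml(outdir / "config.yaml")
    return outdir


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return path
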