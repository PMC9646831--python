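"""Config-driven orchestration: single runs, the porosity x haematocrit
study, the grid-independence ladder, and report (re)generation.

Every run writes a self-contained artifact directory:

    <out>/<condition>/snapshot_{A,B,C,D}.vtk   fields at the landmarks
    <out>/<condition>/wall_series.csv          traction/pressure time series
    <out>/<condition>/indices.csv              TAWSS / OSI / peak pressure
    <out>/<condition>/report.json              metrics, config echo, warnings
    <out>/inlet_waveform.csv                   sampled inlet signal
    <out>/study_report.json, comparison.txt    cross-condition comparison
    <out>/manifest.json                        sha256 of every artifact
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coil_model import CoilProperties
from .geometry_mesh import (
    Mesh,
    SacShape,
    VesselGeometry,
    build_idealized_aneurysm,
    generate_mesh,
)
from .postprocess import (
    HemodynamicIndices,
    compare_conditions,
    compute_indices,
    high_risk_regions,
    iso_velocity_area,
)
from .rheology import BloodProperties
from .solver import SolverConfig, run_pulsatile
from .vtk_io import write_vtk
from .waveform import Waveform


class StudyError(RuntimeError):
    pass


def geometry_from_config(cfg: dict) -> VesselGeometry:
    g = cfg["geometry"]
    return build_idealized_aneurysm(
        parent_width=g["parent_width"],
        parent_length=g["parent_length"],
        curvature=g["curvature"],
        sac_neck_width=g["sac_neck_width"],
        sac_depth=g["sac_depth"],
        sac_dome_radius=g["sac_dome_radius"],
        sac_shape=SacShape(g["sac_shape"]),
        sac_center_arc=g["sac_center_arc"],
        coil_fill_fraction=g["coil_fill_fraction"],
    )


def blood_from_config(cfg: dict, hct: float) -> BloodProperties:
    r = cfg["rheology"]
    return BloodProperties(
        density=r["density"],
        hct=hct,
        plasma_viscosity=r["plasma_viscosity"],
        yield_coefficient=r["yield_coefficient"],
        critical_hct=r["critical_hct"],
        viscosity_exponent=r["viscosity_exponent"],
        gamma_min=r["gamma_min"],
        model=r["model"],
        mu_inf_override=r["mu_inf_override"],
        tau_y_override=r["tau_y_override"],
    )


def waveform_from_config(cfg: dict) -> Waveform:
    w = cfg["waveform"]
    return Waveform(
        period=w["period"],
        mean_velocity=w["mean_velocity"],
        harmonics=tuple((a, p) for a, p in w["harmonics"]),
    )


def solver_from_config(cfg: dict, **overrides) -> SolverConfig:
    s = dict(cfg["solver"])
    s.update(overrides)
    return SolverConfig(
        dt=s["dt"],
        cycles_to_run=s["cycles_to_run"],
        cycles_to_discard=s["cycles_to_discard"],
        pressure_velocity_scheme=s["pressure_velocity_scheme"],
        divergence_tolerance=s["divergence_tolerance"],
        nonlinear_tolerance=s["nonlinear_tolerance"],
        max_inner_iterations=s["max_inner_iterations"],
        seed=s["seed"],
    )


def coil_from_config(cfg: dict, eps: float | None) -> CoilProperties | None:
    if eps is None:
        return None
    c = cfg["coil"]
    return CoilProperties(
        porosity=eps,
        wire_diameter=c["wire_diameter"],
        permeability_override=c["permeability_override"],
        inertial_override=c["inertial_override"],
    )


def condition_label(eps: float | None, hct: float) -> str:
    e = "open" if eps is None else f"eps{eps:g}"
    return f"{e}_hct{hct:g}"


def run_single(
    cfg: dict,
    eps: float | None,
    hct: float,
    out_dir: str | Path,
    mesh: Mesh | None = None,
) -> HemodynamicIndices:
    """One pulsatile run for a (porosity, haematocrit) condition.

    Writes the per-run artifact set and returns the computed indices.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geom = geometry_from_config(cfg)
    if mesh is None:
        mesh = generate_mesh(geom, cfg["mesh"]["resolution"], kind=cfg["mesh"]["kind"])
    props = blood_from_config(cfg, hct)
    w = waveform_from_config(cfg)
    coil = coil_from_config(cfg, eps)
    scfg = solver_from_config(cfg)

    result = run_pulsatile(mesh, props, coil, w, scfg)
    pp = cfg["postprocess"]
    idx = compute_indices(
        result,
        mesh,
        geom,
        osi_window=pp["osi_window_fraction"],
        noise_floor=pp["osi_noise_floor"],
    )

    series = result.wall_series
    for name, state in result.landmark_states.items():
        write_vtk(
            out / f"snapshot_{name}.vtk",
            mesh,
            point_data={"velocity": state.u, "pressure": state.p},
            cell_data={
                "apparent_viscosity": state.mu_cell[: mesh.n_cells]
                if not mesh.is_quad
                else _quad_cell_field(mesh, state.mu_cell),
                "coil_mask": mesh.coil_mask.astype(float),
            },
            title=f"landmark {name} t={state.t:.6g}s",
        )

    nt, ne = series.pressures.shape
    df = pd.DataFrame(
        {
            "time_s": np.repeat(series.times, ne),
            "face_id": np.tile(np.arange(ne), nt),
            "arclength_m": np.tile(series.arclength, nt),
            "chain": np.tile(series.chain, nt),
            "tag": np.tile(series.tags, nt),
            "traction_x_pa": series.tractions[:, :, 0].ravel(),
            "traction_y_pa": series.tractions[:, :, 1].ravel(),
            "traction_mag_pa": series.magnitudes.ravel(),
            "pressure_pa": series.pressures.ravel(),
        }
    )
    df.to_csv(out / "wall_series.csv", index=False, float_format="%.9e")

    pd.DataFrame(
        {
            "arclength_m": series.arclength,
            "chain": series.chain,
            "tag": series.tags,
            "tawss_pa": idx.tawss,
            "osi": idx.osi,
            "peak_pressure_pa": idx.peak_pressure,
        }
    ).to_csv(out / "indices.csv", index=False, float_format="%.9e")

    regions = high_risk_regions(
        idx.arclength, idx.osi, pp["osi_threshold"], chain=idx.chain
    )
    iso = {
        f"{lvl:g}": {
            name: iso_velocity_area(state, mesh, lvl)
            for name, state in result.landmark_states.items()
        }
        for lvl in pp["iso_velocity_levels"]
    }
    report = {
        "sacflow_version": __version__,
        "condition": {"porosity": eps, "hct": hct},
        "mesh": {"nodes": mesh.n_nodes, "cells": mesh.n_cells, "h": mesh.h},
        "landmarks": result.landmarks.as_dict(),
        "landmark_metrics": idx.landmark_metrics,
        "global_max": idx.global_max,
        "periodicity": result.periodicity,
        "divergence_residual_max": float(result.divergence_history.max()),
        "dt_effective": result.dt,
        "steps_per_cycle": result.steps_per_cycle,
        "scheme": cfg["solver"]["pressure_velocity_scheme"],
        "high_risk_regions": [vars(r) for r in regions],
        "iso_velocity_area_m2": iso,
        "geometry_signature": idx.geometry_signature,
        "warnings": result.warnings,
        "config": cfg,
    }
    with open(out / "report.json", "w") as f:
        json.dump(report, f, indent=1, sort_keys=True)
    return idx


def _quad_cell_field(mesh: Mesh, tri_field: np.ndarray) -> np.ndarray:
    _, parent = mesh.triangulated()
    out = np.zeros(mesh.n_cells)
    cnt = np.zeros(mesh.n_cells)
    np.add.at(out, parent, tri_field)
    np.add.at(cnt, parent, 1.0)
    return out / np.maximum(cnt, 1.0)


def run_study(cfg: dict, out_dir: str | Path) -> dict:
    """Full porosity x haematocrit sweep plus comparison report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geom = geometry_from_config(cfg)
    mesh = generate_mesh(geom, cfg["mesh"]["resolution"], kind=cfg["mesh"]["kind"])
    w = waveform_from_config(cfg)
    w.sample_csv(out / "inlet_waveform.csv", cfg["solver"]["dt"])

    conditions: list[tuple[float | None, float]] = [
        (eps, hct) for eps in cfg["coil"]["porosities"] for hct in cfg["hct"]
    ]
    if cfg["study"]["include_uncoiled_baseline"]:
        conditions += [(None, hct) for hct in cfg["hct"]]

    indices: dict[tuple, HemodynamicIndices] = {}
    for eps, hct in conditions:
        label = condition_label(eps, hct)
        try:
            indices[(eps, hct)] = run_single(cfg, eps, hct, out / label, mesh=mesh)
        except Exception as exc:
            raise StudyError(
                f"run failed for condition porosity={eps}, hct={hct}: {exc}"
            ) from exc

    ref = cfg["study"]["reference_condition"]
    if ref is None:
        ref = (max(cfg["coil"]["porosities"]), max(cfg["hct"]))
    else:
        ref = tuple(ref)
    coiled = {k: v for k, v in indices.items() if k[0] is not None}
    comparison = compare_conditions(coiled, reference=ref) if len(coiled) >= 2 else None

    study = {
        "sacflow_version": __version__,
        "conditions": [
            {"porosity": e, "hct": h, "label": condition_label(e, h)}
            for e, h in conditions
        ],
        "reference_condition": list(ref),
        "comparison": comparison.to_records() if comparison else [],
        "config": cfg,
    }
    with open(out / "study_report.json", "w") as f:
        json.dump(study, f, indent=1, sort_keys=True)
    if comparison:
        (out / "comparison.txt").write_text(comparison.to_table() + "\n")
    write_manifest(out)
    return study


def grid_independence(cfg: dict, out_dir: str | Path) -> dict:
    """Nested-mesh convergence of the neck-average velocity at A and B.

    Runs the first (porosity, hct) condition on each resolution of the
    ladder and tabulates successive relative changes; the recommended mesh
    is the coarsest whose change from the previous one is below target.
    """
    gs = cfg["grid_study"]
    resolutions = list(gs["resolutions"])
    if len(resolutions) < 3:
        raise StudyError("grid study needs at least 3 resolutions")
    if sorted(resolutions, reverse=True) != resolutions:
        raise StudyError("grid study resolutions must decrease monotonically")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    geom = geometry_from_config(cfg)
    w = waveform_from_config(cfg)
    eps = gs["porosity"]
    hct = cfg["hct"][0]
    props = blood_from_config(cfg, hct)
    coil = coil_from_config(cfg, eps)
    scfg = solver_from_config(
        cfg,
        cycles_to_run=gs["cycles_to_run"],
        cycles_to_discard=gs["cycles_to_discard"],
    )

    from .postprocess import sac_mean_inflow_velocity

    rows = []
    for h in resolutions:
        mesh = generate_mesh(geom, h, kind=cfg["mesh"]["kind"])
        result = run_pulsatile(mesh, props, coil, w, scfg)
        va = sac_mean_inflow_velocity(result.landmark_states["A"], mesh, geom)
        vb = sac_mean_inflow_velocity(result.landmark_states["B"], mesh, geom)
        rows.append(
            {"h": h, "cells": mesh.n_cells, "v_neck_A": va, "v_neck_B": vb}
        )

    for i, row in enumerate(rows):
        if i == 0:
            row["change_A_percent"] = None
            row["change_B_percent"] = None
        else:
            prev = rows[i - 1]
            row["change_A_percent"] = 100.0 * abs(row["v_neck_A"] - prev["v_neck_A"]) / abs(
                prev["v_neck_A"]
            )
            row["change_B_percent"] = 100.0 * abs(row["v_neck_B"] - prev["v_neck_B"]) / abs(
                prev["v_neck_B"]
            )
    target = gs["target_change_percent"]
    recommended = None
    for row in rows[1:]:
        if row["change_A_percent"] < target and row["change_B_percent"] < target:
            recommended = row["h"]
            break

    table = _grid_table(rows, target, recommended)
    report = {
        "condition": {"porosity": eps, "hct": hct},
        "monitored": "neck-average velocity magnitude at maximum acceleration (A) "
        "and peak systole (B)",
        "rows": rows,
        "target_change_percent": target,
        "recommended_resolution": recommended,
        "config": cfg,
    }
    with open(out / "grid_report.json", "w") as f:
        json.dump(report, f, indent=1, sort_keys=True)
    (out / "grid_table.txt").write_text(table + "\n")
    return report


def _grid_table(rows: list[dict], target: float, recommended) -> str:
    hdr = (
        f"{'mesh':>8} {'h (m)':>10} {'cells':>8} {'v_neck@A':>10} {'v_neck@B':>10} "
        f"{'dA %':>7} {'dB %':>7}"
    )
    names = ["coarse", "medium", "fine", "very fine", "ultra"]
    lines = [hdr, "-" * len(hdr)]
    for i, r in enumerate(rows):
        nm = names[i] if i < len(names) else f"level{i}"
        da = "-" if r["change_A_percent"] is None else f"{r['change_A_percent']:.3f}"
        db = "-" if r["change_B_percent"] is None else f"{r['change_B_percent']:.3f}"
        lines.append(
            f"{nm:>8} {r['h']:10.3e} {r['cells']:8d} {r['v_neck_A']:10.5f} "
            f"{r['v_neck_B']:10.5f} {da:>7} {db:>7}"
        )
    lines.append(f"target change: {target}%  recommended h: {recommended}")
    return "\n".join(lines)


def write_manifest(out_dir: str | Path) -> dict:
    """Checksum every artifact file under the output directory."""
    out = Path(out_dir)
    entries = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            data = p.read_bytes()
            entries[str(p.relative_to(out))] = {
                "sha256": hashlib.sha256(data).hexdigest(),
                "bytes": len(data),
            }
    manifest = {"files": entries}
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True)
    return manifest


def rebuild_reports(cfg: dict, out_dir: str | Path) -> dict:
    """Regenerate study-level tables from stored per-run report.json files."""
    out = Path(out_dir)
    reports = sorted(out.glob("*/report.json"))
    if not reports:
        raise StudyError(f"no per-run reports found under {out}")
    rows = []
    for rp in reports:
        with open(rp) as f:
            rows.append(json.load(f))
    summary = {
        "runs": [
            {
                "condition": r["condition"],
                "landmark_metrics": r["landmark_metrics"],
                "global_max": r["global_max"],
            }
            for r in rows
        ]
    }
    with open(out / "study_summary.json", "w") as f:
        json.dump(summary, f, indent=1, sort_keys=True)
    write_manifest(out)
    return summary
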