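"""Pipeline orchestration: stack pair → displacements → tractions → maps.

:func:`run_pipeline` executes the file-based stages in fixed order (load,
focal-shift correction, surface localization, PIV, lensing correction,
inverse solve, unfolding, metrics) and records every artifact with a
content hash in a JSON manifest, so that re-running an identical
configuration reproduces identical hashes for all deterministic stages.

:func:`run_synthetic_loop` is the in-memory closed loop used for
validation and examples: prescribe a traction pattern, solve the forward
problem, advect synthetic beads, render the stack pair, and push it
through the full measurement pipeline to compare recovered tractions with
the prescribed ground truth.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import fem, inverse, io, metrics, optics, piv, synthetic, unfold
from .config import RunConfig
from .errors import ConfigError
from .geometry import (
    ImageStack,
    WellGeometry,
    locate_bottom_surface,
    locate_top_surface,
    locate_well_axis,
)

__all__ = [
    "run_pipeline",
    "run_synthetic_loop",
    "make_synthetic_pair",
    "ring_traction",
    "export_vtk",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def export_vtk(
    path: str | Path, mesh: fem.Mesh, fields: dict[str, np.ndarray] | None = None
) -> None:
    """Write nodal displacement/traction fields on the mesh as VTU.

    Field names should carry units (``displacement_um``, ``traction_Pa``);
    see :func:`welltfm.io.write_vtu`."""
    io.write_vtu(path, mesh, point_data=fields)


def ring_traction(
    geometry: WellGeometry,
    magnitude: float = -500.0,
    z_center: float | None = None,
    half_width: float = 1.0,
    profile: str = "sharp",
):
    """Axisymmetric normal traction band on the well wall (Pa).

    Negative ``magnitude`` is inward/contractile.  ``profile`` selects a
    sharp-edged band (|z − z_c| ≤ half_width) or a smooth Gaussian band
    (σ = half_width), the latter being insensitive to how mesh nodes
    sample the band edge.  Returns a callable usable with
    :meth:`welltfm.fem.TractionField.from_function`.
    """
    cx, cy = geometry.center_xy
    if z_center is None:
        z_center = geometry.bottom_z + geometry.depth / 2.0
    if profile not in ("sharp", "gaussian"):
        raise ValueError("profile must be 'sharp' or 'gaussian'")

    def fn(x: np.ndarray) -> np.ndarray:
        r = np.hypot(x[:, 0] - cx, x[:, 1] - cy)
        rhat = np.zeros_like(x)
        nz = r > 1e-9
        rhat[nz, 0] = (x[nz, 0] - cx) / r[nz]
        rhat[nz, 1] = (x[nz, 1] - cy) / r[nz]
        if profile == "sharp":
            band = (np.abs(x[:, 2] - z_center) <= half_width).astype(float)
        else:
            band = np.exp(-((x[:, 2] - z_center) ** 2) / (2 * half_width**2))
        on_wall = np.abs(r - geometry.radius) <= max(
            geometry.fillet_top, geometry.fillet_bottom, 0.3
        )
        return magnitude * rhat * (band * on_wall)[:, None]

    return fn


def _area_weighted_mean_tn_wall(
    traction: fem.TractionField, mesh: fem.Mesh, geometry: WellGeometry
) -> float:
    wc = unfold.decompose_wall(traction, mesh, geometry)
    return float((wc.areas * wc.component("T_n")).sum() / wc.areas.sum())


def make_synthetic_pair(
    geometry: WellGeometry,
    mesh: fem.Mesh,
    displacement_nodes: np.ndarray,
    seed: int = 0,
    roi_xy: tuple[float, float] | None = None,
    roi_size: float = 30.0,
    z_pad_below: float = 2.0,
    z_pad_above: float = 1.2,
    pixel_size_xy: float = synthetic.DEFAULT_PIXEL_SIZE_XY,
    z_step: float = synthetic.DEFAULT_Z_STEP,
    noise_sd: float = 10.0,
    bulk_density: float = 0.23,
    surface_density: float = 1.1,
) -> tuple[ImageStack, ImageStack, synthetic.BeadField]:
    """Render a reference/deformed stack pair for a known displacement field.

    Beads are sampled over the whole gel, restricted to a square imaging
    region of interest of side ``roi_size`` µm centered on the well, advected
    by the FEM displacement field, and rendered with the default confocal
    calibration.  Returns (reference, deformed, beads-in-ROI).
    """
    cx, cy = geometry.center_xy if roi_xy is None else roi_xy
    beads = synthetic.sample_beads(
        geometry,
        bulk_density=bulk_density,
        surface_density=surface_density,
        seed=seed,
    )
    half = roi_size / 2.0
    margin = 1.5
    p = beads.positions
    keep = (
        (np.abs(p[:, 0] - cx) <= half + margin)
        & (np.abs(p[:, 1] - cy) <= half + margin)
        & (p[:, 2] >= geometry.bottom_z - z_pad_below - margin)
    )
    beads = replace(beads, positions=p[keep])
    warped = synthetic.warp_beads(
        beads,
        lambda pts: fem.interpolate_nodal_field(mesh, displacement_nodes, pts),
    )
    nx = int(round(roi_size / pixel_size_xy))
    z0 = geometry.bottom_z - z_pad_below
    nz = int(round((geometry.top_z + z_pad_above - z0) / z_step))
    origin = (cx - half, cy - half, z0)
    shape = (nz, nx, nx)
    ref = synthetic.render_stack(
        beads, shape, pixel_size_xy, z_step, noise_sd=noise_sd, seed=seed + 1,
        origin=origin,
    )
    dfm = synthetic.render_stack(
        warped, shape, pixel_size_xy, z_step, noise_sd=noise_sd, seed=seed + 2,
        origin=origin,
    )
    return ref, dfm, beads


def run_synthetic_loop(
    seed: int = 0,
    geometry: WellGeometry | None = None,
    mesh_edge: float = 2.2,
    ring_magnitude: float = -500.0,
    ring_half_width: float = 1.5,
    material: fem.MaterialModel | None = None,
    piv_config: piv.PivConfig | None = None,
    noise_sd: float = 10.0,
    quality_min: float = 0.3,
    inverse_config: inverse.InverseConfig | None = None,
    operator: inverse.InverseOperator | None = None,
) -> dict:
    """Closed-loop synthetic experiment: prescribed ring → recovered ring.

    Prescribes an inward normal traction band on the well wall, renders the
    corresponding bead-stack pair, and runs PIV → surface interpolation →
    inverse solve.  Returns ground truth and recovered summaries, including
    the area-weighted mean wall normal traction for both.
    """
    geometry = geometry or WellGeometry(
        radius=7.5, depth=11.5, gel_height=100.0, center_xy=(15.0, 15.0)
    )
    material = material or fem.MaterialModel()
    piv_config = piv_config or piv.PivConfig()
    if operator is not None:
        mesh = operator.mesh
    else:
        mesh = fem.build_mesh(geometry, mesh_edge)
    truth = fem.TractionField.from_function(
        mesh,
        ("well_wall", "well_bottom"),
        ring_traction(geometry, ring_magnitude, half_width=ring_half_width),
    )
    if operator is None:
        operator = inverse.InverseOperator(mesh, material)
    u_nodes = operator.forward_displacement(truth)
    ref, dfm, beads = make_synthetic_pair(
        geometry, mesh, u_nodes, seed=seed, noise_sd=noise_sd
    )
    field = piv.piv3d(ref, dfm, piv_config)
    field.valid &= field.quality >= quality_min
    field = piv.filter_outliers(field)
    measured = inverse.interpolate_measured_to_surface(field, mesh)
    if inverse_config is None:
        inverse_config = inverse.InverseConfig(regularization_lambda="lcurve")
    result = operator.solve(measured, inverse_config)

    mean_tn_truth = _area_weighted_mean_tn_wall(truth, mesh, geometry)
    mean_tn_rec = _area_weighted_mean_tn_wall(result.traction, mesh, geometry)
    # PIV fidelity against the FEM displacement at the sample points
    pts = field.points[field.valid]
    u_true = fem.interpolate_nodal_field(mesh, u_nodes, pts)
    piv_rms = float(
        np.sqrt(((field.vectors[field.valid] - u_true) ** 2).sum(1).mean())
    )
    return {
        "geometry": geometry,
        "mesh": mesh,
        "operator": operator,
        "truth": truth,
        "result": result,
        "displacement_field": field,
        "n_beads": len(beads),
        "mean_tn_wall_truth": mean_tn_truth,
        "mean_tn_wall_recovered": mean_tn_rec,
        "mean_tn_wall_rel_error": abs(mean_tn_rec - mean_tn_truth)
        / abs(mean_tn_truth),
        "piv_rms_error_um": piv_rms,
        "lambda": result.regularization_lambda,
    }


# --------------------------------------------------------------------------
# file-based pipeline
# --------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages on a stack pair from disk; returns the manifest.

    The manifest (also written to ``<output_dir>/manifest.json``) records,
    per stage, the parameters used, wall-clock time and the SHA-256 of every
    artifact written.  A stage failure is recorded in the manifest before
    the exception propagates.
    """
    if config.reference_stack is None or config.deformed_stack is None:
        raise ConfigError("run_pipeline requires reference and deformed stacks")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "seed": config.seed}

    def record(stage: str, params: dict, artifacts: dict[str, Path], t0: float):
        manifest["stages"].append(
            {
                "stage": stage,
                "params": params,
                "seconds": round(time.time() - t0, 3),
                "artifacts": {
                    k: {"path": str(v), "sha256": _sha256(v)}
                    for k, v in artifacts.items()
                },
            }
        )
        _write_manifest(out, manifest)

    def fail(stage: str, exc: Exception):
        manifest["stages"].append({"stage": stage, "error": repr(exc)})
        _write_manifest(out, manifest)

    stage = "load"
    t0 = time.time()
    try:
        ref = io.read_stack(
            config.reference_stack, config.pixel_size_xy, config.z_step
        )
        dfm = io.read_stack(
            config.deformed_stack, config.pixel_size_xy, config.z_step
        )
        record(stage, {"shape": list(ref.shape)}, {}, t0)

        stage = "visser"
        t0 = time.time()
        if config.optics is not None:
            scale = optics.axial_scale(config.optics)
            ref = optics.apply_visser(ref, config.optics)
            dfm = optics.apply_visser(dfm, config.optics)
        else:
            scale = 1.0
        record(stage, {"axial_scale": scale}, {}, t0)

        stage = "locate"
        t0 = time.time()
        top_z = locate_top_surface(ref)
        geometry = config.geometry.with_top(top_z)
        z_mid = top_z - geometry.depth / 2.0
        (cx, cy), r_fit = locate_well_axis(ref, z_mid, geometry.radius)
        geometry = geometry.with_center(cx, cy)
        bottom_z = locate_bottom_surface(top_z, geometry)
        record(
            stage,
            {
                "top_z": top_z,
                "center": [cx, cy],
                "fitted_radius": r_fit,
                "bottom_z": bottom_z,
            },
            {},
            t0,
        )

        stage = "piv"
        t0 = time.time()
        field = piv.piv3d(ref, dfm, config.piv)
        field.valid &= field.quality >= config.quality_min
        field = piv.filter_outliers(field)
        disp_path = out / "displacements.csv"
        io.write_displacement_csv(disp_path, field)
        record(
            stage,
            {"box": list(config.piv.box_size),
             "overlap": config.piv.overlap_fraction,
             "n_valid": int(field.valid.sum())},
            {"displacements": disp_path},
            t0,
        )

        stage = "lensing"
        t0 = time.time()
        if config.lensing_calibration is not None:
            cal = io.read_displacement_csv(config.lensing_calibration)
            field = optics.lensing_correction(field, cal)
            corr_path = out / "displacements_corrected.csv"
            io.write_displacement_csv(corr_path, field)
            record(stage, {"applied": True}, {"corrected": corr_path}, t0)
        else:
            record(stage, {"applied": False}, {}, t0)

        stage = "solve"
        t0 = time.time()
        mesh = fem.build_mesh(geometry, config.mesh_edge_length)
        op = inverse.InverseOperator(mesh, config.material)
        measured = inverse.interpolate_measured_to_surface(field, mesh)
        inv_cfg = config.inverse
        if (
            inv_cfg.regularization_lambda == "auto"
            and inv_cfg.noise_sd is None
        ):
            inv_cfg = replace(inv_cfg, noise_sd=piv.estimate_noise_sd(field))
        result = op.solve(measured, inv_cfg)
        trac_path = out / "tractions.csv"
        _write_traction_csv(trac_path, mesh, result.traction)
        vtu_path = out / "solution.vtu"
        full_t = np.zeros((mesh.n_nodes, 3))
        full_t[result.traction.node_ids] = result.traction.tractions
        export_vtk(
            vtu_path,
            mesh,
            {
                "displacement_um": result.model_displacement,
                "traction_Pa": full_t,
            },
        )
        record(
            stage,
            {"nodes": mesh.n_nodes,
             "lambda": result.regularization_lambda,
             "misfit": result.misfit},
            {"tractions": trac_path, "vtu": vtu_path},
            t0,
        )

        stage = "unfold"
        t0 = time.time()
        wall = unfold.decompose_wall(result.traction, mesh, geometry)
        bottom = unfold.decompose_bottom(result.traction, mesh, geometry)
        artifacts: dict[str, Path] = {}
        profiles = {}
        for comp in unfold.WALL_COMPONENTS:
            m = unfold.unfold_wall_map(
                wall, geometry, comp, excluded_band=config.excluded_band
            )
            p = out / f"wall_{comp}.csv"
            _write_map_csv(p, m)
            artifacts[f"wall_{comp}"] = p
            profiles[f"wall_{comp}"] = unfold.circumferential_profile(m)
        for comp in unfold.BOTTOM_COMPONENTS:
            profiles[f"bottom_{comp}"] = unfold.radial_profile(
                bottom, geometry, comp
            )
        prof_path = out / "profiles.csv"
        _write_profiles_csv(prof_path, profiles)
        artifacts["profiles"] = prof_path
        record(stage, {"excluded_band": config.excluded_band}, artifacts, t0)

        stage = "report"
        t0 = time.time()
        report = {
            "mean_Tn_wall_Pa": _area_weighted_mean_tn_wall(
                result.traction, mesh, geometry
            ),
            "cov_Tn_wall": _safe_cov(profiles["wall_T_n"]),
            "net_wall_normal_force_nN": metrics.net_force(
                result.traction,
                node_ids=wall.node_ids,
                component=_expand(wall, result.traction, "T_n"),
            ),
            "contact_area_um2": metrics.contact_area(geometry),
            "cell_volume_um3": metrics.cell_volume(geometry),
        }
        rep_path = out / "metrics.json"
        rep_path.write_text(json.dumps(report, indent=2, sort_keys=True))
        record(stage, {}, {"metrics": rep_path}, t0)
    except Exception as exc:
        fail(stage, exc)
        raise
    return manifest


def _safe_cov(profile) -> float | None:
    from .errors import UndefinedMetricError

    try:
        return metrics.coefficient_of_variation(profile)
    except UndefinedMetricError:
        return None


def _expand(wall, traction, comp: str) -> np.ndarray:
    lut = {n: i for i, n in enumerate(wall.node_ids)}
    out = np.zeros(len(traction.node_ids))
    vals = wall.component(comp)
    for i, n in enumerate(traction.node_ids):
        if n in lut:
            out[i] = vals[lut[n]]
    return out


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )


def _write_traction_csv(path: Path, mesh: fem.Mesh, traction) -> None:
    import pandas as pd

    pos = mesh.nodes[traction.node_ids]
    pd.DataFrame(
        {
            "node_id": traction.node_ids,
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "z_um": pos[:, 2],
            "tx_Pa": traction.tractions[:, 0],
            "ty_Pa": traction.tractions[:, 1],
            "tz_Pa": traction.tractions[:, 2],
            "area_um2": traction.areas,
        }
    ).to_csv(path, index=False)


def _write_map_csv(path: Path, m) -> None:
    import pandas as pd

    df = pd.DataFrame(m.values, index=m.axis1, columns=m.axis0)
    df.index.name = "z_um_or_y"
    df.to_csv(path)


def _write_profiles_csv(path: Path, profiles: dict) -> None:
    import pandas as pd

    rows = []
    for name, p in profiles.items():
        for i in range(len(p.abscissa)):
            rows.append(
                {
                    "profile": name,
                    "abscissa_um": p.abscissa[i],
                    "mean_Pa": p.mean[i],
                    "std_Pa": p.std[i],
                    "n": int(p.n[i]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
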