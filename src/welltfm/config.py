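"""Run configuration: YAML loading and validation.

All lengths are µm, moduli Pa.  A config file has blocks ``paths``,
``imaging``, ``geometry``, ``optics``, ``piv``, ``mesh``, ``material``,
``inverse``, ``unfold`` and a top-level ``seed``; every block validates
against the corresponding domain type's invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .fem import MaterialModel
from .geometry import WellGeometry
from .inverse import InverseConfig
from .optics import OpticalParams
from .piv import PivConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    reference_stack: Path | None
    deformed_stack: Path | None
    output_dir: Path
    pixel_size_xy: float
    z_step: float
    geometry: WellGeometry
    optics: OpticalParams | None
    piv: PivConfig
    material: MaterialModel
    inverse: InverseConfig
    mesh_edge_length: float
    excluded_band: float = 1.0
    quality_min: float = 0.3
    lensing_calibration: Path | None = None
    seed: int | None = None
    check_inputs: bool = True

    def __post_init__(self) -> None:
        if self.pixel_size_xy <= 0 or self.z_step <= 0:
            raise ConfigError("voxel sizes must be positive")
        if self.mesh_edge_length <= 0:
            raise ConfigError("mesh edge length must be positive")
        if self.check_inputs:
            for p in (self.reference_stack, self.deformed_stack,
                      self.lensing_calibration):
                if p is not None and not Path(p).exists():
                    raise ConfigError(f"input file does not exist: {p}")


def _block(cfg: dict, name: str) -> dict:
    v = cfg.get(name, {})
    if not isinstance(v, dict):
        raise ConfigError(f"config block '{name}' must be a mapping")
    return v


def load_config(path: str | Path, check_inputs: bool = True) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    try:
        paths = _block(cfg, "paths")
        imaging = _block(cfg, "imaging")
        geo = _block(cfg, "geometry")
        geometry = WellGeometry(
            radius=float(geo["radius"]),
            depth=float(geo["depth"]),
            gel_height=float(geo["gel_height"]),
            lateral_extent=float(geo.get("lateral_extent", 0.0)),
            fillet_bottom=float(geo.get("fillet_bottom", 0.5)),
            fillet_top=float(geo.get("fillet_top", 1.0)),
        )
        opt = cfg.get("optics")
        optics = None
        if opt:
            optics = OpticalParams(
                na=float(opt["na"]),
                n_immersion=float(opt["n_immersion"]),
                n_sample=float(opt["n_sample"]),
                z_step_nominal=float(opt.get("z_step", imaging["z_step"])),
            )
        pivb = _block(cfg, "piv")
        piv = PivConfig(
            box_size=tuple(pivb.get("box", (32, 32, 8))),
            overlap_fraction=float(pivb.get("overlap", 0.5)),
            max_displacement=(
                tuple(pivb["max_displacement"])
                if "max_displacement" in pivb
                else None
            ),
        )
        matb = _block(cfg, "material")
        material = MaterialModel(
            youngs_modulus=float(matb.get("youngs_modulus", 15000.0)),
            poisson_ratio=float(matb.get("poisson_ratio", 0.45)),
            law=matb.get("law", "linear"),
        )
        invb = _block(cfg, "inverse")
        inv = InverseConfig(
            regularization_lambda=invb.get("regularization_lambda", 0.0),
            noise_sd=invb.get("noise_sd"),
        )
        meshb = _block(cfg, "mesh")
        return RunConfig(
            reference_stack=(
                Path(paths["reference"]) if "reference" in paths else None
            ),
            deformed_stack=(
                Path(paths["deformed"]) if "deformed" in paths else None
            ),
            output_dir=Path(paths.get("output_dir", ".")),
            pixel_size_xy=float(imaging["pixel_size_xy"]),
            z_step=float(imaging["z_step"]),
            geometry=geometry,
            optics=optics,
            piv=piv,
            material=material,
            inverse=inv,
            mesh_edge_length=float(meshb.get("target_edge_length", 1.5)),
            excluded_band=float(cfg.get("unfold", {}).get("excluded_band", 1.0)),
            quality_min=float(pivb.get("quality_min", 0.3)),
            lensing_calibration=(
                Path(paths["lensing_calibration"])
                if "lensing_calibration" in paths
                else None
            ),
            seed=cfg.get("seed"),
            check_inputs=check_inputs,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc
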