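"""Synthetic bead fields and rendered confocal-like stacks.

This module is the forward model of the imaging experiment: 200 nm
fluorescent beads distributed through the gel, concentrated near its free
surfaces (gel top, well wall, well bottom), rendered as anisotropic Gaussian
blobs on a voxel grid with additive Gaussian noise, and warped by a
prescribed displacement field to produce the "deformed" member of a stack
pair.  Default calibration follows the imaging regime the pipeline targets:
0.104 µm lateral pixels and 0.2 µm z-steps, so a ≈0.24 µm blob spans about
2.3 pixels — near the optimum particle image diameter for PIV.

The default axial-to-lateral PSF ratio of 3 emulates confocal axial
elongation; it is the reason synthetic z displacements are noisier than
lateral ones, as in the real instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .geometry import ImageStack, WellGeometry

__all__ = ["BeadField", "sample_beads", "render_stack", "warp_beads"]

DEFAULT_PIXEL_SIZE_XY = 0.104  # µm
DEFAULT_Z_STEP = 0.2  # µm
DEFAULT_PSF_SIGMA_XY = 0.12  # µm, ≈ 240 nm FWHM-ish particle image
DEFAULT_PSF_AXIAL_RATIO = 3.0
DEFAULT_SURFACE_LAYER = 0.6  # µm


@dataclass
class BeadField:
    """Point beads in physical µm coordinates (N × 3 array of x, y, z)."""

    positions: np.ndarray
    bead_diameter: float = 0.2
    intensity_scale: float = 1000.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.positions)


def _inside_gel(p: np.ndarray, geom: WellGeometry) -> np.ndarray:
    """Boolean mask of points inside the gel (outside the cavity)."""
    cx, cy = geom.center_xy
    half = geom.lateral_extent / 2
    in_box = (
        (np.abs(p[:, 0] - cx) <= half)
        & (np.abs(p[:, 1] - cy) <= half)
        & (p[:, 2] >= geom.base_z)
        & (p[:, 2] <= geom.top_z)
    )
    r = np.hypot(p[:, 0] - cx, p[:, 1] - cy)
    in_cavity = (r < geom.radius) & (p[:, 2] > geom.bottom_z)
    return in_box & ~in_cavity


def sample_beads(
    geometry: WellGeometry,
    bulk_density: float = 0.23,
    surface_density: float = 1.1,
    surface_layer_thickness: float = DEFAULT_SURFACE_LAYER,
    seed: int = 0,
    bead_diameter: float = 0.2,
    intensity_scale: float = 1000.0,
) -> BeadField:
    """Draw a reproducible bead field: uniform bulk plus surface layers.

    Parameters
    ----------
    bulk_density : float
        Beads per µm³ in the gel bulk.  The default 0.23 µm⁻³ equals the
        0.0005 beads/voxel floor above which volumetric PIV error saturates,
        at the default 0.104 × 0.104 × 0.2 µm voxel.
    surface_density : float
        Beads per µm² concentrated within ``surface_layer_thickness`` of the
        gel top, well wall and well bottom; the default ≈1.1 µm⁻² yields on
        the order of 12 beads per 32×32×8 interrogation box at a surface.
    seed : int
        Seeds bulk counts and positions; identical inputs give identical
        fields.

    Counts in each region are Poisson with mean density × region measure.
    Surface-layer depths decay exponentially into the gel with scale
    ``surface_layer_thickness / 2`` (clipped at the full thickness), so the
    bead concentration peaks at the free surface itself, as it does when
    beads are squeezed against the mold during polymerization.
    """
    if bulk_density < 0 or surface_density < 0:
        raise ValueError("densities must be >= 0")
    if surface_layer_thickness <= 0:
        raise ValueError("surface_layer_thickness must be positive")
    rng = np.random.default_rng(seed)
    cx, cy = geometry.center_xy
    half = geometry.lateral_extent / 2
    R, t = geometry.radius, surface_layer_thickness
    parts: list[np.ndarray] = [np.empty((0, 3))]

    def layer_depth(n: int) -> np.ndarray:
        # exponential accumulation profile peaking at the surface
        return np.minimum(rng.exponential(t / 2.0, n), t)

    # Bulk: Poisson-sample the full prism, then discard points in the cavity.
    # Thinning a Poisson process keeps it Poisson with the gel's volume.
    box_vol = geometry.lateral_extent**2 * geometry.gel_height
    n_box = rng.poisson(bulk_density * box_vol)
    if n_box:
        p = np.column_stack(
            [
                rng.uniform(cx - half, cx + half, n_box),
                rng.uniform(cy - half, cy + half, n_box),
                rng.uniform(geometry.base_z, geometry.top_z, n_box),
            ]
        )
        parts.append(p[_inside_gel(p, geometry)])

    # Gel top surface: square minus the cavity opening, beads within t below.
    top_area = geometry.lateral_extent**2
    n_top = rng.poisson(surface_density * top_area)
    if n_top:
        p = np.column_stack(
            [
                rng.uniform(cx - half, cx + half, n_top),
                rng.uniform(cy - half, cy + half, n_top),
                geometry.top_z - layer_depth(n_top),
            ]
        )
        r = np.hypot(p[:, 0] - cx, p[:, 1] - cy)
        parts.append(p[r >= R])

    # Well wall: cylinder r ∈ [R, R + t].
    wall_area = 2 * np.pi * R * geometry.depth
    n_wall = rng.poisson(surface_density * wall_area)
    if n_wall:
        theta = rng.uniform(0, 2 * np.pi, n_wall)
        rr = R + layer_depth(n_wall)
        zz = rng.uniform(geometry.bottom_z, geometry.top_z, n_wall)
        parts.append(
            np.column_stack([cx + rr * np.cos(theta), cy + rr * np.sin(theta), zz])
        )

    # Well bottom: disk r < R, beads within t below the floor.
    bot_area = np.pi * R**2
    n_bot = rng.poisson(surface_density * bot_area)
    if n_bot:
        theta = rng.uniform(0, 2 * np.pi, n_bot)
        rr = R * np.sqrt(rng.uniform(0, 1, n_bot))
        zz = geometry.bottom_z - layer_depth(n_bot)
        parts.append(
            np.column_stack([cx + rr * np.cos(theta), cy + rr * np.sin(theta), zz])
        )

    positions = np.vstack(parts)
    return BeadField(
        positions=positions,
        bead_diameter=bead_diameter,
        intensity_scale=intensity_scale,
        seed=seed,
    )


def render_stack(
    beads: BeadField,
    stack_shape: tuple[int, int, int],
    pixel_size_xy: float = DEFAULT_PIXEL_SIZE_XY,
    z_step: float = DEFAULT_Z_STEP,
    psf_sigma_xy: float = DEFAULT_PSF_SIGMA_XY,
    psf_sigma_z: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> ImageStack:
    """Render beads as anisotropic Gaussian blobs on a voxel grid.

    ``stack_shape`` is ``(nz, ny, nx)``.  Each bead contributes
    ``intensity_scale · exp(−Δxy²/2σ_xy² − Δz²/2σ_z²)`` evaluated at voxel
    centers within ±4σ; beads outside the field of view are clipped.
    Additive Gaussian background noise of standard deviation ``noise_sd``
    is drawn from ``seed``.  Bit-identical for identical inputs.
    """
    if psf_sigma_z is None:
        psf_sigma_z = DEFAULT_PSF_AXIAL_RATIO * psf_sigma_xy
    if psf_sigma_xy <= 0 or psf_sigma_z <= 0:
        raise ValueError("PSF sigmas must be positive")
    nz, ny, nx = stack_shape
    vol = np.zeros(stack_shape, dtype=np.float64)
    if len(beads):
        x0, y0, z0 = origin
        # bead centers in fractional voxel indices
        jx = (beads.positions[:, 0] - x0) / pixel_size_xy
        jy = (beads.positions[:, 1] - y0) / pixel_size_xy
        jz = (beads.positions[:, 2] - z0) / z_step
        sx = psf_sigma_xy / pixel_size_xy
        sz = psf_sigma_z / z_step
        wx = int(np.ceil(4 * sx))
        wz = int(np.ceil(4 * sz))
        amp = beads.intensity_scale
        for bx, by, bz in zip(jx, jy, jz):
            ix0, ix1 = int(np.floor(bx)) - wx, int(np.floor(bx)) + wx + 1
            iy0, iy1 = int(np.floor(by)) - wx, int(np.floor(by)) + wx + 1
            iz0, iz1 = int(np.floor(bz)) - wz, int(np.floor(bz)) + wz + 1
            ix0, iy0, iz0 = max(ix0, 0), max(iy0, 0), max(iz0, 0)
            ix1, iy1, iz1 = min(ix1, nx), min(iy1, ny), min(iz1, nz)
            if ix0 >= ix1 or iy0 >= iy1 or iz0 >= iz1:
                continue
            gx = np.exp(-((np.arange(ix0, ix1) - bx) ** 2) / (2 * sx**2))
            gy = np.exp(-((np.arange(iy0, iy1) - by) ** 2) / (2 * sx**2))
            gz = np.exp(-((np.arange(iz0, iz1) - bz) ** 2) / (2 * sz**2))
            vol[iz0:iz1, iy0:iy1, ix0:ix1] += amp * (
                gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
            )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol += rng.normal(0.0, noise_sd, size=vol.shape)
    return ImageStack(
        data=vol, pixel_size_xy=pixel_size_xy, z_step=z_step, origin=origin
    )


def warp_beads(
    beads: BeadField,
    displacement: Callable[[np.ndarray], np.ndarray],
) -> BeadField:
    """Advect beads by a displacement field: p → p + u(p).

    ``displacement`` maps an (N, 3) array of positions to (N, 3)
    displacements in µm; it must be defined (finite) at every bead.
    """
    if len(beads) == 0:
        return replace(beads, positions=beads.positions.copy())
    u = np.asarray(displacement(beads.positions), dtype=float)
    if u.shape != beads.positions.shape:
        raise ValueError(
            f"displacement returned shape {u.shape}, "
            f"expected {beads.positions.shape}"
        )
    bad = ~np.isfinite(u).all(axis=1)
    if bad.any():
        idx = np.flatnonzero(bad)
        raise ValueError(
            f"displacement undefined at bead indices {idx[:10].tolist()}"
            + ("..." if len(idx) > 10 else "")
        )
    return replace(beads, positions=beads.positions + u)
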