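"""Well/gel geometry, image-stack container, and surface localization.

Coordinate conventions (shared by every downstream module):

* right-handed Cartesian frame, x/y in the image plane, z increasing from the
  glass coverslip toward the objective (i.e. "up" is toward the gel top);
* the well axis is vertical through ``center_xy``;
* the azimuth θ is measured counter-clockwise from +x;
* all physical coordinates are in µm, converted from voxel indices at voxel
  centers (index 0 maps to the origin coordinate).

The gel occupies a square prism of side ``lateral_extent`` and height
``gel_height`` whose top face is the plane ``z = top_z``.  A cylindrical
cavity (the well) of radius ``radius`` and depth ``depth`` opens on the top
face; its bottom and top rims are rounded by fillets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import fftconvolve
from skimage.filters import gaussian

from .errors import AmbiguousSurfaceError, DetectionFailureError

__all__ = [
    "WellGeometry",
    "ImageStack",
    "locate_top_surface",
    "locate_well_axis",
    "locate_bottom_surface",
]


@dataclass(frozen=True)
class WellGeometry:
    """Parametric description of a cylindrical micro-well in a gel slab.

    Parameters
    ----------
    radius, depth : float
        Cavity radius and depth in µm.
    gel_height : float
        Total gel thickness (glass to top surface) in µm.
    lateral_extent : float
        Side length of the square gel prism in µm.  Defaults to six well
        radii so that the traction-free lateral boundary is mechanically
        remote from the well.
    fillet_bottom, fillet_top : float
        Rounding radii of the cavity bottom and top rims in µm.
    center_xy : tuple of float
        Well-axis position in µm.
    top_z : float
        z of the gel top surface in µm.
    """

    radius: float
    depth: float
    gel_height: float
    lateral_extent: float = 0.0
    fillet_bottom: float = 0.5
    fillet_top: float = 1.0
    center_xy: tuple[float, float] = (0.0, 0.0)
    top_z: float = 0.0

    def __post_init__(self) -> None:
        if self.lateral_extent == 0.0:
            object.__setattr__(self, "lateral_extent", 6.0 * self.radius)
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if not (0 < self.depth < self.gel_height):
            raise ValueError("depth must satisfy 0 < depth < gel_height")
        if self.fillet_bottom < 0 or self.fillet_top < 0:
            raise ValueError("fillet radii must be >= 0")
        if self.fillet_bottom + self.fillet_top >= self.depth:
            raise ValueError("fillet_bottom + fillet_top must be < depth")
        if self.lateral_extent < 2 * (self.radius + self.fillet_top):
            raise ValueError("lateral_extent too small for the cavity")

    @property
    def bottom_z(self) -> float:
        """z of the cavity floor plane (µm)."""
        return self.top_z - self.depth

    @property
    def base_z(self) -> float:
        """z of the glass-bonded gel base (µm)."""
        return self.top_z - self.gel_height

    def with_center(self, cx: float, cy: float) -> "WellGeometry":
        return replace(self, center_xy=(float(cx), float(cy)))

    def with_top(self, top_z: float) -> "WellGeometry":
        return replace(self, top_z=float(top_z))


@dataclass
class ImageStack:
    """A 3D fluorescence volume with voxel calibration.

    ``data`` is indexed ``[z, y, x]`` (tifffile page order); ``origin`` is the
    physical (x, y, z) position in µm of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    pixel_size_xy: float
    z_step: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("stack must be a 3D array with all dims >= 1")
        if self.pixel_size_xy <= 0 or self.z_step <= 0:
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def z_coords(self) -> np.ndarray:
        """Physical z (µm) of every plane."""
        return self.origin[2] + self.z_step * np.arange(self.data.shape[0])

    def voxel_to_um(self, idx_zyx: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (z, y, x) to physical (x, y, z) µm."""
        idx = np.asarray(idx_zyx, dtype=float)
        x = self.origin[0] + idx[..., 2] * self.pixel_size_xy
        y = self.origin[1] + idx[..., 1] * self.pixel_size_xy
        z = self.origin[2] + idx[..., 0] * self.z_step
        return np.stack([x, y, z], axis=-1)


def locate_top_surface(stack: ImageStack, rel_tol: float = 0.05) -> float:
    """Find the gel top surface from the plane-mean intensity profile.

    Beads accumulate at the free gel surfaces, so the plane whose mean
    intensity peaks marks the gel top.  Returns the physical z (µm) of that
    plane.  Invariant to uniform intensity scaling.

    Raises
    ------
    AmbiguousSurfaceError
        If the profile is flat: the peak does not exceed the profile minimum
        by more than ``rel_tol`` of the overall dynamic range.
    """
    if stack.shape[0] < 3:
        raise ValueError("need at least 3 planes to locate a surface")
    means = stack.data.reshape(stack.shape[0], -1).mean(axis=1)
    span = means.max() - means.min()
    scale = max(abs(means.max()), abs(means.min()))
    if scale == 0 or span <= rel_tol * scale:
        raise AmbiguousSurfaceError(
            "plane-mean intensity profile has no unique peak"
        )
    return float(stack.z_coords[int(np.argmax(means))])


def locate_bottom_surface(top_z: float, geometry: WellGeometry) -> float:
    """Cavity floor plane: the gel top offset downward by the model depth."""
    if geometry.depth <= 0:
        raise ValueError("geometry.depth must be positive")
    return top_z - geometry.depth


def _fit_circle(yx: np.ndarray) -> tuple[float, float, float, float]:
    """Algebraic (Kasa) least-squares circle fit; returns (cy, cx, r, rms)."""
    y, x = yx[:, 0], yx[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r = float(np.sqrt(c + cx**2 + cy**2))
    rms = float(np.sqrt(np.mean((np.hypot(x - cx, y - cy) - r) ** 2)))
    return float(cy), float(cx), r, rms


def locate_well_axis(
    stack: ImageStack,
    z_mid: float,
    expected_radius: float,
    radius_band: float = 0.3,
    smooth_um: float = 1.2,
    manual: tuple[float, float, float] | None = None,
) -> tuple[tuple[float, float], float]:
    """Detect the well circumference in one plane and fit its center/radius.

    The cavity appears as a dark disk in the bead channel.  The plane
    nearest ``z_mid`` is smoothed and scanned with a disk matched filter of
    the expected radius to find the center candidate; the rim is then
    located as the maximum outward radial intensity gradient along rays and
    fitted with a least-squares circle (iterated).  A fitted radius outside
    ``radius_band`` (fractional) of ``expected_radius`` raises
    :class:`DetectionFailureError` — the caller may fall back to the
    ``manual`` path, which returns a user-supplied circle ``(cx, cy, r)``
    unchanged.  Returns ``((cx, cy), radius)`` in µm.
    """
    if manual is not None:
        cx, cy, r = manual
        return (float(cx), float(cy)), float(r)
    zc = stack.z_coords
    if not (zc.min() < z_mid < zc.max()):
        raise ValueError("z_mid must lie strictly inside the stack")
    plane = stack.data[int(np.argmin(np.abs(zc - z_mid)))].astype(float)
    px = stack.pixel_size_xy
    sm = gaussian(plane, sigma=smooth_um / px, preserve_range=True)
    lo, hi = sm.min(), sm.max()
    if hi - lo <= 1e-9 * max(abs(hi), 1.0):
        raise DetectionFailureError("featureless plane: no circular edge found")
    sm = (sm - lo) / (hi - lo)
    ny, nx = sm.shape
    r_px = expected_radius / px

    # matched filter: darkest disk-shaped response away from the borders
    rr = int(np.ceil(r_px))
    yy, xx = np.mgrid[-rr : rr + 1, -rr : rr + 1]
    kernel = (yy**2 + xx**2 <= r_px**2).astype(float)
    kernel /= kernel.sum()
    resp = fftconvolve(sm, kernel, mode="same")
    margin = int(np.ceil(0.8 * r_px))
    interior = np.full_like(resp, np.inf)
    if 2 * margin >= min(ny, nx):
        raise DetectionFailureError("image too small for the expected radius")
    interior[margin:-margin, margin:-margin] = resp[margin:-margin, margin:-margin]
    cy0, cx0 = np.unravel_index(np.argmin(interior), resp.shape)
    center = np.array([cy0, cx0], dtype=float)

    # refine center and radius: radial edge (max outward gradient) per ray,
    # then least-squares circle fit, iterated
    angles = np.linspace(0, 2 * np.pi, 72, endpoint=False)
    radii_s = np.arange(0.4 * r_px, 1.6 * r_px, 0.25)
    fit_r = r_px
    for _ in range(3):
        ys = center[0] + radii_s[None, :] * np.sin(angles)[:, None]
        xs = center[1] + radii_s[None, :] * np.cos(angles)[:, None]
        prof = map_coordinates(sm, [ys, xs], order=1, mode="nearest")
        grad = np.gradient(prof, axis=1)
        peak = np.argmax(grad, axis=1)
        strength = grad[np.arange(len(angles)), peak]
        ok = strength > 0.25 * np.median(strength)
        ok &= (peak > 0) & (peak < len(radii_s) - 1)
        if ok.sum() < len(angles) // 2:
            raise DetectionFailureError(
                "no consistent circular edge found around the candidate center"
            )
        # parabolic sub-sample refinement of each ray's edge radius
        p0 = peak[ok]
        g = grad[ok]
        num = g[np.arange(ok.sum()), p0 - 1] - g[np.arange(ok.sum()), p0 + 1]
        den = (
            g[np.arange(ok.sum()), p0 - 1]
            - 2 * g[np.arange(ok.sum()), p0]
            + g[np.arange(ok.sum()), p0 + 1]
        )
        delta = np.where(np.abs(den) > 1e-12, 0.5 * num / den, 0.0)
        r_edge = radii_s[p0] + np.clip(delta, -1, 1) * 0.25
        pts = np.column_stack(
            [
                center[0] + r_edge * np.sin(angles[ok]),
                center[1] + r_edge * np.cos(angles[ok]),
            ]
        )
        cy_f, cx_f, fit_r, fit_rms = _fit_circle(pts)
        center = np.array([cy_f, cx_f])
    if fit_rms > 0.15 * fit_r:
        raise DetectionFailureError(
            f"edge points scatter too widely for a circle "
            f"(rms {fit_rms:.1f} px on radius {fit_r:.1f} px)"
        )
    # a Gaussian-smoothed disk has its maximum radial gradient slightly
    # inside the true rim; undo the curvature bias ~ σ²/(2R)
    sig_px = smooth_um / px
    fit_r += sig_px**2 / (2 * fit_r)
    r_um = fit_r * px
    if abs(r_um - expected_radius) > radius_band * expected_radius:
        raise DetectionFailureError(
            f"fitted radius {r_um:.2f} µm outside ±{radius_band:.0%} of "
            f"expected {expected_radius} µm"
        )
    cx_um = stack.origin[0] + center[1] * px
    cy_um = stack.origin[1] + center[0] * px
    return (float(cx_um), float(cy_um)), float(r_um)
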