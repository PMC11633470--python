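"""Cylindrical decomposition, unfolded maps, and circumferential profiles.

The well's cylindrical symmetry makes tractions easiest to read in a local
orthonormal frame.  On the wall, at azimuth θ:

* ``T_n`` — normal, along (cos θ, sin θ, 0); positive = outward (extensile),
  negative = inward (contractile);
* ``T_v`` — vertical, along +z (positive = upward);
* ``T_c`` — circumferential, along (−sin θ, cos θ, 0); positive =
  counter-clockwise seen from above.

On the bottom disk, ``T_n`` is the vertical component, ``T_r`` points
radially outward (a cell pulling the rim toward the center gives negative
``T_r``), and ``T_c`` is as on the wall.

Wall maps are "unfolded" onto a regular (θ, z) rectangle by scattered
linear interpolation with the data replicated across the 0/360° seam; the
top-most band of the wall (default 1 µm) is excluded because the rounded
rim is where discretization and geometric uncertainty concentrate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import griddata

from .fem import Mesh, TractionField
from .geometry import WellGeometry

__all__ = [
    "WallComponents",
    "BottomComponents",
    "UnfoldedMap",
    "TractionProfiles",
    "decompose_wall",
    "decompose_bottom",
    "unfold_wall_map",
    "unfold_bottom_map",
    "circumferential_profile",
    "radial_profile",
    "align_profiles",
]

WALL_COMPONENTS = ("T_n", "T_v", "T_c")
BOTTOM_COMPONENTS = ("T_n", "T_r", "T_c")


@dataclass
class WallComponents:
    """Per-node wall tractions in the (normal, vertical, circumferential)
    frame, with cylindrical node coordinates."""

    theta: np.ndarray  # radians in [0, 2π)
    z: np.ndarray  # µm
    components: np.ndarray  # (n, 3) = (T_n, T_v, T_c) Pa
    node_ids: np.ndarray
    areas: np.ndarray

    def component(self, name: str) -> np.ndarray:
        return self.components[:, WALL_COMPONENTS.index(name)]


@dataclass
class BottomComponents:
    """Per-node bottom tractions in the (normal, radial, circumferential)
    frame; ``axis_degenerate`` flags nodes at r ≈ 0 where the radial and
    circumferential directions are undefined (components set to 0)."""

    r: np.ndarray  # µm
    theta: np.ndarray
    components: np.ndarray  # (n, 3) = (T_n, T_r, T_c) Pa
    node_ids: np.ndarray
    areas: np.ndarray
    axis_degenerate: np.ndarray = field(default=None)

    def component(self, name: str) -> np.ndarray:
        return self.components[:, BOTTOM_COMPONENTS.index(name)]


@dataclass
class UnfoldedMap:
    """A traction component resampled onto a regular unfolded grid.

    For a wall map the axes are θ (degrees, [0, 360)) and z (µm); for a
    bottom map they are Cartesian x and y (µm) masked to the disk (NaN
    outside).
    """

    axis0: np.ndarray
    axis1: np.ndarray
    values: np.ndarray  # (len(axis1), len(axis0)) Pa
    component: str
    excluded_band: float = 0.0

    @property
    def theta_deg(self) -> np.ndarray:
        return self.axis0

    @property
    def z(self) -> np.ndarray:
        return self.axis1


@dataclass
class TractionProfiles:
    """Circumference-averaged profile: mean ± std of one traction component
    versus z (wall) or r (bottom)."""

    component: str
    abscissa: np.ndarray  # µm
    mean: np.ndarray  # Pa
    std: np.ndarray  # Pa
    n: np.ndarray  # samples per abscissa
    weights: np.ndarray | None = None  # arc length / annulus measure
    displayed: np.ndarray | None = None  # set by align_profiles

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, float).reshape(-1)
        self.mean = np.asarray(self.mean, float).reshape(-1)
        self.std = np.asarray(self.std, float).reshape(-1)
        self.n = np.asarray(self.n).reshape(-1)
        if not (len(self.abscissa) == len(self.mean) == len(self.std) == len(self.n)):
            raise ValueError("profile arrays must have equal lengths")
        if (self.std < -1e-12).any():
            raise ValueError("std must be non-negative")


def _cyl_angles(
    nodes: np.ndarray, geometry: WellGeometry
) -> tuple[np.ndarray, np.ndarray]:
    cx, cy = geometry.center_xy
    dx, dy = nodes[:, 0] - cx, nodes[:, 1] - cy
    return np.hypot(dx, dy), np.mod(np.arctan2(dy, dx), 2 * np.pi)


def decompose_wall(
    tractions: TractionField,
    mesh: Mesh,
    geometry: WellGeometry,
    radial_tolerance: float | None = None,
) -> WallComponents:
    """Project wall-node tractions onto the local cylindrical frame.

    Nodes whose radial distance deviates from the wall cylinder by more
    than ``radial_tolerance`` (default: the top fillet radius plus half a
    bottom fillet, i.e. the filleted transition zones) are excluded with a
    warning.
    """
    if radial_tolerance is None:
        radial_tolerance = max(
            geometry.fillet_top + 0.5 * geometry.fillet_bottom, 0.25
        )
    wall_ids = mesh.group_nodes("well_wall")
    lut = {n: i for i, n in enumerate(tractions.node_ids)}
    rows = np.array([lut[n] for n in wall_ids if n in lut], dtype=int)
    ids = np.array([n for n in wall_ids if n in lut], dtype=np.int64)
    pos = mesh.nodes[ids]
    r, theta = _cyl_angles(pos, geometry)
    off = np.abs(r - geometry.radius) > radial_tolerance
    if off.any():
        warnings.warn(
            f"{off.sum()} wall nodes farther than {radial_tolerance} µm from "
            "the wall cylinder were excluded from the decomposition",
            stacklevel=2,
        )
    keep = ~off
    ids, rows, pos = ids[keep], rows[keep], pos[keep]
    r, theta = r[keep], theta[keep]
    T = tractions.tractions[rows]
    n_hat = np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
    c_hat = np.column_stack([-np.sin(theta), np.cos(theta), np.zeros_like(theta)])
    comps = np.column_stack(
        [(T * n_hat).sum(1), T[:, 2], (T * c_hat).sum(1)]
    )
    return WallComponents(
        theta=theta,
        z=pos[:, 2],
        components=comps,
        node_ids=ids,
        areas=tractions.areas[rows],
    )


def decompose_bottom(
    tractions: TractionField,
    mesh: Mesh,
    geometry: WellGeometry,
    radial_tolerance: float | None = None,
) -> BottomComponents:
    """Project bottom-disk tractions onto the (normal, radial,
    circumferential) frame.  The node at the axis (r = 0) has no defined
    radial/circumferential direction; its T_r and T_c are set to 0 and the
    node is flagged."""
    if radial_tolerance is None:
        radial_tolerance = max(geometry.fillet_bottom, 0.25)
    bot_ids = mesh.group_nodes("well_bottom")
    lut = {n: i for i, n in enumerate(tractions.node_ids)}
    rows = np.array([lut[n] for n in bot_ids if n in lut], dtype=int)
    ids = np.array([n for n in bot_ids if n in lut], dtype=np.int64)
    pos = mesh.nodes[ids]
    r, theta = _cyl_angles(pos, geometry)
    off = r > geometry.radius + radial_tolerance
    if off.any():
        warnings.warn(
            f"{off.sum()} bottom nodes outside the disk were excluded",
            stacklevel=2,
        )
    keep = ~off
    ids, rows, pos, r, theta = ids[keep], rows[keep], pos[keep], r[keep], theta[keep]
    T = tractions.tractions[rows]
    degen = r < 1e-9
    with np.errstate(invalid="ignore"):
        r_hat = np.column_stack(
            [np.cos(theta), np.sin(theta), np.zeros_like(theta)]
        )
    c_hat = np.column_stack([-np.sin(theta), np.cos(theta), np.zeros_like(theta)])
    tr = (T * r_hat).sum(1)
    tc = (T * c_hat).sum(1)
    tr[degen] = 0.0
    tc[degen] = 0.0
    comps = np.column_stack([T[:, 2], tr, tc])
    return BottomComponents(
        r=r,
        theta=theta,
        components=comps,
        node_ids=ids,
        areas=tractions.areas[rows],
        axis_degenerate=degen,
    )


def unfold_wall_map(
    wall: WallComponents,
    geometry: WellGeometry,
    component: str = "T_n",
    n_theta: int = 90,
    n_z: int = 60,
    excluded_band: float = 1.0,
) -> UnfoldedMap:
    """Interpolate one wall component onto a regular (θ, z) rectangle.

    Node values are reproduced exactly (piecewise-linear scattered
    interpolation); θ-periodicity is honored by replicating the data across
    the 0°/360° seam.  The top ``excluded_band`` µm of the wall — the
    rounded rim where discretization error peaks — is removed from the map.
    """
    if len(wall.theta) == 0:
        raise ValueError("empty wall component set")
    vals = wall.component(component)
    # the straight wall spans [bottom + bottom fillet, top]; the bottom
    # fillet band belongs to the floor decomposition
    z_lo = geometry.bottom_z + geometry.fillet_bottom
    z_hi = geometry.top_z - excluded_band
    th_deg = np.degrees(wall.theta)
    # replicate across the seam so the interpolant wraps
    th_all = np.concatenate([th_deg - 360.0, th_deg, th_deg + 360.0])
    z_all = np.tile(wall.z, 3)
    v_all = np.tile(vals, 3)
    gt = np.linspace(0.0, 360.0, n_theta, endpoint=False)
    gz = np.linspace(z_lo, z_hi, n_z)
    TT, ZZ = np.meshgrid(gt, gz)
    grid = griddata(
        np.column_stack([th_all, z_all]), v_all, (TT, ZZ), method="linear"
    )
    missing = ~np.isfinite(grid)
    if missing.any():
        grid[missing] = griddata(
            np.column_stack([th_all, z_all]),
            v_all,
            (TT[missing], ZZ[missing]),
            method="nearest",
        )
    return UnfoldedMap(
        axis0=gt, axis1=gz, values=grid, component=component,
        excluded_band=excluded_band,
    )


def unfold_bottom_map(
    bottom: BottomComponents,
    geometry: WellGeometry,
    component: str = "T_r",
    n_xy: int = 80,
) -> UnfoldedMap:
    """Rasterize one bottom component onto a Cartesian grid masked to the
    disk (NaN outside)."""
    if len(bottom.r) == 0:
        raise ValueError("empty bottom component set")
    vals = bottom.component(component)
    R = geometry.radius
    x = bottom.r * np.cos(bottom.theta)
    y = bottom.r * np.sin(bottom.theta)
    gx = np.linspace(-R, R, n_xy)
    XX, YY = np.meshgrid(gx, gx)
    grid = griddata(np.column_stack([x, y]), vals, (XX, YY), method="linear")
    rr = np.hypot(XX, YY)
    missing = ~np.isfinite(grid) & (rr <= R)
    if missing.any():
        grid[missing] = griddata(
            np.column_stack([x, y]), vals, (XX[missing], YY[missing]),
            method="nearest",
        )
    grid[rr > R] = np.nan
    return UnfoldedMap(axis0=gx, axis1=gx, values=grid, component=component)


def circumferential_profile(map_: UnfoldedMap) -> TractionProfiles:
    """Mean and sample standard deviation over θ for each z row of a wall
    map.  Row weights are the (constant) wall arc length."""
    v = map_.values
    mean = v.mean(axis=1)
    std = v.std(axis=1, ddof=1) if v.shape[1] > 1 else np.zeros(v.shape[0])
    n = np.full(v.shape[0], v.shape[1])
    w = np.full(v.shape[0], 1.0)
    return TractionProfiles(
        component=map_.component, abscissa=map_.axis1, mean=mean, std=std,
        n=n, weights=w,
    )


def radial_profile(
    bottom: BottomComponents,
    geometry: WellGeometry,
    component: str = "T_r",
    bin_width: float | None = None,
) -> TractionProfiles:
    """Circumference-averaged bottom profile versus radius, in annular bins
    of ``bin_width`` (default: the median nodal spacing)."""
    if len(bottom.r) == 0:
        raise ValueError("empty bottom component set")
    vals = bottom.component(component)
    R = geometry.radius
    if bin_width is None:
        bin_width = max(np.sqrt(np.median(bottom.areas)), R / 20)
    edges = np.arange(0.0, R + bin_width, bin_width)
    idx = np.clip(np.digitize(bottom.r, edges) - 1, 0, len(edges) - 2)
    centers, mean, std, n, w = [], [], [], [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        if not sel.any():
            continue
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        mean.append(vals[sel].mean())
        std.append(vals[sel].std(ddof=1) if sel.sum() > 1 else 0.0)
        n.append(int(sel.sum()))
        w.append(np.pi * (edges[b + 1] ** 2 - edges[b] ** 2))
    return TractionProfiles(
        component=component, abscissa=np.array(centers), mean=np.array(mean),
        std=np.array(std), n=np.array(n), weights=np.array(w),
    )


def align_profiles(profiles: list[TractionProfiles]) -> list[TractionProfiles]:
    """Align wall profiles of different depths at their lowest point.

    Each profile's abscissa is shifted so its minimum becomes 0 (distance
    above the well bottom).  Samples beyond the shortest profile's extent
    are retained but flagged ``displayed = False`` so that group statistics
    exclude them (an overhang has no cross-profile standard deviation).
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    shifted = []
    for p in profiles:
        shifted.append(
            TractionProfiles(
                component=p.component,
                abscissa=p.abscissa - p.abscissa.min(),
                mean=p.mean.copy(),
                std=p.std.copy(),
                n=p.n.copy(),
                weights=None if p.weights is None else p.weights.copy(),
            )
        )
    common = min(p.abscissa.max() for p in shifted)
    for p in shifted:
        p.displayed = p.abscissa <= common + 1e-9
    return shifted
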