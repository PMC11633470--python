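"""Volumetric PIV: block-wise 3D cross-correlation of a stack pair.

The deformed and reference stacks are tiled into interrogation boxes
(default 32 × 32 × 8 voxels).  Each box pair is zero-mean normalized and
cross-correlated by FFT; the correlation peak gives the integer voxel
displacement of the gel between the two states, refined to sub-voxel
precision by a three-point Gaussian fit per axis.  Displacements are
reported in µm at the box centers.  A normalized-median test validates the
field against spurious vectors, and a seeding diagnostic estimates the
particle count per interrogation volume — volumetric PIV error saturates
once boxes hold about four particles (0.0005 particles per voxel at the
default box size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.fft
from scipy import ndimage

from .geometry import ImageStack

__all__ = [
    "PivConfig",
    "DisplacementField",
    "piv3d",
    "subpixel_peak",
    "filter_outliers",
    "diagnose_seeding",
    "particles_per_box",
]


@dataclass(frozen=True)
class PivConfig:
    """PIV parameters.  ``box_size`` is (nx, ny, nz) voxels."""

    box_size: tuple[int, int, int] = (32, 32, 8)
    overlap_fraction: float = 0.5
    max_displacement: tuple[int, int, int] | None = None
    subpixel_method: str = "gaussian"
    centroid_positions: bool = True

    def __post_init__(self) -> None:
        bx, by, bz = self.box_size
        if bx < 8 or by < 8 or bz < 4:
            raise ValueError("box must be >= 8 voxels in xy and >= 4 in z")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.subpixel_method not in ("gaussian", "parabolic"):
            raise ValueError("subpixel_method must be 'gaussian' or 'parabolic'")

    @property
    def search_radius(self) -> tuple[int, int, int]:
        """Per-axis (x, y, z) peak-search limit in voxels."""
        if self.max_displacement is not None:
            return self.max_displacement
        return tuple(max(1, b // 4) for b in self.box_size)


@dataclass
class DisplacementField:
    """Sampled 3D displacement vectors with validity and peak quality.

    ``points`` and ``vectors`` are (N, 3) arrays of (x, y, z) µm; ``valid``
    flags usable vectors; ``quality`` is the normalized cross-correlation
    coefficient at the peak.  When produced by :func:`piv3d` the samples form
    a regular grid of logical shape ``grid_shape`` = (nz, ny, nx boxes),
    flattened in C order.
    """

    points: np.ndarray
    vectors: np.ndarray
    valid: np.ndarray
    quality: np.ndarray
    grid_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.vectors = np.asarray(self.vectors, dtype=float).reshape(-1, 3)
        self.valid = np.asarray(self.valid, dtype=bool).reshape(-1)
        self.quality = np.asarray(self.quality, dtype=float).reshape(-1)
        n = len(self.points)
        if not (len(self.vectors) == len(self.valid) == len(self.quality) == n):
            raise ValueError("points/vectors/valid/quality lengths differ")
        if self.valid.any() and not np.isfinite(self.vectors[self.valid]).all():
            raise ValueError("valid vectors must be finite")

    def __len__(self) -> int:
        return len(self.points)


def _three_point_offset(cm: float, c0: float, cp: float, method: str) -> float:
    """Sub-voxel offset of a correlation peak from its two neighbors."""
    if method == "gaussian" and cm > 0 and c0 > 0 and cp > 0:
        lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
    else:  # parabolic fallback (also used when a neighbor is <= 0)
        lm, l0, lp = cm, c0, cp
    denom = 2 * (lm - 2 * l0 + lp)
    if denom >= 0:  # not a local max in the fitted model
        return 0.0
    return float((lm - lp) / denom)


def subpixel_peak(
    correlation_volume: np.ndarray, method: str = "gaussian"
) -> tuple[np.ndarray, bool]:
    """Locate the correlation maximum with sub-voxel refinement.

    Returns ``(peak_zyx, valid)`` where ``peak_zyx`` is the fractional peak
    index (z, y, x).  A peak on the volume boundary cannot be refined and is
    flagged invalid (integer position still returned).
    """
    c = np.asarray(correlation_volume, dtype=float)
    idx = np.array(np.unravel_index(np.argmax(c), c.shape))
    on_edge = (idx == 0).any() or (idx == np.array(c.shape) - 1).any()
    if on_edge:
        return idx.astype(float), False
    out = idx.astype(float)
    for ax in range(3):
        sel_m = list(idx)
        sel_p = list(idx)
        sel_m[ax] -= 1
        sel_p[ax] += 1
        out[ax] += _three_point_offset(
            c[tuple(sel_m)], c[tuple(idx)], c[tuple(sel_p)], method
        )
    return out, True


def piv3d(
    reference: ImageStack, deformed: ImageStack, config: PivConfig | None = None
) -> DisplacementField:
    """Block-wise 3D cross-correlation PIV between two stacks.

    Each interrogation box of the reference stack is used as a template and
    correlated (FFT) against an extended search window of the deformed
    stack, ``search_radius`` voxels larger per side.  Because the template
    is fully contained in the window for every admissible lag, the
    correlation carries no finite-window overlap taper: an integer-voxel
    translation scores its exact full-energy maximum at the true lag
    (Cauchy-Schwarz), and the three-point sub-voxel fit is unbiased.

    Displacement sign convention: the returned vector is the motion of gel
    material from the reference to the deformed state, in µm.  Boxes are
    placed only fully inside the stacks; each yields one vector.  With
    ``config.centroid_positions`` (default) the vector is anchored at the
    box's reference-intensity centroid rather than its geometric center:
    beads concentrate in a thin layer on the gel surfaces, so a box
    straddling a surface reports the displacement *of* that surface, and
    the centroid anchor places the vector where the beads actually are.
    Deterministic for fixed inputs.
    """
    config = config or PivConfig()
    if reference.shape != deformed.shape:
        raise ValueError("reference and deformed stacks must share shape")
    if (
        reference.pixel_size_xy != deformed.pixel_size_xy
        or reference.z_step != deformed.z_step
    ):
        raise ValueError("stacks must share voxel calibration")
    bx, by, bz = config.box_size
    nz, ny, nx = reference.shape
    if bx > nx or by > ny or bz > nz:
        raise ValueError("interrogation box larger than the stack")
    box_zyx = (bz, by, bx)
    steps = tuple(
        max(1, int(round(b * (1 - config.overlap_fraction)))) for b in box_zyx
    )
    starts = [
        np.arange(0, dim - b + 1, s)
        for dim, b, s in zip(reference.shape, box_zyx, steps)
    ]
    grid_shape = tuple(len(s) for s in starts)
    sr = config.search_radius  # (x, y, z)
    m_zyx = (sr[2], sr[1], sr[0])
    win_zyx = tuple(b + 2 * m for b, m in zip(box_zyx, m_zyx))
    fft_shape = tuple(scipy.fft.next_fast_len(w) for w in win_zyx)

    ref = reference.data.astype(np.float64, copy=False)
    dfm = deformed.data.astype(np.float64, copy=False)

    z0, y0, x0 = np.meshgrid(*starts, indexing="ij")
    z0, y0, x0 = z0.ravel(), y0.ravel(), x0.ravel()
    nboxes = len(z0)

    vectors = np.full((nboxes, 3), np.nan)
    valid = np.zeros(nboxes, dtype=bool)
    quality = np.zeros(nboxes)
    anchor_idx = np.column_stack(
        [z0 + (bz - 1) / 2.0, y0 + (by - 1) / 2.0, x0 + (bx - 1) / 2.0]
    )

    # admissible lags: l in [0, 2m] per axis (displacement d = l - m)
    mask = np.zeros(fft_shape, dtype=bool)
    mask[: 2 * m_zyx[0] + 1, : 2 * m_zyx[1] + 1, : 2 * m_zyx[2] + 1] = True
    # ones-box kernel for per-lag patch sums (ZNCC normalization)
    kern = np.zeros(fft_shape)
    kern[:bz, :by, :bx] = 1.0
    fk = np.conj(scipy.fft.rfftn(kern))
    n_box = float(bz * by * bx)

    chunk = max(1, int(2**23 // np.prod(fft_shape)))  # bound FFT memory
    dims = (nz, ny, nx)
    for lo in range(0, nboxes, chunk):
        hi = min(lo + chunk, nboxes)
        m = hi - lo
        a = np.empty((m,) + box_zyx)
        bwin = np.zeros((m,) + win_zyx)
        for k in range(m):
            i = lo + k
            s = (z0[i], y0[i], x0[i])
            a[k] = ref[
                s[0] : s[0] + bz, s[1] : s[1] + by, s[2] : s[2] + bx
            ]
            # search window [s - m, s + b + m), clipped to the stack and
            # zero-padded so the lag origin stays fixed
            sl_src, sl_dst = [], []
            for ax in range(3):
                w0 = s[ax] - m_zyx[ax]
                w1 = s[ax] + box_zyx[ax] + m_zyx[ax]
                c0, c1 = max(w0, 0), min(w1, dims[ax])
                sl_src.append(slice(c0, c1))
                sl_dst.append(slice(c0 - w0, c1 - w0))
            bwin[k][tuple(sl_dst)] = dfm[tuple(sl_src)]
        if config.centroid_positions:
            w = np.clip(a, 0.0, None)
            wsum = w.sum(axis=(1, 2, 3))
            ok_w = wsum > 0
            for ax, idx0 in ((0, z0), (1, y0), (2, x0)):
                axes = tuple(d for d in (1, 2, 3) if d != ax + 1)
                prof = w.sum(axis=axes)  # (m, box_zyx[ax])
                cen = (prof * np.arange(box_zyx[ax])).sum(axis=1)
                cen = np.where(ok_w, cen / np.maximum(wsum, 1e-300), 0.0)
                anchor_idx[lo:hi, ax] = np.where(
                    ok_w, idx0[lo:hi] + cen, anchor_idx[lo:hi, ax]
                )
        # zero-mean template: the window's DC offset then cancels exactly
        a -= a.mean(axis=(1, 2, 3), keepdims=True)
        na = np.sqrt((a**2).sum(axis=(1, 2, 3)))
        fa = scipy.fft.rfftn(a, s=fft_shape, axes=(1, 2, 3))
        fb = scipy.fft.rfftn(bwin, s=fft_shape, axes=(1, 2, 3))
        corr = scipy.fft.irfftn(
            np.conj(fa) * fb, s=fft_shape, axes=(1, 2, 3)
        )
        # zero-normalized cross-correlation: divide each lag by the
        # contrast energy of the deformed patch it aligns with, so the
        # peak is scale-invariant (identical content scores exactly 1)
        fb2 = scipy.fft.rfftn(bwin**2, s=fft_shape, axes=(1, 2, 3))
        s1 = scipy.fft.irfftn(fk[None] * fb, s=fft_shape, axes=(1, 2, 3))
        s2 = scipy.fft.irfftn(fk[None] * fb2, s=fft_shape, axes=(1, 2, 3))
        var = np.maximum(s2 - s1**2 / n_box, 0.0)
        denom = np.sqrt(var) * np.maximum(na, 1e-300)[:, None, None, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            ncc = np.where(denom > 0, corr / denom, -np.inf)
        corr_m = np.where(mask[None], ncc, -np.inf)
        peaks = corr_m.reshape(m, -1).argmax(axis=1)
        pk = np.array(np.unravel_index(peaks, fft_shape)).T  # (m, 3) zyx
        d_int = pk - np.array(m_zyx)
        ok_k = (na > 0) & (np.abs(d_int) < np.array(m_zyx)).all(axis=1)

        # symmetric refinement: re-extract the deformed box at the integer
        # offset; identical content then gives exactly zero refinement, and
        # the overlap taper of the three-point values is divided out
        b2 = np.zeros((m,) + box_zyx)
        for k in np.flatnonzero(ok_k):
            i = lo + k
            s = (z0[i] + d_int[k, 0], y0[i] + d_int[k, 1], x0[i] + d_int[k, 2])
            sl_src, sl_dst = [], []
            for ax in range(3):
                c0, c1 = max(s[ax], 0), min(s[ax] + box_zyx[ax], dims[ax])
                sl_src.append(slice(c0, c1))
                sl_dst.append(slice(c0 - s[ax], c1 - s[ax]))
            b2[k][tuple(sl_dst)] = dfm[tuple(sl_src)]
        b2 -= b2.mean(axis=(1, 2, 3), keepdims=True)
        nb = np.sqrt((b2**2).sum(axis=(1, 2, 3)))
        c0v = (a * b2).sum(axis=(1, 2, 3))
        frac = np.zeros((m, 3))
        ok_ax = np.ones(m, dtype=bool)
        for ax in range(3):
            slm_a = [slice(None)] * 4
            slm_b = [slice(None)] * 4
            slm_a[ax + 1] = slice(1, None)
            slm_b[ax + 1] = slice(None, -1)
            cm = (a[tuple(slm_a)] * b2[tuple(slm_b)]).sum(axis=(1, 2, 3))
            cp = (a[tuple(slm_b)] * b2[tuple(slm_a)]).sum(axis=(1, 2, 3))
            env = 1.0 - 1.0 / box_zyx[ax]  # overlap taper of a one-voxel lag
            cm, cp = cm / env, cp / env
            for k in np.flatnonzero(ok_k):
                f = _three_point_offset(
                    cm[k], c0v[k], cp[k], config.subpixel_method
                )
                if not np.isfinite(f) or abs(f) >= 1:
                    ok_ax[k] = False
                else:
                    frac[k, ax] = f
        ok_k &= ok_ax
        lag = d_int + frac
        sel = np.flatnonzero(ok_k)
        vectors[lo + sel, 0] = lag[sel, 2] * reference.pixel_size_xy
        vectors[lo + sel, 1] = lag[sel, 1] * reference.pixel_size_xy
        vectors[lo + sel, 2] = lag[sel, 0] * reference.z_step
        valid[lo + sel] = True
        denom = np.maximum(na * nb, 1e-300)
        quality[lo + sel] = np.where(
            nb[sel] > 0, c0v[sel] / denom[sel], 0.0
        )

    points = reference.voxel_to_um(anchor_idx)
    vectors[~valid] = 0.0
    return DisplacementField(
        points=points,
        vectors=vectors,
        valid=valid,
        quality=quality,
        grid_shape=grid_shape,
    )


def filter_outliers(
    field: DisplacementField,
    window: int = 1,
    threshold: float = 2.0,
    eps: float = 0.02,
) -> DisplacementField:
    """Normalized-median validation of a gridded displacement field.

    For each valid vector, the residual to the median of its neighbors
    (within ``window`` grid steps), normalized by the median absolute
    neighbor fluctuation plus ``eps`` (µm), is compared to ``threshold``
    per component.  Failing vectors are invalidated and their values
    replaced by the neighborhood median.  A field with no outliers is
    returned unchanged.
    """
    if len(field) == 0:
        raise ValueError("field is empty")
    if field.grid_shape is None:
        raise ValueError("outlier filtering requires a gridded field")
    if not field.valid.any():
        raise ValueError("all vectors invalid; nothing to filter")
    gz, gy, gx = field.grid_shape
    u = field.vectors.reshape(gz, gy, gx, 3).copy()
    ok = field.valid.reshape(gz, gy, gx).copy()
    u_nan = np.where(ok[..., None], u, np.nan)

    w = window
    pad = np.pad(
        u_nan, ((w, w), (w, w), (w, w), (0, 0)), constant_values=np.nan
    )
    shifts = []
    for dz in range(-w, w + 1):
        for dy in range(-w, w + 1):
            for dx in range(-w, w + 1):
                if dz == dy == dx == 0:
                    continue
                shifts.append(
                    pad[
                        w + dz : w + dz + gz,
                        w + dy : w + dy + gy,
                        w + dx : w + dx + gx,
                    ]
                )
    nb = np.stack(shifts)  # (n_nb, gz, gy, gx, 3)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(nb, axis=0)
        spread = np.nanmedian(np.abs(nb - med[None]), axis=0)
        resid = np.abs(u - med) / (spread + eps)
    has_nb = np.isfinite(med).all(axis=-1)
    bad = ok & has_nb & (np.nan_to_num(resid, nan=0.0) > threshold).any(axis=-1)
    u[bad] = med[bad]
    ok[bad] = False
    return replace(
        field,
        vectors=u.reshape(-1, 3),
        valid=ok.reshape(-1),
        quality=field.quality.copy(),
    )


def estimate_noise_sd(field: DisplacementField, window: int = 1) -> float:
    """Robust per-component displacement noise estimate (µm).

    Uses the median absolute deviation of each vector from its
    neighborhood median (×1.4826 for Gaussian consistency), averaged over
    components.  Smooth field variation contributes little because the
    neighborhood median tracks it; the estimate reflects the random
    vector-to-vector scatter.
    """
    if field.grid_shape is None:
        raise ValueError("noise estimation requires a gridded field")
    gz, gy, gx = field.grid_shape
    u = np.where(
        field.valid[:, None], field.vectors, np.nan
    ).reshape(gz, gy, gx, 3)
    w = window
    pad = np.pad(u, ((w, w), (w, w), (w, w), (0, 0)), constant_values=np.nan)
    shifts = [
        pad[w + dz : w + dz + gz, w + dy : w + dy + gy, w + dx : w + dx + gx]
        for dz in range(-w, w + 1)
        for dy in range(-w, w + 1)
        for dx in range(-w, w + 1)
        if not (dz == dy == dx == 0)
    ]
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(np.stack(shifts), axis=0)
        resid = np.abs(u - med)
        sd = 1.4826 * np.nanmedian(resid, axis=(0, 1, 2))
    sd = sd[np.isfinite(sd)]
    if sd.size == 0:
        raise ValueError("no valid vectors for noise estimation")
    return float(sd.mean())


def particles_per_box(
    density_per_voxel: float, box_size: tuple[int, int, int] = (32, 32, 8)
) -> float:
    """Arithmetic seeding rule: density (voxel⁻¹) × box voxel count."""
    return float(density_per_voxel * np.prod(box_size))


def diagnose_seeding(
    stack: ImageStack,
    config: PivConfig | None = None,
    threshold_rel: float = 0.15,
) -> float:
    """Estimate particles per interrogation volume by local-maximum counting.

    Beads are detected as 3D local intensity maxima above
    ``threshold_rel × max``; the count is divided by the number of
    non-overlapping boxes tiling the detected region.  Returns 0 for an
    empty (constant) stack.
    """
    config = config or PivConfig()
    bx, by, bz = config.box_size
    nz, ny, nx = stack.shape
    tz, ty, tx = (nz // bz) * bz, (ny // by) * by, (nx // bx) * bx
    if tz == 0 or ty == 0 or tx == 0:
        raise ValueError("stack smaller than one interrogation box")
    data = np.asarray(stack.data[:tz, :ty, :tx], dtype=float)
    lo, hi = data.min(), data.max()
    if hi <= lo:
        return 0.0
    thresh = lo + threshold_rel * (hi - lo)
    is_max = (data == ndimage.maximum_filter(data, size=3)) & (data > thresh)
    n_boxes = (tz // bz) * (ty // by) * (tx // bx)
    return float(is_max.sum() / n_boxes)
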