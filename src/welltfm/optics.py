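"""Optical corrections: axial focal-shift rescaling and lensing subtraction.

When the immersion medium (index n₁) and the sample (index n₂) differ in
refractive index, moving the objective by a nominal z-step Δs moves the
focal plane by a different amount Δf.  The apparent axial coordinate of
every plane in a confocal stack must therefore be rescaled before any
physical distances are computed.  The correction used here is Visser's
geometric-optics formula

    Δf = tan(arcsin(NA / n₁)) / tan(arcsin(NA / n₂)) · Δs

Separately, a cell sitting in the well acts as a weak lens (its refractive
index ≈1.36 exceeds the medium's ≈1.34), shifting the apparent positions of
beads imaged through it.  Because the well geometry is reproducible, this
artifact can be measured once (e.g. by imaging beads through a force-free,
trypsinized cell) and subtracted from every measured displacement field
before traction computation.

Fixed correction order in the pipeline: Visser rescale of the z-grid →
PIV → lensing subtraction → inverse solve.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import LinearNDInterpolator

from .errors import CoverageError
from .geometry import ImageStack
from .piv import DisplacementField

__all__ = [
    "OpticalParams",
    "visser_focal_shift",
    "axial_scale",
    "apply_visser",
    "lensing_correction",
]


@dataclass(frozen=True)
class OpticalParams:
    """Objective/sample optics: NA, immersion index n1, sample index n2,
    and the nominal z-step Δs in µm."""

    na: float
    n_immersion: float
    n_sample: float
    z_step_nominal: float

    def __post_init__(self) -> None:
        if self.n_immersion <= 1 or self.n_sample <= 1:
            raise ValueError("refractive indices must exceed 1")
        if not 0 < self.na < min(self.n_immersion, self.n_sample):
            raise ValueError(
                "NA must satisfy 0 < NA < min(n_immersion, n_sample); "
                "arcsin is undefined otherwise"
            )
        if self.z_step_nominal <= 0:
            raise ValueError("z_step_nominal must be positive")


def visser_focal_shift(params: OpticalParams) -> float:
    """Corrected focal z-step Δf (µm) for one nominal objective step Δs."""
    t1 = np.tan(np.arcsin(params.na / params.n_immersion))
    t2 = np.tan(np.arcsin(params.na / params.n_sample))
    return float(t1 / t2 * params.z_step_nominal)


def axial_scale(params: OpticalParams) -> float:
    """Dimensionless Δf/Δs by which apparent z-coordinates are stretched."""
    return visser_focal_shift(params) / params.z_step_nominal


def apply_visser(stack: ImageStack, params: OpticalParams) -> ImageStack:
    """Rescale a stack's axial calibration from nominal to true focal steps.

    Intensities are untouched; only ``z_step`` and the z of ``origin`` are
    multiplied by Δf/Δs, so all downstream geometry sees physical µm.
    """
    s = axial_scale(params)
    ox, oy, oz = stack.origin
    return ImageStack(
        data=stack.data,
        pixel_size_xy=stack.pixel_size_xy,
        z_step=stack.z_step * s,
        origin=(ox, oy, oz * s),
    )


def lensing_correction(
    field: DisplacementField, calibration: DisplacementField
) -> DisplacementField:
    """Subtract a measured lensing-artifact field from a displacement field.

    The calibration field (displacements that persist with zero true force,
    e.g. PIV of a trypsinized-cell pair) is linearly interpolated at every
    valid sample point of ``field`` and subtracted component-wise.  Validity
    masks propagate; points outside the calibration's convex hull raise
    :class:`CoverageError`.
    """
    cal_pts = calibration.points[calibration.valid]
    cal_vec = calibration.vectors[calibration.valid]
    if len(cal_pts) < 4:
        raise CoverageError("calibration field has fewer than 4 valid samples")
    interp = LinearNDInterpolator(cal_pts, cal_vec)
    out = field.vectors.copy()
    valid = field.valid.copy()
    targets = field.points[valid]
    cal_at = interp(targets)
    missing = ~np.isfinite(cal_at).all(axis=1)
    if missing.any():
        pts = targets[missing][:5]
        raise CoverageError(
            f"calibration does not cover {missing.sum()} valid points, "
            f"e.g. {np.round(pts, 3).tolist()}"
        )
    out[valid] = out[valid] - cal_at
    return replace(field, vectors=out, valid=valid, quality=field.quality.copy())
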