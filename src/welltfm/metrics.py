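"""Per-well summary metrics: mean tractions, homogeneity, SNR, net force,
contact area and cell volume.

Sign conventions follow the cylindrical decomposition: a negative mean
``T_n``-wall means the cell pulls the wall inward (contractile), a positive
mean means it pushes outward (extensile).  Forces integrate tractions over
lumped nodal areas; with tractions in Pa and areas in µm², 1 Pa·µm² = 1 pN,
reported in nN.
"""

from __future__ import annotations

import numpy as np

from .errors import UndefinedMetricError
from .fem import TractionField
from .geometry import WellGeometry
from .unfold import TractionProfiles

__all__ = [
    "mean_traction",
    "coefficient_of_variation",
    "snr",
    "net_force",
    "contact_area",
    "cell_volume",
]

PN_PER_NN = 1e3


def _profile_weights(profile: TractionProfiles, weights) -> np.ndarray:
    if weights is not None:
        w = np.asarray(weights, float)
    elif profile.weights is not None:
        w = profile.weights
    else:
        w = np.ones_like(profile.mean)
    if profile.displayed is not None:
        w = np.where(profile.displayed, w, 0.0)
    return w


def mean_traction(
    profile: TractionProfiles, weights: np.ndarray | None = None
) -> float:
    """Measure-weighted mean of a signed traction profile (Pa).

    Weights default to the profile's own arc/annulus measures (equal
    weights if none were recorded), so the result approximates the surface
    average of the component.  The sign is kept: negative = contractile,
    positive = extensile for T_n-wall.
    """
    if len(profile.mean) == 0:
        raise ValueError("empty profile")
    w = _profile_weights(profile, weights)
    return float((w * profile.mean).sum() / w.sum())


def coefficient_of_variation(
    profile: TractionProfiles, mean_tolerance: float = 1e-9
) -> float:
    """Spatial homogeneity: sample std of profile values over their mean.

    Uses the (n−1) sample standard deviation of the profile's mean curve.
    Undefined (raises) when the mean is below ``mean_tolerance`` in
    magnitude; the absolute value is reported.
    """
    v = profile.mean if profile.displayed is None else profile.mean[profile.displayed]
    if len(v) == 0:
        raise ValueError("empty profile")
    m = v.mean()
    if abs(m) < mean_tolerance:
        raise UndefinedMetricError(
            f"profile mean {m:.3e} Pa below tolerance; CoV undefined"
        )
    s = v.std(ddof=1) if len(v) > 1 else 0.0
    return float(abs(s / m))


def snr(
    signal_profile: TractionProfiles, noise_profile: TractionProfiles
) -> float:
    """Signal-to-noise ratio of traction profiles.

    Ratio of the mean absolute value of the signal profile to that of the
    noise profile (e.g. an empty-well or trypsinized-cell measurement) on
    matched abscissae.  Returns ``inf`` for an identically-zero noise
    profile rather than raising.
    """
    if len(signal_profile.mean) != len(noise_profile.mean):
        raise ValueError("profiles must share abscissae (align first)")
    s = np.abs(signal_profile.mean).mean()
    n = np.abs(noise_profile.mean).mean()
    if n == 0:
        return float("inf")
    return float(s / n)


def net_force(
    tractions: TractionField,
    node_ids: np.ndarray | None = None,
    component: np.ndarray | str = "magnitude",
    sign: str | None = None,
) -> float:
    """Integrated force Σ (traction component × nodal area) in nN.

    ``component`` may be ``"magnitude"``, an axis name ``"x"/"y"/"z"``, or a
    per-node signed scalar array (e.g. a cylindrical component from the
    decomposition).  ``sign`` = ``"positive"``/``"negative"`` restricts the
    sum to nodes where the component has that sign (e.g. the extensile part
    of T_n-wall).
    """
    sel = np.ones(len(tractions.node_ids), dtype=bool)
    if node_ids is not None:
        sel = np.isin(tractions.node_ids, node_ids)
    if isinstance(component, str):
        if component == "magnitude":
            comp = np.linalg.norm(tractions.tractions, axis=1)
        else:
            comp = tractions.tractions[:, "xyz".index(component)]
    else:
        comp = np.asarray(component, float)
        if comp.shape != (len(tractions.node_ids),):
            raise ValueError("component array must have one value per node")
    if sign == "positive":
        sel &= comp > 0
    elif sign == "negative":
        sel &= comp < 0
    elif sign is not None:
        raise ValueError("sign must be 'positive', 'negative' or None")
    if not sel.any():
        raise ValueError("empty node selection for net force")
    return float((comp[sel] * tractions.areas[sel]).sum() / PN_PER_NN)


def contact_area(geometry: WellGeometry, include_fillets: bool = True) -> float:
    """Cell–gel contact area of the well (µm²): wall plus closed bottom.

    With zero fillets this is 2πR·depth + πR².  With fillets the flat floor
    shrinks to radius R − f_b, the straight wall to depth − f_b − f_t, and
    the two toroidal transition bands (areas by Pappus' theorem) are added.
    """
    R, d = geometry.radius, geometry.depth
    fb = geometry.fillet_bottom if include_fillets else 0.0
    ft = geometry.fillet_top if include_fillets else 0.0
    wall = 2 * np.pi * R * (d - fb - ft)
    floor = np.pi * (R - fb) ** 2
    arc_b = 2 * np.pi * fb * ((R - fb) * np.pi / 2 + fb) if fb > 0 else 0.0
    arc_t = 2 * np.pi * ft * ((R + ft) * np.pi / 2 - ft) if ft > 0 else 0.0
    return float(wall + floor + arc_b + arc_t)


def cell_volume(geometry: WellGeometry, include_fillets: bool = False) -> float:
    """Volume of the well cavity ≈ cell volume (µm³).

    The default is the cylinder approximation πR²·depth used when reporting
    cell volumes; ``include_fillets`` applies the exact fillet corrections
    (the bottom fillet removes material, the top fillet adds the flared
    rim).
    """
    R, d = geometry.radius, geometry.depth
    v = np.pi * R**2 * d
    if not include_fillets:
        return float(v)
    fb, ft = geometry.fillet_bottom, geometry.fillet_top
    if fb > 0:
        # material removed between the sharp corner and the bottom arc
        zz = np.linspace(0.0, fb, 257)
        r_arc = (R - fb) + np.sqrt(np.maximum(fb**2 - (fb - zz) ** 2, 0.0))
        v -= np.trapezoid(np.pi * (R**2 - r_arc**2), zz)
    if ft > 0:
        zz = np.linspace(0.0, ft, 257)  # distance below the gel top
        r_arc = (R + ft) - np.sqrt(np.maximum(ft**2 - (ft - zz) ** 2, 0.0))
        v += np.trapezoid(np.pi * (r_arc**2 - R**2), zz)
    return float(v)
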