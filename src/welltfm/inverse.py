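"""Traction reconstruction from measured surface displacements.

The unknowns are nodal traction vectors on the well wall and well bottom;
the gel top surface is constrained traction-free *by construction* (its
traction degrees of freedom are simply not part of the unknown set), while
measured displacements on the gel top still enter the data misfit.  The
constrained optimization

    min_T  Σᵢ wᵢ ‖u_model(xᵢ) − u_meas(xᵢ)‖²  +  λ Σⱼ aⱼ ‖Tⱼ‖²
    s.t.   u_model = Forward(T)   (discrete mechanical equilibrium)

is reduced to an unconstrained linear least-squares problem by eliminating
u through the forward elastic operator: each traction degree of freedom has
a precomputed displacement sensitivity column (one sparse solve with the
factorized stiffness).  The weights wᵢ and penalty weights aⱼ are lumped
nodal areas, so both terms approximate surface integrals.  With λ = 0 and
noiseless forward-consistent data the reconstruction is exact up to
discretization; with noisy data λ can be chosen automatically by the
discrepancy principle against the estimated displacement noise.

The direct alternative — imposing the measured displacements as essential
boundary conditions everywhere — is also provided (:func:`direct_dirichlet_solve`)
as a diagnostic: it leaks the measurement noise into spurious tractions on
the gel top, which is precisely what the inverse formulation avoids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

from .errors import ConfigError, CoverageError, SolverError
from .fem import (
    MaterialModel,
    Mesh,
    TractionField,
    assemble_stiffness,
    base_fixed_dofs,
    lumped_node_areas,
    nodal_force_to_traction,
    surface_mass_matrix,
    traction_to_loads,
)
from .piv import DisplacementField

__all__ = [
    "InverseConfig",
    "SurfaceDisplacements",
    "InverseResult",
    "InverseOperator",
    "interpolate_measured_to_surface",
    "solve_inverse",
    "direct_dirichlet_solve",
    "misfit",
]

MEASURED_GROUPS = ("gel_top", "well_wall", "well_bottom")
TRACTION_GROUPS = ("well_wall", "well_bottom")


@dataclass(frozen=True)
class InverseConfig:
    """Free parameters of the inverse solve.

    ``regularization_lambda`` scales the area-weighted Tikhonov penalty on
    traction magnitude (λ = 0 reproduces consistent data exactly up to
    discretization); ``"auto"`` selects λ by the discrepancy principle and
    requires ``noise_sd``.  ``solver_tol`` is the relative cutoff for small
    singular values in the λ = 0 least-squares solve.
    """

    regularization_lambda: float | str = 0.0
    noise_sd: float | None = None
    solver_tol: float = 1e-10
    max_basis: int | None = None

    def __post_init__(self) -> None:
        lam = self.regularization_lambda
        if isinstance(lam, str):
            if lam not in ("auto", "lcurve"):
                raise ConfigError(
                    "regularization_lambda must be >= 0, 'auto' or 'lcurve'"
                )
            if lam == "auto" and self.noise_sd is not None and self.noise_sd <= 0:
                raise ConfigError("'auto' regularization requires noise_sd > 0")
        elif lam < 0:
            raise ConfigError("regularization_lambda must be >= 0")
        if self.solver_tol <= 0:
            raise ConfigError("solver_tol must be positive")


@dataclass
class SurfaceDisplacements:
    """Measured displacements interpolated onto mesh surface nodes."""

    node_ids: np.ndarray
    displacements: np.ndarray  # (n, 3) µm
    extrapolated: np.ndarray  # flags nodes outside the measurement hull

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64).reshape(-1)
        self.displacements = np.asarray(self.displacements, float).reshape(-1, 3)
        self.extrapolated = np.asarray(self.extrapolated, bool).reshape(-1)


@dataclass
class InverseResult:
    traction: TractionField
    model_displacement: np.ndarray  # (N, 3) µm at all mesh nodes
    misfit: float
    regularization_lambda: float


def interpolate_measured_to_surface(
    field: DisplacementField,
    mesh: Mesh,
    groups: tuple[str, ...] = MEASURED_GROUPS,
) -> SurfaceDisplacements:
    """Interpolate a scattered displacement field onto mesh surface nodes.

    Linear simplex interpolation of each component; surface nodes outside
    the convex hull of the measurements take the nearest sample's value and
    are flagged ``extrapolated``.
    """
    pts = field.points[field.valid]
    vec = field.vectors[field.valid]
    if len(pts) < 4:
        raise CoverageError("need at least 4 valid displacement samples")
    ids = mesh.group_nodes(*groups)
    targets = mesh.nodes[ids]
    lin = LinearNDInterpolator(pts, vec)
    out = lin(targets)
    extrap = ~np.isfinite(out).all(axis=1)
    if extrap.any():
        nn = NearestNDInterpolator(pts, vec)
        out[extrap] = nn(targets[extrap])
    return SurfaceDisplacements(node_ids=ids, displacements=out, extrapolated=extrap)


def misfit(
    model: np.ndarray, measured: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Area-weighted squared displacement residual Σ wᵢ‖Δuᵢ‖² (µm²·µm²)."""
    model = np.asarray(model, float)
    measured = np.asarray(measured, float)
    if model.shape != measured.shape:
        raise ValueError(f"shape mismatch: {model.shape} vs {measured.shape}")
    d2 = ((model - measured) ** 2).sum(axis=-1)
    if weights is None:
        return float(d2.sum())
    weights = np.asarray(weights, float)
    if weights.shape != d2.shape:
        raise ValueError("weights do not match the node set")
    return float((weights * d2).sum())


class InverseOperator:
    """Precomputed sensitivity operator for repeated inverse solves.

    Building the operator factorizes the stiffness matrix once and computes
    the displacement response of every traction degree of freedom (one
    column per unknown).  ``solve`` then reduces to a dense least-squares
    problem, so sweeping λ, noise levels or datasets is cheap.
    """

    def __init__(
        self,
        mesh: Mesh,
        material: MaterialModel,
        K=None,
        traction_groups: tuple[str, ...] = TRACTION_GROUPS,
        measured_groups: tuple[str, ...] = MEASURED_GROUPS,
        chunk: int = 192,
    ) -> None:
        self.mesh = mesh
        self.material = material
        self.traction_groups = traction_groups
        self.measured_groups = measured_groups
        if K is None:
            K = assemble_stiffness(mesh, material)
        self.K = K
        self.fixed = base_fixed_dofs(mesh)
        n = K.shape[0]
        self.free = np.ones(n, dtype=bool)
        self.free[self.fixed] = False
        self.lu = spla.splu(K[self.free][:, self.free].tocsc())

        self.t_nodes = mesh.group_nodes(*traction_groups)
        self.m_nodes = mesh.group_nodes(*measured_groups)
        self.t_areas = lumped_node_areas(mesh, traction_groups)[self.t_nodes]
        self.m_weights = lumped_node_areas(mesh, measured_groups)[self.m_nodes]
        m_dofs = (3 * self.m_nodes[:, None] + np.arange(3)).ravel()

        # unit-traction load columns come from the consistent surface mass
        # matrix: a unit traction in component c at node j loads dof (m, c)
        # with Ms[m, j]
        Ms = surface_mass_matrix(mesh, traction_groups)
        n_t = 3 * len(self.t_nodes)
        G = np.empty((len(m_dofs), n_t))
        free_idx = np.flatnonzero(self.free)
        for lo in range(0, len(self.t_nodes), chunk):
            hi = min(lo + chunk, len(self.t_nodes))
            cols = np.asarray(Ms[:, self.t_nodes[lo:hi]].todense())  # (N, k)
            k = hi - lo
            rhs = np.zeros((n, 3 * k))
            for c in range(3):
                rhs[c::3, c::3] = cols  # dof (3m+c) of column (3j+c)
            sol = self.lu.solve(rhs[self.free])
            ufull = np.zeros((n, 3 * k))
            ufull[free_idx] = sol
            G[:, 3 * lo : 3 * hi] = ufull[m_dofs]
        self.G = G
        # SVD in area-scaled variables (used for λ sweeps / auto selection)
        self._w_dof = np.repeat(self.m_weights, 3)
        self._a_dof = np.repeat(self.t_areas, 3)
        A = (np.sqrt(self._w_dof)[:, None] * G) / np.sqrt(self._a_dof)[None, :]
        self._U, self._s, self._Vt = np.linalg.svd(A, full_matrices=False)

    # -- solving ----------------------------------------------------------

    def _traction_dofs_to_field(self, t: np.ndarray) -> TractionField:
        return TractionField(
            node_ids=self.t_nodes,
            tractions=t.reshape(-1, 3),
            areas=self.t_areas,
        )

    def measured_vector(self, measured: SurfaceDisplacements) -> np.ndarray:
        order = {n: i for i, n in enumerate(measured.node_ids)}
        idx = np.array([order[n] for n in self.m_nodes])
        return measured.displacements[idx].ravel()

    def solve(
        self, measured: SurfaceDisplacements, config: InverseConfig | None = None
    ) -> InverseResult:
        config = config or InverseConfig()
        d = self.measured_vector(measured)
        b = np.sqrt(self._w_dof) * d
        lam = config.regularization_lambda
        Utb = self._U.T @ b
        if lam == "lcurve":
            lam = self._lcurve_lambda(Utb, b)
        elif lam == "auto":
            if config.noise_sd is None:
                raise ConfigError(
                    "'auto' regularization requires noise_sd (estimate it "
                    "with welltfm.piv.estimate_noise_sd)"
                )
            lam = self._discrepancy_lambda(Utb, b, config.noise_sd)
        lam = float(lam)
        if lam == 0.0:
            with np.errstate(divide="ignore"):
                filt = np.where(
                    self._s > config.solver_tol * self._s[0], 1.0 / self._s, 0.0
                )
            y = self._Vt.T @ (filt * Utb)
        else:
            filt = self._s / (self._s**2 + lam)
            y = self._Vt.T @ (filt * Utb)
        t = y / np.sqrt(self._a_dof)
        traction = self._traction_dofs_to_field(t)
        u_model = self.forward_displacement(traction)
        mis = misfit(
            u_model[self.m_nodes],
            d.reshape(-1, 3),
            self.m_weights,
        )
        return InverseResult(
            traction=traction,
            model_displacement=u_model,
            misfit=mis,
            regularization_lambda=lam,
        )

    def forward_displacement(self, traction: TractionField) -> np.ndarray:
        loads = traction_to_loads(self.mesh, traction).ravel()
        u = np.zeros(self.K.shape[0])
        u[self.free] = self.lu.solve(loads[self.free])
        return u.reshape(-1, 3)

    def _discrepancy_lambda(self, Utb, b, noise_sd: float) -> float:
        """λ with residual ≈ its expectation under iid displacement noise."""
        target = 3 * noise_sd**2 * self._w_dof.sum()
        resid_perp = float(b @ b - Utb @ Utb)  # component outside range(A)

        def resid(lam: float) -> float:
            r = (lam / (self._s**2 + lam)) * Utb
            return resid_perp + float(r @ r)

        if resid(0.0) >= target:
            return 0.0
        lo, hi = 1e-14 * self._s[0] ** 2, 1e4 * self._s[0] ** 2
        for _ in range(80):
            mid = np.sqrt(lo * hi)
            if resid(mid) < target:
                lo = mid
            else:
                hi = mid
        return float(np.sqrt(lo * hi))

    def _lcurve_lambda(self, Utb, b) -> float:
        """L-curve corner: λ maximizing the curvature of
        (log residual norm, log solution norm) over a λ sweep."""
        s2 = self._s**2
        resid_perp = float(b @ b - Utb @ Utb)
        lams = np.logspace(
            np.log10(s2.min()) - 3, np.log10(s2.max()) + 1, 120
        )
        rho = np.empty_like(lams)
        eta = np.empty_like(lams)
        for i, lam in enumerate(lams):
            r = (lam / (s2 + lam)) * Utb
            y = (self._s / (s2 + lam)) * Utb
            rho[i] = resid_perp + r @ r
            eta[i] = y @ y
        x = np.log(np.maximum(rho, 1e-300)) / 2
        y = np.log(np.maximum(eta, 1e-300)) / 2
        t = np.log(lams)
        dx, dy = np.gradient(x, t), np.gradient(y, t)
        d2x, d2y = np.gradient(dx, t), np.gradient(dy, t)
        with np.errstate(divide="ignore", invalid="ignore"):
            kappa = (dx * d2y - dy * d2x) / np.power(dx**2 + dy**2, 1.5)
        kappa[:3] = kappa[-3:] = -np.inf
        kappa[~np.isfinite(kappa)] = -np.inf
        return float(lams[int(np.argmax(kappa))])


def solve_inverse(
    mesh: Mesh,
    material: MaterialModel,
    measured: SurfaceDisplacements,
    config: InverseConfig | None = None,
    operator: InverseOperator | None = None,
) -> InverseResult:
    """Reconstruct well-surface tractions from measured surface displacements.

    See :class:`InverseOperator`; building the operator dominates the cost,
    so pass one explicitly when solving repeatedly on the same mesh.
    """
    if operator is None:
        operator = InverseOperator(mesh, material)
    return operator.solve(measured, config)


def direct_dirichlet_solve(
    mesh: Mesh,
    material: MaterialModel,
    measured: SurfaceDisplacements,
    K=None,
) -> TractionField:
    """Impose measured displacements as essential BCs and return the
    boundary reactions as tractions (diagnostic).

    All measured surfaces — including the gel top — are constrained, so any
    inconsistency (noise) in the data surfaces as non-zero gel-top
    tractions; compare with the inverse approach, whose gel-top tractions
    vanish identically.
    """
    if K is None:
        K = assemble_stiffness(mesh, material)
    n = K.shape[0]
    base = base_fixed_dofs(mesh)
    mdofs = (3 * measured.node_ids[:, None] + np.arange(3)).ravel()
    fixed = np.concatenate([base, mdofs])
    vals = np.concatenate([np.zeros(base.size), measured.displacements.ravel()])
    # deduplicate (a measured node cannot also be a base node by construction)
    fixed, first = np.unique(fixed, return_index=True)
    vals = vals[first]
    free = np.ones(n, dtype=bool)
    free[fixed] = False
    u = np.zeros(n)
    u[fixed] = vals
    rhs = -K[:, fixed][free] @ vals
    if free.sum() == 0:
        raise SolverError("no free dofs in direct Dirichlet solve")
    u[free] = spla.splu(K[free][:, free].tocsc()).solve(rhs)
    r = (K @ u).reshape(-1, 3)
    groups = MEASURED_GROUPS
    return nodal_force_to_traction(
        mesh, measured.node_ids, r[measured.node_ids], groups=groups
    )
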