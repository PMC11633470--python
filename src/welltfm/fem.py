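"""Tetrahedral FEM for the gel-with-well: meshing and the forward problem.

The solid is a square gel prism bonded to glass at its base, with a
cylindrical cavity (the well) opening on its top face; the cavity rims are
rounded by fillets.  The mesh is a boundary-fitted structured grid built in
cylindrical logical coordinates — an inner disk region below the cavity and
an outer annular region graded out to the square lateral boundary — whose
prisms are subdivided into linear tetrahedra with a globally conforming
minimum-node-index diagonal rule.  Surface facets are classified
geometrically into the groups ``base`` (glass), ``lateral``, ``gel_top``,
``well_wall`` and ``well_bottom``.

Elasticity is solved in small strain by default (polyacrylamide is linear
elastic over the strains cells impose); a compressible Neo-Hookean law with
Newton iteration is available for consistency checks at larger loads.
Internal unit system: µm, Pa, pN (1 Pa·µm² = 1 pN), which keeps all matrix
entries near unity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .errors import MeshingError, SolverError
from .geometry import WellGeometry

__all__ = [
    "Mesh",
    "MaterialModel",
    "TractionField",
    "build_mesh",
    "box_mesh",
    "assemble_stiffness",
    "solve_forward",
    "solve_linear",
    "traction_to_loads",
    "nodal_force_to_traction",
    "lumped_node_areas",
    "facet_areas",
    "interpolate_nodal_field",
]

SURFACE_GROUPS = ("gel_top", "well_wall", "well_bottom", "base", "lateral")


# --------------------------------------------------------------------------
# data types
# --------------------------------------------------------------------------


@dataclass
class Mesh:
    """Linear tetrahedral mesh with labeled boundary facet groups."""

    nodes: np.ndarray  # (N, 3) µm
    tets: np.ndarray  # (M, 4) int, positively oriented
    surface_groups: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def group_nodes(self, *names: str) -> np.ndarray:
        """Sorted unique node ids appearing in the named facet groups."""
        ids = [self.surface_groups[n].ravel() for n in names]
        return np.unique(np.concatenate(ids)) if ids else np.empty(0, int)

    def volumes(self) -> np.ndarray:
        p = self.nodes[self.tets]
        return _signed_volumes(p)

    def boundary_facets(self) -> np.ndarray:
        return np.vstack(list(self.surface_groups.values()))


@dataclass(frozen=True)
class MaterialModel:
    """Isotropic gel material: Young's modulus (Pa), Poisson ratio, law tag."""

    youngs_modulus: float = 15000.0
    poisson_ratio: float = 0.45
    law: str = "linear"

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not -1 < self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must be in (-1, 0.5)")
        if self.law not in ("linear", "neo_hookean"):
            raise ValueError("law must be 'linear' or 'neo_hookean'")

    @property
    def lame(self) -> tuple[float, float]:
        E, nu = self.youngs_modulus, self.poisson_ratio
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        return lam, mu


@dataclass
class TractionField:
    """Traction vectors (Pa) at surface nodes, with lumped nodal areas (µm²)."""

    node_ids: np.ndarray
    tractions: np.ndarray
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64).reshape(-1)
        self.tractions = np.asarray(self.tractions, dtype=float).reshape(-1, 3)
        self.areas = np.asarray(self.areas, dtype=float).reshape(-1)
        if not (len(self.node_ids) == len(self.tractions) == len(self.areas)):
            raise ValueError("node_ids/tractions/areas lengths differ")
        if not np.isfinite(self.tractions).all():
            raise ValueError("tractions must be finite")
        if len(self.areas) and not (self.areas > 0).all():
            raise ValueError("nodal areas must be positive")

    @classmethod
    def from_function(cls, mesh: Mesh, groups: tuple[str, ...], fn) -> "TractionField":
        """Sample a traction function T(x) -> (N,3) Pa at the group nodes."""
        ids = mesh.group_nodes(*groups)
        areas = lumped_node_areas(mesh, groups)[ids]
        return cls(node_ids=ids, tractions=fn(mesh.nodes[ids]), areas=areas)

    def total_force(self) -> np.ndarray:
        """Integrated force Σ T·a in pN."""
        return (self.tractions * self.areas[:, None]).sum(axis=0)


# --------------------------------------------------------------------------
# mesh generation
# --------------------------------------------------------------------------


def _signed_volumes(p: np.ndarray) -> np.ndarray:
    d = p[:, 1:] - p[:, :1]
    return np.einsum("ij,ij->i", d[:, 0], np.cross(d[:, 1], d[:, 2])) / 6.0


def _graded_steps(total: float, h0: float, growth: float = 1.35) -> np.ndarray:
    """Monotone positions 0..total with spacing h0 at 0, growing geometrically."""
    if total <= h0:
        return np.array([0.0, total])
    steps = [h0]
    while sum(steps) < total:
        steps.append(steps[-1] * growth)
    steps = np.array(steps) * (total / sum(steps))
    return np.concatenate([[0.0], np.cumsum(steps)])


def _split_prism(b0, b1, b2, t0, t1, t2, out: list) -> None:
    """Tetrahedralize a prism with quad-face diagonals through each face's
    minimum global node id (globally conforming)."""
    ids = (b0, b1, b2, t0, t1, t2)
    m = int(np.argmin(ids))
    bot, top = [b0, b1, b2], [t0, t1, t2]
    if m >= 3:
        bot, top = top, bot
        m -= 3
    bot = bot[m:] + bot[:m]
    top = top[m:] + top[:m]
    a0, a1, a2 = bot
    a3, a4, a5 = top
    # faces (a0,a1,a4,a3) and (a2,a0,a3,a5) take diagonals a0-a4, a0-a5;
    # the third face (a1,a2,a5,a4) takes the diagonal through its min node
    if min(a1, a5) < min(a2, a4):
        out.append((a0, a1, a2, a5))
        out.append((a0, a1, a5, a4))
        out.append((a0, a4, a5, a3))
    else:
        out.append((a0, a1, a2, a4))
        out.append((a0, a4, a2, a5))
        out.append((a0, a4, a5, a3))


def _extract_boundary(tets: np.ndarray) -> np.ndarray:
    faces = np.concatenate(
        [tets[:, c] for c in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3))]
    )
    key = np.sort(faces, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return faces[idx[counts == 1]]


def _arc_params(fillet: float, h: float) -> np.ndarray:
    """Interior arc angles resolving a fillet to chordal error <= h/4."""
    if fillet <= 0:
        return np.empty(0)
    sag = min(h / (4 * fillet), 1.0)
    phi_max = 2 * np.arccos(1 - sag)
    n_seg = max(2, int(np.ceil((np.pi / 2) / max(phi_max, 1e-6))))
    return np.linspace(0, np.pi / 2, n_seg + 1)[1:-1]


def build_mesh(geometry: WellGeometry, target_edge_length: float) -> Mesh:
    """Boundary-fitted tet mesh of the gel prism with its filleted cavity.

    ``target_edge_length`` (µm) sets the resolution near the well; element
    size grows geometrically toward the remote lateral and base boundaries.
    Fillet arcs are resolved to a chordal error below a quarter edge length.
    """
    h = float(target_edge_length)
    if not 0 < h < geometry.radius / 2:
        raise MeshingError(
            f"target_edge_length must be in (0, radius/2); got {h} for "
            f"radius {geometry.radius}"
        )
    R, fb, ft = geometry.radius, geometry.fillet_bottom, geometry.fillet_top
    cx, cy = geometry.center_xy
    L2 = geometry.lateral_extent / 2.0
    z_top, z_bot, z_base = geometry.top_z, geometry.bottom_z, geometry.base_z

    # --- angular discretization: multiple of 8 so rays hit the four square
    # corners exactly (otherwise the outer boundary cuts them off)
    n_theta = max(16, 8 * int(np.ceil(2 * np.pi * R / h / 8)))
    thetas = 2 * np.pi * np.arange(n_theta) / n_theta

    # --- radial levels -------------------------------------------------------
    n_in_flat = max(2, int(np.ceil((R - fb) / h)))
    radii_in = list(np.linspace(0.0, R - fb, n_in_flat + 1))
    for phi in _arc_params(fb, h):
        radii_in.append((R - fb) + fb * np.sin(phi))
    radii_in.append(R)
    radii_in = np.unique(np.round(radii_in, 9))
    n_in = len(radii_in) - 1  # ring index of the wall column
    t_out = _graded_steps(1.0, h / max(L2 - R, h))
    t_out = t_out[1:]  # wall column is t=0, handled as ring n_in
    n_out = len(t_out)

    # --- vertical levels -----------------------------------------------------
    hz = min(h, (z_top - z_bot) / 6)
    low = z_bot - _graded_steps(z_bot - z_base, max(hz, 2 * fb))
    low = np.sort(low)  # ascending, ends exactly at z_bot
    k_floor = len(low) - 1
    up_start = z_bot + fb
    up_end = z_top - ft
    n_up = max(2, int(np.ceil((up_end - up_start) / hz)))
    # first linspace point (z_bot + fb) is supplied by the raised floor level
    # when fb > 0, and coincides with the floor level itself when fb == 0
    up = list(np.linspace(up_start, up_end, n_up + 1))[1:]
    for psi in _arc_params(ft, h):
        up.append(z_top - ft + ft * np.sin(psi))
    if ft > 0:
        up.append(z_top)
    levels = np.concatenate([low, np.unique(np.round(up, 9))])
    n_lev = len(levels)

    # wall radius profile r_wall(z) for levels above the floor
    def wall_radius(z: float) -> float:
        if z <= z_bot + fb:
            return R
        if ft > 0 and z > z_top - ft:
            return R + ft - np.sqrt(max(ft**2 - (z - (z_top - ft)) ** 2, 0.0))
        return R

    # cavity floor profile z_floor(r) including the bottom fillet
    def floor_z(r: float) -> float:
        if fb <= 0 or r <= R - fb:
            return z_bot
        return z_bot + fb - np.sqrt(max(fb**2 - (r - (R - fb)) ** 2, 0.0))

    r_sq = L2 / np.maximum(np.abs(np.cos(thetas)), np.abs(np.sin(thetas)))

    # --- nodes ---------------------------------------------------------------
    # ring 0 = axis; rings 1..n_in-1 inner; ring n_in = wall; rings beyond outer
    nodes: list[tuple[float, float, float]] = []
    nid: dict[tuple[int, int, int], int] = {}

    def add(ring: int, j: int, k: int, x: float, y: float, z: float) -> None:
        nid[(ring, j, k)] = len(nodes)
        nodes.append((x, y, z))

    n_rings = n_in + n_out + 1
    for k in range(n_lev):
        z = levels[k]
        inner_active = k <= k_floor
        for ring in range(n_rings):
            if ring < n_in and not inner_active:
                continue
            if ring == 0:
                zz = floor_z(0.0) if k == k_floor else z
                add(0, 0, k, cx, cy, zz)
                continue
            if ring < n_in:
                r = radii_in[ring]
                zz = floor_z(r) if k == k_floor else z
                for j in range(n_theta):
                    add(ring, j, k, cx + r * np.cos(thetas[j]),
                        cy + r * np.sin(thetas[j]), zz)
                continue
            # wall and outer rings
            rw = R if k <= k_floor else wall_radius(z)
            if k == k_floor:
                # the wall column carries the bottom-fillet arc top; the
                # raise decays to zero at the next ring outward
                zv = z_bot + fb if ring == n_in else z_bot
            else:
                zv = z
            t = 0.0 if ring == n_in else t_out[ring - n_in - 1]
            for j in range(n_theta):
                r = rw + t * (r_sq[j] - rw)
                add(ring, j, k, cx + r * np.cos(thetas[j]),
                    cy + r * np.sin(thetas[j]), zv)

    nodes_arr = np.array(nodes)

    # --- prisms --> tets -----------------------------------------------------
    tet_list: list[tuple[int, int, int, int]] = []

    def col(ring: int, j: int) -> tuple[int, int]:
        return (ring, 0 if ring == 0 else j % n_theta)

    cross_tris: list[tuple[tuple[int, int], ...]] = []
    inner_flag: list[bool] = []
    for j in range(n_theta):
        cross_tris.append((col(0, 0), col(1, j), col(1, j + 1)))
        inner_flag.append(True)
    for ring in range(1, n_rings - 1):
        inner = ring < n_in
        for j in range(n_theta):
            a, b, c, d = col(ring, j), col(ring + 1, j), col(ring + 1, j + 1), col(ring, j + 1)
            cross_tris.append((a, b, c))
            inner_flag.append(inner)
            cross_tris.append((a, c, d))
            inner_flag.append(inner)

    for k in range(n_lev - 1):
        for tri, inner in zip(cross_tris, inner_flag):
            if inner and k >= k_floor:
                continue  # cavity
            ids_b = [nid[(r, j, k)] for (r, j) in tri]
            ids_t = [nid[(r, j, k + 1)] for (r, j) in tri]
            _split_prism(*ids_b, *ids_t, tet_list)

    tets = np.array(tet_list, dtype=np.int64)

    # drop unused nodes, fix orientation
    used, inv = np.unique(tets, return_inverse=True)
    tets = inv.reshape(tets.shape)
    nodes_arr = nodes_arr[used]
    p = nodes_arr[tets]
    vols = _signed_volumes(p)
    neg = vols < 0
    tets[neg] = tets[neg][:, [0, 1, 3, 2]]
    vols = np.abs(vols)
    if (vols < 1e-12).any():
        raise MeshingError(
            f"{(vols < 1e-12).sum()} degenerate tetrahedra generated; "
            f"geometry: {geometry}"
        )

    boundary = _extract_boundary(tets)
    groups = _classify_boundary(boundary, nodes_arr, geometry)
    return Mesh(nodes=nodes_arr, tets=tets, surface_groups=groups)


def _classify_boundary(
    boundary: np.ndarray, nodes: np.ndarray, geometry: WellGeometry
) -> dict[str, np.ndarray]:
    cx, cy = geometry.center_xy
    L2 = geometry.lateral_extent / 2.0
    tol = 1e-6 * max(geometry.gel_height, geometry.lateral_extent)
    pts = nodes[boundary]  # (K, 3, 3)
    zc = pts[..., 2]
    xc = np.abs(pts[..., 0] - cx)
    yc = np.abs(pts[..., 1] - cy)
    is_base = (np.abs(zc - geometry.base_z) < tol).all(axis=1)
    is_top = (np.abs(zc - geometry.top_z) < tol).all(axis=1)
    is_lat = (np.abs(xc - L2) < tol).all(axis=1) | (np.abs(yc - L2) < tol).all(axis=1)
    is_lat &= ~is_base & ~is_top
    cavity = ~(is_base | is_top | is_lat)
    cen_z = zc.mean(axis=1)
    split = geometry.bottom_z + geometry.fillet_bottom + tol
    is_bottom = cavity & (cen_z <= split)
    is_wall = cavity & ~is_bottom
    groups = {
        "gel_top": boundary[is_top],
        "well_wall": boundary[is_wall],
        "well_bottom": boundary[is_bottom],
        "base": boundary[is_base],
        "lateral": boundary[is_lat],
    }
    return groups


def box_mesh(
    lx: float, ly: float, lz: float, nx: int, ny: int, nz: int
) -> Mesh:
    """Structured tet mesh of a box [0,lx]×[0,ly]×[0,lz].

    Boundary groups: ``base`` (z=0), ``gel_top`` (z=lz), ``lateral`` (sides).
    Useful for verification against closed-form elasticity solutions.
    """
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    nid = lambda i, j, k: (k * (ny + 1) + j) * (nx + 1) + i
    nodes = np.array(
        [(x, y, z) for z in zs for y in ys for x in xs], dtype=float
    )
    tet_list: list[tuple[int, int, int, int]] = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                c = [nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k),
                     nid(i, j + 1, k)]
                ct = [nid(i, j, k + 1), nid(i + 1, j, k + 1),
                      nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1)]
                _split_prism(c[0], c[1], c[2], ct[0], ct[1], ct[2], tet_list)
                _split_prism(c[0], c[2], c[3], ct[0], ct[2], ct[3], tet_list)
    tets = np.array(tet_list, dtype=np.int64)
    p = nodes[tets]
    vols = _signed_volumes(p)
    tets[vols < 0] = tets[vols < 0][:, [0, 1, 3, 2]]
    boundary = _extract_boundary(tets)
    pts = nodes[boundary]
    tol = 1e-9 * max(lx, ly, lz)
    is_base = (np.abs(pts[..., 2]) < tol).all(axis=1)
    is_top = (np.abs(pts[..., 2] - lz) < tol).all(axis=1)
    groups = {
        "base": boundary[is_base],
        "gel_top": boundary[is_top],
        "lateral": boundary[~is_base & ~is_top],
    }
    return Mesh(nodes=nodes, tets=tets, surface_groups=groups)


# --------------------------------------------------------------------------
# surface integrals
# --------------------------------------------------------------------------


def facet_areas(mesh: Mesh, facets: np.ndarray) -> np.ndarray:
    p = mesh.nodes[facets]
    return 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )


def lumped_node_areas(mesh: Mesh, groups: tuple[str, ...]) -> np.ndarray:
    """Per-node lumped area (one third of adjacent facet areas) over groups.

    Returns a length-N array, zero away from the named surfaces.
    """
    out = np.zeros(mesh.n_nodes)
    for g in groups:
        facets = mesh.surface_groups[g]
        if len(facets) == 0:
            continue
        areas = facet_areas(mesh, facets)
        np.add.at(out, facets.ravel(), np.repeat(areas / 3.0, 3))
    return out


def surface_mass_matrix(
    mesh: Mesh, groups: tuple[str, ...]
) -> sp.csc_matrix:
    """Scalar surface mass matrix ∫NᵢNⱼ dA = A/12 (1 + δᵢⱼ) over groups.

    Maps nodal surface values to consistent nodal integrals; (N × N),
    nonzero only on the named surfaces.
    """
    rows, cols, vals = [], [], []
    for g in groups:
        facets = mesh.surface_groups[g]
        if len(facets) == 0:
            continue
        A = facet_areas(mesh, facets)
        for a in range(3):
            for b in range(3):
                rows.append(facets[:, a])
                cols.append(facets[:, b])
                vals.append(A / (6.0 if a == b else 12.0))
    if not rows:
        return sp.csc_matrix((mesh.n_nodes, mesh.n_nodes))
    M = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(mesh.n_nodes, mesh.n_nodes),
    )
    return M.tocsc()


def traction_to_loads(
    mesh: Mesh,
    traction: TractionField,
    groups: tuple[str, ...] = ("well_wall", "well_bottom"),
) -> np.ndarray:
    """Consistent nodal loads (pN) from nodal tractions supported on groups.

    The nodal traction basis is restricted to facets of the named groups, so
    a traction on a rim node does not spill onto adjacent surfaces (the gel
    top remains exactly traction-free when loading only the well surfaces).
    """
    tval = np.zeros((mesh.n_nodes, 3))
    tval[traction.node_ids] = traction.tractions
    Ms = surface_mass_matrix(mesh, groups)
    return np.asarray(Ms @ tval)


def nodal_force_to_traction(
    mesh: Mesh, node_ids: np.ndarray, forces: np.ndarray,
    groups: tuple[str, ...] = ("well_wall", "well_bottom"),
) -> TractionField:
    """Convert nodal forces (pN) to tractions (Pa) via lumped nodal areas.

    Conserves total force exactly: Σ traction·area = Σ force."""
    node_ids = np.asarray(node_ids, dtype=np.int64)
    forces = np.asarray(forces, dtype=float).reshape(-1, 3)
    areas_all = lumped_node_areas(mesh, groups)
    areas = areas_all[node_ids]
    if (areas <= 0).any():
        bad = node_ids[areas <= 0]
        raise ValueError(f"nodes not on surfaces {groups}: {bad[:10].tolist()}")
    return TractionField(
        node_ids=node_ids, tractions=forces / areas[:, None], areas=areas
    )


# --------------------------------------------------------------------------
# assembly and solve
# --------------------------------------------------------------------------


def _shape_gradients(mesh: Mesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-element shape-function gradients (M,4,3) and volumes (M,)."""
    p = mesh.nodes[mesh.tets]
    d = p[:, 1:] - p[:, :1]  # (M, 3, 3) edge matrix
    vol = np.einsum("ij,ij->i", d[:, 0], np.cross(d[:, 1], d[:, 2])) / 6.0
    dinv = np.linalg.inv(d)  # rows of dinv^T are gradients of N1..N3
    g = np.empty((len(p), 4, 3))
    g[:, 1:] = np.transpose(dinv, (0, 2, 1))
    g[:, 0] = -g[:, 1:].sum(axis=1)
    return g, vol


def assemble_stiffness(mesh: Mesh, material: MaterialModel) -> sp.csr_matrix:
    """Small-strain isotropic stiffness matrix (3N × 3N, units pN/µm)."""
    lam, mu = material.lame
    g, vol = _shape_gradients(mesh)
    gg = np.einsum("eak,ebk->eab", g, g)  # (M,4,4)
    ke = (
        lam * np.einsum("eai,ebj->eaibj", g, g)
        + mu * np.einsum("eaj,ebi->eaibj", g, g)
        + mu * np.einsum("eab,ij->eaibj", gg, np.eye(3))
    ) * vol[:, None, None, None, None]
    dofs = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(-1, 12)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    K = sp.coo_matrix(
        (ke.reshape(len(g), 12, 12).ravel(), (rows, cols)),
        shape=(3 * mesh.n_nodes, 3 * mesh.n_nodes),
    )
    return K.tocsr()


def solve_linear(
    K: sp.csr_matrix,
    loads: np.ndarray,
    fixed_dofs: np.ndarray,
    fixed_values: np.ndarray | None = None,
    lu: spla.SuperLU | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve K u = f with Dirichlet constraints; returns (u, reactions).

    ``loads`` is (N,3) pN; ``fixed_dofs`` indexes the flattened 3N dof
    vector.  Reactions are returned on the full dof vector (nonzero only at
    constrained dofs).
    """
    n = K.shape[0]
    f = np.asarray(loads, dtype=float).reshape(-1)
    if f.size != n:
        raise ValueError("load vector size mismatch")
    fixed_dofs = np.asarray(fixed_dofs, dtype=np.int64)
    if fixed_dofs.size == 0:
        raise SolverError("no Dirichlet constraints: singular system")
    uc = np.zeros(fixed_dofs.size) if fixed_values is None else np.asarray(
        fixed_values, dtype=float
    )
    free = np.ones(n, dtype=bool)
    free[fixed_dofs] = False
    u = np.zeros(n)
    u[fixed_dofs] = uc
    rhs = f[free] - K[:, fixed_dofs][free] @ uc
    if lu is None:
        lu = spla.splu(K[free][:, free].tocsc())
    u[free] = lu.solve(rhs)
    r = K @ u - f
    reactions = np.zeros(n)
    reactions[fixed_dofs] = r[fixed_dofs]
    # solver sanity: residual at free dofs small relative to the load
    free_res = np.linalg.norm(r[free])
    scale = max(np.linalg.norm(f), np.linalg.norm(K @ u), 1e-30)
    if free_res > 1e-8 * scale:
        raise SolverError(f"linear solve residual {free_res:.3e} too large")
    return u.reshape(-1, 3), reactions.reshape(-1, 3)


def base_fixed_dofs(mesh: Mesh) -> np.ndarray:
    ids = mesh.group_nodes("base")
    if ids.size == 0:
        raise SolverError("mesh has no base facets to constrain")
    return (3 * ids[:, None] + np.arange(3)).ravel()


def solve_forward(
    mesh: Mesh,
    material: MaterialModel,
    applied_tractions: TractionField,
    K: sp.csr_matrix | None = None,
    newton_tol: float = 1e-9,
    max_newton: int = 25,
) -> np.ndarray:
    """Forward elastic problem: tractions on the well surfaces → displacements.

    Boundary conditions: base fully fixed; gel top and lateral faces
    traction-free.  Returns nodal displacements (N, 3) in µm.  For the
    ``neo_hookean`` law the equilibrium is found by Newton iteration with
    the linear solution as the initial guess.
    """
    well_nodes = set(mesh.group_nodes("well_wall", "well_bottom").tolist())
    if not set(applied_tractions.node_ids.tolist()) <= well_nodes:
        raise ValueError("applied tractions must be supported on the well surfaces")
    loads = traction_to_loads(mesh, applied_tractions)
    fixed = base_fixed_dofs(mesh)
    if K is None:
        K = assemble_stiffness(mesh, material)
    u, _ = solve_linear(K, loads, fixed)
    if material.law == "linear":
        return u
    # Newton for compressible Neo-Hookean
    f_ext = loads.reshape(-1)
    free = np.ones(3 * mesh.n_nodes, dtype=bool)
    free[fixed] = False
    g, vol = _shape_gradients(mesh)
    x = u.reshape(-1).copy()
    x[fixed] = 0.0
    ref_norm = max(np.linalg.norm(f_ext), 1e-30)
    for _ in range(max_newton):
        f_int, Kt = _neo_hookean_system(mesh, material, x.reshape(-1, 3), g, vol)
        res = f_ext - f_int
        if np.linalg.norm(res[free]) <= newton_tol * ref_norm:
            return x.reshape(-1, 3)
        Ktff = Kt[free][:, free].tocsc()
        dx = spla.splu(Ktff).solve(res[free])
        x[free] += dx
    raise SolverError("Newton iteration did not converge for neo_hookean law")


def _neo_hookean_system(mesh, material, u, g, vol):
    """Internal force vector and tangent for compressible Neo-Hookean.

    W = μ/2 (I₁ − 3) − μ ln J + λ/2 (ln J)², P = μ(F − F⁻ᵀ) + λ ln J F⁻ᵀ.
    """
    lam, mu = material.lame
    ue = u[mesh.tets]  # (M,4,3)
    F = np.einsum("eai,eaJ->eiJ", ue, g) + np.eye(3)
    J = np.linalg.det(F)
    if (J <= 0).any():
        raise SolverError("element inversion during Newton iteration")
    Finv = np.linalg.inv(F)
    FinvT = np.transpose(Finv, (0, 2, 1))
    lnJ = np.log(J)
    P = mu * (F - FinvT) + lam * lnJ[:, None, None] * FinvT
    fint_e = np.einsum("eiJ,eaJ,e->eai", P, g, vol)
    f_int = np.zeros((mesh.n_nodes, 3))
    np.add.at(f_int, mesh.tets, fint_e)
    # tangent: A_iJkL = μ δik δJL + λ Finv_Ji Finv_Lk + (μ − λ lnJ) Finv_Jk Finv_Li
    eye = np.eye(3)
    A = (
        mu * np.einsum("ik,JL->iJkL", eye, eye)[None]
        + lam * np.einsum("eJi,eLk->eiJkL", Finv, Finv)
        + (mu - lam * lnJ)[:, None, None, None, None]
        * np.einsum("eJk,eLi->eiJkL", Finv, Finv)
    )
    ke = np.einsum("eiJkL,eaJ,ebL,e->eaibk", A, g, g, vol)
    dofs = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(-1, 12)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    Kt = sp.coo_matrix(
        (ke.reshape(len(g), 12, 12).ravel(), (rows, cols)),
        shape=(3 * mesh.n_nodes, 3 * mesh.n_nodes),
    ).tocsr()
    return f_int.reshape(-1), Kt


# --------------------------------------------------------------------------
# field interpolation at scattered points
# --------------------------------------------------------------------------


def interpolate_nodal_field(
    mesh: Mesh, values: np.ndarray, points: np.ndarray, n_candidates: int = 48
) -> np.ndarray:
    """Evaluate a nodal field at arbitrary points by FEM interpolation.

    Locates each point in the tet mesh (nearest-centroid candidates, then a
    barycentric containment test) and interpolates linearly; points outside
    every element fall back to the value at the nearest mesh node.
    """
    values = np.asarray(values, dtype=float)
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    p = mesh.nodes[mesh.tets]
    d = np.transpose(p[:, 1:] - p[:, :1], (0, 2, 1))  # (M,3,3) columns=edges
    dinv = np.linalg.inv(d)
    centroids = p.mean(axis=1)
    tree = cKDTree(centroids)
    k = min(n_candidates, len(centroids))
    _, cand = tree.query(pts, k=k)
    cand = np.atleast_2d(cand)
    out = np.empty((len(pts),) + values.shape[1:])
    resolved = np.zeros(len(pts), dtype=bool)
    for rank in range(k):
        todo = ~resolved
        if not todo.any():
            break
        ti = cand[todo, rank]
        rel = pts[todo] - p[ti, 0]
        lam = np.einsum("nij,nj->ni", dinv[ti], rel)
        lam0 = 1.0 - lam.sum(axis=1)
        inside = (lam >= -1e-9).all(axis=1) & (lam0 >= -1e-9)
        if inside.any():
            rows = np.flatnonzero(todo)[inside]
            t_in = ti[inside]
            w = np.column_stack([lam0[inside], lam[inside]])
            out[rows] = np.einsum("na,na...->n...", w, values[mesh.tets[t_in]])
            resolved[rows] = True
    if not resolved.all():
        node_tree = cKDTree(mesh.nodes)
        _, nn = node_tree.query(pts[~resolved])
        out[~resolved] = values[nn]
    return out
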