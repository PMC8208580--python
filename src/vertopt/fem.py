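"""Voxel linear-elasticity FEM with SIMP-interpolated stiffness.

Each in-domain voxel is a trilinear (8-node) hexahedral element whose
Young's modulus is interpolated as ``E = rho^P * E0`` (solid isotropic
material with penalization).  Elements outside the analysis domain carry no
stiffness and are removed from the system; arch-gap elements stay at the
void floor ``d`` so the mesh remains numerically connected.

Symmetry planes are enforced as homogeneous normal-displacement constraints
(u . n = 0); point and edge constraints are snapped to the nearest grid
nodes (points) or to all nodes within half a voxel of the analytic curve
(edges).  Compliance is evaluated as the work of the external tractions,
f_i = t . u integrated over the loaded boundary, which for the discrete
system equals the force-displacement dot product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from vertopt import geometry as geo
from vertopt.geometry import AnalysisDomain, DensityField, PLANE_NORMAL_AXIS
from vertopt.loads import LoadCase, LoadGroup, assemble_tractions

# Local node order of the hexahedron: lexicographic in (i, j, k) offsets.
_NODE_OFFSETS = np.array([
    (0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
    (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1),
])


@dataclass(frozen=True)
class MaterialModel:
    """Isotropic linear-elastic material with SIMP penalization."""

    E0: float = 2.0e10   # Young's modulus of solid bone, Pa
    nu: float = 0.3      # Poisson ratio
    P: float = 3.0       # SIMP penalization exponent

    def __post_init__(self) -> None:
        if self.E0 <= 0:
            raise ValueError("E0 must be positive")
        if not 0 <= self.nu < 0.5:
            raise ValueError("nu must lie in [0, 0.5)")
        if self.P < 1:
            raise ValueError("P must be >= 1")


def _elastic_tensor(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic stiffness in Voigt order (xx, yy, zz, yz, xz, xy)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] = lam + 2 * mu
    C[np.arange(3, 6), np.arange(3, 6)] = mu
    return C


def _shape_gradients(xi: float, et: float, ze: float) -> np.ndarray:
    """Gradients of the 8 trilinear shape functions on [-1, 1]^3."""
    s = _NODE_OFFSETS * 2 - 1  # node signs
    g = np.empty((8, 3))
    for a in range(8):
        sa = s[a]
        g[a, 0] = sa[0] * (1 + sa[1] * et) * (1 + sa[2] * ze) / 8
        g[a, 1] = sa[1] * (1 + sa[0] * xi) * (1 + sa[2] * ze) / 8
        g[a, 2] = sa[2] * (1 + sa[0] * xi) * (1 + sa[1] * et) / 8
    return g


def _b_matrix(grad_phys: np.ndarray) -> np.ndarray:
    """6x24 strain-displacement matrix from physical shape gradients."""
    B = np.zeros((6, 24))
    for a in range(8):
        gx, gy, gz = grad_phys[a]
        c = 3 * a
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c + 1] = gz
        B[3, c + 2] = gy
        B[4, c] = gz
        B[4, c + 2] = gx
        B[5, c] = gy
        B[5, c + 1] = gx
    return B


def element_stiffness(material: MaterialModel, h: float,
                      n_gauss: int = 2) -> np.ndarray:
    """Reference 24x24 stiffness of a cubic voxel of edge ``h``.

    Computed with tensor-product Gauss quadrature (2-point rule is exact
    for the trilinear element).  The matrix is symmetric positive
    semidefinite with a 6-dimensional rigid-body nullspace.
    """
    if h <= 0:
        raise ValueError("element size must be positive")
    C = _elastic_tensor(material.E0, material.nu)
    pts, wts = np.polynomial.legendre.leggauss(n_gauss)
    jac = h / 2  # d(phys)/d(ref) per axis
    K = np.zeros((24, 24))
    for xi, wx in zip(pts, wts):
        for et, wy in zip(pts, wts):
            for ze, wz in zip(pts, wts):
                grad = _shape_gradients(xi, et, ze) / jac
                B = _b_matrix(grad)
                K += (wx * wy * wz) * (B.T @ C @ B) * jac ** 3
    return (K + K.T) / 2


def _center_b_matrix(h: float) -> np.ndarray:
    """Strain-displacement matrix at the element center (for recovery)."""
    return _b_matrix(_shape_gradients(0.0, 0.0, 0.0) / (h / 2))


@dataclass
class ElasticitySolution:
    """Displacement solution of one load case on the current density."""

    case: LoadCase
    u: np.ndarray               # (n_nodes, 3) nodal displacements, m
    compliance: float           # f_i = t . u, J
    element_unit_energy: np.ndarray  # u_e^T k0(E=E0) u_e per active element
    fem: "VoxelFEM" = field(repr=False, default=None)

    @property
    def f_i(self) -> float:
        return self.compliance

    def strain_energy_density(self, rho_active: np.ndarray) -> np.ndarray:
        """Per-element strain energy density (J/m^3) at the given density."""
        vol = self.fem.domain.h ** 3
        return 0.5 * (rho_active ** self.fem.material.P) * \
            self.element_unit_energy / vol

    def element_strains(self) -> np.ndarray:
        """(n_active, 6) element-center strains in Voigt order."""
        ue = self.u.reshape(-1)[self.fem.edof]
        return ue @ self.fem.B_center.T


class SingularSystemError(RuntimeError):
    """The constrained stiffness matrix is singular (unconstrained rigid mode)."""


class VoxelFEM:
    """Assembler/solver bound to one domain + material.

    Precomputes the element connectivity once; :meth:`solve_group` then
    assembles ``K(rho)`` and solves every case of a load group, reusing a
    single factorization where the cases are algebraically related
    (negated or mirror-image partners of a linear problem).
    """

    # Above this many free dofs, switch from sparse LU to Jacobi-CG (the
    # LU fill of 3D elasticity grows steeply with system size).
    direct_dof_limit = 20_000

    def __init__(self, domain: AnalysisDomain, material: MaterialModel):
        self.domain = domain
        self.material = material
        self.h = domain.h
        self.k0 = element_stiffness(MaterialModel(1.0, material.nu, material.P),
                                    self.h)
        self.B_center = _center_b_matrix(self.h)

        nx, ny, nz = domain.shape
        self._nshape = (nx + 1, ny + 1, nz + 1)
        self.n_nodes = (nx + 1) * (ny + 1) * (nz + 1)
        self.active = np.argwhere(domain.in_domain)  # (n_active, 3)
        self.n_active = len(self.active)
        if self.n_active == 0:
            raise ValueError("domain has no in-domain elements")

        node_ids = self._node_id(self.active[:, None, :] + _NODE_OFFSETS[None])
        self.enodes = node_ids                       # (n_active, 8)
        edof = (3 * node_ids[:, :, None] + np.arange(3)).reshape(self.n_active, 24)
        self.edof = edof.astype(np.int32)
        ii = np.repeat(self.edof, 24, axis=1).ravel()
        jj = np.tile(self.edof, (1, 24)).ravel()
        self._rows = ii
        self._cols = jj
        self._warm = {}
        self._fixed_cache = {}
        # Nodes (and dofs) attached to at least one in-domain element; all
        # other grid nodes carry no stiffness and are excluded from solves.
        active_nodes = np.zeros(self.n_nodes, dtype=bool)
        active_nodes[self.enodes.ravel()] = True
        self.active_nodes = active_nodes
        self.active_dofs = np.repeat(active_nodes, 3)

    def _node_id(self, ijk: np.ndarray) -> np.ndarray:
        ny1, nz1 = self._nshape[1], self._nshape[2]
        return (ijk[..., 0] * ny1 + ijk[..., 1]) * nz1 + ijk[..., 2]

    # ---- densities -------------------------------------------------------

    def rho_active(self, rho: DensityField | np.ndarray) -> np.ndarray:
        """Density values of the active (in-domain) elements."""
        vals = rho.values if isinstance(rho, DensityField) else np.asarray(rho)
        return vals[tuple(self.active.T)]

    # ---- constraints -----------------------------------------------------

    def _plane_nodes(self, axis: int) -> np.ndarray:
        """Node ids lying on the coordinate plane axis = 0."""
        xs, ys, zs = self.domain.node_coords()
        coords = (xs, ys, zs)[axis]
        i0 = int(np.argmin(np.abs(coords)))
        if abs(coords[i0]) > 1e-9 * self.h:
            return np.zeros(0, dtype=np.int64)
        idx = [np.arange(n) for n in self._nshape]
        idx[axis] = np.array([i0])
        I, J, K = np.meshgrid(*idx, indexing="ij")
        ijk = np.stack([I.ravel(), J.ravel(), K.ravel()], axis=1)
        return self._node_id(ijk)

    def _nearest_node(self, point: Sequence[float]) -> int:
        """Nearest *active* grid node to an analytic constraint location."""
        xs, ys, zs = self.domain.node_coords()
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        d2 = ((X - point[0]) ** 2 + (Y - point[1]) ** 2
              + (Z - point[2]) ** 2).ravel()
        d2[~self.active_nodes] = np.inf
        return int(np.argmin(d2))

    def _edge_circle_nodes(self, circ) -> np.ndarray:
        """Nodes within half a voxel of the circle y^2+z^2=r^2 at x=0."""
        xs, ys, zs = self.domain.node_coords()
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        dist = np.sqrt(X ** 2 + (np.hypot(Y, Z) - circ.radius) ** 2)
        keep = dist <= 0.5 * self.h * (1 + 1e-9)
        if circ.y_min is not None:
            keep &= Y >= circ.y_min - 1e-12
        if circ.z_min is not None:
            keep &= Z >= circ.z_min - 1e-12
        ijk = np.argwhere(keep)
        return self._node_id(ijk)

    def fixed_dofs(self, case: LoadCase) -> np.ndarray:
        """Sorted unique constrained dof indices for one load case."""
        key = (case.name, case.index, case.facet_region, case.halfspace,
               case.point_constraints, case.edge_constraints,
               case.plane_constraints, case.symmetry_planes,
               case.antisymmetry_planes)
        cached = self._fixed_cache.get(key)
        if cached is not None:
            return cached
        dofs = []
        for plane in sorted(case.symmetry_planes):
            axis = PLANE_NORMAL_AXIS[plane]
            nodes = self._plane_nodes(axis)
            dofs.append(3 * nodes + axis)
        for plane in sorted(case.antisymmetry_planes):
            axis = PLANE_NORMAL_AXIS[plane]
            nodes = self._plane_nodes(axis)
            for c in (a for a in range(3) if a != axis):
                dofs.append(3 * nodes + c)
        for point, comps in case.point_constraints:
            nid = self._nearest_node(point)
            dofs.extend(np.array([3 * nid + c]) for c in comps)
        for axis, coord, comps in case.plane_constraints:
            xs, ys, zs = self.domain.node_coords()
            along = (xs, ys, zs)[axis]
            sel = np.abs(along - coord) <= 1e-9 * max(self.h, abs(coord) or 1)
            idx = [np.arange(n) for n in self._nshape]
            idx[axis] = np.flatnonzero(sel)
            I, J, Kk = np.meshgrid(*idx, indexing="ij")
            nodes = self._node_id(np.stack([I.ravel(), J.ravel(), Kk.ravel()],
                                           axis=1))
            for c in comps:
                dofs.append(3 * nodes + c)
        for circ in case.edge_constraints:
            nodes = self._edge_circle_nodes(circ)
            if len(nodes) == 0:
                raise ValueError(
                    f"edge-circle constraint (r={circ.radius:g}) selects no "
                    "nodes on this mesh; the grid is too coarse")
            for c in circ.components:
                dofs.append(3 * nodes + c)
        if not dofs:
            out = np.zeros(0, dtype=np.int64)
        else:
            out = np.unique(np.concatenate(
                [np.asarray(d).ravel() for d in dofs]))
        self._fixed_cache[key] = out
        return out

    # ---- assembly and solution ------------------------------------------

    def assemble(self, rho: DensityField | np.ndarray) -> sp.csr_matrix:
        """Global stiffness K(rho) on all node dofs (3 per grid node)."""
        ra = self.rho_active(rho)
        scale = self.material.E0 * np.maximum(ra, 0.0) ** self.material.P
        data = (scale[:, None, None] * self.k0[None]).ravel()
        n = 3 * self.n_nodes
        K = sp.coo_matrix((data, (self._rows, self._cols)), shape=(n, n))
        return K.tocsr()

    def _solve_free(self, K: sp.csr_matrix, free: np.ndarray, warm_key=None):
        Kff = K[free][:, free]
        n = Kff.shape[0]
        if n <= self.direct_dof_limit:
            try:
                lu = spla.splu(Kff.tocsc())
            except RuntimeError as err:  # singular factorization
                raise SingularSystemError(
                    "stiffness matrix is singular; a rigid-body mode is "
                    f"likely unconstrained ({err})") from None

            def solve(b, _lu=lu, _K=Kff):
                x = _lu.solve(b)
                nb = np.linalg.norm(b)
                if nb > 0:
                    res = np.linalg.norm(_K @ x - b) / nb
                    if not np.isfinite(res) or res > 1e-6:
                        raise SingularSystemError(
                            f"direct solve residual {res:.2e}; a rigid-body "
                            "mode is likely unconstrained")
                return x
        else:
            diag = Kff.diagonal()
            if np.any(diag <= 0):
                raise SingularSystemError(
                    "zero diagonal in stiffness matrix; a rigid-body mode "
                    "is likely unconstrained")
            M = sp.diags(1.0 / diag)

            def solve(b, _K=Kff, _M=M, _key=warm_key):
                x0 = self._warm.get(_key)
                if x0 is not None and len(x0) != len(b):
                    x0 = None
                x, info = spla.cg(_K, b, x0=x0, M=_M, rtol=1e-8, atol=0.0,
                                  maxiter=20000)
                if info != 0:
                    res = np.linalg.norm(_K @ x - b) / max(np.linalg.norm(b), 1e-300)
                    raise SingularSystemError(
                        f"CG did not converge (info={info}, rel. residual {res:.2e})")
                if _key is not None:
                    self._warm[_key] = x
                return x

        def full_solve(b_full):
            x = np.zeros_like(b_full)
            xf = solve(b_full[free])
            if not np.all(np.isfinite(xf)):
                raise SingularSystemError(
                    "non-finite solution; a rigid-body mode is likely "
                    "unconstrained")
            x[free] = xf
            return x

        return full_solve

    def solve_group(self, rho: DensityField | np.ndarray, group: LoadGroup,
                    use_partner_identities: bool | None = None
                    ) -> list[ElasticitySolution]:
        """Solve every case of a load group at the given density.

        ``use_partner_identities=None`` (auto) exploits the exact algebraic
        relations between paired cases (negation; mirror images when the
        density is mirror-symmetric), falling back to independent solves
        whenever the premise does not hold.
        """
        vals = rho.values if isinstance(rho, DensityField) else np.asarray(rho)
        K = self.assemble(vals)
        n = 3 * self.n_nodes
        ndof_free_cache: dict = {}
        sols: list[ElasticitySolution | None] = [None] * len(group.cases)

        for idx, case in enumerate(group.cases):
            partner = case.partner
            if partner is not None and use_partner_identities is not False:
                kind = partner[0]
                base = sols[partner[1]]
                if kind == "negate" and base is not None:
                    sols[idx] = self._from_negation(case, base)
                    continue
                if kind == "mirror" and base is not None:
                    axis = partner[2]
                    if self._mirror_symmetric(vals, axis):
                        sols[idx] = self._from_mirror(case, base, axis)
                        continue
                    if use_partner_identities:
                        raise ValueError(
                            "density is not mirror-symmetric; cannot use the "
                            "mirror partner identity")
            sols[idx] = self._solve_case(K, case, ndof_free_cache, n, vals)
        return sols  # type: ignore[return-value]

    def _solve_case(self, K, case, cache, n, vals) -> ElasticitySolution:
        f = assemble_tractions(case, self.domain)
        fixed = self.fixed_dofs(case)
        key = hash(fixed.tobytes())
        if key not in cache:
            free = self.active_dofs.copy()
            free[fixed] = False
            cache[key] = self._solve_free(K, np.flatnonzero(free),
                                          warm_key=(case.name, case.index))
        u = cache[key](f.ravel()).reshape(-1, 3)
        comp = float(f.ravel() @ u.ravel())
        q = self._unit_energies(u, vals)
        return ElasticitySolution(case, u, comp, q, fem=self)

    def _unit_energies(self, u: np.ndarray, vals: np.ndarray) -> np.ndarray:
        ue = u.reshape(-1)[self.edof]
        return np.einsum("ei,ij,ej->e", ue, self.k0 * self.material.E0, ue)

    def _from_negation(self, case, base: ElasticitySolution) -> ElasticitySolution:
        return ElasticitySolution(case, -base.u, base.compliance,
                                  base.element_unit_energy.copy(), fem=self)

    def _mirror_symmetric(self, vals: np.ndarray, axis: int,
                          tol: float = 1e-12) -> bool:
        if axis in self.domain.reduced_axes:
            return True
        return bool(np.allclose(vals, np.flip(vals, axis=axis), atol=tol))

    def _mirror_u(self, u: np.ndarray, axis: int) -> np.ndarray:
        """Reflect a nodal vector field across the plane axis = 0."""
        U = u.reshape(*self._nshape, 3)
        U = np.flip(U, axis=axis).copy()
        U[..., axis] *= -1
        return U.reshape(-1, 3)

    def _from_mirror(self, case, base: ElasticitySolution, axis: int
                     ) -> ElasticitySolution:
        u = self._mirror_u(base.u, axis)
        # Element energies mirror along the element grid.
        q = np.zeros(self.domain.shape)
        q[tuple(self.active.T)] = base.element_unit_energy
        q = np.flip(q, axis=axis)
        qa = q[tuple(self.active.T)]
        return ElasticitySolution(case, u, base.compliance, qa, fem=self)


def assemble_and_solve(domain: AnalysisDomain, rho: DensityField,
                       material: MaterialModel, case: LoadCase
                       ) -> ElasticitySolution:
    """One-shot solve of a single load case (convenience wrapper)."""
    fem = VoxelFEM(domain, material)
    group = LoadGroup(cases=[case], name=case.name)
    return fem.solve_group(rho, group, use_partner_identities=False)[0]


def group_objective(solutions: Sequence[ElasticitySolution]) -> float:
    """Multi-load objective: the average compliance (1/N) sum_i f_i."""
    if len(solutions) == 0:
        raise ValueError("need at least one solution")
    return float(np.mean([s.compliance for s in solutions]))


def sensitivity(domain: AnalysisDomain, rho: DensityField,
                material: MaterialModel,
                solutions: Sequence[ElasticitySolution]) -> np.ndarray:
    """Compliance sensitivity d f / d rho_e on the element grid.

    Standard self-adjoint SIMP sensitivity,
    ``-(1/N) sum_i P rho^(P-1) u_e^T k0 u_e``; entries are <= 0 on design
    elements and reported as 0 on fixed regions and outside the domain.
    """
    fem = solutions[0].fem
    ra = fem.rho_active(rho)
    N = len(solutions)
    acc = np.zeros_like(ra)
    for s in solutions:
        acc += s.element_unit_energy
    sens_active = -(material.P * ra ** (material.P - 1)) * acc / N
    out = np.zeros(domain.shape)
    out[tuple(fem.active.T)] = sens_active
    out[domain.labels != geo.DESIGN] = 0.0
    return out
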