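"""Anatomically motivated load cases on the vertebral-body domain.

Nine load cases model the external loads a teleost vertebra experiences
from the deformation of its surrounding tissues: compression by the
intervertebral (notochord-derived) tissue on the concave surfaces, bending
and diagonal bending during axial undulation, shear and torsion for
contrast, and tension transmitted through the neural/hemal arches by the
lateral musculature.  Each case is a traction field on a named boundary
facet set, plus the displacement constraints that remove rigid-body modes,
under the symmetry reduction appropriate to the case.

Paired cases (the two bending halves, the two shear senses, clockwise and
counterclockwise torsion) form a :class:`LoadGroup` whose objective is the
average of the member compliances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from vertopt.geometry import AnalysisDomain, Facets

DEFAULT_F = 1.0e6  # traction magnitude, N/m^2

CASE_NAMES = (
    "compressive_normal",
    "compressive_horizontal",
    "bending_surface",
    "bending_edge",
    "diagonal_bending",
    "shear",
    "torsion",
    "arch_tension_lr",
    "arch_tension_dv",
)

# Default (preferred) geometric reduction per case.  For shear and torsion
# the traction field is *antisymmetric* under the remaining mirror planes
# (reflecting a case yields its negation), so the half/full models reduce
# exactly to an eighth model with antisymmetric plane conditions
# (tangential displacement = 0 on the plane); both constructions are
# supported and agree to solver tolerance.
CASE_SYMMETRY = {
    "compressive_normal": ("XY", "YZ", "ZX"),
    "compressive_horizontal": ("XY", "YZ", "ZX"),
    "bending_surface": ("XY", "YZ"),
    "bending_edge": ("XY", "YZ"),
    "diagonal_bending": ("XY", "YZ"),
    "shear": ("XY", "YZ", "ZX"),
    "torsion": ("XY", "YZ", "ZX"),
    "arch_tension_lr": ("XY", "YZ", "ZX"),
    "arch_tension_dv": ("XY", "ZX"),
}

# Alternative reductions accepted per case (the literal constructions:
# half model for shear, full model for torsion).
CASE_SYMMETRY_ALT = {
    "shear": (("XY",),),
    "torsion": ((),),
}


def _sign0(v: np.ndarray) -> np.ndarray:
    """sign(v) with exact zeros mapped to 0 (mid-plane facets get no load)."""
    return np.sign(v)


@dataclass(frozen=True)
class EdgeCircleConstraint:
    """Displacement constraint on the circle y^2 + z^2 = radius^2 at x = 0.

    ``components`` are the constrained displacement components (0=x, 1=y,
    2=z); optional half-space filters restrict the circle to y >= y_min
    and/or z >= z_min.
    """

    radius: float
    components: tuple
    y_min: Optional[float] = None
    z_min: Optional[float] = None


@dataclass(frozen=True)
class LoadCase:
    """One traction field + constraint set on an analysis domain."""

    name: str
    traction: Callable[[np.ndarray, np.ndarray], np.ndarray] = field(repr=False)
    facet_region: str = "CONCAVE_SURFACE"
    halfspace: Optional[tuple] = None        # (axis, sign): keep sign*coord >= 0
    F: float = DEFAULT_F
    w: Optional[float] = None
    point_constraints: tuple = ()            # ((x, y, z), (components,)), ...
    edge_constraints: tuple = ()             # EdgeCircleConstraint, ...
    plane_constraints: tuple = ()            # (axis, coord, (components,)), ...
    symmetry_planes: frozenset = frozenset()      # u . n = 0 on these planes
    antisymmetry_planes: frozenset = frozenset()  # tangential u = 0 on these
    facet_filter: Optional[Callable] = field(default=None, repr=False)
    index: int = 0                           # position within its group
    partner: Optional[tuple] = None          # ("negate", i) | ("mirror", i, axis)


@dataclass(frozen=True)
class LoadGroup:
    """Load cases sharing one domain, averaged into a single objective."""

    cases: Sequence[LoadCase]
    name: str = ""
    equivariant_axes: tuple = ()  # unreduced axes whose mirror maps the group to itself

    def __post_init__(self) -> None:
        if len(self.cases) < 1:
            raise ValueError("a load group needs at least one case")

    @property
    def weights(self) -> np.ndarray:
        n = len(self.cases)
        return np.full(n, 1.0 / n)


def _require_symmetry(domain: AnalysisDomain, name: str) -> frozenset:
    allowed = [frozenset(CASE_SYMMETRY[name])]
    allowed += [frozenset(a) for a in CASE_SYMMETRY_ALT.get(name, ())]
    if domain.symmetry_planes not in allowed:
        raise ValueError(
            f"load case {name!r} requires a model reduced by one of "
            f"{[sorted(a) for a in allowed]}, got "
            f"{sorted(domain.symmetry_planes)}")
    return domain.symmetry_planes


def make_load_group(name: str, domain: AnalysisDomain, F: float = DEFAULT_F,
                    w: Optional[float] = None) -> LoadGroup:
    """Build one of the nine named load groups on a matching domain.

    ``w`` (vertical-to-horizontal load ratio) applies to the diagonal
    bending case only.
    """
    if name not in CASE_NAMES:
        raise ValueError(f"unknown load case {name!r}; choose from {CASE_NAMES}")
    if w is not None and name != "diagonal_bending":
        raise ValueError(f"parameter w applies only to 'diagonal_bending', "
                         f"not {name!r}")
    planes = _require_symmetry(domain, name)
    p = domain.params
    C_R = p.C_R
    R = p.outer_radius

    def case(**kw) -> LoadCase:
        kw.setdefault("symmetry_planes", planes)
        kw.setdefault("F", F)
        return LoadCase(name=name, **kw)

    if name == "compressive_normal":
        cases = [case(traction=lambda c, n, F=F: -F * n)]
        equiv = ()
    elif name == "compressive_horizontal":
        cases = [case(traction=_axial(F))]
        equiv = ()
    elif name in ("bending_surface", "bending_edge"):
        region = "CONCAVE_SURFACE" if name == "bending_surface" else "DISTAL_EDGE"
        cases = [
            case(traction=_axial(F), facet_region=region, halfspace=(1, -1),
                 point_constraints=(((0.0, C_R, 0.0), (1,)),), index=0),
            case(traction=_axial(F), facet_region=region, halfspace=(1, 1),
                 point_constraints=(((0.0, -C_R, 0.0), (1,)),), index=1,
                 partner=("mirror", 0, 1)),
        ]
        equiv = (1,)
    elif name == "diagonal_bending":
        if w is None:
            w = 0.8
        if w < 0:
            raise ValueError("w must be non-negative")
        cases = [
            case(traction=_diagonal(F, w), w=w, halfspace=(1, -1),
                 point_constraints=(((0.0, C_R, 0.0), (1,)),), index=0),
            case(traction=_diagonal(F, w), w=w, halfspace=(1, 1),
                 point_constraints=(((0.0, -C_R, 0.0), (1,)),), index=1,
                 partner=("mirror", 0, 1)),
        ]
        equiv = (1,)
    elif name == "shear":
        eighth = len(planes) == 3
        constraints = dict(
            point_constraints=(((0.0, C_R, 0.0), (0,)),) if eighth else
            (((0.0, C_R, 0.0), (0,)), ((0.0, -C_R, 0.0), (0,))),
            edge_constraints=(EdgeCircleConstraint(C_R, (1,), z_min=0.0),),
            symmetry_planes=frozenset({"XY"}),
            antisymmetry_planes=frozenset({"YZ", "ZX"}) if eighth else frozenset(),
        )
        cases = [
            case(traction=_shear(F), facet_region="DISTAL_EDGE", index=0,
                 **constraints),
            case(traction=_shear(-F), facet_region="DISTAL_EDGE", index=1,
                 partner=("negate", 0), **constraints),
        ]
        equiv = (0, 1)
    elif name == "torsion":
        eighth = len(planes) == 3
        constraints = dict(
            edge_constraints=(EdgeCircleConstraint(C_R, (0, 1, 2)),),
            symmetry_planes=frozenset(),
            antisymmetry_planes=(frozenset({"XY", "YZ", "ZX"}) if eighth
                                 else frozenset()),
        )
        cases = [
            case(traction=_torsion(F, R), facet_region="DISTAL_EDGE", index=0,
                 **constraints),
            case(traction=_torsion(-F, R), facet_region="DISTAL_EDGE", index=1,
                 partner=("negate", 0), **constraints),
        ]
        equiv = (0, 1, 2)
    elif name == "arch_tension_lr":
        cases = [case(traction=_lateral(F), facet_region="ARCH_EXTERNAL_SURFACE")]
        equiv = ()
    elif name == "arch_tension_dv":
        cases = [case(
            traction=_arch_dv(F), facet_region="ARCH_DISTAL_EDGE",
            edge_constraints=(EdgeCircleConstraint(C_R, (0,), y_min=0.0,
                                                   z_min=0.0),))]
        equiv = ()

    # Keep only equivariant axes that are not already reduced by symmetry.
    reduced = set(domain.reduced_axes)
    equiv = tuple(a for a in equiv if a not in reduced)
    return LoadGroup(cases=tuple(cases), name=name, equivariant_axes=equiv)


# ---- traction field factories (position, outward normal) -> (M, 3) -------

def _axial(F: float):
    """t = -F x/|x|: axial load toward the vertebral-body center."""
    def t(c, n):
        out = np.zeros_like(c)
        out[:, 0] = -F * _sign0(c[:, 0])
        return out
    return t


def _diagonal(F: float, w: float):
    """t = F(-x/|x| + w z/|z|): horizontal plus vertical bending."""
    def t(c, n):
        out = np.zeros_like(c)
        out[:, 0] = -F * _sign0(c[:, 0])
        out[:, 2] = F * w * _sign0(c[:, 2])
        return out
    return t


def _shear(F: float):
    """t = (0, F, 0) on the x > 0 rim and (0, -F, 0) on the x < 0 rim."""
    def t(c, n):
        out = np.zeros_like(c)
        out[:, 1] = F * _sign0(c[:, 0])
        return out
    return t


def _torsion(F: float, R: float):
    """Clockwise torsion t = sign(x) * (0, F z / R, -F y / R) on the rims."""
    def t(c, n):
        s = _sign0(c[:, 0])
        out = np.zeros_like(c)
        out[:, 1] = F * c[:, 2] / R * s
        out[:, 2] = -F * c[:, 1] / R * s
        return out
    return t


def _lateral(F: float):
    """t = F y/|y|: left-right tension on the arch surfaces."""
    def t(c, n):
        out = np.zeros_like(c)
        out[:, 1] = F * _sign0(c[:, 1])
        return out
    return t


def _arch_dv(F: float):
    """t = (-F, 0, F z/|z|): dorsal-ventral tension at the arch distal edge."""
    def t(c, n):
        out = np.zeros_like(c)
        out[:, 0] = -F
        out[:, 2] = F * _sign0(c[:, 2])
        return out
    return t


# ---- traction assembly ----------------------------------------------------

def select_facets(case: LoadCase, domain: AnalysisDomain) -> Facets:
    """The facet set a case loads, after the half-space restriction."""
    try:
        facets = domain.facets[case.facet_region]
    except KeyError:
        raise ValueError(f"domain has no facet region {case.facet_region!r}")
    if case.halfspace is not None:
        axis, sgn = case.halfspace
        facets = facets.restrict(sgn * facets.centroids[:, axis] >= 0)
    if case.facet_filter is not None:
        facets = facets.restrict(case.facet_filter(facets.centroids))
    if len(facets) == 0:
        raise ValueError(
            f"facet region {case.facet_region!r} is empty for case "
            f"{case.name!r} (geometry/reduction mismatch?)")
    return facets


def assemble_tractions(case: LoadCase, domain: AnalysisDomain) -> np.ndarray:
    """Consistent nodal forces of a case's traction field.

    Constant traction per facet (evaluated at the centroid), spread equally
    over the facet's four nodes; returns an (n_nodes, 3) array.  The total
    force equals the facet-wise quadrature of the traction field exactly.
    """
    facets = select_facets(case, domain)
    t = case.traction(facets.centroids, facets.normals)
    area = domain.h ** 2
    nx, ny, nz = domain.shape
    nshape = (nx + 1, ny + 1, nz + 1)
    f = np.zeros((nshape[0] * nshape[1] * nshape[2], 3))

    # The 4 nodes of the face of element (i,j,k) with direction (axis, sign):
    # nodes at offset sign-side along `axis`, all 4 corners across the others.
    for axis in (0, 1, 2):
        for sgn in (-1, 1):
            m = (facets.axis == axis) & (facets.sign == sgn)
            if not m.any():
                continue
            elems = facets.elems[m]
            base = elems.copy()
            if sgn > 0:
                base[:, axis] += 1
            others = [a for a in (0, 1, 2) if a != axis]
            contrib = t[m] * (area / 4)
            for da in (0, 1):
                for db in (0, 1):
                    corner = base.copy()
                    corner[:, others[0]] += da
                    corner[:, others[1]] += db
                    nid = (corner[:, 0] * nshape[1] + corner[:, 1]) * nshape[2] \
                        + corner[:, 2]
                    np.add.at(f, nid, contrib)
    return f


def total_force(case: LoadCase, domain: AnalysisDomain) -> np.ndarray:
    """Integral of the traction over the loaded region (N)."""
    return assemble_tractions(case, domain).sum(axis=0)
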