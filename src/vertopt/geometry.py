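"""Parametric vertebral-body analysis domain on a regular voxel grid.

The analysis domain is a bounding cylinder (axis = x, the cranial-caudal
direction) that contains

* the **autocentrum**: an amphicoelous (biconcave) hourglass shell -- a
  central cylinder of radius ``C_R`` and length ``C_X`` continued by two
  cones of half angle ``theta`` and slant length ``L``, shelled radially to
  thickness ``C_T``.  Its density is pinned at 1.
* the **vertebral arches**: four wedge sectors of angular width ``xi``
  flanking the dorsal (+z) and ventral (-z) midlines, each a distance
  ``eta`` from the midline, so the dorsal/ventral gaps have angular width
  ``2*eta``.  Density pinned at 1; the gaps are pinned at the void floor
  ``d``.
* the **design domain**: everything else between the autocentrum shell and
  the bounding cylinder, where the optimizer is free to place material.

Axis convention: x = cranial-caudal, y = left-right, z = dorsal-ventral,
origin at the vertebral-body center.  Geometry is sampled by analytic
signed-distance tests at voxel centers on a regular hexahedral grid.
Lengths are SI meters throughout; :meth:`GeometryParams.from_cm` accepts
the desk-reference centimeter values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

# Region labels for the voxel grid.
OUTSIDE = 0
AUTOCENTRUM = 1
ARCH = 2
ARCH_GAP = 3
DESIGN = 4

REGION_NAMES = {
    OUTSIDE: "OUTSIDE",
    AUTOCENTRUM: "AUTOCENTRUM",
    ARCH: "ARCH",
    ARCH_GAP: "ARCH_GAP",
    DESIGN: "DESIGN",
}

# Symmetry plane names -> index of the axis normal to the plane.
PLANE_NORMAL_AXIS = {"YZ": 0, "ZX": 1, "XY": 2}
AXIS_PLANE = {v: k for k, v in PLANE_NORMAL_AXIS.items()}

# Sub-classification of OUTSIDE space, used for boundary-facet detection.
_VOID_INNER = 1   # inside the concave funnel (notochord / intervertebral space)
_VOID_AXIAL = 2   # beyond the distal rims along x
_VOID_RADIAL = 3  # outside the bounding cylinder


class ResolutionError(ValueError):
    """Raised when the voxel size cannot resolve the autocentrum shell."""


@dataclass(frozen=True)
class GeometryParams:
    """Geometric parameters of the vertebral-body analysis domain.

    Defaults are the desk-reference configuration (values in meters;
    0.04 cm radius etc.).  ``d`` is the void floor density used for the
    arch gaps and as the lower box bound of the design variables.
    """

    C_R: float = 0.04e-2   # radius of cylindrical part (chordacentrum), m
    C_T: float = 0.02e-2   # autocentrum shell thickness, m
    C_X: float = 0.04e-2   # length of cylindrical part, m
    L: float = 0.6e-2      # slant length of conical part, m
    theta: float = 45.0    # half angle of conical part, degrees
    xi: float = 5.0        # angular width of each vertebral arch wedge, degrees
    eta: float = 15.0      # half width of dorsal/ventral arch gap, degrees
    d: float = 0.01        # void floor density

    def __post_init__(self) -> None:
        for name in ("C_R", "C_T", "C_X", "L"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.theta < 90:
            raise ValueError("theta must lie in (0, 90) degrees")
        if self.xi < 0 or self.eta < 0:
            raise ValueError("xi and eta must be non-negative")
        if self.xi + self.eta >= 90:
            raise ValueError("xi + eta must be < 90 degrees")
        if not 0 < self.d < 1:
            raise ValueError("void floor d must lie in (0, 1)")

    @classmethod
    def from_cm(cls, C_R: float = 0.04, C_T: float = 0.02, C_X: float = 0.04,
                L: float = 0.6, **kw) -> "GeometryParams":
        """Construct from lengths given in centimeters."""
        return cls(C_R=C_R * 1e-2, C_T=C_T * 1e-2, C_X=C_X * 1e-2, L=L * 1e-2, **kw)

    @property
    def outer_radius(self) -> float:
        """Outer radius R = C_T + C_R + L*sin(theta) of the conical part."""
        return self.C_T + self.C_R + self.L * math.sin(math.radians(self.theta))

    @property
    def half_length(self) -> float:
        """Axial half extent C_X/2 + L*cos(theta)."""
        return self.C_X / 2 + self.L * math.cos(math.radians(self.theta))

    def inner_profile(self, ax: np.ndarray) -> np.ndarray:
        """Radius of the concave (inner) hourglass surface at |x| = ``ax``."""
        ax = np.asarray(ax, dtype=float)
        tan_t = math.tan(math.radians(self.theta))
        return self.C_R + np.maximum(ax - self.C_X / 2, 0.0) * tan_t


@dataclass(frozen=True)
class Facets:
    """A set of boundary facets of the voxel mesh.

    ``elems`` holds the (i, j, k) grid index of the element owning each
    facet; ``axis``/``sign`` give the outward face direction.  All facets
    are axis-aligned squares of area h^2.
    """

    elems: np.ndarray      # (M, 3) int
    axis: np.ndarray       # (M,) int, 0/1/2
    sign: np.ndarray       # (M,) int, +1/-1
    centroids: np.ndarray  # (M, 3) float
    normals: np.ndarray    # (M, 3) float, outward unit normals

    def __len__(self) -> int:
        return len(self.axis)

    def restrict(self, mask: np.ndarray) -> "Facets":
        return Facets(self.elems[mask], self.axis[mask], self.sign[mask],
                      self.centroids[mask], self.normals[mask])


@dataclass(frozen=True)
class AnalysisDomain:
    """Labeled voxel discretization of the vertebral-body analysis domain."""

    params: GeometryParams
    h: float                       # voxel edge length, m
    shape: tuple                   # (nx, ny, nz) elements
    lo: np.ndarray                 # (3,) physical coordinate of grid min corner
    labels: np.ndarray             # (nx, ny, nz) int8 region labels
    symmetry_planes: frozenset     # subset of {"XY", "YZ", "ZX"}
    facets: Mapping[str, Facets] = field(repr=False)

    @property
    def reduction(self) -> float:
        """Symmetry reduction factor: 1, 1/2, 1/4 or 1/8."""
        return 0.5 ** len(self.symmetry_planes)

    @property
    def reduced_axes(self) -> tuple:
        """Axes along which the grid spans only the non-negative half."""
        return tuple(sorted(PLANE_NORMAL_AXIS[p] for p in self.symmetry_planes))

    @property
    def in_domain(self) -> np.ndarray:
        """Boolean mask of elements belonging to the analysis domain Omega."""
        return self.labels != OUTSIDE

    @property
    def n_elements(self) -> int:
        return int(self.in_domain.sum())

    def element_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) physical coordinates of voxel centers."""
        nx, ny, nz = self.shape
        xs = self.lo[0] + (np.arange(nx) + 0.5) * self.h
        ys = self.lo[1] + (np.arange(ny) + 0.5) * self.h
        zs = self.lo[2] + (np.arange(nz) + 0.5) * self.h
        return np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)

    def node_coords(self) -> tuple:
        """1D node coordinate arrays (x, y, z) of the (n+1)^3 grid nodes."""
        nx, ny, nz = self.shape
        return (self.lo[0] + np.arange(nx + 1) * self.h,
                self.lo[1] + np.arange(ny + 1) * self.h,
                self.lo[2] + np.arange(nz + 1) * self.h)

    def full_domain(self) -> "AnalysisDomain":
        """The unreduced (full) domain at the same resolution."""
        if not self.symmetry_planes:
            return self
        return build_domain(self.params, self.h, symmetry=())

    def volume(self) -> float:
        """Volume of Omega (m^3)."""
        return self.n_elements * self.h ** 3


@dataclass
class DensityField:
    """Per-element relative density on an :class:`AnalysisDomain`.

    ``values`` is defined on the domain grid; OUTSIDE elements carry 0 and
    are ignored by every consumer.  ``fixed`` marks elements whose density
    is pinned (autocentrum and arches at 1, arch gaps at the floor d).
    """

    domain: AnalysisDomain
    values: np.ndarray  # (nx, ny, nz) float

    @property
    def fixed(self) -> np.ndarray:
        lab = self.domain.labels
        return (lab == AUTOCENTRUM) | (lab == ARCH) | (lab == ARCH_GAP)

    @property
    def design(self) -> np.ndarray:
        return self.domain.labels == DESIGN

    def copy(self) -> "DensityField":
        return DensityField(self.domain, self.values.copy())


def _normalize_symmetry(symmetry) -> frozenset:
    """Accept a plane collection or a reduction fraction."""
    if symmetry is None:
        return frozenset()
    if isinstance(symmetry, (int, float)):
        table = {1.0: (), 0.5: ("XY",), 0.25: ("XY", "YZ"),
                 0.125: ("XY", "YZ", "ZX")}
        try:
            symmetry = table[float(symmetry)]
        except KeyError:
            raise ValueError(
                f"reduction fraction {symmetry!r} not in {{1, 1/2, 1/4, 1/8}}; "
                "pass an explicit plane tuple to disambiguate")
    planes = frozenset(symmetry)
    unknown = planes - set(PLANE_NORMAL_AXIS)
    if unknown:
        raise ValueError(f"unknown symmetry plane(s) {sorted(unknown)}")
    return planes


def _classify_centers(params: GeometryParams, x: np.ndarray, y: np.ndarray,
                      z: np.ndarray, h: float):
    """Label voxel centers; returns (labels, void_type) int8 arrays."""
    ax = np.abs(x)
    r = np.hypot(y, z)
    R = params.outer_radius
    hl = params.half_length
    prof = params.inner_profile(np.minimum(ax, hl))

    labels = np.full(x.shape, OUTSIDE, dtype=np.int8)
    void = np.zeros(x.shape, dtype=np.int8)

    beyond_axial = ax > hl
    inner = (~beyond_axial) & (r < prof)
    radial = (~beyond_axial) & (r > R)
    void[beyond_axial] = _VOID_AXIAL
    void[inner] = _VOID_INNER
    void[radial] = _VOID_RADIAL

    in_dom = ~(beyond_axial | inner | radial)
    shell = in_dom & (r <= prof + params.C_T)
    labels[shell] = AUTOCENTRUM

    ext = in_dom & ~shell  # external domain: arches, gaps, design
    # Pole angle: angular distance (deg) from the nearest of the +-z midlines.
    alpha = np.degrees(np.arctan2(np.abs(y), np.abs(z)))
    # Angular half-width subtended by half a voxel at this radius: used to
    # keep the thin arch wedges connected on coarse grids.
    delta = np.degrees(np.arctan2(h / 2, np.maximum(r, h / 2)))
    gap = ext & (alpha < params.eta)
    arch = np.zeros(x.shape, dtype=bool)
    if params.xi > 0:
        arch = (ext & ~gap
                & (alpha - delta <= params.eta + params.xi)
                & (alpha + delta >= params.eta))
    labels[ext & ~gap & ~arch] = DESIGN
    if params.eta > 0:
        labels[gap] = ARCH_GAP
    else:
        labels[gap] = DESIGN  # degenerate: no gap region
    labels[arch] = ARCH
    return labels, void


def _arch_sector(params: GeometryParams, y: np.ndarray, z: np.ndarray,
                 h: float) -> np.ndarray:
    """True where the azimuth lies within an arch wedge (voxel-overlap rule)."""
    if params.xi <= 0:
        return np.zeros(y.shape, dtype=bool)
    r = np.hypot(y, z)
    alpha = np.degrees(np.arctan2(np.abs(y), np.abs(z)))
    delta = np.degrees(np.arctan2(h / 2, np.maximum(r, h / 2)))
    return (alpha - delta <= params.eta + params.xi) & (alpha + delta >= params.eta)


def build_domain(params: GeometryParams, element_size: float,
                 symmetry=("XY", "YZ", "ZX")) -> AnalysisDomain:
    """Discretize the analysis domain to a labeled voxel mesh.

    Parameters
    ----------
    params
        Geometry of the vertebral body.
    element_size
        Voxel edge length h (m).  Must not exceed the autocentrum shell
        thickness ``C_T``, otherwise the shell cannot be resolved.
    symmetry
        Symmetry planes across which the model is reduced (the grid spans
        only the non-negative side of each plane's normal axis), or a
        reduction fraction in {1, 1/2, 1/4, 1/8}.

    Returns
    -------
    AnalysisDomain
        Labeled grid with named boundary facet sets ``CONCAVE_SURFACE``,
        ``DISTAL_EDGE``, ``ARCH_EXTERNAL_SURFACE`` and ``ARCH_DISTAL_EDGE``.
    """
    h = float(element_size)
    if h <= 0:
        raise ValueError("element_size must be positive")
    if h > params.C_T * (1 + 1e-9):
        raise ResolutionError(
            f"element_size {h:g} m cannot resolve the autocentrum shell "
            f"thickness C_T = {params.C_T:g} m; use element_size <= C_T")
    planes = _normalize_symmetry(symmetry)
    reduced = {PLANE_NORMAL_AXIS[p] for p in planes}

    ext = np.array([params.half_length, params.outer_radius, params.outer_radius])
    n_half = np.maximum(np.ceil(ext / h - 1e-9).astype(int), 1)
    shape = tuple(int(n) if a in reduced else int(2 * n)
                  for a, n in enumerate(n_half))
    lo = np.array([0.0 if a in reduced else -n_half[a] * h for a in range(3)])

    nx, ny, nz = shape
    # Pad by one virtual element ring so neighbor queries are uniform.
    xs = lo[0] + (np.arange(-1, nx + 1) + 0.5) * h
    ys = lo[1] + (np.arange(-1, ny + 1) + 0.5) * h
    zs = lo[2] + (np.arange(-1, nz + 1) + 0.5) * h
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    # Reflect virtual centers on reduced-axis lower boundaries so that cut
    # planes are recognized as interior (their mirror image is material).
    plabels, pvoid = _classify_centers(params, X, Y, Z, h)
    labels = plabels[1:-1, 1:-1, 1:-1].copy()

    facets = _collect_facets(params, plabels, pvoid, X, Y, Z, h)
    return AnalysisDomain(params=params, h=h, shape=shape, lo=lo,
                          labels=labels, symmetry_planes=planes, facets=facets)


def _collect_facets(params, plabels, pvoid, X, Y, Z, h):
    """Identify named boundary facet sets from the padded label grid."""
    core = (slice(1, -1),) * 3
    lab = plabels[core]
    concave, distal, arch_ext, arch_distal = [], [], [], []

    offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for dx, dy, dz in offs:
        axis = 0 if dx else (1 if dy else 2)
        sign = dx + dy + dz
        nb = plabels[1 + dx: plabels.shape[0] - 1 + dx,
                     1 + dy: plabels.shape[1] - 1 + dy,
                     1 + dz: plabels.shape[2] - 1 + dz]
        nbv = pvoid[1 + dx: pvoid.shape[0] - 1 + dx,
                    1 + dy: pvoid.shape[1] - 1 + dy,
                    1 + dz: pvoid.shape[2] - 1 + dz]
        is_out = nb == OUTSIDE
        auto = lab == AUTOCENTRUM
        arch = lab == ARCH

        def _facet_entry(mask):
            idx = np.argwhere(mask)
            if len(idx) == 0:
                return None
            cent = np.empty((len(idx), 3))
            cent[:, 0] = X[core][mask] + (h / 2) * dx
            cent[:, 1] = Y[core][mask] + (h / 2) * dy
            cent[:, 2] = Z[core][mask] + (h / 2) * dz
            normals = np.tile(np.array([dx, dy, dz], dtype=float), (len(idx), 1))
            return idx, np.full(len(idx), axis), np.full(len(idx), sign), cent, normals

        e = _facet_entry(auto & is_out & (nbv == _VOID_INNER))
        if e:
            concave.append(e)
        e = _facet_entry(auto & is_out & (nbv == _VOID_AXIAL))
        if e:
            distal.append(e)
        e = _facet_entry(arch & is_out & (nbv != _VOID_INNER))
        if e:
            arch_ext.append(e)
        # Distal edge of the arches: axial rim facets within the arch
        # angular sector (the wedge pinches out axially on coarse grids, so
        # the sector test on the facet centroid is the robust test).
        rim = (auto | arch) & is_out & (nbv == _VOID_AXIAL)
        if rim.any() and axis == 0:
            idx = np.argwhere(rim)
            cy = Y[core][rim]
            cz = Z[core][rim]
            sect = _arch_sector(params, cy, cz, h)
            keep = np.zeros(rim.shape, dtype=bool)
            keep[tuple(idx[sect].T)] = True
            e = _facet_entry(keep)
            if e:
                arch_distal.append(e)

    def _merge(parts):
        if not parts:
            z3 = np.zeros((0, 3))
            return Facets(np.zeros((0, 3), int), np.zeros(0, int),
                          np.zeros(0, int), z3, z3)
        return Facets(*(np.concatenate([p[i] for p in parts]) for i in range(5)))

    return {
        "CONCAVE_SURFACE": _merge(concave),
        "DISTAL_EDGE": _merge(distal),
        "ARCH_EXTERNAL_SURFACE": _merge(arch_ext),
        "ARCH_DISTAL_EDGE": _merge(arch_distal),
    }


def initial_density(domain: AnalysisDomain, init_value: float | None = None
                    ) -> DensityField:
    """Initial density field: pinned fixed regions, ``init_value`` elsewhere.

    The autocentrum and arches start (and stay) at rho = 1, the arch gaps at
    the floor d, and every design element at ``init_value`` (default: the
    floor d, so material accretes from nothing during optimization).
    """
    d = domain.params.d
    if init_value is None:
        init_value = d
    if not d - 1e-12 <= init_value <= 1 + 1e-12:
        raise ValueError(f"init_value {init_value} outside [d, 1] = [{d}, 1]")
    vals = np.zeros(domain.shape)
    lab = domain.labels
    vals[lab == AUTOCENTRUM] = 1.0
    vals[lab == ARCH] = 1.0
    vals[lab == ARCH_GAP] = d
    vals[lab == DESIGN] = float(init_value)
    return DensityField(domain, vals)


def mirror_full(domain: AnalysisDomain, field: DensityField | np.ndarray
                ) -> DensityField:
    """Reflect a reduced-model field across its symmetry planes.

    Returns a :class:`DensityField` on the unreduced grid.  Applying the
    active reflections to the output is the identity.
    """
    values = field.values if isinstance(field, DensityField) else np.asarray(field)
    if values.shape != domain.shape:
        raise ValueError("field shape does not match domain shape")
    full = domain.full_domain()
    out = values
    for axis in domain.reduced_axes:
        out = np.concatenate([np.flip(out, axis=axis), out], axis=axis)
    if out.shape != full.shape:  # pragma: no cover - sanity guard
        raise AssertionError("mirrored field does not match the full grid")
    return DensityField(full, out.astype(float, copy=True))


def restrict_to_reduced(full_field: np.ndarray, domain: AnalysisDomain) -> np.ndarray:
    """Restrict a full-grid array to a reduced domain's octant/quadrant/half."""
    out = np.asarray(full_field)
    for axis in domain.reduced_axes:
        n = out.shape[axis] // 2
        out = np.take(out, np.arange(n, 2 * n), axis=axis)
    return out
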