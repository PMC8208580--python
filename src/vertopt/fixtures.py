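"""Tiny synthetic test domains: boxes, bars, cantilevers.

These generators produce small rectangular :class:`AnalysisDomain` objects
(every element a design element unless a label array is given) with the six
outer faces exposed as facet regions ``XMIN`` .. ``ZMAX``.  They support
patch tests, sensitivity checks and 2D-like optimization benchmarks without
the full vertebra geometry.
"""

from __future__ import annotations

import numpy as np

from vertopt.geometry import (
    OUTSIDE,
    DESIGN,
    AnalysisDomain,
    DensityField,
    Facets,
    GeometryParams,
)
from vertopt.loads import LoadCase


def box_domain(shape, h: float, labels=None, d: float = 0.01,
               params: GeometryParams | None = None) -> AnalysisDomain:
    """An unreduced box of ``shape`` voxels with edge length ``h``.

    ``labels`` defaults to all-DESIGN.  The grid origin sits at (0, 0, 0),
    so plane constraints at coordinate 0 act on the min faces.
    """
    shape = tuple(int(n) for n in shape)
    if labels is None:
        labels = np.full(shape, DESIGN, dtype=np.int8)
    labels = np.asarray(labels, dtype=np.int8)
    if labels.shape != shape:
        raise ValueError("labels shape mismatch")
    params = params or GeometryParams(d=d)
    lo = np.zeros(3)
    facets = _box_facets(labels, lo, h)
    return AnalysisDomain(params=params, h=float(h), shape=shape, lo=lo,
                          labels=labels, symmetry_planes=frozenset(),
                          facets=facets)


def _box_facets(labels: np.ndarray, lo: np.ndarray, h: float):
    """Boundary faces of the in-domain region on the six box sides."""
    names = {0: ("XMIN", "XMAX"), 1: ("YMIN", "YMAX"), 2: ("ZMIN", "ZMAX")}
    in_dom = labels != OUTSIDE
    out = {}
    for axis in range(3):
        for sign, name in zip((-1, 1), names[axis]):
            layer = 0 if sign < 0 else labels.shape[axis] - 1
            idx = np.argwhere(np.take(in_dom, layer, axis=axis))
            elems = np.insert(idx, axis, layer, axis=1)
            cent = lo + (elems + 0.5) * h
            cent[:, axis] += sign * h / 2
            normals = np.zeros((len(elems), 3))
            normals[:, axis] = sign
            out[name] = Facets(elems=elems,
                               axis=np.full(len(elems), axis),
                               sign=np.full(len(elems), sign),
                               centroids=cent, normals=normals)
    return out


def uniform_density(domain: AnalysisDomain, value: float = 1.0) -> DensityField:
    """Constant density on the in-domain elements."""
    vals = np.where(domain.in_domain, float(value), 0.0)
    return DensityField(domain, vals)


def face_traction_case(name: str, region: str, traction_vector,
                       fixed_planes=(), symmetry_planes=(),
                       facet_filter=None, point_constraints=()) -> LoadCase:
    """A generic constant-traction load case for fixture domains.

    ``fixed_planes`` is a tuple of (axis, coordinate, components) plane
    constraints; ``traction_vector`` is a constant (3,) vector or a
    callable (centroids, normals) -> (M, 3).
    """
    if callable(traction_vector):
        t = traction_vector
    else:
        vec = np.asarray(traction_vector, dtype=float)

        def t(c, n, _v=vec):
            return np.tile(_v, (len(c), 1))

    return LoadCase(name=name, traction=t, facet_region=region,
                    plane_constraints=tuple(fixed_planes),
                    symmetry_planes=frozenset(symmetry_planes),
                    facet_filter=facet_filter,
                    point_constraints=tuple(point_constraints))


def cantilever_2d(nx: int = 16, ny: int = 10, h: float = 1e-3,
                  traction: float = -1e6):
    """A one-voxel-thick cantilever: clamped at x = 0, tip load in -y.

    Plane-strain conditions are imposed by constraining u_z on both z
    faces.  Returns (domain, load_case).
    """
    dom = box_domain((nx, ny, 1), h)
    case = face_traction_case(
        "cantilever_tip", "XMAX", (0.0, traction, 0.0),
        fixed_planes=((0, 0.0, (0, 1, 2)), (2, 0.0, (2,)), (2, h, (2,))),
        facet_filter=lambda c: c[:, 1] <= 2.5 * h,
    )
    return dom, case
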