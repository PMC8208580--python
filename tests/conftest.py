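"""Shared fixtures: small geometries, fixture domains, painting helpers."""

from __future__ import annotations

import numpy as np
import pytest

from vertopt import fem, geometry as geo
from vertopt.fixtures import box_domain, uniform_density


@pytest.fixture(scope="session")
def table_params() -> geo.GeometryParams:
    """The reference vertebra geometry (desk defaults)."""
    return geo.GeometryParams()


@pytest.fixture(scope="session")
def coarse_params() -> geo.GeometryParams:
    """A 2x scaled-up vertebra: same shape, half the voxels per axis.

    Doubling every length doubles the resolvable element size, which keeps
    unit tests fast while exercising identical geometry/label logic.
    """
    return geo.GeometryParams(C_R=0.08e-2, C_T=0.04e-2, C_X=0.08e-2, L=1.2e-2)


@pytest.fixture(scope="session")
def coarse_h() -> float:
    return 0.04e-2


@pytest.fixture(scope="session")
def material() -> fem.MaterialModel:
    return fem.MaterialModel()


@pytest.fixture(scope="session")
def eighth_domain(coarse_params, coarse_h):
    return geo.build_domain(coarse_params, coarse_h,
                            symmetry=("XY", "YZ", "ZX"))


@pytest.fixture(scope="session")
def full_domain(coarse_params, coarse_h):
    return geo.build_domain(coarse_params, coarse_h, symmetry=())


@pytest.fixture()
def small_box():
    dom = box_domain((4, 4, 4), 1e-3)
    return dom, uniform_density(dom, 0.5)


def paint_design(domain, predicate) -> "geo.DensityField":
    """Density field: floor everywhere, rho = 1 on design elements where
    ``predicate(s_frac, phi_deg, height_vox)`` holds.

    ``s_frac`` is the axial fraction in [0, 1], ``phi_deg`` the azimuth from
    +y in (-180, 180], ``height_vox`` the radial protrusion above the
    autocentrum outer surface in voxels.
    """
    field = geo.initial_density(domain)
    p = domain.params
    cent = domain.element_centers()
    x, y, z = cent[..., 0], cent[..., 1], cent[..., 2]
    nx = domain.shape[0]
    s = (x - domain.lo[0]) / (nx * domain.h)
    phi = np.degrees(np.arctan2(z, y))
    shell_outer = p.inner_profile(np.minimum(np.abs(x), p.half_length)) + p.C_T
    hgt = (np.hypot(y, z) - shell_outer) / domain.h
    mask = (domain.labels == geo.DESIGN) & predicate(s, phi, hgt)
    field.values[mask] = 1.0
    return field


@pytest.fixture(scope="session")
def painter():
    return paint_design


def oc_reference(dom, grp, material, v_f, init, iters=150, move=0.2):
    """Independent optimality-criteria optimizer (multiplicative update).

    The classic OC scheme: rho <- clip(rho * sqrt(-dc / lambda)) with the
    multiplier bisected to meet the volume bound.  Shares only the FEM
    solver with the production reaction-diffusion scheme; the update path
    is entirely separate, so it serves as an independent benchmark.
    """
    d = dom.params.d
    vals = np.where(dom.in_domain, float(init), 0.0)
    design = dom.labels == geo.DESIGN
    vfem = fem.VoxelFEM(dom, material)
    for _ in range(iters):
        sols = vfem.solve_group(vals, grp)
        sens = fem.sensitivity(dom, geo.DensityField(dom, vals),
                               material, sols)
        s = sens[design]
        x = vals[design]
        l1, l2 = 1e-40, 1e6
        while (l2 - l1) / (l1 + l2) > 1e-8:
            lm = 0.5 * (l1 + l2)
            xnew = np.clip(x * np.sqrt(np.maximum(-s, 0) / lm),
                           np.maximum(x - move, d), np.minimum(x + move, 1.0))
            if xnew.mean() > v_f:
                l1 = lm
            else:
                l2 = lm
        vals = vals.copy()
        vals[design] = xnew
    return fem.group_objective(vfem.solve_group(vals, grp))
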