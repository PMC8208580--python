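"""Feature extraction: isosurfaces, occupancy maps, structure classification."""

import numpy as np
import pytest
from scipy import ndimage

from vertopt import features as ft, geometry as geo
from vertopt.fixtures import box_domain


@pytest.fixture(scope="module")
def full_dom(coarse_params, coarse_h):
    return geo.build_domain(coarse_params, coarse_h, symmetry=())


class TestExtractIsosurface:
    def test_sphere_area_matches_analytic(self):
        h = 1e-3
        dom = box_domain((20, 20, 20), h)
        cent = dom.element_centers()
        c0 = cent.reshape(-1, 3).mean(axis=0)
        r = np.linalg.norm(cent - c0, axis=-1)
        radius = 7 * h
        # Smooth radial ramp so the 0.5 level sits exactly at `radius`.
        vals = np.clip(1.0 - (r - radius) / (2 * h) * 0.5 - 0.0, 0.0, 1.0)
        vals = 0.5 + (radius - r) / (4 * h)
        mesh = ft.extract_isosurface(geo.DensityField(dom, np.clip(vals, 0, 1)))
        assert mesh.area == pytest.approx(4 * np.pi * radius ** 2, rel=0.05)

    def test_void_field_gives_empty_mesh(self, full_dom):
        rho = geo.DensityField(full_dom,
                               np.where(full_dom.in_domain, 0.01, 0.0))
        mesh = ft.extract_isosurface(rho)
        assert len(mesh.vertices) == 0

    def test_mirror_equivariance(self):
        rng = np.random.default_rng(0)
        dom = box_domain((8, 8, 8), 1e-3)
        vals = ndimage.gaussian_filter(rng.random(dom.shape), 1.2)
        vals = (vals - vals.min()) / (vals.ptp() if hasattr(vals, 'ptp')
                                      else np.ptp(vals))
        m1 = ft.extract_isosurface(geo.DensityField(dom, vals))
        m2 = ft.extract_isosurface(geo.DensityField(dom, vals[::-1]))
        # Marching cubes resolves ambiguous cells asymmetrically, so the
        # meshes agree only to a fraction of a voxel.
        assert m1.area == pytest.approx(m2.area, rel=5e-3)
        lo = dom.lo[0]
        hi = dom.lo[0] + dom.shape[0] * dom.h
        flipped_x = (lo + hi) - m2.vertices[:, 0]
        assert np.sort(m1.vertices[:, 0])[::10] == pytest.approx(
            np.sort(flipped_x)[::10], abs=0.5 * dom.h)


class TestUnwrapOccupancy:
    def test_empty_design_all_zero(self, full_dom):
        rho = geo.initial_density(full_dom)
        occ = ft.unwrap_occupancy(rho)
        assert not occ.occ.any()
        assert not occ.coated.any()

    def test_lateral_slab_gives_full_height_column(self, full_dom, painter):
        rho = painter(full_dom, lambda s, phi, hgt: np.abs(phi) <= 8)
        occ = ft.unwrap_occupancy(rho)
        cols = np.flatnonzero(occ.occ.any(axis=0))
        # All occupied azimuth bins hug the +y midline.
        assert len(cols) > 0
        assert np.all(np.abs(occ.phi_centers[cols]) < 15)
        # The column spans every axial slab that can hold design material
        # tall enough to clear the height floor.
        heights = occ.height[:, cols].max(axis=1)
        assert (heights >= 2).sum() >= 0.6 * occ.reachable.sum()

    def test_arch_sectors_masked(self, full_dom):
        occ = ft.unwrap_occupancy(geo.initial_density(full_dom))
        p = full_dom.params
        near_pole = (np.abs(occ.phi_centers - 90) < p.eta + p.xi) | \
                    (np.abs(occ.phi_centers + 90) < p.eta + p.xi)
        assert np.array_equal(occ.arch_mask, near_pole)

    def test_mirror_equivariance(self, full_dom):
        rng = np.random.default_rng(6)
        vals = np.where(full_dom.labels == geo.DESIGN,
                        (rng.random(full_dom.shape) > 0.8).astype(float), 0.0)
        base = geo.initial_density(full_dom)
        rho = geo.DensityField(full_dom, np.maximum(base.values, vals))
        m0 = ft.unwrap_occupancy(rho)
        flipped = geo.DensityField(full_dom, rho.values[::-1])
        m1 = ft.unwrap_occupancy(flipped)
        assert np.array_equal(m1.occ, m0.occ[::-1])

    def test_reduced_field_auto_mirrored(self, coarse_params, coarse_h):
        red = geo.build_domain(coarse_params, coarse_h,
                               symmetry=("XY", "YZ", "ZX"))
        rho = geo.initial_density(red, 1.0)
        occ = ft.unwrap_occupancy(rho)
        assert occ.occ.shape[0] == 2 * red.shape[0]


class TestCountAndClassify:
    def test_axial_slab_is_plate_ridge_per_side(self, full_dom, painter):
        rho = painter(full_dom, lambda s, phi, hgt:
                      (np.abs(phi) <= 10) | (np.abs(np.abs(phi) - 180) <= 10))
        rep = ft.count_and_classify(ft.unwrap_occupancy(rho))
        per = rep.counts_per_side()
        assert per["right"]["PLATE_RIDGE"] == 1
        assert per["left"]["PLATE_RIDGE"] == 1

    def test_four_corner_bumps_are_humps(self, full_dom, painter):
        def bumps(s, phi, hgt):
            near_rim = (s < 0.12) | (s > 0.88)
            lateral = (np.abs(np.abs(phi) - 30) < 10) | \
                      (np.abs(np.abs(phi) - 150) < 10)
            return near_rim & lateral
        rho = painter(full_dom, bumps)
        rep = ft.count_and_classify(ft.unwrap_occupancy(rho))
        assert rep.counts()["HUMP"] == 8  # 4 per lateral side at the corners

    def test_central_block_is_pillar(self, full_dom, painter):
        rho = painter(full_dom, lambda s, phi, hgt:
                      (np.abs(s - 0.5) < 0.15) & (np.abs(phi) < 12))
        rep = ft.count_and_classify(ft.unwrap_occupancy(rho))
        right = [c for c in rep.components if c.side == "right"]
        assert len(right) == 1
        assert right[0].classification == "PILLAR"
        assert not right[0].touches_distal_rim

    def test_oblique_v_counts_arms_as_diagonal_ridges(self, full_dom, painter):
        def vee(s, phi, hgt):
            return (np.abs(phi) < 45) & \
                (np.abs(np.abs(phi) - 40 * (1 - 2 * np.abs(s - 0.5))) < 6)
        rho = painter(full_dom, vee)
        rep = ft.count_and_classify(ft.unwrap_occupancy(rho))
        right = [c for c in rep.components if c.side == "right"]
        assert sum(c.multiplicity for c in right
                   if c.classification == "DIAGONAL_RIDGE") >= 2

    def test_uniform_coating_reads_as_shell(self, full_dom, painter):
        # Thin coating (below the protrusion floor) everywhere.
        rho = painter(full_dom, lambda s, phi, hgt: hgt <= 1.8)
        rep = ft.count_and_classify(ft.unwrap_occupancy(rho))
        counts = rep.counts_per_side()
        assert counts["right"]["SHELL"] == 1
        assert counts["left"]["SHELL"] == 1
        assert sum(rep.counts().values()) == 2

    def test_broad_thick_band_is_shell(self, full_dom, painter):
        rho = painter(full_dom, lambda s, phi, hgt: np.abs(phi) < 68)
        rep = ft.count_and_classify(ft.unwrap_occupancy(rho))
        right = [c for c in rep.components if c.side == "right"]
        assert len(right) == 1
        assert right[0].classification == "SHELL"

    def test_counting_invariant_under_reflections(self, full_dom, painter):
        rho = painter(full_dom, lambda s, phi, hgt:
                      (np.abs(s - 0.5) < 0.2) & (np.abs(np.abs(phi) - 25) < 8))
        base = ft.count_and_classify(ft.unwrap_occupancy(rho)).counts()
        for axis in range(3):
            flipped = geo.DensityField(full_dom,
                                       np.flip(rho.values, axis=axis))
            c = ft.count_and_classify(ft.unwrap_occupancy(flipped)).counts()
            assert c == base

    def test_dilation_never_increases_component_count(self, full_dom, painter):
        rng = np.random.default_rng(12)
        rho = painter(full_dom, lambda s, phi, hgt:
                      (np.abs(phi) < 60) &
                      (rng.random(s.shape) > 0.93))
        occ = ft.unwrap_occupancy(rho)
        rep0 = ft.count_and_classify(occ)
        occ.occ = ndimage.binary_dilation(occ.occ, np.ones((3, 3), bool))
        rep1 = ft.count_and_classify(occ)
        n0 = sum(1 for c in rep0.components)
        n1 = sum(1 for c in rep1.components)
        assert n1 <= max(n0, 1)

    def test_level_threshold_robustness(self, full_dom, painter):
        """Counts shift by at most 1 across occupancy levels 0.45-0.55."""
        rng = np.random.default_rng(3)
        base = painter(full_dom, lambda s, phi, hgt:
                       (np.abs(s - 0.5) < 0.25) & (np.abs(phi) < 15))
        # Soften the solid block so its boundary straddles the level.
        noise = 0.1 * ndimage.gaussian_filter(rng.random(full_dom.shape), 1.0)
        vals = np.clip(base.values - noise, 0.0, 1.0)
        vals[~(full_dom.labels == geo.DESIGN)] = base.values[
            ~(full_dom.labels == geo.DESIGN)]
        rho = geo.DensityField(full_dom, vals)
        totals = []
        for level in (0.45, 0.5, 0.55):
            cfg = ft.ClassifierConfig(level=level)
            rep = ft.count_and_classify(ft.unwrap_occupancy(rho, config=cfg),
                                        cfg)
            totals.append(sum(rep.counts().values()))
        assert max(totals) - min(totals) <= 1


class TestClassifyDesign:
    def test_reduced_input_accepted(self, coarse_params, coarse_h):
        red = geo.build_domain(coarse_params, coarse_h,
                               symmetry=("XY", "YZ", "ZX"))
        rep = ft.classify_design(geo.initial_density(red))
        assert rep.counts() == {c: 0 for c in ft.CLASSES}
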