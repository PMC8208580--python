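"""FEM: element stiffness, solves, compliance, sensitivities, identities."""

import numpy as np
import pytest

from vertopt import fem, geometry as geo, loads, optimizer as op
from vertopt.fixtures import box_domain, face_traction_case, uniform_density


class TestElementStiffness:
    def test_symmetric_and_rank(self, material):
        k = fem.element_stiffness(material, 1e-3)
        assert np.allclose(k, k.T, atol=0)
        evals = np.linalg.eigvalsh(k)
        scale = np.abs(evals).max()
        assert (np.abs(evals) < 1e-10 * scale).sum() == 6  # rigid-body modes
        assert np.all(evals > -1e-10 * scale)

    def test_rigid_translation_gives_zero_force(self, material):
        k = fem.element_stiffness(material, 2e-4)
        for comp in range(3):
            u = np.zeros(24)
            u[comp::3] = 1.0
            assert np.allclose(k @ u, 0.0, atol=1e-9 * np.abs(k).max())

    def test_quadrature_is_exact(self, material):
        """2-point Gauss integrates the trilinear stiffness exactly: a
        brute-force higher-order rule reproduces it to round-off."""
        k2 = fem.element_stiffness(material, 3e-4, n_gauss=2)
        k4 = fem.element_stiffness(material, 3e-4, n_gauss=4)
        assert np.allclose(k2, k4, rtol=1e-12)


class TestAssembleAndSolve:
    def test_uniaxial_bar_matches_analytic(self, material):
        """sigma * l / E0 tip displacement of a roller-guided bar."""
        h, nx = 1e-3, 8
        dom = box_domain((nx, 3, 3), h)
        rho = uniform_density(dom, 1.0)
        sigma = 2.0e6
        case = face_traction_case(
            "bar", "XMAX", (sigma, 0, 0),
            fixed_planes=((0, 0.0, (0,)), (1, 0.0, (1,)), (2, 0.0, (2,))))
        sol = fem.assemble_and_solve(dom, rho, material, case)
        tip = sol.u.reshape(nx + 1, 4, 4, 3)[-1, :, :, 0]
        exact = sigma * nx * h / material.E0
        assert np.allclose(tip, exact, rtol=1e-6)

    def test_compliance_scales_inversely_with_stiffness(self, material):
        dom = box_domain((4, 3, 3), 1e-3)
        rho = uniform_density(dom, 0.7)
        case = face_traction_case(
            "bar", "XMAX", (1e6, 0, 0),
            fixed_planes=((0, 0.0, (0, 1, 2)),))
        f1 = fem.assemble_and_solve(dom, rho, material, case).compliance
        stiff = fem.MaterialModel(2 * material.E0, material.nu, material.P)
        f2 = fem.assemble_and_solve(dom, rho, stiff, case).compliance
        assert f2 == pytest.approx(f1 / 2, rel=1e-9)

    def test_zero_traction_zero_solution(self, material):
        dom = box_domain((3, 3, 3), 1e-3)
        rho = uniform_density(dom, 1.0)
        case = face_traction_case("null", "XMAX", (0.0, 0.0, 0.0),
                                  fixed_planes=((0, 0.0, (0, 1, 2)),))
        sol = fem.assemble_and_solve(dom, rho, material, case)
        assert np.allclose(sol.u, 0.0)
        assert sol.compliance == 0.0

    def test_energy_identity(self, eighth_domain, material):
        """External work equals twice the stored strain energy."""
        rho = geo.initial_density(eighth_domain, 0.5)
        grp = loads.make_load_group("compressive_normal", eighth_domain)
        sol = fem.VoxelFEM(eighth_domain, material).solve_group(rho, grp)[0]
        ra = fem.VoxelFEM(eighth_domain, material).rho_active(rho)
        energy = 0.5 * float((ra ** material.P * sol.element_unit_energy).sum())
        assert sol.compliance == pytest.approx(2 * energy, rel=1e-6)

    def test_unconstrained_rigid_mode_raises(self, material):
        dom = box_domain((3, 3, 3), 1e-3)
        rho = uniform_density(dom, 1.0)
        case = face_traction_case("loose", "XMAX", (1e6, 0, 0))  # no fixity
        with pytest.raises(fem.SingularSystemError):
            fem.assemble_and_solve(dom, rho, material, case)

    def test_compliance_monotone_in_density(self, material):
        """Pointwise more material never increases compliance."""
        rng = np.random.default_rng(11)
        dom = box_domain((5, 4, 4), 1e-3)
        case = face_traction_case("bend", "XMAX", (0, 1e6, 0),
                                  fixed_planes=((0, 0.0, (0, 1, 2)),))
        vfem = fem.VoxelFEM(dom, material)
        grp = loads.LoadGroup(cases=[case], name="bend")
        for _ in range(3):
            a = 0.01 + 0.99 * rng.random(dom.shape)
            b = np.clip(a - 0.3 * rng.random(dom.shape), 0.01, 1.0)
            fa = fem.group_objective(vfem.solve_group(a, grp))
            fb = fem.group_objective(vfem.solve_group(b, grp))
            assert fa <= fb * (1 + 1e-9)

    def test_mesh_convergence_compressive(self, coarse_params, material):
        """Compliance at rho = 1 changes < 5% when the mesh is refined."""
        vals = []
        for h in (0.04e-2, 0.02e-2):
            dom = geo.build_domain(coarse_params, h,
                                   symmetry=("XY", "YZ", "ZX"))
            grp = loads.make_load_group("compressive_normal", dom)
            rho = geo.initial_density(dom, 1.0)
            rho.values[dom.labels == geo.ARCH_GAP] = 1.0  # pure solid body
            sol = fem.VoxelFEM(dom, material).solve_group(rho, grp)[0]
            vals.append(sol.compliance / dom.reduction)
        assert abs(vals[1] - vals[0]) / vals[1] < 0.05


class TestSensitivity:
    def test_matches_central_finite_differences(self, material):
        """Adjoint sensitivity vs central differences on a 4^3 fixture."""
        dom = box_domain((4, 4, 4), 1e-3)
        rng = np.random.default_rng(5)
        vals = 0.2 + 0.6 * rng.random(dom.shape)
        case = face_traction_case("bend", "XMAX", (0, 1e6, 0.3e6),
                                  fixed_planes=((0, 0.0, (0, 1, 2)),))
        grp = loads.LoadGroup(cases=[case], name="bend")
        vfem = fem.VoxelFEM(dom, material)
        sols = vfem.solve_group(vals, grp)
        sens = fem.sensitivity(dom, geo.DensityField(dom, vals), material, sols)
        delta = 1e-6
        rng2 = np.random.default_rng(9)
        picks = [tuple(rng2.integers(0, 4, size=3)) for _ in range(6)]
        for ijk in picks:
            vp, vm = vals.copy(), vals.copy()
            vp[ijk] += delta
            vm[ijk] -= delta
            fp = fem.group_objective(vfem.solve_group(vp, grp))
            fm = fem.group_objective(vfem.solve_group(vm, grp))
            fd = (fp - fm) / (2 * delta)
            assert sens[ijk] == pytest.approx(fd, rel=0.01)

    def test_nonpositive_and_zero_on_fixed(self, eighth_domain, material):
        rho = geo.initial_density(eighth_domain, 0.4)
        grp = loads.make_load_group("compressive_normal", eighth_domain)
        sols = fem.VoxelFEM(eighth_domain, material).solve_group(rho, grp)
        sens = fem.sensitivity(eighth_domain, rho, material, sols)
        assert np.all(sens <= 0)
        assert np.all(sens[eighth_domain.labels != geo.DESIGN] == 0)


class TestPartnerIdentities:
    """Paired load cases are exact negations / mirror images."""

    @pytest.mark.parametrize("name", ["shear", "torsion"])
    def test_negation_partner_equals_direct_solve(self, eighth_domain,
                                                  material, name):
        rho = geo.initial_density(eighth_domain, 0.35)
        grp = loads.make_load_group(name, eighth_domain)
        vfem = fem.VoxelFEM(eighth_domain, material)
        fast = vfem.solve_group(rho, grp)
        slow = vfem.solve_group(rho, grp, use_partner_identities=False)
        for a, b in zip(fast, slow):
            assert a.compliance == pytest.approx(b.compliance, rel=1e-6)
            assert np.allclose(a.u, b.u, atol=1e-6 * np.abs(b.u).max())

    def test_mirror_partner_equals_direct_solve(self, coarse_params, coarse_h,
                                                material):
        dom = geo.build_domain(coarse_params, coarse_h, symmetry=("XY", "YZ"))
        rho = geo.initial_density(dom, 0.35)  # y-symmetric field
        grp = loads.make_load_group("bending_surface", dom)
        vfem = fem.VoxelFEM(dom, material)
        fast = vfem.solve_group(rho, grp)
        slow = vfem.solve_group(rho, grp, use_partner_identities=False)
        for a, b in zip(fast, slow):
            assert a.compliance == pytest.approx(b.compliance, rel=1e-6)
        assert np.allclose(fast[1].element_unit_energy,
                           slow[1].element_unit_energy,
                           rtol=1e-5, atol=1e-12)

    def test_mirror_partner_refused_for_asymmetric_density(
            self, coarse_params, coarse_h, material):
        dom = geo.build_domain(coarse_params, coarse_h, symmetry=("XY", "YZ"))
        rho = geo.initial_density(dom, 0.35)
        ny = dom.shape[1]
        sl = rho.values[:, ny // 4, :]
        sl[dom.labels[:, ny // 4, :] == geo.DESIGN] = 0.9
        grp = loads.make_load_group("bending_surface", dom)
        vfem = fem.VoxelFEM(dom, material)
        with pytest.raises(ValueError, match="mirror-symmetric"):
            vfem.solve_group(rho, grp, use_partner_identities=True)

    @pytest.mark.parametrize("name", ["shear", "torsion"])
    def test_eighth_reduction_matches_literal_model(self, coarse_params,
                                                    coarse_h, material, name):
        """Antisymmetric eighth model reproduces the half/full construction."""
        results = {}
        for sym in [loads.CASE_SYMMETRY[name], loads.CASE_SYMMETRY_ALT[name][0]]:
            dom = geo.build_domain(coarse_params, coarse_h, symmetry=sym)
            grp = loads.make_load_group(name, dom)
            rho = geo.initial_density(dom, 0.3)
            sols = fem.VoxelFEM(dom, material).solve_group(rho, grp)
            results[len(sym)] = fem.group_objective(sols) / dom.reduction
        vals = list(results.values())
        assert vals[0] == pytest.approx(vals[1], rel=1e-6)


class TestGroupObjective:
    def test_average_of_compliances(self, eighth_domain, material):
        rho = geo.initial_density(eighth_domain, 0.4)
        grp = loads.make_load_group("shear", eighth_domain)
        sols = fem.VoxelFEM(eighth_domain, material).solve_group(rho, grp)
        f = fem.group_objective(sols)
        assert f == pytest.approx(np.mean([s.compliance for s in sols]))
        assert sols[0].compliance == pytest.approx(sols[1].compliance)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fem.group_objective([])
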