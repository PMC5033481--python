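import math

import numpy as np
import pytest

from fesff.forcefield import (
    ForceConstant,
    ForceFieldParamSet,
    TorsionParams,
    build_param_set,
    consistency_check,
    displaced_geometry,
    finite_difference_fc,
    fit_cosine_series,
    mode_force_constant,
)
from fesff.internals import InternalCoordinate, coordinate_value
from fesff.modes import assign_modes, compute_modes
from fesff.synthetic import (
    build_template,
    cosine_series_energy,
    generate_torsion_scan,
)
from fesff.units import MDYNE_PER_A_TO_KCAL, convert_force_constant

from conftest import make_diatomic


BOND = InternalCoordinate("stretch", (0, 1), "K(Fe-Fe)")


class TestModeRoute:
    def test_diatomic_round_trip(self):
        model = make_diatomic(k_mdyne=0.230)
        modes = compute_modes(model.to_bundle(), project_tr=True)
        bond = model.internal_coordinates()[0]
        fc = mode_force_constant(modes, 5, bond, model.coords)
        assert fc.value_mdyne == pytest.approx(0.230, rel=1e-6)
        assert fc.value == pytest.approx(0.230 * MDYNE_PER_A_TO_KCAL,
                                         rel=1e-6)

    def test_k_scales_with_frequency_squared(self):
        m1 = make_diatomic(k_mdyne=0.5)
        m4 = make_diatomic(k_mdyne=2.0)  # doubled frequency, same mu
        k1 = mode_force_constant(compute_modes(m1.to_bundle(), True), 5,
                                 m1.internal_coordinates()[0], m1.coords)
        k4 = mode_force_constant(compute_modes(m4.to_bundle(), True), 5,
                                 m4.internal_coordinates()[0], m4.coords)
        assert k4.value == pytest.approx(4.0 * k1.value, rel=1e-9)

    def test_rigid_mode_rejected(self, fe2):
        modes = compute_modes(fe2.to_bundle(), project_tr=True)
        with pytest.raises(ValueError, match="undefined"):
            mode_force_constant(modes, 0)  # translation


class TestFiniteDifference:
    def test_quadratic_oracle_exact(self):
        r0 = 2.22
        coords = np.array([[0.0, 0, 0], [0, 0, r0]])

        def oracle(x):
            r = np.linalg.norm(x[1] - x[0])
            return 0.5 * 209.0 * (r - r0) ** 2

        fc = finite_difference_fc(oracle, coords, BOND, step=0.01)
        assert fc.value == pytest.approx(209.0, rel=1e-10)
        assert fc.method == "finite_difference"

    @pytest.mark.parametrize("npoints", [5, 7])
    def test_morse_curvature_converges_to_2Da2(self, npoints):
        d_e, a, r0 = 100.0, 1.5, 2.0
        coords = np.array([[0.0, 0, 0], [0, 0, r0]])

        def morse(x):
            r = np.linalg.norm(x[1] - x[0])
            return d_e * (1.0 - math.exp(-a * (r - r0))) ** 2

        errs = []
        for h in (0.04, 0.02, 0.01):
            fc = finite_difference_fc(morse, coords, BOND, step=h,
                                      npoints=npoints)
            errs.append(abs(fc.value - 2 * d_e * a * a))
        assert errs[-1] < 1e-3              # -> 450 as h -> 0
        assert errs[0] > errs[-1]           # observed convergence in h

    def test_even_npoints_rejected(self):
        with pytest.raises(ValueError, match="npoints"):
            finite_difference_fc(lambda x: 0.0, np.zeros((2, 3)), BOND,
                                 npoints=4)

    def test_template_stretch_and_bend_recovery(self, template):
        """Constrained displacement isolates each generating constant;
        the quadratic potential makes the 5-point stencil exact."""
        coords_set = template.internal_coordinates()
        for term, coord in zip(template.terms, coords_set):
            if term.kind == "torsion":
                continue
            hold = [c for c in coords_set if c.label != coord.label]
            fc = finite_difference_fc(template.energy, template.coords,
                                      coord, hold=hold)
            assert fc.value == pytest.approx(term.constant, rel=1e-6), \
                coord.label

    def test_displaced_geometry_moves_only_target(self, rieske):
        coords_set = rieske.internal_coordinates()
        target = coords_set[0]
        hold = coords_set[1:]
        x = displaced_geometry(rieske.coords, target, 0.02, hold=hold)
        assert coordinate_value(target, x) == pytest.approx(
            coordinate_value(target, rieske.coords) + 0.02, abs=1e-10)
        for c in hold:
            assert coordinate_value(c, x) == pytest.approx(
                coordinate_value(c, rieske.coords), abs=1e-10), c.label

    def test_single_term_routes_agree(self):
        model = make_diatomic(k_mdyne=1.145)
        modes = compute_modes(model.to_bundle(), project_tr=True)
        bond = model.internal_coordinates()[0]
        k_mode = mode_force_constant(modes, 5, bond, model.coords)
        k_fd = finite_difference_fc(model.energy, model.coords, bond)
        passed, ratio = consistency_check(k_mode, k_fd)
        assert passed
        assert ratio == pytest.approx(1.0, rel=1e-6)


class TestConsistency:
    def test_pass_fail_and_ratio(self):
        a = ForceConstant("K(x)", "K-stretch", 209.0, "mode")
        b = ForceConstant("K(x)", "K-stretch", 209.0, "finite_difference")
        ok, ratio = consistency_check(a, b)
        assert ok and ratio == 1.0
        c = ForceConstant("K(x)", "K-stretch", 250.0, "mode")
        d = ForceConstant("K(x)", "K-stretch", 200.0, "finite_difference")
        ok, ratio = consistency_check(c, d, tolerance=0.20)
        assert not ok
        assert ratio == pytest.approx(1.25)

    def test_label_mismatch(self):
        a = ForceConstant("K(x)", "K-stretch", 1.0, "mode")
        b = ForceConstant("K(y)", "K-stretch", 1.0, "finite_difference")
        with pytest.raises(ValueError, match="mismatch"):
            consistency_check(a, b)

    def test_mdyne_consistency(self):
        rec = ForceConstant("K(x)", "K-stretch", 209.0, "mode")
        assert convert_force_constant(rec.value_mdyne, "mdyne_per_A",
                                      "kcal_per_mol_A2") == pytest.approx(
            rec.value, rel=1e-9)
        bend = ForceConstant("H(x)", "H-bend", 70.0, "mode")
        assert bend.value_mdyne is None


class TestCosineFit:
    def test_exact_recovery_single_term(self):
        scan = generate_torsion_scan([(1, 2.0, 0.0)], grid_deg=30.0)
        fit = fit_cosine_series(scan, [1, 2, 3])
        assert dict((n, v) for n, v, _ in fit.terms) == pytest.approx(
            {1: 2.0})
        assert fit.residual_rms == pytest.approx(0.0, abs=1e-12)
        assert fit.offset == pytest.approx(0.0, abs=1e-12)

    def test_constant_scan_all_zero(self):
        scan = generate_torsion_scan([], grid_deg=30.0)
        fit = fit_cosine_series(scan, [1, 2, 3])
        assert fit.terms == []

    def test_phase_180_and_free_phase(self):
        scan = generate_torsion_scan([(2, 1.5, 180.0)], grid_deg=30.0)
        fit = fit_cosine_series(scan, [1, 2, 3])
        assert fit.terms == [(2, pytest.approx(1.5), 180.0)]
        scan2 = generate_torsion_scan([(3, 0.8, 60.0)], grid_deg=15.0)
        fit2 = fit_cosine_series(scan2, [3], fix_phases=False)
        n, v, g = fit2.terms[0]
        assert (n, v, g) == (3, pytest.approx(0.8), pytest.approx(60.0))

    def test_underdetermined_rejected(self):
        scan = generate_torsion_scan([(1, 1.0, 0.0)], grid_deg=120.0)  # 3 pts
        with pytest.raises(ValueError, match="underdetermined"):
            fit_cosine_series(scan, [1, 2, 3])

    def test_noisy_recovery_within_5_sigma(self):
        truth = [(1, 2.0, 0.0), (3, 0.7, 180.0)]
        sigma = 0.01
        for seed in range(100):
            scan = generate_torsion_scan(truth, grid_deg=30.0,
                                         noise_sd=sigma, seed=seed)
            fit = fit_cosine_series(scan, [1, 3])
            got = {n: (v, g) for n, v, g in fit.terms}
            for n, v, g in truth:
                assert got[n][0] == pytest.approx(v, abs=5 * sigma)
                assert got[n][1] == g

    def test_fit_reproduces_scan_energies(self):
        truth = [(1, 1.2, 0.0), (2, 0.5, 180.0)]
        scan = generate_torsion_scan(truth, grid_deg=30.0)
        fit = fit_cosine_series(scan, [1, 2])
        model = cosine_series_energy(fit.terms, scan.angles_deg) + fit.offset
        np.testing.assert_allclose(model, scan.energies, atol=1e-10)


class TestParamSet:
    def _pipeline(self, name):
        model = build_template(name)
        modes = compute_modes(model.to_bundle(), project_tr=True)
        coords_set = model.internal_coordinates()
        assignment = assign_modes(modes, coords_set, model.coords)
        fd = {}
        for c in coords_set:
            if c.kind == "torsion":
                continue
            hold = [o for o in coords_set if o.label != c.label]
            fd[c.label] = finite_difference_fc(model.energy, model.coords,
                                               c, hold=hold)
        return model, modes, coords_set, assignment, fd

    def test_rieske_param_labels(self):
        model, modes, coords_set, assignment, fd = self._pipeline("rieske")
        params = build_param_set(assignment, modes, coords_set,
                                 model.coords, fd_results=fd)
        labels = {r.label for r in params.stretches + params.bends}
        assert {"K(Fe-S(b))", "K(Fe-S(t))", "K(Fe-N(t))", "K(Fe-Fe)",
                "H(S(b)-Fe-S(t))", "H(S(t)-Fe-S(t))", "H(S(b)-Fe-N(t))",
                "H(N(t)-Fe-N(t))"} <= labels
        # finite-difference values preferred: they equal the generators
        by_label = {t.label: t.constant for t in model.terms}
        for rec in params.stretches + params.bends:
            assert rec.value == pytest.approx(by_label[rec.label], rel=1e-6)

    def test_mode_route_ratio_reported_on_multiterm_template(self):
        model, modes, coords_set, assignment, fd = self._pipeline("fes_4cys")
        ratios = {}
        for label, (idx, _) in assignment.assignments.items():
            c = next(x for x in coords_set if x.label == label)
            if c.kind != "stretch":
                continue
            k_mode = mode_force_constant(modes, idx, c, model.coords)
            _, ratio = consistency_check(k_mode, fd[label])
            ratios[label] = ratio
        assert ratios
        assert all(np.isfinite(r) and r > 0 for r in ratios.values())

    def test_equivalent_labels_averaged(self):
        from fesff.modes import ModeAssignment, NormalModeSet
        # two symmetric Fe-S(t) estimates 160 and 166 -> single record 163
        fd = {
            "K(Fe-S(t))": ForceConstant("K(Fe-S(t))", "K-stretch", 160.0,
                                        "finite_difference"),
            "K(Fe-S(t))#2": ForceConstant("K(Fe-S(t))#2", "K-stretch",
                                          166.0, "finite_difference"),
        }
        model = make_diatomic()
        coords = [InternalCoordinate("stretch", (0, 1), "K(Fe-S(t))"),
                  InternalCoordinate("stretch", (0, 1), "K(Fe-S(t))#2")]
        modes = compute_modes(model.to_bundle(), project_tr=True)
        assignment = ModeAssignment(
            assignments={"K(Fe-S(t))": (5, 1.0), "K(Fe-S(t))#2": (5, 1.0)},
            unassigned=[])
        params = build_param_set(assignment, modes, coords, model.coords,
                                 fd_results=fd)
        assert len(params.stretches) == 1
        assert params.stretches[0].value == pytest.approx(163.0)

    def test_empty_assignment_gives_empty_set(self, fe2):
        from fesff.modes import ModeAssignment
        modes = compute_modes(fe2.to_bundle(), project_tr=True)
        params = build_param_set(
            ModeAssignment(assignments={}, unassigned=["K(Fe-Fe)"]),
            modes, fe2.internal_coordinates(), fe2.coords)
        assert params.stretches == [] and params.bends == []

    def test_duplicate_labels_rejected(self):
        a = ForceConstant("K(x)", "K-stretch", 1.0, "manual")
        with pytest.raises(ValueError, match="duplicate"):
            ForceFieldParamSet(stretches=[a, a])

    def test_json_round_trip(self, tmp_path):
        params = ForceFieldParamSet(
            stretches=[ForceConstant("K(Fe-Fe)", "K-stretch", 33.0,
                                     "manual")],
            bends=[ForceConstant("H(a)", "H-bend", 70.0, "manual")],
            torsions=[TorsionParams("T(x)", [(2, 5.0, 180.0)], offset=0.1,
                                    residual_rms=0.01)],
            metadata={"template": "fes_4cys"})
        p = tmp_path / "params.json"
        params.to_json(p)
        loaded = ForceFieldParamSet.from_json(p)
        assert loaded == params
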