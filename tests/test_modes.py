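import numpy as np
import pandas as pd
import pytest

from fesff.bundle import QMBundle
from fesff.internals import InternalCoordinate
from fesff.modes import (
    apply_scale,
    assign_modes,
    compute_modes,
    decompose_mode,
    fit_scale_factor,
    projected_reduced_mass,
    spectrum_report,
)
from fesff.synthetic import HarmonicModel, HarmonicTerm
from fesff.units import MDYNE_PER_A_TO_KCAL, atomic_mass, diatomic_frequency

from conftest import make_diatomic


def two_decoupled_diatomics(k1=0.8, k2=1.6):
    """Two far-separated Fe2 springs: block-diagonal brute-force oracle."""
    coords = np.array([[0, 0, 0], [0, 0, 2.5],
                       [50, 0, 0], [50, 0, 2.5]], dtype=float)
    masses = np.full(4, atomic_mass("Fe"))
    terms = [
        HarmonicTerm("stretch", (0, 1), "bond-a",
                     constant=k1 * MDYNE_PER_A_TO_KCAL, equilibrium=2.5),
        HarmonicTerm("stretch", (2, 3), "bond-b",
                     constant=k2 * MDYNE_PER_A_TO_KCAL, equilibrium=2.5),
    ]
    return HarmonicModel(["Fe"] * 4, coords, masses, terms, label="pair")


class TestComputeModes:
    def test_fe2_frequency_and_projected_reduced_mass(self, fe2):
        modes = compute_modes(fe2.to_bundle(), project_tr=True)
        expect = diatomic_frequency(0.230, 55.845, 55.845)
        assert modes.frequencies[-1] == pytest.approx(expect, rel=1e-6)
        assert np.abs(modes.frequencies[:-1]).max() < 1e-6
        bond = fe2.internal_coordinates()[0]
        mu = projected_reduced_mass(modes, 5, bond, fe2.coords)
        assert mu == pytest.approx(55.845 / 2.0, rel=1e-9)  # pair mass 27.92

    def test_stored_reduced_mass_convention(self, fe2):
        # the per-mode (coordinate-free) convention gives the atomic mass
        # for a homonuclear diatomic; bounded by the heaviest atom always
        modes = compute_modes(fe2.to_bundle(), project_tr=True)
        assert modes.reduced_masses[-1] == pytest.approx(55.845, rel=1e-9)

    def test_reduced_masses_bounded_by_heaviest_atom(self, template):
        modes = compute_modes(template.to_bundle(), project_tr=True)
        assert np.all(modes.reduced_masses > 0)
        assert np.all(modes.reduced_masses
                      <= template.masses.max() * (1 + 1e-12))

    def test_zero_hessian_all_zero(self):
        b = QMBundle(elements=["Fe", "Fe"],
                     coords=np.array([[0, 0, 0], [0, 0, 2.7]], dtype=float),
                     hessian=np.zeros((6, 6)))
        modes = compute_modes(b)
        assert np.all(modes.frequencies == 0.0)

    def test_negative_eigenvalue_reported_as_imaginary(self, fe2):
        h = -fe2.to_bundle().hessian  # one unstable direction
        b = QMBundle(elements=list(fe2.elements), coords=fe2.coords,
                     masses=fe2.masses, hessian=h)
        modes = compute_modes(b, project_tr=True)
        assert np.sum(modes.frequencies < -1e-6) == 1

    def test_eigenvectors_orthonormal(self, template):
        modes = compute_modes(template.to_bundle())
        v = np.array([modes.mass_weighted_eigenvector(i)
                      for i in range(modes.n_modes)])
        np.testing.assert_allclose(v @ v.T, np.eye(modes.n_modes),
                                   atol=1e-8)

    def test_eckart_projection_preserves_internal_frequencies(self, template):
        raw = compute_modes(template.to_bundle(), project_tr=False)
        proj = compute_modes(template.to_bundle(), project_tr=True)
        n_rigid = 6
        np.testing.assert_allclose(
            raw.frequencies[n_rigid:], proj.frequencies[n_rigid:],
            rtol=1e-6, atol=1e-6)
        # eigenvalue noise ~1e-15 maps to ~1e-6 cm^-1 through the sqrt
        assert np.abs(proj.frequencies[:n_rigid]).max() < 1e-4


class TestDecompose:
    def test_diatomic_stretch_weight_one(self, fe2):
        modes = compute_modes(fe2.to_bundle(), project_tr=True)
        bond = fe2.internal_coordinates()
        w = decompose_mode(modes, 5, bond, fe2.coords)
        assert w["K(Fe-Fe)"] == pytest.approx(1.0)

    def test_translation_mode_all_weights_zero(self, fe2):
        modes = compute_modes(fe2.to_bundle(), project_tr=True)
        coords_set = fe2.internal_coordinates()
        # modes 0..4 are rigid translations/rotations after projection
        w = decompose_mode(modes, 0, coords_set, fe2.coords)
        assert all(v == 0.0 for v in w.values())

    def test_rieske_fe_fe_mode_dominates(self, rieske):
        modes = compute_modes(rieske.to_bundle(), project_tr=True)
        coords_set = rieske.internal_coordinates()
        fefe = next(c for c in coords_set if c.label == "K(Fe-Fe)")
        weights = [decompose_mode(modes, i, coords_set,
                                  rieske.coords)["K(Fe-Fe)"]
                   for i in range(modes.n_modes)]
        best = int(np.argmax(weights))
        # the mode carrying the most Fe-Fe character is a genuine internal
        # mode and Fe-Fe is its top coordinate
        assert modes.frequencies[best] > 1.0
        w_best = decompose_mode(modes, best, coords_set, rieske.coords)
        assert max(w_best, key=w_best.get) == "K(Fe-Fe)"

    def test_empty_coordinate_set_rejected(self, fe2):
        modes = compute_modes(fe2.to_bundle())
        with pytest.raises(ValueError, match="empty"):
            decompose_mode(modes, 0, [], fe2.coords)


class TestAssign:
    def test_diatomic_one_to_one(self, fe2):
        modes = compute_modes(fe2.to_bundle(), project_tr=True)
        a = assign_modes(modes, fe2.internal_coordinates(), fe2.coords)
        assert a.assignments["K(Fe-Fe)"][0] == 5
        assert a.unassigned == []

    def test_two_decoupled_diatomics_map_to_own_frequencies(self):
        model = two_decoupled_diatomics()
        modes = compute_modes(model.to_bundle(), project_tr=True)
        a = assign_modes(modes, model.internal_coordinates(), model.coords)
        nu_a = modes.frequencies[a.assignments["bond-a"][0]]
        nu_b = modes.frequencies[a.assignments["bond-b"][0]]
        assert nu_a == pytest.approx(
            diatomic_frequency(0.8, 55.845, 55.845), rel=1e-6)
        assert nu_b == pytest.approx(
            diatomic_frequency(1.6, 55.845, 55.845), rel=1e-6)

    def test_threshold_one_leaves_mixed_coordinates_unassigned(self, rieske):
        modes = compute_modes(rieske.to_bundle(), project_tr=True)
        a = assign_modes(modes, rieske.internal_coordinates(),
                         rieske.coords, threshold=1.0)
        assert len(a.unassigned) > 0

    def test_threshold_validation(self, fe2):
        modes = compute_modes(fe2.to_bundle())
        with pytest.raises(ValueError, match="threshold"):
            assign_modes(modes, fe2.internal_coordinates(), fe2.coords,
                         threshold=0.0)


class TestScaling:
    def test_apply_scale(self, fe2):
        modes = compute_modes(fe2.to_bundle(), project_tr=True)
        scaled = apply_scale(modes, 1.06)
        np.testing.assert_allclose(scaled.frequencies,
                                   modes.frequencies * 1.06, rtol=1e-15)
        np.testing.assert_array_equal(scaled.cart_displacements,
                                      modes.cart_displacements)
        assert scaled.scale_factor == pytest.approx(1.06)
        back = apply_scale(scaled, 1.0 / 1.06)
        np.testing.assert_allclose(back.frequencies, modes.frequencies,
                                   rtol=1e-12)
        with pytest.raises(ValueError):
            apply_scale(modes, 0.0)

    def test_fit_scale_factor_exact_ratio_and_single_pair(self):
        pairs = [(100.0, 106.0), (250.0, 265.0), (400.0, 424.0)]
        assert fit_scale_factor(pairs) == pytest.approx(1.06, rel=1e-12)
        assert fit_scale_factor([(400.0, 424.0)]) == pytest.approx(1.06)
        with pytest.raises(ValueError):
            fit_scale_factor([])

    def test_fit_scale_factor_against_grid_search(self):
        rng = np.random.default_rng(7)
        calc = rng.uniform(100, 500, size=9)
        obs = 1.043 * calc + rng.normal(0, 5.0, size=9)
        f = fit_scale_factor(list(zip(calc, obs)))
        grid = np.linspace(0.9, 1.2, 60001)
        loss = [(np.sum((obs - g * calc) ** 2), g) for g in grid]
        g_best = min(loss)[1]
        assert f == pytest.approx(g_best, abs=1e-5)


class TestSpectrumReport:
    @staticmethod
    def _modes_with(freqs):
        from fesff.modes import NormalModeSet
        n = len(freqs)
        return NormalModeSet(
            frequencies=np.array(freqs, dtype=float),
            cart_displacements=np.eye(n),
            reduced_masses=np.ones(n),
            masses=np.ones(max(n // 3, 1)),
        )

    @staticmethod
    def _assignment(mapping):
        from fesff.modes import ModeAssignment
        return ModeAssignment(assignments={k: (v, 1.0)
                                           for k, v in mapping.items()},
                              unassigned=[])

    def test_single_row_deviation(self):
        modes = self._modes_with([427.6])
        a = self._assignment({"B2u_b": 0})
        obs = pd.DataFrame({"label": ["B2u_b"], "wavenumber": [409.0]})
        rep = spectrum_report(modes, a, obs)
        assert rep.loc[0, "deviation"] == pytest.approx(18.6)
        assert rep.attrs["mad"] == pytest.approx(18.6)

    def test_identical_tables_zero_deviation_and_order_invariance(self):
        modes = self._modes_with([200.0, 300.0, 400.0])
        a = self._assignment({"x": 0, "y": 1, "z": 2})
        obs = pd.DataFrame({"label": ["x", "y", "z"],
                            "wavenumber": [200.0, 300.0, 400.0]})
        rep1 = spectrum_report(modes, a, obs)
        assert np.allclose(rep1["deviation"], 0.0)
        shuffled = obs.sample(frac=1.0, random_state=3)
        rep2 = spectrum_report(modes, a, shuffled)
        pd.testing.assert_frame_equal(rep1, rep2)

    def test_unmatched_label_flagged_not_dropped(self):
        modes = self._modes_with([200.0])
        a = self._assignment({"x": 0})
        obs = pd.DataFrame({"label": ["x", "ghost"],
                            "wavenumber": [210.0, 999.0]})
        rep = spectrum_report(modes, a, obs)
        ghost = rep[rep["label"] == "ghost"].iloc[0]
        assert not ghost["matched"]
        assert np.isnan(ghost["deviation"])
        assert len(rep) == 2
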