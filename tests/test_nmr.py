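"""NMR chain: preprocessing, PQN, quantification, folds, PCA, OPLS-DA."""

import math

import numpy as np
import pandas as pd
import pytest

from irquant.datatypes import MetaboliteAssignment, Spectrum1D
from irquant.nmr import (
    fold_change_table,
    heatmap_matrix,
    oplsda_fit_and_permute,
    pca_scores,
    pqn_normalize,
    quantify_cohort,
    quantify_metabolites,
    reference_to_tsp,
    truncate_water,
)


def _lorentz_spec(centers, amps, hwhm=0.002, n=8192, **kw):
    ppm = np.linspace(-1.0, 10.0, n)
    y = np.zeros_like(ppm)
    for c, a in zip(centers, amps):
        y += a * (hwhm / math.pi) / ((ppm - c) ** 2 + hwhm**2)
    return Spectrum1D(ppm, y, **kw)


class TestReferencing:
    def test_offset_apex_shifted_to_zero(self):
        spec = _lorentz_spec([0.02], [10.0])
        out = reference_to_tsp(spec)
        apex = out.ppm[np.argmax(out.intensity)]
        assert abs(apex) < 1e-9

    def test_already_centered_identity(self):
        spec = _lorentz_spec([0.0], [10.0])
        out = reference_to_tsp(spec)
        step = spec.ppm[1] - spec.ppm[0]
        assert abs(out.ppm[np.argmax(out.intensity)]) <= step / 2

    def test_known_offset_recovered(self):
        offset = 0.015
        spec = _lorentz_spec([offset], [10.0])
        out = reference_to_tsp(spec)
        step = spec.ppm[1] - spec.ppm[0]
        shift_applied = spec.ppm[0] - out.ppm[0]
        assert abs(shift_applied - offset) <= step

    def test_no_peak_raises(self):
        ppm = np.linspace(-1, 10, 100)
        spec = Spectrum1D(ppm, np.zeros_like(ppm))
        with pytest.raises(ValueError):
            reference_to_tsp(spec)


class TestWaterTruncation:
    def test_water_point_removed_neighbor_kept(self):
        ppm = np.array([4.5, 4.8, 5.1])
        out = truncate_water(Spectrum1D(ppm, np.ones(3)))
        assert 4.8 not in out.ppm
        assert 4.5 in out.ppm and 5.1 in out.ppm

    def test_length_accounting(self):
        ppm = np.linspace(-2.0, 11.0, 1301)
        spec = Spectrum1D(ppm, np.ones_like(ppm))
        out = truncate_water(spec)
        dropped = np.sum(
            (ppm < -1.0) | (ppm > 10.0) | ((ppm >= 4.67) & (ppm <= 4.98))
        )
        assert out.ppm.size == ppm.size - dropped


class TestPqn:
    def test_factor_ratio_two(self):
        s1 = _lorentz_spec([1.0, 3.0, 7.0], [5, 7, 9])
        s2 = s1.copy_with(intensity=2.0 * s1.intensity)
        _, factors = pqn_normalize([s1, s2])
        assert factors[1] / factors[0] == pytest.approx(2.0, rel=1e-9)

    def test_identical_spectra_equal_factors(self):
        s = _lorentz_spec([1.0, 3.0], [5, 7])
        normalized, factors = pqn_normalize([s, s.copy_with(), s.copy_with()])
        assert np.allclose(factors, factors[0])
        for n in normalized[1:]:
            np.testing.assert_allclose(n.intensity, normalized[0].intensity)

    def test_relative_peak_ratios_preserved(self):
        s1 = _lorentz_spec([1.0, 3.0], [5, 10])
        s2 = s1.copy_with(intensity=3.0 * s1.intensity)
        normalized, _ = pqn_normalize([s1, s2])
        a = MetaboliteAssignment("A", 1.0)
        b = MetaboliteAssignment("B", 3.0)
        raw_ratio = quantify_metabolites(s1, [a, b])
        raw_ratio = raw_ratio["B"] / raw_ratio["A"]
        for n in normalized:
            q = quantify_metabolites(n, [a, b])
            assert q["B"] / q["A"] == pytest.approx(raw_ratio, rel=1e-12)

    def test_dilution_recovery(self, nmr_cohort):
        spectra, truth = nmr_cohort
        cohort = [truncate_water(reference_to_tsp(s)) for s in spectra]
        _, factors = pqn_normalize(cohort)
        d = truth.dilution_factors
        scale = np.median(d / factors)
        err = np.abs(factors * scale - d) / d
        assert np.median(err) <= 0.02

    def test_mismatched_axes_rejected(self):
        s1 = _lorentz_spec([1.0], [5], n=1000)
        s2 = _lorentz_spec([1.0], [5], n=1001)
        with pytest.raises(ValueError):
            pqn_normalize([s1, s2])


class TestQuantification:
    def test_linearity(self):
        a = [MetaboliteAssignment("X", 1.03)]
        s1 = _lorentz_spec([1.03], [4.0])
        s2 = _lorentz_spec([1.03], [8.0])
        q1 = quantify_metabolites(s1, a)["X"]
        q2 = quantify_metabolites(s2, a)["X"]
        assert q2 == pytest.approx(2.0 * q1, rel=1e-12)

    def test_flat_zero(self):
        ppm = np.linspace(-1, 10, 5000)
        q = quantify_metabolites(
            Spectrum1D(ppm, np.zeros_like(ppm)), [MetaboliteAssignment("X", 2.0)]
        )
        assert q["X"] == 0.0

    def test_cross_talk_below_closed_form_bound(self):
        # Lorentzian tail mass inside a window [a, b] away from the center is
        # (arctan(b/g) - arctan(a/g)) / pi -- the independent oracle.
        hwhm = 0.002
        halfwidth = 0.02
        sep = 5 * 2 * hwhm * 5  # >= 5 linewidths (FWHM) separation
        c1, c2 = 2.0, 2.0 + sep
        spec = _lorentz_spec([c1, c2], [10.0, 10.0], hwhm=hwhm, n=2**15)
        asg = [
            MetaboliteAssignment("A", c1, halfwidth),
            MetaboliteAssignment("B", c2, halfwidth),
        ]
        q = quantify_metabolites(spec, asg)
        lone = quantify_metabolites(
            _lorentz_spec([c1], [10.0], hwhm=hwhm, n=2**15), [asg[0]]
        )
        crosstalk = (q["A"] - lone["A"]) / lone["A"]
        bound = (
            math.atan((sep + halfwidth) / hwhm) - math.atan((sep - halfwidth) / hwhm)
        ) / math.pi * 10.0 / lone["A"]
        assert crosstalk <= bound + 1e-9
        assert crosstalk < 0.01

    def test_empty_window_raises(self):
        ppm = np.linspace(-1, 10, 50)  # step 0.22 >> window
        spec = Spectrum1D(ppm, np.ones_like(ppm))
        with pytest.raises(ValueError):
            quantify_metabolites(spec, [MetaboliteAssignment("X", 2.005, 0.02)])

    def test_water_overlap_warns(self):
        spec = truncate_water(_lorentz_spec([1.0], [5.0]))
        with pytest.warns(UserWarning):
            quantify_metabolites(spec, [MetaboliteAssignment("W", 4.66, 0.02)])


class TestFoldChanges:
    def _quant(self):
        rng = np.random.default_rng(0)
        idx = [f"s{i}" for i in range(8)]
        q = pd.DataFrame(
            {"m1": np.r_[np.ones(4), np.ones(4)], "m2": np.r_[np.ones(4), 0.5 * np.ones(4)]},
            index=idx,
        )
        q += rng.normal(0, 1e-9, q.shape)  # break exact ties for Welch
        design = pd.Series(["g1"] * 4 + ["g2"] * 4, index=idx)
        return q, design

    def test_identical_arms_fold_one(self):
        idx = [f"s{i}" for i in range(6)]
        q = pd.DataFrame({"m": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]}, index=idx)
        design = pd.Series(["a"] * 3 + ["b"] * 3, index=idx)
        entries = fold_change_table(q, design, {"a_vs_b": ("a", "b")})
        assert entries[0].fold_change == pytest.approx(1.0)
        assert entries[0].p_value == pytest.approx(1.0)

    def test_halved_arm(self):
        q, design = self._quant()
        entries = fold_change_table(q, design, {"c": ("g1", "g2")})
        by = {e.metabolite: e for e in entries}
        assert by["m2"].fold_change == pytest.approx(0.5, abs=1e-6)

    def test_planted_fold_recovery(self, nmr_cohort, assignments):
        spectra, truth = nmr_cohort
        cohort = [truncate_water(reference_to_tsp(s)) for s in spectra]
        cohort, _ = pqn_normalize(cohort)
        quant = quantify_cohort(cohort, assignments)
        design = pd.Series(truth.group_labels, index=truth.sample_ids)
        entries = fold_change_table(quant, design)
        est = {(e.metabolite, e.comparison): e.fold_change for e in entries}
        planted = truth.planted_fold_changes
        for met, comp in [
            ("Phenylalanine", "veh_sham_vs_veh_IR"),
            ("Acetate", "veh_sham_vs_veh_IR"),
            ("Valine", "veh_sham_vs_veh_IR"),
            ("Glutamine", "SCN_sham_vs_SCN_IR"),
        ]:
            assert est[(met, comp)] == pytest.approx(planted.loc[met, comp], abs=0.05)

    def test_zero_denominator_rejected(self):
        idx = [f"s{i}" for i in range(4)]
        q = pd.DataFrame({"m": [0.0, 0.0, 1.0, 1.0]}, index=idx)
        design = pd.Series(["a", "a", "b", "b"], index=idx)
        with pytest.raises(ValueError):
            fold_change_table(q, design, {"c": ("a", "b")})


class TestPca:
    def test_line_explains_everything(self):
        t = np.linspace(0, 1, 10)
        X = np.outer(t, [1.0, 2.0, -1.0])
        _, _, ratio = pca_scores(X, 1)
        assert ratio[0] == pytest.approx(1.0)

    def test_reconstruction_completeness(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 5))
        scores, loadings, _ = pca_scores(X, 5)
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(scores @ loadings, Xc, atol=1e-8)

    def test_cluster_separation(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 6))
        X[20:, 0] += 5.0  # 5 within-cluster sd apart
        scores, _, _ = pca_scores(X, 1)
        a, b = scores[:20, 0], scores[20:, 0]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or a.max() < b.min() or b.max() < a.min()

    def test_rank_guard(self):
        X = np.outer(np.arange(4.0), [1.0, 2.0])
        with pytest.raises(ValueError):
            pca_scores(X, 2)


class TestOplsda:
    def test_perfect_separation_minimal_p(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 10))
        y = np.array([0] * 6 + [1] * 6)
        X[y == 1, 0] += 10.0
        m = oplsda_fit_and_permute(X, y, n_permutations=99, seed=0)
        assert m.permutation_p == pytest.approx(1.0 / 100.0)

    def test_planted_direction_recovered(self):
        rng = np.random.default_rng(7)
        direction = np.zeros(15)
        direction[3] = 1.0
        X = rng.normal(size=(20, 15))
        y = np.array([0] * 10 + [1] * 10)
        X[y == 1] += 4.0 * direction
        m = oplsda_fit_and_permute(X, y, n_permutations=50, seed=0)
        cos = abs(m.predictive_loading @ direction) / np.linalg.norm(m.predictive_loading)
        assert cos >= 0.9

    def test_single_class_rejected(self):
        X = np.zeros((6, 3))
        with pytest.raises(ValueError):
            oplsda_fit_and_permute(X, np.zeros(6), n_permutations=10)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 8))
        y = np.array([0] * 6 + [1] * 6)
        a = oplsda_fit_and_permute(X, y, n_permutations=50, seed=3)
        b = oplsda_fit_and_permute(X, y, n_permutations=50, seed=3)
        assert a.permutation_p == b.permutation_p
        np.testing.assert_array_equal(a.permutation_q2, b.permutation_q2)


class TestHeatmap:
    def _entries(self, folds):
        from irquant.datatypes import FoldChangeEntry

        out = []
        for i, (met, comp, f) in enumerate(folds):
            out.append(FoldChangeEntry(met, comp, f, 0.5, False, shift_ppm=10 - i))
        return out

    def test_uniform_folds_at_center(self):
        mat, fig = heatmap_matrix(self._entries([("a", "c1", 1.0), ("b", "c1", 1.0)]))
        assert (mat.to_numpy() == 1.0).all()

    def test_orientation(self):
        mat, _ = heatmap_matrix(
            self._entries([("a", "c1", 1.15), ("b", "c1", 0.82)])
        )
        assert mat.loc["a", "c1"] > 1.0 > mat.loc["b", "c1"]

    def test_full_panel_dimensions(self, nmr_cohort, assignments):
        spectra, truth = nmr_cohort
        cohort = [truncate_water(reference_to_tsp(s)) for s in spectra]
        quant = quantify_cohort(cohort, assignments)
        design = pd.Series(truth.group_labels, index=truth.sample_ids)
        entries = fold_change_table(quant, design)
        mat, _ = heatmap_matrix(entries)
        assert mat.shape == (24, 3)


class TestPreprocessingOrderStability:
    def test_reference_truncate_commute_then_pqn(self, assignments, folds_24h):
        # grid chosen so 0.00 ppm is an exact sample: the reference shift is
        # then 0 and the two preprocessing orders must agree exactly
        from irquant.synthetic import generate_nmr_cohort

        spectra, _ = generate_nmr_cohort(
            3, assignments, folds_24h, seed=1, n_points=11 * 745 + 1
        )
        a = [truncate_water(reference_to_tsp(s)) for s in spectra]
        b = [reference_to_tsp(truncate_water(s)) for s in spectra]
        na, fa = pqn_normalize(a)
        nb, fb = pqn_normalize(b)
        np.testing.assert_allclose(fa, fb, rtol=1e-9)
        for sa, sb in zip(na, nb):
            np.testing.assert_allclose(sa.intensity, sb.intensity, rtol=1e-9)
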