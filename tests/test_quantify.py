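"""Standard curves, inverse prediction, consensus, LOD and detection calls."""

import numpy as np
import pytest

from meatmarkers import (
    IntensitySpec,
    MixtureDesign,
    MixtureSample,
    consensus_estimate,
    detect_contaminant,
    detection_threshold,
    estimate_fraction,
    fit_standard_curve,
    lod_estimate,
    simulate_mixture_intensities,
)

DESIGN = MixtureDesign("pork", "beef")


class TestMixtureDesign:
    def test_default_levels_are_the_six_point_series(self):
        assert DESIGN.fractions == (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

    @pytest.mark.parametrize(
        "fractions",
        [(0.0, 0.5), (0.0, 0.5, 0.4), (0.0, 0.5, 1.2), (0.2, 0.2, 0.4)],
    )
    def test_invalid_designs_rejected(self, fractions):
        with pytest.raises(ValueError):
            MixtureDesign("a", "b", fractions)


class TestFitStandardCurve:
    def test_exact_line_recovered(self):
        y = [1000 * f for f in DESIGN.fractions]
        curve = fit_standard_curve(DESIGN, y, "PEP")
        assert curve.slope == pytest.approx(1000)
        assert curve.intercept == pytest.approx(0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1)

    def test_constant_intensities_give_zero_slope_and_r2(self):
        curve = fit_standard_curve(DESIGN, [5.0] * 6, "PEP")
        assert curve.slope == pytest.approx(0, abs=1e-12)
        assert curve.r_squared == 0

    def test_replicates_averaged_by_default(self):
        reps = [[1000 * f - 1, 1000 * f + 1] for f in DESIGN.fractions]
        curve = fit_standard_curve(DESIGN, reps, "PEP")
        assert curve.slope == pytest.approx(1000)
        assert curve.n_points == 6

    def test_all_replicates_fit_when_requested(self):
        reps = [[1000 * f - 1, 1000 * f + 1] for f in DESIGN.fractions]
        curve = fit_standard_curve(DESIGN, reps, "PEP", average_replicates=False)
        assert curve.n_points == 12

    def test_simulated_noisy_slope_within_three_se(self):
        spec = IntensitySpec(
            {"PEP": (500.0, 50.0)}, noise_sd=10.0, replicates=3, seed=11
        )
        table = simulate_mixture_intensities(spec)
        reps = [
            list(table.loc[table.fraction == f, "PEP"]) for f in spec.fractions
        ]
        curve = fit_standard_curve(DESIGN, reps, "PEP")
        assert abs(curve.slope - 500.0) <= 3 * curve.slope_se

    def test_wrong_level_count_rejected(self):
        with pytest.raises(ValueError):
            fit_standard_curve(DESIGN, [1.0, 2.0], "PEP")


class TestEstimateFraction:
    def _curve(self, slope=1000.0, intercept=0.0):
        y = [slope * f + intercept for f in DESIGN.fractions]
        return fit_standard_curve(DESIGN, y, "PEP")

    def test_exact_inversion(self):
        est = estimate_fraction(self._curve(), 200.0)
        assert est.estimate == pytest.approx(0.20)
        assert not est.clipped

    def test_intensity_below_intercept_clips_to_zero_with_flag(self):
        est = estimate_fraction(self._curve(intercept=100.0), 50.0)
        assert est.estimate == 0.0 and est.clipped

    def test_round_trip_identity_on_noiseless_curve(self):
        curve = self._curve(slope=750.0, intercept=25.0)
        for f in np.linspace(0, 1, 11):
            est = estimate_fraction(curve, 750.0 * f + 25.0)
            assert est.estimate == pytest.approx(f, abs=1e-9)

    def test_interval_contains_truth_for_noisy_curve(self):
        spec = IntensitySpec({"PEP": (800.0, 30.0)}, noise_sd=15.0, seed=3)
        table = simulate_mixture_intensities(spec)
        curve = fit_standard_curve(DESIGN, list(table["PEP"]), "PEP")
        est = estimate_fraction(curve, 800.0 * 0.3 + 30.0)
        assert est.lower <= 0.3 <= est.upper

    def test_flat_curve_unquantifiable(self):
        curve = fit_standard_curve(DESIGN, [5.0] * 6, "PEP")
        with pytest.raises(ValueError):
            estimate_fraction(curve, 5.0)


class TestConsensus:
    def test_median_of_three(self):
        assert consensus_estimate([0.18, 0.20, 0.22]) == (0.20, pytest.approx(0.02))

    def test_single_estimate_is_itself_with_zero_spread(self):
        assert consensus_estimate([0.4]) == (0.4, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            consensus_estimate([])

    def test_median_beats_mean_under_one_corrupted_peptide(self):
        rng = np.random.default_rng(5)
        median_err, mean_err = [], []
        for _ in range(100):
            truth = 0.3
            panel = truth + rng.normal(0, 0.01, size=3)
            panel[2] = truth * 2  # one marker biased x2
            med, _ = consensus_estimate(panel)
            median_err.append(abs(med - truth))
            mean_err.append(abs(panel.mean() - truth))
        assert np.mean(median_err) < np.mean(mean_err)


class TestLod:
    def test_arithmetic(self):
        curve = fit_standard_curve(
            DESIGN, [1000 * f for f in DESIGN.fractions], "PEP"
        )
        blanks = [0.0, 3.0, -3.0, 3.0, -3.0]  # sd 3
        sd = np.std(blanks, ddof=1)
        assert lod_estimate(curve, blanks) == pytest.approx(3.3 * sd / 1000)

    def test_zero_blank_spread_gives_zero_lod(self):
        curve = fit_standard_curve(
            DESIGN, [1000 * f for f in DESIGN.fractions], "PEP"
        )
        assert lod_estimate(curve, [10.0, 10.0, 10.0]) == 0.0

    def test_needs_blanks_and_positive_slope(self):
        curve = fit_standard_curve(
            DESIGN, [1000 * f for f in DESIGN.fractions], "PEP"
        )
        with pytest.raises(ValueError):
            lod_estimate(curve, [1.0, 2.0])
        flat = fit_standard_curve(DESIGN, [5.0] * 6, "PEP")
        with pytest.raises(ValueError):
            lod_estimate(flat, [1.0, 2.0, 3.0])


class TestDetectContaminant:
    PANEL = {"pork": ["VNVDEVGGEALGR"], "chicken": ["IGDEFVADLDQLQR"]}

    def test_planted_signal_flagged_with_supporting_peptide(self):
        sample = MixtureSample("s1", {"VNVDEVGGEALGR": 500.0, "IGDEFVADLDQLQR": 0.0})
        calls = {c.species: c for c in detect_contaminant(sample, self.PANEL)}
        assert calls["pork"].detected
        assert calls["pork"].supporting_peptides == ("VNVDEVGGEALGR",)
        assert not calls["chicken"].detected

    def test_all_zero_intensities_detect_nothing(self):
        sample = MixtureSample("s1", {k: 0.0 for ks in self.PANEL.values() for k in ks})
        assert not any(c.detected for c in detect_contaminant(sample, self.PANEL))

    def test_detected_species_quantified_when_curve_present(self):
        curve = fit_standard_curve(
            DESIGN, [1000 * f for f in DESIGN.fractions], "VNVDEVGGEALGR"
        )
        sample = MixtureSample("s1", {"VNVDEVGGEALGR": 300.0})
        calls = {
            c.species: c
            for c in detect_contaminant(
                sample, {"pork": ["VNVDEVGGEALGR"]}, {"VNVDEVGGEALGR": curve}
            )
        }
        assert calls["pork"].fraction == pytest.approx(0.30)

    def test_negative_intensities_rejected(self):
        with pytest.raises(ValueError):
            MixtureSample("s1", {"X": -1.0})

    def test_threshold_is_mean_plus_three_sd(self):
        blanks = [10.0, 12.0, 8.0, 10.0]
        assert detection_threshold(blanks) == pytest.approx(
            np.mean(blanks) + 3 * np.std(blanks, ddof=1)
        )


class TestComplementarySymmetry:
    def test_forward_and_reverse_fits_mirror_on_noiseless_data(self):
        """Target-in-background vs background-in-target on fractions summing to 1."""
        slope, intercept = 900.0, 40.0
        y_forward = [slope * f + intercept for f in DESIGN.fractions]
        reverse = MixtureDesign("beef", "pork")
        y_reverse = [slope * (1 - f) + intercept for f in reverse.fractions]
        fwd = fit_standard_curve(DESIGN, y_forward, "PEP")
        rev = fit_standard_curve(reverse, y_reverse, "PEP")
        assert rev.slope == pytest.approx(-fwd.slope)
        assert rev.intercept == pytest.approx(fwd.intercept + fwd.slope)
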