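"""Tests for mass-balance inversion and longitudinal FFM prediction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bodycomp as bc
from bodycomp.models import PolynomialCoefficients
from bodycomp.solver import _solve_forbes_fm

from conftest import bisect_root, random_covariates, random_fat_mass


class TestSolveFm:
    def test_published_inversion_example(self, aa_female_34_165):
        """AA female, age 34, height 165: FM inverts to 27.75 kg at 75 kg
        total mass and 20.74 kg at 65 kg."""
        assert bc.solve_fm(75.0, aa_female_34_165) == pytest.approx(
            27.75, abs=5e-3)
        assert bc.solve_fm(65.0, aa_female_34_165) == pytest.approx(
            20.74, abs=5e-3)

    def test_round_trip_and_bisection_agreement(self):
        """solve_fm inverts F + FFM(F) back to F and matches a plain
        200-iteration bisection for 500 random feasible states."""
        rng = np.random.default_rng(7)
        for _ in range(500):
            cov = random_covariates(rng)
            F = random_fat_mass(rng, cov.sex)
            W = F + bc.nhanes_ffm(F, cov)
            got = bc.solve_fm(W, cov)
            assert got == pytest.approx(F, abs=1e-6)
            # bracket on the increasing branch (g turns over past ~88 kg)
            oracle = bisect_root(
                lambda x: x + bc.nhanes_ffm(x, cov) - W, 0.0, min(W, 88.0))
            assert got == pytest.approx(oracle, abs=1e-6)

    def test_near_zero_fat_bound(self, aa_female_34_165):
        """Just above the zero-fat bound the root matches bisection."""
        ffm0 = bc.zero_fat_ffm(aa_female_34_165)
        W = ffm0 + 1e-3
        got = bc.solve_fm(W, aa_female_34_165)
        oracle = bisect_root(
            lambda x: x + bc.nhanes_ffm(x, aa_female_34_165) - W, 0.0, W)
        assert got == pytest.approx(oracle, abs=1e-8)
        # root is ~ epsilon / (1 + phi'(0)), a few times 1e-3
        assert 0 < got < 1e-2

    def test_infeasible_mass_reports_zero_fat_bound(self, aa_female_34_165):
        with pytest.raises(bc.InfeasibleMassError) as exc:
            bc.solve_fm(10.0, aa_female_34_165)
        assert exc.value.zero_fat_ffm_kg == pytest.approx(
            bc.zero_fat_ffm(aa_female_34_165))

    def test_roots_beyond_increasing_branch_are_ambiguous(self,
                                                          aa_female_34_165):
        """A coefficient row whose total-mass function turns over before
        the only root triggers the ambiguity error listing the roots."""
        wiggly = PolynomialCoefficients({
            "1": 30.0, "F": 5.0, "A": 0.0, "H": 0.0, "FA": 0.0, "FH": 0.0,
            "F2": -0.3, "F2A": 0.0, "F3": 0.004, "F4": 0.0, "F2H": 0.0,
            "F3H": 0.0})
        with pytest.raises(bc.AmbiguousRootError) as exc:
            bc.solve_fm(70.0, aa_female_34_165, coefficients=wiggly)
        for root in exc.value.roots:
            ffm = root + 30.0 + 5 * root - 0.3 * root**2 + 0.004 * root**3
            assert ffm == pytest.approx(70.0, abs=1e-6)
        # a target below the local maximum still has a root on the
        # increasing branch and solves cleanly
        assert bc.solve_fm(50.0, aa_female_34_165,
                           coefficients=wiggly) < 13.8


class TestDeltaFfmNhanes:
    def test_published_ten_kg_loss_example(self, aa_female_34_165):
        """75 kg baseline, 10 kg loss: predicted change in FFM is
        -2.99 kg."""
        scen = bc.WeightChangeScenario(75.0, -10.0, aa_female_34_165)
        change = bc.delta_ffm_nhanes(scen)
        assert change.delta_ffm_kg == pytest.approx(-2.99, abs=5e-3)
        assert change.delta_fm_kg == pytest.approx(-10.0 + 2.99, abs=5e-3)

    def test_zero_change_is_identity(self, aa_female_34_165):
        scen = bc.WeightChangeScenario(75.0, 0.0, aa_female_34_165)
        change = bc.delta_ffm_nhanes(scen)
        assert change.delta_ffm_kg == pytest.approx(0.0, abs=1e-8)
        assert change.delta_fm_kg == pytest.approx(0.0, abs=1e-8)

    def test_mass_conservation_over_random_scenarios(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            cov = random_covariates(rng)
            F = random_fat_mass(rng, cov.sex)
            W = F + bc.nhanes_ffm(F, cov)
            dW = float(rng.uniform(-10, 10))
            change = bc.delta_ffm_nhanes(bc.WeightChangeScenario(W, dW, cov))
            assert change.delta_fm_kg + change.delta_ffm_kg == \
                pytest.approx(dW, abs=1e-6)

    def test_scenario_validation(self, aa_female_34_165):
        with pytest.raises(bc.ValidationError, match="baseline_total_kg"):
            bc.WeightChangeScenario(-5.0, 1.0, aa_female_34_165)
        with pytest.raises(bc.ValidationError, match="delta_total_kg"):
            bc.WeightChangeScenario(60.0, -60.0, aa_female_34_165)


class TestForbesCalibrationAndDelta:
    def test_point_on_original_curve_gives_zero_translate(self):
        ffm = bc.forbes_ffm(10.0, bc.ForbesModel.female())
        assert bc.calibrate_forbes_d(10.0, ffm, bc.SexCategory.FEMALE) == \
            pytest.approx(0.0, abs=1e-12)

    def test_translate_arithmetic_example(self):
        d = bc.calibrate_forbes_d(30.0, 50.0, bc.SexCategory.FEMALE)
        assert d == pytest.approx(50.0 - 10.4 * math.log(30.0) - 14.2,
                                  abs=1e-12)
        assert d == pytest.approx(0.43, abs=5e-3)

    @settings(derandomize=True, max_examples=100)
    @given(fm=st.floats(0.5, 90.0), ffm=st.floats(20.0, 90.0),
           male=st.booleans())
    def test_calibrated_curve_passes_through_baseline(self, fm, ffm, male):
        sex = bc.SexCategory.MALE if male else bc.SexCategory.FEMALE
        d = bc.calibrate_forbes_d(fm, ffm, sex)
        model = bc.ForbesModel.for_sex(sex, translate_d=d)
        assert bc.forbes_ffm(fm, model) == pytest.approx(ffm, abs=1e-10)

    def test_ten_kg_loss_against_bisection_oracle(self):
        """Baseline (FM 30, FFM 50), 10 kg loss on the calibrated female
        curve: the final FM and the change in FFM match a bisection
        solve of F + 10.4 ln F + 14.2 + D = 70."""
        d = 50.0 - 10.4 * math.log(30.0) - 14.2
        f_final = bisect_root(
            lambda F: F + 10.4 * math.log(F) + 14.2 + d - 70.0, 1e-6, 70.0)
        change = bc.delta_ffm_forbes(30.0, 50.0, -10.0,
                                     bc.SexCategory.FEMALE)
        assert change.fm_final_kg == pytest.approx(f_final, abs=1e-6)
        expected = 10.4 * (math.log(f_final) - math.log(30.0))
        assert change.delta_ffm_kg == pytest.approx(expected, abs=1e-6)
        assert -2.9 < change.delta_ffm_kg < -2.7

    def test_zero_change_is_identity(self):
        change = bc.delta_ffm_forbes(25.0, 45.0, 0.0, bc.SexCategory.MALE)
        assert change.delta_ffm_kg == pytest.approx(0.0, abs=1e-10)
        assert change.fm_final_kg == pytest.approx(25.0, abs=1e-8)

    def test_secant_invariance_under_vertical_shift(self):
        """Two baselines with equal FM but FFM differing by 5 kg travel
        parallel translates, so the same weight change produces the same
        change in FFM (200 random scenarios, 1e-8 kg)."""
        rng = np.random.default_rng(23)
        checked = 0
        while checked < 200:
            fm_b = float(rng.uniform(5.0, 60.0))
            ffm_b = float(rng.uniform(30.0, 65.0))
            dw = float(rng.uniform(-15.0, 15.0))
            sex = (bc.SexCategory.MALE, bc.SexCategory.FEMALE)[
                rng.integers(2)]
            try:
                a = bc.delta_ffm_forbes(fm_b, ffm_b, dw, sex)
                b = bc.delta_ffm_forbes(fm_b, ffm_b + 5.0, dw, sex)
            except bc.InfeasibleMassError:
                continue
            assert a.delta_ffm_kg == pytest.approx(b.delta_ffm_kg, abs=1e-8)
            checked += 1

    def test_sign_agreement_with_polynomial_model(self):
        """For moderate weight changes from mid-band baselines, the
        polynomial and Forbes predictions of the FFM change share sign."""
        rng = np.random.default_rng(31)
        for _ in range(50):
            cov = random_covariates(rng)
            F = float(rng.uniform(15.0, 40.0))
            W = F + bc.nhanes_ffm(F, cov)
            dw = float(rng.uniform(2.0, 10.0)) * (-1 if rng.random() < 0.5
                                                  else 1)
            nh = bc.delta_ffm_nhanes(bc.WeightChangeScenario(W, dw, cov))
            fo = bc.delta_ffm_forbes(F, W - F, dw, cov.sex)
            assert math.copysign(1, nh.delta_ffm_kg) == \
                math.copysign(1, fo.delta_ffm_kg)

    def test_nonpositive_baseline_fat_rejected(self):
        with pytest.raises(bc.DomainError):
            bc.calibrate_forbes_d(0.0, 50.0, bc.SexCategory.FEMALE)


class TestErrorSummary:
    def test_perfect_prediction(self):
        s = bc.summarize_errors([1.0, 2.0], [1.0, 2.0])
        assert s.mean_error_kg == 0.0 and s.sd_error_kg == 0.0 and s.n == 2

    def test_closed_forms(self):
        s = bc.summarize_errors([0.0, 0.0], [1.0, -1.0])
        assert s.mean_error_kg == 0.0
        assert s.sd_error_kg == pytest.approx(math.sqrt(2), rel=1e-12)
        s = bc.summarize_errors([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert s.mean_error_kg == pytest.approx(2.0)
        assert s.sd_error_kg == pytest.approx(1.0)

    def test_validation(self):
        with pytest.raises(bc.ValidationError):
            bc.summarize_errors([1.0], [1.0, 2.0])
        with pytest.raises(bc.ValidationError):
            bc.summarize_errors([], [])


class TestEvaluateModels:
    def test_polynomial_model_scores_zero_on_its_own_predictions(self):
        """Measured data manufactured exactly on the polynomial model
        yields zero mean error for the polynomial entries and a small but
        generally nonzero Forbes baseline error."""
        rng = np.random.default_rng(41)
        records = []
        for i in range(20):
            cov = random_covariates(rng)
            F = float(rng.uniform(15.0, 40.0))
            W = F + bc.nhanes_ffm(F, cov)
            dw = float(rng.uniform(-8.0, 5.0))
            ch = bc.delta_ffm_nhanes(bc.WeightChangeScenario(W, dw, cov))
            records.append(bc.FollowUpRecord(
                id=str(i), cov=cov,
                fm_baseline_kg=ch.fm_baseline_kg,
                ffm_baseline_kg=ch.ffm_baseline_kg,
                fm_final_kg=ch.fm_final_kg,
                ffm_final_kg=ch.ffm_final_kg))
        out = bc.evaluate_models(records)
        assert set(out) == {
            "nhanes_fm_baseline", "nhanes_fm_final", "nhanes_delta_ffm",
            "forbes_fm_baseline", "forbes_fm_final", "forbes_delta_ffm"}
        for key in ("nhanes_fm_baseline", "nhanes_fm_final",
                    "nhanes_delta_ffm"):
            assert out[key].mean_error_kg == pytest.approx(0.0, abs=1e-6)
            assert out[key].n == 20
        assert abs(out["forbes_fm_baseline"].mean_error_kg) > 1e-3

    def test_forbes_inversion_helper_matches_curve(self):
        model = bc.ForbesModel.male()
        fm = _solve_forbes_fm(80.0, model)
        assert fm + bc.forbes_ffm(fm, model) == pytest.approx(80.0,
                                                              abs=1e-8)
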