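"""Cohort generator: intercept calibration, determinism, shift, weight courses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit
from scipy.stats import chi2_contingency

from ordval.preprocess import dehydration_category, stable_weight
from ordval.schema import OUTCOME_COL, OUTCOME_LEVELS
from ordval.synthetic import (
    CohortSpec,
    EffectMap,
    calibrate_intercepts,
    generate_cohort,
    generate_weight_course,
    null_effect_map,
    outcome_codes,
    read_cohort_csv,
    shift_spec,
    spec_from_yaml,
    spec_to_yaml,
    write_cohort_csv,
)
from tests.conftest import mini_spec


class TestCalibrateIntercepts:
    def test_closed_form_when_eta_constant(self):
        thetas = calibrate_intercepts((0.2, 0.6, 0.2), np.zeros(100))
        assert np.allclose(thetas, [logit(0.2), logit(0.8)], atol=1e-8)

    def test_matches_root_finding_oracle_on_empirical_cdf(self):
        # independent oracle: bisect mean expit(t - eta) = target on a grid
        rng = np.random.default_rng(5)
        eta = rng.logistic(size=20000)
        thetas = calibrate_intercepts((1 / 3, 1 / 3, 1 / 3), eta)
        for t, target in zip(thetas, (1 / 3, 2 / 3)):
            assert abs(np.mean(expit(t - eta)) - target) < 1e-6
        # simulation oracle: outcomes drawn at these thresholds hit the
        # targets within Monte-Carlo error
        u = rng.uniform(size=len(eta))
        y = 1 + (u > expit(thetas[0] - eta)) + (u > expit(thetas[1] - eta))
        freq = np.bincount(y, minlength=4)[1:] / len(y)
        assert np.allclose(freq, 1 / 3, atol=3 * np.sqrt((1 / 3) * (2 / 3) / len(eta)))

    def test_ascending_and_error_on_bad_prevalences(self):
        eta = np.random.default_rng(0).normal(size=500)
        thetas = calibrate_intercepts((431 / 2139, 1431 / 2139, 277 / 2139), eta)
        assert thetas[0] < thetas[1]
        with pytest.raises(ValueError):
            calibrate_intercepts((0.5, 0.5, 0.2), eta)
        with pytest.raises(ValueError):
            calibrate_intercepts((0.2, 0.6, 0.2), np.array([np.inf, 0.0]))

    @settings(max_examples=25, deadline=None)
    @given(
        p1=st.floats(0.05, 0.6),
        p2=st.floats(0.05, 0.6),
        seed=st.integers(0, 10_000),
    )
    def test_calibration_postcondition_property(self, p1, p2, seed):
        p3 = 1.0 - p1 - p2
        if p3 < 0.05:
            return
        eta = np.random.default_rng(seed).normal(scale=1.5, size=2000)
        thetas = calibrate_intercepts((p1, p2, p3), eta)
        assert np.all(np.diff(thetas) > 0)
        assert abs(np.mean(expit(thetas[0] - eta)) - p1) < 1e-6
        assert abs(np.mean(expit(thetas[1] - eta)) - (p1 + p2)) < 1e-6


class TestGenerateCohort:
    def test_empty_cohort_has_full_schema(self, schema):
        coh = generate_cohort(CohortSpec(n=0, seed=0))
        assert len(coh) == 0
        assert list(coh.columns) == list(schema.columns)

    def test_deterministic_under_seed(self):
        spec = CohortSpec(n=200, seed=42)
        a, b = generate_cohort(spec), generate_cohort(spec)
        pd.testing.assert_frame_equal(a, b)

    def test_outcome_independent_of_predictors_under_null_effects(self):
        # with all effects zero the outcome must not associate with any
        # predictor; no chi-square p-value should be systematically small
        pvals = []
        for seed in range(5):
            spec = CohortSpec(n=4000, effect_map=null_effect_map(), seed=seed)
            coh = generate_cohort(spec)
            tab = pd.crosstab(coh["eyes"], coh[OUTCOME_COL])
            pvals.append(chi2_contingency(tab).pvalue)
        assert sum(p < 0.05 for p in pvals) <= 1

    def test_marginals_hit_targets_within_mc_error(self):
        spec = CohortSpec(n=8000, seed=7)
        coh = generate_cohort(spec)
        freq = coh[OUTCOME_COL].value_counts(normalize=True)
        for level, target in zip(OUTCOME_LEVELS, spec.prevalences):
            se = np.sqrt(target * (1 - target) / spec.n)
            assert abs(freq[level] - target) < 3 * se

    def test_unknown_predictor_in_effect_map_errors(self):
        with pytest.raises(ValueError, match="known"):
            CohortSpec(n=10, effect_map=EffectMap(linear={"not_a_predictor": 1.0}))

    def test_invalid_prevalences_error(self):
        with pytest.raises(ValueError):
            CohortSpec(n=10, prevalences=(0.5, 0.5, 0.0))
        with pytest.raises(ValueError):
            CohortSpec(n=10, prevalences=(0.4, 0.4, 0.4))


class TestShiftSpec:
    def test_default_shift_hits_validation_severe_fraction(self):
        spec = CohortSpec(n=2139, seed=3)
        val = generate_cohort(shift_spec(spec))
        assert len(val) == 1580
        severe = (val[OUTCOME_COL] == "severe").mean()
        se = np.sqrt(0.076 * (1 - 0.076) / 1580)
        assert abs(severe - 120 / 1580) < 3 * se

    def test_age_location_shift_lowers_median_age(self):
        spec = CohortSpec(n=3000, seed=4)
        train = generate_cohort(spec)
        val = generate_cohort(shift_spec(spec))
        assert val["age"].median() < train["age"].median() - 2.0

    def test_shift_missing_errors(self):
        spec = CohortSpec(n=10, shift=None, seed=0)
        with pytest.raises(ValueError):
            shift_spec(spec)


class TestWeightCourse:
    def test_noise_free_inversion(self):
        ws = generate_weight_course(10.0, 50.0, noise_sd=0.0)
        assert ws.admission_weight == pytest.approx(45.0)
        stable = stable_weight(ws)
        assert stable == pytest.approx(50.0)
        pct, cat = dehydration_category(ws.admission_weight, stable)
        assert pct == pytest.approx(10.0)
        assert cat == "severe"

    def test_zero_dehydration_gives_none(self):
        ws = generate_weight_course(0.0, 60.0, noise_sd=0.0)
        assert ws.admission_weight == pytest.approx(60.0)
        pct, cat = dehydration_category(ws.admission_weight, stable_weight(ws))
        assert pct == pytest.approx(0.0)
        assert cat == "none"

    def test_monte_carlo_recovery_with_noise(self):
        recovered = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            ws = generate_weight_course(5.0, 60.0, noise_sd=0.1, rng=rng)
            stable = stable_weight(ws)
            if stable is None:
                continue
            pct, _ = dehydration_category(ws.admission_weight, stable)
            recovered.append(pct)
        assert len(recovered) >= 150
        assert abs(np.mean(recovered) - 5.0) < 0.5

    def test_invalid_inputs_error(self):
        with pytest.raises(ValueError):
            generate_weight_course(5.0, 60.0, noise_sd=-0.1)
        with pytest.raises(ValueError):
            generate_weight_course(100.0, 60.0)
        with pytest.raises(ValueError):
            generate_weight_course(5.0, 0.0)


class TestSerialization:
    def test_spec_yaml_round_trip_byte_identical(self):
        spec = CohortSpec(n=123, seed=9)
        text = spec_to_yaml(spec)
        assert spec_to_yaml(spec_from_yaml(text)) == text

    def test_cohort_csv_round_trip(self, tmp_path):
        coh = generate_cohort(mini_spec(n=50, seed=2))
        path = tmp_path / "cohort.csv"
        write_cohort_csv(coh, path)
        back = read_cohort_csv(path, mini_spec(n=1, seed=0).schema)
        assert list(back.columns) == list(coh.columns)
        assert (outcome_codes(back) == outcome_codes(coh)).all()
        np.testing.assert_allclose(back["age"], coh["age"], rtol=1e-12)
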