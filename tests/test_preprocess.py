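"""Criterion standard, binning, splines and design-matrix encoding."""

import numpy as np
import pandas as pd
import pytest

from ordval.preprocess import (
    DesignEncoder,
    SplineBasis,
    bin_predictors,
    complete_cases,
    dehydration_category,
    encode_design,
    rcs_basis,
    stable_weight,
)
from ordval.schema import OUTCOME_COL, default_schema
from ordval.synthetic import CohortSpec, WeightSeries, generate_cohort


def series(*weights):
    return WeightSeries(patient_id=0, weights=tuple(weights), admission_weight=weights[0])


class TestStableWeight:
    def test_oracle_enumeration_on_three_weights(self):
        # oracle: enumerate consecutive pairs, keep <2% relative difference,
        # take the pair with the largest mean
        w = [44.0, 44.5, 44.3]
        pairs = [(a, b) for a, b in zip(w, w[1:]) if abs(b - a) / max(a, b) < 0.02]
        expected = max((a + b) / 2 for a, b in pairs)
        assert stable_weight(series(*w)) == pytest.approx(expected) == pytest.approx(44.4)

    def test_identical_pair(self):
        assert stable_weight(series(50.0, 50.0)) == pytest.approx(50.0)

    def test_not_stabilized(self):
        assert stable_weight(series(40.0, 42.0)) is None

    def test_earliest_pair_wins_ties(self):
        # two qualifying pairs with equal means: (50, 50) at t=0 and t=3
        assert stable_weight(series(50.0, 50.0, 10.0, 50.0, 50.0)) == pytest.approx(50.0)

    def test_nonpositive_weight_errors(self):
        with pytest.raises(ValueError):
            stable_weight(series(50.0, -1.0))


class TestDehydrationCategory:
    @pytest.mark.parametrize(
        "admission,stable,pct,cat",
        [
            (45.0, 50.0, 10.0, "severe"),
            (48.5, 50.0, 3.0, "some"),  # 3% boundary belongs to "some"
            (45.5, 50.0, 9.0, "some"),  # 9% boundary belongs to "some"
            (50.0, 50.0, 0.0, "none"),
            (52.0, 50.0, -4.0, "none"),  # weight loss on rehydration: none
        ],
    )
    def test_examples(self, admission, stable, pct, cat):
        p, c = dehydration_category(admission, stable)
        assert p == pytest.approx(pct)
        assert c == cat

    def test_monotone_in_percent(self):
        cats = [dehydration_category(50.0 * (1 - p / 100), 50.0)[1] for p in np.linspace(-5, 20, 200)]
        rank = {"none": 0, "some": 1, "severe": 2}
        assert all(rank[a] <= rank[b] for a, b in zip(cats, cats[1:]))

    def test_zero_weight_errors(self):
        with pytest.raises(ValueError):
            dehydration_category(0.0, 50.0)


class TestBinPredictors:
    def test_bin_edges(self):
        raw = pd.DataFrame(
            {
                "vomiting_episodes": [0, 1, 5, 6, 10, 11],
                "diarrheal_episodes": [0, 9, 10, 19, 20, 25],
                "diarrhea_duration_hr": [0, 12, 13, 23, 24, 48],
            }
        )
        out = bin_predictors(raw)
        assert list(out["vomiting_episodes"]) == ["<1", "1-5", "1-5", "6-10", "6-10", ">10"]
        assert list(out["diarrheal_episodes"]) == ["<10", "<10", "10-19", "10-19", ">19", ">19"]
        assert list(out["diarrhea_duration_hr"]) == ["<13", "<13", "13-23", "13-23", ">23", ">23"]

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            bin_predictors(pd.DataFrame({"vomiting_episodes": [-1]}))

    def test_already_binned_untouched(self):
        coh = generate_cohort(CohortSpec(n=20, seed=0))
        out = bin_predictors(coh)
        pd.testing.assert_frame_equal(out, coh)


class TestCompleteCases:
    def test_identity_when_complete(self):
        coh = generate_cohort(CohortSpec(n=50, seed=1))
        kept, dropped = complete_cases(coh)
        assert dropped == 0
        pd.testing.assert_frame_equal(kept, coh)

    def test_drop_counts(self):
        coh = generate_cohort(CohortSpec(n=2172, seed=1)).copy()
        coh.loc[:32, "age"] = np.nan  # 33 incomplete rows
        kept, dropped = complete_cases(coh)
        assert dropped == 33
        assert len(kept) == 2139

    def test_all_dropped_errors(self):
        coh = generate_cohort(CohortSpec(n=1, seed=1)).copy()
        coh[OUTCOME_COL] = np.nan
        with pytest.raises(ValueError):
            complete_cases(coh)


class TestSplines:
    def test_zero_below_first_knot(self):
        basis = SplineBasis(knots=(1.0, 2.0, 4.0))
        x = np.linspace(-3, 1.0, 20)
        cols = rcs_basis(x, basis)
        np.testing.assert_allclose(cols[:, 0], x)
        np.testing.assert_allclose(cols[:, 1], 0.0, atol=1e-15)

    def test_linear_beyond_last_knot_by_finite_differences(self):
        basis = SplineBasis(knots=(0.0, 1.0, 2.0))
        x = np.linspace(2.5, 10.0, 50)  # beyond the boundary knot
        nl = rcs_basis(x, basis)[:, 1]
        second_diff = np.diff(nl, 2)
        np.testing.assert_allclose(second_diff, 0.0, atol=1e-9)

    def test_degenerate_knots_error(self):
        with pytest.raises(ValueError):
            SplineBasis(knots=(1.0, 1.0, 2.0))
        with pytest.raises(ValueError):
            SplineBasis.from_training(np.ones(100))

    def test_knots_at_percentiles(self):
        x = np.arange(1000.0)
        basis = SplineBasis.from_training(x)
        np.testing.assert_allclose(basis.knots, np.percentile(x, [10, 50, 90]))


class TestEncodeDesign:
    def test_set1_column_count_from_level_sets(self, schema):
        # derived count: sum of (levels - 1) over categoricals + 3 continuous
        expected = sum(len(v) - 1 for v in schema.categorical.values()) + 3
        coh = generate_cohort(CohortSpec(n=300, seed=5))
        dm = encode_design(coh, 1)
        assert dm.p == expected == 23

    @pytest.mark.parametrize("pair", [(1, 2), (3, 4)])
    def test_interaction_sets_strictly_wider(self, pair, cohort_small):
        a = encode_design(cohort_small, pair[0])
        b = encode_design(cohort_small, pair[1])
        assert b.p > a.p
        assert set(a.main_blocks) == set(b.main_blocks)
        # hierarchy: every interaction's parents are present as main blocks
        for bname in b.interaction_blocks:
            pa, pb = b.block_parents[bname]
            assert pa in b.main_blocks and pb in b.main_blocks

    def test_spline_set_uses_two_columns_per_continuous(self, cohort_small):
        dm1 = encode_design(cohort_small, 1)
        dm3 = encode_design(cohort_small, 3)
        assert dm3.p == dm1.p + 3  # one extra nonlinear column per continuous

    def test_constant_continuous_predictor_errors_for_splines(self, cohort_small):
        coh = cohort_small.copy()
        coh["age"] = 30.0
        with pytest.raises(ValueError):
            encode_design(coh, 3)

    def test_round_trip_identity(self, cohort_small):
        enc = DesignEncoder(2).fit(cohort_small)
        a = enc.transform(cohort_small)
        b = enc.transform(cohort_small)
        np.testing.assert_array_equal(a.X, b.X)
        assert a.columns == b.columns

    def test_knots_frozen_for_test_data(self, cohort_small):
        enc = DesignEncoder(3).fit(cohort_small)
        train_knots = {k: v.knots for k, v in enc.knots_.items()}
        test = generate_cohort(CohortSpec(n=100, seed=77))
        enc.transform(test)
        assert {k: v.knots for k, v in enc.knots_.items()} == train_knots

    def test_unseen_level_errors(self, cohort_small):
        enc = DesignEncoder(1).fit(cohort_small)
        bad = cohort_small.copy()
        bad["eyes"] = bad["eyes"].cat.add_categories("glazed")
        bad.iloc[0, bad.columns.get_loc("eyes")] = "glazed"
        with pytest.raises(ValueError, match="glazed"):
            enc.transform(bad)

    def test_no_constant_columns(self, cohort_small):
        for set_id in (1, 2, 3, 4):
            dm = encode_design(cohort_small, set_id)
            assert np.all(dm.X.std(axis=0) > 0)
            assert np.all(np.isfinite(dm.X))
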