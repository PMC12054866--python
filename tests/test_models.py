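"""Proportional-odds and ridge fits, stepwise selection, prediction contract."""

import numpy as np
import pytest
from scipy.special import expit

from ordval.cumlogit import ConvergenceError, fit_cumlogit
from ordval.models import fit_polr, fit_ridge, stepwise_interactions, stepwise_main
from ordval.preprocess import DesignMatrix, encode_design
from ordval.synthetic import generate_cohort, outcome_codes
from tests.conftest import mini_spec


def simulate_po(n, beta, thetas=(-1.0, 1.0), seed=0):
    """Draw from an exactly specified proportional-odds model."""
    rng = np.random.default_rng(seed)
    p = len(beta)
    X = rng.normal(size=(n, p))
    eta = X @ np.asarray(beta)
    u = rng.uniform(size=n)
    y = 1 + (u > expit(thetas[0] - eta)) + (u > expit(thetas[1] - eta))
    return X, y.astype(int)


def plain_dm(X, names=None):
    names = names or [f"x{i}" for i in range(X.shape[1])]
    return DesignMatrix(
        X=X,
        columns=list(names),
        blocks={c: [i] for i, c in enumerate(names)},
        block_parents={},
        main_blocks=list(names),
        interaction_blocks=[],
        set_id=1,
    )


class TestPolr:
    def test_intercept_only_reproduces_empirical_frequencies(self):
        _, y = simulate_po(500, [0.0])
        dm = plain_dm(np.empty((500, 0)), names=[])
        fit = fit_polr(dm, y, block_names=[])
        freq = np.bincount(y, minlength=4)[1:] / len(y)
        np.testing.assert_allclose(fit.predict_proba(dm)[0], freq, atol=1e-6)

    def test_parameter_recovery_at_n5000(self):
        X, y = simulate_po(5000, [1.0], seed=3)
        fit = fit_polr(plain_dm(X), y)
        assert abs(fit.core.beta[0] - 1.0) < 0.1
        assert fit.core.thetas[0] < fit.core.thetas[1]

    def test_duplicated_column_errors(self):
        X, y = simulate_po(200, [1.0], seed=1)
        dm = plain_dm(np.column_stack([X, X]))
        with pytest.raises(ValueError, match="rank"):
            fit_polr(dm, y)

    def test_missing_category_errors(self):
        X, y = simulate_po(200, [1.0], seed=1)
        y[y == 3] = 2
        with pytest.raises(ValueError, match="absent"):
            fit_polr(plain_dm(X), y)

    def test_complete_separation_errors(self):
        x = np.concatenate([np.zeros(30), np.ones(30), 2 * np.ones(30)])
        y = np.concatenate([np.ones(30), 2 * np.ones(30), 3 * np.ones(30)]).astype(int)
        with pytest.raises((ConvergenceError, ValueError)):
            fit_cumlogit(x[:, None] * 100, y)

    def test_matches_statsmodels_ordered_model(self):
        sm = pytest.importorskip("statsmodels.miscmodels.ordinal_model")
        X, y = simulate_po(800, [0.8, -0.4], seed=5)
        ours = fit_cumlogit(X, y)
        theirs = sm.OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=False)
        np.testing.assert_allclose(ours.beta, theirs.params[:2], atol=1e-3)
        assert ours.loglik == pytest.approx(theirs.llf, abs=1e-4)

    def test_probability_simplex_and_monotonicity(self):
        X, y = simulate_po(500, [1.0, 0.5], seed=2)
        fit = fit_polr(plain_dm(X), y)
        probs = fit.predict_proba(plain_dm(X))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(probs >= 0)
        # raising a positive-slope predictor shifts mass to higher categories
        grid = np.column_stack([np.linspace(-3, 3, 50), np.zeros(50)])
        pg = fit.core.predict_proba(grid)
        above1 = pg[:, 1] + pg[:, 2]
        assert np.all(np.diff(above1) > 0)
        assert np.all(np.diff(pg[:, 2]) > 0)


class TestRidge:
    def test_lambda_zero_matches_polr(self):
        X, y = simulate_po(400, [0.7, -0.3], seed=4)
        dm = plain_dm(X)
        a = fit_polr(dm, y)
        b = fit_ridge(dm, y, 0.0)
        np.testing.assert_allclose(a.core.beta, b.core.beta, atol=1e-4)

    def test_infinite_shrinkage_limit(self):
        X, y = simulate_po(400, [0.7, -0.3], seed=4)
        dm = plain_dm(X)
        fit = fit_ridge(dm, y, 1e8)
        assert np.linalg.norm(fit.core.beta) < 1e-4
        freq = np.bincount(y, minlength=4)[1:] / len(y)
        np.testing.assert_allclose(fit.predict_proba(dm).mean(axis=0), freq, atol=1e-3)

    def test_norm_monotone_in_lambda(self):
        X, y = simulate_po(300, [1.0, -0.8, 0.5], seed=6)
        dm = plain_dm(X)
        norms = [
            np.linalg.norm(fit_ridge(dm, y, lam).core.beta)
            for lam in np.geomspace(0.01, 100, 8)
        ]
        assert all(b <= a + 1e-6 for a, b in zip(norms, norms[1:]))

    def test_negative_lambda_errors(self):
        X, y = simulate_po(100, [1.0], seed=0)
        with pytest.raises(ValueError):
            fit_ridge(plain_dm(X), y, -1.0)


class TestStepwise:
    def test_dominant_predictor_selected_first(self):
        coh = generate_cohort(mini_spec(600, seed=8))
        y = outcome_codes(coh)
        # overwrite one latent draw: make eyes indicator strongly predictive
        X, _ = simulate_po(600, [0.0, 0.0], seed=8)
        strong = (y - 2.0)  # perfectly rank-correlated but not separating
        strong = strong + np.random.default_rng(1).normal(0, 0.5, 600)
        dm = plain_dm(np.column_stack([X, strong]), names=["a", "b", "signal"])
        path = stepwise_main(dm, y, max_size=3)
        assert path.steps[0] == "signal"

    def test_max_size_zero_gives_intercept_only(self, encoded_small):
        dm, y = encoded_small
        path = stepwise_main(dm, y, max_size=0)
        assert path.steps == []
        assert path.null_fit.block_names == []

    def test_blocks_enter_whole(self, encoded_small):
        dm, y = encoded_small
        path = stepwise_main(dm, y, max_size=2)
        for fit in path.fits:
            for block in fit.block_names:
                assert set(dm.blocks[block]) <= set(fit.column_index)

    def test_interactions_respect_hierarchy(self, cohort_small):
        dm = encode_design(cohort_small, 2)
        y = outcome_codes(cohort_small)
        mains = ["skin_pinch", "eyes", "age"]
        path = stepwise_interactions(dm, y, mains, max_ints=2)
        allowed = set(mains)
        for step in path.steps:
            pa, pb = dm.block_parents[step]
            assert pa in allowed and pb in allowed

    def test_no_interaction_candidates_for_single_main(self, cohort_small):
        dm = encode_design(cohort_small, 2)
        y = outcome_codes(cohort_small)
        path = stepwise_interactions(dm, y, ["eyes"], max_ints=3)
        assert path.steps == []

    def test_true_interaction_ranked_first(self):
        # outcome driven by a pure product term between two noise mains
        rng = np.random.default_rng(9)
        n = 2000
        X = rng.normal(size=(n, 3))
        inter = X[:, 0] * X[:, 1]
        eta = 1.5 * inter
        u = rng.uniform(size=n)
        y = (1 + (u > expit(-1 - eta)) + (u > expit(1 - eta))).astype(int)
        cols = np.column_stack([X, X[:, 0] * X[:, 1], X[:, 0] * X[:, 2], X[:, 1] * X[:, 2]])
        names = ["a", "b", "c", "a:b", "a:c", "b:c"]
        dm = DesignMatrix(
            X=cols,
            columns=names,
            blocks={c: [i] for i, c in enumerate(names)},
            block_parents={"a:b": ("a", "b"), "a:c": ("a", "c"), "b:c": ("b", "c")},
            main_blocks=["a", "b", "c"],
            interaction_blocks=["a:b", "a:c", "b:c"],
            set_id=2,
        )
        path = stepwise_interactions(dm, y, ["a", "b", "c"], max_ints=1)
        assert path.steps == ["a:b"]


class TestSerialization:
    def test_polr_json_round_trip_reproduces_predictions(self):
        from ordval.models import PolrFit

        X, y = simulate_po(300, [0.9, -0.4], seed=12)
        dm = plain_dm(X)
        fit = fit_polr(dm, y)
        back = PolrFit.from_json(fit.to_json())
        np.testing.assert_array_equal(back.predict_proba(dm), fit.predict_proba(dm))

    def test_ridge_json_round_trip_reproduces_predictions(self):
        from ordval.models import RidgeFit

        X, y = simulate_po(300, [0.9, -0.4], seed=13)
        dm = plain_dm(X)
        fit = fit_ridge(dm, y, 2.0)
        back = RidgeFit.from_json(fit.to_json())
        np.testing.assert_array_equal(back.predict_proba(dm), fit.predict_proba(dm))
        assert back.lam == 2.0
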