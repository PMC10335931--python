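"""Quintile stratification, the penalized fit, and vote-counting selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from infantfm.linmodel import LinearFMModel
from infantfm.selection import (
    SelectionSpec,
    VoteTable,
    choose_lambda,
    lasso_fit,
    quintile_bins,
    run_selection,
    select_variables,
    stratified_subsample,
)
from infantfm.synthetic import GeneratorSpec, generate_cohort


class TestQuintileBins:
    def test_even_split(self):
        bins = quintile_bins(np.arange(1, 11), 5)
        assert [np.sum(bins == b) for b in range(5)] == [2, 2, 2, 2, 2]
        # lowest values land in bin 0
        assert bins[0] == 0 and bins[-1] == 4

    def test_remainder_goes_to_lowest_bins(self):
        bins = quintile_bins(np.arange(133), 5)
        assert [np.sum(bins == b) for b in range(5)] == [27, 27, 27, 26, 26]

    def test_constant_y_stable_order(self):
        bins = quintile_bins(np.zeros(11), 5)
        sizes = [np.sum(bins == b) for b in range(5)]
        assert max(sizes) - min(sizes) <= 1
        # stable tie-break: first records occupy the first bins
        assert list(bins[:3]) == [0, 0, 0]

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            quintile_bins(np.arange(3), 5)

    @given(n=st.integers(5, 200))
    @settings(derandomize=True, max_examples=30)
    def test_sizes_differ_by_at_most_one(self, n):
        rng = np.random.default_rng(n)
        bins = quintile_bins(rng.normal(size=n), 5)
        sizes = [np.sum(bins == b) for b in range(5)]
        assert max(sizes) - min(sizes) <= 1 and sum(sizes) == n


class TestStratifiedSubsample:
    def test_eighty_percent_per_bin(self):
        bins = np.repeat(np.arange(5), 10)
        idx = stratified_subsample(bins, 0.8, np.random.default_rng(0))
        assert len(idx) == 40
        for b in range(5):
            assert np.sum(bins[idx] == b) == 8

    def test_fraction_one_is_identity(self):
        bins = np.repeat(np.arange(5), 7)
        idx = stratified_subsample(bins, 1.0, np.random.default_rng(0))
        assert np.array_equal(idx, np.arange(35))

    def test_minimum_one_per_bin(self):
        bins = np.array([0, 1, 1, 2, 2, 2])
        idx = stratified_subsample(bins, 0.8, np.random.default_rng(0))
        assert 0 in bins[idx]  # the singleton bin keeps its record

    def test_no_replacement(self):
        bins = np.zeros(10, dtype=int)
        idx = stratified_subsample(bins, 0.8, np.random.default_rng(1))
        assert len(np.unique(idx)) == len(idx)


class TestLassoFit:
    def test_soft_threshold_single_predictor(self):
        # standardized predictor, y = 2x exactly: OLS beta 2.0, lambda 0.5
        # soft-thresholds to 1.5
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        x = (x - x.mean()) / x.std()
        y = 2.0 * x
        icept, betas = lasso_fit(x[:, None], y, 0.5)
        assert betas[0] == pytest.approx(1.5, abs=1e-6)
        assert icept == pytest.approx(0.0, abs=1e-9)

    def test_full_shrinkage(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 4))
        y = X @ [1.0, 0.5, -0.3, 0.2] + 3.0
        icept, betas = lasso_fit(X, y, 1e3)
        assert np.all(betas == 0.0)
        assert icept == pytest.approx(y.mean())

    def test_lambda_zero_is_ols(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 3))
        y = X @ [1.0, -2.0, 0.5] + 1.0 + rng.normal(size=60) * 0.1
        icept, betas = lasso_fit(X, y, 0.0)
        design = np.column_stack([np.ones(60), X])
        ols = np.linalg.lstsq(design, y, rcond=None)[0]
        assert icept == pytest.approx(ols[0], abs=1e-6)
        np.testing.assert_allclose(betas, ols[1:], atol=1e-6)

    def test_grid_search_oracle_two_predictors(self):
        """Coordinate descent agrees with direct minimization of the objective."""
        rng = np.random.default_rng(3)
        for trial in range(5):
            n = rng.integers(6, 13)
            X = rng.normal(size=(n, 2))
            y = X @ rng.normal(size=2) + rng.normal(size=n) * 0.3
            lam = float(rng.uniform(0.05, 0.5))
            icept, betas = lasso_fit(X, y, lam)

            Xs = (X - X.mean(0)) / X.std(0)
            yc = y - y.mean()

            def objective(b1, b2):
                r = yc - Xs @ [b1, b2]
                return 0.5 * np.mean(r**2) + lam * (abs(b1) + abs(b2))

            # two-stage grid around the reported solution
            b_std = betas * X.std(0)
            best = (objective(*b_std), tuple(b_std))
            for step, half in ((0.01, 0.5), (0.0002, 0.012)):
                g1 = np.arange(best[1][0] - half, best[1][0] + half, step)
                g2 = np.arange(best[1][1] - half, best[1][1] + half, step)
                for a in g1:
                    for b in g2:
                        val = objective(a, b)
                        if val < best[0]:
                            best = (val, (a, b))
            assert objective(*b_std) <= best[0] + 1e-4

    def test_affine_rescaling_preserves_fit(self):
        """Scaling a column rescales its beta and keeps zeros exactly zero."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 5))
        y = X[:, 0] * 2 + rng.normal(size=80) * 0.2
        _, b_ref = lasso_fit(X, y, 0.1)
        X2 = X.copy()
        X2[:, 0] *= 37.0
        X2[:, 3] = X[:, 3] * 0.001 + 5.0
        _, b_scaled = lasso_fit(X2, y, 0.1)
        assert b_scaled[0] == pytest.approx(b_ref[0] / 37.0, rel=1e-9)
        assert (b_ref == 0) [1:].tolist() == (b_scaled == 0)[1:].tolist()

    def test_nan_rejected(self):
        X = np.ones((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            lasso_fit(X, np.ones(10), 0.1)


@pytest.fixture(scope="module")
def small_cohort():
    return generate_cohort(GeneratorSpec("3M", seed=3, low_fm_fraction=0.0))


class TestRunSelection:

    def test_beta_matrix_shape_and_reproducibility(self, small_cohort):
        spec = SelectionSpec(blocks=5, reps_per_block=12, vote_threshold=25, seed=11)
        votes1 = run_selection(small_cohort, spec)
        votes2 = run_selection(small_cohort, spec)
        assert votes1.betas.shape == (60, 16)
        np.testing.assert_array_equal(votes1.betas, votes2.betas)

    def test_strong_signal_variables_always_voted(self):
        truth = LinearFMModel.from_mapping(
            "3M", {"thigh_circ": 0.10, "calf_circ": 0.12, "subscapular_sf": 0.05}, -2.5
        )
        spec = GeneratorSpec(
            "3M", n=200, true_model=truth, noise_sd=0.11, low_fm_fraction=0.0, seed=11
        )
        cohort = generate_cohort(spec)
        votes = run_selection(
            cohort, SelectionSpec(blocks=10, reps_per_block=12, vote_threshold=50, seed=21)
        ).votes
        for name in truth.variables:
            assert votes[name] >= 0.9 * 120, name

    def test_pure_noise_never_dominates(self):
        truth = LinearFMModel.from_mapping("3M", {}, 1.2)
        spec = GeneratorSpec(
            "3M", n=200, true_model=truth, noise_sd=0.3, low_fm_fraction=0.0, seed=13
        )
        cohort = generate_cohort(spec)
        votes = run_selection(
            cohort, SelectionSpec(blocks=10, reps_per_block=12, vote_threshold=50, seed=23)
        ).votes
        # scaled version of the 500/1200 rule: no variable may clear it
        assert max(votes.values()) < 120 * 500 / 1200

    def test_lambda_rules_available(self, small_cohort):
        X = small_cohort.design_matrix(("weight", "thigh_circ", "calf_sf"))
        y = small_cohort.fm_array()
        lam_cv = choose_lambda(X, y, SelectionSpec(lambda_rule="cv"))
        lam_1se = choose_lambda(X, y, SelectionSpec(lambda_rule="lambda_1se"))
        lam_fix = choose_lambda(
            X, y, SelectionSpec(lambda_rule="fixed", lambda_value=0.25)
        )
        assert lam_1se >= lam_cv > 0
        assert lam_fix == 0.25


class TestSelectVariables:
    def _table(self, votes_a: int, total: int = 1200) -> VoteTable:
        betas = np.zeros((total, 2))
        betas[:votes_a, 0] = 1.0
        betas[:, 1] = 1.0
        return VoteTable(("a", "b"), betas)

    def test_threshold_boundary(self):
        assert select_variables(self._table(500), 500) == ["a", "b"]
        assert select_variables(self._table(499), 500) == ["b"]

    def test_empty_selection(self):
        betas = np.zeros((1200, 2))
        assert select_variables(VoteTable(("a", "b"), betas), 500) == []

    def test_threshold_above_total_rejected(self):
        with pytest.raises(ValueError):
            select_variables(self._table(10, total=100), 200)


def test_spec_validation():
    with pytest.raises(ValueError, match="vote_threshold"):
        SelectionSpec(blocks=10, reps_per_block=10, vote_threshold=500)
    with pytest.raises(ValueError, match="subsample_fraction"):
        SelectionSpec(subsample_fraction=0.0)
    with pytest.raises(ValueError, match="lambda_value"):
        SelectionSpec(lambda_rule="fixed")
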