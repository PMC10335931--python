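"""Bland-Altman, Deming, correlation, and mean-comparison statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from infantfm.agreement import (
    bland_altman,
    compare_means,
    correlation_and_r2,
    deming_regression,
    validate_model,
)
from infantfm.crossval import CVSpec, run_cv
from infantfm.published import published_equation
from infantfm.synthetic import GeneratorSpec, generate_cohort


class TestBlandAltman:
    def test_identity_data(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        ba = bland_altman(x, x)
        assert ba.bias == 0.0
        assert ba.loa_lower == 0.0 and ba.loa_upper == 0.0
        assert ba.pct_below_loa == 0.0 and ba.pct_above_loa == 0.0

    def test_three_point_closed_form(self):
        ba = bland_altman(np.array([-1.0, 0.0, 1.0]), np.zeros(3))
        assert ba.bias == pytest.approx(0.0)
        assert ba.sd_diff == pytest.approx(1.0)
        assert ba.loa_lower == pytest.approx(-1.96)
        assert ba.loa_upper == pytest.approx(1.96)
        # CI half-widths from the stated formulas
        t = stats.t.ppf(0.975, 2)
        assert ba.ci_bias[1] - ba.bias == pytest.approx(t / np.sqrt(3))
        assert ba.ci_loa_upper[1] - ba.loa_upper == pytest.approx(t * np.sqrt(1.0))

    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(x + 0.5, x)
        assert ba.bias == pytest.approx(0.5)
        assert ba.loa_upper - ba.loa_lower == pytest.approx(0.0)

    @given(
        st.lists(st.floats(-5, 5), min_size=3, max_size=40),
        st.lists(st.floats(-5, 5), min_size=3, max_size=40),
    )
    @settings(derandomize=True, max_examples=40)
    def test_antisymmetry(self, a, b):
        n = min(len(a), len(b))
        x, y = np.array(a[:n]), np.array(b[:n])
        f, g = bland_altman(x, y), bland_altman(y, x)
        assert f.bias == pytest.approx(-g.bias, abs=1e-12)
        assert f.loa_lower == pytest.approx(-g.loa_upper, abs=1e-12)
        assert f.pct_below_loa == pytest.approx(g.pct_above_loa)

    def test_five_percent_outside_on_large_normal(self):
        d = np.random.default_rng(0).normal(size=100000)
        ba = bland_altman(d, np.zeros_like(d))
        assert ba.pct_below_loa + ba.pct_above_loa == pytest.approx(5.0, abs=0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bland_altman(np.ones(4), np.ones(5))


class TestDeming:
    def test_identity_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        fit = deming_regression(x, x.copy())
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.equivalence

    def test_noiseless_scaling_recovered(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        fit = deming_regression(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert not fit.equivalence

    def test_reciprocal_symmetry_at_unit_ratio(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=60) + 2
        y = 1.4 * x + rng.normal(size=60) * 0.5
        fwd = deming_regression(x, y).slope
        back = deming_regression(y, x).slope
        assert fwd * back == pytest.approx(1.0, rel=1e-10)

    def test_large_ratio_approaches_ols(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=80)
        y = 0.8 * x + rng.normal(size=80) * 0.4
        fit = deming_regression(x, y, variance_ratio=1e8)
        ols = np.polyfit(x, y, 1)[0]
        assert fit.slope == pytest.approx(ols, rel=1e-3)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            deming_regression(np.ones(5), np.arange(5.0))


class TestCorrelation:
    def test_perfect_lines(self):
        x = np.array([1.0, 2.0, 3.0])
        r, p, r2 = correlation_and_r2(x, 2 * x)
        assert (r, r2) == (pytest.approx(1.0), pytest.approx(1.0))
        r, p, r2 = correlation_and_r2(x, -x)
        assert (r, r2) == (pytest.approx(-1.0), pytest.approx(1.0))

    def test_three_point_hand_computation(self):
        r, p, r2 = correlation_and_r2(
            np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0])
        )
        assert r == pytest.approx(3 / np.sqrt(2 * 14 / 3), abs=1e-4)  # 0.98198
        assert r2 == pytest.approx(0.9643, abs=1e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation_and_r2(np.ones(5), np.arange(5.0))


class TestCompareMeans:
    def test_identical_samples_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        name, _, p = compare_means(x, x.copy())
        assert p == pytest.approx(1.0)

    def test_separated_normals_detected(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 200)
        b = rng.normal(5, 1, 200)
        name, _, p = compare_means(a, b)
        assert name == "student_t"
        assert p < 0.001

    def test_skewed_sample_routes_to_mann_whitney(self):
        rng = np.random.default_rng(4)
        a = np.exp(rng.normal(0, 1.5, 150))  # heavy lognormal
        b = rng.normal(2, 1, 150)
        name, _, _ = compare_means(a, b)
        assert name == "mann_whitney_u"


class TestValidateModel:
    def test_self_consistency_on_noiseless_cohort(self, noiseless_6m):
        cohort, truth = noiseless_6m
        report = validate_model(truth, cohort)
        assert report.bias == pytest.approx(0.0, abs=1e-12)
        assert report.pearson_r == pytest.approx(1.0)
        assert report.deming_equivalence
        assert report.mean_predicted == pytest.approx(report.mean_measured)

    def test_single_gross_outlier_fraction(self):
        spec = GeneratorSpec("6M", n=50, noise_sd=0.0, low_fm_fraction=0.0, seed=30)
        cohort = generate_cohort(spec)
        import dataclasses

        records = list(cohort.records)
        rec = records[0]
        records[0] = dataclasses.replace(rec, fm_kg=rec.fm_kg + 3.0)
        from infantfm.cohort import CohortTable

        bumped = CohortTable("6M", records)
        report = validate_model(spec.true_model, bumped)
        assert report.pct_below_loa == pytest.approx(100.0 / 50)
        assert report.pct_above_loa == 0.0

    def test_plots_written(self, tmp_path, cohort_3m):
        model = published_equation("3M")
        validate_model(model, cohort_3m, plots_dir=tmp_path)
        assert (tmp_path / "bland_altman_3M.png").exists()
        assert (tmp_path / "deming_3M.png").exists()

    def test_median_r2_over_seeds_near_reference(self):
        """Scaled-down reproduction: median R² across seeds within ±0.08 of 0.69."""
        from infantfm.cohort import exclude_low_fm

        truth_vars = published_equation("3M").variables
        r2s = []
        for seed in range(7):
            spec = GeneratorSpec("3M", seed=400 + seed)
            cohort, _ = exclude_low_fm(generate_cohort(spec))
            res = run_cv(cohort, truth_vars, CVSpec(seed=500 + seed))
            report = validate_model(res.final_model, cohort)
            r2s.append(report.r_squared)
        assert abs(float(np.median(r2s)) - 0.69) <= 0.08
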