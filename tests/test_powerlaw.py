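"""Frequency/variance transforms, the OLS power law, and the heterogeneity index."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from quadlaw import (
    AnalysisError,
    DomainError,
    FitError,
    OccurrenceMatrix,
    SurveyDesign,
    UndefinedTransformError,
    analyze,
    analyze_summary,
    binomial_transform,
    classify_distribution,
    fit_power_law,
    heterogeneity_index,
    observed_transform,
    reconstruct_points,
    species_count_variance,
    species_frequency,
)


def ols_normal_equations(x, y):
    """Independent oracle: simple OLS via explicit normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    beta = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    alpha = (sy - beta * sx) / n
    return alpha, beta, y - (alpha + beta * x)


class TestFrequency:
    def test_single_presence_among_fifty_lquadrats(self):
        counts = [1] + [0] * 49
        assert species_frequency(counts, 4) == pytest.approx(1 / 200)

    def test_saturated(self):
        assert species_frequency([4, 4, 4], 4) == 1.0

    def test_hand_computed(self):
        assert species_frequency([2, 1, 0], 4) == pytest.approx(0.25)

    def test_empty_counts_raise(self):
        with pytest.raises(DomainError):
            species_frequency([], 4)

    def test_counts_above_m_raise(self):
        with pytest.raises(DomainError):
            species_frequency([5, 0], 4)


class TestVariance:
    def test_singleton_among_fifty(self):
        counts = [1] + [0] * 49
        assert species_count_variance(counts, "sample") == pytest.approx(0.02)

    def test_constant_counts_have_zero_variance(self):
        assert species_count_variance([3, 3, 3]) == 0.0

    def test_hand_computed_sample(self):
        assert species_count_variance([2, 1, 0], "sample") == pytest.approx(1.0)

    def test_population_divides_by_n(self):
        assert species_count_variance([2, 1, 0], "population") == pytest.approx(2 / 3)

    def test_fewer_than_two_counts_raise(self):
        with pytest.raises(DomainError):
            species_count_variance([1])


class TestTransforms:
    @pytest.mark.parametrize(
        "p, expected", [(0.005, -2.9053), (0.5, -1.2041)]
    )
    def test_binomial_transform_values(self, p, expected):
        assert binomial_transform(p, 4, 10) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize(
        "v, expected", [(1.0, -1.2041), (0.02, -2.9031)]
    )
    def test_observed_transform_values(self, v, expected):
        assert observed_transform(v, 4, 10) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_degenerate_frequency_undefined(self, p):
        with pytest.raises(UndefinedTransformError):
            binomial_transform(p, 4)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedTransformError):
            observed_transform(0.0, 4)

    def test_equal_binomial_variance_lands_on_identity(self):
        # if v equals the binomial variance n·p(1−p), then y == x exactly
        p, n = 0.3, 4
        v = n * p * (1 - p)
        assert observed_transform(v, n) == pytest.approx(binomial_transform(p, n))


class TestFitPowerLaw:
    def test_collinear_points_fit_exactly(self):
        pts = [(0, 1), (1, 3), (2, 5), (3, 7)]
        fit = fit_power_law(pts)
        assert fit.r_squared == pytest.approx(1.0)
        np.testing.assert_allclose(fit.residuals, 0, atol=1e-12)
        assert (fit.alpha, fit.beta) == (pytest.approx(1.0), pytest.approx(2.0))

    def test_too_few_points_raise(self):
        with pytest.raises(FitError):
            fit_power_law([(0, 1), (1, 2)])

    def test_degenerate_abscissa_raises(self):
        with pytest.raises(FitError):
            fit_power_law([(1, 0), (1, 1), (1, 2)])

    @given(
        st.lists(
            st.tuples(
                st.floats(-5, 5, allow_nan=False),
                st.floats(-5, 5, allow_nan=False),
            ),
            min_size=3,
            max_size=12,
        ).filter(lambda pts: np.ptp([p[0] for p in pts]) > 1e-3)
    )
    def test_matches_normal_equations_oracle(self, pts):
        fit = fit_power_law(pts)
        alpha, beta, resid = ols_normal_equations(*np.array(pts).T)
        assert fit.alpha == pytest.approx(alpha, rel=1e-10, abs=1e-10)
        assert fit.beta == pytest.approx(beta, rel=1e-10, abs=1e-10)
        np.testing.assert_allclose(fit.residuals, resid, atol=1e-10)

    @given(
        st.lists(
            st.tuples(st.floats(-5, 5), st.floats(-5, 5)),
            min_size=3,
            max_size=12,
        ).filter(lambda pts: np.ptp([p[0] for p in pts]) > 1e-3)
    )
    def test_residuals_sum_to_zero(self, pts):
        assert abs(fit_power_law(pts).residuals.sum()) < 1e-10

    def test_base_change_rescales_but_preserves_fit_quality(self, table1):
        """β and R² are base-invariant; α and δ scale by ln 10."""
        fit10 = fit_power_law(reconstruct_points(table1, 4, 10))
        pts_e = reconstruct_points(
            type(table1)(table1.frame.assign(delta=table1.delta * math.log(10))),
            4,
            math.e,
        )
        fit_e = fit_power_law(pts_e)
        assert fit_e.r_squared == pytest.approx(fit10.r_squared, abs=1e-12)
        assert fit_e.beta == pytest.approx(fit10.beta, abs=1e-12)
        assert fit_e.alpha == pytest.approx(fit10.alpha * math.log(10), abs=1e-10)


class TestHeterogeneityIndex:
    def test_on_identity_line_is_zero(self):
        assert heterogeneity_index(-1.5, -1.5) == 0.0

    def test_singleton_species_value(self):
        assert heterogeneity_index(-2.9053, -2.8943) == pytest.approx(0.0110)

    def test_base_change_scales_delta_by_ln10(self):
        p, v, n = 0.3, 2.0, 4
        d10 = heterogeneity_index(
            binomial_transform(p, n, 10), observed_transform(v, n, 10)
        )
        de = heterogeneity_index(
            binomial_transform(p, n, math.e), observed_transform(v, n, math.e)
        )
        assert de == pytest.approx(d10 * math.log(10))


class TestClassification:
    @pytest.mark.parametrize(
        "delta, tol, expected",
        [
            (0.3054, 0.0, "patchy"),
            (0.0, 0.0, "random"),
            (0.0, 0.5, "random"),
            (-0.2, 0.0, "uniform"),
            (0.03, 0.05, "random"),
            (-0.03, 0.05, "random"),
        ],
    )
    def test_sign_criteria(self, delta, tol, expected):
        assert classify_distribution(delta, tol) == expected

    def test_negative_tolerance_raises(self):
        with pytest.raises(DomainError):
            classify_distribution(0.1, -0.1)


class TestReconstruction:
    def test_point_for_singleton_row(self, table1):
        pts = reconstruct_points(table1, 4, 10)
        idx = table1.species.index("Grateloupia acuminata")
        assert pts[idx][0] == pytest.approx(-2.9053, abs=5e-5)
        assert pts[idx][1] == pytest.approx(-2.8943, abs=5e-5)

    def test_zero_delta_row_on_identity(self):
        import pandas as pd

        from quadlaw import SummaryTable

        t = SummaryTable(
            pd.DataFrame({"species": ["z"], "p": [0.4], "delta": [0.0]})
        )
        (x, y), = reconstruct_points(t, 4, 10)
        assert y == x

    def test_degenerate_p_raises_naming_row(self):
        import pandas as pd

        from quadlaw import SummaryTable

        t = SummaryTable(
            pd.DataFrame({"species": ["u"], "p": [1.0], "delta": [0.1]})
        )
        with pytest.raises(UndefinedTransformError, match="u"):
            reconstruct_points(t)

    def test_published_residuals_reproduced(self, table1):
        """Refitting the reconstructed points reproduces every printed ε."""
        result = analyze_summary(table1)
        printed = table1.frame["epsilon"].to_numpy()
        recomputed = np.array([s.epsilon for s in result.species_stats])
        np.testing.assert_allclose(recomputed, printed, atol=5e-4)
        assert result.fit.r_squared == pytest.approx(0.9809, abs=5e-4)


def _matrix_from_counts(counts_by_species, m=4):
    """Build a matrix whose per-L counts equal the given sequences."""
    n = len(next(iter(counts_by_species.values())))
    arr = np.zeros((n, m, len(counts_by_species)), dtype=np.uint8)
    for k, counts in enumerate(counts_by_species.values()):
        for j, c in enumerate(counts):
            arr[j, :c, k] = 1
    return OccurrenceMatrix(
        SurveyDesign(n, m), list(counts_by_species), arr
    )


class TestAnalyze:
    def test_exactly_three_species_fit(self):
        m = _matrix_from_counts(
            {"a": [1, 0, 2, 1], "b": [2, 3, 1, 2], "c": [0, 1, 0, 4]}
        )
        result = analyze(m)
        assert result.fit.n_points == 3
        assert abs(result.fit.residuals.sum()) < 1e-10

    def test_all_absent_matrix_refuses(self):
        m = _matrix_from_counts({"a": [0] * 4, "b": [0] * 4, "c": [0] * 4})
        with pytest.raises(AnalysisError):
            analyze(m)

    def test_excluded_species_carry_reasons(self):
        m = _matrix_from_counts(
            {
                "absent": [0, 0, 0, 0],
                "everywhere": [4, 4, 4, 4],
                "constant": [2, 2, 2, 2],
                "a": [1, 0, 2, 1],
                "b": [2, 3, 1, 2],
                "c": [0, 1, 0, 4],
            }
        )
        result = analyze(m)
        reasons = {s.species: s.reason for s in result.excluded}
        assert set(reasons) == {"absent", "everywhere", "constant"}
        assert result.fit.n_points == 3

    def test_epsilon_alignment_matches_fit_residuals(self):
        m = _matrix_from_counts(
            {"a": [1, 0, 2, 1], "b": [2, 3, 1, 2], "c": [0, 1, 0, 4]}
        )
        result = analyze(m)
        np.testing.assert_allclose(
            [s.epsilon for s in result.included], result.fit.residuals
        )
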