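"""ICER, dominance classification, acceptability curves, confidence ellipse."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renal_cea.cea import (
    Category,
    NO_EFFECTIVENESS_LOSS,
    category_frequencies,
    ceac,
    classify,
    confidence_ellipse,
    incremental,
    restricted_acceptance,
)
from renal_cea.errors import DegenerateCovarianceError
from renal_cea.markov import OutcomeSummary


def summary(cost: float, qaly: float) -> OutcomeSummary:
    return OutcomeSummary(total_cost=cost, total_qaly=qaly,
                          total_cost_undiscounted=cost,
                          total_qaly_undiscounted=qaly,
                          total_life_years=qaly, discount_rate=0.0,
                          per_patient_annual_cost=cost,
                          per_patient_annual_qaly=qaly)


class TestIncremental:
    def test_simple_ratio(self):
        res = incremental(summary(0.0, 0.0), summary(100.0, 0.01))
        assert res.icer == pytest.approx(10_000.0)

    def test_dominant_quadrant(self):
        res = incremental(summary(10.0, 0.0), summary(5.0, 0.1))
        assert res.category is Category.DOMINANT

    def test_ratio_of_published_deltas(self):
        # ratio of the printed undiscounted per-patient annual deltas;
        # the source's own table prints a ratio from unrounded internals,
        # so only the arithmetic on the printed deltas is asserted
        res = incremental(summary(0.0, 0.0), summary(425.0, 0.0176))
        assert res.icer == pytest.approx(24147.73, abs=0.01)

    def test_zero_delta_qaly_undefined_icer(self):
        res = incremental(summary(0.0, 0.1), summary(50.0, 0.1))
        assert res.icer is None
        assert res.category is Category.DOMINATED

    def test_icer_scale_invariant(self):
        a = incremental(summary(0.0, 0.0), summary(100.0, 0.01))
        b = incremental(summary(0.0, 0.0), summary(700.0, 0.07))
        assert a.icer == pytest.approx(b.icer)


class TestClassify:
    @pytest.mark.parametrize("dc, de, wtpt, expected", [
        (-1.0, 0.1, 0.0, Category.DOMINANT),
        (-1.0, 0.0, 45e3, Category.DOMINANT),
        (0.0, 0.1, 45e3, Category.DOMINANT),
        (100.0, 0.01, 45e3, Category.EFFICIENT_HIGHER_EFFECTIVENESS),
        (100.0, 0.001, 45e3, Category.NOT_ACCEPTABLE),
        (-1000.0, -0.01, 45e3, Category.EFFICIENT_LOWER_COST),
        (-100.0, -0.01, 45e3, Category.NOT_ACCEPTABLE),
        (1.0, -0.1, 45e3, Category.DOMINATED),
        (1.0, 0.0, 45e3, Category.DOMINATED),
        (0.0, -0.1, 45e3, Category.DOMINATED),
        (0.0, 0.0, 45e3, Category.NOT_ACCEPTABLE),
    ])
    def test_categories(self, dc, de, wtpt, expected):
        assert classify(dc, de, wtpt) is expected

    @given(dc=st.floats(-1e4, 1e4), de=st.floats(-1.0, 1.0),
           wtpt=st.floats(0.0, 9e4))
    @settings(max_examples=300, deadline=None)
    def test_partition_of_the_plane(self, dc, de, wtpt):
        cats = [c for c in Category
                if classify(dc, de, wtpt) is c]
        assert len(cats) == 1

    def test_boundary_grid_partition(self):
        grid = [-1.0, -0.5, 0.0, 0.5, 1.0]
        for dc in grid:
            for de in grid:
                for wtpt in (0.0, 0.5, 1.0, 45e3):
                    assert classify(dc, de, wtpt) in Category


class TestCeac:
    def test_uniform_dominance_accepts_everywhere(self):
        samples = np.array([[-10.0, 0.1]] * 20)
        curve = ceac(samples, np.linspace(0, 90e3, 91))
        np.testing.assert_array_equal(curve.acceptance["T"], 1.0)
        np.testing.assert_array_equal(curve.acceptance["L"], 0.0)

    def test_zero_threshold_counts_cost_sign(self):
        samples = np.array([[10.0, 0.001], [-10.0, -0.001]])
        curve = ceac(samples, np.array([0.0]))
        assert curve.acceptance["T"][0] == pytest.approx(0.5)

    def test_acceptances_sum_to_one(self, rng):
        samples = rng.normal([200.0, 0.01], [500.0, 0.02], size=(500, 2))
        curve = ceac(samples, np.arange(0.0, 90_001.0, 1000.0))
        np.testing.assert_allclose(
            curve.acceptance["T"] + curve.acceptance["L"], 1.0, atol=1e-12)

    def test_monotone_when_all_effect_gains(self, rng):
        samples = np.column_stack([rng.normal(100, 300, 400),
                                   rng.uniform(0.001, 0.05, 400)])
        curve = ceac(samples, np.arange(0.0, 90_001.0, 1000.0))
        assert np.all(np.diff(curve.acceptance["T"]) >= 0)

    def test_tie_splitting(self):
        samples = np.array([[0.0, 0.0]])
        curve = ceac(samples, np.array([0.0, 45e3]))
        np.testing.assert_array_equal(curve.acceptance["T"], [0.5, 0.5])

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            ceac(np.empty((0, 2)), np.array([0.0]))
        with pytest.raises(ValueError):
            ceac(np.array([[1.0, 1.0]]), np.array([]))


class TestRestrictedAcceptance:
    def test_uniform_dominance(self):
        samples = np.array([[-1.0, 0.1]] * 5)
        out = restricted_acceptance(samples, 45e3)
        assert out == {"T": 1.0, "L": 0.0}

    def test_three_to_one_split(self):
        samples = np.array([[-1.0, 0.1], [100.0, 0.01], [-5.0, 0.2],
                            [1.0, -0.1]])  # last: reference dominant
        out = restricted_acceptance(samples, 45e3)
        assert out["T"] == pytest.approx(0.75)
        assert out["L"] == pytest.approx(0.25)

    def test_empty_subset_rejected(self):
        # a QALY gain priced above the threshold is acceptable for neither
        # scenario without invoking an effectiveness loss
        samples = np.array([[100.0, 0.001]])
        with pytest.raises(ValueError):
            restricted_acceptance(samples, 45e3)

    def test_subset_definition_matches_categories(self):
        assert Category.DOMINANT in NO_EFFECTIVENESS_LOSS
        assert Category.EFFICIENT_LOWER_COST not in NO_EFFECTIVENESS_LOSS


class TestCategoryFrequencies:
    def test_frequencies_sum_to_one_per_scenario(self, rng):
        samples = rng.normal([100.0, 0.005], [400.0, 0.02], size=(200, 2))
        freq = category_frequencies(samples, 45e3)
        for label in ("T", "L"):
            total = sum(freq[label][c.value] for c in Category)
            assert total == pytest.approx(1.0)


class TestConfidenceEllipse:
    def test_isotropic_radius_is_chi2_quantile(self, rng):
        samples = rng.standard_normal((50_000, 2))
        ell = confidence_ellipse(samples, level=0.95)
        assert ell.chi2_quantile == pytest.approx(5.9915, abs=1e-4)
        np.testing.assert_allclose(ell.center, [0.0, 0.0], atol=0.02)

    def test_center_is_sample_mean(self, rng):
        samples = rng.normal([3.0, -2.0], [1.0, 0.5], size=(100, 2))
        ell = confidence_ellipse(samples)
        np.testing.assert_allclose(ell.center, samples.mean(axis=0))

    def test_boundary_points_lie_on_contour(self, rng):
        samples = rng.multivariate_normal([1.0, 2.0],
                                          [[2.0, 0.8], [0.8, 1.0]], 500)
        ell = confidence_ellipse(samples)
        d2 = ell.mahalanobis_sq(ell.boundary(64))
        np.testing.assert_allclose(d2, ell.chi2_quantile, rtol=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(DegenerateCovarianceError):
            confidence_ellipse(np.array([[0.0, 0.0], [1.0, 1.0]]))

    def test_singular_covariance_rejected(self):
        collinear = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(DegenerateCovarianceError):
            confidence_ellipse(collinear)
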