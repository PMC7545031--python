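"""Attachment/proliferation rate decomposition and its closed-form corollaries.

Reference inputs throughout: the published total-colonization logistic
(K_c=8.855974, y_c0=0.007333, mu_c=0.184677 h^-1) and the proliferation-only
rate constant mu_p=0.09949397 h^-1.
"""

import numpy as np
import pytest

from rhizofit import reference
from rhizofit.data import build_series
from rhizofit.decomposition import (
    AttachmentDecomposition,
    colonization_rate,
    fit_quadratic_relation,
    proliferation_rate,
    spline_cross_check,
)
from rhizofit.exceptions import (
    DomainError,
    InvalidParameterError,
    SingularDesignError,
    ValidationError,
)
from rhizofit.models import LogisticParams, logistic_density
from rhizofit.simulate import generate_dataset


class TestColonizationRate:
    def test_peak_is_quarter_mu_K(self, colonization):
        t_inflection = np.log((colonization.K - colonization.y0) / colonization.y0) / colonization.mu
        assert colonization_rate(colonization, t_inflection) == pytest.approx(
            colonization.mu * colonization.K / 4.0, rel=1e-9
        )
        assert colonization_rate(colonization, t_inflection) == pytest.approx(0.40888, abs=5e-5)

    def test_initial_rate(self, colonization):
        assert colonization_rate(colonization, 0.0) == pytest.approx(1.353e-3, abs=1e-6)

    @pytest.mark.parametrize("t", [0.0, 10.0, 38.0, 96.0])
    def test_two_algebraic_forms_agree(self, colonization, t):
        # the explicit derivative equals mu y (1 - y/K) evaluated at y_c(t)
        y = logistic_density(colonization, t)
        alt = colonization.mu * y * (1.0 - y / colonization.K)
        assert colonization_rate(colonization, t) == pytest.approx(alt, rel=1e-12)

    def test_declining_curve_rejected(self):
        with pytest.raises(InvalidParameterError):
            colonization_rate(LogisticParams(K=5.0, y0=6.0, mu=0.1), 1.0)


class TestProliferationRate:
    def test_boundary_zeros(self, colonization, mu_p):
        assert proliferation_rate(mu_p, 0.0, colonization.K) == 0.0
        assert proliferation_rate(mu_p, colonization.K, colonization.K) == 0.0

    def test_value_near_the_colonization_peak(self, colonization, mu_p):
        assert proliferation_rate(mu_p, 4.2558, colonization.K) == pytest.approx(0.2199, abs=5e-4)


class TestAttachmentRate:
    def test_reported_peak_value(self, decomp):
        assert decomp.attachment_rate(38.0) == pytest.approx(0.188, abs=1e-3)

    def test_reported_tail_value(self, decomp):
        assert decomp.attachment_rate(96.0) == pytest.approx(1.82e-5, abs=1e-7)

    def test_reported_starting_value(self, decomp):
        assert decomp.attachment_rate(1.0) == pytest.approx(7.5e-4, abs=1e-5)

    def test_peak_time_is_logistic_inflection(self, decomp, colonization):
        # R_a shares the inflection of y_c at ln((K-y0)/y0)/mu ~ 38.42 h
        fine = decomp.rates(np.arange(30.0, 46.0, 0.01))
        t_inflection = np.log((colonization.K - colonization.y0) / colonization.y0) / colonization.mu
        assert fine.peak_attachment_time == pytest.approx(t_inflection, abs=0.01)

    def test_equal_rates_give_zero_attachment(self, colonization):
        d = AttachmentDecomposition(colonization, colonization.mu)
        rc = d.rates()
        np.testing.assert_allclose(rc.R_a, 0.0, atol=1e-15)
        assert rc.attached_fraction == pytest.approx(0.0, abs=1e-12)
        valid = np.isfinite(rc.p)
        # numerator is pure rounding noise (~1e-17); the vanishing denominator
        # near the horizon amplifies it, hence the looser absolute bound
        np.testing.assert_allclose(rc.p[valid], 0.0, atol=1e-10)

    def test_mu_p_above_mu_c_warns_and_goes_negative(self, colonization):
        with pytest.warns(UserWarning, match="negative"):
            d = AttachmentDecomposition(colonization, colonization.mu * 1.5)
        assert d.attachment_rate(38.0) < 0


class TestAttachedCumulative:
    def test_single_point_grid_is_zero(self, decomp):
        np.testing.assert_array_equal(decomp.attached_cumulative(np.array([0.0])), [0.0])

    def test_closed_form_total(self, decomp, colonization, mu_p):
        # (1 - mu_p/mu_c)(y_c(96) - y_c0), the integral's antiderivative
        got = decomp.attached_cumulative(np.arange(0.0, 97.0))[-1]
        closed = (1.0 - mu_p / colonization.mu) * (
            logistic_density(colonization, 96.0) - colonization.y0
        )
        assert got == pytest.approx(closed, abs=1e-4)
        assert got == pytest.approx(4.081, abs=0.01)

    def test_quadrature_converges_under_refinement(self, decomp):
        coarse = decomp.attached_cumulative(np.arange(0.0, 97.0))[-1]
        fine = decomp.attached_cumulative(np.arange(0.0, 96.5, 0.5))[-1]
        assert abs(fine - coarse) / coarse < 1e-3

    def test_non_decreasing(self, decomp):
        cum = decomp.attached_cumulative(np.arange(0.0, 97.0))
        assert np.all(np.diff(cum) >= 0)

    def test_unsorted_grid_rejected(self, decomp):
        with pytest.raises(ValidationError, match="increasing"):
            decomp.attached_cumulative(np.array([0.0, 2.0, 1.0]))


class TestContributionProportion:
    def test_value_at_peak_hour(self, decomp):
        # oracle: denominator closed form K_c (mu_p/mu_c)(y_c(96) - y_c(38))
        assert decomp.contribution_proportion(38.0) == pytest.approx(0.00858, rel=0.02)

    def test_denominator_closed_form_at_zero(self, decomp, colonization, mu_p):
        # K_c (mu_p/mu_c)(y_c(96) - y_c0) = 42.217 (frozen from the closed form)
        denom = decomp.attachment_rate(0.0) / decomp.contribution_proportion(0.0)
        closed = colonization.K * (mu_p / colonization.mu) * (
            logistic_density(colonization, 96.0) - colonization.y0
        )
        assert closed == pytest.approx(42.217, abs=0.01)
        assert denom == pytest.approx(closed, rel=0.01)

    def test_horizon_is_excluded(self, decomp):
        with pytest.raises(DomainError, match="horizon"):
            decomp.contribution_proportion(96.0)
        with pytest.raises(DomainError):
            decomp.contribution_proportion(95.5)  # within one grid step

    def test_grid_column_is_nan_at_horizon_only(self, decomp):
        rc = decomp.rates()
        assert np.isnan(rc.p[-1])
        assert np.isfinite(rc.p[:-1]).all()


class TestQuadraticRelation:
    def test_exact_coefficients_from_logistic_pairs(self, decomp, colonization, mu_p):
        # R_a = (mu_c - mu_p)(y_c - y_c^2/K_c) exactly, so OLS recovers
        # c1 = mu_c - mu_p and c2 = -(mu_c - mu_p)/K_c with ~zero residual
        q = decomp.quadratic_relation()
        assert abs(q.c0) < 1e-6
        assert q.c1 == pytest.approx(colonization.mu - mu_p, abs=1e-6)
        assert q.c2 == pytest.approx(-(colonization.mu - mu_p) / colonization.K, abs=1e-6)
        rc = decomp.rates()
        assert np.abs(q(rc.y_c) - rc.R_a).max() < 1e-10

    def test_reported_coefficients_put_vertex_at_reported_density(self):
        # the published quadratic peaks where colonization density was 4.26
        c0, c1, c2 = reference.QUADRATIC_COEFFICIENTS
        from rhizofit.decomposition import QuadraticRelation

        q = QuadraticRelation(c0, c1, c2)
        assert q.vertex_yc == pytest.approx(4.27, abs=0.005)

    def test_collinear_points_singular(self):
        with pytest.raises(SingularDesignError):
            fit_quadratic_relation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestConservationInvariants:
    def test_rate_conservation_to_machine_precision(self, decomp):
        rc = decomp.rates()
        np.testing.assert_allclose(rc.R_c - rc.R_p - rc.R_a, 0.0, atol=1e-15)

    def test_fundamental_theorem_for_total_rate(self, decomp):
        g = np.arange(0.0, 97.0)
        rc = decomp.rates(g)
        integral = np.trapezoid(rc.R_c, g)
        assert integral == pytest.approx(rc.y_c[-1] - rc.y_c[0], rel=1e-3)

    def test_attached_fraction_closed_form(self, decomp, colonization, mu_p):
        # a corollary the equations force: the attached share of the density
        # gain equals 1 - mu_p/mu_c = 0.4613
        rc = decomp.rates(np.arange(0.0, 97.0))
        assert rc.attached_fraction == pytest.approx(1.0 - mu_p / colonization.mu, rel=1e-3)
        assert rc.attached_fraction == pytest.approx(0.4613, abs=5e-4)

    def test_rates_csv_round_trip(self, decomp, tmp_path):
        frame = decomp.rates().to_frame()
        path = tmp_path / "rates.csv"
        frame.to_csv(path, index=False)
        import pandas as pd

        back = pd.read_csv(path)
        np.testing.assert_allclose(back["R_a"], frame["R_a"], rtol=1e-12)
        assert back["p_t"].isna().iloc[-1]

    def test_summary_mentions_peak(self, decomp):
        text = decomp.rates().summary()
        assert "peak attachment rate" in text and "38" in text


class TestSplineCrossCheck:
    def test_noiseless_dense_design_agrees(self, dense_total_design, decomp):
        """With gap-free noiseless sampling the spline path reproduces the
        parametric attachment rate within 5% wherever it is appreciable."""
        df, _ = generate_dataset(dense_total_design)
        cs = build_series(df, "total")
        ps = build_series(df, "proliferation")
        rc = decomp.rates(np.arange(2.0, 97.0))
        report = spline_cross_check(cs, ps, rc)
        assert report.max_rel_deviation < 0.05
        assert report.peak_time_spline == report.peak_time_parametric

    def test_interpolating_spline_limit(self, decomp, make_series, colonization):
        # both paths built from the same parametric curve: as smoothing -> 0
        # the only residual disagreement is the finite-difference truncation
        t = np.arange(2.0, 97.0)
        series = make_series(t, logistic_density(colonization, t))
        rc = decomp.rates(t)
        report = spline_cross_check(series, series, rc, smoothing=0.0)
        # residual disagreement is the O(h^2 mu^2) truncation of the 1-h
        # central difference, ~1.1% at the fastest-growing grid points
        assert report.max_rel_deviation < 0.02

    def test_non_overlapping_domains_rejected(self, decomp, make_series, colonization):
        t = np.arange(2.0, 20.0)
        series = make_series(t, logistic_density(colonization, t))
        rc = decomp.rates(np.arange(50.0, 97.0))
        with pytest.raises(ValidationError, match="overlap"):
            spline_cross_check(series, series, rc)
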