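import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fishsde import (
    DiffusionParams,
    PolynomialModel,
    PotentialParams,
    SDEModel,
    bistability_report,
    drift_from_potential,
    empirical_potential,
    potential_from_drift,
    potential_value,
)
from fishsde.potential import MonostableError, NotCubicError

REF = PotentialParams(alpha=0.0, beta=-0.01, xl=5.0, xh=20.0)


class TestPotentialValue:
    def test_wells_are_zeros_when_unbiased(self):
        assert potential_value(REF, 5.0) == pytest.approx(0.0)
        assert potential_value(REF, 20.0) == pytest.approx(0.0)

    def test_hand_evaluation_at_midpoint(self):
        assert potential_value(REF, 12.5) == pytest.approx(31.640625)

    def test_pure_tilt_when_beta_zero(self):
        p = PotentialParams(alpha=2.0, beta=0.0, xl=1.0, xh=2.0)
        xs = np.linspace(0, 10, 11)
        np.testing.assert_allclose(potential_value(p, xs), -2.0 * xs)


class TestDriftConversion:
    def test_reference_cubic(self):
        np.testing.assert_allclose(drift_from_potential(REF),
                                   [50.0, -16.5, 1.5, -0.04], atol=1e-12)

    def test_unbiased_drift_roots(self):
        coefs = drift_from_potential(REF)
        roots = np.sort(np.polynomial.Polynomial(coefs).roots().real)
        np.testing.assert_allclose(roots, [5.0, 12.5, 20.0], atol=1e-9)

    def test_beta_zero_gives_constant_drift(self):
        p = PotentialParams(alpha=3.0, beta=0.0, xl=1.0, xh=2.0)
        np.testing.assert_allclose(drift_from_potential(p), [3.0, 0, 0, 0])

    def test_matches_numerical_gradient(self):
        coefs = drift_from_potential(REF)
        xs = np.linspace(0, 25, 501)
        h = 1e-6
        grad = (potential_value(REF, xs + h) - potential_value(REF, xs - h)) / (
            2 * h
        )
        drift = np.polynomial.polynomial.polyval(xs, coefs)
        np.testing.assert_allclose(drift, -grad, atol=1e-5)


class TestPotentialFromDrift:
    def test_reference_inverse(self):
        p = potential_from_drift([50.0, -16.5, 1.5, -0.04])
        assert (p.alpha, p.beta) == pytest.approx((0.0, -0.01), abs=1e-12)
        assert (p.xl, p.xh) == pytest.approx((5.0, 20.0), abs=1e-9)

    @given(
        alpha=st.floats(-1.0, 1.0),
        beta=st.floats(-0.05, -1e-4),
        xl=st.floats(1.0, 12.0),
        gap=st.floats(0.5, 20.0),
    )
    @settings(max_examples=100, deadline=None, database=None,
              derandomize=True)
    def test_round_trip_identity(self, alpha, beta, xl, gap):
        p = PotentialParams(alpha=alpha, beta=beta, xl=xl, xh=xl + gap)
        back = potential_from_drift(drift_from_potential(p))
        assert back.alpha == pytest.approx(p.alpha, abs=1e-9)
        assert back.beta == pytest.approx(p.beta, abs=1e-9)
        assert back.xl == pytest.approx(p.xl, abs=1e-9)
        assert back.xh == pytest.approx(p.xh, abs=1e-9)

    def test_not_cubic_rejected(self):
        with pytest.raises(NotCubicError):
            potential_from_drift([1.0, 2.0, 3.0, 0.0])

    def test_complex_well_pair_rejected(self):
        # cubic whose implied well pair solves z^2 - s z + q with
        # s^2 - 4q < 0 (s=2, q=50): no real wells
        beta, s, q = -0.01, 2.0, 50.0
        cubic = [-2 * beta * q * s, 2 * beta * (s * s + 2 * q),
                 -6 * beta * s, 4 * beta]
        with pytest.raises(MonostableError):
            potential_from_drift(cubic)


class TestEmpiricalPotential:
    def test_constant_drift_gives_linear_potential(self):
        xs = np.arange(0, 5.01, 0.1)
        _, v = empirical_potential(xs, np.full_like(xs, 2.0))
        np.testing.assert_allclose(v, -2.0 * xs, atol=1e-9)

    def test_matches_analytic_potential_on_fine_grid(self):
        # trapezoid error bound at h=0.1 for this drift: (h^2/12) * span
        # of F' ~ 1.6e-2
        xs = np.arange(0.05, 25.0, 0.1)
        drift = np.polynomial.polynomial.polyval(xs, drift_from_potential(REF))
        _, v = empirical_potential(xs, drift)
        expected = potential_value(REF, xs) - potential_value(REF, xs[0])
        np.testing.assert_allclose(v, expected, atol=1.6e-2)

    def test_second_order_convergence(self):
        def max_err(h):
            xs = np.arange(0.0, 25.0 + h / 2, h)
            drift = np.polynomial.polynomial.polyval(
                xs, drift_from_potential(REF)
            )
            _, v = empirical_potential(xs, drift)
            ref = potential_value(REF, xs) - potential_value(REF, xs[0])
            return np.abs(v - ref).max()

        assert max_err(0.05) < max_err(0.2) / 8  # ~O(h^2): 16x expected

    def test_needs_two_bins(self):
        with pytest.raises(ValueError):
            empirical_potential(np.array([1.0]), np.array([0.0]))

    def test_unsorted_bins_rejected(self):
        with pytest.raises(ValueError):
            empirical_potential(np.array([1.0, 0.5]), np.array([0.0, 0.0]))


class TestBistabilityReport:
    def model(self, params):
        return SDEModel(
            drift=PolynomialModel(drift_from_potential(params), "drift"),
            diffusion=DiffusionParams(1.0, 0.0, 0.0),
        )

    def test_symmetric_double_well(self):
        rep = bistability_report(self.model(REF))
        assert rep["bistable"] and rep["confining"]
        np.testing.assert_allclose(sorted(rep["wells"]), [5.0, 20.0],
                                   atol=1e-9)
        assert rep["barrier_x"] == pytest.approx(12.5)
        assert rep["barrier_height"] == pytest.approx(31.640625)
        assert rep["tilt_direction"] == "unbiased"

    def test_tilted_landscape_reports_deeper_well(self):
        tilted = PotentialParams(alpha=-0.5, beta=-0.01, xl=5.0, xh=20.0)
        rep = bistability_report(self.model(tilted))
        # alpha < 0 adds +|alpha| x to V: small-x well is favoured
        assert rep["tilt_direction"] == "toward_close"
        assert rep["barrier_height"] > 0

    def test_positive_leading_coefficient_flagged(self):
        m = SDEModel(
            drift=PolynomialModel([0.0, 1.0, 0.0, 0.04], "drift"),
            diffusion=DiffusionParams(1.0, 0.0, 0.0),
        )
        rep = bistability_report(m)
        assert not rep["confining"]

    def test_monostable_flagged_not_raised(self):
        m = SDEModel(
            drift=PolynomialModel([1.0, 0.0, 0.0, -0.04], "drift"),
            diffusion=DiffusionParams(1.0, 0.0, 0.0),
        )
        rep = bistability_report(m)
        assert not rep["bistable"]
        assert len(rep["wells"]) == 1

    def test_non_cubic_rejected(self):
        m = SDEModel(
            drift=PolynomialModel([1.0, -1.0, 0.0, 0.0], "drift"),
            diffusion=DiffusionParams(1.0, 0.0, 0.0),
        )
        with pytest.raises(NotCubicError):
            bistability_report(m)


def test_diffusion_params_evaluate():
    g = DiffusionParams(b0=0.53125, b1=0.075, b2=-0.003)
    assert g(5.0) == pytest.approx(0.83125)
    assert g(20.0) == pytest.approx(0.83125)
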