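"""Unit and property tests for the closed-form model layer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ageperf import (
    CellTypeSpec,
    DegeneratePeakError,
    IMAPParams,
    IMAPShape,
    MooreParams,
    SilerParams,
    asymptotic_population,
    imap_curve,
    imap_growth_rate,
    imap_performance,
    imap_reduced,
    imap_senescence,
    moore_performance,
    multitype_performance,
    nondimensionalize,
    normalized_peak,
    peak_age,
    peak_location,
    redimensionalize,
    siler_equivalent_a2,
    siler_hazard,
    time_constant,
)
from conftest import random_interior_shapes

positive = st.floats(min_value=0.05, max_value=20.0)
# rates kept small enough that e^{rate * t} stays far from overflow
rate = st.floats(min_value=0.05, max_value=4.0)


class TestMoore:
    def test_zero_age_gives_zero(self):
        assert moore_performance(0.0, MooreParams(3.0, 0.2, 1.0, 0.05)) == 0.0

    def test_direct_evaluation(self):
        # a(1-e^{-b}) + c(1-e^{d}) at t=1, evaluated independently
        value = moore_performance(1.0, MooreParams(1.0, 1.0, 1.0, 0.1))
        assert value == pytest.approx(0.52694964075291, rel=1e-12)

    def test_negative_raw_value_is_clamped_and_flagged(self):
        value, clamped = moore_performance(
            3.0, MooreParams(1.0, 1.0, 5.0, 1.0), return_clamped=True
        )
        assert value == 0.0 and clamped

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(ValueError):
            MooreParams(1.0, -0.1, 1.0, 1.0)


class TestSiler:
    def test_hazard_at_birth_is_sum_of_amplitudes(self):
        p = SilerParams(a1=0.3, b1=1.0, a2=0.05, a3=0.01, b3=0.4)
        assert siler_hazard(0.0, p) == pytest.approx(0.36)

    def test_direct_evaluation(self):
        p = SilerParams(a1=1.0, b1=1.0, a2=0.5, a3=0.01, b3=0.5)
        assert siler_hazard(2.0, p) == pytest.approx(0.6625181015212032, rel=1e-12)

    def test_constant_hazard_when_only_mature_term(self):
        p = SilerParams(a1=0.0, b1=1.0, a2=0.7, a3=0.0, b3=1.0)
        assert np.allclose(siler_hazard(np.array([0.0, 3.0, 80.0]), p), 0.7)

    def test_equivalent_a2_at_birth(self):
        assert siler_equivalent_a2(0.0, 1.5, 1.0, 0.2, 0.3) == pytest.approx(-(1.5 + 0.2))

    def test_equivalent_a2_closed_form_zero_crossing(self):
        # a1=1, b1=1, a3=0: a2(t) = 1 - 2 e^{-t}, zero at ln 2
        assert siler_equivalent_a2(np.log(2.0), 1.0, 1.0, 0.0, 1.0) == pytest.approx(0.0, abs=1e-15)

    @given(a1=positive, b1=rate, a3=positive, b3=rate,
           t=st.floats(min_value=0.0, max_value=50.0))
    @settings(max_examples=200, deadline=None)
    def test_bridge_identity_to_moore(self, a1, b1, a3, b3, t):
        """Substituting the age-dependent mature hazard into the Siler form
        reproduces Moore's two-term curve to machine precision."""
        a2_t = siler_equivalent_a2(t, a1, b1, a3, b3)
        lhs = a1 * np.exp(-b1 * t) + a2_t + a3 * np.exp(b3 * t)
        rhs = a1 * (1.0 - np.exp(-b1 * t)) + a3 * (1.0 - np.exp(b3 * t))
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-9)


class TestIMAPComponents:
    def test_growth_rate_baseline_and_efolding(self):
        assert imap_growth_rate(0.0, 0.5, 0.2) == pytest.approx(0.5)
        assert imap_growth_rate(1.0 / 0.2, 0.5, 0.2) == pytest.approx(0.5 / np.e)

    def test_growth_rate_direct_value(self):
        assert imap_growth_rate(10.0, 0.5, 0.2) == pytest.approx(0.06766764161830635, rel=1e-12)

    def test_senescence_vanishes_at_death(self):
        assert imap_senescence(100.0, 2.0, 0.05, 100.0) == 0.0

    def test_senescence_near_baseline_at_birth_when_betar_td_large(self):
        assert imap_senescence(0.0, 1.0, 1.0, 50.0) == pytest.approx(1.0, rel=1e-12)

    def test_senescence_direct_value(self):
        assert imap_senescence(50.0, 2.0, 0.05, 100.0) == pytest.approx(
            1.8358300027522023, rel=1e-12
        )

    def test_asymptotic_population(self):
        assert asymptotic_population(1e6, 2.0, 0.5) == pytest.approx(54598150.033144236, rel=1e-12)
        assert asymptotic_population(10.0, 0.5, 0.5) == pytest.approx(10.0 * np.e)
        # no-growth limit: alpha0 -> 0 leaves N_inf at N0
        assert asymptotic_population(10.0, 1e-12, 1.0) == pytest.approx(10.0)


class TestIMAPCurve:
    def test_vanishes_at_death_and_clamps_beyond(self):
        p = IMAPParams(scale=5.0, alpha0=0.3, alphar=0.2, betar=0.02, td=100.0)
        assert imap_performance(100.0, p) == pytest.approx(0.0, abs=1e-12)
        value, clamped = imap_performance(120.0, p, return_clamped=True)
        assert value == 0.0 and clamped

    def test_birth_value_is_scale_times_decline_factor(self):
        p = IMAPParams(scale=5.0, alpha0=0.3, alphar=0.2, betar=0.02, td=100.0)
        assert imap_performance(0.0, p) == pytest.approx(5.0 * (1 - np.exp(-0.02 * 100.0)))

    def test_reduced_curve_at_endpoints(self):
        s = IMAPShape(50.0, 15.0, 10.0, td=80.0)
        assert imap_reduced(1.0, s) == pytest.approx(0.0, abs=1e-12)
        expected0 = np.exp(-50.0 / 15.0) * (1.0 - np.exp(-10.0))
        assert imap_reduced(0.0, s) == pytest.approx(expected0, rel=1e-12)

    def test_reduced_curve_midlife_value(self):
        # the "blue" reference shape evaluated independently
        s = IMAPShape(50.0, 15.0, 10.0, td=80.0)
        assert imap_reduced(0.5, s) == pytest.approx(0.9914325475806115, rel=1e-10)

    def test_three_evaluation_routes_agree(self):
        """Dimensional form, asymptotic form and scaled reduced form are the
        same curve to 1e-12 relative on random parameters and grids."""
        rng = np.random.default_rng(42)
        for s in random_interior_shapes(rng, 25):
            p = redimensionalize(s)
            t = np.linspace(0.0, s.td, 101)
            via_dimensional = imap_performance(t, p, clamp=False)
            via_reduced = imap_curve(t, s, clamp=False)
            # asymptotic form written out explicitly
            via_asymptotic = s.scale_inf * np.exp(
                -(p.alpha0 / p.alphar) * np.exp(-p.alphar * t)
            ) * (1.0 - np.exp(p.betar * (t - p.td)))
            np.testing.assert_allclose(via_dimensional, via_reduced, rtol=1e-12, atol=1e-300)
            np.testing.assert_allclose(via_dimensional, via_asymptotic, rtol=1e-12, atol=1e-300)

    def test_positive_then_zero_and_unimodal(self):
        rng = np.random.default_rng(7)
        for s in random_interior_shapes(rng, 10):
            t = np.linspace(0.0, s.td, 2001)
            y = imap_curve(t, s)
            assert np.all(y[1:-1] > 0.0)
            assert y[-1] == pytest.approx(0.0, abs=1e-9 * s.scale_inf)
            signs = np.sign(np.diff(y[y > 0]))
            # a single sign change of the derivative: rise then fall
            assert np.sum(np.diff(signs[signs != 0]) != 0) <= 1


class TestNondimensionalization:
    def test_published_sprint_rates_recover_table_shape(self):
        p = IMAPParams(scale=1.0, alpha0=0.276, alphar=0.172, betar=0.0176, td=124.13)
        s = nondimensionalize(p)
        assert s.alpha0_star == pytest.approx(34.26, abs=5e-3)
        assert s.alphar_star == pytest.approx(21.35, abs=5e-2)
        assert s.betar_star == pytest.approx(2.18, abs=5e-3)

    def test_roundtrip_identity(self):
        p = IMAPParams(scale=3.2, alpha0=0.4, alphar=0.15, betar=0.03, td=90.0)
        q = redimensionalize(nondimensionalize(p))
        for name in ("scale", "alpha0", "alphar", "betar", "td"):
            assert getattr(q, name) == pytest.approx(getattr(p, name), rel=1e-12)

    def test_unit_lifespan_leaves_rates_unchanged(self):
        p = IMAPParams(scale=1.0, alpha0=3.0, alphar=2.0, betar=1.0, td=1.0)
        s = nondimensionalize(p)
        assert (s.alpha0_star, s.alphar_star, s.betar_star) == (3.0, 2.0, 1.0)

    def test_scale_inf_relation(self):
        p = IMAPParams(scale=2.0, alpha0=1.0, alphar=0.5, betar=0.1, td=10.0)
        s = nondimensionalize(p)
        assert s.scale_inf == pytest.approx(2.0 * np.exp(s.alpha0_star / s.alphar_star), rel=1e-12)


class TestPeak:
    def test_peak_matches_brute_force_grid(self):
        """Root-finding on the stationarity condition agrees with a dense
        grid argmax of the reduced curve."""
        rng = np.random.default_rng(2024)
        grid = np.linspace(0.0, 1.0, 200_001)
        for s in random_interior_shapes(rng, 30):
            u_star = peak_location(s)
            u_grid = grid[np.argmax(imap_reduced(grid, s))]
            assert abs(u_star - u_grid) <= 1.0 / 200_000

    def test_normalized_peak_invariant_under_lifespan_rescaling(self):
        s = IMAPShape(34.26, 21.40, 2.19, td=124.13)
        assert normalized_peak(s) == pytest.approx(normalized_peak(s.with_td(12.0)), abs=1e-10)

    def test_peak_age_scales_with_lifespan(self):
        s = IMAPShape(34.26, 21.40, 2.19, td=124.13)
        assert peak_age(s.with_td(62.065)) == pytest.approx(peak_age(s) / 2.0, rel=1e-9)

    def test_monotone_curve_reports_degenerate_boundary(self):
        # growth pull below senescence drag at birth: curve decreasing on [0,1]
        s = IMAPShape(alpha0_star=0.01, alphar_star=5.0, betar_star=5.0, td=10.0)
        with pytest.raises(DegeneratePeakError) as err:
            peak_location(s)
        assert err.value.boundary == 0.0

    def test_time_constant_unit_case(self):
        s = IMAPShape(10.0, 7.3, 1.0, td=7.3)
        assert time_constant(s) == pytest.approx(1.0)


class TestMultitype:
    def test_single_constant_type_grows_exponentially(self):
        t = np.linspace(0.0, 5.0, 21)
        spec = CellTypeSpec(phi=2.0, n0=100.0,
                            growth_rate_fn=lambda _t: 0.3,
                            senescence_fn=lambda tt: np.full_like(tt, 0.5))
        expected = 2.0 * 0.5 * 100.0 * np.exp(0.3 * t)
        np.testing.assert_allclose(multitype_performance(t, [spec]), expected, rtol=1e-8)

    def test_single_type_collapses_to_imap_closed_form(self):
        """One cell type with the saturating growth rate and the senescent
        functionality reproduces the closed-form curve via quadrature."""
        p = IMAPParams(scale=1.0, alpha0=0.3, alphar=0.2, betar=0.02, td=100.0)
        t = np.linspace(0.0, 99.0, 45)
        spec = CellTypeSpec(
            phi=1.0, n0=1.0,
            growth_rate_fn=lambda tt: p.alpha0 * np.exp(-p.alphar * tt),
            senescence_fn=lambda tt: 1.0 - np.exp(p.betar * (tt - p.td)),
        )
        np.testing.assert_allclose(
            multitype_performance(t, [spec]), imap_performance(t, p, clamp=False), rtol=1e-6
        )

    def test_two_half_populations_equal_one_full(self):
        t = np.linspace(0.0, 10.0, 11)
        mk = lambda n0: CellTypeSpec(phi=1.5, n0=n0,
                                     growth_rate_fn=lambda tt: 0.1 * np.exp(-0.05 * tt),
                                     senescence_fn=lambda tt: 1.0 - tt / 20.0)
        one = multitype_performance(t, [mk(10.0)])
        two = multitype_performance(t, [mk(5.0), mk(5.0)])
        np.testing.assert_allclose(one, two, rtol=1e-12)

    def test_empty_type_list_rejected(self):
        with pytest.raises(ValueError):
            multitype_performance([0.0, 1.0], [])
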