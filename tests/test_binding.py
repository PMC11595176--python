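"""Unit and property tests for the equilibrium binding models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.stats import linregress

from bindspec.binding import (
    ScatchardSeries,
    TwoClassModel,
    bound_concentration_from_delta_a,
    bound_concentration_from_signal,
    bound_fraction,
    estimate_two_class,
    fit_single_class,
    scatchard_transform,
    single_class_signal,
    solve_two_class_equilibrium,
    two_class_bound,
)
from bindspec.exceptions import (
    DegenerateDataError,
    EmptySeriesError,
    InvalidReferenceError,
    SplitError,
)
from bindspec.simulate import NoiseSpec, gen_scatchard, gen_titration

from conftest import EPS_412, SINGLE, TWO_CLASS


class TestBoundFraction:
    @pytest.mark.parametrize("a_obs,a_free,a_bound,expected", [
        (0.5, 0.2, 0.8, 0.5),
        (0.2, 0.2, 0.8, 0.0),
        (0.8, 0.2, 0.8, 1.0),
    ])
    def test_reference_interpolation(self, a_obs, a_free, a_bound, expected):
        assert bound_fraction(a_obs, a_free, a_bound) == pytest.approx(expected)

    def test_degenerate_references_raise(self):
        with pytest.raises(InvalidReferenceError):
            bound_fraction(0.5, 0.3, 0.3)

    def test_out_of_range_values_warned_not_clamped(self):
        with pytest.warns(UserWarning, match="outside"):
            x = bound_fraction(0.9, 0.2, 0.8)
        assert x == pytest.approx(7.0 / 6.0)


class TestBeerLambertInversion:
    @pytest.mark.parametrize("signal,eps,l,expected", [
        (0.20, 0.20, 1.0, 1.0),
        (0.0, 0.20, 1.0, 0.0),
        (0.902641, 0.20, 1.0, 4.513205),
    ])
    def test_from_signal(self, signal, eps, l, expected):
        assert bound_concentration_from_signal(signal, eps, l) == \
            pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("da,eps,expected", [
        (0.257558, 0.257558, 1.0),   # the bound-state 412 nm extinction
        (0.0, 0.257558, 0.0),
        (0.128779, 0.257558, 0.5),
    ])
    def test_from_delta_a(self, da, eps, expected):
        assert bound_concentration_from_delta_a(da, eps, 1.0) == \
            pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("func", [bound_concentration_from_signal,
                                      bound_concentration_from_delta_a])
    def test_nonpositive_eps_rejected(self, func):
        with pytest.raises(ValueError):
            func(0.1, 0.0, 1.0)


class TestSingleClassSignal:
    def test_fitted_parameter_point(self):
        # direct minus-root evaluation at the top of the titration grid
        val = single_class_signal(6.04, 2.0, 2.7, 0.3, 0.20, 1.0)
        assert val == pytest.approx(0.5 * 0.20 * (11.74 - np.sqrt(137.8276 - 130.464)),
                                    rel=1e-12)
        assert val == pytest.approx(0.9026, abs=5e-5)

    def test_no_ligand_no_signal(self):
        assert single_class_signal(0.0, 2.0, 2.7, 0.3, 0.20, 1.0) == 0.0

    def test_zero_kd_excess_sites_binds_everything(self):
        assert single_class_signal(1.0, 2.0, 2.7, 0.0, 0.20, 1.0) == \
            pytest.approx(0.20, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(c_t=st.floats(0.0, 100.0), c_h=st.floats(0.0, 100.0),
           n=st.floats(0.01, 10.0), kd=st.floats(0.0, 50.0),
           eb=st.floats(0.01, 5.0))
    def test_minus_root_bounded_by_limiting_species(self, c_t, c_h, n, kd, eb):
        val = single_class_signal(c_t, c_h, n, kd, eb, 1.0)
        bound = eb * min(c_t, n * c_h)
        assert val <= bound + 1e-9 * max(1.0, bound)
        assert val >= -1e-12

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(c_t=st.floats(0.1, 50.0), c_h=st.floats(0.1, 50.0),
           n=st.floats(0.1, 8.0), kd=st.floats(1e-3, 20.0),
           eb=st.floats(0.05, 2.0))
    def test_back_substitution_recovers_kd(self, c_t, c_h, n, kd, eb):
        """The minus root solves the mass-balance quadratic: substituting it
        back into the equilibrium expression reproduces K_d."""
        xalp = single_class_signal(c_t, c_h, n, kd, eb, 1.0)
        lp = xalp / eb
        kd_back = (c_t - lp) * (n * c_h - lp) / lp
        assert kd_back == pytest.approx(kd, rel=1e-9)


class TestSingleClassFit:
    def test_noiseless_round_trip(self, clean_titration):
        fit = fit_single_class(clean_titration)
        assert fit.n_sites == pytest.approx(SINGLE["n"], rel=1e-6)
        assert fit.k_d == pytest.approx(SINGLE["k_d"], rel=1e-4)
        assert fit.eps_bound == pytest.approx(SINGLE["eps_bound"], rel=1e-6)
        assert fit.r_squared > 1 - 1e-12
        assert fit.k_b == pytest.approx(1.0 / fit.k_d)

    def test_noisy_recovery_within_quoted_uncertainty(self, noisy_titration):
        fit = fit_single_class(noisy_titration)
        assert fit.n_sites == pytest.approx(2.7, abs=0.2)
        assert fit.eps_bound == pytest.approx(0.20, abs=0.02)
        assert 0.0 <= fit.r_squared <= 1.0

    def test_standard_errors_present_and_positive(self, noisy_titration):
        fit = fit_single_class(noisy_titration)
        assert set(fit.standard_errors) == {"n_sites", "k_d", "eps_bound"}
        assert all(v >= 0 for v in fit.standard_errors.values())

    def test_zero_signal_is_degenerate(self, clean_titration):
        s = clean_titration
        s.a_obs = s.a_free.copy()  # observed == free: nothing bound
        with pytest.raises(DegenerateDataError):
            fit_single_class(s)

    def test_too_few_points_rejected(self):
        short = gen_titration(c_ligand_grid=np.linspace(1.0, 6.0, 3),
                              noise=NoiseSpec(sigma=0.0, seed=0))
        with pytest.raises(ValueError):
            fit_single_class(short)

    def test_median_bias_of_n_under_noise(self):
        """200 noise replicates at sigma_A = 0.005: the median fitted n is
        within 5% of the generating value."""
        ns = []
        for seed in range(200):
            s = gen_titration(noise=NoiseSpec(sigma=0.005, seed=seed))
            ns.append(fit_single_class(s).n_sites)
        assert abs(np.median(ns) - SINGLE["n"]) / SINGLE["n"] <= 0.05


def _single_class_forward(kd, n, c_t, c_h_grid):
    """Exact (lp, l_free) for one site class via the two-class container
    with two identical half-classes."""
    model = TwoClassModel(n1=n / 2, kd1=kd, n2=n / 2, kd2=kd)
    lp = np.array([solve_two_class_equilibrium(c_t, ch, model, tol=1e-13)[1]
                   for ch in c_h_grid])
    return lp


class TestScatchardTransform:
    def test_single_class_data_collinear(self):
        """One site class puts every transformed point on the line
        ratio = n/K_d - occupancy/K_d."""
        c_h = np.arange(1.0, 13.0)
        lp = _single_class_forward(0.3, 2.7, 5.0, c_h)
        series = scatchard_transform(c_h, EPS_412 * lp, 5.0, EPS_412)
        res = linregress(series.occupancy, series.ratio)
        assert res.slope == pytest.approx(-1.0 / 0.3, rel=1e-6)
        assert -res.intercept / res.slope == pytest.approx(2.7, rel=1e-6)
        pred = res.slope * series.occupancy + res.intercept
        assert np.max(np.abs(series.ratio - pred)) < 1e-9

    def test_zero_bound_gives_zero_axes(self):
        series = scatchard_transform(np.arange(1.0, 7.0), np.zeros(6), 5.0,
                                     EPS_412)
        assert np.all(series.occupancy == 0)
        assert np.all(series.ratio == 0)

    def test_two_class_data_deviate_from_any_line(self, clean_scatchard_pair):
        c_h, d_a = clean_scatchard_pair
        series = scatchard_transform(c_h, d_a, 5.0, EPS_412)
        res = linregress(series.occupancy, series.ratio)
        resid = series.ratio - (res.slope * series.occupancy + res.intercept)
        assert np.max(np.abs(resid)) > 1e-3

    def test_nonphysical_points_dropped_and_empty_raises(self):
        # delta_a implying lp > c_total -> l_free < 0 -> dropped
        c_h = np.arange(1.0, 7.0)
        d_a = np.full(6, 10.0)  # lp ~ 38.8 uM >> 5 uM
        with pytest.raises(EmptySeriesError):
            scatchard_transform(c_h, d_a, 5.0, EPS_412)

    def test_mass_balance_of_kept_points(self, clean_scatchard_pair):
        c_h, d_a = clean_scatchard_pair
        series = scatchard_transform(c_h, d_a, 5.0, EPS_412)
        assert np.allclose(series.lp + series.l_free, 5.0, atol=1e-9)


class TestTwoClassModel:
    def test_canonical_ordering_and_reciprocals(self):
        m = TwoClassModel(n1=2.2, kd1=1.8, n2=0.79, kd2=0.15)
        assert (m.kd1, m.kd2) == (0.15, 1.8)
        assert (m.n1, m.n2) == (0.79, 2.2)
        assert m.kb1 * m.kd1 == pytest.approx(1.0)
        assert m.kb2 * m.kd2 == pytest.approx(1.0)

    def test_bound_trivials(self):
        assert two_class_bound(0.0, 5.0, TWO_CLASS) == 0.0
        # half-saturation of the weak class alone
        weak = TwoClassModel(n1=1e-12, kd1=1e-13, n2=2.2, kd2=1.8)
        assert two_class_bound(1.8, 1.0, weak) == pytest.approx(1.1, rel=1e-9)

    def test_saturation_limit(self):
        val = two_class_bound(1e6, 5.0, TWO_CLASS)
        assert val == pytest.approx((0.79 + 2.2) * 5.0, rel=1e-5)

    def test_dilute_and_saturating_ratio_limits(self):
        """ratio -> n1/kd1 + n2/kd2 as L -> 0; occupancy -> n1 + n2 as
        L -> inf."""
        m = TWO_CLASS
        c_h = 1.0
        lo = two_class_bound(1e-8, c_h, m) / (c_h * 1e-8)
        assert lo == pytest.approx(m.n1 / m.kd1 + m.n2 / m.kd2, rel=1e-6)
        hi = two_class_bound(1e8, c_h, m) / c_h
        assert hi == pytest.approx(m.n1 + m.n2, rel=1e-6)


class TestTwoClassEquilibrium:
    def test_against_independent_root_finder(self):
        l_free, lp = solve_two_class_equilibrium(5.0, 5.0, TWO_CLASS,
                                                 tol=1e-12)
        oracle = brentq(
            lambda L: L + two_class_bound(L, 5.0, TWO_CLASS) - 5.0,
            0.0, 5.0, xtol=1e-13)
        assert l_free == pytest.approx(oracle, abs=1e-9)
        assert 0.36 < l_free < 0.37
        assert lp == pytest.approx(5.0 - l_free, abs=1e-9)

    @pytest.mark.parametrize("c_t,c_h,expected", [
        (0.0, 5.0, (0.0, 0.0)),
        (3.0, 0.0, (3.0, 0.0)),
    ])
    def test_trivial_totals(self, c_t, c_h, expected):
        assert solve_two_class_equilibrium(c_t, c_h, TWO_CLASS) == expected

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(c_t=st.floats(0.01, 50.0), c_h=st.floats(0.01, 50.0))
    def test_mass_conservation(self, c_t, c_h):
        l_free, lp = solve_two_class_equilibrium(c_t, c_h, TWO_CLASS,
                                                 tol=1e-10)
        assert l_free + lp == pytest.approx(c_t, abs=1e-9)
        assert 0.0 <= l_free <= c_t


class TestTwoClassEstimate:
    def test_single_class_data_give_equal_classes(self):
        c_h = np.arange(1.0, 13.0)
        lp = _single_class_forward(0.3, 2.7, 5.0, c_h)
        series = scatchard_transform(c_h, EPS_412 * lp, 5.0, EPS_412)
        est = estimate_two_class(series)
        assert abs(est.model.kd1 - est.model.kd2) / est.model.kd1 < 1e-6
        assert est.model.kd1 == pytest.approx(0.3, rel=1e-6)

    def test_reciprocal_binding_constants(self, clean_scatchard_pair):
        c_h, d_a = clean_scatchard_pair
        est = estimate_two_class(scatchard_transform(c_h, d_a, 5.0, EPS_412))
        assert est.kb1 * est.model.kd1 == pytest.approx(1.0)
        assert est.kb2 * est.model.kd2 == pytest.approx(1.0)
        assert est.line_low.slope < 0 and est.line_high.slope < 0
        assert est.model.kd1 < est.model.kd2

    def test_exact_intercepts_method_consistency(self, clean_scatchard_pair):
        """The exact-intercept system reproduces the two line intercepts it
        was solved from."""
        c_h, d_a = clean_scatchard_pair
        series = scatchard_transform(c_h, d_a, 5.0, EPS_412)
        est = estimate_two_class(series, method="exact_intercepts")
        m = est.model
        assert m.n1 / m.kd1 + m.n2 / m.kd2 == \
            pytest.approx(est.line_low.intercept, rel=1e-9)
        assert m.n1 + m.n2 == pytest.approx(est.line_high.x_intercept,
                                            rel=1e-9)

    def test_split_leaving_two_points_rejected(self, clean_scatchard_pair):
        c_h, d_a = clean_scatchard_pair
        series = scatchard_transform(c_h, d_a, 5.0, EPS_412)
        with pytest.raises(SplitError):
            estimate_two_class(series, split=2)
        short = ScatchardSeries(occupancy=series.occupancy[:4],
                                ratio=series.ratio[:4], lp=series.lp[:4],
                                l_free=series.l_free[:4])
        with pytest.raises(SplitError):
            estimate_two_class(short)
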