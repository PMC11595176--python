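"""Tests for the synthetic-data generators: determinism, physicality and
round-trip closure with the fitting modules."""

import numpy as np
import pytest

from bindspec.binding import fit_single_class, scatchard_transform, two_class_bound
from bindspec.kinetics import fit_decay
from bindspec.simulate import (
    DEFAULT_TWO_CLASS,
    EPS_BOUND_412,
    MeltModel,
    NoiseSpec,
    gen_decay,
    gen_melt,
    gen_piecewise_linear,
    gen_scatchard,
    gen_titration,
    spawn_seeds,
)
from bindspec.transitions import find_tm, fit_segmented


class TestNoiseSpec:
    def test_identical_spec_identical_output(self):
        base = np.linspace(0.0, 1.0, 50)
        a = NoiseSpec(sigma=0.01, seed=42).apply(base)
        b = NoiseSpec(sigma=0.01, seed=42).apply(base)
        assert a.tobytes() == b.tobytes()
        c = NoiseSpec(sigma=0.01, seed=43).apply(base)
        assert a.tobytes() != c.tobytes()

    def test_zero_sigma_is_exact_copy(self):
        base = np.linspace(0.0, 1.0, 10)
        out = NoiseSpec(sigma=0.0, seed=1).apply(base)
        assert out.tobytes() == base.tobytes()

    def test_multiplicative_scales(self):
        out = NoiseSpec(kind="gaussian_multiplicative", sigma=0.5,
                        seed=3).apply(np.zeros(20))
        assert np.all(out == 0.0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(kind="lognormal", sigma=0.1)
        with pytest.raises(ValueError):
            NoiseSpec(sigma=-1.0)

    def test_spawn_seeds_deterministic_and_bounded(self):
        a = spawn_seeds(7, 10)
        assert a == spawn_seeds(7, 10)
        assert len(set(a)) == 10
        assert all(0 <= s < 2**31 for s in a)


class TestGeneratorDeterminism:
    @pytest.mark.parametrize("gen,kwargs", [
        (gen_titration, {}),
        (gen_decay, {}),
    ])
    def test_byte_identical_repeats(self, gen, kwargs):
        a = gen(noise=NoiseSpec(sigma=0.01, seed=5), **kwargs)
        b = gen(noise=NoiseSpec(sigma=0.01, seed=5), **kwargs)
        for field in ("a_obs", "delta_a"):
            if hasattr(a, field):
                assert getattr(a, field).tobytes() == getattr(b, field).tobytes()

    def test_scatchard_and_melt_repeats(self):
        a = gen_scatchard(noise=NoiseSpec(sigma=0.01, seed=5))
        b = gen_scatchard(noise=NoiseSpec(sigma=0.01, seed=5))
        assert a[1].tobytes() == b[1].tobytes()
        ma = gen_melt(noise=NoiseSpec(sigma=0.02, sigma_is_range_fraction=True,
                                      seed=5))
        mb = gen_melt(noise=NoiseSpec(sigma=0.02, sigma_is_range_fraction=True,
                                      seed=5))
        assert ma.f350.tobytes() == mb.f350.tobytes()


class TestTitrationGenerator:
    def test_noiseless_round_trip_recovers_generators(self, clean_titration):
        fit = fit_single_class(clean_titration)
        assert fit.n_sites == pytest.approx(2.7, rel=1e-6)
        assert fit.eps_bound == pytest.approx(0.20, rel=1e-6)

    def test_physical_absorbances_at_zero_noise(self, clean_titration):
        for col in (clean_titration.a_free, clean_titration.a_obs,
                    clean_titration.a_bound):
            assert np.all(col >= 0.0)

    def test_zero_kd_saturates_low_protein_solution(self):
        s = gen_titration(k_d=0.0, noise=NoiseSpec(sigma=0.0, seed=0))
        sat = s.c_ligand_total <= 2.7 * 2.0  # below the site capacity
        assert np.allclose(s.a_obs[sat], s.a_bound[sat], atol=1e-12)

    def test_equal_extinctions_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            gen_titration(eps_free=0.20, eps_bound=0.20,
                          noise=NoiseSpec(sigma=0.0, seed=0))


class TestScatchardGenerator:
    def test_noiseless_points_on_two_class_curve(self, clean_scatchard_pair):
        c_h, d_a = clean_scatchard_pair
        series = scatchard_transform(c_h, d_a, 5.0, EPS_BOUND_412)
        m = DEFAULT_TWO_CLASS
        expected = (m.n1 / (m.kd1 + series.l_free)
                    + m.n2 / (m.kd2 + series.l_free))
        assert series.ratio == pytest.approx(expected, rel=1e-8)

    def test_degenerate_single_class_model_collinear(self):
        from bindspec.binding import TwoClassModel
        single = TwoClassModel(n1=1.35, kd1=0.3, n2=1.35, kd2=0.3)
        c_h, d_a = gen_scatchard(model=single,
                                 noise=NoiseSpec(sigma=0.0, seed=0))
        series = scatchard_transform(c_h, d_a, 5.0, EPS_BOUND_412)
        coeffs = np.polyfit(series.occupancy, series.ratio, 1)
        resid = series.ratio - np.polyval(coeffs, series.occupancy)
        assert np.max(np.abs(resid)) < 1e-9

    def test_zero_protein_gives_zero_signal(self):
        c_h, d_a = gen_scatchard(c_protein_grid=[0.0, 2.0, 4.0, 8.0],
                                 noise=NoiseSpec(sigma=0.0, seed=0))
        assert d_a[0] == 0.0
        assert np.all(d_a[1:] > 0.0)


class TestDecayGenerator:
    def test_noiseless_round_trip(self):
        trace = gen_decay(noise=NoiseSpec(sigma=0.0, seed=0))
        fit = fit_decay(trace, n_components=1)
        assert fit.lifetimes[0] == pytest.approx(400.0, rel=1e-8)

    def test_zero_amplitude_trace_flat(self):
        trace = gen_decay(baseline=0.2, amplitudes=[0.0], lifetimes=[400.0],
                          noise=NoiseSpec(sigma=0.0, seed=0))
        assert np.all(trace.delta_a == 0.2)

    def test_generating_parameters_average_lifetime(self):
        from bindspec.kinetics import average_lifetime
        assert average_lifetime([1.0, 1.0], [400.0, 2000.0]) == \
            pytest.approx(1733.33, abs=0.01)


class TestMeltGenerator:
    def test_channels_positive(self, clean_melt):
        assert np.all(clean_melt.f330 > 0)
        assert np.all(clean_melt.f350 > 0)

    def test_round_trip_tm(self, clean_melt):
        est = find_tm(clean_melt)
        assert est.tm_values == pytest.approx([56.2, 72.2], abs=0.3)

    def test_no_transition_curve_yields_no_peak(self):
        from bindspec.exceptions import NoPeakError
        model = MeltModel(transitions=[])
        melt = gen_melt(model=model, noise=NoiseSpec(sigma=0.0, seed=0))
        with pytest.raises(NoPeakError):
            find_tm(melt)

    def test_midpoint_outside_grid_rejected(self):
        model = MeltModel(transitions=[(150.0, 1.5, {"f350": 4000.0})])
        with pytest.raises(ValueError):
            gen_melt(model=model)


class TestPiecewiseGenerator:
    def test_segments_meet_exactly_at_breakpoints(self):
        xy = gen_piecewise_linear([2.0], [1.0, -0.5], start=(0.0, 0.0),
                                  x_grid=np.array([0.0, 1.0, 2.0, 3.0, 4.0,
                                                   5.0, 6.0]),
                                  noise=NoiseSpec(sigma=0.0, seed=0))
        # left limit and right limit at the kink agree
        assert xy.y[2] == pytest.approx(2.0)
        assert xy.y[3] == pytest.approx(2.0 - 0.5)

    def test_round_trip_three_segments(self, clean_three_piece):
        fit = fit_segmented(clean_three_piece, 3)
        assert fit.breakpoints == pytest.approx([1.5, 6.0], abs=1e-6)

    def test_kink_recovery_under_noise(self):
        """2%-of-range noise, 30 seeded replicates: the median recovered
        kink stays within 1 degree of the generating value."""
        bps = []
        for seed in spawn_seeds(123, 30):
            xy = gen_piecewise_linear(
                [57.0], [0.05, 0.35], start=(25.0, -20.0),
                x_grid=np.arange(25.0, 80.5, 2.5),
                noise=NoiseSpec(sigma=0.02, sigma_is_range_fraction=True,
                                seed=seed),
                x_kind="temperature")
            bps.append(fit_segmented(xy, 2).breakpoints[0])
        assert abs(np.median(bps) - 57.0) <= 1.0

    def test_slope_count_validated(self):
        with pytest.raises(ValueError):
            gen_piecewise_linear([1.0, 2.0], [0.5, 0.2],
                                 noise=NoiseSpec(sigma=0.0, seed=0))
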