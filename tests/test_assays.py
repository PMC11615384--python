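import numpy as np
import pytest

from quatevol import (GrowthCurve, KineticTrace, MeltCurve, RateTable,
                      estimate_tm, fit_michaelis_menten, initial_rate,
                      max_growth_rate, two_step_tm)
from quatevol.assays import AssayError
from quatevol.simulate import (simulate_growth, simulate_melt,
                               simulate_progress_trace, simulate_rate_table)

PAPER_SUBSTRATES = (25, 50, 75, 100, 150, 250, 500)


class TestInitialRate:
    def test_beer_lambert_arithmetic(self):
        # slope 0.01415 AU/min over epsilon 14150 1/(M cm) and 1 cm -> 1 uM/min
        t = np.arange(0, 300, 10.0)
        trace = KineticTrace(time_s=t, a412=0.01415 / 60.0 * t)
        rate = initial_rate(trace)
        assert rate.v_uM_per_min == pytest.approx(1.0, rel=1e-9)

    def test_flat_trace_has_zero_rate(self):
        trace = KineticTrace(time_s=np.arange(10.0), a412=np.full(10, 0.2))
        assert initial_rate(trace).v_uM_per_min == pytest.approx(0.0)

    def test_progress_curve_initial_rate_within_3_percent(self):
        sim = simulate_progress_trace(kcat_s=50.0, km_uM=40.0,
                                      enzyme_uM=0.025, s0_uM=500.0)
        rate = initial_rate(sim.trace)
        assert rate.v_uM_per_min / 60.0 == pytest.approx(sim.v0_uM_per_s,
                                                         rel=0.03)

    def test_rate_scales_inversely_with_extinction_coefficient(self):
        t = np.arange(0, 100, 5.0)
        a = 1e-4 * t
        v1 = initial_rate(KineticTrace(time_s=t, a412=a)).v_uM_per_min
        v2 = initial_rate(KineticTrace(time_s=t, a412=a,
                                       epsilon_M_cm=2 * 14150.0)).v_uM_per_min
        assert v1 == pytest.approx(2 * v2)

    def test_noise_dominated_trace_rejected(self):
        rng = np.random.default_rng(0)
        trace = KineticTrace(time_s=np.arange(20.0),
                             a412=rng.standard_normal(20))
        with pytest.raises(AssayError, match="R"):
            initial_rate(trace)


class TestMichaelisMenten:
    def test_noiseless_recovery_is_exact(self):
        sim = simulate_rate_table(50.0, 40.0, 0.025,
                                  substrate_uM=PAPER_SUBSTRATES)
        fit = fit_michaelis_menten(sim.table, enzyme_uM=0.025)
        assert fit.kcat_s == pytest.approx(50.0, rel=1e-6)
        assert fit.km_uM == pytest.approx(40.0, rel=1e-6)

    def test_half_max_at_km_on_fitted_curve(self):
        sim = simulate_rate_table(50.0, 40.0, 0.025,
                                  substrate_uM=PAPER_SUBSTRATES)
        fit = fit_michaelis_menten(sim.table, enzyme_uM=0.025)
        v_at_km = fit.vmax * fit.km_uM / (fit.km_uM + fit.km_uM)
        assert v_at_km == pytest.approx(fit.vmax / 2)

    def test_noisy_replicates_recover_within_5_percent(self):
        sim = simulate_rate_table(50.0, 40.0, 0.025,
                                  substrate_uM=PAPER_SUBSTRATES,
                                  noise_cv=0.02, replicates=3, seed=8)
        fit = fit_michaelis_menten(sim.table, enzyme_uM=0.025)
        assert fit.kcat_s == pytest.approx(50.0, rel=0.05)
        assert fit.km_uM == pytest.approx(40.0, rel=0.05)

    def test_scale_equivariance(self):
        sim = simulate_rate_table(50.0, 40.0, 0.025,
                                  substrate_uM=PAPER_SUBSTRATES,
                                  noise_cv=0.05, seed=4)
        base = fit_michaelis_menten(sim.table, enzyme_uM=0.025)
        scaled = RateTable(substrate_uM=sim.table.substrate_uM,
                           velocity=3.0 * sim.table.velocity)
        fit = fit_michaelis_menten(scaled, enzyme_uM=0.025)
        assert fit.vmax == pytest.approx(3.0 * base.vmax, rel=1e-8)
        assert fit.km_uM == pytest.approx(base.km_uM, rel=1e-8)

    def test_too_few_substrate_levels_rejected(self):
        with pytest.raises(AssayError, match="4"):
            RateTable(substrate_uM=[25, 50, 75], velocity=[1, 2, 3])

    def test_per_site_velocities_need_no_enzyme_concentration(self):
        S = np.array(PAPER_SUBSTRATES, float)
        v = 50.0 * S / (40.0 + S)
        fit = fit_michaelis_menten(
            RateTable(substrate_uM=S, velocity=v,
                      velocity_units="per_site_s"))
        assert fit.kcat_s == pytest.approx(50.0, rel=1e-6)


class TestMeltCurves:
    def test_symmetric_sigmoid_midpoint(self):
        sim = simulate_melt((70.0,))
        res = estimate_tm(sim.curve)
        assert res.tm_C == pytest.approx(70.0, abs=0.1)

    def test_linear_ramp_interpolates_to_center(self):
        T = np.linspace(60.0, 80.0, 21)
        curve = MeltCurve(temperature_C=T, signal=(T - 60) / 20)
        assert estimate_tm(curve).tm_C == pytest.approx(70.0)

    def test_noisy_sigmoid_within_three_tenths_degree(self):
        errors = [abs(estimate_tm(simulate_melt((70.0,), noise_sd=0.02,
                                                seed=s).curve).tm_C - 70.0)
                  for s in range(10)]
        assert max(errors) < 0.3

    def test_descending_ellipticity_signal_handled(self):
        sim = simulate_melt((70.0,))
        flipped = MeltCurve(temperature_C=sim.curve.temperature_C,
                            signal=-sim.curve.signal)
        assert estimate_tm(flipped).tm_C == pytest.approx(70.0, abs=0.1)

    def test_affine_transform_invariance(self):
        sim = simulate_melt((66.0,), noise_sd=0.01, seed=3)
        base = estimate_tm(sim.curve).tm_C
        scaled = MeltCurve(temperature_C=sim.curve.temperature_C,
                           signal=-5.0 * sim.curve.signal + 12.0)
        assert estimate_tm(scaled).tm_C == pytest.approx(base, abs=1e-9)

    def test_flat_signal_rejected(self):
        with pytest.raises(AssayError, match="transition"):
            estimate_tm(MeltCurve(temperature_C=np.arange(20.0, 90.0),
                                  signal=np.full(70, 0.3)))


class TestTwoStepMelt:
    def test_double_sigmoid_recovers_both_midpoints(self):
        sim = simulate_melt((49.0, 67.5))
        res = two_step_tm(sim.curve, split_C=65.0)
        assert res.tm_C == pytest.approx(49.0, abs=0.5)
        assert res.tm2_C == pytest.approx(67.5, abs=0.5)

    def test_split_below_single_transition_reduces_to_second_segment(self):
        sim = simulate_melt((72.0,))
        single = estimate_tm(sim.curve).tm_C
        res = two_step_tm(sim.curve, split_C=55.0)
        assert res.tm_C is None
        assert res.tm2_C == pytest.approx(single, abs=0.2)

    def test_flat_second_segment_reduces_to_first(self):
        sim = simulate_melt((45.0,))
        res = two_step_tm(sim.curve, split_C=65.0)
        assert res.tm2_C is None
        assert res.tm_C == pytest.approx(45.0, abs=0.3)

    def test_split_outside_range_rejected(self):
        sim = simulate_melt((70.0,))
        with pytest.raises(AssayError, match="outside"):
            two_step_tm(sim.curve, split_C=100.0)


class TestGrowth:
    def test_pure_exponential_rate_exact(self):
        t = np.linspace(0.0, 5.0, 21)
        curve = GrowthCurve(time_h=t, od600=0.05 * np.exp(0.6 * t))
        fit = max_growth_rate(curve)
        assert fit.mu_max_h == pytest.approx(0.6, abs=1e-6)

    def test_noiseless_logistic_recovered(self):
        sim = simulate_growth(r_h=0.8, capacity=1.2)
        fit = max_growth_rate(sim.curve)
        assert fit.model == "logistic"
        assert fit.mu_max_h == pytest.approx(0.8, abs=1e-3)

    def test_noisy_triplicate_mean_within_5_percent(self):
        mus = [max_growth_rate(simulate_growth(r_h=0.8, noise_cv=0.03,
                                               seed=s).curve).mu_max_h
               for s in (1, 2, 3)]
        assert np.mean(mus) == pytest.approx(0.8, rel=0.05)

    def test_no_growth_flagged_with_zero_rate(self):
        curve = GrowthCurve(time_h=np.linspace(0, 10, 20),
                            od600=np.full(20, 0.05))
        fit = max_growth_rate(curve)
        assert fit.no_growth and fit.mu_max_h == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(AssayError):
            max_growth_rate(GrowthCurve(time_h=np.arange(5.0),
                                        od600=np.linspace(0.05, 1.0, 5)))
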