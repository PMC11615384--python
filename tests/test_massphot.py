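import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quatevol import (EventTable, OligomerProfile, classify_dispersity,
                      compare_conditions, detect_oligomers, fit_calibration,
                      subunit_fractions)
from quatevol.massphot import MassPhotError
from quatevol.simulate import simulate_mp_events


def profile_from(fractions, monomer=48.0):
    return OligomerProfile.from_fractions(monomer, fractions)


class TestCalibration:
    def test_noiseless_proportional_standards_give_exact_line(self):
        standards = {
            "s86": (np.full(60, 0.086), 86.0),
            "s430": (np.full(60, 0.430), 430.0),
        }
        cal = fit_calibration(standards)
        assert cal.slope == pytest.approx(1000.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-9)
        assert cal.r_squared == pytest.approx(1.0)

    def test_third_collinear_standard_keeps_the_line(self):
        standards = {
            "s86": (np.full(60, 0.086), 86.0),
            "s146": (np.full(60, 0.146), 146.0),
            "s430": (np.full(60, 0.430), 430.0),
        }
        cal = fit_calibration(standards)
        assert cal.slope == pytest.approx(1000.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-9)

    def test_noisy_standards_recover_slope_within_5_percent(self):
        rng = np.random.default_rng(12)
        standards = {}
        for mass in (86.0, 146.0, 430.0):
            contrasts = (mass / 1000) * (1 + 0.02 * rng.standard_normal(1000))
            standards[f"s{int(mass)}"] = (contrasts, mass)
        cal = fit_calibration(standards)
        assert abs(cal.slope - 1000.0) / 1000.0 < 0.05

    def test_calibration_invertible_on_own_standards(self):
        standards = {
            "a": (np.full(60, 0.1), 100.0),
            "b": (np.full(60, 0.4), 400.0),
        }
        cal = fit_calibration(standards)
        assert cal.to_mass(np.array([0.1, 0.4])) == pytest.approx([100., 400.])

    def test_fewer_than_two_standards_rejected(self):
        with pytest.raises(MassPhotError, match="standards"):
            fit_calibration({"only": (np.full(60, 0.1), 100.0)})

    def test_degenerate_identical_contrasts_rejected(self):
        with pytest.raises(MassPhotError, match="identical"):
            fit_calibration({"a": (np.full(60, 0.2), 100.0),
                             "b": (np.full(60, 0.2), 200.0)})


class TestDetectOligomers:
    def test_pure_hexamer_recovered_as_single_component(self):
        sim = simulate_mp_events({6: 1.0}, 48.0, n_events=3000,
                                 sigma_rel=15.0 / 288.0, seed=101)
        prof = detect_oligomers(sim.events, 48.0, n_max=12)
        assert [c.n for c in prof.components] == [6]
        assert prof.components[0].particle_fraction >= 0.98
        assert prof.components[0].mean_kda == pytest.approx(288.0, rel=0.02)

    def test_dimer_hexamer_mixture_fractions_within_tolerance(self):
        sim = simulate_mp_events({2: 0.7, 6: 0.3}, 48.0, n_events=5000,
                                 seed=102)
        prof = detect_oligomers(sim.events, 48.0, n_max=12)
        fr = prof.particle_fractions()
        assert abs(fr[2] - 0.7) < 0.03
        assert abs(fr[6] - 0.3) < 0.03

    def test_zero_variance_events_at_twice_monomer(self):
        ev = EventTable(data=pd.DataFrame({"mass_kda": np.full(200, 96.0)}))
        prof = detect_oligomers(ev, 48.0)
        assert [c.n for c in prof.components] == [2]
        assert prof.components[0].particle_fraction == pytest.approx(1.0)

    def test_events_below_floor_excluded_and_reported(self):
        masses = np.concatenate([np.full(50, 20.0), np.full(150, 96.0)])
        ev = EventTable(data=pd.DataFrame({"mass_kda": masses}))
        prof = detect_oligomers(ev, 48.0, mass_floor=40.0)
        assert prof.n_below_floor == 50
        assert prof.unassigned_fraction == pytest.approx(0.25)
        assert prof.components[0].particle_fraction == pytest.approx(0.75)

    def test_all_events_below_floor_is_an_error(self):
        ev = EventTable(data=pd.DataFrame({"mass_kda": np.full(100, 10.0)}))
        with pytest.raises(MassPhotError, match="floor"):
            detect_oligomers(ev, 48.0)

    def test_event_order_does_not_matter(self):
        sim = simulate_mp_events({2: 0.5, 6: 0.5}, 48.0, n_events=2000,
                                 seed=103)
        shuffled = EventTable(data=sim.events.data.sample(
            frac=1.0, random_state=1).reset_index(drop=True))
        a = detect_oligomers(sim.events, 48.0)
        b = detect_oligomers(shuffled, 48.0)
        for ca, cb in zip(a.components, b.components):
            assert ca.particle_fraction == pytest.approx(cb.particle_fraction,
                                                         abs=1e-9)

    def test_contrast_events_require_calibration(self):
        ev = EventTable(data=pd.DataFrame({"contrast": np.full(100, 0.3)}))
        with pytest.raises(MassPhotError, match="calibration"):
            detect_oligomers(ev, 48.0)

    def test_resampling_stability_at_large_n(self):
        sim = simulate_mp_events({2: 0.6, 6: 0.4}, 48.0, n_events=5000,
                                 seed=104)
        full = detect_oligomers(sim.events, 48.0).particle_fractions()
        sub = EventTable(data=sim.events.data.sample(
            frac=0.9, random_state=2).reset_index(drop=True))
        part = detect_oligomers(sub, 48.0).particle_fractions()
        for n in full:
            assert abs(full[n] - part.get(n, 0.0)) < 0.01


class TestSubunitFractions:
    def test_equal_particle_mixture_weights_by_stoichiometry(self):
        prof = profile_from({2: 0.5, 6: 0.5})
        assert subunit_fractions(prof) == pytest.approx({2: 0.25, 6: 0.75})

    def test_single_species_is_unity(self):
        assert subunit_fractions(profile_from({6: 1.0})) == {6: 1.0}

    @given(st.dictionaries(st.integers(1, 12),
                           st.floats(0.01, 1.0), min_size=1, max_size=5))
    @settings(deadline=None, max_examples=50)
    def test_fractions_sum_to_one_and_preserve_weight_order(self, raw):
        total = sum(raw.values())
        fractions = {n: f / total for n, f in raw.items()}
        prof = profile_from(fractions)
        sub = subunit_fractions(prof)
        assert sum(sub.values()) == pytest.approx(1.0)
        weights = {n: n * f for n, f in fractions.items()}
        wtot = sum(weights.values())
        for n in fractions:
            assert sub[n] == pytest.approx(weights[n] / wtot)


class TestClassify:
    def test_ladder_profile_is_polydisperse_with_flags(self):
        prof = profile_from({2: 0.10, 3: 0.06, 4: 0.25, 6: 0.30,
                             8: 0.20, 10: 0.09})
        rep = classify_dispersity(prof)
        assert rep.label == "polydisperse"
        assert rep.even_series and rep.oddmers_present

    def test_dominant_species_is_monodisperse(self):
        assert classify_dispersity(
            profile_from({6: 0.95, 2: 0.05})).label == "monodisperse(6)"
        assert classify_dispersity(
            profile_from({2: 1.0})).label == "monodisperse(2)"

    def test_two_species_half_half_is_mixed(self):
        assert classify_dispersity(
            profile_from({6: 0.5, 8: 0.5})).label == "mixed"

    def test_growing_dominant_fraction_never_flips_to_polydisperse(self):
        base = {2: 0.2, 4: 0.2, 6: 0.2, 8: 0.4}
        seen_mono = False
        for boost in np.linspace(0.0, 0.55, 12):
            rest = 1.0 - (0.4 + boost)
            fr = {2: rest / 3, 4: rest / 3, 6: rest / 3, 8: 0.4 + boost}
            label = classify_dispersity(profile_from(fr)).label
            if seen_mono:
                assert label.startswith("monodisperse")
            seen_mono = seen_mono or label.startswith("monodisperse")
        assert seen_mono


class TestCompareConditions:
    def test_identical_profiles_have_zero_deltas(self):
        a = profile_from({6: 0.5, 8: 0.5})
        shift = compare_conditions(a, profile_from({6: 0.5, 8: 0.5}))
        assert np.allclose(shift.deltas["particle_delta"], 0.0)
        assert np.allclose(shift.deltas["subunit_delta"], 0.0)

    def test_effector_induced_shift_octamer_to_hexamer(self):
        before = profile_from({8: 1.0})
        after = profile_from({6: 0.5, 8: 0.5})
        shift = compare_conditions(before, after)
        row = shift.deltas.set_index("n")
        assert row.loc[6, "particle_delta"] == pytest.approx(0.5)
        assert row.loc[8, "particle_delta"] == pytest.approx(-0.5)

    def test_simulated_effector_shift_recovered(self):
        a = simulate_mp_events({8: 1.0}, 48.0, n_events=5000, seed=105)
        b = simulate_mp_events({6: 0.5, 8: 0.5}, 48.0, n_events=5000, seed=106)
        pa = detect_oligomers(a.events, 48.0)
        pb = detect_oligomers(b.events, 48.0)
        shift = compare_conditions(pa, pb)
        row = shift.deltas.set_index("n")
        assert abs(row.loc[6, "particle_delta"] - 0.5) < 0.03

    def test_monomer_mass_mismatch_rejected(self):
        with pytest.raises(MassPhotError):
            compare_conditions(profile_from({2: 1.0}, monomer=48.0),
                               profile_from({2: 1.0}, monomer=50.0))


def test_profile_invariants_enforced():
    with pytest.raises(MassPhotError):
        profile_from({2: 0.5, 6: 0.6})  # fractions exceed 1
    with pytest.raises(MassPhotError):
        OligomerProfile(monomer_mass=48.0, components=[], unassigned_fraction=0.5)
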