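"""Digital twin: twitch model, excitability gate, pharmacology, mechanics."""

import math
import warnings

import numpy as np
import pytest

import myoslice as ms
from myoslice.twin import diastolic_operating_point


class TestGeometry:
    def test_cross_section(self):
        assert ms.SliceGeometry().cross_section == pytest.approx(1.5)

    @pytest.mark.parametrize("kwargs", [
        {"length": 0.0}, {"width": -1.0}, {"thickness": 0.0},
    ])
    def test_positive_dimensions_enforced(self, kwargs):
        with pytest.raises(ValueError):
            ms.SliceGeometry(**kwargs)


class TestActiveForce:
    def test_zero_at_onset_and_after_relaxation(self, tissue):
        assert ms.active_force(0.0, tissue) == pytest.approx(0.0)
        assert ms.active_force(60_000.0, tissue) == pytest.approx(0.0, abs=1e-12)

    def test_peak_equals_peak_twitch_force_at_reference(self, tissue):
        t = np.linspace(0.0, 3000.0, 60_001)
        f = ms.active_force(t, tissue, length_fraction=0.83, rate=60.0)
        assert f.max() == pytest.approx(tissue.peak_twitch_force, rel=1e-6)
        assert t[f.argmax()] == pytest.approx(tissue.time_to_peak, abs=0.1)

    def test_single_peaked(self, tissue):
        t = np.linspace(0.0, 3000.0, 3001)
        f = ms.active_force(t, tissue)
        sign_changes = np.sum(np.diff(np.sign(np.diff(f))) != 0)
        assert sign_changes == 1

    def test_negative_time_rejected(self, tissue):
        with pytest.raises(ValueError):
            ms.active_force(-1.0, tissue)


class TestExcitable:
    def test_interval_equal_to_rp_fails(self, tissue):
        state = ms.ChamberState(last_activation_time=0.0)
        assert not ms.excitable(0.425, 50.0, 1.0, tissue, state)

    def test_interval_one_ms_beyond_rp_activates(self, tissue):
        state = ms.ChamberState(last_activation_time=0.0)
        assert ms.excitable(0.426, 50.0, 1.0, tissue, state)
        assert state.last_activation_time == pytest.approx(0.426)

    def test_subthreshold_never_activates(self, tissue):
        state = ms.ChamberState(last_activation_time=-1e9)
        assert not ms.excitable(100.0, 10.0, 1.0, tissue, state)

    def test_strength_duration_charge_tradeoff(self, tissue):
        # 10 mA is subthreshold at 1 ms but its charge reaches threshold at 3 ms
        state = ms.ChamberState(last_activation_time=-1e9)
        assert ms.excitable(100.0, 10.0, 3.0, tissue, state)


class TestApplyDrug:
    def test_zero_concentration_is_identity(self, tissue):
        drug = ms.DrugEffect("dofetilide", "rp_acute_hill", ec50=3.0, emax=160.0)
        assert ms.apply_drug(tissue, drug) == tissue

    def test_hill_midpoint_gives_half_ceiling(self, tissue):
        drug = ms.DrugEffect("dofetilide", "rp_acute_hill", ec50=3.0,
                             emax=160.0, concentration=3.0)
        dosed = ms.apply_drug(tissue, drug)
        assert dosed.refractory_period - tissue.refractory_period == \
            pytest.approx(80.0)

    def test_delayed_effect_zero_on_day_zero(self, tissue):
        drug = ms.DrugEffect("pentamidine", "rp_delayed", ec50=0.01,
                             emax=312.0, onset_tau=5.0, concentration=1.0)
        dosed = ms.apply_drug(tissue, drug, elapsed_days=0.0)
        assert dosed.refractory_period == tissue.refractory_period

    def test_delayed_effect_monotone_and_converges_to_acute(self, tissue):
        delayed = ms.DrugEffect("pentamidine", "rp_delayed", ec50=0.01,
                                emax=312.0, onset_tau=5.0, concentration=1.0)
        acute = ms.DrugEffect("pentamidine", "rp_acute_hill", ec50=0.01,
                              emax=312.0, concentration=1.0)
        rps = [ms.apply_drug(tissue, delayed, d).refractory_period
               for d in (0, 1, 2, 5, 10, 20, 50, 200)]
        assert all(b >= a for a, b in zip(rps, rps[1:]))
        assert rps[-1] == pytest.approx(
            ms.apply_drug(tissue, acute).refractory_period, abs=1e-6)

    def test_inotropic_scale_ceiling(self, tissue):
        iso = ms.DrugEffect("isoprenaline", "inotropic_scale", ec50=1e-3,
                            emax=5.5, concentration=1e3)
        dosed = ms.apply_drug(tissue, iso)
        assert dosed.peak_twitch_force / tissue.peak_twitch_force == \
            pytest.approx(5.5, rel=1e-5)

    def test_unknown_mechanism_rejected(self):
        with pytest.raises(ValueError):
            ms.DrugEffect("x", "made_up", ec50=1.0, emax=1.0)


class TestPreload:
    def test_one_mn_preload_within_tolerance(self, tissue):
        state = ms.adjust_preload(tissue, 1.0)
        assert state.preload == pytest.approx(1.0, abs=0.01)

    def test_preload_sets_length_fraction_083(self, tissue):
        state = ms.adjust_preload(tissue, 1.0)
        _, length = diastolic_operating_point(tissue, state)
        frac = length / tissue.length_tension.l_max(tissue.geometry.length)
        assert frac == pytest.approx(0.83, abs=0.02)

    def test_zero_target_gives_slack(self, tissue):
        state = ms.adjust_preload(tissue, 0.0)
        assert state.preload == pytest.approx(0.0, abs=0.01)

    def test_unreachable_target_raises(self, tissue):
        with pytest.raises(ValueError, match="drive range"):
            ms.adjust_preload(tissue, 1e9)


class TestSimulateRun:
    def test_unstimulated_trace_is_flat_at_preload(self, tissue, transducer):
        config = ms.SimulationConfig(duration=10.0, seed=0)
        trace = ms.simulate_run(tissue, ms.StimulusSchedule([]), config)
        force = ms.trace_to_force(trace, transducer)
        assert np.mean(force) == pytest.approx(1.0, abs=0.02)
        assert np.std(force) < 0.1

    def test_twelve_twitches_at_culture_pacing(self, paced_trace, transducer):
        trace, schedule = paced_trace
        force = ms.trace_to_force(trace, transducer)
        events = ms.detect_twitches(force, trace.time, schedule.times)
        assert len(events) == 12

    def test_seeded_runs_are_bit_identical(self, tissue):
        schedule = ms.pacing_schedule(0.2, 30.0)
        config = ms.SimulationConfig(duration=34.0, seed=7)
        a = ms.simulate_run(tissue, schedule, config)
        b = ms.simulate_run(tissue, schedule, config)
        assert np.array_equal(a.flux, b.flux)
        assert np.array_equal(a.stim_current, b.stim_current)

    def test_noise_free_diastolic_equals_preload_within_1pct(
            self, noise_free_trace, transducer):
        trace, schedule = noise_free_trace
        force = ms.trace_to_force(trace, transducer)
        events = ms.detect_twitches(force, trace.time, schedule.times)
        assert np.allclose(events["diastolic_force"], 1.0, rtol=0.01, atol=0.01)

    def test_forces_non_negative(self, paced_trace, transducer):
        trace, _ = paced_trace
        force = ms.trace_to_force(trace, transducer)
        assert force.min() > 0.0  # 1 mN preload keeps the noisy trace positive

    def test_schedule_beyond_duration_rejected(self, tissue):
        schedule = ms.pacing_schedule(0.2, 60.0)
        config = ms.SimulationConfig(duration=10.0, seed=0)
        with pytest.raises(ValueError):
            ms.simulate_run(tissue, schedule, config)

    def test_auxotonic_hooke_consistency(self, tissue, transducer):
        """Force at 6% shortening equals k * 0.06 * length exactly: the trace
        force and the spring displacement stay on the Hooke line."""
        iso = ms.DrugEffect("isoprenaline", "inotropic_scale", ec50=1e-3,
                            emax=5.5, concentration=1e3)
        strong = ms.apply_drug(tissue, iso)
        schedule = ms.pacing_schedule(0.2, 10.0)
        config = ms.SimulationConfig(duration=14.0, seed=0, noise=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ms.SaturationWarning)
            trace = ms.simulate_run(strong, schedule, config)
        force = ms.trace_to_force(trace, transducer)
        x = force / transducer.spring_constant
        k_check = 0.06 * tissue.geometry.length * transducer.spring_constant
        # at the sample where shortening crosses 6%, force is k * 0.06 * L
        i = int(np.argmin(np.abs(x - 0.06 * tissue.geometry.length)))
        assert force[i] == pytest.approx(k_check, rel=0.02)


class TestLengthTensionSweep:
    def test_sweep_passive_hits_1mN_at_083_lmax(self, tissue):
        stretch = np.linspace(0.0, 1.6, 33)
        length, passive, active = ms.length_tension_sweep(tissue, stretch)
        summary = ms.length_tension_analysis(length, active, passive)
        assert summary.fraction_at_preload == pytest.approx(0.83, abs=0.02)

    def test_active_force_non_negative_for_all_lengths(self, tissue):
        frac = np.linspace(0.0, 2.0, 201)
        assert np.all(tissue.length_tension.active_factor(frac) >= 0)
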