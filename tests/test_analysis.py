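"""Trace analysis: twitch detection, pair classification, contracture."""

import warnings

import numpy as np
import pandas as pd
import pytest

import myoslice as ms
from myoslice.analysis import classify_pair, contracture, longterm_summary


class TestDetectTwitches:
    def test_noise_free_amplitudes_equal_within_1pct(self, noise_free_trace,
                                                     transducer):
        trace, schedule = noise_free_trace
        force = ms.trace_to_force(trace, transducer)
        events = ms.detect_twitches(force, trace.time, schedule.times)
        assert len(events) == 12
        amps = events["amplitude"].to_numpy()
        assert np.ptp(amps) / amps.mean() < 0.01

    def test_unstimulated_trace_yields_no_events(self, tissue, transducer):
        config = ms.SimulationConfig(duration=10.0, seed=0)
        trace = ms.simulate_run(tissue, ms.StimulusSchedule([]), config)
        force = ms.trace_to_force(trace, transducer)
        events = ms.detect_twitches(force, trace.time, [2.0, 4.0, 6.0])
        assert events.empty

    def test_empty_schedule_empty_result(self, paced_trace, transducer):
        trace, _ = paced_trace
        force = ms.trace_to_force(trace, transducer)
        assert ms.detect_twitches(force, trace.time, []).empty

    def test_amplitude_invariant_to_flux_offset(self, paced_trace, transducer):
        trace, schedule = paced_trace
        force = ms.trace_to_force(trace, transducer)
        shifted = force + 3.0  # constant flux offset = constant force offset
        a = ms.detect_twitches(force, trace.time, schedule.times)
        b = ms.detect_twitches(shifted, trace.time, schedule.times)
        assert np.allclose(a["amplitude"], b["amplitude"])
        assert np.allclose(b["diastolic_force"] - a["diastolic_force"], 3.0)

    def test_event_ordering_invariants(self, paced_trace, transducer):
        trace, schedule = paced_trace
        force = ms.trace_to_force(trace, transducer)
        ev = ms.detect_twitches(force, trace.time, schedule.times)
        assert (ev["amplitude"] >= 0).all()
        assert (ev["peak_time"] >= ev["onset"]).all()
        assert (ev["onset"] >= ev["stimulus_time"]).all()

    def test_inotropic_amplitude_ratio_recovered(self, tissue):
        iso = ms.DrugEffect("isoprenaline", "inotropic_scale", ec50=1e-3,
                            emax=5.5, concentration=1e3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ms.SaturationWarning)
            ratio = ms.inotropy_ratio(tissue, iso, seed=3)
        assert ratio == pytest.approx(5.5, rel=0.02)


def _paired_trace(tissue, interval_ms, seed=0, noise=True):
    proto = ms.PairedPulseProtocol(step_duration=30.0)
    schedule = ms.paired_pulse_schedule(proto, 0.2, intervals_ms=[interval_ms])
    config = ms.SimulationConfig(duration=schedule.end_time + 4.0, seed=seed,
                                 noise=noise)
    trace = ms.simulate_run(tissue, schedule, config)
    force = ms.trace_to_force(trace)
    return trace, schedule, force


class TestClassifyPair:
    def test_interval_above_rp_gives_two_contractions(self, tissue):
        trace, schedule, force = _paired_trace(tissue, 500.0)
        regs, extras = schedule.regular_events(), schedule.extra_events()
        ref = ms.detect_twitches(force, trace.time, [regs[0].time])
        cls = classify_pair(force, trace.time, regs[0].time, extras[0].time,
                            ref["amplitude"].iloc[0])
        assert cls == "two_contractions"

    def test_interval_at_or_below_rp_gives_one(self, tissue):
        trace, schedule, force = _paired_trace(tissue, 425.0)
        regs, extras = schedule.regular_events(), schedule.extra_events()
        ref = ms.detect_twitches(force, trace.time, [regs[0].time])
        cls = classify_pair(force, trace.time, regs[0].time, extras[0].time,
                            ref["amplitude"].iloc[0])
        assert cls == "one_contraction"

    def test_subthreshold_extra_gives_one(self, tissue):
        weak = ms.make_pulse(10.0)  # below the 30 mA threshold at 1 ms
        events = [ms.stim.StimEvent(1.0, ms.make_pulse(), "regular"),
                  ms.stim.StimEvent(1.8, weak, "extra")]
        schedule = ms.StimulusSchedule(events)
        config = ms.SimulationConfig(duration=6.0, seed=0)
        trace = ms.simulate_run(tissue, schedule, config)
        force = ms.trace_to_force(trace)
        ref = ms.detect_twitches(force, trace.time, [1.0])
        cls = classify_pair(force, trace.time, 1.0, 1.8,
                            ref["amplitude"].iloc[0])
        assert cls == "one_contraction"

    def test_monotone_in_interval_noise_free(self, tissue):
        """If interval i elicits two contractions, every longer interval does."""
        outcomes = []
        for iv in (350.0, 400.0, 420.0, 430.0, 500.0, 700.0, 900.0):
            trace, schedule, force = _paired_trace(tissue, iv, noise=False)
            regs, extras = schedule.regular_events(), schedule.extra_events()
            ref = ms.detect_twitches(force, trace.time, [regs[0].time])
            outcomes.append(classify_pair(force, trace.time, regs[0].time,
                                          extras[0].time,
                                          ref["amplitude"].iloc[0]))
        flips = [a != b for a, b in zip(outcomes, outcomes[1:])]
        assert sum(flips) == 1  # single transition: one -> two


class TestContracture:
    def _flat(self, minutes=20.0, fs=10.0):
        t = np.arange(0, minutes * 60, 1 / fs)
        return t, np.full_like(t, 1.0)

    def test_flat_baseline_is_zero(self):
        t, f = self._flat()
        assert contracture(f, t) == pytest.approx(0.0, abs=1e-9)

    def test_linear_ramp_recovered(self):
        t, f = self._flat()
        ramp = f + 2.0 * t / t[-1]
        assert contracture(ramp, t) == pytest.approx(2.0, rel=0.02)

    def test_negative_drift_reported_not_clipped(self):
        t, f = self._flat()
        assert contracture(f - 1.5 * t / t[-1], t) == pytest.approx(-1.5, rel=0.02)

    def test_twitches_do_not_bias_baseline(self, tissue):
        # superimpose twitch transients on a drifting baseline
        t = np.arange(0, 1200, 0.02)
        drift = 0.8 * t / t[-1]
        twitches = np.zeros_like(t)
        for t0 in np.arange(0, 1195, 5.0):
            m = (t >= t0) & (t < t0 + 2.0)
            twitches[m] += 6.0 * tissue.twitch_shape((t[m] - t0) * 1e3)
        est = contracture(1.0 + drift + twitches, t)
        assert est == pytest.approx(0.8, abs=0.1)


class TestLongtermSummary:
    @staticmethod
    def _stream(amplitudes, dia=1.0, period_s=5.0):
        n = len(amplitudes)
        t = np.arange(n) * period_s
        return pd.DataFrame({
            "stimulus_time": t, "onset": t + 0.05, "peak_time": t + 0.15,
            "peak_force": dia + np.asarray(amplitudes),
            "diastolic_force": dia,
            "amplitude": np.asarray(amplitudes),
        })

    def test_constant_stream_identical_cycles(self):
        events = self._stream(np.full(720, 6.0))
        out = longterm_summary(events, exchange_interval_h=0.25)
        assert len(out) == 4
        assert out["amp_min"].nunique() == 1 and out["amp_max"].nunique() == 1

    def test_dia_sys_ratio(self):
        events = self._stream(np.full(10, 7.14 - 1.0), dia=1.0)
        out = longterm_summary(events, exchange_interval_h=1.0)
        assert out["dia_sys_ratio"].iloc[0] == pytest.approx(1.0 / 7.14, rel=1e-6)

    def test_modulated_twin_stream_matches_generator_envelope(self, tissue):
        period_h, depth = 0.05, 0.3
        schedule = ms.pacing_schedule(0.2, 3 * period_h * 3600.0)
        config = ms.SimulationConfig(duration=3 * period_h * 3600.0 + 4.0,
                                     seed=2, medium_modulation=(period_h, depth))
        trace = ms.simulate_run(tissue, schedule, config)
        force = ms.trace_to_force(trace)
        events = ms.detect_twitches(force, trace.time, schedule.times)
        out = longterm_summary(events, exchange_interval_h=period_h)

        ref_config = ms.SimulationConfig(duration=64.0, seed=2)
        ref = ms.simulate_run(tissue, ms.pacing_schedule(0.2, 60.0), ref_config)
        ref_amp = ms.detect_twitches(ms.trace_to_force(ref), ref.time,
                                     np.arange(12) * 5.0)["amplitude"].mean()
        phases = (events["stimulus_time"] / 3600.0) % period_h / period_h
        mod = 1.0 - depth * np.exp(-phases / 0.25)
        events = events.assign(expected=ref_amp * mod)
        for cyc, grp in events.groupby(
                np.floor(events["stimulus_time"] / (period_h * 3600)).astype(int)):
            row = out[out["cycle"] == cyc].iloc[0]
            assert row["amp_min"] == pytest.approx(grp["expected"].min(), rel=0.02)
            assert row["amp_max"] == pytest.approx(grp["expected"].max(), rel=0.02)

    def test_empty_stream(self):
        out = longterm_summary(pd.DataFrame(), 36.0)
        assert out.empty
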