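"""High-level experiment pipelines run against the digital twin.

These tie the stimulation engine, twin simulation, transduction and trace
analysis into the workflows performed on the bench:

* :func:`measure_refractory_period` — the full paired-pulse determination
  (coarse descending ladder, optional fine bisection to 1 ms) through the
  raw-trace path;
* :func:`rp_dose_response` — synthetic acute dose-response experiment for a
  refractory-prolonging drug, as Hill-fit input;
* :func:`inotropy_ratio` — twitch-amplitude ratio between a control and a
  drug-scaled recording, recovered by the trace analyser.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import RefractoryResult, detect_twitches, refractory_period
from .biomech import DoseResponse
from .stim import PairedPulseProtocol, PulseShape, make_pulse, paired_pulse_schedule, pacing_schedule
from .transduce import SpringTransducer, trace_to_force
from .twin import DrugEffect, SimulationConfig, TissueParams, apply_drug, simulate_run


def _simulate_protocol(tissue, protocol, intervals_ms, base_rate, pulse,
                       transducer, seed, sample_rate, noise):
    schedule = paired_pulse_schedule(protocol, base_rate, pulse,
                                     intervals_ms=intervals_ms)
    duration = schedule.end_time + 4.0
    config = SimulationConfig(duration=duration, sample_rate=sample_rate,
                              seed=seed, noise=noise, transducer=transducer)
    trace = simulate_run(tissue, schedule, config)
    return trace, schedule


def measure_refractory_period(
    tissue: TissueParams,
    protocol: PairedPulseProtocol | None = None,
    *,
    base_rate: float = 0.2,
    pulse: PulseShape | None = None,
    transducer: SpringTransducer | None = None,
    seed: int = 0,
    sample_rate: float = 500.0,
    noise: bool = True,
) -> RefractoryResult:
    """End-to-end refractory-period determination on the twin.

    Runs the coarse descending-interval protocol as a simulated recording,
    classifies every paired-pulse step from the raw trace, and (when the
    protocol requests it) refines the coarse bracket by bisection with
    fresh simulated probes down to ``fine_step`` ms.  The returned result
    carries all interval classifications and the grid precision achieved.
    """
    if protocol is None:
        protocol = PairedPulseProtocol(fine_refine=True)
    if pulse is None:
        pulse = make_pulse()
    if transducer is None:
        transducer = SpringTransducer()

    trace, schedule = _simulate_protocol(
        tissue, protocol, protocol.intervals_ms, base_rate, pulse,
        transducer, seed, sample_rate, noise)
    coarse = refractory_period(trace, protocol, schedule, transducer)
    if coarse.censored is not None or not protocol.fine_refine:
        return coarse

    lo = coarse.refractory_period  # longest failing interval
    succeeding = [iv for iv, c in coarse.classifications.items()
                  if c == "two_contractions" and iv > lo]
    hi = min(succeeding)
    classifications = dict(coarse.classifications)
    probe = 0
    while hi - lo > protocol.fine_step + 1e-9:
        mid = lo + round((hi - lo) / 2 / protocol.fine_step) * protocol.fine_step
        mid = min(max(mid, lo + protocol.fine_step), hi - protocol.fine_step)
        probe += 1
        trace_m, schedule_m = _simulate_protocol(
            tissue, protocol, [mid], base_rate, pulse, transducer,
            (seed + 7919 * probe) % (2**31 - 1), sample_rate, noise)
        step = refractory_period(trace_m, protocol, schedule_m, transducer)
        cls = step.classifications[round(mid, 3)]
        classifications[round(mid, 3)] = cls
        if cls == "one_contraction":
            lo = mid
        else:
            hi = mid
    return RefractoryResult(classifications=classifications,
                            refractory_period=lo, censored=None,
                            precision=protocol.fine_step)


def rp_dose_response(
    drug: DrugEffect,
    doses,
    tissue: TissueParams | None = None,
    *,
    n_replicates: int = 6,
    noise_sd: float = 20.0,
    seed: int = 0,
    elapsed_days: float = 0.0,
) -> DoseResponse:
    """Synthetic acute dose-response experiment: ΔRP (ms) vs concentration.

    For each dose the refractory-period change is read from the twin's
    pharmacology model and jittered with Gaussian measurement noise of
    ``noise_sd`` ms, ``n_replicates`` slices per dose.  Returns the data as
    a :class:`~myoslice.biomech.DoseResponse` ready for Hill fitting.
    """
    if tissue is None:
        tissue = TissueParams()
    rng = np.random.default_rng(seed)
    doses = np.asarray(doses, dtype=float)
    concs, responses = [], []
    for c in doses:
        dosed = apply_drug(tissue, replace(drug, concentration=float(c)),
                           elapsed_days=elapsed_days)
        delta = dosed.refractory_period - tissue.refractory_period
        concs.extend([c] * n_replicates)
        responses.extend(delta + rng.normal(0.0, noise_sd, n_replicates))
    return DoseResponse(np.array(concs), np.array(responses))


def paced_twitch_amplitudes(
    tissue: TissueParams,
    *,
    rate: float = 0.2,
    n_beats: int = 12,
    transducer: SpringTransducer | None = None,
    seed: int = 0,
    sample_rate: float = 500.0,
    noise: bool = True,
) -> pd.DataFrame:
    """Simulate a paced recording and return its detected twitch table."""
    if transducer is None:
        transducer = SpringTransducer()
    schedule = pacing_schedule(rate, n_beats / rate)
    config = SimulationConfig(duration=schedule.end_time + 4.0,
                              sample_rate=sample_rate, seed=seed,
                              noise=noise, transducer=transducer)
    trace = simulate_run(tissue, schedule, config)
    force = trace_to_force(trace, transducer)
    return detect_twitches(force, trace.time, schedule.times)


def inotropy_ratio(
    tissue: TissueParams,
    drug: DrugEffect,
    *,
    rate: float = 0.2,
    n_beats: int = 12,
    seed: int = 0,
    noise: bool = True,
) -> float:
    """Mean twitch-amplitude ratio, drug / control, through the trace path.

    Both recordings are simulated, converted to flux and back, and analysed
    with :func:`~myoslice.analysis.detect_twitches`; the ratio of mean
    amplitudes recovers the drug's inotropic scale.
    """
    control = paced_twitch_amplitudes(tissue, rate=rate, n_beats=n_beats,
                                      seed=seed, noise=noise)
    dosed_tissue = apply_drug(tissue, drug)
    dosed = paced_twitch_amplitudes(dosed_tissue, rate=rate, n_beats=n_beats,
                                    seed=(seed + 1) % (2**31 - 1), noise=noise)
    if control.empty or dosed.empty:
        raise RuntimeError("twitch detection returned no events")
    return float(dosed["amplitude"].mean() / control["amplitude"].mean())
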