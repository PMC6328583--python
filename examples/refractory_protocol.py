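"""Determine the refractory period with the paired-pulse protocol.

Every regular 0.2 Hz pacing pulse is followed by an extra pulse; the
extra-pulse interval steps down from 1000 to 250 ms (25 ms per 30 s step).
The longest interval that fails to elicit a second distinct contraction is
the refractory period; a bisection pass refines it to 1 ms.
"""

import myoslice as ms

tissue = ms.TissueParams(refractory_period=425.0)  # healthy cultured baseline
protocol = ms.PairedPulseProtocol(fine_refine=True)

result = ms.measure_refractory_period(tissue, protocol, seed=1)
print(f"ground-truth refractory period: {tissue.refractory_period:.0f} ms")
print(f"protocol read-back:            {result.refractory_period:.0f} ms "
      f"(precision {result.precision:g} ms)")

frame = result.to_frame()
transition = frame[frame["classification"] == "two_contractions"].tail(2)
print("intervals near the transition (ms -> classification):")
print(frame[(frame.interval_ms >= 400) & (frame.interval_ms <= 450)]
      .to_string(index=False))
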