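"""Pharmacology on the twin: acute hERG block and delayed trafficking block.

An acute channel blocker (dofetilide-type: EC50 3 nM, ceiling 160 ms)
prolongs the refractory period immediately; the synthetic dose-response
experiment (6 doses x 6 replicate slices, 20 ms measurement noise) is fitted
with a Hill curve.  A trafficking inhibitor (pentamidine-type) has no effect
on day 0 and saturates over about two weeks.
"""

import numpy as np

import myoslice as ms

dofetilide = ms.DrugEffect("dofetilide", "rp_acute_hill", ec50=3.0, emax=160.0)
doses = [0.3, 1.0, 3.0, 10.0, 30.0, 100.0]  # nM

dr = ms.rp_dose_response(dofetilide, doses, n_replicates=6, noise_sd=20.0,
                         seed=1)
ms.hill_fit(dr, fix_hill_n=1.0)
print("acute dose-response fit (generating EC50 3 nM, ceiling 160 ms):")
print(f"  EC50 = {dr.ec50:.2f} nM, Emax = {dr.emax:.1f} ms, "
      f"residual = {dr.residual_norm:.1f} ms")

pentamidine = ms.DrugEffect("pentamidine", "rp_delayed", ec50=0.001,
                            emax=312.0, onset_tau=5.0, concentration=1.0)
tissue = ms.TissueParams()
print("\ndelayed block: refractory prolongation vs exposure time")
for day in (0, 1, 3, 7, 14, 28):
    dosed = ms.apply_drug(tissue, pentamidine, elapsed_days=day)
    delta = dosed.refractory_period - tissue.refractory_period
    print(f"  day {day:2d}: +{delta:5.1f} ms")
print("(ineffective on day 0, ~94% of the 312 ms plateau by day 14)")
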