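# Methods

This note records the models, calibrations and numerical choices behind
`myoslice`, and what the synthetic experiments do and do not show.

## Chamber mechanics and transduction

The mounted slice and the spring share a fixed distance budget
(`total_span`): muscle length L plus spring deflection x = F/k is constant
for a given drive setting. At every sample the force balances

    F = P(L) + A(t),   L = span − F/k,

where P is the passive (diastolic) curve and A(t) the active drive. The
equation is solved by vectorised Newton iteration over the whole sample
array (converges in a handful of iterations; forces are clipped at zero
because the mount cannot push). Hooke's law is therefore exact by
construction: trace force and tip displacement always satisfy F = kx.

Passive curve: exponential in strain beyond a slack length of 0.9 of the
reference mounted length, P(L) = a·(e^{b·(L−L_s)/L_ref} − 1) with b = 10
per unit strain and a chosen so that P(L_ref) = 1 mN. This puts the 1 mN
preload exactly at the reference length and produces passive forces of
~10 mN at 20% stretch, a realistic range for failing human myocardium.

Active length dependence: concave parabola in the length fraction
f = L/L_max with curvature 4 (zero active force at f = 0.5 and 1.5),
normalised to 1 at f = 0.83 and calibrated so that the 1 mN preload sits at
83% of the optimum length — i.e. L_max = L_ref/0.83. The length–tension
factor of a twitch is evaluated at the **end-diastolic** length, not
instantaneously during shortening. This mirrors the physiology of
length-dependent activation (set by end-diastolic sarcomere length) and
keeps twitch amplitude linear in inotropic state, which is what makes an
amplitude-ratio readout a faithful estimator of an inotropic scale factor.

Transduction is affine around the operating point: B = B₀ + s·x with
s = 7 T/m. Per-sample flux noise is s × 0.5 µm (the "resolution" constant
is read as the one-sigma single-sample displacement error, so averaging N
samples improves it by √N). Excursions beyond the ±1.2 mT sensor budget
emit a warning but are not clipped; strong (e.g. 5.5-fold inotropic)
contractions do exceed the budget, since 7 T/m × 0.44 mm ≈ 3 mT.

## Twitch waveform and excitability

The twitch is a difference of exponentials, e^{−t/τ_d} − e^{−t/τ_r},
peak-normalised; τ_d is the relaxation time constant (default 300 ms) and
τ_r is solved from the configured time-to-peak (default 150 ms). These two
constants are free choices — only the waveform's general shape is
constrained by high-resolution twitch recordings — and were fixed once at
values typical of human ventricular twitches at 37 °C.

A stimulus activates the tissue iff (a) its charge I·w reaches the
threshold charge (threshold current 30 mA at 1 ms width; the
strength–duration relation holds charge constant, matching an escalation
rule capped at 75 mA and 3 ms) and (b) the interval since the last
activation strictly exceeds the refractory period. The boundary is closed
on the refractory side — an interval exactly equal to RP fails — with a
1 ns numeric tolerance so float jitter in event times cannot flip the
boundary case. Premature beats are attenuated by amplitude restitution
1 − 0.45·e^{−(Δt−RP)/150 ms}: immediately after the refractory period a
beat still has ~55% amplitude, well above the 10% distinct-contraction
threshold, so restitution adds realism without changing the protocol's
grid semantics.

Force–frequency behaviour is a piecewise-linear factor table over
12–180 bpm relative to 60 bpm. The default ("cultured") table gains force
at bradycardia (1.25 at 12 bpm) and declines toward 180 bpm; a "fresh"
table without the bradycardia gain is provided. This is a qualitative
surface only.

## Refractory-period protocol

The descending ladder (1000 → 250 ms) uses a 25 ms decrement per 30 s step
— the interval range and step duration are fixed by the protocol
definition, the decrement is a package choice giving 31 steps (~15.5 min).
Each step contributes ~6 pairs at 0.2 Hz; steps are classified by majority
vote over their pairs to resist noise. A pair counts as two contractions
when the force upswing after the extra stimulus reaches θ = 0.10 of the
preceding regular twitch amplitude; the upswing criterion (maximum force
after the extra minus force at the extra) is insensitive to the decaying
tail of the first twitch that a premature beat rides on. θ must be well
below 1 because premature beats are attenuated; 0.10 sits comfortably above
the noise floor (a 6 mN twitch against ~0.04 mN force noise).

Fine refinement is a bisection between the longest failing and shortest
succeeding coarse interval, each probe being a fresh 30 s simulated step,
until the bracket reaches the 1 ms fine step. The reported RP is the
longest failing interval, so a non-integer ground truth is floored to the
grid — the estimate is exact for integer RPs and at most one fine step low
otherwise. Censoring: all intervals succeeding ⇒ RP below the 250 ms
floor ("low"); none succeeding ⇒ RP at or above the 1000 ms ceiling
("high").

Stimulation markers in a recorded trace are quantised to the 500 Hz sample
grid (±1 ms). Analyses that need exact pair intervals therefore accept the
schedule object alongside the trace; trace-only analysis is supported and
adequate on the 25 ms coarse grid.

## Pharmacology

All drug actions are Hill surfaces R(C) = E_max·Cⁿ/(EC₅₀ⁿ + Cⁿ), n = 1 by
default. Acute refractory prolongation adds R(C) to RP immediately;
delayed (trafficking-type) block scales it by 1 − e^{−t/τ_onset} with
τ_onset = 5 days, so the effect is absent on day 0, ~94% developed at day
14, and plateaus within the two-week window. The delayed effect is monotone
in exposure time and converges to the acute surface as t → ∞.

The synthetic dose-response experiment draws 6 replicates per dose at
{0.3, 1, 3, 10, 30, 100} nM with Gaussian noise of 20 ms — replicate count
and noise chosen to mirror a typical 5–6-slice experiment with ~18 ms SEM.
`hill_fit` is least squares (`scipy.optimize.curve_fit`) parameterised in
log EC₅₀, multi-started over seven log-spaced EC₅₀ seeds spanning the dose
range (hence invariant to concentration units). The Hill coefficient is
fixed at 1 for simple channel-block surfaces and free on request. All-zero
responses return E_max ≈ 0 with EC₅₀ flagged unidentifiable, as do fits
landing more than two decades outside the dose range.

## Morphometry

Phantoms are sinusoidal striation fields with configurable period,
orientation, phase disorder and additive noise; slab, grid and
random-label phantoms serve the other estimators. All phantom generation
is seed-reproducible.

Sarcomere length: the fibre axis is estimated from the image-gradient
structure tensor (a simplification of full 2-D spectral methods), the
image rotated onto it, and row spectra averaged after Hann windowing and
4× zero padding. The power-spectrum maximum restricted to 1/3–1 µm⁻¹ is
refined by quadratic interpolation on log power. Guards: the band maximum
must be a genuine local maximum (a monotone flank at the band edge is
leakage from out-of-band structure), must stand 5× above the median band
power, and the implied length must fall in 1–3 µm (with a 5% margin for
sub-bin refinement at the edges). Accuracy on phantoms is limited by the
refined bin, in practice ≲ 0.001 µm at 10–20% noise.

Membrane distance: Euclidean distance transform with anisotropic voxel
sampling. The mean is taken over the whole tissue volume (membrane voxels
contribute zero), which makes the statistic agree with the continuous
closed form — exactly d/4 for parallel planes spaced d — independent of
the voxelised membrane thickness; restricting the mean to non-membrane
voxels (available as an option) carries an O(voxel/d) upward bias, ~11% at
d = 1 µm with 0.1 µm voxels.

Cross-sections: connected-component labelling of intracellular regions in
the transverse plane; components touching the image border (partial cells)
are dropped, components below 50 µm² are excluded as capillary-scale
lumina, components above 1200 µm² are flagged as merged cells from broken
membranes. ECM fraction thresholds the membrane/matrix channel by Otsu
unless an explicit cut is given.

## Transcript trends

Expression change is the log2 ratio of cultured to fresh transcript counts
(pseudocount 0.5 guards zero counts). The linear trend is ordinary least
squares of the ratio on culture day over days {8, 14, 24, 35} only — no
synthetic day-0 anchor — reporting the day-0 intercept and slope × 35.
This convention reproduces the shipped reference tables' printed intercept
and slope×35 columns within the ±0.02 bound implied by their two-decimal
input rounding. Trends with |slope × 35| ≥ 1 (one doubling over the span)
are classified positive/negative, otherwise flat; the threshold is a
documentation convention, not an inferential cut. The regression pools the
contributing patients; no patient-effect adjustment is applied.

## Problem sizes and determinism

Simulations run at the device's 500 Hz per chamber. The full coarse
refractory protocol is ~930 s of simulated time (~4.7 × 10⁵ samples) plus
~5 bisection probes of 30 s each; it computes in well under a second, so
tests and the acceptance script use the full-fidelity protocol. The test
suite shortens only the per-step duration in the interval sweep (10 s,
2 pairs per step) to keep the whole suite in a few seconds. Every
stochastic path takes an explicit seed (`numpy.random.default_rng`);
identical seeds give bit-identical traces, and derived seeds stay below
2³¹.

## Known limitations

No ionic/action-potential model (RP is a scalar state), no oxygen or
nutrient transport, no arrhythmia generation beyond premature-beat
attenuation, no remodelling that couples gene expression to mechanics.
The sensor is a single effective flux component (affine model), not a
3-axis dipole field. Passing recovery tests on the twin demonstrates the
analysis chain is correct and self-consistent under calibrated noise; it
does not certify performance on real tissue, where twitch shapes, drift
and artefacts are richer than the generator emulates.
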