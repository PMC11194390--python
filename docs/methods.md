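# Methods

This note records the models implemented by `pulsekfd`, the defaults and
why they were chosen, the numerical choices that matter, and what the
synthetic experiments can and cannot show.

## Katz's fractal dimension of a beat

A single cardiac cycle of PPG, min-max normalized to [0, 1], is traced as
a planar polyline with time in integer sample units and amplitude
multiplied by `alpha * Fs / HR`.  This gain puts the two axes in the same
unit: the amplitude full scale spans `alpha / HR` seconds' worth of
samples (about 0.25 s for `alpha = 0.3` at a 0.82 s cycle).  The statistic
is the simplified Katz form

    KFD = log10(L) / log10(d),

with `L` the summed Euclidean length of consecutive segments and `d` the
maximum distance from the first point.  Since the polyline from the first
point to its farthest point is at least as long as the straight chord,
`L >= d` always, so `KFD >= 1` whenever `d > 1`; a sampled straight line
gives exactly 1.  When `d <= 1` the denominator is non-positive and the
computation refuses with a hint to raise `alpha` or the sampling rate.
Katz's original step-normalized variant
`log10(n) / (log10(n) + log10(d/L))` is provided as
`katz_fd_classic` for comparison but is not used by the pipeline; the
simplified form is the one whose straight-line value is exactly 1.

`alpha` defaults to 0.3, the value that maximizes the KFD-compliance
correlation on large 1D-model virtual populations; `sweep_alpha`
re-derives the optimum for any cohort over a 0.1-0.5 grid (step 0.05,
ties toward smaller `alpha`).  On the smooth zero-dimensional cohorts
generated here the sweep prefers smaller values (~0.1); the 0.3 default is
kept because it is the established operating point for realistic,
reflection-rich waveforms.

KFD series are cleaned by two rules applied together: (i) values outside
median +/- 3 SD; (ii) a state-transition rule - values are discretized
into 20 equal-width bins, first-order transition frequencies tallied, and
a value is discarded when every transition it participates in has
empirical probability below 1%.  The bin count and the
"all-transitions-rare" reading are our choices (only the 1% figure is
prescribed); on i.i.d. series the rule also trims sparse distribution
tails, which is visible as ~10-35% removals on large cohorts.

## Windkessel models

Both models share the WK4 topology: inflow `q_in(t)` charges the central
compliance C1; flow `q` passes through inertance L to the peripheral
node with compliance C2 and resistance R.  The fixed-C1 model is the
linear system

    dq/dt   = (p_c - p_p) / L
    dp_c/dt = (q_in - q) / C1
    dp_p/dt = (q - p_p / R) / C2.

The time-varying model replaces C1 by a cycle-periodic C1(t); eliminating
`q` and `p_c` gives the equivalent third-order ODE in `p_p` alone, and we
integrate the first-order form directly.  The C1(t) law models
pressure-dependent stiffening:

    C1(t) = C1_baseline * (1 - m * s(t)),

with `s(t)` the previous warm-up cycle's central pressure rescaled to
[0, 1] (a distension proxy) and `m` a single modulation depth, default
0.3.  The law is a pluggable callable; it is a stated stand-in for
whatever cycle-resolved compliance course a particular study prescribes.
The first warm-up cycle runs unmodulated because no distension proxy
exists yet.

Forcing is a half-sine ejection pulse over the first
`T_systole_fraction = 0.35` of the cycle, rescaled so its trapezoidal
integral equals the stroke volume exactly.  Defaults `L = 0.02
mmHg.s^2/mL` and `C2 = 0.08 * C1_baseline` are typical lumped-model
magnitudes; both are exposed in the cohort spec.  "AC" for these cohorts
means the time-average of C1(t), which reduces to `C1_baseline` for the
fixed model.

Steady state: cycles are integrated one at a time from a mean-pressure
initial condition until the peripheral pressure repeats within 0.1 mmHg
(max over the cycle), with a 50-cycle budget; non-convergence raises an
error carrying the last residual.  Two integration paths exist:

- single subjects use adaptive LSODA (rtol 1e-8, atol 1e-10, dense output
  resampled to 500 Hz) - the reference path;
- cohorts use a vectorized classical RK4 advancing all subjects on a
  common 1024-point cardiac-phase grid (each subject keeps its own
  period).  The ~0.8 ms step is far below the system's time constants,
  and the two paths agree within the 0.1 mmHg steady-state tolerance
  (cross-checked in the tests).  This makes a 4374-subject cohort a
  seconds-scale computation on one CPU and keeps the sensitivity analysis
  (which re-simulates every subject twice per parameter) cheap.

The PPG surrogate of a converged cycle is the peripheral volume beat
`V(t) = C2 * p_p(t)`; its span `delta_v = C2 * PP` stands in for the
pulsatile blood-volume amplitude.

## Virtual cohorts

Cohort parameters are independent truncated-Gaussian draws (+/- 3 SD)
with defaults SV 61.7 +/- 4.1 mL, AC 1.03 +/- 0.26 mL/mmHg, R 0.78 +/-
0.07 mmHg.s/mL and heart rate 1/0.82 Hz +/- 0.1 Hz - the population
spread of the large 1D-model virtual database these experiments mirror.
Only the mean cycle length is published for the heart rate, so its SD is
our choice of a plausible adult spread.  No parameter covariance is
published; independent sampling is the simplest reproducible reading and
the sampler is a single function to swap if a joint distribution becomes
available.  Non-convergent subjects are dropped (not retried) to keep the
cohort i.i.d.; more than 5% of them aborts the build.

## Preprocessing

Pipeline order is segmentation -> per-beat normalization -> denoising ->
amplitude-time scaling -> KFD.  The order matters: the running median,
for instance, commutes with the normalization only when no artifact sets
the normalization scale, and a guard test documents the chosen order.

- Segmentation is multi-scale trough detection (AMPD applied to minima):
  a sample is marked at scale k when strictly below both neighbours at
  distance k; the operating scale maximizes the number of marks, and
  troughs are samples marked at every scale up to it.  Beats are
  half-open `[onset, offset)` intervals, per-beat HR = fs / length.
- The band-pass is a 0.665-35 Hz Kaiser-window FIR cascade (high-pass
  transition 0.3 Hz, low-pass 5 Hz, 40 dB stopband), applied centered
  (symmetric taps => zero phase) with odd-reflection edge padding.
- The five-Gaussian denoiser fits two forward and three reflected waves
  by bounded nonlinear least squares.  The parameterization enforces the
  domain rules by construction: reflected amplitudes are nested fractions
  of the principal forward amplitude (each < forward_1, non-increasing),
  reflected centers are nested fractions of the remaining cycle
  (non-decreasing, inside the beat), widths in [0.02, 0.4] cycles.
  Starts come from greedy peak peeling (subtract the largest bump five
  times) plus landmark-based restarts; the best of the (deterministic)
  starts wins.  Exact admissible 5-Gaussian beats are recovered to
  machine precision.
- Quality screening is template matching: beats are length-resampled to
  100 points, the template is their pointwise mean, and a beat passes at
  Pearson correlation >= 0.86 (the conventional cutoff; configurable).
- Residual SNR of a record is `10 log10(var(filtered) / var(residual))`
  with the band-pass output as the clean reference.

## Morphology comparators

SI = height / (systolic-to-diastolic transit time) with a configurable
subject height (default 1.75 m - the lumped model has no height of its
own); RI = diastolic / systolic amplitude; AGI = (b - c - d - e) / a from
the second derivative of the smoothed beat (Savitzky-Golay, window ~ 5%
of the beat).  Because smooth Windkessel beats - like stiff-subject PPG -
often lack a distinct secondary peak, the detector falls back to the
first-derivative shoulder (first local maximum of dy/dt on the falling
limb) for the diastolic wave; without the fallback validity on noiseless
0D cohorts is a few percent, with it above 95%.  Missing fiducials are
flagged and excluded, never imputed.  Outlier rules: SI outside median
+/- 1 SD is masked; RI and AGI outside +/- 2 SD.

## Surrogate models and the noise harness

`fit_surrogate` is plain OLS with intercept for
`AC_est = a dV + b / PP` and `1/PP_est = c dV + d KFD`; no
regularization, since both are two-regressor fits.  Composing the second
into the first reproduces the direct AC-on-(dV, KFD) regression exactly
when 1/PP is itself an exact linear function of (dV, KFD); with model
error the two differ, so the consistency check is run in that exact
regime.

The noise harness tiles each beat eight times, injects white Gaussian
noise at a fixed SNR (variance = var(signal)/10^(SNR/10)), band-pass
filters the tiled record, extracts and renormalizes the middle cycle,
optionally refits the five-Gaussian model, recomputes KFD/SI/RI/AGI,
applies each feature's outlier rule, and reports Pearson r against AC
with Fisher-z 95% intervals, alongside a noiseless baseline.  Both
per-seed rows and multi-seed medians are available from the returned
table.

## Sensitivity analysis

For each subject one parameter (AC -> C1_baseline with C2 keeping the
fixed C2/C1 ratio, R, or SV) is shifted by +/- one population SD and the
subject re-simulated.  The index is `I = ((V - V0) / (V0 - 1)) / v * 100`
for KFD - the divisor is the fractal excess because a smooth noiseless
beat sits barely above the straight-line floor of 1 - and `/ V0` for SI
(the conventional pre-modification form; the divisor is exposed).  Both
perturbation directions are stored; summaries default to +SD.  Records
with `V0 = 1` (zero divisor) are flagged invalid and excluded.

## Problem sizes and determinism

Default experiment sizes: cohort correlation experiments at n = 4374
(the reference population size) with five independent seeds; unit-level
property checks use 100-1000 random instances; the in-package noise
harness examples run at n = 200 with three seeds.  All randomness flows
through seeded `numpy` generators; simulations are deterministic given a
profile, so repeated runs are bit-identical.

## Known limitations

- The cycle-resolved compliance law C1(t) is a stand-in.  With it, the
  fixed-C1 model's beats already encode compliance smoothly (KFD-AC
  r ~ 0.5 at cohort scale, similar to the time-varying model), so this
  package does not reproduce the strong fixed-vs-varying contrast
  reported for 0D models built with other (unpublished) cohort
  constructions, in which the fixed-C1 model degrades to r ~ 0.2.  The
  law and the inflow shape are pluggable precisely so alternative
  constructions can be substituted.
- 0D beats are far smoother than 1D-model or measured PPG: KFD's dynamic
  range across a 0D cohort is ~1e-3, so its correlations are more
  noise- and seed-sensitive than on reflection-rich waveforms, and the
  alpha optimum shifts below 0.3.
- Passing tests on these cohorts show the pipeline's correctness and the
  relative noise robustness of KFD versus morphology indices; they do not
  by themselves establish clinical performance - real PPG adds motion
  artifacts, baseline wander, device coupling and physiological
  covariance that the generator does not emulate.
- The loader for the public 4374-subject pulse-wave database expects a
  plain-text export and performs no science of its own; database-specific
  correlation magnitudes are therefore only reproducible where that
  download is available.
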