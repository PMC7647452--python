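# Methods

This note documents the models, numerical choices and defaults behind the
package, and what the synthetic study does and does not establish.

## Signal model of the synthetic generator

Each pulse is the sum of two Gaussian components: a systolic wave
(center 0.18 s, width 0.075 s for a 0.8 s reference cycle) and a
diastolic wave (center 0.50 s, width 0.20 s, relative amplitude 0.45).
All shape parameters scale proportionally with the actual cycle length,
so waveform morphology is self-similar across heart rates; this makes the
area difference ratio (ADR) rate-invariant by construction, which is the
behaviour the method expects of a pure shape parameter.

The diastolic component is strong enough to be a modest secondary wave
rather than a fully merged shoulder. This is deliberate: the trough is
defined as the minimum between adjacent systolic peaks, and localizing
that minimum to 50 ms under 20 dB measurement noise requires the
inter-beat valley to have usable curvature. A merged shoulder leaves a
near-flat valley in which the argmin wanders by 60–100 ms; the secondary
wave restores the sharp descent-into-upstroke corner of real pulses. The
window verification rule of the peak detector suppresses the secondary
wave exactly as it must suppress real dicrotic waves.

Beat boundaries come from a phase accumulator over the instantaneous
heart rate, so intervals remain consistent through rate changes:

    HR(t) = HR0 + eff(ce) · ΔHR · exp(−(t − t_s)/τ) · 1[t ≥ t_s] + OU(t)

with defaults HR0 = 76 bpm (subject-jittered, clipped to 70–95 bpm),
ΔHR = 12 bpm, τ = 60 s, and a stationary Ornstein–Uhlenbeck drift
(sd 2.5 bpm, correlation time 30 s) representing spontaneous autonomic
variability. The drug attenuation is a Hill sigmoid
`eff(ce) = 1/(1 + (ce/EC50)^γ)` with EC50 = 1.5 ng/ml and γ = 4.5, chosen
so that 1 ng/ml retains most of the response (eff ≈ 0.86) while 3 ng/ml
is near-null (eff ≈ 0.04) — the response pattern the study design is
meant to produce. The heart-rate floor exists because the fixed 0.6 s
verification window stops covering the systolic wave when cycles grow
beyond ≈ 0.95 s, at which point a visible diastolic wave becomes
detectable as a spurious peak; that is a property of the fixed-window
rule, and the generator stays inside its valid regime.

Two waveform deformations accompany the stimulus:

* a drug-attenuated steepening of the catacrotic limb (`slope_gain`,
  default 0.01) that compresses the diastolic component toward the peak;
* a drug-*independent* deformation of the diastolic wave (`shape_gain`)
  whose magnitude is randomized per subject (mean 0, sd 0.22, clipped to
  ±0.35) at the study level, raising-and-narrowing or lowering the wave.
  It models vasomotor shape changes that noxious stimulation produces
  regardless of analgesic level, and is the dominant source of
  between-subject variability in the shape parameters (DSmin, ADR).

Measurement noise: additive white Gaussian noise at a configurable SNR
(default 20 dB relative to the clean signal power), sinusoidal baseline
wander (5% of peak amplitude at 0.25 Hz), optional powerline component
(off by default; at fs = 100 Hz a 50 Hz tone sits at the Nyquist edge).

Ground truth is computed on the clean waveform: true peaks by argmax per
beat, true troughs by argmin between peaks, and true per-beat parameters
by running the normalization/feature code on the clean signal with the
true fiducials. Detection accuracy is therefore scored against an oracle
that shares no state with the detector's input (the noisy signal).

What the generator does **not** emulate: respiration-driven amplitude
modulation, motion artifacts, arrhythmia, sensor saturation, and any
physiologically detailed cardiovascular coupling. Passing tests establish
that the pipeline recovers what this model produces; robustness on real
recordings with those artifacts is untested by construction.

## Denoising

Multilevel db4 DWT, symmetric signal extension (configurable), three
levels so that the cardiac band (0.5–4 Hz) lies inside the untouched
approximation cA(3) (0–6.25 Hz at fs = 100). Noise sigma is estimated
once from the level-1 details as `median(|cD1|)/0.6745` and rescales the
threshold at every detail level. SURE thresholds minimize Stein's
unbiased risk exactly over the sorted absolute coefficients; the minimax
threshold is `σ(0.3936 + 0.1829·log2 n)` and 0 for n ≤ 32. Hard
shrinkage keeps strictly `|c| > T`; soft shrinkage is
`sign(c)·max(|c|−T, 0)`. With a clean reference the four rule×mode
combinations are ranked by SNR (Eq. `10·log10(Σ(x−x̄)²/Σ(y−x)²)`), ties
broken by RMSE and then by the fixed order sure-soft, sure-hard,
minimax-soft, minimax-hard; without a reference the configured default
combination is applied and only thresholds are reported.

## Detection, normalization, features

Peak candidates are sign changes of the first difference; a candidate
survives iff it is the *first* sample attaining the maximum of the 0.6 s
window centered on it (windows clipped at record edges; the
first-attainment rule prevents double peaks on plateaus). Records shorter
than one window yield no peaks. Troughs are the first-occurrence argmin
on the open interval between adjacent peaks.

Cycles live on the half-open sample interval (t(i), t(i+1)]; the baseline
is the chord through the two trough samples, evaluated in fraction form
so the end trough maps to exactly 0; amplitude division makes the peak
exactly 1. Cycles whose adjusted peak is non-positive are dropped and
counted.

Features per beat (times from sample indices at fs): `DS` is defined as
the chord-slope magnitude from the systolic peak to the following trough,
which on a normalized cycle reduces to `1/DI` — this is what makes the
DI–DS rank correlation maximal after amplitude normalization. Derivatives
use `numpy.gradient` (central differences, one-sided at segment ends);
the DSmin location is the first sample attaining the minimum; `DTI` runs
from that sample to the *following* (end) trough, since the steepest
descent lies on the catacrotic limb. The ADR triangle is the right
triangle with vertices at the peak, the end trough, and the point below
the peak at trough level, so `S_Δ = DI·peak/2`; the curve area is
trapezoidal. Beats whose catacrotic segment has fewer than 3 samples are
dropped and counted. Beat time is the end-trough time, which also decides
window membership.

Because `mean_pre`/`RMS_pre` are taken over the same −70…−10 s window
that defines the pre-value, every pre-value is 0 up to rounding; the
report keeps the pre-values anyway since the downstream tests (pre vs
post) are defined on them.

## Statistics

* P_K: pairs with tied predictor levels are excluded (ordinal-predictor
  convention); response ties count half. The jackknife deletes one
  subject at a time and skips replicates that lose the second predictor
  level. Under the null the *folded* statistic `max(raw, 1−raw)` has mean
  ≈ 0.56 and sd ≈ 0.07 at 15 subjects per group, so "near 0.5" for a null
  parameter means ≈ 0.5–0.65 at this sample size.
* Wilcoxon signed-rank: zero differences dropped; exact two-sided p by a
  sign-flip dynamic program over doubled (average) ranks for ≤ 25
  remaining pairs — this handles ties exactly — and a tie-corrected
  normal approximation beyond. All-zero differences give p = 1 with a
  warning.
* Mann-Whitney: exact for groups ≤ 20 without ties, tie-corrected normal
  approximation otherwise (scipy backend).
* Kruskal-Wallis and Spearman: scipy backends; constant inputs are
  flagged as NaN correlations.
* Sample size: smallest integer n such that a two-sided two-sample
  t test with noncentrality `(diff/sd)·sqrt(n/2)` on `2n−2` df reaches
  the requested power, iterating n upward over the noncentral-t
  distribution.
* No multiple-testing correction is applied; the report carries the
  number of tests performed.

## Problem sizes and defaults used in the checks

The simulated acceptance checks use the study design itself: 45 records
(15 per concentration), 140–150 s at fs = 100 Hz, stimulus at 70–75 s.
A full study simulates and processes in a few seconds; the whole test
suite runs in well under a minute.

## Known limitations

* The fixed 0.6 s verification window constrains valid heart rates to
  roughly 63–120 bpm when the pulse has a visible diastolic wave (see
  above); the generator's defaults stay inside this regime, and so must
  real inputs.
* The chord-based per-cycle baseline removal assumes troughs are reliable;
  a missed peak merges two cycles and the beat is silently shaped by the
  merged chord (such beats surface through the feature invariants).
* The pre-value ≈ 0 construction means between-group comparisons of
  pre-values are comparisons of rounding noise; they are reported but
  carry no information by design.
* Generator defaults were calibrated once against the qualitative
  response pattern the study design prescribes (graded interval-parameter
  response, flat ADR) and then frozen; they are qualitative emulations,
  not fits to any recording.
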