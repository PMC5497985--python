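# Methods

`teplab` implements the measurement and analysis stack of a paired-pulse
TMS-EEG + behavior study design, together with a synthetic-cohort generator
that provides known ground truth for every estimator. This note documents
the models, the defaults and why they were chosen, the numerical
conventions, and what the synthetic data does and does not establish about
real recordings.

## Electrophysiological measures

### Early TEP

The TMS-evoked potential (TEP) immediately after a single pulse indexes
local cortical excitability. Per subject, trials are averaged per channel,
the mean over a pre-stimulus baseline window is subtracted per channel, and
the early TEP is the rectified windowed mean

    earlyTEP = mean_{c in coil} mean_{15 ms <= t <= 40 ms} |ERP_c(t)|   [µV]

over the electrodes under the coil center (FC4, FC6, F4, F6). The matching
rectified AUC (trapezoid integral of |ERP| over the same window, in µV·ms)
is reported alongside; for a fixed window the two are proportional, so any
analysis can use either. Pooling order is: average trials → rectify per
channel → average channels → window statistic.

### LICI

Long-interval cortical inhibition (LICI) is the suppression of the response
to a test pulse (TS) by a conditioning pulse (CS) 100 ms earlier,
attributed to GABA-B-mediated inhibition. Comparing paired-pulse to
single-pulse responses is confounded by the lingering CS response under the
TS window; this is removed by shift-subtraction: the subject's single-pulse
ERP is repositioned so its pulse onset lies at the CS time and subtracted
from the paired-pulse ERP. LICI is then

    LICI = [1 − rectAUC(corrected paired) / rectAUC(single)] × 100   [%]

with both AUCs over the same post-TS window (default 50–150 ms) on the coil
channels. 100 % is full suppression, 0 % none, negative values
facilitation. A zero single-pulse AUC raises a degenerate-signal error
rather than returning an undefined ratio.

### Numerical conventions

- Times are in ms relative to test-pulse onset; the CS sits at a negative
  offset. Window endpoints are inclusive. Quadrature is the composite
  trapezoid on the uniform grid.
- **Grid alignment of the shift.** 100 ms is not a whole number of samples
  at 2048 Hz (204.8). The CS–TS offset is realized as
  `round(interval × fs / 1000)` samples (205 samples = 100.098 ms) in both
  the simulator and `shift_subtract`, so the subtraction cancels the CS
  response exactly sample-by-sample. All stated tolerances absorb the
  ≤ half-sample discretization of the nominal interval.
- **Undefined samples.** Shifting leaves the trailing `shift` samples of
  the corrected ERP without a subtrahend; they are carried through
  unmodified but flagged invalid and excluded from every window statistic
  (zero-filling would bias the AUC ratio).
- **Baseline.** Default −400 to −110 ms: ends before the CS (with a 2 ms
  artifact guard), mean-subtraction per channel. Configurable.
- **Pulse artifact.** Analysis windows are placed outside −2 to +14 ms
  around each pulse by construction (the early-TEP window starts at 15 ms);
  no interpolation is applied to synthetic data.

### Known limitation: rectification noise bias

The rectified-AUC estimator is biased when noise is non-negligible:
E|s + n| > |s| wherever |s| ≲ σ, and the corrected-paired ERP (numerator,
signal scaled by 1 − LICI/100, noise from two ERPs) is inflated relatively
more than the single-pulse ERP (denominator), so LICI is systematically
*under*-estimated at low SNR. With the default generator (template peak
~10 µV, windowed signal ~3 µV on coil channels, 50 trials) the measured
bias curve is approximately:

| single-trial noise sd (µV) | residual ERP noise (µV) | mean LICI estimate (truth 30 %) |
|---|---|---|
| 0 | 0 | 30.0 |
| 2 | 0.28 | 29.0 |
| 3 (default) | 0.42 | 27.6 |
| 5 | 0.71 | 24.6 |
| 8 | 1.13 | 18.8 |

(`analysis/05_recovery_and_calibration.py` recomputes this curve.) The
default of 3 µV emulates well-cleaned epoched data — residual noise in the
50-trial average ≈ 0.4 µV against µV-scale windowed signal — which is the
regime the rectified-AUC method presumes; the remaining −2 to −3 point bias
is a property of the estimator, not of the simulator, and is visible in all
recovery outputs rather than corrected away.

## Synthetic EEG generator

The canonical TEP is a causal (zero before the pulse) sum of
Gaussian-windowed damped sinusoids at fixed latencies — 25 ms (dominant,
10 µV, 35 Hz), 60 ms (−8 µV, 14 Hz), 100 ms (6 µV, 9 Hz), 185 ms (−3 µV,
5 Hz) — chosen so that the early-TEP window (15–40 ms) contains the
dominant component and the LICI window (50–150 ms) contains measurable
signal. Each channel scales the template by `exp(−d/0.35)` where `d` is the
scalp distance from the coil centroid over FC4/FC6/F4/F6 (approximate
right-frontal 10–20 positions). Paired epochs superpose the CS response at
the grid-aligned CS offset and a TS response multiplied by
`1 − lici_true/100`; with zero noise the pipeline therefore recovers
`lici_true` exactly up to grid discretization. Noise is white Gaussian per
sample (default 3 µV, above); optional 1/f coloring and an exponential
decay artifact (off by default) support robustness studies. The generator
does **not** model real TMS artifacts (muscle, blink, recharge), volume
conduction, or inter-trial nonstationarity — recovery results here validate
the *estimators*, not robustness to raw-data artifacts, whose removal is
assumed upstream.

Protocol defaults: 2048 Hz sampling, 50 single + 50 paired pulses,
CS–TS interval 100 ms, epoch window −500 to +500 ms.

## Behavioral tasks

### Stop-signal / SSRT

Trials present a go cue; 25 % carry a stop signal after a staircase-tracked
stop-signal delay (SSD: +50 ms after a successful stop, −50 ms after a
failed one, floored at 0, start 250 ms). The simulator implements the
independent race model: on stop trials a response escapes iff the sampled
go RT < SSD + SSRT. Stop trials are deterministically interleaved (exactly
one per block of four, at a seeded position) so the stop fraction is exact.
The staircase converges to ~50 % stop success, where the mean method is
unbiased:

    SSRT = mean RT(correct go) − mean SSD.

An integration-method estimator (go-RT quantile at the observed respond
rate minus mean SSD) is available behind a flag. Trial count (400), start
SSD and step are configurable defaults; they are design choices, not
reconstructions of any particular experiment. Go errors (wrong cue) occur
at 2 % by default.

### Delay discounting

Subjective value is hyperbolic, V = A / (1 + kD) (k in 1/day); choices are
logistic in the value difference, P(delayed) = σ(β(V_delayed − V_imm)).
The default item set is the standard 27-item monetary-choice grid (amounts
11–85, delays 7–186 days). Fitting maximizes the joint likelihood over
(k, β): a log-spaced grid over k ∈ [1e−5, 1] crossed with a coarse β grid
seeds a bounded L-BFGS-B polish in log space. One-sided choice sets have no
interior optimum; the fit is then pinned at a bound and flagged
not-converged. Recovery at k = 0.01/day, β = 0.5, 27 × 5 items is within
[0.005, 0.02] for ≥ 90 % of seeds.

### Arithmetic and memory

The speeded arithmetic task (greater/smaller than 4, 2 s deadline) is
scored as correct-and-timely over all presented trials by default (late or
omitted responses are failures of a speeded task); a timely-only
denominator is available by flag since either convention is defensible.
Subjects with fewer than 3 accurate-and-timely trials are flagged for
discard. The four-alternative recognition task is proportion correct,
chance 0.25. Per-session trial counts (40 arithmetic, 20 memory) are
generator defaults.

## Cohort model and score tables

The default cohort mirrors a two-group cross-sectional design: 16 heavy
smartphone users (SU) vs 35 nonusers (NU). Group truth parameters (means ±
between-subject sd) place effects where the estimators should find them:
lower TEP amplitude scale in SU (0.91 vs 1.00, sd 0.15), LICI 29 ± 5 % (SU)
vs 26 ± 6 % (NU), log-normal k with median 0.021 vs 0.010, arithmetic
accuracy 0.72 vs 0.80, and no true group difference in SSRT or memory.
Questionnaire subscale totals (six CAARS subscales, CAS, BDI, RSMS, an
app-usage index) are multivariate normal with explicit pairwise correlation
targets (default: usage × inattention ρ = 0.5); a non-PSD implied
correlation matrix is rejected with the offending eigenvalue. A null-cohort
spec (identical groups) supports calibration studies. Everything is
deterministic given the spec seed.

## Statistics layer

Pooled-variance Student's t (df = n₁ + n₂ − 2 — matching the df convention
of two-group reports at these sample sizes) with Cohen's d on the pooled
sd; classical split-plot 2×2 mixed ANOVA from explicit sums of squares
(between effect against subject-within-group error; within and interaction
against the time×subject error; partial η² = SS_eff/(SS_eff + SS_err);
unequal group sizes handled with weighted marginal means; subjects with a
missing time level are rejected, never imputed); Pearson r with df = n − 2
and t-transform p; Bonferroni as min(1, p·m) with the family size an
explicit parameter. Outlier exclusion is single-pass per group per
measure: drop |x − mean| > 2 sd (sample sd); with n < 3 nothing is
excluded.

**Calibration caveat.** The t layer itself is exactly calibrated (null
rejection ≈ 5 %), but per-group 2-SD exclusion before a t-test is
anticonservative: at n = 16/35 it roughly doubles the null rejection rate
(~10 %), because trimming tails shrinks the variance estimate more than the
mean difference. The pipeline keeps the exclusion rule available (it is
part of the emulated design) but the calibration studies report both rates,
and `compare_groups(..., threshold_sd=None)` disables exclusion.

## Problem sizes in tests and the acceptance script

Recovery studies use 100 subjects/agents/seeds per condition, type-I
calibration 1000 null cohorts, power 500 replicates — sizes at which
Monte-Carlo error is well inside every stated tolerance. The full suite
runs in well under a minute on one core apart from the 100-subject EEG
recovery (~10 s).
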