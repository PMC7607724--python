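# Methods

`pupilgaze` analyzes within-subject 2×2 listening experiments in which a
speech-clarity factor (high vs. low SNR) is crossed with a linguistic
factor (low- vs. high-ambiguity sentences), and the dependent measures are
task-evoked pupil dilation, microsaccade rate, and comprehension accuracy.
This note documents the models, the numeric choices, what the synthetic
data emulate, and the known limitations.

## Pupil preprocessing

Stages run in a fixed order: blink masking → MAD outlier masking → trial
exclusion → linear interpolation → low-pass filtering → baseline
correction.

- **Blink masking.** Device-flagged blink intervals are expanded by 50 ms
  before and 200 ms after (closed intervals on the sample grid) and set to
  NaN. Overlapping expanded windows merge naturally.
- **Outlier masking.** Samples whose distance from the trial median
  exceeds 3× the raw median absolute deviation are NaN-ed. The MAD carries
  no 1.4826 normality factor, and the statistics are computed over the
  whole recorded trial *after* blink masking, so blink samples cannot
  poison them. The boundary is strict (a constant trace masks nothing).
  Note a structural consequence: for near-Gaussian noise the 3×MAD rule
  marks about 4.3% of samples (threshold ≈ 2.02 σ), which sets a floor on
  the interpolated-sample fraction in simulation.
- **Exclusion.** A trial is dropped when more than 40% (strictly) of the
  samples from 0.5 s before sentence onset to 1 s after sentence offset
  are NaN, judged on the pre-interpolation mask — the NaN percentage is
  only well-defined before interpolation. Exactly 40.0% is kept.
- **Interpolation.** Interior NaN runs are linearly interpolated between
  bracketing finite samples; leading/trailing runs are filled with the
  nearest finite value.
- **Filtering.** 201-tap linear-phase FIR low-pass at 10 Hz, designed by
  the Kaiser-window method. β defaults to 5.0 (≈50 dB sidelobes); the
  design sources fix cutoff and length but not β. The filter is applied
  with reflection padding and group-delay compensation, so the output is
  time-aligned (zero net phase — consistent with the zero-phase-lag
  smoothing used for rate curves) with exactly unit DC gain. Measured
  contracts: 2 Hz gain within 1%, 50 Hz gain < 0.1%.
- **Baseline.** The mean over the closed-open window [−0.5 s, 0 s) is
  subtracted; closed-open avoids counting the onset sample in the
  baseline. Re-application yields a baseline of 0 to within 1e-9.

## Pupil metrics

All three measures live in the window from 0.5 s after sentence onset to
1 s after sentence offset, which tracks each sentence's duration. Mean
dilation is the window average; peak dilation is the window maximum; peak
latency is the time of that maximum relative to sentence onset, first
occurrence on ties. (Latency could equally be referenced to the window
start — a constant 0.5 s shift that cannot affect any ANOVA.) Trial values
are averaged per participant and condition cell; participants missing a
cell entirely are dropped listwise with a warning, because the
repeated-measures analyses need complete cells.

Behavioral scoring: a response is correct when the keypress matches the
probe's ground-truth relatedness. Timeouts are scored incorrect by
default; a configurable policy excludes them instead, since the scoring
of non-responses is genuinely underdetermined.

## Microsaccade detection

The detector is the standard relative-velocity-threshold family
(Engbert–Kliegl). Gaze position is differentiated with the 5-point stencil
v_i = (p_{i+2} + p_{i+1} − p_{i−1} − p_{i−2}) / (6Δt), exact for
quadratic position profiles. Per component, σ is estimated by the robust
median estimator σ² = median(v²) − median(v)², and the threshold is
η = 15σ. A configurable floor σ_min = 0.01 deg/s prevents zero thresholds
on noise-free synthetic gaze. Note that for Gaussian velocity noise the
median estimator returns ≈0.675 of the true standard deviation, so "15σ"
sits at ≈10 true standard deviations; both conventions appear in the
literature, and the multiplier is configurable.

Candidate samples satisfy the elliptic criterion
(vx/ηx)² + (vy/ηy)² > 1 (a scalar speed criterion is available as a
config switch); maximal candidate runs persisting ≥ 6 ms become events.
Event duration counts the full extent of the run (n samples × Δt), and
events overlapping expanded blink windows are discarded. No merging of
events across sub-threshold gaps is performed. Because the threshold is a
multiple of the trial's own velocity variability, detection is invariant
to affine changes of gaze units.

A boundary subtlety: the 5-point stencil spreads a step-like displacement
over ≈5 samples of velocity, so a sufficiently violent sub-6-ms
displacement can still produce a ≥6 ms suprathreshold run. The 6 ms
persistence rule is the rejecting mechanism for brief transients whose
peak velocity is below about twice the threshold — the regime tested.

Rate curves place a unit-area Gaussian (σ = 0.02 s, zero phase lag) at
each event onset (midpoint optional) and sum, giving events/s; the mean
rate uses the same analysis window as the pupil metrics.

## Statistics

Every test reduces to contrast scores, because all factors have two
levels: for each effect the per-participant score is a (level-mean)
difference — double difference for the interaction — and
F(1, n−1) = t², with partial η² = SS_effect/(SS_effect + SS_error).
No sphericity correction is applied anywhere: with two levels per factor
sphericity holds trivially. Zero-variance degenerate inputs report F = 0,
p = 1 with a logged warning rather than NaN, keeping simulation sweeps
total.

The pooled two-experiment analysis is a split-plot: the between-subjects
factor is tested against between-subject error on participant means, and
each within effect and its Experiment crossing comes from a regression of
the contrast scores on (intercept, effect-coded group), giving
df_den = N − 2 and Type III sums of squares that remain correct with
unequal group sizes (38 vs. 35). Simple effects are paired tests on the
two cells at a fixed level of the other factor, using that level's own
paired error term.

The "effect of Clarity larger than effect of Ambiguity" contrast is a
one-sample F(1, n−1) on the per-participant difference of signed effect
scores d_C − d_A; an absolute-value variant is available, since the
construction is not uniquely determined by the reported statistic alone.

Partial correlations residualize both variables on (1, covariate) by
least squares and test the Pearson correlation of residuals with
t = r√(df/(1−r²)), df = n − 3.

## Acoustic masking

SNR is defined as 20·log10(RMS_target/RMS_masker) — the field's RMS-power
convention — and `mix_at_snr` rescales the designated component so the
re-measured SNR is exact to 1e-6 dB. The envelope-modulated pink masker
imposes the target's Hilbert amplitude envelope, low-pass filtered at
30 Hz with a 4th-order Butterworth applied forward-backward (zero phase;
the order and phase handling are design choices), on 1/f noise built by
spectral shaping. Babble averages 30 independent random-order
concatenations of the sentence set, truncated to the shortest stream.
Stimulus framing places 3 s of masker before onset and 1.2 s after
offset with 10 ms linear on/off ramps; the total length is exactly
lead + signal + tail in samples. RMS normalization matches stimuli to a
target RMS to 1e-9 relative tolerance.

## Synthetic data generator

The generator emulates the study design end to end: per participant, 4
blocks × 28 trials (7 per cell), ordered by rejection sampling under the
run-length caps (no more than 3 consecutive equal ambiguity labels, no
more than 2 consecutive equal clarity labels; bounded at 10,000 tries,
never silently relaxed; uniformity over admissible orders is not
claimed). Sentence durations are uniform on [1.4, 4.8] s, traces span
[−3 s, offset + 1.2 s] at 500 Hz.

Pupil model: tonic level + per-trial linear drift + amplitude × evoked
shape + white Gaussian noise. The evoked shape is a boxcar spanning the
sentence convolved with the two-parameter gamma-family pupil impulse
response h(t) ∝ t^n·e^(−nt/t_max) (n = 10.1, t_max = 0.93 s) and
peak-normalized per trial, so "amplitude" is the evoked peak in pupil
a.u. The trial amplitude is base + β_clarity·[low SNR] +
β_ambiguity·[HA] + β_interaction·[both], plus participant-level random
intercepts (SD 8 a.u.) and random effect slopes (SD 12 a.u.) — the
dominant source of between-subject variance in group contrasts, chosen
so that group-level F statistics land in the range typical of
pupillometry designs of this size. Defaults: tonic 1000, base amplitude
20, β = (10, 6, −4) a.u. (the negative interaction emulates sub-additive
combination of challenges), trace noise SD 20, drift SD 30. Blinks are
Poisson intervals (0.1 /s, 0.1–0.35 s) NaN-ed at source; spikes are
isolated ±100 a.u. samples (0.2 /s).

Gaze: white fixational jitter (SD 0.01°) plus ballistic microsaccades
from an inhomogeneous Poisson process (base 1.5 /s with ±0.25 /s
between-participant spread) with Gaussian-profile post-onset inhibition
(depth 0.7 at 0.3 s, width 0.2 s), thinning-sampled. Each event has a
raised-cosine velocity profile; amplitudes are uniform on [0.15°, 0.8°],
durations ~2/slope scaled by U(0.7, 1.3) with main-sequence slope 100/s,
giving 14–26 ms durations. Responses are Bernoulli with per-condition
accuracies in the high-intelligibility range (0.82–0.92 by default) and
a 2% timeout rate.

All response-model shapes and magnitudes are stand-in surrogates — the
analysis pipeline's sources specify no generative model in arbitrary
units. What passing tests on these data show is that the pipeline
recovers what was injected under realistic artifact levels; they cannot
certify behavior on features the generator lacks: pupil foreshortening
and gaze-position artifacts, temporally correlated (1/f-like) pupil
noise, heavy-tailed artifact distributions, saccadic drift/tremor
microstructure, or session-level nonstationarity. One visible
consequence: the simulated interpolated-sample fraction (~8%) exceeds
what clean laboratory recordings show, because white Gaussian noise
pins the 3×MAD rule at its ~4.3% floor and blinks add the rest.

## Problem sizes for replicated checks

Replicated statistical checks (type-I calibration over 500 simulated
experiments with all β = 0; 100-replicate power/recovery runs) use
reduced traces — 100 Hz sampling, fixed 1.4 s sentences, 0.6 s pre-onset
and 1.0 s tail — which keep every analysis window and the 201-tap filter
valid while making per-experiment simulation cheap. The full-scale study
simulation used for the reported worked example runs at 250 Hz with the
complete duration range. These sizes are package choices for routine
verification; all windows, rules, and thresholds are identical to the
500 Hz configuration.

## Degenerate inputs and tie-breaks

Ties in the peak search take the first occurrence. All-NaN pupil input is
a hard error at the outlier stage (a fully blinked trial is excluded with
reason `nan_fraction`). Traces shorter than the filter are excluded with
reason `too_short`. A zero-RMS masker or silent normalization input is a
hard error. Constant-covariate partial correlation is refused with a
pointer to the plain correlation.
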