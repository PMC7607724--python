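# pupilgaze

Task-evoked pupillometry and microsaccade analysis for listening-effort
experiments.

Hearing scientists use pupil dilation as a physiological index of the
cognitive demand of listening: the pupil dilates more when speech is
masked by noise, and when the linguistic content is harder to process
(for example, sentences containing semantically ambiguous words).
`pupilgaze` implements the complete analysis chain for within-subject
2×2 designs crossing a speech-**Clarity** factor (high vs. low SNR) with
a semantic-**Ambiguity** factor (low- vs. high-ambiguity sentences):

- **Pupil preprocessing** — blink masking (−50 ms/+200 ms around each
  device-flagged blink → NaN), 3×MAD outlier removal, linear
  interpolation, trial exclusion when >40% of the samples from −0.5 s to
  offset+1 s are NaN, 10 Hz zero-net-phase FIR low-pass (Kaiser window,
  201 taps), and baseline correction against the [−0.5, 0) s pre-onset
  window.
- **Pupil metrics** — mean dilation, peak dilation and peak latency in
  the window from 0.5 s post-onset to 1 s post-offset, averaged per
  participant × condition cell.
- **Microsaccades** — Engbert–Kliegl-style detection (5-point velocity
  transform, relative threshold at 15× a median-based velocity SD,
  ≥ 6 ms persistence), Gaussian-kernel rate curves (σ = 0.02 s, unit
  area per event), and windowed mean rates.
- **Statistics, from scratch** — 2×2 repeated-measures ANOVAs with
  partial η² (every 1-df within-subject F equals the squared paired t),
  simple effects, the pooled split-plot design with Experiment as a
  between-subjects factor, an effect-magnitude contrast (is the Clarity
  effect larger than the Ambiguity effect?), and partial correlations
  with df = n − 3.
- **Acoustic masking** — 30-stream babble synthesis, envelope-modulated
  pink-noise maskers (Hilbert envelope, 30 Hz Butterworth, zero phase),
  exact RMS-based SNR mixing, 3 s lead / 1.2 s tail framing with 10 ms
  ramps, and RMS normalization.
- **Synthetic data** — a generator that emulates the full study (500 Hz
  traces, 3 s baseline, 1.4–4.8 s sentences, blinks, spikes, drift,
  condition-dependent evoked responses built from the gamma-family pupil
  impulse response, fixational gaze noise with ballistic microsaccades
  and post-onset inhibition, Bernoulli responses) with complete ground
  truth, so every stage is testable without any recordings.

For the model details, defaults and limitations see
[docs/methods.md](docs/methods.md).

## Worked example

```python
from pupilgaze import SimConfig, simulate_experiment, analyze_experiment

cfg = SimConfig(n_participants=24, seed=42, sampling_rate=250.0)
trials, traces, truth = simulate_experiment(cfg)
result = analyze_experiment(trials, traces)
for r in result.anovas["mean_dilation"]:
    print(f"  {r.effect}: F(1, {r.df_den}) = {r.F:.2f}, p = {r.p:.4f}, "
          f"partial eta^2 = {r.partial_eta_sq:.3f}")
```

prints (group cell means LA_high 16.01, HA_high 23.34, LA_low 23.42,
HA_low 26.27 a.u.; 3 of 2688 trials excluded):

```
  Clarity: F(1, 23) = 7.35, p = 0.0124, partial eta^2 = 0.242
  Ambiguity: F(1, 23) = 6.92, p = 0.0150, partial eta^2 = 0.231
  Clarity x Ambiguity: F(1, 23) = 4.81, p = 0.0387, partial eta^2 = 0.173
```

Pupil dilation is larger for low-SNR and for high-ambiguity sentences —
the generator's injected Clarity and Ambiguity effects (10 and 6 a.u. on
the evoked peak) recovered at the group level, with the negative injected
interaction visible as the sub-additive HA_low cell.

The same pipeline runs from the shell:

```sh
pupilgaze simulate --out data/ --seed 7          # synthetic dataset + truth
pupilgaze run --config study.yaml --out results/ # simulate/ingest + analyze
pupilgaze preprocess --data data/ --out clean/   # stage-by-stage verbs:
pupilgaze metrics --data data/ --out tables/     #   exclusions, tables,
pupilgaze microsaccades --data data/ --out ms/   #   events, rate curves
pupilgaze stats --tables tables/ --design within2x2 --out report.json
pupilgaze mask --target s.wav --mode env_pink --snr -2 --out masked.wav
```

All inputs and outputs are plain CSV/JSON (samples as `t,pupil,gaze_x,
gaze_y`; blinks as `start_s,end_s`; one condition table per measure),
plus WAV for the masking verbs. A `manifest.json` snapshot of every
config value and seed makes each run reproducible.

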