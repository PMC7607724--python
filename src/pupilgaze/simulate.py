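"""Synthetic eye-tracking experiments with known ground truth.

Generates complete two-factor (Clarity x Ambiguity) listening experiments:
500 Hz pupil-area traces with a pre-onset baseline, condition-dependent
task-evoked dilation, slow drift, blinks, outlier spikes; fixational gaze
noise with superposed ballistic microsaccades; and Bernoulli behavioral
responses. Every injected event is recorded in a ground-truth object so each
downstream analysis stage can be validated against what was actually put in.

The evoked pupil response is modeled as a boxcar demand pulse spanning the
sentence convolved with the standard two-parameter gamma-family pupil
impulse response h(t) = t^n * exp(-n*t/t_max) (n = 10.1, t_max = 0.93 s),
peak-normalized so that the trial's "amplitude" parameter is the peak of the
evoked component in pupil a.u. The source study specifies no response model
or effect magnitudes in a.u.; these shapes and the default amplitudes are
stand-in surrogates chosen to look like typical task-evoked pupil data, not
values estimated from any dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .data import SampleTrace, TrialInfo

__all__ = [
    "SimConfig",
    "GroundTruth",
    "GenerationError",
    "condition_order",
    "pupil_irf",
    "simulate_experiment",
]


class GenerationError(RuntimeError):
    """Constraint-satisfying generation failed within the retry budget."""


def _default_accuracy() -> dict:
    # stand-in per-condition probabilities in the >0.8 range typical of a
    # highly intelligible speech task, with the low-SNR/high-ambiguity cell
    # hardest
    return {
        ("high_snr", "LA"): 0.92,
        ("high_snr", "HA"): 0.92,
        ("low_snr", "LA"): 0.88,
        ("low_snr", "HA"): 0.82,
    }


@dataclass
class SimConfig:
    """Parameters of one simulated experiment.

    Amplitude parameters are in pupil a.u. (the evoked-response peak).
    ``beta_clarity`` adds to low-SNR trials, ``beta_ambiguity`` to
    high-ambiguity trials, ``beta_interaction`` to the low-SNR/HA cell.
    """

    n_participants: int = 10
    n_trials_per_condition: int = 28  # split over n_blocks blocks
    n_blocks: int = 4
    sampling_rate: float = 500.0
    pre_onset_s: float = 3.0
    tail_s: float = 1.2
    duration_range_s: tuple = (1.4, 4.8)
    experiment: int = 1

    tonic_pupil: float = 1000.0
    response_amplitude_base: float = 20.0
    beta_clarity: float = 10.0
    beta_ambiguity: float = 6.0
    beta_interaction: float = -4.0
    pupil_irf_shape_n: float = 10.1
    pupil_irf_tmax_s: float = 0.93
    noise_sd: float = 20.0
    drift_sd: float = 30.0  # a.u. of net drift over one trial
    subject_amplitude_sd: float = 8.0  # between-participant base amplitude
    subject_effect_sd: float = 12.0  # between-participant effect slopes

    blink_rate_hz: float = 0.1
    blink_duration_range_s: tuple = (0.1, 0.35)
    spike_rate_hz: float = 0.2
    spike_magnitude: float = 100.0

    fixation_noise_sd_deg: float = 0.01
    ms_base_rate_hz: float = 1.5
    ms_subject_rate_sd_hz: float = 0.25  # between-participant rate spread
    ms_inhibition_depth: float = 0.7
    ms_inhibition_t_s: float = 0.3
    ms_inhibition_width_s: float = 0.2
    ms_amplitude_range_deg: tuple = (0.15, 0.8)
    ms_main_sequence_slope: float = 100.0  # peak velocity ~ slope * amplitude

    accuracy: dict = field(default_factory=_default_accuracy)
    timeout_prob: float = 0.02
    max_run_ambiguity: int = 3
    max_run_clarity: int = 2
    seed: int = 0

    def validate(self) -> None:
        errors = []
        for cond, p in self.accuracy.items():
            if not (0.0 <= p <= 1.0):
                errors.append(f"accuracy[{cond}] = {p} outside [0, 1]")
        for name in ("blink_rate_hz", "spike_rate_hz", "ms_base_rate_hz",
                     "noise_sd", "drift_sd"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be nonnegative")
        if not (0.0 <= self.ms_inhibition_depth <= 1.0):
            errors.append("ms_inhibition_depth must lie in [0, 1]")
        if not (0.0 <= self.timeout_prob <= 1.0):
            errors.append("timeout_prob must lie in [0, 1]")
        if self.n_trials_per_condition % self.n_blocks:
            errors.append("n_trials_per_condition must divide evenly into "
                          "n_blocks blocks")
        if errors:
            raise ValueError("invalid SimConfig: " + "; ".join(errors))


@dataclass
class GroundTruth:
    """Per-trial record of everything the generator injected."""

    amplitude: float
    blink_intervals: list
    spike_indices: list
    microsaccades: list  # (onset_s, duration_s, amplitude_deg, direction_rad)
    is_correct: bool


# ---------------------------------------------------------------------------
# condition ordering
# ---------------------------------------------------------------------------


def _max_run(labels) -> int:
    arr = np.asarray(labels)
    if arr.size == 0:
        return 0
    # boundaries of constant runs -> longest gap between change points
    change = np.flatnonzero(arr[1:] != arr[:-1])
    edges = np.concatenate(([-1], change, [arr.size - 1]))
    return int(np.max(np.diff(edges)))


def condition_order(
    n_per_cond: int,
    max_run_ambiguity: int = 3,
    max_run_clarity: int = 2,
    rng: np.random.Generator | int | None = None,
    max_tries: int = 10_000,
) -> list[tuple[str, str]]:
    """Pseudorandom order of the four (clarity, ambiguity) cells.

    Returns a permutation of ``n_per_cond`` copies of each cell with no run
    of more than *max_run_ambiguity* equal ambiguity labels and no run of
    more than *max_run_clarity* equal clarity labels. Rejection sampling
    with a bounded retry budget; uniformity over admissible orders is not
    claimed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cells = [(c, a) for c in ("high_snr", "low_snr") for a in ("LA", "HA")]
    pool = np.array([i for i in range(4) for _ in range(n_per_cond)])
    n = pool.size

    def _violates(labels: np.ndarray, cap: int) -> np.ndarray:
        """Rows containing a run longer than cap (run > cap <=> cap
        consecutive equal-neighbor pairs)."""
        if labels.shape[1] <= cap:
            return np.zeros(labels.shape[0], dtype=bool)
        same = labels[:, 1:] == labels[:, :-1]
        win = np.lib.stride_tricks.sliding_window_view(same, cap, axis=1)
        return win.all(axis=-1).any(axis=1)

    batch = 128
    tried = 0
    while tried < max_tries:
        m = min(batch, max_tries - tried)
        # batch of random permutations via argsort of random keys
        perms = pool[np.argsort(rng.random((m, n)), axis=1)]
        # cell index encodes clarity in bit 1 and ambiguity in bit 0
        ok = ~(_violates(perms & 1, max_run_ambiguity)
               | _violates(perms >> 1, max_run_clarity))
        hits = np.flatnonzero(ok)
        if hits.size:
            return [cells[i] for i in perms[hits[0]]]
        tried += m
    raise GenerationError(
        f"no admissible condition order found in {max_tries} tries "
        f"(n_per_cond={n_per_cond})")


# ---------------------------------------------------------------------------
# pupil response model
# ---------------------------------------------------------------------------


def pupil_irf(t: np.ndarray, shape_n: float = 10.1,
              tmax_s: float = 0.93) -> np.ndarray:
    """Gamma-family pupil impulse response, peak-normalized to 1 at tmax."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = (t[pos] / tmax_s) ** shape_n * np.exp(
        shape_n * (1.0 - t[pos] / tmax_s))
    return out


def _evoked_shape(n_samples: int, onset_idx: int, dur_samples: int,
                  fs: float, shape_n: float, tmax_s: float) -> np.ndarray:
    """Boxcar (sentence span) convolved with the IRF, peak-normalized."""
    box = np.zeros(n_samples)
    box[onset_idx:onset_idx + dur_samples] = 1.0
    # IRF support: 4 s covers the rise and most of the decay at tmax=0.93
    s = np.arange(0, int(round(4.0 * fs))) / fs
    h = pupil_irf(s, shape_n, tmax_s)
    resp = fftconvolve(box, h)[:n_samples]
    peak = resp.max()
    if peak > 0:
        resp /= peak
    return resp


# ---------------------------------------------------------------------------
# per-trial generation
# ---------------------------------------------------------------------------


def _raised_cosine_displacement(n: int) -> np.ndarray:
    """Normalized ballistic displacement profile (0 -> 1) over n samples."""
    u = np.arange(1, n + 1) / n
    return u - np.sin(2 * np.pi * u) / (2 * np.pi)


def _place_microsaccades(cfg: SimConfig, rng: np.random.Generator,
                         t: np.ndarray, base: float) -> list:
    """Inhomogeneous Poisson onsets (post-onset inhibition) by thinning."""
    span = t[-1] - t[0]
    if base <= 0:
        return []
    n_cand = rng.poisson(base * span)
    onsets = np.sort(rng.uniform(t[0], t[-1], size=n_cand))
    keep = []
    for on in onsets:
        rate = base * (1.0 - cfg.ms_inhibition_depth * math.exp(
            -0.5 * ((on - cfg.ms_inhibition_t_s)
                    / cfg.ms_inhibition_width_s) ** 2)) if on >= 0 else base
        if rng.uniform() <= rate / base:
            keep.append(on)
    events = []
    mean_dur = 2.0 / cfg.ms_main_sequence_slope
    last_end = -np.inf
    for on in keep:
        dur = mean_dur * rng.uniform(0.7, 1.3)
        amp = rng.uniform(*cfg.ms_amplitude_range_deg)
        direction = rng.uniform(0, 2 * np.pi)
        # drop overlapping events and ones that would run off the trace
        if on <= last_end + 0.01 or on + dur >= t[-1] - 0.01 or on <= t[0] + 0.01:
            continue
        events.append((float(on), float(dur), float(amp), float(direction)))
        last_end = on + dur
    return events


def _simulate_trial(
    cfg: SimConfig,
    rng: np.random.Generator,
    clarity: str,
    ambiguity: str,
    duration_s: float,
    t: np.ndarray,
    evoked: np.ndarray,
    subject_effects: tuple[float, float, float, float],
    subject_ms_rate: float,
) -> tuple[SampleTrace, GroundTruth, bool, str, float | None]:
    fs = cfg.sampling_rate
    n = t.size
    span = t[-1] - t[0]

    base_i, beta_c_i, beta_a_i, beta_x_i = subject_effects
    amp = (cfg.response_amplitude_base + base_i
           + (cfg.beta_clarity + beta_c_i if clarity == "low_snr" else 0.0)
           + (cfg.beta_ambiguity + beta_a_i if ambiguity == "HA" else 0.0)
           + (cfg.beta_interaction + beta_x_i
              if (clarity == "low_snr" and ambiguity == "HA") else 0.0))

    drift_slope = rng.normal(0.0, cfg.drift_sd) / span if cfg.drift_sd > 0 else 0.0
    pupil = cfg.tonic_pupil + drift_slope * (t - t[0]) + amp * evoked
    if cfg.noise_sd > 0:
        pupil = pupil + rng.normal(0.0, cfg.noise_sd, size=n)

    # outlier spikes: isolated large-deviation samples
    spike_idx: list[int] = []
    if cfg.spike_rate_hz > 0:
        n_spikes = rng.poisson(cfg.spike_rate_hz * span)
        if n_spikes:
            spike_idx = sorted(
                int(i) for i in rng.choice(n, size=min(n_spikes, n),
                                           replace=False))
            signs = rng.choice([-1.0, 1.0], size=len(spike_idx))
            pupil[spike_idx] += signs * cfg.spike_magnitude

    # blinks: Poisson-placed intervals where the device reports no pupil
    blinks: list[tuple[float, float]] = []
    if cfg.blink_rate_hz > 0:
        n_blinks = rng.poisson(cfg.blink_rate_hz * span)
        starts = np.sort(rng.uniform(t[0], t[-1], size=n_blinks))
        for s in starts:
            d = rng.uniform(*cfg.blink_duration_range_s)
            e = min(s + d, t[-1])
            if blinks and s <= blinks[-1][1]:
                blinks[-1] = (blinks[-1][0], max(blinks[-1][1], e))
            else:
                blinks.append((float(s), float(e)))
        for (s, e) in blinks:
            pupil[(t >= s - 1e-9) & (t <= e + 1e-9)] = np.nan

    # gaze: fixational noise plus ballistic microsaccades
    gaze_x = rng.normal(0.0, cfg.fixation_noise_sd_deg, size=n)
    gaze_y = rng.normal(0.0, cfg.fixation_noise_sd_deg, size=n)
    events = _place_microsaccades(cfg, rng, t, subject_ms_rate)
    for (on, dur, ampl, direction) in events:
        i0 = int(np.searchsorted(t, on - 1e-9))
        n_ms = max(2, int(round(dur * fs)))
        i1 = min(i0 + n_ms, n)
        prof = _raised_cosine_displacement(i1 - i0) * ampl
        gaze_x[i0:i1] += prof * math.cos(direction)
        gaze_y[i0:i1] += prof * math.sin(direction)
        gaze_x[i1:] += ampl * math.cos(direction)
        gaze_y[i1:] += ampl * math.sin(direction)

    # behavior
    p_correct = cfg.accuracy[(clarity, ambiguity)]
    probe_related = bool(rng.uniform() < 0.5)
    correct = bool(rng.uniform() < p_correct)
    if rng.uniform() < cfg.timeout_prob:
        response, rt, correct = "none", None, False
    else:
        if correct:
            response = "related" if probe_related else "unrelated"
        else:
            response = "unrelated" if probe_related else "related"
        rt = float(min(3.5, 0.3 + rng.lognormal(mean=-0.3, sigma=0.5)))

    # arrays are constructed on the shared validated grid; skip the
    # uniform-spacing re-check for speed
    trace = object.__new__(SampleTrace)
    trace.sampling_rate = fs
    trace.t = t
    trace.pupil = pupil
    trace.gaze_x = gaze_x
    trace.gaze_y = gaze_y
    trace.blink_intervals = blinks
    truth = GroundTruth(
        amplitude=float(amp),
        blink_intervals=list(blinks),
        spike_indices=spike_idx,
        microsaccades=events,
        is_correct=correct,
    )
    return trace, truth, probe_related, response, rt


def simulate_experiment(
    cfg: SimConfig,
) -> tuple[list[TrialInfo], list[SampleTrace], list[GroundTruth]]:
    """Generate a full experiment: trials, traces and ground truth.

    Per participant, ``n_blocks`` blocks of pseudorandomly ordered trials
    (run-length caps on both factors), each trial a fresh trace. Output is
    deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate
    per_block = cfg.n_trials_per_condition // cfg.n_blocks
    lo, hi = cfg.duration_range_s

    # shared time grids / evoked shapes cached by sample count
    grid_cache: dict[int, np.ndarray] = {}
    evoked_cache: dict[tuple[int, int], np.ndarray] = {}
    pre_n = int(round(cfg.pre_onset_s * fs))

    trials: list[TrialInfo] = []
    traces: list[SampleTrace] = []
    truths: list[GroundTruth] = []
    for p in range(cfg.n_participants):
        pid = f"P{p + 1:03d}"
        # participant-level random intercept (overall responsiveness) and
        # random slopes (idiosyncratic effect sizes), the dominant source of
        # between-subject variance in group-level contrasts
        base_i = rng.normal(0.0, cfg.subject_amplitude_sd) \
            if cfg.subject_amplitude_sd > 0 else 0.0
        slopes = rng.normal(0.0, cfg.subject_effect_sd, size=3) \
            if cfg.subject_effect_sd > 0 else np.zeros(3)
        subject_effects = (base_i, float(slopes[0]), float(slopes[1]),
                           float(slopes[2]))
        subject_ms_rate = max(0.0, cfg.ms_base_rate_hz + (
            rng.normal(0.0, cfg.ms_subject_rate_sd_hz)
            if cfg.ms_subject_rate_sd_hz > 0 else 0.0))
        for block in range(1, cfg.n_blocks + 1):
            order = condition_order(per_block, cfg.max_run_ambiguity,
                                    cfg.max_run_clarity, rng)
            for (clarity, ambiguity) in order:
                duration = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
                dur_n = max(1, int(round(duration * fs)))
                n = pre_n + dur_n + int(round(cfg.tail_s * fs)) + 1
                if n not in grid_cache:
                    grid_cache[n] = (np.arange(n) - pre_n) / fs
                t = grid_cache[n]
                ck = (n, dur_n)
                if ck not in evoked_cache:
                    evoked_cache[ck] = _evoked_shape(
                        n, pre_n, dur_n, fs,
                        cfg.pupil_irf_shape_n, cfg.pupil_irf_tmax_s)
                trace, truth, probe_related, response, rt = _simulate_trial(
                    cfg, rng, clarity, ambiguity, duration, t,
                    evoked_cache[ck], subject_effects, subject_ms_rate)
                trials.append(TrialInfo(
                    participant_id=pid,
                    experiment=cfg.experiment,
                    block=block,
                    clarity=clarity,
                    ambiguity=ambiguity,
                    sentence_duration_s=duration,
                    probe_related=probe_related,
                    response=response,
                    response_time_s=rt,
                ))
                traces.append(trace)
                truths.append(truth)
    return trials, traces, truths
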