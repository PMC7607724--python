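"""Pupil-trace preprocessing: artifact removal, exclusion, filtering, baseline.

The stages run in a fixed order — blink masking, MAD outlier masking, linear
interpolation, trial exclusion, 10 Hz low-pass filtering, baseline
correction — and each is available separately. Exclusion is judged on the
pre-interpolation NaN mask within the window from 0.5 s before sentence
onset to 1 s after sentence offset: a trial with more than 40% NaN there is
dropped.

The low-pass filter is a 201-tap linear-phase FIR designed by the Kaiser
window method (cutoff 10 Hz at the trace's sampling rate). It is applied
with group-delay compensation and reflection padding, so the output is
time-aligned with the input (zero net phase) and has exactly unit DC gain.
MAD is the raw median absolute deviation, with no normality scaling factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import firwin

from .data import TIME_EPS, PipelineConfig, SampleTrace, TrialInfo

__all__ = [
    "CleanTrial",
    "PreprocessError",
    "mask_blinks",
    "mask_outliers",
    "interpolate_gaps",
    "exclusion_decision",
    "lowpass_10hz",
    "baseline_correct",
    "preprocess_trial",
]


class PreprocessError(ValueError):
    """A preprocessing stage received degenerate or invalid input."""


@dataclass
class CleanTrial:
    """A preprocessed pupil trace or an exclusion verdict.

    When ``excluded`` is True, only ``nan_fraction`` and the reason are
    meaningful; ``trace`` and ``baseline_mean`` are None.
    """

    trace: SampleTrace | None
    baseline_mean: float | None
    nan_fraction: float
    n_interpolated: int
    excluded: bool
    exclusion_reason: str  # none | nan_fraction | too_short


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def mask_blinks(trace: SampleTrace, cfg: PipelineConfig) -> SampleTrace:
    """NaN the pupil from 50 ms before to 200 ms after each device blink.

    The window is closed on both ends; overlapping expanded windows merge
    naturally. Gaze channels are untouched (blink handling for gaze happens
    in microsaccade detection).
    """
    if not trace.blink_intervals:
        return trace.copy()
    out = trace.copy()
    for (s, e) in trace.blink_intervals:
        lo = s - cfg.blink_pre_s
        hi = e + cfg.blink_post_s
        out.pupil[(out.t >= lo - TIME_EPS) & (out.t <= hi + TIME_EPS)] = np.nan
    return out


def mask_outliers(trace: SampleTrace, cfg: PipelineConfig) -> SampleTrace:
    """NaN pupil samples further than ``mad_k`` raw MADs from the median.

    Median and MAD are computed over the finite samples of the whole trial
    (after blink masking, so blink samples do not contribute). The boundary
    is strict: |x - median| must exceed mad_k * MAD.
    """
    x = trace.pupil
    finite = np.isfinite(x)
    if finite.all():
        xf = x
    elif finite.any():
        xf = x[finite]
    else:
        raise PreprocessError("all pupil samples are NaN; cannot compute "
                              "outlier statistics")
    med = float(np.median(xf))
    mad = float(np.median(np.abs(xf - med)))
    out = trace.copy()
    with np.errstate(invalid="ignore"):
        out.pupil[np.abs(x - med) > cfg.mad_k * mad] = np.nan
    return out


def interpolate_gaps(trace: SampleTrace) -> SampleTrace:
    """Linearly interpolate interior NaN runs; extend edges with the nearest
    finite value."""
    finite = np.isfinite(trace.pupil)
    n_finite = int(finite.sum())
    if n_finite < 2:
        raise PreprocessError(
            f"need at least 2 finite pupil samples to interpolate, "
            f"have {n_finite}")
    out = trace.copy()
    if n_finite < trace.pupil.size:
        out.pupil = np.interp(trace.t, trace.t[finite], trace.pupil[finite])
    return out


def exclusion_decision(
    trace_preinterp: SampleTrace,
    trial: TrialInfo,
    cfg: PipelineConfig,
) -> tuple[float, bool]:
    """NaN fraction in the exclusion window and the (strict) >40% verdict.

    Computed on the pre-interpolation NaN mask over samples with t in
    [onset - 0.5 s, offset + 1 s] (closed).
    """
    lo = trial.sentence_onset_s + cfg.exclusion_window[0]
    hi = trial.sentence_offset_s + cfg.exclusion_window[1]
    t = trace_preinterp.t
    if lo < t[0] - TIME_EPS or hi > t[-1] + TIME_EPS:
        raise PreprocessError(
            f"exclusion window [{lo}, {hi}] outside recorded span "
            f"[{t[0]}, {t[-1]}]")
    in_win = (t >= lo - TIME_EPS) & (t <= hi + TIME_EPS)
    frac = float(np.mean(~np.isfinite(trace_preinterp.pupil[in_win])))
    return frac, frac > cfg.nan_frac_max


@lru_cache(maxsize=8)
def _fir_taps(fs: float, cutoff: float, length: int, beta: float) -> np.ndarray:
    return firwin(length, cutoff, window=("kaiser", beta), fs=fs)


def lowpass_10hz(trace: SampleTrace, cfg: PipelineConfig) -> SampleTrace:
    """Zero-net-phase 10 Hz FIR low-pass (Kaiser window, 201 taps).

    The linear-phase filter's group delay of (length-1)/2 samples is
    compensated by reflection-padding the input by that amount on both
    sides and taking the central 'valid' segment, so the output is the same
    length as, and time-aligned with, the input.
    """
    x = trace.pupil
    if not np.all(np.isfinite(x)):
        raise PreprocessError("pupil must be fully finite before filtering "
                              "(interpolate first)")
    if x.size <= cfg.fir_length:
        raise PreprocessError(
            f"trace of {x.size} samples is too short for a "
            f"{cfg.fir_length}-tap filter")
    taps = _fir_taps(trace.sampling_rate, cfg.lp_cutoff_hz,
                     cfg.fir_length, cfg.kaiser_beta)
    pad = (cfg.fir_length - 1) // 2
    # reflection padding (no edge duplication), cheaper than np.pad
    xe = np.concatenate([x[pad:0:-1], x, x[-2:-pad - 2:-1]])
    out = trace.copy()
    out.pupil = np.convolve(xe, taps, mode="valid")
    return out


def baseline_correct(
    trace: SampleTrace,
    cfg: PipelineConfig,
) -> tuple[SampleTrace, float]:
    """Subtract the mean pupil size over the pre-onset baseline window.

    The window is closed-open [start, end) — at the defaults, [-0.5 s, 0 s),
    so the sample at sentence onset itself is not part of the baseline.
    """
    lo, hi = cfg.baseline_window
    in_win = (trace.t >= lo - TIME_EPS) & (trace.t < hi - TIME_EPS)
    if not in_win.any():
        raise PreprocessError(
            f"baseline window [{lo}, {hi}) contains no samples")
    baseline = float(np.mean(trace.pupil[in_win]))
    out = trace.copy()
    out.pupil = trace.pupil - baseline
    return out, baseline


def preprocess_trial(
    trace: SampleTrace,
    trial: TrialInfo,
    cfg: PipelineConfig | None = None,
) -> CleanTrial:
    """Full preprocessing pipeline for one trial.

    Order: blink masking -> outlier masking -> exclusion decision (on the
    pre-interpolation NaN mask) -> interpolation -> low-pass filtering ->
    baseline correction. Excluded trials skip the later stages.
    """
    cfg = cfg or PipelineConfig()
    if trace.pupil.size <= cfg.fir_length:
        return CleanTrial(trace=None, baseline_mean=None, nan_fraction=1.0,
                          n_interpolated=0, excluded=True,
                          exclusion_reason="too_short")
    try:
        masked = mask_blinks(trace, cfg)
        masked = mask_outliers(masked, cfg)
    except PreprocessError:
        return CleanTrial(trace=None, baseline_mean=None, nan_fraction=1.0,
                          n_interpolated=0, excluded=True,
                          exclusion_reason="nan_fraction")
    nan_fraction, excluded = exclusion_decision(masked, trial, cfg)
    n_interp = int(np.sum(~np.isfinite(masked.pupil)))
    if excluded:
        return CleanTrial(trace=None, baseline_mean=None,
                          nan_fraction=nan_fraction, n_interpolated=n_interp,
                          excluded=True, exclusion_reason="nan_fraction")
    filled = interpolate_gaps(masked)
    filtered = lowpass_10hz(filled, cfg)
    corrected, baseline = baseline_correct(filtered, cfg)
    return CleanTrial(trace=corrected, baseline_mean=baseline,
                      nan_fraction=nan_fraction, n_interpolated=n_interp,
                      excluded=False, exclusion_reason="none")
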