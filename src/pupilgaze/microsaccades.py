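"""Velocity-threshold microsaccade detection and rate estimation.

Detection follows the classic relative-velocity-threshold family
(Engbert-Kliegl): gaze position is differentiated with a 5-point moving
window, a per-trial threshold is set at 15 times a median-based estimate of
the velocity standard deviation per component, candidate samples satisfy an
elliptic criterion (vx/eta_x)^2 + (vy/eta_y)^2 > 1, and maximal candidate
runs persisting 6 ms or longer become events. Because the threshold is a
multiple of the trial's own velocity variability, detection is invariant to
affine changes of gaze units.

Rate curves place a unit-area Gaussian (sigma = 0.02 s, zero phase lag) at
each event occurrence and sum; the mean rate is averaged over the same
analysis window as the pupil metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import TIME_EPS, PipelineConfig, SampleTrace, TrialInfo
from .metrics import metric_window

__all__ = [
    "MicrosaccadeEvent",
    "RateCurve",
    "gaze_velocity",
    "velocity_threshold",
    "detect_microsaccades",
    "rate_curve",
    "mean_rate",
]


@dataclass
class MicrosaccadeEvent:
    """One detected ballistic gaze event (times onset-relative, seconds).

    ``duration_s`` counts the full extent of the run of suprathreshold
    samples (n_samples / sampling_rate), and ``offset_s`` is defined as
    ``onset_s + duration_s``.
    """

    onset_s: float
    offset_s: float
    duration_s: float
    peak_velocity: float  # deg/s
    amplitude_deg: float  # net displacement onset -> offset


@dataclass
class RateCurve:
    """Microsaccade rate (events/s) on the source trace's time grid."""

    t: np.ndarray
    rate: np.ndarray


def gaze_velocity(trace: SampleTrace) -> tuple[np.ndarray, np.ndarray]:
    """5-point moving-window velocity of the gaze components, in deg/s.

    v_i = (p_{i+2} + p_{i+1} - p_{i-1} - p_{i-2}) / (6 * dt); exact for
    polynomial position profiles up to degree 2. The first and last two
    samples are undefined (NaN).
    """
    n = trace.t.size
    if n < 5:
        raise ValueError(f"need at least 5 samples for velocity, have {n}")
    dt = trace.dt
    vx = np.full(n, np.nan)
    vy = np.full(n, np.nan)
    for p, v in ((trace.gaze_x, vx), (trace.gaze_y, vy)):
        v[2:-2] = (p[4:] + p[3:-1] - p[1:-3] - p[:-4]) / (6.0 * dt)
    return vx, vy


def _blink_mask(trace: SampleTrace, cfg: PipelineConfig) -> np.ndarray:
    """True where a sample falls inside an expanded blink window."""
    mask = np.zeros(trace.t.size, dtype=bool)
    for (s, e) in trace.blink_intervals:
        mask |= ((trace.t >= s - cfg.blink_pre_s - TIME_EPS)
                 & (trace.t <= e + cfg.blink_post_s + TIME_EPS))
    return mask


def _median_sigma(v: np.ndarray) -> float:
    """Median-based velocity scale: sqrt(median(v^2) - median(v)^2)."""
    med = np.median(v)
    var = np.median(np.square(v)) - med * med
    return math.sqrt(max(var, 0.0))


def velocity_threshold(
    vx: np.ndarray,
    vy: np.ndarray,
    cfg: PipelineConfig | None = None,
) -> tuple[float, float]:
    """Per-component detection thresholds eta = k * sigma_median.

    A configurable floor on sigma (``ms_sigma_floor``, deg/s) prevents
    zero thresholds on noise-free synthetic gaze.
    """
    cfg = cfg or PipelineConfig()
    valid = np.isfinite(vx) & np.isfinite(vy)
    if valid.sum() < 100:
        raise ValueError(
            f"only {int(valid.sum())} valid velocity samples; need >= 100 "
            "for stable threshold statistics")
    etas = []
    for v in (vx[valid], vy[valid]):
        sigma = max(_median_sigma(v), cfg.ms_sigma_floor)
        etas.append(cfg.ms_threshold_k * sigma)
    return etas[0], etas[1]


def detect_microsaccades(
    trace: SampleTrace,
    cfg: PipelineConfig | None = None,
) -> list[MicrosaccadeEvent]:
    """Detect microsaccades in one trial's gaze trace.

    Candidate samples exceed the relative velocity threshold (elliptic
    criterion by default; a scalar speed criterion is available via
    ``cfg.ms_criterion``); maximal candidate runs persisting at least
    ``ms_min_duration_s`` become events. Samples inside expanded blink
    windows are excluded from detection, so no event overlaps a blink.
    """
    cfg = cfg or PipelineConfig()
    vx, vy = gaze_velocity(trace)
    blink = _blink_mask(trace, cfg)
    vx = np.where(blink, np.nan, vx)
    vy = np.where(blink, np.nan, vy)
    eta_x, eta_y = velocity_threshold(vx, vy, cfg)
    with np.errstate(invalid="ignore"):
        if cfg.ms_criterion == "elliptic":
            crit = (vx / eta_x) ** 2 + (vy / eta_y) ** 2 > 1.0
        else:  # scalar speed against the combined threshold
            crit = np.hypot(vx, vy) > math.hypot(eta_x, eta_y)
    crit &= np.isfinite(vx) & np.isfinite(vy)

    dt = trace.dt
    min_samples = int(math.ceil(cfg.ms_min_duration_s / dt - 1e-9))
    events: list[MicrosaccadeEvent] = []
    idx = np.flatnonzero(crit)
    if idx.size == 0:
        return events
    # split into maximal runs of consecutive indices
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    speed = np.hypot(vx, vy)
    for s, e in zip(starts, ends):
        i0, i1 = int(idx[s]), int(idx[e])
        n_run = i1 - i0 + 1
        if n_run < min_samples:
            continue
        duration = n_run * dt
        events.append(MicrosaccadeEvent(
            onset_s=float(trace.t[i0]),
            offset_s=float(trace.t[i0] + duration),
            duration_s=float(duration),
            peak_velocity=float(np.nanmax(speed[i0:i1 + 1])),
            amplitude_deg=float(np.hypot(
                trace.gaze_x[i1] - trace.gaze_x[i0],
                trace.gaze_y[i1] - trace.gaze_y[i0])),
        ))
    return events


def rate_curve(
    events: list[MicrosaccadeEvent],
    t_grid: np.ndarray,
    cfg: PipelineConfig | None = None,
) -> RateCurve:
    """Smooth event times into a rate curve (events/s) on *t_grid*.

    Each event contributes a unit-area Gaussian of standard deviation
    ``ms_kernel_sd_s`` centered (zero phase lag) at its onset (or midpoint,
    per ``cfg.ms_timestamp``). An empty event list yields a zero curve.
    """
    cfg = cfg or PipelineConfig()
    t_grid = np.asarray(t_grid, dtype=float)
    sd = cfg.ms_kernel_sd_s
    rate = np.zeros_like(t_grid)
    norm = 1.0 / (sd * math.sqrt(2.0 * math.pi))
    for ev in events:
        center = (ev.onset_s if cfg.ms_timestamp == "onset"
                  else 0.5 * (ev.onset_s + ev.offset_s))
        rate += norm * np.exp(-0.5 * ((t_grid - center) / sd) ** 2)
    return RateCurve(t=t_grid, rate=rate)


def mean_rate(
    curve: RateCurve,
    trial: TrialInfo,
    cfg: PipelineConfig | None = None,
) -> float:
    """Mean of the rate curve over the standard analysis window."""
    cfg = cfg or PipelineConfig()
    lo, hi = metric_window(trial, cfg)
    in_win = (curve.t >= lo - TIME_EPS) & (curve.t <= hi + TIME_EPS)
    if not in_win.any():
        raise ValueError(f"metric window [{lo}, {hi}] contains no samples")
    return float(np.mean(curve.rate[in_win]))
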