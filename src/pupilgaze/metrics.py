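"""Per-trial dependent measures and participant-by-condition aggregation.

Three pupil measures are taken per trial from the baseline-corrected trace,
all within the analysis window from 0.5 s after sentence onset to 1 s after
sentence offset: mean dilation, peak dilation, and peak latency (time of
the maximum, first occurrence on ties, relative to sentence onset).
Behavioral accuracy is the proportion of correct semantic-relatedness
responses. Trial values are averaged per participant and condition cell
into a :class:`ConditionTable`, the input to all statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TIME_EPS, PipelineConfig, TrialInfo
from .preprocess import CleanTrial

__all__ = [
    "TrialMetrics",
    "ConditionTable",
    "CELL_LABELS",
    "cell_label",
    "metric_window",
    "trial_metrics",
    "score_behavior",
    "build_condition_table",
]

logger = logging.getLogger(__name__)

#: canonical cell order: ambiguity within clarity, high SNR first
CELL_LABELS = ("LA_high", "HA_high", "LA_low", "HA_low")


def cell_label(clarity: str, ambiguity: str) -> str:
    return f"{ambiguity}_{'high' if clarity == 'high_snr' else 'low'}"


@dataclass
class TrialMetrics:
    """Pupil measures for one trial (baseline-corrected a.u.; latency in s
    relative to sentence onset). No ordering between peak and mean dilation
    is implied — a trace that is negative through most of the window can
    have a peak below its own absolute mean."""

    mean_dilation: float
    peak_dilation: float
    peak_latency_s: float


@dataclass
class ConditionTable:
    """Participant x condition matrix of one dependent measure.

    ``values``: DataFrame indexed by participant id with the four cells of
    the 2x2 design as columns; ``n_trials``: per-cell contributing trial
    counts after exclusion.
    """

    measure: str
    values: pd.DataFrame
    n_trials: pd.DataFrame

    @property
    def participants(self) -> list[str]:
        return list(self.values.index)

    def __len__(self) -> int:
        return len(self.values)


def metric_window(trial: TrialInfo, cfg: PipelineConfig | None = None) -> tuple[float, float]:
    """Analysis window (0.5 s post onset, 1 s post offset), onset-relative."""
    cfg = cfg or PipelineConfig()
    if trial.sentence_duration_s <= 0:
        raise ValueError("sentence duration must be positive")
    lo = trial.sentence_onset_s + cfg.metric_window[0]
    hi = trial.sentence_offset_s + cfg.metric_window[1]
    if hi <= lo:
        raise ValueError(
            f"empty metric window ({lo}, {hi}) for duration "
            f"{trial.sentence_duration_s}")
    return lo, hi


def trial_metrics(clean: CleanTrial, trial: TrialInfo,
                  cfg: PipelineConfig | None = None) -> TrialMetrics:
    """Mean, peak and peak latency of the corrected trace in the analysis
    window. The caller must filter out excluded trials first."""
    if clean.excluded or clean.trace is None:
        raise ValueError("cannot compute metrics for an excluded trial")
    cfg = cfg or PipelineConfig()
    lo, hi = metric_window(trial, cfg)
    t = clean.trace.t
    in_win = (t >= lo - TIME_EPS) & (t <= hi + TIME_EPS)
    if not in_win.any():
        raise ValueError("metric window contains no samples")
    x = clean.trace.pupil[in_win]
    tw = t[in_win]
    i_peak = int(np.argmax(x))  # argmax returns the first maximum on ties
    return TrialMetrics(
        mean_dilation=float(np.mean(x)),
        peak_dilation=float(x[i_peak]),
        peak_latency_s=float(tw[i_peak]),
    )


def score_behavior(trial: TrialInfo, none_policy: str = "incorrect") -> bool | None:
    """Score the semantic-relatedness response.

    Correct iff the keypress matches the probe's ground-truth relatedness.
    Timeouts (``response == 'none'``) are scored incorrect under the default
    policy; under ``none_policy='exclude'`` they return None so the caller
    can drop them.
    """
    if trial.response == "none":
        if none_policy == "exclude":
            return None
        return False
    expected = "related" if trial.probe_related else "unrelated"
    return trial.response == expected


def build_condition_table(
    records: list[tuple[TrialInfo, float]],
    measure: str,
) -> ConditionTable:
    """Average per-trial values into a participant x cell table.

    *records* pairs each trial with one scalar value of the chosen measure
    (a pupil metric, a correctness indicator, a microsaccade rate, ...).
    Participants lacking at least one usable trial in any of the four cells
    are dropped listwise with a logged warning (the repeated-measures
    analyses require complete cells).
    """
    if not records:
        raise ValueError("no records to aggregate")
    rows = [{
        "participant": tr.participant_id,
        "cell": cell_label(tr.clarity, tr.ambiguity),
        "value": float(v),
    } for tr, v in records]
    df = pd.DataFrame(rows)
    means = df.pivot_table(index="participant", columns="cell",
                           values="value", aggfunc="mean")
    counts = df.pivot_table(index="participant", columns="cell",
                            values="value", aggfunc="count")
    means = means.reindex(columns=CELL_LABELS)
    counts = counts.reindex(columns=CELL_LABELS).fillna(0).astype(int)
    complete = means.notna().all(axis=1)
    dropped = list(means.index[~complete])
    if dropped:
        logger.warning("dropping %d participant(s) with empty cells for "
                       "measure %s: %s", len(dropped), measure, dropped)
    means = means.loc[complete]
    counts = counts.loc[complete]
    if means.empty:
        raise ValueError(
            f"no participant has usable trials in all 4 cells for {measure}")
    return ConditionTable(measure=measure, values=means, n_trials=counts)
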