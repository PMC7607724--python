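"""Domain types and tabular I/O for eye-tracking trials.

All times are stored in seconds relative to sentence onset (onset = 0, so
sentence offset = ``sentence_duration_s``): every analysis window downstream
is defined relative to onset or offset, which makes this the natural frame.

On-disk formats are plain CSV: one samples file per trial with columns
``t,pupil,gaze_x,gaze_y`` plus a companion blink table ``start_s,end_s``,
a trial-metadata table with one row per trial, and a manifest mapping trial
keys to file paths.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "SampleTrace",
    "TrialInfo",
    "PipelineConfig",
    "CLARITY_LEVELS",
    "AMBIGUITY_LEVELS",
    "RESPONSE_LEVELS",
    "read_trial_table",
    "write_trial_table",
    "read_samples",
    "write_samples",
    "trial_key",
    "write_dataset",
    "read_dataset",
]

#: grid-comparison slop for time windows (well below one sample at 500 Hz)
TIME_EPS = 1e-9

CLARITY_LEVELS = ("high_snr", "low_snr")
AMBIGUITY_LEVELS = ("LA", "HA")
RESPONSE_LEVELS = ("related", "unrelated", "none")


class FormatError(ValueError):
    """An input file violates the expected tabular format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SampleTrace:
    """One trial's continuous eye-tracker recording.

    Parameters
    ----------
    sampling_rate : float
        Samples per second (the study standard is 500 Hz).
    t : ndarray
        Time in seconds relative to sentence onset; strictly increasing with
        constant step ``1/sampling_rate``.
    pupil : ndarray
        Pupil area in arbitrary eye-tracker units; NaN marks missing data.
    gaze_x, gaze_y : ndarray
        Gaze position in degrees of visual angle.
    blink_intervals : list of (start_s, end_s)
        Closed intervals flagged by the recording device.
    """

    sampling_rate: float
    t: np.ndarray
    pupil: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    blink_intervals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.gaze_x = np.asarray(self.gaze_x, dtype=float)
        self.gaze_y = np.asarray(self.gaze_y, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.t.size
        if self.pupil.size != n or self.gaze_x.size != n or self.gaze_y.size != n:
            raise FormatError(
                "pupil/gaze arrays must have the same length as t "
                f"(t has {n} samples)"
            )
        if n >= 2:
            dt = 1.0 / self.sampling_rate
            steps = np.diff(self.t)
            bad = np.flatnonzero(np.abs(steps - dt) > TIME_EPS)
            if bad.size:
                i = int(bad[0])
                raise FormatError(
                    f"non-uniform timestamps: step t[{i}]->t[{i + 1}] is "
                    f"{steps[i]:.9g} s, expected {dt:.9g} s"
                )
        for (s, e) in self.blink_intervals:
            if s < self.t[0] - TIME_EPS or e > self.t[-1] + TIME_EPS:
                raise FormatError(
                    f"blink interval ({s}, {e}) outside recorded span "
                    f"[{self.t[0]}, {self.t[-1]}]"
                )

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def copy(self) -> "SampleTrace":
        """Copy with a fresh pupil array; t and gaze are shared read-only
        (preprocessing stages only ever rewrite pupil)."""
        # the source trace is already validated; skip re-validation
        new = object.__new__(SampleTrace)
        new.sampling_rate = self.sampling_rate
        new.t = self.t
        new.pupil = self.pupil.copy()
        new.gaze_x = self.gaze_x
        new.gaze_y = self.gaze_y
        new.blink_intervals = list(self.blink_intervals)
        return new


@dataclass
class TrialInfo:
    """Design metadata for one trial of the 2x2 Clarity x Ambiguity task."""

    participant_id: str
    experiment: int
    block: int
    clarity: str  # high_snr | low_snr
    ambiguity: str  # LA | HA
    sentence_duration_s: float
    probe_related: bool
    response: str  # related | unrelated | none
    sentence_onset_s: float = 0.0
    response_time_s: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.clarity not in CLARITY_LEVELS:
            raise FormatError(f"unknown clarity level {self.clarity!r}")
        if self.ambiguity not in AMBIGUITY_LEVELS:
            raise FormatError(f"unknown ambiguity level {self.ambiguity!r}")
        if self.response not in RESPONSE_LEVELS:
            raise FormatError(f"unknown response value {self.response!r}")
        if self.response == "none" and self.response_time_s is not None:
            raise FormatError("response=none implies response_time_s absent")

    @property
    def sentence_offset_s(self) -> float:
        return self.sentence_onset_s + self.sentence_duration_s


@dataclass
class PipelineConfig:
    """Every numeric analysis parameter of the pipeline, with study defaults.

    Windows whose right edge rides on the sentence offset are stored as
    (onset-relative start, offset-relative end) offsets: ``exclusion_window``
    (-0.5, 1.0) means "0.5 s before onset to 1 s after offset", and
    ``metric_window`` (0.5, 1.0) means "0.5 s after onset to 1 s after
    offset".
    """

    blink_pre_s: float = 0.05
    blink_post_s: float = 0.20
    mad_k: float = 3.0
    nan_frac_max: float = 0.40
    exclusion_window: tuple = (-0.5, 1.0)
    lp_cutoff_hz: float = 10.0
    fir_length: int = 201
    kaiser_beta: float = 5.0
    baseline_window: tuple = (-0.5, 0.0)
    metric_window: tuple = (0.5, 1.0)
    ms_threshold_k: float = 15.0
    ms_min_duration_s: float = 0.006
    ms_kernel_sd_s: float = 0.02
    ms_sigma_floor: float = 0.01  # deg/s; keeps thresholds off zero
    ms_criterion: str = "elliptic"  # elliptic | speed
    ms_timestamp: str = "onset"  # onset | midpoint, for rate curves
    none_response_policy: str = "incorrect"  # incorrect | exclude

    def validate(self) -> None:
        errors = []
        for name in ("blink_pre_s", "blink_post_s", "ms_min_duration_s",
                     "ms_kernel_sd_s", "lp_cutoff_hz"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be positive")
        if not (0.0 < self.nan_frac_max < 1.0):
            errors.append("nan_frac_max must lie in (0, 1)")
        if self.fir_length % 2 == 0:
            errors.append("fir_length must be odd (linear-phase type I FIR)")
        if self.mad_k <= 0:
            errors.append("mad_k must be positive")
        if self.ms_threshold_k <= 0:
            errors.append("ms_threshold_k must be positive")
        if self.baseline_window[1] <= self.baseline_window[0]:
            errors.append("baseline_window must have positive length")
        if self.ms_criterion not in ("elliptic", "speed"):
            errors.append("ms_criterion must be 'elliptic' or 'speed'")
        if self.ms_timestamp not in ("onset", "midpoint"):
            errors.append("ms_timestamp must be 'onset' or 'midpoint'")
        if self.none_response_policy not in ("incorrect", "exclude"):
            errors.append("none_response_policy must be 'incorrect' or 'exclude'")
        if errors:
            raise ValueError("invalid PipelineConfig: " + "; ".join(errors))


# ---------------------------------------------------------------------------
# trial table I/O
# ---------------------------------------------------------------------------

_TRIAL_FIELDS = [
    "participant_id", "experiment", "block", "clarity", "ambiguity",
    "sentence_onset_s", "sentence_duration_s", "probe_related",
    "response", "response_time_s",
]


def _parse_bool(v) -> bool:
    s = str(v).strip().lower()
    if s in ("true", "1", "t", "yes"):
        return True
    if s in ("false", "0", "f", "no"):
        return False
    raise ValueError(f"cannot parse boolean from {v!r}")


def read_trial_table(path: str | os.PathLike) -> list[TrialInfo]:
    """Read a trial-metadata CSV into :class:`TrialInfo` records.

    Unknown columns are preserved in ``extra``; row order is preserved.
    Raises :class:`FormatError` naming the missing column, or the offending
    row number for unparseable enum/boolean values.
    """
    df = pd.read_csv(path)
    for col in _TRIAL_FIELDS:
        if col not in df.columns and col != "response_time_s":
            raise FormatError(f"trial table {path} is missing required column "
                              f"'{col}'")
    has_rt = "response_time_s" in df.columns
    extra_cols = [c for c in df.columns if c not in _TRIAL_FIELDS]
    trials: list[TrialInfo] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        try:
            rt = rec["response_time_s"] if has_rt else None
            if rt is not None and (pd.isna(rt) or str(rt) == ""):
                rt = None
            trials.append(TrialInfo(
                participant_id=str(rec["participant_id"]),
                experiment=int(rec["experiment"]),
                block=int(rec["block"]),
                clarity=str(rec["clarity"]),
                ambiguity=str(rec["ambiguity"]),
                sentence_onset_s=float(rec["sentence_onset_s"]),
                sentence_duration_s=float(rec["sentence_duration_s"]),
                probe_related=_parse_bool(rec["probe_related"]),
                response=str(rec["response"]),
                response_time_s=None if rt is None else float(rt),
                extra={c: rec[c] for c in extra_cols},
            ))
        except (ValueError, FormatError) as exc:
            raise FormatError(f"trial table {path}, data row {i}: {exc}") from exc
    return trials


def write_trial_table(trials: Sequence[TrialInfo], path: str | os.PathLike) -> None:
    rows = []
    for tr in trials:
        row = {f: getattr(tr, f) for f in _TRIAL_FIELDS}
        row.update(tr.extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# samples I/O
# ---------------------------------------------------------------------------


def read_samples(
    path: str | os.PathLike,
    sampling_rate: float,
    blink_path: str | os.PathLike | None = None,
) -> SampleTrace:
    """Read one trial's samples CSV (columns ``t,pupil,gaze_x,gaze_y``).

    Blink intervals come from the companion table at *blink_path*
    (columns ``start_s,end_s``); device-flagged missing samples are already
    NaN in the pupil column. Non-uniform timestamps raise a
    :class:`FormatError` reporting the first violating index.
    """
    df = pd.read_csv(path)
    for col in ("t", "pupil", "gaze_x", "gaze_y"):
        if col not in df.columns:
            raise FormatError(f"samples file {path} is missing column '{col}'")
    blinks: list[tuple[float, float]] = []
    if blink_path is not None and os.path.exists(blink_path):
        bdf = pd.read_csv(blink_path)
        for col in ("start_s", "end_s"):
            if col not in bdf.columns:
                raise FormatError(
                    f"blink file {blink_path} is missing column '{col}'")
        blinks = [(float(s), float(e))
                  for s, e in zip(bdf["start_s"], bdf["end_s"])]
    return SampleTrace(
        sampling_rate=sampling_rate,
        t=df["t"].to_numpy(float),
        pupil=df["pupil"].to_numpy(float),
        gaze_x=df["gaze_x"].to_numpy(float),
        gaze_y=df["gaze_y"].to_numpy(float),
        blink_intervals=blinks,
    )


def write_samples(
    trace: SampleTrace,
    path: str | os.PathLike,
    blink_path: str | os.PathLike | None = None,
) -> None:
    pd.DataFrame({
        "t": trace.t,
        "pupil": trace.pupil,
        "gaze_x": trace.gaze_x,
        "gaze_y": trace.gaze_y,
    }).to_csv(path, index=False, na_rep="NaN", float_format="%.10g")
    if blink_path is not None:
        pd.DataFrame(trace.blink_intervals or [],
                     columns=["start_s", "end_s"]).to_csv(blink_path,
                                                          index=False)


# ---------------------------------------------------------------------------
# dataset layout (manifest-keyed directory of per-trial files)
# ---------------------------------------------------------------------------


def trial_key(trial: TrialInfo, index: int) -> str:
    """Stable per-trial file key: ``{participant}_b{block}_t{index:04d}``."""
    return f"{trial.participant_id}_b{trial.block}_t{index:04d}"


def write_dataset(
    trials: Sequence[TrialInfo],
    traces: Sequence[SampleTrace],
    out_dir: str | os.PathLike,
    sampling_rate: float | None = None,
) -> None:
    """Write trials.csv, per-trial samples/blink CSVs and a manifest."""
    out_dir = str(out_dir)
    os.makedirs(os.path.join(out_dir, "samples"), exist_ok=True)
    os.makedirs(os.path.join(out_dir, "blinks"), exist_ok=True)
    write_trial_table(trials, os.path.join(out_dir, "trials.csv"))
    rows = []
    for i, (tr, trace) in enumerate(zip(trials, traces)):
        key = trial_key(tr, i)
        spath = os.path.join("samples", f"{key}.csv")
        bpath = os.path.join("blinks", f"{key}.csv")
        write_samples(trace, os.path.join(out_dir, spath),
                      os.path.join(out_dir, bpath))
        rows.append({"key": key, "samples": spath, "blinks": bpath,
                     "sampling_rate": trace.sampling_rate})
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "manifest.csv"),
                              index=False)


def read_dataset(
    data_dir: str | os.PathLike,
) -> tuple[list[TrialInfo], list[SampleTrace], list[str]]:
    """Read a dataset directory written by :func:`write_dataset`.

    Returns (trials, traces, keys) in manifest row order.
    """
    data_dir = str(data_dir)
    trials = read_trial_table(os.path.join(data_dir, "trials.csv"))
    manifest = pd.read_csv(os.path.join(data_dir, "manifest.csv"))
    if len(manifest) != len(trials):
        raise FormatError(
            f"manifest has {len(manifest)} rows but trials.csv has "
            f"{len(trials)}")
    traces = []
    keys = []
    for row in manifest.itertuples(index=False):
        traces.append(read_samples(
            os.path.join(data_dir, row.samples),
            sampling_rate=float(row.sampling_rate),
            blink_path=os.path.join(data_dir, row.blinks),
        ))
        keys.append(str(row.key))
    return trials, traces, keys
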