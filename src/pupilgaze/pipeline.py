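"""One-command orchestration of the full analysis.

``run_all`` simulates (or ingests) a dataset, preprocesses every trial,
extracts pupil metrics, detects microsaccades, scores behavior, runs the
2x2 repeated-measures statistics, and writes every artifact plus a run
manifest. The pipeline is a pure function of (input data, config, seed):
re-running with an identical manifest reproduces identical numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (PipelineConfig, SampleTrace, TrialInfo, read_dataset,
                   trial_key, write_dataset)
from .metrics import build_condition_table, score_behavior, trial_metrics
from .microsaccades import detect_microsaccades, mean_rate, rate_curve
from .preprocess import CleanTrial, preprocess_trial
from .simulate import SimConfig, simulate_experiment
from .stats import AnovaResult, rmanova_2x2

__all__ = [
    "ConfigError",
    "RunManifest",
    "load_config",
    "analyze_experiment",
    "run_all",
]

logger = logging.getLogger(__name__)

PUPIL_MEASURES = ("mean_dilation", "peak_dilation", "peak_latency")


class ConfigError(ValueError):
    """Configuration file violates the schema (all violations listed)."""


@dataclass
class RunManifest:
    """Reproducibility record written next to the run's artifacts."""

    version: str
    seed: int | None
    pipeline_config: dict
    sim_config: dict | None
    n_trials: int
    n_excluded: int
    n_analyzed: int

    def write(self, path: str) -> None:
        def sanitize(obj):
            if isinstance(obj, dict):
                return {"/".join(k) if isinstance(k, tuple) else str(k):
                        sanitize(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [sanitize(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        with open(path, "w") as fh:
            json.dump(sanitize(dataclasses.asdict(self)), fh, indent=2,
                      default=str)


def _build_dataclass(cls, section: dict, name: str, errors: list):
    valid = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in section.items():
        if key not in valid:
            errors.append(f"{name}: unknown field '{key}'")
            continue
        if isinstance(val, list):
            val = tuple(val)
        if isinstance(val, dict) and key == "accuracy":
            val = {tuple(k.split("/")): v for k, v in val.items()}
        kwargs[key] = val
    try:
        obj = cls(**kwargs)
        obj.validate()
        return obj
    except (TypeError, ValueError) as exc:
        errors.append(f"{name}: {exc}")
        return None


def load_config(path: str | None) -> tuple[PipelineConfig, SimConfig, dict]:
    """Parse a YAML config with ``pipeline:`` and ``simulate:`` sections.

    Schema violations are collected and reported all at once. Every study
    parameter is overridable but defaults to the canonical analysis values,
    so an empty config is a complete "paper mode" configuration.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    known = {"pipeline", "simulate", "run"}
    for key in raw:
        if key not in known:
            errors.append(f"unknown top-level section '{key}'")
    pcfg = _build_dataclass(PipelineConfig, raw.get("pipeline", {}) or {},
                            "pipeline", errors)
    scfg = _build_dataclass(SimConfig, raw.get("simulate", {}) or {},
                            "simulate", errors)
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return pcfg, scfg, raw.get("run", {}) or {}


# ---------------------------------------------------------------------------
# in-memory analysis
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    """Everything the pipeline computes for one experiment."""

    trials: list
    clean: list
    tables: dict  # measure -> ConditionTable
    anovas: dict  # measure -> list[AnovaResult]
    n_excluded: int
    excluded_pct: float
    interpolated_pct: float
    ms_events: list  # per-trial event lists (None for excluded gaze)


def analyze_experiment(
    trials: list[TrialInfo],
    traces: list[SampleTrace],
    cfg: PipelineConfig | None = None,
) -> ExperimentResult:
    """Preprocess, extract all dependent measures, and run the 2x2 rmANOVAs."""
    cfg = cfg or PipelineConfig()
    cfg.validate()
    clean: list[CleanTrial] = []
    ms_events = []
    metric_records: dict[str, list] = {m: [] for m in PUPIL_MEASURES}
    behavior_records = []
    rate_records = []
    interp_fracs = []
    for trial, trace in zip(trials, traces):
        ct = preprocess_trial(trace, trial, cfg)
        clean.append(ct)
        if not ct.excluded:
            tm = trial_metrics(ct, trial, cfg)
            metric_records["mean_dilation"].append((trial, tm.mean_dilation))
            metric_records["peak_dilation"].append((trial, tm.peak_dilation))
            metric_records["peak_latency"].append((trial, tm.peak_latency_s))
            interp_fracs.append(ct.nan_fraction)
        correct = score_behavior(trial, cfg.none_response_policy)
        if correct is not None:
            behavior_records.append((trial, float(correct)))
        events = detect_microsaccades(trace, cfg)
        ms_events.append(events)
        curve = rate_curve(events, trace.t, cfg)
        rate_records.append((trial, mean_rate(curve, trial, cfg)))

    tables = {}
    anovas = {}
    for measure in PUPIL_MEASURES:
        tables[measure] = build_condition_table(metric_records[measure],
                                                measure)
    tables["accuracy"] = build_condition_table(behavior_records, "accuracy")
    tables["ms_rate"] = build_condition_table(rate_records, "ms_rate")
    for measure, table in tables.items():
        anovas[measure] = rmanova_2x2(table)
    n_excluded = sum(ct.excluded for ct in clean)
    return ExperimentResult(
        trials=trials,
        clean=clean,
        tables=tables,
        anovas=anovas,
        n_excluded=n_excluded,
        excluded_pct=100.0 * n_excluded / max(len(clean), 1),
        interpolated_pct=100.0 * float(np.mean(interp_fracs)) if interp_fracs
        else 0.0,
        ms_events=ms_events,
    )


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------


def _anova_dict(res: AnovaResult) -> dict:
    return {"effect": res.effect, "F": res.F, "df_num": res.df_num,
            "df_den": res.df_den, "p": res.p,
            "partial_eta_sq": res.partial_eta_sq}


def write_tables(tables: dict, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for measure, table in tables.items():
        df = table.values.copy()
        df.index.name = "participant"
        df.to_csv(os.path.join(out_dir, f"{measure}.csv"))


def write_stats_report(anovas: dict, path: str, extra: dict | None = None) -> None:
    report = {measure: [_anova_dict(r) for r in results]
              for measure, results in anovas.items()}
    if extra:
        report.update(extra)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
    # human-readable summary alongside
    lines = []
    for measure, results in anovas.items():
        lines.append(f"== {measure} ==")
        for r in results:
            lines.append(
                f"  {r.effect}: F({r.df_num}, {r.df_den}) = {r.F:.3f}, "
                f"p = {r.p:.4g}, partial eta^2 = {r.partial_eta_sq:.3f}")
    with open(os.path.splitext(path)[0] + ".txt", "w") as fh:
        fh.write("\n".join(lines) + "\n")


def run_all(
    config_path: str | None = None,
    out_dir: str = "pupilgaze_out",
    seed: int | None = None,
    data_dir: str | None = None,
    simulate: bool = True,
) -> ExperimentResult:
    """End-to-end run: simulate or ingest, analyze, write all artifacts."""
    pcfg, scfg, run_opts = load_config(config_path)
    simulate = bool(run_opts.get("simulate", simulate))
    data_dir = run_opts.get("data_dir", data_dir)
    os.makedirs(out_dir, exist_ok=True)

    if simulate:
        if seed is not None:
            scfg.seed = int(seed)
        trials, traces, truths = simulate_experiment(scfg)
        sim_dir = os.path.join(out_dir, "data")
        write_dataset(trials, traces, sim_dir)
        pd.DataFrame([{
            "key": trial_key(tr, i),
            "amplitude": truth.amplitude,
            "n_blinks": len(truth.blink_intervals),
            "n_spikes": len(truth.spike_indices),
            "n_microsaccades": len(truth.microsaccades),
            "is_correct": truth.is_correct,
        } for i, (tr, truth) in enumerate(zip(trials, truths))]).to_csv(
            os.path.join(sim_dir, "truth.csv"), index=False)
        keys = [trial_key(tr, i) for i, tr in enumerate(trials)]
    else:
        if data_dir is None:
            raise ConfigError("data_dir required when not simulating")
        trials, traces, keys = read_dataset(data_dir)

    result = analyze_experiment(trials, traces, pcfg)

    # exclusions report
    pd.DataFrame([{
        "key": key,
        "nan_fraction": ct.nan_fraction,
        "excluded": ct.excluded,
        "reason": ct.exclusion_reason,
    } for key, ct in zip(keys, result.clean)]).to_csv(
        os.path.join(out_dir, "exclusions.csv"), index=False)

    write_tables(result.tables, os.path.join(out_dir, "tables"))

    # per-trial microsaccade events
    ev_rows = []
    for key, events in zip(keys, result.ms_events):
        for ev in events:
            ev_rows.append({"key": key, "onset_s": ev.onset_s,
                            "offset_s": ev.offset_s,
                            "duration_s": ev.duration_s,
                            "amplitude_deg": ev.amplitude_deg,
                            "peak_velocity": ev.peak_velocity})
    pd.DataFrame(ev_rows, columns=["key", "onset_s", "offset_s",
                                   "duration_s", "amplitude_deg",
                                   "peak_velocity"]).to_csv(
        os.path.join(out_dir, "microsaccade_events.csv"), index=False)

    write_stats_report(result.anovas, os.path.join(out_dir, "stats.json"))

    RunManifest(
        version=__version__,
        seed=scfg.seed if simulate else seed,
        pipeline_config=dataclasses.asdict(pcfg),
        sim_config=dataclasses.asdict(scfg) if simulate else None,
        n_trials=len(trials),
        n_excluded=result.n_excluded,
        n_analyzed=len(trials) - result.n_excluded,
    ).write(os.path.join(out_dir, "manifest.json"))
    logger.info("run complete: %d trials, %d excluded",
                len(trials), result.n_excluded)
    return result
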