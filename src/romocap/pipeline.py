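"""Config-driven orchestration: simulate-or-load -> preprocess ->
kinematics -> segmentation -> cohort table -> statistics -> reports.

A pipeline run is fully determined by its configuration and master
seed: identical config + seed reproduce the cohort table byte for
byte.  Every run writes a provenance file (config, seed, package
version) next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, RomocapError
from .io_formats import (TrialMetadata, UNILATERAL_TASKS, read_trajectories,
                         write_cohort_table)
from .kinematics import PRIMARY_ANGLE_BY_TASK, primary_angle
from .preprocessing import FilterSpec, interpolate_gaps, lowpass_filter
from .segmentation import (EXCLUSION_GRANULARITY, POOLING_RULES, pool_sides,
                           segment_trial)
from .stats import analyze_cohort, pooling_justified, side_comparison
from .synthetic_data import CohortSpec, simulate_cohort

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    mode: str = "simulate"
    seed: int = 0
    output_dir: str = "romocap_out"
    log_level: str = "INFO"
    cohort: dict = field(default_factory=dict)       # CohortSpec overrides
    input_manifest: str | None = None                # mode == "load"
    filter: FilterSpec = field(default_factory=FilterSpec)
    max_gap: int = 20
    expected_reps: int = 6
    prominence: float = 0.2
    pooling_rule: str = "exclude_first"
    exclusion_granularity: str = "per_set"
    alpha: float = 0.05

    def __post_init__(self):
        if self.mode not in ("simulate", "load"):
            raise ConfigError(f"mode must be simulate/load, got {self.mode!r}")
        if self.mode == "load" and not self.input_manifest:
            raise ConfigError("mode 'load' requires input_manifest")
        if self.pooling_rule not in POOLING_RULES:
            raise ConfigError(f"unknown pooling_rule {self.pooling_rule!r}")
        if self.exclusion_granularity not in EXCLUSION_GRANULARITY:
            raise ConfigError(
                f"unknown exclusion_granularity {self.exclusion_granularity!r}")
        rate = self.cohort.get("sample_rate", 100.0)
        if self.filter.cutoff_hz >= rate / 2:
            raise ConfigError(
                f"filter cutoff {self.filter.cutoff_hz} Hz >= Nyquist "
                f"({rate / 2} Hz)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


_KNOWN_TOP = {"mode", "seed", "output_dir", "log_level", "cohort",
              "input_manifest", "filter", "max_gap", "expected_reps",
              "prominence", "pooling_rule", "exclusion_granularity", "alpha"}
_KNOWN_FILTER = {"cutoff_hz", "order", "zero_phase"}
_KNOWN_COHORT = {f.name for f in dataclasses.fields(CohortSpec)}


def validate_config(path) -> PipelineConfig:
    """Load and schema-check a YAML/JSON pipeline configuration.

    Unknown keys are rejected by name (catches typos such as
    ``cuttoff``); omitted keys take their documented defaults.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = sorted(set(raw) - _KNOWN_TOP)
    if unknown:
        raise ConfigError(f"unknown config key(s): {unknown}")
    fdict = raw.get("filter", {}) or {}
    bad = sorted(set(fdict) - _KNOWN_FILTER)
    if bad:
        raise ConfigError(f"unknown filter key(s): {bad}")
    cdict = raw.get("cohort", {}) or {}
    bad = sorted(set(cdict) - _KNOWN_COHORT)
    if bad:
        raise ConfigError(f"unknown cohort key(s): {bad}")
    kwargs = {k: v for k, v in raw.items() if k not in ("filter",)}
    if "cohort" in kwargs:
        kwargs["cohort"] = dict(cdict)
    try:
        spec = FilterSpec(**fdict)
        return PipelineConfig(filter=spec, **kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# trial processing
# ---------------------------------------------------------------------------

def process_trial(meta: TrialMetadata, traj, config: PipelineConfig):
    """Preprocess one trial and segment its primary angle curve."""
    if traj.has_gaps():
        traj = interpolate_gaps(traj, max_gap=config.max_gap)
    traj = lowpass_filter(traj, config.filter)
    series = primary_angle(traj, meta.task, side=meta.side)
    if config.exclusion_granularity == "per_side_first_set_only":
        rule = config.pooling_rule if meta.set_index == 1 else "all"
    else:
        rule = config.pooling_rule
    return segment_trial(series, meta, expected=config.expected_reps,
                         min_prominence_frac=config.prominence,
                         pooling_rule=rule)


def _trials_from_manifest(path):
    man = pd.read_csv(path, dtype={"participant": str})
    needed = {"path", "participant", "group", "session", "task", "side", "set"}
    missing = needed - set(man.columns)
    if missing:
        raise ConfigError(f"manifest missing column(s): {sorted(missing)}")
    base = Path(path).parent
    for _, row in man.iterrows():
        meta = TrialMetadata(participant_id=str(row["participant"]),
                             group=row["group"], session=row["session"],
                             task=row["task"], side=row["side"],
                             set_index=int(row["set"]))
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        yield meta, read_trajectories(p, task=meta.task)


def build_cohort_tables(results, alpha: float = 0.05):
    """Aggregate per-trial results into participant-level tables.

    Returns ``(participant_table, trial_table, per_rep_table)``.  Set
    means are averaged per side, then sides are pooled when the
    preliminary side comparison finds no systematic asymmetry.
    """
    trial_rows, rep_rows = [], []
    for res in results:
        m = res.metadata
        label = f"{res.primary_label}_ROM"
        base = dict(participant=m.participant_id, group=m.group,
                    session=m.session, task=m.task, side=m.side,
                    set=m.set_index)
        trial_rows.append({**base, "parameter": label, "value": res.pooled_rom})
        trial_rows.append({**base, "parameter": "duration",
                           "value": res.duration_s})
        for r_idx, rep in enumerate(res.repetitions, start=1):
            rep_rows.append({**base, "parameter": label,
                             "repetition": r_idx, "value": rep.rom})
    trial_table = pd.DataFrame(trial_rows)
    per_rep = pd.DataFrame(rep_rows)

    # mean over the two sets, per side
    side_level = (trial_table
                  .groupby(["participant", "group", "session", "task",
                            "side", "parameter"], as_index=False)["value"]
                  .mean())

    bilateral = side_level[side_level["side"] != "none"]
    justified = True
    if len(bilateral) and bilateral["side"].nunique() == 2:
        try:
            justified = pooling_justified(side_comparison(bilateral), alpha)
        except RomocapError as exc:
            log.warning("side comparison skipped: %s", exc)
    if not justified:
        log.warning("systematic side difference detected; keeping sides "
                    "separate in the cohort table")

    rows = []
    keys = ["participant", "group", "session", "task", "parameter"]
    for key, sub in side_level.groupby(keys):
        rec = dict(zip(keys, key))
        by_side = dict(zip(sub["side"], sub["value"]))
        if "none" in by_side:
            rec["value"] = by_side["none"]
            rows.append(rec)
        else:
            pooled = pool_sides(by_side.get("left"), by_side.get("right"),
                                justified)
            if isinstance(pooled, dict):
                for s, v in pooled.items():
                    if v is not None:
                        rows.append({**rec, "side": s, "value": v})
            elif pooled is not None:
                rows.append({**rec, "value": pooled})
    participant_table = pd.DataFrame(rows)
    return participant_table, trial_table, per_rep


def summarize_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) per group/session/task/parameter, shaped for reporting."""
    g = table.groupby(["task", "parameter", "group", "session"])["value"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    out["mean_sd"] = out.apply(
        lambda r: f"{r['mean']:.2f} ({r['std']:.2f})", axis=1)
    return out


def run_pipeline(config: PipelineConfig):
    """Execute all stages and write outputs under ``config.output_dir``.

    Returns ``(participant_table, outputs)`` where ``outputs`` maps
    artifact names to file paths.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    if config.mode == "simulate":
        spec = CohortSpec(seed=config.seed, **config.cohort)
        trials, truth = simulate_cohort(spec)
        truth.to_csv(out_dir / "truth_table.csv", index=False)
    else:
        trials = list(_trials_from_manifest(config.input_manifest))
    log.info("stage simulate/load: %d trials (%.1f s)", len(trials),
             time.time() - t0)

    results, failures = [], 0
    for meta, traj in trials:
        try:
            results.append(process_trial(meta, traj, config))
        except RomocapError as exc:
            failures += 1
            log.warning("trial %s/%s/%s/%s set %d failed: %s",
                        meta.participant_id, meta.session, meta.task,
                        meta.side, meta.set_index, exc)
    if not results:
        raise RomocapError("pipeline: every trial failed to process")

    participant_table, trial_table, per_rep = build_cohort_tables(
        results, config.alpha)
    stats_table = analyze_cohort(participant_table, alpha=config.alpha)
    summary = summarize_cohort(participant_table)

    outputs = {}
    write_cohort_table(participant_table, out_dir / "cohort_table.csv")
    outputs["cohort_table"] = out_dir / "cohort_table.csv"
    trial_table.to_csv(out_dir / "trial_table.csv", index=False)
    outputs["trial_table"] = out_dir / "trial_table.csv"
    per_rep.to_csv(out_dir / "per_repetition_table.csv", index=False)
    outputs["per_repetition_table"] = out_dir / "per_repetition_table.csv"
    stats_table.to_csv(out_dir / "stats_results.csv", index=False)
    outputs["stats_results"] = out_dir / "stats_results.csv"
    summary.to_csv(out_dir / "summary_table.csv", index=False)
    outputs["summary_table"] = out_dir / "summary_table.csv"

    n_warn = sum(len(r.warnings) for r in results)
    prov = {
        "package": "romocap",
        "version": __version__,
        "seed": config.seed,
        "config": _jsonable(config.to_dict()),
        "n_trials": len(trials),
        "n_failed": failures,
        "n_segmentation_warnings": n_warn,
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(out_dir / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(prov, fh, indent=2)
    outputs["provenance"] = out_dir / "provenance.json"
    log.info("pipeline complete: %d trials processed, %d failed, %d warnings",
             len(results), failures, n_warn)
    return participant_table, outputs


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
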