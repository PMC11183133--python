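"""Orchestration: simulate -> extract -> agree -> model -> report.

One :func:`run_study` call reproduces the whole analysis on synthetic data:
it simulates the two-device study, runs the single-sensor extraction on
every recording, compares chest against lumbar (and against ground truth),
fits the device/task and device/environment mixed models, compares bout
statistics, and renders a Markdown report.  All outputs are plain CSV/JSON
under a fixed directory layout, and the run is a pure function of the
configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import agreement_table
from .io import (dump_yaml, load_yaml, write_ground_truth_json,
                 write_recording_csv)
from .models import compare_bout_stats, fit_device_task_model, fit_environment_model
from .pipeline import (PipelineConfig, compute_bout_stats, extract_gait,
                       filter_bouts, aggregate_endpoints)
from .synthetic import (SimulationConfig, StudyBundle, WALK_TASKS,
                        ACTIVITY_TASKS, simulate_study)
from .types import ENDPOINTS, AccelRecording

__all__ = ["RunConfig", "StudyReport", "run_study", "validate_inputs",
           "extract_study", "truth_endpoints"]

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of a full reproducible run."""

    out_dir: str = "chestgait_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    stages: tuple[str, ...] = ("simulate", "extract", "agree", "model", "report")
    write_raw: bool = True
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = load_yaml(path)
        sim = SimulationConfig(**raw.pop("simulation", {}))
        pipe = PipelineConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in raw.pop("pipeline", {}).items()})
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        cfg = cls(simulation=sim, pipeline=pipe, **raw)
        if "seed" not in raw:
            cfg.seed = sim.seed
        cfg.simulation.seed = cfg.seed
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class StudyReport:
    """Key result tables of one run plus provenance."""

    agreement: dict          # name -> DataFrame
    models: dict             # endpoint -> ModelResult
    bout_comparison: pd.DataFrame | None
    provenance: dict
    out_dir: Path


# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def extract_study(bundle: StudyBundle, pipeline_cfg: PipelineConfig,
                  ) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Run the extraction pipeline over every recording of a bundle.

    Returns (pooled stride table, bout-stats table, per-recording logs).
    Bout statistics are computed on outside-lab sessions after the
    9 s / 4-cycle bout filter.
    """
    stride_tabs, bout_rows, logs = [], [], []
    for (subject, visit, task, location), rec in bundle.recordings.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = extract_gait(rec, pipeline_cfg)
        stride_tabs.append(res.strides)
        logs.append({"subject": subject, "visit": visit, "task": task,
                     "location": location, **res.log})
        if task == "outside_activities":
            kept, rep = filter_bouts(res.bouts,
                                     pipeline_cfg.bout_min_duration_s,
                                     pipeline_cfg.bout_min_cycles)
            stats_row = compute_bout_stats(kept)
            bout_rows.append({"subject": subject, "visit": visit,
                              "location": location, **stats_row,
                              "n_bouts_removed": rep["n_removed"]})
    strides = pd.concat([t for t in stride_tabs if not t.empty],
                        ignore_index=True) if stride_tabs else pd.DataFrame()
    return strides, pd.DataFrame(bout_rows), logs


def truth_endpoints(bundle: StudyBundle) -> pd.DataFrame:
    """Cross-visit median endpoints computed from the simulation ground truth."""
    rows = []
    for (subject, visit, task), truth in bundle.truths.items():
        if truth.strides.empty:
            continue
        med = truth.strides.median(numeric_only=True)
        rows.append({"subject": subject, "visit": visit, "task": task,
                     **{ep: med[ep] for ep in ENDPOINTS if ep in med}})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.groupby(["subject", "task"], sort=True)[ENDPOINTS].mean().reset_index()


def _location_wide(cross: pd.DataFrame, test: str, ref: str,
                   ) -> pd.DataFrame:
    t = cross[cross["location"] == test].drop(columns="location")
    r = cross[cross["location"] == ref].drop(columns="location")
    return t.merge(r, on=["subject", "task"], suffixes=("_test", "_ref"))


def run_study(config: RunConfig) -> StudyReport:
    """Execute the configured stages end to end; see module docstring."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.simulation.seed = config.seed
    cfg_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
    }
    (out / "config.yaml").write_text(cfg_yaml)

    bundle = simulate_study(config.simulation)
    if "simulate" in config.stages and config.write_raw:
        raw = out / "raw"
        raw.mkdir(exist_ok=True)
        meta = bundle.metadata.copy()
        files = []
        for _, row in meta.iterrows():
            name = (f"{row.subject}_v{row.visit}_{row.task}_{row.location}.csv")
            write_recording_csv(
                bundle.recordings[(row.subject, row.visit, row.task,
                                   row.location)], raw / name)
            files.append(name)
        meta["file"] = files
        _write_csv(meta, raw / "metadata.csv")
        for (subject, visit, task), truth in bundle.truths.items():
            write_ground_truth_json(
                truth, raw / f"{subject}_v{visit}_{task}_truth.json")

    if "extract" not in config.stages:
        return StudyReport(agreement={}, models={}, bout_comparison=None,
                           provenance=provenance, out_dir=out)

    strides, bout_stats, logs = extract_study(bundle, config.pipeline)
    _write_csv(strides, out / "strides" / "strides.csv")
    per_visit, cross = aggregate_endpoints(strides)
    _write_csv(per_visit, out / "endpoints" / "endpoints_per_visit.csv")
    _write_csv(cross, out / "endpoints" / "endpoints_cross_visit.csv")
    if not bout_stats.empty:
        _write_csv(bout_stats, out / "strides" / "bout_stats.csv")
    (out / "strides").mkdir(exist_ok=True)
    (out / "strides" / "processing_log.json").write_text(
        json.dumps(logs, indent=1, sort_keys=True, default=str))

    agreement: dict = {}
    models: dict = {}
    bout_cmp = None

    if "agree" in config.stages:
        wide = _location_wide(cross, "chest", "lumbar")
        for group, tasks in (("walk", WALK_TASKS), ("activity", ACTIVITY_TASKS)):
            sub = wide[wide["task"].isin(tasks)]
            if sub.empty:
                continue
            eps = list(ENDPOINTS) + (["gait_speed_p95_mps"]
                                     if group == "activity" else [])
            tab = agreement_table(sub, eps, by=["task"])
            agreement[f"chest_vs_lumbar_{group}"] = tab
            _write_csv(tab, out / "agreement" / f"chest_vs_lumbar_{group}.csv")
        # chest vs simulation ground truth
        truth = truth_endpoints(bundle)
        chest = cross[cross["location"] == "chest"].drop(columns="location")
        merged = chest.merge(truth, on=["subject", "task"],
                             suffixes=("_test", "_ref"))
        if not merged.empty:
            tab = agreement_table(merged, list(ENDPOINTS), by=["task"])
            agreement["chest_vs_truth"] = tab
            _write_csv(tab, out / "agreement" / "chest_vs_truth.csv")
        if config.make_plots and not wide.empty:
            from .plots import plot_bland_altman, plot_scatter

            plot_dir = out / "agreement" / "plots"
            plot_dir.mkdir(parents=True, exist_ok=True)
            for task, g in wide.groupby("task"):
                t = g["gait_speed_mps_test"].to_numpy()
                r = g["gait_speed_mps_ref"].to_numpy()
                if len(g) < 3:
                    continue
                plot_bland_altman(t, r, plot_dir / f"ba_gait_speed_{task}.png",
                                  title=f"gait speed, {task}", units="(m/s)")
                plot_scatter(t, r, plot_dir / f"scatter_gait_speed_{task}.png",
                             title=f"gait speed, {task}", units="(m/s)")

    if "model" in config.stages:
        ages = bundle.metadata.groupby("subject")["age"].first()
        long = cross.rename(columns={"location": "device"})
        long["age"] = long["subject"].map(ages)
        for ep in ENDPOINTS:
            walk = long[long["task"].isin(WALK_TASKS)].rename(
                columns={ep: "value"})[["subject", "age", "device", "task", "value"]]
            if walk["task"].nunique() >= 2 and walk["subject"].nunique() >= 5:
                res = fit_device_task_model(walk, endpoint=ep)
                models[ep] = res
                _write_csv(res.anova.assign(endpoint=ep),
                           out / "models" / f"anova_{ep}.csv")
                _write_csv(res.contrasts.assign(endpoint=ep),
                           out / "models" / f"contrasts_{ep}.csv")
            act = long[long["task"].isin(ACTIVITY_TASKS)].copy()
            if (not act.empty and act["task"].nunique() >= 2
                    and act["subject"].nunique() >= 5):
                act["environment"] = np.where(
                    act["task"] == "outside_activities", "outside", "in_lab")
                env = act.rename(columns={ep: "value"})[
                    ["subject", "age", "device", "environment", "value"]]
                res_env = fit_environment_model(env, endpoint=ep)
                _write_csv(res_env.anova.assign(endpoint=ep),
                           out / "models" / f"anova_environment_{ep}.csv")
        if not bout_stats.empty:
            per_subj = (bout_stats.groupby(["subject", "location"])
                        [["mean_bout_duration_s", "total_walking_time_s",
                          "n_bouts", "total_steps"]].mean().reset_index())
            chest_b = per_subj[per_subj["location"] == "chest"].drop(columns="location")
            lumbar_b = per_subj[per_subj["location"] == "lumbar"].drop(columns="location")
            if len(chest_b) >= 3:
                bout_cmp = compare_bout_stats(chest_b, lumbar_b)
                _write_csv(bout_cmp, out / "models" / "bout_comparison.csv")

    if "report" in config.stages:
        _render_report(out, agreement, models, bout_cmp, provenance)

    return StudyReport(agreement=agreement, models=models,
                       bout_comparison=bout_cmp, provenance=provenance,
                       out_dir=out)


def _render_report(out: Path, agreement: dict, models: dict,
                   bout_cmp, provenance: dict) -> None:
    rep = out / "report"
    rep.mkdir(exist_ok=True)
    lines = ["# Study report", "",
             f"- package version: {provenance['package_version']}",
             f"- seed: {provenance['seed']}",
             f"- config sha256: {provenance['config_sha256']}", ""]
    for name, tab in agreement.items():
        lines += [f"## Agreement: {name}", "", tab.to_markdown(index=False), ""]
    for ep, res in models.items():
        lines += [f"## Mixed model: {ep}", "", res.anova.to_markdown(index=False),
                  "", res.contrasts.to_markdown(index=False), ""]
    if bout_cmp is not None:
        lines += ["## Bout comparison (chest vs lumbar)", "",
                  bout_cmp.to_markdown(index=False), ""]
    (rep / "report.md").write_text("\n".join(lines))


# ---------------------------------------------------------------------------

def validate_inputs(source) -> list[dict]:
    """Report-only validation of recordings or a run input directory.

    Accepts a list of :class:`AccelRecording` or a directory containing
    recording CSVs plus ``metadata.csv``.  Checks sampling uniformity
    (gaps flagged with their timestamp), unit plausibility (mean vector
    magnitude near 1 g; values near 9.8 suggest m/s^2 mislabelled as g),
    and metadata completeness.  Never mutates inputs.
    """
    from .io import read_recording_csv

    issues: list[dict] = []
    recs: list[tuple[str, AccelRecording]] = []
    if isinstance(source, (str, Path)):
        src = Path(source)
        if not src.exists():
            raise FileNotFoundError(f"input directory {src} does not exist")
        meta_path = src / "metadata.csv"
        if not meta_path.exists():
            issues.append({"kind": "metadata_missing", "detail": str(meta_path)})
            files = sorted(src.glob("*.csv"))
        else:
            meta = pd.read_csv(meta_path)
            for col in ("subject", "visit", "task", "location", "file"):
                if col not in meta.columns:
                    issues.append({"kind": "metadata_incomplete", "detail": col})
            files = [src / f for f in meta.get("file", pd.Series(dtype=str))]
        for f in files:
            if not Path(f).exists():
                issues.append({"kind": "file_missing", "detail": str(f)})
                continue
            try:
                recs.append((Path(f).name, _read_raw(f)))
            except ValueError as exc:
                issues.append({"kind": "unreadable", "detail": f"{f}: {exc}"})
    else:
        recs = [(r.subject or f"recording_{i}", r) for i, r in enumerate(source)]

    for name, rec in recs:
        dt = np.diff(rec.time)
        if dt.size:
            gaps = np.where(dt > 1.5 / rec.fs)[0]
            for g in gaps[:10]:
                issues.append({"kind": "sampling_gap", "recording": name,
                               "at_s": float(rec.time[g]),
                               "gap_s": float(dt[g])})
        mag = float(np.linalg.norm(rec.accel, axis=1).mean())
        if abs(mag - 9.80665) < 2.0:
            issues.append({"kind": "unit_suspect", "recording": name,
                           "detail": f"mean magnitude {mag:.2f} suggests m/s^2 "
                                     "mislabelled as g"})
        elif abs(mag - 1.0) > 0.2:
            issues.append({"kind": "magnitude_out_of_range", "recording": name,
                           "detail": f"mean |a| = {mag:.3f} g"})
    return issues


def _read_raw(path) -> AccelRecording:
    """Read a raw CSV tolerating non-uniform grids (validation only)."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    rec = AccelRecording.__new__(AccelRecording)
    rec.time = t
    rec.accel = df[["ax_g", "ay_g", "az_g"]].to_numpy()
    rec.fs = fs
    rec.location = "unknown"
    rec.subject = rec.visit = rec.task = None
    rec.sensor_height = None
    return rec
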