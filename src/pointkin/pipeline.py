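"""Orchestration: simulate -> preprocess -> segment -> extract -> exclude
-> stats as a reproducible, configured, logged pipeline.

Every stage reads and writes plain-text intermediates under the run
directory, so any stage can be re-run from persisted outputs.  One global
seed governs all stochastic stages through derived substreams; the seed
and a config hash are recorded in the run report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exclusion import ExclusionConfig, apply_exclusions
from .kinematics import (
    KinematicSummary,
    ReportingFrame,
    extract_parameters,
    lateral_contrast,
    time_normalize,
)
from .preprocess import FilterConfig, compute_velocity, lowpass_filter
from .segmentation import SegmentationConfig, TaskGeometry, segment_trial
from .simulate import DesignSpec, EffectSpec, NoiseSpec, synthesize_experiment
from .stats import PermConfig, cell_means, cluster_permutation_ttest, ks_normality, rm_anova
from .trajectory import read_trajectories

log = logging.getLogger("pointkin")

STAGES = ("simulate", "preprocess", "segment", "extract", "exclude", "anova", "permtest")


@dataclass
class PipelineConfig:
    out_dir: str = "pointkin_run"
    seed: int = 0
    design: DesignSpec = field(default_factory=DesignSpec)
    effects: EffectSpec = field(default_factory=EffectSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    filter: FilterConfig = field(default_factory=FilterConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    exclusion: ExclusionConfig = field(default_factory=ExclusionConfig)
    permutation: PermConfig = field(default_factory=PermConfig)
    stages: tuple[str, ...] = STAGES

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Build a config from a YAML file of nested sections; unspecified
        fields keep their defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        sections = {
            "design": DesignSpec,
            "effects": EffectSpec,
            "noise": NoiseSpec,
            "filter": FilterConfig,
            "segmentation": SegmentationConfig,
            "exclusion": ExclusionConfig,
            "permutation": PermConfig,
        }
        for key, klass in sections.items():
            if key in raw:
                params = dict(raw[key])
                for tup_key in ("screened_parameters", "stages"):
                    if tup_key in params:
                        params[tup_key] = tuple(params[tup_key])
                kwargs[key] = klass(**params)
        for key in ("out_dir", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "stages" in raw:
            kwargs["stages"] = tuple(raw["stages"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dataclass_fields__"):
                return asdict(o)
            return str(o)

        text = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _stage_dir(cfg: PipelineConfig, name: str) -> Path:
    d = Path(cfg.out_dir) / name
    d.mkdir(parents=True, exist_ok=True)
    return d


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> Path:
    out = _stage_dir(cfg, "raw")
    exp = synthesize_experiment(cfg.design, cfg.effects, cfg.noise, seed=cfg.seed)
    exp.write(out)
    log.info("simulate: %d trials, %d subjects -> %s", len(exp.trials), cfg.design.n_subjects, out)
    return out


def _load_all_series(raw: Path, trial_table: pd.DataFrame) -> dict[str, "TrajectorySeries"]:
    events = {
        row.trial_id: {
            "stimulus": row.t_stimulus_s,
            "home_release": row.t_home_release_s,
            "home_return": row.t_home_return_s,
            "addressee_release": row.t_addressee_release_s,
            "addressee_select": row.t_addressee_select_s,
        }
        for row in trial_table.itertuples()
    }
    series = {}
    for path in sorted(raw.glob("sub-*_trajectories.csv")):
        series.update(read_trajectories(path, events=events))
    return series


def stage_preprocess(cfg: PipelineConfig) -> dict:
    """Filter every trajectory; persists filtered streams per subject."""
    from .trajectory import write_trajectories

    raw = Path(cfg.out_dir) / "raw"
    table = pd.read_csv(raw / "trials.csv", dtype={"trial_id": str}, float_precision="round_trip")
    series = _load_all_series(raw, table)
    out = _stage_dir(cfg, "filtered")
    filtered = {tid: lowpass_filter(s, cfg.filter) for tid, s in series.items()}
    by_subject: dict[int, dict] = {}
    for row in table.itertuples():
        by_subject.setdefault(row.subject, {})[row.trial_id] = filtered[row.trial_id]
    for subj, trials in by_subject.items():
        write_trajectories(out / f"sub-{subj:02d}_trajectories.csv", trials)
    log.info("preprocess: filtered %d trials -> %s", len(filtered), out)
    return filtered


def _load_filtered(cfg: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    raw = Path(cfg.out_dir) / "raw"
    table = pd.read_csv(raw / "trials.csv", dtype={"trial_id": str}, float_precision="round_trip")
    filt_dir = Path(cfg.out_dir) / "filtered"
    series = _load_all_series(filt_dir, table)
    return table, series


def stage_segment(cfg: PipelineConfig, series: dict | None = None) -> pd.DataFrame:
    if series is None:
        table, series = _load_filtered(cfg)
    else:
        table = pd.read_csv(Path(cfg.out_dir) / "raw" / "trials.csv", dtype={"trial_id": str}, float_precision="round_trip")
    rows = []
    for row in table.itertuples():
        b = segment_trial(series[row.trial_id], cfg.segmentation, cfg.design.geometry)
        rec = {"trial_id": row.trial_id, "subject": row.subject}
        rec.update(b.as_dict())
        rows.append(rec)
    phases = pd.DataFrame(rows)
    out = _stage_dir(cfg, "phases")
    phases.to_csv(out / "phases.csv", index=False, float_format="%.17g")
    log.info("segment: %d trials (%d valid) -> %s", len(phases), int(phases["valid"].sum()), out)
    return phases


def stage_extract(cfg: PipelineConfig, series: dict | None = None,
                  phases: pd.DataFrame | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract per-trial parameters and 100-sample lateral profiles."""
    from .segmentation import PhaseBounds

    if series is None:
        _, series = _load_filtered(cfg)
    if phases is None:
        phases = pd.read_csv(Path(cfg.out_dir) / "phases" / "phases.csv", dtype={"trial_id": str}, float_precision="round_trip")
    table = pd.read_csv(Path(cfg.out_dir) / "raw" / "trials.csv", dtype={"trial_id": str}, float_precision="round_trip")
    frame = cfg.design.reporting_frame

    param_rows, prof_x, prof_vx, prof_ids = [], [], [], []
    for row in phases.itertuples():
        s = series[row.trial_id]
        bounds = PhaseBounds(
            t_stimulus=row.t_stimulus,
            t_release=row.t_release,
            forward_onset=row.forward_onset,
            forward_offset=row.forward_offset,
            hold_onset=row.hold_onset,
            hold_offset=row.hold_offset,
            backward_onset=row.backward_onset,
            backward_offset=row.backward_offset,
            reasons=tuple(str(row.reasons).split(";")) if isinstance(row.reasons, str) and row.reasons else (),
        )
        summary = extract_parameters(s, bounds, frame)
        rec = {"trial_id": row.trial_id, "subject": row.subject}
        rec.update(summary.as_dict())
        param_rows.append(rec)
        if summary.valid:
            prof = time_normalize(s, bounds)
            prof_ids.append(row.trial_id)
            prof_x.append(prof.position[:, 0])
            prof_vx.append(prof.velocity[:, 0])
    params = pd.DataFrame(param_rows)
    params = table.merge(params, on=["trial_id", "subject"])
    params["valid_movement"] = params["valid"]

    out = _stage_dir(cfg, "params")
    params.to_csv(out / "params.csv", index=False, float_format="%.17g")
    profiles = pd.DataFrame(np.asarray(prof_x), index=pd.Index(prof_ids, name="trial_id"))
    profiles_v = pd.DataFrame(np.asarray(prof_vx), index=pd.Index(prof_ids, name="trial_id"))
    profiles.to_csv(out / "profiles_x.csv", float_format="%.17g")
    profiles_v.to_csv(out / "profiles_vx.csv", float_format="%.17g")
    log.info("extract: %d trials, %d profiles -> %s", len(params), len(profiles), out)
    return params, profiles


def stage_exclude(cfg: PipelineConfig, params: pd.DataFrame | None = None):
    if params is None:
        params = pd.read_csv(Path(cfg.out_dir) / "params" / "params.csv", dtype={"trial_id": str}, float_precision="round_trip")
    retained, report = apply_exclusions(params, cfg.exclusion)
    out = _stage_dir(cfg, "exclusion")
    retained.to_csv(out / "retained.csv", index=False, float_format="%.17g")
    report.to_json(out / "exclusion.json")
    for line in report.log_lines():
        log.info("%s", line)
    return retained, report


def stage_anova(cfg: PipelineConfig, retained: pd.DataFrame | None = None) -> dict:
    """Cell means, KS normality screen, and the full factorial rm-ANOVA for
    every kinematic parameter."""
    if retained is None:
        retained = pd.read_csv(Path(cfg.out_dir) / "exclusion" / "retained.csv", dtype={"trial_id": str}, float_precision="round_trip")
    params = [p for p in KinematicSummary.PARAMS if retained[p].notna().any()]
    means = cell_means(retained, params)
    results, ks = {}, {}
    for p in params:
        res = rm_anova(means, dv=p)
        results[p] = res.table.reset_index().to_dict(orient="records")
        ks[p] = asdict(ks_normality(means[p]))
    out = _stage_dir(cfg, "anova")
    means.to_csv(out / "cell_means.csv", index=False, float_format="%.17g")
    flat = []
    for p, rows in results.items():
        for r in rows:
            flat.append({"parameter": p, **{k: r[k] for k in ("effect", "F", "df1", "df2", "p", "eta_p2")}})
    pd.DataFrame(flat).to_csv(out / "anova_table.csv", index=False)
    payload = {"anova": results, "ks_normality": ks}
    with open(out / "anova.json", "w") as fh:
        json.dump(payload, fh, indent=1, default=float)
    log.info("anova: %d parameters x %d effects -> %s", len(params), 7, out)
    return payload


def _profile_contrasts(cfg: PipelineConfig, retained: pd.DataFrame,
                       profiles: pd.DataFrame, profiles_v: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-subject difference curves for the three lateral contrasts."""
    labels = retained[retained["trial_id"].isin(profiles.index)]
    pos = profiles.loc[labels["trial_id"]].to_numpy()
    vel = profiles_v.loc[labels["trial_id"]].to_numpy()
    contrast = lateral_contrast(labels, pos, vel)

    # outward lateral displacement (x flipped for the left sign) pooled over
    # the outer signs: mind - object
    cp = contrast.cell_position
    flipped = cp.copy()
    left_rows = flipped.index.get_level_values("sign") == "left"
    flipped.loc[left_rows] = -flipped.loc[left_rows]
    flip_contrast = type(contrast)(cell_position=flipped, cell_velocity=contrast.cell_velocity)
    action_by_sign = flip_contrast.subject_action_difference(
        select={"sign": ["left", "right"]}
    )

    # addressee-directed displacement: (right addressee - left addressee),
    # averaged over actions
    subj = cp.groupby(level=["subject", "addressee"]).mean()
    addressee = (
        subj.xs("right", level="addressee") - subj.xs("left", level="addressee")
    ).sort_index().to_numpy()

    # action x addressee on signed lateral velocity:
    # (mind R-L) - (object R-L)
    cv = contrast.cell_velocity
    sv = cv.groupby(level=["subject", "action", "addressee"]).mean()
    rl = sv.xs("right", level="addressee") - sv.xs("left", level="addressee")
    act_addr = (
        rl.xs("mind", level="action") - rl.xs("object", level="action")
    ).sort_index().to_numpy()
    return {
        "action_by_sign_lateral": action_by_sign,
        "addressee_lateral": addressee,
        "action_by_addressee_lateral_velocity": act_addr,
    }


def stage_permtest(cfg: PipelineConfig, retained: pd.DataFrame | None = None,
                   profiles: pd.DataFrame | None = None,
                   profiles_v: pd.DataFrame | None = None) -> dict:
    out_dir = Path(cfg.out_dir)
    if retained is None:
        retained = pd.read_csv(out_dir / "exclusion" / "retained.csv", dtype={"trial_id": str}, float_precision="round_trip")
    if profiles is None:
        profiles = pd.read_csv(out_dir / "params" / "profiles_x.csv", index_col="trial_id", float_precision="round_trip")
        profiles.index = profiles.index.astype(str)
    if profiles_v is None:
        profiles_v = pd.read_csv(out_dir / "params" / "profiles_vx.csv", index_col="trial_id", float_precision="round_trip")
        profiles_v.index = profiles_v.index.astype(str)

    perm_cfg = replace(cfg.permutation, seed=np.random.SeedSequence([cfg.seed, 7]).entropy % (2**31)
                       if cfg.permutation.seed is None else cfg.permutation.seed)
    contrasts = _profile_contrasts(cfg, retained, profiles, profiles_v)
    results = {}
    for name, diffs in contrasts.items():
        res = cluster_permutation_ttest(diffs, perm_cfg)
        results[name] = {
            "threshold": res.threshold,
            "n_permutations": res.n_permutations,
            "tail": res.tail,
            "clusters": [
                {"start": c.start, "stop": c.stop, "mass": c.mass, "p": c.p, "sign": c.sign}
                for c in res.clusters
            ],
        }
        log.info("permtest %s: %d cluster(s), min p = %.4g", name, len(res.clusters), res.min_p)
    out = _stage_dir(cfg, "permtest")
    with open(out / "clusters.json", "w") as fh:
        json.dump(results, fh, indent=1, default=float)
    return results


def analyze_experiment(
    experiment,
    filter_cfg: FilterConfig = FilterConfig(),
    seg_cfg: SegmentationConfig = SegmentationConfig(),
    excl_cfg: ExclusionConfig = ExclusionConfig(),
):
    """In-memory filter -> segment -> extract -> exclude for an
    :class:`~pointkin.simulate.Experiment`.

    Returns ``(retained, report, profiles_x, profiles_vx)`` where the
    profile frames are indexed by trial_id (valid trials only).  Useful for
    simulation studies that do not need persisted intermediates.
    """
    geometry = experiment.design.geometry
    frame = experiment.design.reporting_frame
    rows, prof_x, prof_vx, ids = [], [], [], []
    for tr in experiment.trials:
        f = lowpass_filter(tr.series, filter_cfg)
        vel = compute_velocity(f)
        bounds = segment_trial(f, seg_cfg, geometry, velocity=vel)
        summary = extract_parameters(f, bounds, frame, velocity=vel)
        rec = {
            "trial_id": tr.trial_id,
            "subject": tr.subject,
            "block": tr.block,
            "trial_in_block": tr.trial_in_block,
            "action": tr.action,
            "addressee": tr.addressee,
            "sign": tr.sign,
            "communicator_correct": tr.communicator_correct,
            "addressee_correct": tr.addressee_correct,
        }
        rec.update(summary.as_dict())
        rec["valid_movement"] = summary.valid
        rows.append(rec)
        if summary.valid:
            prof = time_normalize(f, bounds)
            ids.append(tr.trial_id)
            prof_x.append(prof.position[:, 0])
            prof_vx.append(prof.velocity[:, 0])
    params = pd.DataFrame(rows)
    retained, report = apply_exclusions(params, excl_cfg)
    idx = pd.Index(ids, name="trial_id")
    return (
        retained,
        report,
        pd.DataFrame(np.asarray(prof_x), index=idx),
        pd.DataFrame(np.asarray(prof_vx), index=idx),
    )


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the run report.

    Identical config + seed give identical outputs.  Stage failures abort
    with the stage name; completed intermediates remain for debugging.
    """
    report: dict = {
        "software_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": {},
    }
    state: dict = {}
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        t0 = _time.perf_counter()
        try:
            if stage == "simulate":
                stage_simulate(cfg)
                info = {"n_trials": cfg.design.n_subjects * cfg.design.n_trials_total}
            elif stage == "preprocess":
                state["series"] = stage_preprocess(cfg)
                info = {"n_filtered": len(state["series"])}
            elif stage == "segment":
                state["phases"] = stage_segment(cfg, state.get("series"))
                info = {
                    "n_trials": len(state["phases"]),
                    "n_valid": int(state["phases"]["valid"].sum()),
                }
            elif stage == "extract":
                params, profiles = stage_extract(cfg, state.get("series"), state.get("phases"))
                state["params"] = params
                info = {"n_params": len(params), "n_profiles": len(profiles)}
            elif stage == "exclude":
                retained, excl = stage_exclude(cfg, state.get("params"))
                state["retained"] = retained
                info = json.loads(excl.to_json())
                report["exclusion"] = info
            elif stage == "anova":
                payload = stage_anova(cfg, state.get("retained"))
                report["anova"] = payload["anova"]
                info = {"n_parameters": len(payload["anova"])}
            elif stage == "permtest":
                clusters = stage_permtest(cfg, state.get("retained"))
                report["clusters"] = clusters
                info = {k: len(v["clusters"]) for k, v in clusters.items()}
        except Exception as exc:  # noqa: BLE001 - annotate stage then re-raise
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        report["stages"][stage] = {
            "seconds": round(_time.perf_counter() - t0, 3),
            **info,
        }
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
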