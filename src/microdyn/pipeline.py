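"""End-to-end pipeline: configuration, orchestration, and the run report.

The analysis follows the standard two-level microstate workflow:

1. preprocess every subject (band-pass, average reference, 2-s epochs,
   amplitude-based rejection; subjects retaining less than a configurable
   fraction of their data are excluded),
2. per-subject AAHC of the GFP-peak maps down to k = 4 templates,
3. AAHC aggregation of subject templates per treatment group, then across the
   whole sample (grand mean maps),
4. hierarchical sorting: grand maps onto the canonical A–D labelling, group
   maps onto the grand maps, subject maps onto their group's maps,
5. backfitting of each subject's sorted templates onto the continuous data,
6. temporal statistics (duration, occurrence, coverage, transitions) and the
   group-level inference (TANOVA, split-plot ANOVAs, follow-ups, moderation).
"""
from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from ._version import __version__
from .containers import CLASSES, CohortTable, EpochSet, Montage, TemplateSet
from .dynamics import backfit_labels, compute_temporal_stats, compute_transition_stats
from .inference import (
    AnovaResult,
    ModerationResult,
    TanovaResult,
    anova_table,
    followup_oneway,
    mixed_anova,
    moderation_analysis,
    tanova_topography,
)
from .io import read_recording, write_recording, write_templates
from .preprocess import average_reference, bandpass_filter, reject_artifacts, segment_epochs
from .synthcohort import TRAITS, Cohort, SynthConfig, make_canonical_templates, simulate_cohort
from .topoclust import (
    aahc_cluster,
    aggregate_templates,
    compute_gev,
    compute_gfp,
    extract_gfp_peaks,
    sort_templates,
)


class FilterCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    low_hz: float = 2.0
    high_hz: float = 20.0
    order: int = 4


class EpochCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seconds: float = 2.0


class RejectCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_abs_uv: float = 100.0
    min_fraction_kept: float = 0.5


class ClusterCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k: int = 4
    max_gfp_maps: int | None = 1000  # random subsample of peak maps fed to AAHC
    min_separation_ms: float | None = None


class BackfitCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_duration_ms: float = 0.0  # short-run filter, off by default
    include_boundary_runs: bool = False


class StatsCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_perm: int = 5000
    alpha: float = 0.05
    sphericity_alpha: float = 0.05
    marginal_alpha: float = 0.10  # flag for "marginally significant" follow-ups
    moderators: tuple[str, ...] = (*TRAITS, "substance_rating")
    moderation_outcomes: tuple[str, ...] = ("duration_overall_ms",)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    simulate: SynthConfig | None = None
    cohort_dir: str | None = None
    out_dir: str | None = None
    filter: FilterCfg = FilterCfg()
    epoch: EpochCfg = EpochCfg()
    reject: RejectCfg = RejectCfg()
    cluster: ClusterCfg = ClusterCfg()
    backfit: BackfitCfg = BackfitCfg()
    stats: StatsCfg = StatsCfg()
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything a run produced, JSON-serialisable."""

    version: str
    config: dict
    config_hash: str
    n_subjects: int
    excluded_subjects: list[dict]
    per_subject: pd.DataFrame  # id, group, retained_s, gev_percent, duration_overall_ms
    grand_gev_percent: float
    mean_subject_gev_percent: float
    anovas: dict[str, pd.DataFrame]
    tanova_p: dict[str, float]
    followups: pd.DataFrame
    moderations: pd.DataFrame
    group_stats: pd.DataFrame  # group × class means of the characteristics
    decision_log: list[str]
    timings_s: dict[str, float] = field(default_factory=dict)

    def summary_dict(self) -> dict:
        return {
            "version": self.version,
            "config_hash": self.config_hash,
            "n_subjects": self.n_subjects,
            "excluded_subjects": self.excluded_subjects,
            "grand_gev_percent": self.grand_gev_percent,
            "mean_subject_gev_percent": self.mean_subject_gev_percent,
            "tanova_p": self.tanova_p,
            "per_subject": self.per_subject.to_dict(orient="records"),
            "anovas": {k: v.to_dict(orient="records") for k, v in self.anovas.items()},
            "followups": self.followups.to_dict(orient="records"),
            "moderations": self.moderations.to_dict(orient="records"),
            "group_stats": self.group_stats.to_dict(orient="records"),
            "decision_log": self.decision_log,
            "timings_s": self.timings_s,
            "config": self.config,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary_dict(), indent=1, default=float))


@dataclass
class CohortResult:
    """In-memory artefacts of `run_cohort` (templates, tables, report)."""

    report: RunReport
    cohort_table: CohortTable
    grand_templates: TemplateSet
    group_templates: dict[str, TemplateSet]
    subject_templates: dict[str, TemplateSet]
    canonical_templates: TemplateSet


def _subject_peak_maps(ep: EpochSet, cluster_cfg: ClusterCfg) -> np.ndarray:
    """Pool the GFP-peak topographies across a subject's artifact-free epochs."""
    maps = []
    for e in range(ep.n_epochs):
        gfp = compute_gfp(ep.epochs[e])
        peaks = extract_gfp_peaks(gfp, cluster_cfg.min_separation_ms, ep.fs)
        if peaks.size:
            maps.append(ep.epochs[e][:, peaks].T)
    if not maps:
        return np.empty((0, ep.n_channels))
    return np.concatenate(maps, axis=0)


def run_cohort(
    subject_epochs: list[EpochSet],
    subjects: pd.DataFrame,
    cfg: PipelineConfig,
    montage: Montage,
) -> CohortResult:
    """Run stages 2–6 on preprocessed, in-memory epoch sets.

    ``subjects`` needs columns ``subject_id`` and ``group`` (plus any trait /
    rating columns used by the moderation analyses); row order matches
    ``subject_epochs``.
    """
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    rng = np.random.default_rng(cfg.seed)
    k = cfg.cluster.k
    ids = subjects["subject_id"].tolist()
    groups = subjects["group"].tolist()
    group_levels = list(dict.fromkeys(groups))  # preserve first-appearance order

    # --- subject-level clustering -------------------------------------------------
    peak_maps: dict[str, np.ndarray] = {}
    subj_ts: dict[str, TemplateSet] = {}
    for sid, ep in zip(ids, subject_epochs):
        pm = _subject_peak_maps(ep, cfg.cluster)
        if pm.shape[0] < k:
            raise ValueError(f"subject {sid}: fewer GFP-peak maps than k={k}")
        peak_maps[sid] = pm
        sel = pm
        if cfg.cluster.max_gfp_maps and pm.shape[0] > cfg.cluster.max_gfp_maps:
            idx = rng.choice(pm.shape[0], cfg.cluster.max_gfp_maps, replace=False)
            sel = pm[np.sort(idx)]
        subj_ts[sid] = aahc_cluster(sel, k=k, level="subject", montage=montage)
    timings["subject_clustering"] = time.perf_counter() - t0

    # --- two-level aggregation and hierarchical sorting ---------------------------
    t1 = time.perf_counter()
    group_ts = {
        gl: aggregate_templates(
            [subj_ts[sid] for sid, g in zip(ids, groups) if g == gl], k=k, level="group"
        )
        for gl in group_levels
    }
    grand_ts = aggregate_templates([subj_ts[sid] for sid in ids], k=k, level="grand")
    canonical = make_canonical_templates(montage, k=4) if k == 4 else None
    if canonical is not None:
        grand_ts = sort_templates(grand_ts, canonical)
    group_ts = {gl: sort_templates(ts, grand_ts) for gl, ts in group_ts.items()}
    subj_sorted = {
        sid: sort_templates(subj_ts[sid], group_ts[g]) for sid, g in zip(ids, groups)
    }
    timings["aggregation_sorting"] = time.perf_counter() - t1

    # --- backfitting and temporal statistics --------------------------------------
    t2 = time.perf_counter()
    stats_rows, trans_rows, subj_rows = [], [], []
    for sid, g, ep in zip(ids, groups, subject_epochs):
        ts = subj_sorted[sid]
        ls = backfit_labels(
            ep, ts,
            min_separation_ms=cfg.cluster.min_separation_ms,
            min_duration_ms=cfg.backfit.min_duration_ms,
        )
        tstats = compute_temporal_stats(
            ls, include_boundary_runs=cfg.backfit.include_boundary_runs
        )
        ttable = compute_transition_stats(ls)
        gev = compute_gev(ep, ts, ls.labels)
        stats_rows.append(tstats.to_frame(sid))
        trans_rows.append(ttable.to_frame(sid))
        subj_rows.append(
            {
                "subject_id": sid,
                "group": g,
                "retained_s": ep.retained_seconds,
                "gev_percent": gev,
                "duration_overall_ms": tstats.duration_overall_ms,
                "occurrence_C_per_s": tstats.occurrence_per_s.get("C", np.nan),
                "coverage_C_percent": tstats.coverage_percent.get("C", np.nan),
                "coverage_D_percent": tstats.coverage_percent.get("D", np.nan),
                "delta_BC_percent": ttable.delta_percent[1, 2] if k == 4 else np.nan,
            }
        )
    per_subject = pd.DataFrame(subj_rows)
    extra_cols = [c for c in subjects.columns if c not in ("subject_id", "group")]
    subjects_full = per_subject.merge(
        subjects[["subject_id", *extra_cols]], on="subject_id", how="left"
    )
    ct = CohortTable(
        subjects=subjects_full,
        stats_long=pd.concat(stats_rows, ignore_index=True),
        transitions_long=pd.concat(trans_rows, ignore_index=True),
    )
    timings["backfit_stats"] = time.perf_counter() - t2

    # --- inference -----------------------------------------------------------------
    t3 = time.perf_counter()
    tanova_p: dict[str, float] = {}
    if len(group_levels) == 2:
        g1, g2 = group_levels
        for j, cls in enumerate(grand_ts.labels):
            m1 = np.stack([subj_sorted[sid].maps[j] for sid, g in zip(ids, groups) if g == g1])
            m2 = np.stack([subj_sorted[sid].maps[j] for sid, g in zip(ids, groups) if g == g2])
            res: TanovaResult = tanova_topography(m1, m2, n_perm=cfg.stats.n_perm, seed=rng)
            tanova_p[cls] = res.p_value

    anovas: dict[str, pd.DataFrame] = {}
    anova_results: dict[str, dict[str, AnovaResult]] = {}
    for dv in ("duration", "occurrence", "coverage", "transitions"):
        try:
            res = mixed_anova(ct, dv, alpha_sphericity=cfg.stats.sphericity_alpha)
        except ValueError as exc:  # e.g. single group
            warnings.warn(f"mixed ANOVA for {dv} skipped: {exc}")
            continue
        anova_results[dv] = res
        anovas[dv] = anova_table(res).assign(characteristic=dv)

    followup_rows = []
    if len(group_levels) == 2:
        for dv, col in (
            ("duration", "duration_ms"),
            ("occurrence", "occurrence_per_s"),
            ("coverage", "coverage_percent"),
        ):
            long = ct.long(dv)
            for cls in CLASSES[:k]:
                sel = long[long["level"] == cls].dropna(subset=["value"])
                ow = followup_oneway(sel["value"], sel["group"])
                followup_rows.append(
                    {"characteristic": dv, "cell": cls, "F": ow.F, "df_den": ow.df_den,
                     "p": ow.p, "p_adjusted": ow.p_adjusted, "eta_sq": ow.eta_sq,
                     "marginal": ow.p < cfg.stats.marginal_alpha, **ow.group_means}
                )
        trans = ct.long("transitions")
        m = k * (k - 1)
        for cell in sorted(trans["level"].unique()):
            sel = trans[trans["level"] == cell]
            ow = followup_oneway(sel["value"], sel["group"], bonferroni_m=m)
            followup_rows.append(
                {"characteristic": "transitions", "cell": cell, "F": ow.F,
                 "df_den": ow.df_den, "p": ow.p, "p_adjusted": ow.p_adjusted,
                 "eta_sq": ow.eta_sq, "marginal": ow.p_adjusted < cfg.stats.marginal_alpha,
                 **ow.group_means}
            )
    followups = pd.DataFrame(followup_rows)

    moderation_rows = []
    if len(group_levels) == 2:
        for outcome in cfg.stats.moderation_outcomes:
            if outcome not in subjects_full.columns:
                continue
            for mod in cfg.stats.moderators:
                if mod not in subjects_full.columns:
                    continue
                dfm = subjects_full.dropna(subset=[outcome, mod])
                try:
                    mr: ModerationResult = moderation_analysis(
                        dfm[outcome], dfm["group"], dfm[mod],
                        group_order=(group_levels[1], group_levels[0]),
                    )
                except ValueError as exc:
                    warnings.warn(f"moderation {outcome} × {mod} skipped: {exc}")
                    continue
                row = {
                    "outcome": outcome, "moderator": mod,
                    "delta_r_sq_percent": mr.delta_r_sq, "F": mr.F_interaction,
                    "df_den": mr.df_den, "p": mr.p_interaction,
                }
                for gl, (r, pr, dfr) in mr.within_group.items():
                    row[f"r_{gl}"] = r
                    row[f"p_r_{gl}"] = pr
                moderation_rows.append(row)
    moderations = pd.DataFrame(moderation_rows)
    timings["inference"] = time.perf_counter() - t3

    group_stats = (
        ct.stats_long.assign(group=ct.stats_long["subject_id"].map(
            dict(zip(ids, groups))))
        .groupby(["group", "class"], sort=False)[
            ["duration_ms", "occurrence_per_s", "coverage_percent"]]
        .mean()
        .reset_index()
    )

    decision_log = [
        f"filter: zero-phase Butterworth order {cfg.filter.order} per pass, "
        f"{cfg.filter.low_hz}-{cfg.filter.high_hz} Hz",
        f"rejection: +/-{cfg.reject.max_abs_uv} uV; subject exclusion below "
        f"{cfg.reject.min_fraction_kept:.0%} retained",
        f"clustering: AAHC, k={k}, worst cluster by summed GEV contribution "
        f"(ties: smaller size, lower index); "
        f"max {cfg.cluster.max_gfp_maps} GFP-peak maps per subject",
        "backfit: nearest-GFP-peak interpolation, midpoint boundary "
        "(equidistant sample joins the later peak)",
        ("boundary runs included in duration/occurrence"
         if cfg.backfit.include_boundary_runs
         else "boundary-truncated runs excluded from duration/occurrence, "
              "included in coverage"),
        (f"short-run filter at {cfg.backfit.min_duration_ms} ms"
         if cfg.backfit.min_duration_ms > 0 else "no minimum-duration filter"),
        f"TANOVA: {cfg.stats.n_perm} permutations, observed included in the null",
        f"GG correction applied when Mauchly p < {cfg.stats.sphericity_alpha}",
        f"seed: {cfg.seed}",
    ]

    report = RunReport(
        version=__version__,
        config=cfg.model_dump(mode="json"),
        config_hash=cfg.config_hash(),
        n_subjects=len(ids),
        excluded_subjects=[],
        per_subject=per_subject,
        grand_gev_percent=float(grand_ts.gev_percent),
        mean_subject_gev_percent=float(per_subject["gev_percent"].mean()),
        anovas=anovas,
        tanova_p=tanova_p,
        followups=followups,
        moderations=moderations,
        group_stats=group_stats,
        decision_log=decision_log,
        timings_s=timings,
    )
    return CohortResult(
        report=report,
        cohort_table=ct,
        grand_templates=grand_ts,
        group_templates=group_ts,
        subject_templates=subj_sorted,
        canonical_templates=canonical if canonical is not None else grand_ts,
    )


def run_pipeline(cfg: PipelineConfig) -> CohortResult:
    """Execute the full pipeline from a simulated or on-disk cohort.

    Exactly one of ``cfg.simulate`` / ``cfg.cohort_dir`` must be set. Subjects
    whose retained data fraction falls below ``reject.min_fraction_kept`` (or
    whose epochs are all rejected) are excluded and logged, mirroring the
    usual "<50 % of data" exclusion rule. Deterministic under fixed seeds.
    """
    if (cfg.simulate is None) == (cfg.cohort_dir is None):
        raise ValueError("set exactly one of simulate / cohort_dir")

    t0 = time.perf_counter()
    if cfg.simulate is not None:
        cohort = simulate_cohort(cfg.simulate)
        montage = cohort.montage
        subjects = cohort.table
        loader = (cohort.subject_recording(i)[0] for i in range(cohort.n_subjects))
    else:
        cohort_dir = Path(cfg.cohort_dir)
        subjects = pd.read_csv(cohort_dir / "cohort.csv")
        first = read_recording(cohort_dir / subjects["subject_id"].iloc[0])
        montage = first.montage
        def _iter():
            yield first
            for sid in subjects["subject_id"].iloc[1:]:
                yield read_recording(cohort_dir / sid)
        loader = _iter()

    epoch_sets, kept_rows, excluded = [], [], []
    for (_, row), rec in zip(subjects.iterrows(), loader):
        n_candidates = None
        try:
            filtered = average_reference(bandpass_filter(
                rec, cfg.filter.low_hz, cfg.filter.high_hz, cfg.filter.order))
            seg = segment_epochs(filtered, cfg.epoch.seconds)
            n_candidates = seg.n_epochs
            ep = reject_artifacts(seg, cfg.reject.max_abs_uv)
        except ValueError as exc:
            excluded.append({"subject_id": row["subject_id"], "reason": str(exc)})
            continue
        frac = ep.n_epochs / n_candidates if n_candidates else 0.0
        if frac < cfg.reject.min_fraction_kept:
            excluded.append({
                "subject_id": row["subject_id"],
                "reason": f"only {frac:.0%} of epochs retained",
            })
            continue
        ep.epochs = ep.epochs.astype(np.float32)  # bound pipeline memory
        epoch_sets.append(ep)
        kept_rows.append(row)
    if not epoch_sets:
        raise ValueError("no subjects survived preprocessing")
    kept = pd.DataFrame(kept_rows).reset_index(drop=True)

    result = run_cohort(epoch_sets, kept, cfg, montage)
    result.report.excluded_subjects = excluded
    result.report.timings_s["preprocess"] = time.perf_counter() - t0

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.report.save(out / "report.json")
        write_templates(result.grand_templates, out / "templates_grand")
        for gl, ts in result.group_templates.items():
            write_templates(ts, out / f"templates_group_{gl}")
        ct = result.cohort_table
        ct.subjects.to_csv(out / "subjects.csv", index=False)
        ct.stats_long.to_csv(out / "temporal_stats.csv", index=False)
        ct.transitions_long.to_csv(out / "transitions.csv", index=False)
    return result


def simulate_to_dir(config: SynthConfig, out_dir: str | Path) -> Path:
    """Materialise a synthetic cohort: one container per subject + cohort.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    for i in range(cohort.n_subjects):
        rec, gt = cohort.subject_recording(i)
        write_recording(rec, out / gt.subject_id)
    cols = ["subject_id", "group", *TRAITS, "substance_rating"]
    cohort.table[cols].to_csv(out / "cohort.csv", index=False)
    truth_cols = [c for c in cohort.table.columns if c.startswith("dwell_")] + [
        "planted_effect_ms"]
    cohort.table[["subject_id", *truth_cols]].to_csv(out / "ground_truth.csv", index=False)
    write_templates(cohort.templates, out / "templates_planted")
    (out / "config.json").write_text(config.model_dump_json(indent=1))
    return out
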