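"""End-to-end orchestration: simulate -> physio -> preprocess -> ICA ->
group clustering -> statistics -> report.

Every stage seed derives from the master seed so a run is reproducible
end to end; the JSON report records matched networks, cluster tables,
behavioural statistics and every threshold actually applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .group_networks import (
    sogica_cluster,
    subject_network_zmaps,
    templates_from_atlas,
)
from .ica import decompose_subject
from .physio import cardiac_rate, respiratory_rate, tumescence_percent_change
from .preprocess import preprocess_subject
from .stats import (
    MonteCarloResult,
    StatsConfig,
    behavioral_group_tests,
    montecarlo_min_cluster,
    roi_behavior_correlation,
    roi_group_ttest,
    threshold_and_label,
    voxelwise_group_anova,
)
from .synthdata import Cohort, CohortConfig, simulate_cohort

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "analyze_cohort", "make_fixtures"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    n_components: int = 30
    n_clusters: int | None = None
    r_min: float = 0.25
    n_discard: int = 2
    fwhm_mm: float = 6.0
    regress_nuisance: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig(**d["cohort"])
        if "stats" in d and isinstance(d["stats"], dict):
            d["stats"] = StatsConfig(**d["stats"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _physio_summaries(cohort: Cohort) -> pd.DataFrame:
    """Reduce each subject's traces to TR-locked summaries."""
    cfg = cohort.config
    rows = []
    for s in cohort.subjects:
        if not s.physio:
            continue
        _, tum = tumescence_percent_change(s.physio["tumescence"], cfg.tr_s, cfg.n_volumes)
        _, card = cardiac_rate(s.physio["cardiac_events"], cfg.tr_s, cfg.n_volumes)
        _, resp = respiratory_rate(s.physio["respiratory"], cfg.tr_s, cfg.n_volumes)
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "tumescence_pct_mean": tum,
                "cardiac_rate_bpm": card,
                "respiratory_rate_cpm": resp,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AnalysisResult:
    networks: dict  # name -> {"subjects": [...], "zmaps": {group: array}}
    matched: list[str]
    absent: list[str]
    cluster_tables: dict  # network -> ClusterTable
    roi_tests: dict  # network -> list of per-cluster dicts
    min_cluster: MonteCarloResult | None
    behavioural: pd.DataFrame
    physio_summaries: pd.DataFrame
    correlations: pd.DataFrame
    decompositions: list


def analyze_cohort(
    cohort: Cohort,
    run_cfg: RunConfig | None = None,
    mc_result: MonteCarloResult | None = None,
    with_stats: bool = True,
) -> AnalysisResult:
    """Run preprocessing, ICA, clustering, matching and statistics in memory."""
    if run_cfg is None:
        run_cfg = RunConfig(cohort=cohort.config)
    cfg = cohort.config
    mask = cohort.brain

    try:
        physio_df = _physio_summaries(cohort)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("physio", str(exc)) from exc

    subject_ics = []
    for s in cohort.subjects:
        try:
            pre = preprocess_subject(
                s.volume,
                s.wm_mask,
                s.csf_mask,
                n_discard=run_cfg.n_discard,
                fwhm_mm=run_cfg.fwhm_mm,
                regress_nuisance=run_cfg.regress_nuisance,
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("preprocess", f"{s.subject_id}: {exc}") from exc
        try:
            decomp = decompose_subject(
                pre, mask, n_components=run_cfg.n_components, seed=s.truth.seed + 101
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("ica", f"{s.subject_id}: {exc}") from exc
        subject_ics.append((s.subject_id, decomp))

    try:
        clusters = sogica_cluster(subject_ics, n_clusters=run_cfg.n_clusters or run_cfg.n_components)
        templates = templates_from_atlas(cohort.atlas, mask)
        zmaps = subject_network_zmaps(clusters, templates, subject_ics, r_min=run_cfg.r_min)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("group", str(exc)) from exc

    matched = sorted(zmaps)
    absent = sorted(set(t.name for t in templates) - set(matched))

    groups_of = {s.subject_id: s.group for s in cohort.subjects}
    networks: dict = {}
    for name, per_subject in zmaps.items():
        by_group = {"EDp": [], "HC": []}
        sids = {"EDp": [], "HC": []}
        for sid in sorted(per_subject):
            g = groups_of[sid]
            by_group[g].append(per_subject[sid])
            sids[g].append(sid)
        networks[name] = {
            "zmaps": {g: np.asarray(v) for g, v in by_group.items()},
            "subjects": sids,
        }

    cluster_tables: dict = {}
    roi_tests: dict = {}
    correlations_rows = []
    subjects_df = cohort.subjects_table()
    behavioural = pd.DataFrame()
    if with_stats:
        try:
            if mc_result is None:
                mc_result = montecarlo_min_cluster(mask, run_cfg.stats)
            for name, nd in networks.items():
                a, b = nd["zmaps"]["EDp"], nd["zmaps"]["HC"]
                if len(a) < 2 or len(b) < 2:
                    raise ValueError(
                        f"network {name}: need >= 2 subjects per group "
                        f"(got {len(a)} EDp, {len(b)} HC)"
                    )
                statmap = voxelwise_group_anova(a, b, mask, cohort.atlas.grid)
                table = threshold_and_label(
                    statmap,
                    run_cfg.stats.voxel_p,
                    mc_result.min_cluster_size,
                    run_cfg.stats.connectivity,
                )
                cluster_tables[name] = table
                tests = []
                edp_scores = subjects_df[subjects_df["group"] == "EDp"]
                for _, row in table.clusters.iterrows():
                    roi = table.cluster_mask(int(row["label"]))[mask]
                    res = roi_group_ttest(a, b, roi)
                    res["label"] = int(row["label"])
                    tests.append(res)
                    # Brain-behaviour correlation within the patient group.
                    roi_vals = np.asarray(a)[:, roi].mean(axis=1)
                    edp_sids = nd["subjects"]["EDp"]
                    sc = edp_scores.set_index("subject_id").loc[edp_sids]
                    for score in ("SAI_E", "IIEF5"):
                        if score in sc.columns and len(roi_vals) >= 3:
                            r, p = roi_behavior_correlation(roi_vals, sc[score].to_numpy())
                            correlations_rows.append(
                                {"network": name, "cluster": int(row["label"]),
                                 "score": score, "r": r, "p": p, "n": len(roi_vals)}
                            )
                roi_tests[name] = tests
            merged = subjects_df.merge(
                physio_df.drop(columns=["group"]), on="subject_id", how="left"
            ) if len(physio_df) else subjects_df
            behavioural = behavioral_group_tests(merged)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("stats", str(exc)) from exc

    return AnalysisResult(
        networks=networks,
        matched=matched,
        absent=absent,
        cluster_tables=cluster_tables,
        roi_tests=roi_tests,
        min_cluster=mc_result if with_stats else None,
        behavioural=behavioural,
        physio_summaries=physio_df,
        correlations=pd.DataFrame(correlations_rows),
        decompositions=subject_ics,
    )


def _report_dict(cohort: Cohort, run_cfg: RunConfig, result: AnalysisResult) -> dict:
    report = {
        "version": __version__,
        "config": run_cfg.to_dict(),
        "master_seed": cohort.config.master_seed,
        "networks_matched": result.matched,
        "networks_absent": result.absent,
        "thresholds": {
            "voxel_p": run_cfg.stats.voxel_p,
            "alpha": run_cfg.stats.alpha,
            "min_cluster_size": (
                result.min_cluster.min_cluster_size if result.min_cluster else None
            ),
            "mask_voxels": (
                result.min_cluster.mask_voxels if result.min_cluster else None
            ),
        },
        "cluster_tables": {
            name: tab.clusters.to_dict(orient="records")
            for name, tab in result.cluster_tables.items()
        },
        "roi_tests": result.roi_tests,
        "behavioural": result.behavioural.to_dict(orient="records"),
        "correlations": result.correlations.to_dict(orient="records"),
    }
    return report


def run_pipeline(run_cfg: RunConfig, out_dir: str | Path) -> dict:
    """Simulate a cohort and run the full analysis, writing all outputs.

    Returns the report dictionary (also written as ``report.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        cohort = simulate_cohort(run_cfg.cohort)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", str(exc)) from exc
    result = analyze_cohort(cohort, run_cfg)

    cohort.subjects_table().to_csv(out / "subjects.tsv", sep="\t", index=False)
    result.physio_summaries.to_csv(out / "physio_summaries.tsv", sep="\t", index=False)
    result.behavioural.to_csv(out / "behavioural_tests.tsv", sep="\t", index=False)
    result.correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)
    for name, tab in result.cluster_tables.items():
        tab.clusters.to_csv(out / f"clusters_{name}.tsv", sep="\t", index=False)
    run_cfg.to_yaml(out / "config.yaml")
    report = _report_dict(cohort, run_cfg, result)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report


def make_fixtures(size: str = "tiny", master_seed: int = 0) -> RunConfig:
    """Packaged test configurations.

    ``tiny``: 4+4 subjects on a coarse 6-mm grid, 60 volumes, 10 components
    (fast enough for continuous testing). ``demo``: the full 16+19 cohort at
    default settings.
    """
    if size == "tiny":
        cohort = CohortConfig(
            n_EDp=4, n_HC=4, n_volumes=60, voxel_mm=6.0, master_seed=master_seed
        )
        stats = StatsConfig(n_iterations=200, sim_seed=master_seed)
        return RunConfig(cohort=cohort, stats=stats, n_components=10)
    if size == "demo":
        cohort = CohortConfig(master_seed=master_seed)
        stats = StatsConfig(sim_seed=master_seed)
        return RunConfig(cohort=cohort, stats=stats, n_components=30)
    raise ValueError("size must be 'tiny' or 'demo'")
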