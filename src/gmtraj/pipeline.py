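"""End-to-end orchestration: simulate -> mask -> fit -> cluster -> crossover -> report.

A single :class:`RunConfig` (one YAML file on disk) drives the whole analysis.
One global seed derives the per-stage seeds (seed + stage index) so any stage
can be re-run in isolation; every run writes a resolved-config copy with a
content hash alongside its tables.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster_mc import ClusterParams, extent_threshold, extract_cluster_table, simulate_null_max_clusters
from .crossover import (
    cross_term_check,
    crossover_point,
    extract_roi_means,
    fit_roi_trend,
    summarize_crossovers,
    welch_beyond_crossover,
)
from .robust_glm import build_design, critical_t, fit_voxelwise, split_by_sign
from .synth import CohortConfig, generate_covariates, generate_gm_maps, load_cohort, write_cohort
from .volume_io import make_analysis_mask, write_mask, write_stat_map

__all__ = ["RunConfig", "AnalysisResult", "run_full_analysis", "write_report"]

# stage indices for seed derivation
_STAGE_SIMULATE = 0
_STAGE_MONTECARLO = 1


@dataclass
class RunConfig:
    """Resolved settings for one full analysis run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    terms: tuple[str, ...] = ("abstinence_weeks", "years_use")
    nuisance: tuple[str, ...] = ("age",)
    roi_nuisance: tuple[str, ...] = ()
    mask_threshold: float = 0.05
    seed: int = 0
    out_dir: str | None = None
    manifest: str | None = None  # load this cohort instead of simulating
    write_maps: bool = False

    def __post_init__(self):
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig.from_dict(self.cohort)
        if isinstance(self.cluster, dict):
            self.cluster = ClusterParams(**self.cluster)
        self.terms = tuple(self.terms)
        self.nuisance = tuple(self.nuisance)
        self.roi_nuisance = tuple(self.roi_nuisance)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["terms"] = list(self.terms)
        d["nuisance"] = list(self.nuisance)
        d["roi_nuisance"] = list(self.roi_nuisance)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class AnalysisResult:
    """Everything a run produced, in memory."""

    config: RunConfig
    cohort: pd.DataFrame
    statmaps: object
    extent_voxels: int
    extent_ul: float
    t_critical: float
    clusters: pd.DataFrame
    crossovers: pd.DataFrame
    summaries: dict
    cluster_labels: dict
    truth: list | None = None


_OTHER_TERM = {"abstinence_weeks": "years_use", "years_use": "abstinence_weeks"}


def run_full_analysis(config: RunConfig) -> AnalysisResult:
    """Execute every stage in order; writes artifacts when ``out_dir`` is set."""
    # --- stage: cohort (simulate or load) -----------------------------------
    try:
        if config.manifest:
            cohort, maps = load_cohort(config.manifest)
            truth = None
        else:
            cc = CohortConfig.from_dict(config.cohort.to_dict())
            cc.seed = config.seed + _STAGE_SIMULATE
            cohort, maps = _simulate(cc)
            config.cohort = cc
            truth = maps[1]
            maps = maps[0]
    except Exception as e:
        raise RuntimeError(f"stage 'cohort' failed: {e}") from e

    # validate design inputs before any fitting (names the missing column)
    design = build_design(cohort, terms=(*config.terms, *config.nuisance))

    # --- stage: mask --------------------------------------------------------
    try:
        mask = make_analysis_mask(maps, mean_threshold=config.mask_threshold)
    except Exception as e:
        raise RuntimeError(f"stage 'mask' failed: {e}") from e

    # --- stage: voxelwise robust regression ---------------------------------
    try:
        is_cd = (cohort["group"] == "CD").to_numpy()
        cd_maps = [m for m, c in zip(maps, is_cd) if c]
        statmaps = fit_voxelwise(cd_maps, design, mask)
        t_crit = critical_t(config.cluster.voxel_p_two_tailed, statmaps.df_resid)
    except Exception as e:
        raise RuntimeError(f"stage 'fit' failed: {e}") from e

    # --- stage: Monte-Carlo extent threshold --------------------------------
    try:
        params = ClusterParams(**{**asdict(config.cluster), "seed": config.seed + _STAGE_MONTECARLO})
        null = simulate_null_max_clusters(mask, params)
        ext = extent_threshold(null, params.alpha_fwe, voxel_volume=mask.voxel_volume_ul)
    except Exception as e:
        raise RuntimeError(f"stage 'cluster-null' failed: {e}") from e

    # --- stage: clusters + crossovers ---------------------------------------
    cluster_frames = []
    crossover_rows = []
    labels_by_key = {}
    for term in config.terms:
        pos_t, neg_t = split_by_sign(statmaps.beta[term], statmaps.t[term])
        for polarity, tmap in (("positive", pos_t), ("negative", neg_t)):
            ctab = extract_cluster_table(
                tmap, t_crit, ext.size_voxels, mask.affine,
                connectivity=params.connectivity, term=term, polarity=polarity,
            )
            cluster_frames.append(ctab.table)
            labels_by_key[(term, polarity)] = ctab.labels
            for cid in ctab.table["cluster_id"]:
                series = extract_roi_means(maps, cohort, ctab.labels, cid)
                fit = fit_roi_trend(series, term, nuisance=config.roi_nuisance)
                xr = crossover_point(fit, series.control_mean, cluster_id=cid)
                welch = welch_beyond_crossover(series, xr.crossover, covariate=term)
                other = _OTHER_TERM.get(term)
                cross = (
                    cross_term_check(series, other) if other else
                    {"testable": False, "covariate": None, "slope": np.nan,
                     "t": np.nan, "p": np.nan, "significant": False}
                )
                crossover_rows.append(
                    {
                        "term": term,
                        "polarity": polarity,
                        "cluster_id": cid,
                        "slope": xr.slope,
                        "intercept": xr.intercept,
                        "control_mean": xr.control_mean,
                        "crossover": xr.crossover,
                        "valid": xr.valid,
                        "welch_t": welch.t,
                        "welch_df": welch.df,
                        "welch_p": welch.p,
                        "n_beyond": welch.n_beyond,
                        "cross_term": cross["covariate"],
                        "cross_term_t": cross["t"],
                        "cross_term_p": cross["p"],
                        "cross_term_significant": cross["significant"],
                    }
                )
    nonempty = [f for f in cluster_frames if len(f)]
    clusters = (
        pd.concat(nonempty, ignore_index=True)
        if nonempty
        else pd.DataFrame(columns=cluster_frames[0].columns if cluster_frames else None)
    )
    crossovers = pd.DataFrame(crossover_rows)

    summaries = {}
    for (term, polarity), grp in (
        crossovers[crossovers["valid"]].groupby(["term", "polarity"])
        if len(crossovers)
        else ()
    ):
        summaries[(term, polarity)] = summarize_crossovers(grp["crossover"])

    result = AnalysisResult(
        config=config,
        cohort=cohort,
        statmaps=statmaps,
        extent_voxels=ext.size_voxels,
        extent_ul=ext.size_voxels * mask.voxel_volume_ul,
        t_critical=t_crit,
        clusters=clusters,
        crossovers=crossovers,
        summaries=summaries,
        cluster_labels=labels_by_key,
        truth=truth,
    )
    if config.out_dir:
        _write_artifacts(result, maps, mask)
    return result


def _simulate(cc: CohortConfig):
    cohort = generate_covariates(cc)
    maps, truth = generate_gm_maps(cohort, cc)
    return cohort, (maps, truth)


def _write_artifacts(result: AnalysisResult, maps, mask) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    resolved = yaml.safe_dump(result.config.to_dict(), sort_keys=True)
    digest = hashlib.sha256(resolved.encode()).hexdigest()
    (out / "resolved_config.yaml").write_text(resolved)
    (out / "provenance.yaml").write_text(
        yaml.safe_dump(
            {
                "gmtraj_version": __version__,
                "numpy_version": np.__version__,
                "config_sha256": digest,
                "seed": result.config.seed,
            }
        )
    )
    result.cohort.to_csv(out / "covariates.csv", index=False)
    result.clusters.to_csv(out / "clusters.tsv", sep="\t", index=False)
    result.crossovers.to_csv(out / "crossovers.tsv", sep="\t", index=False)
    write_mask(np.asarray(mask.data), mask.affine, out / "analysis_mask.nii.gz")
    if result.config.write_maps:
        write_cohort(result.cohort, maps, out / "cohort")
        for term in result.statmaps.terms:
            write_stat_map(result.statmaps.t[term], mask.affine, out / f"tmap_{term}.nii.gz")
            write_stat_map(result.statmaps.beta[term], mask.affine, out / f"betamap_{term}.nii.gz")
    write_report(result.clusters, result.crossovers, result.summaries, out / "report.md",
                 extent_ul=result.extent_ul, t_critical=result.t_critical)


def write_report(
    clusters: pd.DataFrame,
    crossovers: pd.DataFrame,
    summaries: dict,
    path,
    extent_ul: float = float("nan"),
    t_critical: float = float("nan"),
) -> Path:
    """Render the human-readable cluster/crossover summary as markdown."""
    lines = ["# Grey-matter trajectory analysis report", ""]
    lines.append(f"Voxel threshold |t| >= {t_critical:.3f}; cluster extent >= {extent_ul:.0f} ul.")
    lines.append("")
    if clusters is None or len(clusters) == 0:
        lines.append("**No surviving clusters.**")
    else:
        lines.append("## Clusters")
        lines.append("")
        lines.append("```")
        lines.append(clusters.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
        lines.append("```")
        lines.append("")
        lines.append("## Crossover points")
        lines.append("")
        cols = ["term", "polarity", "cluster_id", "slope", "intercept",
                "control_mean", "crossover", "welch_t", "welch_p"]
        lines.append("```")
        lines.append(crossovers[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        lines.append("```")
        lines.append("")
        if summaries:
            lines.append("## Crossover summaries")
            lines.append("")
            lines.append("| term | polarity | n | mean | sd | min | max |")
            lines.append("|---|---|---|---|---|---|---|")
            for (term, polarity), s in sorted(summaries.items()):
                sd = f"{s['sd']:.1f}" if s["sd"] is not None else "-"
                lines.append(
                    f"| {term} | {polarity} | {s['n']} | {s['mean']:.1f} | {sd} "
                    f"| {s['min']:.1f} | {s['max']:.1f} |"
                )
    path = Path(str(path))
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n")
    return path
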