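"""End-to-end orchestration: per-subject dynamics to cohort statistics.

``run_subject`` takes one ROI series through z-scoring, thresholding, bin
selection, avalanche extraction, and repertoire counting; ``run_cohort``
runs the group comparisons, phenotype-wise correlations, interaction
regression with 5-fold cross-validation, and the residual permutation test
on a cohort table; ``run_sweeps`` repeats the analysis over the threshold
and bin-length robustness grids.  Every report embeds the configuration
hash and seed so that equal configurations give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .avalanches import (
    AnalysisConfig,
    EventRaster,
    RoiTimeSeries,
    bin_raster,
    binarize,
    branching_ratio_overall,
    extract_avalanches,
    select_bin_length,
    zscore_transform,
)
from .repertoire import functional_repertoire
from .stats import (
    fdr_adjust,
    kfold_cv_predict,
    kruskal_wallis,
    residual_permutation_test,
    subgroup_correlations,
    wilcoxon_ranksum,
)

__all__ = ["RunConfig", "run_subject", "run_cohort", "run_sweeps"]

log = logging.getLogger("flexms")


@dataclass
class RunConfig:
    """Run-wide configuration (analysis knobs, paths, seed)."""

    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    series_dir: str | None = None
    cohort_csv: str | None = None
    output_dir: str = "results"
    sweep_thresholds: bool = False
    sweep_bins: bool = False
    seed: int = 0
    cv_folds: int = 5
    permutation_iterations: int = 10_000
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        analysis = AnalysisConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (raw.pop("analysis", {}) or {}).items()
        })
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(analysis=analysis, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _subject_dynamics(series: RoiTimeSeries, analysis: AnalysisConfig) -> dict:
    """Core per-recording computation on an already-loaded series."""
    z = zscore_transform(series)
    raster = binarize(z, analysis.z_threshold)
    if analysis.bin_length_policy == "critical-select":
        bin_length, sigma_table = select_bin_length(
            raster, analysis.bin_candidates, analysis.truncation_policy
        )
    else:
        bin_length = analysis.fixed_bin_length
        binned = bin_raster(raster, bin_length)
        aset = extract_avalanches(binned, analysis.truncation_policy)
        sigma_table = {bin_length: branching_ratio_overall(aset)}
    binned = bin_raster(raster, bin_length)
    aset = extract_avalanches(binned, analysis.truncation_policy)
    sigma = branching_ratio_overall(aset)
    rep = functional_repertoire(aset, subject_id=series.subject_id)
    return {
        "subject_id": series.subject_id,
        "recording_id": series.recording_id,
        "z_threshold": analysis.z_threshold,
        "bin_length": int(bin_length),
        "sigma": sigma,
        "sigma_table": {int(k): float(v) for k, v in sigma_table.items()},
        "n_avalanches": aset.n_avalanches,
        "n_excluded_single_bin": aset.n_excluded_single_bin,
        "n_truncated_discarded": aset.n_truncated_discarded,
        "repertoire_size": rep.size,
        "_repertoire": rep,  # in-memory only; stripped before serialization
        "_avalanche_set": aset,
    }


def run_subject(series_path: str | Path | RoiTimeSeries, config: RunConfig) -> dict:
    """Per-subject report: sigma table, chosen bin length, repertoire size."""
    t0 = time.time()
    series = (
        series_path
        if isinstance(series_path, RoiTimeSeries)
        else fio.read_series(series_path)
    )
    report = _subject_dynamics(series, config.analysis)
    report["config_hash"] = config.config_hash()
    report["seed"] = config.seed
    log.info("subject %s: %d avalanches, repertoire %d, sigma %.3f (%.1fs)",
             report["subject_id"], report["n_avalanches"], report["repertoire_size"],
             report["sigma"], time.time() - t0)
    return {k: v for k, v in report.items() if not k.startswith("_")}


def run_cohort(config: RunConfig, cohort: pd.DataFrame | None = None) -> dict:
    """Cohort statistics bundle on a clinical table with repertoire sizes.

    Runs the HC-vs-MS rank-sum comparison, the three-group Kruskal-Wallis
    test (BH-FDR over that family of group tests), phenotype-wise Spearman
    correlations of repertoire size with each clinical score, the EDSS
    interaction regression with k-fold cross-validation, and the residual
    permutation test between phenotypes.
    """
    if cohort is None:
        if config.cohort_csv is None:
            raise ValueError("no cohort table: set cohort_csv or pass a DataFrame")
        cohort = fio.read_cohort_csv(config.cohort_csv)
    required = {"group", "repertoire_size", "edss"}
    missing = sorted(required - set(cohort.columns))
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if cohort["group"].nunique() < 2:
        raise ValueError("need at least two groups")

    rep = cohort["repertoire_size"]
    hc = rep[cohort["group"] == "HC"].to_numpy(dtype=float)
    ms = rep[cohort["group"] != "HC"].to_numpy(dtype=float)
    ranksum = wilcoxon_ranksum(hc, ms)
    kw_groups = [
        rep[cohort["group"] == g].to_numpy(dtype=float)
        for g in ("HC", "RRMS", "SPMS")
        if (cohort["group"] == g).any()
    ]
    kw = kruskal_wallis(kw_groups)
    p_fdr = fdr_adjust([ranksum.p_value, kw.p_value])

    group_tests = pd.DataFrame(
        [
            {"test": "ranksum_HC_vs_MS", "statistic": ranksum.statistic,
             "p": ranksum.p_value, "p_fdr": p_fdr[0]},
            {"test": "kruskal_wallis_3group", "statistic": kw.statistic,
             "p": kw.p_value, "p_fdr": p_fdr[1]},
        ]
    )

    correlations = []
    for score in ("edss", "fss", "sdmt", "bdi", "disease_duration_months"):
        if score not in cohort.columns:
            continue
        tab = subgroup_correlations(cohort, "phenotype", score)
        tab.insert(0, "score", score)
        correlations.append(tab)
    correlations = pd.concat(correlations, ignore_index=True)

    regression = kfold_cv_predict(cohort, "edss", k=config.cv_folds, seed=config.seed)
    perm = residual_permutation_test(
        regression.residuals_standardized,
        regression.groups,
        n_iterations=config.permutation_iterations,
        seed=config.seed,
    )
    return {
        "group_tests": group_tests,
        "correlations": correlations,
        "regression": regression,
        "permutation": perm,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }


def _cohort_from_subject_rows(rows: list[dict], clinical: pd.DataFrame) -> pd.DataFrame:
    dyn = pd.DataFrame(rows)
    merged = clinical.drop(columns=["repertoire_size"], errors="ignore").merge(
        dyn[["subject_id", "repertoire_size"]], on="subject_id", how="inner"
    )
    return merged


def run_sweeps(
    config: RunConfig,
    series: dict[str, RoiTimeSeries] | None = None,
    clinical: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Robustness grid: repeat the pipeline per (threshold, bin length).

    For every combination of the configured threshold sweep and bin-length
    candidates, recompute each subject's repertoire size at that fixed
    setting and the headline HC-vs-MS rank-sum statistic.  Returns a
    long-format table with one row per (threshold, bin_length, subject).
    """
    thresholds = (
        list(config.analysis.threshold_sweep)
        if config.sweep_thresholds or config.analysis.threshold_sweep
        else [config.analysis.z_threshold]
    )
    bins = list(config.analysis.bin_candidates)
    if series is None:
        if config.series_dir is None:
            raise ValueError("no series: set series_dir or pass series mapping")
        paths = sorted(Path(config.series_dir).glob("*"))
        series = {p.stem: fio.read_series(p) for p in paths}
    if clinical is None and config.cohort_csv is not None:
        clinical = fio.read_cohort_csv(config.cohort_csv)

    z_cache = {sid: zscore_transform(s) for sid, s in series.items()}
    rows = []
    for thr in thresholds:
        rasters = {sid: binarize(z, thr) for sid, z in z_cache.items()}
        for L in bins:
            per_subject = {}
            for sid, raster in rasters.items():
                binned = bin_raster(raster, L)
                aset = extract_avalanches(binned, config.analysis.truncation_policy)
                try:
                    sigma = branching_ratio_overall(aset)
                except ValueError:
                    sigma = float("nan")
                rep = functional_repertoire(aset, subject_id=sid)
                per_subject[sid] = (rep.size, sigma, aset.n_avalanches)
            stat = p = float("nan")
            if clinical is not None:
                merged = clinical.drop(columns=["repertoire_size"], errors="ignore").copy()
                merged["repertoire_size"] = merged["subject_id"].map(
                    {sid: v[0] for sid, v in per_subject.items()}
                )
                merged = merged.dropna(subset=["repertoire_size"])
                hc = merged.loc[merged["group"] == "HC", "repertoire_size"]
                ms = merged.loc[merged["group"] != "HC", "repertoire_size"]
                if len(hc) and len(ms):
                    res = wilcoxon_ranksum(hc, ms)
                    stat, p = res.statistic, res.p_value
            for sid, (size, sigma, n_aval) in per_subject.items():
                rows.append({
                    "z_threshold": thr, "bin_length": L, "subject_id": sid,
                    "repertoire_size": size, "sigma": sigma, "n_avalanches": n_aval,
                    "ranksum_statistic": stat, "ranksum_p": p,
                })
    table = pd.DataFrame(rows)
    table.attrs["config_hash"] = config.config_hash()
    return table
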