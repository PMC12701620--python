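"""End-to-end orchestration: simulate/segment/extract/analyze with one log.

``analyze_cohort`` turns a cohort table into an :class:`AnalysisReport`
(correlation matrix, feature clusters, per-feature ROC summaries, median-
split log-rank results, univariate Cox fits and the stepwise multivariate
model, per endpoint).  ``run_pipeline`` wires a simulated cohort through the
analysis and writes deterministic CSV reports plus a run log.
"""
from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortSimParams, simulate_cohort
from .config import PipelineConfig
from .features import FEATURE_COLUMNS, extract_all
from .io import write_table
from .segmentation import label_components, min_size_filter, threshold_segment
from .survival import (
    DegenerateOutcomeError,
    censor_at_horizon,
    cox_stepwise,
    cox_univariate,
    median_followup,
    median_split_km,
    roc_horizon,
    spearman_cluster,
)
from .volume import SuvVolume

#: candidate set for the multivariate stepwise model: routine clinical
#: covariates plus one representative of each correlated feature family
STEPWISE_CANDIDATES = [
    "ecog_band",
    "ips_band",
    "bulky",
    "b_signs",
    "treatment",
    "suv_mean",
    "med_edge_d_mm",
    "tlg_g",
]

COX_UNIVARIATE_VARIABLES = ["ecog_band", "ips_band", "bulky", "b_signs", "treatment"] + FEATURE_COLUMNS


def extract_features_from_volume(volume: SuvVolume, config: PipelineConfig) -> pd.DataFrame:
    """Segment one volume and return its 12 features as a one-row table."""
    mask = threshold_segment(volume, config.threshold_suv)
    lesions = label_components(
        mask, volume.spacing_mm, volume.origin_mm, connectivity=config.connectivity
    )
    lesions = min_size_filter(lesions, config.min_voxels)
    fv = extract_all(volume, lesions, erosion_spacing_mm=config.erosion_spacing_mm)
    return pd.DataFrame([fv.as_dict()])


@dataclass
class AnalysisReport:
    correlation: pd.DataFrame
    clusters: pd.DataFrame  # feature, cluster
    roc: dict[str, pd.DataFrame]  # endpoint -> per-feature ROC table
    km: dict[str, pd.DataFrame]  # endpoint -> per-feature log-rank table
    cox_univariate: dict[str, pd.DataFrame]
    cox_multivariate: dict[str, pd.DataFrame]
    median_followup_years: float
    n_patients: int

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {"correlation": self.correlation, "clusters": self.clusters}
        for ep in self.roc:
            out[f"roc_{ep}"] = self.roc[ep]
            out[f"km_{ep}"] = self.km[ep]
            out[f"cox_univariate_{ep}"] = self.cox_univariate[ep]
            out[f"cox_multivariate_{ep}"] = self.cox_multivariate[ep]
        return out


def analyze_cohort(
    cohort: pd.DataFrame,
    config: PipelineConfig | None = None,
    endpoints: tuple[str, ...] = ("os", "pfs"),
) -> AnalysisReport:
    """Run the full statistical chain on a cohort table."""
    config = config or PipelineConfig()
    cohort = censor_at_horizon(cohort, config.horizon_years)

    corr, assignment = spearman_cluster(cohort)
    clusters = pd.DataFrame(
        {"feature": list(assignment.labels), "cluster": list(assignment.labels.values())}
    )

    roc_tables, km_tables, cox_uni, cox_multi = {}, {}, {}, {}
    for ep in endpoints:
        roc_rows, km_rows, cox_rows = [], [], []
        for feat in FEATURE_COLUMNS:
            try:
                r = roc_horizon(cohort, feat, ep, config.horizon_years)
                roc_rows.append(
                    {
                        "feature": feat,
                        "auc": r.auc,
                        "cutoff": r.cutoff,
                        "sensitivity_pct": 100 * r.sensitivity,
                        "specificity_pct": 100 * r.specificity,
                        "p_value": r.p_value,
                        "n_pos": r.n_pos,
                        "n_neg": r.n_neg,
                        "n_excluded": r.n_excluded,
                    }
                )
            except DegenerateOutcomeError:
                pass
            try:
                k = median_split_km(cohort, feat, ep)
                km_rows.append(
                    {
                        "feature": feat,
                        "median_threshold": k.threshold,
                        "chi_square": k.chi_square,
                        "p_value": k.p_value,
                    }
                )
            except DegenerateOutcomeError:
                pass
        for var in COX_UNIVARIATE_VARIABLES:
            try:
                fit = cox_univariate(cohort, var, ep)
                row = fit.table.iloc[0]
                cox_rows.append(
                    {
                        "variable": var,
                        "hazard_ratio": row["hazard_ratio"],
                        "ci_low": row["ci_low"],
                        "ci_high": row["ci_high"],
                        "p_value": row["p_value"],
                        "flagged": fit.flagged,
                    }
                )
            except DegenerateOutcomeError:
                pass
        roc_tables[ep] = pd.DataFrame(roc_rows)
        km_tables[ep] = pd.DataFrame(km_rows)
        cox_uni[ep] = pd.DataFrame(cox_rows)
        multi = cox_stepwise(cohort, STEPWISE_CANDIDATES, ep, config.stepwise_retention_p)
        cox_multi[ep] = multi.table.reset_index(names="variable")

    return AnalysisReport(
        correlation=corr,
        clusters=clusters,
        roc=roc_tables,
        km=km_tables,
        cox_univariate=cox_uni,
        cox_multivariate=cox_multi,
        median_followup_years=median_followup(cohort),
        n_patients=len(cohort),
    )


def write_report(report: AnalysisReport, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in report.tables().items():
        path = out_dir / f"{name}.csv"
        write_table(df, path, index=(name == "correlation"))
        written.append(path)
    return written


def run_pipeline(config: PipelineConfig, cohort: pd.DataFrame | None = None) -> tuple[AnalysisReport, dict]:
    """Simulate (or accept) a cohort, analyze it, and write report + log.

    Returns the report and the run log.  Report CSVs are byte-stable for a
    given config and seed; the log carries timestamps and therefore is not.
    """
    stages = []

    def record(stage: str, **counts) -> None:
        stages.append(
            {"stage": stage, "time": datetime.datetime.now().isoformat(), **counts}
        )

    if cohort is None:
        params = CohortSimParams(n_patients=config.n_patients, seed=config.seed)
        cohort = simulate_cohort(params)
        record("simulate_cohort", n_patients=len(cohort))

    report = analyze_cohort(cohort, config)
    record(
        "analyze",
        n_patients=report.n_patients,
        n_features=len(FEATURE_COLUMNS),
    )

    log = {
        "version": __version__,
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stages,
    }
    if config.out_dir:
        written = write_report(report, config.out_dir)
        record("write_report", n_tables=len(written))
        with open(Path(config.out_dir) / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2)
    return report, log
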