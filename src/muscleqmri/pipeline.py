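"""End-to-end orchestration: cohort assembly, per-metric statistics, ROC and
composite-index report.

``run_pipeline`` accepts either a synthetic-cohort configuration (preset
pair + n + seed) or a pre-assembled cohort table (CSV path or DataFrame)
and produces the full statistics report: paired injured-vs-control
comparisons with median (IQR) effect summaries, Spearman and partial
Spearman correlations against total and endomysial collagen fraction,
univariate ROC for the metrics that enter the classification analysis, and
the incremental composite-index AUC trajectory. Everything is deterministic
given the seed.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import statistics as st
from .synth import SyntheticCohort, gen_cohort

__all__ = ["PipelineConfig", "roi_median", "run_pipeline", "report_to_json"]

#: metrics entering paired comparisons and correlation analyses
ANALYSIS_METRICS = (
    "ecv_pct",
    "native_t1_ms",
    "t2_msme_ms",
    "t2star_short_ms",
    "t2star_long_ms",
    "t2star_short_frac_pct",
    "perfusion_total_ml_100g",
    "perfusion_max_ml_min_100g",
    "sm0_kpa",
    "sm80_kpa",
    "smi",
    "skewness",
    "kurtosis",
    "energy",
)

#: metrics entering the ROC analysis (SM0/SM80 excluded as redundant with SMi)
ROC_METRICS = ("smi", "ecv_pct", "t2_msme_ms", "t2star_short_ms", "kurtosis", "energy")

#: default composite-panel build order (strongest univariate markers first)
PANEL_ORDER = ("ecv_pct", "smi", "t2_msme_ms", "t2star_short_ms", "kurtosis", "energy")

DEFAULT_COVARIATES = (
    "inflammation_score",
    "centronucleation_score",
    "calcification_score",
    "perfusion_max_ml_min_100g",
    "perfusion_total_ml_100g",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Exactly one of ``cohort`` (table/CSV path) or ``preset_pair`` is used."""

    cohort: object = None  # DataFrame or CSV path
    preset_pair: tuple = ("pooled_injured", "pooled_control")
    n_animals: int = 18
    seed: int = 0
    covariates: tuple = DEFAULT_COVARIATES
    fibrosis_threshold_pct: float = st.FIBROSIS_THRESHOLD_PCT
    alpha: float = 0.05
    panel_order: tuple = PANEL_ORDER
    synthetic: bool = True

    def __post_init__(self):
        if (self.cohort is not None) == self.synthetic:
            raise ValueError("exactly one of {cohort table | synthetic preset} must be active")


def roi_median(parameter_map, mask, summary: str = "mean") -> float:
    """ROI summary of a parameter map over valid (finite) masked voxels.

    The default summary is the arithmetic mean; ``summary='median'`` is
    available. NaN voxels inside the ROI are excluded; an all-invalid ROI
    yields NaN.
    """
    m = np.asarray(parameter_map, dtype=float)
    roi = np.asarray(mask).astype(bool)
    if m.shape != roi.shape:
        raise ValueError("mask extent must match the map")
    if not roi.any():
        raise ValueError("ROI mask is empty")
    vals = m[roi]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    if summary == "mean":
        return float(vals.mean())
    if summary == "median":
        return float(np.median(vals))
    raise ValueError("summary must be 'mean' or 'median'")


def _log(msg: str, t0: float) -> None:
    print(f"[muscleqmri +{time.perf_counter() - t0:6.2f}s] {msg}", file=sys.stderr)


def _paired_frames(table: pd.DataFrame):
    inj = table[table["group"] == "injured"].set_index("animal_id").sort_index()
    ctl = table[table["group"] == "control"].set_index("animal_id").sort_index()
    common = inj.index.intersection(ctl.index)
    return inj.loc[common], ctl.loc[common]


def run_pipeline(config: PipelineConfig):
    """Assemble the cohort table and run the full statistics layer.

    Returns ``(cohort_table, report)``; the report is JSON-serializable.
    Per-metric failures (too few usable values, degenerate columns) are
    recorded in ``report['errors']`` and the pipeline continues with missing
    entries.
    """
    t0 = time.perf_counter()
    if config.synthetic:
        cohort: SyntheticCohort = gen_cohort(
            config.preset_pair, config.n_animals, seed=config.seed
        )
        table = cohort.table
        _log(f"generated synthetic cohort n={config.n_animals} seed={config.seed}", t0)
    else:
        table = (
            pd.read_csv(config.cohort)
            if not isinstance(config.cohort, pd.DataFrame)
            else config.cohort.copy()
        )
        _log(f"loaded cohort table with {len(table)} rows", t0)

    metrics = [m for m in ANALYSIS_METRICS if m in table.columns]
    report: dict = {
        "config": {
            "seed": config.seed,
            "n_rows": int(len(table)),
            "synthetic": bool(config.synthetic),
            "fibrosis_threshold_pct": config.fibrosis_threshold_pct,
            "alpha": config.alpha,
        },
        "comparisons": {},
        "correlations": {},
        "roc": {},
        "composite": [],
        "errors": [],
    }

    # paired injured-vs-control comparisons, Bonferroni over the metric family
    inj, ctl = _paired_frames(table)
    m_tests = len(metrics)
    for m in metrics:
        try:
            res = st.paired_wilcoxon(inj[m], ctl[m], m_tests=m_tests)
            report["comparisons"][m] = {
                "statistic": res.statistic,
                "p": res.p_value,
                "p_bonferroni": res.p_adjusted,
                "n_pairs": res.n,
                **res.effect,
            }
        except ValueError as e:
            report["errors"].append(f"comparison[{m}]: {e}")
    _log(f"paired comparisons for {len(report['comparisons'])} metrics", t0)

    # Spearman and partial Spearman vs collagen fractions
    covs = [c for c in config.covariates if c in table.columns]
    for m in metrics:
        entry = {}
        for tag, collagen in (("total", "collagen_total_pct"), ("endo", "collagen_endo_pct")):
            if collagen not in table.columns:
                continue
            try:
                r = st.spearman(table[m], table[collagen])
                entry[tag] = {"r": r.r, "p": r.p_value, "n": r.n}
            except ValueError as e:
                report["errors"].append(f"spearman[{m},{tag}]: {e}")
            try:
                cov_cols = [table[c].to_numpy(dtype=float) for c in covs if c != m]
                rp = st.partial_spearman(table[m], table[collagen], cov_cols or None)
                entry[f"partial_{tag}"] = {"r": rp.r, "p": rp.p_value, "n": rp.n, "k": rp.n_covariates}
            except ValueError as e:
                report["errors"].append(f"partial_spearman[{m},{tag}]: {e}")
        if entry:
            report["correlations"][m] = entry
    _log("correlation analyses done", t0)

    # ROC analysis against the collagen-threshold classification
    if "collagen_total_pct" in table.columns:
        labels = st.classify_fibrosis(
            table["collagen_total_pct"].to_numpy(), config.fibrosis_threshold_pct
        )
        if len(set(labels)) < 2:
            report["errors"].append("roc: only one class present; ROC skipped")
        else:
            for m in config.panel_order:
                if m not in table.columns:
                    continue
                x = table[m].to_numpy(dtype=float)
                auc, ci = st.roc_auc(x, labels)
                # orient so AUC >= 0.5, as each metric may contribute negatively
                oriented = max(auc, 1.0 - auc)
                report["roc"][m] = {
                    "auc": oriented,
                    "auc_raw": auc,
                    "ci": list(ci) if auc >= 0.5 else [1 - ci[1], 1 - ci[0]],
                }
            panel = [m for m in config.panel_order if m in table.columns]
            if len(panel) >= 2:
                for res in st.incremental_panel(table, panel, labels):
                    report["composite"].append(
                        {
                            "metrics": list(res.metrics),
                            "signs": {k: int(v) for k, v in res.signs.items()},
                            "auc": res.auc,
                            "ci": list(res.ci),
                        }
                    )
    _log("ROC and composite indices done", t0)
    return table, report


def report_to_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
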