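"""End-to-end orchestration of the two study arms.

Cross-sectional arm: preprocess every subject's series, build the five
network connectivity matrices, sweep the density grid for global
efficiency (GE) and clustering coefficient (CC), run the 2 x 5 x 9
standardized-regression grid (measure ~ disease burden and processing
speed ~ measure, Bonferroni n = 10), and -- only for cells significant in
both families -- a bootstrap mediation (burden -> measure -> speed).

Reliability arm: filter subjects to >= 3 visits, fit linear mixed-model
time trends, compute ICC(1,1) per network x density x measure, per-subject
across-visit SD/CV, and the variability-on-covariates regressions.

Every run returns a manifest recording parameters, seeds, transform
lambdas, method names and the exclusion log.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from fcgraph import __version__ as _pkg_version
from fcgraph.atlas import build_networks
from fcgraph.connectome import DensityGrid, correlation_matrix
from fcgraph.metrics import metrics_across_densities
from fcgraph.preprocess import (
    DEFAULT_FD_THRESHOLD_MM,
    DEFAULT_MIN_SECONDS,
    preprocess_timeseries,
)
from fcgraph.stats import (
    N_COMPARISONS,
    icc_oneway,
    fit_longitudinal_trend,
    mediation_bootstrap,
    standardized_regression,
    variability_regression,
    visit_variability,
    yeo_johnson,
)

MEASURES = ("ge", "cc")
#: Headline mediation cell used when the gate is open there (the density at
#: which the cross-sectional associations are typically strongest).
DEFAULT_MEDIATION_CELL = ("DMN", "ge", 0.20)


class PipelineError(RuntimeError):
    pass


def compute_metric_table(
    cohort,
    grid: DensityGrid = DensityGrid(),
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    min_seconds: float = DEFAULT_MIN_SECONDS,
    networks=None,
):
    """Preprocess every subject x visit and compute the tidy metric table.

    Returns (metric table, mean-FD per subject x visit, exclusion log).
    """
    nets = networks if networks is not None else build_networks(cohort.config.atlas)
    tables, fd_rows, excluded = [], [], []
    for subject, visit in cohort.keys:
        ts = cohort.timeseries[(subject, visit)]
        censored, fd, mask, ok = preprocess_timeseries(
            ts,
            cohort.motion[(subject, visit)],
            cohort.nuisance[(subject, visit)],
            fd_threshold_mm=fd_threshold_mm,
            min_seconds=min_seconds,
        )
        fd_rows.append(
            {
                "subject_id": subject,
                "visit_id": visit,
                "mean_fd": fd.mean_fd,
                "n_kept": mask.n_kept,
                "retained_seconds": mask.retained_seconds,
            }
        )
        if not ok:
            excluded.append(
                {
                    "subject_id": subject,
                    "visit_id": visit,
                    "reason": f"retained {mask.retained_seconds:.1f} s < {min_seconds} s after scrubbing",
                }
            )
            continue
        for net in nets:
            cm = correlation_matrix(censored, net)
            tables.append(metrics_across_densities(cm, grid))
    if not tables:
        raise PipelineError("no subject/visit survived preprocessing exclusions")
    return pd.concat(tables, ignore_index=True), pd.DataFrame(fd_rows), excluded


def _regression_grid(metrics: pd.DataFrame, covariates: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """The 2-measure x network x density grid of both simple-regression
    families, on Yeo-Johnson transformed variables."""
    merged = metrics.merge(covariates[["subject_id", "fw", "tmtb_z"]], on="subject_id")
    fw_t, fw_spec = yeo_johnson(merged.drop_duplicates("subject_id")["fw"].to_numpy())
    lambdas = {"fw": fw_spec.lmbda}
    tmtb_t, tmtb_spec = yeo_johnson(merged.drop_duplicates("subject_id")["tmtb_z"].to_numpy())
    lambdas["tmtb_z"] = tmtb_spec.lmbda
    subj_order = merged.drop_duplicates("subject_id")["subject_id"]
    fw_map = dict(zip(subj_order, fw_t))
    tmtb_map = dict(zip(subj_order, tmtb_t))
    rows = []
    for (network, density), cell in merged.groupby(["network", "density"], sort=True):
        fw_v = cell["subject_id"].map(fw_map).to_numpy()
        tmtb_v = cell["subject_id"].map(tmtb_map).to_numpy()
        for measure in MEASURES:
            metric_t, spec = yeo_johnson(cell[measure].to_numpy())
            lambdas[f"{network}:{measure}:{density:g}"] = spec.lmbda
            r1 = standardized_regression(metric_t, fw_v)       # measure ~ burden
            r2 = standardized_regression(tmtb_v, metric_t)     # speed ~ measure
            rows.append(
                {
                    "network": network,
                    "measure": measure,
                    "density": density,
                    "beta_metric_fw": r1.std_beta,
                    "p_metric_fw": r1.p_bonferroni,
                    "beta_tmtb_metric": r2.std_beta,
                    "p_tmtb_metric": r2.p_bonferroni,
                    "gate_open": (r1.p_bonferroni < 0.05) and (r2.p_bonferroni < 0.05),
                }
            )
    return pd.DataFrame(rows), lambdas


def _select_mediation_cell(grid: pd.DataFrame):
    """Among gate-open cells, pick the one with the best (smallest) worst
    corrected p over the two families; prefer the canonical headline cell
    on ties."""
    open_cells = grid[grid["gate_open"]].copy()
    if open_cells.empty:
        return None
    open_cells["score"] = np.maximum(open_cells["p_metric_fw"], open_cells["p_tmtb_metric"])
    net0, meas0, dens0 = DEFAULT_MEDIATION_CELL
    open_cells["is_default"] = (
        (open_cells["network"] == net0)
        & (open_cells["measure"] == meas0)
        & (np.isclose(open_cells["density"], dens0))
    )
    open_cells = open_cells.sort_values(["score", "is_default"], ascending=[True, False])
    best = open_cells.iloc[0]
    return str(best["network"]), str(best["measure"]), float(best["density"])


def run_cross_sectional(
    cohort,
    grid: DensityGrid = DensityGrid(),
    n_boot: int = 50_000,
    seed: int = 0,
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    min_seconds: float = DEFAULT_MIN_SECONDS,
    networks=None,
) -> dict:
    """Full cross-sectional arm on a cohort (synthetic or loaded).

    Returns a dict with the metric table, the regression grid, overall-FC
    control regressions, the mediation result (or None if the gate never
    opens), and the run manifest.
    """
    metrics, fd_table, excluded = compute_metric_table(
        cohort, grid, fd_threshold_mm, min_seconds, networks=networks
    )
    covariates = cohort.covariates
    analyzed = metrics["subject_id"].unique()
    covariates = covariates[covariates["subject_id"].isin(analyzed)]
    reg_grid, lambdas = _regression_grid(metrics, covariates)

    # overall-FC control: burden must not act through overall connectivity
    fc_rows = []
    merged = metrics.drop_duplicates(["subject_id", "network"]).merge(
        covariates[["subject_id", "fw"]], on="subject_id"
    )
    for network, cell in merged.groupby("network", sort=True):
        fw_t, _ = yeo_johnson(cell["fw"].to_numpy())
        fc_t, _ = yeo_johnson(cell["overall_fc"].to_numpy())
        res = standardized_regression(fc_t, fw_t, n_comparisons=1)
        fc_rows.append({"network": network, "std_beta": res.std_beta, "p_raw": res.p_raw})
    fc_control = pd.DataFrame(fc_rows)

    cell = _select_mediation_cell(reg_grid)
    mediation = None
    if cell is not None:
        network, measure, density = cell
        sel = metrics[(metrics["network"] == network) & np.isclose(metrics["density"], density)]
        sel = sel.merge(covariates[["subject_id", "fw", "tmtb_z"]], on="subject_id")
        x, _ = yeo_johnson(sel["fw"].to_numpy())
        m, _ = yeo_johnson(sel[measure].to_numpy())
        y, _ = yeo_johnson(sel["tmtb_z"].to_numpy())
        mediation = mediation_bootstrap(x, m, y, n_boot=n_boot, seed=seed)
    manifest = {
        "arm": "cross-sectional",
        "package_version": _pkg_version,
        "seed": seed,
        "n_boot": n_boot,
        "fd_threshold_mm": fd_threshold_mm,
        "min_seconds": min_seconds,
        "densities": list(grid),
        "n_comparisons": N_COMPARISONS,
        "pipeline_order": ["nuisance_regression", "detrend", "bandpass", "scrub"],
        "bandpass": "butterworth order 2, 0.01-0.08 Hz, forward-backward (zero phase)",
        "mediation_cell": cell,
        "mediation_p_method": "percentile bootstrap, two-sided",
        "transform_lambdas": lambdas,
        "subjects_in": int(cohort.covariates["subject_id"].nunique()),
        "subjects_analyzed": int(len(analyzed)),
        "exclusions": excluded,
    }
    return {
        "metrics": metrics,
        "fd": fd_table,
        "regressions": reg_grid,
        "fc_control": fc_control,
        "mediation": mediation,
        "manifest": manifest,
    }


def run_reliability(
    serial_metrics: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    min_visits: int = 3,
    fit_trends: bool = True,
) -> dict:
    """Reliability arm on a tidy serial table.

    ``serial_metrics`` columns: subject_id, visit_id, time_days, network,
    density, measure, value.  Subjects with fewer than ``min_visits``
    visits are excluded up front (and listed in the manifest).  Computes,
    per network x density x measure: the mixed-model time trend, ICC(1,1)
    with its CI, per-subject SD/CV, and (when covariates are supplied) the
    variability regression over the ten explanatory variables.
    """
    df = serial_metrics.copy()
    visit_counts = df.groupby("subject_id")["visit_id"].nunique()
    kept_subjects = visit_counts.index[visit_counts >= min_visits]
    excluded = sorted(set(visit_counts.index) - set(kept_subjects))
    df = df[df["subject_id"].isin(kept_subjects)]
    if df["subject_id"].nunique() < 2:
        raise PipelineError("reliability analysis needs >= 2 subjects with enough visits")

    icc_rows, trend_rows, var_tables, var_reg = [], [], [], {}
    group_cols = ["network", "density", "measure"]
    for (network, density, measure), cell in df.groupby(group_cols, sort=True):
        icc = icc_oneway(cell)
        icc_rows.append(
            {
                "network": network,
                "density": density,
                "measure": measure,
                "icc": icc.icc,
                "ci_low": icc.ci_low,
                "ci_high": icc.ci_high,
            }
        )
        if fit_trends:
            fit = fit_longitudinal_trend(cell, time_col="time_days")
            trend_rows.append(
                {
                    "network": network,
                    "density": density,
                    "measure": measure,
                    "beta_time": fit.beta_time,
                    "p_time": fit.p_time,
                    "method": fit.method,
                }
            )
        var = visit_variability(cell, min_visits=min_visits)
        var.insert(1, "network", network)
        var.insert(2, "density", density)
        var.insert(3, "measure", measure)
        var_tables.append(var)
        if covariates is not None:
            var_reg[(network, density, measure)] = variability_regression(var, covariates)

    manifest = {
        "arm": "reliability",
        "package_version": _pkg_version,
        "min_visits": min_visits,
        "icc_model": "one-way random effects ANOVA, ICC(1,1), F-distribution CI",
        "subjects_in": int(len(visit_counts)),
        "subjects_analyzed": int(len(kept_subjects)),
        "subjects_excluded": excluded,
    }
    return {
        "icc": pd.DataFrame(icc_rows),
        "trends": pd.DataFrame(trend_rows),
        "variability": pd.concat(var_tables, ignore_index=True) if var_tables else pd.DataFrame(),
        "variability_regressions": var_reg,
        "manifest": manifest,
    }
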