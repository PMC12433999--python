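"""Attrition x clustering-structure x handling experiment grid.

Runs the full factorial analysis behind the package: for each replicate, a
survey population is generated (or a fixed one reused), attrition is imposed
at each requested rate under a MAR mechanism, each missing-data handling
(complete-case analysis or sequential-KNN imputation) is applied, and every
clustering structure is fitted.  Each cell yields the prevalence estimate
with its interval, the per-level variance components and ICCs, and the model
diagnostics (log-likelihood, AIC, BIC).

By default the MAR dropout is *prevalence-correlated*: the site coefficient
is aimed at whichever site shows the higher observed prevalence, so dropout
preferentially removes outcomes from high-prevalence strata.  This is the
regime in which complete-case analysis underestimates prevalence and
imputation has signal to recover.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import derived_seed, replicate_seed
from .attrition import MARModel, apply_attrition
from .dataset import SurveyDataset
from .glmm import LEVEL_ORDER, FitResult, ModelSpec, fit_glmm, fit_intercept_only
from .icc import icc_result
from .prevalence import adjusted_prevalence, crude_prevalence
from .sknn import SknnConfig, impute_sknn
from .synthetic import PopulationConfig, generate_population

#: named clustering structures, outermost level first
STRUCTURES: dict[str, tuple[str, ...]] = {
    "none": (),
    "site": ("site",),
    "interviewer": ("interviewer",),
    "household": ("household",),
    "site_interviewer": ("site", "interviewer"),
    "household_site": ("site", "household"),
    "three_level": ("site", "interviewer", "household"),
}

HANDLINGS = ("complete_case", "sknn_imputed")


@dataclass(frozen=True)
class ExperimentGrid:
    """The factorial design: rates x structures x handlings x replicates."""

    attrition_rates: tuple[float, ...] = (0.0, 0.10, 0.20)
    structures: tuple[str, ...] = tuple(STRUCTURES)
    handlings: tuple[str, ...] = HANDLINGS
    replicates: int = 1
    seed: int = 0
    redraw_population: bool = True
    estimation: str = "agq"
    q: int = 9
    mar_site_coef: float = 0.4
    mar_household_size_coef: float = 0.1
    mar_interviewer_sex_coef: float = 0.0
    prevalence_correlated: bool = True
    sknn: SknnConfig = field(default_factory=SknnConfig)

    def __post_init__(self):
        unknown = [s for s in self.structures if s not in STRUCTURES]
        if unknown:
            raise ValueError(f"unknown structures {unknown}; choose from {list(STRUCTURES)}")
        unknown = [h for h in self.handlings if h not in HANDLINGS]
        if unknown:
            raise ValueError(f"unknown handlings {unknown}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(not 0.0 <= r < 1.0 for r in self.attrition_rates):
            raise ValueError("attrition rates must be in [0, 1)")

    def model_spec(self, structure: str) -> ModelSpec:
        return ModelSpec(
            random_levels=STRUCTURES[structure], estimation=self.estimation, q=self.q
        )


def prevalence_correlated_mar(
    data: SurveyDataset, target_rate: float, grid: ExperimentGrid, seed: int
) -> MARModel:
    """MAR model whose site coefficient targets the higher-prevalence site.

    The reference site is chosen from *observed* site rates (an observed-data
    quantity, so the mechanism stays MAR), making dropout prevalence-correlated
    when sites genuinely differ.
    """
    site_rates = data.df.groupby("site_id", sort=False)["outcome"].mean()
    reference = str(site_rates.idxmax()) if grid.prevalence_correlated else "1"
    return MARModel(
        target_rate=target_rate,
        site_coef=grid.mar_site_coef,
        household_size_coef=grid.mar_household_size_coef,
        interviewer_sex_coef=grid.mar_interviewer_sex_coef,
        site_reference=reference,
        seed=seed,
    )


def _nan_row() -> dict:
    row = {}
    for lv in LEVEL_ORDER:
        row[f"sigma2_{lv}"] = np.nan
        row[f"icc_{lv}"] = np.nan
    row.update(
        icc_cumulative=np.nan, loglik=np.nan, aic=np.nan, bic=np.nan,
        theta_per_1000=np.nan, se_per_1000=np.nan, lcb=np.nan, ucb=np.nan, ci_width=np.nan,
    )
    return row


def _fit_cell(data: SurveyDataset, structure: str, spec: ModelSpec) -> dict:
    row = _nan_row()
    if structure == "none":
        fit = fit_intercept_only(data)
        est = crude_prevalence(data)[0]
    else:
        fit = fit_glmm(data, spec)
        est = adjusted_prevalence(fit) if fit.converged else None
        ic = icc_result(fit.varcomps)
        for lv, s2 in fit.varcomps.sigma2.items():
            row[f"sigma2_{lv}"] = s2
            row[f"icc_{lv}"] = ic.per_level[lv]
        row["icc_cumulative"] = ic.cumulative
    row.update(loglik=fit.loglik, aic=fit.aic, bic=fit.bic)
    if structure == "none":
        row["icc_cumulative"] = 0.0
    if est is not None:
        row.update(
            theta_per_1000=est.theta, se_per_1000=est.sigma,
            lcb=est.lcb, ucb=est.ucb, ci_width=est.ci_width,
        )
    row["n_complete"] = fit.n_obs
    row["events"] = fit.n_events
    row["converged"] = bool(fit.converged)
    return row


def run_grid(
    population: PopulationConfig | SurveyDataset, grid: ExperimentGrid
) -> pd.DataFrame:
    """Execute the grid; one row per (replicate, rate, handling, structure).

    Failures (degenerate or non-converged fits) are recorded as rows with
    ``converged=False`` and missing statistics, never dropped silently.
    Deterministic given the grid seed.
    """
    rows = []
    for rep in range(grid.replicates):
        if isinstance(population, PopulationConfig):
            pop_seed = replicate_seed(grid.seed, rep) if grid.redraw_population else population.seed
            data, _ = generate_population(population.with_seed(pop_seed))
        else:
            data = population
        for rate_idx, rate in enumerate(grid.attrition_rates):
            cell_datasets: dict[str, SurveyDataset] = {}
            if rate == 0.0:
                cell_datasets["complete_case"] = data
            else:
                mar = prevalence_correlated_mar(
                    data, rate, grid, seed=derived_seed(grid.seed, "attrition", rep, rate_idx)
                )
                attrited = apply_attrition(data, mar)
                if "complete_case" in grid.handlings:
                    cell_datasets["complete_case"] = attrited
                if "sknn_imputed" in grid.handlings:
                    sknn_cfg = replace(
                        grid.sknn, seed=derived_seed(grid.seed, "impute", rep, rate_idx)
                    )
                    cell_datasets["sknn_imputed"] = impute_sknn(attrited, sknn_cfg)
            for handling, ds in cell_datasets.items():
                for structure in grid.structures:
                    base = dict(
                        replicate=rep, attrition=rate, handling=handling, structure=structure
                    )
                    try:
                        base.update(_fit_cell(ds, structure, grid.model_spec(structure)))
                    except Exception as exc:  # recorded, never silently dropped
                        base.update(_nan_row())
                        base.update(
                            n_complete=ds.complete_cases().n, events=np.nan,
                            converged=False, error=str(exc),
                        )
                    rows.append(base)
    table = pd.DataFrame(rows)
    lead = ["replicate", "attrition", "handling", "structure"]
    return table[lead + [c for c in table.columns if c not in lead]]


def compare_models(table: pd.DataFrame) -> pd.DataFrame:
    """Rank one cell's structures by AIC (BIC as tie-break).

    All rows must belong to the same (replicate, attrition, handling) cell.
    """
    keys = table[["replicate", "attrition", "handling"]].drop_duplicates()
    if len(keys) > 1:
        raise ValueError("rows mix replicate/attrition/handling cells; rank one cell at a time")
    ranked = table.sort_values(["aic", "bic"], kind="stable").reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked


def summarize_grid(table: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged summary per (attrition, handling, structure)."""
    agg = {
        "theta_per_1000": "mean",
        "se_per_1000": "mean",
        "ci_width": "mean",
        "icc_cumulative": "mean",
        "aic": "mean",
        "bic": "mean",
        "converged": "mean",
    }
    for lv in LEVEL_ORDER:
        agg[f"icc_{lv}"] = "mean"
    out = (
        table.groupby(["attrition", "handling", "structure"], sort=False)
        .agg(agg)
        .reset_index()
    )
    counts = (
        table.groupby(["attrition", "handling", "structure"], sort=False)
        .size()
        .rename("replicates")
        .reset_index()
    )
    return out.merge(counts, on=["attrition", "handling", "structure"])


def fit_result_record(fit: FitResult) -> dict[str, float | str | bool]:
    """Flat key-value serialisation of a fit, for text output."""
    rec: dict[str, float | str | bool] = {
        "beta0_hat": fit.beta0_hat,
        "se_beta0": fit.se_beta0,
        "loglik": fit.loglik,
        "aic": fit.aic,
        "bic": fit.bic,
        "n_obs": fit.n_obs,
        "n_events": fit.n_events,
        "converged": fit.converged,
        "method": fit.method,
    }
    for lv, s2 in fit.varcomps.sigma2.items():
        rec[f"sigma2_{lv}"] = s2
    ic = icc_result(fit.varcomps)
    for lv, v in ic.per_level.items():
        rec[f"icc_{lv}"] = v
    rec["icc_cumulative"] = ic.cumulative
    return rec
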