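"""Crude and cluster-adjusted prevalence per 1,000 with Wald intervals.

Crude estimates use the binomial Wald convention on the proportion scale,
scaled to events per 1,000: theta = 1000 p, sigma = 1000 sqrt(p(1-p)/n),
bounds theta -/+ 1.96 sigma.  Lower bounds are deliberately not truncated at
zero - for very rare outcomes in small groups the Wald interval can cross
zero, and the tables keep the sign.

Adjusted estimates transform a fitted random-intercept model.  The default
estimand is population-averaged: 1000 * E[logit^{-1}(beta0 + Z)] with
Z ~ N(0, sum of fitted cluster variances), evaluated by quadrature; interval
bounds apply the same transform to beta0 -/+ 1.96 se(beta0).  A
cluster-conditional variant (1000 * logit^{-1}(beta0), the rate in a cluster
with average effects) is exposed and labelled.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2_contingency

from ._quadrature import mean_expit_gaussian
from .dataset import SurveyDataset
from .glmm import FitResult, NotConvergedError

Z95 = 1.96  # fixed normal quantile for all 95% intervals


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Point estimate per 1,000 with Wald interval."""

    theta: float  # rate per 1,000
    sigma: float  # standard error per 1,000
    lcb: float
    ucb: float
    n: int
    events: float = np.nan
    label: str = "all"
    estimand: str = "crude"

    @classmethod
    def from_counts(cls, events: float, n: int, label: str = "all") -> "PrevalenceEstimate":
        if n <= 0:
            raise ValueError("empty group")
        p = events / n
        theta = 1000.0 * p
        sigma = 1000.0 * np.sqrt(p * (1.0 - p) / n)
        return cls(
            theta=theta,
            sigma=sigma,
            lcb=theta - Z95 * sigma,
            ucb=theta + Z95 * sigma,
            n=int(n),
            events=float(events),
            label=label,
        )

    @classmethod
    def from_point(cls, theta: float, sigma: float, n: int = 0, label: str = "all") -> "PrevalenceEstimate":
        """Rebuild the Wald interval from a printed (theta, sigma) pair."""
        return cls(
            theta=float(theta),
            sigma=float(sigma),
            lcb=theta - Z95 * sigma,
            ucb=theta + Z95 * sigma,
            n=int(n),
            label=label,
        )

    @property
    def ci_width(self) -> float:
        return self.ucb - self.lcb

    def covers(self, rate_per_1000: float) -> bool:
        return self.lcb <= rate_per_1000 <= self.ucb


def crude_prevalence(
    data: SurveyDataset, group_by: str | Sequence[str] | None = None
) -> list[PrevalenceEstimate]:
    """Per-group crude prevalence per 1,000 on the complete cases.

    Groups appear in first-appearance order (matching how survey tables list
    villages); empty groups are skipped with a warning.
    """
    df = data.df[data.df["outcome"].notna()]
    if group_by is None:
        y = df["outcome"].to_numpy()
        return [PrevalenceEstimate.from_counts(float(y.sum()), len(y))]
    cols = [group_by] if isinstance(group_by, str) else list(group_by)
    out = []
    for key, sub in df.groupby(cols, sort=False):
        label = key if isinstance(key, str) else "/".join(str(k) for k in key)
        if len(sub) == 0:
            warnings.warn(f"group {label!r} is empty; skipped", stacklevel=2)
            continue
        y = sub["outcome"].to_numpy()
        out.append(PrevalenceEstimate.from_counts(float(y.sum()), len(y), label=str(label)))
    return out


def _pa_rate(fit: FitResult, values: dict[str, float]) -> float:
    """Population-averaged rate at perturbed parameter values.

    ``values`` maps fit.param_names entries to values; levels whose variance
    was estimated at zero stay fixed at zero.
    """
    beta0 = values["beta0"]
    total = 0.0
    for lv, s2 in fit.varcomps.sigma2.items():
        name = f"log_sd_{lv}"
        total += np.exp(2.0 * values[name]) if name in values else s2
    return float(mean_expit_gaussian(beta0, total))


def adjusted_prevalence(
    fit: FitResult, estimand: str = "population_averaged", ci_method: str = "delta"
) -> PrevalenceEstimate:
    """Cluster-adjusted prevalence per 1,000 from a fitted model.

    For the population-averaged estimand the default interval is a delta-method
    Wald interval that propagates the joint uncertainty of the intercept and
    the variance components: the two are strongly anti-correlated (a larger
    fitted variance forces a lower intercept for the same marginal rate), so
    transforming the intercept's interval alone at plugged-in variances
    systematically over-covers.  ``ci_method="transform"`` gives that simpler
    plug-in transform interval instead.
    """
    if not fit.converged:
        raise NotConvergedError("refusing to report prevalence from a non-converged fit")
    if estimand not in ("population_averaged", "conditional"):
        raise ValueError("estimand must be 'population_averaged' or 'conditional'")
    if ci_method not in ("delta", "transform"):
        raise ValueError("ci_method must be 'delta' or 'transform'")
    if not fit.varcomps.sigma2 and estimand == "population_averaged":
        # no random levels: exact reduction to the crude binomial estimate
        est = PrevalenceEstimate.from_counts(fit.n_events, fit.n_obs, label="adjusted")
        return PrevalenceEstimate(
            theta=est.theta, sigma=est.sigma, lcb=est.lcb, ucb=est.ucb,
            n=est.n, events=est.events, label="adjusted", estimand="population_averaged",
        )
    total = fit.varcomps.cluster_total

    if estimand == "conditional" or total == 0.0:
        # monotone scalar transform of beta0: exact interval mapping
        transform = lambda b: float(expit(b))
        name = "conditional" if estimand == "conditional" else "population_averaged"
        theta = 1000.0 * transform(fit.beta0_hat)
        lcb = 1000.0 * transform(fit.beta0_hat - Z95 * fit.se_beta0)
        ucb = 1000.0 * transform(fit.beta0_hat + Z95 * fit.se_beta0)
        sigma = (ucb - lcb) / (2.0 * Z95)
        return PrevalenceEstimate(
            theta=theta, sigma=sigma, lcb=lcb, ucb=ucb, n=fit.n_obs, events=fit.n_events,
            label="adjusted", estimand=name,
        )

    transform = lambda b: float(mean_expit_gaussian(b, total))
    theta = 1000.0 * transform(fit.beta0_hat)
    if ci_method == "delta" and fit.param_cov is not None:
        at = {"beta0": fit.beta0_hat}
        for lv, s2 in fit.varcomps.sigma2.items():
            if s2 > 0:
                at[f"log_sd_{lv}"] = 0.5 * np.log(s2)
        names = [nm for nm in fit.param_names if nm in at]
        idx = [fit.param_names.index(nm) for nm in names]
        cov = fit.param_cov[np.ix_(idx, idx)]
        h = 1e-4
        grad = np.empty(len(names))
        for a, nm in enumerate(names):
            up = dict(at)
            dn = dict(at)
            up[nm] += h
            dn[nm] -= h
            grad[a] = (_pa_rate(fit, up) - _pa_rate(fit, dn)) / (2.0 * h)
        var = float(grad @ cov @ grad)
        sigma = 1000.0 * np.sqrt(max(var, 0.0))
        lcb, ucb = theta - Z95 * sigma, theta + Z95 * sigma
    else:
        lcb = 1000.0 * transform(fit.beta0_hat - Z95 * fit.se_beta0)
        ucb = 1000.0 * transform(fit.beta0_hat + Z95 * fit.se_beta0)
        sigma = (ucb - lcb) / (2.0 * Z95)
    return PrevalenceEstimate(
        theta=theta, sigma=sigma, lcb=lcb, ucb=ucb, n=fit.n_obs, events=fit.n_events,
        label="adjusted", estimand="population_averaged",
    )


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    low_expected: bool  # True when some expected cell count < 1


def chi2_homogeneity(data: SurveyDataset, grouping: str) -> Chi2Result:
    """Pearson chi-square test of equal outcome proportions across groups.

    Computed on the groups x {0, 1} count table without continuity
    correction; df = groups - 1.
    """
    df = data.df[data.df["outcome"].notna()]
    table = pd.crosstab(df[grouping], df["outcome"]).to_numpy()
    if table.shape[0] < 2:
        raise ValueError("need at least two groups for a homogeneity test")
    if table.shape[1] < 2:
        # one outcome class entirely absent: no heterogeneity measurable
        return Chi2Result(0.0, table.shape[0] - 1, 1.0, True)
    res = chi2_contingency(table, correction=False)
    low = bool((res.expected_freq < 1.0).any())
    return Chi2Result(float(res.statistic), int(res.dof), float(res.pvalue), low)


def summary_arithmetic(
    table: Sequence[PrevalenceEstimate], kind: str, labels: Sequence[str] | None = None
) -> float:
    """Range or unweighted mean of point estimates across table rows."""
    rows = list(table)
    if labels is not None:
        wanted = set(labels)
        rows = [r for r in rows if r.label in wanted]
    if not rows:
        raise ValueError("no rows selected")
    theta = np.array([r.theta for r in rows])
    if kind == "range":
        return float(theta.max() - theta.min())
    if kind == "mean_by":
        return float(theta.mean())
    raise ValueError("kind must be 'range' or 'mean_by'")


def estimates_to_frame(table: Sequence[PrevalenceEstimate]) -> pd.DataFrame:
    """Machine twin of the survey's grouped prevalence tables."""
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "n": r.n,
                "events": r.events,
                "theta_per_1000": r.theta,
                "sigma": r.sigma,
                "lcb": r.lcb,
                "ucb": r.ucb,
            }
            for r in table
        ]
    )
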