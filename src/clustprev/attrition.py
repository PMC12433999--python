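"""Missing-at-random attrition on survey outcomes.

Dropout is simulated record-wise on the *outcome only*: cluster labels and
covariates stay fully observed, as in a census frame where screening
non-response loses the screening result.  The dropout probability is a
logistic function of observed fields (site, household size, interviewer sex),
never of the outcome itself - the MAR contract.  The intercept is not user
set; it is calibrated by bisection so the mean dropout probability over the
records hits the requested marginal rate.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from ._rng import substream
from .dataset import SurveyDataset


class CalibrationError(ValueError):
    """The target rate cannot be reached with the given coefficients."""


@dataclass(frozen=True)
class MARModel:
    """Logit-linear dropout model on observed covariates.

    logit P(drop) = intercept + site_coef * [site == site_reference]
                    + household_size_coef * (household size - mean size)
                    + interviewer_sex_coef * [interviewer_sex == 'F']

    ``intercept`` is solved by :func:`calibrate_intercept`, not user-set.
    """

    target_rate: float
    site_coef: float = 0.4
    household_size_coef: float = 0.1
    interviewer_sex_coef: float = 0.0
    site_reference: str = "1"
    seed: int = 0
    intercept: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.target_rate < 1.0:
            raise ValueError("target_rate must be in [0, 1)")

    def linear_predictor(self, data: SurveyDataset) -> np.ndarray:
        """Covariate part of the dropout logit (no intercept)."""
        df = data.df
        size = data.household_sizes().to_numpy(dtype=float)
        xi = (
            self.site_coef * (df["site_id"].to_numpy() == self.site_reference)
            + self.household_size_coef * (size - size.mean())
            + self.interviewer_sex_coef * (df["interviewer_sex"].to_numpy() == "F")
        )
        return np.asarray(xi, dtype=float)


def calibrate_intercept(data: SurveyDataset, model: MARModel, tol: float = 1e-6) -> float:
    """Bisection on the intercept until the mean dropout probability hits target.

    Deterministic; raises :class:`CalibrationError` if the rate is outside the
    attainable range (0.001, 0.999) or the bracket cannot be closed.
    """
    if not 0.001 < model.target_rate < 0.999:
        raise CalibrationError("target_rate must be in (0.001, 0.999) for calibration")
    xi = model.linear_predictor(data)

    def mean_rate(c: float) -> float:
        return float(expit(c + xi).mean())

    lo, hi = -40.0, 40.0
    if not mean_rate(lo) < model.target_rate < mean_rate(hi):
        raise CalibrationError("target rate unattainable with these coefficients")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_rate(mid) < model.target_rate:
            lo = mid
        else:
            hi = mid
        if abs(mean_rate(0.5 * (lo + hi)) - model.target_rate) < tol:
            break
    return 0.5 * (lo + hi)


def apply_attrition(data: SurveyDataset, model: MARModel) -> SurveyDataset:
    """Set outcomes to missing independently with the model's probabilities.

    Calibrates the intercept first if it is unset.  ``target_rate == 0``
    returns the dataset unchanged.  Deterministic given ``model.seed``.
    """
    if model.target_rate == 0.0:
        return data.copy()
    if model.intercept is None:
        model = replace(model, intercept=calibrate_intercept(data, model))
    p = expit(model.intercept + model.linear_predictor(data))
    rng = substream(model.seed, "attrition")
    drop = rng.random(data.n) < p
    df = data.df.copy()
    df.loc[drop, "outcome"] = np.nan
    return SurveyDataset(df, validate=False)
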