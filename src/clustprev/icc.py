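"""Variance decomposition and intraclass correlation for the latent scale.

For a logistic random-intercept model the individual-level residual has no
free variance; the standard latent-threshold convention fixes it at pi^2/3
(the variance of the standard logistic distribution).  The ICC of a level is
then

    ICC_level = sigma2_level / (sum of included cluster variances + pi^2/3)

and the cumulative ICC of a model is the sum of its cluster variances over the
same total - the share of latent outcome variance attributable to any of the
modelled clusters.  The cumulative ICC is monotone non-decreasing as levels
are added, which is how a two-level model's 0.10 can rise to ~0.41 when
household clustering enters.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .glmm import FitResult, VarianceComponents

#: threshold above which clustering at a level is called substantial
SUBSTANTIAL_ICC = 0.1


@dataclass(frozen=True)
class ICCResult:
    """Per-level and cumulative intraclass correlations for one model."""

    per_level: dict[str, float]
    cumulative: float
    convention: str = "latent-logistic (residual pi^2/3)"

    def substantial(self, threshold: float = SUBSTANTIAL_ICC) -> dict[str, bool]:
        """Which levels exceed the substantial-clustering threshold."""
        return {lv: v > threshold for lv, v in self.per_level.items()}


def icc(varcomps: VarianceComponents, level: str) -> float:
    """Share of total latent variance attributable to one included level."""
    if level not in varcomps.sigma2:
        raise KeyError(f"level {level!r} not in variance components {varcomps.levels}")
    return varcomps.sigma2[level] / varcomps.total


def icc_cumulative(varcomps: VarianceComponents) -> float:
    """Share of total latent variance attributable to all included levels."""
    if not varcomps.sigma2:
        return 0.0
    return varcomps.cluster_total / varcomps.total


def icc_result(varcomps: VarianceComponents) -> ICCResult:
    return ICCResult(
        per_level={lv: icc(varcomps, lv) for lv in varcomps.levels},
        cumulative=icc_cumulative(varcomps),
    )


def icc_from_fit(fit: FitResult) -> ICCResult:
    return icc_result(fit.varcomps)


def variance_decomposition(varcomps: VarianceComponents) -> pd.DataFrame:
    """Table of (level, sigma2, share); shares sum to 1 with the residual row."""
    total = varcomps.total
    rows = [
        {"level": lv, "sigma2": s2, "share": s2 / total} for lv, s2 in varcomps.sigma2.items()
    ]
    rows.append(
        {"level": "residual", "sigma2": varcomps.residual, "share": varcomps.residual / total}
    )
    return pd.DataFrame(rows, columns=["level", "sigma2", "share"])
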