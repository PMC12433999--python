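"""Published summary tables from a two-site Nairobi epilepsy prevalence survey.

These are the printed grouped-prevalence tables (per-1,000 point estimates,
standard errors and 95% Wald bounds by site, village and interviewer) and the
printed three-level model intervals under 0/10/20% simulated attrition, from
the two-stage census the synthetic generator emulates.  The individual-level
data behind them are access-restricted; only these printed summaries are
shipped, as fixtures for the table-arithmetic routines.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_site_village_table() -> pd.DataFrame:
    """Prevalence per 1,000 by site and by village (columns: group, label,
    theta_per_1000, sigma, lcb, ucb)."""
    return _load("site_village.csv")


def load_interviewer_table() -> pd.DataFrame:
    """Prevalence per 1,000 grouped by screening interviewer (columns: site,
    label, sex, theta_per_1000, sigma, lcb, ucb)."""
    return _load("interviewer.csv")


def load_attrition_intervals() -> pd.DataFrame:
    """Printed prevalence intervals by attrition level, handling and model
    structure (columns: handling, attrition, structure, estimate, lcb, ucb)."""
    return _load("attrition_intervals.csv")
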