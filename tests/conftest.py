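import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from clustprev.dataset import SurveyDataset
from clustprev.synthetic import PopulationConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_dataset(rows) -> SurveyDataset:
    """Build a SurveyDataset from (site, village, household, interviewer, sex, outcome) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["site_id", "village_id", "household_id", "interviewer_id", "interviewer_sex", "outcome"],
    )
    df.insert(0, "individual_id", np.arange(len(df)))
    return SurveyDataset(df)


def small_population(
    beta0: float,
    sigma_u: float = 0.0,
    sigma_v: float = 0.0,
    sigma_w: float = 0.0,
    n_sites: int = 2,
    villages: int = 2,
    interviewers: int = 3,
    households: int = 100,
    size_mean: float = 4.0,
    seed: int = 0,
) -> PopulationConfig:
    """Compact symmetric configuration for simulation-based tests."""
    return PopulationConfig(
        beta0=beta0,
        sigma_u=sigma_u,
        sigma_v=sigma_v,
        sigma_w=sigma_w,
        n_sites=n_sites,
        villages_per_site=(villages,) * n_sites,
        interviewers_per_site=(interviewers,) * n_sites,
        households_per_village=(households,) * n_sites,
        household_size_means=(size_mean,) * n_sites,
        seed=seed,
    )


@pytest.fixture
def tiny_nested():
    """16 records: 2 sites x 2 interviewers x 2 households x 2 individuals.

    Outcomes follow a fixed deterministic pattern with events in several
    clusters, suitable for likelihood-oracle comparisons.
    """
    rows = []
    iid = 0
    for s in range(2):
        for j in range(2):
            intv = s * 2 + j
            for h in range(2):
                hh = intv * 2 + h
                for _ in range(2):
                    rows.append((s, s * 2 + j, hh, intv, "F" if intv % 2 else "M", float(iid * 7 % 5 == 0)))
                    iid += 1
    return make_dataset(rows)


@pytest.fixture
def bernoulli_47_of_5000():
    """5,000 independent records with 47 events in one big cluster block."""
    y = np.zeros(5000)
    y[:47] = 1.0
    df = pd.DataFrame(
        {
            "individual_id": np.arange(5000),
            "site_id": "0",
            "village_id": "0",
            "household_id": np.arange(5000),  # singleton households
            "interviewer_id": "0",
            "interviewer_sex": "F",
            "outcome": y,
        }
    )
    return SurveyDataset(df)


def trapezoid_mean_expit(mu: float, sigma2: float, n_points: int = 4001) -> float:
    """Independent trapezoid-rule oracle for E[expit(mu + Z)], Z ~ N(0, sigma2)."""
    from scipy.special import expit

    sd = np.sqrt(sigma2)
    z = np.linspace(-8.0 * sd, 8.0 * sd, n_points)
    dens = np.exp(-0.5 * (z / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    return float(np.trapezoid(expit(mu + z) * dens, z))
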