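"""Synthetic clustered survey populations.

Generates two-stage census-style survey data with the hierarchical structure
of a two-site urban HDSS prevalence study: individuals nested in households,
households screened by one interviewer, interviewers working in one site, and
villages grouped within sites.  The binary outcome follows an intercept-only
logistic model with independent Gaussian random intercepts at the site,
interviewer and household levels:

    Y ~ Bernoulli( logit^{-1}( beta0 + u_site + v_interviewer + w_household ) )

with u ~ N(0, sigma_u^2), v ~ N(0, sigma_v^2), w ~ N(0, sigma_w^2).

The :func:`epina_like_config` preset solves the intercept and the three SDs so
that the latent-scale intraclass correlations are 0.40 (household), 0.10
(interviewer) and 0.07 (site) and the marginal event rate is 9.4 per 1,000 -
the structure of the Nairobi two-site epilepsy survey the package emulates.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from ._quadrature import mean_expit_gaussian
from ._rng import substream
from .dataset import SurveyDataset

MAX_HOUSEHOLD_SIZE = 15

# latent-logistic residual variance (pi^2 / 3); shared convention with clustprev.icc
_RESIDUAL = np.pi**2 / 3.0


class ConfigurationError(ValueError):
    """Invalid population configuration."""


def truncated_geometric_pmf(mean: float, max_size: int = MAX_HOUSEHOLD_SIZE) -> np.ndarray:
    """PMF on 1..max_size proportional to q**(s-1), with the given mean.

    Used as the household-size distribution; ``q`` is solved numerically.
    """
    if not 1.0 < mean < max_size:
        raise ConfigurationError(f"household size mean must lie in (1, {max_size}), got {mean}")
    s = np.arange(1, max_size + 1, dtype=float)

    def m(q: float) -> float:
        w = q ** (s - 1)
        return float((s * w).sum() / w.sum())

    midpoint = (1 + max_size) / 2.0
    if abs(mean - midpoint) < 1e-12:
        q = 1.0
    elif mean < midpoint:
        q = brentq(lambda q: m(q) - mean, 1e-12, 1.0)
    else:
        q = brentq(lambda q: m(q) - mean, 1.0, 50.0)
    w = q ** (s - 1)
    return w / w.sum()


@dataclass(frozen=True)
class PopulationConfig:
    """Data-generating configuration for one synthetic survey population.

    ``households_per_village`` is one count per site (every village in that
    site gets that many households).  ``household_size_means`` gives the
    site-specific mean of a truncated-geometric size distribution on 1..15;
    ``household_size_dist`` may instead supply an explicit PMF over sizes
    1..15, applied to every site.
    """

    beta0: float
    sigma_u: float = 0.0
    sigma_v: float = 0.0
    sigma_w: float = 0.0
    n_sites: int = 2
    villages_per_site: tuple[int, ...] = (12, 8)
    interviewers_per_site: tuple[int, ...] = (18, 12)
    households_per_village: tuple[int, ...] = (1150, 665)
    household_size_means: tuple[float, ...] = (2.5, 4.0)
    household_size_dist: tuple[float, ...] | None = None
    interviewer_sex_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        for name in ("sigma_u", "sigma_v", "sigma_w"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("villages_per_site", "interviewers_per_site", "households_per_village",
                     "household_size_means"):
            val = getattr(self, name)
            object.__setattr__(self, name, tuple(val))
            if len(getattr(self, name)) != self.n_sites:
                raise ConfigurationError(f"{name} must have one entry per site")
        if any(v < 1 for v in self.villages_per_site):
            raise ConfigurationError("each site needs at least one village")
        if any(v < 1 for v in self.interviewers_per_site):
            raise ConfigurationError("each site needs at least one interviewer")
        if any(v < 1 for v in self.households_per_village):
            raise ConfigurationError("households_per_village entries must be >= 1")
        if self.household_size_dist is not None:
            p = np.asarray(self.household_size_dist, dtype=float)
            if len(p) != MAX_HOUSEHOLD_SIZE or (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ConfigurationError(
                    f"household_size_dist must be a probability vector over sizes 1..{MAX_HOUSEHOLD_SIZE}"
                )
            object.__setattr__(self, "household_size_dist", tuple(p))
        else:
            for m in self.household_size_means:
                if not 1.0 < m < MAX_HOUSEHOLD_SIZE:
                    raise ConfigurationError("household_size_means must lie in (1, 15)")
        if not 0.0 <= self.interviewer_sex_prob <= 1.0:
            raise ConfigurationError("interviewer_sex_prob must be in [0, 1]")

    @property
    def total_latent_variance(self) -> float:
        return self.sigma_u**2 + self.sigma_v**2 + self.sigma_w**2

    def size_pmf(self, site: int) -> np.ndarray:
        if self.household_size_dist is not None:
            return np.asarray(self.household_size_dist, dtype=float)
        return truncated_geometric_pmf(self.household_size_means[site])

    def with_seed(self, seed: int) -> "PopulationConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class TrueParameters:
    """The data-generating parameters plus the realized random draws."""

    beta0: float
    sigma_u: float
    sigma_v: float
    sigma_w: float
    u: pd.Series  # site_id -> realized site effect
    v: pd.Series  # interviewer_id -> realized interviewer effect
    w: pd.Series  # household_id -> realized household effect

    def latent_icc(self) -> dict[str, float]:
        total = self.sigma_u**2 + self.sigma_v**2 + self.sigma_w**2 + _RESIDUAL
        return {
            "site": self.sigma_u**2 / total,
            "interviewer": self.sigma_v**2 / total,
            "household": self.sigma_w**2 / total,
        }


def marginal_prevalence(config: PopulationConfig, n_points: int = 1001) -> float:
    """Population-averaged event probability implied by the configuration.

    Computes ``E[logit^{-1}(beta0 + Z)]`` with ``Z ~ N(0, sigma_u^2 + sigma_v^2
    + sigma_w^2)`` by Gauss-Hermite quadrature; the empirical outcome rate of a
    large generated population converges to this value.
    """
    return float(mean_expit_gaussian(config.beta0, config.total_latent_variance, n_points))


def solve_intercept(target_prevalence: float, total_latent_variance: float) -> float:
    """Intercept beta0 such that the marginal event rate equals the target."""
    if not 0.0 < target_prevalence < 1.0:
        raise ConfigurationError("target prevalence must be in (0, 1)")
    if total_latent_variance == 0:
        return float(logit(target_prevalence))

    def f(b: float) -> float:
        return mean_expit_gaussian(b, total_latent_variance) - target_prevalence

    return float(brentq(f, -40.0, 40.0, xtol=1e-12))


def epina_like_config(
    seed: int = 0,
    icc_household: float = 0.397,
    icc_interviewer: float = 0.101,
    icc_site: float = 0.070,
    prevalence_per_1000: float = 9.4,
    **overrides,
) -> PopulationConfig:
    """Preset calibrated to the two-site Nairobi survey structure.

    Latent-scale variance components are solved from the target ICCs under the
    latent-logistic convention (residual pi^2/3), and the intercept from the
    target marginal rate; nothing is hard-coded from fitted estimates.
    """
    icc_sum = icc_household + icc_interviewer + icc_site
    if not 0.0 < icc_sum < 1.0:
        raise ConfigurationError("ICC targets must sum to a value in (0, 1)")
    total = _RESIDUAL / (1.0 - icc_sum)
    sigma_u = float(np.sqrt(icc_site * total))
    sigma_v = float(np.sqrt(icc_interviewer * total))
    sigma_w = float(np.sqrt(icc_household * total))
    beta0 = solve_intercept(prevalence_per_1000 / 1000.0, total - _RESIDUAL)
    return PopulationConfig(
        beta0=beta0, sigma_u=sigma_u, sigma_v=sigma_v, sigma_w=sigma_w, seed=seed, **overrides
    )


def _assign_villages_to_interviewers(
    n_villages: int, n_interviewers: int, rng: np.random.Generator
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Random whole-village allocation within one site.

    Returns ``(village_order, interviewers_of_village)`` where the latter lists
    the interviewer indices working each village.  When interviewers outnumber
    villages, some villages host more than one interviewer and their households
    are split; otherwise each interviewer covers one or more whole villages.
    """
    villages = rng.permutation(n_villages)
    interviewers = rng.permutation(n_interviewers)
    per_village: list[list[int]] = [[] for _ in range(n_villages)]
    if n_interviewers >= n_villages:
        for pos, intv in enumerate(interviewers):
            per_village[villages[pos % n_villages]].append(int(intv))
    else:
        for pos, vil in enumerate(villages):
            per_village[vil].append(int(interviewers[pos % n_interviewers]))
    return villages, [np.array(v, dtype=int) for v in per_village]


def generate_population(config: PopulationConfig) -> tuple[SurveyDataset, TrueParameters]:
    """Draw one survey population from the configured hierarchical model.

    Deterministic given ``config.seed``; all stage RNGs are split from that
    one seed.  Returns the dataset and the realized random effects (for
    parameter-recovery checks).
    """
    seed = config.seed
    rng_struct = substream(seed, "structure")
    rng_sizes = substream(seed, "sizes")
    rng_eff = substream(seed, "effects")
    rng_out = substream(seed, "outcomes")
    rng_sex = substream(seed, "sex")

    hh_site: list[np.ndarray] = []
    hh_village: list[np.ndarray] = []
    hh_interviewer: list[np.ndarray] = []
    hh_size: list[np.ndarray] = []

    village_offset = 0
    interviewer_offset = 0
    n_interviewers_total = sum(config.interviewers_per_site)
    for site in range(config.n_sites):
        n_vil = config.villages_per_site[site]
        n_int = config.interviewers_per_site[site]
        per_vil_households = config.households_per_village[site]
        _, intv_of_village = _assign_villages_to_interviewers(n_vil, n_int, rng_struct)
        pmf = config.size_pmf(site)
        for vil in range(n_vil):
            n_hh = per_vil_households
            hh_site.append(np.full(n_hh, site))
            hh_village.append(np.full(n_hh, village_offset + vil))
            crew = intv_of_village[vil]
            if len(crew) == 1:
                assigned = np.full(n_hh, crew[0])
            else:
                assigned = crew[rng_struct.integers(0, len(crew), size=n_hh)]
            hh_interviewer.append(interviewer_offset + assigned)
            hh_size.append(rng_sizes.choice(np.arange(1, MAX_HOUSEHOLD_SIZE + 1), size=n_hh, p=pmf))
        village_offset += n_vil
        interviewer_offset += n_int

    hh_site_arr = np.concatenate(hh_site)
    hh_village_arr = np.concatenate(hh_village)
    hh_interviewer_arr = np.concatenate(hh_interviewer)
    hh_size_arr = np.concatenate(hh_size)
    n_households = len(hh_site_arr)

    u = rng_eff.normal(0.0, config.sigma_u, size=config.n_sites) if config.sigma_u > 0 else np.zeros(config.n_sites)
    v = (
        rng_eff.normal(0.0, config.sigma_v, size=n_interviewers_total)
        if config.sigma_v > 0
        else np.zeros(n_interviewers_total)
    )
    w = rng_eff.normal(0.0, config.sigma_w, size=n_households) if config.sigma_w > 0 else np.zeros(n_households)

    intv_site = np.repeat(np.arange(config.n_sites), config.interviewers_per_site)
    intv_sex = np.where(rng_sex.random(n_interviewers_total) < config.interviewer_sex_prob, "F", "M")

    # expand households to individuals
    ind_household = np.repeat(np.arange(n_households), hh_size_arr)
    eta = (
        config.beta0
        + u[hh_site_arr][ind_household]
        + v[hh_interviewer_arr][ind_household]
        + w[ind_household]
    )
    y = (rng_out.random(len(eta)) < expit(eta)).astype(float)

    df = pd.DataFrame(
        {
            "individual_id": np.arange(len(eta)),
            "site_id": hh_site_arr[ind_household],
            "village_id": hh_village_arr[ind_household],
            "household_id": ind_household,
            "interviewer_id": hh_interviewer_arr[ind_household],
            "interviewer_sex": intv_sex[hh_interviewer_arr[ind_household]],
            "outcome": y,
        }
    )
    data = SurveyDataset(df)
    truth = TrueParameters(
        beta0=config.beta0,
        sigma_u=config.sigma_u,
        sigma_v=config.sigma_v,
        sigma_w=config.sigma_w,
        u=pd.Series(u, index=pd.Index([str(s) for s in range(config.n_sites)], name="site_id")),
        v=pd.Series(v, index=pd.Index([str(i) for i in range(n_interviewers_total)], name="interviewer_id")),
        w=pd.Series(w, index=pd.Index([str(h) for h in range(n_households)], name="household_id")),
    )
    return data, truth
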