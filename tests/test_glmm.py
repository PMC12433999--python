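"""Likelihood machinery: closed forms, quadrature oracles, fits, LRT."""
import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import chi2

from clustprev.dataset import SurveyDataset
from clustprev.glmm import (
    DegenerateFitError,
    ModelSpec,
    StructureError,
    VarianceComponents,
    fit_glmm,
    fit_intercept_only,
    loglik_oracle,
    lrt,
    marginal_loglik,
)
from clustprev.synthetic import generate_population

from conftest import make_dataset, small_population, trapezoid_mean_expit


class TestInterceptOnly:
    def test_proportion_recovered_exactly(self, bernoulli_47_of_5000):
        fit = fit_intercept_only(bernoulli_47_of_5000)
        assert expit(fit.beta0_hat) == pytest.approx(0.0094, abs=1e-15)
        assert fit.se_beta0 == pytest.approx(1 / np.sqrt(5000 * 0.0094 * 0.9906), rel=1e-12)
        p = 0.0094
        ll = 5000 * (p * np.log(p) + (1 - p) * np.log(1 - p))
        assert fit.loglik == pytest.approx(ll, rel=1e-12)

    def test_one_event_in_two_gives_zero_intercept(self):
        data = make_dataset([(0, 0, 0, 0, "F", 1.0), (0, 0, 1, 0, "F", 0.0)])
        assert fit_intercept_only(data).beta0_hat == pytest.approx(0.0, abs=1e-14)

    def test_all_zero_outcomes_degenerate(self):
        data = make_dataset([(0, 0, h, 0, "F", 0.0) for h in range(10)])
        with pytest.raises(DegenerateFitError):
            fit_intercept_only(data)

    def test_aic_bic_identity(self, bernoulli_47_of_5000):
        fit = fit_intercept_only(bernoulli_47_of_5000)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * 1, rel=1e-15)
        assert fit.bic == pytest.approx(-2 * fit.loglik + np.log(5000) * 1, rel=1e-15)


class TestOracle:
    def test_zero_variance_collapses_to_bernoulli(self, tiny_nested):
        y = tiny_nested.outcome
        beta0 = -0.7
        expected = float(np.sum(y * beta0 - np.logaddexp(0, beta0)))
        got = loglik_oracle(tiny_nested, beta0, {"site": 0.0, "household": 0.0}, n_points=30)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_single_observation_against_trapezoid(self):
        data = make_dataset([(0, 0, 0, 0, "F", 1.0)])
        beta0, s2 = -1.2, 0.8
        got = loglik_oracle(data, beta0, {"household": s2}, n_points=60)
        expected = np.log(trapezoid_mean_expit(beta0, s2, n_points=20001))
        assert got == pytest.approx(expected, abs=1e-8)

    def test_quadrature_converged(self, tiny_nested):
        sig = {"site": 0.3, "interviewer": 0.2, "household": 0.5}
        a = loglik_oracle(tiny_nested, -1.0, sig, n_points=30)
        b = loglik_oracle(tiny_nested, -1.0, sig, n_points=60)
        assert abs(a - b) < 1e-8

    def test_refuses_large_data(self):
        rows = [(0, 0, h, 0, "F", float(h % 2)) for h in range(60)]
        data = make_dataset(rows)
        with pytest.raises(ValueError, match="oracle"):
            loglik_oracle(data, -1.0, {"household": 0.5})


@pytest.mark.parametrize(
    "sigma2",
    [
        {"household": 0.5},
        {"site": 0.3, "household": 0.8},
        {"site": 0.3, "interviewer": 0.2, "household": 0.5},
        {"site": 1.2, "interviewer": 0.6, "household": 2.0},
    ],
)
@pytest.mark.parametrize("beta0", [-1.0, 0.4])
def test_dense_agq_matches_oracle(tiny_nested, sigma2, beta0):
    """The dense tensor-quadrature likelihood agrees with the naive recursion."""
    spec = ModelSpec(random_levels=tuple(sigma2), estimation="agq", agq_scope="all", q=25)
    got = marginal_loglik(tiny_nested, spec, beta0, sigma2)
    expected = loglik_oracle(tiny_nested, beta0, sigma2, n_points=50)
    assert got == pytest.approx(expected, abs=1e-4)  # actual agreement ~1e-10
    assert got == pytest.approx(expected, abs=1e-8)


def test_innermost_agq_close_to_oracle_single_level(tiny_nested):
    """With one random level the adaptive innermost scheme is itself exact-converging."""
    spec = ModelSpec(random_levels=("household",), estimation="agq", agq_scope="innermost", q=25)
    got = marginal_loglik(tiny_nested, spec, -0.8, {"household": 0.9})
    expected = loglik_oracle(tiny_nested, -0.8, {"household": 0.9}, n_points=50)
    assert got == pytest.approx(expected, abs=1e-8)


class TestFitGlmm:
    def test_no_random_levels_reduces_to_intercept_only(self, bernoulli_47_of_5000):
        a = fit_glmm(bernoulli_47_of_5000, ModelSpec(random_levels=()))
        b = fit_intercept_only(bernoulli_47_of_5000)
        assert a.beta0_hat == b.beta0_hat and a.loglik == b.loglik

    def test_zero_variance_data_recovers_flat_model(self):
        cfg = small_population(beta0=logit(0.05), n_sites=4, villages=2,
                               interviewers=4, households=150, seed=12)
        data, _ = generate_population(cfg)
        base = fit_intercept_only(data)
        fit = fit_glmm(data, ModelSpec(estimation="laplace"))
        assert fit.converged
        for s2 in fit.varcomps.sigma2.values():
            assert s2 < 0.05
        assert abs(fit.beta0_hat - base.beta0_hat) < 3 * base.se_beta0

    def test_tiny_fit_matches_oracle_at_optimum(self, tiny_nested):
        spec = ModelSpec(
            random_levels=("site", "household"), estimation="agq", agq_scope="all", q=30
        )
        fit = fit_glmm(tiny_nested, spec)
        sig = {lv: max(v, 1e-12) for lv, v in fit.varcomps.sigma2.items()}
        expected = loglik_oracle(tiny_nested, fit.beta0_hat, sig, n_points=60)
        assert fit.loglik == pytest.approx(expected, abs=1e-4)

    def test_fit_never_degrades_objective(self, tiny_nested):
        spec = ModelSpec(random_levels=("site", "household"), estimation="laplace")
        base = fit_intercept_only(tiny_nested)
        start = marginal_loglik(tiny_nested, spec, base.beta0_hat, {"site": 0.09, "household": 0.09})
        fit = fit_glmm(tiny_nested, spec)
        assert fit.loglik >= start - 1e-9

    def test_recovers_household_variance(self):
        cfg = small_population(beta0=logit(0.1), sigma_w=1.5, n_sites=2, villages=2,
                               interviewers=3, households=400, seed=17)
        data, _ = generate_population(cfg)
        fit = fit_glmm(data, ModelSpec(random_levels=("household",), estimation="agq", q=9))
        assert fit.converged
        assert fit.varcomps["household"] == pytest.approx(1.5**2, rel=0.35)

    def test_removing_a_null_level_barely_moves_intercept(self):
        # true interviewer variance is zero: dropping that level is inert
        cfg = small_population(beta0=logit(0.08), sigma_u=0.0, sigma_v=0.0, sigma_w=1.2,
                               n_sites=2, villages=2, interviewers=3, households=250, seed=23)
        data, _ = generate_population(cfg)
        full = fit_glmm(data, ModelSpec(estimation="agq", q=9))
        reduced = fit_glmm(
            data, ModelSpec(random_levels=("site", "household"), estimation="agq", q=9)
        )
        assert abs(full.beta0_hat - reduced.beta0_hat) < full.se_beta0

    def test_non_nested_labels_raise_structure_error(self):
        df = pd.DataFrame(
            {
                "individual_id": ["1", "2", "3", "4"],
                "site_id": ["0", "0", "1", "1"],
                "village_id": ["0", "0", "1", "1"],
                "household_id": ["0", "0", "0", "0"],  # household spans two sites
                "interviewer_id": ["0", "0", "1", "1"],
                "interviewer_sex": ["F", "F", "F", "F"],
                "outcome": [0.0, 1.0, 0.0, 1.0],
            }
        )
        data = SurveyDataset(df, validate=False)
        with pytest.raises(StructureError):
            fit_glmm(data, ModelSpec(random_levels=("site", "household")))

    def test_single_cluster_level_rejected(self):
        data = make_dataset([(0, 0, 0, 0, "F", float(i % 2)) for i in range(6)])
        with pytest.raises(StructureError, match="at least 2"):
            fit_glmm(data, ModelSpec(random_levels=("household",)))

    def test_determinism(self, tiny_nested):
        spec = ModelSpec(random_levels=("household",), estimation="agq", q=9)
        a = fit_glmm(tiny_nested, spec)
        b = fit_glmm(tiny_nested, spec)
        assert a.beta0_hat == b.beta0_hat
        assert a.loglik == b.loglik
        assert a.varcomps.sigma2 == b.varcomps.sigma2


class TestModelSpecValidation:
    def test_levels_reordered_to_nesting(self):
        spec = ModelSpec(random_levels=("household", "site"))
        assert spec.random_levels == ("site", "household")

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(random_levels=("region",)),
            dict(random_levels=("site", "site")),
            dict(q=0),
            dict(tol=0.0),
            dict(estimation="reml"),
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelSpec(**kwargs)

    def test_varcomps_validation(self):
        with pytest.raises(ValueError):
            VarianceComponents(sigma2={"household": -1.0})
        vc = VarianceComponents(sigma2={"household": 2.19})
        assert vc.residual == pytest.approx(np.pi**2 / 3, rel=1e-15)


class TestLRT:
    def test_identical_fits(self, tiny_nested):
        f = fit_intercept_only(tiny_nested)
        res = lrt(f, f)
        assert res.statistic == 0.0 and res.p_value == 1.0 and res.df == 0

    def test_chi_square_tail_value(self):
        null = fit_like(-103.0, {}, 100)
        alt = fit_like(-100.0, {"household": 0.5}, 100)
        res = lrt(null, alt)
        assert res.statistic == pytest.approx(6.0)
        assert res.df == 1
        assert res.p_value == pytest.approx(chi2.sf(6.0, 1), rel=1e-12)
        assert res.p_value == pytest.approx(0.0143, abs=5e-4)
        assert res.boundary  # variance-component test: boundary caveat flagged

    def test_negative_statistic_clipped_with_warning(self):
        null = fit_like(-100.0, {}, 100)
        alt = fit_like(-100.5, {"household": 0.2}, 100)
        with pytest.warns(RuntimeWarning, match="clipped"):
            res = lrt(null, alt)
        assert res.statistic == 0.0

    def test_different_records_rejected(self):
        a = fit_like(-100.0, {}, 100)
        b = fit_like(-90.0, {"household": 0.2}, 120)
        with pytest.raises(ValueError, match="different records"):
            lrt(a, b)


def fit_like(loglik, sigma2, n_obs):
    from clustprev.glmm import FitResult

    return FitResult(
        beta0_hat=-2.0,
        se_beta0=0.1,
        varcomps=VarianceComponents(sigma2=sigma2),
        loglik=loglik,
        n_obs=n_obs,
        n_events=10,
        converged=True,
        method="synthetic",
    )
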