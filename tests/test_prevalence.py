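"""Crude/adjusted prevalence arithmetic, homogeneity tests, table summaries."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit

from clustprev.datasets import load_interviewer_table, load_site_village_table
from clustprev.glmm import FitResult, ModelSpec, VarianceComponents, fit_glmm, fit_intercept_only
from clustprev.prevalence import (
    PrevalenceEstimate,
    adjusted_prevalence,
    chi2_homogeneity,
    crude_prevalence,
    estimates_to_frame,
    summary_arithmetic,
)
from clustprev.synthetic import generate_population

from conftest import make_dataset, small_population, trapezoid_mean_expit


class TestCrude:
    def test_rate_per_1000(self, bernoulli_47_of_5000):
        est = crude_prevalence(bernoulli_47_of_5000)[0]
        assert est.theta == pytest.approx(9.40, abs=1e-12)
        assert est.sigma == pytest.approx(1000 * np.sqrt(0.0094 * 0.9906 / 5000), rel=1e-12)

    def test_wald_bounds_from_printed_all_row(self):
        est = PrevalenceEstimate.from_point(9.40, 0.41)
        assert round(est.lcb, 2) == 8.60
        assert round(est.ucb, 2) == 10.20

    def test_negative_lower_bound_not_truncated(self):
        est = PrevalenceEstimate.from_point(1.11, 0.79)
        assert est.lcb < 0
        assert round(est.lcb, 2) == -0.44  # printed table rounds to -0.43

    def test_ci_symmetry_around_point(self):
        est = PrevalenceEstimate.from_counts(12, 700)
        assert (est.lcb + est.ucb) / 2 == pytest.approx(est.theta, abs=1e-9)

    def test_groups_in_first_appearance_order(self):
        data, _ = generate_population(
            small_population(beta0=logit(0.1), households=20, seed=6)
        )
        ests = crude_prevalence(data, group_by="village_id")
        assert [e.label for e in ests] == list(data.df["village_id"].unique())

    def test_group_consistency_weighted_mean(self):
        data, _ = generate_population(
            small_population(beta0=logit(0.15), sigma_w=1.0, households=50, seed=7)
        )
        overall = crude_prevalence(data)[0]
        groups = crude_prevalence(data, group_by="interviewer_id")
        weighted = sum(e.theta * e.n for e in groups) / sum(e.n for e in groups)
        assert weighted == pytest.approx(overall.theta, abs=1e-9)
        frame = estimates_to_frame(groups)
        assert set(frame.columns) >= {"label", "n", "theta_per_1000", "lcb", "ucb"}


@given(
    theta=st.floats(min_value=0.0, max_value=1000.0),
    sigma=st.floats(min_value=0.0, max_value=100.0),
)
@settings(max_examples=50, deadline=None)
def test_interval_width_identity(theta, sigma):
    est = PrevalenceEstimate.from_point(theta, sigma)
    assert est.ci_width == pytest.approx(2 * 1.96 * sigma, abs=1e-9)
    assert (est.lcb + est.ucb) / 2 == pytest.approx(theta, abs=1e-9)


class TestAdjusted:
    def test_no_levels_equals_crude(self, bernoulli_47_of_5000):
        fit = fit_intercept_only(bernoulli_47_of_5000)
        adj = adjusted_prevalence(fit)
        crude = crude_prevalence(bernoulli_47_of_5000)[0]
        assert adj.theta == pytest.approx(crude.theta, abs=1e-12)
        assert adj.lcb == pytest.approx(crude.lcb, abs=1e-12)
        assert adj.ucb == pytest.approx(crude.ucb, abs=1e-12)

    def test_balanced_outcome_gives_500_symmetric(self):
        data = make_dataset([(0, 0, 0, 0, "F", 1.0), (0, 0, 1, 0, "F", 0.0)])
        adj = adjusted_prevalence(fit_intercept_only(data))
        assert adj.theta == pytest.approx(500.0, abs=1e-9)
        assert adj.ucb - adj.theta == pytest.approx(adj.theta - adj.lcb, abs=1e-9)

    def test_population_averaged_against_trapezoid(self):
        fit = FitResult(
            beta0_hat=-4.69,
            se_beta0=0.25,
            varcomps=VarianceComponents(sigma2={"household": 2.5}),
            loglik=-100.0,
            n_obs=1000,
            n_events=10,
            converged=True,
            method="synthetic",
        )
        adj = adjusted_prevalence(fit, ci_method="transform")
        expected = trapezoid_mean_expit(-4.69, 2.5, n_points=20001)
        assert adj.theta / 1000 == pytest.approx(expected, abs=1e-6)
        lo = trapezoid_mean_expit(-4.69 - 1.96 * 0.25, 2.5, n_points=20001)
        assert adj.lcb / 1000 == pytest.approx(lo, abs=1e-6)

    def test_conditional_variant_labelled(self):
        fit = FitResult(
            beta0_hat=-4.0,
            se_beta0=0.2,
            varcomps=VarianceComponents(sigma2={"household": 1.0}),
            loglik=-10.0,
            n_obs=100,
            n_events=5,
            converged=True,
            method="synthetic",
        )
        cond = adjusted_prevalence(fit, estimand="conditional")
        pa = adjusted_prevalence(fit, ci_method="transform")
        assert cond.estimand == "conditional"
        assert cond.theta < pa.theta  # averaging over a rare-outcome logit lifts the rate

    def test_non_converged_fit_refused(self):
        fit = FitResult(
            beta0_hat=-4.0, se_beta0=0.2,
            varcomps=VarianceComponents(sigma2={"household": 1.0}),
            loglik=-10.0, n_obs=100, n_events=5, converged=False, method="synthetic",
        )
        from clustprev.glmm import NotConvergedError

        with pytest.raises(NotConvergedError):
            adjusted_prevalence(fit)

    def test_delta_interval_from_fit(self):
        cfg = small_population(beta0=logit(0.1), sigma_w=1.2, households=150, seed=15)
        data, _ = generate_population(cfg)
        fit = fit_glmm(data, ModelSpec(random_levels=("household",), estimation="agq", q=9))
        adj = adjusted_prevalence(fit)
        assert adj.lcb < adj.theta < adj.ucb
        assert adj.sigma > 0
        # delta interval is tighter than the plug-in transform interval
        trans = adjusted_prevalence(fit, ci_method="transform")
        assert adj.ci_width <= trans.ci_width * 1.05


class TestChi2:
    def test_identical_groups_no_signal(self):
        rows = []
        for g in range(2):
            rows += [(0, g, 10 * g + i, g, "F", 1.0) for i in range(10)]
            rows += [(0, g, 10 * g + i, g, "F", 0.0) for i in range(10, 50)]
        data = make_dataset([(s, v, h + 100 * v, j, sx, y) for (s, v, h, j, sx, y) in rows])
        res = chi2_homogeneity(data, "village_id")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_textbook_two_by_two(self):
        rows = []
        rows += [(0, 0, i, 0, "F", 1.0) for i in range(90)]
        rows += [(0, 0, 100 + i, 0, "F", 0.0) for i in range(10)]
        rows += [(0, 1, 200 + i, 1, "F", 1.0) for i in range(80)]
        rows += [(0, 1, 300 + i, 1, "F", 0.0) for i in range(20)]
        data = make_dataset(rows)
        res = chi2_homogeneity(data, "village_id")
        # hand computation: expected 85/15 per row, sum (O-E)^2/E = 2*(25/85 + 25/15)
        expected = 2 * (25 / 85 + 25 / 15)
        assert res.statistic == pytest.approx(expected, rel=1e-12)
        assert res.statistic == pytest.approx(3.9216, abs=5e-5)
        assert res.df == 1

    def test_single_group_rejected(self):
        data = make_dataset([(0, 0, i, 0, "F", float(i % 2)) for i in range(10)])
        with pytest.raises(ValueError, match="two groups"):
            chi2_homogeneity(data, "village_id")


@pytest.fixture()
def village_estimates():
    table = load_site_village_table()
    return {
        group: [
            PrevalenceEstimate.from_point(r.theta_per_1000, r.sigma, label=r.label)
            for r in sub.itertuples()
        ]
        for group, sub in table.groupby("group", sort=False)
    }


class TestSummaryArithmetic:
    def test_village_ranges(self, village_estimates):
        assert summary_arithmetic(village_estimates["village_viwandani"], "range") == pytest.approx(20.41)
        assert summary_arithmetic(village_estimates["village_korogocho"], "range") == pytest.approx(12.76)

    def test_interviewer_gender_means(self):
        table = load_interviewer_table()
        means = {}
        for (site, sex), sub in table.groupby(["site", "sex"], sort=False):
            ests = [PrevalenceEstimate.from_point(r.theta_per_1000, r.sigma) for r in sub.itertuples()]
            means[(site, sex)] = summary_arithmetic(ests, "mean_by")
        assert round(means[("Viwandani", "F")], 2) == 7.44
        assert round(means[("Viwandani", "M")], 2) == 8.79
        assert round(means[("Korogocho", "F")], 2) == 9.31
        assert round(means[("Korogocho", "M")], 2) == 11.64

    def test_single_row_range_zero(self):
        assert summary_arithmetic([PrevalenceEstimate.from_point(5.0, 1.0)], "range") == 0.0

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            summary_arithmetic([PrevalenceEstimate.from_point(5.0, 1.0, label="a")], "range", labels=["b"])
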