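"""Intercept-only logistic models with nested Gaussian random intercepts.

The model for individual ``k`` interviewed by interviewer ``j`` in site ``i``
(household ``h``) is

    Y ~ Bernoulli(pi),   logit(pi) = beta0 + u_i + v_ij + w_h,

with independent mean-zero normal random intercepts at any ordered subset of
the levels site > interviewer > household.  The marginal likelihood integrates
the random effects out level by level, exploiting the nesting (inner integrals
per household, then per interviewer, then per site).

Estimation maximises the full marginal likelihood.  Three evaluation schemes
are available through :class:`ModelSpec`:

``laplace``
    Joint Laplace approximation at all levels.  The joint posterior mode of
    all random effects is found by Newton iterations; the log-determinant of
    the sparse (tree-structured) Hessian is computed by exact innermost-first
    elimination, so the cost is linear in the number of clusters.
``agq`` with ``agq_scope="innermost"`` (default scope)
    Adaptive Gauss-Hermite quadrature (Q nodes, centred and scaled at each
    inner cluster's conditional mode) on the innermost level, Laplace on the
    remaining outer levels.  The innermost level is where clusters are small
    (households of 1-15 members) and the Laplace approximation is poorest;
    outer clusters hold hundreds to thousands of observations each, where
    Laplace is accurate.
``agq`` with ``agq_scope="all"``
    Dense tensor-product Gauss-Hermite at every level.  Exact in the limit of
    large Q; intended for small fixtures and accuracy checks (cost grows as
    Q^levels).

Because the model has no covariates, all computations reduce to household
sufficient statistics (size, event count) grouped by parent cluster, which
keeps a full fit on ~50,000 records well under a second.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit, logsumexp
from scipy.stats import chi2

from ._quadrature import hermite_nodes
from .dataset import SurveyDataset

RESIDUAL_VARIANCE = np.pi**2 / 3.0  # latent-logistic residual convention

LEVEL_ORDER = ("site", "interviewer", "household")  # outermost to innermost
LEVEL_COLUMNS = {"site": "site_id", "interviewer": "interviewer_id", "household": "household_id"}

_LOG_SD_MIN = -8.0
_LOG_SD_MAX = 4.0
_LOG_SD_ZERO = -6.0  # fitted log-SD below this is reported as a zero variance


class StructureError(ValueError):
    """Cluster labels do not form the declared nesting."""


class DegenerateFitError(ValueError):
    """All-0 or all-1 outcomes: the logit intercept is infinite."""


class NotConvergedError(RuntimeError):
    """An operation requiring a converged fit received a non-converged one."""


@dataclass(frozen=True)
class ModelSpec:
    """Which random levels to fit and how to evaluate the likelihood."""

    random_levels: tuple[str, ...] = LEVEL_ORDER
    estimation: str = "laplace"  # "laplace" | "agq"
    q: int = 9
    agq_scope: str = "innermost"  # "innermost" | "all"
    max_iter: int = 2000
    tol: float = 1e-8
    #: skip the observed-information standard error (simulation studies that
    #: only need point estimates)
    compute_se: bool = True

    def __post_init__(self):
        levels = tuple(self.random_levels)
        unknown = [lv for lv in levels if lv not in LEVEL_ORDER]
        if unknown:
            raise ValueError(f"unknown random levels {unknown}; choose from {LEVEL_ORDER}")
        if len(set(levels)) != len(levels):
            raise ValueError("duplicate random levels")
        ordered = tuple(lv for lv in LEVEL_ORDER if lv in levels)
        object.__setattr__(self, "random_levels", ordered)
        if self.estimation not in ("laplace", "agq"):
            raise ValueError("estimation must be 'laplace' or 'agq'")
        if self.agq_scope not in ("innermost", "all"):
            raise ValueError("agq_scope must be 'innermost' or 'all'")
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")

    @property
    def n_levels(self) -> int:
        return len(self.random_levels)


@dataclass(frozen=True)
class VarianceComponents:
    """Random-intercept variances plus the fixed latent residual.

    The residual variance of the latent logistic scale is the constant
    pi^2/3; it is a convention, not an estimated parameter.
    """

    sigma2: dict[str, float]
    residual: float = RESIDUAL_VARIANCE

    def __post_init__(self):
        for lv, s2 in self.sigma2.items():
            if lv not in LEVEL_ORDER:
                raise ValueError(f"unknown level {lv!r}")
            if s2 < 0:
                raise ValueError(f"negative variance for {lv}")
        ordered = {lv: float(self.sigma2[lv]) for lv in LEVEL_ORDER if lv in self.sigma2}
        object.__setattr__(self, "sigma2", ordered)

    def __getitem__(self, level: str) -> float:
        return self.sigma2[level]

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(self.sigma2)

    @property
    def cluster_total(self) -> float:
        return float(sum(self.sigma2.values()))

    @property
    def total(self) -> float:
        return self.cluster_total + self.residual


@dataclass(frozen=True)
class FitResult:
    """One fitted model structure."""

    beta0_hat: float
    se_beta0: float
    varcomps: VarianceComponents
    loglik: float
    n_obs: int
    n_events: int
    converged: bool
    method: str
    spec: ModelSpec | None = None
    cluster_effect_predictions: dict[str, pd.Series] = field(default_factory=dict)
    message: str = ""
    #: names of the free parameters with estimated covariance ("beta0" plus
    #: "log_sd_<level>" for levels not at the zero boundary)
    param_names: tuple[str, ...] = ("beta0",)
    #: observed-information covariance of those parameters (None if unavailable)
    param_cov: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return 1 + len(self.varcomps.sigma2)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + np.log(self.n_obs) * self.n_params


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float
    boundary: bool  # True when the null pins a variance at its boundary


def _bern_loglik(eta, n, k):
    """sum over a cluster of the Bernoulli log-likelihood, eta on logit scale."""
    return k * eta - n * np.logaddexp(0.0, eta)


# ---------------------------------------------------------------------------
# nested structure with household sufficient statistics
# ---------------------------------------------------------------------------
class _Structure:
    """Factorised nested clusters plus innermost sufficient-statistic groups.

    Innermost clusters sharing the same parent cluster and the same (size,
    events) pair are interchangeable in an intercept-only model; they are
    collapsed into groups with multiplicities, which is what makes large fits
    cheap.
    """

    def __init__(self, df: pd.DataFrame, levels: tuple[str, ...]):
        self.levels = levels
        m = len(levels)
        self.m = m
        y = df["outcome"].to_numpy()
        self.n_obs = len(df)
        self.n_events = int(y.sum())

        codes: list[np.ndarray] = []
        labels: list[pd.Index] = []
        for lv in levels:
            c, lab = pd.factorize(df[LEVEL_COLUMNS[lv]], sort=False)
            codes.append(np.asarray(c))
            labels.append(pd.Index(lab))
        self.counts = [len(lab) for lab in labels]
        self.labels = labels

        # parent maps between adjacent included levels; verify strict nesting
        self.parent: list[np.ndarray | None] = [None] * m
        for ell in range(1, m):
            grp = pd.Series(codes[ell - 1]).groupby(codes[ell])
            if int(grp.nunique().max()) > 1:
                raise StructureError(
                    f"{levels[ell]} clusters are not nested within {levels[ell - 1]} clusters"
                )
            self.parent[ell] = grp.first().sort_index().to_numpy()

        # ancestors of each level's clusters at every outer included level
        self.anc: list[dict[int, np.ndarray]] = [dict() for _ in range(m)]
        for ell in range(1, m):
            a = self.parent[ell]
            self.anc[ell][ell - 1] = a
            for outer in range(ell - 2, -1, -1):
                a = self.parent[outer + 1][a]
                self.anc[ell][outer] = a

        inner = codes[m - 1]
        n_inner = self.counts[m - 1]
        hh_n = np.bincount(inner, minlength=n_inner).astype(float)
        hh_k = np.bincount(inner, weights=y, minlength=n_inner)
        if m >= 2:
            # parent of each innermost cluster at level m-2
            first = pd.Series(codes[m - 2]).groupby(inner).first().sort_index().to_numpy()
            key = np.stack([first, hh_n.astype(int), hh_k.astype(int)], axis=1)
        else:
            first = np.zeros(n_inner, dtype=int)
            key = np.stack([hh_n.astype(int), hh_k.astype(int)], axis=1)
        uniq, inv = np.unique(key, axis=0, return_inverse=True)
        self.inner_group = inv  # innermost cluster -> group
        self.G = len(uniq)
        self.g_m = np.bincount(inv, minlength=self.G).astype(float)
        if m >= 2:
            g_parent = uniq[:, 0]
            self.g_n = uniq[:, 1].astype(float)
            self.g_k = uniq[:, 2].astype(float)
        else:
            g_parent = np.zeros(self.G, dtype=int)
            self.g_n = uniq[:, 0].astype(float)
            self.g_k = uniq[:, 1].astype(float)
        # ancestors of each group at every outer level
        self.g_anc: dict[int, np.ndarray] = {}
        if m >= 2:
            self.g_anc[m - 2] = g_parent
            for outer in range(m - 3, -1, -1):
                self.g_anc[outer] = self.anc[m - 2][outer][g_parent]
        self.n_inner_total = float(self.g_m.sum())  # == n_inner

    @property
    def n_outer_levels(self) -> int:
        return self.m - 1


# ---------------------------------------------------------------------------
# likelihood engines
# ---------------------------------------------------------------------------
class _Engine:
    """Evaluates the marginal log-likelihood for one data structure.

    Keeps warm-start state for the random-effect modes across parameter
    evaluations during optimisation.
    """

    def __init__(self, struct: _Structure, spec: ModelSpec):
        self.s = struct
        self.spec = spec
        self.reset_state()

    def reset_state(self):
        s = self.s
        self.b = [np.zeros(s.counts[ell]) for ell in range(s.m - 1)]
        self.wg = np.zeros(s.G)
        self.what = np.zeros(s.G)

    # -- parameter packing ---------------------------------------------------
    def unpack(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        beta0 = float(theta[0])
        log_sd = np.clip(np.asarray(theta[1:], dtype=float), _LOG_SD_MIN, _LOG_SD_MAX)
        return beta0, np.exp(2.0 * log_sd)

    def loglik(self, theta: np.ndarray) -> float:
        # evaluations are deliberately stateless (modes restart from zero) so
        # the objective is a deterministic, optimizer-friendly function of theta
        self.reset_state()
        beta0, sig2 = self.unpack(theta)
        if self.spec.estimation == "laplace":
            return self._laplace(beta0, sig2)[0]
        if self.spec.agq_scope == "innermost":
            return self._agq_inner(beta0, sig2)[0]
        return self._agq_dense(beta0, sig2)

    # -- joint Laplace -------------------------------------------------------
    def _offsets(self, beta0: float, b: list[np.ndarray]) -> np.ndarray:
        s = self.s
        t = np.full(s.G, beta0)
        for ell in range(s.m - 1):
            t = t + b[ell][s.g_anc[ell]]
        return t

    def _laplace_F(self, beta0, sig2, b, wg) -> float:
        s = self.s
        eta = self._offsets(beta0, b) + wg
        val = float(np.sum(s.g_m * _bern_loglik(eta, s.g_n, s.g_k)))
        val -= 0.5 * float(np.sum(s.g_m * wg**2)) / sig2[s.m - 1]
        for ell in range(s.m - 1):
            val -= 0.5 * float(np.sum(b[ell] ** 2)) / sig2[ell]
        return val

    def _eliminate(self, s_g: np.ndarray, sig2, with_inner_schur: bool):
        """Innermost-first elimination of the tree-structured Hessian.

        ``s_g`` is the data curvature per (representative) innermost cluster.
        With ``with_inner_schur`` the innermost level itself is a coordinate
        block (joint Laplace); otherwise it has already been integrated out by
        quadrature and only contributes curvature to the outer levels.
        Returns per-level gamma (coupling to every remaining ancestor),
        diagonal d, and the log-determinant contribution.
        """
        s = self.s
        m = s.m
        gam: list[np.ndarray | None] = [None] * m
        dlev: list[np.ndarray | None] = [None] * m
        logdet = 0.0
        if with_inner_schur:
            d_g = s_g + 1.0 / sig2[m - 1]
            gam[m - 1] = s_g
            dlev[m - 1] = d_g
            logdet += float(np.sum(s.g_m * np.log(d_g)))
            carry_g = s_g**2 / d_g  # per household, subtracted from every ancestor
            n_out = m - 1
        else:
            carry_g = np.zeros(s.G)
            n_out = m - 1
        if n_out >= 1:
            ell = n_out - 1  # level m-2
            S = np.bincount(s.g_anc[ell], weights=s.g_m * s_g, minlength=s.counts[ell])
            D = np.bincount(s.g_anc[ell], weights=s.g_m * carry_g, minlength=s.counts[ell])
            gam[ell] = S - D
            dlev[ell] = gam[ell] + 1.0 / sig2[ell]
            logdet += float(np.sum(np.log(dlev[ell])))
            carry = D + gam[ell] ** 2 / dlev[ell]
            for ell in range(n_out - 2, -1, -1):
                S = np.bincount(s.g_anc[ell], weights=s.g_m * s_g, minlength=s.counts[ell])
                child = ell + 1
                D = np.bincount(s.parent[child], weights=carry, minlength=s.counts[ell])
                gam[ell] = S - D
                dlev[ell] = gam[ell] + 1.0 / sig2[ell]
                logdet += float(np.sum(np.log(dlev[ell])))
                carry = D + gam[ell] ** 2 / dlev[ell]
        return gam, dlev, logdet

    def _solve(self, grad_b, grad_w, s_g, gam, dlev, sig2, with_inner: bool):
        """Solve H x = grad using the elimination factors."""
        s = self.s
        m = s.m
        n_out = m - 1
        Rt = [g.copy() for g in grad_b]
        if with_inner:
            inv_d = 1.0 / dlev[m - 1]
            coef_g = s_g * inv_d * grad_w
            for ell in range(n_out):
                Rt[ell] -= np.bincount(s.g_anc[ell], weights=s.g_m * coef_g, minlength=s.counts[ell])
        for ell in range(n_out - 1, 0, -1):
            coef = gam[ell] / dlev[ell] * Rt[ell]
            for outer in range(ell):
                anc = s.anc[ell][outer] if ell >= 1 else None
                Rt[outer] -= np.bincount(anc, weights=coef, minlength=s.counts[outer])
        x = [None] * n_out
        if n_out >= 1:
            x[0] = Rt[0] / dlev[0]
            for ell in range(1, n_out):
                A = np.zeros(s.counts[ell])
                for outer in range(ell):
                    A += x[outer][s.anc[ell][outer]]
                x[ell] = (Rt[ell] - gam[ell] * A) / dlev[ell]
        if with_inner:
            A_g = np.zeros(s.G)
            for ell in range(n_out):
                A_g += x[ell][s.g_anc[ell]]
            x_w = (grad_w - s_g * A_g) / dlev[m - 1]
        else:
            x_w = None
        return x, x_w

    def _laplace(self, beta0, sig2, gtol: float = 1e-7, max_newton: int = 100):
        s = self.s
        m = s.m
        b = [bi.copy() for bi in self.b]
        wg = self.wg.copy()
        F = self._laplace_F(beta0, sig2, b, wg)
        restarted = False
        it = 0
        while True:
            eta = self._offsets(beta0, b) + wg
            pi = expit(eta)
            s_g = s.g_n * pi * (1.0 - pi)
            resid = s.g_k - s.g_n * pi
            grad_w = resid - wg / sig2[m - 1]
            grad_b = []
            gmax = float(np.max(np.abs(grad_w))) if s.G else 0.0
            for ell in range(m - 1):
                g = (
                    np.bincount(s.g_anc[ell], weights=s.g_m * resid, minlength=s.counts[ell])
                    - b[ell] / sig2[ell]
                )
                grad_b.append(g)
                gmax = max(gmax, float(np.max(np.abs(g))))
            gam, dlev, logdet = self._eliminate(s_g, sig2, with_inner_schur=True)
            if gmax < gtol or it >= max_newton:
                if it >= max_newton and not restarted:
                    # retry once from the origin
                    restarted = True
                    it = 0
                    b = [np.zeros_like(bi) for bi in b]
                    wg = np.zeros_like(wg)
                    F = self._laplace_F(beta0, sig2, b, wg)
                    continue
                break
            x, x_w = self._solve(grad_b, grad_w, s_g, gam, dlev, sig2, with_inner=True)
            # Newton decrement: stop when the expected improvement is negligible
            decr = float(np.sum(self.s.g_m * grad_w * x_w))
            for ell in range(m - 1):
                decr += float(grad_b[ell] @ x[ell])
            if decr < 2e-9 * (1.0 + abs(F)):
                break
            # cap the step so far-from-mode curvature can't cause huge overshoots
            norm = max(float(np.max(np.abs(x_w), initial=0.0)),
                       max((float(np.max(np.abs(xi), initial=0.0)) for xi in x), default=0.0))
            if norm > 10.0:
                scale = 10.0 / norm
                x = [xi * scale for xi in x]
                x_w = x_w * scale
            alpha = 1.0
            for _ in range(40):
                b_new = [b[ell] + alpha * x[ell] for ell in range(m - 1)]
                w_new = wg + alpha * x_w
                F_new = self._laplace_F(beta0, sig2, b_new, w_new)
                if F_new >= F - 1e-12:
                    break
                alpha *= 0.5
            improved = F_new - F
            b, wg, F = b_new, w_new, max(F_new, F)
            it += 1
            if improved < 1e-10 * (1.0 + abs(F)):
                break
        self.b, self.wg = [bi.copy() for bi in b], wg.copy()
        n_coords_log = s.n_inner_total * np.log(sig2[m - 1])
        for ell in range(m - 1):
            n_coords_log += s.counts[ell] * np.log(sig2[ell])
        ll = F - 0.5 * n_coords_log - 0.5 * logdet
        return float(ll), b, wg

    # -- adaptive GH on the innermost level, Laplace outside ------------------
    def _household_agq(self, t: np.ndarray, sig2_in: float):
        """Per-group marginal log-likelihood of the innermost integral.

        Returns (loglik, d/dt, curvature -d2/dt2), each of shape (G,), for the
        integral over the innermost random effect at offset ``t``.
        """
        s = self.s
        z, wn = hermite_nodes(self.spec.q)
        what = self.what.copy()
        # conditional mode of the innermost effect, per group (concave scalar problem)
        for _ in range(50):
            pi = expit(t + what)
            f1 = s.g_k - s.g_n * pi - what / sig2_in
            f2 = s.g_n * pi * (1.0 - pi) + 1.0 / sig2_in
            step = f1 / f2
            what = what + np.clip(step, -4.0, 4.0)
            if np.max(np.abs(step)) < 1e-10:
                break
        self.what = what.copy()
        sd = 1.0 / np.sqrt(s.g_n * expit(t + what) * (1.0 - expit(t + what)) + 1.0 / sig2_in)
        wq = what[:, None] + sd[:, None] * z[None, :]
        eta = t[:, None] + wq
        logc = (
            np.log(wn)[None, :]
            + 0.5 * z[None, :] ** 2
            + np.log(sd / np.sqrt(sig2_in))[:, None]
            + _bern_loglik(eta, s.g_n[:, None], s.g_k[:, None])
            - 0.5 * wq**2 / sig2_in
        )
        ll = logsumexp(logc, axis=1)
        p = np.exp(logc - ll[:, None])
        pi_q = expit(eta)
        S1 = s.g_k[:, None] - s.g_n[:, None] * pi_q
        S2 = s.g_n[:, None] * pi_q * (1.0 - pi_q)
        d1 = np.sum(p * S1, axis=1)
        curv = np.sum(p * S2, axis=1) - (np.sum(p * S1**2, axis=1) - d1**2)
        return ll, d1, np.clip(curv, 1e-12, None)

    def _agq_inner(self, beta0, sig2, gtol: float = 1e-7, max_newton: int = 100):
        s = self.s
        m = s.m
        if m == 1:
            ll_g, _, _ = self._household_agq(np.full(s.G, beta0), sig2[0])
            return float(np.sum(s.g_m * ll_g)), [], None
        b = [bi.copy() for bi in self.b]

        def F_of(bb):
            t = self._offsets(beta0, bb)
            ll_g, d1, curv = self._household_agq(t, sig2[m - 1])
            val = float(np.sum(s.g_m * ll_g))
            for ell in range(m - 1):
                val -= 0.5 * float(np.sum(bb[ell] ** 2)) / sig2[ell]
            return val, ll_g, d1, curv

        F, ll_g, d1, curv = F_of(b)
        restarted = False
        it = 0
        while True:
            grad_b = []
            gmax = 0.0
            for ell in range(m - 1):
                g = (
                    np.bincount(s.g_anc[ell], weights=s.g_m * d1, minlength=s.counts[ell])
                    - b[ell] / sig2[ell]
                )
                grad_b.append(g)
                gmax = max(gmax, float(np.max(np.abs(g))))
            gam, dlev, logdet = self._eliminate(curv, sig2, with_inner_schur=False)
            if gmax < gtol or it >= max_newton:
                if it >= max_newton and not restarted:
                    restarted = True
                    it = 0
                    b = [np.zeros_like(bi) for bi in b]
                    F, ll_g, d1, curv = F_of(b)
                    continue
                break
            x, _ = self._solve(grad_b, None, curv, gam, dlev, sig2, with_inner=False)
            decr = 0.0
            for ell in range(m - 1):
                decr += float(grad_b[ell] @ x[ell])
            if decr < 2e-9 * (1.0 + abs(F)):
                break
            norm = max((float(np.max(np.abs(xi), initial=0.0)) for xi in x), default=0.0)
            if norm > 10.0:
                x = [xi * (10.0 / norm) for xi in x]
            alpha = 1.0
            for _ in range(40):
                b_new = [b[ell] + alpha * x[ell] for ell in range(m - 1)]
                F_new, ll_new, d1_new, curv_new = F_of(b_new)
                if F_new >= F - 1e-12:
                    break
                alpha *= 0.5
            improved = F_new - F
            b, F, ll_g, d1, curv = b_new, max(F_new, F), ll_new, d1_new, curv_new
            it += 1
            if improved < 1e-10 * (1.0 + abs(F)):
                break
        self.b = [bi.copy() for bi in b]
        n_coords_log = 0.0
        for ell in range(m - 1):
            n_coords_log += s.counts[ell] * np.log(sig2[ell])
        ll = F - 0.5 * n_coords_log - 0.5 * logdet
        return float(ll), b, None

    # -- dense tensor-product GH (small data) ---------------------------------
    def _agq_dense(self, beta0, sig2) -> float:
        s = self.s
        m = s.m
        Q = max(self.spec.q, 3)
        z, wn = hermite_nodes(Q)
        logw = np.log(wn)
        sd = np.sqrt(sig2)
        if m == 1:
            eta = beta0 + sd[0] * z  # (Q,)
            lb = _bern_loglik(eta[None, :], s.g_n[:, None], s.g_k[:, None])
            ll_g = logsumexp(logw[None, :] + lb, axis=1)
            return float(np.sum(s.g_m * ll_g))
        if m == 2:
            eta = beta0 + sd[0] * z[:, None] + sd[1] * z[None, :]  # (Q0, Q1)
            lb = _bern_loglik(
                eta[None, :, :], s.g_n[:, None, None], s.g_k[:, None, None]
            )  # (G, Q0, Q1)
            val = logsumexp(logw[None, None, :] + lb, axis=2)  # (G, Q0)
            A = np.zeros((s.counts[0], Q))
            np.add.at(A, s.g_anc[0], s.g_m[:, None] * val)
            ll_c = logsumexp(logw[None, :] + A, axis=1)
            return float(np.sum(ll_c))
        # m == 3
        eta = (
            beta0
            + sd[0] * z[:, None, None]
            + sd[1] * z[None, :, None]
            + sd[2] * z[None, None, :]
        )  # (Q0, Q1, Q2)
        lb = _bern_loglik(
            eta[None, ...], s.g_n[:, None, None, None], s.g_k[:, None, None, None]
        )  # (G, Q0, Q1, Q2)
        val2 = logsumexp(logw[None, None, None, :] + lb, axis=3)  # (G, Q0, Q1)
        A1 = np.zeros((s.counts[1], Q, Q))
        np.add.at(A1, s.g_anc[1], s.g_m[:, None, None] * val2)
        val1 = logsumexp(logw[None, None, :] + A1, axis=2)  # (n1, Q0)
        A0 = np.zeros((s.counts[0], Q))
        np.add.at(A0, s.parent[1], val1)
        ll_c = logsumexp(logw[None, :] + A0, axis=1)
        return float(np.sum(ll_c))

    # -- posterior modes for reporting ----------------------------------------
    def cluster_modes(self, theta: np.ndarray) -> dict[str, pd.Series]:
        beta0, sig2 = self.unpack(theta)
        s = self.s
        if self.spec.estimation == "laplace":
            _, b, wg = self._laplace(beta0, sig2)
            inner_vals = wg
        else:
            _, b, _ = self._agq_inner(beta0, sig2)
            t = self._offsets(beta0, b) if s.m > 1 else np.full(s.G, beta0)
            self._household_agq(t, sig2[s.m - 1])
            inner_vals = self.what
        out: dict[str, pd.Series] = {}
        for ell in range(s.m - 1):
            out[s.levels[ell]] = pd.Series(b[ell], index=s.labels[ell])
        out[s.levels[s.m - 1]] = pd.Series(
            inner_vals[s.inner_group], index=s.labels[s.m - 1]
        )
        return out


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------
def _complete(data: SurveyDataset) -> pd.DataFrame:
    df = data.df[data.df["outcome"].notna()]
    if len(df) == 0:
        raise ValueError("no complete records")
    return df


def fit_intercept_only(data: SurveyDataset) -> FitResult:
    """Empty logistic model: the crude (no-clustering) prevalence on the logit scale.

    Closed form: logit^{-1}(beta0_hat) is the sample proportion, the standard
    error is [n p (1-p)]^{-1/2}, and the log-likelihood is the Bernoulli
    log-likelihood at the proportion.
    """
    df = _complete(data)
    y = df["outcome"].to_numpy()
    n = len(y)
    k = float(y.sum())
    if k == 0 or k == n:
        raise DegenerateFitError(
            f"outcome is all-{int(k > 0)}; the intercept is infinite on the logit scale"
        )
    p = k / n
    beta0 = float(logit(p))
    se = 1.0 / np.sqrt(n * p * (1.0 - p))
    ll = k * np.log(p) + (n - k) * np.log(1.0 - p)
    return FitResult(
        beta0_hat=beta0,
        se_beta0=float(se),
        varcomps=VarianceComponents(sigma2={}),
        loglik=float(ll),
        n_obs=n,
        n_events=int(k),
        converged=True,
        method="closed_form",
        spec=ModelSpec(random_levels=()),
    )


def _method_name(spec: ModelSpec) -> str:
    if spec.estimation == "laplace":
        return "laplace"
    return f"agq(q={spec.q},{spec.agq_scope})"


def fit_glmm(data: SurveyDataset, spec: ModelSpec, start: Mapping[str, float] | None = None) -> FitResult:
    """Maximise the marginal likelihood of the nested random-intercept model.

    Complete-case records only.  The optimiser works on (beta0, log-SD per
    level) with Nelder-Mead; variance components are kept non-negative by the
    log-SD parameterisation and a fitted log-SD below -6 is reported as a zero
    variance.  The standard error of beta0 comes from the observed information
    (numerical Hessian of the marginal log-likelihood) at the optimum.
    """
    if spec.n_levels == 0:
        return fit_intercept_only(data)
    df = _complete(data)
    base = fit_intercept_only(SurveyDataset(df, validate=False))
    struct = _Structure(df, spec.random_levels)
    for lv, cnt in zip(struct.levels, struct.counts):
        if cnt < 2:
            raise StructureError(f"level {lv!r} has {cnt} cluster(s); need at least 2")
    engine = _Engine(struct, spec)

    theta0 = np.concatenate([[base.beta0_hat], np.full(spec.n_levels, np.log(0.3))])
    if start is not None:
        theta0[0] = start.get("beta0", theta0[0])
        for i, lv in enumerate(spec.random_levels):
            if lv in start:
                theta0[1 + i] = 0.5 * np.log(max(start[lv], 1e-12))

    neg = lambda th: -engine.loglik(th)
    # quasi-Newton leg for fast global progress, then a derivative-free polish
    # (the quadrature objective has a ~1e-4 noise floor that finite-difference
    # gradients cannot resolve near the optimum)
    bounds = [(-30.0, 10.0)] + [(_LOG_SD_MIN, _LOG_SD_MAX)] * spec.n_levels
    res1 = minimize(
        neg,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options=dict(maxiter=60, eps=1e-3, ftol=1e-11, gtol=1e-6),
    )
    x1 = res1.x if np.isfinite(res1.fun) and res1.fun <= -engine.loglik(theta0) + 1e-6 else theta0
    res = minimize(
        neg,
        x1,
        method="Nelder-Mead",
        options=dict(
            xatol=1e-4,
            fatol=max(spec.tol, 1e-7) * max(1.0, abs(base.loglik)),
            maxiter=spec.max_iter,
            maxfev=spec.max_iter,
        ),
    )
    theta_hat = res.x
    loglik = -float(res.fun)
    converged = bool(res.success)

    log_sd = np.clip(theta_hat[1:], _LOG_SD_MIN, _LOG_SD_MAX)
    sigma2_raw = np.exp(2.0 * log_sd)
    sigma2 = {
        lv: (0.0 if log_sd[i] < _LOG_SD_ZERO else float(sigma2_raw[i]))
        for i, lv in enumerate(spec.random_levels)
    }

    if spec.compute_se:
        se, se_ok, names, cov = _se_beta0(engine, theta_hat, log_sd, spec.random_levels)
    else:
        se, se_ok, names, cov = float("nan"), True, ("beta0",), None
    modes = engine.cluster_modes(theta_hat)
    return FitResult(
        beta0_hat=float(theta_hat[0]),
        se_beta0=se,
        varcomps=VarianceComponents(sigma2=sigma2),
        loglik=loglik,
        n_obs=struct.n_obs,
        n_events=struct.n_events,
        converged=converged and se_ok,
        method=_method_name(spec),
        spec=spec,
        cluster_effect_predictions=modes,
        message=res.message,
        param_names=names,
        param_cov=cov,
    )


def _se_beta0(
    engine: _Engine, theta_hat: np.ndarray, log_sd: np.ndarray, levels: tuple[str, ...]
) -> tuple[float, bool, tuple[str, ...], np.ndarray | None]:
    """Wald SE of beta0 (and parameter covariance) from the observed information.

    Variance components estimated at (numerically) zero are held fixed: their
    log-SD coordinates carry no curvature and are dropped before inversion.
    """
    active = [0] + [1 + i for i in range(len(log_sd)) if log_sd[i] > -4.0]
    names = tuple(
        "beta0" if j == 0 else f"log_sd_{levels[j - 1]}" for j in active
    )
    p = len(active)
    h = np.array([5e-3 * max(1.0, abs(theta_hat[j])) for j in active])
    f0 = engine.loglik(theta_hat)

    def f(delta: dict[int, float]) -> float:
        th = theta_hat.copy()
        for j, d in delta.items():
            th[j] += d
        return engine.loglik(th)

    H = np.zeros((p, p))
    for a in range(p):
        ja = active[a]
        H[a, a] = -(f({ja: h[a]}) - 2.0 * f0 + f({ja: -h[a]})) / h[a] ** 2
        for bidx in range(a + 1, p):
            jb = active[bidx]
            val = -(
                f({ja: h[a], jb: h[bidx]})
                - f({ja: h[a], jb: -h[bidx]})
                - f({ja: -h[a], jb: h[bidx]})
                + f({ja: -h[a], jb: -h[bidx]})
            ) / (4.0 * h[a] * h[bidx])
            H[a, bidx] = H[bidx, a] = val
    try:
        cov = np.linalg.inv(H)
        var = float(cov[0, 0])
        if var > 0 and np.all(np.diag(cov) > 0):
            return float(np.sqrt(var)), True, names, cov
    except np.linalg.LinAlgError:
        pass
    if H[0, 0] > 0:
        return float(1.0 / np.sqrt(H[0, 0])), False, ("beta0",), None
    return float("nan"), False, ("beta0",), None


def marginal_loglik(
    data: SurveyDataset, spec: ModelSpec, beta0: float, sigma2: Mapping[str, float] | Sequence[float]
) -> float:
    """Evaluate the spec's likelihood approximation at given parameter values.

    Useful for oracle-equivalence checks and for verifying that fitting never
    degrades the objective relative to its starting point.
    """
    if spec.n_levels == 0:
        df = _complete(data)
        y = df["outcome"].to_numpy()
        return float(np.sum(_bern_loglik(beta0, 1.0, y)))
    df = _complete(data)
    struct = _Structure(df, spec.random_levels)
    engine = _Engine(struct, spec)
    if isinstance(sigma2, Mapping):
        s2 = [sigma2[lv] for lv in spec.random_levels]
    else:
        s2 = list(sigma2)
    log_sd = [0.5 * np.log(max(float(v), 1e-12)) for v in s2]
    return engine.loglik(np.array([beta0] + log_sd))


def loglik_oracle(
    data: SurveyDataset,
    beta0: float,
    sigma2: Mapping[str, float],
    n_points: int = 40,
    max_clusters: int = 50,
) -> float:
    """Marginal log-likelihood by direct dense Gauss-Hermite quadrature.

    A deliberately naive reference: per-cluster recursion in tree order with
    plain (non-adaptive) high-order quadrature at every level.  Only intended
    as a test oracle on small datasets; refuses more than ``max_clusters``
    clusters in total.
    """
    df = _complete(data)
    levels = [lv for lv in LEVEL_ORDER if lv in sigma2]
    y_all = df["outcome"].to_numpy()
    if not levels:
        return float(np.sum(_bern_loglik(beta0, 1.0, y_all)))
    total_clusters = sum(df[LEVEL_COLUMNS[lv]].nunique() for lv in levels)
    if total_clusters > max_clusters:
        raise ValueError(
            f"{total_clusters} clusters exceed the oracle limit of {max_clusters}; "
            "the oracle is for small test fixtures only"
        )
    z, wn = hermite_nodes(n_points)
    logw = np.log(wn)
    sds = [np.sqrt(float(sigma2[lv])) for lv in levels]

    def cluster_loglik(level_idx: int, sub: pd.DataFrame, offset: float) -> float:
        sd = sds[level_idx]
        last = level_idx == len(levels) - 1
        if last:
            yv = sub["outcome"].to_numpy()
            eta = beta0 + offset + sd * z  # (Q,)
            vals = logw + np.sum(_bern_loglik(eta[None, :], 1.0, yv[:, None]), axis=0)
            return float(logsumexp(vals))
        children = list(sub.groupby(LEVEL_COLUMNS[levels[level_idx + 1]], sort=False))
        vals = np.empty(n_points)
        for qi in range(n_points):
            off = offset + sd * z[qi]
            inner = 0.0
            for _, child in children:
                inner += cluster_loglik(level_idx + 1, child, off)
            vals[qi] = logw[qi] + inner
        return float(logsumexp(vals))

    total = 0.0
    for _, top in df.groupby(LEVEL_COLUMNS[levels[0]], sort=False):
        total += cluster_loglik(0, top, 0.0)
    return total


def lrt(fit_null: FitResult, fit_alt: FitResult) -> LRTResult:
    """Likelihood-ratio test of nested model structures on the same records.

    The statistic is clipped at zero (warning issued) when numerics leave the
    alternative below the null.  For tests involving variance components the
    null lies on the parameter boundary; the naive chi-square p-value is
    reported with ``boundary=True`` as a caveat rather than corrected.
    """
    if fit_null.n_obs != fit_alt.n_obs:
        raise ValueError(
            f"fits use different records (n={fit_null.n_obs} vs {fit_alt.n_obs}); not comparable"
        )
    df_diff = fit_alt.n_params - fit_null.n_params
    if df_diff < 0:
        raise ValueError("null model has more parameters than the alternative")
    stat = 2.0 * (fit_alt.loglik - fit_null.loglik)
    if stat < 0:
        warnings.warn(
            f"alternative log-likelihood below null by {-stat / 2:.3g}; statistic clipped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        stat = 0.0
    if df_diff == 0:
        p = 1.0
    else:
        p = float(chi2.sf(stat, df_diff))
    boundary = len(fit_alt.varcomps.sigma2) > len(fit_null.varcomps.sigma2)
    return LRTResult(statistic=float(stat), df=df_diff, p_value=p, boundary=boundary)
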