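"""Sequential k-nearest-neighbour imputation of missing binary outcomes.

Neighbours are defined by a Gower-style weighted distance over the observed
covariates (household size, interviewer sex) plus cluster co-membership
indicators (same household / interviewer / village / site).  With the default
weights the co-membership terms dominate, household first - in an empty
(intercept-only) survey model the cluster structure is the only information
available, and household proximity must dominate for the imputation to
preserve the household-level clustering.

Records are processed in a deterministic order - those with the most observed
household members first, so the best-informed records are imputed first and,
when ``sequential`` is on, join the donor pool for later records.

Two vote rules are provided.  ``"prob"`` (default) imputes 1 with probability
equal to the share of 1s among the k donors (a seeded, probability-matching
draw); it preserves event rates even when the outcome is rare.  ``"majority"``
imputes the donors' modal value; for an outcome with a marginal rate of a few
per 1,000 the mode is almost surely 0, which systematically deflates the
imputed-data rate - hence it is not the default.  Both rules agree whenever
the donors are unanimous and for k = 1.

The default neighbourhood is k = 15.  A very small k makes the donor share a
one-or-two-donor estimate of the local event rate; stochastic imputation from
such noisy cell rates inflates the between-household variance (the classic
small-cell hot-deck effect) and with it the fitted household ICC.  k = 15
keeps the household donors in front (they always sort first) while the
remaining neighbourhood donors stabilise the vote, which preserves both the
event rate and the clustering structure of the completed data.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .dataset import SurveyDataset
from .glmm import ModelSpec, fit_glmm
from .icc import icc_from_fit

#: distance weights; co-membership indicators add their weight on mismatch
DEFAULT_WEIGHTS = {
    "household": 3.0,
    "interviewer": 1.0,
    "village": 1.0,
    "site": 0.5,
    "household_size": 0.5,
    "interviewer_sex": 0.5,
}


class ImputationError(ValueError):
    pass


@dataclass(frozen=True)
class SknnConfig:
    k: int = 15
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    sequential: bool = True
    vote: str = "prob"  # "prob" | "majority"
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.vote not in ("prob", "majority"):
            raise ValueError("vote must be 'prob' or 'majority'")
        unknown = set(self.weights) - set(DEFAULT_WEIGHTS)
        if unknown:
            raise ValueError(f"unknown distance weights {sorted(unknown)}")
        w = dict(DEFAULT_WEIGHTS)
        w.update(self.weights)
        object.__setattr__(self, "weights", w)


def _index_lists(codes: np.ndarray) -> list[np.ndarray]:
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    bounds = np.flatnonzero(np.diff(sorted_codes)) + 1
    return [np.asarray(a) for a in np.split(order, bounds)]


def impute_sknn(
    data: SurveyDataset, config: SknnConfig = SknnConfig(), return_log: bool = False
):
    """Fill every missing outcome from its k nearest donors.

    Observed outcomes are never altered; the output has zero missing
    outcomes.  Deterministic given data, config and seed.  Raises
    :class:`ImputationError` naming the record when fewer than k donors
    exist.
    """
    df = data.df
    y = df["outcome"].to_numpy().copy()
    missing = np.flatnonzero(np.isnan(y))
    if len(missing) == 0:
        out = data.copy()
        return (out, pd.DataFrame(columns=["individual_id", "donors", "share", "imputed"])) if return_log else out
    n = len(df)
    n_complete = n - len(missing)
    if n_complete < config.k:
        raise ImputationError(f"only {n_complete} complete records but k={config.k}")

    w = config.weights
    hh, _ = pd.factorize(df["household_id"], sort=False)
    iv, _ = pd.factorize(df["interviewer_id"], sort=False)
    vl, _ = pd.factorize(df["village_id"], sort=False)
    st, _ = pd.factorize(df["site_id"], sort=False)
    sex = (df["interviewer_sex"].to_numpy() == "F").astype(float)
    size = data.household_sizes().to_numpy(dtype=float)
    size_range = max(float(size.max() - size.min()), 1.0)

    hh_idx = _index_lists(hh)

    donor = ~np.isnan(y)
    # process best-informed households first; ties broken by record position
    obs_in_hh = np.array([donor[hh_idx[h]].sum() for h in hh[missing]])
    order = np.lexsort((missing, -obs_in_hh))
    missing = missing[order]

    # any record outside a (same-interviewer | same-village) candidate pool
    # differs in household, interviewer and village at once, so its distance
    # is at least this bound
    outside_bound = w["household"] + w["interviewer"] + w["village"]

    rng = substream(config.seed, "impute")
    ids = df["individual_id"].to_numpy()
    log_rows = []

    def distances(i: int, cand: np.ndarray) -> np.ndarray:
        d = (
            w["household"] * (hh[cand] != hh[i])
            + w["interviewer"] * (iv[cand] != iv[i])
            + w["village"] * (vl[cand] != vl[i])
            + w["site"] * (st[cand] != st[i])
            + w["household_size"] * np.abs(size[cand] - size[i]) / size_range
            + w["interviewer_sex"] * (sex[cand] != sex[i])
        )
        # encode the record-position tie-break into the value; positions add at
        # most ~1e-4, far below the smallest genuine distance difference
        return d + cand * 1e-9

    # Precompute, per missing record, its nearest candidates among records of
    # the same interviewer or village (every record closer than outside_bound
    # lives there).  Distances ignore missingness, so the cache stays valid as
    # imputed records join the donor pool; the walk below filters by the
    # current donor mask.
    buffer_n = max(64, 8 * config.k)
    nearest: dict[int, np.ndarray] = {}
    miss_df = pd.DataFrame({"i": missing, "iv": iv[missing], "vl": vl[missing]})
    for (_, _), grp in miss_df.groupby(["iv", "vl"], sort=False):
        rows = grp["i"].to_numpy()
        pool = np.flatnonzero((iv == iv[rows[0]]) | (vl == vl[rows[0]]))
        dmat = (
            w["household"] * (hh[pool][None, :] != hh[rows][:, None])
            + w["interviewer"] * (iv[pool][None, :] != iv[rows][:, None])
            + w["village"] * (vl[pool][None, :] != vl[rows][:, None])
            + w["site"] * (st[pool][None, :] != st[rows][:, None])
            + w["household_size"] * np.abs(size[pool][None, :] - size[rows][:, None]) / size_range
            + w["interviewer_sex"] * (sex[pool][None, :] != sex[rows][:, None])
            + pool[None, :] * 1e-9
        )
        take = min(buffer_n, dmat.shape[1])
        if take < dmat.shape[1]:
            part = np.argpartition(dmat, take - 1, axis=1)[:, :take]
        else:
            part = np.broadcast_to(np.arange(dmat.shape[1]), dmat.shape).copy()
        for r, i in enumerate(rows):
            cols = part[r]
            ordered = cols[np.argsort(dmat[r, cols], kind="stable")]
            nearest[int(i)] = pool[ordered]

    def pick(i: int, cand: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = distances(i, cand)
        sel = np.argsort(d, kind="stable")[: config.k]
        return cand[sel], d[sel]

    for i in missing:
        cached = nearest[int(i)]
        cand = cached[donor[cached] & (cached != i)][: config.k]
        if len(cand) < config.k:
            # cache exhausted by non-donors: rescan the whole pool
            pool = np.flatnonzero((iv == iv[i]) | (vl == vl[i]))
            pool = pool[donor[pool] & (pool != i)]
            cand = pick(i, pool)[0] if len(pool) >= config.k else pool
        use_full = len(cand) < config.k
        if not use_full:
            chosen, dist = cand, distances(i, cand)
            # exact as long as the kth neighbour is inside the pool's bound
            use_full = dist[-1] >= outside_bound - 1e-6
        if use_full:
            full = np.flatnonzero(donor)
            full = full[full != i]
            if len(full) < config.k:
                raise ImputationError(
                    f"record {ids[i]!r}: only {len(full)} donors available, need k={config.k}"
                )
            chosen, dist = pick(i, full)
        votes = y[chosen]
        share = float(votes.mean())
        if config.vote == "prob":
            val = 1.0 if rng.random() < share else 0.0
        else:  # majority
            if share > 0.5:
                val = 1.0
            elif share < 0.5:
                val = 0.0
            else:
                nearest = votes[dist == dist[0]]
                if nearest.min() == nearest.max():
                    val = float(nearest[0])
                else:
                    val = float(rng.integers(0, 2))
        y[i] = val
        if config.sequential:
            donor[i] = True
        if return_log:
            log_rows.append(
                {
                    "individual_id": ids[i],
                    "donors": ";".join(str(ids[j]) for j in chosen),
                    "share": share,
                    "imputed": val,
                }
            )

    out_df = df.copy()
    out_df["outcome"] = y
    out = SurveyDataset(out_df, validate=False)
    if return_log:
        return out, pd.DataFrame(log_rows, columns=["individual_id", "donors", "share", "imputed"])
    return out


@dataclass(frozen=True)
class ImputationQuality:
    accuracy: float
    prevalence_error: float  # imputed-data crude rate minus truth rate, per 1,000
    n_imputed: int
    icc_shift: dict[str, float] | None = None


def imputation_quality(
    truth: SurveyDataset,
    attrited: SurveyDataset,
    imputed: SurveyDataset,
    compute_icc_shift: bool = False,
    spec: ModelSpec | None = None,
) -> ImputationQuality:
    """Compare imputed outcomes to the pre-attrition truth.

    ``attrited`` identifies which cells were imputed.  ``icc_shift`` (optional,
    fits two models) is the per-level ICC of the imputed-data fit minus that
    of the truth fit.
    """
    for other in (attrited, imputed):
        if not truth.df["individual_id"].equals(other.df["individual_id"]):
            raise ValueError("record IDs are misaligned between datasets")
    y_true = truth.outcome
    y_imp = imputed.outcome
    mask = np.isnan(attrited.outcome) & ~np.isnan(y_true)
    if np.isnan(y_imp[mask]).any():
        raise ValueError("imputed dataset still has missing outcomes in imputed cells")
    accuracy = float((y_imp[mask] == y_true[mask]).mean()) if mask.any() else 1.0
    err = imputed.df["outcome"].mean() - truth.df["outcome"].mean()
    shift = None
    if compute_icc_shift:
        spec = spec or ModelSpec(estimation="agq")
        icc_true = icc_from_fit(fit_glmm(truth, spec)).per_level
        icc_imp = icc_from_fit(fit_glmm(imputed, spec)).per_level
        shift = {lv: icc_imp[lv] - icc_true[lv] for lv in icc_true}
    return ImputationQuality(
        accuracy=accuracy,
        prevalence_error=float(1000.0 * err),
        n_imputed=int(mask.sum()),
        icc_shift=shift,
    )
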