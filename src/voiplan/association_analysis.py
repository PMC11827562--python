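"""Associations between anxiety factor scores and behaviour / model quantities.

Two routes: a mixed-effects ordered-logistic regression of raw Likert
responses on design variables and factor scores (random intercept per
subject, fitted by maximum likelihood with Gauss-Hermite quadrature), and
per-variable ordinary linear regressions of model variables/parameters on
the four factor scores, everything z-scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp, roots_hermitenorm
from statsmodels.tools import numdiff

from .synthetic_data import FACTOR_NAMES
from .voi_core import likert_log_probabilities

__all__ = [
    "OrdinalRegressionResult",
    "ParameterRegressionResult",
    "ordinal_mixed_regression",
    "parameter_regressions",
    "subject_model_summary",
    "summarize_willingness",
    "zscore",
]

#: Response variables regressed on factor scores, in reporting order.
MODEL_RESPONSES: tuple[str, ...] = (
    "VOI",
    "U_info",
    "U_plan",
    "U_outcome",
    "C_plan",
    "C_info",
    "U_leisure",
    "log_scale_ratio",
)


class RegressionError(RuntimeError):
    """Raised when a regression cannot be fitted (separation, degeneracy)."""


def zscore(x: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, SD 1 (population SD); constant input errors."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise RegressionError("cannot z-score a constant column")
    return (x - x.mean()) / sd


@dataclass(frozen=True)
class OrdinalRegressionResult:
    """ML fit of the random-intercept cumulative-logit model."""

    coefficients: pd.DataFrame  # term, estimate, se, z, p, ci_low, ci_high
    sigma_subject: float  # random-intercept SD
    n_subjects: int
    n_trials: int
    loglik: float
    converged: bool

    def coef(self, term: str) -> float:
        row = self.coefficients.loc[self.coefficients["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["estimate"].iloc[0])

    def pvalue(self, term: str) -> float:
        row = self.coefficients.loc[self.coefficients["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["p"].iloc[0])


@dataclass(frozen=True)
class ParameterRegressionResult:
    """Standardized OLS coefficients of model quantities on factor scores."""

    table: pd.DataFrame  # response, term, estimate, se, ci_low, ci_high, p, degenerate

    def coef(self, response: str, factor: str) -> float:
        row = self.table.loc[
            (self.table["response"] == response) & (self.table["term"] == factor)
        ]
        if row.empty:
            raise KeyError((response, factor))
        return float(row["estimate"].iloc[0])


def _design_matrix(
    trials: pd.DataFrame,
    scores: pd.DataFrame,
    cost_scale: str,
    include_threeway: bool,
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
    merged = trials.merge(scores, on="subject", how="left", validate="many_to_one")
    if merged[list(FACTOR_NAMES)].isna().any().any():
        missing = merged.loc[
            merged[list(FACTOR_NAMES)].isna().any(axis=1), "subject"
        ].unique()
        raise RegressionError(f"subjects without factor scores: {missing.tolist()}")
    outcome = np.where(merged["valence"].eq("gain"), 1.0, -1.0)
    prob = merged["p"].to_numpy(float)
    if cost_scale == "rank":
        cost = merged["cost_rank"].to_numpy(float)
    elif cost_scale == "dollars":
        cost = merged["cost_dollars"].to_numpy(float)
    else:
        raise ValueError("cost_scale must be 'rank' or 'dollars'")
    o, pr, co = zscore(outcome), zscore(prob), zscore(cost)
    cols = {
        "outcome": o,
        "probability": pr,
        "cost": co,
        "outcome:probability": zscore(o * pr),
        "outcome:cost": zscore(o * co),
        "probability:cost": zscore(pr * co),
    }
    if include_threeway:
        cols["outcome:probability:cost"] = zscore(o * pr * co)
    for f in FACTOR_NAMES:
        cols[f] = zscore(merged[f].to_numpy(float))
    x = np.column_stack(list(cols.values()))
    y = merged["response"].to_numpy(np.int64)
    subj = merged["subject"].to_numpy()
    return x, list(cols.keys()), y, subj


def _ordered_logistic_derivs(
    z: np.ndarray, kappa: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log pmf and its derivatives for the cumulative-logit likelihood.

    Returns (logp, d_hi, d_lo) where d_hi is d logP / d kappa_{y-1} (zero for
    y = 5) and d_lo is d logP / d kappa_{y-2} (zero for y = 1); the derivative
    wrt the latent z is -(d_hi + d_lo).  Shapes follow z (nodes x trials).
    """
    edges = np.concatenate([[-np.inf], kappa, [np.inf]])
    with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
        a = edges[y] - z
        b = edges[y - 1] - z
        lsa = -np.logaddexp(0.0, -a)
        lsb = -np.logaddexp(0.0, -b)
        lsna = -np.logaddexp(0.0, a)
        lsnb = -np.logaddexp(0.0, b)
        d = b - a
        l1me = np.where(d > -1e-10, np.log(np.maximum(-d, 1e-300)), np.log1p(-np.exp(d)))
        logp = lsa + lsnb + l1me
        d_hi = np.exp(lsna - lsnb - l1me)
        d_lo = -np.exp(lsb - lsa - l1me)
    return logp, np.nan_to_num(d_hi), np.nan_to_num(d_lo)


def _ordinal_mixed_nll_grad(
    params: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    trial_subj: np.ndarray,
    bounds: np.ndarray,
    nodes: np.ndarray,
    log_weights: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Negative marginal log likelihood and gradient (Gauss-Hermite mixture).

    Subjects must be contiguous blocks (``bounds`` as for ``reduceat``);
    ``trial_subj`` maps each trial to its 0-based subject block.
    """
    k = x.shape[1]
    beta = params[:k]
    kappa = np.empty(4)
    kappa[0] = params[k]
    kappa[1:] = params[k] + np.cumsum(np.exp(params[k + 1 : k + 4]))
    sigma = np.exp(params[k + 4])

    eta = x @ beta
    z = eta[None, :] + sigma * nodes[:, None]  # (Q, T)
    logp, d_hi, d_lo = _ordered_logistic_derivs(z, kappa, y)
    per_subject = np.add.reduceat(logp, bounds, axis=1) + log_weights[:, None]  # (Q, S)
    ll_subject = logsumexp(per_subject, axis=0)  # (S,)
    ll = float(ll_subject.sum())
    if not np.isfinite(ll):
        return 1e12, np.zeros_like(params)

    # posterior node weights per subject, expanded to trials
    r = np.exp(per_subject - ll_subject[None, :])  # (Q, S)
    rt = r[:, trial_subj]  # (Q, T)
    dv = -(d_hi + d_lo)

    w_eta = (rt * dv).sum(axis=0)  # (T,)
    gbeta = x.T @ w_eta
    w_hi = (rt * d_hi).sum(axis=0)
    w_lo = (rt * d_lo).sum(axis=0)
    gkappa = np.zeros(4)
    hi_mask = y <= 4
    lo_mask = y >= 2
    np.add.at(gkappa, y[hi_mask] - 1, w_hi[hi_mask])
    np.add.at(gkappa, y[lo_mask] - 2, w_lo[lo_mask])
    gsigma = float(nodes @ (rt * dv).sum(axis=1))

    grad = np.empty_like(params)
    grad[:k] = gbeta
    # chain rule through the ordered cut-point transform
    csum = np.cumsum(gkappa[::-1])[::-1]
    grad[k] = csum[0]
    grad[k + 1 : k + 4] = csum[1:] * np.exp(params[k + 1 : k + 4])
    grad[k + 4] = gsigma * sigma
    return -ll, -grad


def ordinal_mixed_regression(
    trials: pd.DataFrame,
    scores: pd.DataFrame,
    cost_scale: str = "rank",
    include_threeway: bool = True,
    n_quadrature: int = 31,
) -> OrdinalRegressionResult:
    """Random-intercept ordered-logistic regression of Likert responses.

    Fixed effects: outcome valence, probability, cost (rank-transformed by
    default), their pairwise (and optionally 3-way) interactions, and the four
    anxiety factor scores; every predictor z-scored.  Maximum likelihood with
    Gauss-Hermite quadrature over the subject intercept; Wald tests from the
    numerical Hessian.
    """
    observed = np.unique(trials["response"].to_numpy())
    if observed.size < 2:
        raise RegressionError(
            f"response is degenerate: single Likert category {observed.tolist()}"
        )
    x, names, y, subj = _design_matrix(trials, scores, cost_scale, include_threeway)
    order = np.argsort(subj, kind="stable")
    x, y, subj = x[order], y[order], subj[order]
    bounds = np.flatnonzero(np.r_[True, subj[1:] != subj[:-1]])
    n_subjects = bounds.size
    trial_subj = np.cumsum(np.r_[False, subj[1:] != subj[:-1]])

    raw_nodes, raw_weights = roots_hermitenorm(n_quadrature)
    log_weights = np.log(raw_weights) - 0.5 * np.log(2 * np.pi)

    k = x.shape[1]
    cum = np.clip(
        np.cumsum(np.bincount(y, minlength=6)[1:5]) / y.size, 1e-3, 1 - 1e-3
    )
    kappa0 = np.log(cum / (1 - cum))
    incr = np.clip(np.diff(kappa0), 1e-3, None)
    p0 = np.concatenate([np.zeros(k), [kappa0[0]], np.log(incr), [np.log(0.5)]])

    args = (x, y, trial_subj, bounds, raw_nodes, log_weights)

    res = optimize.minimize(
        _ordinal_mixed_nll_grad, p0, args=args, jac=True,
        method="L-BFGS-B", options={"maxiter": 500},
    )
    if not res.success and abs(res.fun) > 1e11:
        raise RegressionError(f"ordinal mixed fit failed: {res.message}")

    # Hessian as the Jacobian of the analytic gradient
    hess = numdiff.approx_fprime(
        res.x, lambda q: _ordinal_mixed_nll_grad(q, *args)[1], centered=True
    )
    hess = 0.5 * (hess + hess.T)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    se_all = np.sqrt(np.clip(np.diag(cov), 0, None))

    est = res.x[:k]
    se = se_all[:k]
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, est / se, np.nan)
    pvals = 2 * stats.norm.sf(np.abs(zstat))
    table = pd.DataFrame(
        {
            "term": names,
            "estimate": est,
            "se": se,
            "z": zstat,
            "p": pvals,
            "ci_low": est - 1.96 * se,
            "ci_high": est + 1.96 * se,
        }
    )
    return OrdinalRegressionResult(
        coefficients=table,
        sigma_subject=float(np.exp(res.x[k + 4])),
        n_subjects=int(n_subjects),
        n_trials=int(y.size),
        loglik=float(-res.fun),
        converged=bool(res.success),
    )


def subject_model_summary(post) -> pd.DataFrame:
    """Per-subject table of posterior-mean parameters and trial-averaged latents.

    ``post`` is a PosteriorSummary; trial-level VOI/U_info/U_plan are averaged
    over each subject's trials before any z-scoring, and the outcome-scaling
    composite log(s_gain / s_loss) is appended.
    """
    means = post.subject_means.copy()
    latents = (
        post.trial_latents.groupby("subject")[["VOI", "U_info", "U_plan"]]
        .mean()
        .reset_index()
    )
    out = means.merge(latents, on="subject", validate="one_to_one")
    out["log_scale_ratio"] = np.log(out["s_gain"] / out["s_loss"])
    return out


def parameter_regressions(
    subject_table: pd.DataFrame,
    scores: pd.DataFrame,
    responses: tuple[str, ...] = MODEL_RESPONSES,
) -> ParameterRegressionResult:
    """One standardized OLS per model variable/parameter on the factor scores.

    Responses with zero variance across subjects are flagged as degenerate
    (NaN estimates) rather than fitted.
    """
    import statsmodels.api as sm

    merged = subject_table.merge(scores, on="subject", validate="one_to_one")
    n = len(merged)
    if n < len(FACTOR_NAMES) + 2:
        raise RegressionError(f"too few subjects ({n}) for 4-predictor regression")
    xz = np.column_stack([zscore(merged[f].to_numpy(float)) for f in FACTOR_NAMES])
    design = sm.add_constant(xz)
    rows = []
    for resp in responses:
        yv = merged[resp].to_numpy(float)
        if yv.std(ddof=0) == 0:
            for f in FACTOR_NAMES:
                rows.append(
                    {"response": resp, "term": f, "estimate": np.nan, "se": np.nan,
                     "ci_low": np.nan, "ci_high": np.nan, "p": np.nan, "degenerate": True}
                )
            continue
        fit = sm.OLS(zscore(yv), design).fit()
        ci = fit.conf_int()
        for i, f in enumerate(FACTOR_NAMES):
            rows.append(
                {
                    "response": resp,
                    "term": f,
                    "estimate": float(fit.params[i + 1]),
                    "se": float(fit.bse[i + 1]),
                    "ci_low": float(ci[i + 1, 0]),
                    "ci_high": float(ci[i + 1, 1]),
                    "p": float(fit.pvalues[i + 1]),
                    "degenerate": False,
                }
            )
    return ParameterRegressionResult(table=pd.DataFrame(rows))


def summarize_willingness(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM of the display score per outcome x probability x cost cell.

    Cells absent from the data appear with NaN mean and n = 0.
    """
    df = trials.copy()
    if "display_score" not in df.columns:
        df["display_score"] = df["response"] - 3
    levels = [
        sorted(df["valence"].unique()),
        sorted(df["p"].unique()),
        sorted(df["cost_rank"].unique()),
    ]
    full_index = pd.MultiIndex.from_product(levels, names=["valence", "p", "cost_rank"])
    grouped = df.groupby(["valence", "p", "cost_rank"])["display_score"]
    out = pd.DataFrame(
        {
            "mean": grouped.mean(),
            "sem": grouped.sem(),
            "n": grouped.size(),
        }
    ).reindex(full_index)
    out["n"] = out["n"].fillna(0).astype(int)
    return out.reset_index()
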