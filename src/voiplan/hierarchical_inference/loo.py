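"""PSIS-LOO model comparison on pointwise log likelihoods."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LooResult", "psis_loo", "compare_models"]

PARETO_K_THRESHOLD = 0.7


@dataclass(frozen=True)
class LooResult:
    """Expected log predictive density estimated by PSIS-LOO."""

    name: str
    elpd: float
    se: float
    pointwise: np.ndarray  # (n_trials,) pointwise elpd contributions
    pareto_k: np.ndarray  # (n_trials,)
    n_samples: int

    @property
    def n_points(self) -> int:
        return self.pointwise.size

    @property
    def n_high_k(self) -> int:
        return int((self.pareto_k > PARETO_K_THRESHOLD).sum())

    def __post_init__(self) -> None:
        total = float(self.pointwise.sum())
        if not np.isclose(total, self.elpd, rtol=1e-6, atol=1e-6):
            raise ValueError("pointwise contributions must sum to the total ELPD")


def psis_loo(loglik: np.ndarray, name: str = "model") -> LooResult:
    """PSIS-LOO from a (chains, draws, trials) log-likelihood array."""
    import arviz as az

    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim != 3:
        raise ValueError("loglik must be (chains, draws, trials)")
    # az.loo requires a posterior group; a token variable suffices
    idata = az.from_dict(
        posterior={"lp": loglik.sum(axis=2)}, log_likelihood={"y": loglik}
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True)
    result = LooResult(
        name=name,
        elpd=float(res.elpd_loo),
        se=float(res.se),
        pointwise=np.asarray(res.loo_i.values, dtype=float),
        pareto_k=np.asarray(res.pareto_k.values, dtype=float),
        n_samples=loglik.shape[0] * loglik.shape[1],
    )
    if result.n_high_k > 0:
        warnings.warn(
            f"{name}: {result.n_high_k}/{result.n_points} observations have "
            f"Pareto k > {PARETO_K_THRESHOLD}; LOO may be unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    return result


def compare_models(loo_results: list[LooResult]) -> pd.DataFrame:
    """Rank models by ELPD with pairwise differences to the best model.

    ``elpd_diff`` is best-model ELPD minus this model's ELPD (0 for the best);
    ``se_diff`` is the paired standard error of the pointwise differences.
    """
    if not loo_results:
        raise ValueError("need at least one LooResult")
    n_points = {r.n_points for r in loo_results}
    if len(n_points) > 1:
        raise ValueError(f"models evaluated on different trial sets: sizes {sorted(n_points)}")
    ranked = sorted(loo_results, key=lambda r: r.elpd, reverse=True)
    best = ranked[0]
    rows = []
    for rank, r in enumerate(ranked):
        diff_pointwise = best.pointwise - r.pointwise
        n = diff_pointwise.size
        se_diff = float(np.sqrt(n * diff_pointwise.var(ddof=1))) if rank else 0.0
        rows.append(
            {
                "model": r.name,
                "rank": rank,
                "elpd_loo": r.elpd,
                "se": r.se,
                "elpd_diff": float(diff_pointwise.sum()),
                "se_diff": se_diff,
                "n_high_pareto_k": r.n_high_k,
                "warning": r.n_high_k > 0,
            }
        )
    return pd.DataFrame(rows)
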