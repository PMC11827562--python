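"""Fit the hierarchical planning model to a trial table.

Three variants are supported: the full model (six parameters per subject),
``no_scaling`` (s_gain = s_loss = 1), and ``shared_Cinfo`` (one information
cost across all subjects).  Sampling is NUTS over the unconstrained
parameterization defined in ``_logp``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..voi_core import PARAM_NAMES, likert_log_probabilities
from ._logp import logp_grad as _logp_grad
from .nuts import NutsConfig, sample_nuts, split_rhat

__all__ = [
    "ModelSpec",
    "SamplerConfig",
    "PosteriorSummary",
    "FitError",
    "VARIANTS",
    "fit_model",
    "pointwise_loglik",
]


class FitError(RuntimeError):
    """Raised when the posterior cannot be sampled from the supplied data."""


#: Subject-level parameter columns and hyper-meaned subset per model variant.
VARIANTS: dict[str, dict] = {
    "full": {
        "subject_params": ("U_outcome", "C_plan", "C_info", "U_leisure", "s_gain", "s_loss"),
        "hyper_params": ("U_outcome", "C_plan", "C_info", "U_leisure"),
        "global_cinfo": False,
    },
    "no_scaling": {
        "subject_params": ("U_outcome", "C_plan", "C_info", "U_leisure"),
        "hyper_params": ("U_outcome", "C_plan", "C_info", "U_leisure"),
        "global_cinfo": False,
    },
    "shared_Cinfo": {
        "subject_params": ("U_outcome", "C_plan", "U_leisure", "s_gain", "s_loss"),
        "hyper_params": ("U_outcome", "C_plan", "U_leisure"),
        "global_cinfo": True,
    },
}


@dataclass(frozen=True)
class ModelSpec:
    """Which model variant to fit; priors are fixed as in ``_logp``."""

    variant: str = "full"
    n_cutpoints: int = 4

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; use one of {sorted(VARIANTS)}")
        if self.n_cutpoints != 4:
            raise ValueError("the response scale is fixed at 5 categories / 4 cut points")

    @property
    def layout(self) -> dict:
        return VARIANTS[self.variant]


@dataclass(frozen=True)
class SamplerConfig:
    """Defaults follow the study: 500 warmup, 1000 iterations, 4 chains."""

    warmup: int = 500
    iterations: int = 1000
    chains: int = 4
    seed: int = 0
    max_treedepth: int = 10
    target_accept: float = 0.8

    @property
    def retained_draws(self) -> int:
        return (self.iterations - self.warmup) * self.chains

    def to_nuts(self) -> NutsConfig:
        return NutsConfig(
            warmup=self.warmup,
            iterations=self.iterations,
            chains=self.chains,
            seed=self.seed,
            max_treedepth=self.max_treedepth,
            target_accept=self.target_accept,
        )


@dataclass
class PosteriorSummary:
    """Posterior draws, per-subject means, latent trial variables, diagnostics."""

    variant: str
    subjects: np.ndarray  # original subject labels, in index order
    theta: np.ndarray  # (chains, kept, n_sub, 6) constrained draws, all six params
    mu: np.ndarray  # (chains, kept, n_hyper)
    hyper_names: tuple[str, ...]
    kappa: np.ndarray  # (chains, kept, 4)
    shared_cinfo: np.ndarray | None  # (chains, kept) when variant == shared_Cinfo
    subject_means: pd.DataFrame
    trial_latents: pd.DataFrame
    diagnostics: dict
    data: dict  # trial arrays used for the fit (subject_idx, p, cost_rank, is_gain, y)

    @property
    def n_draws(self) -> int:
        return self.theta.shape[0] * self.theta.shape[1]

    @property
    def theta_flat(self) -> np.ndarray:
        return self.theta.reshape(-1, *self.theta.shape[2:])

    @property
    def kappa_flat(self) -> np.ndarray:
        return self.kappa.reshape(-1, self.kappa.shape[-1])

    def kappa_mean(self) -> np.ndarray:
        return self.kappa_flat.mean(axis=0)


def _trials_to_arrays(trials: pd.DataFrame) -> tuple[dict, np.ndarray]:
    required = {"subject", "p", "cost_rank", "response"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if "valence" in trials.columns:
        is_gain = trials["valence"].eq("gain").to_numpy(np.int64)
    elif "is_gain" in trials.columns:
        is_gain = trials["is_gain"].to_numpy(np.int64)
    else:
        raise ValueError("trial table needs a 'valence' or 'is_gain' column")
    y = trials["response"].to_numpy(np.int64)
    if y.min() < 1 or y.max() > 5:
        raise ValueError("responses must be ordered categories in 1..5")
    labels, subject_idx = np.unique(trials["subject"].to_numpy(), return_inverse=True)
    data = {
        "subject_idx": subject_idx.astype(np.int64),
        "p": trials["p"].to_numpy(float),
        "cost_rank": trials["cost_rank"].to_numpy(float),
        "is_gain": is_gain,
        "y": y,
    }
    return data, labels


def _make_logp(data: dict, spec: ModelSpec, n_sub: int):
    layout = spec.layout
    sp = layout["subject_params"]
    hyper = layout["hyper_params"]
    idx = {name: (sp.index(name) if name in sp else -1) for name in PARAM_NAMES}
    hyper_idx = np.array(
        [hyper.index(name) if name in hyper else -1 for name in sp], dtype=np.int64
    )
    args = (
        data["subject_idx"],
        data["p"],
        data["cost_rank"],
        data["is_gain"].astype(np.int64),
        data["y"],
        n_sub,
        len(sp),
        len(hyper),
        layout["global_cinfo"],
        idx["U_outcome"],
        idx["C_plan"],
        idx["C_info"],
        idx["U_leisure"],
        idx["s_gain"],
        idx["s_loss"],
        hyper_idx,
    )

    def fn(q: np.ndarray) -> tuple[float, np.ndarray]:
        return _logp_grad(q, *args)

    dim = len(hyper) + int(layout["global_cinfo"]) + 4 + n_sub * len(sp)
    return fn, dim


def _unpack_draws(flat: np.ndarray, spec: ModelSpec, n_sub: int):
    """Constrained (mu, shared_cinfo, kappa, theta-as-6-cols) from raw draws."""
    layout = spec.layout
    sp = layout["subject_params"]
    n_hyper = len(layout["hyper_params"])
    off = 0
    mu = flat[:, :n_hyper]
    off += n_hyper
    shared = None
    if layout["global_cinfo"]:
        shared = np.exp(flat[:, off])
        off += 1
    cut_raw = flat[:, off : off + 4]
    kappa = np.empty_like(cut_raw)
    kappa[:, 0] = cut_raw[:, 0]
    for k in range(1, 4):
        kappa[:, k] = kappa[:, k - 1] + np.exp(cut_raw[:, k])
    off += 4
    theta_sp = np.exp(flat[:, off:]).reshape(flat.shape[0], n_sub, len(sp))
    # expand to the canonical six columns
    s = flat.shape[0]
    theta = np.ones((s, n_sub, 6))
    for k, name in enumerate(PARAM_NAMES):
        if name in sp:
            theta[:, :, k] = theta_sp[:, :, sp.index(name)]
        elif name == "C_info" and shared is not None:
            theta[:, :, k] = shared[:, None]
        # absent scale params stay at 1.0
    return mu, shared, kappa, theta


def compute_latents(theta_flat: np.ndarray, data: dict) -> dict[str, np.ndarray]:
    """Per-draw trial-level U_info, U_plan, VOI from constrained theta draws."""
    subj = data["subject_idx"]
    p = data["p"]
    cost = data["cost_rank"]
    gain = data["is_gain"].astype(bool)
    uo = theta_flat[:, subj, 0]
    cp = theta_flat[:, subj, 1]
    ci = theta_flat[:, subj, 2]
    ul = theta_flat[:, subj, 3]
    s = np.where(gain, theta_flat[:, subj, 4], theta_flat[:, subj, 5])
    u_plan = p * s * uo - cp
    u_info = p * (s * uo - cp) - ci * cost
    voi = u_info - np.maximum(u_plan, ul)
    return {"U_info": u_info, "U_plan": u_plan, "VOI": voi}


def fit_model(
    trials: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    cfg: SamplerConfig = SamplerConfig(),
) -> PosteriorSummary:
    """Sample the hierarchical posterior with NUTS and summarize it.

    Warns when any hyper-mean or cut point has split-Rhat > 1.01.
    """
    data, labels = _trials_to_arrays(trials)
    n_sub = len(labels)
    fn, dim = _make_logp(data, spec, n_sub)
    try:
        result = sample_nuts(fn, dim, cfg.to_nuts())
    except FloatingPointError as err:  # pragma: no cover - degenerate data
        raise FitError(str(err)) from err

    chains, kept, _ = result.draws.shape
    flat = result.draws.reshape(chains * kept, dim)
    mu, shared, kappa, theta = _unpack_draws(flat, spec, n_sub)

    # reshape back to (chains, kept, ...)
    mu_c = mu.reshape(chains, kept, -1)
    kappa_c = kappa.reshape(chains, kept, 4)
    theta_c = theta.reshape(chains, kept, n_sub, 6)
    shared_c = shared.reshape(chains, kept) if shared is not None else None

    rhat = {}
    for h, name in enumerate(spec.layout["hyper_params"]):
        rhat[f"mu_{name}"] = split_rhat(mu_c[:, :, h])
    for k in range(4):
        rhat[f"kappa_{k + 1}"] = split_rhat(kappa_c[:, :, k])
    if shared_c is not None:
        rhat["C_info_shared"] = split_rhat(shared_c)
    bad = {k: v for k, v in rhat.items() if v > 1.01}
    if bad:
        warnings.warn(f"split-Rhat > 1.01 for {bad}", RuntimeWarning, stacklevel=2)

    means = theta.mean(axis=0)  # (n_sub, 6)
    subject_means = pd.DataFrame(means, columns=list(PARAM_NAMES))
    subject_means.insert(0, "subject", labels)

    latents = compute_latents(theta, data)
    trial_latents = pd.DataFrame(
        {
            "subject": labels[data["subject_idx"]],
            "p": data["p"],
            "cost_rank": data["cost_rank"],
            "is_gain": data["is_gain"],
            "response": data["y"],
            "U_info": latents["U_info"].mean(axis=0),
            "U_plan": latents["U_plan"].mean(axis=0),
            "VOI": latents["VOI"].mean(axis=0),
        }
    )

    diagnostics = {
        "rhat": rhat,
        "n_divergent": int(result.divergences.sum()),
        "n_divergent_warmup": int(result.n_divergent_warmup),
        "mean_accept": float(result.accept_stat.mean()),
        "mean_treedepth": float(result.treedepth.mean()),
        "step_size": result.step_size.tolist(),
        "retained_draws": chains * kept,
    }

    return PosteriorSummary(
        variant=spec.variant,
        subjects=labels,
        theta=theta_c,
        mu=mu_c,
        hyper_names=tuple(spec.layout["hyper_params"]),
        kappa=kappa_c,
        shared_cinfo=shared_c,
        subject_means=subject_means,
        trial_latents=trial_latents,
        diagnostics=diagnostics,
        data=data,
    )


def pointwise_loglik(post: PosteriorSummary, trials: pd.DataFrame | None = None) -> np.ndarray:
    """Per-draw, per-trial log likelihood, shaped (chains, kept, n_trials).

    With ``trials`` given, validates that it matches the fitted data (shape
    and responses); by default the stored fit data are used.
    """
    data = post.data
    if trials is not None:
        check, _ = _trials_to_arrays(trials)
        if check["y"].shape != data["y"].shape or not np.array_equal(check["y"], data["y"]):
            raise ValueError("supplied trials do not match the fitted data")
    theta_flat = post.theta_flat
    latents = compute_latents(theta_flat, data)
    ll = likert_log_probabilities(latents["VOI"], post.kappa_flat, data["y"])
    chains, kept = post.theta.shape[:2]
    return ll.reshape(chains, kept, -1)
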