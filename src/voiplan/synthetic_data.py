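"""Fully synthetic study generator.

Produces agents with truncated-normal parameters, factorial design grids,
ordered-logistic Likert responses, anxiety factor scores with planted linear
associations to the true agent parameters, and discretized questionnaire item
tables that round-trip through the scoring module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .voi_core import (
    DEFAULT_COST_SET,
    AgentParams,
    CutPoints,
    Scenario,
    likert_probabilities,
    scenarios_to_arrays,
    value_of_information,
)

__all__ = [
    "PopulationConfig",
    "PlantedAssociation",
    "DEFAULT_PROBABILITIES",
    "DEFAULT_KAPPA",
    "FACTOR_NAMES",
    "sample_agents",
    "build_design_grid",
    "simulate_trials",
    "simulate_factor_scores",
    "simulate_questionnaires",
    "agents_to_frame",
    "trial_voi_components",
]

DEFAULT_PROBABILITIES: tuple[float, ...] = (0.01, 0.10, 0.50, 0.90, 0.99)
DEFAULT_VALENCES: tuple[str, ...] = ("gain", "loss")

#: Default cut points used when simulating studies; aligned with the VOI
#: quartiles of the default population so that agents spread responses across
#: all five categories.
DEFAULT_KAPPA = CutPoints((-2.6, -1.6, -0.7, 0.0))

FACTOR_NAMES: tuple[str, ...] = (
    "somatic_anxiety",
    "cognitive_anxiety",
    "negative_affect",
    "low_self_esteem",
)

# Columns of the planted-association coefficient matrix: the six agent
# parameters (z-scored across subjects) plus the log scale ratio.
PLANTED_PREDICTORS: tuple[str, ...] = (
    "U_outcome",
    "C_plan",
    "C_info",
    "U_leisure",
    "s_gain",
    "s_loss",
    "log_scale_ratio",
)


@dataclass(frozen=True)
class PopulationConfig:
    """Population hyper-parameters for sampling synthetic agents.

    Subject parameters are drawn from Normal(mu, sd_subject) truncated to
    (0, inf); the two outcome-scaling parameters are drawn from
    Normal(scale_prior_mean, scale_prior_sd) truncated likewise.
    """

    mu_U_outcome: float = 1.5
    mu_C_plan: float = 0.8
    mu_C_info: float = 0.5
    mu_U_leisure: float = 0.4
    sd_subject: float = 1.0
    scale_prior_mean: float = 1.0
    scale_prior_sd: float = 1.0
    n_subjects: int = 40

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.sd_subject < 0 or self.scale_prior_sd < 0:
            raise ValueError("standard deviations must be >= 0")


def _truncnorm_ppf(u: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Inverse CDF of Normal(mean, sd) truncated to (0, inf).

    Exact inverse-CDF sampling keeps draws stable under a fixed seed, unlike
    rejection sampling.  A zero sd degenerates to the (positive) mean.
    """
    if sd == 0:
        if mean <= 0:
            raise ValueError("degenerate truncated normal requires a positive mean")
        return np.full_like(np.asarray(u, dtype=float), mean)
    a = (0.0 - mean) / sd
    return stats.truncnorm.ppf(u, a=a, b=np.inf, loc=mean, scale=sd)


def sample_agents(
    cfg: PopulationConfig, seed: int | np.random.Generator = 0
) -> list[AgentParams]:
    """Draw ``cfg.n_subjects`` agents from the truncated-normal population."""
    rng = np.random.default_rng(seed)
    n = cfg.n_subjects
    u = rng.uniform(size=(n, 6))
    cols = {
        "U_outcome": _truncnorm_ppf(u[:, 0], cfg.mu_U_outcome, cfg.sd_subject),
        "C_plan": _truncnorm_ppf(u[:, 1], cfg.mu_C_plan, cfg.sd_subject),
        "C_info": _truncnorm_ppf(u[:, 2], cfg.mu_C_info, cfg.sd_subject),
        "U_leisure": _truncnorm_ppf(u[:, 3], cfg.mu_U_leisure, cfg.sd_subject),
        "s_gain": _truncnorm_ppf(u[:, 4], cfg.scale_prior_mean, cfg.scale_prior_sd),
        "s_loss": _truncnorm_ppf(u[:, 5], cfg.scale_prior_mean, cfg.scale_prior_sd),
    }
    return [
        AgentParams(**{k: float(v[i]) for k, v in cols.items()}) for i in range(n)
    ]


def build_design_grid(
    probabilities: tuple[float, ...] = DEFAULT_PROBABILITIES,
    costs: tuple[float, ...] = DEFAULT_COST_SET,
    valences: tuple[str, ...] = DEFAULT_VALENCES,
    magnitude: float = 1000.0,
) -> list[Scenario]:
    """Full factorial crossing of valence x probability x cost.

    Defaults reproduce the 2 x 5 x 3 = 30-scenario study design.
    """
    for name, levels in (
        ("probabilities", probabilities),
        ("costs", costs),
        ("valences", valences),
    ):
        if len(levels) == 0:
            raise ValueError(f"{name} must be nonempty")
        if len(set(levels)) != len(levels):
            raise ValueError(f"duplicate levels in {name}: {levels}")
    cost_set = tuple(sorted(costs))
    return [
        Scenario(valence=v, p=p, cost_dollars=c, magnitude=magnitude, cost_set=cost_set)
        for v in valences
        for p in probabilities
        for c in costs
    ]


def simulate_trials(
    agents: list[AgentParams],
    grid: list[Scenario],
    kappa: CutPoints = DEFAULT_KAPPA,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate one Likert response per subject x scenario.

    Returns a long-format trial table with design columns, the latent VOI,
    the sampled ``response`` category (1..5) and its display score (-2..+2).
    """
    rng = np.random.default_rng(seed)
    arrs = scenarios_to_arrays(grid)
    rows = []
    for j, agent in enumerate(agents):
        voi = np.array([value_of_information(agent, sc) for sc in grid])
        probs = likert_probabilities(voi, kappa)  # (n_scenarios, 5)
        cum = np.cumsum(probs, axis=1)
        u = rng.uniform(size=len(grid))
        cats = 1 + (u[:, None] > cum[:, :-1]).sum(axis=1)
        rows.append(
            pd.DataFrame(
                {
                    "subject": j,
                    "valence": np.where(arrs["is_gain"] == 1, "gain", "loss"),
                    "p": arrs["p"],
                    "cost_dollars": arrs["cost_dollars"],
                    "cost_rank": arrs["cost_rank"],
                    "voi_true": voi,
                    "response": cats,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    out["display_score"] = out["response"] - 3
    return out


@dataclass(frozen=True)
class PlantedAssociation:
    """Linear map from z-scored true agent parameters to factor-score means.

    ``coefficients`` is (4 factors x 7 predictors) over PLANTED_PREDICTORS;
    factor score = coefficients @ z + Normal(0, residual_sd) per factor.
    The default plants the qualitative sign pattern used throughout the
    end-to-end tests: somatic anxiety loads (-U_outcome, -C_plan, -C_info,
    +U_leisure) and negative affect loads (-C_plan, +C_info), all at 0.4.
    """

    coefficients: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                # U_out  C_plan C_info U_leis s_gain s_loss log_ratio
                [-0.4, -0.4, -0.4, 0.4, 0.0, 0.0, 0.0],  # somatic
                [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],  # cognitive
                [0.0, -0.4, 0.4, 0.0, 0.0, 0.0, 0.0],  # negative affect
                [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],  # low self-esteem
            ]
        )
    )
    residual_sd: float = 1.0

    def __post_init__(self) -> None:
        coefs = np.asarray(self.coefficients, dtype=float)
        if coefs.shape != (4, len(PLANTED_PREDICTORS)):
            raise ValueError(f"coefficients must be 4x{len(PLANTED_PREDICTORS)}")
        if not np.all(np.isfinite(coefs)):
            raise ValueError("coefficients must be finite")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        object.__setattr__(self, "coefficients", coefs)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def agents_to_frame(agents: list[AgentParams]) -> pd.DataFrame:
    """True-parameter table, one row per subject, plus the log scale ratio."""
    df = pd.DataFrame([a.as_array() for a in agents], columns=list(PLANTED_PREDICTORS[:6]))
    df.insert(0, "subject", np.arange(len(agents)))
    df["log_scale_ratio"] = np.log(df["s_gain"] / df["s_loss"])
    return df


def simulate_factor_scores(
    agents: list[AgentParams],
    planted: PlantedAssociation | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Factor scores as a planted linear function of z-scored true parameters."""
    planted = planted or PlantedAssociation()
    rng = np.random.default_rng(seed)
    truth = agents_to_frame(agents)
    z = np.column_stack([_zscore(truth[c].to_numpy()) for c in PLANTED_PREDICTORS])
    mean = z @ planted.coefficients.T
    scores = mean + rng.normal(scale=planted.residual_sd, size=mean.shape)
    out = pd.DataFrame(scores, columns=list(FACTOR_NAMES))
    out.insert(0, "subject", truth["subject"].to_numpy())
    return out


def simulate_questionnaires(
    factor_scores: pd.DataFrame,
    loadings: np.ndarray,
    uniquenesses: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    thresholds: tuple[float, ...] | None = None,
    reverse_items: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Discretized 41-item questionnaire responses from latent factor scores.

    Continuous item = loadings @ factors + sqrt(uniqueness) * noise, cut into
    the four response levels 1..4.  Default thresholds are the standard-normal
    quartiles of the latent item scale.  Items in ``reverse_items`` (0-based
    column indices; defaults to the STAIT anxiety-absent set) are emitted in
    anxiety-absent orientation, i.e. flipped to 5 - x, so a scorer must
    reverse them back.

    Returns a wide table: subject, item_01 .. item_41 (STAIT 1-20 then
    STICSAT 1-21), raw recorded values 1..4.
    """
    from .questionnaire_scoring import STAIT_REVERSE_ITEMS  # avoid cycle at import

    loadings = np.asarray(loadings, dtype=float)
    if loadings.shape != (41, 4):
        raise ValueError(f"loadings must be 41x4, got {loadings.shape}")
    if uniquenesses is None:
        uniquenesses = np.clip(1.0 - (loadings**2).sum(axis=1), 0.05, None)
    uniquenesses = np.asarray(uniquenesses, dtype=float)
    if uniquenesses.shape != (41,) or np.any(uniquenesses <= 0):
        raise ValueError("uniquenesses must be 41 positive values")
    if reverse_items is None:
        reverse_items = tuple(i - 1 for i in STAIT_REVERSE_ITEMS)  # STAIT items are cols 0..19
    rng = np.random.default_rng(seed)
    f = factor_scores[list(FACTOR_NAMES)].to_numpy()
    latent = f @ loadings.T + rng.normal(size=(len(f), 41)) * np.sqrt(uniquenesses)
    if thresholds is None:
        thresholds = tuple(stats.norm.ppf([0.25, 0.5, 0.75]))
    cuts = np.asarray(thresholds, dtype=float)
    items = 1 + (latent[..., None] > cuts).sum(axis=-1)  # values 1..4, higher = more anxious
    items = items.astype(np.int64)
    rev = np.asarray(reverse_items, dtype=np.int64)
    items[:, rev] = 5 - items[:, rev]
    cols = {f"item_{i + 1:02d}": items[:, i] for i in range(41)}
    out = pd.DataFrame(cols)
    out.insert(0, "subject", factor_scores["subject"].to_numpy())
    return out


def default_loadings(seed: int = 1234) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic 41x4 simple-structure loading matrix and uniquenesses.

    Stands in for the external oblique-factor loading structure when the real
    configuration file is unavailable: items are partitioned across the four
    factors with primary loadings around 0.7 and small seeded cross-loadings.
    """
    rng = np.random.default_rng(seed)
    lam = rng.normal(scale=0.05, size=(41, 4))
    assignment = np.arange(41) % 4
    rng.shuffle(assignment)
    lam[np.arange(41), assignment] += 0.7
    psi = np.clip(1.0 - (lam**2).sum(axis=1), 0.1, None)
    return lam, psi


def trial_voi_components(
    agents: list[AgentParams], grid: list[Scenario]
) -> pd.DataFrame:
    """Per subject x scenario deterministic U_info, U_plan, VOI table."""
    from .voi_core import utility_info, utility_plan

    rows = []
    for j, agent in enumerate(agents):
        for sc in grid:
            rows.append(
                {
                    "subject": j,
                    "valence": sc.valence,
                    "p": sc.p,
                    "cost_rank": sc.cost_rank,
                    "U_info": utility_info(agent, sc),
                    "U_plan": utility_plan(agent, sc),
                    "voi": value_of_information(agent, sc),
                }
            )
    return pd.DataFrame(rows)
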