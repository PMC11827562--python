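"""Deterministic core of the resource-rational planning model.

An agent facing a hypothetical future outcome chooses between three options:
pay for non-instrumental information (and plan only if the outcome will
occur), plan in uncertainty, or forgo both and enjoy leisure ("live in
denial").  The value of information (VOI) is the net utility of the
information option relative to the better information-free alternative.
Likert responses are modelled as an ordered-logistic emission from VOI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "AgentParams",
    "Scenario",
    "CutPoints",
    "LikertResponse",
    "DEFAULT_COST_SET",
    "N_LIKERT",
    "rank_transform_cost",
    "utility_info",
    "utility_plan",
    "value_of_information",
    "likert_probabilities",
    "likert_log_probabilities",
]

#: Dollar cost levels of the study design, in rank order.
DEFAULT_COST_SET: tuple[float, ...] = (0.0, 5.0, 100.0)

#: Number of ordered response categories ("definitely not" .. "definitely yes").
N_LIKERT: int = 5

PARAM_NAMES: tuple[str, ...] = (
    "U_outcome",
    "C_plan",
    "C_info",
    "U_leisure",
    "s_gain",
    "s_loss",
)


class InvalidParameterError(ValueError):
    """A model parameter violates its positivity constraint."""


class InvalidCutpointsError(ValueError):
    """Cut points are not strictly increasing."""


@dataclass(frozen=True)
class AgentParams:
    """Per-subject utilities and costs; all strictly positive."""

    U_outcome: float
    C_plan: float
    C_info: float
    U_leisure: float
    s_gain: float = 1.0
    s_loss: float = 1.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(
                    f"{name} must be finite and > 0, got {value!r}"
                )

    def scale(self, valence: str) -> float:
        """Outcome scaling for the given valence ('gain' or 'loss')."""
        if valence == "gain":
            return self.s_gain
        if valence == "loss":
            return self.s_loss
        raise ValueError(f"valence must be 'gain' or 'loss', got {valence!r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES])


@dataclass(frozen=True)
class Scenario:
    """One hypothetical choice situation from the design grid.

    ``cost_rank`` is the 0-based rank of ``cost_dollars`` within the design's
    cost set; the model consumes the rank, never the raw dollars.
    """

    valence: str
    p: float
    cost_dollars: float
    magnitude: float = 1000.0
    cost_set: tuple[float, ...] = DEFAULT_COST_SET
    cost_rank: int = field(init=False)

    def __post_init__(self) -> None:
        if self.valence not in ("gain", "loss"):
            raise ValueError(f"valence must be 'gain' or 'loss', got {self.valence!r}")
        if not 0 < self.p <= 1:
            # p = 1 is allowed for evaluating the VOI curve at its endpoint;
            # the study design itself stays strictly inside (0, 1).
            raise ValueError(f"p must lie in (0, 1], got {self.p!r}")
        object.__setattr__(
            self, "cost_rank", rank_transform_cost(self.cost_dollars, self.cost_set)
        )


@dataclass(frozen=True)
class CutPoints:
    """Ordered thresholds partitioning the VOI scale into Likert categories."""

    kappa: tuple[float, ...]

    def __post_init__(self) -> None:
        kappa = tuple(float(k) for k in self.kappa)
        if len(kappa) != N_LIKERT - 1:
            raise InvalidCutpointsError(
                f"expected {N_LIKERT - 1} cut points, got {len(kappa)}"
            )
        if not all(a < b for a, b in zip(kappa, kappa[1:])):
            raise InvalidCutpointsError(f"cut points must be strictly increasing: {kappa}")
        object.__setattr__(self, "kappa", kappa)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.kappa, dtype=float)


@dataclass(frozen=True)
class LikertResponse:
    """Ordered response category 1..5 with its display score -2..+2."""

    category: int

    def __post_init__(self) -> None:
        if not 1 <= self.category <= N_LIKERT:
            raise ValueError(f"category must be in 1..{N_LIKERT}, got {self.category}")

    @property
    def display_score(self) -> int:
        return self.category - 3


def rank_transform_cost(
    cost_dollars: float, cost_set: Sequence[float] = DEFAULT_COST_SET
) -> int:
    """Map a dollar cost to its 0-based rank within the configured cost set.

    Unknown cost levels raise; no interpolation is performed.
    """
    ordered = sorted(cost_set)
    for rank, level in enumerate(ordered):
        if cost_dollars == level:
            return rank
    raise ValueError(f"cost {cost_dollars!r} not in configured cost set {ordered}")


def utility_info(agent: AgentParams, sc: Scenario) -> float:
    """Net utility of paying for information: p*(s*U_outcome - C_plan) - C_info*c."""
    s = agent.scale(sc.valence)
    return sc.p * (s * agent.U_outcome - agent.C_plan) - agent.C_info * sc.cost_rank


def utility_plan(agent: AgentParams, sc: Scenario) -> float:
    """Net utility of planning in uncertainty: p*s*U_outcome - C_plan."""
    s = agent.scale(sc.valence)
    return sc.p * s * agent.U_outcome - agent.C_plan


def value_of_information(agent: AgentParams, sc: Scenario) -> float:
    """VOI = U_info - max(U_plan, U_leisure).

    Piecewise linear in p with a single kink at
    p* = (U_leisure + C_plan) / (s * U_outcome); ties at the kink resolve
    toward the planning branch (max is unaffected).
    """
    return utility_info(agent, sc) - max(utility_plan(agent, sc), agent.U_leisure)


def likert_probabilities(voi: float | np.ndarray, kappa: CutPoints) -> np.ndarray:
    """Ordered-logistic category probabilities given latent VOI.

    P(category <= k) = logistic(kappa_k - voi); larger VOI shifts mass toward
    "definitely yes".  Accepts scalar or array VOI; category axis is last.
    """
    k = kappa.as_array()
    v = np.asarray(voi, dtype=float)
    cum = expit(k - v[..., None])  # (..., 4) cumulative P(cat <= k)
    ones = np.ones(v.shape + (1,))
    zeros = np.zeros(v.shape + (1,))
    cdf = np.concatenate([zeros, cum, ones], axis=-1)
    return np.diff(cdf, axis=-1)


def likert_log_probabilities(
    voi: np.ndarray, kappa_arr: np.ndarray, category: np.ndarray
) -> np.ndarray:
    """Log P(category | voi) under the ordered logistic, numerically stable.

    Vectorized over leading dimensions of ``voi``; ``category`` is 1-based and
    broadcasts against ``voi``.  ``kappa_arr`` is a plain ordered array (it may
    carry draw dimensions matching ``voi`` on the left).
    """
    voi = np.asarray(voi, dtype=float)
    category = np.asarray(category, dtype=np.int64)
    k = np.asarray(kappa_arr, dtype=float)
    if k.ndim == 1:
        edges = np.concatenate([[-np.inf], k, [np.inf]])
        hi = edges[category] - voi
        lo = edges[category - 1] - voi
    elif k.ndim == 2 and category.ndim == 1:
        # per-draw cut points: k is (draws, 4), voi is (draws, trials)
        edges = np.concatenate(
            [np.full((k.shape[0], 1), -np.inf), k, np.full((k.shape[0], 1), np.inf)],
            axis=1,
        )
        hi = edges[:, category] - voi
        lo = edges[:, category - 1] - voi
    else:  # pragma: no cover - unused shape combination
        raise ValueError("unsupported kappa/category shapes")
    # log(sigmoid(hi) - sigmoid(lo)) in a stable form:
    # = log(sigmoid(hi)) + log1p(-exp(log sigmoid(lo) - log sigmoid(hi)))
    log_sig_hi = -np.logaddexp(0.0, -hi)
    log_sig_lo = -np.logaddexp(0.0, -lo)
    with np.errstate(divide="ignore"):
        out = log_sig_hi + np.log1p(-np.exp(log_sig_lo - log_sig_hi))
    return out


def enumerate_choice_voi(agent: AgentParams, sc: Scenario) -> float:
    """Brute-force VOI: U_info minus the best of the explicit alternatives.

    Enumerates the information-free options (plan, deny) rather than using the
    closed-form max; used as an independent oracle in tests.
    """
    alternatives = [utility_plan(agent, sc), agent.U_leisure]
    return utility_info(agent, sc) - max(alternatives)


def scenarios_to_arrays(
    scenarios: Iterable[Scenario],
) -> dict[str, np.ndarray]:
    """Columnar view of a scenario list (p, cost_rank, valence sign)."""
    sc = list(scenarios)
    return {
        "p": np.array([s.p for s in sc]),
        "cost_rank": np.array([s.cost_rank for s in sc], dtype=np.int64),
        "cost_dollars": np.array([s.cost_dollars for s in sc]),
        "is_gain": np.array([s.valence == "gain" for s in sc], dtype=np.int64),
    }
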