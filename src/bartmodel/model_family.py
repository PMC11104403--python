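"""The classic four-parameter BART model and its variant family.

The agent holds a per-trial belief about the per-pump burst probability,

    p_belief = 1 - (priorBelief + learningRate * n_successes)
                   / (1 + learningRate * n_pumps),

where ``n_pumps`` / ``n_successes`` count the evidence accumulated on
previous trials (a pump "succeeds" when it does not burst the balloon, so a
burst trial contributes ``n_pumps - 1`` successes).  From that belief and a
risk-taking propensity the agent computes a per-trial target pump count,

    number_t = -riskTaking / ln(1 - p_belief),

and at each pump opportunity ``l`` within a trial pumps with probability

    p_pump(l) = sigmoid(-inverseTemperature * (l - number_t)).

The trial likelihood is a product of Bernoulli pump decisions; when the
balloon bursts, the would-be stop decision is censored (never observed), so
burst trials contribute pump terms only.

A family of 15 variants is obtained by letting each of the four parameters
be either a participant-level random effect or a single group-level fixed
value, excluding the fully fixed model.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit, log_expit

from .task_engine import TrialRecord

__all__ = [
    "PARAM_NAMES",
    "EPS_BELIEF",
    "ParticipantParams",
    "BeliefState",
    "ModelSpec",
    "belief_update",
    "optimal_pumps",
    "pump_probability",
    "trial_loglik",
    "update_state",
    "initial_state",
    "outcome_distribution",
    "enumerate_family",
    "block_loglik_matrix",
]

#: canonical parameter order used everywhere downstream
PARAM_NAMES = ("prior_belief", "learning_rate", "risk_taking", "inverse_temperature")

#: belief clamp; keeps the target pump count defined when the transformed
#: prior exceeds 1
EPS_BELIEF = 1e-6

_SHORT = {
    "prior_belief": "pb",
    "learning_rate": "lr",
    "risk_taking": "rt",
    "inverse_temperature": "it",
}


@dataclass(frozen=True)
class ParticipantParams:
    """Natural-scale parameters of one agent.

    ``prior_belief`` is the prior per-pump success probability (its
    complement is the initial burst belief); ``learning_rate`` in [0, 1]
    weights accumulated evidence; ``risk_taking`` > 0 scales the target pump
    count; ``inverse_temperature`` > 0 sets choice consistency.
    """

    prior_belief: float
    learning_rate: float
    risk_taking: float
    inverse_temperature: float

    def __post_init__(self) -> None:
        if self.prior_belief <= 0:
            raise ValueError("prior_belief must be positive")
        if not (0.0 <= self.learning_rate <= 1.0):
            raise ValueError("learning_rate must lie in [0, 1]")
        if self.risk_taking <= 0:
            raise ValueError("risk_taking must be positive")
        if self.inverse_temperature <= 0:
            raise ValueError("inverse_temperature must be positive")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.prior_belief, self.learning_rate, self.risk_taking, self.inverse_temperature]
        )


@dataclass(frozen=True)
class BeliefState:
    """Evidence counters and the implied burst belief before a trial."""

    cum_pumps: int = 0
    cum_successes: int = 0
    p_belief: float = 0.5

    def __post_init__(self) -> None:
        if self.cum_successes > self.cum_pumps:
            raise ValueError("cum_successes cannot exceed cum_pumps")
        if not (EPS_BELIEF <= self.p_belief <= 1 - EPS_BELIEF):
            raise ValueError("p_belief must be clamped to [eps, 1-eps]")


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters are participant-level random effects.

    ``random`` is the subset of :data:`PARAM_NAMES` estimated with a group
    mean, group SD and per-participant error; the rest are group-level fixed
    effects (a single shared value, no participant error term).
    """

    random: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = set(self.random) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        if not self.random:
            raise ValueError("at least one parameter must be participant-level")
        ordered = tuple(p for p in PARAM_NAMES if p in self.random)
        object.__setattr__(self, "random", ordered)

    @property
    def fixed(self) -> tuple[str, ...]:
        return tuple(p for p in PARAM_NAMES if p not in self.random)

    @property
    def name(self) -> str:
        if len(self.random) == len(PARAM_NAMES):
            return "full"
        return "+".join(_SHORT[p] for p in self.random)

    def is_random(self, param: str) -> bool:
        return param in self.random

    def to_json(self) -> str:
        return json.dumps(
            {p: ("random" if p in self.random else "fixed") for p in PARAM_NAMES}
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        return cls(tuple(p for p in PARAM_NAMES if d.get(p) == "random"))

    @classmethod
    def full(cls) -> "ModelSpec":
        return cls(PARAM_NAMES)


def enumerate_family() -> list[ModelSpec]:
    """All 2^4 - 1 = 15 assignments of random vs fixed status.

    Every non-empty subset of the four parameters may be participant-level;
    the all-fixed assignment (no individual differences at all) is excluded.
    Order: by decreasing number of random parameters, full model first.
    """
    specs = []
    for k in range(4, 0, -1):
        for combo in itertools.combinations(PARAM_NAMES, k):
            specs.append(ModelSpec(combo))
    return specs


# ---------------------------------------------------------------------------
# core model equations
# ---------------------------------------------------------------------------

def _clamp_belief(p):
    return np.clip(p, EPS_BELIEF, 1.0 - EPS_BELIEF)


def belief_update(
    prior_belief: float,
    learning_rate: float,
    cum_successes: float,
    cum_pumps: float,
):
    """Burst belief implied by the prior and the accumulated evidence.

    Returns ``1 - (prior_belief + learning_rate * cum_successes) /
    (1 + learning_rate * cum_pumps)`` clamped to ``[eps, 1 - eps]``.
    Vectorized over any argument.
    """
    prior_belief = np.asarray(prior_belief, dtype=float)
    learning_rate = np.asarray(learning_rate, dtype=float)
    cs = np.asarray(cum_successes, dtype=float)
    cp = np.asarray(cum_pumps, dtype=float)
    if np.any(prior_belief < 0) or np.any(learning_rate < 0):
        raise ValueError("parameters must be non-negative")
    if np.any(cs < 0) or np.any(cp < 0):
        raise ValueError("evidence counts must be non-negative")
    if np.any(cs > cp):
        raise ValueError("cum_successes cannot exceed cum_pumps")
    p = 1.0 - (prior_belief + learning_rate * cs) / (1.0 + learning_rate * cp)
    out = _clamp_belief(p)
    return float(out) if out.ndim == 0 else out


def optimal_pumps(risk_taking: float, p_belief: float):
    """Target pump count ``-riskTaking / ln(1 - p_belief)``.

    Strictly decreasing in the burst belief, linear in risk-taking.  The
    belief must be strictly inside (0, 1); callers clamp first.
    """
    risk_taking = np.asarray(risk_taking, dtype=float)
    p = np.asarray(p_belief, dtype=float)
    if np.any(risk_taking <= 0):
        raise ValueError("risk_taking must be positive")
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("p_belief must be strictly inside (0, 1); clamp first")
    out = -risk_taking / np.log1p(-p)
    return float(out) if out.ndim == 0 else out


def pump_probability(inverse_temperature: float, opportunity, number_t):
    """Probability of pumping at the given 1-based pump opportunity."""
    opportunity = np.asarray(opportunity, dtype=float)
    if np.any(opportunity < 1):
        raise ValueError("opportunity is 1-based")
    out = expit(-np.asarray(inverse_temperature, dtype=float) * (opportunity - number_t))
    return float(out) if out.ndim == 0 else out


def initial_state(params: ParticipantParams) -> BeliefState:
    """Pre-first-trial state: no evidence, belief from the prior alone."""
    p = belief_update(params.prior_belief, params.learning_rate, 0, 0)
    return BeliefState(0, 0, p)


def update_state(
    state: BeliefState, trial: TrialRecord, params: ParticipantParams
) -> BeliefState:
    """Post-trial belief state.

    Evidence counters accumulate over trials: a burst trial contributes one
    failure (its last pump) and ``n_pumps - 1`` successes.
    """
    cp = state.cum_pumps + trial.n_pumps
    cs = state.cum_successes + trial.n_pumps - (1 if trial.burst else 0)
    p = belief_update(params.prior_belief, params.learning_rate, cs, cp)
    return BeliefState(cp, cs, p)


def trial_loglik(
    trial: TrialRecord, state: BeliefState, params: ParticipantParams
) -> float:
    """Log-likelihood of one observed balloon under the current belief.

    Non-burst trial with n pumps: the participant pumped at opportunities
    1..n and declined at n+1, giving n pump terms and one stop term.  Burst
    trial: the stop decision is censored by the explosion, so only the pump
    terms 1..n remain.  Belief and target are constant within the trial.
    """
    number_t = optimal_pumps(params.risk_taking, state.p_belief)
    beta = params.inverse_temperature
    n = trial.n_pumps
    ll = 0.0
    if n > 0:
        opp = np.arange(1, n + 1, dtype=float)
        ll += float(np.sum(log_expit(-beta * (opp - number_t))))
    if not trial.burst:
        # log(1 - sigmoid(-x)) = log(sigmoid(x))
        ll += float(log_expit(beta * ((n + 1) - number_t)))
    return ll


def outcome_distribution(
    threshold: int, state: BeliefState, params: ParticipantParams
) -> np.ndarray:
    """Probabilities of every possible outcome of one balloon.

    Entry ``k`` for ``k < threshold`` is the probability of voluntarily
    stopping after exactly ``k`` pumps; the last entry is the burst
    probability (pumping all the way to the threshold).  Sums to 1.
    """
    number_t = optimal_pumps(params.risk_taking, state.p_belief)
    beta = params.inverse_temperature
    opp = np.arange(1, threshold + 1, dtype=float)
    p_pump = expit(-beta * (opp - number_t))
    probs = np.empty(threshold + 1)
    survive = 1.0
    for k in range(threshold):
        probs[k] = survive * (1.0 - p_pump[k])
        survive *= p_pump[k]
    probs[threshold] = survive
    return probs


# ---------------------------------------------------------------------------
# vectorized block likelihood (sampler hot path)
# ---------------------------------------------------------------------------

def block_loglik_matrix(
    n_pumps: np.ndarray,
    burst: np.ndarray,
    prior_belief: np.ndarray,
    learning_rate: np.ndarray,
    risk_taking: np.ndarray,
    inverse_temperature: np.ndarray,
    evidence_window: str = "cumulative",
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-participant block log-likelihood, vectorized over participants.

    ``n_pumps`` and ``burst`` are (N, T) observation arrays (trials in
    presentation order); parameters are length-N natural-scale vectors.
    ``mask`` (N, T, boolean) marks real trials; padding rows (for ragged
    cohorts) must be padded with ``n_pumps = 0, burst = False`` at the end
    and are excluded from both the likelihood and the evidence counters.
    Evidence counters are functions of the data alone, so beliefs for all
    trials are computed in closed form without a sequential scan.

    ``evidence_window`` selects cumulative accumulation over all previous
    trials (default; matches the classic implementation) or only the single
    previous trial (``"last_trial"``, the literal reading of the update
    rule's wording).
    """
    n_pumps = np.asarray(n_pumps, dtype=int)
    burst = np.asarray(burst, dtype=bool)
    N, T = n_pumps.shape
    succ = n_pumps - burst.astype(int)
    if evidence_window == "cumulative":
        cp = np.concatenate(
            [np.zeros((N, 1)), np.cumsum(n_pumps, axis=1)[:, :-1]], axis=1
        )
        cs = np.concatenate([np.zeros((N, 1)), np.cumsum(succ, axis=1)[:, :-1]], axis=1)
    elif evidence_window == "last_trial":
        cp = np.concatenate([np.zeros((N, 1)), n_pumps[:, :-1]], axis=1)
        cs = np.concatenate([np.zeros((N, 1)), succ[:, :-1]], axis=1)
    else:
        raise ValueError("evidence_window must be 'cumulative' or 'last_trial'")

    pb = np.asarray(prior_belief, dtype=float)[:, None]
    lr = np.asarray(learning_rate, dtype=float)[:, None]
    rt = np.asarray(risk_taking, dtype=float)[:, None]
    beta = np.asarray(inverse_temperature, dtype=float)[:, None, None]

    p_belief = _clamp_belief(1.0 - (pb + lr * cs) / (1.0 + lr * cp))  # (N, T)
    number_t = -rt / np.log1p(-p_belief)  # (N, T)

    L = int(n_pumps.max()) + 1
    opp = np.arange(1, L + 1, dtype=float)  # (L,)
    z = beta * (opp[None, None, :] - number_t[:, :, None])  # (N, T, L)
    log_pump = log_expit(-z)
    cum_pump = np.concatenate(
        [np.zeros((N, T, 1)), np.cumsum(log_pump, axis=2)], axis=2
    )
    ll = np.take_along_axis(cum_pump, n_pumps[:, :, None], axis=2)[:, :, 0]
    log_stop = log_expit(z)  # log(1 - p_pump)
    stop_terms = np.take_along_axis(log_stop, n_pumps[:, :, None], axis=2)[:, :, 0]
    ll = ll + np.where(burst, 0.0, stop_terms)
    if mask is not None:
        ll = ll * np.asarray(mask, dtype=float)
    return ll.sum(axis=1)
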