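"""Generative choice models for the two tasks.

PRL: a four-parameter reinforcement-learning model.  Each stimulus carries a
value Q, updated after feedback with separate learning rates for reward
(``alpha_rew``) and punishment (``alpha_pun``):

    Q_c <- Q_c + alpha * (outcome - Q_c),   outcome in {0, 1}

Choice follows a softmax over values with reinforcement sensitivity ``beta``
and an additive stickiness bonus ``kappa`` for repeating the previous choice:

    P(a) ∝ exp(beta * Q_a + kappa * 1[a == previous choice])

WCST: a three-parameter sequential attention-learning model.  A weight vector
over the three sorting dimensions (color, shape, number) lives on the simplex.
The match signal of a deck is the attention mass on the dimensions it shares
with the response card; choice probabilities are the match signals raised to
the decision-consistency power ``d`` and normalised.  After feedback the
attention mass is reallocated toward the feedback-consistent dimensions at
rate ``r`` (reward) or ``p`` (punishment).

Every model is exposed three ways: per-trial primitives (choice probabilities
and state updates), an exact sequence log-likelihood, and a seeded simulator
that plays the task environment and emits the trial CSV dialect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import tasks
from .io import TRIAL_COLUMNS, card_to_str, str_to_card, TrialDataError
from .tasks import (
    Card,
    DIMENSIONS,
    PRLConfig,
    STIMULI,
    WCSTConfig,
    prl_advance,
    prl_feedback,
    prl_initial_state,
    shuffled_deck,
    wcst_initial_state,
    wcst_match,
    wcst_step,
)

__all__ = [
    "PRLParams",
    "PRLAgentState",
    "WCSTParams",
    "WCSTAgentState",
    "MATCH_EPS",
    "prl_choice_probs",
    "prl_update",
    "prl_loglik",
    "prl_simulate",
    "wcst_choice_probs",
    "wcst_update",
    "wcst_loglik",
    "wcst_simulate",
]

#: Floor on WCST match signals so that observed unique errors (zero-match
#: choices) keep a finite log-likelihood.
MATCH_EPS = 1e-6


# ---------------------------------------------------------------------------
# PRL model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PRLParams:
    """Subject-level parameters of the four-parameter PRL model."""

    alpha_rew: float  # reward learning rate, (0, 1)
    alpha_pun: float  # punishment learning rate, (0, 1)
    beta: float  # reinforcement sensitivity, > 0
    kappa: float  # stickiness, unbounded

    def __post_init__(self) -> None:
        for name in ("alpha_rew", "alpha_pun"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or not math.isfinite(v):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.beta < 0 or not math.isfinite(self.beta):
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not math.isfinite(self.kappa):
            raise ValueError("kappa must be finite")


@dataclass(frozen=True)
class PRLAgentState:
    """Latent state of the PRL learner: one value per stimulus plus the
    previous choice (None before the first trial)."""

    q_values: tuple[float, float] = (0.5, 0.5)  # (Q_A, Q_B)
    prev_choice: str | None = None


def _stim_index(stimulus: str) -> int:
    if stimulus not in STIMULI:
        raise ValueError(f"unknown stimulus {stimulus!r}")
    return STIMULI.index(stimulus)


def prl_choice_probs(params: PRLParams, state: PRLAgentState) -> dict[str, float]:
    """Softmax choice probabilities with stickiness bonus for the previous
    choice; invariant to adding a constant to both Q values."""
    logits = np.array([params.beta * q for q in state.q_values])
    if state.prev_choice is not None:
        logits[_stim_index(state.prev_choice)] += params.kappa
    logits -= logits.max()  # overflow guard
    w = np.exp(logits)
    probs = w / w.sum()
    return {"A": float(probs[0]), "B": float(probs[1])}


def prl_update(
    params: PRLParams, state: PRLAgentState, choice: str, outcome: int
) -> PRLAgentState:
    """Delta-rule update of the chosen stimulus only, with the learning rate
    selected by the feedback valence."""
    if outcome not in (0, 1):
        raise ValueError(f"outcome must be 0 or 1, got {outcome!r}")
    i = _stim_index(choice)
    rate = params.alpha_rew if outcome == 1 else params.alpha_pun
    q = list(state.q_values)
    q[i] = q[i] + rate * (outcome - q[i])
    return PRLAgentState(q_values=(q[0], q[1]), prev_choice=choice)


def _check_single_ordered(trials: pd.DataFrame) -> pd.DataFrame:
    if "subject_id" in trials.columns and trials["subject_id"].nunique() > 1:
        raise TrialDataError("expected trials from a single subject")
    if "trial_index" in trials.columns:
        idx = trials["trial_index"].to_numpy()
        if (np.diff(idx) <= 0).any():
            raise TrialDataError("trials must be ordered by trial_index")
    return trials


def prl_loglik(params: PRLParams, trials: pd.DataFrame) -> float:
    """Exact log-likelihood (nats) of an ordered single-subject PRL sequence.

    Needs only ``choice`` and ``feedback`` columns.
    """
    trials = _check_single_ordered(trials)
    state = PRLAgentState()
    ll = 0.0
    for choice, outcome in zip(trials["choice"], trials["feedback"]):
        probs = prl_choice_probs(params, state)
        ll += math.log(probs[choice])
        state = prl_update(params, state, choice, int(outcome))
    return ll


def prl_simulate(
    params: PRLParams,
    config: PRLConfig = PRLConfig(),
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "sim",
    group: str = "sim",
    initial_optimal: str = "A",
    rt_rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Play a full PRL session with a softmax-RL agent; returns the trial
    CSV dialect.  Identical seeds give bit-identical output."""
    rng = np.random.default_rng(seed)
    env = prl_initial_state(config, initial_optimal)
    agent = PRLAgentState()
    rows = []
    for t in range(1, config.n_trials + 1):
        probs = prl_choice_probs(params, agent)
        choice = "A" if rng.random() < probs["A"] else "B"
        outcome = prl_feedback(env, choice, rng, config)
        rows.append(
            {
                "subject_id": subject_id,
                "group": group,
                "task": "prl",
                "trial_index": t,
                "phase_or_set": env.phase,
                "rule": "",
                "stimulus_or_card": env.optimal_stimulus,
                "choice": choice,
                "feedback": outcome,
                "rt_ms": round(float(rt_rng.lognormal(6.9, 0.3)), 1)
                if rt_rng is not None
                else np.nan,
            }
        )
        agent = prl_update(params, agent, choice, outcome)
        if t < config.n_trials:
            env = prl_advance(env, config)
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


# ---------------------------------------------------------------------------
# WCST model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WCSTParams:
    """Subject-level parameters of the sequential attention-learning model."""

    r: float  # reward rate, (0, 1)
    p: float  # punishment rate, (0, 1)
    d: float  # decision consistency, >= 0

    def __post_init__(self) -> None:
        for name in ("r", "p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or not math.isfinite(v):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.d < 0 or not math.isfinite(self.d):
            raise ValueError(f"d must be >= 0, got {self.d}")


@dataclass(frozen=True)
class WCSTAgentState:
    """Attention weights over (color, shape, number); a point on the
    3-simplex."""

    attention: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        a = np.asarray(self.attention, dtype=float)
        if (a < -1e-9).any() or abs(a.sum() - 1.0) > 1e-9:
            raise ValueError(f"attention must lie on the simplex, got {self.attention}")


def _match_signal(
    params: WCSTParams, state: WCSTAgentState, card: Card, config: WCSTConfig
) -> np.ndarray:
    att = dict(zip(DIMENSIONS, state.attention))
    m = np.empty(4)
    for k in range(4):
        dims = wcst_match(card, k + 1, config)
        m[k] = max(sum(att[d] for d in dims), MATCH_EPS)
    return m


def wcst_choice_probs(
    params: WCSTParams,
    state: WCSTAgentState,
    card: Card,
    config: WCSTConfig = WCSTConfig(),
) -> np.ndarray:
    """Deck choice probabilities: match signals raised to the consistency
    power ``d`` and normalised (d=0 is uniform choice)."""
    m = _match_signal(params, state, card, config)
    # power on log scale for numerical safety at large d
    logw = params.d * np.log(m)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def wcst_update(
    params: WCSTParams,
    state: WCSTAgentState,
    card: Card,
    choice: int,
    feedback: int,
    config: WCSTConfig = WCSTConfig(),
) -> WCSTAgentState:
    """Reallocate attention toward the feedback-consistent dimensions.

    Positive feedback implicates the matched dimensions; negative feedback
    implicates their complement.  The reallocation target is the current
    attention restricted to that set and renormalised, mixed in at rate ``r``
    (reward) or ``p`` (punishment).
    """
    if feedback not in (0, 1):
        raise ValueError(f"feedback must be 0 or 1, got {feedback!r}")
    matched = wcst_match(card, choice, config)
    consistent = matched if feedback == 1 else frozenset(DIMENSIONS) - matched
    if not consistent:
        return state  # degenerate: no dimension implicated, leave unchanged
    a = np.asarray(state.attention, dtype=float)
    mask = np.array([d in consistent for d in DIMENSIONS], dtype=float)
    mass = float((a * mask).sum())
    if mass < 1e-12:
        target = mask / mask.sum()
    else:
        target = a * mask / mass
    lam = params.r if feedback == 1 else params.p
    new = (1.0 - lam) * a + lam * target
    new = new / new.sum()  # guard drift
    return WCSTAgentState(attention=tuple(float(x) for x in new))


def wcst_loglik(
    params: WCSTParams, trials: pd.DataFrame, config: WCSTConfig = WCSTConfig()
) -> float:
    """Exact log-likelihood (nats) of an ordered single-subject WCST
    sequence; needs ``stimulus_or_card``, ``choice`` and ``feedback``."""
    trials = _check_single_ordered(trials)
    if "stimulus_or_card" not in trials.columns:
        raise TrialDataError("WCST likelihood requires the stimulus_or_card column")
    state = WCSTAgentState()
    ll = 0.0
    for text, choice, feedback in zip(
        trials["stimulus_or_card"], trials["choice"], trials["feedback"]
    ):
        card = str_to_card(text)
        choice = int(choice)
        probs = wcst_choice_probs(params, state, card, config)
        ll += math.log(probs[choice - 1])
        state = wcst_update(params, state, card, choice, int(feedback), config)
    return ll


def wcst_simulate(
    params: WCSTParams,
    config: WCSTConfig = WCSTConfig(),
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "sim",
    group: str = "sim",
    rt_rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Play a WCST session to completion with the attention-learning agent."""
    rng = np.random.default_rng(seed)
    deck = shuffled_deck(config)
    env = wcst_initial_state(config)
    agent = WCSTAgentState()
    rows = []
    while not env.finished:
        card = deck[(env.trial_index - 1) % len(deck)]
        probs = wcst_choice_probs(params, agent, card, config)
        choice = int(rng.choice(4, p=probs)) + 1
        rule = env.active_rule(config)
        set_index = env.set_index
        trial_index = env.trial_index
        feedback, env = wcst_step(env, card, choice, config)
        rows.append(
            {
                "subject_id": subject_id,
                "group": group,
                "task": "wcst",
                "trial_index": trial_index,
                "phase_or_set": set_index,
                "rule": rule,
                "stimulus_or_card": card_to_str(card),
                "choice": choice,
                "feedback": feedback,
                "rt_ms": round(float(rt_rng.lognormal(7.3, 0.3)), 1)
                if rt_rng is not None
                else np.nan,
            }
        )
        agent = wcst_update(params, agent, card, choice, feedback, config)
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)
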