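"""Task environments for the two set-shifting paradigms.

Two tasks are modelled:

* **Probabilistic reversal learning (PRL)** — a two-alternative choice task.
  One stimulus is "optimal" and returns positive feedback with probability
  ``p_good`` (default 0.8), the other with ``p_bad`` (default 0.2).  After a
  fixed acquisition phase (default 40 trials) the contingencies reverse for
  the remainder of the session.

* **Wisconsin Card Sorting Task (WCST)** — response cards varying on three
  dimensions (color, shape, number) are sorted onto four fixed key decks.
  Feedback is deterministic under a hidden rule dimension; the rule changes
  after a criterion run of consecutive correct sorts (default 10), for a
  maximum number of sets (default 9).

Both environments are plain data + pure transition functions so that agents,
likelihoods and behavioural metrics can share them without hidden state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "STIMULI",
    "COLORS",
    "SHAPES",
    "NUMBERS",
    "DIMENSIONS",
    "KEY_CARDS",
    "PRLConfig",
    "PRLState",
    "Card",
    "WCSTConfig",
    "WCSTState",
    "prl_phase_of",
    "prl_initial_state",
    "prl_feedback",
    "prl_advance",
    "full_deck",
    "shuffled_deck",
    "wcst_match",
    "wcst_initial_state",
    "wcst_step",
]

STIMULI = ("A", "B")

COLORS = ("red", "green", "yellow", "blue")
SHAPES = ("triangle", "star", "cross", "circle")
NUMBERS = (1, 2, 3, 4)
DIMENSIONS = ("color", "shape", "number")


# ---------------------------------------------------------------------------
# Probabilistic reversal learning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PRLConfig:
    """Session layout and feedback contingencies of the PRL task.

    Parameters
    ----------
    n_acquisition : int
        Trials before the reversal (default 40).
    n_reversal : int
        Trials after the reversal (default 40; the session is symmetric).
    p_good : float
        Probability of positive feedback when the currently optimal stimulus
        is chosen (default 0.8).
    p_bad : float
        Probability of positive feedback for the other stimulus (default 0.2).
    seed : int
        Seed for the feedback stream when an environment RNG is derived from
        the config.
    """

    n_acquisition: int = 40
    n_reversal: int = 40
    p_good: float = 0.8
    p_bad: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_acquisition < 1:
            raise ValueError("n_acquisition must be >= 1")
        if self.n_reversal < 0:
            raise ValueError("n_reversal must be >= 0")
        if not (0.0 <= self.p_bad < self.p_good <= 1.0):
            raise ValueError("require 0 <= p_bad < p_good <= 1")

    @property
    def n_trials(self) -> int:
        return self.n_acquisition + self.n_reversal


@dataclass(frozen=True)
class PRLState:
    """Position within a PRL session: which trial, which phase, and which
    stimulus currently carries the rich contingency."""

    trial_index: int  # 1-based
    phase: str  # "acquisition" | "reversal"
    optimal_stimulus: str  # "A" | "B"


def prl_phase_of(trial_index: int, config: PRLConfig) -> str:
    """Phase label of a 1-based trial index."""
    if not 1 <= trial_index <= config.n_trials:
        raise IndexError(
            f"trial_index {trial_index} outside session 1..{config.n_trials}"
        )
    return "acquisition" if trial_index <= config.n_acquisition else "reversal"


def prl_initial_state(config: PRLConfig, initial_optimal: str = "A") -> PRLState:
    if initial_optimal not in STIMULI:
        raise ValueError(f"unknown stimulus {initial_optimal!r}")
    return PRLState(trial_index=1, phase="acquisition", optimal_stimulus=initial_optimal)


def _other(stimulus: str) -> str:
    return "B" if stimulus == "A" else "A"


def prl_feedback(
    state: PRLState, choice: str, rng: np.random.Generator, config: PRLConfig
) -> int:
    """Sample feedback (1 positive / 0 negative) for a choice.

    Consumes exactly one uniform variate from ``rng``.
    """
    if choice not in STIMULI:
        raise ValueError(f"unknown stimulus {choice!r}; expected one of {STIMULI}")
    if state.trial_index > config.n_trials:
        raise IndexError("state is past the end of the session")
    p = config.p_good if choice == state.optimal_stimulus else config.p_bad
    return int(rng.random() < p)


def prl_advance(state: PRLState, config: PRLConfig) -> PRLState:
    """Advance to the next trial, flipping the optimal stimulus exactly once
    at the acquisition/reversal boundary."""
    nxt = state.trial_index + 1
    if nxt > config.n_trials:
        raise IndexError("cannot advance past the end of the session")
    phase = prl_phase_of(nxt, config)
    optimal = state.optimal_stimulus
    if state.phase == "acquisition" and phase == "reversal":
        optimal = _other(optimal)
    return PRLState(trial_index=nxt, phase=phase, optimal_stimulus=optimal)


# ---------------------------------------------------------------------------
# Wisconsin Card Sorting Task
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Card:
    """A response card: one value on each of the three sorting dimensions."""

    color: str
    shape: str
    number: int

    def __post_init__(self) -> None:
        if self.color not in COLORS:
            raise ValueError(f"unknown color {self.color!r}")
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.number not in NUMBERS:
            raise ValueError(f"unknown number {self.number!r}")

    def attribute(self, dimension: str):
        if dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {dimension!r}")
        return getattr(self, dimension)


#: The four fixed key decks: 1 red triangle, 2 green stars, 3 yellow crosses,
#: 4 blue circles.
KEY_CARDS = (
    Card("red", "triangle", 1),
    Card("green", "star", 2),
    Card("yellow", "cross", 3),
    Card("blue", "circle", 4),
)

_DEFAULT_RULES = ("color", "shape", "number") * 3


@dataclass(frozen=True)
class WCSTConfig:
    """WCST session parameters.

    The rule sequence defaults to color -> shape -> number cycled three times
    (nine sets).  The deck is the full set of 64 attribute combinations,
    shuffled once with ``seed`` and redealt cyclically; ``max_trials``
    (default 128, two deck passes) caps the session so it terminates even for
    agents that never reach criterion.
    """

    key_cards: tuple = KEY_CARDS
    rule_sequence: tuple = _DEFAULT_RULES
    criterion_consecutive: int = 10
    max_sets: int = 9
    max_trials: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.key_cards) != 4:
            raise ValueError("exactly 4 key decks required")
        if len(self.rule_sequence) != self.max_sets:
            raise ValueError("len(rule_sequence) must equal max_sets")
        if any(r not in DIMENSIONS for r in self.rule_sequence):
            raise ValueError("rules must be drawn from color/shape/number")
        if self.criterion_consecutive < 1:
            raise ValueError("criterion_consecutive must be >= 1")
        if self.max_trials < 1:
            raise ValueError("max_trials must be >= 1")


@dataclass(frozen=True)
class WCSTState:
    trial_index: int = 1  # 1-based index of the next trial to be played
    set_index: int = 1  # 1-based
    consecutive_correct: int = 0
    sets_completed: int = 0
    finished: bool = False

    def active_rule(self, config: WCSTConfig) -> str:
        return config.rule_sequence[self.set_index - 1]


def full_deck() -> list[Card]:
    """All 64 attribute combinations, in canonical order."""
    return [
        Card(c, s, n)
        for c, s, n in itertools.product(COLORS, SHAPES, NUMBERS)
    ]


def shuffled_deck(config: WCSTConfig) -> list[Card]:
    """Seeded shuffle of the 64-card deck; dealt cyclically by trial index."""
    deck = full_deck()
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(deck))
    return [deck[i] for i in order]


def wcst_match(card: Card, deck_index: int, config: WCSTConfig = WCSTConfig()) -> frozenset:
    """Dimensions on which ``card`` matches key deck ``deck_index`` (1..4).

    An empty result marks the choice as a *unique error* candidate: the deck
    shares no attribute with the response card.
    """
    if not 1 <= deck_index <= 4:
        raise ValueError(f"deck_index must be 1..4, got {deck_index}")
    key = config.key_cards[deck_index - 1]
    return frozenset(
        d for d in DIMENSIONS if card.attribute(d) == key.attribute(d)
    )


def wcst_initial_state(config: WCSTConfig) -> WCSTState:
    return WCSTState()


def wcst_step(
    state: WCSTState, card: Card, choice: int, config: WCSTConfig
) -> tuple[int, WCSTState]:
    """Play one sort: feedback is 1 iff the chosen deck matches the card on
    the active rule dimension.

    On the criterion-th consecutive correct sort the set completes, the rule
    advances and the counter resets.  The session finishes when all sets are
    completed or ``max_trials`` trials have been played.
    """
    if state.finished:
        raise RuntimeError("cannot step a finished WCST session")
    rule = state.active_rule(config)
    matches = wcst_match(card, choice, config)
    correct = rule in matches
    feedback = int(correct)

    consecutive = state.consecutive_correct + 1 if correct else 0
    sets_completed = state.sets_completed
    set_index = state.set_index
    if correct and consecutive == config.criterion_consecutive:
        sets_completed += 1
        consecutive = 0  # counter resets on rule change
        if sets_completed < config.max_sets:
            set_index += 1

    trial_index = state.trial_index + 1
    finished = sets_completed == config.max_sets or trial_index > config.max_trials
    return feedback, WCSTState(
        trial_index=trial_index,
        set_index=set_index,
        consecutive_correct=consecutive,
        sets_completed=sets_completed,
        finished=finished,
    )
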