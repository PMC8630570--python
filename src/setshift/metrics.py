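"""Model-agnostic behavioural outcome measures for both tasks.

PRL, per phase: proportion correct, switching after spurious (false) negative
feedback, staying after veridical (true) positive feedback; plus the
proportion of perseverative responses immediately following the reversal.

WCST: sets completed, the three mutually exclusive error proportions
(perseverative / nonperseverative / unique), set-maintenance failures, and
trials to complete the first set.

A measure whose denominator is empty (e.g. no spurious negative feedback was
ever delivered) is reported as ``None`` — unavailable — never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .io import TrialDataError, str_to_card
from .tasks import PRLConfig, WCSTConfig, wcst_match

__all__ = ["PRLMeasures", "WCSTMeasures", "prl_measures", "wcst_measures", "measures_table"]

PHASES = ("acquisition", "reversal")


@dataclass(frozen=True)
class PRLMeasures:
    p_correct: dict
    p_perseverative: float | None
    p_switch_after_spurious_negative: dict
    p_stay_after_veridical_positive: dict
    mean_rt_ms: dict

    def as_row(self) -> dict:
        row: dict = {}
        for ph in PHASES:
            row[f"p_correct_{ph}"] = self.p_correct[ph]
            row[f"p_switch_after_spurious_negative_{ph}"] = (
                self.p_switch_after_spurious_negative[ph]
            )
            row[f"p_stay_after_veridical_positive_{ph}"] = (
                self.p_stay_after_veridical_positive[ph]
            )
            row[f"mean_rt_ms_{ph}"] = self.mean_rt_ms[ph]
        row["p_perseverative"] = self.p_perseverative
        return row


@dataclass(frozen=True)
class WCSTMeasures:
    sets_completed: int
    p_perseverative_errors: float
    p_nonperseverative_errors: float
    p_unique_errors: float
    n_set_maintenance_failures: int
    trials_to_first_set: int | None
    mean_rt_ms: float | None

    def as_row(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def prl_measures(trials: pd.DataFrame, config: PRLConfig = PRLConfig()) -> PRLMeasures:
    """Outcome measures of one subject's PRL session.

    The per-trial optimal stimulus is read from the ``stimulus_or_card``
    column; feedback validity (spurious vs veridical) is judged against it.
    Switch/stay events on the final trial have no successor and are excluded
    from their denominators.
    """
    trials = trials.reset_index(drop=True)
    phase = trials["phase_or_set"].to_numpy()
    choice = trials["choice"].to_numpy()
    optimal = trials["stimulus_or_card"].to_numpy()
    feedback = trials["feedback"].to_numpy(dtype=int)
    n = len(trials)
    if n == 0:
        raise TrialDataError("empty trial sequence")
    correct = choice == optimal

    p_correct, p_switch, p_stay, mean_rt = {}, {}, {}, {}
    has_rt = "rt_ms" in trials.columns and trials["rt_ms"].notna().any()
    for ph in PHASES:
        in_ph = phase == ph
        p_correct[ph] = _ratio(int((correct & in_ph).sum()), int(in_ph.sum()))
        # events need a successor trial
        can_follow = np.zeros(n, dtype=bool)
        can_follow[:-1] = True
        spurious = in_ph & correct & (feedback == 0) & can_follow
        veridical = in_ph & correct & (feedback == 1) & can_follow
        switched = np.zeros(n, dtype=bool)
        switched[:-1] = choice[1:] != choice[:-1]
        p_switch[ph] = _ratio(int((spurious & switched).sum()), int(spurious.sum()))
        p_stay[ph] = _ratio(int((veridical & ~switched).sum()), int(veridical.sum()))
        if has_rt and in_ph.any():
            mean_rt[ph] = float(pd.to_numeric(trials.loc[in_ph, "rt_ms"]).mean())
        else:
            mean_rt[ph] = None

    # perseveration: unbroken run of previously-optimal choices from the
    # first reversal trial, over the number of reversal trials
    rev = np.flatnonzero(phase == "reversal")
    if rev.size == 0:
        p_persev = None
    else:
        prev_optimal = optimal[rev[0] - 1] if rev[0] > 0 else None
        run = 0
        if prev_optimal is not None:
            for i in rev:
                if choice[i] == prev_optimal:
                    run += 1
                else:
                    break
        p_persev = run / rev.size if prev_optimal is not None else None

    return PRLMeasures(
        p_correct=p_correct,
        p_perseverative=p_persev,
        p_switch_after_spurious_negative=p_switch,
        p_stay_after_veridical_positive=p_stay,
        mean_rt_ms=mean_rt,
    )


def wcst_measures(
    trials: pd.DataFrame,
    config: WCSTConfig = WCSTConfig(),
    establish_criterion: int = 5,
) -> WCSTMeasures:
    """Outcome measures of one subject's WCST session.

    Error taxonomy (mutually exclusive, in precedence order):

    * **unique** — the chosen deck matches the card on no dimension;
    * **perseverative** — from the second set on, the choice matches the
      previous set's rule but not the active rule;
    * **nonperseverative** — any other error.

    A set-maintenance failure is an error after at least
    ``establish_criterion`` (default 5) consecutive correct sorts within the
    current set.
    """
    trials = trials.reset_index(drop=True)
    n = len(trials)
    if n == 0:
        raise TrialDataError("empty trial sequence")
    set_idx = pd.to_numeric(trials["phase_or_set"]).astype(int).to_numpy()
    rules = trials["rule"].to_numpy()
    feedback = trials["feedback"].to_numpy(dtype=int)
    choices = pd.to_numeric(trials["choice"]).astype(int).to_numpy()
    if (np.diff(set_idx) < 0).any():
        raise TrialDataError("set indices must be nondecreasing")
    set_rule = {}
    for s, r in zip(set_idx, rules):
        if s in set_rule and set_rule[s] != r:
            raise TrialDataError(f"set {s} carries two different rules")
        set_rule[s] = r

    n_persev = n_nonpersev = n_unique = 0
    n_maintenance = 0
    sets_completed = 0
    trials_to_first_set = None
    consecutive = 0
    current_set = set_idx[0]
    for i in range(n):
        if set_idx[i] != current_set:
            current_set = set_idx[i]
            consecutive = 0
        card = str_to_card(trials["stimulus_or_card"].iloc[i])
        match = wcst_match(card, choices[i], config)
        if feedback[i] == 1:
            consecutive += 1
            if consecutive == config.criterion_consecutive:
                sets_completed += 1
                if set_idx[i] == set_idx[0] and trials_to_first_set is None:
                    trials_to_first_set = int(trials["trial_index"].iloc[i])
                consecutive = 0
        else:
            if consecutive >= establish_criterion:
                n_maintenance += 1
            if len(match) == 0:
                n_unique += 1
            else:
                prev_rule = set_rule.get(set_idx[i] - 1)
                if (
                    set_idx[i] >= 2
                    and prev_rule is not None
                    and prev_rule in match
                    and rules[i] not in match
                ):
                    n_persev += 1
                else:
                    n_nonpersev += 1
            consecutive = 0

    has_rt = "rt_ms" in trials.columns and trials["rt_ms"].notna().any()
    return WCSTMeasures(
        sets_completed=sets_completed,
        p_perseverative_errors=n_persev / n,
        p_nonperseverative_errors=n_nonpersev / n,
        p_unique_errors=n_unique / n,
        n_set_maintenance_failures=n_maintenance,
        trials_to_first_set=trials_to_first_set,
        mean_rt_ms=float(pd.to_numeric(trials["rt_ms"]).mean()) if has_rt else None,
    )


def measures_table(
    trials: pd.DataFrame,
    prl_config: PRLConfig = PRLConfig(),
    wcst_config: WCSTConfig = WCSTConfig(),
) -> pd.DataFrame:
    """Per-subject measure rows for a (possibly multi-task) trial table."""
    rows = []
    for subject, sub in trials.groupby("subject_id", sort=False):
        task = sub["task"].iloc[0]
        if task == "prl":
            row = prl_measures(sub, prl_config).as_row()
        else:
            row = wcst_measures(sub, wcst_config).as_row()
        rows.append(
            {"subject_id": subject, "group": sub["group"].iloc[0], "task": task, **row}
        )
    return pd.DataFrame(rows)
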