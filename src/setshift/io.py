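"""Trial-level CSV dialect shared by every stage of the pipeline.

One row per trial, long format:

``subject_id, group, task, trial_index, phase_or_set, rule, stimulus_or_card,
choice, feedback, rt_ms``

* ``task`` is ``prl`` or ``wcst``.
* ``phase_or_set`` holds the phase label for PRL rows and the 1-based set
  index for WCST rows.
* ``rule`` is the active sorting rule (WCST only; empty for PRL).
* ``stimulus_or_card`` holds the currently optimal stimulus id for PRL rows
  (so that correctness is recoverable from the file alone) and the dealt
  response card, encoded ``color|shape|number``, for WCST rows.
* ``choice`` is a stimulus id (PRL) or a deck index 1-4 (WCST).
* ``feedback`` is 1 (positive) or 0 (negative).
* ``rt_ms`` is optional and never analysed by the models.

Files may start with ``#``-prefixed comment lines (the pipeline embeds its
config hash that way); readers skip them.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .tasks import Card, STIMULI

__all__ = [
    "TRIAL_COLUMNS",
    "TrialDataError",
    "card_to_str",
    "str_to_card",
    "read_trials",
    "write_trials",
    "validate_trials",
]

TRIAL_COLUMNS = [
    "subject_id",
    "group",
    "task",
    "trial_index",
    "phase_or_set",
    "rule",
    "stimulus_or_card",
    "choice",
    "feedback",
    "rt_ms",
]

_REQUIRED = [c for c in TRIAL_COLUMNS if c != "rt_ms"]


class TrialDataError(ValueError):
    """Malformed trial-level data; message carries column/row context."""


def card_to_str(card: Card) -> str:
    return f"{card.color}|{card.shape}|{card.number}"


def str_to_card(text: str) -> Card:
    try:
        color, shape, number = str(text).split("|")
        return Card(color, shape, int(number))
    except Exception as exc:  # re-raise with dialect context
        raise TrialDataError(
            f"unparseable card triple {text!r}; expected 'color|shape|number'"
        ) from exc


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the dialect invariants, raising :class:`TrialDataError` with
    column- and row-level messages."""
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise TrialDataError(f"missing required column(s): {', '.join(missing)}")
    if "rt_ms" not in df.columns:
        df = df.assign(rt_ms=pd.NA)
    # the rule column is legitimately empty for PRL rows; normalise NaN -> ""
    df = df.assign(rule=df["rule"].fillna("").astype(str))

    bad_task = df.loc[~df["task"].isin(["prl", "wcst"])]
    if len(bad_task):
        raise TrialDataError(
            f"invalid task value at row {bad_task.index[0]}: {bad_task['task'].iloc[0]!r}"
        )
    fb = pd.to_numeric(df["feedback"], errors="coerce")
    bad_fb = df.loc[~fb.isin([0, 1])]
    if len(bad_fb):
        raise TrialDataError(
            f"feedback must be 0 or 1; offending row {bad_fb.index[0]}"
        )
    df = df.assign(feedback=fb.astype(int), trial_index=pd.to_numeric(df["trial_index"]).astype(int))

    for subject, sub in df.groupby("subject_id", sort=False):
        idx = sub["trial_index"].to_numpy()
        if not (idx == range(1, len(idx) + 1)).all():
            raise TrialDataError(
                f"subject {subject!r}: trial_index must be contiguous from 1"
            )
        task = sub["task"].iloc[0]
        if (sub["task"] != task).any():
            raise TrialDataError(f"subject {subject!r}: mixed task labels")
        if task == "prl":
            bad = sub.loc[~sub["choice"].isin(STIMULI)]
            if len(bad):
                raise TrialDataError(
                    f"subject {subject!r}: invalid PRL choice at row {bad.index[0]}"
                )
        else:
            choices = pd.to_numeric(sub["choice"], errors="coerce")
            if not choices.isin([1, 2, 3, 4]).all():
                raise TrialDataError(
                    f"subject {subject!r}: WCST choices must be deck indices 1-4"
                )
            for row, text in sub["stimulus_or_card"].items():
                str_to_card(text)  # raises with context on failure
    return df


def read_trials(path: str | Path, validate: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if validate:
        df = validate_trials(df)
    return df


def write_trials(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    path = Path(path)
    cols = [c for c in TRIAL_COLUMNS if c in df.columns]
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, columns=cols)
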