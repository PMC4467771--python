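"""Condition assignment of stream epochs, per task.

Two framings coexist.  The *correct/incorrect* framing (used for inference
about ability) keys on the true answer of each trial: in AT and WM the
correct word's epochs go to the positive bin and every other word's to the
negative bin; in AR only the other sentence noun forms the negative bin and
the remaining six words are excluded, because an attentive but wrong
participant may have counted that noun, and pooling it with six silent words
would dilute the comparison.  The *attended/unattended* framing (used for
the time-sensitivity analysis) keys on the participant's behavioral answer
regardless of correctness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import EpochSet
from .protocol import BatterySchedule, TrialSpec, SET_SIZES
from .simulate import BehavioralResponse

__all__ = [
    "ConditionBinning",
    "bin_attention",
    "bin_wm",
    "bin_ar",
    "bin_trial",
    "bin_task",
    "bin_attended_by_behavior",
    "restrict_set_sizes",
]


@dataclass
class ConditionBinning:
    """Disjoint epoch-index partition: positive / negative / excluded."""

    positive: np.ndarray
    negative: np.ndarray
    excluded: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.positive = np.asarray(self.positive, dtype=int)
        self.negative = np.asarray(self.negative, dtype=int)
        self.excluded = np.asarray(self.excluded, dtype=int)
        sets = [set(self.positive), set(self.negative), set(self.excluded)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("binning sets must be disjoint")

    @property
    def n_total(self) -> int:
        return len(self.positive) + len(self.negative) + len(self.excluded)

    def manifest(self, epochs: EpochSet) -> pd.DataFrame:
        """Per-epoch condition table (TSV-exportable)."""
        cond = np.full(len(epochs), "unused", dtype=object)
        cond[self.positive] = "positive"
        cond[self.negative] = "negative"
        cond[self.excluded] = "excluded"
        out = epochs.metadata[["trial_index", "word_id", "task"]].copy()
        out.insert(0, "epoch_id", np.arange(len(epochs)))
        out["condition"] = cond
        return out


def _trial_rows(epochs: EpochSet, trial_index: int) -> np.ndarray:
    return np.nonzero(epochs.metadata["trial_index"].to_numpy() == trial_index)[0]


def bin_attention(epochs: EpochSet, trial: TrialSpec) -> ConditionBinning:
    """AT: target-word epochs vs. all other stream epochs (7:1 in expectation)."""
    if trial.task != "AT":
        raise ValueError("bin_attention expects an AT trial")
    rows = _trial_rows(epochs, trial.trial_index)
    words = epochs.metadata["word_id"].to_numpy()[rows]
    pos = rows[words == trial.target_word]
    if len(pos) == 0:
        warnings.warn(f"trial {trial.trial_index}: no target epochs survived")
    return ConditionBinning(pos, rows[words != trial.target_word],
                            np.empty(0, int), label="attended")


def bin_wm(epochs: EpochSet, trial: TrialSpec) -> ConditionBinning:
    """WM: epochs of the *correct* recall answer vs. all seven other words.

    Keyed on the true answer, not the participant's: at chance performance
    the P300b lands in both bins equally often and the contrast is null.
    """
    if trial.task != "WM":
        raise ValueError("bin_wm expects a WM trial")
    rows = _trial_rows(epochs, trial.trial_index)
    words = epochs.metadata["word_id"].to_numpy()[rows]
    pos = rows[words == trial.target_word]
    if len(pos) == 0:
        warnings.warn(f"trial {trial.trial_index}: no correct-word epochs survived")
    return ConditionBinning(pos, rows[words != trial.target_word],
                            np.empty(0, int), label="correct")


def bin_ar(epochs: EpochSet, trial: TrialSpec,
           schedule: BatterySchedule) -> ConditionBinning:
    """AR: correct noun vs. the other sentence noun only; the rest excluded."""
    if trial.task != "AR":
        raise ValueError("bin_ar expects an AR trial")
    s = trial.sentence
    correct_id = trial.target_word
    other_label = s.noun2 if schedule.labels[correct_id] == s.noun1 else s.noun1
    other_id = schedule.word_id(other_label)
    rows = _trial_rows(epochs, trial.trial_index)
    words = epochs.metadata["word_id"].to_numpy()[rows]
    pos = rows[words == correct_id]
    neg = rows[words == other_id]
    if len(pos) == 0 or len(neg) == 0:
        warnings.warn(f"trial {trial.trial_index}: empty AR bin after rejection")
    return ConditionBinning(pos, neg, rows[(words != correct_id) & (words != other_id)],
                            label="correct-vs-other-noun")


def bin_trial(epochs: EpochSet, trial: TrialSpec,
              schedule: BatterySchedule) -> ConditionBinning:
    if trial.task == "AT":
        return bin_attention(epochs, trial)
    if trial.task == "WM":
        return bin_wm(epochs, trial)
    return bin_ar(epochs, trial, schedule)


def bin_task(
    epochs: EpochSet,
    schedule: BatterySchedule,
    task: str,
    trials: Sequence[TrialSpec] | None = None,
) -> ConditionBinning:
    """Pool the per-trial binnings of one task over the whole session."""
    if trials is None:
        trials = [t for t in schedule.trials if t.task == task]
    if not trials:
        raise ValueError(f"no {task} trials to bin")
    parts = [bin_trial(epochs, t, schedule) for t in trials]
    return ConditionBinning(
        np.concatenate([p.positive for p in parts]),
        np.concatenate([p.negative for p in parts]),
        np.concatenate([p.excluded for p in parts]),
        label=parts[0].label,
    )


def bin_attended_by_behavior(
    epochs: EpochSet,
    responses: Sequence[BehavioralResponse] | Mapping[int, int],
) -> ConditionBinning:
    """Partition by the participant's answer: attended vs. unattended.

    ``responses`` maps trial -> attended word id (a behavioral log or a
    plain mapping).  Trials without a response are excluded with a warning.
    """
    if isinstance(responses, Mapping):
        attended = dict(responses)
    else:
        attended = {r.trial_index: r.attended_word for r in responses}
    trials = epochs.metadata["trial_index"].to_numpy()
    words = epochs.metadata["word_id"].to_numpy()
    missing = ~np.isin(trials, list(attended))
    if missing.any():
        warnings.warn(
            f"excluding {sorted(set(trials[missing]))} trial(s) without a behavioral response"
        )
    attended_word = np.array([attended.get(t, -1) for t in trials])
    pos = np.nonzero(words == attended_word)[0]
    neg = np.nonzero((words != attended_word) & ~missing)[0]
    return ConditionBinning(pos, neg, np.nonzero(missing)[0], label="attended")


def restrict_set_sizes(trials: Iterable[TrialSpec],
                       allowed: Iterable[int]) -> list[TrialSpec]:
    """WM trials whose memory-set size is in ``allowed``."""
    allowed = set(allowed)
    if not allowed <= set(SET_SIZES):
        raise ValueError(f"allowed sizes must be within {SET_SIZES}")
    out = [t for t in trials if t.task == "WM" and len(t.memory_set) in allowed]
    if not out:
        raise ValueError("no WM trials with the requested set sizes")
    return out
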