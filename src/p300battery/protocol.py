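"""Three-task auditory oddball battery: streams, probes, sentences, schedule.

The battery probes attention (AT), working memory (WM), and grammatical
reasoning (AR) through a single response channel: the participant covertly
counts a designated word inside a stream in which all eight vocabulary words
occur equally often.  Attended occurrences elicit a P300b; the identity of
the counted word is therefore recoverable from EEG alone.

Session layout is fixed: six 12-trial blocks ordered AT, WM, AR, AT, WM, AR
(72 trials).  Within each task the design is exactly balanced — in AT every
word is the target three times; in WM each memory-set size (4, 6, 8) is used
in eight trials; in AR each of the eight sentence templates occurs three
times with unique noun pairings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_VOCABULARY",
    "WordStimulus",
    "StreamSpec",
    "Sentence",
    "TrialSpec",
    "BatterySchedule",
    "TimingModel",
    "generate_stream",
    "solve_sentence",
    "sentence_text",
    "enumerate_sentence_templates",
    "build_schedule",
    "wm_correct_answer",
    "protocol_duration",
    "chance_level",
    "schedule_events",
    "schedule_to_json",
    "schedule_from_json",
]

#: Eight monosyllabic English nouns with distinct onset consonants.
DEFAULT_VOCABULARY: tuple[str, ...] = (
    "back", "cake", "dot", "fish", "gum", "pen", "rock", "toy",
)

N_WORDS = 8
REPETITION_CHOICES = (7, 8, 9, 10)
SET_SIZES = (4, 6, 8)
BLOCK_TASKS = ("AT", "WM", "AR", "AT", "WM", "AR")
TRIALS_PER_BLOCK = 12


@dataclass(frozen=True)
class WordStimulus:
    """One vocabulary item: a spoken monosyllabic noun of fixed duration."""

    word_id: int
    label: str
    duration: float = 0.400  # seconds


def make_vocabulary(labels: Sequence[str] = DEFAULT_VOCABULARY) -> tuple[WordStimulus, ...]:
    if len(labels) != N_WORDS or len(set(labels)) != N_WORDS:
        raise ValueError(f"vocabulary must contain {N_WORDS} distinct labels")
    return tuple(WordStimulus(i, lab) for i, lab in enumerate(labels))


@dataclass(frozen=True)
class StreamSpec:
    """A trial's word stream: each word occurs exactly ``repetitions`` times."""

    repetitions: int
    order: tuple[int, ...]
    isi: float = 0.100  # seconds between word offsets and onsets

    def __post_init__(self) -> None:
        counts = np.bincount(np.asarray(self.order), minlength=N_WORDS)
        if not (counts == self.repetitions).all():
            raise ValueError("stream must contain each word_id exactly `repetitions` times")

    def __len__(self) -> int:
        return len(self.order)


@dataclass(frozen=True)
class Sentence:
    """A two-noun relational sentence; ``noun1`` is the noun mentioned first."""

    noun1: str
    noun2: str
    verb: str  # "precede" | "follow"
    voice: str  # "active" | "passive"
    polarity: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if self.noun1 == self.noun2:
            raise ValueError("sentence nouns must differ")
        if self.verb not in ("precede", "follow"):
            raise ValueError(f"unknown verb {self.verb!r}")
        if self.voice not in ("active", "passive"):
            raise ValueError(f"unknown voice {self.voice!r}")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def template(self) -> tuple[str, str, str]:
        return (self.verb, self.voice, self.polarity)


def solve_sentence(s: Sentence) -> str:
    """Return the noun in first position under the sentence's logical reading.

    With two nouns and two positions, each of "follow" (vs. "precede"),
    passive voice, and negation inverts the described order, so the answer is
    ``noun1`` exactly when an even number of inversions apply.
    """
    flips = (s.verb == "follow") + (s.voice == "passive") + (s.polarity == "negative")
    return s.noun1 if flips % 2 == 0 else s.noun2


def sentence_text(s: Sentence) -> str:
    """English rendering, e.g. 'cake is not preceded by dot'."""
    neg = s.polarity == "negative"
    if s.voice == "active":
        verb = f"{s.verb}s" if not neg else f"does not {s.verb}"
    else:
        part = "preceded" if s.verb == "precede" else "followed"
        verb = f"is {part} by" if not neg else f"is not {part} by"
    return f"{s.noun1} {verb} {s.noun2}"


def enumerate_sentence_templates(noun1: str = "cake", noun2: str = "dot") -> tuple[Sentence, ...]:
    """All 8 sentence types: the full cross of verb x voice x polarity."""
    return tuple(
        Sentence(noun1, noun2, verb, voice, polarity)
        for verb in ("precede", "follow")
        for voice in ("active", "passive")
        for polarity in ("positive", "negative")
    )


@dataclass(frozen=True)
class TrialSpec:
    """One trial: its stream plus the task-specific problem definition.

    ``target_word`` is the word the participant *should* count: the
    experimenter-given target in AT, and the correct answer in WM/AR.
    """

    task: str  # "AT" | "WM" | "AR"
    stream: StreamSpec
    target_word: int
    block_index: int
    trial_index: int
    memory_set: tuple[str, ...] | None = None  # WM only, ordered
    probe_position: int | None = None  # WM only, 1-based
    sentence: Sentence | None = None  # AR only

    def __post_init__(self) -> None:
        if self.task not in ("AT", "WM", "AR"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.task == "WM":
            if self.memory_set is None or self.probe_position is None:
                raise ValueError("WM trial requires memory_set and probe_position")
            if not 1 <= self.probe_position <= len(self.memory_set):
                raise ValueError("probe_position out of range")
        if self.task == "AR" and self.sentence is None:
            raise ValueError("AR trial requires a sentence")


@dataclass(frozen=True)
class TimingModel:
    """Protocol timing constants, all in seconds.

    One stimulus slot is 500 ms (400 ms word + 100 ms gap); since every
    attended target is accompanied by seven distractors, each attended
    stimulus accounts for ~4 s of stream time.
    """

    stimulus_duration: float = 0.400
    isi: float = 0.100
    stimuli_per_target: int = 8
    inter_trial_rest: float = 10.0
    wm_delay: float = 10.0
    ar_post_response_delay: float = 2.0

    @property
    def slot(self) -> float:
        return self.stimulus_duration + self.isi

    @property
    def time_per_target(self) -> float:
        return self.stimuli_per_target * self.slot


def generate_stream(
    repetitions: int,
    rng: np.random.Generator | int | None = None,
    forbid_immediate_repeats: bool = False,
) -> StreamSpec:
    """Uniformly shuffled stream with ``repetitions`` copies of each word.

    ``forbid_immediate_repeats`` resamples until no word directly follows
    itself (off by default).
    """
    if repetitions not in REPETITION_CHOICES:
        raise ValueError(f"repetitions must be one of {REPETITION_CHOICES}, got {repetitions}")
    rng = np.random.default_rng(rng)
    base = np.repeat(np.arange(N_WORDS), repetitions)
    while True:
        order = rng.permutation(base)
        if not forbid_immediate_repeats or (np.diff(order) != 0).all():
            return StreamSpec(repetitions=repetitions, order=tuple(int(w) for w in order))


def wm_correct_answer(memory_set: Sequence[str], probe_position: int) -> str:
    """The word at the probed (1-based) serial position of the memory set."""
    if not 1 <= probe_position <= len(memory_set):
        raise ValueError(
            f"probe_position {probe_position} out of range for set of {len(memory_set)}"
        )
    return memory_set[probe_position - 1]


def protocol_duration(n_targets: int, timing: TimingModel | None = None) -> float:
    """Stream-delivery time in seconds for ``n_targets`` attended targets.

    Excludes question/rest time: each attended target comes with seven
    distractor stimuli at 500 ms per slot, i.e. 4 s per target.
    """
    if n_targets < 0:
        raise ValueError("n_targets must be >= 0")
    timing = timing or TimingModel()
    return n_targets * timing.time_per_target


def chance_level(n_words: int) -> float:
    """Guessing probability with ``n_words`` equiprobable answer options."""
    if n_words < 1:
        raise ValueError("n_words must be >= 1")
    return 1.0 / n_words


@dataclass(frozen=True)
class BatterySchedule:
    """The full 6-block, 72-trial session plan."""

    vocabulary: tuple[WordStimulus, ...]
    blocks: tuple[tuple[TrialSpec, ...], ...]
    timing: TimingModel = field(default_factory=TimingModel)

    @property
    def trials(self) -> tuple[TrialSpec, ...]:
        return tuple(t for block in self.blocks for t in block)

    @property
    def block_order(self) -> tuple[str, ...]:
        return tuple(block[0].task for block in self.blocks)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(w.label for w in self.vocabulary)

    def word_id(self, label: str) -> int:
        return self.labels.index(label)

    def trial(self, trial_index: int) -> TrialSpec:
        return self.trials[trial_index]


def _balanced_reps(rng: np.random.Generator) -> list[int]:
    # each admissible repetition count used 3x within a 12-trial block
    reps = np.repeat(REPETITION_CHOICES, 3)
    return [int(r) for r in rng.permutation(reps)]


def build_schedule(
    vocabulary: Sequence[WordStimulus] | Sequence[str] | None = None,
    rng: np.random.Generator | int | None = None,
    forbid_immediate_repeats: bool = False,
) -> BatterySchedule:
    """Draw a balanced 72-trial session from one random state.

    All randomness (stream orders, per-trial repetition counts, AT target
    order, WM sets and probes, AR noun pairings) flows from ``rng``.
    """
    if vocabulary is None:
        vocab = make_vocabulary()
    elif all(isinstance(w, WordStimulus) for w in vocabulary):
        vocab = tuple(vocabulary)  # type: ignore[arg-type]
        if len(vocab) != N_WORDS:
            raise ValueError(f"vocabulary must contain {N_WORDS} words")
    else:
        vocab = make_vocabulary([str(w) for w in vocabulary])
    rng = np.random.default_rng(rng)
    labels = [w.label for w in vocab]

    # AT: 24 targets, each word exactly 3 times, shuffled then split 12/12.
    at_targets = [int(w) for w in rng.permutation(np.repeat(np.arange(N_WORDS), 3))]

    # WM: each set size 4x per block (8x per session).
    wm_sizes = [int(s) for s in rng.permutation(np.repeat(SET_SIZES, 4))] + [
        int(s) for s in rng.permutation(np.repeat(SET_SIZES, 4))
    ]
    wm_trials: list[tuple[tuple[str, ...], int]] = []
    for size in wm_sizes:
        mem = tuple(labels[i] for i in rng.choice(N_WORDS, size=size, replace=False))
        probe = int(rng.integers(1, size + 1))
        wm_trials.append((mem, probe))

    # AR: 24 unique sentences, each of the 8 templates 3 times.
    templates = enumerate_sentence_templates()
    seen: set[tuple] = set()
    sentences: list[Sentence] = []
    for tpl in templates:
        for _ in range(3):
            while True:
                i, j = rng.choice(N_WORDS, size=2, replace=False)
                s = Sentence(labels[int(i)], labels[int(j)], *tpl.template)
                key = (s.noun1, s.noun2, s.template)
                if key not in seen:
                    seen.add(key)
                    sentences.append(s)
                    break
    sentences = [sentences[int(i)] for i in rng.permutation(len(sentences))]

    at_iter = iter(at_targets)
    wm_iter = iter(wm_trials)
    ar_iter = iter(sentences)
    blocks: list[tuple[TrialSpec, ...]] = []
    trial_index = 0
    for block_index, task in enumerate(BLOCK_TASKS):
        reps = _balanced_reps(rng)
        block: list[TrialSpec] = []
        for r in reps:
            stream = generate_stream(r, rng, forbid_immediate_repeats)
            if task == "AT":
                target = next(at_iter)
                block.append(TrialSpec("AT", stream, target, block_index, trial_index))
            elif task == "WM":
                mem, probe = next(wm_iter)
                answer = wm_correct_answer(mem, probe)
                block.append(
                    TrialSpec(
                        "WM", stream, labels.index(answer), block_index, trial_index,
                        memory_set=mem, probe_position=probe,
                    )
                )
            else:
                s = next(ar_iter)
                answer = solve_sentence(s)
                block.append(
                    TrialSpec("AR", stream, labels.index(answer), block_index,
                              trial_index, sentence=s)
                )
            trial_index += 1
        blocks.append(tuple(block))
    return BatterySchedule(vocabulary=vocab, blocks=tuple(blocks))


EVENT_COLUMNS = (
    "onset_s", "duration_s", "word_id", "trial_index", "block_index", "task",
    "is_target", "stream_pos",
)


def schedule_events(
    schedule: BatterySchedule,
    trial_lead_in: float = 1.5,
    inter_trial_gap: float = 1.5,
    tasks: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Timed stimulus table for the session (one row per stream word).

    ``trial_lead_in``/``inter_trial_gap`` pad each stream so that epoch
    windows never cross trial boundaries; they stand in for the instruction
    and rest periods, whose exact durations do not affect the analyses.
    Restricting ``tasks`` compacts the timeline to the retained trials.
    """
    keep = set(tasks) if tasks is not None else {"AT", "WM", "AR"}
    rows = []
    t = 0.0
    slot = schedule.timing.slot
    for trial in schedule.trials:
        if trial.task not in keep:
            continue
        t += trial_lead_in
        for pos, word in enumerate(trial.stream.order):
            rows.append(
                (t, schedule.timing.stimulus_duration, word, trial.trial_index,
                 trial.block_index, trial.task, word == trial.target_word, pos)
            )
            t += slot
        t += inter_trial_gap
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return df.astype({"word_id": int, "trial_index": int, "block_index": int,
                      "is_target": bool, "stream_pos": int})


# -- serialization -----------------------------------------------------------

def schedule_to_json(schedule: BatterySchedule) -> str:
    def trial_dict(t: TrialSpec) -> dict:
        d: dict = {
            "task": t.task,
            "target_word": t.target_word,
            "block_index": t.block_index,
            "trial_index": t.trial_index,
            "stream": {"repetitions": t.stream.repetitions, "order": list(t.stream.order),
                       "isi": t.stream.isi},
        }
        if t.memory_set is not None:
            d["memory_set"] = list(t.memory_set)
            d["probe_position"] = t.probe_position
        if t.sentence is not None:
            s = t.sentence
            d["sentence"] = {"noun1": s.noun1, "noun2": s.noun2, "verb": s.verb,
                             "voice": s.voice, "polarity": s.polarity}
        return d

    doc = {
        "vocabulary": [w.label for w in schedule.vocabulary],
        "timing": {
            "stimulus_duration": schedule.timing.stimulus_duration,
            "isi": schedule.timing.isi,
            "stimuli_per_target": schedule.timing.stimuli_per_target,
            "inter_trial_rest": schedule.timing.inter_trial_rest,
            "wm_delay": schedule.timing.wm_delay,
            "ar_post_response_delay": schedule.timing.ar_post_response_delay,
        },
        "blocks": [[trial_dict(t) for t in block] for block in schedule.blocks],
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def schedule_from_json(text: str) -> BatterySchedule:
    doc = json.loads(text)
    vocab = make_vocabulary(doc["vocabulary"])
    timing = TimingModel(**doc["timing"])

    def parse_trial(d: Mapping) -> TrialSpec:
        stream = StreamSpec(repetitions=d["stream"]["repetitions"],
                            order=tuple(d["stream"]["order"]), isi=d["stream"]["isi"])
        sentence = Sentence(**d["sentence"]) if "sentence" in d else None
        memory_set = tuple(d["memory_set"]) if "memory_set" in d else None
        return TrialSpec(
            task=d["task"], stream=stream, target_word=d["target_word"],
            block_index=d["block_index"], trial_index=d["trial_index"],
            memory_set=memory_set, probe_position=d.get("probe_position"),
            sentence=sentence,
        )

    blocks = tuple(tuple(parse_trial(t) for t in block) for block in doc["blocks"])
    return BatterySchedule(vocabulary=vocab, blocks=blocks, timing=timing)
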