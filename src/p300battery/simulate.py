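"""Forward simulation of a battery session.

Two parts: a behavioral agent that answers WM/AR problems with configurable
accuracy and counts its attended word, and an EEG synthesizer that adds a
posterior-maximal P300b deflection to every stream event whose word matches
the word the agent attended in that trial.  Unattended events add nothing,
so after baseline correction their expected mean is zero — the generative
counterpart of the analysis assumption that non-P300b epochs average out.

The P300b is a raised-cosine half-wave (default peak 4 uV at 450 ms,
300 ms wide) scaled per channel by a fixed centro-parietal topography.
Background noise is AR(1) by default (coefficient 0.95, matching the
low-frequency dominance of resting EEG), with white and pink (1/f)
alternatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .protocol import (
    BatterySchedule,
    REPETITION_CHOICES,
    solve_sentence,
    schedule_events,
)
from .recording import CHANNELS, EEGRecording, events_with_samples

__all__ = [
    "SimulationConfig",
    "BehavioralResponse",
    "simulate_agent",
    "synthesize_recording",
    "simulate_session",
    "DEFAULT_TOPOGRAPHY",
]

#: Qualitative posterior-maximal scalp weighting of the P300b.
DEFAULT_TOPOGRAPHY: dict[str, float] = {
    **{ch: 0.3 for ch in CHANNELS},
    "CP3": 0.6, "CP4": 0.6, "OZ": 0.6,
    "CPZ": 1.0, "PZ": 1.0, "POZ": 1.0,
}

#: Default background-noise standard deviation (uV, continuous signal before
#: band-pass filtering).  Calibrated so that, for a perfectly accurate
#: simulated participant, the single-participant cluster test first reaches
#: p < 0.05 between 50 and 100 attended stimuli (see docs/methods.md).
DEFAULT_NOISE_SD = 10.0


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one simulated participant."""

    p300_amplitude: float = 4.0  # uV, kernel peak
    p300_latency: float = 0.450  # s after word onset
    p300_width: float = 0.300  # s, full support of the raised cosine
    topography: Mapping[str, float] | None = None  # per-channel weights
    noise_sd: float = DEFAULT_NOISE_SD  # uV
    noise_model: str = "ar1"  # "white" | "ar1" | "pink"
    ar_coef: float = 0.95
    accuracy_wm: float | Mapping[int, float] = 1.0  # per set size or scalar
    accuracy_ar: float = 1.0
    count_accuracy: float = 1.0
    sampling_rate: float = 256.0
    trial_lead_in: float = 1.5  # s of padding before each stream
    inter_trial_gap: float = 1.5  # s of padding after each stream

    def __post_init__(self) -> None:
        for p in (self.accuracy_ar, self.count_accuracy, *(
            self.accuracy_wm.values() if isinstance(self.accuracy_wm, Mapping)
            else [self.accuracy_wm]
        )):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.noise_model not in ("white", "ar1", "pink"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    def wm_accuracy(self, set_size: int) -> float:
        if isinstance(self.accuracy_wm, Mapping):
            return self.accuracy_wm[set_size]
        return self.accuracy_wm

    def channel_weights(self, channels: Sequence[str] = CHANNELS) -> np.ndarray:
        topo = dict(DEFAULT_TOPOGRAPHY if self.topography is None else self.topography)
        return np.array([topo[ch] for ch in channels], dtype=float)


@dataclass(frozen=True)
class BehavioralResponse:
    """What the agent did on one trial."""

    trial_index: int
    task: str
    attended_word: int  # word_id the agent counted
    answer_word: str  # label of the reported answer (equals the counted word)
    reported_count: int
    correct: bool  # answer matches the trial's true target


def simulate_agent(
    schedule: BatterySchedule,
    cfg: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> list[BehavioralResponse]:
    """Behavioral pass over the session.

    AT: the agent always attends the given target.  WM: it recalls the
    probed word with probability ``accuracy_wm(set size)``, otherwise
    reports a uniformly chosen other member of the memory set.  AR: it
    solves the sentence with probability ``accuracy_ar``, otherwise reports
    the other noun.  The agent then counts the word it answered, reporting
    the true count with probability ``count_accuracy`` (else off by one
    within the offered 7-10 options).
    """
    rng = np.random.default_rng(rng)
    labels = schedule.labels
    out: list[BehavioralResponse] = []
    for trial in schedule.trials:
        correct_label = labels[trial.target_word]
        if trial.task == "AT":
            answer = correct_label
        elif trial.task == "WM":
            acc = cfg.wm_accuracy(len(trial.memory_set))
            if rng.random() < acc:
                answer = correct_label
            else:
                others = [w for w in trial.memory_set if w != correct_label]
                answer = others[int(rng.integers(len(others)))]
        else:
            if rng.random() < cfg.accuracy_ar:
                answer = correct_label
            else:
                s = trial.sentence
                answer = s.noun2 if solve_sentence(s) == s.noun1 else s.noun1
        true_count = trial.stream.repetitions
        if rng.random() < cfg.count_accuracy:
            count = true_count
        else:
            options = [c for c in (true_count - 1, true_count + 1)
                       if c in REPETITION_CHOICES]
            count = options[int(rng.integers(len(options)))]
        out.append(
            BehavioralResponse(
                trial_index=trial.trial_index, task=trial.task,
                attended_word=labels.index(answer), answer_word=answer,
                reported_count=count, correct=answer == correct_label,
            )
        )
    return out


def _p300_kernel(cfg: SimulationConfig) -> tuple[int, np.ndarray]:
    """Sampled raised-cosine half-wave; returns (onset sample offset, kernel)."""
    fs = cfg.sampling_rate
    start = math.floor((cfg.p300_latency - cfg.p300_width / 2) * fs)
    stop = math.ceil((cfg.p300_latency + cfg.p300_width / 2) * fs)
    t = np.arange(start, stop + 1) / fs
    phase = np.pi * (t - cfg.p300_latency) / cfg.p300_width
    k = cfg.p300_amplitude * np.cos(phase) ** 2
    k[np.abs(t - cfg.p300_latency) > cfg.p300_width / 2] = 0.0
    return start, k


def _noise(cfg: SimulationConfig, shape: tuple[int, int],
           rng: np.random.Generator) -> np.ndarray:
    n_ch, n_samp = shape
    if cfg.noise_sd == 0:
        return np.zeros(shape)
    if cfg.noise_model == "white":
        return rng.normal(0.0, cfg.noise_sd, shape)
    if cfg.noise_model == "ar1":
        phi = cfg.ar_coef
        burn = 500
        e = rng.normal(0.0, cfg.noise_sd * math.sqrt(1 - phi * phi),
                       (n_ch, n_samp + burn)).astype(np.float32)
        x = lfilter([1.0], [1.0, -phi], e, axis=1)
        return x[:, burn:]
    # pink: shape white noise by 1/sqrt(f), rescale to noise_sd
    w = rng.normal(0.0, 1.0, (n_ch, n_samp))
    spec = np.fft.rfft(w, axis=1)
    f = np.fft.rfftfreq(n_samp, 1.0 / cfg.sampling_rate)
    f[0] = f[1]
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n=n_samp, axis=1)
    x *= cfg.noise_sd / x.std(axis=1, keepdims=True)
    return x


def synthesize_recording(
    schedule: BatterySchedule,
    responses: Sequence[BehavioralResponse],
    cfg: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    tasks: Sequence[str] | None = None,
) -> EEGRecording:
    """Continuous 16-channel EEG for the session.

    Every stream event whose word equals the trial's attended word receives
    the P300b kernel scaled by the channel topography; all other events add
    nothing.  ``tasks`` optionally restricts (and compacts) the session to a
    subset of tasks.
    """
    rng = np.random.default_rng(rng)
    fs = cfg.sampling_rate
    events = schedule_events(schedule, trial_lead_in=cfg.trial_lead_in,
                             inter_trial_gap=cfg.inter_trial_gap, tasks=tasks)
    if not len(events):
        raise ValueError("no events to synthesize")
    events = events_with_samples(events, fs)
    n_samples = int(events["sample_index"].iloc[-1]
                    + round((1.0 + cfg.inter_trial_gap) * fs))
    data = _noise(cfg, (len(CHANNELS), n_samples), rng).astype(np.float32)

    attended = {r.trial_index: r.attended_word for r in responses}
    offset, kernel = _p300_kernel(cfg)
    weights = cfg.channel_weights()
    bump = np.outer(weights, kernel).astype(np.float32)
    hit = events["word_id"].to_numpy() == events["trial_index"].map(attended).to_numpy()
    for s in events.loc[hit, "sample_index"].to_numpy():
        lo = s + offset
        data[:, lo:lo + kernel.size] += bump
    return EEGRecording(data=data, sfreq=fs, events=events)


def simulate_session(
    schedule: BatterySchedule,
    cfg: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    tasks: Sequence[str] | None = None,
) -> tuple[list[BehavioralResponse], EEGRecording]:
    """Agent pass plus EEG synthesis from a single random state."""
    rng = np.random.default_rng(rng)
    responses = simulate_agent(schedule, cfg, rng)
    recording = synthesize_recording(schedule, responses, cfg, rng, tasks=tasks)
    return responses, recording


def behavior_table(responses: Sequence[BehavioralResponse]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_index": [r.trial_index for r in responses],
            "task": [r.task for r in responses],
            "attended_word": [r.attended_word for r in responses],
            "answer_word": [r.answer_word for r in responses],
            "reported_count": [r.reported_count for r in responses],
            "correct": [r.correct for r in responses],
        }
    )


def config_with(cfg: SimulationConfig, **kwargs) -> SimulationConfig:
    """Convenience wrapper around dataclasses.replace."""
    return replace(cfg, **kwargs)
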