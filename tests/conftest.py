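"""Shared fixtures: schedules, simulated sessions, adjacency."""

from __future__ import annotations

import numpy as np
import pytest

import p300battery as pb
from p300battery.cmpt import build_adjacency
from p300battery.io import preprocess_recording


@pytest.fixture(scope="session")
def adjacency():
    return build_adjacency()


@pytest.fixture(scope="session")
def schedule():
    return pb.build_schedule(rng=12345)


@pytest.fixture(scope="session")
def clean_session(schedule):
    """A noiseless simulated session (AT + WM), preprocessed.

    Noiseless data make injected-signal bookkeeping exact; artifact
    rejection is skipped because the z-scored statistics are undefined on
    identical epochs.
    """
    cfg = pb.SimulationConfig(noise_sd=0.0, accuracy_wm=1.0)
    responses, recording = pb.simulate_session(schedule, cfg, 7, tasks=("AT", "WM"))
    epochs = pb.baseline_correct(pb.extract_epochs(pb.bandpass(recording)))
    return schedule, responses, epochs


@pytest.fixture(scope="session")
def noisy_session(schedule):
    """A realistic session at default SNR with an imperfect agent."""
    cfg = pb.SimulationConfig(accuracy_wm={4: 0.95, 6: 0.8, 8: 0.6}, accuracy_ar=0.95)
    responses, recording = pb.simulate_session(schedule, cfg, 11)
    epochs, report = preprocess_recording(recording)
    return schedule, responses, epochs, report
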