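"""On-disk formats and the end-to-end pipeline.

Continuous EEG travels as EDF (16 channels, 256 Hz, physical units uV);
events and behavioral logs as tab-separated tables; epoch sets as an HDF5
container (/data, /times, /channels, /metadata).  All outputs are
deterministic for a fixed config and seed: the EDF start date is a fixed
epoch and result JSON is written with sorted keys, so reruns are
byte-identical.

The EDF writer is a minimal implementation of the published EDF header and
16-bit sample layout; reading goes through :func:`mne.io.read_raw_edf`,
which also serves as an independent cross-check of the writer in the test
suite.
"""

from __future__ import annotations

import hashlib
import io
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .binning import bin_attended_by_behavior, bin_task
from .cmpt import build_adjacency, permutation_test
from .individual_differences import (
    compute_nm,
    glm_performance,
    per_setsize_correlation,
    records_frame,
)
from .monte_carlo import MonteCarloConfig, curves_frame, mc_curve
from .preprocess import (
    ArtifactCriteria,
    EpochSet,
    average_erp,
    bandpass,
    baseline_correct,
    extract_epochs,
    reject_artifacts,
)
from .protocol import build_schedule
from .recording import CHANNELS, EEGRecording, events_with_samples
from .simulate import (
    BehavioralResponse,
    SimulationConfig,
    behavior_table,
    simulate_session,
)

__all__ = [
    "write_edf",
    "read_edf",
    "write_events",
    "read_events",
    "write_behavior",
    "read_behavior",
    "save_epochs",
    "load_epochs",
    "RunConfig",
    "run_pipeline",
]

_EDF_EPOCH = ("01.01.00", "00.00.00")  # fixed start stamp for reproducibility


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(recording: EEGRecording, path: str | Path,
              patient_id: str = "X", recording_id: str = "synthetic") -> Path:
    """Write continuous EEG as 16-bit EDF with 1-second data records.

    The final partial record is zero-padded; physical ranges are per-channel
    data extrema, so quantization error is at most (max-min)/65535 uV.
    """
    path = Path(path)
    fs = recording.sfreq
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(fs))  # samples per record per signal
    data = np.asarray(recording.data, dtype=float)
    ns, n_samples = data.shape
    n_records = -(-n_samples // spr)

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min < 1e-6
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0
    dig_min, dig_max = -32768, 32767
    gain = (phys_max - phys_min) / (dig_max - dig_min)

    header = b"".join([
        _pad("0", 8),
        _pad(patient_id, 80),
        _pad(recording_id, 80),
        _pad(_EDF_EPOCH[0], 8),
        _pad(_EDF_EPOCH[1], 8),
        _pad(str(256 * (ns + 1)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])
    fields = [
        [_pad(ch, 16) for ch in recording.channels],
        [_pad("AgAgCl electrode", 80)] * ns,
        [_pad("uV", 8)] * ns,
        [_pad(f"{v:.3f}"[:8], 8) for v in phys_min],
        [_pad(f"{v:.3f}"[:8], 8) for v in phys_max],
        [_pad(str(dig_min), 8)] * ns,
        [_pad(str(dig_max), 8)] * ns,
        [_pad("BP 0.1-100 Hz", 80)] * ns,
        [_pad(str(spr), 8)] * ns,
        [_pad("", 32)] * ns,
    ]
    padded = np.zeros((ns, n_records * spr))
    padded[:, :n_samples] = data
    digital = np.rint(
        (padded - phys_min[:, None]) / gain[:, None] + dig_min
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(b"".join(f))
        for rec in range(n_records):
            fh.write(digital[:, rec * spr:(rec + 1) * spr].tobytes())
    return path


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file and normalize channels to the 16-electrode montage.

    Unknown extra channels are dropped with a warning; missing montage
    channels are a hard error.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    have = {name.upper().strip(): name for name in raw.ch_names}
    missing = [ch for ch in CHANNELS if ch not in have]
    if missing:
        raise ValueError(f"EDF is missing montage channels: {missing}")
    extras = [name for name in raw.ch_names if name.upper().strip() not in CHANNELS]
    if extras:
        warnings.warn(f"dropping unknown channels {extras}")
    picks = [have[ch] for ch in CHANNELS]
    data = raw.get_data(picks=picks) * 1e6  # V -> uV
    return EEGRecording(data=data, sfreq=float(raw.info["sfreq"]))


REQUIRED_EVENT_COLUMNS = ("onset_s", "word_id", "trial_index", "block_index", "task")


def write_events(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = [c for c in events.columns if c != "sample_index"]
    events[cols].to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path, sfreq: float | None = None) -> pd.DataFrame:
    """Parse an events TSV; onsets must be strictly increasing and unique."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events file lacks required columns {missing}")
    onsets = df["onset_s"].to_numpy()
    if (np.diff(onsets) <= 0).any():
        raise ValueError("event onsets must be strictly increasing and unique")
    if sfreq is not None:
        df = events_with_samples(df, sfreq)
    return df


def write_behavior(responses: Sequence[BehavioralResponse] | pd.DataFrame,
                   path: str | Path) -> Path:
    df = responses if isinstance(responses, pd.DataFrame) else behavior_table(responses)
    df.to_csv(Path(path), sep="\t", index=False)
    return Path(path)


def read_behavior(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "trial_index" not in df.columns or "attended_word" not in df.columns:
        raise ValueError("behavior file needs trial_index and attended_word columns")
    return df


def save_epochs(epochs: EpochSet, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip", shuffle=True)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("channels",
                         data=np.array(epochs.channels, dtype="S8"))
        f.create_dataset(
            "metadata",
            data=np.frombuffer(
                epochs.metadata.to_json(orient="records").encode(), dtype=np.uint8
            ),
        )
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["baseline_corrected"] = epochs.baseline_corrected
        f.attrs["n_dropped"] = epochs.n_dropped
    return path


def load_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        meta = pd.read_json(io.StringIO(bytes(f["metadata"][()]).decode()))
        return EpochSet(
            data=f["data"][()],
            times=f["times"][()],
            channels=tuple(c.decode() for c in f["channels"][()]),
            sfreq=float(f.attrs["sfreq"]),
            metadata=meta,
            baseline_corrected=bool(f.attrs["baseline_corrected"]),
            n_dropped=int(f.attrs["n_dropped"]),
        )


# -- pipeline ---------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full pipeline run."""

    seed: int = 0
    n_participants: int = 1
    tasks: tuple[str, ...] = ("AT", "WM", "AR")
    simulation: Mapping = field(default_factory=dict)  # SimulationConfig overrides
    cmpt_n_perm: int = 1000
    alpha: float = 0.05
    adjacency_threshold: float = 0.6
    run_nm: bool = False
    monte_carlo: Mapping | None = None  # MonteCarloConfig overrides, or None
    write_edf_files: bool = False

    def __post_init__(self) -> None:
        if not self.tasks:
            raise ValueError("no tasks selected")
        if any(t not in ("AT", "WM", "AR") for t in self.tasks):
            raise ValueError(f"unknown task in {self.tasks}")
        if self.run_nm and not {"AT", "WM"} <= set(self.tasks):
            raise ValueError("NM analysis requires both AT and WM tasks")
        if self.n_participants < 1:
            raise ValueError("need at least one participant")

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        doc = json.loads(text)
        if "tasks" in doc:
            doc["tasks"] = tuple(doc["tasks"])
        return cls(**doc)

    def to_json(self) -> str:
        d = asdict(self)
        d["tasks"] = list(self.tasks)
        return json.dumps(d, indent=1, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(doc: dict, path: Path) -> None:
    path.write_text(json.dumps(doc, indent=1, sort_keys=True,
                               default=_json_default) + "\n")


def preprocess_recording(
    recording: EEGRecording,
    criteria: ArtifactCriteria | None = None,
) -> tuple[EpochSet, dict]:
    """Filter -> epoch -> baseline-correct -> artifact-reject."""
    filtered = bandpass(recording)
    epochs = baseline_correct(extract_epochs(filtered))
    return reject_artifacts(epochs, criteria)


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Simulate, preprocess, analyze, and persist one battery study.

    Per participant: a fresh schedule and simulated session, preprocessing,
    and a single-participant cluster test per selected task.  With two or
    more participants a group-level test per task follows; the NM analysis
    (if enabled) uses the attention task's largest significant cluster as
    its region; the Monte Carlo analysis (if configured) averages mean-p
    curves within participants, then across them.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    adjacency = build_adjacency(threshold=cfg.adjacency_threshold)
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_participants)
    sim_cfg = SimulationConfig(**dict(cfg.simulation))

    results: dict = {"participants": {}, "group": {}, "config_hash": cfg.config_hash,
                     "version": __version__, "seed": cfg.seed}
    erps_by_task: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {
        t: [] for t in cfg.tasks}
    per_participant = []

    for p, seed in enumerate(seeds):
        pid = f"p{p:02d}"
        rng = np.random.default_rng(seed)
        schedule = build_schedule(rng=rng)
        responses, recording = simulate_session(schedule, sim_cfg, rng,
                                                tasks=cfg.tasks)
        if cfg.write_edf_files:
            write_edf(recording, out / f"{pid}.edf", patient_id=pid)
            write_events(recording.events, out / f"{pid}_events.tsv")
            write_behavior(responses, out / f"{pid}_behavior.tsv")
        epochs, reject_report = preprocess_recording(recording)
        post = epochs.times >= 0

        pres: dict = {"rejection": reject_report, "tasks": {}}
        for task in cfg.tasks:
            b = bin_task(epochs, schedule, task)
            res = permutation_test(
                epochs.data[b.positive][:, :, post],
                epochs.data[b.negative][:, :, post],
                level="single", n_perm=cfg.cmpt_n_perm,
                rng=np.random.default_rng(seed.spawn(1)[0]),
                adjacency=adjacency, alpha=cfg.alpha,
            )
            pres["tasks"][task] = res.to_dict(times=epochs.times[post])
            erps_by_task[task].append(
                (epochs.data[b.positive][:, :, post].mean(axis=0),
                 epochs.data[b.negative][:, :, post].mean(axis=0))
            )
        results["participants"][pid] = pres
        per_participant.append((pid, schedule, responses, epochs))

    post_times = per_participant[0][3].times[per_participant[0][3].times >= 0]
    group_regions: dict[str, tuple] = {}
    if cfg.n_participants >= 2:
        for task in cfg.tasks:
            pos = np.stack([e[0] for e in erps_by_task[task]])
            neg = np.stack([e[1] for e in erps_by_task[task]])
            res = permutation_test(
                pos, neg, level="group", n_perm=cfg.cmpt_n_perm,
                rng=np.random.default_rng(cfg.seed + 7919),
                adjacency=adjacency, alpha=cfg.alpha,
            )
            results["group"][task] = res.to_dict(times=post_times)
            if res.selected_region is not None:
                group_regions[task] = res.selected_region

    if cfg.run_nm:
        results["nm"] = _nm_analysis(per_participant, group_regions, cfg,
                                     adjacency, out)

    if cfg.monte_carlo is not None:
        results["monte_carlo"] = _mc_analysis(per_participant, cfg, adjacency, out)

    _write_json(results, out / "results.json")
    _write_json({"config": json.loads(cfg.to_json()), "hash": cfg.config_hash,
                 "version": __version__}, out / "manifest.json")
    return results


def _nm_analysis(per_participant, group_regions, cfg, adjacency, out: Path) -> dict:
    from .binning import restrict_set_sizes

    records = []
    for pid, schedule, responses, epochs in per_participant:
        post = epochs.times >= 0
        region = group_regions.get("AT")
        if region is None:
            # single participant: fall back to that participant's own AT cluster
            b = bin_task(epochs, schedule, "AT")
            res = permutation_test(
                epochs.data[b.positive][:, :, post],
                epochs.data[b.negative][:, :, post],
                level="single", n_perm=cfg.cmpt_n_perm,
                rng=np.random.default_rng(cfg.seed + 104729),
                adjacency=adjacency, alpha=cfg.alpha,
            )
            if res.selected_region is None:
                continue
            region = res.selected_region

        sub = epochs.crop(post)
        at_bin = bin_task(sub, schedule, "AT")
        attended_erp = average_erp(sub, at_bin.positive, "attended")
        by_trial = {r.trial_index: r for r in responses}
        correct_erps, performance = {}, {}
        for size in (4, 6, 8):
            trials = restrict_set_sizes(schedule.trials, {size})
            b = bin_task(sub, schedule, "WM", trials=trials)
            correct_erps[size] = average_erp(sub, b.positive, f"correct-{size}")
            performance[size] = float(
                np.mean([by_trial[t.trial_index].correct for t in trials])
            )
        records.extend(compute_nm(attended_erp, correct_erps, region,
                                  performance, participant=pid))

    doc: dict = {"n_records": len(records)}
    if records:
        records_frame(records).to_csv(out / "nm_records.tsv", sep="\t", index=False)
        doc["records"] = [vars(r) for r in records]
        try:
            glm = glm_performance(records)
            doc["glm"] = {name: vars(t) for name, t in glm.terms.items()}
        except ValueError as err:
            doc["glm_error"] = str(err)
        doc["correlations"] = {}
        for size in (4, 6, 8):
            try:
                r, p = per_setsize_correlation(records, size)
                doc["correlations"][str(size)] = {"r": r, "p": p}
            except ValueError as err:
                doc["correlations"][str(size)] = {"error": str(err)}
    return doc


def _mc_analysis(per_participant, cfg, adjacency, out: Path) -> dict:
    mc_cfg = MonteCarloConfig(seed=cfg.seed, **dict(cfg.monte_carlo))
    per_curves = []
    for pid, schedule, responses, epochs in per_participant:
        post = epochs.times >= 0
        b = bin_attended_by_behavior(epochs, responses)
        curves = mc_curve(epochs.data[b.positive][:, :, post],
                          epochs.data[b.negative][:, :, post],
                          mc_cfg, adjacency)
        frame = curves_frame(curves)
        frame.insert(0, "participant", pid)
        per_curves.append(frame)
    allc = pd.concat(per_curves, ignore_index=True)
    allc.to_csv(out / "mc_curves.tsv", sep="\t", index=False)
    mean_across = (
        allc.groupby(["accuracy", "n"], as_index=False)["mean_p"].mean()
    )
    return {"mean_p": mean_across.to_dict(orient="list")}
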