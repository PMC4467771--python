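"""Continuous multichannel EEG container shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 16-electrode 10-10 montage, in acquisition order.
CHANNELS: tuple[str, ...] = (
    "FC3", "C3", "CP3", "FCZ", "CZ", "CPZ", "FC4", "C4", "CP4",
    "T7", "T8", "PZ", "POZ", "OZ", "P7", "P8",
)

DEFAULT_SFREQ = 256.0


@dataclass
class EEGRecording:
    """Continuous EEG: channels x samples in microvolts, plus stimulus events.

    ``events`` is a table with at least ``sample_index`` and ``word_id``
    columns (plus trial metadata); sample indices must be strictly
    increasing and inside the data bounds.
    """

    data: np.ndarray  # (n_channels, n_samples), microvolts
    sfreq: float = DEFAULT_SFREQ
    channels: tuple[str, ...] = CHANNELS
    events: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data must be ({len(self.channels)}, n_samples), got {self.data.shape}"
            )
        if len(self.events):
            s = self.events["sample_index"].to_numpy()
            if (np.diff(s) <= 0).any():
                raise ValueError("event sample indices must be strictly increasing")
            if s[0] < 0 or s[-1] >= self.n_samples:
                raise ValueError("event sample indices outside data bounds")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        return EEGRecording(data=data, sfreq=self.sfreq, channels=self.channels,
                           events=self.events.copy())


def events_with_samples(events: pd.DataFrame, sfreq: float) -> pd.DataFrame:
    """Attach integer ``sample_index`` derived from ``onset_s``."""
    out = events.copy()
    out["sample_index"] = np.rint(out["onset_s"].to_numpy() * sfreq).astype(int)
    return out
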