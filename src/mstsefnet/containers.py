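"""Core data containers shared across the pipeline.

``EpochedEEG`` (trials × channels × samples plus labels) is the common
currency: the synthetic generator produces it, the preprocessing module
reduces continuous recordings to it, and the network consumes it.
Epoch sets round-trip through a plain directory format — one ``.npy``
array per field plus a JSON sidecar with labels, sampling rate and
channel names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["EpochedEEG", "ContinuousRecording", "save_epochs", "load_epochs"]


@dataclass
class EpochedEEG:
    """Epoched multichannel EEG: ``data`` is (n_trials, n_channels, n_samples)."""

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str]
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D, got shape {self.data.shape}")
        if self.data.shape[0] != self.labels.shape[0]:
            raise ValueError("labels length must match the trial axis")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length must match the channel axis")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.labels.size and self.class_names:
            if self.labels.min() < 0 or self.labels.max() >= len(self.class_names):
                raise ValueError("labels out of range for class_names")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names) if self.class_names else (
            int(self.labels.max()) + 1 if self.labels.size else 0)

    def select(self, indices) -> "EpochedEEG":
        idx = np.asarray(indices)
        return EpochedEEG(self.data[idx], self.labels[idx], self.fs,
                          list(self.channel_names), list(self.class_names))


@dataclass
class ContinuousRecording:
    """A continuous multichannel recording with cue events.

    ``events`` is a list of ``(sample_index, event_code)`` pairs, sample
    indices 0-based into the time axis.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels × time), got {self.data.shape}")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match channel axis")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n = self.data.shape[1]
        for s, _ in self.events:
            if not 0 <= s < n:
                raise ValueError(f"event sample index {s} outside [0, {n})")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def pick_channels(self, names: list[str]) -> "ContinuousRecording":
        missing = [n for n in names if n not in self.channel_names]
        if missing:
            raise ValueError(f"channels not present: {missing}")
        idx = [self.channel_names.index(n) for n in names]
        return ContinuousRecording(self.data[idx], self.fs, list(names), list(self.events))


def save_epochs(epochs: EpochedEEG, out_dir: str | Path) -> Path:
    """Write an epoch set as ``data.npy`` + ``meta.json``; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.save(out / "data.npy", epochs.data)
    meta = {
        "labels": epochs.labels.tolist(),
        "fs": float(epochs.fs),
        "channel_names": list(epochs.channel_names),
        "class_names": list(epochs.class_names),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    return out


def load_epochs(in_dir: str | Path) -> EpochedEEG:
    src = Path(in_dir)
    if not (src / "meta.json").exists():
        raise FileNotFoundError(f"no meta.json under {src}")
    meta = json.loads((src / "meta.json").read_text())
    data = np.load(src / "data.npy")
    return EpochedEEG(data, np.asarray(meta["labels"], dtype=np.int64), meta["fs"],
                      meta["channel_names"], meta.get("class_names", []))
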