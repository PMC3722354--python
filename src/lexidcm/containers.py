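"""Sensor-space data containers and their HDF5 serialization.

Epochs are stored as trials x sensors x time arrays at a 480 Hz grid over a
peristimulus window (default -100..1000 ms), with a condition label per trial
and a provenance note recording the cleaning status of the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["EpochSet", "Evoked", "GFPSeries", "save_epochs", "load_epochs"]

DEFAULT_SFREQ = 480.0


@dataclass
class EpochSet:
    """Trial-level sensor data: (n_trials, n_sensors, n_times)."""

    data: np.ndarray
    times_ms: np.ndarray
    conditions: list[str]  # one label per trial
    dt: float = 1.0 / DEFAULT_SFREQ
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.times_ms = np.asarray(self.times_ms, float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x sensors x time")
        if self.data.shape[0] != len(self.conditions):
            raise ValueError("one condition label per trial required")
        if self.data.shape[2] != self.times_ms.size:
            raise ValueError("time axis mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    def select(self, condition: str) -> "EpochSet":
        idx = [i for i, c in enumerate(self.conditions) if c == condition]
        if not idx:
            raise ValueError(f"no trials with condition {condition!r}")
        return EpochSet(
            self.data[idx], self.times_ms, [condition] * len(idx), self.dt, self.provenance
        )

    def prestim_mask(self) -> np.ndarray:
        return self.times_ms < 0


@dataclass
class Evoked:
    """Averaged sensor data: (n_sensors, n_times), with the robust weights
    (trials x time, averaged over sensors) that produced it."""

    data: np.ndarray
    times_ms: np.ndarray
    condition: str
    weights: np.ndarray | None = None
    dt: float = 1.0 / DEFAULT_SFREQ

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.times_ms = np.asarray(self.times_ms, float)
        if self.data.ndim != 2 or self.data.shape[1] != self.times_ms.size:
            raise ValueError("evoked data must be sensors x time matching times")

    def crop(self, tmin_ms: float, tmax_ms: float) -> "Evoked":
        m = (self.times_ms >= tmin_ms - 1e-9) & (self.times_ms <= tmax_ms + 1e-9)
        return Evoked(self.data[:, m], self.times_ms[m], self.condition, None, self.dt)


@dataclass
class GFPSeries:
    """Global field power: sum over sensors of squared amplitude per sample."""

    values: np.ndarray
    times_ms: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.times_ms = np.asarray(self.times_ms, float)
        if self.values.shape != self.times_ms.shape:
            raise ValueError("GFP values and times must align")


def save_epochs(path, epochs: EpochSet, extra: dict[str, np.ndarray] | None = None) -> None:
    """Write an EpochSet to HDF5 (/epochs, /times, /labels [+ extras])."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("epochs", data=epochs.data)
        fh.create_dataset("times", data=epochs.times_ms)
        fh.create_dataset(
            "labels", data=np.array(epochs.conditions, dtype=h5py.string_dtype())
        )
        fh.attrs["dt"] = epochs.dt
        fh.attrs["provenance"] = epochs.provenance
        for k, v in (extra or {}).items():
            fh.create_dataset(k, data=v)


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as fh:
        return EpochSet(
            data=fh["epochs"][()],
            times_ms=fh["times"][()],
            conditions=[s.decode() if isinstance(s, bytes) else str(s) for s in fh["labels"][()]],
            dt=float(fh.attrs["dt"]),
            provenance=str(fh.attrs.get("provenance", "raw")),
        )
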