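"""Shared in-memory containers and HDF5 serialization.

The central container is :class:`EpochSet`, a trials x channels x time
array of EEG voltage (microvolt) with per-trial metadata, carried through
every stage of the pipeline (epoching, filtering, artifact screening,
decomposition, condition statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

__all__ = ["EpochSet", "read_epochs_h5", "write_epochs_h5"]

#: valid lock types for an EpochSet
LOCKS = ("stimulus", "response_onset", "response_offset")


@dataclass
class EpochSet:
    """Epoched multichannel signal.

    Parameters
    ----------
    data
        Array of shape (n_trials, n_channels, n_times), microvolt.
    times
        Time axis in ms relative to the lock event, strictly increasing.
    channels
        Channel labels, one per data row.
    sfreq
        Sampling rate in Hz.
    lock
        One of ``stimulus``, ``response_onset``, ``response_offset``.
    metadata
        One row per trial (accuracy, rt, rd, latencies, ...).
    """

    data: np.ndarray
    times: np.ndarray
    channels: list[str]
    sfreq: float
    lock: str
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, times)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel count mismatch")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis mismatch")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("time axis must be strictly increasing")
        if self.lock not in LOCKS:
            raise ValueError(f"unknown lock {self.lock!r}")
        if len(self.metadata) not in (0, self.n_trials):
            raise ValueError("metadata rows must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean mask for times in the closed window [start, end] ms."""
        lo, hi = window
        return (self.times >= lo) & (self.times <= hi)

    def select_trials(self, index) -> "EpochSet":
        index = np.asarray(index)
        meta = self.metadata
        if len(meta):
            meta = meta.iloc[index].reset_index(drop=True)
        return replace(self, data=self.data[index], metadata=meta)

    def select_channels(self, names: list[str]) -> "EpochSet":
        idx = [self.channel_index(n) for n in names]
        return replace(self, data=self.data[:, idx, :], channels=list(names))

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(), metadata=self.metadata.copy())


def write_epochs_h5(path, epochs: EpochSet) -> None:
    """Write an EpochSet to an HDF5 container (datasets: data, times, channels)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset(
            "channels", data=np.array(epochs.channels, dtype=h5py.string_dtype())
        )
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["lock"] = epochs.lock
        g = f.create_group("metadata")
        for col in epochs.metadata.columns:
            vals = epochs.metadata[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype(str).astype(h5py.string_dtype())
            g.create_dataset(col, data=vals)


def read_epochs_h5(path) -> EpochSet:
    """Read an EpochSet written by :func:`write_epochs_h5`."""
    with h5py.File(path, "r") as f:
        meta = {}
        for col, ds in f["metadata"].items():
            vals = ds[()]
            if vals.dtype.kind in ("S", "O"):
                vals = np.array([v.decode() if isinstance(v, bytes) else v for v in vals])
            meta[col] = vals
        return EpochSet(
            data=f["data"][()],
            times=f["times"][()],
            channels=[c.decode() if isinstance(c, bytes) else c for c in f["channels"][()]],
            sfreq=float(f.attrs["sfreq"]),
            lock=str(f.attrs["lock"]),
            metadata=pd.DataFrame(meta),
        )
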