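"""Central data containers: epoched multi-channel voltage data and its
HDF5 serialization.

`EpochSet` is the unit every pipeline stage consumes and returns:
trials x channels x time in microvolts, one shared time axis, per-trial
condition labels, and the cap geometry needed for adjacency and
topographic plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

CONDITIONS = ("standard", "deviant", "target")


@dataclass
class EpochSet:
    """Epoched EEG data.

    Parameters
    ----------
    data:
        ``(n_trials, n_channels, n_times)`` voltages in μV.
    sampling_rate_hz:
        Sampling rate of the shared time axis.
    t0_offset_ms:
        Latency of the first sample relative to stimulus onset
        (−300 for the standard −300..600 ms epoch).
    condition:
        Per-trial label, one of ``standard``/``deviant``/``target``.
    channel_names, channel_positions:
        Cap labels and 2-D (or 3-D) coordinates.
    event_ids:
        Optional index of each trial's event in the generating stimulus
        schedule; used for deviant/preceding-standard trial matching.
    """

    data: np.ndarray
    sampling_rate_hz: float
    t0_offset_ms: float
    condition: np.ndarray
    channel_names: list[str]
    channel_positions: np.ndarray
    event_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, times)")
        self.condition = np.asarray(self.condition, dtype=object)
        bad = set(self.condition) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        if len(self.condition) != self.n_trials:
            raise ValueError("one condition label per trial required")
        if len(self.channel_names) != self.n_channels:
            raise ValueError("one channel name per channel required")
        if self.event_ids is not None:
            self.event_ids = np.asarray(self.event_ids, dtype=int)

    # -- basic geometry -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Time axis in ms relative to stimulus onset."""
        step = 1000.0 / self.sampling_rate_hz
        return self.t0_offset_ms + step * np.arange(self.n_times)

    # -- selection ------------------------------------------------------
    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not present; available: {self.channel_names}"
            ) from None

    def select_trials(self, mask_or_index: np.ndarray) -> "EpochSet":
        idx = np.asarray(mask_or_index)
        return replace(
            self,
            data=self.data[idx],
            condition=self.condition[idx],
            event_ids=None if self.event_ids is None else self.event_ids[idx],
        )

    def pick_condition(self, label: str) -> "EpochSet":
        if label not in CONDITIONS:
            raise ValueError(f"unknown condition {label!r}")
        return self.select_trials(self.condition == label)

    # -- I/O ------------------------------------------------------------
    def to_hdf5(self, path: str | Path) -> None:
        """Write the documented HDF5 container (datasets ``data``,
        ``times_ms``, ``condition``, ``channel_positions``; attrs
        ``sampling_rate_hz``, ``units``)."""
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("times_ms", data=self.times_ms)
            f.create_dataset(
                "condition", data=np.array([str(c) for c in self.condition], dtype="S")
            )
            f.create_dataset(
                "channel_names", data=np.array(self.channel_names, dtype="S")
            )
            f.create_dataset("channel_positions", data=self.channel_positions)
            if self.event_ids is not None:
                f.create_dataset("event_ids", data=self.event_ids)
            f.attrs["sampling_rate_hz"] = self.sampling_rate_hz
            f.attrs["t0_offset_ms"] = self.t0_offset_ms
            f.attrs["units"] = "uV"

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            event_ids = f["event_ids"][...] if "event_ids" in f else None
            return cls(
                data=f["data"][...],
                sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
                t0_offset_ms=float(f.attrs["t0_offset_ms"]),
                condition=np.array([s.decode() for s in f["condition"][...]], dtype=object),
                channel_names=[s.decode() for s in f["channel_names"][...]],
                channel_positions=f["channel_positions"][...],
                event_ids=event_ids,
            )

    def epoch_to_csv(self, trial: int, path: str | Path) -> None:
        """Plain-text export of one epoch (columns: time_ms, then one
        column per channel), for small fixtures and inspection."""
        header = "time_ms," + ",".join(self.channel_names)
        table = np.column_stack([self.times_ms, self.data[trial].T])
        np.savetxt(path, table, delimiter=",", header=header, comments="")
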