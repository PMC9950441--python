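"""Epoched EEG container shared by the simulation, preprocessing and statistics layers."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Default sampling rate of the analysis pipeline, Hz.
FS_DEFAULT = 128.0
#: Default epoch window relative to movement onset, seconds.
EPOCH_WINDOW = (-1.0, 2.0)


def default_times(fs: float = FS_DEFAULT, window: tuple[float, float] = EPOCH_WINDOW) -> np.ndarray:
    """Time axis in seconds, sample-aligned so that t=0 is an exact sample."""
    lo = int(round(window[0] * fs))
    hi = int(round(window[1] * fs))
    return np.arange(lo, hi + 1) / fs


@dataclass
class EpochArray:
    """Trials x channels x samples voltage tensor time-locked to movement onset.

    data is in microvolts.  ``metadata`` carries one row per trial with at least
    the columns participant, group, correct, confidence, movement_onset.
    """

    data: np.ndarray
    times: np.ndarray
    channels: list[str]
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n_tr, n_ch, n_t = self.data.shape
        if n_ch != len(self.channels):
            raise ValueError(f"{n_ch} data channels but {len(self.channels)} names")
        if n_t != self.times.size:
            raise ValueError(f"{n_t} samples but {self.times.size} time points")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel names")
        if len(self.metadata) not in (0, n_tr):
            raise ValueError("metadata rows must match trial count")
        if len(self.metadata) == 0:
            self.metadata = pd.DataFrame(index=range(n_tr))

    # -- basic geometry -----------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def fs(self) -> float:
        if self.times.size < 2:
            return float("nan")
        return 1.0 / float(np.median(np.diff(self.times)))

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError as exc:
            raise KeyError(f"channel {name!r} not in epochs") from exc

    def time_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of samples with lo <= t <= hi (closed interval)."""
        eps = 1e-9
        return (self.times >= lo - eps) & (self.times <= hi + eps)

    # -- selection ----------------------------------------------------------
    def select_trials(self, index) -> "EpochArray":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            data=self.data[index],
            metadata=self.metadata.iloc[index].reset_index(drop=True),
        )

    def select_channels(self, names: list[str]) -> "EpochArray":
        idx = [self.channel_index(n) for n in names]
        return replace(self, data=self.data[:, idx, :], channels=list(names))

    def copy(self) -> "EpochArray":
        return replace(self, data=self.data.copy(), metadata=self.metadata.copy())

    # -- persistence --------------------------------------------------------
    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("times", data=self.times)
            f.create_dataset("channels", data=np.array(self.channels, dtype="S16"))
            meta = f.create_group("metadata")
            for col in self.metadata.columns:
                values = self.metadata[col].to_numpy()
                if values.dtype == object:
                    values = values.astype("S32")
                meta.create_dataset(str(col), data=values)

    @classmethod
    def from_hdf5(cls, path) -> "EpochArray":
        import h5py

        with h5py.File(path, "r") as f:
            data = f["data"][()]
            times = f["times"][()]
            channels = [c.decode() for c in f["channels"][()]]
            cols = {}
            for key in f["metadata"]:
                values = f["metadata"][key][()]
                if values.dtype.kind == "S":
                    values = np.array([v.decode() for v in values])
                cols[key] = values
        return cls(data=data, times=times, channels=channels, metadata=pd.DataFrame(cols))


def concatenate_epochs(parts: list[EpochArray]) -> EpochArray:
    """Stack epochs from several participants; channels/time axes must agree."""
    if not parts:
        raise ValueError("nothing to concatenate")
    first = parts[0]
    for p in parts[1:]:
        if p.channels != first.channels:
            raise ValueError("channel mismatch between epoch arrays")
        if not np.allclose(p.times, first.times):
            raise ValueError("time-axis mismatch between epoch arrays")
    data = np.concatenate([p.data for p in parts], axis=0)
    meta = pd.concat([p.metadata for p in parts], ignore_index=True)
    return EpochArray(data=data, times=first.times, channels=list(first.channels), metadata=meta)
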