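"""Labelled EEG epoch container and file I/O.

An :class:`EpochSet` holds a stack of fixed-duration multi-channel EEG
epochs time-locked to flicker onset, with sampling metadata and optional
per-epoch key labels.  Containers round-trip through HDF5 and export to a
long-format CSV; real recordings can be imported from EDF via ``mne``
(optional dependency).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = ["EpochSet"]


@dataclass
class EpochSet:
    """Collection of multi-channel EEG epochs.

    Attributes
    ----------
    data : ndarray, shape (n_epochs, n_channels, n_samples)
        Epoch voltages in microvolt.
    labels : list of str or None
        Per-epoch intended/cued key symbol; ``None`` for unlabelled data.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Electrode labels, one per channel row.
    """

    data: np.ndarray
    labels: list[str] | None
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (epochs, channels, samples), got shape {self.data.shape}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"CH{i + 1}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length does not match channel dimension")
        if self.labels is not None and len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length does not match epoch dimension")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def epoch_duration(self) -> float:
        """Epoch length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to flicker onset."""
        return np.arange(self.n_samples) / self.fs

    def select_channels(self, names: list[str]) -> "EpochSet":
        """Return a copy restricted to ``names`` (in the given order)."""
        missing = [n for n in names if n not in self.channel_names]
        if missing:
            raise KeyError(f"unknown channels: {missing}")
        idx = [self.channel_names.index(n) for n in names]
        return EpochSet(
            data=self.data[:, idx, :].copy(),
            labels=None if self.labels is None else list(self.labels),
            fs=self.fs,
            channel_names=list(names),
        )

    def subset(self, epoch_indices) -> "EpochSet":
        """Return a copy containing only the given epoch indices."""
        idx = np.asarray(epoch_indices, dtype=int)
        labels = None if self.labels is None else [self.labels[i] for i in idx]
        return EpochSet(self.data[idx].copy(), labels, self.fs, list(self.channel_names))

    def epochs_for(self, label: str) -> "EpochSet":
        """Return the sub-set of epochs carrying ``label``."""
        if self.labels is None:
            raise ValueError("EpochSet is unlabelled")
        idx = [i for i, lab in enumerate(self.labels) if lab == label]
        return self.subset(idx)

    # ------------------------------------------------------------------ I/O

    def to_hdf5(self, path) -> None:
        """Write the container to an HDF5 file."""
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=self.data)
            fh.attrs["fs"] = float(self.fs)
            fh.create_dataset(
                "channel_names", data=np.array(self.channel_names, dtype="S32")
            )
            if self.labels is not None:
                fh.create_dataset("labels", data=np.array(self.labels, dtype="S8"))

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as fh:
            data = fh["data"][()]
            fs = float(fh.attrs["fs"])
            channel_names = [s.decode() for s in fh["channel_names"][()]]
            labels = None
            if "labels" in fh:
                labels = [s.decode() for s in fh["labels"][()]]
        return cls(data=data, labels=labels, fs=fs, channel_names=channel_names)

    def to_csv(self, path) -> None:
        """Long-format CSV export (epoch, label, channel, sample, time_s, uV)."""
        n_e, n_c, n_s = self.data.shape
        epoch_idx = np.repeat(np.arange(n_e), n_c * n_s)
        chan_idx = np.tile(np.repeat(np.arange(n_c), n_s), n_e)
        samp_idx = np.tile(np.arange(n_s), n_e * n_c)
        frame = pd.DataFrame(
            {
                "epoch": epoch_idx,
                "label": (
                    np.repeat(self.labels, n_c * n_s) if self.labels is not None else ""
                ),
                "channel": np.asarray(self.channel_names)[chan_idx],
                "sample": samp_idx,
                "time_s": samp_idx / self.fs,
                "amplitude_uV": self.data.ravel(),
            }
        )
        frame.to_csv(path, index=False)

    @classmethod
    def from_edf(cls, path, epoch_duration: float, channels: list[str] | None = None) -> "EpochSet":
        """Import a continuous EDF recording and cut it into contiguous epochs.

        Requires ``mne``.  The recording is split into consecutive
        non-overlapping windows of ``epoch_duration`` seconds; labels are
        left unset.
        """
        import mne  # optional dependency

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        if channels is not None:
            raw.pick(channels)
        fs = float(raw.info["sfreq"])
        sig = raw.get_data() * 1e6  # volt -> microvolt
        n_samp = int(round(epoch_duration * fs))
        n_epochs = sig.shape[1] // n_samp
        data = np.stack(
            [sig[:, k * n_samp : (k + 1) * n_samp] for k in range(n_epochs)], axis=0
        )
        return cls(data=data, labels=None, fs=fs, channel_names=list(raw.ch_names))
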