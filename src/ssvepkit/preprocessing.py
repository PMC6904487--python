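"""Epoch cleaning, spectra and classification-channel selection.

Epochs are average referenced, linearly detrended, baseline corrected
(whole-epoch mean, since epochs start at flicker onset and no pre-stimulus
window exists) and notch filtered at the mains frequency.  Channel
selection retains, for each flicker frequency, the candidate electrodes
with the largest trial-averaged SSVEP amplitude at the fundamental,
measured on zero-padded FFT amplitude spectra.
"""

from __future__ import annotations

import numpy as np
import scipy.signal

from .epochs import EpochSet
from .flicker_design import FlickerSpec

__all__ = [
    "OCCIPITOPARIETAL_CANDIDATES",
    "preprocess",
    "fft_amplitude_spectrum",
    "select_channels",
    "average_double_epoch",
]

#: Standard occipitoparietal candidate electrodes for SSVEP channel selection.
OCCIPITOPARIETAL_CANDIDATES = (
    "Iz", "O1", "Oz", "O2", "PO7", "PO3", "POz", "PO8", "PO4",
    "P1", "P3", "P5", "P7", "P9", "Pz", "P2", "P4", "P6", "P8", "P10",
)


def preprocess(epochs: EpochSet, notch_hz: float = 50.0, notch_q: float = 30.0) -> EpochSet:
    """Average reference, detrend, baseline correct and notch filter.

    Steps, per epoch:

    1. average reference: subtract the across-channel mean at each sample;
    2. linear detrend per channel (removes drift and, with it, any
       constant offset);
    3. baseline correction: subtract each channel's whole-epoch mean;
    4. zero-phase second-order IIR notch at ``notch_hz`` (quality factor
       ``notch_q``), applied forward-backward so no phase distortion is
       introduced.  Skipped when ``notch_hz`` is None or falls at/above
       Nyquist.

    Raises
    ------
    ValueError
        For single-channel input; average referencing requires at least
        two channels.
    """
    if epochs.n_channels < 2:
        raise ValueError(
            "preprocess requires >= 2 channels: average referencing is undefined "
            f"for {epochs.n_channels} channel(s)"
        )
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)  # average reference
    data = scipy.signal.detrend(data, axis=2, type="linear")
    data = data - data.mean(axis=2, keepdims=True)
    if notch_hz is not None and 0 < notch_hz < epochs.fs / 2:
        b, a = scipy.signal.iirnotch(notch_hz, notch_q, fs=epochs.fs)
        data = scipy.signal.filtfilt(b, a, data, axis=2)
    return EpochSet(
        data=data,
        labels=None if epochs.labels is None else list(epochs.labels),
        fs=epochs.fs,
        channel_names=list(epochs.channel_names),
    )


def fft_amplitude_spectrum(
    epoch: np.ndarray, fs: float, pad_to: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-padded FFT amplitude spectrum of a multi-channel epoch.

    The epoch is zero-padded to ``pad_to`` seconds, giving a bin spacing
    of ``1/pad_to`` Hz (0.2 Hz at the 5 s default, enough to separate
    adjacent flicker frequencies).  Amplitudes follow the
    ``2*|X(f)|/N_unpadded`` convention: a unit-amplitude sinusoid spanning
    the unpadded epoch reads ~1 at its bin.

    Parameters
    ----------
    epoch : ndarray, shape (n_channels, n_samples) or (n_samples,)
    fs : float
        Sampling rate (Hz).
    pad_to : float
        Padded duration in seconds; must be >= the epoch duration.

    Returns
    -------
    freqs : ndarray of bin frequencies (Hz)
    amplitude : ndarray, shape (n_channels, n_bins), in microvolt
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    n_samples = epoch.shape[1]
    duration = n_samples / fs
    if pad_to < duration - 1e-12:
        raise ValueError(f"pad_to ({pad_to} s) must be >= epoch duration ({duration} s)")
    n_fft = int(round(pad_to * fs))
    spectrum = np.fft.rfft(epoch, n=n_fft, axis=1)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    amplitude = 2.0 * np.abs(spectrum) / n_samples
    return freqs, amplitude


def select_channels(
    training: EpochSet,
    candidates: list[str] | tuple[str, ...] = OCCIPITOPARIETAL_CANDIDATES,
    k: int = 4,
    spec: FlickerSpec | None = None,
    pad_to: float = 5.0,
) -> list[str]:
    """Pick classification channels from the SSVEP amplitude topography.

    For each key frequency, the trial-averaged SSVEP spectrum is evaluated
    at the fundamental and the ``k`` candidate channels with maximal
    amplitude are taken; the result is the union of these per-frequency
    picks, returned in candidate-list order.  Ties are broken toward the
    earlier candidate.

    ``spec`` supplies the key frequencies; ``training`` must be labelled
    with key symbols from ``spec.key_order``.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    candidates = [c for c in candidates if c in training.channel_names]
    if not candidates:
        raise ValueError("no candidate channels present in the EpochSet")
    if spec is None:
        raise ValueError("a FlickerSpec is required to locate the fundamentals")
    if training.labels is None:
        raise ValueError("training EpochSet must be labelled")

    cand_set = training.select_channels(candidates)
    selected: set[str] = set()
    for key_idx, symbol in enumerate(spec.key_order, start=1):
        sub = cand_set.epochs_for(symbol)
        if sub.n_epochs == 0:
            continue
        avg = sub.data.mean(axis=0)
        freqs, amp = fft_amplitude_spectrum(avg, fs=training.fs, pad_to=pad_to)
        bin_idx = int(np.argmin(np.abs(freqs - spec.frequencies[key_idx - 1])))
        amps = amp[:, bin_idx]
        # stable sort keeps candidate-list order among exact ties
        top = np.argsort(-amps, kind="stable")[: min(k, len(candidates))]
        selected.update(candidates[i] for i in top)
    return [c for c in candidates if c in selected]


def average_double_epoch(first: np.ndarray, second: np.ndarray) -> np.ndarray:
    """Sample-wise mean of the two halves of a double flicker epoch."""
    first = np.asarray(first, dtype=float)
    second = np.asarray(second, dtype=float)
    if first.shape != second.shape:
        raise ValueError(f"shape mismatch: {first.shape} vs {second.shape}")
    return 0.5 * (first + second)
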