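"""Individualized template training for the filter-bank CCA speller.

Training produces, for each of the keys and each harmonic sub-band, two
templates:

* a **template SSVEP** ``Y``: the trial-averaged multi-channel response to
  the key's flicker, band-pass filtered to the harmonic range; and
* a **template sinusoid** ``Z``: a unit sinusoid at the harmonic of the
  key's flicker frequency whose phase is chosen, per frequency and
  harmonic, to maximize single-trial classification accuracy on the
  training data.  The optimal phase absorbs the subject's SSVEP onset
  latency ``tau``.

The harmonic sub-band for harmonic ``j`` spans ``j*(f1 - delta_f)`` to
``j*(f_max + delta_f)`` Hz, so every key's ``j``-th harmonic falls inside
band ``j``.  All templates exclude the first 0.25 s of the epoch, which
contains a frequency-non-specific evoked response.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import scipy.signal

from .epochs import EpochSet
from .flicker_design import FlickerSpec, build_flicker_spec

__all__ = [
    "FilterBankSpec",
    "PhaseGrid",
    "TemplateBank",
    "harmonic_band",
    "bandpass",
    "build_ssvep_templates",
    "optimize_sinusoid_phase",
    "build_template_bank",
]

logger = logging.getLogger(__name__)

#: Trim applied to every correlated series: onset window excluded from
#: templates and single-trial epochs alike.
DEFAULT_TRIM = 0.25


def harmonic_band(j: int, f1: float, f_max: float, delta_f: float) -> tuple[float, float]:
    """Band edges (high-pass, low-pass) in Hz for harmonic ``j``.

    ``(j*(f1 - delta_f), j*(f_max + delta_f))`` — wide enough to contain
    the ``j``-th harmonic of every flicker frequency with half an
    increment of margin on either side.
    """
    if j < 1:
        raise ValueError(f"harmonic index must be >= 1, got {j}")
    return (j * (f1 - delta_f), j * (f_max + delta_f))


def bandpass(signal: np.ndarray, band: tuple[float, float], fs: float, order: int = 4, axis: int = -1) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward-backward).

    ``order`` is the order of the underlying Butterworth prototype; the
    forward-backward application doubles the effective attenuation and
    cancels phase distortion, which keeps the filtered SSVEP aligned with
    the sinusoid templates.
    """
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band {band} must satisfy 0 < low < high < fs/2 ({fs / 2} Hz)")
    sos = scipy.signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return scipy.signal.sosfiltfilt(sos, np.asarray(signal, dtype=float), axis=axis)


@dataclass(frozen=True)
class FilterBankSpec:
    """Harmonic filter-bank definition.

    Bands derive from the flicker frequency range: band ``j`` spans
    ``j*(f1 - delta_f)`` .. ``j*(f_max + delta_f)`` Hz.
    """

    n_harmonics: int = 5
    f1: float = 10.0
    f_max: float = 15.4
    delta_f: float = 0.2
    filter_order: int = 4

    @classmethod
    def from_flicker_spec(cls, spec: FlickerSpec, n_harmonics: int = 5, filter_order: int = 4) -> "FilterBankSpec":
        return cls(
            n_harmonics=n_harmonics,
            f1=spec.f1,
            f_max=spec.f_max,
            delta_f=spec.delta_f,
            filter_order=filter_order,
        )

    def band(self, j: int) -> tuple[float, float]:
        return harmonic_band(j, self.f1, self.f_max, self.delta_f)

    @property
    def bands(self) -> list[tuple[float, float]]:
        return [self.band(j) for j in range(1, self.n_harmonics + 1)]

    def usable_harmonics(self, fs: float) -> list[int]:
        """Harmonic indices whose band fits below Nyquist at rate ``fs``.

        Harmonics that would exceed Nyquist are dropped with a warning
        (arises at low sampling rates).
        """
        usable = [j for j in range(1, self.n_harmonics + 1) if self.band(j)[1] < fs / 2]
        if len(usable) < self.n_harmonics:
            warnings.warn(
                f"dropping harmonics {usable[-1] + 1 if usable else 1}..{self.n_harmonics}: "
                f"band exceeds Nyquist ({fs / 2} Hz)",
                stacklevel=2,
            )
        return usable


@dataclass(frozen=True)
class PhaseGrid:
    """Candidate sinusoid phases for the optimal-phase search.

    Default: 20 equally spaced values 0, 0.1*pi, ..., 1.9*pi.
    """

    phases: np.ndarray = field(default_factory=lambda: np.arange(20) * 0.1 * np.pi)

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", np.asarray(self.phases, dtype=float))
        if self.phases.ndim != 1 or self.phases.size < 1:
            raise ValueError("phase grid must be a non-empty 1-D array")

    def __len__(self) -> int:
        return self.phases.size


def _trim_samples(trim: float, fs: float) -> int:
    return int(round(trim * fs))


def _orth_time_basis(x: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis (samples x rank) of the centered row space of ``x``.

    Rank-revealing via SVD so scaled-copy channels (noise-free epochs,
    average-referenced data) do not inflate the subspace.
    """
    xc = x - x.mean(axis=-1, keepdims=True)
    u, s, _ = np.linalg.svd(xc.T, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        raise ValueError("zero-variance input: correlation undefined")
    rank = int(np.sum(s > rtol * s[0]))
    return u[:, :rank]


def sinusoid_bank(
    frequencies: np.ndarray,
    harmonic: int,
    phases: np.ndarray,
    fs: float,
    n_samples_full: int,
    trim: float = DEFAULT_TRIM,
) -> np.ndarray:
    """Sinusoids ``sin(2*pi*j*f*t + phi)`` on the full epoch timeline, trimmed.

    Returns an array of shape ``(n_frequencies, n_phases, n_trimmed)``.
    The time base starts at flicker onset; trimming removes the first
    ``trim`` seconds so the series align with trimmed templates.
    """
    t = np.arange(n_samples_full) / fs
    arg = 2 * np.pi * harmonic * np.asarray(frequencies)[:, None, None] * t[None, None, :]
    bank = np.sin(arg + np.asarray(phases)[None, :, None])
    return bank[:, :, _trim_samples(trim, fs):]


def build_ssvep_templates(
    training: EpochSet,
    spec: FlickerSpec,
    bank_spec: FilterBankSpec | None = None,
    trim: float = DEFAULT_TRIM,
    harmonics: list[int] | None = None,
) -> np.ndarray:
    """Trial-averaged, band-passed, trimmed SSVEP templates.

    Per key: average the single-trial EEG across its cued trials, band-pass
    the average to each harmonic range, then drop the first ``trim``
    seconds.

    Returns
    -------
    ndarray, shape (n_keys, n_harmonics, n_channels, n_trimmed_samples)
    """
    if bank_spec is None:
        bank_spec = FilterBankSpec.from_flicker_spec(spec)
    if harmonics is None:
        harmonics = bank_spec.usable_harmonics(training.fs)
    if training.labels is None:
        raise ValueError("training EpochSet must be labelled")

    missing = [s for s in spec.key_order if s not in training.labels]
    if missing:
        raise ValueError(f"no training epochs for keys: {missing}")

    n_trim = _trim_samples(trim, training.fs)
    out = np.empty(
        (spec.n_keys, len(harmonics), training.n_channels, training.n_samples - n_trim)
    )
    for k, symbol in enumerate(spec.key_order):
        avg = training.epochs_for(symbol).data.mean(axis=0)
        for h, j in enumerate(harmonics):
            filtered = bandpass(avg, bank_spec.band(j), training.fs, bank_spec.filter_order)
            out[k, h] = filtered[:, n_trim:]
    return out


def optimize_sinusoid_phase(
    epochs: np.ndarray,
    key_index: int,
    harmonic: int,
    spec: FlickerSpec,
    fs: float,
    grid: PhaseGrid | None = None,
    trim: float = DEFAULT_TRIM,
    n_samples_full: int | None = None,
) -> tuple[float, np.ndarray]:
    """Grid search for the sinusoid phase maximizing training accuracy.

    ``epochs`` are the single trials cued at ``key_index`` (1-based),
    already band-passed to the harmonic range and trimmed — shape
    ``(n_epochs, n_channels, n_trimmed_samples)``.

    For each grid phase, every epoch is canonically correlated with
    sinusoids at **all** flicker frequencies (harmonic ``harmonic``) at
    that phase; the epoch votes "correct" iff the maximal correlation
    occurs at the cued frequency.  The phase with the highest vote share
    wins.  Ties are broken toward the phase with the strongest mean
    correlation at the cued frequency, then toward the lowest phase (with
    noise-free training data entire runs of phases can reach 100% votes,
    and the correlation margin pinpoints the underlying SSVEP phase
    within one grid step).

    Returns
    -------
    (optimal_phase, accuracy_per_phase)
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3 or epochs.shape[0] == 0:
        raise ValueError("epochs must be a non-empty (n_epochs, n_channels, n_samples) array")
    if grid is None:
        grid = PhaseGrid()
    n_trim_samp = epochs.shape[2]
    if n_samples_full is None:
        n_samples_full = n_trim_samp + _trim_samples(trim, fs)

    bank = sinusoid_bank(spec.frequencies, harmonic, grid.phases, fs, n_samples_full, trim)
    bank_c = bank - bank.mean(axis=2, keepdims=True)
    bank_norm = np.linalg.norm(bank_c, axis=2)

    n_epochs = epochs.shape[0]
    n_freq, n_phase = bank.shape[0], bank.shape[1]
    r = np.empty((n_epochs, n_freq, n_phase))
    for e in range(n_epochs):
        q = _orth_time_basis(epochs[e])
        proj = np.tensordot(bank_c, q, axes=([2], [0]))  # (n_freq, n_phase, rank)
        r[e] = np.linalg.norm(proj, axis=2) / bank_norm

    votes = np.argmax(r, axis=1) == (key_index - 1)  # (n_epochs, n_phase)
    accuracy = votes.mean(axis=0)
    best = accuracy.max()
    tied = np.flatnonzero(accuracy == best)
    if tied.size > 1:
        margin = r[:, key_index - 1, :].mean(axis=0)
        tied = tied[margin[tied] == margin[tied].max()]
    phi = float(grid.phases[tied[0]])

    # The canonical correlation is invariant to the sinusoid's sign, so the
    # vote cannot distinguish phi from phi + pi (the classifier is equally
    # indifferent).  Resolve the half-cycle by the polarity of the dominant
    # template channel: flip if the trial-averaged SSVEP on its strongest
    # channel anti-correlates with the winning sinusoid, provided the
    # flipped phase is itself on the grid.
    mean_epoch = epochs.mean(axis=0)
    anchor = int(np.argmax(np.sqrt(np.mean(mean_epoch**2, axis=1))))
    t = (np.arange(n_samples_full) / fs)[n_samples_full - n_trim_samp:]
    z = np.sin(2 * np.pi * harmonic * spec.frequencies[key_index - 1] * t + phi)
    a = mean_epoch[anchor] - mean_epoch[anchor].mean()
    if float(np.dot(a, z - z.mean())) < 0:
        flipped = (phi + np.pi) % (2 * np.pi)
        if np.any(np.isclose(np.mod(grid.phases, 2 * np.pi), flipped, atol=1e-9)):
            phi = flipped
    return phi, accuracy


@dataclass
class TemplateBank:
    """Trained per-key, per-harmonic template bank.

    ``ssvep`` has shape (n_keys, n_harmonics, n_channels, n_samples),
    ``sinusoid`` (n_keys, n_harmonics, n_samples) and ``phases``
    (n_keys, n_harmonics); all series share the post-trim sample count.
    """

    ssvep: np.ndarray
    sinusoid: np.ndarray
    phases: np.ndarray
    selected_channels: list[str]
    harmonics: list[int]
    trim: float
    fs: float
    spec: FlickerSpec
    bank_spec: FilterBankSpec
    n_samples_full: int
    meta: dict = field(default_factory=dict)

    #: serialization format version
    VERSION = 1

    def __post_init__(self) -> None:
        if self.ssvep.shape[:2] != self.sinusoid.shape[:2]:
            raise ValueError("ssvep and sinusoid template counts differ")
        if self.ssvep.shape[3] != self.sinusoid.shape[2]:
            raise ValueError("ssvep and sinusoid templates must share post-trim length")
        self._cache: dict = {}

    @property
    def n_keys(self) -> int:
        return self.ssvep.shape[0]

    @property
    def n_harmonics(self) -> int:
        return self.ssvep.shape[1]

    @property
    def n_templates(self) -> int:
        """Number of SSVEP templates (== number of sinusoid templates)."""
        return self.n_keys * self.n_harmonics

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.attrs["version"] = self.VERSION
            fh.create_dataset("ssvep", data=self.ssvep)
            fh.create_dataset("sinusoid", data=self.sinusoid)
            fh.create_dataset("phases", data=self.phases)
            fh.create_dataset("selected_channels", data=np.array(self.selected_channels, dtype="S32"))
            fh.create_dataset("harmonics", data=np.array(self.harmonics, dtype=int))
            fh.attrs["trim"] = self.trim
            fh.attrs["fs"] = self.fs
            fh.attrs["n_samples_full"] = self.n_samples_full
            fh.attrs["filter_order"] = self.bank_spec.filter_order
            fh.attrs["bank_n_harmonics"] = self.bank_spec.n_harmonics
            for name in ("n_keys", "f0", "delta_f", "phi0", "delta_phi"):
                fh.attrs[f"spec_{name}"] = getattr(self.spec, name)
            fh.create_dataset("key_order", data=np.array(self.spec.key_order, dtype="S8"))

    @classmethod
    def from_hdf5(cls, path) -> "TemplateBank":
        with h5py.File(path, "r") as fh:
            spec = build_flicker_spec(
                n_keys=int(fh.attrs["spec_n_keys"]),
                f0=float(fh.attrs["spec_f0"]),
                delta_f=float(fh.attrs["spec_delta_f"]),
                phi0=float(fh.attrs["spec_phi0"]),
                delta_phi=float(fh.attrs["spec_delta_phi"]),
                key_order=[s.decode() for s in fh["key_order"][()]],
            )
            bank_spec = FilterBankSpec.from_flicker_spec(
                spec,
                n_harmonics=int(fh.attrs["bank_n_harmonics"]),
                filter_order=int(fh.attrs["filter_order"]),
            )
            return cls(
                ssvep=fh["ssvep"][()],
                sinusoid=fh["sinusoid"][()],
                phases=fh["phases"][()],
                selected_channels=[s.decode() for s in fh["selected_channels"][()]],
                harmonics=[int(j) for j in fh["harmonics"][()]],
                trim=float(fh.attrs["trim"]),
                fs=float(fh.attrs["fs"]),
                spec=spec,
                bank_spec=bank_spec,
                n_samples_full=int(fh.attrs["n_samples_full"]),
            )


def build_template_bank(
    training: EpochSet,
    spec: FlickerSpec,
    bank_spec: FilterBankSpec | None = None,
    trim: float = DEFAULT_TRIM,
    grid: PhaseGrid | None = None,
    selected_channels: list[str] | None = None,
) -> TemplateBank:
    """Assemble the full template bank from preprocessed training epochs.

    ``training`` is expected to be preprocessed and already restricted to
    the selected classification channels.  Deterministic given its inputs.
    """
    if bank_spec is None:
        bank_spec = FilterBankSpec.from_flicker_spec(spec)
    if grid is None:
        grid = PhaseGrid()
    harmonics = bank_spec.usable_harmonics(training.fs)
    n_trim = _trim_samples(trim, training.fs)

    ssvep = build_ssvep_templates(training, spec, bank_spec, trim, harmonics)
    phases = np.empty((spec.n_keys, len(harmonics)))
    sinusoid = np.empty((spec.n_keys, len(harmonics), training.n_samples - n_trim))

    per_key = {symbol: training.epochs_for(symbol) for symbol in spec.key_order}
    for h, j in enumerate(harmonics):
        band = bank_spec.band(j)
        for k, symbol in enumerate(spec.key_order):
            filtered = bandpass(per_key[symbol].data, band, training.fs, bank_spec.filter_order)
            phi, _acc = optimize_sinusoid_phase(
                filtered[:, :, n_trim:],
                key_index=k + 1,
                harmonic=j,
                spec=spec,
                fs=training.fs,
                grid=grid,
                trim=trim,
                n_samples_full=training.n_samples,
            )
            phases[k, h] = phi
            sinusoid[k, h] = sinusoid_bank(
                spec.frequencies[k : k + 1], j, np.array([phi]), training.fs,
                training.n_samples, trim,
            )[0, 0]

    return TemplateBank(
        ssvep=ssvep,
        sinusoid=sinusoid,
        phases=phases,
        selected_channels=selected_channels or list(training.channel_names),
        harmonics=harmonics,
        trim=trim,
        fs=training.fs,
        spec=spec,
        bank_spec=bank_spec,
        n_samples_full=training.n_samples,
        meta={"reps": training.n_epochs // spec.n_keys},
    )
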