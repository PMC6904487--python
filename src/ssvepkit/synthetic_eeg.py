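"""Synthetic multi-channel EEG with the statistical structure of SSVEP data.

The generator produces flicker-locked epochs containing the ingredients the
decoder relies on, so every downstream stage is testable without
recordings:

* an SSVEP at the attended key's flicker frequency plus harmonics, with
  decaying harmonic amplitudes and a per-channel gain topography
  (occipitoparietal maximum by default);
* a frequency-independent onset latency ``tau``: the entrained response is
  absent before ``tau`` seconds and phase-shifted accordingly after, which
  is what the optimal-phase template search has to absorb;
* a frequency-non-specific onset transient confined to roughly the first
  0.25 s of the epoch (the part excluded from templates);
* endogenous alpha-band interference as a sinusoid with per-epoch random
  frequency and phase; and
* broadband 1/f^beta noise, independent across channels.

Amplitudes are in microvolt.  Harmonic and interference amplitudes are
free parameters of the simulation; the defaults are plausible for
occipital scalp EEG but are not fitted to any recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epochs import EpochSet
from .flicker_design import FlickerSpec

__all__ = [
    "SimConfig",
    "simulate_epoch",
    "simulate_double_epoch",
    "simulate_training_set",
    "simulate_typing_epochs",
]

_DEFAULT_CHANNELS = ("Oz", "O1", "O2", "POz", "PO3", "PO4", "Pz", "Fz")
# Occipitoparietal-weighted topography: strongest over Oz, weak frontally.
_DEFAULT_GAINS = (1.0, 0.9, 0.9, 0.8, 0.7, 0.7, 0.4, 0.1)


@dataclass
class SimConfig:
    """Parameters of the synthetic SSVEP epoch generator.

    Attributes
    ----------
    fs : float
        Sampling rate (Hz).  256 Hz keeps the five-harmonic filter bank
        below Nyquist while staying fast.
    epoch_duration : float
        Flicker epoch length (s).
    channel_names : tuple of str
        Simulated electrode labels.
    channel_gains : array-like
        SSVEP gain topography: shape ``(n_channels,)`` or
        ``(n_channels, n_keys)`` for key-specific topographies.
    harmonic_amplitudes : tuple of float
        Amplitude (microvolt) of harmonics 1..H of the attended frequency.
    latency_tau : float
        SSVEP onset delay (s) relative to flicker onset; the response is
        zero before ``tau``.
    alpha_amplitude : float
        Amplitude of the endogenous alpha interference sinusoid (microvolt);
        its frequency is drawn uniformly from ``alpha_band`` and its phase
        uniformly from [0, 2*pi) per epoch.
    noise_amplitude : float
        RMS (microvolt) of the broadband 1/f^beta noise per channel.
    noise_exponent : float
        Spectral exponent beta of the background noise.
    onset_transient_amplitude, onset_transient_decay : float
        Peak (microvolt) and exponential decay constant (s) of the
        frequency-non-specific evoked response at epoch onset.
    seed : int
        Master seed for deterministic per-epoch seed derivation.
    """

    fs: float = 256.0
    epoch_duration: float = 1.5
    channel_names: tuple[str, ...] = _DEFAULT_CHANNELS
    channel_gains: tuple | np.ndarray = _DEFAULT_GAINS
    harmonic_amplitudes: tuple[float, ...] = (2.0, 1.0, 0.5, 0.3, 0.2)
    latency_tau: float = 0.13
    alpha_amplitude: float = 3.0
    alpha_band: tuple[float, float] = (8.0, 12.0)
    noise_amplitude: float = 2.0
    noise_exponent: float = 1.0
    onset_transient_amplitude: float = 5.0
    onset_transient_decay: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        n_samples = self.fs * self.epoch_duration
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise ValueError(
                f"fs*epoch_duration must be an integer sample count, got {n_samples}"
            )
        if any(a < 0 for a in self.harmonic_amplitudes):
            raise ValueError("harmonic amplitudes must be non-negative")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be non-negative")
        gains = np.asarray(self.channel_gains, dtype=float)
        if gains.shape[0] != len(self.channel_names):
            raise ValueError("channel_gains first dimension must match channel_names")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_duration))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def gains_for_key(self, key_index: int) -> np.ndarray:
        """Per-channel SSVEP gain vector for 1-based ``key_index``."""
        gains = np.asarray(self.channel_gains, dtype=float)
        if gains.ndim == 1:
            return gains
        return gains[:, key_index - 1]

    def replace(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields overridden."""
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


def _deterministic_signal(key_index: int, spec: FlickerSpec, cfg: SimConfig) -> np.ndarray:
    """Noise-free epoch content: delayed harmonic sum plus onset transient."""
    if not 1 <= key_index <= spec.n_keys:
        raise ValueError(f"key_index {key_index} out of range 1..{spec.n_keys}")
    t = cfg.times
    f = spec.frequencies[key_index - 1]
    phi = spec.phases[key_index - 1]
    gains = cfg.gains_for_key(key_index)

    active = t >= cfg.latency_tau
    ssvep = np.zeros_like(t)
    for j, amp in enumerate(cfg.harmonic_amplitudes, start=1):
        ssvep += amp * np.sin(2 * np.pi * j * f * (t - cfg.latency_tau) + phi) * active

    epoch = gains[:, None] * ssvep[None, :]
    if cfg.onset_transient_amplitude:
        transient = cfg.onset_transient_amplitude * np.exp(-t / cfg.onset_transient_decay)
        epoch = epoch + gains[:, None] * transient[None, :]
    return epoch


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int, beta: float) -> np.ndarray:
    """Unit-RMS 1/f^beta noise, synthesized by spectral shaping of white noise."""
    white = rng.standard_normal((n_channels, n_samples))
    spectrum = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-beta / 2.0)
    shaped = np.fft.irfft(spectrum * shaping[None, :], n=n_samples, axis=1)
    rms = np.sqrt(np.mean(shaped**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return shaped / rms


def _stochastic_part(key_index: int, spec: FlickerSpec, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Alpha interference plus broadband noise for one epoch."""
    t = cfg.times
    out = np.zeros((cfg.n_channels, cfg.n_samples))
    if cfg.alpha_amplitude > 0:
        f_alpha = rng.uniform(*cfg.alpha_band)
        phase = rng.uniform(0, 2 * np.pi)
        gains = cfg.gains_for_key(key_index)
        out += cfg.alpha_amplitude * gains[:, None] * np.sin(2 * np.pi * f_alpha * t + phase)[None, :]
    if cfg.noise_amplitude > 0:
        out += cfg.noise_amplitude * _pink_noise(rng, cfg.n_channels, cfg.n_samples, cfg.noise_exponent)
    return out


def simulate_epoch(
    key_index: int, spec: FlickerSpec, cfg: SimConfig, seed: int | None = None
) -> np.ndarray:
    """Simulate one flicker-locked epoch for 1-based ``key_index``.

    Returns an array of shape ``(n_channels, n_samples)`` in microvolt.
    Deterministic given ``seed`` (``cfg.seed`` is used when ``seed`` is
    None).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    return _deterministic_signal(key_index, spec, cfg) + _stochastic_part(key_index, spec, cfg, rng)


def simulate_double_epoch(
    key_index: int, spec: FlickerSpec, cfg: SimConfig, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a double flicker epoch: two consecutive stimulation periods.

    The flicker phase is reset between the two periods, so the
    deterministic SSVEP content is identical in both, while the alpha
    interference and broadband noise are independent draws.  Averaging the
    pair (``preprocessing.average_double_epoch``) halves the noise
    variance.
    """
    ss = np.random.SeedSequence(cfg.seed if seed is None else seed)
    rng_a, rng_b = (np.random.default_rng(child) for child in ss.spawn(2))
    signal = _deterministic_signal(key_index, spec, cfg)
    return (
        signal + _stochastic_part(key_index, spec, cfg, rng_a),
        signal + _stochastic_part(key_index, spec, cfg, rng_b),
    )


def _epoch_seeds(cfg: SimConfig, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(cfg.seed).spawn(n)


def simulate_training_set(
    spec: FlickerSpec, cfg: SimConfig, reps_per_key: int = 20, double_epoch: bool = False
) -> EpochSet:
    """Simulate a cued template-training run.

    Each key is cued ``reps_per_key`` times in a randomized order (the
    order permutation and all per-epoch noise seeds derive
    deterministically from ``cfg.seed``).  With ``double_epoch=True`` each
    trial is the average of two consecutive flicker periods with
    independent noise, emulating the double flicker epoch used to raise
    SSVEP SNR for low-accuracy users.
    """
    if reps_per_key < 1:
        raise ValueError(f"reps_per_key must be >= 1, got {reps_per_key}")
    ss = np.random.SeedSequence(cfg.seed)
    order_rng = np.random.default_rng(ss.spawn(1)[0])
    trials = [(k, r) for k in range(1, spec.n_keys + 1) for r in range(reps_per_key)]
    order_rng.shuffle(trials)

    seeds = ss.spawn(len(trials))
    data = np.empty((len(trials), cfg.n_channels, cfg.n_samples))
    labels = []
    for e, ((key, _rep), child) in enumerate(zip(trials, seeds)):
        if double_epoch:
            rng_a, rng_b = (np.random.default_rng(c) for c in child.spawn(2))
            signal = _deterministic_signal(key, spec, cfg)
            first = signal + _stochastic_part(key, spec, cfg, rng_a)
            second = signal + _stochastic_part(key, spec, cfg, rng_b)
            data[e] = 0.5 * (first + second)
        else:
            rng = np.random.default_rng(child)
            data[e] = _deterministic_signal(key, spec, cfg) + _stochastic_part(key, spec, cfg, rng)
        labels.append(spec.key_order[key - 1])
    return EpochSet(data=data, labels=labels, fs=cfg.fs, channel_names=list(cfg.channel_names))


def simulate_typing_epochs(
    key_sequence: list[str] | str, spec: FlickerSpec, cfg: SimConfig, double_epoch: bool = False
) -> EpochSet:
    """Simulate one epoch per intended key, order preserved.

    ``key_sequence`` may be a string (each character a key symbol) or a
    list of symbols; all symbols must be in ``spec.key_order``.
    """
    symbols = list(key_sequence)
    for sym in symbols:
        if sym not in spec.key_order:
            raise KeyError(f"symbol {sym!r} is not in the keyboard layout")
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.spawn(len(symbols)) if symbols else []
    data = np.empty((len(symbols), cfg.n_channels, cfg.n_samples))
    for e, (sym, child) in enumerate(zip(symbols, seeds)):
        key = spec.key_index(sym)
        if double_epoch:
            rng_a, rng_b = (np.random.default_rng(c) for c in child.spawn(2))
            signal = _deterministic_signal(key, spec, cfg)
            data[e] = signal + 0.5 * (
                _stochastic_part(key, spec, cfg, rng_a) + _stochastic_part(key, spec, cfg, rng_b)
            )
        else:
            rng = np.random.default_rng(child)
            data[e] = _deterministic_signal(key, spec, cfg) + _stochastic_part(key, spec, cfg, rng)
    return EpochSet(data=data, labels=symbols, fs=cfg.fs, channel_names=list(cfg.channel_names))
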