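"""Closed-loop typing-session simulation and the EMG enter-key detector.

A session reproduces the free-communication protocol: the (simulated)
user intends the next character of a target string while the text buffer
matches a prefix of the target, and intends backspace otherwise; each
intended key passes through a *classification channel* — either the full
synthetic-EEG-plus-classifier pipeline or an abstract confusion channel —
and the classified key updates the buffer.  The session ends when the
buffer matches the target, or aborts once more than three times the
target length has been entered.

The EMG enter key is a separate, non-flickering control: a 1 s window of
a frontal channel is declared an enter keystroke when its mean FFT
amplitude over 50-100 Hz exceeds a per-user threshold, subject to a > 4 s
cool-down.  Enter keystrokes are excluded from accuracy and ITR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import classify
from .epochs import EpochSet
from .flicker_design import BACKSPACE, FlickerSpec
from .metrics import free_comm_accuracy, itr_wolpaw
from .preprocessing import fft_amplitude_spectrum, preprocess
from .synthetic_eeg import SimConfig, simulate_epoch
from .templates import TemplateBank

__all__ = [
    "SessionTiming",
    "SessionStep",
    "SessionTranscript",
    "corrective_policy",
    "PerfectChannel",
    "ConfusionChannel",
    "PipelineChannel",
    "run_session",
    "detect_enter",
]


@dataclass(frozen=True)
class SessionTiming:
    """Selection timing: flicker period plus flicker-free interval (s).

    Defaults are the free-communication values (1.5 s + 0.75 s, so
    T = 2.25 s/selection); template training uses a 0.5 s flicker-free
    interval instead.
    """

    flicker_s: float = 1.5
    flicker_free_s: float = 0.75

    @property
    def selection_time(self) -> float:
        return self.flicker_s + self.flicker_free_s


@dataclass
class SessionStep:
    intended: str | None
    classified: str
    buffer_after: str


@dataclass
class SessionTranscript:
    """Record of one closed-loop typing session."""

    target_text: str
    steps: list[SessionStep] = field(default_factory=list)
    outcome: str = "aborted"  # "matched" | "aborted"
    timing: SessionTiming = field(default_factory=SessionTiming)
    n_keys: int = 28

    @property
    def selections(self) -> int:
        return len(self.steps)

    @property
    def accuracy(self) -> float:
        return free_comm_accuracy(self)

    @property
    def itr(self) -> float:
        """Wolpaw ITR (bpm) at the session accuracy and selection time."""
        return itr_wolpaw(self.n_keys, self.accuracy, self.timing.selection_time)

    @property
    def selection_log(self) -> list[str]:
        return [s.classified for s in self.steps]

    def to_dict(self) -> dict:
        return {
            "target_text": self.target_text,
            "outcome": self.outcome,
            "selections": self.selections,
            "accuracy": self.accuracy,
            "itr_bpm": self.itr,
            "flicker_s": self.timing.flicker_s,
            "flicker_free_s": self.timing.flicker_free_s,
            "steps": [
                {"intended": s.intended, "classified": s.classified, "buffer": s.buffer_after}
                for s in self.steps
            ],
        }


def corrective_policy(buffer: str, target: str) -> str | None:
    """Key a user correcting toward ``target`` intends next.

    If the buffer is a (proper) prefix of the target, the next target
    character; otherwise backspace.  Returns ``None`` when the buffer
    already equals the target (terminal state).
    """
    if buffer == target:
        return None
    if target.startswith(buffer):
        return target[len(buffer)]
    return BACKSPACE


class PerfectChannel:
    """Classification channel that always returns the intended key."""

    def __call__(self, intended: str) -> str:
        return intended


class ConfusionChannel:
    """Uniform symmetric confusion channel over the keyboard symbols.

    With probability ``1 - error_rate`` the intended key is returned;
    otherwise one of the remaining keys, uniformly at random.
    """

    def __init__(self, error_rate: float, layout: list[str], seed: int = 0):
        if not 0 <= error_rate <= 1:
            raise ValueError(f"error_rate must be in [0, 1], got {error_rate}")
        self.error_rate = error_rate
        self.layout = list(layout)
        self.rng = np.random.default_rng(seed)

    def __call__(self, intended: str) -> str:
        if self.rng.random() >= self.error_rate:
            return intended
        others = [k for k in self.layout if k != intended]
        return others[self.rng.integers(len(others))]


class PipelineChannel:
    """Full simulate -> preprocess -> classify channel.

    Each call synthesizes a flicker epoch for the intended key (with a
    fresh deterministic seed), preprocesses it, restricts it to the
    bank's selected channels and classifies it against the template bank.
    """

    def __init__(
        self,
        bank: TemplateBank,
        spec: FlickerSpec,
        cfg: SimConfig,
        seed: int = 0,
        n_harmonics: int | None = None,
        notch_hz: float = 50.0,
    ):
        self.bank = bank
        self.spec = spec
        self.cfg = cfg
        self.n_harmonics = n_harmonics
        self.notch_hz = notch_hz
        self._seeds = iter(np.random.SeedSequence(seed).spawn(1_000_000))

    def __call__(self, intended: str) -> str:
        key = self.spec.key_index(intended)
        epoch = simulate_epoch(key, self.spec, self.cfg, seed=next(self._seeds))
        epochs = EpochSet(epoch[None], None, self.cfg.fs, list(self.cfg.channel_names))
        clean = preprocess(epochs, notch_hz=self.notch_hz)
        clean = clean.select_channels(self.bank.selected_channels)
        return classify(clean.data[0], self.bank, self.n_harmonics).decided_key


def run_session(
    target: str,
    channel,
    timing: SessionTiming | None = None,
    n_keys: int = 28,
    layout: list[str] | None = None,
) -> SessionTranscript:
    """Run one closed-loop typing session toward ``target``.

    ``channel`` is any callable mapping an intended key symbol to a
    classified key symbol.  The buffer updates with backspace semantics
    (backspace on an empty buffer is a no-op that still consumes a
    selection); the session ends when the buffer matches the target or
    aborts after ``3 * len(target)`` selections without a match.
    """
    if not target:
        raise ValueError("target must be non-empty")
    if layout is not None:
        bad = [c for c in target if c not in layout]
        if bad:
            raise ValueError(f"target contains characters outside the layout: {bad}")
    timing = timing or SessionTiming()
    transcript = SessionTranscript(target_text=target, timing=timing, n_keys=n_keys)
    buffer = ""
    max_selections = 3 * len(target)
    while True:
        intended = corrective_policy(buffer, target)
        if intended is None:
            transcript.outcome = "matched"
            break
        if transcript.selections >= max_selections:
            transcript.outcome = "aborted"
            break
        classified = channel(intended)
        if classified == BACKSPACE:
            buffer = buffer[:-1]
        else:
            buffer = buffer + classified
        transcript.steps.append(SessionStep(intended, classified, buffer))
    return transcript


def detect_enter(
    window: np.ndarray,
    fs: float,
    threshold: float = 4.0,
    time_since_last: float = np.inf,
    band: tuple[float, float] = (50.0, 100.0),
    cooldown_s: float = 4.0,
) -> bool:
    """EMG enter-key detection from a 1.0 s frontal-channel window.

    True iff the mean FFT amplitude (microvolt, 1 Hz resolution) over the
    50-100 Hz bins exceeds ``threshold`` and more than ``cooldown_s``
    seconds have elapsed since the previous enter event.
    """
    window = np.asarray(window, dtype=float).ravel()
    if abs(window.size / fs - 1.0) > 1e-9:
        raise ValueError(f"window must be exactly 1.0 s long, got {window.size / fs:.3f} s")
    if time_since_last <= cooldown_s:
        return False
    freqs, amp = fft_amplitude_spectrum(window, fs=fs, pad_to=1.0)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(mask):
        raise ValueError(f"no spectral bins inside {band} Hz at fs={fs}")
    return bool(amp[0, mask].mean() > threshold)
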