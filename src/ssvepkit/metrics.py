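"""Speller performance metrics: accuracy, Wolpaw ITR, SNR, learning curves.

The information transfer rate follows Wolpaw's formula

    bits/selection = log2(N) + P*log2(P) + (1-P)*log2((1-P)/(N-1))

with ``N`` the number of selectable keys, ``P`` the classification
accuracy and the convention ``0*log2(0) = 0``; dividing by the selection
time (stimulation plus flicker-free interval) and scaling to minutes
gives bits per minute (bpm).

Learning curves relate classification accuracy to the number of training
trials ``T`` through the inverse exponential

    ACC = a * (1 - exp(-s*(T - i)))

with asymptote ``a``, scaling factor ``s`` and x-intercept ``i``; the
number of trials needed to reach a fraction ``q`` of the asymptote has
the closed form ``i - ln(1-q)/s``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .flicker_design import BACKSPACE

__all__ = [
    "LearningCurveFit",
    "itr_wolpaw",
    "template_training_minutes",
    "qwerty_accuracy",
    "free_comm_accuracy",
    "backspace_proxy_accuracy",
    "snr_at",
    "fit_learning_curve",
    "trials_to_fraction",
]


def itr_wolpaw(n_choices: int, accuracy: float, selection_time: float) -> float:
    """Wolpaw information transfer rate in bits per minute.

    Parameters
    ----------
    n_choices : int
        Number of selectable keys ``N`` (>= 2).
    accuracy : float
        Classification accuracy ``P`` in [0, 1].
    selection_time : float
        Seconds per selection, including the flicker-free interval.

    Below-chance accuracies (< 1/N) return the formula value with a
    warning rather than being clamped.
    """
    if n_choices < 2:
        raise ValueError(f"n_choices must be >= 2, got {n_choices}")
    if not 0 <= accuracy <= 1:
        raise ValueError(f"accuracy must be in [0, 1], got {accuracy}")
    if selection_time <= 0:
        raise ValueError(f"selection_time must be positive, got {selection_time}")
    if accuracy < 1.0 / n_choices:
        warnings.warn(
            f"accuracy {accuracy:.4f} is below chance (1/{n_choices}); "
            "ITR formula value returned unclamped",
            stacklevel=2,
        )
    p = accuracy
    bits = np.log2(n_choices)
    if p > 0:
        bits += p * np.log2(p)
    if p < 1:
        bits += (1 - p) * np.log2((1 - p) / (n_choices - 1))
    return float(bits * 60.0 / selection_time)


def template_training_minutes(
    n_keys: int = 28, reps_per_key: int = 20, flicker_s: float = 1.5, flicker_free_s: float = 0.5
) -> float:
    """Total stimulation time (minutes) for a cued template-training run.

    Each trial occupies ``flicker_s + flicker_free_s`` seconds; the
    default 2 s/trial x 28 keys x 20 reps gives ~18.67 min (rests
    excluded).
    """
    return n_keys * reps_per_key * (flicker_s + flicker_free_s) / 60.0


def qwerty_accuracy(classified: list[str], n_cycles: int, layout: list[str]) -> float:
    """Accuracy of the uncued full-keyboard typing assessment.

    The expected sequence is ``layout`` repeated ``n_cycles`` times; the
    expected pointer advances each epoch regardless of the outcome.
    Accuracy is positional matches over total epochs; epochs beyond the
    expected sequence count as incorrect.
    """
    if not classified:
        raise ValueError("classified sequence is empty")
    expected = list(layout) * n_cycles
    matches = sum(1 for c, e in zip(classified, expected) if c == e)
    return matches / len(classified)


def free_comm_accuracy(transcript) -> float:
    """Accuracy of a free-communication session transcript.

    A selection counts as correct only when it types the next character of
    the target (intended key from the corrective policy, and correctly
    classified).  All superfluous selections are errors — including the
    corrective backspaces themselves, since relative to the target string
    both a misclassified character and the keystroke that deletes it are
    extra entries.  An error-free session on a length-L target therefore
    scores 1.0, while one misclassification corrected by one successful
    backspace scores L/(L+2).
    """
    steps = transcript.steps
    if not steps:
        raise ValueError("transcript has no steps")
    if any(s.intended is None for s in steps):
        raise ValueError("transcript lacks intended-key annotations")
    correct = sum(
        1 for s in steps if s.intended != BACKSPACE and s.classified == s.intended
    )
    return correct / len(steps)


def backspace_proxy_accuracy(selection_log: list[str]) -> float:
    """Free-conversation accuracy proxy: 1 - backspace share of selections.

    When no ground-truth intent exists (genuine conversation), backspace
    corrections stand in for classification or user errors.
    """
    if not selection_log:
        raise ValueError("selection log is empty")
    n_back = sum(1 for s in selection_log if s == BACKSPACE)
    return 1.0 - n_back / len(selection_log)


def snr_at(
    freqs: np.ndarray, amplitude: np.ndarray, target: float, n_neighbors: int = 10
) -> float:
    """Amplitude SNR at a spectral bin: target over mean of flanking bins.

    ``amplitude`` is a 1-D amplitude spectrum on the bin grid ``freqs``;
    the SNR is the amplitude at the bin nearest ``target`` divided by the
    mean amplitude of the ``n_neighbors`` bins on each side (target bin
    excluded).  Invariant to global spectrum scaling.
    """
    freqs = np.asarray(freqs, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float).ravel()
    idx = int(np.argmin(np.abs(freqs - target)))
    lo, hi = idx - n_neighbors, idx + n_neighbors + 1
    if lo < 0 or hi > amplitude.size:
        raise ValueError(
            f"need {n_neighbors} bins on each side of {target} Hz; spectrum too short"
        )
    neighbors = np.concatenate([amplitude[lo:idx], amplitude[idx + 1 : hi]])
    mean_neighbor = neighbors.mean()
    if mean_neighbor == 0:
        return float("inf")
    return float(amplitude[idx] / mean_neighbor)


@dataclass
class LearningCurveFit:
    """Fitted inverse-exponential learning curve ``a*(1 - exp(-s*(T-i)))``."""

    a: float
    s: float
    i: float
    rss: float
    degenerate: bool = False

    def predict(self, trials) -> np.ndarray:
        t = np.asarray(trials, dtype=float)
        return self.a * (1.0 - np.exp(-self.s * (t - self.i)))


def _curve(t, a, s, i):
    return a * (1.0 - np.exp(-s * (t - i)))


def fit_learning_curve(trials, accuracies) -> LearningCurveFit:
    """Least-squares fit of the inverse-exponential learning curve.

    Initialization: ``a`` at the maximum observed accuracy, ``s = 0.2``,
    ``i = 0``; bounds ``0 < a <= 1``, ``s > 0``.  A flat curve (e.g.
    noise-free data at ceiling from the first trial) is fitted with the
    asymptote pinned at the plateau and flagged ``degenerate``.

    Raises
    ------
    RuntimeError
        If the optimizer fails to converge, with scipy's diagnostics.
    """
    trials = np.asarray(trials, dtype=float)
    accuracies = np.asarray(accuracies, dtype=float)
    if trials.size < 4:
        raise ValueError(f"need >= 4 points to fit 3 parameters, got {trials.size}")
    if np.any(np.diff(trials) <= 0):
        raise ValueError("trials must be strictly increasing")

    if np.ptp(accuracies) < 1e-12:
        # already at plateau: curve is flat, steepness unidentifiable
        return LearningCurveFit(
            a=float(accuracies[0]), s=float("inf"), i=float(trials[0] - 1), rss=0.0, degenerate=True
        )

    p0 = (max(float(accuracies.max()), 1e-3), 0.2, 0.0)
    try:
        popt, _ = scipy.optimize.curve_fit(
            _curve,
            trials,
            accuracies,
            p0=p0,
            bounds=([1e-9, 1e-9, -np.inf], [1.0, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"learning-curve fit did not converge: {exc}") from exc
    rss = float(np.sum((accuracies - _curve(trials, *popt)) ** 2))
    return LearningCurveFit(a=float(popt[0]), s=float(popt[1]), i=float(popt[2]), rss=rss)


def trials_to_fraction(fit: LearningCurveFit, q: float = 0.99) -> float:
    """Trials needed to reach fraction ``q`` of the fitted asymptote.

    Closed form ``i - ln(1-q)/s`` (``i + ln(100)/s`` at the default
    ``q = 0.99``).
    """
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    return float(fit.i - np.log(1.0 - q) / fit.s)
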