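"""Offline decoder optimization analyses.

Three analyses probe the free parameters of the filter-bank CCA decoder:

* **harmonic sweep** — re-classify a labelled set while incrementally
  including an additional harmonic sub-band (1, then 1-2, ...), to find
  the per-subject optimal harmonic count;
* **training-trial sweep** — retrain the templates with an incrementally
  growing number of training trials per key (chronological inclusion) and
  fit the inverse-exponential learning curve to the resulting accuracy
  curve;
* **cross-classification** — classify each subject's single-trial EEG
  with every other subject's template bank, to gauge whether generic
  templates could replace individual calibration.

A leave-one-out evaluator estimates training-data accuracy without
circularity: the to-be-classified epoch is excluded from the SSVEP
template average, while the optimal sinusoid phases are computed once on
all the training data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .classifier import classify, classify_epochs
from .epochs import EpochSet
from .flicker_design import FlickerSpec
from .metrics import LearningCurveFit, fit_learning_curve, itr_wolpaw
from .templates import FilterBankSpec, TemplateBank, _trim_samples, bandpass, build_template_bank

__all__ = [
    "SweepResult",
    "evaluate_accuracy",
    "harmonic_sweep",
    "training_trial_sweep",
    "leave_one_out_accuracy",
    "cross_classify",
]


@dataclass
class SweepResult:
    """Accuracy (and ITR) as a function of one swept decoder parameter."""

    parameter: str
    values: list[int]
    accuracies: np.ndarray
    itrs: np.ndarray
    best_value: int
    fit: LearningCurveFit | None = field(default=None)


def evaluate_accuracy(test: EpochSet, bank: TemplateBank, n_harmonics: int | None = None) -> float:
    """Fraction of test epochs whose decided key matches their label."""
    if test.labels is None:
        raise ValueError("test EpochSet must be labelled")
    results = classify_epochs(test, bank, n_harmonics)
    return float(np.mean([r.decided_key == lab for r, lab in zip(results, test.labels)]))


def harmonic_sweep(
    training: EpochSet,
    test: EpochSet,
    spec: FlickerSpec,
    max_harmonics: int = 10,
    selection_time: float = 2.25,
    bank: TemplateBank | None = None,
) -> SweepResult:
    """Classification accuracy at 1..``max_harmonics`` harmonic sub-bands.

    The bank is trained once with every usable harmonic (counts whose
    band exceeds Nyquist are truncated with a warning); per-harmonic
    similarities are computed once per epoch and re-combined for each
    cumulative harmonic count.  The optimal count is the argmax accuracy,
    ties resolving to the fewest harmonics.
    """
    if bank is None:
        bank_spec = FilterBankSpec.from_flicker_spec(spec, n_harmonics=max_harmonics)
        bank = build_template_bank(training, spec, bank_spec)
    n_avail = len(bank.harmonics)
    if n_avail < max_harmonics:
        warnings.warn(
            f"harmonic sweep truncated to {n_avail} harmonics (Nyquist limit)", stacklevel=2
        )
    if test.labels is None:
        raise ValueError("test EpochSet must be labelled")
    epochs = test
    if epochs.channel_names != bank.selected_channels:
        epochs = epochs.select_channels(bank.selected_channels)

    # full per-harmonic similarity matrices, re-combined per count
    rhos = np.stack(
        [classify(epochs.data[e], bank).harmonic_rhos for e in range(epochs.n_epochs)]
    )  # (n_epochs, n_keys, n_avail)
    weights = 1.0 / np.asarray(bank.harmonics, dtype=float)
    accuracies = np.empty(n_avail)
    for n in range(1, n_avail + 1):
        features = (rhos[:, :, :n] ** 2 * weights[None, None, :n]).sum(axis=2)
        decided = np.argmax(features, axis=1)
        accuracies[n - 1] = np.mean(
            [bank.spec.key_order[d] == lab for d, lab in zip(decided, epochs.labels)]
        )
    itrs = np.array(
        [itr_wolpaw(spec.n_keys, min(a, 1.0), selection_time) for a in accuracies]
    )
    best = int(np.argmax(accuracies)) + 1  # argmax returns first max -> fewest harmonics
    return SweepResult(
        parameter="n_harmonics",
        values=list(range(1, n_avail + 1)),
        accuracies=accuracies,
        itrs=itrs,
        best_value=best,
    )


def _first_k_trials(training: EpochSet, spec: FlickerSpec, k: int) -> EpochSet:
    """Chronologically first ``k`` epochs of each key, in original order."""
    counts = {symbol: 0 for symbol in spec.key_order}
    keep = []
    for e, lab in enumerate(training.labels):
        if counts.get(lab, k) < k:
            counts[lab] += 1
            keep.append(e)
    return training.subset(keep)


def training_trial_sweep(
    training: EpochSet,
    test: EpochSet,
    spec: FlickerSpec,
    max_trials: int = 20,
    bank_spec: FilterBankSpec | None = None,
    selection_time: float = 2.25,
) -> SweepResult:
    """Accuracy vs number of training trials per key, with learning-curve fit.

    Templates are retrained for each trial count, including the
    chronologically first ``k`` trials of each key.  The resulting curve
    is fitted with the inverse exponential ``a*(1 - exp(-s*(T-i)))``; a
    flat (already-at-ceiling) curve yields a degenerate-flagged fit.
    """
    if training.labels is None:
        raise ValueError("training EpochSet must be labelled")
    min_reps = min(len([1 for lab in training.labels if lab == s]) for s in spec.key_order)
    if min_reps < max_trials:
        raise ValueError(f"need >= {max_trials} reps per key, have {min_reps}")

    accuracies = np.empty(max_trials)
    for k in range(1, max_trials + 1):
        subset = _first_k_trials(training, spec, k)
        bank = build_template_bank(subset, spec, bank_spec)
        accuracies[k - 1] = evaluate_accuracy(test, bank)
    itrs = np.array(
        [itr_wolpaw(spec.n_keys, min(a, 1.0), selection_time) for a in accuracies]
    )
    fit = (
        fit_learning_curve(np.arange(1, max_trials + 1), accuracies)
        if max_trials >= 4
        else None
    )
    best = int(np.argmax(accuracies)) + 1
    return SweepResult(
        parameter="n_training_trials",
        values=list(range(1, max_trials + 1)),
        accuracies=accuracies,
        itrs=itrs,
        best_value=best,
        fit=fit,
    )


def leave_one_out_accuracy(
    training: EpochSet,
    spec: FlickerSpec,
    bank_spec: FilterBankSpec | None = None,
    n_harmonics: int | None = None,
) -> float:
    """Training-set accuracy with the classified epoch held out of its template.

    For each epoch, the SSVEP template of its cued key is recomputed from
    the remaining trials of that key; the sinusoid phases (and all other
    keys' templates) come from the full-data bank.
    """
    if training.labels is None:
        raise ValueError("training EpochSet must be labelled")
    bank = build_template_bank(training, spec, bank_spec)
    n_trim = _trim_samples(bank.trim, bank.fs)

    correct = 0
    for symbol in spec.key_order:
        idx = [e for e, lab in enumerate(training.labels) if lab == symbol]
        if len(idx) < 2:
            raise ValueError(f"key {symbol!r} needs >= 2 epochs for leave-one-out")
        k = spec.key_order.index(symbol)
        # per-harmonic filtered epochs for this key (for cheap template updates)
        filt = np.stack(
            [
                bandpass(training.data[idx], bank.bank_spec.band(j), bank.fs,
                         bank.bank_spec.filter_order)[:, :, n_trim:]
                for j in bank.harmonics
            ],
            axis=1,
        )  # (reps, n_harm, ch, samples)
        total = filt.sum(axis=0)
        full_row = bank.ssvep[k].copy()
        for r, e in enumerate(idx):
            bank.ssvep[k] = (total - filt[r]) / (len(idx) - 1)
            result = classify(training.data[e], bank, n_harmonics)
            correct += result.decided_key == symbol
        bank.ssvep[k] = full_row
    return correct / training.n_epochs


def cross_classify(
    banks: list[TemplateBank], test_sets: list[EpochSet], n_harmonics: int | None = None
) -> np.ndarray:
    """Cross-subject accuracy matrix.

    ``matrix[m, n]`` is the accuracy of subject ``n``'s labelled epochs
    classified with subject ``m``'s template bank; the diagonal is
    self-classification.  All banks and test sets must share the flicker
    design and sampling rate.
    """
    ref = banks[0]
    for bank in banks[1:]:
        if bank.fs != ref.fs or bank.spec.key_order != ref.spec.key_order or not np.allclose(
            bank.spec.frequencies, ref.spec.frequencies
        ):
            raise ValueError("all template banks must share flicker spec and fs")
    out = np.empty((len(banks), len(test_sets)))
    for m, bank in enumerate(banks):
        for n, test in enumerate(test_sets):
            out[m, n] = evaluate_accuracy(test, bank, n_harmonics)
    return out
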