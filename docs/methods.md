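# Methods

This note documents the models, conventions and free parameters behind
`ssvepkit`, and what the synthetic test bench does and does not establish
about real EEG.

## Flicker design

Keys are assigned joint linear frequency/phase schedules
fᵢ = f₀ + Δf·(i−1), φᵢ = (φ₀ + Δφ·(i−1)) mod 2π, with defaults
f₀ = 10.0 Hz, Δf = 0.2 Hz, φ₀ = 1.5π, Δφ = 0.35π over 28 keys
(10.0 Hz/1.5π … 15.4 Hz/0.95π). The frequency range starts at 10 Hz to
limit endogenous alpha-band interference while staying well below flicker
fusion. Keys map to frequencies in QWERTY reading order (Q…P, A…L, Z…M,
backspace, space); that mapping is a convention — any spatial assignment
can be supplied via `key_order`. Phases are stored reduced to [0, 2π);
the key index is 1-based in the API to match the schedule definitions.

## Synthetic EEG generator

`SimConfig`/`simulate_epoch` produce flicker-locked epochs containing
exactly the structure the decoder exploits, plus the nuisance terms that
limit it:

| component | default | notes |
| --- | --- | --- |
| sampling rate | 256 Hz | keeps 5 harmonic bands (≤ 78 Hz) under Nyquist while fast; real recordings use 1–2 kHz |
| epoch length | 1.5 s | one flicker period |
| SSVEP harmonics | 2.0, 1.0, 0.5, 0.3, 0.2 µV | decaying amplitudes at j·fᵢ; free parameters, plausible for occipital scalp EEG but not fitted to data |
| onset latency τ | 0.13 s | response is zero before τ and phase-shifted by −2π·j·f·τ after; frequency-independent |
| gain topography | Oz 1.0 … Fz 0.1 | per-channel multiplicative gains; optionally per-key (channels × keys) |
| onset transient | 5 µV, 80 ms decay | frequency-non-specific exponential at epoch start; deterministic, removed by the 0.25 s trim |
| alpha interference | 3 µV, 8–12 Hz | single sinusoid, frequency and phase drawn per epoch — deliberately phase-misaligned with flicker |
| background noise | 2 µV RMS, 1/f¹ | spectrally shaped white noise, independent per channel; exponent configurable (β < 0 gives high-frequency-weighted noise for harmonic-sweep scenarios) |

Latency is implemented as zero signal before τ (physical onset), not a
circular shift. A *double flicker epoch* is two consecutive periods with
identical deterministic content (phase reset between them) and
independent noise/alpha draws; averaging them halves noise variance,
which is the mechanism behind the accuracy gain for low-SNR users. All
randomness derives from a single master seed through `SeedSequence`
spawning, so every data set is bit-reproducible.

What the generator does *not* emulate: volume-conduction correlations
between channels (noise is channel-independent), non-stationarity,
blinks/eye movements, amplifier drift beyond a linear trend, or realistic
alpha bursting. Tests passing on this bench therefore establish the
*algorithmic* correctness and the qualitative parameter dependencies
(noise level, trial count, harmonic count, latency mismatch) — not
expected accuracies for human subjects.

## Preprocessing

Average reference → per-channel linear detrend → whole-epoch baseline
subtraction → zero-phase second-order IIR notch (default 50 Hz, Q = 30,
forward–backward). Whole-epoch baseline is used because epochs start at
flicker onset and no pre-stimulus window exists. The notch is not exactly
idempotent on broadband data: each pass re-attenuates the notch shoulder
that finite-epoch leakage repopulates (a few percent RMS on 1/f noise);
the remaining steps are exactly idempotent. For streaming use the
zero-phase (non-causal) filtering would need a causal replacement.

Amplitude spectra use zero-padding to 5 s (0.2 Hz bins, separating
adjacent flicker frequencies) and the convention 2·|X(f)|/N_unpadded, so
a unit sinusoid spanning the epoch reads 1 at its bin. Channel selection
keeps, per fundamental, the k = 4 candidates with maximal trial-averaged
amplitude (union over keys, candidate-list order, earlier candidate wins
exact ties).

## Template training

Harmonic sub-band j spans j·(f₁−Δf) … j·(f₂₈+Δf) Hz (9.8–15.6 Hz for
j = 1 at the defaults); filters are 4th-order Butterworth applied
forward–backward so templates stay phase-aligned with the sinusoids.
Harmonics whose band would exceed Nyquist are dropped with a warning.
Every correlated series — template SSVEPs, sinusoids, and the single
trial at classification time — is trimmed of its first 0.25 s, and
sinusoids are generated on the full epoch timeline before trimming so
their phase reference is flicker onset.

The optimal sinusoid phase is searched on a 20-point grid (0 … 1.9π),
separately per frequency and harmonic. At each candidate phase, every
training epoch is canonically correlated with sinusoids at *all* flicker
frequencies at that same phase (matched-phase convention; a
per-frequency-independent search is a possible variant), and votes
correct iff its cued frequency wins. Two refinements matter numerically:

* **Tie-breaking.** With clean data the vote share is a 0/1 plateau over
  several adjacent phases; among tied phases the one with the largest
  mean canonical correlation at the cued frequency is taken (then the
  lowest phase). On noisy data accuracies are distinct and this reduces
  to a plain argmax.
* **Half-cycle convention.** A canonical correlation is invariant to the
  sinusoid's sign, so φ and φ+π are indistinguishable to the search — and
  to the classifier, which is provably invariant to the flip. The
  optimizer resolves the half-cycle against the polarity of the dominant
  (largest-RMS) template channel when the flipped phase is on the grid,
  which makes the stored phase equal the physical SSVEP phase
  φᵢ − 2π·j·fᵢ·τ on raw data with a positive-gain dominant channel. Note
  that average referencing can invert a channel's effective polarity, so
  this identity is a raw-topography property; inside the preprocessed
  pipeline the phase only matters mod π.

## Classification

`cca_first` computes the first canonical correlation through
rank-revealing SVD whitening: orthonormal time-course bases of both
(centered) series sets, then the SVD of their inner-product matrix. Rank
truncation at 10⁻¹⁰ of the leading singular value makes the computation
well-defined for rank-deficient inputs, which arise routinely
(average-referenced channels sum to zero; noise-free channels are scaled
copies). Weight vectors are recovered by back-substitution through the
whitening.

The five weighted correlations per key/sub-band use spatial-filter
transfers for the two terms whose literal form would apply a scalar
sinusoid weight to a multi-channel series: r(3) applies the x-side filter
of CCA(x,Z) to Y, r(5) applies the Y-side filter of CCA(Y,Z) to both x
and Y; r(4) correlates the two projections of Y under the CCA(x,Y)
filters. The sub-band combination ρ = Σ sign(r)·r² keeps
counter-correlated components from reinforcing; the harmonic combination
R = Σⱼ ρ²/j deliberately squares away ρ's sign. Argmax ties (degenerate
inputs only) resolve to the lowest key index with a logged warning.

## Metrics

* **Wolpaw ITR**: bits/selection = log₂N + P log₂P + (1−P) log₂((1−P)/(N−1)),
  with 0·log 0 ≡ 0 (so P = 1 gives log₂N) scaled by 60/T. Below-chance P
  returns the formula value with a warning — no clamping, since negative
  excursions carry information about degenerate runs.
* **Selection time** T includes the flicker-free interval: 2.25 s
  (1.5 + 0.75) for free communication, 2.0 s (1.5 + 0.5) for the training
  timing.
* **Free-communication accuracy** counts a selection correct only when it
  types the next target character; misclassifications *and* the
  backspaces that repair them are superfluous relative to the target and
  count as errors (one corrected error on a length-L target scores
  L/(L+2)). When no target exists (genuine conversation),
  `backspace_proxy_accuracy` = 1 − backspace share is the documented
  proxy.
* **SNR** (no canonical definition exists for the amplitude-spectrum
  ratio): target bin over the mean of 10 bins on each side, target
  excluded; invariant to global scaling; neighbor count configurable.
* **Learning curve** ACC = a(1 − e^{−s(T−i)}) is fitted by bounded
  least squares (a ← max accuracy, s ← 0.2, i ← 0; 0 < a ≤ 1, s > 0).
  Perfectly flat curves are returned with the asymptote pinned and a
  `degenerate` flag instead of an unidentifiable s.
  trials_to_fraction(q) = i − ln(1−q)/s.

## Session simulation

The corrective policy intends the next target character while the buffer
is a prefix of the target and backspace otherwise; backspace on an empty
buffer is a no-op that still consumes a selection and counts toward the
abort budget of 3× the target length. A session's classification channel
is pluggable: the full simulate→preprocess→classify pipeline, a uniform
confusion channel (useful because its session-length distribution has an
exact absorbing-Markov-chain form, used as an independent oracle in the
tests), or any callable. The EMG enter key (mean 50–100 Hz FFT amplitude
of a 1 s frontal window above a per-user threshold, ≥ 4 s cool-down) is
excluded from accuracy and ITR.

## Problem sizes

The test suite and examples run at reduced scale by design: 2–8 training
trials per key (not 20), 6-key toy keyboards for the sweep analyses, and
256 Hz sampling. The decoding chain is size-agnostic; the noise-free
oracle and the phase-recovery study run at the full 28 keys. The
low-SNR double-epoch comparison uses a calibrated 2.8 µV RMS noise level
chosen to put single-epoch accuracy near 60%, the regime where epoch
averaging has room to help.

## Known limitations

* Sinusoid phases are only identified mod π from CCA; the stored
  convention is anchored to raw-channel polarity (see above).
* The notch stage is not strictly idempotent (shoulder re-attenuation).
* No artifact rejection, online template adaptation, probabilistic
  outputs, dynamic stopping or predictive text; the harmonic weighting
  1/j and the filter order are fixed design constants, not fitted.
* Cross-subject analyses assume identical montages and flicker designs
  across subjects.
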