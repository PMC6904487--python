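import numpy as np
import pytest

import ssvepkit as sk
from ssvepkit.epochs import EpochSet
from ssvepkit.preprocessing import OCCIPITOPARIETAL_CANDIDATES, fft_amplitude_spectrum


def _epochset(data, fs=256.0, labels=None, channel_names=None):
    return EpochSet(np.asarray(data, float), labels, fs, channel_names or [])


class TestPreprocess:
    def test_constant_epoch_becomes_zero(self):
        es = _epochset(np.full((1, 4, 256), 7.3))
        out = sk.preprocess(es)
        assert np.max(np.abs(out.data)) < 1e-9

    def test_linear_ramp_removed(self):
        t = np.arange(256)
        data = np.stack([np.outer([1.0, -2.0, 0.5], t)])  # per-channel ramps
        out = sk.preprocess(_epochset(data))
        assert np.sqrt(np.mean(out.data**2)) < 1e-9

    def test_average_reference_zeroes_channel_mean(self, spec28):
        cfg = sk.SimConfig(seed=2)
        es = sk.simulate_training_set(spec28, cfg, reps_per_key=1)
        out = sk.preprocess(es)
        cross_channel_mean = out.data.mean(axis=1)
        assert np.max(np.abs(cross_channel_mean)) < 1e-9 * np.max(np.abs(out.data))

    def test_mains_tone_attenuated(self):
        fs = 256.0
        t = np.arange(int(1.5 * fs)) / fs
        tone = 10.0 * np.sin(2 * np.pi * 50.0 * t)
        carrier = np.sin(2 * np.pi * 11.0 * t)
        data = np.stack([np.stack([tone + carrier, -tone + carrier])])
        out = sk.preprocess(_epochset(data, fs=fs), notch_hz=50.0)
        freqs, amp = fft_amplitude_spectrum(out.data[0], fs=fs, pad_to=5.0)
        residual = amp[:, np.argmin(np.abs(freqs - 50.0))]
        assert np.all(residual < 1.0)  # >= 20 dB down from 10 uV

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match="referenc"):
            sk.preprocess(_epochset(np.random.default_rng(0).normal(size=(2, 1, 256))))

    def test_idempotent(self, spec28):
        """A second cleaning pass leaves the data essentially unchanged.

        Referencing, detrending and baseline correction are exactly
        idempotent; the IIR notch re-attenuates its shoulder band slightly
        on each pass (spectral leakage of finite epochs), which bounds the
        achievable tolerance at the few-percent level on broadband data.
        """
        es = sk.simulate_training_set(spec28, sk.SimConfig(seed=6), reps_per_key=1)
        once = sk.preprocess(es)
        twice = sk.preprocess(once)
        rms = np.sqrt(np.mean(once.data**2))
        assert np.sqrt(np.mean((twice.data - once.data) ** 2)) < 0.05 * rms
        # without the notch the pipeline is exactly idempotent
        once_nn = sk.preprocess(es, notch_hz=None)
        twice_nn = sk.preprocess(once_nn, notch_hz=None)
        assert np.sqrt(np.mean((twice_nn.data - once_nn.data) ** 2)) < 1e-9 * rms


class TestFFTAmplitudeSpectrum:
    def test_zero_signal_zero_spectrum(self):
        freqs, amp = fft_amplitude_spectrum(np.zeros((2, 384)), fs=256.0)
        assert np.all(amp == 0)

    def test_bin_spacing_follows_padding(self):
        freqs, _ = fft_amplitude_spectrum(np.zeros((1, 384)), fs=256.0, pad_to=5.0)
        assert np.diff(freqs)[0] == pytest.approx(0.2)

    def test_unit_sinusoid_peak_location_and_scale(self):
        fs = 256.0
        t = np.arange(int(1.5 * fs)) / fs
        sig = np.sin(2 * np.pi * 12.0 * t)
        freqs, amp = fft_amplitude_spectrum(sig, fs=fs, pad_to=5.0)
        mask = freqs > 1.0
        assert freqs[mask][np.argmax(amp[0, mask])] == pytest.approx(12.0)
        assert amp[0, np.argmin(np.abs(freqs - 12.0))] == pytest.approx(1.0, rel=0.05)

    def test_pad_shorter_than_epoch_rejected(self):
        with pytest.raises(ValueError):
            fft_amplitude_spectrum(np.zeros((1, 384)), fs=256.0, pad_to=1.0)


class TestSelectChannels:
    def _informative_set(self, spec, informative, candidates, fs=256.0, reps=2):
        """Signal only on `informative`; white noise elsewhere."""
        rng = np.random.default_rng(11)
        n = int(1.5 * fs)
        t = np.arange(n) / fs
        data, labels = [], []
        for key in range(1, spec.n_keys + 1):
            for _ in range(reps):
                epoch = 0.05 * rng.standard_normal((len(candidates), n))
                sig = np.sin(2 * np.pi * spec.frequencies[key - 1] * t)
                for name in informative:
                    epoch[candidates.index(name)] += 5.0 * sig
                data.append(epoch)
                labels.append(spec.key_order[key - 1])
        return EpochSet(np.stack(data), labels, fs, list(candidates))

    def test_informative_channel_selected(self, toy_spec):
        candidates = ["Fz", "Cz", "Oz", "Pz"]
        es = self._informative_set(toy_spec, ["Oz"], candidates)
        picked = sk.select_channels(es, candidates, k=1, spec=toy_spec)
        assert picked == ["Oz"]

    def test_k_at_least_candidate_count_returns_all(self, toy_spec):
        candidates = ["Fz", "Oz"]
        es = self._informative_set(toy_spec, ["Oz"], candidates)
        assert sk.select_channels(es, candidates, k=5, spec=toy_spec) == candidates

    def test_exact_tie_prefers_earlier_candidate(self, toy_spec):
        candidates = ["A1", "A2", "A3"]
        fs, n = 256.0, 384
        t = np.arange(n) / fs
        data, labels = [], []
        for key in range(1, toy_spec.n_keys + 1):
            sig = np.sin(2 * np.pi * toy_spec.frequencies[key - 1] * t)
            data.append(np.stack([sig, sig, 0.0 * sig]))  # A1 == A2 exactly
            labels.append(toy_spec.key_order[key - 1])
        es = EpochSet(np.stack(data), labels, fs, candidates)
        assert sk.select_channels(es, candidates, k=1, spec=toy_spec) == ["A1"]

    def test_occipital_topography_returns_occipital_names(self, spec28):
        """With an occipitally weighted gain map over the standard 20-name
        candidate list, only high-gain posterior sites are retained."""
        candidates = list(OCCIPITOPARIETAL_CANDIDATES)
        occipital = {"Iz", "O1", "Oz", "O2", "PO7", "PO3", "POz", "PO8", "PO4"}
        gains = np.array([1.0 if c in occipital else 0.05 for c in candidates])
        cfg = sk.SimConfig(
            channel_names=tuple(candidates), channel_gains=gains,
            noise_amplitude=0.5, alpha_amplitude=0.0, seed=13,
        )
        es = sk.simulate_training_set(spec28, cfg, reps_per_key=1)
        picked = sk.select_channels(es, candidates, k=4, spec=spec28)
        assert set(picked) <= occipital

    def test_invalid_k_rejected(self, toy_spec):
        es = self._informative_set(toy_spec, ["Oz"], ["Fz", "Oz"])
        with pytest.raises(ValueError):
            sk.select_channels(es, ["Fz", "Oz"], k=0, spec=toy_spec)


class TestAverageDoubleEpoch:
    def test_identity_and_cancellation(self):
        x = np.random.default_rng(1).normal(size=(3, 100))
        assert np.allclose(sk.average_double_epoch(x, x), x)
        assert np.allclose(sk.average_double_epoch(x, -x), 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sk.average_double_epoch(np.zeros((2, 10)), np.zeros((3, 10)))

    def test_noise_variance_halved(self):
        """Averaging independent unit-variance pairs gives variance ~0.5."""
        rng = np.random.default_rng(5)
        a = rng.standard_normal((1000, 64))
        b = rng.standard_normal((1000, 64))
        var = np.var(sk.average_double_epoch(a, b))
        assert var == pytest.approx(0.5, rel=0.05)
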