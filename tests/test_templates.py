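import numpy as np
import pytest

import ssvepkit as sk
from ssvepkit.epochs import EpochSet
from ssvepkit.templates import (
    FilterBankSpec,
    PhaseGrid,
    _trim_samples,
    bandpass,
    build_ssvep_templates,
    optimize_sinusoid_phase,
)


class TestHarmonicBand:
    @pytest.mark.parametrize(
        "j, expected",
        [
            (1, (9.8, 15.6)),
            (2, (19.6, 31.2)),
            (5, (49.0, 78.0)),
        ],
    )
    def test_band_edges(self, j, expected):
        assert sk.harmonic_band(j, 10.0, 15.4, 0.2) == pytest.approx(expected)

    def test_zero_margin(self):
        assert sk.harmonic_band(3, 10.0, 15.4, 0.0) == pytest.approx((30.0, 46.2))

    def test_invalid_harmonic(self):
        with pytest.raises(ValueError):
            sk.harmonic_band(0, 10.0, 15.4, 0.2)


class TestBandpass:
    fs = 256.0

    def _tone(self, f, seconds=3.0):
        t = np.arange(int(seconds * self.fs)) / self.fs
        return np.sin(2 * np.pi * f * t)

    def test_passband_tone_preserved(self):
        tone = self._tone(12.0)
        out = bandpass(tone, (9.8, 15.6), self.fs)
        core = slice(len(tone) // 4, -len(tone) // 4)  # avoid edge transients
        ratio = np.max(np.abs(out[core])) / np.max(np.abs(tone[core]))
        assert ratio >= 0.95

    def test_stopband_tone_attenuated(self):
        tone = self._tone(40.0)
        out = bandpass(tone, (9.8, 15.6), self.fs)
        assert np.max(np.abs(out)) <= 0.1

    def test_zero_signal_stays_zero(self):
        assert np.allclose(bandpass(np.zeros(512), (9.8, 15.6), self.fs), 0.0)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(512), (60.0, 200.0), self.fs)


class TestFilterBankSpec:
    def test_from_flicker_spec_matches_closed_form(self, spec28):
        bs = FilterBankSpec.from_flicker_spec(spec28)
        for j in range(1, 6):
            assert bs.band(j) == pytest.approx(
                (j * (10.0 - 0.2), j * (15.4 + 0.2))
            )

    def test_nyquist_guard_drops_high_harmonics(self, spec28):
        bs = FilterBankSpec.from_flicker_spec(spec28, n_harmonics=10)
        with pytest.warns(UserWarning, match="Nyquist"):
            usable = bs.usable_harmonics(fs=256.0)
        assert usable == [1, 2, 3, 4, 5, 6, 7, 8]  # 9*15.6 > 128 Hz


class TestPhaseGrid:
    def test_default_grid(self):
        grid = PhaseGrid()
        assert len(grid) == 20
        assert grid.phases[0] == 0.0
        assert grid.phases[-1] == pytest.approx(1.9 * np.pi)
        assert np.allclose(np.diff(grid.phases), 0.1 * np.pi)


class TestSsvepTemplates:
    def test_average_of_identical_epochs_is_the_filtered_epoch(self, toy_spec):
        cfg = sk.SimConfig(noise_amplitude=0, alpha_amplitude=0, seed=0)
        one = sk.simulate_epoch(1, toy_spec, cfg)
        data = np.stack([one] * 5)
        es = EpochSet(data, [toy_spec.key_order[0]] * 5, cfg.fs, list(cfg.channel_names))
        # single-key spec to satisfy per-key coverage
        spec1 = sk.build_flicker_spec(n_keys=1, key_order=[toy_spec.key_order[0]])
        bs = FilterBankSpec.from_flicker_spec(toy_spec)
        out = build_ssvep_templates(es, spec1, bs)
        n_trim = _trim_samples(0.25, cfg.fs)
        expected = bandpass(one, bs.band(1), cfg.fs)[:, n_trim:]
        assert np.allclose(out[0, 0], expected, atol=1e-10)

    def test_template_length_after_trim(self, noiseless_bank28):
        assert noiseless_bank28.ssvep.shape[-1] == 320  # (1.5 - 0.25) * 256

    def test_missing_key_raises(self, toy_spec):
        cfg = sk.SimConfig(seed=0)
        es = sk.simulate_training_set(toy_spec, cfg, reps_per_key=1)
        partial = es.subset([i for i, lab in enumerate(es.labels) if lab != "K3"])
        with pytest.raises(ValueError, match="K3"):
            build_ssvep_templates(partial, toy_spec)

    def test_template_error_shrinks_with_reps(self, toy_spec):
        """Template -> signal RMS error decays roughly as 1/sqrt(reps)."""
        spec1 = sk.build_flicker_spec(n_keys=1, key_order=["K1"])
        cfg = sk.SimConfig(noise_amplitude=2.0, alpha_amplitude=0.0, seed=5)
        clean = sk.simulate_epoch(1, spec1, cfg.replace(noise_amplitude=0.0))
        bs = FilterBankSpec.from_flicker_spec(spec1)
        n_trim = _trim_samples(0.25, cfg.fs)
        target = bandpass(clean, bs.band(1), cfg.fs)[:, n_trim:]
        errors = []
        for reps in (4, 64):
            data = np.stack([sk.simulate_epoch(1, spec1, cfg, seed=s) for s in range(reps)])
            es = EpochSet(data, ["K1"] * reps, cfg.fs, list(cfg.channel_names))
            tpl = build_ssvep_templates(es, spec1, bs)
            errors.append(np.sqrt(np.mean((tpl[0, 0] - target) ** 2)))
        # 16x reps -> ~4x error reduction; allow broad Monte-Carlo slack
        assert errors[1] < errors[0] / 2.5


class TestOptimizeSinusoidPhase:
    def _filtered_epochs(self, spec, cfg, key, harmonic, reps=2):
        bs = FilterBankSpec.from_flicker_spec(spec)
        n_trim = _trim_samples(0.25, cfg.fs)
        data = np.stack(
            [sk.simulate_epoch(key, spec, cfg, seed=100 + r) for r in range(reps)]
        )
        return bandpass(data, bs.band(harmonic), cfg.fs)[:, :, n_trim:]

    @pytest.mark.parametrize("tau", [0.0, 0.05])
    def test_recovers_tau_implied_phase(self, spec28, tau):
        cfg = sk.SimConfig(
            noise_amplitude=0, alpha_amplitude=0, onset_transient_amplitude=0,
            latency_tau=tau, seed=0,
        )
        for key in (1, 14, 28):
            filt = self._filtered_epochs(spec28, cfg, key, harmonic=1)
            phi, acc = optimize_sinusoid_phase(filt, key, 1, spec28, cfg.fs)
            expected = (spec28.phases[key - 1] - 2 * np.pi * spec28.frequencies[key - 1] * tau) % (2 * np.pi)
            delta = abs(np.angle(np.exp(1j * (phi - expected))))
            assert delta <= 0.1 * np.pi + 1e-9
            assert acc.max() == 1.0

    def test_single_phase_grid_returned(self, spec28):
        cfg = sk.SimConfig(noise_amplitude=0, alpha_amplitude=0, seed=0)
        filt = self._filtered_epochs(spec28, cfg, 1, harmonic=1)
        grid = PhaseGrid(phases=np.array([0.7 * np.pi]))
        phi, acc = optimize_sinusoid_phase(filt, 1, 1, spec28, cfg.fs, grid=grid)
        assert phi == pytest.approx(0.7 * np.pi)
        assert acc.shape == (1,)

    def test_empty_epochs_rejected(self, spec28):
        with pytest.raises(ValueError):
            optimize_sinusoid_phase(np.empty((0, 4, 320)), 1, 1, spec28, 256.0)


class TestTemplateBank:
    def test_default_bank_counts(self, noiseless_bank28):
        assert noiseless_bank28.n_templates == 140  # 28 keys x 5 harmonics
        assert noiseless_bank28.ssvep.shape[:2] == (28, 5)
        assert noiseless_bank28.sinusoid.shape[:2] == (28, 5)
        assert noiseless_bank28.ssvep.shape[-1] == noiseless_bank28.sinusoid.shape[-1]

    def test_toy_bank_counts(self):
        spec = sk.build_flicker_spec(n_keys=2)
        cfg = sk.SimConfig(noise_amplitude=0, alpha_amplitude=0, seed=0)
        es = sk.preprocess(sk.simulate_training_set(spec, cfg, reps_per_key=1))
        bank = sk.build_template_bank(
            es, spec, FilterBankSpec.from_flicker_spec(spec, n_harmonics=1)
        )
        assert bank.n_templates == 2

    def test_rebuild_is_deterministic_and_serializable(self, tmp_path, toy_spec):
        cfg = sk.SimConfig(seed=3)
        es = sk.preprocess(sk.simulate_training_set(toy_spec, cfg, reps_per_key=2))
        a = sk.build_template_bank(es, toy_spec)
        b = sk.build_template_bank(es, toy_spec)
        assert np.array_equal(a.ssvep, b.ssvep)
        assert np.array_equal(a.phases, b.phases)
        path = tmp_path / "bank.h5"
        a.to_hdf5(path)
        loaded = sk.TemplateBank.from_hdf5(path)
        assert np.array_equal(loaded.ssvep, a.ssvep)
        assert np.array_equal(loaded.sinusoid, a.sinusoid)
        assert loaded.selected_channels == a.selected_channels
        assert loaded.spec.key_order == a.spec.key_order


def test_phase_recovery_property_many_subjects(spec28):
    """Across seeded noiseless subjects with random tau in [0, 0.1] s, nearly
    all fundamental-harmonic optimal phases land within one grid step of the
    closed-form prediction phi - 2*pi*f*tau."""
    rng = np.random.default_rng(2024)
    bs = FilterBankSpec.from_flicker_spec(spec28)
    n_trim = _trim_samples(0.25, 256.0)
    hits = total = 0
    for s in range(10):
        tau = rng.uniform(0.0, 0.1)
        cfg = sk.SimConfig(
            noise_amplitude=0, alpha_amplitude=0, onset_transient_amplitude=0,
            latency_tau=tau, seed=3000 + s,
        )
        for key in range(1, 29):
            data = np.stack(
                [sk.simulate_epoch(key, spec28, cfg, seed=10 * key + r) for r in range(2)]
            )
            filt = bandpass(data, bs.band(1), cfg.fs)[:, :, n_trim:]
            phi, _ = optimize_sinusoid_phase(filt, key, 1, spec28, cfg.fs)
            expected = (
                spec28.phases[key - 1] - 2 * np.pi * spec28.frequencies[key - 1] * tau
            ) % (2 * np.pi)
            delta = abs(np.angle(np.exp(1j * (phi - expected))))
            hits += delta <= 0.1 * np.pi + 1e-9
            total += 1
    assert hits / total >= 0.95
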