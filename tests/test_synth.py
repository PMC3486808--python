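"""Synthetic note/ripple generation, stimulus prep and simulated observers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import hilbert

from cortimbre import synth
from cortimbre.similarity import DissimilarityMatrix


def _spectrum_peak_hz(w: synth.Waveform) -> float:
    spec = np.abs(np.fft.rfft(w.samples))
    freqs = np.fft.rfftfreq(w.samples.size, 1.0 / w.sample_rate)
    return float(freqs[np.argmax(spec)])


class TestSynthNote:
    def test_single_harmonic_is_pure_tone(self):
        p = synth.NoteParams(f0=440.0, n_harmonics=1, vibrato_depth=0.0,
                             shimmer_depth=0.0, attack=0.01, duration=0.5)
        w = synth.synth_note(p, seed=0)
        assert abs(_spectrum_peak_hz(w) - 440.0) < 4.0

    def test_reproducible_for_fixed_seed(self):
        p = synth.INSTRUMENTS["oboe"]
        a = synth.synth_note(p, seed=5)
        b = synth.synth_note(p, seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)
        c = synth.synth_note(p, seed=6)
        assert not np.array_equal(a.samples, c.samples)

    def test_attack_changes_envelope_not_average_spectrum(self):
        """Same harmonic content, different attack: long-run average spectra
        agree (direct FFT oracle) while temporal envelopes differ."""
        base = synth.NoteParams(f0=330.0, attack=0.005, decay=10.0,
                                sustain_level=1.0, duration=2.0)
        fast = synth.synth_note(base, seed=3)
        from dataclasses import replace
        slow = synth.synth_note(replace(base, attack=0.2), seed=3)
        # compare average spectra over the common steady-state portion
        sl = slice(8000, 32000)
        sp_f = np.abs(np.fft.rfft(fast.samples[sl]))
        sp_s = np.abs(np.fft.rfft(slow.samples[sl]))
        keep = sp_f > sp_f.max() * 1e-3
        assert np.allclose(sp_f[keep], sp_s[keep], rtol=0.02)
        env_f = np.abs(hilbert(fast.samples))[:4000]
        env_s = np.abs(hilbert(slow.samples))[:4000]
        assert env_f[800:1600].mean() > 2 * env_s[800:1600].mean()

    def test_vibrato_modulates_instantaneous_frequency(self):
        """6-Hz vibrato: the instantaneous frequency oscillates 6 times/s."""
        p = synth.NoteParams(f0=440.0, n_harmonics=1, attack=0.0, decay=10.0,
                             sustain_level=1.0, vibrato_rate=6.0,
                             vibrato_depth=0.02, duration=2.0)
        w = synth.synth_note(p, seed=0)
        phase = np.unwrap(np.angle(hilbert(w.samples)))
        inst_f = np.diff(phase) * w.sample_rate / (2 * np.pi)
        inst_f = inst_f[4000:28000]  # steady portion, 1.5 s
        dev = inst_f - inst_f.mean()
        crossings = np.sum(np.diff(np.signbit(dev)) != 0)
        cycles = crossings / 2 / 1.5
        assert abs(cycles - 6.0) < 0.5

    def test_harmonics_above_nyquist_truncated(self, caplog):
        p = synth.NoteParams(f0=3000.0, n_harmonics=10, duration=0.3)
        import logging

        with caplog.at_level(logging.WARNING, logger="cortimbre.synth"):
            w = synth.synth_note(p, seed=0)
        assert "Nyquist" in caplog.text
        # a kept-but-aliased 3rd harmonic (9 kHz) would fold to 7 kHz;
        # only window leakage may sit there
        spec = np.abs(np.fft.rfft(w.samples))
        freqs = np.fft.rfftfreq(w.samples.size, 1 / w.sample_rate)
        band = (freqs > 6900) & (freqs < 7100)
        assert spec[band].max() < spec.max() * 1e-3

    @pytest.mark.parametrize("bad", [
        dict(f0=-1.0), dict(sustain_level=1.5), dict(attack=-0.1),
        dict(vibrato_depth=-0.01),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            synth.NoteParams(f0=bad.pop("f0", 220.0), **bad)


class TestSynthRipple:
    def test_zero_rate_zero_scale_is_static_flat(self):
        w = synth.synth_ripple(0.0, 0.0, "down", duration=0.5)
        # every carrier keeps a constant envelope: the signal's RMS over
        # disjoint windows is stable
        x = w.samples
        rms = [np.sqrt(np.mean(x[i : i + 2000] ** 2)) for i in range(0, 6000, 2000)]
        assert np.ptp(rms) / np.mean(rms) < 0.1

    def test_envelope_drift_matches_request(self):
        """Demodulation oracle: each carrier's envelope is a sinusoid at the
        ripple rate whose phase advances across carriers by 2*pi*scale per
        octave, with the sign set by the direction."""
        rate, scale = 8.0, 1.0
        for direction, sgn in (("down", 1.0), ("up", -1.0)):
            w = synth.synth_ripple(rate, scale, direction, duration=1.0,
                                   carriers_per_octave=8, seed=99)
            x = w.samples
            n = x.size
            t = np.arange(n) / w.sample_rate
            x_oct = np.arange(0.0, 5.3, 1.0 / 8)
            freqs = 180.0 * 2.0**x_oct
            freqs = freqs[freqs < w.sample_rate / 2]
            phases = []
            for f in freqs[4:20]:
                spec = np.fft.rfft(x)
                fr = np.fft.rfftfreq(n, 1 / w.sample_rate)
                mask = np.abs(fr - f) < f * 0.02
                band = np.fft.irfft(spec * mask, n)
                env = np.abs(hilbert(band))
                env = env - env.mean()
                ph = np.angle(np.mean(env * np.exp(-2j * np.pi * sgn * rate * t)))
                phases.append(ph)
            dphi = np.unwrap(np.array(phases))
            slope = np.polyfit(np.log2(freqs[4:20] / 180.0), dphi, 1)[0]
            assert abs(slope - 2 * np.pi * scale) < 0.15 * 2 * np.pi

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            synth.synth_ripple(-1.0, 0.5)
        with pytest.raises(ValueError):
            synth.synth_ripple(4.0, 0.5, direction="sideways")


class TestMakeStimulus:
    def test_truncation_ramp_and_rms(self):
        w = synth.synth_note(synth.INSTRUMENTS["trumpet"], seed=0)
        s = synth.make_stimulus(w)
        assert s.samples.size == round(0.25 * w.sample_rate)
        assert abs(s.rms() - synth.RMS_REFERENCE) < 1e-9

    def test_raised_cosine_profile_on_constant_input(self):
        fs = 16000
        w = synth.Waveform(np.ones(fs), fs)
        s = synth.make_stimulus(w)
        n_ramp = round(0.05 * fs)
        expected = 0.5 * (1 + np.cos(np.pi * np.arange(1, n_ramp + 1) / n_ramp))
        tail = s.samples[-n_ramp:]
        np.testing.assert_allclose(tail / s.samples[0], expected, atol=1e-12)

    def test_equal_rms_across_inputs(self):
        a = synth.make_stimulus(synth.synth_note(synth.INSTRUMENTS["piano"], 1))
        b = synth.make_stimulus(synth.synth_note(synth.INSTRUMENTS["cello"], 2))
        assert abs(a.rms() - b.rms()) < 1e-9

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            synth.make_stimulus(synth.Waveform(np.ones(1000), 16000))


class TestPreprocess:
    def test_constant_input_attenuated(self):
        w = synth.Waveform(np.full(1600, 2.0), 16000)
        y = synth.preprocess(w).samples
        np.testing.assert_allclose(y[1:], 2.0 * 0.03, atol=1e-12)

    def test_impulse_response(self):
        x = np.zeros(100)
        x[10] = 1.0
        y = synth.preprocess(synth.Waveform(x, 16000)).samples
        assert y[10] == 1.0 and y[11] == -0.97

    def test_resampling_length_from_44100(self):
        n = 44100
        w = synth.Waveform(np.random.default_rng(0).normal(size=n), 44100)
        y = synth.preprocess(w)
        assert y.sample_rate == 16000
        assert y.samples.size == round(n * 16000 / 44100)


class TestTrialDesign:
    @pytest.mark.parametrize("n,expected", [(13, 156), (2, 2)])
    def test_trial_counts(self, n, expected):
        assert len(synth.trial_design(n, seed=0)) == expected

    def test_each_unordered_pair_twice(self):
        trials = synth.trial_design(5, seed=3)
        assert len(trials) == 20
        from collections import Counter

        c = Counter(frozenset(p) for p in trials)
        assert all(v == 2 for v in c.values())

    @given(n=st.integers(2, 12), seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_design_properties(self, n, seed):
        trials = synth.trial_design(n, seed)
        assert len(trials) == n * (n - 1)
        assert len(set(trials)) == len(trials)
        assert all(i != j for i, j in trials)

    def test_too_few_sounds(self):
        with pytest.raises(ValueError):
            synth.trial_design(1, seed=0)


class TestSimulateObserver:
    def _true(self, n=6):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(n, 3))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        return DissimilarityMatrix(d, [f"i{k}" for k in range(n)])

    def test_noiseless_is_monotone_transform(self):
        true_d = self._true()
        out = synth.simulate_observer(true_d, 0.0, seed=0)
        from scipy.stats import spearmanr

        rho = spearmanr(true_d.upper(), out.averaged.upper()).statistic
        assert rho == pytest.approx(1.0)

    def test_average_is_symmetric(self):
        out = synth.simulate_observer(self._true(), 0.3, seed=1)
        v = out.averaged.values
        np.testing.assert_allclose(v, v.T)

    def test_subject_averaging_recovers_truth(self):
        """Monte-Carlo oracle: 20 subjects at noise 0.05 average out."""
        true_d = self._true(8)
        rated = [
            synth.simulate_observer(true_d, 0.05, seed=s).averaged.upper()
            for s in range(20)
        ]
        mean = np.mean(rated, axis=0)
        r = np.corrcoef(mean, true_d.upper())[0, 1]
        assert r >= 0.95

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_observer(self._true(), -0.1, seed=0)


class TestDatasetAndIO:
    def test_dataset_consistency(self, small_dataset):
        ds = small_dataset
        assert len(ds.waveforms) == len(ds.labels) == len(ds.params) == 11 * 12
        assert set(ds.classes) == {"string", "wind", "percussion"}
        td = ds.true_dissimilarity.values
        np.testing.assert_allclose(td, td.T)
        np.testing.assert_allclose(np.diag(td), 0.0)

    def test_wav_roundtrip(self, tmp_path, violin_note):
        path = tmp_path / "note.wav"
        synth.write_wav(path, violin_note)
        back = synth.read_wav(path)
        assert back.sample_rate == violin_note.sample_rate
        np.testing.assert_allclose(back.samples, violin_note.samples, atol=1e-6)
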