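"""Cortical modulation filterbank: joint transform, control variants, STRFs."""

import numpy as np
import pytest

from cortimbre import cortical, periphery, synth
from cortimbre.cortical import RATES, SCALES


def dense_conv_oracle(z: np.ndarray, kt: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """Direct dense convolution: linear and causal in time, circular along
    the channel axis.  Independent of the FFT implementation path."""
    nc, nt = z.shape
    out = np.zeros((nc, nt), dtype=complex)
    for phi in range(nc):
        zshift = np.roll(z, phi, axis=0)
        w = ks[phi]
        for tau in range(min(kt.size, nt)):
            out[:, tau:] += zshift[:, : nt - tau] * (w * kt[tau])
    return out


def nearest(grid, value):
    return min(grid, key=lambda g: abs(np.log(g / value)))


class TestFilterbank:
    def test_rate_and_scale_lists(self):
        bank = cortical.build_filterbank()
        assert len(bank) == 242
        assert sorted({f.rate for f in bank}) == sorted(RATES)
        assert sorted({f.scale for f in bank}) == sorted(SCALES)
        assert {f.direction for f in bank} == {"up", "down"}

    def test_full_filter_space_size(self, violin_spectrogram):
        t = cortical.cortical_transform(violin_spectrogram)
        assert t.r.size == 128 * 22 * 11 == 30976

    def test_kernel_peak_calibration(self):
        """A filter's peak Fourier response sits at its nominal rate/scale."""
        fr = 500.0
        kt = cortical.temporal_kernel(16.0, fr)
        spec = np.abs(np.fft.fft(kt, 1 << 14))
        f = np.fft.fftfreq(1 << 14, 1 / fr)
        assert abs(f[np.argmax(spec)] - 16.0) < 1.0
        ks = cortical.spectral_kernel(2.0)
        sp = np.abs(np.fft.fft(ks, 1 << 12))
        sf = np.fft.fftfreq(1 << 12, cortical.CHANNEL_STEP_OCT)
        assert abs(sf[np.argmax(sp)] - 2.0) < 0.2


class TestJointTransform:
    def test_zero_spectrogram_gives_zero_tensor(self):
        spec = periphery.AuditorySpectrogram(
            np.zeros((128, 50)), 500.0, periphery.center_frequencies()
        )
        t = cortical.cortical_transform(spec)
        np.testing.assert_allclose(t.r, 0.0)

    @pytest.mark.parametrize("rate,scale,direction", [
        (16.0, 1.0, "down"), (16.0, 1.0, "up"), (32.0, 2.0, "down"),
    ])
    def test_matches_dense_convolution_oracle(self, rate, scale, direction):
        """FFT-path joint transform vs. explicit dense convolution on a
        short spectrogram, 1e-6 relative."""
        rng = np.random.default_rng(0)
        nt = 32
        z = rng.uniform(0.0, 1.0, size=(128, nt))
        spec = periphery.AuditorySpectrogram(z, 500.0, periphery.center_frequencies())
        t = cortical.cortical_transform(spec)
        kt = cortical.temporal_kernel(rate, 500.0)
        if direction == "up":
            kt = np.conj(kt)
        ks = cortical.spectral_kernel(scale)
        expected = np.abs(dense_conv_oracle(z, kt, ks)).mean(axis=1)
        ir = RATES.index(rate) + (0 if direction == "up" else 11)
        got = t.r[:, ir, SCALES.index(scale)]
        np.testing.assert_allclose(got, expected, rtol=1e-6, atol=1e-12)

    def test_ripple_selectivity_subset(self):
        for rate, scale, direction in [(8.0, 1.0, "down"), (16.0, 0.5, "up"),
                                       (4.0, 2.0, "down")]:
            spec = cortical.ripple_spectrogram(rate, scale, direction, 1.0)
            srv = cortical.scale_rate_view(cortical.cortical_transform(spec))
            r, d, s = srv.argmax()
            assert (r, d, s) == (nearest(RATES, rate), direction, nearest(SCALES, scale))

    def test_degree_one_homogeneity(self, violin_spectrogram):
        t1 = cortical.cortical_transform(violin_spectrogram).r
        z2 = periphery.AuditorySpectrogram(
            3.0 * violin_spectrogram.z, violin_spectrogram.frame_rate,
            violin_spectrogram.cfs,
        )
        t3 = cortical.cortical_transform(z2).r
        np.testing.assert_allclose(t3, 3.0 * t1, rtol=1e-6)

    def test_direction_sensitivity_of_full_tensor(self):
        up = cortical.cortical_transform(
            cortical.ripple_spectrogram(8.0, 1.0, "up", 1.0)
        ).ravel()
        dn = cortical.cortical_transform(
            cortical.ripple_spectrogram(8.0, 1.0, "down", 1.0)
        ).ravel()
        cos = up @ dn / (np.linalg.norm(up) * np.linalg.norm(dn))
        assert 1.0 - cos > 0.1


class TestScaleRateView:
    def test_frequency_constant_tensor_equals_slice(self):
        r = np.tile(np.random.default_rng(1).uniform(size=(1, 22, 11)), (128, 1, 1))
        t = cortical.CorticalTensor(r, duration=0.25)
        view = cortical.scale_rate_view(t)
        np.testing.assert_allclose(view.energy, r[0])

    def test_sum_and_mean_reductions_agree(self, violin_spectrogram):
        t = cortical.cortical_transform(violin_spectrogram)
        np.testing.assert_allclose(
            cortical.scale_rate_view(t, "sum").energy,
            128 * cortical.scale_rate_view(t, "mean").energy,
        )

    def test_piano_spreads_rates_vibrato_string_concentrates(self):
        """A rapid piano-like onset distributes energy across temporal
        modulations; a bowed note's 6-Hz vibrato concentrates its rate
        marginal near the grid rate closest to 6 Hz."""
        from dataclasses import replace

        ent = {}
        for name, p in (
            ("piano", synth.INSTRUMENTS["piano"]),
            ("violin", replace(synth.INSTRUMENTS["violin"], vibrato_depth=0.01)),
        ):
            w = synth.synth_note(replace(p, duration=1.0), seed=2)
            spec = periphery.auditory_spectrogram(synth.preprocess(w))
            m = cortical.rate_marginal(cortical.cortical_transform(spec))
            q = m / m.sum()
            ent[name] = -(q * np.log(q)).sum()
            if name == "violin":
                assert RATES[int(np.argmax(q))] == 5.7
        assert ent["piano"] > ent["violin"]


class TestSeparable:
    def test_stacked_length(self, violin_spectrogram):
        sep = cortical.separable_transform(violin_spectrogram)
        assert sep.stacked.size == 22 * 128 + 11 * 128 == 4224

    def test_zero_input(self):
        spec = periphery.AuditorySpectrogram(
            np.zeros((128, 40)), 500.0, periphery.center_frequencies()
        )
        np.testing.assert_allclose(cortical.separable_transform(spec).stacked, 0.0)

    @pytest.mark.parametrize("rate,scale", [(8.0, 1.0), (16.0, 0.5), (32.0, 2.0)])
    def test_direction_blindness(self, rate, scale):
        """Up and down ripples with the same (rate, scale) are
        indistinguishable to separable features, to 1e-6 relative."""
        up = cortical.separable_transform(
            cortical.ripple_spectrogram(rate, scale, "up", 1.0)
        ).stacked
        dn = cortical.separable_transform(
            cortical.ripple_spectrogram(rate, scale, "down", 1.0)
        ).stacked
        assert np.max(np.abs(up - dn)) <= 1e-6 * np.max(np.abs(up))


class TestGlobalModulation:
    def test_zero_input(self):
        spec = periphery.AuditorySpectrogram(
            np.zeros((128, 40)), 500.0, periphery.center_frequencies()
        )
        np.testing.assert_allclose(cortical.global_modulation(spec), 0.0)

    def test_equals_frequency_sum_of_separable(self, violin_spectrogram):
        g = cortical.global_modulation(violin_spectrogram)
        sep = cortical.separable_transform(violin_spectrogram)
        np.testing.assert_allclose(
            g, np.concatenate([sep.rf.sum(axis=1), sep.sf.sum(axis=1)]), rtol=1e-12
        )
        assert g.size == 33

    def test_matches_2d_fourier_peak_for_ripple(self):
        """The global modulation profile peaks where the 2-D Fourier
        spectrum of the spectrogram peaks."""
        rate, scale = 16.0, 1.41
        spec = cortical.ripple_spectrogram(rate, scale, "down", 1.0)
        g = cortical.global_modulation(spec)
        rate_peak = RATES[int(np.argmax(g[:11] + g[11:22]))]
        scale_peak = SCALES[int(np.argmax(g[22:]))]
        # 2-D FFT oracle
        Z = np.abs(np.fft.fft2(spec.z - spec.z.mean()))
        sf = np.fft.fftfreq(128, cortical.CHANNEL_STEP_OCT)
        tf = np.fft.fftfreq(spec.n_frames, 1 / spec.frame_rate)
        i, j = np.unravel_index(np.argmax(Z), Z.shape)
        assert rate_peak == nearest(RATES, abs(tf[j]))
        assert scale_peak == nearest(SCALES, abs(sf[i]))


class TestUndersampled:
    def test_dimension_and_zero(self, violin_spectrogram):
        v = cortical.undersampled_transform(violin_spectrogram)
        assert v.size == 64 * 10 * 6 == 3840
        zero = periphery.AuditorySpectrogram(
            np.zeros((128, 40)), 500.0, periphery.center_frequencies()
        )
        np.testing.assert_allclose(cortical.undersampled_transform(zero), 0.0)

    def test_ripple_argmax_hits_nearest_coarse_filter(self):
        spec = cortical.ripple_spectrogram(8.0, 0.5, "down", 1.0)
        v = cortical.undersampled_transform(spec).reshape(64, 10, 6)
        e = v.sum(axis=0)
        i, j = np.unravel_index(np.argmax(e), e.shape)
        labels = cortical.rate_direction_labels(cortical.UNDERSAMPLED_RATES)
        r, d = labels[i]
        assert r == nearest(cortical.UNDERSAMPLED_RATES, 8.0)
        assert d == "down"
        assert cortical.UNDERSAMPLED_SCALES[j] == nearest(
            cortical.UNDERSAMPLED_SCALES, 0.5
        )


class TestSTRF:
    def test_bank_generation_and_snr_filter(self):
        bank = cortical.synth_strf_bank(200, seed=4)
        assert len(bank) == 200
        kept = cortical.filter_by_snr(bank, 2.0)
        assert kept == [r for r in bank if r.snr >= 2.0]
        again = cortical.synth_strf_bank(200, seed=4)
        np.testing.assert_array_equal(bank[7].weights, again[7].weights)

    def test_misaligned_record_rejected(self, violin_spectrogram):
        bank = cortical.synth_strf_bank(3, seed=0)
        with pytest.raises(ValueError, match="align"):
            cortical.strf_transform(violin_spectrogram, bank)

    def test_alignment_targets_model_grid(self):
        rec = cortical.synth_strf_bank(1, seed=1)[0]
        aligned = cortical.align_strf(rec, frame_rate=500.0)
        assert aligned.is_aligned(500.0)
        assert aligned.weights.shape[1] == 128

    def test_stacked_dimension(self, violin_spectrogram):
        bank = [cortical.align_strf(r) for r in cortical.synth_strf_bank(30, seed=2)]
        for r in bank:
            r.snr = 5.0
        v = cortical.strf_transform(violin_spectrogram, bank)
        assert v.size == 30 * 128

    def test_delta_strf_recovers_profile(self, violin_spectrogram):
        w = np.zeros((1, 128))
        w[0, 64] = 1.0
        rec = cortical.STRFRecord(w, lag_step=1.0 / 500.0, snr=5.0)
        v = cortical.strf_transform(violin_spectrogram, [rec])
        np.testing.assert_allclose(
            v, violin_spectrogram.z.mean(axis=1), rtol=1e-9, atol=1e-15
        )

    def test_gabor_strf_matches_model_filter_on_ripples(self):
        """A receptive field built as the real part of the (8 Hz, 1 c/o,
        downward) model kernel responds across ripple probes like the model
        filter itself (5% on normalized response profiles)."""
        kt = cortical.temporal_kernel(8.0, 500.0)
        ks = np.roll(cortical.spectral_kernel(1.0), 64)
        strf = cortical.STRFRecord(
            np.real(np.outer(kt, ks)), lag_step=1 / 500.0, snr=5.0
        )
        probes = [(4.0, 1.0), (5.7, 1.41), (8.0, 1.0), (8.0, 2.0), (16.0, 1.0),
                  (11.3, 1.41)]
        model_resp, strf_resp = [], []
        for rate, scale in probes:
            spec = cortical.ripple_spectrogram(rate, scale, "down", 1.0)
            joint = cortical._joint_transform(
                spec.z, 500.0, cortical.CHANNEL_STEP_OCT, [8.0], [1.0]
            )
            model_resp.append(joint[:, 1, 0].sum())  # downward half
            strf_resp.append(cortical.strf_transform(spec, [strf]).sum())
        m = np.asarray(model_resp)
        s = np.asarray(strf_resp)
        np.testing.assert_allclose(s / np.linalg.norm(s), m / np.linalg.norm(m),
                                   rtol=0.05, atol=0.01)

    def test_bank_hdf5_roundtrip(self, tmp_path):
        bank = cortical.synth_strf_bank(5, seed=9)
        path = tmp_path / "bank.h5"
        cortical.save_strf_bank(path, bank)
        back = cortical.load_strf_bank(path)
        assert len(back) == 5
        np.testing.assert_allclose(back[3].weights, bank[3].weights)
        assert back[3].snr == bank[3].snr
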