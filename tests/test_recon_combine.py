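import numpy as np
import pytest

from mrsikit.exceptions import ConfigurationError, InvalidParameterError
from mrsikit.recon_combine import (
    KSpaceVolume,
    align_phase,
    apodize,
    combine_channels,
    estimate_noise,
    hamming_window_1d,
    hamming_window_2d,
    image_to_kspace,
    kspace_to_image,
    spatial_filter,
)
from mrsikit.signal_model import EchoGrid, EchoSignal, SpectralComponent, evaluate_model
from mrsikit.synthetic_data import make_echo, metabolite_components


def small_kvol(ny=16, nx=16, n_ch=1, n_sl=1, nt=8, seed=0):
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_ch, n_sl, ny, nx, nt)) + 1j * rng.standard_normal(
        (n_ch, n_sl, ny, nx, nt)
    )
    return KSpaceVolume(data, spectral_width=2000.0)


class TestSpatialFilter:
    def test_hamming_center_and_edge_values(self):
        w = hamming_window_1d(16)
        assert w[8] == pytest.approx(1.0)
        assert w[0] == pytest.approx(0.08, abs=1e-12)

    def test_none_window_is_identity(self):
        kvol = small_kvol()
        out = spatial_filter(kvol, "none")
        np.testing.assert_array_equal(out.data, kvol.data)

    def test_unknown_window_rejected(self):
        with pytest.raises(ConfigurationError):
            spatial_filter(small_kvol(), "kaiser")

    def test_convolution_theorem_on_16x16(self):
        # filtered image = unfiltered image (circularly) convolved with
        # the window's centered inverse transform
        kvol = small_kvol(16, 16, nt=2)
        img_plain = kspace_to_image(kvol)
        img_filt = kspace_to_image(spatial_filter(kvol, "hamming"))
        w = hamming_window_2d(16, 16)
        psf = np.fft.ifft2(np.fft.ifftshift(w))  # unitary DC normalization
        expected = np.empty_like(img_plain)
        for t in range(2):
            expected[0, 0, :, :, t] = np.fft.ifft2(
                np.fft.fft2(img_plain[0, 0, :, :, t]) * np.fft.fft2(psf) * 16 * 16
            ) / (16 * 16)
        # direct check: multiply in k-space == convolve in image space
        conv = np.fft.ifft2(np.fft.fft2(img_plain[0, 0, :, :, 0]) * np.fft.fft2(psf))
        np.testing.assert_allclose(
            img_filt[0, 0, :, :, 0], conv, atol=1e-10 * np.abs(img_plain).max()
        )

    def test_hamming_suppresses_psf_sidelobes(self):
        # point-spread profile through the center, 16-fold zero-padded;
        # the 16-point 0.54/0.46 window leaves ~1% amplitude sidelobes,
        # the unwindowed Dirichlet kernel ~22%
        def peak_sidelobe(win):
            n, pad = 16, 256
            kline = np.zeros(pad, dtype=complex)
            kline[(pad - n) // 2 : (pad + n) // 2] = win
            psf = np.fft.fftshift(np.abs(np.fft.ifft(np.fft.ifftshift(kline))))
            peak = psf.argmax()
            i = peak
            while psf[i + 1] < psf[i]:  # first local minimum bounds mainlobe
                i += 1
            return psf[i:].max() / psf[peak]

        filtered = peak_sidelobe(hamming_window_1d(16))
        plain = peak_sidelobe(np.ones(16))
        assert filtered <= 0.015
        assert plain >= 0.05
        assert filtered < plain / 10.0


class TestKSpaceImage:
    def test_dc_only_gives_uniform_image(self):
        data = np.zeros((1, 1, 16, 16, 1), dtype=complex)
        data[0, 0, 8, 8, 0] = 5.0
        img = kspace_to_image(KSpaceVolume(data, 2000.0))
        assert np.allclose(img, img[0, 0, 0, 0, 0])

    def test_round_trip(self):
        kvol = small_kvol(8, 8, 2, 3, 4)
        img = kspace_to_image(kvol)
        back = image_to_kspace(img)
        np.testing.assert_allclose(back, kvol.data, rtol=0, atol=1e-12)

    def test_delta_phantom_voxel_echo_matches_generator(self):
        # a single-voxel object survives the transform chain unchanged
        grid = EchoGrid(64, 2000.0)
        echo = evaluate_model(
            [SpectralComponent(3.0, -150.0, 0.2, 30.0, 0.0)], grid
        )
        image = np.zeros((1, 1, 8, 8, 64), dtype=complex)
        image[0, 0, 3, 5] = echo
        kvol = KSpaceVolume(image_to_kspace(image), 2000.0)
        voxels = kspace_to_image(kvol)
        np.testing.assert_allclose(voxels[0, 0, 3, 5], echo, atol=1e-12 * 3.0)
        off = voxels.copy()
        off[0, 0, 3, 5] = 0
        assert np.abs(off).max() < 1e-12

    def test_parseval_energy_bookkeeping(self):
        kvol = small_kvol(8, 8, 2, 1, 4)
        img = kspace_to_image(kvol)
        e_k = np.sum(np.abs(kvol.data) ** 2)
        e_img = np.sum(np.abs(img) ** 2)
        assert e_img == pytest.approx(e_k, rel=1e-10)


class TestApodize:
    def test_zero_broadening_is_identity(self, triplet_echo):
        echo, _ = triplet_echo()
        out = apodize(echo, 0.0)
        np.testing.assert_array_equal(out.samples, echo.samples)

    def test_echo_top_sample_unchanged(self, triplet_echo):
        echo, _ = triplet_echo()
        out = apodize(echo, 10.0)
        c = echo.grid.center_index
        assert out.samples[c] == echo.samples[c]

    def test_decay_free_singlet_acquires_10hz_gaussian_width(self):
        grid = EchoGrid(2048, 2000.0)
        c = SpectralComponent(1.0, 0.0, 0.0, 0.0, 0.0)
        echo = EchoSignal(evaluate_model([c], grid), grid)
        out = apodize(echo, 10.0)
        freqs, spec = out.spectrum(n_fft=65536)
        mag = np.abs(spec)
        above = freqs[mag > mag.max() / 2]
        assert above.max() - above.min() == pytest.approx(10.0, abs=0.5)

    def test_negative_broadening_rejected(self, triplet_echo):
        echo, _ = triplet_echo()
        with pytest.raises(InvalidParameterError):
            apodize(echo, -1.0)


class TestEstimateNoise:
    def test_recovers_programmed_sd_within_15_percent(self):
        rng = np.random.default_rng(1)
        sigma = 2.5
        spec = sigma * (rng.standard_normal(512) + 1j * rng.standard_normal(512))
        est = estimate_noise(spec, slice(0, 128))
        assert est == pytest.approx(sigma, rel=0.15)

    def test_noise_free_spectrum_gives_zero(self):
        assert estimate_noise(np.zeros(256, dtype=complex), slice(0, 64)) <= 1e-10

    def test_scales_linearly(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal(256) + 1j * rng.standard_normal(256)
        e1 = estimate_noise(base, slice(0, 128))
        e3 = estimate_noise(3.0 * base, slice(0, 128))
        assert e3 == pytest.approx(3.0 * e1, rel=1e-12)

    def test_region_overlapping_peak_band_rejected(self):
        spec = np.ones(256, dtype=complex)
        with pytest.raises(ConfigurationError):
            estimate_noise(spec, slice(0, 64), peak_bands=[(60, 80)])

    def test_short_region_rejected(self):
        with pytest.raises(ConfigurationError):
            estimate_noise(np.ones(256, dtype=complex), slice(0, 16))


class TestAlignPhase:
    def test_pre_rotated_copies_align_identically(self, triplet_echo):
        echo, _ = triplet_echo()
        rotated = echo.copy_with(echo.samples * np.exp(1j * np.pi / 2))
        a, b = align_phase([echo, rotated])
        np.testing.assert_allclose(a.samples, b.samples, atol=1e-12 * 108)

    def test_echo_top_is_real_nonnegative_after_alignment(self):
        e = make_echo(metabolite_components(), noise_sd=0.2, seed=9)
        (aligned,) = align_phase([e.copy_with(e.samples * np.exp(0.7j))])
        top = aligned.samples[np.argmax(np.abs(aligned.samples))]
        assert abs(top.imag) < 1e-12 * abs(top)
        assert top.real > 0

    def test_aligned_channels_sum_coherently(self):
        base = make_echo(metabolite_components(), noise_sd=0.0)
        echoes = [
            base.copy_with(base.samples * g * np.exp(1j * ph))
            for g, ph in [(1.0, 0.3), (0.7, -2.0), (1.3, 2.8)]
        ]
        aligned = align_phase(echoes)
        tops = [e.samples[np.argmax(np.abs(e.samples))] for e in aligned]
        assert abs(sum(tops)) == pytest.approx(sum(abs(t) for t in tops), rel=1e-12)

    def test_zero_echo_passed_through(self, grid256):
        zero = EchoSignal(np.zeros(256, dtype=complex), grid256)
        (out,) = align_phase([zero])
        np.testing.assert_array_equal(out.samples, zero.samples)


class TestCombineChannels:
    def test_identical_channels_reproduce_single_channel(self, triplet_echo):
        echo, _ = triplet_echo()
        combined, weights = combine_channels([echo] * 4, [0.5] * 4)
        np.testing.assert_allclose(combined.samples, echo.samples, atol=1e-12 * 108)
        assert all(w.weight == pytest.approx(0.25) for w in weights)

    def test_noisy_channel_weight_vanishes(self, triplet_echo):
        echo, _ = triplet_echo()
        _, weights = combine_channels([echo, echo], [0.5, 1e9])
        assert weights[1].weight < 1e-12

    def test_zero_noise_sd_rejected(self, triplet_echo):
        echo, _ = triplet_echo()
        with pytest.raises(ConfigurationError):
            combine_channels([echo], [0.0])

    def test_combined_noise_variance_formula(self):
        # programmed-noise fixture: var(combined) == sum w_i^2 sigma_i^2
        rng = np.random.default_rng(4)
        base = make_echo(metabolite_components(), noise_sd=0.0).samples
        sds = [0.3, 0.8, 0.5, 1.1]
        echoes = [
            EchoSignal.from_samples(
                base + sd * (rng.standard_normal(256) + 1j * rng.standard_normal(256)),
                2000.0,
            )
            for sd in sds
        ]
        combined, weights = combine_channels(echoes, sds)
        pred_var = sum(w.weight**2 * w.noise_sd**2 for w in weights)
        resid = combined.samples - base * sum(
            w.weight * 1.0 for w in weights
        )  # equal true amplitudes
        # empirical variance per real channel over 512 samples
        emp = 0.5 * np.var(np.concatenate([resid.real, resid.imag])) * 2
        assert emp == pytest.approx(pred_var, rel=0.35)

    def test_default_weights_maximize_snr_among_random_normalized_weights(self):
        rng = np.random.default_rng(5)
        amps = np.array([1.0, 0.6, 1.4, 0.9, 0.3, 1.1, 0.8, 0.5])
        sds = np.array([0.4, 0.9, 0.5, 0.3, 1.2, 0.6, 0.7, 1.0])
        w_opt = (amps / sds**2) / np.sum(amps / sds**2)
        snr_opt = np.sum(w_opt * amps) / np.sqrt(np.sum(w_opt**2 * sds**2))
        for _ in range(1000):
            w = rng.random(8)
            w /= w.sum()
            snr = np.sum(w * amps) / np.sqrt(np.sum(w**2 * sds**2))
            assert snr <= snr_opt * (1 + 1e-12)

    def test_combined_snr_beats_best_single_channel(self):
        # seeded 8-channel fixtures with varying gains, phases and noise
        rng = np.random.default_rng(3)
        base = make_echo(metabolite_components(), noise_sd=0.0).samples
        region_sel = None
        for _ in range(3):
            echoes, sds = [], []
            for _c in range(8):
                gain = 0.4 + rng.random()
                phase = rng.uniform(-np.pi, np.pi)
                sd = 0.3 * (1 + rng.random())
                noisy = gain * np.exp(1j * phase) * base + sd * (
                    rng.standard_normal(256) + 1j * rng.standard_normal(256)
                )
                echoes.append(EchoSignal.from_samples(noisy, 2000.0))
                sds.append(sd)

            def snr(echo):
                freqs, spec = echo.spectrum()
                region = np.flatnonzero((freqs >= 300) & (freqs <= 900))
                return np.abs(spec).max() / estimate_noise(spec, region)

            combined, _ = combine_channels(align_phase(echoes), sds)
            assert snr(combined) >= max(snr(e) for e in echoes)
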