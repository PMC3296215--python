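import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrsikit.exceptions import IdentifiabilityError, InvalidParameterError
from mrsikit.signal_model import (
    CRLBResult,
    EchoGrid,
    EchoSignal,
    SpectralComponent,
    compute_crlb,
    decay_to_fwhm,
    evaluate_model,
    fisher_information,
    fwhm_to_decay,
    model_jacobian,
    wrap_phase,
)


class TestEvaluateModel:
    def test_decay_free_on_carrier_component_is_constant(self, grid256):
        c = SpectralComponent(48.0, 0.0, 0.0, 0.0, 0.0)
        s = evaluate_model([c], grid256)
        assert np.allclose(s, 48.0 + 0.0j)

    def test_echo_top_sums_amplitudes(self, triplet, grid256):
        # at t = 0 every zero-phase singlet contributes its full amplitude
        s = evaluate_model(triplet("lorentzian"), grid256)
        assert s[grid256.center_index] == pytest.approx(24 + 36 + 48, abs=1e-12)

    def test_lorentzian_fwhm_matches_alpha_over_pi(self):
        grid = EchoGrid(1024, 2000.0)
        c = SpectralComponent(1.0, 0.0, 0.0, math.pi * 10.0, 0.0)
        echo = EchoSignal(evaluate_model([c], grid), grid)
        freqs, spec = echo.spectrum(n_fft=65536)
        mag = np.abs(spec)
        above = freqs[mag > mag.max() / 2]
        assert above.max() - above.min() == pytest.approx(10.0, abs=0.5)

    def test_negative_decay_rejected(self, grid256):
        bad = SpectralComponent(1.0, 0.0, 0.0, -1.0, 0.0)
        with pytest.raises(InvalidParameterError):
            evaluate_model([bad], grid256)

    def test_negative_amplitude_rejected_at_construction(self):
        with pytest.raises(InvalidParameterError):
            SpectralComponent(-1.0, 0.0)

    @settings(max_examples=25, deadline=None)
    @given(
        a1=st.floats(0.1, 100.0),
        a2=st.floats(0.1, 100.0),
        f1=st.floats(-900.0, 900.0),
        f2=st.floats(-900.0, 900.0),
        alpha=st.floats(0.0, 100.0),
    )
    def test_linearity_in_components(self, a1, a2, f1, f2, alpha):
        grid = EchoGrid(64, 2000.0)
        c1 = SpectralComponent(a1, f1, 0.3, alpha, 0.0)
        c2 = SpectralComponent(a2, f2, -0.7, 0.0, 50.0)
        both = evaluate_model([c1, c2], grid)
        sep = evaluate_model([c1], grid) + evaluate_model([c2], grid)
        np.testing.assert_allclose(both, sep, rtol=0, atol=1e-12 * (a1 + a2))

    def test_two_sided_decay_magnitude_symmetry(self, grid256):
        # |S(t)| at paired indices t = +/- k dt matches for phi = f = 0
        c = SpectralComponent(5.0, 0.0, 0.0, 40.0, 300.0)
        s = np.abs(evaluate_model([c], grid256))
        center = grid256.center_index
        for k in (1, 5, 50, 120):
            assert s[center + k] == pytest.approx(s[center - k], rel=1e-12)


class TestEchoGrid:
    def test_time_axis_is_symmetric_with_dt_from_sw(self):
        grid = EchoGrid(256, 2000.0)
        assert grid.dt == pytest.approx(1 / 2000.0)
        t = grid.times
        assert t[0] == pytest.approx(-grid.dt * 128)
        assert t[-1] == pytest.approx(grid.dt * 127)
        assert t[grid.center_index] == 0.0

    def test_spectrum_phase_referred_to_echo_top(self, grid256):
        # a zero-phase on-resonance component yields a (near-)real spectrum
        c = SpectralComponent(1.0, 250.0, 0.0, 60.0, 0.0)
        echo = EchoSignal(evaluate_model([c], grid256), grid256)
        _, spec = echo.spectrum()
        peak = np.argmax(np.abs(spec))
        assert abs(spec[peak].imag) < 1e-6 * abs(spec[peak].real)


class TestFwhmConversion:
    @pytest.mark.parametrize(
        "fwhm, kind, expected",
        [
            (10.0, "lorentzian", math.pi * 10.0),
            (10.0, "gaussian", math.pi**2 * 100.0 / (4 * math.log(2))),
            (0.0, "lorentzian", 0.0),
            (0.0, "gaussian", 0.0),
        ],
    )
    def test_known_values(self, fwhm, kind, expected):
        assert fwhm_to_decay(fwhm, kind) == pytest.approx(expected, rel=1e-12)

    def test_reference_magnitudes(self):
        # alpha = pi * 10 ~ 31.4159 1/s; beta = pi^2 * 100 / (4 ln 2) ~ 355.9707 1/s^2
        assert fwhm_to_decay(10.0, "lorentzian") == pytest.approx(31.4159, abs=1e-4)
        assert fwhm_to_decay(10.0, "gaussian") == pytest.approx(355.9707, abs=1e-3)

    def test_round_trip(self):
        for kind in ("lorentzian", "gaussian"):
            assert decay_to_fwhm(fwhm_to_decay(7.3, kind), kind) == pytest.approx(7.3)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(InvalidParameterError):
            fwhm_to_decay(-1.0, "lorentzian")


class TestCRLB:
    def test_bounds_scale_linearly_in_noise(self, triplet, grid256):
        comps = triplet("lorentzian")
        r1 = compute_crlb(comps, "lorentzian", grid256, 1.0)
        r2 = compute_crlb(comps, "lorentzian", grid256, 2.0)
        np.testing.assert_allclose(r2.bounds, 2.0 * r1.bounds, rtol=1e-12)

    def test_amplitude_only_closed_form(self, grid256):
        alpha = 25.0
        c = SpectralComponent(10.0, 100.0, 0.2, alpha, 0.0)
        sigma = 0.7
        res = compute_crlb([c], "lorentzian", grid256, sigma, free=["A[0]"])
        expected = sigma / np.sqrt(np.sum(np.exp(-2 * alpha * np.abs(grid256.times))))
        assert res.bounds[0] == pytest.approx(expected, rel=1e-10)

    def test_analytic_jacobian_matches_finite_differences(self, triplet, grid256):
        comps = triplet("voigt")
        kind = "voigt"
        jac = model_jacobian(comps, kind, grid256)
        # central finite differences on the packed parameter vector
        from mrsikit.fitting import _pack, _unpack

        x0 = _pack(comps, kind)
        labels = [c.label for c in comps]
        num = np.empty_like(jac)
        for j in range(x0.size):
            h = 1e-6 * max(abs(x0[j]), 1.0)
            xp, xm = x0.copy(), x0.copy()
            xp[j] += h
            xm[j] -= h
            sp = evaluate_model(_unpack(xp, kind, labels), grid256, validate=False)
            sm = evaluate_model(_unpack(xm, kind, labels), grid256, validate=False)
            num[:, j] = (sp - sm) / (2 * h)
        scale = np.abs(jac).max()
        np.testing.assert_allclose(jac, num, atol=2e-6 * scale)

    def test_fisher_from_jacobian_matches_finite_difference_fisher(self, triplet, grid256):
        comps = triplet("lorentzian")
        fim = fisher_information(comps, "lorentzian", grid256, 1.0)
        from mrsikit.fitting import _pack, _unpack

        x0 = _pack(comps, "lorentzian")
        labels = [c.label for c in comps]
        cols = []
        for j in range(x0.size):
            h = 1e-6 * max(abs(x0[j]), 1.0)
            xp, xm = x0.copy(), x0.copy()
            xp[j] += h
            xm[j] -= h
            sp = evaluate_model(_unpack(xp, "lorentzian", labels), grid256, validate=False)
            sm = evaluate_model(_unpack(xm, "lorentzian", labels), grid256, validate=False)
            cols.append((sp - sm) / (2 * h))
        jn = np.stack(cols, axis=1)
        fim_num = np.real(jn.conj().T @ jn)
        # matrix-norm relative agreement (elementwise fails on ~0 cross terms)
        rel = np.linalg.norm(fim - fim_num) / np.linalg.norm(fim)
        assert rel < 1e-6

    def test_colliding_frequencies_raise_identifiability_error(self, grid256):
        a = SpectralComponent(10.0, 100.0, 0.0, 30.0, 0.0)
        b = SpectralComponent(10.0, 100.0 + 1e-9, 0.0, 30.0, 0.0)
        with pytest.raises(IdentifiabilityError):
            compute_crlb([a, b], "lorentzian", grid256, 1.0)

    def test_positive_bounds_and_tags(self, triplet, grid256):
        res = compute_crlb(triplet("voigt"), "voigt", grid256, 0.5)
        assert isinstance(res, CRLBResult)
        assert np.all(res.bounds > 0)
        assert set(res.amplitude_bounds()) == {"NAA", "Cr", "Cho"}


def test_wrap_phase_into_half_open_interval():
    assert wrap_phase(math.pi) == pytest.approx(math.pi)
    assert wrap_phase(-math.pi) == pytest.approx(math.pi)
    assert wrap_phase(3 * math.pi / 2) == pytest.approx(-math.pi / 2)
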