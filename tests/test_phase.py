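import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oftphase.exceptions import ConfigurationError, DataError
from oftphase.io import PhaseMethod, PhaseRepresentation
from oftphase.phase import (analytic_signal, dft_phase, extract_representation,
                            hilbert_phase, phase_slope, unwrap, wrap)
from tests.conftest import FS, make_epoch


def _wrapped_rep(values):
    return PhaseRepresentation(values=np.asarray(values, float),
                               method=PhaseMethod.HILBERT_PHASE, wrapped=True)


class TestWrap:
    def test_principal_interval(self, rng):
        x = rng.uniform(-50, 50, 10_000)
        w = wrap(x)
        assert np.all((w > -np.pi) & (w <= np.pi))

    def test_boundary_maps_to_plus_pi(self):
        np.testing.assert_allclose(wrap(np.array([np.pi, -np.pi, 3 * np.pi])),
                                   [np.pi, np.pi, np.pi])

    def test_identity_inside_interval(self, rng):
        x = rng.uniform(-np.pi + 1e-9, np.pi, 1000)
        np.testing.assert_allclose(wrap(x), x, atol=1e-12)


class TestDftPhase:
    def test_cosine_has_zero_phase_at_its_bin(self):
        n, k0 = 1024, 37
        epoch = make_epoch(np.cos(2 * np.pi * k0 * np.arange(n) / n))
        rep = dft_phase(epoch)
        assert rep.values[k0] == pytest.approx(0.0, abs=1e-9)
        assert rep.wrapped and rep.axis == "frequency_bins"
        assert len(rep) == n // 2 + 1

    def test_sine_is_in_quadrature(self):
        n, k0 = 1024, 37
        epoch = make_epoch(np.sin(2 * np.pi * k0 * np.arange(n) / n))
        assert dft_phase(epoch).values[k0] == pytest.approx(-np.pi / 2, abs=1e-9)

    def test_conjugate_antisymmetry_of_real_input(self, rng):
        # brute-force full DFT: arg X(N-k) == -arg X(k) for real sequences
        x = rng.standard_normal(128)
        full = np.array([np.sum(x * np.exp(-2j * np.pi * k * np.arange(128) / 128))
                         for k in range(128)])
        for k in range(1, 64):
            assert np.angle(full[128 - k]) == pytest.approx(-np.angle(full[k]),
                                                            abs=1e-8)
        np.testing.assert_allclose(dft_phase(make_epoch(x)).values,
                                   np.angle(full[:65]), atol=1e-8)

    def test_non_finite_input_rejected(self):
        with pytest.raises(DataError):
            dft_phase(make_epoch([1.0, np.nan, 0.0, 0.0]))


class TestAnalyticSignal:
    def test_real_part_equals_input(self, noise_epoch):
        a = analytic_signal(noise_epoch)
        np.testing.assert_allclose(a.values.real, noise_epoch.samples, atol=1e-9)

    def test_cosine_gets_quadrature_imaginary_part(self, tone_epoch):
        a = analytic_signal(tone_epoch)
        t = np.arange(len(tone_epoch)) / FS
        trim = len(tone_epoch) // 20
        np.testing.assert_allclose(a.values.imag[trim:-trim],
                                   np.sin(2 * np.pi * 1000.0 * t)[trim:-trim],
                                   atol=5e-3)

    def test_constant_input_has_no_imaginary_part(self):
        a = analytic_signal(make_epoch(np.full(512, 2.5)))
        assert np.max(np.abs(a.values.imag)) < 1e-9

    def test_unit_tone_envelope_is_flat(self, tone_epoch):
        a = analytic_signal(tone_epoch)
        trim = len(tone_epoch) // 20
        np.testing.assert_allclose(a.envelope[trim:-trim], 1.0, atol=5e-3)

    def test_one_sided_spectrum(self, rng):
        a = analytic_signal(make_epoch(rng.standard_normal(512)))
        spectrum = np.fft.fft(a.values)
        assert np.max(np.abs(spectrum[257:])) < 1e-8 * np.max(np.abs(spectrum))

    def test_modulus_dominates_real_part(self, rng):
        a = analytic_signal(make_epoch(rng.standard_normal(512)))
        assert np.all(a.envelope >= np.abs(a.values.real) - 1e-12)

    def test_projection_property(self, rng):
        # analytic-signal of the real part of an analytic signal is itself
        a1 = analytic_signal(make_epoch(rng.standard_normal(512)))
        a2 = analytic_signal(make_epoch(a1.values.real))
        np.testing.assert_allclose(a1.values, a2.values, atol=1e-9)


class TestHilbertMinimumPhase:
    def test_impulse_has_flat_zero_phase(self):
        x = np.zeros(256)
        x[0] = 1.0
        rep = hilbert_phase(make_epoch(x))
        np.testing.assert_allclose(rep.values, 0.0, atol=1e-10)

    def test_minimum_phase_toy_matches_brute_force_dft(self):
        # h = [1, 0.5] has its zero inside the unit circle, so its DFT arg
        # *is* the minimum phase; the cepstral construction must recover it
        n = 256
        h = np.zeros(n)
        h[0], h[1] = 1.0, 0.5
        rep = hilbert_phase(make_epoch(h))
        truth = np.angle(np.fft.rfft(h))
        np.testing.assert_allclose(wrap(rep.values), truth, atol=1e-9)

    def test_delay_invariance_vs_dft_linear_ramp(self):
        n, d = 256, 9
        h = np.zeros(n)
        h[0], h[1] = 1.0, 0.5
        delayed = np.roll(h, d)
        np.testing.assert_allclose(hilbert_phase(make_epoch(h)).values,
                                   hilbert_phase(make_epoch(delayed)).values,
                                   atol=1e-9)
        k = np.arange(n // 2 + 1)
        ramp = wrap(dft_phase(make_epoch(delayed)).values
                    - dft_phase(make_epoch(h)).values + 2 * np.pi * k * d / n)
        np.testing.assert_allclose(ramp, 0.0, atol=1e-9)

    def test_analytic_time_mode_is_instantaneous_phase(self, tone_epoch):
        rep = hilbert_phase(tone_epoch, mode="analytic_time")
        assert rep.axis == "time_samples"
        assert len(rep) == len(tone_epoch)
        a = analytic_signal(tone_epoch)
        np.testing.assert_allclose(rep.values, np.angle(a.values), atol=1e-12)

    def test_all_zero_epoch_rejected(self):
        with pytest.raises(DataError):
            hilbert_phase(make_epoch(np.zeros(64)))

    def test_unknown_mode_rejected(self, noise_epoch):
        with pytest.raises(ConfigurationError):
            hilbert_phase(noise_epoch, mode="nope")


class TestPhaseSlope:
    def test_linear_phase_gives_constant_slope(self):
        c = 0.37
        rep = _wrapped_rep(wrap(c * np.arange(100)))
        slope = phase_slope(rep)
        assert len(slope) == 99
        np.testing.assert_allclose(slope.values, c, atol=1e-10)

    def test_constant_phase_gives_zero_slope(self):
        slope = phase_slope(_wrapped_rep(np.full(50, 1.2)))
        np.testing.assert_allclose(slope.values, 0.0, atol=1e-12)

    def test_tone_instantaneous_frequency(self, tone_epoch):
        rep = hilbert_phase(tone_epoch, mode="analytic_time")
        slope = phase_slope(rep)
        trim = len(tone_epoch) // 20
        expected = 2 * np.pi * 1000.0 / FS
        np.testing.assert_allclose(wrap(slope.values[trim:-trim]), expected,
                                   atol=2e-2)

    def test_requires_wrapped_input(self):
        rep = PhaseRepresentation(values=np.arange(5.0),
                                  method=PhaseMethod.HILBERT_PHASE,
                                  wrapped=False)
        with pytest.raises(ConfigurationError):
            phase_slope(rep)

    def test_too_short_input(self):
        with pytest.raises(DataError):
            phase_slope(_wrapped_rep([0.1]))


class TestUnwrap:
    def test_single_wrap_corrected(self):
        rep = _wrapped_rep([0.0, np.pi - 0.1, -np.pi + 0.1])
        np.testing.assert_allclose(unwrap(rep).values,
                                   [0.0, np.pi - 0.1, np.pi + 0.1], atol=1e-12)

    def test_continuous_sequence_unchanged(self, rng):
        x = np.cumsum(rng.uniform(-1.0, 1.0, 200) * 0.01)
        x = wrap(x)
        np.testing.assert_allclose(unwrap(_wrapped_rep(x)).values, x, atol=1e-12)

    def test_first_value_preserved_and_diffs_principal(self, rng):
        x = rng.uniform(-np.pi + 1e-9, np.pi, 500)
        u = unwrap(_wrapped_rep(x))
        assert u.values[0] == x[0]
        assert np.max(np.abs(np.diff(u.values))) <= np.pi + 1e-12
        assert not u.wrapped

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**32 - 1))
    def test_round_trip_recovers_wrapped_input(self, seed):
        x = np.random.default_rng(seed).uniform(-np.pi + 1e-9, np.pi, 200)
        u = unwrap(_wrapped_rep(x))
        np.testing.assert_allclose(wrap(u.values), x, atol=1e-9)

    def test_slope_cumsum_reconstructs_unwrapped_phase(self, noise_epoch):
        rep = hilbert_phase(noise_epoch)
        slope = phase_slope(rep)
        reconstructed = rep.values[0] + np.concatenate([[0.0], np.cumsum(slope.values)])
        np.testing.assert_allclose(reconstructed, unwrap(rep).values, atol=1e-9)


class TestExtractRepresentation:
    def test_each_method_yields_one_unwrapped_representation(self, noise_epoch):
        reps = {m: extract_representation(noise_epoch, m) for m in PhaseMethod}
        assert len(reps) == 3
        for method, rep in reps.items():
            assert not rep.wrapped
            assert rep.method is method

    def test_lengths_follow_axis_conventions(self, noise_epoch):
        n = len(noise_epoch)
        assert len(extract_representation(noise_epoch, "dft")) == n // 2 + 1
        assert len(extract_representation(noise_epoch, "hilbert")) == n // 2 + 1
        assert len(extract_representation(noise_epoch, "hilbert_slope")) == n // 2

    def test_spectral_delay_invariance_end_to_end(self, rng):
        x = rng.standard_normal(512)
        a = extract_representation(make_epoch(x), "hilbert")
        b = extract_representation(make_epoch(np.roll(x, 31)), "hilbert")
        np.testing.assert_allclose(a.values, b.values, atol=1e-8)
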