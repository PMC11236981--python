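import numpy as np
import pytest

from oftphase.exceptions import ConfigurationError, DataError
from oftphase.io import Acquisition
from oftphase.preprocess import (apply_highpass, design_highpass,
                                 segment_epochs, zscore_reject)

FS = 5000.0


def _acq(samples, fs=FS, **kw):
    kw.setdefault("acquisition_id", "a")
    return Acquisition(samples=np.asarray(samples, float), fs=fs, **kw)


def _tone(freq, duration=2.0, fs=FS):
    t = np.arange(round(fs * duration)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestFilterDesign:
    def test_butterworth_closed_form(self):
        spec = design_highpass(FS)
        f = np.array([100.0, 500.0, 1000.0, 2400.0])
        r = (f / 500.0) ** 2
        expected = r / np.sqrt(1 + r**2)
        np.testing.assert_allclose(spec.magnitude(f), expected, rtol=1e-12)

    def test_half_power_point_at_cutoff(self):
        spec = design_highpass(FS)
        assert spec.magnitude(500.0) == pytest.approx(1 / np.sqrt(2), rel=1e-12)
        # the realized digital filter matches at the design cutoff too
        assert spec.magnitude_digital([500.0])[0] == pytest.approx(1 / np.sqrt(2), rel=1e-9)

    def test_mains_attenuation_about_minus_40_db(self):
        # |H| at 50 Hz = 0.01/sqrt(1.0001), suppressing the electrical grid
        spec = design_highpass(FS)
        assert spec.magnitude(50.0) == pytest.approx(0.01 / np.sqrt(1.0001), rel=1e-12)

    def test_passband_flat_above_2_khz(self):
        spec = design_highpass(FS)
        f = np.linspace(2000.0, FS / 2 - 1, 50)
        assert np.all(spec.magnitude(f) > 0.99)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            design_highpass(FS, cutoff=2500.0)

    def test_magnitude_monotone_nondecreasing(self):
        spec = design_highpass(FS)
        mags = spec.magnitude(np.linspace(1.0, 2400.0, 200))
        assert np.all(np.diff(mags) >= 0)


class TestFilterApplication:
    @pytest.mark.parametrize("mode", ["zero_phase", "causal"])
    def test_mains_sinusoid_strongly_attenuated(self, mode):
        out = apply_highpass(_acq(_tone(50.0, 4.0)), mode=mode)
        steady = out.samples[5000:-5000]
        assert np.max(np.abs(steady)) <= 0.02

    @pytest.mark.parametrize("mode", ["zero_phase", "causal"])
    def test_carrier_sinusoid_passes(self, mode):
        out = apply_highpass(_acq(_tone(1000.0, 4.0)), mode=mode)
        steady = out.samples[5000:-5000]
        amplitude = np.sqrt(2.0) * np.sqrt(np.mean(steady**2))
        # analog-prototype |H(1 kHz)| ~ 0.970 (within 5% of unity); the
        # realized digital (bilinear) filter differs slightly near Nyquist,
        # and the zero-phase mode squares the magnitude response
        analog = design_highpass(FS).magnitude(1000.0)
        digital = design_highpass(FS).magnitude_digital([1000.0])[0]
        assert abs(analog - 1.0) < 0.05
        expected = digital**2 if mode == "zero_phase" else digital
        assert amplitude == pytest.approx(expected, rel=0.01)

    def test_zero_in_zero_out(self):
        out = apply_highpass(_acq(np.zeros(10_000)))
        assert np.allclose(out.samples, 0.0)
        assert len(out.samples) == 10_000

    def test_dc_offset_removed(self):
        out = apply_highpass(_acq(np.full(20_000, 3.7)))
        assert np.max(np.abs(out.samples[2000:-2000])) <= 3.7e-3

    def test_linearity(self, rng):
        x, y = rng.standard_normal(8_000), rng.standard_normal(8_000)
        fx = apply_highpass(_acq(2.0 * x + 0.5 * y)).samples
        fxy = 2.0 * apply_highpass(_acq(x)).samples + 0.5 * apply_highpass(_acq(y)).samples
        np.testing.assert_allclose(fx, fxy, atol=1e-10)

    def test_fs_mismatch_rejected(self):
        spec = design_highpass(4000.0)
        with pytest.raises(ConfigurationError):
            apply_highpass(_acq(np.zeros(100)), spec)


class TestSegmentation:
    def test_sixty_seconds_gives_thirty_epochs(self, rng):
        acq = _acq(rng.standard_normal(300_000))
        epochs = segment_epochs(acq, 2.0)
        assert len(epochs) == 30
        assert all(len(e) == 10_000 for e in epochs)

    def test_exactly_one_epoch(self, rng):
        assert len(segment_epochs(_acq(rng.standard_normal(10_000)), 2.0)) == 1

    def test_floor_rule_discards_remainder(self, rng):
        epochs = segment_epochs(_acq(rng.standard_normal(17_500)), 2.0)
        assert len(epochs) == 1
        assert len(epochs[0]) == 10_000

    def test_too_short_acquisition_raises(self, rng):
        with pytest.raises(DataError):
            segment_epochs(_acq(rng.standard_normal(9_000)), 2.0)

    def test_concatenation_recovers_truncated_input(self, rng):
        samples = rng.standard_normal(25_000)
        epochs = segment_epochs(_acq(samples), 2.0)
        np.testing.assert_array_equal(
            np.concatenate([e.samples for e in epochs]), samples[:20_000]
        )

    def test_epochs_inherit_class_metadata(self, rng):
        acq = _acq(rng.standard_normal(20_000), class_label="HST6", medium="PBS")
        for i, e in enumerate(segment_epochs(acq)):
            assert (e.class_label, e.medium, e.index) == ("HST6", "PBS", i)


class TestZScoreRejection:
    def test_clean_gaussian_epoch_retained(self, noise_epoch):
        retained, report = zscore_reject([noise_epoch])
        assert len(retained) == 1
        assert report.rows[0]["retained"]

    def test_injected_outlier_rejected(self):
        # a single spike among n = 37 samples standardizes to exactly
        # sqrt(n - 1) = 6, beyond the |z| > 5 criterion
        samples = np.zeros(37)
        samples[5] = 123.0
        retained, report = zscore_reject([_epoch(samples)])
        assert retained == []
        assert report.rows[0]["max_abs_z"] == pytest.approx(6.0)

    def test_boundary_is_strict_exceed(self, rng):
        epoch = _epoch(rng.standard_normal(1_000))
        z = (epoch.samples - epoch.samples.mean()) / epoch.samples.std()
        boundary = float(np.max(np.abs(z)))
        retained, _ = zscore_reject([epoch], threshold=boundary)
        assert len(retained) == 1  # equality does not "exceed"
        retained, _ = zscore_reject([epoch], threshold=boundary * (1 - 1e-12))
        assert retained == []

    def test_retained_epochs_are_standardized(self, noise_epoch):
        (epoch,), _ = zscore_reject([noise_epoch])
        assert epoch.normalized
        assert epoch.samples.mean() == pytest.approx(0.0, abs=1e-12)
        assert epoch.samples.std() == pytest.approx(1.0, rel=1e-12)

    def test_idempotent_on_retained_output(self, rng):
        epochs = [_epoch(rng.standard_normal(5_000)) for _ in range(4)]
        retained, _ = zscore_reject(epochs)
        again, report = zscore_reject(retained)
        assert len(again) == len(retained)
        for before, after in zip(retained, again):
            np.testing.assert_allclose(after.samples, before.samples, atol=1e-12)

    def test_constant_epoch_flagged_degenerate(self):
        retained, report = zscore_reject([_epoch(np.full(100, 2.0))])
        assert retained == []
        assert report.rows[0]["reason"] == "degenerate"

    def test_per_acquisition_basis_pools_parent_statistics(self, rng):
        a = _epoch(rng.standard_normal(1_000), index=0)
        b = _epoch(rng.standard_normal(1_000) + 10.0, index=1)
        retained, _ = zscore_reject([a, b], basis="per_acquisition")
        # pooled mean sits between the two epochs, so neither is centered
        assert all(abs(e.samples.mean()) > 0.1 for e in retained)


def _epoch(samples, **kw):
    from oftphase.io import Epoch
    kw.setdefault("parent_id", "p")
    return Epoch(samples=np.asarray(samples, float), fs=FS, **kw)
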