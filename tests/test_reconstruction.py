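"""Preprocessing, calibration round trips, A-scan pipeline, scan assembly."""

import numpy as np
import pytest

import miroct as m
from miroct.forward_model import dispersion_phase


def _mismatch(gdd_fs2, source):
    k0 = 2 * np.pi / (source.center_wavelength_nm * 1e-3)
    return lambda k: dispersion_phase(1.0, gdd_fs2, k, k0=k0,
                                      double_pass=False)


def _cal_from(source, spec, opds=(300.0, 900.0), mismatch=None):
    frames = m.generate_calibration_frames(spec, source, opds,
                                           mismatch_phase=mismatch)
    fa = m.preprocess(frames.frame_a, frames.dark, frames.reference)
    fb = m.preprocess(frames.frame_b, frames.dark, frames.reference)
    return m.build_calibration(fa, fb, *opds, spec)


class TestPreprocess:
    def test_sample_equal_reference_gives_zero(self, flat_source,
                                               spectrometer):
        t = m.synth_interferogram(m.ReflectorStack(()), flat_source,
                                  spectrometer, noise=False)
        fringe = m.preprocess(t.sample, t.dark, t.reference)
        assert np.allclose(fringe.values[fringe.valid], 0.0, atol=5e-3)

    def test_single_mirror_fringe_amplitude(self, flat_source, spectrometer):
        """Closed form: peak-to-peak of the normalized fringe is 4 r/sqrt(rho)
        (for rho_ref = 0.5 per splitter arm)."""
        r = 0.05
        t = m.synth_interferogram(m.ReflectorStack.single_mirror(200.0, r),
                                  flat_source, spectrometer, noise=False)
        fringe = m.preprocess(t.sample, t.dark, t.reference)
        core = t.reference.counts > 0.5 * t.reference.counts.max()
        expected = 4.0 * r / np.sqrt(0.5) * 0.5  # 2 r / sqrt(rho) each way
        assert np.ptp(fringe.values[core]) == pytest.approx(2 * r / np.sqrt(0.5) * 2,
                                                            rel=0.02)

    def test_saturated_pixels_masked(self, spectrometer):
        n = spectrometer.n_pixels
        full = spectrometer.full_well
        mk = lambda c, kind: m.RawFrame(counts=c, kind=kind,
                                        integration_ms=3.0,
                                        bit_depth=spectrometer.bit_depth)
        sample = np.full(n, 500, dtype=np.int64)
        sample[7] = full
        fringe = m.preprocess(mk(sample, "sample"),
                              mk(np.full(n, 8, dtype=np.int64), "dark"),
                              mk(np.full(n, 400, dtype=np.int64), "reference"))
        assert not fringe.valid[7]
        assert fringe.values[7] == 0.0

    def test_dead_reference_rejected(self, spectrometer):
        n = spectrometer.n_pixels
        zeros = np.zeros(n, dtype=np.int64)
        mk = lambda c, kind: m.RawFrame(counts=c, kind=kind,
                                        integration_ms=3.0, bit_depth=10)
        with pytest.raises(m.CalibrationError):
            m.preprocess(mk(zeros + 5, "sample"), mk(zeros, "dark"),
                         mk(zeros, "reference"))


class TestBuildCalibration:
    def test_recovers_true_pixel_map(self, calibration, spectrometer):
        p0, p1 = calibration.support
        k_true = spectrometer.pixel_k_midir()[p0:p1]
        k_rec = calibration.k_of_pixel[p0:p1]
        assert np.max(np.abs(k_rec - k_true) / k_true) < 1e-4

    def test_no_dispersion_phase_flat(self, calibration):
        assert np.sqrt(np.mean(calibration.dispersion_phase**2)) < 0.02

    def test_cubic_pixel_map_round_trip(self, flat_source):
        spec = m.SpectrometerModel(nonlinearity=(0.01, 0.02))
        cal = _cal_from(flat_source, spec)
        p0, p1 = cal.support
        k_true = spec.pixel_k_midir()[p0:p1]
        k_rec = cal.k_of_pixel[p0:p1]
        assert np.max(np.abs(k_rec - k_true) / k_true) < 1e-3

    def test_injected_gdd_round_trip(self, flat_source, spectrometer):
        mis = _mismatch(800.0, flat_source)
        cal = _cal_from(flat_source, spectrometer, mismatch=mis)
        injected = mis(cal.k_uniform)
        injected = injected - injected.mean()
        err = cal.dispersion_phase - injected
        assert np.sqrt(np.mean(err**2)) < 1e-2

    def test_degenerate_opds_rejected(self, flat_source, spectrometer):
        with pytest.raises(m.CalibrationError):
            m.build_calibration(np.zeros(64), np.zeros(64), 500.0, 500.0,
                                spectrometer)

    def test_phase_discontinuity_raises(self, spectrometer):
        """A phase tear larger than pi between adjacent pixels (broken
        fringe) must fail loudly, reporting the pixel index."""
        n = spectrometer.n_pixels
        p = np.arange(n)
        theta = 0.35 * p.astype(float)
        theta[n // 2:] += 1.3 * np.pi  # tear mid-array
        frame = np.cos(theta)
        with pytest.raises(m.CalibrationError):
            m.build_calibration(frame, np.cos(0.25 * p), 300.0, 900.0,
                                spectrometer)

    def test_idempotent_fixed_point(self, flat_source, spectrometer,
                                    calibration):
        """Re-deriving the calibration from frames synthesized with the same
        models reproduces the map."""
        cal2 = _cal_from(flat_source, spectrometer)
        assert np.allclose(cal2.k_uniform, calibration.k_uniform, rtol=1e-9)
        assert np.allclose(cal2.resample_positions,
                           calibration.resample_positions, atol=1e-9)


class TestReconstructAscan:
    def test_peak_at_mirror_opd(self, mirror_ascan_factory, calibration):
        a = mirror_ascan_factory(100.0)
        i = np.argmax(a.magnitude[4:]) + 4
        pre_pad_bin = np.pi / calibration.k_span
        assert abs(a.depth_um[i] - 100.0) < pre_pad_bin

    def test_flat_spectrum_sinc_width(self, mirror_ascan_factory,
                                      calibration):
        """No window: the point response is a sinc of FWHM 3.791/dK."""
        a = mirror_ascan_factory(100.0, window="none")
        assert m.peak_fwhm(a, 100.0) == pytest.approx(
            3.791 / calibration.k_span, rel=0.02)

    def test_dispersion_compensation_restores_width(self, flat_source,
                                                    spectrometer):
        mis = _mismatch(800.0, flat_source)
        cal = _cal_from(flat_source, spectrometer, mismatch=mis)
        t = m.synth_interferogram(m.ReflectorStack.single_mirror(100.0, 0.05),
                                  flat_source, spectrometer, noise=False,
                                  mismatch_phase=mis)
        fringe = m.preprocess(t.sample, t.dark, t.reference)
        a = m.reconstruct_ascan(fringe, cal, window="none")
        cal0 = _cal_from(flat_source, spectrometer)
        t0 = m.synth_interferogram(m.ReflectorStack.single_mirror(100.0, 0.05),
                                   flat_source, spectrometer, noise=False)
        f0 = m.preprocess(t0.sample, t0.dark, t0.reference)
        a0 = m.reconstruct_ascan(f0, cal0, window="none")
        assert m.peak_fwhm(a, 100.0) == pytest.approx(
            m.peak_fwhm(a0, 100.0), rel=0.05)

    def test_hanning_tradeoff(self, mirror_ascan_factory):
        """Hanning: first sidelobe down by >= 18 dB, FWHM broadened 1.4-1.8x."""
        a_none = mirror_ascan_factory(400.0, window="none", zero_pad_factor=8)
        a_hann = mirror_ascan_factory(400.0, window="hanning",
                                      zero_pad_factor=8)

        def first_sidelobe_db(a):
            mag = a.magnitude
            i = np.argmax(mag[8:]) + 8
            j = i
            while mag[j + 1] < mag[j]:
                j += 1
            k = j
            while mag[k + 1] > mag[k]:
                k += 1
            return 20 * np.log10(mag[k] / mag[i])

        drop = first_sidelobe_db(a_none) - first_sidelobe_db(a_hann)
        assert drop >= 18.0
        ratio = m.peak_fwhm(a_hann, 400.0) / m.peak_fwhm(a_none, 400.0)
        assert 1.4 <= ratio <= 1.8

    def test_parseval(self, mirror_ascan_factory):
        a = mirror_ascan_factory(250.0, window="none", zero_pad_factor=1,
                                 keep_complex=True)
        spectral_power = np.sum(np.abs(a.complex_profile) ** 2)
        # the complex profile is the FFT of the resampled signal
        n = len(a.complex_profile)
        sig_power = spectral_power / n
        # reconstruct the time-domain power independently via the inverse FFT
        sig = np.fft.ifft(a.complex_profile)
        assert np.sum(np.abs(sig) ** 2) == pytest.approx(sig_power,
                                                         rel=1e-9)

    def test_invalid_arguments(self, mirror_ascan_factory, calibration):
        with pytest.raises(ValueError):
            m.reconstruct_ascan(np.zeros(4096), calibration, window="boxcar")
        with pytest.raises(ValueError):
            m.reconstruct_ascan(np.zeros(4096), calibration,
                                zero_pad_factor=0)

    def test_end_to_end_interface_recovery(self, flat_source, spectrometer,
                                           calibration):
        """Every interface OPD lands within one pre-padding depth bin and
        the peak amplitudes are monotone in the reflectivities."""
        stack = m.ReflectorStack((m.Interface(120.0, 0.01),
                                  m.Interface(350.0, 0.02),
                                  m.Interface(700.0, 0.04)))
        t = m.synth_interferogram(stack, flat_source, spectrometer,
                                  noise=False)
        fringe = m.preprocess(t.sample, t.dark, t.reference)
        a = m.reconstruct_ascan(fringe, calibration, window="hanning")
        bin_um = np.pi / calibration.k_span
        peaks = []
        for iface in stack.interfaces:
            sel = np.abs(a.depth_um - iface.z_um) < 3 * bin_um
            i = np.argmax(np.where(sel, a.magnitude, 0.0))
            assert abs(a.depth_um[i] - iface.z_um) < bin_um
            peaks.append(a.magnitude[i])
        assert peaks[0] < peaks[1] < peaks[2]


class TestAssembleScan:
    def _ascan(self, rng):
        depth = np.arange(64) * 4.0
        mag = rng.uniform(0.1, 1.0, 64)
        return m.AScan(depth_um=depth, magnitude=mag,
                       db=20 * np.log10(mag / np.median(mag)),
                       zero_pad_factor=4)

    def test_continuous_scan_bookkeeping(self):
        rng = np.random.default_rng(0)
        scans = [self._ascan(rng) for _ in range(500)]
        b = m.assemble_scan(scans, "continuous_x", speed_mm_s=3.0,
                            integration_ms=3.0)
        assert b.meta["total_time_s"] == pytest.approx(1.5)
        assert b.meta["lateral_spacing_um"] == pytest.approx(9.0)
        assert b.image.shape == (64, 500)

    def test_thousand_lines(self):
        rng = np.random.default_rng(1)
        scans = [self._ascan(rng) for _ in range(1000)]
        b = m.assemble_scan(scans, "continuous_x", speed_mm_s=3.0,
                            integration_ms=3.0)
        assert b.meta["total_time_s"] == pytest.approx(3.0)
        assert b.meta["lateral_spacing_um"] == pytest.approx(9.0)

    def test_stepped_mode_and_volume(self):
        rng = np.random.default_rng(2)
        scans = [self._ascan(rng) for _ in range(4)]
        b = m.assemble_scan(scans, "stepped_y", step_um=10.0)
        assert np.allclose(np.diff(b.lateral_um), 10.0)
        vol = m.assemble_volume([b, b, b], step_um=10.0)
        assert len(vol.bscans) == 3

    def test_single_line_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            m.assemble_scan([self._ascan(rng)], "stepped_y", step_um=10.0)

    def test_inconsistent_depth_axes_rejected(self):
        rng = np.random.default_rng(4)
        a = self._ascan(rng)
        b = m.AScan(depth_um=a.depth_um * 2, magnitude=a.magnitude,
                    db=a.db, zero_pad_factor=4)
        with pytest.raises(ValueError):
            m.assemble_scan([a, b], "stepped_y", step_um=10.0)
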