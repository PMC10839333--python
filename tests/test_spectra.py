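"""Spectrum data model, I/O round-trips and window operations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipospec import (
    AcquisitionParams,
    PeakWindow,
    Spectrum1D,
    baseline_correct,
    integrate,
    peak_fwhm,
    read_spectrum,
    reference_to_anchor,
    total_area,
    write_spectrum,
)
from lipospec.errors import (
    ReferencingError,
    ResolutionError,
    SpectrumFormatError,
    WindowRangeError,
)

from conftest import gaussian, lorentzian


class TestSpectrumModel:
    def test_ascending_axis_stored_descending(self):
        s = Spectrum1D(ppm=[0.0, 1.0, 2.0], intensity=[1.0, 2.0, 3.0],
                       spectrometer_freq=600.13)
        assert list(s.ppm) == [2.0, 1.0, 0.0]
        assert list(s.intensity) == [3.0, 2.0, 1.0]

    @pytest.mark.parametrize(
        "ppm,intensity,err",
        [
            ([0.0, 1.0], [1.0], "equal length"),
            ([0.0], [1.0], "equal length"),
            ([0.0, 1.0, 0.5], [1, 2, 3], "monotone"),
            ([0.0, 0.0, 1.0], [1, 2, 3], "monotone"),
        ],
    )
    def test_invalid_axes_rejected(self, ppm, intensity, err):
        with pytest.raises(ValueError, match=err):
            Spectrum1D(ppm=ppm, intensity=intensity, spectrometer_freq=600.13)

    def test_acquisition_params_positive(self):
        with pytest.raises(ValueError):
            AcquisitionParams(T=298, NS=0, P1=10, RG=1)

    def test_window_ordering_enforced(self):
        with pytest.raises(ValueError):
            PeakWindow("bad", 1.0, 2.0, 2.5)


class TestIO:
    @pytest.mark.parametrize("fmt,ext", [("tsv", ".tsv"), ("jcamp_dx", ".dx")])
    def test_round_trip_identity(self, tmp_path, fmt, ext):
        acq = AcquisitionParams(T=298.0, NS=128, P1=10.0, RG=64.0)
        x = np.linspace(-1, 11, 10_000)
        y = gaussian(x, 5.0, 0.01) + 0.1 * np.sin(x)
        s = Spectrum1D(ppm=x, intensity=y, spectrometer_freq=600.13,
                       acquisition=acq, label="rt", modality="hr_nmr")
        path = str(tmp_path / f"s{ext}")
        write_spectrum(s, path, fmt)
        r = read_spectrum(path, fmt)
        np.testing.assert_allclose(r.ppm, s.ppm, rtol=1e-9)
        assert np.max(np.abs(r.intensity - s.intensity)) < 1e-9 * np.max(np.abs(y))
        assert r.acquisition == acq
        assert r.modality == "hr_nmr"
        assert r.spectrometer_freq == 600.13

    def test_tsv_ascending_input_returned_descending(self, tmp_path):
        path = tmp_path / "asc.tsv"
        rows = "\n".join(f"{x:.1f}\t{y:.1f}" for x, y in [(0.0, 5.0), (1.0, 6.0), (2.0, 7.0)])
        path.write_text("ppm\tintensity\n" + rows + "\n")
        s = read_spectrum(str(path))
        assert list(s.ppm) == [2.0, 1.0, 0.0]
        assert list(s.intensity) == [7.0, 6.0, 5.0]

    def test_jcamp_x_plus_y_table(self, tmp_path):
        path = tmp_path / "tab.dx"
        path.write_text(
            "##TITLE= t\n##JCAMP-DX= 5.00\n##XUNITS= PPM\n"
            "##.OBSERVE FREQUENCY= 600.13\n##NPOINTS= 6\n"
            "##FIRSTX= 0.0\n##LASTX= 5.0\n##XFACTOR= 1.0\n##YFACTOR= 2.0\n"
            "##XYDATA= (X++(Y..Y))\n0.0 1 2 3\n3.0 4 5 6\n##END=\n"
        )
        s = read_spectrum(str(path))
        assert s.n_points == 6
        np.testing.assert_allclose(sorted(s.intensity), [2, 4, 6, 8, 10, 12])

    def test_unparseable_file_names_offending_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("ppm\tintensity\n1.0\t2.0\nnot_a_number\toops\n")
        with pytest.raises(SpectrumFormatError, match="bad.tsv:3"):
            read_spectrum(str(path))

    def test_missing_axis_is_structural_error(self, tmp_path):
        path = tmp_path / "empty.dx"
        path.write_text("##TITLE= x\n##END=\n")
        with pytest.raises(SpectrumFormatError, match="axis|XYDATA"):
            read_spectrum(str(path))


class TestReferencing:
    def _spec_with_peak(self, center, hr_axis):
        y = gaussian(hr_axis, center, 0.005)
        return Spectrum1D(ppm=hr_axis, intensity=y, spectrometer_freq=600.13)

    def test_already_on_anchor_gives_zero_shift(self, hr_axis):
        s = self._spec_with_peak(7.26, hr_axis)
        _, shift = reference_to_anchor(s, 7.26)
        step = abs(hr_axis[1] - hr_axis[0])
        assert abs(shift) <= step

    @pytest.mark.parametrize("true_pos,anchor", [(7.31, 7.26), (4.75, 4.70)])
    def test_known_offset_recovered(self, hr_axis, true_pos, anchor):
        s = self._spec_with_peak(true_pos, hr_axis)
        ref, shift = reference_to_anchor(s, anchor, search_halfwidth=0.2)
        step = abs(hr_axis[1] - hr_axis[0])
        assert shift == pytest.approx(anchor - true_pos, abs=step)
        # peak now sits on the anchor within one grid step
        apex = ref.ppm[np.argmax(ref.intensity)]
        assert abs(apex - anchor) <= step

    def test_idempotence(self, hr_axis):
        s = self._spec_with_peak(7.30, hr_axis)
        ref1, _ = reference_to_anchor(s, 7.26)
        ref2, shift2 = reference_to_anchor(ref1, 7.26)
        step = abs(hr_axis[1] - hr_axis[0])
        assert abs(shift2) < step

    def test_no_peak_in_window_raises(self, hr_axis):
        s = self._spec_with_peak(3.0, hr_axis)
        flat = Spectrum1D(ppm=hr_axis, intensity=np.zeros_like(hr_axis),
                          spectrometer_freq=600.13)
        with pytest.raises(ReferencingError):
            reference_to_anchor(flat, 7.26, search_halfwidth=0.1)


class TestBaselineAndIntegration:
    WINDOW = PeakWindow("w", 4.0, 6.0, 5.0)

    def test_constant_offset_removed(self, hr_axis):
        s = Spectrum1D(ppm=hr_axis, intensity=np.full_like(hr_axis, 3.7),
                       spectrometer_freq=600.13)
        out = baseline_correct(s, self.WINDOW)
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-12)

    def test_linear_ramp_removed(self, hr_axis):
        s = Spectrum1D(ppm=hr_axis, intensity=2.0 * hr_axis - 1.0,
                       spectrometer_freq=600.13)
        out = baseline_correct(s, self.WINDOW)
        assert np.max(np.abs(out.intensity)) < 1e-9

    def test_lorentzian_on_ramp_area_recovered(self, hr_axis):
        gamma = 0.01
        w = PeakWindow("L", 5.0 - 100 * gamma, 5.0 + 100 * gamma, 5.0)
        y = lorentzian(hr_axis, 5.0, gamma, height=1.0) + (0.5 * hr_axis + 2.0)
        s = Spectrum1D(ppm=hr_axis, intensity=y, spectrometer_freq=600.13)
        area = integrate(s, w, baseline=True)
        assert area == pytest.approx(math.pi * gamma, rel=0.02)

    def test_zero_spectrum_integrates_to_zero(self, hr_axis):
        s = Spectrum1D(ppm=hr_axis, intensity=np.zeros_like(hr_axis),
                       spectrometer_freq=600.13)
        assert integrate(s, self.WINDOW) == 0.0

    def test_unit_height_lorentzian_closed_form(self):
        gamma = 0.01
        x = np.linspace(5.0 - 50 * gamma, 5.0 + 50 * gamma, 8001)
        s = Spectrum1D(ppm=x, intensity=lorentzian(x, 5.0, gamma, height=1.0),
                       spectrometer_freq=600.13)
        w = PeakWindow("L", x[0], x[-1], 5.0)
        # area pi*gamma, minus ~1.3% tail truncation at +/-50 gamma
        assert integrate(s, w, baseline=False) == pytest.approx(math.pi * gamma, rel=0.015)

    @given(a=st.floats(0.1, 10), b=st.floats(0.1, 10))
    @settings(max_examples=25, deadline=None)
    def test_integration_linearity(self, a, b):
        x = np.linspace(0, 10, 4001)
        y1 = gaussian(x, 5.0, 0.05)
        y2 = gaussian(x, 5.3, 0.08)
        w = PeakWindow("lin", 3.0, 7.0, 5.0)
        mk = lambda y: Spectrum1D(ppm=x, intensity=y, spectrometer_freq=600.13)
        lhs = integrate(mk(a * y1 + b * y2), w, baseline=False)
        rhs = a * integrate(mk(y1), w, baseline=False) + b * integrate(mk(y2), w, baseline=False)
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_negative_area_floored_with_warning(self, hr_axis):
        s = Spectrum1D(ppm=hr_axis, intensity=-gaussian(hr_axis, 5.0, 0.01),
                       spectrometer_freq=600.13)
        with pytest.warns(UserWarning, match="floored"):
            assert integrate(s, self.WINDOW, baseline=False) == 0.0

    def test_window_outside_axis_raises(self, hr_axis):
        s = Spectrum1D(ppm=hr_axis, intensity=np.zeros_like(hr_axis),
                       spectrometer_freq=600.13)
        with pytest.raises(WindowRangeError):
            integrate(s, PeakWindow("out", 10.0, 12.0, 11.0))

    def test_too_few_samples_raises(self):
        x = np.linspace(0, 10, 21)  # step 0.5
        s = Spectrum1D(ppm=x, intensity=np.ones_like(x), spectrometer_freq=600.13)
        with pytest.raises(ResolutionError):
            integrate(s, PeakWindow("narrow", 4.4, 5.6, 5.0))


class TestFwhm:
    def test_lorentzian_fwhm_is_two_gamma(self, hr_axis):
        gamma = 0.02
        s = Spectrum1D(ppm=hr_axis, intensity=lorentzian(hr_axis, 5.0, gamma, height=1.0),
                       spectrometer_freq=600.13)
        est = peak_fwhm(s, PeakWindow("w", 4.0, 6.0, 5.0))
        step = abs(hr_axis[1] - hr_axis[0])
        assert est.fwhm_ppm == pytest.approx(2 * gamma, abs=step)

    def test_gaussian_fwhm_closed_form(self, hr_axis):
        sigma = 0.01
        s = Spectrum1D(ppm=hr_axis, intensity=gaussian(hr_axis, 5.0, sigma),
                       spectrometer_freq=600.13)
        est = peak_fwhm(s, PeakWindow("w", 4.5, 5.5, 5.0))
        step = abs(hr_axis[1] - hr_axis[0])
        assert est.fwhm_ppm == pytest.approx(2 * math.sqrt(2 * math.log(2)) * sigma, abs=step)

    def test_hz_ppm_consistency(self, hr_axis):
        s = Spectrum1D(ppm=hr_axis, intensity=gaussian(hr_axis, 5.0, 0.01),
                       spectrometer_freq=300.3)
        est = peak_fwhm(s, PeakWindow("w", 4.5, 5.5, 5.0))
        assert est.fwhm_hz / est.fwhm_ppm == pytest.approx(300.3, rel=1e-12)

    def test_grid_refinement_halves_error(self):
        gamma = 0.02
        errs = []
        for n in (2001, 4001):
            x = np.linspace(0, 10, n)
            s = Spectrum1D(ppm=x, intensity=lorentzian(x, 5.0, gamma, height=1.0),
                           spectrometer_freq=600.13)
            est = peak_fwhm(s, PeakWindow("w", 4.0, 6.0, 5.0))
            errs.append(abs(est.fwhm_ppm - 2 * gamma))
        step_coarse = 10 / 2000
        assert errs[0] <= step_coarse
        assert errs[1] <= step_coarse / 2

    def test_windows_without_a_peak_raise(self, hr_axis):
        from lipospec.errors import EstimationError
        # a pure ramp has no peak above the local baseline
        s = Spectrum1D(ppm=hr_axis, intensity=3.0 * hr_axis + 1.0,
                       spectrometer_freq=600.13)
        with pytest.raises(EstimationError):
            peak_fwhm(s, PeakWindow("w", 4.9, 5.1, 5.0))


class TestTotalArea:
    def test_zero_spectrum(self, hr_axis):
        s = Spectrum1D(ppm=hr_axis, intensity=np.zeros_like(hr_axis),
                       spectrometer_freq=600.13)
        assert total_area(s, exclusions=[]) == 0.0

    def test_two_disjoint_lines_add(self, hr_axis):
        y = gaussian(hr_axis, 2.0, 0.01, area=1.5) + gaussian(hr_axis, 8.0, 0.02, area=0.7)
        s = Spectrum1D(ppm=hr_axis, intensity=y, spectrometer_freq=600.13)
        assert total_area(s, exclusions=[]) == pytest.approx(2.2, rel=0.01)

    def test_excluding_all_signal_leaves_zero(self, hr_axis):
        y = gaussian(hr_axis, 5.0, 0.01, area=3.0)
        s = Spectrum1D(ppm=hr_axis, intensity=y, spectrometer_freq=600.13)
        w = PeakWindow("all", 4.0, 6.0, 5.0)
        assert total_area(s, exclusions=[w]) == pytest.approx(0.0, abs=1e-6)

    def test_default_excludes_chloroform_for_extracts(self, hr_axis):
        y = gaussian(hr_axis, 7.26, 0.005, area=1.0) + gaussian(hr_axis, 1.3, 0.005, area=2.0)
        s = Spectrum1D(ppm=hr_axis, intensity=y, spectrometer_freq=600.13,
                       modality="hr_nmr")
        assert total_area(s) == pytest.approx(2.0, rel=0.01)
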