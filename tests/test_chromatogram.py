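import numpy as np
import pytest

from chromval.chromatogram import (Chromatogram, Peak, analyte_area,
                                   detect_peaks, estimate_baseline,
                                   integrate_peak, match_analyte,
                                   subtract_baseline)
from chromval.exceptions import InvalidArgumentError


def make_chrom(signal, dt=0.01):
    t = np.arange(len(signal)) * dt
    return Chromatogram(time=t, signal=np.asarray(signal, dtype=float))


def gaussian(t, apex, sigma, amplitude):
    return amplitude * np.exp(-0.5 * ((t - apex) / sigma) ** 2)


class TestChromatogramContainer:
    def test_rejects_short_or_nonmonotonic_traces(self):
        with pytest.raises(InvalidArgumentError):
            Chromatogram(time=np.arange(5.0), signal=np.zeros(5))
        t = np.arange(20.0)
        t[10] = 5.0
        with pytest.raises(InvalidArgumentError):
            Chromatogram(time=t, signal=np.zeros(20))

    def test_csv_round_trip(self, tmp_path):
        chrom = make_chrom(np.sin(np.linspace(0, 3, 50)))
        chrom.to_csv(tmp_path / "c.csv")
        back = Chromatogram.from_csv(tmp_path / "c.csv")
        np.testing.assert_allclose(back.signal, chrom.signal)


class TestBaseline:
    def test_flat_zero_signal_gives_zero_baseline(self):
        chrom = make_chrom(np.zeros(200))
        np.testing.assert_allclose(estimate_baseline(chrom, window=0.2), 0.0)

    def test_constant_offset_recovered(self):
        chrom = make_chrom(np.full(200, 7.5))
        np.testing.assert_allclose(estimate_baseline(chrom, window=0.2), 7.5)

    def test_drift_recovered_outside_peak(self):
        t = np.arange(2000) * 0.01
        drift = 0.5 * t
        chrom = Chromatogram(time=t, signal=drift + gaussian(t, 10.0, 0.05, 100.0))
        base = estimate_baseline(chrom, window=0.5)
        outside = np.abs(t - 10.0) > 1.0
        # opening preserves the ramp; smoothing leaves only edge effects
        interior = outside & (t > 0.6) & (t < t[-1] - 0.6)
        assert np.max(np.abs(base[interior] - drift[interior])) < 0.05

    def test_baseline_never_exceeds_signal_materially(self):
        t = np.arange(1000) * 0.01
        chrom = Chromatogram(time=t, signal=2.0 + gaussian(t, 5.0, 0.05, 50.0))
        base = estimate_baseline(chrom, window=0.5)
        assert np.all(base <= chrom.signal + 0.5)

    def test_window_validation(self):
        chrom = make_chrom(np.zeros(50))
        with pytest.raises(InvalidArgumentError):
            estimate_baseline(chrom, window=0.005)  # below sampling interval
        with pytest.raises(InvalidArgumentError):
            estimate_baseline(chrom, window=10.0)   # beyond trace span


class TestDetectPeaks:
    def test_flat_trace_yields_no_peaks(self):
        assert detect_peaks(make_chrom(np.zeros(100)), min_height=1.0) == []

    def test_single_gaussian_found_at_injected_apex(self):
        t = np.arange(2000) * 0.01
        chrom = Chromatogram(time=t, signal=gaussian(t, 10.0, 0.05, 10.0))
        peaks = detect_peaks(chrom, min_height=1.0)
        assert len(peaks) == 1
        assert abs(peaks[0].apex_time - 10.0) <= 0.01  # one sample

    def test_two_separated_gaussians_in_time_order(self):
        t = np.arange(2000) * 0.01
        signal = gaussian(t, 5.0, 0.05, 10.0) + gaussian(t, 12.0, 0.05, 20.0)
        peaks = detect_peaks(Chromatogram(time=t, signal=signal), min_height=1.0)
        assert len(peaks) == 2
        assert peaks[0].apex_time < peaks[1].apex_time


class TestIntegration:
    def test_rectangle_pulse_area(self):
        signal = np.zeros(200)
        signal[50:101] = 4.0  # width 0.5 min at dt=0.01
        chrom = make_chrom(signal)
        peak = Peak(apex_time=0.75, start_time=0.5, end_time=1.0, height=4.0)
        assert integrate_peak(chrom, peak) == pytest.approx(4.0 * 0.5)

    def test_triangle_area(self):
        t = np.arange(201) * 0.01
        signal = np.clip(6.0 * (1.0 - np.abs(t - 1.0) / 0.5), 0.0, None)
        chrom = Chromatogram(time=t, signal=signal)
        peak = Peak(apex_time=1.0, start_time=0.5, end_time=1.5, height=6.0)
        assert integrate_peak(chrom, peak) == pytest.approx(6.0 * 1.0 / 2.0, rel=1e-6)

    def test_gaussian_closed_form(self):
        t = np.arange(4001) * 0.0005
        amplitude, sigma = 30.0, 0.02
        chrom = Chromatogram(time=t, signal=gaussian(t, 1.0, sigma, amplitude))
        peak = Peak(apex_time=1.0, start_time=0.8, end_time=1.2, height=amplitude)
        expected = amplitude * sigma * np.sqrt(2.0 * np.pi)
        assert integrate_peak(chrom, peak) == pytest.approx(expected, rel=0.005)

    def test_additive_over_contiguous_subintervals(self):
        t = np.arange(2001) * 0.001
        chrom = Chromatogram(time=t, signal=gaussian(t, 1.0, 0.1, 5.0))
        whole = Peak(apex_time=1.0, start_time=0.5, end_time=1.5, height=5.0)
        left = Peak(apex_time=0.9, start_time=0.5, end_time=1.0, height=5.0)
        right = Peak(apex_time=1.1, start_time=1.0, end_time=1.5, height=5.0)
        total = integrate_peak(chrom, whole)
        assert integrate_peak(chrom, left) + integrate_peak(chrom, right) == \
            pytest.approx(total, rel=1e-9)

    def test_bounds_outside_trace_rejected(self):
        chrom = make_chrom(np.ones(100))
        peak = Peak(apex_time=0.5, start_time=-0.5, end_time=0.9, height=1.0)
        with pytest.raises(InvalidArgumentError):
            integrate_peak(chrom, peak)

    def test_area_invariant_to_constant_offset(self):
        t = np.arange(6001) * 0.0025
        signal = gaussian(t, 9.5, 0.05, 400.0)
        a0 = analyte_area(Chromatogram(time=t, signal=signal), 9.5)
        a1 = analyte_area(Chromatogram(time=t, signal=signal + 25.0), 9.5)
        assert a1 == pytest.approx(a0, rel=0.01)


class TestMatchAnalyte:
    def _peak(self, apex, area):
        return Peak(apex_time=apex, start_time=apex - 0.2, end_time=apex + 0.2,
                    height=1.0, area=area)

    def test_single_peak_at_expected_rt(self):
        p = self._peak(9.5, 100.0)
        assert match_analyte([p], 9.5) is p

    def test_no_peak_within_tolerance(self):
        assert match_analyte([self._peak(9.0, 100.0)], 9.5, tolerance=0.1) is None

    def test_equidistant_tie_broken_toward_larger_area(self):
        small = self._peak(9.45, 10.0)
        big = self._peak(9.55, 50.0)
        assert match_analyte([small, big], 9.5, tolerance=0.1) is big

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(InvalidArgumentError):
            match_analyte([], 9.5, tolerance=0.0)
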