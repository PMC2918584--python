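"""Mass detectors and the FTMS shoulder-peak filter."""

import math

import numpy as np
import pytest

from mzflow import (MassDetectorParams, MzPeak, ParameterError,
                    detect_centroid, detect_exact_mass, detect_local_maxima,
                    detect_recursive, detect_wavelet, filter_shoulder_peaks)
from mzflow.massdetect import MASS_DETECTORS, mexican_hat

from conftest import gaussian_spectrum, make_scan


class TestLocalMaxima:
    def test_interior_maxima(self):
        scan = make_scan([100, 101, 102, 103, 104], [1, 3, 2, 5, 4])
        peaks = detect_local_maxima(scan, MassDetectorParams(noise_level=0))
        assert [p.mz for p in peaks] == [101.0, 103.0]

    def test_boundaries_never_maxima(self):
        scan = make_scan([100, 101, 102, 103], [1, 2, 3, 4])
        assert detect_local_maxima(scan, MassDetectorParams()) == []

    def test_plateau_leftmost_point_wins(self):
        scan = make_scan([100, 101, 102, 103], [1, 5, 5, 1])
        peaks = detect_local_maxima(scan, MassDetectorParams())
        assert [p.mz for p in peaks] == [101.0]

    def test_noise_threshold(self):
        scan = make_scan([100, 101, 102], [1, 3, 1])
        assert detect_local_maxima(scan, MassDetectorParams(noise_level=3)) == []


class TestCentroid:
    def test_threshold(self):
        scan = make_scan([100, 101, 102, 103], [5, 15, 8, 20], mode="centroid")
        peaks = detect_centroid(scan, MassDetectorParams(noise_level=10))
        assert [p.intensity for p in peaks] == [15.0, 20.0]

    def test_zero_noise_is_identity_on_nonzero(self):
        scan = make_scan([100, 101, 102], [5, 0, 8], mode="centroid")
        peaks = detect_centroid(scan, MassDetectorParams(noise_level=0))
        assert [(p.mz, p.intensity) for p in peaks] == [(100.0, 5.0),
                                                        (102.0, 8.0)]

    def test_all_below_noise(self):
        scan = make_scan([100, 101], [1, 2], mode="centroid")
        assert detect_centroid(scan, MassDetectorParams(noise_level=10)) == []


class TestRecursive:
    def test_single_bump_one_peak(self):
        mz, inten = gaussian_spectrum([100.05], [100], sigma=0.02 / 2.355,
                                      mz_range=(100.0, 100.1))
        scan = make_scan(mz, inten)
        params = MassDetectorParams(noise_level=1.0, min_mz_width=0.005,
                                    max_mz_width=0.1)
        peaks = detect_recursive(scan, params)
        assert len(peaks) == 1
        assert peaks[0].mz == pytest.approx(100.05, abs=0.002)

    def test_narrow_region_discarded(self):
        mz, inten = gaussian_spectrum([100.05], [100], sigma=0.02 / 2.355,
                                      mz_range=(100.0, 100.1))
        scan = make_scan(mz, inten)
        params = MassDetectorParams(noise_level=40.0, min_mz_width=0.05,
                                    max_mz_width=0.2)
        # above-40 region of a FWHM-0.02 bump is ~0.02 Da wide < 0.05
        assert detect_recursive(scan, params) == []

    def test_merged_bumps_split(self):
        mz, inten = gaussian_spectrum([100.03, 100.12], [100, 90],
                                      sigma=0.02, mz_range=(99.95, 100.2))
        scan = make_scan(mz, inten)
        params = MassDetectorParams(noise_level=5.0, min_mz_width=0.005,
                                    max_mz_width=0.1)
        peaks = detect_recursive(scan, params)
        assert len(peaks) == 2
        assert peaks[0].mz == pytest.approx(100.03, abs=0.005)
        assert peaks[1].mz == pytest.approx(100.12, abs=0.005)


def exact_mass_oracle(mz, inten, noise):
    """Independent FWHM-midpoint computation by explicit interpolation."""
    out = []
    for i in range(1, len(inten) - 1):
        if inten[i] <= noise or inten[i] <= inten[i - 1]:
            continue
        j = i
        while j + 1 < len(inten) and inten[j + 1] == inten[i]:
            j += 1
        if j + 1 >= len(inten) or inten[j + 1] >= inten[i]:
            continue
        half = inten[i] / 2
        left = right = None
        k = i
        while k > 0:
            if inten[k - 1] <= half:
                f = (inten[k] - half) / (inten[k] - inten[k - 1])
                left = mz[k] + f * (mz[k - 1] - mz[k])
                break
            k -= 1
        k = i
        while k < len(inten) - 1:
            if inten[k + 1] <= half:
                f = (inten[k] - half) / (inten[k] - inten[k + 1])
                right = mz[k] + f * (mz[k + 1] - mz[k])
                break
            k += 1
        if left is not None and right is not None:
            out.append((left + right) / 2)
    return out


class TestExactMass:
    def test_symmetric_triangle(self):
        scan = make_scan([100.00, 100.01, 100.02, 100.03, 100.04],
                         [0, 50, 100, 50, 0])
        peaks = detect_exact_mass(scan, MassDetectorParams())
        assert len(peaks) == 1
        assert peaks[0].mz == pytest.approx(100.02, abs=1e-12)

    def test_asymmetric_triangle(self):
        scan = make_scan([100.00, 100.01, 100.02, 100.03, 100.04],
                         [0, 60, 100, 20, 0])
        peaks = detect_exact_mass(scan, MassDetectorParams())
        # crossings at 100.008333 and 100.026250
        assert peaks[0].mz == pytest.approx(100.0172917, abs=1e-6)

    def test_isolated_spike(self):
        scan = make_scan([100.00, 100.01, 100.02], [0, 100, 0])
        peaks = detect_exact_mass(scan, MassDetectorParams())
        assert peaks[0].mz == pytest.approx(100.01, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_interpolation_oracle_on_random_spectra(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            centers = np.sort(rng.uniform(100.2, 109.8, size=4))
            while np.any(np.diff(centers) < 0.2):
                centers = np.sort(rng.uniform(100.2, 109.8, size=4))
            heights = rng.uniform(50, 500, size=4)
            mz, inten = gaussian_spectrum(centers, heights, sigma=0.01,
                                          grid_step=0.003,
                                          mz_range=(100.0, 110.0))
            scan = make_scan(mz, inten)
            got = [p.mz for p in
                   detect_exact_mass(scan, MassDetectorParams(noise_level=1))
                   if not p.flag]
            expected = exact_mass_oracle(mz, inten, 1.0)
            assert got == pytest.approx(expected, abs=1e-9)


def naive_mexican_hat_transform(inten, d, scale, window):
    """Direct double-loop convolution with the closed-form kernel."""
    half_n = max(1, int(round(window / d)))
    out = np.zeros(len(inten))
    for i in range(len(inten)):
        for k in range(-half_n, half_n + 1):
            j = i - k
            if 0 <= j < len(inten):
                x = k * d
                u = x / scale
                out[i] += inten[j] * (1 - u * u) * math.exp(-0.5 * u * u)
    return out


class TestWavelet:
    def test_clean_gaussian_single_peak(self):
        mz, inten = gaussian_spectrum([100.5], [100], sigma=0.01,
                                      mz_range=(100.0, 101.0))
        scan = make_scan(mz, inten)
        params = MassDetectorParams(noise_level=10, wavelet_scale=0.01,
                                    wavelet_window=0.1)
        peaks = detect_wavelet(scan, params)
        assert len(peaks) == 1
        assert peaks[0].mz == pytest.approx(100.5, abs=0.002)

    def test_noise_only_spectrum(self, rng):
        mz = np.arange(100, 101, 0.001)
        inten = rng.uniform(0, 1.0, size=mz.size)
        scan = make_scan(mz, inten)
        params = MassDetectorParams(noise_level=1000, wavelet_scale=0.01,
                                    wavelet_window=0.05)
        assert detect_wavelet(scan, params) == []

    def test_two_separated_gaussians(self):
        mz, inten = gaussian_spectrum([100.2, 100.3], [100, 80], sigma=0.01,
                                      mz_range=(100.0, 100.5))
        scan = make_scan(mz, inten)
        params = MassDetectorParams(noise_level=10, wavelet_scale=0.01,
                                    wavelet_window=0.1)
        assert len(detect_wavelet(scan, params)) == 2

    def test_transform_matches_naive_convolution(self):
        mz, inten = gaussian_spectrum([100.3], [100], sigma=0.01,
                                      grid_step=0.002, mz_range=(100.0, 100.6))
        d = 0.002
        kernel_based = np.convolve(
            inten, mexican_hat(np.arange(-25, 26) * d, 0.01), mode="same")
        naive = naive_mexican_hat_transform(inten, d, 0.01, 0.05)
        np.testing.assert_allclose(kernel_based, naive, rtol=1e-9, atol=1e-9)

    def test_scale_larger_than_span_rejected(self):
        scan = make_scan([100.0, 100.1, 100.2], [1, 2, 1])
        with pytest.raises(ParameterError):
            detect_wavelet(scan, MassDetectorParams(wavelet_scale=5.0))


class TestShoulderFilter:
    def test_close_shoulder_removed(self):
        peaks = [MzPeak(500.000, 1000.0), MzPeak(500.005, 30.0)]
        out = filter_shoulder_peaks(peaks,
                                    MassDetectorParams(resolution=50000))
        # model value at FWHM/2 is half maximum (500) > 30
        assert [p.mz for p in out] == [500.000]

    def test_distant_peak_retained(self):
        peaks = [MzPeak(500.000, 1000.0), MzPeak(502.0, 30.0)]
        out = filter_shoulder_peaks(peaks,
                                    MassDetectorParams(resolution=50000))
        assert len(out) == 2

    def test_gaussian_decay_beyond_two_fwhm(self):
        peaks = [MzPeak(500.000, 1000.0), MzPeak(500.020, 30.0)]
        out = filter_shoulder_peaks(
            peaks, MassDetectorParams(resolution=50000, model="gaussian"))
        # 1000*exp(-4 ln2 (0.020/0.010)^2) ~ 0.015 < 30
        assert len(out) == 2

    def test_lorentzian_slower_decay(self):
        peaks = [MzPeak(500.000, 1000.0), MzPeak(500.020, 30.0)]
        out = filter_shoulder_peaks(
            peaks, MassDetectorParams(resolution=50000, model="lorentzian"))
        # 1000/(1+(2*0.020/0.010)^2) ~ 58.8 > 30 -> removed
        assert [p.mz for p in out] == [500.000]

    def test_most_intense_survives_and_output_subset(self, rng):
        peaks = [MzPeak(float(m), float(h)) for m, h in
                 zip(np.sort(rng.uniform(400, 600, 30)),
                     rng.uniform(1, 1000, 30))]
        out = filter_shoulder_peaks(peaks, MassDetectorParams(resolution=1000))
        tallest = max(peaks, key=lambda p: p.intensity)
        assert tallest in out
        assert set(id(p) for p in out) <= set(id(p) for p in peaks)


@pytest.mark.parametrize("name", ["local_maxima", "recursive", "exact_mass",
                                  "wavelet"])
@pytest.mark.parametrize("seed", range(3))
def test_detectors_recover_generated_peak_count(name, seed):
    """On well-separated Gaussians + sub-noise noise, every continuous-mode
    detector reports exactly the generated number of peaks."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 6))
    centers = 100.5 + np.arange(n) * 2.0 + rng.uniform(-0.1, 0.1, n)
    heights = rng.uniform(200, 1000, n)
    mz, inten = gaussian_spectrum(centers, heights, sigma=0.01,
                                  grid_step=0.002, mz_range=(99.0, 99.0 + 2.5 * n + 2),
                                  noise=5.0, rng=rng)
    scan = make_scan(mz, inten)
    params = MassDetectorParams(noise_level=100.0, min_mz_width=0.002,
                                max_mz_width=0.5, wavelet_scale=0.01,
                                wavelet_window=0.08)
    peaks = MASS_DETECTORS[name](scan, params)
    assert len(peaks) == n
    got = sorted(p.mz for p in peaks)
    assert got == pytest.approx(sorted(centers), abs=0.05)


@pytest.mark.parametrize("name", sorted(MASS_DETECTORS))
def test_detector_output_sorted_unique(name, rng):
    mz, inten = gaussian_spectrum([101.0, 103.0, 105.0], [100, 200, 300],
                                  noise=2.0, rng=rng)
    scan = make_scan(mz, inten, mode="centroid" if name == "centroid"
                     else "continuous")
    peaks = MASS_DETECTORS[name](scan, MassDetectorParams(noise_level=10))
    mzs = [p.mz for p in peaks]
    assert mzs == sorted(mzs)
    assert len(mzs) == len(set(mzs))
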