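"""Shared fixtures: programmatic spectra, chromatograms and raw files."""

from __future__ import annotations

import numpy as np
import pytest

from mzflow import Chromatogram, ChromPoint, RawDataFile, Scan


def make_scan(mz, intensity, rt=10.0, scan_number=0, ms_level=1,
              mode="continuous") -> Scan:
    return Scan(scan_number=scan_number, rt_seconds=rt, ms_level=ms_level,
                mz=np.asarray(mz, dtype=float),
                intensity=np.asarray(intensity, dtype=float), mode=mode)


def gaussian_spectrum(centers, heights, sigma=0.005, grid_step=0.001,
                      mz_range=(99.0, 111.0), noise=None, rng=None):
    """Continuous spectrum: sum of Gaussian m/z peaks on a regular grid."""
    mz = np.arange(*mz_range, grid_step)
    inten = np.zeros_like(mz)
    for c, h in zip(centers, heights):
        inten += h * np.exp(-0.5 * ((mz - c) / sigma) ** 2)
    if noise is not None and rng is not None:
        inten += rng.uniform(0, noise, size=mz.size)
    return mz, inten


def make_chromatogram(intensities, rt_step=60.0, rt0=0.0, mz=100.0,
                      source="s") -> Chromatogram:
    pts = [ChromPoint(i, rt0 + i * rt_step, mz, float(v))
           for i, v in enumerate(intensities)]
    return Chromatogram(mz=mz, points=pts, source=source)


def gaussian_chromatogram(height=100.0, center=300.0, sigma=10.0,
                          rt_step=3.0, n=60, rt0=None, mz=100.0):
    rt0 = center - (n // 2) * rt_step if rt0 is None else rt0
    rts = rt0 + np.arange(n) * rt_step
    inten = height * np.exp(-0.5 * ((rts - center) / sigma) ** 2)
    pts = [ChromPoint(i, float(t), mz, float(v))
           for i, (t, v) in enumerate(zip(rts, inten))]
    return Chromatogram(mz=mz, points=pts, source="s")


def make_raw_file(name, n_scans=40, rt_step=5.0, peaks=(), mode="centroid",
                  seed=0) -> RawDataFile:
    """Synthetic raw file: each peak is (mz, rt_center, rt_sigma, height)."""
    rng = np.random.default_rng(seed)
    scans = []
    for i in range(n_scans):
        rt = (i + 1) * rt_step
        mzs, intens = [], []
        for mz, c, s, h in peaks:
            v = h * np.exp(-0.5 * ((rt - c) / s) ** 2)
            if v > 1.0:
                mzs.append(mz)
                intens.append(v)
        order = np.argsort(mzs)
        scans.append(Scan(scan_number=i, rt_seconds=rt, ms_level=1,
                          mz=np.asarray(mzs, dtype=float)[order],
                          intensity=np.asarray(intens, dtype=float)[order],
                          mode=mode))
    return RawDataFile(name=name, scans=scans)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
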