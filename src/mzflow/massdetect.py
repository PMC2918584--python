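"""Mass detection (centroiding).

Each scan is converted into discrete :class:`MzPeak` centroids by one of
five pluggable detectors, chosen per instrument characteristics:

``local_maxima``
    every strict local maximum above the noise level (demonstration).
``centroid``
    pass-through thresholding for already-centroided data.
``recursive``
    recursive-threshold splitting with minimum/maximum peak m/z width,
    suppressing narrow noise spikes.
``exact_mass``
    full-width-at-half-maximum centroiding for high-resolution spectra:
    the m/z is the midpoint of the two half-maximum crossings.
``wavelet``
    continuous wavelet transform against the Mexican-hat kernel, for
    noisy spectra.

An optional shoulder-peak filter removes the Fourier-transform artifact
peaks that flank true peaks in FTMS data (typically below 5% of the main
peak's intensity), by rebuilding a theoretical peak model of given mass
resolution around each detected peak in decreasing-intensity order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ParameterError
from .msio import Scan

__all__ = [
    "MzPeak",
    "MassDetectorParams",
    "detect_local_maxima",
    "detect_centroid",
    "detect_recursive",
    "detect_exact_mass",
    "detect_wavelet",
    "filter_shoulder_peaks",
    "MASS_DETECTORS",
]


@dataclass(eq=False)
class MzPeak:
    """A centroided m/z-intensity pair.

    ``raw_points`` optionally keeps the (mz, intensity) profile points
    that formed the peak; ``flag`` marks degraded estimates (e.g. a
    half-maximum crossing that fell off the spectrum edge).
    """

    mz: float
    intensity: float
    raw_points: Optional[List[Tuple[float, float]]] = None
    flag: str = ""


@dataclass
class MassDetectorParams:
    """Parameters shared by the mass detectors.

    noise_level : intensity units; points/maxima at or below it are ignored.
    min_mz_width, max_mz_width : Da; recursive-threshold region widths.
    wavelet_scale : Da; Mexican-hat scale parameter.
    wavelet_window : Da; half-width of the kernel's evaluation window.
    resolution : dimensionless R = m/Δm; shoulder-filter model width.
    model : "gaussian" or "lorentzian" shoulder-filter model shape.
    """

    noise_level: float = 0.0
    min_mz_width: float = 0.001
    max_mz_width: float = 0.1
    wavelet_scale: float = 0.01
    wavelet_window: float = 0.1
    resolution: float = 50000.0
    model: str = "gaussian"

    def __post_init__(self) -> None:
        if self.noise_level < 0:
            raise ParameterError("noise_level must be >= 0")
        if not (0 < self.min_mz_width < self.max_mz_width):
            raise ParameterError("need 0 < min_mz_width < max_mz_width")


def _local_maxima_indices(intensity: np.ndarray, noise: float) -> List[int]:
    """Indices of strict interior local maxima above *noise*.

    Boundary points are never maxima; on a plateau, the leftmost plateau
    point is taken as the maximum.
    """
    n = intensity.size
    out: List[int] = []
    i = 1
    while i < n - 1:
        if intensity[i] <= noise or intensity[i] <= intensity[i - 1]:
            i += 1
            continue
        # walk a possible plateau starting at i
        j = i
        while j + 1 < n and intensity[j + 1] == intensity[i]:
            j += 1
        if j + 1 < n and intensity[j + 1] < intensity[i]:
            out.append(i)
        i = j + 1
    return out


def detect_local_maxima(scan: Scan, params: MassDetectorParams) -> List[MzPeak]:
    """Detect each strict local maximum in a continuous-mode spectrum."""
    idx = _local_maxima_indices(scan.intensity, params.noise_level)
    return [MzPeak(mz=float(scan.mz[i]), intensity=float(scan.intensity[i]))
            for i in idx]


def detect_centroid(scan: Scan, params: MassDetectorParams) -> List[MzPeak]:
    """Accept every data point above the noise level (centroided data)."""
    mask = scan.intensity > params.noise_level
    return [MzPeak(mz=float(m), intensity=float(i))
            for m, i in zip(scan.mz[mask], scan.intensity[mask])]


def detect_recursive(scan: Scan, params: MassDetectorParams) -> List[MzPeak]:
    """Recursive-threshold detection with m/z width bounds.

    Contiguous above-noise regions wider than ``max_mz_width`` are split
    at their lowest-intensity interior point until narrow enough; regions
    narrower than ``min_mz_width`` are discarded as noise spikes.
    """
    mz, inten = scan.mz, scan.intensity
    peaks: List[MzPeak] = []

    def emit(lo: int, hi: int) -> None:  # inclusive index range
        width = mz[hi] - mz[lo]
        if width < params.min_mz_width:
            return
        if width > params.max_mz_width and hi - lo >= 2:
            interior = slice(lo + 1, hi)
            split = lo + 1 + int(np.argmin(inten[interior]))
            emit(lo, split)
            emit(split, hi)
            return
        seg = slice(lo, hi + 1)
        apex = lo + int(np.argmax(inten[seg]))
        peaks.append(MzPeak(
            mz=float(mz[apex]), intensity=float(inten[apex]),
            raw_points=list(zip(mz[seg].tolist(), inten[seg].tolist()))))

    above = inten > params.noise_level
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j > i:
                emit(i, j)
            i = j + 1
        else:
            i += 1
    peaks.sort(key=lambda p: p.mz)
    return _dedupe(peaks)


def detect_exact_mass(scan: Scan, params: MassDetectorParams) -> List[MzPeak]:
    """FWHM centroiding for high-resolution continuous spectra.

    For each local maximum above the noise level, the left and right
    half-maximum crossings are located by linear interpolation between
    adjacent profile points and the peak m/z is placed at their midpoint.
    If a crossing cannot be found on one side (apex at the spectrum
    edge), the apex m/z is used and the peak flagged.
    """
    mz, inten = scan.mz, scan.intensity
    peaks: List[MzPeak] = []
    for apex in _local_maxima_indices(inten, params.noise_level):
        half = inten[apex] / 2.0
        left = _crossing(mz, inten, apex, half, step=-1)
        right = _crossing(mz, inten, apex, half, step=+1)
        if left is None or right is None:
            peaks.append(MzPeak(mz=float(mz[apex]), intensity=float(inten[apex]),
                                flag="edge"))
        else:
            peaks.append(MzPeak(mz=0.5 * (left + right),
                                intensity=float(inten[apex])))
    peaks.sort(key=lambda p: p.mz)
    return _dedupe(peaks)


def _crossing(mz, inten, apex: int, half: float, step: int) -> Optional[float]:
    i = apex
    while 0 <= i + step < len(inten):
        j = i + step
        if inten[j] <= half:
            if inten[i] == inten[j]:
                return float(mz[j])
            frac = (inten[i] - half) / (inten[i] - inten[j])
            return float(mz[i] + frac * (mz[j] - mz[i]))
        if inten[j] > inten[i] and j != apex:
            return None  # rising again before crossing: overlapping peak
        i = j
    return None


def mexican_hat(x: np.ndarray, scale: float) -> np.ndarray:
    """Mexican-hat (Ricker) wavelet, unit-amplitude normalisation."""
    u = x / scale
    return (1.0 - u * u) * np.exp(-0.5 * u * u)


def detect_wavelet(scan: Scan, params: MassDetectorParams) -> List[MzPeak]:
    """Continuous-wavelet-transform detection with a Mexican-hat kernel.

    The spectrum is convolved with the kernel at the configured scale
    over the configured window; local maxima of the transformed signal
    above the noise level become peaks, with the reported m/z taken from
    the nearest raw local maximum.
    """
    mz, inten = scan.mz, scan.intensity
    if len(mz) < 3:
        return []
    span = float(mz[-1] - mz[0])
    if params.wavelet_scale <= 0:
        raise ParameterError("wavelet_scale must be > 0")
    if params.wavelet_scale > span:
        raise ParameterError(
            f"wavelet_scale {params.wavelet_scale} exceeds scan span {span}")
    d = float(np.median(np.diff(mz)))
    half_n = max(1, int(round(params.wavelet_window / d)))
    grid = np.arange(-half_n, half_n + 1) * d
    kernel = mexican_hat(grid, params.wavelet_scale)
    transformed = np.convolve(inten, kernel, mode="same")
    raw_maxima = _local_maxima_indices(inten, 0.0)
    peaks: List[MzPeak] = []
    for i in _local_maxima_indices(transformed, params.noise_level):
        if not raw_maxima:
            continue
        nearest = min(raw_maxima, key=lambda j: (abs(mz[j] - mz[i]), j))
        peaks.append(MzPeak(mz=float(mz[nearest]),
                            intensity=float(inten[nearest])))
    peaks.sort(key=lambda p: p.mz)
    return _dedupe(peaks)


def filter_shoulder_peaks(peaks: Sequence[MzPeak],
                          params: MassDetectorParams) -> List[MzPeak]:
    """Remove FTMS shoulder peaks lying under a theoretical peak model.

    Peaks are processed in decreasing-intensity order; around each
    surviving peak a Gaussian or Lorentzian of height equal to the peak
    and FWHM = mz / resolution is constructed, and every remaining peak
    whose intensity falls below the model value at its m/z is removed.
    The returned list is sorted by m/z and is a subset of the input.
    """
    if params.resolution <= 0:
        raise ParameterError("resolution must be > 0")
    order = sorted(range(len(peaks)),
                   key=lambda i: (-peaks[i].intensity, peaks[i].mz))
    removed = [False] * len(peaks)
    for i in order:
        if removed[i]:
            continue
        center = peaks[i].mz
        h = peaks[i].intensity
        fwhm = center / params.resolution
        for j in range(len(peaks)):
            if j == i or removed[j]:
                continue
            delta = peaks[j].mz - center
            if params.model == "lorentzian":
                model = h / (1.0 + (2.0 * delta / fwhm) ** 2)
            else:
                model = h * math.exp(-4.0 * math.log(2.0) * (delta / fwhm) ** 2)
            if peaks[j].intensity < model:
                removed[j] = True
    kept = [p for p, r in zip(peaks, removed) if not r]
    kept.sort(key=lambda p: p.mz)
    return kept


def _dedupe(peaks: List[MzPeak]) -> List[MzPeak]:
    """Drop duplicate m/z values within one scan, keeping the tallest."""
    out: List[MzPeak] = []
    for p in peaks:
        if out and p.mz == out[-1].mz:
            if p.intensity > out[-1].intensity:
                out[-1] = p
        else:
            out.append(p)
    return out


#: Registry of detectors addressable from configuration files / the CLI.
MASS_DETECTORS: Dict[str, Callable[[Scan, MassDetectorParams], List[MzPeak]]] = {
    "local_maxima": detect_local_maxima,
    "centroid": detect_centroid,
    "recursive": detect_recursive,
    "exact_mass": detect_exact_mass,
    "wavelet": detect_wavelet,
}
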