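"""Chromatogram deconvolution.

Resolves each chromatogram into individual chromatographic peaks
(:class:`Feature`) via four pluggable algorithms:

``baseline``
    maximal runs above a fixed baseline intensity.
``noise_amplitude``
    like ``baseline`` but the baseline is placed per chromatogram at the
    top of the intensity band (of given height) containing most points,
    i.e. where the noise is concentrated.
``savitzky_golay``
    peak borders from the sign structure of the Savitzky-Golay smoothed
    second derivative.
``local_minimum``
    local minima as candidate borders, with absolute/relative height and
    apex-to-edge ratio restrictions.

An experimental peak-shape modeler refits resolved features with an
ideal Gaussian or exponentially-modified-Gaussian (EMG) profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter
from scipy.special import erfc

from .chrombuild import ChromPoint, Chromatogram
from .errors import ParameterError

__all__ = [
    "Feature",
    "PeakModel",
    "resolve_baseline_cutoff",
    "resolve_noise_amplitude",
    "resolve_savitzky_golay",
    "resolve_local_minimum",
    "fit_peak_shape",
    "RESOLVERS",
]


@dataclass(eq=False)
class Feature:
    """A resolved chromatographic peak.

    ``area`` is the trapezoidal integral of intensity over RT
    (intensity·seconds). ``points`` is the contiguous run of
    chromatogram points the feature was built from.
    """

    mz: float
    rt: float
    height: float
    area: float
    rt_start: float
    rt_end: float
    points: List[ChromPoint] = field(default_factory=list)
    source: str = ""
    charge: Optional[int] = None
    isotope_pattern: Optional["object"] = None  # isotopes.IsotopePattern

    def __post_init__(self) -> None:
        if not (self.rt_start <= self.rt <= self.rt_end):
            raise ParameterError("feature apex RT outside its RT bounds")


@dataclass
class PeakModel:
    """Fitted ideal peak shape: Gaussian or EMG."""

    kind: str                 # "gaussian" | "emg"
    height: float
    center: float             # seconds
    width: float              # Gaussian sigma, seconds
    tau: float = 0.0          # EMG exponential decay constant, seconds
    converged: bool = True


def _make_feature(chrom: Chromatogram, lo: int, hi: int) -> Feature:
    """Feature from chromatogram points lo..hi inclusive."""
    pts = chrom.points[lo:hi + 1]
    rt = np.array([p.rt_seconds for p in pts])
    inten = np.array([p.intensity for p in pts])
    apex = int(np.argmax(inten))
    area = float(np.trapezoid(inten, rt)) if len(pts) > 1 else 0.0
    return Feature(
        mz=chrom.mz,
        rt=float(rt[apex]),
        height=float(inten[apex]),
        area=area,
        rt_start=float(rt[0]),
        rt_end=float(rt[-1]),
        points=list(pts),
        source=chrom.source,
    )


def resolve_baseline_cutoff(chrom: Chromatogram, min_height: float,
                            baseline: float, min_duration: float) -> List[Feature]:
    """Resolve maximal runs of points at or above a fixed baseline.

    A run becomes a feature iff its RT duration is at least
    ``min_duration`` and its apex intensity at least ``min_height``.
    """
    if baseline < 0:
        raise ParameterError("baseline must be >= 0")
    inten = chrom.intensity
    rt = chrom.rt
    out: List[Feature] = []
    n = len(inten)
    i = 0
    while i < n:
        if inten[i] >= baseline:
            j = i
            while j + 1 < n and inten[j + 1] >= baseline:
                j += 1
            if rt[j] - rt[i] >= min_duration and inten[i:j + 1].max() >= min_height:
                out.append(_make_feature(chrom, i, j))
            i = j + 1
        else:
            i += 1
    return out


def noise_amplitude_baseline(intensities: np.ndarray, noise_amplitude: float) -> float:
    """Baseline = top of the intensity window of given height holding most points.

    The window bottom is evaluated at every distinct intensity value
    (exact search); ties go to the lowest window.
    """
    if noise_amplitude <= 0:
        raise ParameterError("noise_amplitude must be > 0")
    values = np.sort(np.asarray(intensities, dtype=float))
    if values.size == 0:
        return 0.0
    best_bottom = values[0]
    best_count = -1
    for bottom in np.unique(values):
        count = int(np.searchsorted(values, bottom + noise_amplitude, side="right")
                    - np.searchsorted(values, bottom, side="left"))
        if count > best_count:
            best_count = count
            best_bottom = bottom
    return float(best_bottom + noise_amplitude)


def resolve_noise_amplitude(chrom: Chromatogram, min_height: float,
                            noise_amplitude: float,
                            min_duration: float) -> List[Feature]:
    """Baseline-cutoff resolution with a per-chromatogram adaptive baseline."""
    baseline = noise_amplitude_baseline(chrom.intensity, noise_amplitude)
    return resolve_baseline_cutoff(chrom, min_height, baseline, min_duration)


def resolve_savitzky_golay(chrom: Chromatogram, min_height: float,
                           window: int, min_duration: float,
                           threshold_k: float = 0.05) -> List[Feature]:
    """Detect peak borders from the smoothed second derivative.

    Peak cores are runs where the Savitzky-Golay second derivative (order
    2, odd ``window`` of at least 5 points) falls below a negative
    threshold scaled to the signal; borders extend outward to the
    surrounding zero-crossings of the derivative. The threshold is
    -(apex / w^2) * k where w is the smoothing-window duration in
    seconds.
    """
    if window % 2 == 0 or window < 5:
        raise ParameterError("window must be odd and >= 5")
    if len(chrom) < window:
        raise ParameterError(
            f"chromatogram has {len(chrom)} points, fewer than window {window}")
    rt = chrom.rt
    inten = chrom.intensity
    dt = float(np.median(np.diff(rt))) if len(rt) > 1 else 1.0
    d2 = savgol_filter(inten, window_length=window, polyorder=2,
                       deriv=2, delta=dt)
    apex_height = float(inten.max())
    char_width = window * dt
    threshold = -(apex_height / char_width ** 2) * threshold_k
    n = len(inten)
    out: List[Feature] = []
    last_end = -1
    i = 0
    while i < n:
        if d2[i] < threshold:
            j = i
            while j + 1 < n and d2[j + 1] < threshold:
                j += 1
            lo = i
            while lo - 1 > last_end and d2[lo - 1] < 0:
                lo -= 1
            hi = j
            while hi + 1 < n and d2[hi + 1] < 0:
                hi += 1
            if (rt[hi] - rt[lo] >= min_duration
                    and inten[lo:hi + 1].max() >= min_height):
                out.append(_make_feature(chrom, lo, hi))
                last_end = hi
            i = hi + 1
        else:
            i += 1
    return out


def resolve_local_minimum(chrom: Chromatogram, min_height: float,
                          min_relative_height: float, min_ratio: float,
                          min_duration: float,
                          search_window: float) -> List[Feature]:
    """Split a chromatogram at local minima, with shape restrictions.

    Candidate borders are interior points that are minimal within
    ±``search_window`` seconds. Each resulting segment must satisfy:
    apex >= ``min_height``, apex >= ``min_relative_height`` × the
    chromatogram maximum, apex/edge >= ``min_ratio`` at both edges, and
    duration >= ``min_duration``. Segments failing the edge-ratio test
    are merged with the neighbour across their higher-intensity border
    and re-tested.
    """
    if min_ratio < 1:
        raise ParameterError("min_ratio must be >= 1")
    rt = chrom.rt
    inten = chrom.intensity
    n = len(inten)
    if n < 3:
        return []
    chrom_max = float(inten.max())

    borders = [0]
    for i in range(1, n - 1):
        in_window = (np.abs(rt - rt[i]) <= search_window)
        if (inten[i] == inten[in_window].min()
                and inten[i - 1] >= inten[i] and inten[i + 1] >= inten[i]):
            if borders[-1] != i:
                borders.append(i)
    borders.append(n - 1)
    segments = [(borders[k], borders[k + 1]) for k in range(len(borders) - 1)
                if borders[k + 1] > borders[k]]

    def ratio_ok(lo: int, hi: int) -> bool:
        apex = inten[lo:hi + 1].max()
        for edge in (inten[lo], inten[hi]):
            if apex / max(edge, 1e-30) < min_ratio:
                return False
        return True

    # merge segments failing the edge-ratio rule into the neighbour
    # across their higher-intensity border, until stable
    changed = True
    while changed and len(segments) > 1:
        changed = False
        for k, (lo, hi) in enumerate(segments):
            if ratio_ok(lo, hi):
                continue
            left_border = inten[lo] if k > 0 else -math.inf
            right_border = inten[hi] if k < len(segments) - 1 else -math.inf
            if left_border == -math.inf and right_border == -math.inf:
                continue
            if right_border >= left_border:
                segments[k] = (lo, segments[k + 1][1])
                del segments[k + 1]
            else:
                segments[k - 1] = (segments[k - 1][0], hi)
                del segments[k]
            changed = True
            break

    out: List[Feature] = []
    for lo, hi in segments:
        seg = inten[lo:hi + 1]
        apex_rel = int(np.argmax(seg))
        if apex_rel == 0 or apex_rel == hi - lo:
            continue  # no interior apex (monotone segment)
        apex = float(seg.max())
        if apex < min_height or apex < min_relative_height * chrom_max:
            continue
        if not ratio_ok(lo, hi):
            continue
        if rt[hi] - rt[lo] < min_duration:
            continue
        out.append(_make_feature(chrom, lo, hi))
    return out


# ---------------------------------------------------------------------------
# Peak-shape modeler (experimental)
# ---------------------------------------------------------------------------

def gaussian_shape(t: np.ndarray, h: float, c: float, sigma: float) -> np.ndarray:
    return h * np.exp(-0.5 * ((t - c) / sigma) ** 2)


def emg_shape(t: np.ndarray, h: float, c: float, sigma: float,
              tau: float) -> np.ndarray:
    """Exponentially modified Gaussian, normalised to peak height ~h."""
    tau = max(tau, 1e-6)
    arg = (sigma / tau - (t - c) / sigma) / math.sqrt(2.0)
    out = (h * sigma / tau * math.sqrt(math.pi / 2.0)
           * np.exp(0.5 * (sigma / tau) ** 2 - (t - c) / tau)
           * erfc(arg))
    # renormalise so the fitted h parameter remains the apex height
    peak = out.max() if np.all(np.isfinite(out)) and out.max() > 0 else 1.0
    return out * (h / peak)


def fit_peak_shape(feature: Feature, kind: str = "gaussian"
                   ) -> Tuple[Feature, PeakModel]:
    """Refit a resolved feature with an ideal peak model.

    Returns a copy of the feature whose points are the fitted model
    evaluated on the original RT grid, together with the model. The fit
    never increases the residual relative to the moment-based initial
    guess; on non-convergence the original feature is returned with a
    null (non-converged) model.
    """
    min_pts = {"gaussian": 4, "emg": 5}.get(kind)
    if min_pts is None:
        raise ParameterError(f"unknown peak model {kind!r}")
    if len(feature.points) < min_pts:
        raise ParameterError(
            f"{kind} fit needs >= {min_pts} points, got {len(feature.points)}")
    rt = np.array([p.rt_seconds for p in feature.points])
    inten = np.array([p.intensity for p in feature.points])

    # moment-based initial guesses
    w = np.clip(inten, 0, None) + 1e-12
    c0 = float(np.sum(rt * w) / np.sum(w))
    sigma0 = float(math.sqrt(max(np.sum(w * (rt - c0) ** 2) / np.sum(w), 1e-6)))
    h0 = float(inten.max())
    if kind == "gaussian":
        fn = gaussian_shape
        p0 = [h0, c0, sigma0]
    else:
        fn = emg_shape
        p0 = [h0, c0, max(sigma0 * 0.7, 1e-3), max(sigma0 * 0.5, 1e-3)]

    def residual(params) -> float:
        return float(np.sum((fn(rt, *params) - inten) ** 2))

    try:
        popt, _ = curve_fit(fn, rt, inten, p0=p0, maxfev=5000)
        if not np.all(np.isfinite(popt)) or popt[2] <= 0:
            raise RuntimeError("degenerate fit")
        if residual(popt) > residual(p0):
            popt = np.asarray(p0)
    except (RuntimeError, ValueError):
        null = PeakModel(kind=kind, height=h0, center=c0, width=sigma0,
                         converged=False)
        return feature, null

    fitted = fn(rt, *popt)
    new_points = [ChromPoint(p.scan_number, p.rt_seconds, p.mz, float(v))
                  for p, v in zip(feature.points, fitted)]
    apex = int(np.argmax(fitted))
    refit = Feature(
        mz=feature.mz,
        rt=float(rt[apex]),
        height=float(fitted[apex]),
        area=float(np.trapezoid(fitted, rt)),
        rt_start=feature.rt_start,
        rt_end=feature.rt_end,
        points=new_points,
        source=feature.source,
    )
    model = PeakModel(
        kind=kind, height=float(popt[0]), center=float(popt[1]),
        width=float(popt[2]),
        tau=float(popt[3]) if kind == "emg" else 0.0,
    )
    return refit, model


#: Registry of resolvers addressable from configuration files / the CLI.
RESOLVERS: Dict[str, Callable[..., List[Feature]]] = {
    "baseline": resolve_baseline_cutoff,
    "noise_amplitude": resolve_noise_amplitude,
    "savitzky_golay": resolve_savitzky_golay,
    "local_minimum": resolve_local_minimum,
}
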