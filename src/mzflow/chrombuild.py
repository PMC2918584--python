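"""Chromatogram building.

Connects centroided m/z values across consecutive MS1 scans into
:class:`Chromatogram` traces. Peaks are consumed in order of decreasing
intensity (most intense connected first, ties broken by lower scan
number then lower m/z); each peak either extends the trace whose running
intensity-weighted mean m/z is nearest within the tolerance, or seeds a
new trace. Assembled traces are then closed at scan gaps longer than the
``max_missing_scans`` allowance, and finally filtered by minimum RT span
and minimum apex height.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .errors import ParameterError
from .massdetect import MzPeak

__all__ = ["ChromPoint", "Chromatogram", "build_chromatograms"]


@dataclass(frozen=True)
class ChromPoint:
    """One member data point of a chromatogram."""

    scan_number: int
    rt_seconds: float
    mz: float
    intensity: float


@dataclass(eq=False)
class Chromatogram:
    """An m/z trace over retention time within one raw file.

    ``mz`` is the intensity-weighted mean of the member points' m/z.
    """

    mz: float
    points: List[ChromPoint] = field(default_factory=list)
    source: str = ""

    @property
    def rt(self) -> np.ndarray:
        return np.array([p.rt_seconds for p in self.points])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.points])

    @property
    def height(self) -> float:
        return max(p.intensity for p in self.points)

    @property
    def rt_span(self) -> float:
        return self.points[-1].rt_seconds - self.points[0].rt_seconds

    def __len__(self) -> int:
        return len(self.points)


class _Trace:
    __slots__ = ("mz", "weight", "entries")

    def __init__(self) -> None:
        self.mz = 0.0          # running intensity-weighted mean m/z
        self.weight = 0.0
        self.entries: dict = {}  # scan index -> (rt, mz, intensity)

    def add(self, scan_idx: int, rt: float, mz: float, intensity: float) -> None:
        self.entries[scan_idx] = (rt, mz, intensity)
        w = max(intensity, 1e-30)
        self.weight += w
        self.mz += (mz - self.mz) * w / self.weight


def build_chromatograms(
    scans_peaks: Sequence[Tuple[int, float, Sequence[MzPeak]]],
    mz_tolerance: float,
    min_time_span: float,
    min_height: float,
    max_missing_scans: int = 1,
    source: str = "",
) -> List[Chromatogram]:
    """Connect per-scan centroids into chromatograms.

    Parameters
    ----------
    scans_peaks
        Sequence of ``(scan_number, rt_seconds, peaks)`` in RT order.
    mz_tolerance
        Maximum |Δm/z| in Da between a peak and a trace's running mean.
    min_time_span
        Minimum RT span (s) a returned chromatogram must cover.
    min_height
        Minimum apex intensity of a returned chromatogram.
    max_missing_scans
        A trace may skip at most this many consecutive scans without a
        matching peak; longer gaps split the trace.

    Each input peak joins at most one chromatogram.
    """
    if mz_tolerance <= 0 or min_time_span < 0:
        raise ParameterError("tolerances must be positive")
    rts = [rt for _, rt, _ in scans_peaks]
    if any(b < a for a, b in zip(rts, rts[1:])):
        raise ParameterError("scans must be ordered by retention time")

    # flatten with global decreasing-intensity consumption order
    flat = []
    for idx, (scan_no, rt, peaks) in enumerate(scans_peaks):
        for p in peaks:
            flat.append((-p.intensity, idx, p.mz, scan_no, rt))
    flat.sort()

    traces: List[_Trace] = []
    for neg_int, scan_idx, mz, scan_no, rt in flat:
        intensity = -neg_int
        best = None
        best_d = mz_tolerance
        for tr in traces:
            if scan_idx in tr.entries:
                continue  # one point per scan per trace
            d = abs(tr.mz - mz)
            if d <= best_d:
                if best is None or d < best_d:
                    best, best_d = tr, d
        if best is None:
            tr = _Trace()
            tr.add(scan_idx, rt, mz, intensity)
            traces.append(tr)
        else:
            best.add(scan_idx, rt, mz, intensity)

    # split at gaps, then filter by span and apex height
    out: List[Chromatogram] = []
    for tr in traces:
        idxs = sorted(tr.entries)
        segment: List[int] = []
        segments: List[List[int]] = []
        for i in idxs:
            if segment and i - segment[-1] > max_missing_scans + 1:
                segments.append(segment)
                segment = []
            segment.append(i)
        if segment:
            segments.append(segment)
        for seg in segments:
            pts = []
            for i in seg:
                rt, mz, intensity = tr.entries[i]
                scan_no = scans_peaks[i][0]
                pts.append(ChromPoint(scan_no, rt, mz, intensity))
            chrom = Chromatogram(mz=0.0, points=pts, source=source)
            w = sum(max(p.intensity, 1e-30) for p in pts)
            chrom.mz = sum(p.mz * max(p.intensity, 1e-30) for p in pts) / w
            if chrom.rt_span >= min_time_span and chrom.height >= min_height:
                out.append(chrom)
    out.sort(key=lambda c: (c.mz, c.points[0].rt_seconds))
    return out
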