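"""Alignment benchmarking on synthetic data with known ground truth.

The benchmark emulates a multi-sample LC-MS alignment experiment: one
seed peak list is duplicated into every sample, and each copy's
retention times are passed through a random smooth non-linear warp
(sine + linear, bounded by a configurable maximum deviation) plus small
Gaussian jitter. Optional decoy peaks with no cross-sample identity can
be injected for stress tests. Precision and recall of an alignment are
computed pairwise against the generator's ground truth: an alignment is
an unordered cross-sample pair of features sharing a row, and it is true
iff both features descend from the same seed peak.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .chrombuild import ChromPoint
from .deconvolution import Feature
from .errors import ParameterError

__all__ = [
    "SyntheticParams",
    "GroundTruth",
    "generate_synthetic_dataset",
    "evaluate_alignment",
    "run_benchmark",
]


@dataclass
class SyntheticParams:
    """Synthetic benchmark design.

    Defaults follow the alignment experiment this module reproduces:
    20 samples carrying identical peak information (≈200 seed peaks over
    m/z 100-1000 Da and RT 60-1200 s, log-normal heights), differing
    only by a bounded random non-linear RT deviation; no decoys.
    """

    n_samples: int = 20
    n_peaks: int = 200
    mz_range: Tuple[float, float] = (100.0, 1000.0)
    rt_range: Tuple[float, float] = (60.0, 1200.0)
    max_rt_deviation: float = 40.0
    rt_jitter_sd: float = 0.5
    n_noise_peaks: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ParameterError("need at least 2 samples")
        span = self.rt_range[1] - self.rt_range[0]
        if span <= 0 or self.mz_range[1] <= self.mz_range[0]:
            raise ParameterError("empty m/z or RT range")
        if self.max_rt_deviation >= span:
            raise ParameterError(
                "max_rt_deviation must be smaller than the RT span")


@dataclass
class GroundTruth:
    """Generator-side truth for a synthetic dataset.

    ``identity`` maps each generated feature object to its seed-peak id
    (``None`` for decoys); ``warps`` holds each sample's RT warp
    function (seed RT → sample RT).
    """

    identity: Dict[Feature, Optional[int]]
    warps: Dict[str, Callable[[np.ndarray], np.ndarray]]
    n_samples: int
    n_seed_peaks: int

    def true_pair_count(self) -> int:
        """Number of same-identity unordered cross-sample feature pairs."""
        counts: Dict[int, int] = {}
        for sid in self.identity.values():
            if sid is not None:
                counts[sid] = counts.get(sid, 0) + 1
        return sum(c * (c - 1) // 2 for c in counts.values())


def _make_warp(rng: np.random.Generator, rt_range: Tuple[float, float],
               max_dev: float) -> Callable[[np.ndarray], np.ndarray]:
    """Random smooth sine+linear RT warp with max |r' - r| <= max_dev."""
    r0, r1 = rt_range
    span = r1 - r0
    # total deviation budget, split between the sine and linear terms
    budget = max_dev * rng.uniform(0.3, 1.0)
    sine_frac = rng.uniform(0.0, 1.0)
    a = budget * sine_frac * rng.choice([-1.0, 1.0])
    b = budget * (1.0 - sine_frac) / span * rng.choice([-1.0, 1.0])
    period = span * rng.uniform(0.6, 1.8)
    phase = rng.uniform(0.0, 2.0 * np.pi)

    def warp(r):
        r = np.asarray(r, dtype=float)
        return r + a * np.sin(2.0 * np.pi * r / period + phase) + b * (r - r0)

    return warp


def generate_synthetic_dataset(
    params: SyntheticParams,
) -> Tuple[Dict[str, List[Feature]], GroundTruth]:
    """Generate per-sample feature lists plus ground truth.

    Deterministic under ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    seed_mz = rng.uniform(*params.mz_range, size=params.n_peaks)
    seed_rt = rng.uniform(*params.rt_range, size=params.n_peaks)
    seed_height = rng.lognormal(mean=np.log(1e4), sigma=1.0,
                                size=params.n_peaks)
    peaklists: Dict[str, List[Feature]] = {}
    identity: Dict[Feature, Optional[int]] = {}
    warps: Dict[str, Callable] = {}
    for s in range(params.n_samples):
        name = f"sample_{s:02d}"
        if params.max_rt_deviation > 0:
            warp = _make_warp(rng, params.rt_range, params.max_rt_deviation)
        else:
            warp = lambda r: np.asarray(r, dtype=float)
        warps[name] = warp
        rts = np.asarray(warp(seed_rt), dtype=float)
        if params.rt_jitter_sd > 0:
            rts = rts + rng.normal(0.0, params.rt_jitter_sd,
                                   size=params.n_peaks)
        features: List[Feature] = []
        for i in range(params.n_peaks):
            f = _point_feature(float(seed_mz[i]), float(rts[i]),
                               float(seed_height[i]), name)
            identity[f] = i
            features.append(f)
        for _ in range(params.n_noise_peaks):
            f = _point_feature(float(rng.uniform(*params.mz_range)),
                               float(rng.uniform(*params.rt_range)),
                               float(rng.lognormal(np.log(1e3), 1.0)), name)
            identity[f] = None
            features.append(f)
        features.sort(key=lambda f: (f.mz, f.rt))
        peaklists[name] = features
    truth = GroundTruth(identity=identity, warps=warps,
                        n_samples=params.n_samples,
                        n_seed_peaks=params.n_peaks)
    return peaklists, truth


def _point_feature(mz: float, rt: float, height: float, source: str) -> Feature:
    return Feature(mz=mz, rt=rt, height=height, area=height,
                   rt_start=rt, rt_end=rt,
                   points=[ChromPoint(0, rt, mz, height)], source=source)


def evaluate_alignment(aligned, truth: GroundTruth
                       ) -> Tuple[Optional[float], float]:
    """Pairwise precision and recall of an aligned peak list.

    An alignment is an unordered cross-sample pair of features placed in
    the same row; it is true iff both members carry the same non-null
    seed id. Precision = true pairs / produced pairs (``None`` when no
    pairs were produced); recall = true pairs / all same-id cross-sample
    pairs in the ground truth.
    """
    produced = 0
    true_pairs = 0
    for row in aligned.rows:
        members = list(row.features.values())
        k = len(members)
        produced += k * (k - 1) // 2
        ids = [truth.identity.get(f) for f in members]
        for i in range(k):
            if ids[i] is None:
                continue
            for j in range(i + 1, k):
                if ids[j] == ids[i]:
                    true_pairs += 1
    total_true = truth.true_pair_count()
    precision = true_pairs / produced if produced else None
    recall = true_pairs / total_true if total_true else 0.0
    return precision, recall


def run_benchmark(params: SyntheticParams,
                  aligner_configs: Sequence[Tuple[str, Callable]],
                  csv_path=None):
    """Run several aligner configurations on one synthetic dataset.

    ``aligner_configs`` is a sequence of ``(label, aligner)`` pairs
    where each aligner is a callable taking the per-sample peak lists
    and returning an :class:`~mzflow.alignment.AlignedPeakList`. Returns
    a DataFrame with precision, recall and wall time per configuration,
    optionally also written to ``csv_path``.
    """
    import pandas as pd

    if not aligner_configs:
        raise ParameterError("need at least one aligner configuration")
    peaklists, truth = generate_synthetic_dataset(params)
    records = []
    for label, aligner in aligner_configs:
        t0 = time.perf_counter()
        aligned = aligner(peaklists)
        elapsed = time.perf_counter() - t0
        precision, recall = evaluate_alignment(aligned, truth)
        records.append({"aligner": label,
                        "precision": precision,
                        "recall": recall,
                        "seconds": elapsed})
    df = pd.DataFrame.from_records(records)
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    return df
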