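"""Peak-list alignment across samples.

Two aligners are provided. The **Join aligner** incrementally matches
each sample's features to the best candidate row of a growing master
list inside a fixed two-dimensional (m/z × RT) alignment window. The
**RANSAC aligner** corrects non-linear retention-time drift before
joining: for each new sample it (1) collects candidate alignments in a
wide RANSAC window, (2) robustly fits an RT-correction model by random
sample consensus using 4-point candidate models, (3) smooths the inlier
set with LOESS, (4) recenters each row's alignment window at the
predicted corrected RT, and (5) joins within the narrower alignment
window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from .deconvolution import Feature
from .errors import AlignmentModelError, MzflowError, ParameterError

__all__ = [
    "PeakListRow",
    "AlignedPeakList",
    "AlignmentCandidate",
    "RansacParams",
    "RtCorrectionModel",
    "join_align",
    "collect_candidates",
    "ransac_fit",
    "loess_smooth",
    "ransac_align",
]

logger = logging.getLogger("mzflow.alignment")


@dataclass(eq=False)
class PeakListRow:
    """One aligned row: at most one feature per sample.

    ``mz`` and ``rt`` are the running averages of the member features,
    recomputed on every insertion.
    """

    features: Dict[str, Feature] = field(default_factory=dict)
    identity: Optional["object"] = None  # identify.CompoundRecord

    def add(self, sample: str, feature: Feature) -> None:
        if sample in self.features:
            raise MzflowError(f"row already holds a feature from {sample!r}")
        self.features[sample] = feature

    @property
    def mz(self) -> float:
        return sum(f.mz for f in self.features.values()) / len(self.features)

    @property
    def rt(self) -> float:
        return sum(f.rt for f in self.features.values()) / len(self.features)

    def __len__(self) -> int:
        return len(self.features)


@dataclass(eq=False)
class AlignedPeakList:
    """The master list: aligned rows over an ordered set of samples."""

    rows: List[PeakListRow] = field(default_factory=list)
    samples: List[str] = field(default_factory=list)

    def n_features(self) -> int:
        return sum(len(r) for r in self.rows)


@dataclass(eq=False)
class AlignmentCandidate:
    """A (master row, sample feature) pair inside the RANSAC window."""

    master_rt: float
    sample_rt: float
    master_row: PeakListRow
    sample_feature: Feature
    inlier: bool = False


@dataclass
class RansacParams:
    """RANSAC aligner parameters.

    rm0 : m/z tolerance (Da), shared by the RANSAC and alignment windows.
    rr0 : RANSAC-window RT tolerance (s); should be at least the largest
        expected RT deviation between samples.
    ar0 : alignment-window RT tolerance (s), applied after correction.
    k : number of RANSAC iterations.
    min_points_fraction : acceptance floor on the inlier count as a
        fraction of the candidate count.
    t : inlier residual threshold (s).
    nonlinear : fit a cubic through each 4-point sample if true, else a
        least-squares line.
    seed : RNG seed (per-sample streams are derived from it).
    """

    rm0: float = 0.05
    rr0: float = 50.0
    ar0: float = 25.0
    k: int = 5000
    min_points_fraction: float = 0.2
    t: float = 4.0
    nonlinear: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or not (0 < self.min_points_fraction <= 1) or self.t <= 0:
            raise ParameterError("invalid RANSAC parameters")


class RtCorrectionModel:
    """Mapping from master RT to expected sample RT.

    Holds the (master_rt, sample_rt) support pairs selected by RANSAC
    and a predictor built on them. Predictions interpolate linearly
    between support points and extrapolate with the boundary slope
    outside the support range.
    """

    def __init__(self, support: np.ndarray,
                 curve: Optional[np.ndarray] = None) -> None:
        support = np.asarray(support, dtype=float)
        if support.ndim != 2 or support.shape[1] != 2 or support.shape[0] < 2:
            raise MzflowError("correction model needs >= 2 support pairs")
        self.support = support[np.lexsort((support[:, 1], support[:, 0]))]
        pts = curve if curve is not None else self.support
        # collapse duplicate master RTs (mean sample RT) for interpolation
        xs, idx = np.unique(pts[:, 0], return_inverse=True)
        ys = np.zeros_like(xs)
        counts = np.bincount(idx)
        np.add.at(ys, idx, pts[:, 1])
        ys /= counts
        if xs.size < 2:
            raise MzflowError("correction model support is degenerate "
                              "(all master RTs identical)")
        self._xs, self._ys = xs, ys

    @staticmethod
    def _edge_slope(xs: np.ndarray, ys: np.ndarray) -> float:
        """Least-squares slope over a boundary band of curve points.

        A band (up to 10 points) is used rather than the outermost pair:
        a two-point slope amplifies point-level noise into large errors
        when extrapolating far outside the support.
        """
        m = min(xs.size, 10)
        bx, by = xs[:m], ys[:m]
        if np.ptp(bx) == 0:
            return 0.0
        return float(np.polyfit(bx, by, 1)[0])

    def predict(self, master_rt) -> np.ndarray:
        x = np.atleast_1d(np.asarray(master_rt, dtype=float))
        xs, ys = self._xs, self._ys
        out = np.interp(x, xs, ys)
        below = x < xs[0]
        above = x > xs[-1]
        if below.any():
            out[below] = ys[0] + self._edge_slope(xs, ys) * (x[below] - xs[0])
        if above.any():
            out[above] = ys[-1] + self._edge_slope(xs[::-1], ys[::-1]) * (
                x[above] - xs[-1])
        return out if np.ndim(master_rt) else float(out[0])

    __call__ = predict


# ---------------------------------------------------------------------------
# Join aligner
# ---------------------------------------------------------------------------

def _join_sample(master: AlignedPeakList, sample: str,
                 features: Sequence[Feature], mz_tolerance: float,
                 rt_tolerance: float,
                 centers: Optional[Sequence[float]] = None) -> None:
    """Join one sample's features into the master list (in place).

    Matches are made greedily by score |Δm/z|/mz_tol + |ΔRT|/rt_tol
    (ties: smaller |Δm/z|, then lower m/z/RT for determinism), at most
    one feature per row per sample; unmatched features open new rows.
    ``centers`` optionally overrides each row's RT window center.
    """
    scored = []
    for ri, row in enumerate(master.rows):
        center = centers[ri] if centers is not None else row.rt
        row_mz = row.mz
        for fi, f in enumerate(features):
            dmz = abs(f.mz - row_mz)
            drt = abs(f.rt - center)
            if dmz <= mz_tolerance and drt <= rt_tolerance:
                scored.append((dmz / mz_tolerance + drt / rt_tolerance,
                               dmz, f.mz, f.rt, ri, fi))
    scored.sort()
    used_rows: set = set()
    used_feats: set = set()
    for _, _, _, _, ri, fi in scored:
        if ri in used_rows or fi in used_feats:
            continue
        master.rows[ri].add(sample, features[fi])
        used_rows.add(ri)
        used_feats.add(fi)
    leftovers = [f for fi, f in enumerate(features) if fi not in used_feats]
    for f in sorted(leftovers, key=lambda f: (f.mz, f.rt)):
        row = PeakListRow()
        row.add(sample, f)
        master.rows.append(row)
    master.samples.append(sample)


def join_align(peaklists: Mapping[str, Sequence[Feature]],
               mz_tolerance: float, rt_tolerance: float) -> AlignedPeakList:
    """Align samples with the incremental Join algorithm.

    Samples are processed in the mapping's order; the first sample seeds
    the master list.
    """
    if not peaklists:
        raise ParameterError("need at least one sample")
    master = AlignedPeakList()
    for sample, features in peaklists.items():
        _join_sample(master, sample, list(features), mz_tolerance, rt_tolerance)
    return master


# ---------------------------------------------------------------------------
# RANSAC aligner
# ---------------------------------------------------------------------------

def collect_candidates(master: AlignedPeakList,
                       sample_features: Sequence[Feature],
                       rm0: float, rr0: float) -> List[AlignmentCandidate]:
    """All (row, feature) pairs inside the RANSAC window of any row."""
    if not master.rows:
        raise ParameterError("master list is empty")
    out: List[AlignmentCandidate] = []
    for row in master.rows:
        row_mz, row_rt = row.mz, row.rt
        for f in sample_features:
            if abs(f.mz - row_mz) <= rm0 and abs(f.rt - row_rt) <= rr0:
                out.append(AlignmentCandidate(
                    master_rt=row_rt, sample_rt=f.rt,
                    master_row=row, sample_feature=f))
    return out


def ransac_fit(candidates: Sequence[AlignmentCandidate],
               params: RansacParams) -> RtCorrectionModel:
    """Select a consensus RT-correction support set by RANSAC.

    For ``k`` iterations, 4 candidates are drawn uniformly without
    replacement and an exact cubic (non-linear mode) or least-squares
    line is fitted through them; candidates within residual ``t`` of the
    model are its inliers. The model with the most inliers wins (ties:
    smaller total inlier residual). If the best inlier count falls short
    of ``min_points_fraction`` of the candidates, an
    :class:`AlignmentModelError` is raised, signalling the caller to
    fall back to plain Join alignment. Deterministic under a fixed seed.
    """
    n = len(candidates)
    if n < 4:
        raise ParameterError(f"RANSAC needs >= 4 candidates, got {n}")
    x = np.array([c.master_rt for c in candidates])
    y = np.array([c.sample_rt for c in candidates])
    rng = np.random.default_rng(params.seed)
    degree = 3 if params.nonlinear else 1
    best_mask: Optional[np.ndarray] = None
    best_count = 0
    best_resid = math.inf
    for _ in range(params.k):
        idx = rng.choice(n, size=4, replace=False)
        xs, ys = x[idx], y[idx]
        if np.unique(xs).size < degree + 1:
            continue  # near-singular sample set: redraw
        try:
            if params.nonlinear:
                coef = np.linalg.solve(np.vander(xs, 4), ys)
            else:
                coef = np.polyfit(xs, ys, 1)
        except np.linalg.LinAlgError:
            continue
        resid = np.abs(y - np.polyval(coef, x))
        mask = resid <= params.t
        count = int(mask.sum())
        total = float(resid[mask].sum())
        if count > best_count or (count == best_count and total < best_resid):
            best_mask, best_count, best_resid = mask, count, total
    if best_mask is None or best_count < params.min_points_fraction * n:
        raise AlignmentModelError(
            f"no RANSAC model reached the inlier floor "
            f"({best_count}/{n} < {params.min_points_fraction:.0%}); "
            f"fall back to Join alignment")
    for c, flag in zip(candidates, best_mask):
        c.inlier = bool(flag)
    support = np.column_stack([x[best_mask], y[best_mask]])
    return RtCorrectionModel(support)


def loess_smooth(support, span: float = 0.2) -> RtCorrectionModel:
    """Smooth RANSAC support pairs into an RT-correction predictor.

    Locally weighted regression (LOESS) with bandwidth fraction
    ``span`` is fitted over the support; the smoothed curve backs the
    returned model's predictor. The effective bandwidth is floored so
    that each local fit sees at least 8 support points, protecting
    sparse supports. The default span is chosen small enough that the
    smoother can track retention-time drift with structure on the scale
    of a fraction of the run; wider spans flatten such drift into
    residuals far above typical inlier thresholds.
    """
    support = np.asarray(
        support.support if isinstance(support, RtCorrectionModel) else support,
        dtype=float)
    if support.shape[0] < 4:
        raise ParameterError("LOESS smoothing needs >= 4 support points")
    if np.unique(support[:, 0]).size < 2:
        raise MzflowError("degenerate support: all master RTs identical")
    frac = max(span, min(1.0, 8.0 / support.shape[0]))
    # it=0: outlier rejection is RANSAC's job; robustness reweighting
    # here would down-weight genuine points at drift-curvature peaks
    smoothed = _lowess(support[:, 1], support[:, 0], frac=frac, it=0,
                       return_sorted=True)
    return RtCorrectionModel(support, curve=smoothed)


_ANNEAL_SCHEDULE = (8.0, 6.0, 4.0, 3.0, 2.0, 1.5, 1.0, 1.0, 1.0)


def _refine_support(candidates: Sequence[AlignmentCandidate],
                    support: np.ndarray, t: float,
                    span: float) -> np.ndarray:
    """Locally optimise the consensus set against the smoothed curve.

    The LOESS curve fitted to the current support is tested against
    *all* candidates, and candidates within an annealed threshold (a
    multiple of ``t`` shrinking to ``t`` over the rounds) become the new
    support. The annealing lets the support grow across regions the
    minimal RANSAC model missed — a 4-point model rarely tracks drift
    over the full RT range at the final threshold — while the final
    rounds tighten the set back to true inliers.
    """
    x = np.array([c.master_rt for c in candidates])
    y = np.array([c.sample_rt for c in candidates])
    for factor in _ANNEAL_SCHEDULE:
        curve = loess_smooth(support, span=span)
        mask = np.abs(y - curve.predict(x)) <= factor * t
        if int(mask.sum()) >= 4:
            support = np.column_stack([x[mask], y[mask]])
    final = np.abs(y - loess_smooth(support, span=span).predict(x)) <= t
    for c, flag in zip(candidates, final):
        c.inlier = bool(flag)
    return support


def ransac_align(peaklists: Mapping[str, Sequence[Feature]],
                 params: RansacParams, span: float = 0.2) -> AlignedPeakList:
    """Align samples with RANSAC RT correction followed by Join.

    The master list is seeded from the first sample. For each further
    sample, candidate alignments inside the RANSAC window feed a
    RANSAC + LOESS RT-correction model (with a local-optimisation pass
    that grows the consensus set against the smoothed curve); each
    row's alignment window is recentered at the predicted corrected RT
    and the sample is joined within it. If no acceptable model is found
    for a sample, that sample is joined without correction using the
    wide rr0 window (logged).
    """
    if len(peaklists) < 2:
        raise ParameterError("RANSAC alignment needs >= 2 samples")
    master = AlignedPeakList()
    for j, (sample, features) in enumerate(peaklists.items()):
        features = list(features)
        if j == 0:
            _join_sample(master, sample, features, params.rm0, params.ar0)
            continue
        centers = None
        try:
            candidates = collect_candidates(master, features,
                                            params.rm0, params.rr0)
            if len(candidates) < 4:
                raise AlignmentModelError(
                    f"only {len(candidates)} candidates in the RANSAC window")
            sample_params = RansacParams(**{**params.__dict__,
                                            "seed": _derive_seed(params.seed, j)})
            model = ransac_fit(candidates, sample_params)
            support = _refine_support(candidates, model.support,
                                      params.t, span)
            model = loess_smooth(support, span=span)
            centers = [float(model.predict(row.rt)) for row in master.rows]
        except AlignmentModelError as exc:
            logger.warning("sample %s: %s; joining without RT correction",
                           sample, exc)
            _join_sample(master, sample, features, params.rm0, params.rr0)
            continue
        _join_sample(master, sample, features, params.rm0, params.ar0,
                     centers=centers)
    return master


def _derive_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2 ** 31))
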