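"""Isotope handling: deisotoping, charge detection, pattern prediction.

Isotopologues of one compound appear as features spaced by 1.00335/z Da
(the 13C-12C mass difference over the charge) at the same retention
time. ``group_isotopes`` collapses such chains to their most intense
member; ``predict_isotope_pattern`` computes the theoretical pattern of
a molecular formula by iterated convolution of per-element isotope
distributions over nominal-mass bins; ``score_isotope_similarity``
compares a measured pattern against a prediction.

Isotope masses and abundances are bundled (IUPAC 2013 representative
values), so no network or external chemistry toolkit is needed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .deconvolution import Feature
from .errors import MzflowError, ParameterError

__all__ = [
    "IsotopePattern",
    "ISOTOPE_TABLE",
    "C13_C12_DELTA",
    "parse_formula",
    "monoisotopic_mass",
    "group_isotopes",
    "determine_charge",
    "predict_isotope_pattern",
    "score_isotope_similarity",
]

#: 13C - 12C mass difference in Da; the spacing of isotopologue peaks
#: of a singly-charged ion.
C13_C12_DELTA = 1.00335

#: (isotope mass in Da, natural abundance fraction), most abundant first.
ISOTOPE_TABLE: Dict[str, List[Tuple[float, float]]] = {
    "C": [(12.0, 0.9893), (13.0033548378, 0.0107)],
    "H": [(1.0078250319, 0.999885), (2.0141017781, 0.000115)],
    "N": [(14.0030740052, 0.99636), (15.0001088984, 0.00364)],
    "O": [(15.9949146221, 0.99757), (16.9991315, 0.00038), (17.9991604, 0.00205)],
    "P": [(30.97376151, 1.0)],
    "S": [(31.97207069, 0.9499), (32.9714585, 0.0075),
          (33.96786683, 0.0425), (35.96708088, 0.0001)],
    "Na": [(22.98976928, 1.0)],
    "K": [(38.9637064864, 0.932581), (39.963998166, 0.000117),
          (40.9618252579, 0.067302)],
    "Cl": [(34.96885271, 0.7576), (36.9659026, 0.2424)],
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass
class IsotopePattern:
    """Relative isotopologue abundances of one ion.

    ``entries`` are (m/z, relative abundance) pairs sorted by m/z, with
    the base (most intense) entry at abundance 1. ``charge`` is the ion
    charge, or ``None`` when it could not be determined.
    """

    entries: List[Tuple[float, float]]
    charge: Optional[int] = None

    @property
    def base_mz(self) -> float:
        return max(self.entries, key=lambda e: e[1])[0]

    def offsets(self) -> List[Tuple[float, float]]:
        """Entries re-expressed as m/z offsets from the base peak."""
        base = self.base_mz
        return [(mz - base, ab) for mz, ab in self.entries]

    def shifted_to(self, base_mz: float) -> "IsotopePattern":
        """Copy of the pattern translated so its base peak sits at *base_mz*."""
        delta = base_mz - self.base_mz
        return IsotopePattern(entries=[(mz + delta, ab)
                                       for mz, ab in self.entries],
                              charge=self.charge)


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a Hill-notation molecular formula, e.g. ``"C6H12O6"``."""
    composition: Dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise MzflowError(f"cannot parse formula {formula!r} at {pos}")
        pos = m.end()
        element, count = m.group(1), int(m.group(2) or 1)
        if element not in ISOTOPE_TABLE:
            raise MzflowError(f"unknown element {element!r} in {formula!r}")
        composition[element] = composition.get(element, 0) + count
    if pos != len(formula) or not composition:
        raise MzflowError(f"cannot parse formula {formula!r}")
    return composition


def monoisotopic_mass(formula) -> float:
    """Monoisotopic mass: sum of each element's principal-isotope mass."""
    comp = parse_formula(formula) if isinstance(formula, str) else formula
    return sum(ISOTOPE_TABLE[el][0][0] * n for el, n in comp.items())


# ---------------------------------------------------------------------------
# Deisotoping
# ---------------------------------------------------------------------------

def group_isotopes(features: Sequence[Feature], mz_tolerance: float,
                   rt_tolerance: float, max_charge: int = 3,
                   representative: str = "most_intense") -> List[Feature]:
    """Collapse isotopologue chains into single representative features.

    For each charge z in 1..max_charge, features whose m/z values differ
    by 1.00335/z (within ``mz_tolerance``) and whose RTs differ by at
    most ``rt_tolerance`` are chained; each chain is replaced by its
    most intense member (or lowest-m/z member when ``representative`` is
    ``"lowest_mz"``), which carries the measured pattern and charge.
    Unchained features pass through with charge unknown.
    """
    if max_charge < 1:
        raise ParameterError("max_charge must be >= 1")
    order = sorted(range(len(features)),
                   key=lambda i: (-features[i].height, features[i].mz))
    assigned = [False] * len(features)
    out: List[Feature] = []

    def find(mz_target: float, rt_ref: float, taken: set) -> Optional[int]:
        best, best_d = None, mz_tolerance
        for j, f in enumerate(features):
            if assigned[j] or j in taken:
                continue
            d = abs(f.mz - mz_target)
            if d <= best_d and abs(f.rt - rt_ref) <= rt_tolerance:
                if best is None or d < best_d:
                    best, best_d = j, d
        return best

    def build_chain(i: int, z: int) -> List[int]:
        seed = features[i]
        spacing = C13_C12_DELTA / z
        chain = [i]
        taken = {i}
        for direction in (-1, +1):
            mz_cursor = seed.mz
            while True:
                j = find(mz_cursor + direction * spacing, seed.rt, taken)
                if j is None:
                    break
                chain.append(j)
                taken.add(j)
                mz_cursor = features[j].mz
        return chain

    for i in order:
        if assigned[i]:
            continue
        seed = features[i]
        best_chain: List[int] = [i]
        best_z: Optional[int] = None
        for z in range(1, max_charge + 1):
            chain = build_chain(i, z)
            if len(chain) > len(best_chain):
                best_chain, best_z = chain, z
        for j in best_chain:
            assigned[j] = True
        members = sorted((features[j] for j in best_chain), key=lambda f: f.mz)
        if len(members) == 1:
            out.append(seed)
            continue
        base_height = max(f.height for f in members)
        pattern = IsotopePattern(
            entries=[(f.mz, f.height / base_height) for f in members],
            charge=best_z,
        )
        if representative == "lowest_mz":
            rep = members[0]
        else:
            rep = max(members, key=lambda f: f.height)
        rep.charge = best_z
        rep.isotope_pattern = pattern
        out.append(rep)
    out.sort(key=lambda f: (f.mz, f.rt))
    return out


def determine_charge(pattern: IsotopePattern, max_charge: int = 8) -> Optional[int]:
    """Charge from the median spacing of successive pattern entries.

    z = round(1.00335 / median spacing), clamped to [1, max_charge];
    single-entry patterns give ``None`` (unknown).
    """
    if len(pattern.entries) < 2:
        return None
    mzs = sorted(mz for mz, _ in pattern.entries)
    spacing = float(np.median(np.diff(mzs)))
    if spacing <= 0:
        return None
    return int(min(max(round(C13_C12_DELTA / spacing), 1), max_charge))


# ---------------------------------------------------------------------------
# Pattern prediction
# ---------------------------------------------------------------------------

_Dist = Dict[int, Tuple[float, float]]  # nominal offset -> (prob, prob-weighted mass)


def _element_dist(element: str) -> _Dist:
    principal_mass = ISOTOPE_TABLE[element][0][0]
    dist: _Dist = {}
    for mass, ab in ISOTOPE_TABLE[element]:
        off = int(round(mass - principal_mass))
        p, wm = dist.get(off, (0.0, 0.0))
        dist[off] = (p + ab, wm + ab * mass)
    return dist


def _convolve(a: _Dist, b: _Dist) -> _Dist:
    out: _Dist = {}
    for o1, (p1, wm1) in a.items():
        m1 = wm1 / p1
        for o2, (p2, wm2) in b.items():
            m2 = wm2 / p2
            p = p1 * p2
            o = o1 + o2
            prev_p, prev_wm = out.get(o, (0.0, 0.0))
            out[o] = (prev_p + p, prev_wm + p * (m1 + m2))
    return out


def _power(dist: _Dist, n: int) -> _Dist:
    result: _Dist = {0: (1.0, 0.0)}
    base = dist
    while n:
        if n & 1:
            result = _convolve(result, base)
        n >>= 1
        if n:
            base = _convolve(base, base)
    return result


def predict_isotope_pattern(formula, charge: int = 1,
                            prune_below: float = 1e-4) -> IsotopePattern:
    """Theoretical isotope pattern of a molecular formula.

    Per-element isotope distributions are convolved (exactly, aggregated
    into nominal-mass bins), normalised to a base peak of 1, and entries
    below ``prune_below`` dropped. m/z = isotopologue mass / charge,
    with the electron mass neglected.
    """
    if charge < 1:
        raise ParameterError("charge must be >= 1")
    comp = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    total: _Dist = {0: (1.0, 0.0)}
    for element, count in comp.items():
        if element not in ISOTOPE_TABLE:
            raise MzflowError(f"unknown element {element!r}")
        total = _convolve(total, _power(_element_dist(element), count))
    base_p = max(p for p, _ in total.values())
    entries = []
    for off in sorted(total):
        p, wm = total[off]
        rel = p / base_p
        if rel < prune_below:
            continue
        entries.append((wm / p / charge, rel))
    return IsotopePattern(entries=entries, charge=charge)


def score_isotope_similarity(measured: IsotopePattern,
                             predicted: IsotopePattern,
                             mz_tolerance: float = 0.01) -> float:
    """Similarity in [0, 1] between two normalised isotope patterns.

    Entries are matched greedily by m/z distance within
    ``mz_tolerance``; the score is 1 - (sum of |abundance differences|
    over matched entries plus the abundances of unmatched entries) / 2,
    floored at 0. Callers comparing a measured ion pattern against a
    neutral-formula prediction should first shift the prediction onto
    the measured base peak (see :meth:`IsotopePattern.shifted_to`) so
    that adduct mass and calibration do not defeat the matching.
    """
    a = measured.entries
    b = predicted.entries
    pairs = sorted(
        ((abs(oa - ob), i, j) for i, (oa, _) in enumerate(a)
         for j, (ob, _) in enumerate(b) if abs(oa - ob) <= mz_tolerance),
        key=lambda t: t,
    )
    used_a: set = set()
    used_b: set = set()
    diff = 0.0
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        diff += abs(a[i][1] - b[j][1])
    diff += sum(ab for i, (_, ab) in enumerate(a) if i not in used_a)
    diff += sum(ab for j, (_, ab) in enumerate(b) if j not in used_b)
    return max(0.0, 1.0 - diff / 2.0)
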