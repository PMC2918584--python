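"""Peak identification against a local compound database.

Each peak-list row's neutral molecular mass is computed from its m/z,
charge and the chosen ionisation adduct, then searched against a local
compound table within a mass tolerance; an optional retention-time gate
and isotope-pattern similarity filter narrow the candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .alignment import PeakListRow
from .errors import MzflowError, ParameterError
from .isotopes import (IsotopePattern, monoisotopic_mass,
                       predict_isotope_pattern, score_isotope_similarity)

__all__ = [
    "CompoundRecord",
    "AdductSpec",
    "ADDUCTS",
    "neutral_mass",
    "load_compound_db",
    "search_local_db",
]

#: proton / common cation masses from the bundled isotope table
#: (principal isotope mass minus one electron for the cations)
_ELECTRON = 0.00054858

ADDUCTS: Dict[str, "AdductSpec"] = {}


@dataclass(frozen=True)
class AdductSpec:
    """An ionisation adduct: name, mass in Da, ionisation mode."""

    name: str
    mass: float
    mode: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ParameterError("adduct mass must be > 0")


for _name, _mass, _mode in [
    ("[M+H]+", 1.00728, "positive"),
    ("[M+Na]+", 22.98922, "positive"),
    ("[M+K]+", 38.96316, "positive"),
    ("[M+NH4]+", 18.03383, "positive"),
    ("[M-H]-", 1.00728, "negative"),
]:
    ADDUCTS[_name] = AdductSpec(_name, _mass, _mode)


@dataclass
class CompoundRecord:
    """One entry of the local compound database."""

    name: str
    neutral_mass: float
    formula: Optional[str] = None
    expected_rt: Optional[float] = None

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ParameterError(f"{self.name}: neutral mass must be > 0")


def neutral_mass(mz: float, z: int, adduct: AdductSpec,
                 per_charge_adduct: bool = False) -> float:
    """Neutral molecular mass from measured m/z.

    m_neutral = (m/z × z) ∓ m_adduct: the adduct mass is subtracted in
    positive mode and added in negative mode. By default the adduct mass
    is applied once regardless of charge; ``per_charge_adduct=True``
    applies it z times (z protonations carry z proton masses).
    """
    if z < 1:
        raise ParameterError("charge must be >= 1")
    m = mz * z
    adduct_mass = adduct.mass * (z if per_charge_adduct else 1)
    return m - adduct_mass if adduct.mode == "positive" else m + adduct_mass


def load_compound_db(path) -> List[CompoundRecord]:
    """Load a compound table from CSV.

    Columns: ``name, formula, neutral_mass, rt_seconds``; either
    ``formula`` or ``neutral_mass`` must be present per row (the mass is
    computed from the formula when absent).
    """
    import pandas as pd

    df = pd.read_csv(path)
    if "name" not in df.columns:
        raise MzflowError("compound DB needs a 'name' column")
    records: List[CompoundRecord] = []
    for _, rec in df.iterrows():
        formula = rec.get("formula")
        formula = None if pd.isna(formula) or formula == "" else str(formula)
        mass = rec.get("neutral_mass")
        if mass is None or pd.isna(mass):
            if formula is None:
                raise MzflowError(
                    f"{rec['name']}: needs a formula or a neutral mass")
            mass = monoisotopic_mass(formula)
        rt = rec.get("rt_seconds")
        rt = None if rt is None or pd.isna(rt) else float(rt)
        records.append(CompoundRecord(name=str(rec["name"]),
                                      neutral_mass=float(mass),
                                      formula=formula, expected_rt=rt))
    return records


def search_local_db(row: PeakListRow, db: Sequence[CompoundRecord],
                    adduct: AdductSpec, z="auto",
                    mass_tolerance: float = 0.01,
                    rt_tolerance: Optional[float] = None,
                    isotope_filter: Optional[Tuple[float, float]] = None,
                    per_charge_adduct: bool = False) -> List[CompoundRecord]:
    """Rank database candidates for one aligned row.

    Candidates within ``mass_tolerance`` of the row's neutral mass (and
    within ``rt_tolerance`` of the expected RT, when both are known) are
    returned ordered by absolute mass error, ties by name. With
    ``z="auto"`` the isotope-derived charge of the row's members is
    used, defaulting to 1 when unknown. ``isotope_filter`` is a
    ``(prune_below, min_score)`` pair: candidates with a formula whose
    predicted pattern scores below ``min_score`` against the row's
    measured pattern are dropped (the filter never reorders survivors).
    """
    if not db:
        raise ParameterError("compound database is empty")
    measured_pattern: Optional[IsotopePattern] = None
    charge = None
    for f in row.features.values():
        if f.isotope_pattern is not None and measured_pattern is None:
            measured_pattern = f.isotope_pattern
        if f.charge and charge is None:
            charge = f.charge
    if z == "auto":
        z_used = charge or 1
    else:
        z_used = int(z)
    m_neutral = neutral_mass(row.mz, z_used, adduct,
                             per_charge_adduct=per_charge_adduct)
    hits: List[Tuple[float, str, CompoundRecord]] = []
    for rec in db:
        err = abs(rec.neutral_mass - m_neutral)
        if err > mass_tolerance:
            continue
        if (rt_tolerance is not None and rec.expected_rt is not None
                and abs(rec.expected_rt - row.rt) > rt_tolerance):
            continue
        hits.append((err, rec.name, rec))
    hits.sort(key=lambda h: (h[0], h[1]))
    ranked = [rec for _, _, rec in hits]
    if isotope_filter is not None and measured_pattern is not None:
        prune_below, min_score = isotope_filter
        kept = []
        for rec in ranked:
            if rec.formula is None:
                kept.append(rec)
                continue
            predicted = predict_isotope_pattern(
                rec.formula, charge=z_used,
                prune_below=prune_below).shifted_to(measured_pattern.base_mz)
            if score_isotope_similarity(measured_pattern, predicted) >= min_score:
                kept.append(rec)
        ranked = kept
    return ranked
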