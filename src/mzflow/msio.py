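"""Raw-data input/output.

Reads mzML (1.0/1.1) into the internal scan model, writes aligned peak
lists to CSV/XML, and writes small mzML files used as test fixtures.
Retention times are stored in seconds and m/z in Da throughout the
package, regardless of the units used in the source file.
"""

from __future__ import annotations

import base64
import re
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from lxml import etree

from .errors import FormatError, MzflowError

__all__ = [
    "Scan",
    "RawDataFile",
    "read_mzml",
    "write_mzml_fixture",
    "write_peaklist_csv",
    "read_peaklist_csv",
    "write_peaklist_xml",
    "parse_time",
]

#: median m/z gap below which an unlabelled spectrum is treated as
#: continuous (profile) mode, provided it has at least this many points
_CONTINUOUS_GAP_DA = 0.1
_CONTINUOUS_MIN_POINTS = 50


@dataclass(eq=False)
class Scan:
    """One mass spectrum: m/z-intensity data points at a retention time.

    Parameters
    ----------
    scan_number : int
        Native scan index from the source file.
    rt_seconds : float
        Retention time in seconds (non-negative).
    ms_level : int
        1 for survey scans, >= 2 for fragmentation scans.
    mz, intensity : ndarray
        Parallel arrays; m/z strictly increasing.
    mode : str
        ``"continuous"`` (profile) or ``"centroid"``.
    """

    scan_number: int
    rt_seconds: float
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    mode: str = "continuous"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise FormatError("m/z and intensity arrays differ in length")
        if self.rt_seconds < 0:
            raise FormatError(f"negative retention time {self.rt_seconds}")
        if self.mz.size > 1 and np.any(np.diff(self.mz) <= 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    @property
    def points(self) -> List[Tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass(eq=False)
class RawDataFile:
    """An ordered collection of scans from one sample."""

    name: str
    scans: List[Scan] = field(default_factory=list)

    def ms1_scans(self) -> List[Scan]:
        return [s for s in self.scans if s.ms_level == 1]


def _rt_to_seconds(value: float, unit: str) -> float:
    unit = (unit or "second").lower()
    if unit.startswith("minute"):
        return value * 60.0
    if unit.startswith("hour"):
        return value * 3600.0
    if unit.startswith("second") or unit in ("s", "sec"):
        return value
    raise FormatError(f"unsupported retention-time unit {unit!r}")


def _localname(el) -> str:
    return etree.QName(el).localname


def _cv_params(el) -> dict:
    """accession -> (value, unit name) for the element's direct cvParams."""
    out = {}
    for child in el:
        if _localname(child) == "cvParam":
            out[child.get("accession")] = (child.get("value", ""),
                                           child.get("unitName", ""))
    return out


def _decode_binary_array(array_el) -> Tuple[str, np.ndarray]:
    """Decode one <binaryDataArray>: returns (kind, values).

    Supports 64/32-bit floats, uncompressed or zlib-compressed; any
    other encoding raises :class:`FormatError` naming the accession.
    """
    params = _cv_params(array_el)
    if "MS:1000514" in params:
        kind = "mz"
    elif "MS:1000515" in params:
        kind = "intensity"
    else:
        kind = "other"
    if "MS:1000523" in params:
        dtype = "<f8"
    elif "MS:1000521" in params:
        dtype = "<f4"
    else:
        raise FormatError(
            "unsupported binary encoding in <binaryDataArray> "
            f"(accessions {sorted(params)})")
    compressed = "MS:1000574" in params
    binary = None
    for child in array_el:
        if _localname(child) == "binary":
            binary = child.text or ""
    if binary is None:
        raise FormatError("missing <binary> element in <binaryDataArray>")
    data = base64.b64decode(binary)
    if compressed:
        data = zlib.decompress(data)
    return kind, np.frombuffer(data, dtype=dtype).astype(float)


def _parse_spectrum(spec_el, fallback_index: int) -> Scan:
    params = _cv_params(spec_el)
    ms_level = int(params.get("MS:1000511", ("1", ""))[0] or 1)
    if "MS:1000127" in params:
        mode = "centroid"
    elif "MS:1000128" in params:
        mode = "continuous"
    else:
        mode = None
    rt = 0.0
    mz = np.array([])
    inten = np.array([])
    for child in spec_el:
        name = _localname(child)
        if name == "scanList":
            for scan_el in child:
                if _localname(scan_el) != "scan":
                    continue
                scan_params = _cv_params(scan_el)
                if "MS:1000016" in scan_params:
                    value, unit = scan_params["MS:1000016"]
                    rt = _rt_to_seconds(float(value), unit)
        elif name == "binaryDataArrayList":
            for array_el in child:
                if _localname(array_el) != "binaryDataArray":
                    continue
                kind, values = _decode_binary_array(array_el)
                if kind == "mz":
                    mz = values
                elif kind == "intensity":
                    inten = values
    index = spec_el.get("index")
    index = int(index) if index is not None else fallback_index
    if mode is None:
        mode = _infer_mode(mz)
    return Scan(scan_number=index, rt_seconds=rt, ms_level=ms_level,
                mz=mz, intensity=inten, mode=mode)


def read_mzml(path) -> RawDataFile:
    """Read an mzML 1.0/1.1 file into a :class:`RawDataFile`.

    Scans are returned in file order with retention times converted to
    seconds. Raises :class:`FormatError` on malformed XML, unsupported
    binary encodings, or decreasing retention times, and
    ``FileNotFoundError`` on a missing path.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed mzML in {path.name}: {exc}") from exc
    root = tree.getroot()
    scans: List[Scan] = []
    for idx, spec_el in enumerate(root.iter(f"{{{_MZML_NS}}}spectrum")):
        scans.append(_parse_spectrum(spec_el, idx))
    prev_rt: dict = {}
    for s in scans:
        # RT must be non-decreasing within each MS level stream
        if s.ms_level in prev_rt and s.rt_seconds < prev_rt[s.ms_level] - 1e-9:
            raise FormatError(
                f"retention time decreases at scan {s.scan_number} "
                f"({s.rt_seconds} s after {prev_rt[s.ms_level]} s)"
            )
        prev_rt[s.ms_level] = s.rt_seconds
    return RawDataFile(name=path.name, scans=scans)


def _infer_mode(mz: np.ndarray) -> str:
    if mz.size >= _CONTINUOUS_MIN_POINTS:
        if float(np.median(np.diff(mz))) < _CONTINUOUS_GAP_DA:
            return "continuous"
    return "centroid"


# ---------------------------------------------------------------------------
# mzML fixture writer
# ---------------------------------------------------------------------------

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _encode_array(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


def _cv(parent, accession: str, name: str, value: str = "", **units) -> None:
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    attrs.update(units)
    etree.SubElement(parent, f"{{{_MZML_NS}}}cvParam", attrs)


def write_mzml_fixture(raw: RawDataFile, path) -> Path:
    """Write a minimal, valid mzML 1.1 document for *raw*.

    Intended for generating small test inputs; the output round-trips
    through :func:`read_mzml` with identical RT/m/z/intensity values.
    Arrays are encoded as uncompressed little-endian 64-bit floats.
    """
    path = Path(path)
    root = etree.Element(f"{{{_MZML_NS}}}mzML", {"version": "1.1.0"}, nsmap={None: _MZML_NS})
    cvlist = etree.SubElement(root, f"{{{_MZML_NS}}}cvList", {"count": "2"})
    etree.SubElement(cvlist, f"{{{_MZML_NS}}}cv", {
        "id": "MS", "fullName": "Proteomics Standards Initiative Mass Spectrometry Ontology",
        "URI": "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"})
    etree.SubElement(cvlist, f"{{{_MZML_NS}}}cv", {
        "id": "UO", "fullName": "Unit Ontology",
        "URI": "http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"})
    run = etree.SubElement(root, f"{{{_MZML_NS}}}run", {"id": raw.name or "run"})
    speclist = etree.SubElement(
        run, f"{{{_MZML_NS}}}spectrumList", {"count": str(len(raw.scans))})
    for i, scan in enumerate(raw.scans):
        spec = etree.SubElement(speclist, f"{{{_MZML_NS}}}spectrum", {
            "index": str(i),
            "id": f"scan={scan.scan_number}",
            "defaultArrayLength": str(len(scan)),
        })
        _cv(spec, "MS:1000511", "ms level", str(scan.ms_level))
        if scan.ms_level == 1:
            _cv(spec, "MS:1000579", "MS1 spectrum")
        else:
            _cv(spec, "MS:1000580", "MSn spectrum")
        if scan.mode == "centroid":
            _cv(spec, "MS:1000127", "centroid spectrum")
        else:
            _cv(spec, "MS:1000128", "profile spectrum")
        scans_el = etree.SubElement(spec, f"{{{_MZML_NS}}}scanList", {"count": "1"})
        _cv(scans_el, "MS:1000795", "no combination")
        scan_el = etree.SubElement(scans_el, f"{{{_MZML_NS}}}scan")
        _cv(scan_el, "MS:1000016", "scan start time", repr(scan.rt_seconds),
            unitAccession="UO:0000010", unitName="second", unitCvRef="UO")
        arrays = etree.SubElement(
            spec, f"{{{_MZML_NS}}}binaryDataArrayList", {"count": "2"})
        for accession, name, unit, data in (
            ("MS:1000514", "m/z array",
             {"unitAccession": "MS:1000040", "unitName": "m/z", "unitCvRef": "MS"},
             scan.mz),
            ("MS:1000515", "intensity array",
             {"unitAccession": "MS:1000131", "unitName": "number of detector counts",
              "unitCvRef": "MS"},
             scan.intensity),
        ):
            encoded = _encode_array(data)
            arr = etree.SubElement(
                arrays, f"{{{_MZML_NS}}}binaryDataArray",
                {"encodedLength": str(len(encoded))})
            _cv(arr, "MS:1000523", "64-bit float")
            _cv(arr, "MS:1000576", "no compression")
            _cv(arr, accession, name, **unit)
            etree.SubElement(arr, f"{{{_MZML_NS}}}binary").text = encoded
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)
    return path


# ---------------------------------------------------------------------------
# Peak-list export
# ---------------------------------------------------------------------------

_CSV_FIXED_COLUMNS = ["row id", "mz", "rt", "identity"]
_CSV_SAMPLE_FIELDS = ["mz", "rt", "height", "area"]


def write_peaklist_csv(peaklist, path) -> Path:
    """Export an aligned peak list to CSV.

    One row per aligned row; fixed columns (row id, average m/z, average
    RT, identity) followed by per-sample m/z, RT, height, area columns.
    The written file round-trips through :func:`read_peaklist_csv`.
    Raises :class:`MzflowError` on an empty peak list.
    """
    import pandas as pd

    if not peaklist.rows:
        raise MzflowError("refusing to export an empty peak list")
    path = Path(path)
    records = []
    for rid, row in enumerate(peaklist.rows):
        rec = {
            "row id": rid,
            "mz": row.mz,
            "rt": row.rt,
            "identity": row.identity.name if row.identity is not None else "",
        }
        for sample in peaklist.samples:
            feat = row.features.get(sample)
            for fld in _CSV_SAMPLE_FIELDS:
                rec[f"{sample}:{fld}"] = getattr(feat, fld) if feat is not None else ""
        records.append(rec)
    columns = list(_CSV_FIXED_COLUMNS)
    for sample in peaklist.samples:
        columns.extend(f"{sample}:{fld}" for fld in _CSV_SAMPLE_FIELDS)
    pd.DataFrame.from_records(records, columns=columns).to_csv(path, index=False)
    return path


def read_peaklist_csv(path):
    """Read a peak list written by :func:`write_peaklist_csv`.

    Per-sample chromatographic point data is not stored in the CSV, so
    the reconstructed features carry only m/z, RT, height and area.
    """
    import pandas as pd

    from .alignment import AlignedPeakList, PeakListRow
    from .deconvolution import Feature
    from .identify import CompoundRecord

    df = pd.read_csv(path)
    samples: List[str] = []
    for col in df.columns:
        if col.endswith(":mz") and ":" in col:
            samples.append(col.rsplit(":", 1)[0])
    rows = []
    for _, rec in df.iterrows():
        row = PeakListRow()
        for sample in samples:
            mz = rec[f"{sample}:mz"]
            if pd.isna(mz) or mz == "":
                continue
            feat = Feature(
                mz=float(mz),
                rt=float(rec[f"{sample}:rt"]),
                height=float(rec[f"{sample}:height"]),
                area=float(rec[f"{sample}:area"]),
                rt_start=float(rec[f"{sample}:rt"]),
                rt_end=float(rec[f"{sample}:rt"]),
                points=[],
                source=sample,
            )
            row.add(sample, feat)
        identity = rec.get("identity", "")
        if isinstance(identity, str) and identity:
            row.identity = CompoundRecord(name=identity, neutral_mass=1.0)
        rows.append(row)
    return AlignedPeakList(rows=rows, samples=samples)


def write_peaklist_xml(peaklist, path) -> Path:
    """Export an aligned peak list as flat XML.

    Schema (artifact-defined): ``<peaklist><row id mz rt identity>
    <peak sample mz rt height area/>...</row>...</peaklist>``.
    """
    if not peaklist.rows:
        raise MzflowError("refusing to export an empty peak list")
    path = Path(path)
    root = etree.Element("peaklist", {"samples": ",".join(peaklist.samples)})
    for rid, row in enumerate(peaklist.rows):
        row_el = etree.SubElement(root, "row", {
            "id": str(rid),
            "mz": repr(row.mz),
            "rt": repr(row.rt),
            "identity": row.identity.name if row.identity is not None else "",
        })
        for sample in peaklist.samples:
            feat = row.features.get(sample)
            if feat is None:
                continue
            etree.SubElement(row_el, "peak", {
                "sample": sample,
                "mz": repr(feat.mz),
                "rt": repr(feat.rt),
                "height": repr(feat.height),
                "area": repr(feat.area),
            })
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)
    return path


# ---------------------------------------------------------------------------
# Time parsing
# ---------------------------------------------------------------------------

_TIME_RE = re.compile(
    r"^\s*(?:(?:(?P<h>\d+):)?(?P<m>\d+):(?P<s>\d+(?:\.\d*)?)|(?P<bare>\d+(?:\.\d*)?))\s*$"
)


def parse_time(text) -> float:
    """Parse ``"m:ss"``, ``"hh:mm:ss"`` or bare seconds into seconds.

    >>> parse_time("0:25")
    25.0
    >>> parse_time("02:30")
    150.0
    """
    if isinstance(text, (int, float)):
        return float(text)
    m = _TIME_RE.match(str(text))
    if m is None:
        raise FormatError(f"unparseable time {text!r}")
    if m.group("bare") is not None:
        return float(m.group("bare"))
    hours = int(m.group("h")) if m.group("h") else 0
    return hours * 3600.0 + int(m.group("m")) * 60.0 + float(m.group("s"))
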