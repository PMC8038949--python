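"""Reading, validating and assembling assigned 2D 1H-15N peak lists.

Two dialects are supported: a fixed-column TSV
(``residue_number  residue_type  shift_h_ppm  shift_n_ppm  intensity  flags``,
header mandatory, flags semicolon-separated) and Sparky-style ``.list`` files
(``A18N-H  118.23  8.45  1.2e6`` — note Sparky prints w1 = 15N before
w2 = 1H).  A titration series is an ordered set of such tables at strictly
increasing ligand:protein molar ratios, starting from the apo point (r = 0).
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "PeakRecord",
    "TitrationSeries",
    "read_peak_table",
    "write_peak_table",
    "assemble_series",
    "VALID_FLAGS",
]

VALID_FLAGS = frozenset({"proline", "unassigned", "overlapped"})

_ONE_LETTER = set("ACDEFGHIKLMNPQRSTVWY")
_THREE_LETTER = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F", "GLY": "G",
    "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L", "MET": "M", "ASN": "N",
    "PRO": "P", "GLN": "Q", "ARG": "R", "SER": "S", "THR": "T", "VAL": "V",
    "TRP": "W", "TYR": "Y",
}

_TSV_COLUMNS = ["residue_number", "residue_type", "shift_h_ppm",
                "shift_n_ppm", "intensity", "flags"]

_SPARKY_RE = re.compile(r"^([A-Za-z]{1,3})(\d+)N-H$")


@dataclass
class PeakRecord:
    """One assigned amide cross-peak.

    Shifts are in ppm (1H and 15N); ``intensity`` is an arbitrary-unit peak
    height and may be absent.  ``flags`` marks residues with no usable signal
    (prolines, unassigned, severely overlapped).
    """

    residue_number: int
    residue_type: str
    shift_h: float
    shift_n: float
    intensity: float | None = None
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise ValueError("residue_number must be >= 1")
        bad = set(self.flags) - VALID_FLAGS
        if bad:
            raise ValueError(f"unknown flags: {sorted(bad)}")
        self.flags = frozenset(self.flags)
        if not self.flags:
            import math
            if not (math.isfinite(self.shift_h) and math.isfinite(self.shift_n)):
                raise ValueError(
                    f"residue {self.residue_number}: non-finite shifts on an unflagged record")


@dataclass
class TitrationSeries:
    """A titration: metadata plus per-point peak tables keyed by residue.

    ``points`` is an ordered list of ``(molar_ratio, {residue: PeakRecord})``;
    the first point is the apo spectrum (r = 0) and ratios strictly increase.
    Concentrations are in uM: ``c_pro`` is the initial protein concentration,
    ``c_lig`` the ligand stock concentration.
    """

    protein_id: str
    ligand_id: str
    c_pro: float
    c_lig: float
    points: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.c_pro <= 0 or self.c_lig <= 0:
            raise ValueError("concentrations must be > 0")
        if not self.points:
            raise ValueError("series must contain at least one point")
        ratios = [r for r, _ in self.points]
        if ratios[0] != 0:
            raise ValueError("first titration point must be the apo point (r = 0)")
        if any(b <= a for a, b in zip(ratios, ratios[1:])):
            raise ValueError("molar ratios must be strictly increasing")
        apo_res = set(self.points[0][1])
        for r, table in self.points[1:]:
            extra = set(table) - apo_res
            if extra:
                raise ValueError(
                    f"point r={r} contains residues absent from the apo point: {sorted(extra)}")

    @property
    def ratios(self) -> list[float]:
        return [r for r, _ in self.points]

    @property
    def residues(self) -> list[int]:
        return sorted(self.points[0][1])

    def point(self, r: float) -> dict:
        for rr, table in self.points:
            if abs(rr - r) <= 1e-9:
                return table
        raise KeyError(f"no titration point at ratio {r}")


def _normalize_restype(token: str, lineno: int) -> str:
    t = token.strip().upper()
    if len(t) == 3 and t in _THREE_LETTER:
        return _THREE_LETTER[t]
    if len(t) == 1 and t in _ONE_LETTER:
        return t
    warnings.warn(f"line {lineno}: unknown residue code {token!r}")
    return t


def read_peak_table(path, dialect: str = "tsv") -> list[PeakRecord]:
    """Read a peak table; returns one record per assigned residue.

    Malformed lines raise with their line number; duplicate residues are an
    error; unknown residue-type codes produce a warning.
    """
    path = Path(path)
    if dialect == "tsv":
        records = _read_tsv(path)
    elif dialect == "sparky":
        records = _read_sparky(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not records:
        raise ValueError(f"{path}: no records")
    seen: dict[int, int] = {}
    for rec in records:
        if rec.residue_number in seen:
            raise ValueError(f"{path}: duplicate entry for residue {rec.residue_number}")
        seen[rec.residue_number] = 1
    return records


def _read_tsv(path: Path) -> list[PeakRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            return []
        if [h.strip() for h in header] != _TSV_COLUMNS:
            raise ValueError(f"{path}: line 1: expected header {_TSV_COLUMNS}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(_TSV_COLUMNS):
                raise ValueError(f"{path}: line {lineno}: expected "
                                 f"{len(_TSV_COLUMNS)} fields, got {len(row)}")
            try:
                resnum = int(row[0])
                flags = frozenset(f for f in row[5].split(";") if f)
                shift_h = float(row[2]) if row[2].strip() else float("nan")
                shift_n = float(row[3]) if row[3].strip() else float("nan")
                intensity = float(row[4]) if row[4].strip() else None
                rec = PeakRecord(resnum, _normalize_restype(row[1], lineno),
                                 shift_h, shift_n, intensity, flags)
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def _read_sparky(path: Path) -> list[PeakRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.lower().startswith("assignment"):
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise ValueError(f"{path}: line {lineno}: expected "
                                 f"'assignment w1 w2 [height]', got {line!r}")
            m = _SPARKY_RE.match(parts[0])
            if m is None:
                raise ValueError(f"{path}: line {lineno}: cannot parse "
                                 f"assignment {parts[0]!r}")
            try:
                w1_n15 = float(parts[1])   # Sparky lists w1 = 15N first
                w2_h1 = float(parts[2])
                intensity = float(parts[3]) if len(parts) == 4 else None
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            records.append(PeakRecord(int(m.group(2)),
                                      _normalize_restype(m.group(1), lineno),
                                      w2_h1, w1_n15, intensity))
    return records


def write_peak_table(records, path) -> None:
    """Write records in the TSV dialect; read/write round trips losslessly."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for rec in records:
            writer.writerow([
                rec.residue_number,
                rec.residue_type,
                repr(rec.shift_h),
                repr(rec.shift_n),
                "" if rec.intensity is None else repr(rec.intensity),
                ";".join(sorted(rec.flags)),
            ])


def assemble_series(tables, ratios, c_pro, c_lig,
                    protein_id: str = "", ligand_id: str = "") -> TitrationSeries:
    """Assemble per-point peak tables into a validated TitrationSeries.

    Tables given out of ratio order are reordered (with a warning).  Residues
    present at the apo point but missing at a later point are inserted there
    as ``overlapped``-flagged placeholders, so they are masked at that point
    only rather than dropped globally.
    """
    tables, ratios = list(tables), [float(r) for r in ratios]
    if len(tables) != len(ratios):
        raise ValueError("need one table per ratio")
    if len(tables) < 2:
        raise ValueError("a titration needs at least two points")
    order = sorted(range(len(ratios)), key=lambda i: ratios[i])
    if order != list(range(len(ratios))):
        warnings.warn("tables were not in ratio order; reordering")
        tables = [tables[i] for i in order]
        ratios = [ratios[i] for i in order]
    if any(b <= a for a, b in zip(ratios, ratios[1:])):
        raise ValueError("molar ratios must be strictly increasing")
    if ratios[0] != 0:
        raise ValueError("no apo point: first ratio must be 0")

    keyed = [{rec.residue_number: rec for rec in tab} for tab in tables]
    apo = keyed[0]
    points = [(ratios[0], apo)]
    for r, table in zip(ratios[1:], keyed[1:]):
        filled = dict(table)
        for res, rec0 in apo.items():
            if res not in filled:
                filled[res] = PeakRecord(res, rec0.residue_type,
                                         float("nan"), float("nan"), None,
                                         frozenset({"overlapped"}))
        points.append((r, filled))
    return TitrationSeries(protein_id, ligand_id, c_pro, c_lig, points)
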