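"""Binding-site mapping from CSP and intensity-ratio statistics.

Residues are classified against ensemble statistics of the weighted CSP at a
chosen titration point: ``strong`` (CSP >= mean + SD, the conventional cutoff
for mapping a binding interface and for choosing docking "active" residues),
``moderate`` (mean <= CSP < mean + SD), ``below_mean``, or ``excluded``
(prolines and residues with no usable amide signal, which contribute nothing
to the statistics).  Intensity ratios (holo peak height / apo peak height)
flag disordered-region binding: residues rigidified on ligand binding gain
intensity, with ratio > 3 scored ``strong`` and 1.5 < ratio <= 3 ``moderate``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import CSPProfile
from .peaks import TitrationSeries

__all__ = [
    "ResidueAnnotation",
    "classify_csp",
    "intensity_ratio",
    "classify_enhancement",
    "derive_active_residues",
    "build_annotations",
    "export_annotations",
    "read_annotations",
    "format_residue_ranges",
]

CSP_CLASSES = ("strong", "moderate", "below_mean", "excluded")
ENHANCEMENT_CLASSES = ("strong", "moderate", "none", "invalid")
DOCKING_ROLES = ("active", "passive", "none")

# class -> color map used for structure coloring (binding-interface figures)
CSP_COLORS = {"strong": "red", "moderate": "pink",
              "below_mean": "white", "excluded": "yellow"}
ENHANCEMENT_HIGHLIGHT_COLOR = "cyan"


@dataclass
class ResidueAnnotation:
    residue_number: int
    csp_class: str = "excluded"
    enhancement_class: str = "invalid"
    docking_role: str = "none"

    def __post_init__(self) -> None:
        if self.csp_class not in CSP_CLASSES:
            raise ValueError(f"unknown csp_class {self.csp_class!r}")
        if self.enhancement_class not in ENHANCEMENT_CLASSES:
            raise ValueError(f"unknown enhancement_class {self.enhancement_class!r}")
        if self.docking_role not in DOCKING_ROLES:
            raise ValueError(f"unknown docking_role {self.docking_role!r}")
        if self.csp_class == "excluded" and self.docking_role == "active":
            raise ValueError("excluded residues can never be active")


def classify_csp(profile: CSPProfile, at_ratio: float | None = None,
                 ddof: int = 1) -> tuple[dict[int, str], dict[str, float]]:
    """Classify residues by CSP at one titration point.

    Mean and standard deviation (sample SD, ``ddof=1``, configurable) are
    computed over valid residues only; ties go up: CSP >= mean + SD is
    ``strong`` and CSP >= mean is ``moderate``.  Returns the per-residue
    classes and the thresholds used.
    """
    r = profile.ratios[-1] if at_ratio is None else at_ratio
    csp, valid = profile.at_ratio(r)
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid residues to classify")
    mean = float(np.mean(csp[valid]))
    sd = float(np.std(csp[valid], ddof=ddof))
    classes: dict[int, str] = {}
    for res, c, v in zip(profile.residues, csp, valid):
        if not v:
            classes[int(res)] = "excluded"
        elif c >= mean + sd:
            classes[int(res)] = "strong"
        elif c >= mean:
            classes[int(res)] = "moderate"
        else:
            classes[int(res)] = "below_mean"
    return classes, {"ratio": float(r), "mean": mean, "sd": sd,
                     "strong_threshold": mean + sd}


def intensity_ratio(series: TitrationSeries, point_ratio: float) -> pd.DataFrame:
    """Per-residue holo/apo intensity ratio at one titration point.

    Returns a DataFrame indexed by residue number with columns
    ``intensity_apo``, ``intensity_holo``, ``ratio`` and ``valid``; residues
    missing either intensity (or with apo intensity 0, or flagged at either
    point) are marked invalid rather than producing infinities.
    """
    apo = series.points[0][1]
    holo = series.point(point_ratio)
    rows = []
    for res in sorted(apo):
        rec0, rec1 = apo[res], holo.get(res)
        i0 = rec0.intensity if not rec0.flags else None
        i1 = rec1.intensity if (rec1 is not None and not rec1.flags) else None
        ok = i0 is not None and i1 is not None and i0 > 0
        rows.append({
            "residue_number": res,
            "intensity_apo": np.nan if i0 is None else i0,
            "intensity_holo": np.nan if i1 is None else i1,
            "ratio": (i1 / i0) if ok else np.nan,
            "valid": ok,
        })
    return pd.DataFrame(rows).set_index("residue_number")


def classify_enhancement(profile: pd.DataFrame) -> dict[int, str]:
    """Classify intensity enhancement: ratio > 3 strong, 1.5 < ratio <= 3
    moderate (strict '>' at both boundaries), otherwise none; invalid rows
    stay ``invalid``."""
    classes: dict[int, str] = {}
    for res, row in profile.iterrows():
        if not row["valid"]:
            classes[int(res)] = "invalid"
        elif row["ratio"] > 3.0:
            classes[int(res)] = "strong"
        elif row["ratio"] > 1.5:
            classes[int(res)] = "moderate"
        else:
            classes[int(res)] = "none"
    return classes


def derive_active_residues(csp_classes: dict[int, str],
                           smooth: bool = False) -> dict[int, str]:
    """Docking roles from CSP classes: strong -> active, everything else
    (including excluded) -> none.

    With ``smooth=True``, single non-strong residues bracketed by active
    neighbours are promoted to active (contiguity smoothing; off by default).
    Passive residues are not auto-derived; callers may assign them.
    """
    roles = {res: ("active" if cls == "strong" else "none")
             for res, cls in csp_classes.items()}
    if smooth:
        for res in sorted(roles):
            if (roles[res] == "none" and csp_classes.get(res) != "excluded"
                    and roles.get(res - 1) == "active" and roles.get(res + 1) == "active"):
                roles[res] = "active"
    if not any(role == "active" for role in roles.values()):
        warnings.warn("no residues met the active-residue criterion")
    return roles


def build_annotations(csp_classes: dict[int, str],
                      enhancement_classes: dict[int, str] | None = None,
                      docking_roles: dict[int, str] | None = None) -> list[ResidueAnnotation]:
    enhancement_classes = enhancement_classes or {}
    docking_roles = docking_roles or {}
    return [ResidueAnnotation(res, cls,
                              enhancement_classes.get(res, "invalid"),
                              docking_roles.get(res, "none"))
            for res, cls in sorted(csp_classes.items())]


_ANN_COLUMNS = ["residue_number", "csp_class", "enhancement_class", "docking_role"]


def export_annotations(annotations, path, format: str = "tsv") -> None:
    """Write annotations as a TSV table or a molecular-viewer color script.

    The graphics script emits one generic per-residue command per non-white
    residue using the binding-interface color map (red/pink/yellow; cyan
    side-chain highlight for strong intensity enhancement).
    """
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame([{c: getattr(a, c) for c in _ANN_COLUMNS}
                           for a in annotations])
        df.to_csv(path, sep="\t", index=False)
    elif format == "graphics_script":
        lines = []
        for a in annotations:
            color = CSP_COLORS[a.csp_class]
            if color != "white":
                lines.append(f"color residue {a.residue_number} {color}")
            if a.enhancement_class == "strong":
                lines.append(f"highlight sidechain residue {a.residue_number} "
                             f"{ENHANCEMENT_HIGHLIGHT_COLOR}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_annotations(path) -> list[ResidueAnnotation]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _ANN_COLUMNS:
        raise ValueError(f"{path}: unexpected annotation columns {list(df.columns)}")
    return [ResidueAnnotation(int(r.residue_number), r.csp_class,
                              r.enhancement_class, r.docking_role)
            for r in df.itertuples()]


def format_residue_ranges(residues) -> str:
    """Collapse residue numbers into a comma-separated range list
    (e.g. ``19-22,33,37``) for docking restraint files."""
    residues = sorted(set(int(r) for r in residues))
    if not residues:
        return ""
    spans, start, prev = [], residues[0], residues[0]
    for r in residues[1:]:
        if r == prev + 1:
            prev = r
            continue
        spans.append((start, prev))
        start = prev = r
    spans.append((start, prev))
    return ",".join(f"{a}-{b}" if a != b else f"{a}" for a, b in spans)
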