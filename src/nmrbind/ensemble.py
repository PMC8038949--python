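"""Multi-model coordinate ensembles and NMR-ensemble structure metrics.

An NMR structure is deposited as an ensemble of conformers (here, the 20
lowest-energy conformers convention).  Two precision/geometry metrics are
computed: the per-conformer RMSD to the converged mean structure over a
region-restricted atom selection, and salt-bridge distance statistics
(minimum donor-oxygen to acceptor-nitrogen distance per conformer).

Region definitions for the ARID4B TD151 double Tudor domain are packaged:
the two hybrid Tudor subdomains (HTD-1: residues 8-34 and 87-110; HTD-2:
residues 35-86) and their regular secondary-structure ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .binding import compute_csp  # noqa: F401  (re-export convenience)

__all__ = [
    "Ensemble",
    "RegionSet",
    "EnsembleRMSD",
    "SaltBridgeStat",
    "TD151_REGIONS",
    "read_pdb_ensemble",
    "write_pdb_ensemble",
    "kabsch_superpose",
    "rmsd_to_mean",
    "salt_bridge_stats",
    "deposited_reference_report",
]

BACKBONE = ("N", "CA", "C")
BACKBONE_O = ("N", "CA", "C", "O")


@dataclass
class Ensemble:
    """Ordered conformers sharing one atom table.

    ``atoms`` holds one row per atom: ``(chain_id, residue_number,
    residue_name, atom_name, element)``; ``coords`` has shape
    ``(n_models, n_atoms, 3)`` in Angstrom.
    """

    atoms: list
    coords: np.ndarray
    model_ids: list

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("coords second axis must match the atom table")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        keys = [(a[0], a[1], a[3]) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValueError("(chain, residue, atom name) must be unique")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    def atom_index(self, residue_number: int, atom_name: str,
                   chain_id: str | None = None) -> int:
        for i, (ch, rn, _, an, _) in enumerate(self.atoms):
            if rn == residue_number and an == atom_name and (chain_id is None or ch == chain_id):
                return i
        raise KeyError(f"atom {atom_name} of residue {residue_number} not in ensemble")

    def select(self, residues, atom_names=None, include_hydrogens: bool = False) -> np.ndarray:
        """Indices of atoms in the given residues (and atom names, if given).

        Hydrogens are excluded unless explicitly requested.
        """
        residues = set(int(r) for r in residues)
        idx = []
        for i, (_, rn, _, an, el) in enumerate(self.atoms):
            if rn not in residues:
                continue
            if atom_names is not None and an not in atom_names:
                continue
            if not include_hydrogens and el.upper() == "H":
                continue
            idx.append(i)
        return np.array(idx, dtype=int)


@dataclass
class RegionSet:
    """Named residue-range selections with a default atom selection.

    ``ranges`` maps a label to inclusive 1-based ``(start, stop)`` ranges;
    ranges within one label must not overlap.  The default atom selection is
    the peptide backbone N, CA, C.
    """

    ranges: dict
    atom_selection: tuple = BACKBONE

    def __post_init__(self) -> None:
        for label, spans in self.ranges.items():
            spans = sorted(tuple(s) for s in spans)
            for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                if a2 <= b1:
                    raise ValueError(f"overlapping ranges in region {label!r}")
            if any(a > b for a, b in spans):
                raise ValueError(f"empty range in region {label!r}")

    def residues(self, label: str) -> list[int]:
        out = []
        for a, b in self.ranges[label]:
            out.extend(range(a, b + 1))
        return out


#: Region definitions for the ARID4B TD151 double Tudor domain: the two
#: hybrid Tudor subdomains and their regular secondary-structure ranges.
TD151_REGIONS = RegionSet({
    "htd1": [(8, 34), (87, 110)],
    "htd2": [(35, 86)],
    "htd1_ss": [(15, 20), (23, 33), (88, 92), (98, 108)],
    "htd2_ss": [(36, 42), (48, 57), (65, 69), (75, 85)],
    "all_ss": [(15, 20), (23, 33), (36, 42), (48, 57), (65, 69),
               (75, 85), (88, 92), (98, 108)],
})


@dataclass
class EnsembleRMSD:
    region: str
    atom_selection: tuple
    per_conformer: np.ndarray
    mean: float
    sd: float
    mean_structure: np.ndarray


@dataclass
class SaltBridgeStat:
    donor: tuple
    acceptor: tuple
    per_conformer: np.ndarray
    mean: float
    sd: float
    cutoff: float
    satisfies_criterion: np.ndarray


def read_pdb_ensemble(path) -> Ensemble:
    """Read a (multi-)model PDB file into an Ensemble.

    Models are split on MODEL/ENDMDL.  For alternate locations the highest
    occupancy wins (first on ties).  Hydrogens are retained in the atom table
    but excluded from default selections.  If models disagree on their atom
    sets a warning is raised and the intersection is used.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    per_model = []
    for model in st:
        atoms = {}
        order = []
        for chain in model:
            for residue in chain:
                best = {}
                for atom in residue:
                    key = atom.name
                    if key not in best or atom.occ > best[key].occ:
                        best[key] = atom
                for name, atom in best.items():
                    key = (chain.name, residue.seqid.num, name)
                    atoms[key] = (residue.name, atom.element.name,
                                  (atom.pos.x, atom.pos.y, atom.pos.z))
                    order.append(key)
        per_model.append((order, atoms))

    first_order, _ = per_model[0]
    common = set(per_model[0][1])
    for _, atoms in per_model[1:]:
        common &= set(atoms)
    if any(len(atoms) != len(common) for _, atoms in per_model):
        warnings.warn(f"{path}: models have inconsistent atom sets; "
                      "using their intersection")
    keys = [k for k in first_order if k in common]
    atom_table = [(ch, rn, per_model[0][1][(ch, rn, an)][0], an,
                   per_model[0][1][(ch, rn, an)][1])
                  for ch, rn, an in keys]
    coords = np.array([[atoms[k][2] for k in keys] for _, atoms in per_model])
    model_ids = [m.num if hasattr(m, "num") else i + 1 for i, m in enumerate(st)]
    return Ensemble(atom_table, coords, model_ids)


def write_pdb_ensemble(ensemble: Ensemble, path) -> None:
    """Write an ensemble as a multi-model PDB (MODEL/ENDMDL records)."""
    lines = []
    for m in range(ensemble.n_models):
        lines.append(f"MODEL     {ensemble.model_ids[m]:>4}")
        serial = 1
        for (ch, rn, resname, an, el), (x, y, z) in zip(ensemble.atoms,
                                                        ensemble.coords[m]):
            name = an if len(an) >= 4 else f" {an:<3}"
            lines.append(
                f"ATOM  {serial:>5} {name}{'':1}{resname:>3} {ch:1}{rn:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {el:>2}")
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def kabsch_superpose(mobile, reference):
    """Optimal rigid superposition of paired coordinate sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ x + translation`` maps the mobile set onto the reference in
    the least-squares sense; the rotation is proper (det = +1).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("need equal-length (N, 3) coordinate sets")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    for X in (P0, Q0):
        s = np.linalg.svd(X, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise ValueError("degenerate (collinear or coincident) point set")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def _superpose_coords(mobile, reference):
    R, t, _ = kabsch_superpose(mobile, reference)
    return mobile @ R.T + t


def rmsd_to_mean(ensemble: Ensemble, regions: RegionSet, label: str,
                 atom_selection: tuple | None = None, superpose: bool = True,
                 tol: float = 1e-6, max_iter: int = 100) -> EnsembleRMSD:
    """Per-conformer RMSD to the converged mean structure over a region.

    All conformers are superposed on conformer 1 over the selection, the
    coordinate mean is formed, everything is re-superposed on the mean and
    the mean recomputed, iterating until the mean moves by less than ``tol``
    Angstrom.  Reports each conformer's RMSD to the converged mean and their
    ensemble mean +/- sample SD.

    With ``superpose=False`` the conformers are taken as already superposed
    (the usual state of a deposited NMR ensemble) and the RMSD is computed
    directly against the plain coordinate mean.
    """
    selection = atom_selection if atom_selection is not None else regions.atom_selection
    idx = ensemble.select(regions.residues(label), selection)
    if idx.size == 0:
        raise ValueError(f"empty selection for region {label!r}")
    coords = ensemble.coords[:, idx, :]
    if not superpose:
        mean = coords.mean(axis=0)
        aligned = coords
        rmsds = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=1))
        sd = float(np.std(rmsds, ddof=1)) if ensemble.n_models > 1 else 0.0
        return EnsembleRMSD(label, tuple(selection), rmsds, float(np.mean(rmsds)),
                            sd, mean)
    ref = coords[0]
    mean = None
    for _ in range(max_iter):
        aligned = np.array([_superpose_coords(c, ref) for c in coords])
        new_mean = aligned.mean(axis=0)
        if mean is not None and np.max(np.linalg.norm(new_mean - mean, axis=1)) < tol:
            mean = new_mean
            break
        mean = new_mean
        ref = new_mean
    aligned = np.array([_superpose_coords(c, mean) for c in coords])
    rmsds = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=1))
    sd = float(np.std(rmsds, ddof=1)) if ensemble.n_models > 1 else 0.0
    return EnsembleRMSD(label, tuple(selection), rmsds, float(np.mean(rmsds)),
                        sd, mean)


def salt_bridge_stats(ensemble: Ensemble, donor, acceptor,
                      cutoff: float = 4.0) -> SaltBridgeStat:
    """Ensemble distance statistics for a candidate salt bridge.

    ``donor`` and ``acceptor`` are ``(residue_number, atom_names)`` pairs,
    e.g. ``(50, ("OE1", "OE2"))`` for a Glu carboxylate and ``(37, ("NZ",))``
    for a Lys ammonium.  The per-conformer distance is the minimum over all
    donor-atom x acceptor-atom pairs (the relevant contact when either
    carboxylate oxygen can serve); the criterion holds where the distance is at
    most ``cutoff`` (default 4.0 Angstrom, the common N-O criterion).
    Symmetric under swapping donor and acceptor.
    """
    d_res, d_atoms = donor
    a_res, a_atoms = acceptor
    di = [ensemble.atom_index(d_res, a) for a in d_atoms]
    ai = [ensemble.atom_index(a_res, a) for a in a_atoms]
    dc = ensemble.coords[:, di, :]        # (M, nd, 3)
    ac = ensemble.coords[:, ai, :]        # (M, na, 3)
    diff = dc[:, :, None, :] - ac[:, None, :, :]
    dists = np.min(np.linalg.norm(diff, axis=3), axis=(1, 2))
    sd = float(np.std(dists, ddof=1)) if ensemble.n_models > 1 else 0.0
    return SaltBridgeStat((d_res, tuple(d_atoms)), (a_res, tuple(a_atoms)),
                          dists, float(np.mean(dists)), sd, cutoff,
                          dists <= cutoff)


def deposited_reference_report(pdb_path, regions: RegionSet = TD151_REGIONS) -> dict:
    """Ensemble metrics for a deposited TD151 ensemble (e.g. PDB 7DM4).

    Computes the secondary-structure backbone RMSD-to-mean of each hybrid
    Tudor subdomain under both backbone conventions (N,CA,C and N,CA,C,O),
    the single-superposition RMSD over all secondary structure, and the
    Glu50 carboxylate to Lys37/Lys39 ammonium minimum distances.  Requires a
    local coordinate file; nothing is downloaded.
    """
    ens = read_pdb_ensemble(pdb_path)
    report: dict = {"n_models": ens.n_models}
    for label in ("htd1_ss", "htd2_ss", "all_ss"):
        for sel_name, sel in (("N,CA,C", BACKBONE), ("N,CA,C,O", BACKBONE_O)):
            r = rmsd_to_mean(ens, regions, label, sel)
            report[f"rmsd_{label}_{sel_name}"] = (r.mean, r.sd)
    for lys in (37, 39):
        sb = salt_bridge_stats(ens, (50, ("OE1", "OE2")), (lys, ("NZ",)))
        report[f"glu50_lys{lys}_min_dist"] = (sb.mean, sb.sd)
    return report
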