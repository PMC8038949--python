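"""Synthetic-data generators with known ground truth.

Every analysis stage in this package has a matching generator here, so the
whole pipeline is testable without external data: fast-exchange CSP
titration trajectories under the n-equivalent-sites isotherm, exchange
-broadening intensity profiles with region-dependent enhancement, multi-model
coordinate ensembles with controlled per-region displacement and a
constructed Glu-Lys salt bridge, and protein families evolved on a known
tree.  All generators are seed-deterministic: the same spec yields
byte-identical output.

``td151_like_specs`` packages a fixture mirroring the ARID4B TD151 study
setting (151 residues, an HTD-1 binding hotspot, RGR-motif residues 138-146
designed for >3-fold intensity enhancement, K_D 22 uM with n = 3, ligand
stock 5 mM dsDNA1).  Proline positions and all coordinates/sequences are
synthetic constructions, not the deposited data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import bound_fraction
from .duplexes import DNA_DUPLEXES
from .ensemble import Ensemble, RegionSet
from .peaks import PeakRecord, TitrationSeries
from .phylo import Alignment, TreeNode

__all__ = [
    "TitrationSimSpec",
    "IntensitySimSpec",
    "EnsembleSimSpec",
    "AlignmentSimSpec",
    "simulate_titration",
    "simulate_intensities",
    "make_toy_ensemble",
    "make_template_protein",
    "simulate_alignment",
    "td151_like_specs",
    "td151_like_series",
    "TD151_N_RESIDUES",
    "TD151_RGR_RESIDUES",
    "TD151_LINKER_RESIDUES",
    "TD151_HOTSPOT_RESIDUES",
    "TD151_MODERATE_RESIDUES",
    "TD151_SYNTHETIC_PROLINES",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class TitrationSimSpec:
    """Ground truth for a simulated fast-exchange titration.

    ``cspmax_per_residue`` maps residue number -> saturation CSP (ppm);
    ``direction_angle_per_residue`` (radians, in (0, pi/2)) decomposes the
    combined CSP into 1H and 15N components as ``dH = CSP cos(theta)`` and
    ``dN = 5 CSP sin(theta)``; if omitted, angles are drawn uniformly so
    both nuclei move.  Concentrations in uM; the ligand-stock default
    matches a 5 mM DNA duplex stock.
    """

    true_kd: float
    n_sites: float
    c_pro: float
    c_lig: float = 5000.0
    ratios: tuple = (0.0, 0.2, 0.4, 0.8, 1.2, 1.6)
    residues: tuple = ()
    cspmax_per_residue: dict = field(default_factory=dict)
    direction_angle_per_residue: dict | None = None
    noise_sd_h: float = 0.0
    noise_sd_n: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_kd < 0 or self.n_sites <= 0:
            raise ValueError("invalid binding parameters")
        if self.c_pro <= 0 or self.c_lig <= 0:
            raise ValueError("concentrations must be > 0")
        ratios = tuple(float(r) for r in self.ratios)
        if ratios[0] != 0:
            raise ValueError("first ratio must be 0 (apo)")
        if any(b <= a for a, b in zip(ratios, ratios[1:])):
            raise ValueError("ratios must be strictly increasing")
        self.ratios = ratios
        if not self.residues:
            self.residues = tuple(sorted(self.cspmax_per_residue))
        if any(self.cspmax_per_residue.get(r, 0.0) < 0 for r in self.residues):
            raise ValueError("cspmax must be >= 0")
        if self.noise_sd_h < 0 or self.noise_sd_n < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class IntensitySimSpec:
    """Ground truth for exchange-broadening intensity enhancement.

    ``enhancement_factor`` is the designed holo/apo intensity ratio per
    residue (> 3 for RGR-like residues, 1.5-3 for linker-like, ~1 elsewhere);
    noise is multiplicative lognormal with coefficient of variation
    ``noise_cv`` and unit mean.
    """

    base_intensity: dict
    enhancement_factor: dict
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.base_intensity.values()):
            raise ValueError("base intensity must be > 0")
        if any(v < 0 for v in self.enhancement_factor.values()):
            raise ValueError("enhancement factors must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass
class EnsembleSimSpec:
    """Recipe for a toy multi-model ensemble.

    Starting from a single-conformer template, each region label receives
    i.i.d. Gaussian atom offsets with the given SD (Angstrom); an optional
    salt-bridge geometry pins one acceptor atom at ``target + jitter``
    Angstrom from a donor atom in every model.  Coordinates are rounded to
    the 0.001 A PDB precision so emitted files round-trip exactly.
    """

    template: Ensemble
    regions: RegionSet
    n_models: int
    displacement_sd_per_region: dict = field(default_factory=dict)
    salt_bridge_geometry: tuple | None = None  # (donor, acceptor, target, jitter)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 2:
            raise ValueError("n_models must be >= 2")
        if any(v < 0 for v in self.displacement_sd_per_region.values()):
            raise ValueError("displacement SDs must be >= 0")
        if len(self.template.atoms) == 0:
            raise ValueError("template must be non-empty")
        template_res = {a[1] for a in self.template.atoms}
        for label in self.displacement_sd_per_region:
            if label not in self.regions.ranges:
                raise KeyError(f"region label {label!r} not defined")
            if not template_res.intersection(self.regions.residues(label)):
                raise KeyError(f"region {label!r} has no atoms in the template")


@dataclass
class AlignmentSimSpec:
    """Sequence family evolved on a known tree.

    ``tree`` carries branch lengths in expected substitutions per site;
    sites evolve independently under a Jukes-Cantor-style uniform
    replacement model over the 20 amino acids.
    """

    tree: TreeNode
    seq_length: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seq_length <= 0:
            raise ValueError("seq_length must be > 0")
        tips = list(self.tree.tips())
        if not tips:
            raise ValueError("tree has no leaves")
        for node in self.tree.traverse(include_self=False):
            if node.length is None or node.length < 0 or not math.isfinite(node.length):
                raise ValueError("all branch lengths must be finite and >= 0")


def simulate_titration(spec: TitrationSimSpec,
                       intensity_spec: IntensitySimSpec | None = None,
                       protein_id: str = "synthetic",
                       ligand_id: str = "ligand",
                       residue_types: dict | None = None) -> TitrationSeries:
    """Forward-simulate a fast-exchange titration series.

    Apo peak positions are drawn from plausible amide ranges (1H 6-10 ppm,
    15N 105-130 ppm); at each ratio the predicted combined CSP is decomposed
    along the residue's direction angle, Gaussian ppm noise is added per
    nucleus, and absolute peak positions are emitted.  If an
    ``intensity_spec`` is given, apo intensities are the base values and
    every subsequent point carries enhanced (noisy) intensities, so
    intensity-ratio analysis can run on the same series.
    """
    rng = np.random.default_rng(spec.seed)
    residues = list(spec.residues)
    apo_h = rng.uniform(6.0, 10.0, size=len(residues))
    apo_n = rng.uniform(105.0, 130.0, size=len(residues))
    if spec.direction_angle_per_residue is not None:
        theta = np.array([spec.direction_angle_per_residue[r] for r in residues])
    else:
        theta = rng.uniform(0.0, math.pi / 2.0, size=len(residues))
    cspmax = np.array([spec.cspmax_per_residue.get(r, 0.0) for r in residues])
    types = residue_types or {}

    irng = None
    if intensity_spec is not None:
        irng = np.random.default_rng(intensity_spec.seed)
        sigma2 = math.log1p(intensity_spec.noise_cv**2)

    points = []
    for j, r in enumerate(spec.ratios):
        f = bound_fraction(r, spec.true_kd, spec.n_sites, spec.c_pro, spec.c_lig)
        csp = cspmax * f
        dh = csp * np.cos(theta) + rng.normal(0.0, spec.noise_sd_h, len(residues))
        dn = 5.0 * csp * np.sin(theta) + rng.normal(0.0, spec.noise_sd_n, len(residues))
        table = {}
        for i, res in enumerate(residues):
            intensity = None
            if intensity_spec is not None:
                base = intensity_spec.base_intensity[res]
                if j == 0:
                    intensity = base
                else:
                    factor = intensity_spec.enhancement_factor.get(res, 1.0)
                    noise = 1.0
                    if intensity_spec.noise_cv > 0:
                        noise = math.exp(irng.normal(-sigma2 / 2.0, math.sqrt(sigma2)))
                    intensity = base * factor * noise
            table[res] = PeakRecord(res, types.get(res, "A"),
                                    float(apo_h[i] + dh[i]),
                                    float(apo_n[i] + dn[i]), intensity)
        points.append((r, table))
    return TitrationSeries(protein_id, ligand_id, spec.c_pro, spec.c_lig, points)


def simulate_intensities(spec: IntensitySimSpec) -> tuple[pd.Series, pd.Series]:
    """Apo and holo intensity profiles (pandas Series keyed by residue).

    Holo intensity = base x enhancement factor x unit-mean lognormal noise,
    so the expected holo/apo ratio equals the designed factor exactly.
    """
    rng = np.random.default_rng(spec.seed)
    residues = sorted(spec.base_intensity)
    base = np.array([spec.base_intensity[r] for r in residues])
    factor = np.array([spec.enhancement_factor.get(r, 1.0) for r in residues])
    if spec.noise_cv > 0:
        sigma2 = math.log1p(spec.noise_cv**2)
        noise = np.exp(rng.normal(-sigma2 / 2.0, math.sqrt(sigma2), len(residues)))
    else:
        noise = np.ones(len(residues))
    apo = pd.Series(base, index=residues, name="intensity_apo")
    holo = pd.Series(base * factor * noise, index=residues, name="intensity_holo")
    return apo, holo


def make_template_protein(n_residues: int, glu_positions=(), lys_positions=()) -> Ensemble:
    """Deterministic single-conformer template with a zig-zag backbone.

    Each residue gets backbone N, CA, C; residues named in ``glu_positions``
    become GLU with OE1/OE2 side-chain oxygens, those in ``lys_positions``
    become LYS with an NZ nitrogen, the rest are GLY.  Entirely synthetic
    geometry (non-collinear by construction), intended as an ensemble
    template, not as a physical model.
    """
    glu, lys = set(glu_positions), set(lys_positions)
    atoms, coords = [], []

    def add(res, resname, name, element, xyz):
        atoms.append(("A", res, resname, name, element))
        coords.append(np.round(xyz, 3))

    for i in range(1, n_residues + 1):
        x = 3.8 * (i - 1)
        y = 1.2 * (i % 2)
        z = 0.4 * (i % 3)
        resname = "GLU" if i in glu else ("LYS" if i in lys else "GLY")
        add(i, resname, "N", "N", (x, y, z))
        add(i, resname, "CA", "C", (x + 1.46, y + 0.9, z + 0.3))
        add(i, resname, "C", "C", (x + 2.5, y, z + 0.6))
        if i in glu:
            add(i, resname, "OE1", "O", (x + 1.8, y + 3.0, z + 1.2))
            add(i, resname, "OE2", "O", (x + 2.6, y + 3.4, z + 0.9))
        if i in lys:
            add(i, resname, "NZ", "N", (x + 1.5, y + 3.8, z + 1.5))
    return Ensemble(atoms, np.asarray(coords)[None, :, :], [1])


def make_toy_ensemble(spec: EnsembleSimSpec) -> Ensemble:
    """Replicate a template into a controlled multi-model ensemble."""
    rng = np.random.default_rng(spec.seed)
    coords = np.repeat(spec.template.coords[:1], spec.n_models, axis=0)
    for label, sd in spec.displacement_sd_per_region.items():
        idx = spec.template.select(spec.regions.residues(label),
                                   include_hydrogens=True)
        if sd > 0:
            coords[:, idx, :] += rng.normal(0.0, sd, size=(spec.n_models, idx.size, 3))
    if spec.salt_bridge_geometry is not None:
        (d_res, d_atom), (a_res, a_atom), target, jitter = spec.salt_bridge_geometry
        di = spec.template.atom_index(d_res, d_atom)
        ai = spec.template.atom_index(a_res, a_atom)
        # pin direction points away from the donor atom's nearest same-residue
        # neighbour (e.g. OE2 when pinning to OE1) so a min-over-atom-pairs
        # distance to the donor side chain equals the target exactly
        ref = spec.template.coords[0]
        siblings = [i for i, a in enumerate(spec.template.atoms)
                    if a[1] == d_res and i != di]
        if siblings:
            nearest = min(siblings, key=lambda i: np.linalg.norm(ref[di] - ref[i]))
            u = ref[di] - ref[nearest]
            u = u / np.linalg.norm(u)
        else:
            u = np.array([1.0, 0.0, 0.0])
        for m in range(spec.n_models):
            dist = target + (rng.normal(0.0, jitter) if jitter > 0 else 0.0)
            coords[m, ai] = coords[m, di] + dist * u
    coords = np.round(coords, 3)
    return Ensemble(list(spec.template.atoms), coords,
                    list(range(1, spec.n_models + 1)))


def simulate_alignment(spec: AlignmentSimSpec) -> Alignment:
    """Evolve sequences along the tree under uniform 20-state replacement.

    Along a branch of length ``b`` (substitutions/site) a site changes with
    probability ``(19/20) (1 - exp(-20 b / 19))`` and, when it does, takes
    one of the other 19 residues uniformly — the 20-state analogue of the
    Jukes-Cantor model.
    """
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AMINO_ACIDS))
    root_seq = rng.integers(0, 20, size=spec.seq_length)
    leaves: dict[str, np.ndarray] = {}

    def evolve(node, seq):
        for child in node.children:
            b = child.length or 0.0
            p = (19.0 / 20.0) * (1.0 - math.exp(-20.0 * b / 19.0))
            s = seq.copy()
            hit = rng.random(spec.seq_length) < p
            if hit.any():
                shift = rng.integers(1, 20, size=int(hit.sum()))
                s[hit] = (s[hit] + shift) % 20
            if child.is_tip():
                leaves[child.name] = s
            else:
                evolve(child, s)

    evolve(spec.tree, root_seq)
    ids = sorted(leaves)
    return Alignment(ids, ["".join(aa[leaves[i]]) for i in ids])


# ---------------------------------------------------------------------------
# Packaged TD151-like study fixture (synthetic ground truth)

TD151_N_RESIDUES = 151
TD151_RGR_RESIDUES = tuple(range(138, 147))
TD151_LINKER_RESIDUES = tuple(range(110, 137))
TD151_HOTSPOT_RESIDUES = (18, 19, 20, 21, 22, 88, 99, 100, 101, 102, 103, 104, 105)
TD151_MODERATE_RESIDUES = tuple(range(25, 36)) + tuple(range(90, 96)) + (143, 144, 145)
TD151_SYNTHETIC_PROLINES = (13, 58, 112)  # synthetic placement, not the real sequence


def td151_like_specs(seed: int = 7) -> tuple[TitrationSimSpec, IntensitySimSpec]:
    """Specs mirroring the TD151/dsDNA1 study conditions.

    K_D 22 uM with n = 3 sites per duplex, initial protein 100 uM, ligand
    stock 5000 uM, titration to molar ratio 1.6; an HTD-1-like CSP hotspot,
    RGR-motif residues 138-146 with >3-fold designed intensity enhancement
    and the Gly110-Ile136 linker at 2-fold.  Proline positions are a
    synthetic stand-in.
    """
    residues = tuple(r for r in range(1, TD151_N_RESIDUES + 1)
                     if r not in TD151_SYNTHETIC_PROLINES)
    cspmax = {r: 0.03 for r in residues}
    for r in TD151_MODERATE_RESIDUES:
        cspmax[r] = 0.10
    for r in TD151_HOTSPOT_RESIDUES:
        cspmax[r] = 0.22
    tspec = TitrationSimSpec(
        true_kd=22.0, n_sites=3.0, c_pro=100.0, c_lig=5000.0,
        ratios=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.6),
        residues=residues, cspmax_per_residue=cspmax,
        noise_sd_h=0.005, noise_sd_n=0.025, seed=seed)
    base_rng = np.random.default_rng(seed + 1)
    base = {r: float(base_rng.uniform(5e5, 2e6)) for r in residues}
    factor = {r: 1.0 for r in residues}
    for r in TD151_LINKER_RESIDUES:
        if r in factor:
            factor[r] = 2.0
    for r in TD151_RGR_RESIDUES:
        factor[r] = 4.0
    ispec = IntensitySimSpec(base, factor, noise_cv=0.05, seed=seed + 2)
    return tspec, ispec


def td151_like_series(seed: int = 7) -> TitrationSeries:
    """The packaged TD151-like fixture as a ready-to-analyse series."""
    tspec, ispec = td151_like_specs(seed)
    return simulate_titration(
        tspec, intensity_spec=ispec, protein_id="TD151-like-synthetic",
        ligand_id=DNA_DUPLEXES["dsDNA1"].forward_5to3)
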