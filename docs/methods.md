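# Methods

## Binding model

### Weighted CSP

For each residue the combined amide perturbation between the apo spectrum
and a titration point is

```
CSP = sqrt(δHN² + (δN / 5)²)
```

with δHN and δN in ppm and the ¹⁵N change down-weighted by 5 (the
conventional ratio of amide ¹⁵N to ¹H shift dispersions). `compute_csp`
rejects non-finite inputs; CSP is invariant to the sign of either shift and
zero only when both are zero.

### Isotherm

At molar ratio r = [DNA]/[protein], with initial protein concentration
C_pro and ligand titrated from a stock of concentration C_lig, the protein
is diluted to

```
P_t(r) = 1 / (1/C_pro + r/C_lig)
```

(`total_protein_conc`). The DNA duplex presents n equivalent, independent
protein-binding sites, so total sites are S_t = n·r·P_t and the
protein-bound fraction f is the physical root of

```
K x = (P_t − x)(S_t − x),    K = n·K_D,    f = x/P_t
```

implemented in closed form (`bound_fraction`); the discriminant is clamped
at a −1e-12 relative tolerance and an error is raised beyond it. Predicted
CSP is `CSP_max · f` (`predict_csp`). Exact limits: f(r=0) = 0, and as
K_D → 0, f → min(1, n·r). The closed form is verified in the test suite
against independent `numpy.roots` root-finding to ≤ 1e-10 over random
parameter grids.

Fast exchange is assumed throughout: observed peaks are population-weighted
averages, CSP ∝ bound fraction, and no line-shape modelling is attempted.

### K_D fitting

`fit_kd` fits a shared log₁₀(K_D) plus one CSP_max per residue by
trust-region-reflective least squares (`scipy.optimize.least_squares`) over
all residues' titration curves jointly. Defaults and rationale:

- **n fixed** (default `fix_n=True`): K_D and n are strongly correlated at
  sub-saturating ratios; the study design fixes n from the construct
  length ratio. `fix_n=False` frees n with bounds (0.1, 20).
- **Residue selection** (default): residues whose final-point CSP is at
  least the profile mean; configurable via `residues=`.
- **Multi-start**: 7 K_D starts log-spaced over 10⁻²–10⁴ μM; the lowest-RSS
  solution wins. Bounds: K_D ∈ [10⁻⁴, 10⁶] μM, CSP_max ∈ [0, 10·max(obs)].
- **Degenerate data**: an all-zero profile returns a flagged, non-converged
  result rather than an arbitrary K_D; fewer than 3 usable titration points
  is an error.
- **Uncertainty**: `n_boot > 0` enables residual-resampling bootstrap
  (i.i.d. residual reassignment, refit, 2.5/97.5 percentiles). The interval
  is clamped to bracket the point estimate. *Caveat:* because the apo
  reference point is shared by all residuals of a residue, the noise is
  weakly correlated and the nominal 95% interval is empirically slightly
  anticonservative (~77–85% coverage in internal calibration); treat the CI
  as indicative. Default draws in examples: 200.

## Site mapping

`classify_csp` computes mean and sample SD (ddof = 1) over valid residues
at one titration point (default: final). Classes: `strong` (CSP ≥ mean+SD),
`moderate` (mean ≤ CSP < mean+SD), `below_mean`, and `excluded` for
prolines/unassigned/overlapped residues (never included in statistics).
Ties go up (≥). At least 2 valid residues are required.

`intensity_ratio` returns per-residue holo/apo peak-height ratios at a
chosen point; zero/absent apo intensities and flagged records are marked
invalid rather than producing infinities. `classify_enhancement` uses
strict thresholds: ratio > 3 `strong`, 1.5 < ratio ≤ 3 `moderate`, else
`none`.

`derive_active_residues` promotes `strong` CSP residues to docking-style
"active" status; optional `smooth=True` promotes a single non-excluded
residue bracketed by two actives. Annotations export as TSV or as a simple
graphics command script (`color residue N red`, etc.).

## Ensemble structure

- **Superposition**: hand-implemented Kabsch via SVD with the proper-rotation
  sign correction; degenerate (rank < 2) point sets are rejected. Verified
  in tests against `scipy.spatial.transform.Rotation.align_vectors` and
  against 1000 random rotations per instance.
- **RMSD to mean** (`rmsd_to_mean`): iterative — superpose all conformers on
  the current mean over the selected region/atoms, recompute the mean,
  repeat to 1e-6 Å convergence (max 100 iterations); report per-conformer
  RMSD, mean and sample SD. `superpose=False` computes RMSD against the
  plain coordinate mean without refitting — appropriate for deposited NMR
  ensembles that are already superposed, and the mode under which the
  two-conformer closed form (d/2)/√N holds exactly (any re-superposition
  can only reduce the value).
- **Backbone conventions**: default selection is N, CA, C; N, CA, C, O is
  exposed as `BACKBONE_O` and `deposited_reference_report` computes both,
  since "backbone heavy atoms" is used ambiguously in the literature.
- **Salt bridges** (`salt_bridge_stats`): per conformer, the minimum
  distance over all donor-atom/acceptor-atom pairs (e.g. Glu OE1/OE2 ×
  Lys NZ); default contact criterion 4.0 Å.
- **PDB I/O** via gemmi; altloc conflicts resolve to highest occupancy
  (then first); models with inconsistent atom sets are intersected with a
  warning.

## Phylogenetics and identity

- `percent_identity`: identical/compared columns × 100; gap columns and
  ambiguous codes (X, B, Z) are excluded from the denominator.
  `mode="global_align"` first aligns with Biopython's `PairwiseAligner`
  (global, match +1, mismatch 0, gap −1).
- `p_distance`: proportion of differing comparable columns with pairwise
  deletion; zero comparable columns is an error.
- `neighbor_joining`: Saitou–Nei Q-criterion; deterministic tie-break
  (first strict minimum in index order); negative branch lengths clamped to
  zero with the deficit transferred to the sister branch; 3-taxon closed
  form; trifurcating root. Exact recovery on additive matrices is verified
  against the generating trees and against scikit-bio's `nj`.
- `bootstrap_support`: column resampling, default 1000 replicates, support =
  percentage of replicate trees containing each bipartition of the
  full-data tree; all-identical alignments yield a warning and no supports.
  Newick round-trip preserves branch lengths and integer supports as
  internal labels.

## Synthetic data

Generators (`simulate_titration`, `simulate_intensities`,
`make_toy_ensemble`, `simulate_alignment`) are seed-deterministic and emit
exactly the structures the analysis stages consume.

What they emulate: fast-exchange CSP trajectories under the isotherm above
with per-nucleus Gaussian ppm noise (CSP decomposed along a per-residue
direction angle θ as δHN = CSP·cosθ, δN = 5·CSP·sinθ); region-dependent
intensity enhancement with unit-mean lognormal multiplicative noise;
multi-model ensembles with per-region i.i.d. Gaussian atom displacement and
a constructed Glu–Lys salt bridge pinned at an exact target distance
(direction chosen away from the donor atom's nearest same-residue neighbour
so min-over-pair distances hit the target; coordinates rounded to the
0.001 Å PDB precision); protein families evolved site-independently under a
uniform 20-state (Jukes–Cantor-style) replacement model.

What they do **not** emulate: intermediate/slow exchange, peak overlap and
assignment ambiguity, relaxation/line-shape effects, realistic protein
geometry (the template backbone is a synthetic zig-zag), indels, or
rate heterogeneity across sites.

The packaged TD151-like fixture (`td151_like_series`) mirrors the ARID4B
TD151/dsDNA1 study conditions — K_D 22 μM, n = 3, 100 μM protein, 5 mM DNA
stock, ratios to 1.6, an HTD-1-like hotspot, RGR residues 138–146 at 4-fold
designed enhancement and the linker at 2-fold — but every number, sequence
and coordinate in it is synthetic ground truth, not the deposited data. The
five DNA duplex sequences in `DNA_DUPLEXES` are study metadata.

## Numerical choices

- Fits run in log₁₀(K_D) for scale invariance; multi-start guards against
  the shallow-RSS valley at weak binding.
- RMSD-mean iteration tolerance 1e-6 Å; Kabsch degeneracy detected from
  singular values.
- All random draws use `numpy.random.default_rng`; derived seeds are drawn
  below 2³¹.

## Limitations

- The n-equivalent-independent-sites isotherm ignores cooperativity and
  site heterogeneity; K_D estimates inherit that assumption.
- Bootstrap CIs are indicative, not exact (see above).
- Classification thresholds (mean + SD; ratio 3 / 1.5) are the field's
  conventions, not optimised decision rules.
- Checks against the deposited 7DM4 ensemble and the ARID4A/ARID4B identity
  bound require user-supplied local copies of those accessions; this
  repository verifies the computation pathways on synthetic stand-ins only.
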