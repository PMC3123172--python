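# Methods

`tmdscan` delimits single-spanning helical transmembrane domains (TMDs) from
sequence alone.  It combines four components: a stochastic conformational
search over a discrete backbone alphabet, an all-atom non-bonded energy
model, an implicit-bilayer insertion score, and a sliding-window scan that
aggregates per-residue statistics and calls the TMD center and limits.  This
note documents the model, its assumptions, the tunable parameters, and what
the synthetic test fixtures do and do not demonstrate.

## Peptide construction

A peptide conformation is a string of backbone states, one per residue, each
state a (phi, psi) couple from a 64-state structural alphabet.  The packaged
alphabet is derived by k-means (k = 64) on phi/psi samples drawn from a
synthetic Ramachandran basin mixture (alpha, beta, polyproline-II, 3-10 and
left-handed alpha basins plus a diffuse background), with the canonical
basin centers (including ideal alpha (-57, -47) and beta (-129, 123))
included as anchor states so regular secondary structure is exactly
representable.  The table is packaged data (`data/alphabet64.tsv`),
user-replaceable, and `tmdscan.alphabet.derive_alphabet` reproduces it.

All-atom coordinates are chained with ideal bond lengths and angles
(N-CA 1.458 Å, CA-C 1.525 Å, C-N 1.329 Å, omega fixed at 180°); measured
phi/psi reproduce the assigned states to better than 0.1°.  Side chains are
rigid heavy-atom templates (ideal geometry from the bundled chemical
component dictionary) in one default rotamer per residue type.  The default
chi1 (and chi2 for Phe/Tyr/Trp/His) were fixed once by a torsion grid search
maximizing non-bonded clearance on ideal helix and strand hosts, so that
every type except proline is clash-free in regular secondary structure.
Only the backbone amide hydrogen is built explicitly (required by the
secondary-structure rule); all other hydrogens are implicit in the
heavy-atom types.

Known limitations of this construction: no side-chain flexibility, no
cis-proline, no terminal capping groups or charged termini.  Proline's rigid
ring leaves a backbone-state-independent short contact between its Cδ and
the preceding peptide unit; those two 1-4 pairs are excluded from non-bonded
sums (an artifact of the rigid template, verified by sweeping the preceding
residue through all 64 states), while proline's genuine helix-breaking
clash with the preceding helix turn is retained.

## Energy model

Non-bonded terms over all atom pairs excluding 1-2 and 1-3 bonded pairs
(1-4 at full weight):

* **Lennard-Jones 6-12**: pairwise A/d¹² − B/d⁶ with A, B built from
  per-type radii and well depths by Lorentz-Berthelot combination.
* **Coulomb**: k·qᵢqⱼ/(ε(d)·d) with a distance-dependent sigmoidal
  dielectric rising from 1 (d ≤ 0.2 nm) to 80 (d ≥ 1 nm); the transition is
  a half-cosine, monotone, with midpoint 40.5 at 0.6 nm.  The dielectric's
  argument is the interatomic distance (distance-dependent screening), not
  the membrane depth; this choice is recorded in the parameter file.
* **Intramolecular hydrophobicity**: a contact term
  δᵢⱼ·√|Etrᵢ·Etrⱼ|·((fᵢⱼ+fⱼᵢ)/2)·exp(−max(d−r⁰ᵢ−r⁰ⱼ, 0)/(2·r_sol)), with
  δ = −1 for like pairs (both hydrophobic or both hydrophilic) and +1
  otherwise, and fᵢⱼ the analytic spherical-cap fraction of atom i's
  solvent-augmented sphere (radius r⁰+r_sol, r_sol = 1.4 Å) occluded by
  atom j's.  The term vanishes identically once the augmented spheres
  disjoin (≈ 6–7 Å).
* **Implicit solvation** (hydrophilic environment only): Σ Etrᵢ·Sᵢ over
  atomic accessible surface areas.

Atoms carry one of seven atomic types (aliphatic C, aromatic C,
polar/carbonyl C, N, O, S, polar H) with per-type van der Waals radius,
well depth, transfer energy Etr (kJ·mol⁻¹·Å⁻², positive = hydrophobic) and
hydrophobicity flag; charged side-chain groups override Etr per atom.
Transfer energies follow atomic-solvation-parameter magnitudes of the
Eisenberg–McLachlan family and partial charges are a minimal amide-dipole
plus formal-charge scheme; both live in `data/forcefield.yaml` and are
documented stand-ins for the laboratory-internal parameter sets they model.
Environment handling: *hydrophilic* = all four terms; *hydrophobic* (the
scan's default, a uniform apolar medium) drops solvation; *membrane*
replaces solvation by the bilayer potential below.

## Implicit bilayer and insertion scan

The bilayer is the interface function C(z) = 1/(1+exp(α(z₀−|z|))) with z₀
and α fitted so C(1.35 nm) = 10⁻³ and C(1.8 nm) = 1−10⁻³ (z₀ = 1.575 nm,
α ≈ 30.7 nm⁻¹): 0 in the acyl core, 1 in water.  A rigid structure placed
with its centroid at height z is scored by

* E_pho_mem = −Σ Etrᵢ·Sᵢ·(1−C(zᵢ)) — burying hydrophobic surface
  (Etr > 0) in the core is stabilizing, burying hydrophilic surface is
  penalized; zero in water, and
* E_lip = a_lip·Σ Sᵢ·(1−C(zᵢ)) with a_lip = 0.018 kJ·mol⁻¹·Å⁻² — a uniform
  lipid-perturbation cost per unit inserted surface; zero in water.

The membrane-ness weighting (1−C) is the package's resolution of an
ambiguity in how the interface function enters the hydrophobicity term; it
is pinned by the behavioral contract that a poly-Leu 19-mer helix inserts
near the bilayer center while a poly-Lys helix pays a large penalty at any
interior position (a test enforces this).

Both terms depend only on atomic z, so a rigid orientation is fully
described by the direction of the membrane normal in the molecular frame;
the insertion scan translates the structure along z on a fixed grid
(default ±10 Å, step 0.1 Å) and samples orientations as unit directions —
10000 seeded random directions at full scale, or a deterministic geodesic
grid (42 directions, z step 0.5 Å) at desk scale and for brute-force oracle
comparisons.  ASA is computed once on the isolated structure, since the
rigid scan does not change intramolecular burial.  The tilt angle is
measured between the Cα principal axis and the membrane normal.

## Stochastic search

Each step draws `structures_per_step` backbones by sampling every residue's
state from its position's probability vector (initially uniform), builds
them all-atom, and ranks them by energy.  Structures with any non-bonded
heavy-atom pair under 1.5 Å are resampled up to 3 times (survivors keep
their prohibitive Lennard-Jones penalty).  After ranking, (position, state)
pairs found only in the top decile are multiplied by 1.5 and pairs found
only in the bottom decile by 1/1.5 (at most 100 of each per step, ordered by
the energy of their best/worst carrier); vectors are floored at 10⁻⁴ and
renormalized, preserving ergodicity.  A global archive keeps the 99 best
distinct state strings seen anywhere in the run; the lowest-energy archived
structure is the prime model.  Archived models can be clustered by
single-linkage at 1 Å all-atom superposed RMSD.

Budgets: the *full* preset uses 10⁴ structures/step and 10×length steps
(1.9 × 10⁶ structures per 19-mer window, the published scale); the *desk*
preset — the default for tests, examples and the acceptance harness — uses
200 structures/step and 2×length steps (7.6 × 10³ structures per window),
sized so a complete 5-seed scan of a 29-residue target runs on one CPU in
about 12 minutes.  At desk scale the archived ensembles are much shallower:
in particular they are dominated by compact coil rather than helical
states, so scan helicity percentages sit far below the 75% threshold and
desk-scale TMD calls carry a `helicity_below_threshold` flag.  Desk runs
demonstrate the machinery and the surface-ratio/insertion signals, not
converged secondary structure.

## Descriptors

* **ASA**: Shrake–Rupley with a deterministic 162-point geodesic sphere per
  atom (frequency-4 icosahedron), probe radius 1.4 Å.  Isolated spheres are
  exact to the 162-point quantization (< 2%); overlapping pairs match the
  analytic spherical-cap area within 3%; totals agree with an independent
  implementation within 3%.
* **ASAr**: per-residue hydrophobic/hydrophilic ASA ratio, hydrophobic
  surface = atoms of hydrophobic types (C, S), hydrophilic = N, O, polar H.
  When the hydrophilic denominator falls under 0.1 Å² the ratio is reported
  capped at 99.9 and flagged.  Note that with implicit apolar hydrogens the
  absolute ASAr scale runs higher than hydrogen-explicit conventions; the
  scan consumes only its profile shape (argmax), not its absolute value.
* **Secondary structure**: helix requires the (phi, psi) couple within an
  80° circle (wrapped Euclidean metric) of (−57, −47) *and* an amide-H to
  carbonyl-O distance < 3 Å at i,i+4 (alpha) or i,i+3 (3-10); the H-bond
  test accepts the contact in either direction along the chain so that
  interior residues near the termini are not spuriously demoted.  Beta
  requires the couple within a 90° circle of (−129, 123).  Everything else,
  and terminal residues lacking a defined phi or psi, is coil.  The printed
  helix center (+57, +47) in the source description is treated as a
  typographical sign omission.
* **RMSD**: all-atom Kabsch superposition.
* **MFP percentage**: a residue's environment score (Lennard-Jones +
  hydrophobicity between the residue's atoms and all other residues' atoms
  within 10 Å) as a percentage of the calibrated mean for its residue type;
  more negative scores = more enveloped, so percentages above ~100 indicate
  a well-packed environment and low percentages flag residues needing
  external stabilization.  The packaged calibration uses synthetic
  host-guest fixtures (each type as a guest in poly-Ala 9-mer helix and
  extended hosts; proline extended only) — it preserves the published
  semantics (percentage of a per-type calibrated mean) but is **not** a
  published reference-set calibration; users should calibrate on their own
  structure sets for production work.  Percentages are raw in the API
  (keeping calibrate-then-score exactly self-consistent at 100%) and
  clipped to [0, 200] in scan profiles for display.

## The scan and the TMD call

Windows of 19 residues at shift 1; each window modelled independently in
hydrophobic environment with a per-window seed derived from the master seed
(recorded in the run manifest).  Per-residue pooling excludes the 4
positions at each window end, so an interior residue of a long target is
covered by 11 windows × 99 models = 1089 structures.  Helicity is the
percentage of covering models labelling the residue helical; ASAr is
averaged over covering models and smoothed with a 5-residue moving average;
the per-window mean best-z of the 99 models is assigned to the window's
central residue and smoothed with a 7-window moving average (the 7-window
default follows the methods text of the source; a 3-window option matches
its figure captions); MFP% is averaged like ASAr.

The center call: argmax of smoothed ASAr (the declared primary criterion).
"Deepest insertion" is the minimum of |z̄| — the window whose best placement
sits closest to the bilayer center — because the signed best-z of off-core
windows grows in magnitude as the hydrophobic segment sits off-center in
the peptide.  If the insertion minimum is adjacent to the ASAr maximum the
two are reported as a two-residue center; if it is further than one residue
away the call is flagged `insertion_discordant` (ASAr keeps priority).  Two
ASAr local maxima within 5% are flagged `double_maximum` and arbitrated by
the insertion criterion.  The mean helicity of the 18-residue span around
the center must reach 75% or the call is flagged; the call is withheld only
for flat or empty profiles.  Limits are the maximal contiguous run of
residues with helicity ≥ 75% around the center, trimmed symmetrically to a
26-residue span cap (geometric consistency with a ≤ 30° tilt across the
bilayer plus interfaces); runs under 15 residues are flagged `short_tmd`.
Multi-species consensus averages per-species profiles column-wise over a
supplied alignment (gaps carry no values) and re-runs the call; a species
whose own ASAr maximum deviates from the consensus by more than one column
is reported as anomalous.

## Synthetic fixtures and what they show

`synthetic_tmd` builds a 29-residue single-span fragment: a 19-residue
hydrophobic core flanked by charged tails (Asp/Glu extracellular, Lys/Arg
cytosolic, ≥ 2 charged residues per flank).  The core is a fixed multiset
(3 Phe, 6 Leu, 4 Ile, 4 Val, 2 Ala) arranged with the canonical
mid-membrane hydrophobicity grading — bulky hydrophobics central, small
residues at the core edges — with the seed shuffling mirror-position
assignments.  The grading makes the constructed core midpoint the maximum
of the residue-hydrophobicity profile, which is the fixture's contract: the
package-level recovery test requires the called center within ±2 residues
of that midpoint for 5/5 master seeds at desk scale.  What this shows: the
window bookkeeping, descriptor aggregation and calling logic recover a
constructed hydrophobicity maximum through the full pipeline.  What it does
not show: performance on real sequences, where the hydrophobicity profile
is noisier, helicity signals matter, and the published full-scale budgets
are required.

Other fixtures: ideal poly-Leu/poly-Lys 19-mer helices (membrane sign
convention), ideal alpha/extended coordinate fixtures (secondary-structure
and ASA oracles), a two-bundle model set (clustering), and the host-guest
MFP reference set.

## Numerical choices

* Batched energies run in single precision via a Gram-matrix distance
  product (about 10⁻⁷ relative agreement with the double-precision
  reference path, which is used by all public single-structure functions);
  the discrete archive contents are unaffected in practice and all runs are
  bit-reproducible for a fixed seed.
* Probability draws use inverse-CDF sampling per position from one seeded
  generator; per-window seeds derive from the master seed via
  `SeedSequence([master, window_index])`, kept below 2³¹.
* Moving averages shrink at profile edges (NaN-aware); positions with no
  covering window stay NaN and serialize as "." in TSV output.
* Single-linkage clustering uses scipy's hierarchy on the condensed RMSD
  matrix; the 1 Å threshold is inclusive.
* The clash floor (1.5 Å) only guards numerics; energetic rejection of bad
  contacts is the Lennard-Jones term's job.

## Problem sizes used by the test and acceptance harness

Toy search-optimality runs use a 4-state alphabet on a 5-residue peptide
(1024 enumerable backbones, 20 seeds).  The recovery test scans the
29-residue fixture (11 windows) at desk scale for 5 master seeds.  Oracle
comparisons for the insertion scan use geodesic direction grids of up to
2562 points.  These sizes are the package's desk-scale defaults; the full
preset restores the published budgets.
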