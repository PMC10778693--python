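# Methods

This note documents the models, conventions and design choices behind
`ensdock`, in the spirit of the methods documentation of mature scientific
packages: what is computed, under which assumptions, with which defaults,
and what the synthetic benchmarks do and do not establish.

## Superposition and invariant regions

Rigid superposition is the closed-form least-squares fit (Kabsch): SVD of
the cross-covariance of centered Cα coordinates, with the reflection
corrected to a proper rotation (det = +1).  Selections with fewer than three
matched pairs, or collinear geometry, are rejected rather than silently
fitted.  Atoms are matched across conformers by residue identity
`(chain, resseq, icode)` — never by sequence alignment — because the
intended inputs are conformers of the same protein with common numbering;
a residue referenced but absent is a hard error.  Residues present in only
one of two structures cannot be classified and are excluded from invariance
detection by construction (shared residues only); residues lacking a Cα are
skipped with a logged warning.

Conformationally invariant regions between two states are found by fitting
the second structure onto the first over a reference region's Cα atoms (by
default the region named `NBD1` in the region map — for the intended
receptor family the first nucleotide-binding domain, the natural anchor of
the binding-site search) and keeping every shared residue whose Cα–Cα
distance is **≤ 2.5 Å, inclusive** — "within" a threshold reads most
naturally as ≤, and the boundary case is tested explicitly.

Alternate locations: the highest-occupancy altloc is kept, first on tie
(the standard convention; the upstream parser implements exactly this).
Hydrogens are retained on read and ignored by Cα-based operations.

## Ensembles and docking tasks

An ensemble is one receptor state: exactly one parent (experimental)
conformer, at most one minimized copy, and snapshots at strictly increasing
times.  Snapshot selection takes the nearest frame within ± half an
interval of each requested time (trajectory writing steps rarely divide the
snapshot interval exactly after unit conversion); a miss is an error naming
the requested time.  The default composition — parent + minimized + 10
snapshots at 1 ns intervals from 1 ns — gives 12 conformers per ensemble.

Task enumeration is the full cartesian product ligand × (ensemble,
conformer) in a fixed order (ligands, then ensembles, then conformer
index), so a study of 3 ligands on 3 twelve-conformer ensembles enumerates
exactly 108 searches.

Search-space membership is engine-agnostic: a pose is inside the search
sphere iff its heavy-atom centroid lies within the radius (default 33.0 Å)
of the region center, boundary inclusive.  The region center is the Cα
centroid by default (robust to missing hydrogens); a mass-weighted all-atom
option exists.  A docking engine's own sphere semantics (any-atom,
anchor-atom, ...) are not reproducible engine-agnostically; the centroid
test is the closest neutral analog and is documented as interpretive.

## Pose handling

Scores follow the convention of the empirical scoring functions this
pipeline is designed around: **lower is better** by default, configurable
(`score_direction`) because conventions differ between engines.

* **Ligand RMSD** is plain coordinate RMSD over heavy atoms with **no
  refitting**: all receptors were pre-aligned to one frame, so pose overlap
  is positional by definition; superposing ligands onto each other would
  erase exactly the information being measured.  A symmetry-aware mode
  minimizes over element-preserving automorphisms of the bond graph
  (material for ligands with two topologically equivalent ends, e.g.
  bis-methoxyphenol scaffolds); it is **off by default** so results are
  reproducible under the simplest definition, and exposed as a flag.
* **Redundancy filtering** is greedy best-first: walk the deck in score
  order, keep a pose iff its RMSD to every kept pose exceeds the threshold
  (default 2.0 Å), stop at the cap (default 5000).  This mirrors common
  engine-side non-redundant pose collection.  Internally the filter and the
  all-pairs matrix use the Gram-matrix expansion
  Σ|x−y|² = |x|² + |y|² − 2x·y on flattened heavy-atom coordinates; tests
  assert exact agreement with pairwise RMSD calls.
* **Aggregation** pools the per-search top-k (default 10) of one
  (ligand, ensemble) and min–max normalizes scores: best → 1, worst → a
  0.05 floor (so the weakest hotspot sphere keeps nonzero radius);
  all-equal scores all normalize to 1.  The normalization scope
  (per ligand-ensemble aggregate) and the floor are interpretive choices —
  "normalized score" alone does not fix them — and both are config keys.
* **Hotspot spheres** sit at pose heavy-atom centroids with radius
  r_max × norm_score, exported as TSV and as pseudo-atom PDB (radius in the
  B-factor column).

## Consensus

The cross-ensemble filter keeps a pose iff at least one pose of the same
ligand in the other state's aggregate lies within 2.5 Å RMSD.  All pairs
are evaluated exhaustively (order-independent, reproducible); witnesses are
recorded for auditability, and the matched-pair sets are symmetric in the
argument order.

The cross-ligand criterion needs an atom correspondence between analogs.
It is computed as a maximum common substructure: a maximum clique in the
modular product of the two heavy-atom bond graphs under an element-match
constraint, i.e. the largest common induced subgraph.  The search is exact
and enumerative — appropriate for ligand-sized graphs (tens of heavy atoms,
seconds at most) — with a fully deterministic tie-break: maximum atom
count, then maximum shared-bond count, then lexicographically smallest
index sequence.  Mappings smaller than 3 atoms are an error.  The
cross-ligand RMSD over the mapped atoms uses the **same 2.5 Å threshold**
as the same-ligand filter; this is the analysis's central interpretive
decision (no separate cross-ligand metric is canonical), and the threshold
is a config key.

The consensus report records, for each surviving analog pose, all tautomer
witnesses with their mapped-core RMSDs and whether **both** tautomers
matched.  The pipeline compares the two configured consensus states only
(closed ↔ open by default); additional ensembles (e.g. a domain-deletion
construct) contribute hotspots but are excluded from consensus unless
configured otherwise.

## Nonbonded energetics

Pair energies follow the CHARMM conventions: 12-6 Lennard-Jones with
ε_ij = √(ε_i ε_j) and R_ij = Rmin/2_i + Rmin/2_j, Coulomb with
k = 332.0636 kcal·Å/(mol·e²), both multiplied by the switching polynomial
s(r) = (c²−r²)²(c²+2r²−3s_on²)/(c²−s_on²)³ between s_on = 10 Å and
c = 12 Å; s ≡ 1 below s_on and ≡ 0 at and beyond c.  Energies beyond the
cutoff are exactly zero, so any neighbor-list radius ≥ cutoff (e.g. a
13.5 Å pair list) is a performance hint that cannot change results.
Assumptions exposed as config keys because trajectory-energy tools differ
in their defaults: dielectric = 1, and switching applied multiplicatively
to **both** LJ and electrostatics.  Hydrogens are included in energetics
when parameterized; contact and nucleophile scans use heavy atoms.

Region decomposition assigns every protein atom to a named region (regions
must be pairwise disjoint; overlap is an error at region-map construction);
unassigned atoms accumulate into a synthetic `other` record, which makes
the decomposition exactly additive: Σ regions + other = whole-protein
interaction energy (asserted to 1e−9 kcal/mol against a brute-force pair
loop).

Contact residues are those with ≥ 1 heavy atom within 4.0 Å of a ligand
heavy atom; the nucleophile scan checks Ser OG, Cys SG, His ND1/NE2 and
Lys NZ within 5.0 Å of designated electrophilic ligand atoms, sorted by
distance.  Neither cutoff has a canonical literature value at this level of
abstraction; both defaults are flagged as interpretive config keys.
Protonation-state logic (thiolate vs thiol) is deliberately not modeled —
the scan is purely geometric.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of their arguments plus a seed (byte-identical
reruns, asserted in tests).

* **Toy proteins** are helical Cα+backbone+CB chains on a perturbed ideal
  helix, with consecutive domains named after the canonical six regions so
  region-map and energetics code paths run unchanged.  A built-in parameter
  table (alternating ±1 e charges, ε = 0.1 kcal/mol, Rmin/2 = 1.9 Å) covers
  all synthetic atoms; it is labeled synthetic and is not a force field.
* **Conformer pairs** displace a residue block rigidly (default 5.0 Å on a
  2.5 Å threshold), add small coordinate noise (σ = 0.05 Å), and apply a
  global rigid motion the detector must undo.  Specifications whose ground
  truth would fall within 0.5 Å of the threshold are rejected as ambiguous.
* **Snapshots** add i.i.d. Gaussian noise per atom per frame — they emulate
  the *shape* of trajectory input (timestamps, per-frame coordinates), not
  correlated protein dynamics.
* **Toy ligand pairs** share a labeled chain core with an aperiodic element
  sequence (unique automorphism, so the planted MCS is the only maximum)
  and carry decorations in elements absent from the core (F vs Cl), so no
  mapping can leak past the core.  Analogs share core coordinates in the
  template frame.
* **Pose decks** mix uniform random rigid placements (random orientation,
  Gaussian scores) with planted clusters whose orientation derives from the
  *site* seed, not the deck seed — reusing a site across decks of two
  ensembles, or of two analogs sharing core coordinates, plants genuinely
  shared poses (coinciding within twice the translational jitter, default
  0.5 Å).  Planted poses score 5 sd better than the decoy mean so they
  survive top-k selection by construction.

Passing the planted-recovery suites therefore shows that the *filters and
bookkeeping* are correct — that exactly the planted consensus structure is
recovered, with no false positives from 40–5400-pose decks of decoys — not
that the pipeline would locate a real binding site: real pose decks have
correlated, score-ambiguous clusters, real conformers have non-rigid
displacement fields, and real score distributions are not Gaussian.

## Problem sizes and numerical choices

The default test and acceptance workloads use 48-residue toy proteins,
6-heavy-atom cores with 2–4-atom decorations, 40–400-pose per-search decks,
and full-scale runs of the capacity-critical stages (5000–5400-pose decks
for the redundancy cap; 120×120 aggregates for the cross-ensemble oracle) —
sizes chosen so every stage, including its O(n²) oracles, completes in
seconds while still exercising the stated operating parameters exactly.
Planted-truth suites run 20 independent seeds per scenario.

Ties are broken deterministically everywhere: stable file order for equal
scores, lexicographic order for MCS mappings, region-map insertion order
for energy records.  Floating-point boundary notes: the Gram-matrix RMSD
equals pairwise RMSD to ~1e−9 Å, so membership tests at an *exact*
threshold distance are reliable only to that precision (the study
thresholds are all safely away from generated distances; the inclusive-
boundary unit tests use the sequential formula).

## Known limitations

* Residue matching requires shared numbering; structures from different
  crystal forms need renumbering upstream.
* The MCS search is exponential in the worst case; it is intended for
  ligand-sized graphs, not macromolecules.
* Energy decomposition covers nonbonded intermolecular terms only — no
  bonded terms, no long-range electrostatics beyond the cutoff, no
  solvation — matching its role as an interaction-energy *decomposition*,
  not a free-energy estimate.
* MOL2 support covers the TRIPOS ATOM/BOND records plus a score comment
  line; exotic dialect features (substructure records, charges) are
  ignored.
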