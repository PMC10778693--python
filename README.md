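# ensdock

Engine-agnostic **ensemble-docking consensus analysis** for flexible
receptors.

When a ligand's binding site is unknown and the receptor switches between
functional states (for example a channel's closed and open gating
conformations), a single docking run is rarely conclusive: top-scoring poses
scatter, and scoring functions cannot arbitrate between them.  `ensdock`
implements the analysis layer around any docking engine that makes such a
search decisive:

1. **Conformer ensembles.**  Each receptor state is represented by a set of
   conformers — the experimental structure, its energy-minimized copy, and
   MD snapshots taken at regular intervals — and every ligand is docked
   against every conformer (the task manifest is the full cartesian
   product).
2. **Invariant-region superposition.**  All targets are placed in one frame
   by least-squares (Kabsch) superposition on the conformationally invariant
   regions: the residues whose Cα atoms overlap within a threshold
   (default 2.5 Å) between states after fitting on a reference domain.
   Pose comparison is then plain in-frame heavy-atom RMSD, no refitting.
3. **Per-search retention.**  Each search keeps a capped deck of
   non-redundant poses (greedy best-first, RMSD > 2.0 Å, cap 5000) and
   passes its top 10 by score onward; per-(ligand, ensemble) aggregates are
   summarized as hotspot spheres with radii proportional to min–max
   normalized scores.
4. **Cross-ensemble filter.**  A pose survives only if a near-identical
   placement (RMSD ≤ 2.5 Å) exists on at least one conformer of *each*
   state ensemble — the binding mode must be available to both states.
5. **Cross-ligand (analog) consensus.**  Among the survivors, a pose is a
   *consensus pose* only if a chemical analog reproduces it over their
   maximum common substructure (MCS-mapped heavy-atom RMSD ≤ 2.5 Å).
6. **Energy decomposition.**  For the surviving mode, ligand–protein
   nonbonded energies (12-6 Lennard-Jones + Coulomb, CHARMM-style switching
   between 10 and 12 Å) are decomposed by named protein region over
   trajectory frames, with contact-residue and nucleophile-proximity scans.

The package never runs docking or MD itself; it consumes standard formats
(PDB/PQR structures, SDF/MOL2 scored pose decks, whitespace parameter
tables, YAML region definitions) and ships a synthetic-data module that
generates every input shape with planted ground truth, so the whole pipeline
is testable offline.

## The core statistic

For two poses *a*, *b* of the same ligand in the common frame, the overlap
measure is

    RMSD(a, b) = sqrt( (1/|H|) Σ_{i∈H} |x_i^a − x_i^b|² )

over heavy atoms *H*, and for analog ligands over the MCS atom pairs
(i, j) instead.  A pose *p* of the analog is a consensus pose iff

* ∃ a pose of the same ligand in the other state's aggregate with
  RMSD ≤ t, and
* ∃ a retained pose *q* of at least one tautomer with RMSD_MCS(p, q) ≤ t,

with t = 2.5 Å throughout.  Nonbonded pair energies use
ε_ij = √(ε_i ε_j), R_ij = R_i/2 + R_j/2, k = 332.0636 kcal·Å/(mol·e²), and
the switching polynomial s(r) = (c²−r²)²(c²+2r²−3s²)/(c²−s²)³ for
s < r < c (s = 10 Å, c = 12 Å).

## Worked example

Simulate a synthetic study (two state ensembles, three analog ligands, one
planted consensus site) and run the full pipeline:

```python
import json
from pathlib import Path
from ensdock import PipelineConfig, run_pipeline, simulate_fixtures

study = Path("study")
simulate_fixtures(study, seed=11)
config = PipelineConfig.from_yaml(study / "config.yaml")
run = run_pipeline(config, study, study / "run")

manifest = json.loads((run / "manifest.json").read_text())
print("invariant residues:", manifest["stages"]["align"]["invariant_residues"])
print("alignment targets: ", manifest["stages"]["align"]["alignment_targets"])
print("docking tasks:     ", manifest["stages"]["align"]["docking_tasks"])
print("cross-ensemble survivors:", manifest["stages"]["cross_ensemble"])
report = json.loads((run / "consensus.json").read_text())
print("consensus poses:   ", report["n_consensus_poses"])
print("both tautomers:    ", report["consensus"][0]["both_tautomers"])
```

prints

```
invariant residues: 38
alignment targets:  8
docking tasks:      24
cross-ensemble survivors: {'analog': 1, 'tautomer1': 1, 'tautomer2': 1}
consensus poses:    1
both tautomers:     True
```

The toy protein has 48 residues of which a block of 10 is displaced between
states, so 38 are invariant; 2 ensembles × 4 conformers give 8 aligned
targets and, with 3 ligands, 24 docking tasks.  Exactly the one planted
binding mode survives both consensus criteria, and it is matched by both
tautomers of the natural ligand.  The run directory also contains per-
aggregate TSVs, hotspot pseudo-atom PDBs, the consensus poses as SDF, and a
per-region energy time series (`energies.tsv`).

The same stages are exposed as a CLI:

```bash
ensdock simulate --out study --seed 11
ensdock run --config study/config.yaml
ensdock invariance --reference a.pdb --mobile b.pdb --regions regions.yaml
ensdock filterposes --deck deck.sdf --ligand lig.sdf --out top.sdf
```

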