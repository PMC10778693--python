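"""End-to-end orchestration: fixture simulation and the full consensus pipeline.

``simulate_fixtures`` writes a complete synthetic study to disk — conformer
pairs, trajectory frames, ligand templates, scored pose decks with planted
shared poses, a parameter table and region definitions — in the same standard
formats real inputs would use.  ``run_pipeline`` consumes such a directory
through a :class:`~ensdock.config.PipelineConfig` and executes:

    align -> ensembles -> per-search filters (search space, redundancy,
    top-k) -> aggregation/hotspots -> cross-ensemble shared-pose filter ->
    cross-ligand consensus -> energetics (when frames are available)

Every stage logs its input/output counts so the pose funnel is auditable, and
a manifest records the resolved configuration hash; reruns with the same
config and seed produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import consensus as cns
from . import energetics as en
from . import ensembles as ens
from . import poses as pk
from . import structures as st
from . import synthetic as syn
from .config import EnsembleSpec, PipelineConfig

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


# ---------------------------------------------------------------------------
# Fixture simulation
# ---------------------------------------------------------------------------


def simulate_fixtures(
    out_dir: str | Path,
    seed: int = 0,
    n_conformers: int = 2,
    deck_size: int = 60,
    n_consensus_sites: int = 1,
    core_size: int = 6,
    n_domains: int = 6,
    residues_per_domain: int = 8,
) -> Path:
    """Write a full synthetic study directory and its config.yaml.

    Two channel-state ensembles (closed, open) built from a conformer pair
    with a known invariant set; each ensemble has a parent, a minimized copy
    and ``n_conformers`` snapshots.  Three analog ligands (one rigid analog,
    two tautomers) share a labeled core; ``n_consensus_sites`` planted sites
    are shared across both ensembles and all three ligands, so the pipeline's
    ground-truth consensus count is known by construction.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    closed, open_, region_map, truth = syn.make_conformer_pair(
        n_domains=n_domains, residues_per_domain=residues_per_domain, seed=seed
    )
    (out / "regions.yaml").write_text(yaml.safe_dump(region_map.to_dict()))

    # ligands: analog + two tautomers sharing the analog's core coordinates
    pair1 = syn.make_toy_ligands(core_size, (2, 3), seed=seed, ids=("analog", "tautomer1"))
    pair2 = syn.make_toy_ligands(core_size, (2, 4), seed=seed, ids=("analog", "tautomer2"))
    ligands = {
        "analog": (pair1.topology_a, pair1.coords_a),
        "tautomer1": (pair1.topology_b, pair1.coords_b),
        "tautomer2": (pair2.topology_b, pair2.coords_b),
    }
    lig_dir = out / "ligands"
    lig_dir.mkdir(exist_ok=True)
    for lig_id, (topo, coords) in ligands.items():
        template = pk.Pose(ligand_id=lig_id, coords=coords, score=0.0, topology=topo)
        pk.write_poses_sdf([template], lig_dir / f"{lig_id}.sdf", topology=topo)

    # parameter table covering protein and all ligand atom names
    table = syn.builtin_param_table()
    for topo, _ in ligands.values():
        table.entries.update(syn.builtin_param_table(topo).entries)
    table.to_file(out / "params.tsv")

    # ensembles: parent + minimized + snapshots, written as PDB + frame manifest
    ensembles = {"closed": closed, "open": open_}
    for label, parent in ensembles.items():
        edir = out / "ensembles" / label
        (edir / "frames").mkdir(parents=True, exist_ok=True)
        st.write_pdb(parent, edir / "parent.pdb")
        minimized = syn.make_snapshots(parent, 0.08, [0.0], seed=seed + 11)[0]
        st.write_pdb(minimized, edir / "minimized.pdb")
        times = [1.0 * (i + 1) for i in range(n_conformers)]
        frames = syn.make_snapshots(parent, 0.3, times, seed=seed + 13)
        rows = []
        for i, frame in enumerate(frames):
            fname = f"frames/frame_{i:03d}.pdb"
            st.write_pdb(frame, edir / fname)
            rows.append(f"{frame.time_ns:g}\t{fname}")
        (edir / "frames.tsv").write_text("\n".join(rows) + "\n")

    # planted consensus sites near the NBD1 center of the reference structure
    center = ens.region_center(closed, region_map, "NBD1")
    sites = tuple(
        syn.PlantedSite(
            center=tuple(center + np.array([8.0 * k - 4.0 * (n_consensus_sites - 1), 6.0, 4.0])),
            n_members=1,
            jitter=0.4,
            orientation_seed=1000 + k,
        )
        for k in range(n_consensus_sites)
    )

    # decks: planted sites go into conformer 0's deck of every (ligand, ensemble)
    deck_dir = out / "decks"
    deck_dir.mkdir(exist_ok=True)
    n_total_conf = 2 + n_conformers  # parent + minimized + snapshots
    for lig_id, (topo, coords) in ligands.items():
        for label in ensembles:
            for ic in range(n_total_conf):
                deck = syn.make_pose_deck(
                    topo,
                    coords,
                    n=deck_size,
                    planted=sites if ic == 0 else (),
                    box=40.0,
                    box_center=tuple(center),
                    seed=int(rng.integers(0, 2**31 - 1)),
                    ensemble_label=label,
                    conformer_index=ic,
                )
                pk.write_poses_sdf(
                    deck, deck_dir / f"{lig_id}__{label}__{ic}.sdf", topology=topo
                )

    config = PipelineConfig(
        ensembles={
            label: EnsembleSpec(
                parent=f"ensembles/{label}/parent.pdb",
                minimized=f"ensembles/{label}/minimized.pdb",
                frames_manifest=f"ensembles/{label}/frames.tsv",
                start_ns=1.0,
                interval_ns=1.0,
                count=n_conformers,
            )
            for label in ensembles
        },
        ligand_ids=list(ligands),
        analog_id="analog",
        tautomer_ids=["tautomer1", "tautomer2"],
        electrophile_atoms=[0, 1],
        seed=seed,
    )
    config.to_yaml(out / "config.yaml")
    return out


# ---------------------------------------------------------------------------
# Pipeline execution
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, root: str | Path, out_dir: str | Path) -> Path:
    """Execute the full consensus pipeline; returns the run directory."""
    root = Path(root)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {"config_digest": config.digest(), "stages": {}}

    try:
        # --- inputs -------------------------------------------------------
        stage = "inputs"
        region_map = st.RegionMap.from_dict(yaml.safe_load((root / config.regions).read_text()))
        table = en.ParamTable.from_file(root / config.params)
        topologies: dict[str, pk.LigandTopology] = {}
        templates: dict[str, np.ndarray] = {}
        for lig_id in config.ligand_ids:
            sdf = root / config.ligands_dir / f"{lig_id}.sdf"
            if not sdf.exists():
                raise PipelineError("posekit", f"missing ligand template {sdf}")
            from rdkit import Chem

            mol = next(iter(Chem.SDMolSupplier(str(sdf), sanitize=False, removeHs=False)))
            topologies[lig_id] = pk.topology_from_rdkit(mol, lig_id)
            conf = mol.GetConformer()
            templates[lig_id] = np.array(
                [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
            )

        # --- ensembles ----------------------------------------------------
        stage = "ensembles"
        built: dict[str, ens.ConformerEnsemble] = {}
        for label, spec in config.ensembles.items():
            parent = st.read_structure(root / spec.parent)
            minimized = st.read_structure(root / spec.minimized) if spec.minimized else None
            frames = []
            if spec.frames_manifest:
                mpath = root / spec.frames_manifest
                for line in mpath.read_text().splitlines():
                    if not line.strip():
                        continue
                    t, rel = line.split("\t")
                    frame = st.read_structure(mpath.parent / rel)
                    frames.append(frame.with_provenance("snapshot", time_ns=float(t)))
            built[label] = ens.build_ensemble(
                parent, minimized, frames, spec.start_ns, spec.interval_ns, spec.count,
                state_label=label,
            )
        manifest["stages"]["ensembles"] = {k: len(v) for k, v in built.items()}

        # --- invariance + alignment ----------------------------------------
        stage = "align"
        ref_label = config.reference_state
        if ref_label not in built:
            raise PipelineError(stage, f"reference state {ref_label!r} not among ensembles")
        reference = built[ref_label].conformers[0]
        other_labels = [l for l in built if l != ref_label]
        invariant: set[st.ResidueId] = set(reference.residue_ids())
        for label in other_labels:
            invariant &= st.detect_invariant_residues(
                reference, built[label].conformers[0],
                threshold=config.invariance_threshold,
                region_map=region_map, fit_region=config.fit_region,
            )
        aligned: dict[str, ens.ConformerEnsemble] = {}
        fit_sel = region_map.residues(config.fit_region, reference) & invariant
        for label, ensemble in built.items():
            conformers = st.align_targets(ensemble.conformers, reference, fit_sel or None)
            for c_new, c_old in zip(conformers, ensemble.conformers):
                c_new.provenance = c_old.provenance
                c_new.time_ns = c_old.time_ns
            aligned[label] = ens.ConformerEnsemble(label, conformers)
        tasks = ens.enumerate_tasks(config.ligand_ids, list(aligned.values()))
        manifest["stages"]["align"] = {
            "invariant_residues": len(invariant),
            "alignment_targets": sum(len(e) for e in aligned.values()),
            "docking_tasks": len(tasks),
        }
        logger.info("align: %d invariant residues, %d tasks", len(invariant), len(tasks))

        # --- per-search filters and aggregation -----------------------------
        stage = "posekit"
        center = ens.region_center(reference, region_map, config.fit_region)
        aggregates: dict[tuple[str, str], pk.PoseAggregate] = {}
        funnel: dict[str, dict] = {}
        for lig_id in config.ligand_ids:
            for label, ensemble in aligned.items():
                tops = []
                for ic in range(len(ensemble)):
                    deck_path = root / config.deck_pattern.format(
                        ligand=lig_id, ensemble=label, conformer=ic
                    )
                    if not deck_path.exists():
                        raise PipelineError(stage, f"missing pose deck {deck_path}")
                    deck = pk.read_poses(
                        deck_path, topologies[lig_id],
                        score_field=config.score_field,
                        score_direction=config.score_direction,
                    )
                    for p in deck:
                        p.ensemble_label = label
                        p.conformer_index = ic
                    deck = pk.topk(deck, k=len(deck), score_direction=config.score_direction)
                    in_sphere = ens.search_space_filter(deck, center, config.search_radius)
                    unique = pk.nonredundant_filter(
                        in_sphere, config.redundancy_threshold, config.pose_cap
                    )
                    top = pk.topk(unique, config.top_k, config.score_direction)
                    funnel[f"{lig_id}/{label}/{ic}"] = {
                        "deck": len(deck), "in_sphere": len(in_sphere),
                        "nonredundant": len(unique), "top": len(top),
                    }
                    tops.append(top)
                agg = pk.aggregate(
                    tops, lig_id, label,
                    score_direction=config.score_direction, norm_floor=config.norm_floor,
                )
                aggregates[(lig_id, label)] = agg
                pk.aggregate_to_frame(agg).to_csv(
                    out / f"aggregate_{lig_id}_{label}.tsv", sep="\t", index=False
                )
                pk.spheres_to_pdb(
                    pk.hotspot_spheres(agg, config.r_max), out / f"hotspots_{lig_id}_{label}.pdb"
                )
        manifest["stages"]["posekit"] = funnel

        # --- cross-ensemble filter ------------------------------------------
        stage = "consensus"
        state_a, state_b = config.consensus_states
        filtered: dict[str, list[pk.Pose]] = {}
        for lig_id in config.ligand_ids:
            filtered[lig_id] = cns.shared_poses(
                aggregates[(lig_id, state_a)], aggregates[(lig_id, state_b)],
                threshold=config.share_threshold,
            )
        manifest["stages"]["cross_ensemble"] = {k: len(v) for k, v in filtered.items()}

        # --- cross-ligand consensus -----------------------------------------
        try:
            report = cns.cross_ligand_consensus(
                filtered, config.analog_id, config.tautomer_ids, topologies,
                threshold=config.cross_ligand_threshold,
            )
        except cns.ConsensusError:
            # nothing survived the cross-ensemble filter: empty consensus
            report = cns.ConsensusReport(
                analog_id=config.analog_id,
                tautomer_ids=tuple(config.tautomer_ids),
                threshold=config.cross_ligand_threshold,
                retained=filtered,
                consensus=[],
            )
        report.to_json(out / "consensus.json")
        if report.consensus:
            pk.write_poses_sdf(
                [e.analog_pose for e in report.consensus], out / "consensus.sdf",
                topology=topologies[config.analog_id],
            )
        manifest["stages"]["consensus"] = {"n_consensus_poses": len(report.consensus)}
        logger.info("consensus: %d pose(s)", len(report.consensus))

        # --- energetics ------------------------------------------------------
        stage = "energetics"
        ref_spec = config.ensembles[ref_label]
        if report.consensus and ref_spec.frames_manifest:
            pose = report.consensus[0].analog_pose
            lig_params = table.for_topology(topologies[config.analog_id])
            frames = [
                table.assign(c)
                for c in aligned[ref_label].conformers
                if c.provenance == "snapshot"
            ]
            options = en.NonbondedOptions(
                dielectric=config.dielectric, switch_on=config.switch_on, cutoff=config.cutoff
            )
            records = en.energy_timeseries(
                frames, [pose] * len(frames), lig_params, region_map, options
            )
            en.records_to_frame(records).to_csv(out / "energies.tsv", sep="\t", index=False)
            contacts = en.contact_residues(frames[0], pose, config.contact_cutoff)
            nucleophiles = en.nucleophile_proximity(
                frames[0], pose, config.electrophile_atoms or [0], config.nucleophile_cutoff
            )
            manifest["stages"]["energetics"] = {
                "frames": len(frames),
                "records": len(records),
                "contact_residues": len(contacts),
                "nucleophiles_in_contact": len(nucleophiles),
            }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
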