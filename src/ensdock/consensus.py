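"""Cross-ensemble and cross-ligand pose consensus.

The headline inference of the pipeline: a binding pose is credible when (i)
near-identical placements of the same ligand occur on at least one conformer
of each channel-state ensemble (closed and open), and (ii) a placement of the
rigid synthetic analog coincides — over the chemically shared substructure —
with a placement of at least one tautomer of the natural ligand.  Both tests
are in-frame heavy-atom RMSD comparisons with the same distance threshold;
the cross-ligand atom correspondence comes from a maximum common substructure
(MCS) search.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import networkx as nx
import numpy as np

from .poses import LigandTopology, Pose, PoseAggregate, PoseError, ligand_rmsd, rmsd_matrix


class ConsensusError(ValueError):
    """Invalid consensus input (mismatched ligands, missing mapping, ...)."""


@dataclass(frozen=True)
class AtomMapping:
    """Injective heavy-atom correspondence between two ligand topologies."""

    ligand_a: str
    ligand_b: str
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        a_idx = [p[0] for p in self.pairs]
        b_idx = [p[1] for p in self.pairs]
        if len(set(a_idx)) != len(a_idx) or len(set(b_idx)) != len(b_idx):
            raise ConsensusError("atom mapping must be injective both ways")

    def __len__(self) -> int:
        return len(self.pairs)

    def reversed(self) -> "AtomMapping":
        return AtomMapping(self.ligand_b, self.ligand_a, tuple((j, i) for i, j in self.pairs))


def identity_mapping(topology: LigandTopology) -> AtomMapping:
    idx = topology.heavy_atom_indices
    return AtomMapping(topology.ligand_id, topology.ligand_id, tuple((i, i) for i in idx))


# ---------------------------------------------------------------------------
# Cross-ensemble shared poses
# ---------------------------------------------------------------------------


def shared_pose_pairs(
    agg_a: PoseAggregate,
    agg_b: PoseAggregate,
    threshold: float = 2.5,
) -> list[tuple[Pose, Pose, float]]:
    """All (pose_a, pose_b, rmsd) pairs overlapping within ``threshold``.

    Exhaustive all-pairs evaluation (order-independent and reproducible);
    both aggregates must hold the same ligand in the common frame.
    """
    if agg_a.ligand_id != agg_b.ligand_id:
        raise ConsensusError(
            f"ligand mismatch: {agg_a.ligand_id!r} vs {agg_b.ligand_id!r}"
        )
    d = rmsd_matrix(agg_a.poses, agg_b.poses)
    out = []
    for i, j in zip(*np.nonzero(d <= threshold)):
        out.append((agg_a.poses[int(i)], agg_b.poses[int(j)], float(d[i, j])))
    return out


def shared_poses(
    agg_a: PoseAggregate,
    agg_b: PoseAggregate,
    threshold: float = 2.5,
) -> list[Pose]:
    """Poses of ``agg_a`` with >=1 counterpart in ``agg_b`` within ``threshold`` RMSD.

    A pose passes the cross-ensemble filter when the same binding mode is
    present on at least one conformer of each ensemble.
    """
    pairs = shared_pose_pairs(agg_a, agg_b, threshold)
    seen: dict[int, Pose] = {}
    for pa, _, _ in pairs:
        seen.setdefault(id(pa), pa)
    # preserve agg_a order
    return [p for p in agg_a.poses if id(p) in seen]


# ---------------------------------------------------------------------------
# Maximum common substructure
# ---------------------------------------------------------------------------


def mcs_atom_mapping(a: LigandTopology, b: LigandTopology, min_atoms: int = 3) -> AtomMapping:
    """Maximum common substructure mapping over heavy atoms.

    Exact search: a maximum clique in the modular product of the two
    heavy-atom bond graphs under an element-match constraint (pairs are
    compatible when bond presence agrees), which yields the largest common
    induced subgraph.  Among maximum-size mappings the one with the most
    shared bonds wins, then the lexicographically smallest index sequence —
    the result is fully deterministic.  Intended for ligand-sized graphs
    (tens of heavy atoms).
    """
    ga = a.graph(heavy_only=True)
    gb = b.graph(heavy_only=True)
    product = nx.Graph()
    for i in ga.nodes:
        for j in gb.nodes:
            if ga.nodes[i]["element"] == gb.nodes[j]["element"]:
                product.add_node((i, j))
    for (i1, j1), (i2, j2) in itertools.combinations(product.nodes, 2):
        if i1 == i2 or j1 == j2:
            continue
        if ga.has_edge(i1, i2) == gb.has_edge(j1, j2):
            product.add_edge((i1, j1), (i2, j2))

    best_pairs: tuple | None = None
    best_key: tuple | None = None
    best_size = 0
    if product.number_of_nodes():
        for clique in nx.find_cliques(product):
            if len(clique) < best_size:
                continue
            pairs = tuple(sorted(clique))
            n_bonds = sum(1 for (i1, _), (i2, _) in itertools.combinations(pairs, 2)
                          if ga.has_edge(i1, i2))
            key = (-n_bonds, pairs)
            if len(clique) > best_size or (best_key is not None and key < best_key):
                best_size = len(clique)
                best_key = key
                best_pairs = pairs
    if best_pairs is None or best_size < min_atoms:
        raise ConsensusError(
            f"common substructure of {a.ligand_id!r} and {b.ligand_id!r} has "
            f"{best_size} atoms (< {min_atoms})"
        )
    return AtomMapping(a.ligand_id, b.ligand_id, best_pairs)


# ---------------------------------------------------------------------------
# Cross-ligand consensus
# ---------------------------------------------------------------------------


def _pose_ref(pose: Pose) -> dict:
    return {
        "ligand": pose.ligand_id,
        "ensemble": pose.ensemble_label,
        "conformer": pose.conformer_index,
        "rank": pose.rank,
        "score": pose.score,
    }


@dataclass
class ConsensusEntry:
    """One consensus pose: the analog's witness plus matching tautomer witnesses."""

    analog_pose: Pose
    witnesses: list[tuple[Pose, float]]  # (tautomer pose, RMSD over the mapped core)
    matched_tautomers: tuple[str, ...]

    @property
    def both_tautomers(self) -> bool:
        return len(set(self.matched_tautomers)) >= 2


@dataclass
class ConsensusReport:
    """Outcome of the two-criterion consensus filter.

    ``retained`` holds the per-ligand cross-ensemble survivors that entered
    the cross-ligand stage; ``consensus`` the analog poses matched by at
    least one tautomer over the MCS-mapped core.
    """

    analog_id: str
    tautomer_ids: tuple[str, ...]
    threshold: float
    retained: dict[str, list[Pose]]
    consensus: list[ConsensusEntry]
    mappings: dict[str, AtomMapping] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "analog_id": self.analog_id,
            "tautomer_ids": list(self.tautomer_ids),
            "threshold_angstrom": self.threshold,
            "retained_counts": {k: len(v) for k, v in self.retained.items()},
            "n_consensus_poses": len(self.consensus),
            "consensus": [
                {
                    "analog_pose": _pose_ref(e.analog_pose),
                    "witnesses": [
                        {**_pose_ref(p), "rmsd_mapped_core": r} for p, r in e.witnesses
                    ],
                    "matched_tautomers": list(e.matched_tautomers),
                    "both_tautomers": e.both_tautomers,
                }
                for e in self.consensus
            ],
            "mcs_mapping_sizes": {k: len(m) for k, m in self.mappings.items()},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def cross_ligand_consensus(
    filtered: dict[str, list[Pose]],
    analog_id: str,
    tautomer_ids: Sequence[str],
    topologies: dict[str, LigandTopology],
    threshold: float = 2.5,
    mapping_fn: Callable[[LigandTopology, LigandTopology], AtomMapping] = mcs_atom_mapping,
) -> ConsensusReport:
    """Apply the cross-ligand criterion to the cross-ensemble survivors.

    A pose of the analog joins the consensus iff some retained pose of at
    least one tautomer lies within ``threshold`` RMSD over the MCS-mapped
    shared heavy atoms.  The report records every witness and whether both
    tautomers matched.
    """
    if analog_id not in filtered or not filtered[analog_id]:
        raise ConsensusError(f"no retained poses for analog {analog_id!r}")
    present_tautomers = [t for t in tautomer_ids if filtered.get(t)]
    if not present_tautomers:
        raise ConsensusError("no retained poses for any tautomer")

    mappings: dict[str, AtomMapping] = {}
    for t in present_tautomers:
        mappings[t] = mapping_fn(topologies[analog_id], topologies[t])

    entries: list[ConsensusEntry] = []
    for analog_pose in filtered[analog_id]:
        witnesses: list[tuple[Pose, float]] = []
        matched: list[str] = []
        for t in present_tautomers:
            mapping = mappings[t]
            hit = False
            for taut_pose in filtered[t]:
                r = ligand_rmsd(analog_pose, taut_pose, mapping=mapping.pairs)
                if r <= threshold:
                    witnesses.append((taut_pose, r))
                    hit = True
            if hit:
                matched.append(t)
        if matched:
            entries.append(
                ConsensusEntry(
                    analog_pose=analog_pose,
                    witnesses=witnesses,
                    matched_tautomers=tuple(matched),
                )
            )
    return ConsensusReport(
        analog_id=analog_id,
        tautomer_ids=tuple(tautomer_ids),
        threshold=threshold,
        retained=filtered,
        consensus=entries,
        mappings=mappings,
    )
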