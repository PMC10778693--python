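"""Docking-pose containers, I/O, ligand RMSD, and retention filters.

Poses are scored ligand placements expressed in a common receptor frame (all
docking targets are pre-aligned before pose comparison), so pose overlap is a
plain coordinate RMSD over heavy atoms with no refitting.  The per-search
funnel mirrors standard ensemble-docking practice: collect a capped deck of
non-redundant poses (greedy best-first, RMSD above a redundancy threshold),
keep the top-k by score, aggregate the per-search survivors per
(ligand, ensemble), and summarize the aggregate as hotspot spheres whose
radii encode normalized scores.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd


class PoseError(ValueError):
    """Invalid pose data or an inconsistent pose operation."""


@dataclass(frozen=True)
class LigandTopology:
    """Ligand connectivity: (name, element) atoms plus bonds with orders.

    The bond graph must be connected; ``heavy_atom_indices`` lists the
    non-hydrogen atoms used for RMSD, centroids and substructure mapping.
    """

    ligand_id: str
    atoms: tuple[tuple[str, str], ...]  # (name, element)
    bonds: tuple[tuple[int, int, float], ...]  # (i, j, order)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise PoseError(f"ligand {self.ligand_id!r}: invalid bond ({i}, {j})")
        if n > 1:
            g = self.graph()
            if not nx.is_connected(g):
                raise PoseError(f"ligand {self.ligand_id!r}: bond graph is disconnected")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(e.upper() for _, e in self.atoms)

    @property
    def heavy_atom_indices(self) -> tuple[int, ...]:
        return tuple(i for i, e in enumerate(self.elements) if e not in ("H", "D"))

    def graph(self, heavy_only: bool = False) -> nx.Graph:
        """Bond graph with ``element`` node attributes."""
        g = nx.Graph()
        heavy = set(self.heavy_atom_indices)
        for i, (name, elem) in enumerate(self.atoms):
            if heavy_only and i not in heavy:
                continue
            g.add_node(i, element=elem.upper(), name=name)
        for i, j, order in self.bonds:
            if heavy_only and (i not in heavy or j not in heavy):
                continue
            g.add_edge(i, j, order=order)
        return g


@dataclass(eq=False)
class Pose:
    """One scored ligand placement on one receptor conformer."""

    ligand_id: str
    coords: np.ndarray  # (n_atoms, 3), Angstroms, common aligned frame
    score: float
    rank: int = 1
    ensemble_label: str = ""
    conformer_index: int = 0
    topology: LigandTopology | None = field(default=None, repr=False)
    frame: str = "common"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise PoseError("pose coords must be (n_atoms, 3)")
        if self.topology is not None and len(self.topology) != len(self.coords):
            raise PoseError(
                f"pose has {len(self.coords)} coords but topology "
                f"{self.topology.ligand_id!r} has {len(self.topology)} atoms"
            )
        if self.rank < 1:
            raise PoseError("rank must be >= 1")

    @property
    def conformer_id(self) -> tuple[str, int]:
        return (self.ensemble_label, self.conformer_index)

    def heavy_coords(self) -> np.ndarray:
        if self.topology is None:
            return self.coords
        return self.coords[list(self.topology.heavy_atom_indices)]

    def heavy_centroid(self) -> np.ndarray:
        return self.heavy_coords().mean(axis=0)


@dataclass(eq=False)
class PoseAggregate:
    """Retained poses for one (ligand, ensemble) with normalized scores.

    Scores are min-max normalized within the aggregate so the best raw score
    maps to 1 and the worst to a small positive floor (default 0.05, keeping
    the weakest hotspot sphere visible); with all scores equal every pose
    normalizes to 1.
    """

    ligand_id: str
    ensemble_label: str
    poses: list[Pose]
    norm_scores: np.ndarray

    def __len__(self) -> int:
        return len(self.poses)


@dataclass(frozen=True)
class HotspotSphere:
    """A pose summarized as a sphere at its heavy-atom centroid."""

    center: np.ndarray
    radius: float


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_RDKIT_BOND_ORDERS = {1.0: "SINGLE", 2.0: "DOUBLE", 3.0: "TRIPLE", 1.5: "AROMATIC"}


def topology_from_rdkit(mol, ligand_id: str) -> LigandTopology:
    atoms = tuple(
        (a.GetProp("_name") if a.HasProp("_name") else f"{a.GetSymbol().upper()}{a.GetIdx() + 1}",
         a.GetSymbol())
        for a in mol.GetAtoms()
    )
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), float(b.GetBondTypeAsDouble()))
        for b in mol.GetBonds()
    )
    return LigandTopology(ligand_id=ligand_id, atoms=atoms, bonds=bonds)


def _topology_to_rdkit(topology: LigandTopology):
    from rdkit import Chem
    from rdkit.Geometry import Point3D  # noqa: F401  (conformer coords set by caller)

    mol = Chem.RWMol()
    for name, elem in topology.atoms:
        atom = Chem.Atom(elem.capitalize())
        atom.SetNoImplicit(True)
        mol.AddAtom(atom)
    for i, j, order in topology.bonds:
        bond_type = getattr(Chem.BondType, _RDKIT_BOND_ORDERS.get(order, "SINGLE"))
        mol.AddBond(int(i), int(j), bond_type)
    m = mol.GetMol()
    m.UpdatePropertyCache(strict=False)
    return m


def read_poses(
    path: str | Path,
    topology: LigandTopology,
    format: str | None = None,
    score_field: str = "SCORE",
    score_direction: str = "lower",
) -> list[Pose]:
    """Read a scored pose deck from SDF or MOL2.

    Every entry must match the topology atom count and carry a score — an SDF
    data field (default name ``SCORE``) or a ``SCORE: <value>`` comment in the
    MOL2 molecule record.  Poses are returned in file order with ranks
    assigned by score (best = 1; ties broken by file order).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt == "SDF":
        entries = _read_sdf(path, score_field)
    elif fmt == "MOL2":
        entries = _read_mol2(path, score_field)
    else:
        raise PoseError(f"unknown pose format {fmt!r}")

    poses = []
    for idx, (coords, score) in enumerate(entries):
        if len(coords) != len(topology):
            raise PoseError(
                f"{path}: entry {idx + 1} has {len(coords)} atoms, "
                f"topology {topology.ligand_id!r} has {len(topology)}"
            )
        poses.append(
            Pose(ligand_id=topology.ligand_id, coords=coords, score=score, topology=topology)
        )
    _assign_ranks(poses, score_direction)
    return poses


def _assign_ranks(poses: list[Pose], score_direction: str) -> None:
    sign = 1.0 if score_direction == "lower" else -1.0
    order = sorted(range(len(poses)), key=lambda i: (sign * poses[i].score, i))
    for rank, i in enumerate(order, start=1):
        poses[i].rank = rank


def _read_sdf(path: Path, score_field: str):
    from rdkit import Chem

    entries = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise PoseError(f"{path}: entry {idx + 1} failed to parse")
        if not mol.HasProp(score_field):
            raise PoseError(f"{path}: entry {idx + 1} lacks score field {score_field!r}")
        conf = mol.GetConformer()
        coords = np.array(
            [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
             for i in range(mol.GetNumAtoms())]
        )
        entries.append((coords, float(mol.GetProp(score_field))))
    if not entries:
        raise PoseError(f"{path}: no entries")
    return entries


def write_poses_sdf(
    poses: Sequence[Pose],
    path: str | Path,
    topology: LigandTopology | None = None,
    score_field: str = "SCORE",
) -> None:
    """Write poses as an SDF deck with the score in a data field."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    if not poses:
        raise PoseError("no poses to write")
    topology = topology or poses[0].topology
    mol = _topology_to_rdkit(topology)
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for pose in poses:
        m = Chem.Mol(mol)
        conf = Chem.Conformer(m.GetNumAtoms())
        for i, (x, y, z) in enumerate(pose.coords):
            conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
        m.AddConformer(conf, assignId=True)
        m.SetProp("_Name", pose.ligand_id)
        m.SetProp(score_field, f"{pose.score:.6f}")
        writer.write(m)
    writer.close()


def _read_mol2(path: Path, score_field: str):
    """Minimal TRIPOS MOL2 reader: ATOM block coordinates plus a score comment.

    The score is taken from a ``<score_field>: <value>`` line in the molecule
    record's comment section (line 6 of @<TRIPOS>MOLECULE).
    """
    text = Path(path).read_text()
    blocks = [b for b in text.split("@<TRIPOS>MOLECULE") if b.strip()]
    if not blocks:
        raise PoseError(f"{path}: no MOL2 molecule records")
    entries = []
    for idx, block in enumerate(blocks):
        score = None
        for line in block.splitlines():
            stripped = line.strip()
            if stripped.startswith(f"{score_field}:"):
                score = float(stripped.split(":", 1)[1])
                break
        if score is None:
            raise PoseError(f"{path}: molecule {idx + 1} lacks {score_field!r} comment")
        atom_sec = block.split("@<TRIPOS>ATOM", 1)
        if len(atom_sec) < 2:
            raise PoseError(f"{path}: molecule {idx + 1} has no ATOM section")
        coords = []
        for line in atom_sec[1].splitlines():
            if line.startswith("@<TRIPOS>"):
                break
            parts = line.split()
            if len(parts) >= 5:
                coords.append([float(parts[2]), float(parts[3]), float(parts[4])])
        entries.append((np.asarray(coords), score))
    return entries


def write_poses_mol2(
    poses: Sequence[Pose],
    path: str | Path,
    topology: LigandTopology | None = None,
    score_field: str = "SCORE",
) -> None:
    if not poses:
        raise PoseError("no poses to write")
    topology = topology or poses[0].topology
    with open(path, "w") as fh:
        for pose in poses:
            fh.write("@<TRIPOS>MOLECULE\n")
            fh.write(f"{pose.ligand_id}\n")
            fh.write(f"{len(topology)} {len(topology.bonds)} 0 0 0\n")
            fh.write("SMALL\nNO_CHARGES\n")
            fh.write(f"{score_field}: {pose.score:.6f}\n")
            fh.write("@<TRIPOS>ATOM\n")
            for i, ((name, elem), (x, y, z)) in enumerate(zip(topology.atoms, pose.coords)):
                fh.write(
                    f"{i + 1:>7d} {name:<8s}{x:>10.4f}{y:>10.4f}{z:>10.4f} "
                    f"{elem.capitalize():<6s}1 LIG 0.0000\n"
                )
            fh.write("@<TRIPOS>BOND\n")
            for bi, (i, j, order) in enumerate(topology.bonds):
                label = "ar" if order == 1.5 else str(int(order))
                fh.write(f"{bi + 1:>6d}{i + 1:>6d}{j + 1:>6d} {label}\n")


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------


def _automorphisms(topology: LigandTopology) -> list[dict[int, int]]:
    """Element-preserving automorphisms of the heavy-atom bond graph."""
    g = topology.graph(heavy_only=True)
    matcher = nx.isomorphism.GraphMatcher(
        g, g, node_match=lambda a, b: a["element"] == b["element"]
    )
    return [dict(m) for m in matcher.isomorphisms_iter()]


def ligand_rmsd(
    a: Pose,
    b: Pose,
    mapping: Sequence[tuple[int, int]] | None = None,
    symmetry_aware: bool = False,
) -> float:
    """Coordinate RMSD over mapped heavy atoms, with no refitting.

    Both poses must live in the common aligned receptor frame — pose overlap
    is positional, so superposing the ligands onto each other would defeat
    the comparison.  ``mapping`` is a list of (index_a, index_b) heavy-atom
    pairs; ``None`` means the identity over ``a``'s heavy atoms (same
    topology).  ``symmetry_aware=True`` minimizes the RMSD over the
    element-preserving automorphisms of the (shared) heavy-atom bond graph,
    which matters for ligands with topologically equivalent ends.
    """
    if a.frame != b.frame:
        raise PoseError(f"poses are in different frames: {a.frame!r} vs {b.frame!r}")
    if mapping is None:
        if a.topology is None:
            idx = tuple(range(len(a.coords)))
        else:
            idx = a.topology.heavy_atom_indices
        mapping = [(i, i) for i in idx]
    mapping = list(mapping)
    if len(mapping) < 3:
        raise PoseError("mapping must cover at least 3 heavy atoms")

    def _rmsd(pairs):
        ia = [p[0] for p in pairs]
        ib = [p[1] for p in pairs]
        d = a.coords[ia] - b.coords[ib]
        return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))

    if not symmetry_aware:
        return _rmsd(mapping)
    if a.topology is None:
        raise PoseError("symmetry-aware RMSD needs a topology")
    best = np.inf
    for auto in _automorphisms(a.topology):
        best = min(best, _rmsd([(i, auto[j]) for i, j in mapping]))
    return best


def _heavy_matrix(poses: Sequence[Pose], indices: Sequence[int] | None = None) -> np.ndarray:
    """Stack heavy-atom coordinates as (n_poses, 3 * n_heavy) rows."""
    rows = []
    for p in poses:
        c = p.coords[list(indices)] if indices is not None else p.heavy_coords()
        rows.append(c.ravel())
    return np.asarray(rows)


def rmsd_matrix(
    poses_a: Sequence[Pose],
    poses_b: Sequence[Pose] | None = None,
    mapping: Sequence[tuple[int, int]] | None = None,
) -> np.ndarray:
    """All-pairs in-frame heavy-atom RMSD, vectorized.

    Uses the expansion ``sum|x_i - y_i|^2 = |x|^2 + |y|^2 - 2 x.y`` on
    flattened heavy-atom coordinates; exactly equal to pairwise
    :func:`ligand_rmsd` calls.
    """
    if mapping is not None:
        ia = [p[0] for p in mapping]
        ib = [p[1] for p in mapping]
    else:
        ia = ib = None
    xa = _heavy_matrix(poses_a, ia)
    xb = xa if poses_b is None else _heavy_matrix(poses_b, ib)
    n_heavy = xa.shape[1] // 3
    sq_a = np.einsum("ij,ij->i", xa, xa)
    sq_b = np.einsum("ij,ij->i", xb, xb)
    d2 = sq_a[:, None] + sq_b[None, :] - 2.0 * (xa @ xb.T)
    return np.sqrt(np.maximum(d2, 0.0) / n_heavy)


# ---------------------------------------------------------------------------
# Filters and aggregation
# ---------------------------------------------------------------------------


def nonredundant_filter(
    poses: Sequence[Pose], rmsd_threshold: float = 2.0, cap: int = 5000
) -> list[Pose]:
    """Greedy best-first redundancy filter.

    ``poses`` must be sorted best-first.  A pose is kept iff its heavy-atom
    RMSD to every already-kept pose exceeds ``rmsd_threshold``; selection
    stops once ``cap`` poses are kept.  This mirrors the non-redundant pose
    collection of common docking engines (poses closer than the threshold to
    a better-scoring pose are the same binding mode).
    """
    if not poses:
        return []
    x = _heavy_matrix(poses)
    n_heavy = x.shape[1] // 3
    limit = min(cap, len(poses))
    kept_idx: list[int] = []
    kept_rows = np.empty((limit, x.shape[1]))
    thresh2 = rmsd_threshold**2 * n_heavy
    for i in range(len(poses)):
        k = len(kept_idx)
        if k:
            d2 = np.sum((kept_rows[:k] - x[i]) ** 2, axis=1)
            if np.min(d2) <= thresh2:
                continue
        kept_rows[k] = x[i]
        kept_idx.append(i)
        if len(kept_idx) >= cap:
            break
    return [poses[i] for i in kept_idx]


def topk(poses: Sequence[Pose], k: int = 10, score_direction: str = "lower") -> list[Pose]:
    """The ``k`` best-scoring poses (fewer if the deck is smaller); stable ties."""
    if k < 1:
        raise PoseError("k must be >= 1")
    sign = 1.0 if score_direction == "lower" else -1.0
    order = sorted(range(len(poses)), key=lambda i: (sign * poses[i].score, i))
    return [poses[i] for i in order[:k]]


def aggregate(
    per_search_tops: Iterable[Sequence[Pose]],
    ligand_id: str | None = None,
    ensemble_label: str | None = None,
    score_direction: str = "lower",
    norm_floor: float = 0.05,
) -> PoseAggregate:
    """Pool the per-search survivors of one (ligand, ensemble) and normalize scores.

    Scores are min-max normalized over the pooled aggregate: best raw score
    -> 1, worst -> ``norm_floor``; all-equal scores all -> 1.  Mixing ligands
    or ensembles in one aggregate is an error.
    """
    poses = list(itertools.chain.from_iterable(per_search_tops))
    if not poses:
        raise PoseError("nothing to aggregate")
    ligand_id = ligand_id or poses[0].ligand_id
    ensemble_label = ensemble_label if ensemble_label is not None else poses[0].ensemble_label
    for p in poses:
        if p.ligand_id != ligand_id:
            raise PoseError(f"mixed ligands in aggregate: {p.ligand_id!r} != {ligand_id!r}")
        if p.ensemble_label != ensemble_label:
            raise PoseError(
                f"mixed ensembles in aggregate: {p.ensemble_label!r} != {ensemble_label!r}"
            )
    scores = np.asarray([p.score for p in poses], dtype=float)
    quality = -scores if score_direction == "lower" else scores
    lo, hi = quality.min(), quality.max()
    if hi == lo:
        norm = np.ones_like(quality)
    else:
        norm = norm_floor + (1.0 - norm_floor) * (quality - lo) / (hi - lo)
    return PoseAggregate(
        ligand_id=ligand_id, ensemble_label=ensemble_label, poses=poses, norm_scores=norm
    )


def hotspot_spheres(agg: PoseAggregate, r_max: float = 2.0) -> list[HotspotSphere]:
    """One sphere per aggregated pose: center at the heavy-atom centroid,
    radius proportional to the normalized score (best pose -> ``r_max``)."""
    if r_max <= 0:
        raise PoseError("r_max must be positive")
    return [
        HotspotSphere(center=p.heavy_centroid(), radius=float(r_max * s))
        for p, s in zip(agg.poses, agg.norm_scores)
    ]


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def aggregate_to_frame(agg: PoseAggregate) -> pd.DataFrame:
    rows = []
    for p, s in zip(agg.poses, agg.norm_scores):
        cx, cy, cz = p.heavy_centroid()
        rows.append(
            dict(
                ligand=p.ligand_id, ensemble=p.ensemble_label, conformer=p.conformer_index,
                rank=p.rank, score=p.score, norm_score=float(s), cx=cx, cy=cy, cz=cz,
            )
        )
    return pd.DataFrame(rows)


def spheres_to_pdb(spheres: Sequence[HotspotSphere], path: str | Path) -> None:
    """Pseudo-atom PDB: one HETATM per sphere, radius in the B-factor column."""
    with open(path, "w") as fh:
        for i, s in enumerate(spheres, start=1):
            fh.write(
                f"HETATM{i % 100000:5d}  SPH HOT A{i % 10000:4d}    "
                f"{s.center[0]:8.3f}{s.center[1]:8.3f}{s.center[2]:8.3f}"
                f"{1.00:6.2f}{s.radius:6.2f}           C\n"
            )
        fh.write("END\n")
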