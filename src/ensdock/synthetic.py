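"""Deterministic synthetic fixtures for every pipeline stage.

The generators emulate the shapes of the real study inputs without any
physical realism: multi-domain toy proteins whose residues can be assigned to
named regions, conformer pairs with a rigidly displaced residue subset and a
known invariant set, Gaussian-noise trajectory snapshots, scored pose decks
with planted redundant clusters and planted cross-ensemble/cross-ligand
shared poses, and analog ligand pairs with a known common core.  Every
generator is a pure function of its arguments plus a seed: identical inputs
yield byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .poses import LigandTopology, Pose
from .structures import Atom, RegionMap, ResidueId, Structure
from .energetics import ParamTable


class SynthSpecError(ValueError):
    """A generator specification with an ambiguous or impossible ground truth."""


#: canonical region names cycled over toy-protein domains
_REGION_NAMES = ("NBD1", "ICL1", "ICL4", "NBD2", "ICL2", "ICL3")

#: atoms per toy residue: name, element, offset from the C-alpha (Angstroms)
_RESIDUE_TEMPLATE = (
    ("N", "N", (-1.2, 0.6, 0.0)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (1.3, 0.5, 0.0)),
    ("O", "O", (1.5, 1.7, 0.2)),
    ("CB", "C", (0.0, -1.0, 1.1)),
)


def make_toy_protein(
    n_domains: int = 6,
    residues_per_domain: int = 10,
    seed: int = 0,
    label: str = "toy",
    chain: str = "A",
) -> tuple[Structure, RegionMap]:
    """A helical multi-domain chain with region assignments.

    Each residue contributes five atoms (N, CA, C, O, CB) around an ideal
    C-alpha helix, with a small seeded perturbation so no two conformations
    built from different seeds coincide.  Domains are consecutive residue
    blocks named after the canonical six regions (NBD1, ICL1, ICL4, NBD2,
    ICL2, ICL3), then D7, D8, ... for extras.
    """
    rng = np.random.default_rng(seed)
    n_res = n_domains * residues_per_domain
    atoms: list[Atom] = []
    serial = 1
    for ires in range(n_res):
        theta = 100.0 * np.pi / 180.0 * ires
        ca = np.array([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * ires])
        ca = ca + rng.normal(0.0, 0.05, size=3)
        for name, elem, offset in _RESIDUE_TEMPLATE:
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=elem,
                    resname="ALA",
                    chain=chain,
                    resseq=ires + 1,
                    icode="",
                    coord=ca + np.asarray(offset),
                )
            )
            serial += 1
    regions = {}
    for d in range(n_domains):
        name = _REGION_NAMES[d] if d < len(_REGION_NAMES) else f"D{d + 1}"
        regions[name] = [(chain, d * residues_per_domain + 1, (d + 1) * residues_per_domain)]
    return Structure(label=label, atoms=atoms), RegionMap(regions)


def builtin_param_table(
    topology: LigandTopology | None = None,
    eps: float = 0.1,
    rmin_half: float = 1.9,
) -> ParamTable:
    """Minimal parameter table covering toy protein atoms and a ligand topology.

    Charges alternate +1/-1 e over atom names so synthetic complexes mix
    attraction and repulsion; epsilon 0.1 kcal/mol and Rmin/2 1.9 A for every
    atom.  Synthetic, not a force field.
    """
    entries = {}
    for i, (name, _, _) in enumerate(_RESIDUE_TEMPLATE):
        entries[("ALA", name)] = (1.0 if i % 2 == 0 else -1.0, eps, rmin_half)
    if topology is not None:
        for i, (name, _) in enumerate(topology.atoms):
            entries[("LIG", name.upper())] = (1.0 if i % 2 == 0 else -1.0, eps, rmin_half)
    return ParamTable(entries)


# ---------------------------------------------------------------------------
# Conformer pairs and snapshots
# ---------------------------------------------------------------------------


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def make_conformer_pair(
    n_domains: int = 6,
    residues_per_domain: int = 10,
    displaced: tuple[int, int] = (31, 40),
    displacement: tuple[float, float, float] = (5.0, 0.0, 0.0),
    threshold: float = 2.5,
    noise_sigma: float = 0.05,
    seed: int = 0,
) -> tuple[Structure, Structure, RegionMap, set[ResidueId]]:
    """Two conformers of a toy protein with a known invariant residue set.

    Conformer B equals A except residues ``displaced`` (inclusive resseq
    range) are rigidly translated by ``displacement``; every atom then gets
    Gaussian noise of ``noise_sigma`` and the whole of B undergoes a random
    rigid motion (invariance detection must undo it).  The ground-truth
    invariant set is every residue outside the displaced range.  The spec
    must be unambiguous: displaced residues must end at least 0.5 A beyond
    ``threshold`` and untouched residues at least 0.5 A inside it.
    """
    disp = np.asarray(displacement, dtype=float)
    margin = 0.5
    if np.linalg.norm(disp) > 0 and np.linalg.norm(disp) < threshold + margin:
        raise SynthSpecError(
            f"displacement {np.linalg.norm(disp):.2f} A is within {margin} A of the "
            f"threshold {threshold} A; ground truth would be ambiguous"
        )
    if noise_sigma * 6.0 > threshold - margin:
        raise SynthSpecError("noise_sigma too large for an unambiguous ground truth")

    a, region_map = make_toy_protein(n_domains, residues_per_domain, seed=seed, label="closed")
    rng = np.random.default_rng(seed + 1)
    lo, hi = displaced
    atoms_b = []
    for atom in a.atoms:
        coord = atom.coord.copy()
        if lo <= atom.resseq <= hi:
            coord = coord + disp
        coord = coord + rng.normal(0.0, noise_sigma, size=3)
        atoms_b.append(replace(atom, coord=coord))
    rot = _random_rotation(rng)
    shift = rng.uniform(-20.0, 20.0, size=3)
    for atom in atoms_b:
        atom.coord = rot @ atom.coord + shift
    b = Structure(label="open", atoms=atoms_b)
    if np.linalg.norm(disp) == 0:
        truth = set(a.residue_ids())
    else:
        truth = {r for r in a.residue_ids() if not lo <= r[1] <= hi}
    return a, b, region_map, truth


def make_snapshots(
    parent: Structure,
    sigma: float,
    times: list[float],
    seed: int = 0,
) -> list[Structure]:
    """Trajectory-like frames: i.i.d. Gaussian coordinate noise per atom per frame."""
    if sigma < 0:
        raise SynthSpecError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    frames = []
    for t in times:
        noise = rng.normal(0.0, sigma, size=(len(parent.atoms), 3)) if sigma > 0 else 0.0
        atoms = [
            replace(a, coord=a.coord + (noise[i] if sigma > 0 else 0.0))
            for i, a in enumerate(parent.atoms)
        ]
        frames.append(
            Structure(
                label=f"{parent.label}@{t:g}ns", atoms=atoms, provenance="snapshot", time_ns=t
            )
        )
    return frames


# ---------------------------------------------------------------------------
# Toy ligands
# ---------------------------------------------------------------------------

#: aperiodic element sequence for asymmetric cores (no nontrivial automorphism)
_CORE_ELEMENTS = ("C", "N", "C", "O", "C", "S", "C", "P", "C", "B")


@dataclass(frozen=True)
class ToyLigandPair:
    """Two analog topologies sharing a labeled core, with template geometries."""

    topology_a: LigandTopology
    topology_b: LigandTopology
    coords_a: np.ndarray
    coords_b: np.ndarray
    core_mapping: tuple[tuple[int, int], ...]


def _chain_coords(n: int, rng: np.random.Generator, start=None, step: float = 1.5) -> np.ndarray:
    coords = [np.zeros(3) if start is None else np.asarray(start, float)]
    for _ in range(n - 1):
        d = rng.normal(size=3)
        d = d / np.linalg.norm(d) * step
        coords.append(coords[-1] + d)
    return np.asarray(coords)


def make_toy_ligand(n_atoms: int = 12, seed: int = 0, ligand_id: str = "toy") -> tuple[LigandTopology, np.ndarray]:
    """A single chain-shaped heavy-atom topology with a random-walk geometry."""
    rng = np.random.default_rng(seed)
    elements = [_CORE_ELEMENTS[i % len(_CORE_ELEMENTS)] for i in range(n_atoms)]
    atoms = tuple((f"{e}{i + 1}", e) for i, e in enumerate(elements))
    bonds = tuple((i, i + 1, 1.0) for i in range(n_atoms - 1))
    return LigandTopology(ligand_id, atoms, bonds), _chain_coords(n_atoms, rng)


def make_toy_ligands(
    core_size: int = 6,
    decoration_sizes: tuple[int, int] = (2, 3),
    seed: int = 0,
    ids: tuple[str, str] = ("analog", "tautomer"),
) -> ToyLigandPair:
    """Two analog ligands built from an identical labeled core plus distinct tails.

    The core is a chain with an asymmetric element sequence (its only
    element-preserving automorphism is the identity), so the core mapping is
    unique.  Ligand A's decoration atoms are fluorine and ligand B's are
    chlorine — elements absent from the core — so no maximum-common-
    substructure search can extend beyond the planted core.  Both ligands
    share identical core coordinates in their template geometries.
    """
    if core_size < 3:
        raise SynthSpecError("core_size must be >= 3")
    if core_size > len(_CORE_ELEMENTS):
        raise SynthSpecError(f"core_size must be <= {len(_CORE_ELEMENTS)}")
    core_elems = list(_CORE_ELEMENTS[:core_size])
    if core_elems == core_elems[::-1]:  # guaranteed by the aperiodic sequence
        raise SynthSpecError("core element sequence is palindromic; core would be symmetric")
    rng = np.random.default_rng(seed)
    core_coords = _chain_coords(core_size, rng)

    def build(deco_n: int, deco_elem: str, lig_id: str):
        elements = core_elems + [deco_elem] * deco_n
        atoms = tuple((f"{e}{i + 1}", e) for i, e in enumerate(elements))
        bonds = [(i, i + 1, 1.0) for i in range(core_size - 1)]
        # decoration chain hangs off the last core atom
        prev = core_size - 1
        for k in range(deco_n):
            bonds.append((prev, core_size + k, 1.0))
            prev = core_size + k
        deco_coords = (
            _chain_coords(deco_n + 1, rng, start=core_coords[-1])[1:]
            if deco_n
            else np.empty((0, 3))
        )
        coords = np.vstack([core_coords, deco_coords])
        return LigandTopology(lig_id, atoms, tuple(bonds)), coords

    topo_a, coords_a = build(decoration_sizes[0], "F", ids[0])
    topo_b, coords_b = build(decoration_sizes[1], "CL", ids[1])
    mapping = tuple((i, i) for i in range(core_size))
    return ToyLigandPair(topo_a, topo_b, coords_a, coords_b, mapping)


# ---------------------------------------------------------------------------
# Pose decks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedSite:
    """A planted pose cluster: shared across decks when the same site is reused.

    The cluster orientation derives from ``orientation_seed`` (not the deck
    seed), so planting one site into the decks of two ensembles — or of two
    analog ligands sharing core coordinates — produces poses that coincide
    within ``2 * jitter``.
    """

    center: tuple[float, float, float]
    n_members: int = 1
    jitter: float = 0.5
    orientation_seed: int = 0


def make_pose_deck(
    topology: LigandTopology,
    template_coords: np.ndarray,
    n: int,
    score_mu: float = -80.0,
    score_sd: float = 5.0,
    planted: tuple[PlantedSite, ...] = (),
    box: float = 60.0,
    box_center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    seed: int = 0,
    ensemble_label: str = "",
    conformer_index: int = 0,
    score_direction: str = "lower",
) -> list[Pose]:
    """A scored deck of rigid-body placements of one ligand.

    Decoy poses get uniform random centers in a cube of side ``box`` and
    random orientations, with Gaussian scores N(mu, sd).  Planted clusters
    are placed around their site centers with translational jitter of
    magnitude <= ``jitter`` and site-determined orientation, and receive
    scores 5 sd better than the decoy mean so they survive top-k selection.
    Deterministic under ``seed``.
    """
    n_planted = sum(site.n_members for site in planted)
    if n_planted > n:
        raise SynthSpecError(f"{n_planted} planted poses exceed deck size {n}")
    rng = np.random.default_rng(seed)
    template = np.asarray(template_coords, dtype=float)
    centered = template - template.mean(axis=0)
    better = -1.0 if score_direction == "lower" else 1.0

    poses: list[Pose] = []
    for site in planted:
        rot = _random_rotation(np.random.default_rng(site.orientation_seed))
        # rotate the raw template (not re-centered): analog ligands share core
        # coordinates in the template frame, so reusing a site across their
        # decks makes the planted cores coincide.
        oriented = template @ rot.T
        for _ in range(site.n_members):
            if site.jitter > 0:
                d = rng.normal(size=3)
                shift = d / np.linalg.norm(d) * rng.uniform(0.0, site.jitter)
            else:
                shift = np.zeros(3)
            coords = oriented + np.asarray(site.center) + shift
            score = score_mu + better * 5.0 * score_sd + rng.normal(0.0, 0.2 * score_sd)
            poses.append(
                Pose(
                    ligand_id=topology.ligand_id,
                    coords=coords,
                    score=float(score),
                    topology=topology,
                    ensemble_label=ensemble_label,
                    conformer_index=conformer_index,
                )
            )
    for _ in range(n - n_planted):
        rot = _random_rotation(rng)
        center = np.asarray(box_center) + rng.uniform(-box / 2.0, box / 2.0, size=3)
        coords = centered @ rot.T + center
        poses.append(
            Pose(
                ligand_id=topology.ligand_id,
                coords=coords,
                score=float(rng.normal(score_mu, score_sd)),
                topology=topology,
                ensemble_label=ensemble_label,
                conformer_index=conformer_index,
            )
        )
    sign = 1.0 if score_direction == "lower" else -1.0
    poses.sort(key=lambda p: sign * p.score)
    for rank, p in enumerate(poses, start=1):
        p.rank = rank
    return poses
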