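"""Nonbonded protein-ligand interaction energies with per-region decomposition.

Energies follow the CHARMM nonbonded conventions: a 12-6 Lennard-Jones term

    E_LJ = eps_ij [ (Rmin_ij / r)^12 - 2 (Rmin_ij / r)^6 ]

with Lorentz-Berthelot-style combination rules eps_ij = sqrt(eps_i eps_j) and
Rmin_ij = rmin_half_i + rmin_half_j, and a Coulomb term

    E_coul = k q_i q_j / (dielectric * r),   k = 332.0636 kcal*A/(mol*e^2).

Both terms are multiplied by the CHARMM switching polynomial, which is 1 up to
the switch-on distance (default 10 A), 0 beyond the cutoff (default 12 A),
and C1-continuous in between — so every pair energy beyond the cutoff is
exactly zero and any neighbor-list radius >= cutoff gives identical results.

The decomposition assigns each protein atom to a named region (e.g. NBD1,
NBD2, ICL1-ICL4); atoms in no region accumulate into a synthetic "other"
record, so region totals always sum to the whole-protein interaction energy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .poses import LigandTopology, Pose
from .structures import RegionMap, ResidueId, Structure, StructureError

COULOMB_K = 332.0636  # kcal*A/(mol*e^2)

#: nucleophilic side-chain atoms scanned for proximity to electrophilic ligand atoms
NUCLEOPHILE_ATOMS = {
    "SER": ("OG",),
    "CYS": ("SG",),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
}


class EnergeticsError(ValueError):
    """Missing parameters or inconsistent energetics input."""


@dataclass(frozen=True)
class NonbondedOptions:
    """Global nonbonded settings.

    ``switch_on`` and ``cutoff`` in Angstroms; ``dielectric`` dimensionless
    (1 mirrors explicit-solvent trajectory energy tools); switching applies
    multiplicatively to both the Lennard-Jones and Coulomb terms.
    """

    dielectric: float = 1.0
    switch_on: float = 10.0
    cutoff: float = 12.0
    coulomb_k: float = COULOMB_K
    switching: bool = True

    def __post_init__(self) -> None:
        if self.switching and not self.switch_on < self.cutoff:
            raise EnergeticsError("switch_on must be < cutoff")


@dataclass(frozen=True)
class InteractionEnergyRecord:
    """Ligand-region interaction energy at one frame, kcal/mol."""

    frame_time: float
    region: str
    e_lj: float
    e_coul: float

    @property
    def e_total(self) -> float:
        return self.e_lj + self.e_coul


def switching_factor(r: np.ndarray | float, options: NonbondedOptions) -> np.ndarray | float:
    """CHARMM switching polynomial: 1 below switch-on, 0 beyond cutoff,
    (c^2-r^2)^2 (c^2+2r^2-3 s^2) / (c^2-s^2)^3 in between."""
    if not options.switching:
        return np.ones_like(np.asarray(r, dtype=float))
    r = np.asarray(r, dtype=float)
    c2 = options.cutoff**2
    s2 = options.switch_on**2
    r2 = r * r
    mid = (c2 - r2) ** 2 * (c2 + 2.0 * r2 - 3.0 * s2) / (c2 - s2) ** 3
    return np.where(r <= options.switch_on, 1.0, np.where(r >= options.cutoff, 0.0, mid))


def _pair_terms(q1, eps1, rh1, q2, eps2, rh2, r, options: NonbondedOptions):
    """Vectorized LJ/Coulomb pair terms with switching; r is broadcastable."""
    r = np.asarray(r, dtype=float)
    eps_ij = np.sqrt(np.abs(eps1) * np.abs(eps2))
    rmin_ij = rh1 + rh2
    ratio6 = (rmin_ij / r) ** 6
    e_lj = eps_ij * (ratio6 * ratio6 - 2.0 * ratio6)
    e_coul = options.coulomb_k * q1 * q2 / (options.dielectric * r)
    s = switching_factor(r, options)
    cut = r < options.cutoff if options.switching else np.ones(r.shape, dtype=bool)
    return np.where(cut, e_lj * s, 0.0), np.where(cut, e_coul * s, 0.0)


def pair_energy(atom_i, atom_j, options: NonbondedOptions = NonbondedOptions()) -> tuple[float, float]:
    """(E_LJ, E_coul) in kcal/mol for one atom pair.

    Atoms must carry ``charge``, ``eps`` and ``rmin_half``; epsilon is stored
    positive (well depth magnitude).
    """
    for atom in (atom_i, atom_j):
        if atom.charge is None or atom.eps is None or atom.rmin_half is None:
            raise EnergeticsError(
                f"atom {atom.name!r} of {atom.resname}/{atom.resseq} lacks nonbonded parameters"
            )
    r = float(np.linalg.norm(np.asarray(atom_i.coord) - np.asarray(atom_j.coord)))
    if r <= 0:
        raise EnergeticsError("pair distance must be positive")
    e_lj, e_coul = _pair_terms(
        atom_i.charge, atom_i.eps, atom_i.rmin_half,
        atom_j.charge, atom_j.eps, atom_j.rmin_half,
        r, options,
    )
    return float(e_lj), float(e_coul)


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------


class ParamTable:
    """Per-atom nonbonded parameters keyed by (residue name, atom name)."""

    def __init__(self, entries: dict[tuple[str, str], tuple[float, float, float]]):
        self.entries = dict(entries)

    @classmethod
    def from_file(cls, path: str | Path) -> "ParamTable":
        """Whitespace-delimited table: resname atom_name charge eps rmin_half."""
        entries = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5:
                raise EnergeticsError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            resname, name = parts[0].upper(), parts[1].upper()
            entries[(resname, name)] = (float(parts[2]), abs(float(parts[3])), float(parts[4]))
        return cls(entries)

    def to_file(self, path: str | Path) -> None:
        lines = ["# resname atom charge eps rmin_half"]
        for (resname, name), (q, eps, rh) in sorted(self.entries.items()):
            lines.append(f"{resname} {name} {q:.4f} {eps:.4f} {rh:.4f}")
        Path(path).write_text("\n".join(lines) + "\n")

    def lookup(self, resname: str, atom_name: str, strict: bool = True):
        key = (resname.upper(), atom_name.upper())
        if key not in self.entries:
            if strict:
                raise EnergeticsError(f"no parameters for atom {atom_name!r} in {resname!r}")
            return None
        return self.entries[key]

    def assign(self, structure: Structure, strict: bool = True) -> Structure:
        """Return a copy of ``structure`` with charge/eps/rmin_half filled in."""
        from dataclasses import replace

        atoms = []
        for a in structure.atoms:
            params = self.lookup(a.resname, a.name, strict=strict)
            if params is None:
                atoms.append(replace(a, coord=a.coord.copy()))
            else:
                q, eps, rh = params
                atoms.append(replace(a, coord=a.coord.copy(), charge=q, eps=eps, rmin_half=rh))
        return Structure(structure.label, atoms, structure.provenance, structure.time_ns)

    def for_topology(
        self, topology: LigandTopology, resname: str = "LIG", strict: bool = True
    ) -> np.ndarray:
        """(n_atoms, 3) array of (charge, eps, rmin_half) for a ligand topology."""
        rows = []
        for name, _ in topology.atoms:
            params = self.lookup(resname, name, strict=strict)
            if params is None:
                raise EnergeticsError(f"no ligand parameters for atom {name!r}")
            rows.append(params)
        return np.asarray(rows, dtype=float)


# ---------------------------------------------------------------------------
# Region decomposition
# ---------------------------------------------------------------------------


def _structure_params(structure: Structure) -> np.ndarray:
    rows = []
    for a in structure.atoms:
        if a.charge is None or a.eps is None or a.rmin_half is None:
            raise EnergeticsError(
                f"protein atom {a.name!r} of {a.resname}/{a.resseq} lacks nonbonded parameters"
            )
        rows.append((a.charge, a.eps, a.rmin_half))
    return np.asarray(rows, dtype=float)


def region_interaction_energy(
    frame: Structure,
    ligand_pose: Pose,
    ligand_params: np.ndarray,
    regions: RegionMap,
    options: NonbondedOptions = NonbondedOptions(),
) -> list[InteractionEnergyRecord]:
    """Ligand-protein interaction energy decomposed by named protein region.

    Returns one record per region in the map's order plus an ``other`` record
    for protein atoms outside every named region; by construction the records
    sum exactly to the whole-protein interaction energy.  ``ligand_params``
    is the (n_atoms, 3) charge/eps/rmin_half array for the pose's atoms.
    """
    names = regions.names()
    region_residues = {name: regions.residues(name, frame) for name in names}
    assignment = np.full(len(frame.atoms), len(names), dtype=int)  # default: "other"
    for k, name in enumerate(names):
        members = region_residues[name]
        for i, a in enumerate(frame.atoms):
            if a.residue_id in members:
                assignment[i] = k

    prot_params = _structure_params(frame)
    lig = np.asarray(ligand_params, dtype=float)
    if lig.shape != (len(ligand_pose.coords), 3):
        raise EnergeticsError("ligand_params must be (n_ligand_atoms, 3)")

    # pairwise distances protein x ligand
    diff = frame.coords[:, None, :] - ligand_pose.coords[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=2))
    e_lj, e_coul = _pair_terms(
        prot_params[:, 0:1], prot_params[:, 1:2], prot_params[:, 2:3],
        lig[None, :, 0], lig[None, :, 1], lig[None, :, 2],
        r, options,
    )
    lj_per_atom = e_lj.sum(axis=1)
    coul_per_atom = e_coul.sum(axis=1)

    t = frame.time_ns if frame.time_ns is not None else 0.0
    records = []
    for k, name in enumerate(list(names) + ["other"]):
        mask = assignment == k
        records.append(
            InteractionEnergyRecord(
                frame_time=t,
                region=name,
                e_lj=float(lj_per_atom[mask].sum()),
                e_coul=float(coul_per_atom[mask].sum()),
            )
        )
    return records


def energy_timeseries(
    frames: Sequence[Structure],
    poses_per_frame: Sequence[Pose],
    ligand_params: np.ndarray,
    regions: RegionMap,
    options: NonbondedOptions = NonbondedOptions(),
) -> list[InteractionEnergyRecord]:
    """Per-region interaction energies over a trajectory, sorted by time then region."""
    if len(frames) != len(poses_per_frame):
        raise EnergeticsError(
            f"{len(frames)} frames but {len(poses_per_frame)} poses"
        )
    records: list[InteractionEnergyRecord] = []
    for frame, pose in zip(frames, poses_per_frame):
        records.extend(region_interaction_energy(frame, pose, ligand_params, regions, options))
    order = {name: i for i, name in enumerate(regions.names() + ["other"])}
    records.sort(key=lambda rec: (rec.frame_time, order[rec.region]))
    return records


def records_to_frame(records: Sequence[InteractionEnergyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(time_ns=r.frame_time, region=r.region, e_lj=r.e_lj,
                 e_coul=r.e_coul, e_total=r.e_total)
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# Contacts and nucleophile proximity
# ---------------------------------------------------------------------------


def contact_residues(
    frame: Structure, ligand_pose: Pose, cutoff: float = 4.0
) -> set[ResidueId]:
    """Residues with >=1 heavy atom within ``cutoff`` of >=1 ligand heavy atom."""
    if cutoff <= 0:
        raise EnergeticsError("cutoff must be positive")
    heavy_idx = [i for i, a in enumerate(frame.atoms) if not a.is_hydrogen]
    if not heavy_idx:
        return set()
    lig = ligand_pose.heavy_coords()
    prot = frame.coords[heavy_idx]
    d2 = np.sum((prot[:, None, :] - lig[None, :, :]) ** 2, axis=2)
    close = np.min(d2, axis=1) <= cutoff**2
    return {frame.atoms[i].residue_id for i, hit in zip(heavy_idx, close) if hit}


def nucleophile_proximity(
    frame: Structure,
    ligand_pose: Pose,
    electrophile_atoms: Sequence[int],
    cutoff: float = 5.0,
) -> list[tuple[ResidueId, str, str, float]]:
    """Nucleophilic side chains near designated electrophilic ligand atoms.

    Scans Ser OG, Cys SG, His ND1/NE2 and Lys NZ; returns
    ``(residue_id, resname, atom_name, min_distance)`` for every nucleophilic
    atom within ``cutoff`` of any electrophilic ligand atom, sorted by
    distance.  Purely geometric — protonation states are not modeled.
    """
    if cutoff <= 0:
        return []
    for i in electrophile_atoms:
        if not 0 <= i < len(ligand_pose.coords):
            raise EnergeticsError(f"electrophile atom index {i} out of range")
    elec = ligand_pose.coords[list(electrophile_atoms)]
    hits = []
    for i, a in enumerate(frame.atoms):
        wanted = NUCLEOPHILE_ATOMS.get(a.resname.upper())
        if not wanted or a.name.upper() not in wanted:
            continue
        d = float(np.min(np.linalg.norm(elec - frame.coords[i], axis=1)))
        if d <= cutoff:
            hits.append((a.residue_id, a.resname, a.name, d))
    hits.sort(key=lambda h: h[3])
    return hits
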