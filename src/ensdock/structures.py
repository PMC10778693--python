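"""Structure containers, PDB/PQR input, and rigid-body superposition.

The unit of analysis is a :class:`Structure`: an ordered atom table with
coordinates in Angstroms, residue identity ``(chain, resseq, icode)``, and
optional per-atom nonbonded parameters (charge, Lennard-Jones epsilon and
Rmin/2).  Receptor conformers of the same protein share residue numbering, so
atoms are matched across conformers by residue identity — never by sequence
alignment.

Superposition is the closed-form least-squares (Kabsch) fit on C-alpha atoms.
Conformationally invariant regions between two conformers are the residues
whose C-alpha atoms remain within a distance threshold after superposing on a
reference region (by convention the first nucleotide-binding domain, NBD1).
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: residue identity within and across conformers
ResidueId = tuple[str, int, str]


class StructureError(ValueError):
    """Malformed structure input or an invalid structural operation."""


class DegenerateSelectionError(StructureError):
    """Superposition selection with <3 pairs or collinear geometry."""


@dataclass
class Atom:
    """One atom record.

    ``charge`` is in elementary charge units, ``eps`` in kcal/mol (stored
    positive), ``rmin_half`` in Angstroms; all three are optional and only
    needed for energetics.
    """

    serial: int
    name: str
    element: str
    resname: str
    chain: str
    resseq: int
    icode: str
    coord: np.ndarray
    charge: float | None = None
    eps: float | None = None
    rmin_half: float | None = None

    @property
    def residue_id(self) -> ResidueId:
        return (self.chain, self.resseq, self.icode)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Structure:
    """An ordered atom collection with a provenance tag.

    ``provenance`` is one of ``parent`` (experimental structure), ``minimized``
    or ``snapshot``; snapshots carry ``time_ns``.  Structures are treated as
    immutable after construction: transforms return new instances.
    """

    label: str
    atoms: list[Atom]
    provenance: str = "parent"
    time_ns: float | None = None
    _coords: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(f"structure {self.label!r} has no atoms")
        coords = np.asarray([a.coord for a in self.atoms], dtype=float)
        if not np.isfinite(coords).all():
            raise StructureError(f"structure {self.label!r} has non-finite coordinates")
        self._coords = coords

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Angstroms."""
        return self._coords

    def residue_ids(self) -> list[ResidueId]:
        """Unique residue identities in first-atom order."""
        seen: dict[ResidueId, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_id, None)
        return list(seen)

    def ca_index(self) -> dict[ResidueId, int]:
        """Map residue identity -> atom index of its C-alpha (hydrogens ignored)."""
        out: dict[ResidueId, int] = {}
        for i, a in enumerate(self.atoms):
            if a.name == "CA" and not a.is_hydrogen:
                out.setdefault(a.residue_id, i)
        return out

    def atom_index(self) -> dict[tuple[ResidueId, str], int]:
        return {(a.residue_id, a.name): i for i, a in enumerate(self.atoms)}

    def transformed(self, transform: "RigidTransform", label: str | None = None) -> "Structure":
        """Return a copy with ``transform`` applied to every coordinate."""
        new_coords = transform.apply(self.coords)
        atoms = [replace(a, coord=new_coords[i]) for i, a in enumerate(self.atoms)]
        return Structure(
            label=label if label is not None else self.label,
            atoms=atoms,
            provenance=self.provenance,
            time_ns=self.time_ns,
        )

    def with_provenance(self, provenance: str, time_ns: float | None = None) -> "Structure":
        atoms = [replace(a, coord=a.coord.copy()) for a in self.atoms]
        return Structure(self.label, atoms, provenance=provenance, time_ns=time_ns)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> rotation @ x + translation``.

    ``rmsd`` is the post-fit RMSD (Angstroms) over the selection the transform
    was fitted on.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-6):
            raise StructureError("rotation must be proper (det = +1)")
        if self.rmsd < 0:
            raise StructureError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), 0.0)


class RegionMap:
    """Named residue regions as chain + inclusive residue ranges.

    Regions must be pairwise disjoint.  For energy decomposition at least the
    six canonical regions (NBD1, NBD2, ICL1-ICL4) are expected, but any names
    are accepted.
    """

    def __init__(self, regions: dict[str, list[tuple[str, int, int]]]):
        self.regions = {name: [tuple(r) for r in ranges] for name, ranges in regions.items()}
        self._check_disjoint()

    def _check_disjoint(self) -> None:
        seen: dict[tuple[str, int], str] = {}
        for name, ranges in self.regions.items():
            for chain, start, end in ranges:
                if end < start:
                    raise StructureError(f"region {name!r}: range {start}-{end} is inverted")
                for resseq in range(start, end + 1):
                    key = (chain, resseq)
                    if key in seen and seen[key] != name:
                        raise StructureError(
                            f"regions {seen[key]!r} and {name!r} overlap at {chain}/{resseq}"
                        )
                    seen[key] = name

    def names(self) -> list[str]:
        return list(self.regions)

    def region_of(self, residue_id: ResidueId) -> str | None:
        chain, resseq, _ = residue_id
        for name, ranges in self.regions.items():
            for rchain, start, end in ranges:
                if chain == rchain and start <= resseq <= end:
                    return name
        return None

    def residues(self, name: str, structure: Structure) -> set[ResidueId]:
        """Residue identities of ``name`` present in ``structure``.

        Every residue referenced by the region definition must exist in the
        structure.
        """
        ranges = self.regions[name]
        present = set(structure.residue_ids())
        by_key: dict[tuple[str, int], list[ResidueId]] = {}
        for rid in present:
            by_key.setdefault((rid[0], rid[1]), []).append(rid)
        out: set[ResidueId] = set()
        for chain, start, end in ranges:
            for resseq in range(start, end + 1):
                hits = by_key.get((chain, resseq))
                if not hits:
                    raise StructureError(
                        f"region residue {chain}/{resseq} not found in structure "
                        f"{structure.label!r}"
                    )
                out.update(hits)
        return out

    def to_dict(self) -> dict:
        return {name: [list(r) for r in ranges] for name, ranges in self.regions.items()}

    @classmethod
    def from_dict(cls, data: dict) -> "RegionMap":
        return cls({name: [tuple(r) for r in ranges] for name, ranges in data.items()})


# ---------------------------------------------------------------------------
# File input
# ---------------------------------------------------------------------------


def _prescan_pdb(path: Path) -> None:
    """Fail fast with a line number on unparseable coordinate records."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise StructureError(f"{path}:{lineno}: truncated coordinate record")
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                    int(line[22:26])
                except ValueError as exc:
                    raise StructureError(f"{path}:{lineno}: malformed record ({exc})") from exc


def read_structures(path: str | Path, format: str | None = None) -> list[Structure]:
    """Read a PDB or PQR file; one :class:`Structure` per MODEL.

    ``format`` is ``"PDB"`` or ``"PQR"``; by default it is inferred from the
    suffix.  PQR files populate ``Atom.charge`` and set ``rmin_half`` from the
    radius column.  For disordered atoms the highest-occupancy alternate
    location is kept (first on tie).  Hydrogens are retained.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if path.stat().st_size == 0:
        raise StructureError(f"{path}: empty file")
    fmt = (format or ("PQR" if path.suffix.lower() == ".pqr" else "PDB")).upper()
    if fmt not in ("PDB", "PQR"):
        raise StructureError(f"unknown structure format {fmt!r}")
    if fmt == "PDB":
        _prescan_pdb(path)

    parser = PDBParser(PERMISSIVE=False, QUIET=True, is_pqr=(fmt == "PQR"))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises PDBConstructionException subclasses
        raise StructureError(f"{path}: parse error: {exc}") from exc

    structures = []
    for model in bio:
        atoms: list[Atom] = []
        for chain in model:
            for residue in chain:
                _, resseq, icode = residue.id
                for atom in residue:  # DisorderedAtom yields highest-occupancy child
                    element = (atom.element or "").strip() or atom.get_name()[0]
                    atoms.append(
                        Atom(
                            serial=atom.serial_number or len(atoms) + 1,
                            name=atom.get_name(),
                            element=element.upper(),
                            resname=residue.resname.strip(),
                            chain=chain.id,
                            resseq=resseq,
                            icode=icode.strip(),
                            coord=np.asarray(atom.coord, dtype=float),
                            charge=atom.get_charge() if fmt == "PQR" else None,
                            rmin_half=atom.get_radius() if fmt == "PQR" else None,
                        )
                    )
        if not atoms:
            continue
        label = path.stem if len(bio) == 1 else f"{path.stem}/model{model.id + 1}"
        structures.append(Structure(label=label, atoms=atoms))
    if not structures:
        raise StructureError(f"{path}: no atoms found")
    return structures


def read_structure(path: str | Path, format: str | None = None) -> Structure:
    """Read a single-model PDB/PQR file; error if it contains several models."""
    models = read_structures(path, format=format)
    if len(models) != 1:
        raise StructureError(
            f"{path}: {len(models)} models present; use read_structures() for multi-model files"
        )
    return models[0]


def write_pdb(structures: Structure | Sequence[Structure], path: str | Path) -> None:
    """Write one or more structures as (multi-model) PDB."""
    if isinstance(structures, Structure):
        structures = [structures]
    multi = len(structures) > 1
    with open(path, "w") as handle:
        for imodel, s in enumerate(structures, start=1):
            if multi:
                handle.write(f"MODEL     {imodel:4d}\n")
            for i, a in enumerate(s.atoms, start=1):
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                handle.write(
                    f"ATOM  {i % 100000:5d} {name:<4.4s} {a.resname:<3.3s} "
                    f"{a.chain[:1]}{a.resseq:4d}{(a.icode or ' '):1s}   "
                    f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2.2s}\n"
                )
            if multi:
                handle.write("ENDMDL\n")
        handle.write("END\n")


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------


def _matched_ca_pairs(
    mobile: Structure,
    reference: Structure,
    selection: Iterable[ResidueId] | None,
) -> tuple[np.ndarray, np.ndarray]:
    ca_m = mobile.ca_index()
    ca_r = reference.ca_index()
    if selection is None:
        residues = sorted(set(ca_m) & set(ca_r))
    else:
        residues = sorted(set(selection))
        missing = [r for r in residues if r not in ca_m or r not in ca_r]
        if missing:
            raise StructureError(
                "selection residues missing a matched C-alpha in both structures: "
                + ", ".join(f"{c}/{s}{i}" for c, s, i in missing[:10])
            )
    if len(residues) < 3:
        raise DegenerateSelectionError(f"need >=3 matched C-alpha pairs, got {len(residues)}")
    p = mobile.coords[[ca_m[r] for r in residues]]
    q = reference.coords[[ca_r[r] for r in residues]]
    return p, q


def kabsch_fit(mobile_points: np.ndarray, reference_points: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid fit of ``mobile_points`` onto ``reference_points``.

    Closed-form solution via SVD of the cross-covariance matrix, with the
    reflection corrected to a proper rotation.
    """
    p = np.asarray(mobile_points, float)
    q = np.asarray(reference_points, float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise StructureError("point sets must both be (n, 3)")
    if len(p) < 3:
        raise DegenerateSelectionError(f"need >=3 points, got {len(p)}")
    cp, cq = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - cp, q - cq
    if min(np.linalg.matrix_rank(p0, tol=1e-8), np.linalg.matrix_rank(q0, tol=1e-8)) < 2:
        raise DegenerateSelectionError("selection is collinear; rotation is underdetermined")
    h = p0.T @ q0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cq - rot @ cp
    fitted = p @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - q) ** 2, axis=1))))
    return RigidTransform(rotation=rot, translation=trans, rmsd=rmsd)


def kabsch_superpose(
    mobile: Structure,
    reference: Structure,
    selection: Iterable[ResidueId] | None = None,
) -> RigidTransform:
    """Fit ``mobile`` onto ``reference`` over the C-alpha atoms of ``selection``.

    ``selection`` is a set of residue identities matched across the two
    structures; ``None`` uses all shared C-alpha residues.  The mobile
    structure is not modified; apply the transform with
    :meth:`Structure.transformed`.
    """
    p, q = _matched_ca_pairs(mobile, reference, selection)
    return kabsch_fit(p, q)


def detect_invariant_residues(
    a: Structure,
    b: Structure,
    fit_selection: Iterable[ResidueId] | None = None,
    threshold: float = 2.5,
    region_map: RegionMap | None = None,
    fit_region: str = "NBD1",
) -> set[ResidueId]:
    """Residues whose C-alpha atoms overlap within ``threshold`` Angstroms.

    ``b`` is superposed onto ``a`` using the C-alpha atoms of
    ``fit_selection`` (or of the region named ``fit_region`` in
    ``region_map``, NBD1 by default); then every residue shared by both
    structures whose post-fit C-alpha distance is <= ``threshold`` (inclusive)
    is returned.  Residues lacking a C-alpha are skipped with a warning.
    """
    if threshold <= 0:
        raise StructureError("threshold must be positive")
    if fit_selection is None and region_map is not None:
        fit_selection = region_map.residues(fit_region, a)
    transform = kabsch_superpose(b, a, selection=fit_selection)
    ca_a, ca_b = a.ca_index(), b.ca_index()
    shared_residues = set(a.residue_ids()) & set(b.residue_ids())
    no_ca = [r for r in shared_residues if r not in ca_a or r not in ca_b]
    if no_ca:
        logger.warning("skipping %d shared residue(s) lacking a C-alpha atom", len(no_ca))
    residues = sorted(shared_residues - set(no_ca))
    pa = a.coords[[ca_a[r] for r in residues]]
    pb = transform.apply(b.coords[[ca_b[r] for r in residues]])
    dist = np.linalg.norm(pa - pb, axis=1)
    return {r for r, d in zip(residues, dist) if d <= threshold}


def align_targets(
    targets: Sequence[Structure],
    reference: Structure,
    selection: Iterable[ResidueId] | None = None,
) -> list[Structure]:
    """Superpose every target onto ``reference`` over ``selection`` C-alphas.

    Returns transformed copies in the reference frame; input order and count
    are preserved.
    """
    selection = set(selection) if selection is not None else None
    return [t.transformed(kabsch_superpose(t, reference, selection)) for t in targets]
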