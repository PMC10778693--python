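"""Receptor conformer ensembles and docking-task bookkeeping.

An ensemble represents one channel state (e.g. closed, open, open without
NBD2) by an ordered set of conformers: the experimental parent structure, an
optionally energy-minimized copy, and trajectory snapshots taken at regular
time intervals.  Docking tasks are the cartesian product of ligands with
every conformer of every ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import RegionMap, Structure, StructureError

#: standard atomic masses (amu) for the mass-weighted center option
_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "B": 10.81,
}


class EnsembleError(ValueError):
    """Invalid ensemble composition or snapshot selection."""


@dataclass
class ConformerEnsemble:
    """Ordered conformers for one channel state.

    Exactly one ``parent`` conformer, at most one ``minimized``, and snapshot
    times strictly increasing.
    """

    state_label: str
    conformers: list[Structure]

    def __post_init__(self) -> None:
        tags = [c.provenance for c in self.conformers]
        if tags.count("parent") != 1:
            raise EnsembleError(
                f"ensemble {self.state_label!r}: expected exactly one parent, got {tags.count('parent')}"
            )
        if tags.count("minimized") > 1:
            raise EnsembleError(f"ensemble {self.state_label!r}: more than one minimized conformer")
        times = [c.time_ns for c in self.conformers if c.provenance == "snapshot"]
        if any(t is None for t in times):
            raise EnsembleError("snapshot conformers must carry a time")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise EnsembleError("snapshot times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.conformers)


@dataclass(frozen=True)
class DockingTask:
    """One docking search: a ligand against one conformer of one ensemble."""

    ligand_id: str
    ensemble_label: str
    conformer_index: int


def build_ensemble(
    parent: Structure,
    minimized: Structure | None,
    frames: list[Structure],
    start_ns: float,
    interval_ns: float,
    count: int,
    state_label: str | None = None,
) -> ConformerEnsemble:
    """Assemble parent + minimized + ``count`` snapshots at regular times.

    Snapshot times are ``start_ns, start_ns + interval_ns, ...``; each
    requested time is matched to the nearest frame within +/- half an
    interval (trajectory writing intervals rarely divide the snapshot
    interval exactly).  ``frames`` must be sorted by time.
    """
    if count < 0:
        raise EnsembleError("count must be >= 0")
    times = [f.time_ns for f in frames]
    if any(t is None for t in times):
        raise EnsembleError("every frame must carry a time")
    if any(b <= a for a, b in zip(times, times[1:])):
        raise EnsembleError("frames must be sorted by strictly increasing time")

    conformers = [parent.with_provenance("parent")]
    if minimized is not None:
        conformers.append(minimized.with_provenance("minimized"))
    times_arr = np.asarray(times, dtype=float)
    for i in range(count):
        want = start_ns + i * interval_ns
        if len(frames) == 0:
            raise EnsembleError(f"no frame within tolerance of requested time {want} ns")
        j = int(np.argmin(np.abs(times_arr - want)))
        if abs(times_arr[j] - want) > interval_ns / 2:
            raise EnsembleError(
                f"no frame within {interval_ns / 2} ns of requested time {want} ns"
            )
        conformers.append(frames[j].with_provenance("snapshot", time_ns=float(times_arr[j])))
    return ConformerEnsemble(state_label=state_label or parent.label, conformers=conformers)


def enumerate_tasks(
    ligand_ids: list[str], ensembles: list[ConformerEnsemble]
) -> list[DockingTask]:
    """Cartesian product ligand x (ensemble, conformer), in deterministic order.

    Order is ligands, then ensembles, then conformer index, so re-running a
    study enumerates identical task lists.
    """
    if not ligand_ids or not ensembles:
        raise EnsembleError("ligand_ids and ensembles must be non-empty")
    return [
        DockingTask(ligand_id=lig, ensemble_label=ens.state_label, conformer_index=i)
        for lig in ligand_ids
        for ens in ensembles
        for i in range(len(ens))
    ]


def region_center(
    structure: Structure,
    region_map: RegionMap,
    name: str = "NBD1",
    mode: str = "ca",
) -> np.ndarray:
    """Geometric center of a named region.

    ``mode="ca"`` (default) is the centroid of the region's C-alpha atoms —
    robust to missing hydrogens; ``mode="mass"`` is the mass-weighted
    all-atom center.
    """
    residues = region_map.residues(name, structure)
    if mode == "ca":
        ca = structure.ca_index()
        idx = [ca[r] for r in sorted(residues) if r in ca]
        if not idx:
            raise StructureError(f"region {name!r} has no C-alpha atoms")
        return structure.coords[idx].mean(axis=0)
    if mode == "mass":
        idx = [i for i, a in enumerate(structure.atoms) if a.residue_id in residues]
        masses = np.asarray(
            [_MASSES.get(structure.atoms[i].element.upper(), 12.011) for i in idx]
        )
        return (structure.coords[idx] * masses[:, None]).sum(axis=0) / masses.sum()
    raise StructureError(f"unknown center mode {mode!r}")


def search_space_filter(poses, center, radius: float):
    """Retain poses whose heavy-atom centroid lies within ``radius`` of ``center``.

    The boundary is inclusive and input order is preserved.  This is the
    engine-agnostic analog of a docking search sphere: the pose position is
    its heavy-atom centroid.
    """
    if radius <= 0:
        raise EnsembleError("radius must be positive")
    center = np.asarray(center, dtype=float)
    kept = []
    for pose in poses:
        if np.linalg.norm(pose.heavy_centroid() - center) <= radius:
            kept.append(pose)
    return kept
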