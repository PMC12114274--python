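"""Docking-pose RMSD clustering and representative selection.

Poses share one receptor frame and atom ordering, so RMSD is computed
without re-superposition and without symmetry correction. Clustering is
the energy-seeded leader algorithm: the lowest-energy unassigned pose seeds
a cluster and absorbs every unassigned pose within the threshold.
Representatives are accumulated over clusters ranked by size until the
required fraction of all poses is covered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Pose",
    "ClusterSet",
    "pose_rmsd",
    "cluster_poses",
    "select_representatives",
    "read_pose_tsv",
    "write_cluster_table",
]


@dataclass(frozen=True)
class Pose:
    pose_id: int
    ligand_coords: np.ndarray  # (n_atoms, 3), Å, fixed atom order
    binding_energy: float  # kcal/mol, lower is better

    def __post_init__(self) -> None:
        coords = np.asarray(self.ligand_coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"ligand_coords must be (n, 3), got {coords.shape}")
        object.__setattr__(self, "ligand_coords", coords)


@dataclass
class ClusterSet:
    clusters: list[list[int]]  # pose ids, disjoint and exhaustive
    representatives: list[int]  # pose ids, one per represented cluster, in rank order
    coverage: float
    threshold: float
    _poses: dict[int, Pose] = field(default_factory=dict, repr=False)

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    @property
    def n_poses(self) -> int:
        return sum(self.sizes)


def pose_rmsd(a: Pose, b: Pose) -> float:
    """RMSD over matched atoms in the shared docking frame (no fitting)."""
    if a.ligand_coords.shape != b.ligand_coords.shape:
        raise ValueError(
            f"atom-count mismatch: {a.ligand_coords.shape[0]} vs "
            f"{b.ligand_coords.shape[0]}")
    diff = a.ligand_coords - b.ligand_coords
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def cluster_poses(poses: list[Pose], threshold: float = 10.0) -> ClusterSet:
    """Energy-sorted leader clustering at the given RMSD threshold.

    Repeatedly seed a new cluster with the lowest-energy unassigned pose
    (ties by pose_id ascending) and assign every unassigned pose within
    ``threshold`` of the seed. Clusters are reported in seeding order; the
    seed is therefore its cluster's minimum-energy member and its
    representative.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not poses:
        raise ValueError("need at least one pose")
    n_atoms = {p.ligand_coords.shape[0] for p in poses}
    if len(n_atoms) != 1:
        raise ValueError("all poses must share one atom count")
    ids = [p.pose_id for p in poses]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate pose ids")

    order = sorted(poses, key=lambda p: (p.binding_energy, p.pose_id))
    unassigned = {p.pose_id: p for p in order}
    clusters: list[list[int]] = []
    seeds: list[int] = []
    for seed in order:
        if seed.pose_id not in unassigned:
            continue
        members = [pid for pid, pose in unassigned.items()
                   if pose_rmsd(seed, pose) <= threshold]
        members.sort()
        for pid in members:
            del unassigned[pid]
        clusters.append(members)
        seeds.append(seed.pose_id)
    return ClusterSet(clusters=clusters, representatives=seeds,
                      coverage=1.0, threshold=threshold,
                      _poses={p.pose_id: p for p in poses})


def select_representatives(clusters: ClusterSet, min_coverage: float = 0.70) -> ClusterSet:
    """Keep best-energy representatives of the largest clusters until at
    least ``min_coverage`` of all poses is represented.

    Clusters are ranked by size descending, ties by better (lower)
    representative energy, then by lower representative pose id.
    """
    if not 0 < min_coverage <= 1:
        raise ValueError("min_coverage must be in (0, 1]")
    total = clusters.n_poses
    if total == 0:
        raise ValueError("empty cluster set")

    def rank_key(item: tuple[list[int], int]) -> tuple:
        members, rep = item
        energy = clusters._poses[rep].binding_energy if rep in clusters._poses else 0.0
        return (-len(members), energy, rep)

    ranked = sorted(zip(clusters.clusters, clusters.representatives), key=rank_key)
    chosen: list[int] = []
    covered = 0
    for members, rep in ranked:
        chosen.append(rep)
        covered += len(members)
        if covered / total >= min_coverage:
            break
    return ClusterSet(clusters=clusters.clusters, representatives=chosen,
                      coverage=covered / total, threshold=clusters.threshold,
                      _poses=clusters._poses)


def read_pose_tsv(path: str | Path) -> list[Pose]:
    """Read poses from delimited text: pose_id, energy, then x y z triples."""
    poses = []
    with Path(path).open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("pose_id"):
                continue
            fields = line.replace(",", "\t").split()
            if (len(fields) - 2) % 3 != 0 or len(fields) < 5:
                raise ValueError(f"line {lineno}: expected pose_id, energy and "
                                 f"x y z triples, got {len(fields)} fields")
            pose_id = int(fields[0])
            energy = float(fields[1])
            coords = np.array([float(v) for v in fields[2:]]).reshape(-1, 3)
            poses.append(Pose(pose_id=pose_id, ligand_coords=coords,
                              binding_energy=energy))
    if not poses:
        raise ValueError(f"{path}: no poses found")
    return poses


def write_cluster_table(clusters: ClusterSet, path: str | Path) -> None:
    with Path(path).open("w") as handle:
        handle.write("cluster\tsize\trepresentative\tmembers\n")
        rep_set = set(clusters.representatives)
        for i, members in enumerate(clusters.clusters, start=1):
            seed = min(
                members,
                key=lambda pid: (clusters._poses[pid].binding_energy, pid)
            ) if clusters._poses else members[0]
            marker = seed if seed in rep_set else ""
            handle.write(f"{i}\t{len(members)}\t{marker}\t"
                         f"{','.join(map(str, members))}\n")
        handle.write(f"# coverage\t{clusters.coverage:.4f}\n")
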