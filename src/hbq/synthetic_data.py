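"""Generators for every input the pipeline consumes.

All generators are pure functions of their spec plus a seed, so every test
and benchmark is reproducible bit for bit. Planted ground truth (bond sets,
variable subsets, cluster memberships, IC50 values) is returned alongside
the data so recovery can be asserted exactly in the noiseless limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hbond_features import FeatureMatrix, VariableKey
from .pharm_stats import predict_response
from .pose_clustering import Pose
from .structure_io import AtomRecord, ComplexStructure, Role

__all__ = [
    "PlantedModelSpec",
    "PlantedTruth",
    "ComplexSpec",
    "PlantedContact",
    "PlantedBridge",
    "synth_feature_table",
    "synth_complex",
    "synth_pose_set",
    "synth_dose_response",
]


# ---------------------------------------------------------------------------
# planted sparse linear model


@dataclass
class PlantedModelSpec:
    n_rows: int = 40
    p_variables: int = 31
    true_subset: tuple[int, ...] = (0, 2, 5, 9, 14, 19, 24, 30)  # 0-based columns
    betas: tuple[float, ...] = (-90.0, 80.0, -85.0, 75.0, -80.0, 90.0, -75.0, 85.0)
    intercept: float = 60.0
    noise_sd: float = 0.0  # I% units
    distance_range: tuple[float, float] = (2.4, 3.0)
    missing_rate: float = 0.0
    fill: float = 3.0
    bridged_fraction: float = 0.3  # fraction of catalog rendered with W prefix
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.distance_range
        if not 0 < lo < hi:
            raise ValueError("distance_range must satisfy 0 < lo < hi")
        if hi > self.fill:
            raise ValueError("distance_range upper bound must not exceed fill")
        if len(self.true_subset) != len(self.betas):
            raise ValueError("true_subset and betas must have equal length")
        if len(set(self.true_subset)) != len(self.true_subset):
            raise ValueError("true_subset has duplicates")
        if any(not 0 <= j < self.p_variables for j in self.true_subset):
            raise ValueError("true_subset indices out of range")
        if self.noise_sd < 0 or not 0 <= self.missing_rate < 1:
            raise ValueError("invalid noise_sd or missing_rate")
        if self.n_rows < len(self.true_subset) + 2:
            raise ValueError("n_rows too small to ever identify the planted subset")


@dataclass
class PlantedTruth:
    subset: tuple[VariableKey, ...]
    subset_columns: tuple[int, ...]
    betas: tuple[float, ...]
    intercept: float


def synth_feature_table(spec: PlantedModelSpec) -> tuple[FeatureMatrix, PlantedTruth]:
    """Distance matrix with a planted sparse linear dependence of I% on a
    known column subset plus Gaussian noise.

    The response is computed from the matrix AFTER missing cells are set to
    the fill value, so a noiseless fit on the true subset is exact.
    Responses are intentionally not clipped to [0, 100].
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.distance_range
    values = rng.uniform(lo, hi, size=(spec.n_rows, spec.p_variables))
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values[mask] = spec.fill

    cols = np.array(spec.true_subset)
    response = (spec.intercept + values[:, cols] @ np.array(spec.betas)
                + rng.normal(0.0, spec.noise_sd, size=spec.n_rows))

    n_bridged = int(round(spec.bridged_fraction * spec.p_variables))
    variables = []
    for j in range(spec.p_variables):
        bridged = j < n_bridged
        variables.append(VariableKey(index=j + 1, residue_key=f"Res{j + 1}",
                                     bridged=bridged))
    matrix = FeatureMatrix(
        row_ids=[f"cmpd{i + 1}" for i in range(spec.n_rows)],
        variables=variables, values=values, response=response, fill=spec.fill)
    truth = PlantedTruth(
        subset=tuple(variables[j] for j in spec.true_subset),
        subset_columns=tuple(spec.true_subset),
        betas=spec.betas, intercept=spec.intercept)
    return matrix, truth


# ---------------------------------------------------------------------------
# toy complexes with planted hydrogen-bond geometry


@dataclass(frozen=True)
class PlantedContact:
    residue_key: str  # e.g. "Trp74" -> residue name TRP, number 74
    distance: float  # Å, ligand polar atom to protein polar atom

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("planted distance must be positive")


@dataclass(frozen=True)
class PlantedBridge:
    residue_key: str
    ligand_water: float  # Å
    water_protein: float  # Å

    def __post_init__(self) -> None:
        if self.ligand_water <= 0 or self.water_protein <= 0:
            raise ValueError("planted distances must be positive")


@dataclass
class ComplexSpec:
    contacts: tuple[PlantedContact, ...] = ()
    bridges: tuple[PlantedBridge, ...] = ()
    decoy_carbons: int = 0
    cutoff: float = 3.0
    chains: tuple[str, ...] = ("A",)  # planted residues cycle over these
    ligand_id: str = "synth"
    group_spacing: float = 25.0  # Å between planted interaction sites


def _split_residue_key(key: str) -> tuple[str, int]:
    i = len(key)
    while i > 0 and key[i - 1].isdigit():
        i -= 1
    name, number = key[:i], key[i:]
    if not name or not number:
        raise ValueError(f"cannot split residue key {key!r}")
    return name.upper()[:3], int(number)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def synth_complex(spec: ComplexSpec, seed: int = 0) -> ComplexStructure:
    """Build a complex whose detected bond set is exactly the planted one.

    Each planted contact or bridge gets its own ligand polar atom, placed on
    a widely spaced grid so groups cannot interact across sites; bridge
    atoms are laid out collinearly (ligand, water, protein), which keeps the
    ligand-protein distance equal to the sum of the legs and hence beyond
    the cutoff. Decoy carbons are planted close to ligand atoms to exercise
    the polar filter.
    """
    for bridge in spec.bridges:
        if bridge.ligand_water + bridge.water_protein <= spec.cutoff:
            raise ValueError(
                f"bridge to {bridge.residue_key}: legs sum to "
                f"{bridge.ligand_water + bridge.water_protein:.2f} Å <= cutoff; "
                "the bridge would also register as a direct bond")
    max_planted = max(
        [c.distance for c in spec.contacts]
        + [b.ligand_water + b.water_protein for b in spec.bridges]
        + [0.0])
    # adjacent sites must stay out of each other's cutoff reach
    if spec.group_spacing <= 2 * max_planted + spec.cutoff + 0.5:
        raise ValueError("group_spacing too small for the planted distances")

    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    serial = 0
    placed: list[np.ndarray] = []

    def place(position: np.ndarray) -> np.ndarray:
        placed.append(position)
        return position

    def separated_direction(origin: np.ndarray, distance: float) -> np.ndarray:
        for _ in range(100):
            pos = origin + distance * _random_unit(rng)
            if all(np.linalg.norm(pos - q) >= 0.5 for q in placed):
                return pos
        raise RuntimeError("could not place atom without a 0.5 Å overlap")

    def add(atom_name: str, element: str, residue_name: str, residue_number: int,
            chain: str, coords: np.ndarray, role: Role) -> AtomRecord:
        nonlocal serial
        serial += 1
        atom = AtomRecord(serial=serial, atom_name=atom_name, element=element,
                          residue_name=residue_name, residue_number=residue_number,
                          chain_id=chain, coords=coords, role=role)
        atoms.append(atom)
        return atom

    n_sites = len(spec.contacts) + len(spec.bridges)
    site = 0
    water_number = 1000

    for contact in spec.contacts:
        origin = place(np.array([site * spec.group_spacing, 0.0, 0.0]))
        site += 1
        add(f"O{site}", "O", "LIG", 1, "X", origin, Role.LIGAND)
        resname, resnum = _split_residue_key(contact.residue_key)
        chain = spec.chains[(site - 1) % len(spec.chains)]
        pos = separated_direction(origin, contact.distance)
        add("N", "N", resname, resnum, chain, place(pos), Role.PROTEIN)

    for bridge in spec.bridges:
        origin = place(np.array([site * spec.group_spacing, 0.0, 0.0]))
        site += 1
        add(f"O{site}", "O", "LIG", 1, "X", origin, Role.LIGAND)
        resname, resnum = _split_residue_key(bridge.residue_key)
        chain = spec.chains[(site - 1) % len(spec.chains)]
        direction = _random_unit(rng)
        water_pos = place(origin + bridge.ligand_water * direction)
        water_number += 1
        add("O", "O", "HOH", water_number, "W", water_pos, Role.WATER)
        protein_pos = place(water_pos + bridge.water_protein * direction)
        add("O", "O", resname, resnum, chain, protein_pos, Role.PROTEIN)

    # decoy carbons hug the ligand atoms but are never polar
    ligand_atoms = [a for a in atoms if a.role is Role.LIGAND]
    for d in range(spec.decoy_carbons):
        if ligand_atoms:
            anchor = ligand_atoms[d % len(ligand_atoms)].coords
        else:
            anchor = np.zeros(3)
        pos = separated_direction(anchor, float(rng.uniform(1.5, 2.5)))
        add(f"C{d + 1}", "C", "LIG", 1, "X", place(pos), Role.LIGAND)

    if not any(a.role is Role.LIGAND for a in atoms):
        # keep the one-ligand invariant even for contact-free specs
        add("C1", "C", "LIG", 1, "X", place(np.zeros(3)), Role.LIGAND)
    if n_sites == 0 and spec.decoy_carbons == 0:
        raise ValueError("empty complex spec")
    return ComplexStructure(ligand_id=spec.ligand_id, atoms=atoms)


# ---------------------------------------------------------------------------
# pose sets with known cluster structure


def synth_pose_set(
    centers,
    sizes,
    jitter_sd: float = 1.0,
    energy_bases=None,
    energy_spread: float = 0.5,
    seed: int = 0,
    min_separation: float | None = None,
) -> tuple[list[Pose], list[int]]:
    """Poses jittered isotropically around cluster centers, with energies
    drawn per cluster.

    Returns the pose list and the planted cluster label per pose. If
    ``min_separation`` is given, every pair of centers must differ by more
    than that RMSD, otherwise an error is raised.
    """
    centers = [np.asarray(c, dtype=float) for c in centers]
    if len(centers) != len(sizes):
        raise ValueError("centers and sizes must have equal length")
    if any(c.shape != centers[0].shape or c.ndim != 2 or c.shape[1] != 3
           for c in centers):
        raise ValueError("all centers must be (n_atoms, 3) with one atom count")
    if min_separation is not None:
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                rmsd = float(np.sqrt(np.mean(
                    np.sum((centers[i] - centers[j]) ** 2, axis=1))))
                if rmsd <= min_separation:
                    raise ValueError(
                        f"centers {i} and {j} are {rmsd:.2f} Å apart, "
                        f"below the required separation {min_separation}")
    if energy_bases is None:
        energy_bases = [-8.0 - k for k in range(len(centers))]
    if len(energy_bases) != len(centers):
        raise ValueError("energy_bases and centers must have equal length")

    rng = np.random.default_rng(seed)
    poses: list[Pose] = []
    labels: list[int] = []
    pose_id = 1
    for label, (center, size, base) in enumerate(zip(centers, sizes, energy_bases)):
        for _ in range(size):
            coords = center + rng.normal(0.0, jitter_sd, size=center.shape)
            energy = float(base + rng.uniform(-energy_spread, energy_spread))
            poses.append(Pose(pose_id=pose_id, ligand_coords=coords,
                              binding_energy=energy))
            labels.append(label)
            pose_id += 1
    return poses, labels


# ---------------------------------------------------------------------------
# dose-response tables


def synth_dose_response(ic50: float, doses, noise_sd: float = 0.0,
                        seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Responses from Y = 100/(1 + X/IC50) plus Gaussian noise."""
    doses = np.asarray(doses, dtype=float)
    rng = np.random.default_rng(seed)
    responses = predict_response(doses, ic50) + rng.normal(0.0, noise_sd,
                                                           size=doses.shape)
    return doses, responses
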