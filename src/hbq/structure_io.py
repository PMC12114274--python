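"""Reading and writing of minimized complex structures.

Atom records are parsed from fixed-column PDB-style files (``ATOM`` /
``HETATM`` lines only) and partitioned into protein / ligand / water roles.
Role assignment is driven by residue names supplied by the caller (for the
ligand) and a configurable water-name set, because minimization round-trips
through different programs do not use the HETATM flag consistently.

Distances downstream are plain Cartesian distances in Å; no periodic
boundary handling is applied.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "Role",
    "AtomRecord",
    "ComplexStructure",
    "ParseError",
    "NoLigandError",
    "WATER_RESIDUE_NAMES",
    "POLAR_ELEMENTS",
    "read_structure",
    "write_structure",
    "polar_atoms",
]

#: Residue names recognised as explicit solvent.
WATER_RESIDUE_NAMES = frozenset({"HOH", "WAT", "SOL"})

#: Heavy-atom elements eligible as hydrogen-bond partners.
POLAR_ELEMENTS = frozenset({"N", "O", "S"})


class Role(str, enum.Enum):
    """Structural role of an atom within a complex."""

    PROTEIN = "protein"
    LIGAND = "ligand"
    WATER = "water"


class ParseError(ValueError):
    """A fixed-column atom record could not be parsed."""


class NoLigandError(ValueError):
    """The file contained no atom with a ligand residue name."""


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    coords: np.ndarray  # shape (3,), Å
    role: Role

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,):
            raise ValueError(f"coords must be a 3-vector, got shape {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"non-finite coordinates for atom serial {self.serial}")
        if not self.element:
            raise ValueError(f"empty element for atom serial {self.serial}")
        object.__setattr__(self, "coords", coords)

    @property
    def residue_key(self) -> str:
        """Chain-agnostic residue label, e.g. ``Trp74``."""
        return f"{self.residue_name.capitalize()}{self.residue_number}"


class Protonation(str, enum.Enum):
    NEUTRAL = "neutral"
    DEPROTONATED = "deprotonated"


@dataclass
class ComplexStructure:
    """One minimized ligand-protein-water complex."""

    ligand_id: str
    atoms: list[AtomRecord] = field(default_factory=list)
    protonation_tag: Protonation = Protonation.NEUTRAL
    pose_index: int = 1

    def __post_init__(self) -> None:
        if self.pose_index < 1:
            raise ValueError("pose_index must be >= 1")

    def atoms_with_role(self, role: Role) -> list[AtomRecord]:
        return [a for a in self.atoms if a.role is role]

    @property
    def row_label(self) -> str:
        """Conformation label: ligand id, minus sign for deprotonated forms."""
        label = self.ligand_id
        if self.protonation_tag is Protonation.DEPROTONATED and not label.endswith("-"):
            label += "-"
        return label

    def role_counts(self) -> dict[str, int]:
        counts = {r.value: 0 for r in Role}
        for atom in self.atoms:
            counts[atom.role.value] += 1
        return counts


def _infer_element(element_field: str, atom_name: str) -> str:
    """Element from columns 77-78 when present, else first letter of the name."""
    element = element_field.strip()
    if element:
        return element.capitalize() if len(element) > 1 else element.upper()
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return ""


def _parse_atom_line(line: str, lineno: int) -> dict:
    try:
        return {
            "serial": int(line[6:11]),
            "atom_name": line[12:16].strip(),
            "residue_name": line[17:20].strip(),
            "chain_id": line[21:22].strip(),
            "residue_number": int(line[22:26]),
            "x": float(line[30:38]),
            "y": float(line[38:46]),
            "z": float(line[46:54]),
            "element_field": line[76:78] if len(line) >= 78 else "",
        }
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {lineno}: malformed atom record: {exc}") from None


def read_structure(
    path: str | Path,
    ligand_residue_names: Iterable[str],
    *,
    water_residue_names: Iterable[str] = WATER_RESIDUE_NAMES,
    ligand_id: str | None = None,
    protonation_tag: Protonation = Protonation.NEUTRAL,
    pose_index: int = 1,
) -> ComplexStructure:
    """Parse a PDB-style file into a role-partitioned :class:`ComplexStructure`.

    Role assignment: residue name in the water set -> water; in the ligand
    set -> ligand; anything else -> protein.

    Raises
    ------
    ParseError
        If a fixed-column ATOM/HETATM line cannot be parsed (names the line).
    NoLigandError
        If no atom matches a ligand residue name.
    """
    path = Path(path)
    ligand_set = {name.upper() for name in ligand_residue_names}
    water_set = {name.upper() for name in water_residue_names}
    if ligand_set & water_set:
        raise ValueError("ligand residue names overlap the water residue names")

    atoms: list[AtomRecord] = []
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            rec = _parse_atom_line(line, lineno)
            resname = rec["residue_name"].upper()
            if resname in water_set:
                role = Role.WATER
            elif resname in ligand_set:
                role = Role.LIGAND
            else:
                role = Role.PROTEIN
            element = _infer_element(rec["element_field"], rec["atom_name"])
            if not element:
                raise ParseError(f"line {lineno}: cannot infer element from atom name "
                                 f"{rec['atom_name']!r}")
            atoms.append(
                AtomRecord(
                    serial=rec["serial"],
                    atom_name=rec["atom_name"],
                    element=element,
                    residue_name=rec["residue_name"],
                    residue_number=rec["residue_number"],
                    chain_id=rec["chain_id"],
                    coords=np.array([rec["x"], rec["y"], rec["z"]]),
                    role=role,
                )
            )

    if not any(a.role is Role.LIGAND for a in atoms):
        raise NoLigandError(
            f"{path.name}: no ligand atoms (looked for residue names {sorted(ligand_set)})"
        )
    return ComplexStructure(
        ligand_id=ligand_id if ligand_id is not None else path.stem,
        atoms=atoms,
        protonation_tag=protonation_tag,
        pose_index=pose_index,
    )


def write_structure(structure: ComplexStructure, path: str | Path) -> None:
    """Write atom records back out in the same fixed-column dialect.

    Protein atoms become ATOM records, ligand and water become HETATM;
    coordinates are printed at the dialect's %8.3f precision.
    """
    path = Path(path)
    with path.open("w") as handle:
        for atom in structure.atoms:
            record = "ATOM  " if atom.role is Role.PROTEIN else "HETATM"
            name = atom.atom_name
            # PDB column convention: 1-3 char names start in column 14
            name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
            x, y, z = atom.coords
            handle.write(
                f"{record}{atom.serial:>5d} {name_field} "
                f"{atom.residue_name:<3s} {atom.chain_id:1s}"
                f"{atom.residue_number:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}\n"
            )


def polar_atoms(
    structure: ComplexStructure,
    role: Role | str,
    polar_elements: frozenset[str] | set[str] = POLAR_ELEMENTS,
) -> list[AtomRecord]:
    """Atoms of the given role whose element is polar (N, O, S by default)."""
    if isinstance(role, str):
        try:
            role = Role(role)
        except ValueError:
            raise ValueError(f"unknown role {role!r}; expected one of "
                             f"{[r.value for r in Role]}") from None
    if not isinstance(role, Role):
        raise ValueError(f"unknown role {role!r}")
    return [a for a in structure.atoms if a.role is role and a.element in polar_elements]
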