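"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from hbq.structure_io import POLAR_ELEMENTS, AtomRecord, ComplexStructure, Role

# ---------------------------------------------------------------------------
# brute-force hydrogen-bond oracles (kept deliberately naive and independent
# of the package's vectorized detectors)


def brute_force_direct(structure: ComplexStructure, cutoff: float = 3.0) -> set:
    """Triple-checked all-pairs enumeration; returns hashable bond tuples."""
    bonds = set()
    for lig in structure.atoms:
        if lig.role is not Role.LIGAND or lig.element not in POLAR_ELEMENTS:
            continue
        for prot in structure.atoms:
            if prot.role is not Role.PROTEIN or prot.element not in POLAR_ELEMENTS:
                continue
            d = float(np.linalg.norm(lig.coords - prot.coords))
            if d <= cutoff:
                bonds.add((lig.serial, prot.serial, prot.residue_key, round(d, 9)))
    return bonds


def brute_force_bridges(structure: ComplexStructure, cutoff: float = 3.0) -> set:
    """Naive triple loop over (ligand polar, water O, protein polar)."""
    bonds = set()
    for lig in structure.atoms:
        if lig.role is not Role.LIGAND or lig.element not in POLAR_ELEMENTS:
            continue
        for wat in structure.atoms:
            if wat.role is not Role.WATER or wat.element != "O":
                continue
            d_lw = float(np.linalg.norm(lig.coords - wat.coords))
            if d_lw > cutoff:
                continue
            for prot in structure.atoms:
                if prot.role is not Role.PROTEIN or prot.element not in POLAR_ELEMENTS:
                    continue
                d_wp = float(np.linalg.norm(wat.coords - prot.coords))
                if d_wp <= cutoff:
                    bonds.add((lig.serial, wat.serial, prot.serial,
                               prot.residue_key, round(d_lw, 9)))
    return bonds


def random_complex(rng: np.random.Generator, n_ligand: int = 10,
                   n_protein: int = 30, n_water: int = 10,
                   box: float = 12.0) -> ComplexStructure:
    """Random atoms in a tight box so some pairs land under the cutoff."""
    atoms = []
    serial = 0
    resnames = ["TRP", "SER", "ARG", "CYS", "PHE", "GLY"]
    elements = ["N", "O", "S", "C"]
    for _ in range(n_ligand):
        serial += 1
        atoms.append(AtomRecord(
            serial=serial, atom_name="L", element=elements[rng.integers(4)],
            residue_name="LIG", residue_number=1, chain_id="X",
            coords=rng.uniform(0, box, 3), role=Role.LIGAND))
    for i in range(n_protein):
        serial += 1
        atoms.append(AtomRecord(
            serial=serial, atom_name="P",
            element=elements[rng.integers(4)],
            residue_name=resnames[rng.integers(len(resnames))],
            residue_number=int(rng.integers(1, 50)),
            chain_id="ABCDEFG"[i % 7],
            coords=rng.uniform(0, box, 3), role=Role.PROTEIN))
    for _ in range(n_water):
        serial += 1
        atoms.append(AtomRecord(
            serial=serial, atom_name="O", element="O",
            residue_name="HOH", residue_number=int(rng.integers(1000, 2000)),
            chain_id="W", coords=rng.uniform(0, box, 3), role=Role.WATER))
    return ComplexStructure(ligand_id="rand", atoms=atoms)


def hbond_key_direct(bond) -> tuple:
    return (bond.ligand_atom_serial, bond.protein_atom_serial,
            bond.residue_key, round(bond.length, 9))


def hbond_key_bridged(bond) -> tuple:
    return (bond.ligand_atom_serial, bond.water_serial, bond.protein_atom_serial,
            bond.residue_key, round(bond.length, 9))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240517)
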