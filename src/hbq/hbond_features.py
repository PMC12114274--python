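"""Direct and water-bridged hydrogen-bond detection and the distance
feature matrix.

A hydrogen bond is defined purely by distance: any ligand polar heavy atom
within the cutoff (default 3.0 Å) of a protein polar heavy atom counts as a
direct bond; a water oxygen within the cutoff of both a ligand polar atom
and a protein polar atom defines a bridged bond. No donor/acceptor or angle
criteria are applied, and distances are heavy-atom to heavy-atom.

Variables are keyed by chain-agnostic residue labels ("Trp74"), with a "W"
prefix marking water-bridged contacts ("WSer73"). Bonds on the same residue
key collapse to the minimum length; absent bonds are encoded with a fill
value equal to the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure_io import ComplexStructure, Role, polar_atoms

__all__ = [
    "HBond",
    "VariableKey",
    "FeatureMatrix",
    "detect_direct_hbonds",
    "detect_water_bridges",
    "build_feature_matrix",
    "write_matrix_tsv",
    "read_matrix_tsv",
]


@dataclass(frozen=True)
class HBond:
    """A single ligand-protein contact, direct or water-mediated."""

    residue_key: str
    bridged: bool
    length: float
    ligand_atom_serial: int
    protein_atom_serial: int
    water_serial: int | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("bond length must be positive")
        if self.bridged != (self.water_serial is not None):
            raise ValueError("bridged flag must match presence of water_serial")

    @property
    def rendered_key(self) -> str:
        return ("W" + self.residue_key) if self.bridged else self.residue_key


@dataclass(frozen=True, order=True)
class VariableKey:
    """One column of the feature matrix: a (residue, bridged?) contact type."""

    index: int  # 1-based, rendered as "Vj"
    residue_key: str
    bridged: bool

    @property
    def label(self) -> str:
        return f"V{self.index}"

    @property
    def rendered(self) -> str:
        return ("W" + self.residue_key) if self.bridged else self.residue_key


@dataclass
class FeatureMatrix:
    """Rows = ligand conformations, columns = residue-keyed bond lengths."""

    row_ids: list[str]
    variables: list[VariableKey]
    values: np.ndarray  # (n_rows, p), Å
    response: np.ndarray  # (n_rows,), percent inhibition
    fill: float = 3.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        n, p = self.values.shape
        if len(self.row_ids) != n:
            raise ValueError("row_ids length does not match values")
        if len(self.variables) != p:
            raise ValueError("variables length does not match values")
        if len(self.response) != n:
            raise ValueError("response length does not match values")
        if len(set(self.row_ids)) != n:
            raise ValueError("duplicate row_ids")
        if np.any(self.values <= 0) or np.any(self.values > self.fill + 1e-12):
            raise ValueError("matrix cells must satisfy 0 < value <= fill")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def column_index(self, key: "VariableKey | str | int") -> int:
        """Resolve a VariableKey, a 'Vj' label, a rendered name or a 0-based
        position to a column index."""
        if isinstance(key, VariableKey):
            return self.variables.index(key)
        if isinstance(key, int):
            if not 0 <= key < self.n_variables:
                raise KeyError(f"column position {key} out of range")
            return key
        for i, var in enumerate(self.variables):
            if key in (var.label, var.rendered):
                return i
        raise KeyError(f"no variable matching {key!r}")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.row_ids,
                          columns=[v.label for v in self.variables])
        df["I_percent"] = self.response
        df.index.name = "row_id"
        return df


def detect_direct_hbonds(structure: ComplexStructure, cutoff: float = 3.0) -> list[HBond]:
    """All ligand-polar / protein-polar atom pairs within ``cutoff`` Å."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig = polar_atoms(structure, Role.LIGAND)
    prot = polar_atoms(structure, Role.PROTEIN)
    if not lig or not prot:
        return []
    dists = cdist(np.array([a.coords for a in lig]),
                  np.array([a.coords for a in prot]))
    bonds = []
    for i, j in np.argwhere(dists <= cutoff):
        bonds.append(HBond(
            residue_key=prot[j].residue_key,
            bridged=False,
            length=float(dists[i, j]),
            ligand_atom_serial=lig[i].serial,
            protein_atom_serial=prot[j].serial,
        ))
    bonds.sort(key=lambda b: (b.ligand_atom_serial, b.protein_atom_serial))
    return bonds


def detect_water_bridges(
    structure: ComplexStructure,
    cutoff: float = 3.0,
    length_convention: Literal["ligand", "sum"] = "ligand",
) -> list[HBond]:
    """All (ligand polar, water O, protein polar) triples with both legs
    within ``cutoff`` Å.

    The recorded length is the ligand-water leg by default; the
    ``"sum"`` convention records the sum of the two legs instead.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if length_convention not in ("ligand", "sum"):
        raise ValueError(f"unknown length convention {length_convention!r}")
    lig = polar_atoms(structure, Role.LIGAND)
    prot = polar_atoms(structure, Role.PROTEIN)
    waters = [a for a in polar_atoms(structure, Role.WATER) if a.element == "O"]
    if not lig or not prot or not waters:
        return []
    wat_xyz = np.array([a.coords for a in waters])
    d_lw = cdist(np.array([a.coords for a in lig]), wat_xyz)
    d_wp = cdist(wat_xyz, np.array([a.coords for a in prot]))
    bonds = []
    for i, w in np.argwhere(d_lw <= cutoff):
        for j in np.flatnonzero(d_wp[w] <= cutoff):
            length = d_lw[i, w] if length_convention == "ligand" else d_lw[i, w] + d_wp[w, j]
            bonds.append(HBond(
                residue_key=prot[j].residue_key,
                bridged=True,
                length=float(length),
                ligand_atom_serial=lig[i].serial,
                protein_atom_serial=prot[j].serial,
                water_serial=waters[w].serial,
            ))
    bonds.sort(key=lambda b: (b.ligand_atom_serial, b.water_serial, b.protein_atom_serial))
    return bonds


def build_feature_matrix(
    records: Sequence[tuple[ComplexStructure, float]],
    cutoff: float = 3.0,
    fill: float | None = None,
    length_convention: Literal["ligand", "sum"] = "ligand",
) -> FeatureMatrix:
    """Assemble the distance feature matrix from complexes and their I%.

    The variable catalog is the union of (residue_key, bridged) pairs over
    all records, ordered by first appearance and indexed V1...Vp. Each cell
    holds the minimum bond length for that row and variable, or ``fill``
    (default: the cutoff) when the contact is absent. Conformations of one
    compound enter as separate rows sharing the compound's I%.
    """
    if not records:
        raise ValueError("empty record list")
    if fill is None:
        fill = cutoff

    row_ids: list[str] = []
    responses: list[float] = []
    per_row_bonds: list[list[HBond]] = []
    catalog: dict[tuple[str, bool], int] = {}

    for structure, inhibition in records:
        if not 0 <= inhibition <= 100:
            raise ValueError(
                f"{structure.row_label}: I% must be in [0, 100], got {inhibition}")
        row_id = structure.row_label
        if row_id in row_ids:
            raise ValueError(f"duplicate row id {row_id!r}")
        bonds = detect_direct_hbonds(structure, cutoff)
        bonds += detect_water_bridges(structure, cutoff, length_convention)
        for bond in bonds:
            catalog.setdefault((bond.residue_key, bond.bridged), len(catalog))
        row_ids.append(row_id)
        responses.append(float(inhibition))
        per_row_bonds.append(bonds)

    variables = [VariableKey(index=pos + 1, residue_key=key, bridged=bridged)
                 for (key, bridged), pos in sorted(catalog.items(), key=lambda kv: kv[1])]
    values = np.full((len(row_ids), len(variables)), fill, dtype=float)
    for r, bonds in enumerate(per_row_bonds):
        for bond in bonds:
            c = catalog[(bond.residue_key, bond.bridged)]
            # multiple bonds on one residue key collapse to the shortest
            values[r, c] = min(values[r, c], bond.length)
    return FeatureMatrix(row_ids=row_ids, variables=variables, values=values,
                         response=np.array(responses), fill=fill)


def write_matrix_tsv(matrix: FeatureMatrix, path: str | Path,
                     catalog_path: str | Path | None = None) -> None:
    """Write the matrix as TSV plus a sidecar catalog mapping Vj to the
    rendered residue key."""
    path = Path(path)
    matrix.to_dataframe().to_csv(path, sep="\t", float_format="%.6g")
    if catalog_path is None:
        catalog_path = path.with_suffix(path.suffix + ".catalog")
    with Path(catalog_path).open("w") as handle:
        handle.write("variable\trendered\tresidue_key\tbridged\n")
        for var in matrix.variables:
            handle.write(f"{var.label}\t{var.rendered}\t{var.residue_key}\t"
                         f"{int(var.bridged)}\n")


def read_matrix_tsv(path: str | Path, catalog_path: str | Path | None = None,
                    fill: float | None = None) -> FeatureMatrix:
    """Read a matrix written by :func:`write_matrix_tsv`.

    Without a sidecar catalog, variables are reconstructed from the header
    labels alone (rendered key unknown, treated as direct bonds named by the
    label)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "I_percent" not in df.columns:
        raise ValueError(f"{path.name}: missing I_percent column")
    response = df.pop("I_percent").to_numpy()

    if catalog_path is None:
        candidate = path.with_suffix(path.suffix + ".catalog")
        catalog_path = candidate if candidate.exists() else None
    if catalog_path is not None:
        cat = pd.read_csv(catalog_path, sep="\t")
        lookup = {row.variable: (row.residue_key, bool(row.bridged))
                  for row in cat.itertuples()}
        variables = []
        for i, label in enumerate(df.columns):
            residue_key, bridged = lookup.get(label, (label, False))
            variables.append(VariableKey(index=i + 1, residue_key=residue_key,
                                         bridged=bridged))
    else:
        variables = [VariableKey(index=i + 1, residue_key=label, bridged=False)
                     for i, label in enumerate(df.columns)]
    values = df.to_numpy(dtype=float)
    if fill is None:
        fill = float(values.max())
    return FeatureMatrix(row_ids=list(df.index.astype(str)), variables=variables,
                         values=values, response=response, fill=fill)
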