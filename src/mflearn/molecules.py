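"""Molecular geometries and multi-fidelity energy tables.

The core containers of the package live here: :class:`Molecule` (atomic
numbers + Cartesian coordinates in Ångström), :class:`FidelityHierarchy`
(an ordered ladder of quantum-chemistry methods, cheapest first, each with
a unit time-cost per calculation) and :class:`MultiFidelityDataset`
(per-fidelity energy labels, in kcal/mol, aligned to a list of molecules,
with missing labels allowed at the expensive end of the ladder).

Geometries are exchanged as standard multi-frame XYZ files; labels as tidy
CSV tables with columns ``id, fidelity, energy_kcal_mol``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Molecule",
    "FidelityHierarchy",
    "MultiFidelityDataset",
    "XYZFormatError",
    "read_xyz",
    "write_xyz",
    "read_labels",
    "write_labels",
    "assemble_dataset",
    "DEFAULT_ALLOWED_ELEMENTS",
    "DEFAULT_FIDELITY_NAMES",
]

#: Element symbols for Z = 1..36, enough for small organic chemistry.
_SYMBOLS = (
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe "
    "Co Ni Cu Zn Ga Ge As Se Br Kr"
).split()
SYMBOL_TO_Z = {s: i + 1 for i, s in enumerate(_SYMBOLS)}
Z_TO_SYMBOL = {z: s for s, z in SYMBOL_TO_Z.items()}

#: Default element universe: H, C, N, O (small organic molecules).
DEFAULT_ALLOWED_ELEMENTS = frozenset({1, 6, 7, 8})

#: Default four-level fidelity ladder, cheapest first.
DEFAULT_FIDELITY_NAMES = ("DFT/STO-3G", "DFT/cc-pVTZ", "CCSD", "DLPNO-CCSD(T)")


class XYZFormatError(ValueError):
    """Raised when an XYZ file cannot be parsed; message names the frame."""


@dataclass(eq=False)
class Molecule:
    """A single molecular geometry.

    Parameters
    ----------
    id : str
        Identifier, unique within a dataset.
    atomic_numbers : array of int, shape (n_atoms,)
        Nuclear charges Z (all positive).
    coordinates : array of float, shape (n_atoms, 3)
        Cartesian coordinates in Ångström.
    """

    id: str
    atomic_numbers: np.ndarray
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=np.int64)
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.atomic_numbers.ndim != 1 or self.atomic_numbers.size < 1:
            raise ValueError(f"molecule {self.id!r}: need at least one atom")
        if self.coordinates.shape != (self.atomic_numbers.size, 3):
            raise ValueError(
                f"molecule {self.id!r}: coordinates must be ({self.atomic_numbers.size}, 3), "
                f"got {self.coordinates.shape}"
            )
        if np.any(self.atomic_numbers < 1):
            raise ValueError(f"molecule {self.id!r}: atomic numbers must be positive")

    @property
    def n_atoms(self) -> int:
        return int(self.atomic_numbers.size)

    @property
    def symbols(self) -> list[str]:
        return [Z_TO_SYMBOL[int(z)] for z in self.atomic_numbers]

    def check_elements(self, allowed: frozenset[int] = DEFAULT_ALLOWED_ELEMENTS) -> None:
        """Raise if any atomic number falls outside ``allowed``."""
        bad = sorted(set(int(z) for z in self.atomic_numbers) - set(allowed))
        if bad:
            raise ValueError(f"molecule {self.id!r}: elements {bad} not in allowed set {sorted(allowed)}")

    @classmethod
    def from_symbols(cls, id: str, symbols: Sequence[str], coordinates) -> "Molecule":
        try:
            numbers = [SYMBOL_TO_Z[s] for s in symbols]
        except KeyError as exc:  # pragma: no cover - convenience path
            raise ValueError(f"unknown element symbol {exc.args[0]!r}") from exc
        return cls(id=id, atomic_numbers=np.array(numbers), coordinates=np.asarray(coordinates))


def read_xyz(
    path,
    allowed_elements: frozenset[int] | None = DEFAULT_ALLOWED_ELEMENTS,
) -> list[Molecule]:
    """Read a (multi-frame) XYZ file into a list of :class:`Molecule`.

    Each frame is ``n_atoms`` on one line, a comment line, then one
    ``symbol x y z`` line per atom.  The first whitespace token of a
    non-empty comment line is taken as the molecule ID; otherwise the
    frame gets a sequential ID ``mol{k}`` (0-based frame index).

    Set ``allowed_elements=None`` to disable the element-universe check.
    """
    lines = Path(path).read_text().splitlines()
    molecules: list[Molecule] = []
    pos = 0
    frame = 0
    while pos < len(lines):
        if not lines[pos].strip():  # tolerate trailing blank lines
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].strip())
        except ValueError:
            raise XYZFormatError(f"frame {frame}: malformed atom count line {lines[pos]!r}")
        if n_atoms < 1:
            raise XYZFormatError(f"frame {frame}: atom count must be >= 1, got {n_atoms}")
        if pos + 2 + n_atoms > len(lines):
            raise XYZFormatError(f"frame {frame}: truncated (expected {n_atoms} atom lines)")
        comment = lines[pos + 1].strip()
        mol_id = comment.split()[0] if comment else f"mol{frame}"
        numbers = np.empty(n_atoms, dtype=np.int64)
        coords = np.empty((n_atoms, 3), dtype=np.float64)
        for a in range(n_atoms):
            parts = lines[pos + 2 + a].split()
            if len(parts) < 4:
                raise XYZFormatError(f"frame {frame}: atom line {a} has {len(parts)} fields, need 4")
            sym = parts[0]
            if sym not in SYMBOL_TO_Z:
                raise XYZFormatError(f"frame {frame}: unknown element symbol {sym!r}")
            numbers[a] = SYMBOL_TO_Z[sym]
            try:
                coords[a] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise XYZFormatError(f"frame {frame}: coordinate parse failure on atom line {a}")
        mol = Molecule(id=mol_id, atomic_numbers=numbers, coordinates=coords)
        if allowed_elements is not None:
            try:
                mol.check_elements(allowed_elements)
            except ValueError as exc:
                raise XYZFormatError(f"frame {frame}: {exc}") from exc
        molecules.append(mol)
        pos += 2 + n_atoms
        frame += 1
    return molecules


def write_xyz(path, molecules: Iterable[Molecule]) -> None:
    """Write molecules as a multi-frame XYZ file (round-trips with read_xyz)."""
    with open(path, "w") as fh:
        for mol in molecules:
            fh.write(f"{mol.n_atoms}\n{mol.id}\n")
            for sym, (x, y, z) in zip(mol.symbols, mol.coordinates):
                fh.write(f"{sym:<2s} {x:18.10f} {y:18.10f} {z:18.10f}\n")


@dataclass(frozen=True)
class FidelityHierarchy:
    """Ordered ladder of fidelities, cheapest first.

    ``unit_costs[f-1]`` is the time (abstract units) of one calculation at
    fidelity ``f``; costs must be strictly increasing with fidelity.
    Fidelity indices are 1-based: ``f = 1`` is the cheapest, ``f = F`` the
    target.
    """

    names: tuple[str, ...] = DEFAULT_FIDELITY_NAMES
    unit_costs: tuple[float, ...] = (1.0, 30.0, 300.0, 3000.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "unit_costs", tuple(float(c) for c in self.unit_costs))
        if len(self.names) < 2:
            raise ValueError("hierarchy needs at least two fidelities")
        if len(set(self.names)) != len(self.names):
            raise ValueError("fidelity names must be unique")
        if len(self.unit_costs) != len(self.names):
            raise ValueError("one unit cost per fidelity required")
        costs = np.asarray(self.unit_costs)
        if np.any(costs <= 0) or np.any(np.diff(costs) <= 0):
            raise ValueError("unit costs must be positive and strictly increasing")

    @property
    def F(self) -> int:
        """Index of the target fidelity (== number of levels)."""
        return len(self.names)

    def index(self, name: str) -> int:
        """1-based index of a fidelity name."""
        try:
            return self.names.index(name) + 1
        except ValueError:
            raise KeyError(f"unknown fidelity {name!r}; known: {list(self.names)}")

    def cost(self, f: int) -> float:
        if not 1 <= f <= self.F:
            raise IndexError(f"fidelity index {f} outside 1..{self.F}")
        return self.unit_costs[f - 1]


@dataclass
class MultiFidelityDataset:
    """Molecules plus per-fidelity energy labels (kcal/mol).

    ``labels`` is an (n_molecules, F) float array; missing labels are NaN.
    The dataset enforces *downward closure*: a molecule labeled at fidelity
    f+1 must also be labeled at fidelity f, so missingness only occurs at
    the expensive end of the ladder.
    """

    molecules: list[Molecule]
    labels: np.ndarray
    hierarchy: FidelityHierarchy = field(default_factory=FidelityHierarchy)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.float64)
        n, F = len(self.molecules), self.hierarchy.F
        if self.labels.shape != (n, F):
            raise ValueError(f"labels must be ({n}, {F}), got {self.labels.shape}")
        self._check_closure()

    def _check_closure(self) -> None:
        present = ~np.isnan(self.labels)
        # label at f+1 requires label at f: present mask must be a prefix row-wise
        bad = np.where(np.any(~present[:, :-1] & present[:, 1:], axis=1))[0]
        if bad.size:
            ids = [self.molecules[i].id for i in bad[:10]]
            raise ValueError(
                "downward closure violated (label at a fidelity without the cheaper "
                f"fidelity) for molecules: {ids}"
            )

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.molecules]

    def labels_at(self, f: int) -> np.ndarray:
        """Label vector at 1-based fidelity ``f`` (NaN where missing)."""
        if not 1 <= f <= self.hierarchy.F:
            raise IndexError(f"fidelity index {f} outside 1..{self.hierarchy.F}")
        return self.labels[:, f - 1]

    def top_fidelity_per_molecule(self) -> np.ndarray:
        """Highest labeled fidelity per molecule (0 if unlabeled everywhere)."""
        return (~np.isnan(self.labels)).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format label table (id, fidelity, energy_kcal_mol)."""
        rows = []
        for i, mol in enumerate(self.molecules):
            for j, name in enumerate(self.hierarchy.names):
                if not np.isnan(self.labels[i, j]):
                    rows.append((mol.id, name, self.labels[i, j]))
        return pd.DataFrame(rows, columns=["id", "fidelity", "energy_kcal_mol"])


def read_labels(path) -> pd.DataFrame:
    """Read a label CSV with columns id, fidelity, energy_kcal_mol."""
    table = pd.read_csv(path)
    missing = {"id", "fidelity", "energy_kcal_mol"} - set(table.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    return table


def write_labels(dataset: MultiFidelityDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def assemble_dataset(
    molecules: Sequence[Molecule],
    label_table: pd.DataFrame,
    hierarchy: FidelityHierarchy,
) -> MultiFidelityDataset:
    """Combine molecules and a tidy label table into a dataset.

    The table must have columns ``id, fidelity, energy_kcal_mol``.  Unknown
    molecule IDs, unknown fidelity names, duplicate (id, fidelity) entries
    and downward-closure violations are all rejected with the offending
    identifiers in the error message.  Assembly is equivariant under
    permutation of the molecule list.
    """
    id_to_row = {m.id: i for i, m in enumerate(molecules)}
    if len(id_to_row) != len(molecules):
        raise ValueError("molecule IDs must be unique")
    unknown_ids = sorted(set(label_table["id"]) - set(id_to_row))
    if unknown_ids:
        raise ValueError(f"label table references unknown molecule IDs: {unknown_ids[:10]}")
    unknown_fid = sorted(set(label_table["fidelity"]) - set(hierarchy.names))
    if unknown_fid:
        raise ValueError(f"label table references unknown fidelities: {unknown_fid}")
    dup = label_table.duplicated(subset=["id", "fidelity"], keep=False)
    if dup.any():
        pairs = label_table.loc[dup, ["id", "fidelity"]].drop_duplicates().values.tolist()
        raise ValueError(f"duplicate (id, fidelity) label entries: {pairs[:10]}")

    labels = np.full((len(molecules), hierarchy.F), np.nan)
    for rec in label_table.itertuples(index=False):
        labels[id_to_row[rec.id], hierarchy.index(rec.fidelity) - 1] = rec.energy_kcal_mol
    # MultiFidelityDataset validates downward closure and reports offenders
    return MultiFidelityDataset(list(molecules), labels, hierarchy)
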