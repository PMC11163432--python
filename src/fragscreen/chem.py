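"""Ligand parsing: SMILES records and the molecular-graph substrate.

All fingerprint schemes operate on :class:`MolecularGraph`, a minimal
element/bond-order view of a molecule. Parsing, valence checking and
aromaticity perception are delegated to RDKit; the graph keeps a handle on
the parsed molecule so substructure-key evaluation can reuse it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: Bond-order codes used in path and environment encodings. Aromatic bonds
#: get their own symbol so kekulization choices never leak into bit values.
BOND_CODES = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: 4,
}


class SmilesParseError(ValueError):
    """Raised when a SMILES record cannot be parsed; carries the record text."""

    def __init__(self, record: str):
        self.record = record
        super().__init__(f"unparsable SMILES record: {record!r}")


class SmilesRecord(NamedTuple):
    """One library entry: a SMILES string and its identifier."""

    smiles: str
    mol_id: str


@dataclass(frozen=True)
class Atom:
    element: str
    formal_charge: int
    aromatic: bool
    n_hydrogens: int
    in_ring: bool


@dataclass(frozen=True)
class Bond:
    atoms: tuple[int, int]
    order: int  # 1, 2, 3 or 4 (aromatic)


@dataclass
class MolecularGraph:
    """Atoms and bonds of a parsed ligand.

    Invariants: at least one atom; bond endpoints are valid, distinct atom
    indices.
    """

    atoms: list[Atom]
    bonds: list[Bond]
    source_smiles: str
    _rdkit_mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("molecular graph must contain at least one atom")
        n = len(self.atoms)
        for bond in self.bonds:
            i, j = bond.atoms
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond endpoint out of range: {bond.atoms}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self) -> list[list[tuple[int, int]]]:
        """Adjacency as per-atom lists of (neighbor index, bond-order code)."""
        adj: list[list[tuple[int, int]]] = [[] for _ in self.atoms]
        for bond in self.bonds:
            i, j = bond.atoms
            adj[i].append((j, bond.order))
            adj[j].append((i, bond.order))
        return adj

    def to_rdkit(self) -> Chem.Mol:
        if self._rdkit_mol is None:
            mol = Chem.MolFromSmiles(self.source_smiles)
            if mol is None:  # pragma: no cover - graph came from a valid parse
                raise SmilesParseError(self.source_smiles)
            object.__setattr__(self, "_rdkit_mol", mol)
        return self._rdkit_mol


def graph_from_rdkit(mol: Chem.Mol, source_smiles: str) -> MolecularGraph:
    atoms = [
        Atom(
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            aromatic=a.GetIsAromatic(),
            n_hydrogens=a.GetTotalNumHs(),
            in_ring=a.IsInRing(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = [
        Bond(
            atoms=(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
            order=BOND_CODES.get(b.GetBondType(), 1),
        )
        for b in mol.GetBonds()
    ]
    return MolecularGraph(atoms=atoms, bonds=bonds, source_smiles=source_smiles,
                          _rdkit_mol=mol)


def parse_smiles(record: str) -> MolecularGraph:
    """Parse a single SMILES string into a :class:`MolecularGraph`.

    Aromaticity is perceived by RDKit; the result is deterministic for a
    given record. Raises :class:`SmilesParseError` on invalid input.
    """
    if not record or not record.strip():
        raise SmilesParseError(record)
    smiles = record.strip()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise SmilesParseError(smiles)
    return graph_from_rdkit(mol, smiles)


def read_smiles_file(path) -> list[SmilesRecord]:
    """Read a SMILES library: one ``SMILES<whitespace>identifier`` per line.

    Lines starting with ``#`` and blank lines are skipped. A record without
    an explicit identifier gets its 1-based line number as identifier.
    """
    records: list[SmilesRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else str(lineno)
            records.append(SmilesRecord(smiles=smiles, mol_id=mol_id))
    return records


def write_smiles_file(path, records: list[SmilesRecord]) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f"{rec.smiles}\t{rec.mol_id}\n")
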