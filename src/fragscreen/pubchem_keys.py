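"""Synthetic 881-entry substructure-key table.

The 881-bit substructure-key fingerprint scheme assigns one bit per keyed
feature: hierarchic element counts, ring-system features, atom pairs, atom
neighborhoods, and SMARTS patterns. The genuine CACTVS/PubChem key list is
distributed with external descriptor software and is not bundled with any
toolkit available here, so this module generates a *synthetic* table that
follows the published section layout and sizes exactly:

======================================  =========  =====
section                                 bits       count
======================================  =========  =====
hierarchic element counts               0-114      115
ring features (sizes 3-10 + global)     115-262    148
simple atom pairs                       263-326    64
simple atom nearest neighbors           327-415    89
detailed atom neighborhoods             416-459    44
simple SMARTS patterns                  460-712    253
complex SMARTS patterns                 713-880    168
======================================  =========  =====

Bit semantics match the scheme's contract — bit k is set iff the keyed
feature occurs at least ``min_count`` times — but the individual patterns
are this package's own systematic enumeration, not the external tool's,
so bit-for-bit parity with externally computed descriptor tables is not
implied. Precomputed 881-column descriptor tables can be ingested instead
(see :func:`fragscreen.io.read_descriptor_table`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

from rdkit import Chem

from .chem import MolecularGraph

N_KEYS = 881

_ATOMIC_NUM = {
    "C": 6, "N": 7, "O": 8, "S": 16, "P": 15, "F": 9, "Cl": 17, "Br": 35,
    "I": 53, "Si": 14, "B": 5, "Se": 34,
}


class KeyTableError(ValueError):
    """Raised when a key table is malformed (names the offending key)."""


@dataclass(frozen=True)
class SubstructureKey:
    """One keyed feature: bit ``index`` is set when the pattern occurs at
    least ``min_count`` times.

    ``kind`` selects the evaluator: ``element`` (pattern is an element
    symbol, or ``H`` for total hydrogen count), ``ring`` (pattern is
    ``size:class`` with size ``any`` or 3-10), or ``smarts``.
    """

    index: int
    kind: str
    pattern: str
    min_count: int
    description: str


class SubstructureKeyTable:
    """Ordered table of exactly 881 substructure keys, indices 0..880."""

    def __init__(self, keys: list[SubstructureKey]):
        if len(keys) != N_KEYS:
            raise KeyTableError(
                f"key table must have exactly {N_KEYS} entries, got {len(keys)}"
            )
        if [k.index for k in keys] != list(range(N_KEYS)):
            raise KeyTableError("key indices must be 0..880, each exactly once")
        self.keys = keys
        self._compiled: dict[int, Chem.Mol] = {}
        for key in keys:
            if key.kind == "smarts":
                patt = Chem.MolFromSmarts(key.pattern)
                if patt is None:
                    raise KeyTableError(
                        f"key {key.index}: malformed SMARTS {key.pattern!r}"
                    )
                self._compiled[key.index] = patt
            elif key.kind not in ("element", "ring"):
                raise KeyTableError(
                    f"key {key.index}: unknown kind {key.kind!r}"
                )

    def __len__(self) -> int:
        return len(self.keys)

    def __iter__(self):
        return iter(self.keys)

    def find(self, text: str) -> list[SubstructureKey]:
        """Keys whose description contains ``text`` (case-insensitive)."""
        needle = text.lower()
        return [k for k in self.keys if needle in k.description.lower()]

    # -- evaluation --------------------------------------------------------

    def evaluate(self, mol: MolecularGraph) -> set[int]:
        """Indices of all keys satisfied by the molecule."""
        element_counts = self._element_counts(mol)
        ring_counts = None  # computed lazily; needs the RDKit mol
        rdmol = None
        out: set[int] = set()
        for key in self.keys:
            if key.kind == "element":
                if element_counts.get(key.pattern, 0) >= key.min_count:
                    out.add(key.index)
            elif key.kind == "ring":
                if ring_counts is None:
                    ring_counts = _ring_feature_counts(mol.to_rdkit())
                if ring_counts.get(key.pattern, 0) >= key.min_count:
                    out.add(key.index)
            else:
                if rdmol is None:
                    rdmol = mol.to_rdkit()
                patt = self._compiled[key.index]
                if key.min_count == 1:
                    if rdmol.HasSubstructMatch(patt):
                        out.add(key.index)
                else:
                    matches = rdmol.GetSubstructMatches(
                        patt, uniquify=True, maxMatches=key.min_count + 64
                    )
                    if len(matches) >= key.min_count:
                        out.add(key.index)
        return out

    @staticmethod
    def _element_counts(mol: MolecularGraph) -> dict[str, int]:
        counts: dict[str, int] = {}
        n_h = 0
        for atom in mol.atoms:
            counts[atom.element] = counts.get(atom.element, 0) + 1
            n_h += atom.n_hydrogens
        counts["H"] = counts.get("H", 0) + n_h
        return counts


def _ring_feature_counts(rdmol: Chem.Mol) -> dict[str, int]:
    """Count SSSR rings per (size, class) feature label."""
    info = rdmol.GetRingInfo()
    counts: dict[str, int] = {}

    def bump(label: str) -> None:
        counts[label] = counts.get(label, 0) + 1

    for atom_ring, bond_ring in zip(info.AtomRings(), info.BondRings()):
        atoms = [rdmol.GetAtomWithIdx(i) for i in atom_ring]
        bonds = [rdmol.GetBondWithIdx(i) for i in bond_ring]
        size = len(atom_ring)
        aromatic = all(a.GetIsAromatic() for a in atoms)
        hetero = any(a.GetSymbol() != "C" for a in atoms)
        classes = ["any"]
        if not hetero:
            classes.append("carbocyclic")
        if any(a.GetSymbol() == "N" for a in atoms):
            classes.append("nitrogen")
        if any(a.GetSymbol() == "O" for a in atoms):
            classes.append("oxygen")
        if hetero:
            classes.append("hetero")
        if aromatic:
            classes.append("aromatic")
            if hetero:
                classes.append("heteroaromatic")
        elif all(b.GetBondType() == Chem.BondType.SINGLE for b in bonds):
            classes.append("saturated")
        else:
            classes.append("unsaturated")
        size_tag = str(size) if 3 <= size <= 10 else "other"
        for cls in classes:
            bump(f"{size_tag}:{cls}")
        bump("any:any")
    return counts


# ---------------------------------------------------------------------------
# Table generation
# ---------------------------------------------------------------------------

def _element_section() -> list[tuple[str, str, int, str]]:
    custom = [
        ("H", [1, 2, 4, 8, 16, 32]),
        ("C", [1, 2, 4, 8, 16, 32]),
        ("N", [1, 2, 4, 8]),
        ("O", [1, 2, 4, 8, 16]),
        ("F", [1, 2, 4]),
        ("S", [1, 2, 4, 8]),
        ("Cl", [1, 2, 4]),
        ("Br", [1, 2, 4]),
        ("I", [1, 2]),
        ("P", [1, 2, 4]),
    ]
    rare = [
        "Li", "Be", "B", "Na", "Mg", "Al", "Si", "K", "Ca", "Sc", "Ti", "V",
        "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se",
        "Sn", "Sb", "Te", "Ba", "W", "Pt", "Au", "Hg", "Pb", "Bi", "Ag",
        "Pd", "Cd", "Mo", "Zr",
    ]
    entries = []
    for symbol, thresholds in custom:
        for t in thresholds:
            entries.append(
                ("element", symbol, t, f"at least {t} {symbol} atom(s)")
            )
    for symbol in rare:
        for t in (1, 2):
            entries.append(
                ("element", symbol, t, f"at least {t} {symbol} atom(s)")
            )
    assert len(entries) == 115
    return entries


_RING_CLASSES = [
    ("any", [1, 2, 3], "ring"),
    ("carbocyclic", [1, 2], "carbocyclic ring"),
    ("nitrogen", [1, 2], "nitrogen-containing ring"),
    ("oxygen", [1, 2], "oxygen-containing ring"),
    ("hetero", [1, 2], "heteroatom-containing ring"),
    ("saturated", [1, 2], "saturated ring"),
    ("unsaturated", [1, 2], "unsaturated non-aromatic ring"),
    ("aromatic", [1, 2], "aromatic ring"),
    ("heteroaromatic", [1], "heteroaromatic ring"),
]


def _ring_section() -> list[tuple[str, str, int, str]]:
    entries = []
    for size in range(3, 11):
        for cls, thresholds, label in _RING_CLASSES:
            for t in thresholds:
                entries.append(
                    ("ring", f"{size}:{cls}", t,
                     f"at least {t} {label}(s) of size {size}")
                )
    for t in (1, 2, 3, 4):
        entries.append(("ring", "any:any", t, f"at least {t} ring(s) of any size"))
    assert len(entries) == 148
    return entries


def _pair_section() -> list[tuple[str, str, int, str]]:
    elements = ["C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "Si", "B", "Se"]
    entries = []
    for a, b in itertools.combinations_with_replacement(elements, 2):
        smarts = f"[#{_ATOMIC_NUM[a]}]~[#{_ATOMIC_NUM[b]}]"
        entries.append(("smarts", smarts, 1, f"{a} bonded to {b}"))
        if len(entries) == 64:
            break
    assert len(entries) == 64
    return entries


def _neighbor_section() -> list[tuple[str, str, int, str]]:
    centers = ["C", "N", "O", "S", "P"]
    nbrs = ["C", "N", "O", "S", "P", "F", "Cl", "Br"]
    entries = []
    for center in centers:
        for a, b in itertools.combinations_with_replacement(nbrs, 2):
            smarts = (f"[#{_ATOMIC_NUM[center]}](~[#{_ATOMIC_NUM[a]}])"
                      f"~[#{_ATOMIC_NUM[b]}]")
            entries.append(
                ("smarts", smarts, 1, f"{center} with neighbors {a},{b}")
            )
            if len(entries) == 89:
                return entries
    raise AssertionError("neighbor section underfilled")


def _detailed_neighbor_section() -> list[tuple[str, str, int, str]]:
    entries = []
    for center in ("C", "N"):
        for trio in itertools.combinations_with_replacement(
                ["C", "N", "O", "S"], 3):
            smarts = f"[#{_ATOMIC_NUM[center]}]" + "".join(
                f"(~[#{_ATOMIC_NUM[x]}])" for x in trio[:-1]
            ) + f"~[#{_ATOMIC_NUM[trio[-1]]}]"
            entries.append(
                ("smarts", smarts, 1,
                 f"{center} with neighbors {','.join(trio)}")
            )
    for center, trio in (("S", ("C", "C", "C")), ("S", ("C", "C", "N")),
                         ("P", ("C", "C", "C")), ("P", ("O", "O", "O"))):
        smarts = f"[#{_ATOMIC_NUM[center]}]" + "".join(
            f"(~[#{_ATOMIC_NUM[x]}])" for x in trio[:-1]
        ) + f"~[#{_ATOMIC_NUM[trio[-1]]}]"
        entries.append(
            ("smarts", smarts, 1, f"{center} with neighbors {','.join(trio)}")
        )
    assert len(entries) == 44
    return entries


def _simple_smarts_section() -> list[tuple[str, str, int, str]]:
    elements = ["C", "N", "O", "S", "P"]
    bonds = {"-": "single", "=": "double", "#": "triple"}
    pair_patterns = []
    for a, b in itertools.combinations_with_replacement(elements, 2):
        for bond, bond_name in bonds.items():
            pair_patterns.append(
                (f"{a}{bond}{b}", f"{a} {bond_name}-bonded to {b}")
            )
    entries = []
    for threshold in (1, 2, 3):
        for smarts, desc in pair_patterns:
            entries.append(
                ("smarts", smarts, threshold,
                 f"at least {threshold} of {desc}")
            )
    for threshold in (1, 2):
        for a, b in itertools.combinations_with_replacement(
                ["c", "n", "o", "s"], 2):
            entries.append(
                ("smarts", f"{a}:{b}", threshold,
                 f"at least {threshold} aromatic {a.upper()}-{b.upper()} bond(s)")
            )
    hydro = ["[CH3]", "[CH2]", "[CH1]", "[NH2]", "[NH1]", "[OH1]", "[SH1]"]
    for threshold in (1, 2):
        for h in hydro:
            for nbr in ("[#6]", "[#7]", "[#8]"):
                entries.append(
                    ("smarts", f"{h}-{nbr}", threshold,
                     f"at least {threshold} {h} single-bonded to {nbr}")
                )
    for charged, desc in (("[N+]", "positively charged N"),
                          ("[O-]", "negatively charged O"),
                          ("[S-]", "negatively charged S"),
                          ("[C-]", "carbanion"),
                          ("[P+]", "positively charged P")):
        entries.append(("smarts", charged, 1, f"at least 1 {desc}"))
    for t in (1, 2, 4, 8):
        entries.append(("smarts", "[R]", t, f"at least {t} ring atom(s)"))
    for hal in ("F", "Cl", "Br", "I"):
        for t in (1, 2, 3):
            entries.append(
                ("smarts", f"[{hal}]-[#6]", t,
                 f"at least {t} {hal}-carbon bond(s)")
            )
    for degree_key in ("[CX4]", "[CX3]", "[CX2]", "[NX3]", "[NX2]", "[OX2]"):
        for t in (1, 2):
            entries.append(
                ("smarts", degree_key, t,
                 f"at least {t} atom(s) matching {degree_key}")
            )
    for sub_key in ("[cH0]", "[cH1]"):
        for t in (1, 2, 3):
            entries.append(
                ("smarts", sub_key, t,
                 f"at least {t} aromatic carbon(s) matching {sub_key}")
            )
    for t in (1, 2, 3, 4):
        entries.append(
            ("smarts", "[!#6;!#1]", t, f"at least {t} heteroatom(s)")
        )
    for t in (1, 2, 3, 4):
        entries.append(("smarts", "[#6;R]", t, f"at least {t} ring carbon(s)"))
    for t in (1, 2):
        entries.append(("smarts", "[#7;R]", t, f"at least {t} ring nitrogen(s)"))
    for t in (1, 2):
        entries.append(("smarts", "[#8;R]", t, f"at least {t} ring oxygen(s)"))
    for t in (1, 2, 4, 6, 8):
        entries.append(("smarts", "[a]", t, f"at least {t} aromatic atom(s)"))
    assert len(entries) == 253
    return entries


def _complex_smarts_section() -> list[tuple[str, str, int, str]]:
    elements = ["C", "N", "O", "S"]
    bonds = ["-", "="]
    seen = set()
    entries = []
    for e1, b1, e2, b2, e3 in itertools.product(
            elements, bonds, elements, bonds, elements):
        forward = f"{e1}{b1}{e2}{b2}{e3}"
        backward = f"{e3}{b2}{e2}{b1}{e1}"
        canonical = min(forward, backward)
        if canonical in seen:
            continue
        seen.add(canonical)
        entries.append(
            ("smarts", canonical, 1, f"three-atom chain {canonical}")
        )
    assert len(entries) == 144
    for sub in ("C", "N", "O", "S", "F", "Cl", "Br", "I"):
        entries.append(
            ("smarts", f"c1ccccc1{sub}", 1,
             f"benzene ring substituted with {sub}")
        )
    aromatic_rings = [
        ("c1ccncc1", "pyridine ring"),
        ("c1ccoc1", "furan ring"),
        ("c1ccsc1", "thiophene ring"),
        ("c1cc[nH]c1", "pyrrole ring"),
        ("c1cncnc1", "pyrimidine ring"),
        ("c1cnc[nH]1", "imidazole ring"),
    ]
    for smarts, desc in aromatic_rings:
        entries.append(("smarts", smarts, 1, desc))
    four_atom = [
        ("C-C-C-C", "butane chain"),
        ("C-C=C-C", "internal alkene chain"),
        ("C=C-C=C", "conjugated diene"),
        ("C-C-C-N", "propylamine chain"),
        ("C-C-C-O", "propanol chain"),
        ("N-C-C-N", "ethylenediamine motif"),
        ("O-C-C-O", "glycol motif"),
        ("C-C(=O)-N", "amide motif"),
        ("C-C(=O)-O", "carboxyl/ester motif"),
        ("O=C-C=O", "dicarbonyl motif"),
    ]
    for smarts, desc in four_atom:
        entries.append(("smarts", smarts, 1, desc))
    assert len(entries) == 168
    return entries


def build_default_keys() -> SubstructureKeyTable:
    """Build the packaged synthetic 881-key table."""
    raw = (
        _element_section()
        + _ring_section()
        + _pair_section()
        + _neighbor_section()
        + _detailed_neighbor_section()
        + _simple_smarts_section()
        + _complex_smarts_section()
    )
    keys = [
        SubstructureKey(index=i, kind=kind, pattern=pattern,
                        min_count=count, description=desc)
        for i, (kind, pattern, count, desc) in enumerate(raw)
    ]
    return SubstructureKeyTable(keys)


@lru_cache(maxsize=1)
def default_key_table() -> SubstructureKeyTable:
    return build_default_keys()


def write_key_table_tsv(table: SubstructureKeyTable, path) -> None:
    with open(path, "w") as handle:
        handle.write("index\tkind\tpattern\tmin_count\tdescription\n")
        for key in table:
            handle.write(
                f"{key.index}\t{key.kind}\t{key.pattern}\t{key.min_count}\t"
                f"{key.description}\n"
            )


def read_key_table_tsv(path) -> SubstructureKeyTable:
    keys = []
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("index\t"):
            raise KeyTableError("missing key-table header")
        for line in handle:
            idx, kind, pattern, count, desc = line.rstrip("\n").split("\t")
            keys.append(SubstructureKey(int(idx), kind, pattern,
                                        int(count), desc))
    return SubstructureKeyTable(keys)
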