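"""Ligand fingerprints: Morgan (extended-connectivity), FP2-style linear
paths, and 881-bit substructure keys, with a common folding convention.

Conventions shared by all hashed schemes:

* identifiers are 32-bit values from a pinned FNV-1a hash, so bit patterns
  are reproducible across runs and platforms;
* an identifier is folded to a bit index by ``identifier mod length``;
  indices are 0-based internally and rendered 1-based only in text dumps;
* standard lengths are 881 (substructure keys), 1024 (FP2) and 2048
  (Morgan); their concatenation is 3953 bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .chem import MolecularGraph, SmilesRecord, parse_smiles

FNV_OFFSET = 0x811C9DC5
FNV_PRIME = 0x01000193
_MASK32 = 0xFFFFFFFF


class Scheme(str, Enum):
    PUBCHEM = "pubchem"
    FP2 = "fp2"
    MORGAN = "morgan"


#: Standard folded length per scheme.
SCHEME_LENGTHS = {Scheme.PUBCHEM: 881, Scheme.FP2: 1024, Scheme.MORGAN: 2048}

#: Fixed block order of the combined fingerprint.
BLOCK_ORDER = (Scheme.PUBCHEM, Scheme.FP2, Scheme.MORGAN)

#: Ablation name -> blocks retained (order is always BLOCK_ORDER).
ABLATIONS: dict[str, tuple[Scheme, ...]] = {
    "full": (Scheme.PUBCHEM, Scheme.FP2, Scheme.MORGAN),
    "noFP2": (Scheme.PUBCHEM, Scheme.MORGAN),
    "noPubChem": (Scheme.FP2, Scheme.MORGAN),
    "noMF": (Scheme.PUBCHEM, Scheme.FP2),
    "onlyMF": (Scheme.MORGAN,),
}


def fnv1a_32(data: bytes) -> int:
    """Pinned 32-bit FNV-1a hash; the only hash behind Morgan and FP2 bits."""
    h = FNV_OFFSET
    for byte in data:
        h = ((h ^ byte) * FNV_PRIME) & _MASK32
    return h


def hash_identifier(*parts) -> int:
    """Hash a heterogeneous tuple (ints and strings) to a 32-bit identifier."""
    chunks = []
    for part in parts:
        if isinstance(part, str):
            chunks.append(b"s" + part.encode())
        else:
            chunks.append(b"i" + int(part).to_bytes(8, "big", signed=True))
    return fnv1a_32(b"\x1f".join(chunks))


def fold_identifier(hash_value: int, length: int) -> int:
    """Fold a hash value to a bit index: ``hash_value mod length``, 0-based.

    Text dumps render indices 1-based (the common display convention);
    internally bit 0 is a real bit.
    """
    if length < 1:
        raise ValueError("fold length must be positive")
    if hash_value < 0:
        raise ValueError("hash value must be non-negative")
    return hash_value % length


@dataclass(frozen=True)
class BitFingerprint:
    """A fixed-length bit vector for one scheme, stored as its set bits."""

    scheme: Scheme
    length: int
    set_bits: frozenset[int]

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("fingerprint length must be positive")
        if any(not (0 <= b < self.length) for b in self.set_bits):
            raise ValueError("set bit outside [0, length)")

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.length, dtype=np.uint8)
        if self.set_bits:
            arr[sorted(self.set_bits)] = 1
        return arr

    @property
    def n_bits_set(self) -> int:
        return len(self.set_bits)


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto coefficient |a∩b| / |a∪b|; 0.0 when both are empty."""
    if a.scheme != b.scheme or a.length != b.length:
        raise ValueError(
            f"fingerprint mismatch: {a.scheme.value}/{a.length} vs "
            f"{b.scheme.value}/{b.length}"
        )
    union = len(a.set_bits | b.set_bits)
    if union == 0:
        return 0.0
    return len(a.set_bits & b.set_bits) / union


# ---------------------------------------------------------------------------
# Morgan (extended-connectivity) fingerprint
# ---------------------------------------------------------------------------

def _initial_invariants(mol: MolecularGraph) -> list[int]:
    adj = mol.neighbors()
    inv = []
    for idx, atom in enumerate(mol.atoms):
        inv.append(
            hash_identifier(
                "ATOM",
                atom.element,
                len(adj[idx]),
                atom.n_hydrogens,
                atom.formal_charge,
                int(atom.in_ring),
                int(atom.aromatic),
            )
        )
    return inv


def morgan_identifiers(mol: MolecularGraph, radius: int = 2) -> set[int]:
    """All distinct environment identifiers up to ``radius`` iterations.

    Round r hashes each atom's round-(r-1) identifier with the sorted
    (bond order, neighbor identifier) pairs, which makes the result
    independent of atom input order. An atom whose environment atom set
    stopped growing keeps its identifier and contributes no duplicate.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if mol.n_atoms == 0:
        raise ValueError("cannot fingerprint an empty molecule")
    adj = mol.neighbors()
    ids = _initial_invariants(mol)
    envs: list[frozenset[int]] = [frozenset([i]) for i in range(mol.n_atoms)]
    identifiers: set[int] = set(ids)
    for rnd in range(1, radius + 1):
        new_ids = list(ids)
        new_envs = list(envs)
        for a in range(mol.n_atoms):
            grown = frozenset().union(envs[a], *(envs[n] for n, _ in adj[a]))
            if grown == envs[a]:
                continue  # saturated environment: dedup, keep old identifier
            pairs = sorted((order, ids[n]) for n, order in adj[a])
            flat = [x for pair in pairs for x in pair]
            new_ids[a] = hash_identifier("ITER", rnd, ids[a], *flat)
            new_envs[a] = grown
            identifiers.add(new_ids[a])
        ids, envs = new_ids, new_envs
    return identifiers


def morgan_fingerprint(mol: MolecularGraph, radius: int = 2,
                       length: int = 2048) -> BitFingerprint:
    """Extended-connectivity fingerprint folded to ``length`` bits.

    Defaults (radius 2, 2048 bits) follow the ECFP4-style configuration
    standard in virtual screening.
    """
    bits = frozenset(
        fold_identifier(h, length) for h in morgan_identifiers(mol, radius)
    )
    return BitFingerprint(scheme=Scheme.MORGAN, length=length, set_bits=bits)


# ---------------------------------------------------------------------------
# FP2-style linear-path fingerprint
# ---------------------------------------------------------------------------

def linear_path_encodings(mol: MolecularGraph, max_atoms: int = 7
                          ) -> set[tuple]:
    """Distinct encodings of all simple linear paths of 2..max_atoms atoms.

    A path is read as (element, bond, element, ..., element) in whichever
    direction is lexicographically smaller, so both traversal directions
    collapse to one encoding. Single atoms and ring closures as such are
    not indexed — only linear segments.
    """
    if mol.n_atoms == 0:
        raise ValueError("cannot fingerprint an empty molecule")
    adj = mol.neighbors()
    elements = [a.element for a in mol.atoms]
    encodings: set[tuple] = set()

    def extend(path: list[int], encoding: list) -> None:
        if len(path) >= 2:
            forward = tuple(encoding)
            backward = tuple(reversed(encoding))
            encodings.add(min(forward, backward))
        if len(path) == max_atoms:
            return
        last = path[-1]
        for nbr, order in adj[last]:
            if nbr in path:
                continue
            path.append(nbr)
            encoding.extend((order, elements[nbr]))
            extend(path, encoding)
            path.pop()
            del encoding[-2:]

    for start in range(mol.n_atoms):
        extend([start], [elements[start]])
    return encodings


def fp2_fingerprint(mol: MolecularGraph, length: int = 1024) -> BitFingerprint:
    """Path-based fingerprint over linear fragments of up to 7 atoms,
    folded to ``length`` bits (1024 by default)."""
    bits = frozenset(
        fold_identifier(hash_identifier("PATH", *enc), length)
        for enc in linear_path_encodings(mol)
    )
    return BitFingerprint(scheme=Scheme.FP2, length=length, set_bits=bits)


# ---------------------------------------------------------------------------
# Substructure-key fingerprint (881 keys)
# ---------------------------------------------------------------------------

def pubchem_fingerprint(mol: MolecularGraph, keys=None) -> BitFingerprint:
    """881-bit substructure-key fingerprint.

    Bit k is set iff key k's pattern occurs in the molecule at least its
    minimum count. Keys default to the packaged 881-entry table (see
    :mod:`fragscreen.pubchem_keys`).
    """
    from .pubchem_keys import default_key_table

    table = keys if keys is not None else default_key_table()
    bits = frozenset(table.evaluate(mol))
    return BitFingerprint(scheme=Scheme.PUBCHEM, length=len(table),
                          set_bits=bits)


# ---------------------------------------------------------------------------
# Combined fingerprint
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CombinedFingerprint:
    """Concatenation of per-scheme blocks in fixed PUBCHEM|FP2|MORGAN order."""

    blocks: tuple[Scheme, ...]
    offsets: dict[Scheme, int]
    lengths: dict[Scheme, int]
    length: int
    set_bits: frozenset[int]

    def block(self, scheme: Scheme) -> BitFingerprint:
        """Recover one original block from the concatenated vector."""
        if scheme not in self.blocks:
            raise KeyError(f"block {scheme.value} not present")
        start = self.offsets[scheme]
        stop = start + self.lengths[scheme]
        bits = frozenset(b - start for b in self.set_bits if start <= b < stop)
        return BitFingerprint(scheme=scheme, length=self.lengths[scheme],
                              set_bits=bits)

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.length, dtype=np.uint8)
        if self.set_bits:
            arr[sorted(self.set_bits)] = 1
        return arr


def combine_fingerprints(
    pub: BitFingerprint | None,
    fp2: BitFingerprint | None,
    mf: BitFingerprint | None,
    ablation: str = "full",
) -> CombinedFingerprint:
    """Concatenate the retained scheme blocks for an ablation setting.

    The full three-block vector is 881 + 1024 + 2048 = 3953 bits.
    """
    if ablation not in ABLATIONS:
        raise ValueError(
            f"unknown ablation {ablation!r}; expected one of {list(ABLATIONS)}"
        )
    retained = ABLATIONS[ablation]
    if not retained:  # pragma: no cover - no such ablation is defined
        raise ValueError("cannot drop every fingerprint block")
    provided = {Scheme.PUBCHEM: pub, Scheme.FP2: fp2, Scheme.MORGAN: mf}
    offsets: dict[Scheme, int] = {}
    lengths: dict[Scheme, int] = {}
    set_bits: set[int] = set()
    offset = 0
    for scheme in retained:
        fp = provided[scheme]
        if fp is None:
            raise ValueError(f"ablation {ablation!r} requires a "
                             f"{scheme.value} fingerprint")
        if fp.scheme != scheme:
            raise ValueError(f"expected {scheme.value} block, got "
                             f"{fp.scheme.value}")
        if fp.length != SCHEME_LENGTHS[scheme]:
            raise ValueError(
                f"{scheme.value} block must have standard length "
                f"{SCHEME_LENGTHS[scheme]}, got {fp.length}"
            )
        offsets[scheme] = offset
        lengths[scheme] = fp.length
        set_bits.update(offset + b for b in fp.set_bits)
        offset += fp.length
    return CombinedFingerprint(blocks=retained, offsets=offsets,
                               lengths=lengths, length=offset,
                               set_bits=frozenset(set_bits))


def combined_fingerprint_for(mol: MolecularGraph, ablation: str = "full",
                             keys=None) -> CombinedFingerprint:
    """Compute only the blocks an ablation retains and concatenate them."""
    if ablation not in ABLATIONS:
        raise ValueError(
            f"unknown ablation {ablation!r}; expected one of {list(ABLATIONS)}"
        )
    retained = ABLATIONS[ablation]
    pub = pubchem_fingerprint(mol, keys) if Scheme.PUBCHEM in retained else None
    fp2 = fp2_fingerprint(mol) if Scheme.FP2 in retained else None
    mf = morgan_fingerprint(mol) if Scheme.MORGAN in retained else None
    return combine_fingerprints(pub, fp2, mf, ablation=ablation)


def fingerprint_for_scheme(mol: MolecularGraph, scheme: Scheme,
                           keys=None) -> BitFingerprint:
    if scheme == Scheme.MORGAN:
        return morgan_fingerprint(mol)
    if scheme == Scheme.FP2:
        return fp2_fingerprint(mol)
    return pubchem_fingerprint(mol, keys)


def ablation_length(ablation: str) -> int:
    return sum(SCHEME_LENGTHS[s] for s in ABLATIONS[ablation])


# ---------------------------------------------------------------------------
# scikit-learn transformer wrappers
# ---------------------------------------------------------------------------

from sklearn.base import BaseEstimator, TransformerMixin  # noqa: E402


class _FingerprintTransformer(TransformerMixin, BaseEstimator):
    """Stateless SMILES -> bit-matrix transformer (fit is a no-op)."""

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def _fingerprint(self, smiles: str):
        raise NotImplementedError

    def transform(self, X) -> np.ndarray:
        rows = []
        for smiles in X:
            fp = self._fingerprint(str(smiles))
            rows.append(fp.to_array())
        if not rows:
            raise ValueError("cannot transform an empty SMILES collection")
        return np.stack(rows)


class MorganFingerprinter(_FingerprintTransformer):
    """Extended-connectivity fingerprints as a sklearn transformer."""

    def __init__(self, radius: int = 2, n_bits: int = 2048):
        self.radius = radius
        self.n_bits = n_bits

    def _fingerprint(self, smiles: str) -> BitFingerprint:
        return morgan_fingerprint(parse_smiles(smiles), radius=self.radius,
                                  length=self.n_bits)


class FP2Fingerprinter(_FingerprintTransformer):
    """Linear-path fingerprints as a sklearn transformer."""

    def __init__(self, n_bits: int = 1024):
        self.n_bits = n_bits

    def _fingerprint(self, smiles: str) -> BitFingerprint:
        return fp2_fingerprint(parse_smiles(smiles), length=self.n_bits)


class PubChemFingerprinter(_FingerprintTransformer):
    """881-bit substructure-key fingerprints as a sklearn transformer.

    ``keys=None`` uses the packaged synthetic key table.
    """

    def __init__(self, keys=None):
        self.keys = keys

    def _fingerprint(self, smiles: str) -> BitFingerprint:
        return pubchem_fingerprint(parse_smiles(smiles), keys=self.keys)


class CombinedFingerprinter(_FingerprintTransformer):
    """Concatenated multi-scheme fingerprints under an ablation setting."""

    def __init__(self, ablation: str = "full", keys=None):
        self.ablation = ablation
        self.keys = keys

    def _fingerprint(self, smiles: str) -> CombinedFingerprint:
        return combined_fingerprint_for(parse_smiles(smiles),
                                        ablation=self.ablation,
                                        keys=self.keys)
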