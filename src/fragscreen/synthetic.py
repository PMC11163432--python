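"""Desk-scale synthetic screening benchmarks with a planted scaffold signal.

The generator emulates the shape of the standard actives/decoys screening
collections: per target, a handful of actives, a ~60:1 decoy:active ratio
(a 30:1 preset mirrors the smaller collections), template pockets with
structural-match scores and bound template ligands, and a pairwise target
sequence-identity matrix.

The planted signal lives at the fingerprint level, which is all the
screening routes ever see. Targets belong to scaffold *families*: each
family has a chemical scaffold and an amino-acid signature. A target's
template ligands are noisy copies of its family scaffold, its pocket
residues are drawn from the family's residue profile, and — with
probability ``signal_strength`` per molecule — its actives are decorated
copies of the same scaffold. Decoys are unrelated random molecules of
matched size, so at ``signal_strength = 0`` actives are distributionally
identical to decoys. Families make leave-one-target-out training
meaningful: the held-out target's scaffold is still represented by its
family partners in training.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from .benchmark import Benchmark, BenchmarkTarget
from .chem import SmilesRecord, parse_smiles
from .pockets import AMINO_ACIDS, TargetProfile, TemplatePocketRecord
from .pockets import sequence_identity

_ELEMENTS = ["C", "N", "O", "S"]
_ELEMENT_P = [0.70, 0.12, 0.12, 0.06]
_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}


@dataclass(frozen=True)
class BenchmarkSpec:
    """Benchmark geometry and signal parameters.

    ``decoy_ratio`` defaults to 60 decoys per active (the regime of the
    large standard collection); ``signal_strength`` in [0, 1] is the
    per-active probability of carrying the family scaffold.
    """

    n_targets: int = 10
    actives_per_target: int = 5
    decoy_ratio: int = 60
    signal_strength: float = 1.0
    n_families: int = 4
    scaffold_size: tuple[int, int] = (9, 13)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_targets, self.actives_per_target, self.decoy_ratio,
               self.n_families) < 1:
            raise ValueError("all benchmark counts must be positive")
        if not (0.0 <= self.signal_strength <= 1.0):
            raise ValueError("signal_strength must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Random molecules
# ---------------------------------------------------------------------------

def _free_valence(mol: Chem.RWMol, idx: int, used: dict[int, int]) -> int:
    atom = mol.GetAtomWithIdx(idx)
    cap = _VALENCE.get(atom.GetSymbol(), 4)
    if atom.GetIsAromatic():
        cap = 4 if atom.GetSymbol() == "C" else 3
        return max(0, cap - 3 - used.get(idx, 0))
    return max(0, cap - used.get(idx, 0))


def _attach_atoms(mol: Chem.RWMol, used: dict[int, int], n_new: int,
                  rng: np.random.Generator) -> None:
    """Grow a molecule by ``n_new`` singly-bonded heavy atoms."""
    for _ in range(n_new):
        hosts = [i for i in range(mol.GetNumAtoms())
                 if _free_valence(mol, i, used) >= 1]
        if not hosts:
            break
        host = int(rng.choice(hosts))
        symbol = str(rng.choice(_ELEMENTS, p=_ELEMENT_P))
        new_idx = mol.AddAtom(Chem.Atom(symbol))
        mol.AddBond(host, new_idx, Chem.BondType.SINGLE)
        used[host] = used.get(host, 0) + 1
        used[new_idx] = used.get(new_idx, 0) + 1


def _graph_distances(mol: Chem.RWMol, start: int) -> dict[int, int]:
    dist = {start: 0}
    frontier = [start]
    while frontier:
        nxt = []
        for idx in frontier:
            for nbr in mol.GetAtomWithIdx(idx).GetNeighbors():
                j = nbr.GetIdx()
                if j not in dist:
                    dist[j] = dist[idx] + 1
                    nxt.append(j)
        frontier = nxt
    return dist


def _build_random_mol(rng: np.random.Generator, n_atoms: int) -> Chem.Mol:
    mol = Chem.RWMol()
    used: dict[int, int] = {}
    aromatic_seed = n_atoms >= 8 and rng.random() < 0.30
    if aromatic_seed:
        ring = [mol.AddAtom(Chem.Atom("C")) for _ in range(6)]
        for atom_idx in ring:
            mol.GetAtomWithIdx(atom_idx).SetIsAromatic(True)
        for k in range(6):
            mol.AddBond(ring[k], ring[(k + 1) % 6], Chem.BondType.AROMATIC)
    else:
        mol.AddAtom(Chem.Atom("C"))
    _attach_atoms(mol, used, n_atoms - mol.GetNumAtoms(), rng)
    # occasional double bond on a chain C-C / C-N / C-O pair
    for bond in list(mol.GetBonds()):
        if bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        a, b = mol.GetAtomWithIdx(i), mol.GetAtomWithIdx(j)
        if a.GetIsAromatic() or b.GetIsAromatic():
            continue
        if "C" not in (a.GetSymbol(), b.GetSymbol()):
            continue
        if (_free_valence(mol, i, used) >= 1
                and _free_valence(mol, j, used) >= 1
                and rng.random() < 0.12):
            bond.SetBondType(Chem.BondType.DOUBLE)
            used[i] = used.get(i, 0) + 1
            used[j] = used.get(j, 0) + 1
    # occasional aliphatic ring closure
    if n_atoms >= 5 and rng.random() < 0.35:
        candidates = []
        for i in range(mol.GetNumAtoms()):
            if _free_valence(mol, i, used) < 1:
                continue
            dist = _graph_distances(mol, i)
            for j, d in dist.items():
                if j > i and 2 <= d <= 5 and _free_valence(mol, j, used) >= 1 \
                        and mol.GetBondBetweenAtoms(i, j) is None:
                    candidates.append((i, j))
        if candidates:
            i, j = candidates[int(rng.integers(len(candidates)))]
            mol.AddBond(i, j, Chem.BondType.SINGLE)
            used[i] = used.get(i, 0) + 1
            used[j] = used.get(j, 0) + 1
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def generate_molecule(seed: int, size_range: tuple[int, int] = (3, 30)) -> str:
    """One random, valid SMILES with a heavy-atom count in ``size_range``.

    Deterministic per seed; always parsable by :func:`parse_smiles`.
    """
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid size range")
    rng = np.random.default_rng(seed)
    return _random_smiles(rng, (lo, hi))


def _random_smiles(rng: np.random.Generator,
                   size_range: tuple[int, int]) -> str:
    lo, hi = size_range
    n_atoms = int(rng.integers(lo, hi + 1))
    for _ in range(50):
        try:
            return Chem.MolToSmiles(_build_random_mol(rng, n_atoms))
        except Exception:  # rare valence corner; redraw deterministically
            continue
    raise RuntimeError("random molecule generation failed repeatedly")


def _decorate(rng: np.random.Generator, scaffold_smiles: str,
              n_extra_range: tuple[int, int]) -> str:
    """A noisy copy of the scaffold: extra singly-bonded substituents."""
    base = Chem.MolFromSmiles(scaffold_smiles)
    for _ in range(50):
        mol = Chem.RWMol(base)
        # seed `used` so that the free valence of every parsed atom equals
        # its hydrogen count (aromatic ring membership consumes 3)
        used = {a.GetIdx(): _VALENCE.get(a.GetSymbol(), 4)
                - a.GetTotalNumHs() - (3 if a.GetIsAromatic() else 0)
                for a in mol.GetAtoms()}
        n_extra = int(rng.integers(n_extra_range[0], n_extra_range[1] + 1))
        _attach_atoms(mol, used, n_extra, rng)
        try:
            out = mol.GetMol()
            Chem.SanitizeMol(out)
            return Chem.MolToSmiles(out)
        except Exception:
            continue
    return scaffold_smiles


# ---------------------------------------------------------------------------
# Families and targets
# ---------------------------------------------------------------------------

def _family_residue_profile(rng: np.random.Generator) -> np.ndarray:
    """A residue distribution with a boosted 6-residue family signature."""
    weights = np.ones(20)
    signature = rng.choice(20, size=6, replace=False)
    weights[signature] = 6.0
    return weights / weights.sum()


def _sample_sequence(rng: np.random.Generator, profile: np.ndarray,
                     length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length, p=profile))


def generate_target(
    seed: int,
    spec: BenchmarkSpec,
    target_id: str,
    family: int,
    family_scaffold: str,
    family_profile: np.ndarray,
) -> BenchmarkTarget:
    """One benchmark target: profile, actives, decoys, template metadata."""
    rng = np.random.default_rng(seed)
    # target-level perturbation of the family residue profile
    noise = rng.dirichlet(np.ones(20))
    profile_p = 0.8 * family_profile + 0.2 * noise
    profile_p = profile_p / profile_p.sum()
    sequence = _sample_sequence(rng, profile_p, int(rng.integers(80, 121)))

    scaffold_n = Chem.MolFromSmiles(family_scaffold).GetNumAtoms()
    deco_range = (1, 4)
    size_range = (scaffold_n + deco_range[0], scaffold_n + deco_range[1])

    n_actives = spec.actives_per_target
    n_decoys = spec.actives_per_target * spec.decoy_ratio
    molecules: list[tuple[str, int]] = []
    for _ in range(n_actives):
        if rng.random() < spec.signal_strength:
            smiles = _decorate(rng, family_scaffold, deco_range)
        else:
            smiles = _random_smiles(rng, size_range)
        molecules.append((smiles, 1))
    for _ in range(n_decoys):
        molecules.append((_random_smiles(rng, size_range), 0))

    # identifier namespace is blind to the active/decoy split
    order = rng.permutation(len(molecules))
    ids = [""] * len(molecules)
    for serial, mol_idx in enumerate(order):
        ids[mol_idx] = f"{target_id}_M{serial:05d}"
    actives = [SmilesRecord(s, i) for (s, lab), i in zip(molecules, ids)
               if lab == 1]
    decoys = [SmilesRecord(s, i) for (s, lab), i in zip(molecules, ids)
              if lab == 0]

    candidates: list[TemplatePocketRecord] = []
    n_accepted = int(rng.integers(4, 9))
    for k in range(n_accepted):
        n_ligs = int(rng.integers(1, 4))
        ligands = [
            SmilesRecord(_decorate(rng, family_scaffold, (0, 2)),
                         f"{target_id}_T{k}_L{m}")
            for m in range(n_ligs)
        ]
        candidates.append(TemplatePocketRecord(
            template_id=f"{target_id}_T{k}",
            pocket_residues=_sample_sequence(
                rng, profile_p, int(rng.integers(10, 25))),
            tm_score=float(rng.uniform(0.65, 0.95)),
            aligned_fraction=float(rng.uniform(0.85, 1.0)),
            seq_identity=float(rng.uniform(0.05, 0.5)),
            rank_score=float(rng.uniform(0.0, 1.0)),
            template_ligands=ligands,
        ))
    # two sub-threshold pockets exercise the filter cascade
    for k in range(2):
        candidates.append(TemplatePocketRecord(
            template_id=f"{target_id}_R{k}",
            pocket_residues=_sample_sequence(
                rng, profile_p, int(rng.integers(10, 25))),
            tm_score=float(rng.uniform(0.2, 0.55)),
            aligned_fraction=float(rng.uniform(0.5, 0.75)),
            seq_identity=float(rng.uniform(0.05, 0.5)),
            rank_score=float(rng.uniform(0.0, 1.0)),
            template_ligands=[],
        ))

    profile = TargetProfile.from_candidates(target_id, sequence, candidates)
    return BenchmarkTarget(profile=profile, actives=actives, decoys=decoys,
                           candidates=candidates, family=family)


def generate_benchmark(spec: BenchmarkSpec, out_dir=None) -> Benchmark:
    """Generate a full multi-target benchmark; optionally write it to disk
    (see :func:`fragscreen.io.write_benchmark`). Fully reproducible from
    ``spec.seed``."""
    root = np.random.SeedSequence(spec.seed)
    family_seeds, *target_seeds = root.spawn(spec.n_targets + 1)
    fam_rng = np.random.default_rng(family_seeds)
    scaffolds = [_random_smiles(fam_rng, spec.scaffold_size)
                 for _ in range(spec.n_families)]
    profiles = [_family_residue_profile(fam_rng)
                for _ in range(spec.n_families)]

    targets = []
    for t in range(spec.n_targets):
        family = t % spec.n_families
        child_seed = int(target_seeds[t].generate_state(1)[0] % (2**31))
        targets.append(generate_target(
            seed=child_seed, spec=spec,
            target_id=f"T{t:03d}", family=family,
            family_scaffold=scaffolds[family],
            family_profile=profiles[family]))

    ids = [t.target_id for t in targets]
    identity = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i, ti in enumerate(targets):
        for j in range(i + 1, len(targets)):
            val = sequence_identity(ti.profile.sequence,
                                    targets[j].profile.sequence)
            identity.iloc[i, j] = identity.iloc[j, i] = val

    benchmark = Benchmark(targets=targets, identity=identity,
                          spec={**asdict(spec), "scaffolds": scaffolds})
    if out_dir is not None:
        from .io import write_benchmark
        write_benchmark(benchmark, out_dir)
    return benchmark
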