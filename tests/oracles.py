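"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a deliberately different route than
the package implementation (recursive instead of iterative, explicit
loops instead of vectorized counting, third-party path enumeration), so
agreement is a genuine dual-route check.
"""

import math
from functools import lru_cache

import networkx as nx

from fragscreen.chem import MolecularGraph
from fragscreen.fingerprints import fold_identifier, hash_identifier


# ---------------------------------------------------------------------------
# Morgan environments, recomputed top-down recursively
# ---------------------------------------------------------------------------

def morgan_identifiers_recursive(mol: MolecularGraph, radius: int) -> set:
    adj = mol.neighbors()

    @lru_cache(maxsize=None)
    def ball(a: int, r: int) -> frozenset:
        if r == 0:
            return frozenset([a])
        prev = ball(a, r - 1)
        return frozenset(prev | {n for x in prev for n, _ in adj[x]})

    def init(a: int) -> int:
        atom = mol.atoms[a]
        return hash_identifier("ATOM", atom.element, len(adj[a]),
                               atom.n_hydrogens, atom.formal_charge,
                               int(atom.in_ring), int(atom.aromatic))

    @lru_cache(maxsize=None)
    def ident(a: int, r: int) -> int:
        if r == 0:
            return init(a)
        if ball(a, r) == ball(a, r - 1):
            return ident(a, r - 1)
        pairs = sorted((order, ident(n, r - 1)) for n, order in adj[a])
        flat = [x for pair in pairs for x in pair]
        return hash_identifier("ITER", r, ident(a, r - 1), *flat)

    out = set()
    for a in range(mol.n_atoms):
        out.add(ident(a, 0))
        for r in range(1, radius + 1):
            if ball(a, r) != ball(a, r - 1):
                out.add(ident(a, r))
    return out


# ---------------------------------------------------------------------------
# FP2 paths via networkx simple-path enumeration
# ---------------------------------------------------------------------------

def fp2_bits_bruteforce(mol: MolecularGraph, length: int = 1024) -> set:
    graph = nx.Graph()
    for i, atom in enumerate(mol.atoms):
        graph.add_node(i, element=atom.element)
    for bond in mol.bonds:
        graph.add_edge(*bond.atoms, order=bond.order)
    encodings = set()
    for src in graph.nodes:
        for dst in graph.nodes:
            if src >= dst:
                continue
            for path in nx.all_simple_paths(graph, src, dst, cutoff=6):
                enc = [mol.atoms[path[0]].element]
                for a, b in zip(path, path[1:]):
                    enc.append(graph.edges[a, b]["order"])
                    enc.append(mol.atoms[b].element)
                fwd, bwd = tuple(enc), tuple(reversed(enc))
                encodings.add(min(fwd, bwd))
    return {fold_identifier(hash_identifier("PATH", *enc), length)
            for enc in encodings}


# ---------------------------------------------------------------------------
# Screening metrics by explicit counting
# ---------------------------------------------------------------------------

def ef_bruteforce(labels, x: float) -> float:
    top = math.ceil(x * len(labels))
    hits = 0
    for label in labels[:top]:
        if label == 1:
            hits += 1
    total = sum(1 for label in labels if label == 1)
    return (hits / total) / x


def rocef_bruteforce(labels, fpr: float) -> float:
    n_actives = sum(labels)
    n_decoys = len(labels) - n_actives
    fp = tp = 0
    for label in labels:
        if label == 1:
            tp += 1
        else:
            fp += 1
        if fp / n_decoys >= fpr:
            return (tp / n_actives) / fpr
    raise AssertionError("false-positive fraction never reached")


def aupr_bruteforce(labels) -> float:
    n_actives = sum(labels)
    total = 0.0
    hits = 0
    for rank, label in enumerate(labels, start=1):
        if label == 1:
            hits += 1
            total += hits / rank
    return total / n_actives
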