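"""Target-side features: template-pocket filtering, the 20-dimensional
pocket amino-acid composition, and pairwise sequence identity.

Structural pocket detection (threading, structural alignment, pocket
ranking) happens upstream; this module consumes its per-target metadata:
for each candidate template pocket, a TM-score to the target structure,
the aligned fraction of the template sequence, the template-target
sequence identity, an upstream rank score, the pocket residues and any
template ligands bound in the pocket.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio import Align

from .chem import SmilesRecord

#: The 20 standard amino acids in alphabetical one-letter order; fixes the
#: coordinate order of every composition vector.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Default template-pocket acceptance thresholds: structural match
# TM-score > 0.6, at least 80% of the template aligned, at most the top
# 75 pockets by upstream rank.
TM_MIN = 0.6
COV_MIN = 0.8
MAX_POCKETS = 75


@dataclass
class TemplatePocketRecord:
    """One candidate template pocket with its acceptance scores."""

    template_id: str
    pocket_residues: str
    tm_score: float
    aligned_fraction: float
    seq_identity: float
    rank_score: float
    template_ligands: list[SmilesRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pocket_residues:
            raise ValueError(
                f"template {self.template_id}: pocket residues empty")
        for name in ("tm_score", "aligned_fraction", "seq_identity"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(
                    f"template {self.template_id}: {name}={val} outside [0,1]")


class NoUsableTemplatesError(ValueError):
    """Raised when a target retains no usable template pockets."""


def filter_template_pockets(
    candidates: list[TemplatePocketRecord],
    tm_min: float = TM_MIN,
    cov_min: float = COV_MIN,
    seqid_cutoff: float | None = None,
    max_pockets: int = MAX_POCKETS,
) -> list[TemplatePocketRecord]:
    """Apply the template acceptance rules.

    A pocket survives iff ``tm_score > tm_min`` and ``aligned_fraction >=
    cov_min`` and, in benchmarking mode (``seqid_cutoff`` given),
    ``seq_identity <= seqid_cutoff``. Survivors are ranked by the upstream
    ``rank_score`` (descending, template id breaking ties) and truncated
    to ``max_pockets``. An empty result is legal here and flagged by the
    consumers that need pockets.
    """
    survivors = [
        rec
        for rec in candidates
        if rec.tm_score > tm_min
        and rec.aligned_fraction >= cov_min
        and (seqid_cutoff is None or rec.seq_identity <= seqid_cutoff)
    ]
    survivors.sort(key=lambda rec: (-rec.rank_score, rec.template_id))
    return survivors[:max_pockets]


def _single_pocket_composition(residues: str) -> np.ndarray | None:
    vec = np.zeros(20)
    for aa in residues:
        idx = _AA_INDEX.get(aa.upper())
        if idx is not None:  # non-standard codes are dropped
            vec[idx] += 1
    total = vec.sum()
    if total == 0:
        return None
    return vec / total


def pocket_composition(
    accepted: list[TemplatePocketRecord],
    pooled: bool = False,
) -> np.ndarray:
    """Mean amino-acid composition of the accepted template pockets.

    Default is the equal-weight mean of per-pocket compositions, which is
    robust to pocket-size imbalance; ``pooled=True`` instead normalizes
    the pooled residue counts of all pockets. Non-standard residue codes
    are dropped before normalization; a pocket left empty by that is
    skipped. The result is a probability vector over ``AMINO_ACIDS``.
    """
    if not accepted:
        raise NoUsableTemplatesError("no template pockets to average")
    if pooled:
        counts = np.zeros(20)
        for rec in accepted:
            for aa in rec.pocket_residues:
                idx = _AA_INDEX.get(aa.upper())
                if idx is not None:
                    counts[idx] += 1
        if counts.sum() == 0:
            raise NoUsableTemplatesError(
                "all pocket residues are non-standard")
        return counts / counts.sum()
    per_pocket = [
        comp
        for rec in accepted
        if (comp := _single_pocket_composition(rec.pocket_residues)) is not None
    ]
    if not per_pocket:
        raise NoUsableTemplatesError("all pocket residues are non-standard")
    return np.mean(per_pocket, axis=0)


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    # Fixed global-alignment scoring: match 1, mismatch 0, gap open -1,
    # gap extend -0.5. Documented so identities are reproducible.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.5
    return aligner


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical columns in an optimal global alignment.

    The pair is ordered canonically before aligning, so the function is
    exactly symmetric even when the optimal alignment is degenerate.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    first, second = sorted((seq_a.upper(), seq_b.upper()))
    alignment = _aligner().align(first, second)[0]
    a_row, b_row = str(alignment[0]), str(alignment[1])
    matches = sum(1 for x, y in zip(a_row, b_row) if x == y and x != "-")
    return matches / len(a_row)


@dataclass
class TargetProfile:
    """A screening target: its accepted pockets and composition feature."""

    target_id: str
    sequence: str
    accepted_pockets: list[TemplatePocketRecord]
    composition: np.ndarray

    def __post_init__(self) -> None:
        self.composition = np.asarray(self.composition, dtype=float)
        if self.composition.shape != (20,):
            raise ValueError("composition must be a 20-vector")
        if np.any(self.composition < 0) or not np.isclose(
                self.composition.sum(), 1.0, atol=1e-9):
            raise ValueError("composition must be a probability vector")
        if len(self.accepted_pockets) > MAX_POCKETS:
            raise ValueError(
                f"more than {MAX_POCKETS} accepted pockets on "
                f"{self.target_id}")

    @classmethod
    def from_candidates(
        cls,
        target_id: str,
        sequence: str,
        candidates: list[TemplatePocketRecord],
        tm_min: float = TM_MIN,
        cov_min: float = COV_MIN,
        seqid_cutoff: float | None = None,
        max_pockets: int = MAX_POCKETS,
        pooled_composition: bool = False,
    ) -> "TargetProfile":
        accepted = filter_template_pockets(
            candidates, tm_min=tm_min, cov_min=cov_min,
            seqid_cutoff=seqid_cutoff, max_pockets=max_pockets)
        if not accepted:
            raise NoUsableTemplatesError(
                f"target {target_id}: no template pocket passes the filters")
        comp = pocket_composition(accepted, pooled=pooled_composition)
        return cls(target_id=target_id, sequence=sequence,
                   accepted_pockets=accepted, composition=comp)
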