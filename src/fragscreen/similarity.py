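"""Template-ligand similarity screening.

The ligand-homology route: candidate ligands are ranked by fingerprint
similarity to the ligands bound in the target's accepted template
pockets. The Morgan fingerprint is the default ligand representation —
combining schemes does not help here because similarity weights every
bit equally — and the default aggregation over template ligands is the
maximum Tanimoto coefficient. The aggregation is pluggable (``max`` or
``mean_topk``) so alternative template-pooling scores can be dropped in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .chem import SmilesParseError, SmilesRecord, parse_smiles
from .fingerprints import (BitFingerprint, Scheme, combined_fingerprint_for,
                           fingerprint_for_scheme, tanimoto)
from .metrics import RankedScreen
from .pockets import TargetProfile

logger = logging.getLogger(__name__)

AGGREGATIONS = ("max", "mean_topk")


class NoTemplateLigandsError(ValueError):
    """Target has no usable template ligands: not screenable by similarity."""


@dataclass
class TemplateLigandSet:
    """Fingerprinted, deduplicated template ligands of one target."""

    target_id: str
    scheme: str
    fingerprints: list[BitFingerprint]
    ligand_ids: list[str]
    #: (pocket template id, ligand id) per retained fingerprint.
    provenance: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.fingerprints:
            raise NoTemplateLigandsError(
                f"target {self.target_id}: no template ligands")
        lengths = {fp.length for fp in self.fingerprints}
        schemes = {fp.scheme for fp in self.fingerprints}
        if len(lengths) != 1 or len(schemes) != 1:
            raise ValueError("template fingerprints must share scheme/length")

    def __len__(self) -> int:
        return len(self.fingerprints)


def _fingerprint(smiles: str, scheme: str) -> BitFingerprint:
    mol = parse_smiles(smiles)
    if scheme == "combined":
        # Wrap the full concatenation as a Morgan-schemed vector of length
        # 3953 so tanimoto()'s scheme/length guard still applies uniformly.
        comb = combined_fingerprint_for(mol, ablation="full")
        return BitFingerprint(scheme=Scheme.MORGAN, length=comb.length,
                              set_bits=comb.set_bits)
    return fingerprint_for_scheme(mol, Scheme(scheme))


def build_template_ligand_set(profile: TargetProfile,
                              scheme: str = "morgan") -> TemplateLigandSet:
    """Fingerprint every template ligand of the accepted pockets.

    Identical SMILES are deduplicated (first occurrence wins);
    unparsable template ligands are skipped with a warning.
    """
    fingerprints, ids, provenance = [], [], []
    seen: set[str] = set()
    skipped = 0
    for pocket in profile.accepted_pockets:
        for rec in pocket.template_ligands:
            if rec.smiles in seen:
                continue
            try:
                fp = _fingerprint(rec.smiles, scheme)
            except SmilesParseError:
                skipped += 1
                continue
            seen.add(rec.smiles)
            fingerprints.append(fp)
            ids.append(rec.mol_id)
            provenance.append((pocket.template_id, rec.mol_id))
    if skipped:
        logger.warning("target %s: skipped %d unparsable template ligand(s)",
                       profile.target_id, skipped)
    if not fingerprints:
        raise NoTemplateLigandsError(
            f"target {profile.target_id}: no usable template ligands")
    return TemplateLigandSet(target_id=profile.target_id, scheme=scheme,
                             fingerprints=fingerprints, ligand_ids=ids,
                             provenance=provenance)


def similarity_score(candidate: BitFingerprint, templates: TemplateLigandSet,
                     aggregation: str = "max", top_k: int = 3
                     ) -> tuple[float, str]:
    """Aggregate Tanimoto similarity of a candidate to the template set.

    Returns (score, best-matching template ligand id). ``max`` takes the
    best pairwise coefficient; ``mean_topk`` averages the ``top_k`` best.
    Both are monotone in every single pairwise similarity.
    """
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    sims = np.array([tanimoto(candidate, fp)
                     for fp in templates.fingerprints])
    best_idx = int(np.argmax(sims))
    if aggregation == "max":
        score = float(sims[best_idx])
    else:
        k = min(top_k, len(sims))
        score = float(np.sort(sims)[-k:].mean())
    return score, templates.ligand_ids[best_idx]


class SimilarityScreener(BaseEstimator):
    """Rank candidates by fingerprint similarity to template ligands.

    Parameters
    ----------
    scheme:
        Ligand representation: ``"morgan"`` (default), ``"fp2"``,
        ``"pubchem"``, or ``"combined"`` (full 3953-bit concatenation;
        available for sensitivity checks, not default).
    aggregation, top_k:
        How pairwise similarities over the template set are pooled.
    """

    def __init__(self, scheme: str = "morgan", aggregation: str = "max",
                 top_k: int = 3):
        self.scheme = scheme
        self.aggregation = aggregation
        self.top_k = top_k

    def fit(self, profile: TargetProfile) -> "SimilarityScreener":
        self.templates_ = build_template_ligand_set(profile,
                                                    scheme=self.scheme)
        self.target_id_ = profile.target_id
        return self

    def score_one(self, smiles: str) -> tuple[float, str]:
        if not hasattr(self, "templates_"):
            raise ValueError("screener is not fitted")
        return similarity_score(_fingerprint(smiles, self.scheme),
                                self.templates_,
                                aggregation=self.aggregation,
                                top_k=self.top_k)

    def screen_library(self, ligands: list[SmilesRecord],
                       labels: dict[str, int] | None = None) -> RankedScreen:
        if not hasattr(self, "templates_"):
            raise ValueError("screener is not fitted")
        ids, scores, labs, infos = [], [], [], []
        skipped = 0
        for rec in ligands:
            try:
                score, best = self.score_one(rec.smiles)
            except SmilesParseError:
                skipped += 1
                continue
            ids.append(rec.mol_id)
            scores.append(score)
            labs.append(labels.get(rec.mol_id) if labels else None)
            infos.append({"best_template": best})
        if skipped:
            logger.warning("target %s: skipped %d unparsable ligand(s)",
                           self.target_id_, skipped)
        if not ids:
            raise ValueError(f"target {self.target_id_}: no scoreable ligands")
        return RankedScreen.from_scores(self.target_id_, ids, scores, labs,
                                        infos)


def similarity_screen_library(
    profile: TargetProfile,
    ligands: list[SmilesRecord],
    scheme: str = "morgan",
    labels: dict[str, int] | None = None,
    aggregation: str = "max",
    top_k: int = 3,
) -> RankedScreen:
    screener = SimilarityScreener(scheme=scheme, aggregation=aggregation,
                                  top_k=top_k).fit(profile)
    return screener.screen_library(ligands, labels=labels)
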