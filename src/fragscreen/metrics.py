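"""Screening evaluation: enrichment factors, ROC enrichment, and the
area under the precision-recall curve.

Every metric consumes a :class:`RankedScreen` — a per-target list of
(ligand id, score, active/decoy label) already sorted by score descending
with identifier-ascending tie-breaking, so metric values never depend on
tie permutations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ScreenEntry:
    ligand_id: str
    score: float
    label: int | None = None
    info: dict[str, Any] = field(default_factory=dict, compare=False)


@dataclass
class RankedScreen:
    """A scored, sorted candidate list for one target."""

    target_id: str
    entries: list[ScreenEntry]

    def __post_init__(self) -> None:
        for prev, cur in zip(self.entries, self.entries[1:]):
            if (-prev.score, prev.ligand_id) > (-cur.score, cur.ligand_id):
                raise ValueError(
                    f"screen {self.target_id} is not sorted by "
                    "(score desc, ligand id asc)")
        for e in self.entries:
            if e.label is not None and e.label not in (0, 1):
                raise ValueError(f"label must be 0/1, got {e.label!r}")

    @classmethod
    def from_scores(
        cls,
        target_id: str,
        ligand_ids: Iterable[str],
        scores: Iterable[float],
        labels: Iterable[int] | None = None,
        info: Iterable[dict] | None = None,
    ) -> "RankedScreen":
        """Build a screen, applying the canonical sort."""
        ids = list(ligand_ids)
        scr = [float(s) for s in scores]
        labs = list(labels) if labels is not None else [None] * len(ids)
        infos = list(info) if info is not None else [{}] * len(ids)
        rows = sorted(
            zip(ids, scr, labs, infos), key=lambda r: (-r[1], r[0]))
        return cls(target_id=target_id, entries=[
            ScreenEntry(ligand_id=i, score=s, label=l, info=inf)
            for i, s, l, inf in rows])

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> np.ndarray:
        if any(e.label is None for e in self.entries):
            raise ValueError(
                f"screen {self.target_id} has unlabeled entries")
        return np.array([e.label for e in self.entries], dtype=int)

    @property
    def n_actives(self) -> int:
        return int(self.labels.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, len(self) + 1),
            "ligand_id": [e.ligand_id for e in self.entries],
            "score": [e.score for e in self.entries],
            "label": [e.label for e in self.entries],
        })


def _require_labels(screen: RankedScreen) -> np.ndarray:
    labels = screen.labels
    if len(labels) == 0:
        raise ValueError(f"screen {screen.target_id} is empty")
    return labels


def enrichment_factor(screen: RankedScreen, x: float = 0.01) -> float:
    """EF_x: the fraction of all actives recovered in the top ``x`` of the
    ranked list, divided by ``x``; 1 is the random expectation, and the
    cap is min(1/x, N / N_actives).

    The top-fraction cutoff is ``ceil(x * N)`` entries, so any x > 0
    selects at least one entry.
    """
    if not (0 < x <= 1):
        raise ValueError("x must lie in (0, 1]")
    labels = _require_labels(screen)
    n_actives = labels.sum()
    if n_actives == 0:
        raise ValueError(f"screen {screen.target_id} has no actives")
    top = math.ceil(x * len(labels))
    return float(labels[:top].sum() / n_actives / x)


def roc_enrichment(screen: RankedScreen, fpr: float = 0.01) -> float:
    """ROCEF: true-positive rate at the rank where the false-positive
    fraction first reaches ``fpr``, divided by ``fpr``; a perfect ranking
    scores 1/fpr (100 at a 1% false-positive rate) independent of the
    active/decoy ratio.
    """
    if not (0 < fpr <= 1):
        raise ValueError("fpr must lie in (0, 1]")
    labels = _require_labels(screen)
    n_actives = labels.sum()
    n_decoys = len(labels) - n_actives
    if n_actives == 0:
        raise ValueError(f"screen {screen.target_id} has no actives")
    if n_decoys == 0:
        raise ValueError(f"screen {screen.target_id} has no decoys")
    fp = np.cumsum(1 - labels)
    tp = np.cumsum(labels)
    reached = np.nonzero(fp / n_decoys >= fpr)[0]
    k = reached[0]  # fp >= 1 at the last rank, so always reached
    return float(tp[k] / n_actives / fpr)


def precision_recall_aupr(screen: RankedScreen) -> float:
    """Area under the precision-recall curve in its average-precision
    (step-integrated) form: the mean over actives of the precision at
    their rank. No linear interpolation between operating points."""
    labels = _require_labels(screen)
    n_actives = labels.sum()
    if n_actives == 0:
        raise ValueError(f"screen {screen.target_id} has no actives")
    ranks = np.arange(1, len(labels) + 1)
    precision_at = np.cumsum(labels) / ranks
    return float(precision_at[labels == 1].sum() / n_actives)


def roc_curve_points(screen: RankedScreen) -> pd.DataFrame:
    """FPR/TPR at every rank, for plotting."""
    labels = _require_labels(screen)
    n_actives = labels.sum()
    n_decoys = len(labels) - n_actives
    return pd.DataFrame({
        "fpr": np.cumsum(1 - labels) / max(n_decoys, 1),
        "tpr": np.cumsum(labels) / max(n_actives, 1),
    })


def evaluate_screen(screen: RankedScreen, x: float = 0.01,
                    fpr: float = 0.01) -> dict[str, float]:
    labels = _require_labels(screen)
    return {
        "target_id": screen.target_id,
        "ef": enrichment_factor(screen, x=x),
        "rocef": roc_enrichment(screen, fpr=fpr),
        "aupr": precision_recall_aupr(screen),
        "n": int(len(labels)),
        "n_actives": int(labels.sum()),
    }


def aggregate_metrics(per_target: list[dict[str, float]]) -> dict:
    """Unweighted means and standard deviations across targets.

    Targets missing a metric (None/NaN) are excluded from that metric's
    mean; the count of exclusions is reported per metric.
    """
    if not per_target:
        raise ValueError("no per-target metrics to aggregate")
    table = pd.DataFrame(per_target)
    summary: dict[str, float | int] = {"n_targets": len(table)}
    for name in ("ef", "rocef", "aupr"):
        if name not in table:
            continue
        values = pd.to_numeric(table[name], errors="coerce")
        valid = values.dropna()
        summary[f"mean_{name}"] = float(valid.mean()) if len(valid) else float("nan")
        summary[f"sd_{name}"] = float(valid.std(ddof=0)) if len(valid) else float("nan")
        summary[f"n_missing_{name}"] = int(values.isna().sum())
    return {"summary": summary, "per_target": table}
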