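"""Score-to-precision calibration and best-precision meta-combination.

Raw scores from different screening routes (a Tanimoto-based similarity
score, boosted-tree regression outputs) live on incomparable scales. To
combine them, each method's pooled cross-validation predictions (all
targets merged, actives and decoys) are converted into a monotone mapping
from raw score to *predicted precision* — the empirical fraction of
actives among pooled predictions scoring at that level. The meta-method
then ranks every ligand by the best predicted precision any single
method assigns it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .metrics import RankedScreen

#: Pooled-prediction table columns.
POOLED_COLUMNS = ("method", "target_id", "ligand_id", "score", "label")


class PrecisionCalibrator(BaseEstimator):
    """Monotone mapping from a method's raw score to predicted precision.

    Parameters
    ----------
    method:
        ``"isotonic"`` (default) fits a non-decreasing step function by
        isotonic regression of the 0/1 label on the score; each fitted
        block's value is exactly the empirical precision of the pooled
        predictions in that score range, and the fit is parameter-free.
        ``"logistic"`` fits a one-feature logistic curve instead.

    Attributes
    ----------
    breakpoints_x_, breakpoints_y_:
        The fitted monotone mapping as interpolation breakpoints
        (isotonic thresholds, or a dense logistic evaluation grid).
    n_pooled_, n_positive_:
        Size and positive count of the fitted pool.
    """

    def __init__(self, method: str = "isotonic"):
        self.method = method

    def fit(self, scores, labels) -> "PrecisionCalibrator":
        scores = np.asarray(scores, dtype=float).ravel()
        labels = np.asarray(labels, dtype=int).ravel()
        if scores.shape != labels.shape or scores.size == 0:
            raise ValueError("scores and labels must be equal-length, non-empty")
        if set(np.unique(labels)) - {0, 1}:
            raise ValueError("labels must be 0/1")
        if self.method == "isotonic":
            if len(np.unique(labels)) == 1:
                # Constant mapping at the pool's precision (0 or 1).
                const = float(labels[0])
                self.breakpoints_x_ = np.array([scores.min(), scores.max()])
                self.breakpoints_y_ = np.array([const, const])
            else:
                iso = IsotonicRegression(y_min=0.0, y_max=1.0,
                                         out_of_bounds="clip")
                iso.fit(scores, labels)
                self.breakpoints_x_ = np.asarray(iso.X_thresholds_, dtype=float)
                self.breakpoints_y_ = np.asarray(iso.y_thresholds_, dtype=float)
        elif self.method == "logistic":
            if len(np.unique(labels)) == 1:
                raise ValueError(
                    "logistic calibration needs both labels in the pool")
            logit = LogisticRegression(C=1e6)
            logit.fit(scores.reshape(-1, 1), labels)
            grid = np.linspace(scores.min(), scores.max(), 512)
            prob = logit.predict_proba(grid.reshape(-1, 1))[:, 1]
            if logit.coef_[0, 0] < 0:  # enforce a non-decreasing mapping
                prob = np.full_like(grid, labels.mean())
            self.breakpoints_x_ = grid
            self.breakpoints_y_ = np.clip(prob, 0.0, 1.0)
        else:
            raise ValueError(f"unknown calibration method {self.method!r}")
        self.n_pooled_ = int(labels.size)
        self.n_positive_ = int(labels.sum())
        return self

    def predict(self, scores) -> np.ndarray:
        """Predicted precision for raw scores; scores beyond the fitted
        range take the boundary value, outputs are clamped to [0, 1]."""
        check_is_fitted(self, "breakpoints_x_")
        scores = np.asarray(scores, dtype=float)
        out = np.interp(scores, self.breakpoints_x_, self.breakpoints_y_)
        return np.clip(out, 0.0, 1.0)

    def transform(self, scores) -> np.ndarray:
        return self.predict(scores)

    # -- JSON archive ------------------------------------------------------

    def to_dict(self, method_name: str = "") -> dict:
        check_is_fitted(self, "breakpoints_x_")
        return {
            "method_name": method_name,
            "calibration": self.method,
            "breakpoints_x": self.breakpoints_x_.tolist(),
            "breakpoints_y": self.breakpoints_y_.tolist(),
            "n_pooled": self.n_pooled_,
            "n_positive": self.n_positive_,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PrecisionCalibrator":
        cal = cls(method=payload.get("calibration", "isotonic"))
        cal.breakpoints_x_ = np.asarray(payload["breakpoints_x"], dtype=float)
        cal.breakpoints_y_ = np.asarray(payload["breakpoints_y"], dtype=float)
        cal.n_pooled_ = int(payload.get("n_pooled", 0))
        cal.n_positive_ = int(payload.get("n_positive", 0))
        return cal

    def save(self, path, method_name: str = "") -> None:
        with open(path, "w") as handle:
            json.dump(self.to_dict(method_name), handle, indent=1,
                      sort_keys=True)

    @classmethod
    def load(cls, path) -> "PrecisionCalibrator":
        with open(path) as handle:
            return cls.from_dict(json.load(handle))


def fit_precision_calibration(pooled: pd.DataFrame, method: str,
                              calibration: str = "isotonic"
                              ) -> PrecisionCalibrator:
    """Fit a calibrator for one method from a pooled-prediction table
    (columns ``method, target_id, ligand_id, score, label``)."""
    rows = pooled[pooled["method"] == method]
    if rows.empty:
        raise ValueError(f"no pooled predictions for method {method!r}")
    labels = rows["label"].to_numpy(dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError(
            f"method {method!r}: pooled predictions contain a single class")
    return PrecisionCalibrator(method=calibration).fit(
        rows["score"].to_numpy(dtype=float), labels)


def predict_precision(cal: PrecisionCalibrator, score) -> float | np.ndarray:
    out = cal.predict(np.atleast_1d(score))
    return float(out[0]) if np.isscalar(score) else out


def meta_combine(per_method: dict[str, RankedScreen],
                 target_id: str | None = None) -> RankedScreen:
    """Best-precision meta-combination of ≥1 calibrated screens.

    Each input screen's scores must already be predicted precisions. A
    ligand's combined score is the maximum predicted precision over the
    methods that scored it; the winning method and the per-method values
    are recorded in the entry info.
    """
    if not per_method:
        raise ValueError("meta_combine needs at least one method screen")
    if target_id is None:
        target_id = next(iter(per_method.values())).target_id
    per_ligand: dict[str, dict] = {}
    for method, screen in per_method.items():
        for entry in screen.entries:
            slot = per_ligand.setdefault(
                entry.ligand_id,
                {"label": entry.label, "precisions": {}})
            slot["precisions"][method] = entry.score
            if slot["label"] is None:
                slot["label"] = entry.label
    ids, scores, labels, infos = [], [], [], []
    for ligand_id, slot in per_ligand.items():
        winner = max(
            slot["precisions"].items(), key=lambda kv: (kv[1], kv[0]))
        ids.append(ligand_id)
        scores.append(winner[1])
        labels.append(slot["label"])
        infos.append({"winner": winner[0],
                      "precisions": dict(slot["precisions"])})
    return RankedScreen.from_scores(target_id, ids, scores, labels, infos)
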