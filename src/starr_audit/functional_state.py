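"""Universal functional-state prediction for CRMs (active vs non-active).

A CRM's functional state in a cell type is called from four active
enhancer epigenetic marks — chromatin accessibility (ATAC), H3K4me1,
H3K4me3 and H3K27ac — via logistic regression. Each feature is the per-bp
mean fold enrichment of the mark over an input control (both library-size
normalized), log1p-transformed; features are z-standardized at training
time and the standardization is frozen into the model.

The original predictor's published weights (trained across dozens of cell
types) are not distributed; this module ships a trainer with the same model
family and feature definition and accepts user-supplied weights via the
JSON model format.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .genomic_core import GenomicInterval
from .tracks import SignalTrack, mean_fold_enrichment

__all__ = [
    "FEATURE_ORDER",
    "FeatureVector",
    "UfspModel",
    "StateCall",
    "extract_features",
    "extract_feature_matrix",
    "ufsp_train",
    "ufsp_predict",
]

FEATURE_ORDER = ("atac", "h3k4me1", "h3k4me3", "h3k27ac")


@dataclass
class FeatureVector:
    element_id: str
    features: np.ndarray  # 4 values in FEATURE_ORDER

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.shape != (4,):
            raise ValueError("expected exactly 4 features")
        if not np.all(np.isfinite(self.features)) or np.any(self.features < 0):
            raise ValueError(f"non-finite or negative feature for {self.element_id}")


@dataclass
class StateCall:
    element_id: str
    probability: float
    state: str  # "active" | "non-active"


@dataclass
class UfspModel:
    """Logistic model: weights on standardized log1p fold-enrichment features."""

    weights: np.ndarray  # 4 coefficients
    intercept: float
    feature_means: np.ndarray
    feature_scales: np.ndarray
    threshold: float = 0.5
    feature_order: Sequence[str] = field(default=FEATURE_ORDER)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feature_means) / self.feature_scales

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != len(self.weights):
            raise ValueError(
                f"feature matrix has shape {X.shape}, expected (*, {len(self.weights)})"
            )
        z = self.standardize(X) @ self.weights + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def save(self, path: str | Path) -> None:
        payload = {
            "feature_order": list(self.feature_order),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "feature_means": self.feature_means.tolist(),
            "feature_scales": self.feature_scales.tolist(),
            "threshold": self.threshold,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "UfspModel":
        p = json.loads(Path(path).read_text())
        return cls(
            weights=np.asarray(p["weights"], dtype=np.float64),
            intercept=float(p["intercept"]),
            feature_means=np.asarray(p["feature_means"], dtype=np.float64),
            feature_scales=np.asarray(p["feature_scales"], dtype=np.float64),
            threshold=float(p["threshold"]),
            feature_order=tuple(p["feature_order"]),
        )


def extract_features(
    element: GenomicInterval,
    marks: Dict[str, SignalTrack],
    input_track: SignalTrack,
) -> FeatureVector:
    """log1p(per-bp mean fold enrichment over input) for the four marks."""
    missing = [m for m in FEATURE_ORDER if m not in marks]
    if missing:
        raise ValueError(f"missing mark tracks: {missing}")
    feats = [
        np.log1p(mean_fold_enrichment(element, marks[m], input_track))
        for m in FEATURE_ORDER
    ]
    return FeatureVector(element_id=element.id or f"{element.chrom}:{element.start}", features=np.asarray(feats))


def extract_feature_matrix(
    elements: Sequence[GenomicInterval],
    marks: Dict[str, SignalTrack],
    input_track: SignalTrack,
) -> tuple:
    """(ids, n×4 matrix) for a collection of elements."""
    fvs = [extract_features(el, marks, input_track) for el in elements]
    ids = [fv.element_id for fv in fvs]
    X = np.vstack([fv.features for fv in fvs]) if fvs else np.empty((0, 4))
    return ids, X


def ufsp_train(
    positives: np.ndarray,
    negatives: np.ndarray,
    ridge: float = 1e-4,
    threshold: float = 0.5,
) -> UfspModel:
    """Maximum-likelihood logistic fit with a small L2 ridge (keeps weights
    finite on separable data). Deterministic given fixed inputs.

    ``positives``/``negatives`` are n×4 feature matrices (rows: elements).
    """
    positives = np.atleast_2d(np.asarray(positives, dtype=np.float64))
    negatives = np.atleast_2d(np.asarray(negatives, dtype=np.float64))
    if positives.size == 0 or negatives.size == 0:
        raise ValueError("both classes must be nonempty")
    X = np.vstack([positives, negatives])
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])

    means = X.mean(axis=0)
    scales = X.std(axis=0)
    zero_var = scales == 0
    if np.any(zero_var):
        warnings.warn(
            f"constant feature(s) at index {np.flatnonzero(zero_var).tolist()}; "
            "retained with unit scale",
            stacklevel=2,
        )
        scales = np.where(zero_var, 1.0, scales)
    Xs = (X - means) / scales

    clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=2000, tol=1e-10)
    clf.fit(Xs, y)
    return UfspModel(
        weights=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        feature_means=means,
        feature_scales=scales,
        threshold=threshold,
    )


def ufsp_predict(
    model: UfspModel,
    ids: Sequence[str],
    X: np.ndarray,
) -> List[StateCall]:
    """Per-element probability and thresholded state (inclusive at threshold)."""
    probs = model.predict_proba(X)
    return [
        StateCall(
            element_id=eid,
            probability=float(p),
            state="active" if p >= model.threshold else "non-active",
        )
        for eid, p in zip(ids, probs)
    ]
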