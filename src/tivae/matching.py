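"""Latent-unit -> tissue association via single-feature linear SVMs.

A latent unit is declared to encode a tissue when a binary linear SVM,
given only that unit's activation, predicts tissue membership with
cross-validated F1 (for the tissue class) strictly above a threshold. With
``latent_dim`` units, ``n_tissues`` tissues and ``n_folds`` folds this runs
``n_folds * latent_dim * n_tissues`` classifiers per embedding model. A unit
may be associated with several tissues and a tissue with several units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

__all__ = [
    "MatchConfig",
    "TissueLatentMap",
    "match_tissues",
    "f1_positive_class",
    "associations_from_f1",
]


@dataclass(frozen=True)
class MatchConfig:
    n_folds: int = 5
    svm_c: float = 1.0
    class_weight_balanced: bool = True
    f1_threshold: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be positive")
        if not 0.0 < self.f1_threshold <= 1.0:
            raise ValueError("f1_threshold must lie in (0, 1]")


@dataclass
class TissueLatentMap:
    """Cross-validated F1 per (latent unit, tissue) and the derived associations."""

    f1_matrix: pd.DataFrame  # index: latent unit, columns: tissue IDs
    associations: dict[str, set[int]]
    threshold: float

    def associated_units(self, tissue: str) -> set[int]:
        return set(self.associations.get(tissue, set()))


def associations_from_f1(f1_matrix: pd.DataFrame, threshold: float) -> dict[str, set[int]]:
    """Tissue -> latent units whose cross-validated F1 strictly exceeds threshold."""
    return {
        tissue: set(f1_matrix.index[f1_matrix[tissue] > threshold].tolist())
        for tissue in f1_matrix.columns
    }


def f1_positive_class(true_labels: np.ndarray, predicted: np.ndarray) -> float:
    """F1 of the positive (1) class; 0 when precision + recall is 0."""
    t = np.asarray(true_labels).astype(bool)
    p = np.asarray(predicted).astype(bool)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("label vectors must be equal-length and non-empty")
    tp = float(np.sum(t & p))
    fp = float(np.sum(~t & p))
    fn = float(np.sum(t & ~p))
    denom = 2 * tp + fp + fn
    return 0.0 if denom == 0 else 2 * tp / denom


def match_tissues(
    activations: np.ndarray,
    tissue_labels: np.ndarray,
    config: MatchConfig = MatchConfig(),
) -> TissueLatentMap:
    """Associate latent units with tissues by thresholded cross-validated F1.

    For every (unit, tissue) pair, a linear SVM (C from config, optionally
    balanced class weights) sees only that unit's activation column and the
    one-vs-rest tissue label under stratified k-fold cross-validation; the
    fold-mean F1 of the tissue class is compared strictly against the
    threshold. Deterministic given ``config.seed``.
    """
    activations = np.asarray(activations, dtype=np.float64)
    tissue_labels = np.asarray(tissue_labels)
    if activations.ndim != 2 or activations.shape[0] != tissue_labels.shape[0]:
        raise ValueError("activations and tissue_labels disagree on row count")
    tissues = sorted(np.unique(tissue_labels).tolist())
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues to match against")
    counts = {t: int(np.sum(tissue_labels == t)) for t in tissues}
    small = [t for t, c in counts.items() if c < config.n_folds]
    if small:
        raise ValueError(
            f"tissues with fewer rows than n_folds={config.n_folds}: {small}"
        )

    latent_dim = activations.shape[1]
    f1 = np.zeros((latent_dim, len(tissues)))
    class_weight = "balanced" if config.class_weight_balanced else None
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)

    for j, tissue in enumerate(tissues):
        y = (tissue_labels == tissue).astype(int)
        folds = list(skf.split(activations, y))
        for u in range(latent_dim):
            x = activations[:, u : u + 1]
            scores = []
            for train_idx, test_idx in folds:
                clf = LinearSVC(C=config.svm_c, class_weight=class_weight, max_iter=5000)
                clf.fit(x[train_idx], y[train_idx])
                scores.append(f1_positive_class(y[test_idx], clf.predict(x[test_idx])))
            f1[u, j] = float(np.mean(scores))

    f1_frame = pd.DataFrame(f1, index=pd.RangeIndex(latent_dim, name="unit"), columns=tissues)
    associations = associations_from_f1(f1_frame, config.f1_threshold)
    return TissueLatentMap(
        f1_matrix=f1_frame, associations=associations, threshold=config.f1_threshold
    )
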