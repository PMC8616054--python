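"""PCA and class-separation analysis of 16-value tile features.

Whether the learned features distinguish the four matrix classes is
judged quantitatively: PCA for a low-dimensional view, silhouette scores
for how tightly tiles of one class cluster relative to other classes
(restricted to any feature subset), and leave-one-out 1-nearest-neighbour
accuracy as a non-parametric classification check.  Single-feature
silhouettes ranked in descending order identify the small discriminative
subset; which feature *indices* those are depends on training randomness,
so only the existence of such a subset is meaningful across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors


@dataclass
class EmbeddingResult:
    """Mean-centered PCA of the (n, 16) feature matrix."""

    components: np.ndarray  # (k, 16), orthonormal rows
    explained_variance: np.ndarray  # (k,), non-increasing
    explained_variance_ratio: np.ndarray
    mean: np.ndarray  # (16,)
    projections: np.ndarray  # (n, k)
    class_labels: np.ndarray  # (n,)


@dataclass
class SeparationReport:
    """Per-feature separation scores and the resulting ranking."""

    per_feature: dict[int, float]  # 1-based feature index -> silhouette
    ranking: list[int]  # 1-based indices, best first
    top_k_joint: float = float("nan")  # joint score of the top-k subset
    bottom_k_joint: float = float("nan")
    k: int = 4
    pair_scores: dict[tuple[int, int], float] = field(default_factory=dict)


def fit_pca(
    features: np.ndarray,
    n_components: int = 2,
    class_labels: np.ndarray | list[str] | None = None,
) -> EmbeddingResult:
    """Mean-centered PCA, deterministic up to a fixed sign convention.

    Each component is flipped so its largest-magnitude loading is
    positive, making results reproducible across SVD implementations.
    """
    x = np.asarray(features, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("features must be a 2D (n_tiles, n_features) array")
    n, p = x.shape
    if n_components > p:
        raise ValueError(f"n_components {n_components} exceeds feature count {p}")
    if n < n_components + 1:
        raise ValueError(
            f"need at least n_components + 1 = {n_components + 1} samples, got {n}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    proj = pca.fit_transform(x)
    comps = pca.components_.copy()
    for i in range(n_components):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            proj[:, i] = -proj[:, i]
    labels = (
        np.asarray(class_labels)
        if class_labels is not None
        else np.full(n, "unlabeled")
    )
    return EmbeddingResult(
        components=comps,
        explained_variance=pca.explained_variance_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        mean=pca.mean_.copy(),
        projections=proj,
        class_labels=labels,
    )


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("separation scoring needs at least 2 classes")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 tiles")
    return labels


def score_separation(
    features: np.ndarray,
    labels: np.ndarray | list[str],
    feature_indices: list[int] | None = None,
) -> float:
    """Silhouette score of the labeled tiles on a feature subset.

    ``feature_indices`` are 1-based (features are conventionally numbered
    f1..f16); ``None`` scores all features jointly.  Returns a value in
    [-1, 1]: 1 for tight well-separated classes, ~0 for overlapping
    clouds.
    """
    x = np.asarray(features, dtype=np.float64)
    labels = _check_labels(labels)
    if feature_indices is not None:
        idx = np.asarray(feature_indices, dtype=int) - 1
        if idx.min() < 0 or idx.max() >= x.shape[1]:
            raise ValueError(f"feature indices must be in 1..{x.shape[1]}")
        x = x[:, idx]
    return float(silhouette_score(x, labels))


def rank_features(
    features: np.ndarray,
    labels: np.ndarray | list[str],
    k: int = 4,
) -> SeparationReport:
    """Rank features by single-feature silhouette, best first.

    Ties are broken by ascending feature index.  The top-k and bottom-k
    subsets are additionally re-scored jointly.
    """
    x = np.asarray(features, dtype=np.float64)
    labels = _check_labels(labels)
    p = x.shape[1]
    scores = {
        j + 1: score_separation(x, labels, [j + 1]) for j in range(p)
    }
    ranking = sorted(scores, key=lambda j: (-scores[j], j))
    top = ranking[:k]
    bottom = ranking[-k:]
    return SeparationReport(
        per_feature=scores,
        ranking=ranking,
        top_k_joint=score_separation(x, labels, top),
        bottom_k_joint=score_separation(x, labels, bottom),
        k=k,
    )


def score_feature_pairs(
    features: np.ndarray,
    labels: np.ndarray | list[str],
    pairs: list[tuple[int, int]],
) -> dict[tuple[int, int], float]:
    """Joint silhouette for each (1-based) feature pair."""
    return {
        (i, j): score_separation(features, labels, [i, j]) for i, j in pairs
    }


def knn_loo_accuracy(
    features: np.ndarray, labels: np.ndarray | list[str]
) -> float:
    """Leave-one-out 1-nearest-neighbour classification accuracy."""
    x = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    nn = NearestNeighbors(n_neighbors=2).fit(x)
    _, idx = nn.kneighbors(x)
    neighbor = np.where(idx[:, 1] != np.arange(len(x)), idx[:, 1], idx[:, 0])
    return float(np.mean(labels[neighbor] == labels))
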