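"""Post-hoc analysis of the learned chemical space.

Two complementary clusterings of the tested molecules are compared:
hierarchical (Ward) clustering of the latent vectors themselves, which
responds to any large latent dimension whether or not it matters for potency,
and the same clustering applied to Shapley attribution rows, which groups
molecules only by the features that actually drive the potency prediction.
Attributions are computed exactly for the forest component of the stacked
model (the GP residual term is small by construction and excluded).
2-D projections (PCA / UMAP / t-SNE) support visual inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import adjusted_rand_score

from agglearn.learner import EmbeddingMatrix, StackedModel
from agglearn.treeshap import forest_shap_values

__all__ = [
    "AttributionMatrix",
    "ClusterComparison",
    "latent_cluster",
    "shap_attributions",
    "shap_cluster",
    "top_dimensions",
    "project_2d",
    "compare_clusterings",
]


@dataclass(frozen=True)
class AttributionMatrix:
    """Per-molecule, per-dimension Shapley attributions of the forest.

    Local accuracy: each row sums (with ``base_value``) to the forest's
    prediction for that molecule.
    """

    molecule_ids: tuple[str, ...]
    attributions: np.ndarray  # (n, d)
    base_value: float
    mode: str = "tree-exact"

    def __post_init__(self):
        if self.attributions.ndim != 2 or len(self.molecule_ids) != len(self.attributions):
            raise ValueError("attributions must be (n_molecules, d)")


@dataclass(frozen=True)
class ClusterComparison:
    latent_labels: np.ndarray
    attribution_labels: np.ndarray
    agreement: float  # adjusted Rand index


def latent_cluster(embeddings: EmbeddingMatrix, n_clusters: int = 7) -> np.ndarray:
    """Agglomerative (Ward linkage, Euclidean) clustering of latent vectors."""
    return _ward_labels(embeddings.vectors, n_clusters)


def _ward_labels(X: np.ndarray, n_clusters: int) -> np.ndarray:
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > len(X):
        raise ValueError("n_clusters exceeds number of molecules")
    if n_clusters == 1:
        return np.zeros(len(X), dtype=int)
    model = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward")
    return model.fit_predict(X)


def shap_attributions(model: StackedModel, subset: EmbeddingMatrix) -> AttributionMatrix:
    """Exact Shapley attributions of the forest component over ``subset``.

    Attribution covers the random-forest part of the stacked model only; the
    GP residual correction is excluded, so local accuracy is with respect to
    ``model.rf.predict``, not the stacked prediction.
    """
    if not hasattr(model.rf, "estimators_"):
        raise ValueError("model is not fitted")
    phi, base = forest_shap_values(model.rf, subset.vectors)
    return AttributionMatrix(
        molecule_ids=subset.molecule_ids,
        attributions=phi,
        base_value=base,
        mode="tree-exact",
    )


def shap_cluster(attributions: AttributionMatrix, n_clusters: int = 7) -> np.ndarray:
    """The latent-clustering procedure applied to attribution rows instead."""
    return _ward_labels(attributions.attributions, n_clusters)


def compare_clusterings(
    latent_labels: np.ndarray, attribution_labels: np.ndarray
) -> ClusterComparison:
    """Adjusted Rand index between the two clusterings of the same molecules."""
    if len(latent_labels) != len(attribution_labels):
        raise ValueError("label vectors must align")
    return ClusterComparison(
        latent_labels=np.asarray(latent_labels),
        attribution_labels=np.asarray(attribution_labels),
        agreement=float(adjusted_rand_score(latent_labels, attribution_labels)),
    )


def top_dimensions(
    attributions: AttributionMatrix, labels: np.ndarray, k: int
) -> dict[int, list[int]]:
    """Per cluster, the ``k`` dimensions with largest mean |attribution|.

    Ties are broken by ascending dimension index for determinism.
    """
    A = attributions.attributions
    labels = np.asarray(labels)
    if len(labels) != len(A):
        raise ValueError("labels must align with attribution rows")
    if k > A.shape[1]:
        raise ValueError("k exceeds the number of dimensions")
    out: dict[int, list[int]] = {}
    for lab in np.unique(labels):
        mean_abs = np.abs(A[labels == lab]).mean(axis=0)
        order = sorted(range(A.shape[1]), key=lambda j: (-mean_abs[j], j))
        out[int(lab)] = order[:k]
    return out


def project_2d(
    embeddings: EmbeddingMatrix, method: str = "pca", seed: int = 0
) -> np.ndarray:
    """2-D coordinates of the molecules; PCA deterministic, UMAP/t-SNE seeded."""
    X = embeddings.vectors
    if len(X) < 3:
        raise ValueError("need at least 3 points to project")
    if method == "pca":
        return PCA(n_components=2, svd_solver="full").fit_transform(X)
    if method == "tsne":
        perplexity = min(30.0, (len(X) - 1) / 3.0)
        return TSNE(
            n_components=2, random_state=seed, init="pca", perplexity=perplexity
        ).fit_transform(X)
    if method == "umap":
        import umap

        reducer = umap.UMAP(n_components=2, random_state=seed,
                            n_neighbors=min(15, len(X) - 1))
        return reducer.fit_transform(X)
    raise ValueError(f"unknown projection method {method!r}")
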