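"""Population-structure analyses: embedding, clustering, agreement.

These are the descriptive tools used to show that restricted progenitors
form expression clusters distinct from HSCs: t-SNE embeddings (arbitrary
units, qualitative), consensus k-means over many restarts ("reproducible
k-means"), hierarchical clustering, and chance-corrected agreement between
labelings.  Distances are Euclidean on the expression scale as given; an
optional z-score flag standardizes genes first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import adjusted_rand_score, confusion_matrix

from .datatypes import ExpressionMatrix


@dataclass
class ClusterResult:
    """Consensus k-means labeling with a reproducibility summary."""

    labels: pd.Series          # per-cell integer labels in [0, k)
    k: int
    restarts: int
    stability: float           # fraction of restarts matching the consensus
    seed: int
    inertia: float


def _values(matrix: ExpressionMatrix | pd.DataFrame, zscore: bool) -> pd.DataFrame:
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if zscore:
        sd = df.std(axis=0, ddof=0).replace(0.0, 1.0)
        df = (df - df.mean(axis=0)) / sd
    return df


def embed_tsne(
    matrix: ExpressionMatrix | pd.DataFrame,
    perplexity: float = 10.0,
    seed: int = 0,
    zscore: bool = False,
) -> pd.DataFrame:
    """2-D t-SNE embedding (coordinates in arbitrary units).

    Deterministic given ``seed``.  Requires at least ``3 * perplexity``
    cells, the usual rule of thumb for a meaningful neighborhood size.
    """
    df = _values(matrix, zscore)
    n = df.shape[0]
    if n < 3 * perplexity:
        raise ValueError(
            f"{n} cells is too few for perplexity {perplexity}; "
            f"need >= {int(np.ceil(3 * perplexity))} or a smaller perplexity"
        )
    coords = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(df.to_numpy())
    return pd.DataFrame(coords, index=df.index, columns=["tsne1", "tsne2"])


def _match_accuracy(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Accuracy of b against a, maximized over label matchings (Hungarian)."""
    cm = confusion_matrix(labels_a, labels_b)
    r, c = linear_sum_assignment(-cm)
    return float(cm[r, c].sum()) / labels_a.size


def kmeans_reproducible(
    matrix: ExpressionMatrix | pd.DataFrame,
    k: int = 2,
    restarts: int = 50,
    seed: int = 0,
    zscore: bool = False,
) -> ClusterResult:
    """Consensus k-means over independent restarts.

    The consensus is the best-inertia labeling; stability is the fraction
    of restarts whose partition matches the consensus exactly (up to label
    permutation).  Cells are processed in id-sorted order so the result is
    invariant to input row ordering.
    """
    df = _values(matrix, zscore)
    n = df.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if n <= k:
        raise ValueError(f"need more cells ({n}) than clusters ({k})")
    order = np.argsort(df.index.to_numpy())
    X = df.to_numpy()[order]

    rng = np.random.default_rng(seed)
    run_labels, inertias = [], []
    for _ in range(restarts):
        km = KMeans(
            n_clusters=k, n_init=1,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(X)
        run_labels.append(km.labels_)
        inertias.append(km.inertia_)

    best = int(np.argmin(inertias))
    consensus_sorted = run_labels[best]
    stability = float(
        np.mean([_match_accuracy(consensus_sorted, l) == 1.0 for l in run_labels])
    )
    labels = np.empty(n, dtype=int)
    labels[order] = consensus_sorted
    return ClusterResult(
        labels=pd.Series(labels, index=df.index, name="cluster"),
        k=k, restarts=restarts, stability=stability, seed=seed,
        inertia=float(inertias[best]),
    )


@dataclass
class HierarchicalResult:
    """Linkage matrix plus helpers for cutting into flat clusters."""

    linkage: np.ndarray
    cell_ids: list
    method: str
    metric: str

    def cut(self, k: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust") - 1
        return pd.Series(labels, index=self.cell_ids, name="cluster")

    def cophenetic_distances(self) -> np.ndarray:
        return hierarchy.cophenet(self.linkage)


def hierarchical_cluster(
    matrix: ExpressionMatrix | pd.DataFrame,
    linkage: str = "average",
    distance: str = "euclidean",
    zscore: bool = False,
) -> HierarchicalResult:
    """Agglomerative clustering; deterministic."""
    df = _values(matrix, zscore)
    if df.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    valid_linkage = {"single", "complete", "average", "ward", "centroid",
                     "median", "weighted"}
    if linkage not in valid_linkage:
        raise ValueError(f"unknown linkage {linkage!r}; valid: {sorted(valid_linkage)}")
    try:
        dists = pdist(df.to_numpy(), metric=distance)
    except ValueError as exc:
        raise ValueError(f"unknown distance metric {distance!r}") from exc
    Z = hierarchy.linkage(dists, method=linkage)
    return HierarchicalResult(Z, list(df.index), linkage, distance)


def cluster_agreement(labels_a, labels_b) -> dict[str, float]:
    """Adjusted Rand index and best-matching accuracy between labelings."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size != b.size:
        raise ValueError(f"label length mismatch: {a.size} vs {b.size}")
    return {
        "ari": float(adjusted_rand_score(a, b)),
        "accuracy_under_best_matching": _match_accuracy(
            pd.factorize(a)[0], pd.factorize(b)[0]
        ),
    }
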