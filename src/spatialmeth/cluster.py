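"""Top-variable probe selection and unsupervised hierarchical clustering.

The core classification step: rank probes by across-sample variability,
keep the top 10,000, and agglomeratively cluster the sample columns.
Clustering defaults to Euclidean distance on M values with Ward linkage;
beta-space clustering is available since methylation studies vary on
this.  The number of clusters can be fixed or chosen automatically by
mean silhouette width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist, squareform

from .matrices import BetaMatrix, MValueMatrix, beta_to_m

VARIABILITY_CRITERIA = ("sd", "mad")


def select_top_variable_probes(
    beta: BetaMatrix, k: int = 10_000, criterion: str = "sd"
) -> list[str]:
    """Return the ``min(k, n_probes)`` most variable probes.

    Probes are ranked by across-sample standard deviation of beta
    (``sd``, the default) or median absolute deviation (``mad``),
    descending; ties broken lexicographically by probe id so the
    selection is deterministic.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if beta.shape[1] < 2:
        raise ValueError("need >= 2 samples to rank probe variability")
    if criterion == "sd":
        score = beta.values.std(axis=1, ddof=1)
    elif criterion == "mad":
        med = beta.values.median(axis=1)
        score = (beta.values.sub(med, axis=0)).abs().median(axis=1)
    else:
        raise ValueError(f"criterion must be one of {VARIABILITY_CRITERIA}, got {criterion!r}")
    # mergesort is stable, so pre-sorting by probe id fixes the tie order
    order = (
        pd.DataFrame({"score": score})
        .sort_index(kind="mergesort")
        .sort_values(by="score", ascending=False, kind="mergesort")
    )
    return order.index[: min(k, len(order))].tolist()


@dataclass
class ClusterAssignment:
    """Sample -> cluster label (contiguous integers from 1) plus a method record."""

    labels: dict[str, int]
    k: int
    method: dict

    def __post_init__(self) -> None:
        observed = sorted(set(self.labels.values()))
        if observed != list(range(1, self.k + 1)):
            raise ValueError(f"labels must be contiguous 1..{self.k}, got {observed}")

    def samples_in(self, label: int) -> list[str]:
        return [s for s, c in self.labels.items() if c == label]

    def cluster_ids(self) -> list[int]:
        return list(range(1, self.k + 1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(self.labels), "cluster": list(self.labels.values())}
        )


def simplified_silhouette(X: np.ndarray, labels: np.ndarray, metric: str = "euclidean") -> float:
    """Mean centroid-based (simplified) silhouette of a partition.

    Per sample, ``a`` is the distance to its own cluster centroid and
    ``b`` the distance to the nearest other centroid; the silhouette is
    ``(b - a) / max(a, b)``.  Unlike the classic pairwise silhouette —
    which pins every singleton cluster at 0 and therefore can never
    favor a partition that isolates a genuinely distinct single sample —
    the centroid form lets a lone sample score well when it sits far
    from every other centroid.  Multi-region tumor designs expect such
    singleton clones (the primary resection here), so k-selection uses
    this form.
    """
    labs = np.unique(labels)
    if len(labs) < 2:
        raise ValueError("need >= 2 clusters for a silhouette")
    centroids = np.vstack([X[labels == lab].mean(axis=0) for lab in labs])
    d = cdist(X, centroids, metric=metric)
    own_col = np.searchsorted(labs, labels)
    a = d[np.arange(len(X)), own_col]
    d_other = d.copy()
    d_other[np.arange(len(X)), own_col] = np.inf
    b = d_other.min(axis=1)
    denom = np.maximum(a, b)
    s = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
    return float(s.mean())


def _relabel_first_appearance(samples: list[str], raw: np.ndarray) -> dict[str, int]:
    mapping: dict[int, int] = {}
    labels = {}
    for s, r in zip(samples, raw):
        if r not in mapping:
            mapping[r] = len(mapping) + 1
        labels[s] = mapping[r]
    return labels


def hierarchical_cluster(
    matrix: BetaMatrix | MValueMatrix,
    k_clusters: int | None = 3,
    metric: str = "euclidean",
    linkage_method: str = "ward",
    space: str = "m",
    max_auto_k: int = 6,
) -> tuple[np.ndarray, ClusterAssignment]:
    """Agglomeratively cluster sample columns; cut at ``k_clusters``.

    When ``k_clusters`` is None, k is chosen over ``2..min(max_auto_k,
    n_samples - 1)`` by the mean centroid-based silhouette of the cut
    (see :func:`simplified_silhouette`), computed in the same space and
    metric used for linkage.  Returns the scipy linkage matrix (the
    dendrogram) and the assignment; labels are renumbered in sample
    order of first appearance so output is deterministic.
    """
    values = _as_space(matrix, space)
    samples = list(values.columns)
    n = len(samples)
    if n < 2:
        raise ValueError("need >= 2 samples to cluster")
    if k_clusters is not None and k_clusters > n:
        raise ValueError(f"k_clusters={k_clusters} exceeds n_samples={n}")

    X = values.to_numpy().T  # samples x probes
    dist = pdist(X, metric=metric)
    Z = linkage(dist, method=linkage_method)

    if k_clusters is None:
        best_k, best_score = None, -np.inf
        for k in range(2, min(max_auto_k, n - 1) + 1):
            raw = fcluster(Z, t=k, criterion="maxclust")
            if len(set(raw)) < 2:
                continue
            score = simplified_silhouette(X, raw, metric=metric)
            if score > best_score + 1e-12:
                best_k, best_score = k, score
        k_clusters = best_k if best_k is not None else 1
        selection = {"auto_k": True, "silhouette": float(best_score)}
    else:
        selection = {"auto_k": False}

    raw = fcluster(Z, t=k_clusters, criterion="maxclust") if k_clusters > 1 else np.ones(n, int)
    labels = _relabel_first_appearance(samples, raw)
    assignment = ClusterAssignment(
        labels=labels,
        k=len(set(labels.values())),
        method={"metric": metric, "linkage": linkage_method, "space": space, **selection},
    )
    return Z, assignment


def sample_distance_matrix(
    matrix: BetaMatrix | MValueMatrix, metric: str = "euclidean", space: str = "m"
) -> pd.DataFrame:
    """Pairwise sample-by-sample distances used for both clustering and the phylogeny."""
    values = _as_space(matrix, space)
    d = squareform(pdist(values.to_numpy().T, metric=metric))
    return pd.DataFrame(d, index=values.columns, columns=values.columns)


def _as_space(matrix: BetaMatrix | MValueMatrix, space: str) -> pd.DataFrame:
    if space not in ("beta", "m"):
        raise ValueError(f"space must be 'beta' or 'm', got {space!r}")
    if isinstance(matrix, MValueMatrix):
        return matrix.values
    if space == "m":
        return beta_to_m(matrix).values
    return matrix.values
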