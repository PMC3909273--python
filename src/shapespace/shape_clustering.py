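"""Discovery of discrete shape classes in principal-component space.

Two clustering families are swept over a range of cluster counts k:
agglomerative hierarchical clustering (Euclidean distance, Ward linkage) and
Gaussian mixture models (full covariance, best of several EM restarts).  Each
fitted model is scored by its average silhouette value and the best-scoring
model across the whole sweep is selected.  Cells whose silhouette falls below
a threshold are then relabelled by a k-nearest-neighbour majority vote among
the confidently assigned cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

from .preprocess import PCEmbedding

__all__ = [
    "ClusterModel",
    "ShapeAssignment",
    "fit_hierarchical",
    "fit_gmm",
    "silhouette_values",
    "sweep_and_select",
    "knn_correct",
]


@dataclass
class ClusterModel:
    """One fitted clustering of the embedding.

    ``labels`` are integers 1..k with every label occupied.  ``fit_metadata``
    records method-specific diagnostics (e.g. per-restart log-likelihoods).
    """

    method: str  # "hierarchical" or "gmm"
    k: int
    labels: np.ndarray
    mean_silhouette: float
    per_cell_silhouette: np.ndarray
    fit_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if present.min() < 1 or present.max() > self.k:
            raise ValueError("labels must lie in 1..k")
        if len(present) != self.k:
            raise ValueError("every label in 1..k must be occupied")


@dataclass
class ShapeAssignment:
    """Final per-cell shape labels after low-confidence correction.

    ``shape_means`` row i is the mean PC coordinate of cells labelled i+1;
    it is the source of the shape-separation matrix used by the weighted
    heterogeneity distance.
    """

    labels: np.ndarray
    silhouette: np.ndarray
    corrected: np.ndarray
    shape_means: np.ndarray
    cell_ids: np.ndarray
    tc_ids: np.ndarray
    mean_silhouette_before: float
    mean_silhouette_after: float

    @property
    def shape_ids(self) -> np.ndarray:
        return np.arange(1, self.shape_means.shape[0] + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "tc_id": self.tc_ids,
                "shape_id": self.labels,
                "silhouette": self.silhouette,
                "corrected": self.corrected,
            }
        )


def _cluster_distance_sums(
    coords: np.ndarray, labels: np.ndarray, order: np.ndarray, chunk: int = 2048
) -> np.ndarray:
    """Sum of Euclidean distances from each cell to all cells of each cluster.

    Returns (n_cells, n_clusters); computed in row chunks so the full n x n
    distance matrix is never materialised.
    """
    n = coords.shape[0]
    k = len(order)
    sums = np.empty((n, k))
    masks = [labels == c for c in order]
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = cdist(coords[start:stop], coords)
        for j, m in enumerate(masks):
            sums[start:stop, j] = d[:, m].sum(axis=1)
    return sums


def silhouette_values(coords: np.ndarray | PCEmbedding, labels: np.ndarray) -> np.ndarray:
    """Per-cell silhouette s(i) = (b - a) / max(a, b) with Euclidean distances.

    a(i) is the mean distance to the other cells of i's cluster; b(i) is the
    smallest mean distance to the cells of any other cluster.  Cells in
    singleton clusters get s = 0 by convention, as do cells where both a and
    b vanish (exact duplicates).
    """
    if isinstance(coords, PCEmbedding):
        coords = coords.coords
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    clusters, inverse = np.unique(labels, return_inverse=True)
    if len(clusters) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    counts = np.bincount(inverse)
    sums = _cluster_distance_sums(coords, labels, clusters)
    n = coords.shape[0]
    own_count = counts[inverse]
    own_sum = sums[np.arange(n), inverse]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = own_sum / np.maximum(own_count - 1, 1)
        other = sums / counts[np.newaxis, :]
        other[np.arange(n), inverse] = np.inf
        b = other.min(axis=1)
        s = (b - a) / np.maximum(a, b)
    s = np.where(np.maximum(a, b) == 0, 0.0, s)  # duplicate-point convention
    s = np.where(own_count == 1, 0.0, s)  # singleton convention
    return s


def fit_hierarchical(
    embedding: PCEmbedding,
    k: int,
    _linkage_cache: np.ndarray | None = None,
) -> ClusterModel:
    """Ward-linkage agglomerative clustering in PC space, cut at k clusters."""
    coords = embedding.coords
    n = coords.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range [2, {n}]")
    Z = _linkage_cache if _linkage_cache is not None else linkage(coords, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = _compact_labels(raw)
    k_eff = int(labels.max())
    sil = silhouette_values(coords, labels) if k_eff >= 2 else np.zeros(n)
    return ClusterModel(
        method="hierarchical",
        k=k_eff,
        labels=labels,
        mean_silhouette=float(sil.mean()),
        per_cell_silhouette=sil,
        fit_metadata={"requested_k": k},
    )


def _compact_labels(raw: np.ndarray) -> np.ndarray:
    """Map arbitrary integer labels onto contiguous 1..k preserving order of
    first appearance of the sorted unique values."""
    present = np.unique(raw)
    lut = {c: i + 1 for i, c in enumerate(present)}
    return np.asarray([lut[c] for c in raw], dtype=int)


def fit_gmm(
    embedding: PCEmbedding,
    k: int,
    restarts: int = 10,
    seed: int = 0,
) -> ClusterModel:
    """Gaussian mixture fit in PC space, best total log-likelihood of
    ``restarts`` independently initialised EM runs.

    Restart r always uses the RNG stream derived from (seed, r), so the model
    selected from restarts=m is among the candidates of any restarts > m with
    the same seed.  Components use full covariances with a small diagonal
    regularisation; initialisation is k-means++.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    coords = embedding.coords
    best = None
    best_ll = -np.inf
    lls: list[float] = []
    last_error: Exception | None = None
    for r in range(restarts):
        rs = np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm = GaussianMixture(
                    n_components=k,
                    covariance_type="full",
                    reg_covar=1e-6,
                    init_params="k-means++",
                    max_iter=300,
                    n_init=1,
                    random_state=int(rs),
                ).fit(coords)
            ll = float(gm.score(coords) * coords.shape[0])
        except Exception as exc:  # EM degeneracy on this restart
            last_error = exc
            continue
        lls.append(ll)
        if ll > best_ll:
            best_ll, best = ll, gm
    if best is None:
        raise RuntimeError(f"all GMM restarts failed: {last_error}")
    raw = best.predict(coords) + 1
    labels = _compact_labels(raw)
    k_eff = int(labels.max())
    sil = (
        silhouette_values(coords, labels)
        if k_eff >= 2
        else np.zeros(coords.shape[0])
    )
    return ClusterModel(
        method="gmm",
        k=k_eff,
        labels=labels,
        mean_silhouette=float(sil.mean()),
        per_cell_silhouette=sil,
        fit_metadata={
            "requested_k": k,
            "restarts": restarts,
            "restart_log_likelihoods": lls,
            "best_log_likelihood": best_ll,
        },
    )


def sweep_and_select(
    embedding: PCEmbedding,
    k_range: tuple[int, int] = (5, 30),
    seed: int = 0,
    restarts: int = 10,
) -> tuple[ClusterModel, pd.DataFrame]:
    """Fit both methods for every k in the inclusive range and return the
    model with the highest mean silhouette plus the full sweep table.

    Ties are broken in favour of hierarchical clustering, then smaller k.
    Fit failures are recorded in the sweep table and skipped.
    """
    k_min, k_max = k_range
    n = embedding.n_cells
    if not (2 <= k_min <= k_max <= n - 1):
        raise ValueError(f"k_range {k_range} outside [2, {n - 1}]")
    Z = linkage(embedding.coords, method="ward")
    rows = []
    best: ClusterModel | None = None
    for k in range(k_min, k_max + 1):
        for method in ("hierarchical", "gmm"):
            try:
                if method == "hierarchical":
                    model = fit_hierarchical(embedding, k, _linkage_cache=Z)
                else:
                    model = fit_gmm(embedding, k, restarts=restarts, seed=seed + k)
            except Exception as exc:
                rows.append(
                    {"method": method, "k": k, "mean_silhouette": np.nan,
                     "error": str(exc)}
                )
                continue
            rows.append(
                {"method": method, "k": k,
                 "mean_silhouette": model.mean_silhouette, "error": ""}
            )
            if best is None or model.mean_silhouette > best.mean_silhouette + 1e-12:
                best = model
    if best is None:
        raise RuntimeError("every fit in the sweep failed")
    sweep = pd.DataFrame(rows)
    return best, sweep


def knn_correct(
    embedding: PCEmbedding,
    model: ClusterModel,
    silhouette_threshold: float = 0.6,
    n_neighbors: int = 10,
) -> ShapeAssignment:
    """Relabel low-confidence cells by majority vote of their nearest
    confidently clustered neighbours.

    Cells with silhouette below the threshold are assigned the most common
    label among their ``n_neighbors`` nearest cells with silhouette at or
    above the threshold (ties broken by the single nearest neighbour's
    label).  One pass only; silhouettes are recomputed on the final labels.
    """
    coords = embedding.coords
    sil0 = model.per_cell_silhouette
    labels = model.labels.copy()
    low = sil0 < silhouette_threshold
    high = ~low
    n_ref = int(high.sum())
    if low.any():
        if n_ref == 0:
            raise ValueError(
                "no cells at or above the silhouette threshold to serve as "
                "KNN references"
            )
        k_use = n_neighbors
        if n_ref < n_neighbors:
            warnings.warn(
                f"only {n_ref} reference cells available; using all of them "
                f"instead of n_neighbors={n_neighbors}",
                stacklevel=2,
            )
            k_use = n_ref
        nn = NearestNeighbors(n_neighbors=k_use).fit(coords[high])
        _, idx = nn.kneighbors(coords[low])
        ref_labels = labels[high]
        for row, cell in zip(idx, np.where(low)[0]):
            votes = ref_labels[row]
            counts = np.bincount(votes)
            winners = set(np.flatnonzero(counts == counts.max()))
            # tie among winning labels broken by the nearest voting neighbour
            labels[cell] = next(v for v in votes if v in winners)
    if len(np.unique(labels)) != labels.max():
        labels = _compact_labels(labels)  # a cluster emptied by relabeling
    k = int(labels.max())
    sil1 = (
        silhouette_values(coords, labels)
        if len(np.unique(labels)) >= 2
        else np.zeros_like(sil0)
    )
    means = np.vstack(
        [coords[labels == s].mean(axis=0) for s in range(1, k + 1)]
    )
    return ShapeAssignment(
        labels=labels,
        silhouette=sil1,
        corrected=low.copy(),
        shape_means=means,
        cell_ids=embedding.cell_ids,
        tc_ids=embedding.tc_ids,
        mean_silhouette_before=float(sil0.mean()),
        mean_silhouette_after=float(sil1.mean()),
    )
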