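"""Per-condition shape heterogeneity profiles and their clustering.

A treatment-condition heterogeneity profile (TCHP) is the vector of shape
fractions in one condition.  Profiles are normalised by subtracting the
wild-type profile, so a normalised TCHP is a zero-sum vector of enrichments
and depletions.  Conditions are compared with a weighted distance that takes
into account how far apart the shapes themselves lie in PC space: with
Delta = x1 - x2 and M the matrix of Euclidean distances between per-shape
mean PC coordinates, the squared distance is -Delta M Delta^T.  Because a
Euclidean distance matrix is conditionally negative definite on zero-sum
vectors, this quadratic form is non-negative after the sign flip, and D is a
pseudometric: differences concentrated on well-separated shapes count for
more than the same differences on nearby shapes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .shape_clustering import ShapeAssignment

__all__ = [
    "TCHP",
    "ShapeDistanceMatrix",
    "TCHPClustering",
    "compute_tchp",
    "normalize_tchp",
    "tchp_distance",
    "cluster_tchps",
    "enriched_shapes",
    "shapes_present",
]

_ZERO_SUM_TOL = 1e-6


@dataclass
class TCHP:
    """Shape-fraction profile of one treatment condition.

    Raw profiles are compositional (entries in [0,1], summing to 1);
    normalised profiles are wild-type-subtracted and sum to 0.
    """

    tc_id: str
    fractions: np.ndarray
    normalized: bool
    n_cells: int

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.normalized:
            if abs(self.fractions.sum()) > _ZERO_SUM_TOL:
                raise ValueError(
                    f"normalized TCHP for {self.tc_id!r} does not sum to 0"
                )
        else:
            if np.any(self.fractions < -1e-12) or np.any(self.fractions > 1 + 1e-12):
                raise ValueError(
                    f"raw TCHP fractions for {self.tc_id!r} outside [0, 1]"
                )
            if abs(self.fractions.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"raw TCHP fractions for {self.tc_id!r} do not sum to 1"
                )

    @property
    def n_shapes(self) -> int:
        return len(self.fractions)


@dataclass
class ShapeDistanceMatrix:
    """Pairwise Euclidean distances between per-shape mean PC coordinates."""

    M: np.ndarray
    source_means: np.ndarray
    shape_ids: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        k = self.M.shape[0]
        if self.M.shape != (k, k):
            raise ValueError("M must be square")
        if not np.allclose(self.M, self.M.T, atol=1e-9):
            raise ValueError("M must be symmetric")
        if not np.allclose(np.diag(self.M), 0, atol=1e-9):
            raise ValueError("M must have a zero diagonal")
        if np.any(self.M < -1e-12):
            raise ValueError("M must be nonnegative")

    @classmethod
    def from_shape_means(
        cls, means: np.ndarray, shape_ids: np.ndarray | None = None
    ) -> "ShapeDistanceMatrix":
        means = np.asarray(means, dtype=float)
        if shape_ids is None:
            shape_ids = np.arange(1, means.shape[0] + 1)
        return cls(
            M=squareform(pdist(means)),
            source_means=means,
            shape_ids=np.asarray(shape_ids),
        )

    @classmethod
    def from_assignment(cls, assignment: ShapeAssignment) -> "ShapeDistanceMatrix":
        return cls.from_shape_means(assignment.shape_means, assignment.shape_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.M, index=self.shape_ids, columns=self.shape_ids)


@dataclass
class TCHPClustering:
    """Complete-linkage grouping of conditions by weighted TCHP distance."""

    cluster_labels: dict[str, int]
    linkage_matrix: np.ndarray
    n_clusters: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tc_id": list(self.cluster_labels), "cluster": list(self.cluster_labels.values())}
        )


def compute_tchp(
    assignment: ShapeAssignment, n_shapes: int | None = None
) -> list[TCHP]:
    """Per-condition shape fractions from the final cell labels.

    Shapes absent from a condition get fraction 0.  Conditions with zero
    cells cannot occur here (every cell carries a tc_id), but an explicitly
    empty condition list would simply be absent from the output.
    """
    k = n_shapes or int(assignment.shape_means.shape[0])
    df = pd.DataFrame({"tc_id": assignment.tc_ids, "shape": assignment.labels})
    profiles = []
    for tc_id, grp in df.groupby("tc_id", sort=True):
        counts = np.bincount(grp["shape"], minlength=k + 1)[1:]
        n = len(grp)
        if n == 0:
            warnings.warn(f"condition {tc_id!r} has no cells; excluded", stacklevel=2)
            continue
        profiles.append(
            TCHP(tc_id=str(tc_id), fractions=counts / n, normalized=False, n_cells=n)
        )
    return profiles


def normalize_tchp(profiles: list[TCHP], wildtype_id: str) -> list[TCHP]:
    """Subtract the wild-type profile from every profile."""
    by_id = {p.tc_id: p for p in profiles}
    if wildtype_id not in by_id:
        raise ValueError(f"wild-type condition {wildtype_id!r} not found")
    wt = by_id[wildtype_id]
    if wt.normalized:
        raise ValueError("wild-type profile must be a raw profile")
    return [
        TCHP(
            tc_id=p.tc_id,
            fractions=p.fractions - wt.fractions,
            normalized=True,
            n_cells=p.n_cells,
        )
        for p in profiles
    ]


def _normalized_diff(x1: TCHP, x2: TCHP) -> np.ndarray:
    if not (x1.normalized and x2.normalized):
        raise ValueError("tchp_distance requires normalized profiles")
    if x1.n_shapes != x2.n_shapes:
        raise ValueError("profile lengths differ")
    delta = x1.fractions - x2.fractions
    if abs(delta.sum()) > _ZERO_SUM_TOL:
        raise ValueError("profile difference is not zero-sum; inputs invalid")
    return delta


def tchp_distance(x1: TCHP, x2: TCHP, M: ShapeDistanceMatrix) -> float:
    """Weighted distance between two normalised profiles.

    D = sqrt(-Delta M Delta^T), clamped at 0 against round-off.  The
    quadratic form is non-positive on zero-sum vectors because a Euclidean
    distance matrix is conditionally negative definite, so D is real.
    """
    delta = _normalized_diff(x1, x2)
    if len(delta) != M.M.shape[0]:
        raise ValueError("profile length does not match M")
    q = float(delta @ M.M @ delta)
    return float(np.sqrt(max(0.0, -q)))


def _pairwise_tchp_distances(
    profiles: list[TCHP], M: ShapeDistanceMatrix
) -> np.ndarray:
    """Condensed distance vector over profiles (pdist ordering)."""
    X = np.vstack([p.fractions for p in profiles])
    for p in profiles:
        if not p.normalized:
            raise ValueError("cluster_tchps requires normalized profiles")
    n = len(profiles)
    out = []
    for i in range(n - 1):
        delta = X[i] - X[i + 1 :]
        q = np.einsum("ij,jk,ik->i", delta, M.M, delta)
        out.append(np.sqrt(np.maximum(0.0, -q)))
    return np.concatenate(out) if out else np.empty(0)


def cluster_tchps(
    profiles: list[TCHP], M: ShapeDistanceMatrix, n_clusters: int
) -> TCHPClustering:
    """Complete-linkage hierarchical clustering of normalised profiles under
    the weighted distance, cut at ``n_clusters``.

    The cut height is a required choice: the original selection rule (best
    overlap with an external reference grouping) needs that reference, so the
    cluster count is exposed as configuration instead.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    if not 1 <= n_clusters <= len(profiles):
        raise ValueError(
            f"n_clusters={n_clusters} outside [1, {len(profiles)}]"
        )
    dvec = _pairwise_tchp_distances(profiles, M)
    Z = linkage(dvec, method="complete")
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    return TCHPClustering(
        cluster_labels={p.tc_id: int(c) for p, c in zip(profiles, raw)},
        linkage_matrix=Z,
        n_clusters=int(len(np.unique(raw))),
    )


def enriched_shapes(profile: TCHP, threshold: float = 0.10) -> set[int]:
    """Shapes making up strictly more than ``threshold`` of the population."""
    if profile.normalized:
        raise ValueError("enrichment is defined on raw profiles")
    return {i + 1 for i, f in enumerate(profile.fractions) if f > threshold}


def shapes_present(profile: TCHP) -> set[int]:
    """Shapes with nonzero fraction in a raw profile."""
    if profile.normalized:
        raise ValueError("presence is defined on raw profiles")
    return {i + 1 for i, f in enumerate(profile.fractions) if f > 0}


def tchp_long_format(
    profiles: list[TCHP], clustering: TCHPClustering | None = None
) -> pd.DataFrame:
    """Heatmap-ready long format: one row per (tc_id, shape)."""
    rows = []
    for p in profiles:
        for s, f in enumerate(p.fractions, start=1):
            rows.append(
                {
                    "tc_id": p.tc_id,
                    "shape": s,
                    "fraction": f,
                    "normalized": p.normalized,
                    "cluster": (
                        clustering.cluster_labels.get(p.tc_id)
                        if clustering
                        else None
                    ),
                }
            )
    return pd.DataFrame(rows)
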