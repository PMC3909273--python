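"""Shape-transition statistics from per-cell trajectories.

Cells imaged at fixed intervals yield a shape label per frame; every
consecutive frame pair contributes one transition count (self-pairs included,
so the diagonal holds the probability of staying put).  Row-normalising the
count matrix gives the maximum-likelihood estimate of a first-order Markov
transition matrix, which is compared against the consensus dependency
network: network edges should align with observed transitions, and mass
between distant blocks of shape space should be scarce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network_inference import ConsensusNetwork

__all__ = [
    "TrajectorySet",
    "TransitionMatrix",
    "estimate_transitions",
    "stability_ranking",
    "consistency_report",
]


@dataclass
class TrajectorySet:
    """Per-cell ordered shape labels sampled at a fixed frame interval."""

    frames: pd.DataFrame  # columns: cell_id, frame_index, shape_id
    frame_interval_min: float

    def __post_init__(self) -> None:
        required = {"cell_id", "frame_index", "shape_id"}
        if not required.issubset(self.frames.columns):
            raise ValueError(f"trajectory frame needs columns {sorted(required)}")
        self.frames = self.frames.sort_values(["cell_id", "frame_index"]).reset_index(
            drop=True
        )
        for cell, grp in self.frames.groupby("cell_id"):
            idx = grp["frame_index"].to_numpy()
            if np.any(np.diff(idx) <= 0):
                raise ValueError(
                    f"frame indices for cell {cell!r} are not strictly increasing"
                )
        if (self.frames["shape_id"] < 1).any():
            raise ValueError("shape ids must be >= 1")

    @property
    def n_cells(self) -> int:
        return self.frames["cell_id"].nunique()

    @property
    def n_frames_total(self) -> int:
        return len(self.frames)

    def write_tsv(self, path: str | Path) -> None:
        self.frames.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(
        cls, path: str | Path, frame_interval_min: float = 5.0
    ) -> "TrajectorySet":
        return cls(
            frames=pd.read_csv(path, sep="\t"),
            frame_interval_min=frame_interval_min,
        )


@dataclass
class TransitionMatrix:
    """Counts and row-normalised probabilities of shape-to-shape transitions.

    Rows with zero counts (never-visited shapes) keep all-zero probability
    rows and are listed in ``unobserved_shapes`` rather than being smoothed;
    optional add-alpha smoothing is available at estimation time.
    ``n_transitions`` counts every frame pair including self-pairs;
    ``n_changes`` counts only off-diagonal pairs.
    """

    counts: np.ndarray
    probabilities: np.ndarray
    n_transitions: int
    n_changes: int
    shape_ids: np.ndarray
    unobserved_shapes: list[int] = field(default_factory=list)

    @property
    def n_shapes(self) -> int:
        return self.counts.shape[0]

    def to_frame(self, kind: str = "probabilities") -> pd.DataFrame:
        mat = self.probabilities if kind == "probabilities" else self.counts
        return pd.DataFrame(mat, index=self.shape_ids, columns=self.shape_ids)


def estimate_transitions(
    trajectories: TrajectorySet,
    n_shapes: int | None = None,
    alpha: float = 0.0,
) -> TransitionMatrix:
    """Maximum-likelihood first-order Markov estimate from frame pairs.

    ``alpha`` adds a flat pseudocount to every entry before normalisation
    (default 0: pure MLE).
    """
    df = trajectories.frames
    if df.empty:
        raise ValueError("empty trajectory set")
    k = int(n_shapes or df["shape_id"].max())
    counts = np.zeros((k, k), dtype=int)
    any_pair = False
    for _, grp in df.groupby("cell_id"):
        s = grp["shape_id"].to_numpy(dtype=int)
        if len(s) < 2:
            continue
        any_pair = True
        np.add.at(counts, (s[:-1] - 1, s[1:] - 1), 1)
    if not any_pair:
        raise ValueError("no consecutive frame pairs in the trajectory set")
    row_sums = counts.sum(axis=1)
    smoothed = counts + alpha
    srows = smoothed.sum(axis=1)
    probs = np.zeros((k, k), dtype=float)
    nz = srows > 0
    probs[nz] = smoothed[nz] / srows[nz, np.newaxis]
    unobserved = [i + 1 for i in range(k) if row_sums[i] == 0]
    if alpha > 0:
        # smoothing gives unobserved rows the flat distribution; keep them
        # flagged but zero only when alpha == 0
        pass
    else:
        probs[~nz] = 0.0
    n_trans = int(counts.sum())
    return TransitionMatrix(
        counts=counts,
        probabilities=probs,
        n_transitions=n_trans,
        n_changes=int(n_trans - np.trace(counts)),
        shape_ids=np.arange(1, k + 1),
        unobserved_shapes=unobserved,
    )


def stability_ranking(matrix: TransitionMatrix) -> list[tuple[int, float]]:
    """Shapes ordered by self-transition probability, most stable first;
    ties broken by shape id."""
    diag = np.diag(matrix.probabilities)
    order = sorted(range(matrix.n_shapes), key=lambda i: (-diag[i], i))
    return [(int(matrix.shape_ids[i]), float(diag[i])) for i in order]


def consistency_report(
    matrix: TransitionMatrix,
    network: ConsensusNetwork,
    blocks: tuple[set[int], set[int]] = ({1, 2, 3}, {5, 6, 7}),
) -> dict:
    """Compare observed transitions with the dependency network.

    Reports, per network edge, the empirical parent->child transition
    probability; the total transition probability mass crossing between the
    two shape blocks (both directions, as a share of all transitions); and
    observed off-diagonal transitions with no corresponding network edge
    (including child->parent back-transitions).
    """
    k = matrix.n_shapes
    idx = {int(s): i for i, s in enumerate(matrix.shape_ids)}
    edge_probs = []
    edge_set = set()
    for e in network.edges:
        edge_set.add((e.parent, e.child))
        p = (
            float(matrix.probabilities[idx[e.parent], idx[e.child]])
            if e.parent in idx and e.child in idx
            else None
        )
        edge_probs.append(
            {
                "parent": e.parent,
                "child": e.child,
                "sign": e.sign,
                "transition_probability": p,
                "observed": bool(
                    p is not None
                    and matrix.counts[idx[e.parent], idx[e.child]] > 0
                ),
            }
        )
    block_a, block_b = blocks
    total = max(matrix.n_transitions, 1)
    cross = 0
    for i_shape in block_a:
        for j_shape in block_b:
            if i_shape in idx and j_shape in idx:
                cross += matrix.counts[idx[i_shape], idx[j_shape]]
                cross += matrix.counts[idx[j_shape], idx[i_shape]]
    unexplained = []
    for i in range(k):
        for j in range(k):
            if i == j or matrix.counts[i, j] == 0:
                continue
            pair = (int(matrix.shape_ids[i]), int(matrix.shape_ids[j]))
            if pair not in edge_set:
                unexplained.append(
                    {
                        "from": pair[0],
                        "to": pair[1],
                        "count": int(matrix.counts[i, j]),
                        "probability": float(matrix.probabilities[i, j]),
                        "is_back_transition": (pair[1], pair[0]) in edge_set,
                    }
                )
    return {
        "edges": edge_probs,
        "cross_block_mass": cross / total,
        "cross_block_counts": int(cross),
        "blocks": [sorted(block_a), sorted(block_b)],
        "unexplained_transitions": unexplained,
        "n_transitions": matrix.n_transitions,
        "n_changes": matrix.n_changes,
    }
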