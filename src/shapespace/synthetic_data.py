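"""Synthetic screen generator: cells, condition panels and trajectories.

The original screen (hundreds of RNAi/overexpression treatment conditions,
~12,000 cells, 145 morphology features) is not publicly deposited, so this
module generates data with the same statistical structure so that every
downstream stage can be exercised and validated:

* **Cells** — each shape class is a Gaussian archetype in a 3-D latent
  morphology space; a cell's 145 features are an exponentiated affine lift of
  its latent position plus noise, giving strictly positive, log-normal-like,
  correlated features such that the scale/log/PCA preprocessing recovers the
  latent space.
* **Condition panels** — per-condition shape-frequency vectors derived from
  the wild-type mixture by propagating perturbations through a planted
  signed dependency graph, so the panel carries inter-shape correlations for
  network inference to find.
* **Trajectories** — independent first-order Markov chains of shape labels
  sampled at a fixed frame interval.

The wild-type mixture defaults to the measured control distribution
(3% shape 1, 0% shape 2, 6.9% shape 3, 20% shape 4, 17% shape 5,
18.6% shape 6, 33.8% shape 7), renormalised from its printed 99.3% total to
sum to exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .preprocess import FeatureTable
from .transitions import TrajectorySet

__all__ = [
    "ShapeArchetype",
    "ConditionSpec",
    "TrajectoryConfig",
    "WILDTYPE_WEIGHTS",
    "WILDTYPE_RENORM_FACTOR",
    "default_archetypes",
    "default_dependency_graph",
    "default_transition_matrix",
    "generate_cells",
    "generate_condition_panel",
    "generate_trajectories",
]

# Control distribution of the seven shapes as percentages; printed values sum
# to 99.3, renormalised to a proper composition.
_WILDTYPE_RAW = np.array([3.0, 0.0, 6.9, 20.0, 17.0, 18.6, 33.8])
WILDTYPE_RENORM_FACTOR = float(_WILDTYPE_RAW.sum() / 100.0)  # 0.993
WILDTYPE_WEIGHTS = _WILDTYPE_RAW / _WILDTYPE_RAW.sum()


@dataclass
class ShapeArchetype:
    """One latent shape class: a Gaussian in 3-D latent morphology space."""

    shape_id: int
    latent_mean: np.ndarray
    latent_cov: np.ndarray

    def __post_init__(self) -> None:
        self.latent_mean = np.asarray(self.latent_mean, dtype=float)
        self.latent_cov = np.asarray(self.latent_cov, dtype=float)
        if self.latent_mean.shape != (3,):
            raise ValueError("latent_mean must be a 3-vector")
        if self.latent_cov.shape != (3, 3):
            raise ValueError("latent_cov must be 3x3")
        if not np.allclose(self.latent_cov, self.latent_cov.T, atol=1e-12):
            raise ValueError("latent_cov must be symmetric")
        if np.linalg.eigvalsh(self.latent_cov).min() <= 0:
            raise ValueError("latent_cov must be positive-definite")


@dataclass
class ConditionSpec:
    """One treatment condition: its size and shape-class mixture weights."""

    tc_id: str
    n_cells: int
    shape_weights: np.ndarray
    is_wildtype: bool = False

    def __post_init__(self) -> None:
        self.shape_weights = np.asarray(self.shape_weights, dtype=float)
        if self.n_cells <= 0:
            raise ValueError(f"n_cells must be positive for {self.tc_id!r}")
        if np.any(self.shape_weights < 0):
            raise ValueError(f"negative shape weight in {self.tc_id!r}")
        if abs(self.shape_weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"shape weights for {self.tc_id!r} must sum to 1")


@dataclass
class TrajectoryConfig:
    """Markov-chain sampling parameters for live-imaging emulation.

    Defaults mirror a 3-hour acquisition at 5-minute intervals (37 frames).
    """

    transition_matrix: np.ndarray
    n_cells: int = 50
    n_frames: int = 37
    frame_interval_min: float = 5.0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        P = self.transition_matrix
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(P < 0) or np.any(P > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if self.n_cells <= 0 or self.n_frames < 1:
            raise ValueError("n_cells and n_frames must be positive")


# Corners of the unit cube give up to 8 archetype centroids with pairwise
# separation >= 1 before scaling; order chosen so consecutive ids differ.
_CENTROID_TEMPLATE = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 1, 0],
        [1, 0, 1],
        [0, 1, 1],
        [1, 1, 1],
    ],
    dtype=float,
)


def default_archetypes(
    k: int = 7, separation: float = 8.0, within_sd: float = 1.0
) -> list[ShapeArchetype]:
    """k well-separated spherical archetypes.

    Centroids sit on cube corners scaled so the minimum pairwise centroid
    distance equals ``separation``; within-class covariance is isotropic
    with standard deviation ``within_sd`` (default separation/within_sd = 8,
    comfortably past the 5x ratio at which the full pipeline is expected to
    recover the classes).
    """
    if not 1 <= k <= len(_CENTROID_TEMPLATE):
        raise ValueError(f"k must be in 1..{len(_CENTROID_TEMPLATE)}")
    cov = np.eye(3) * within_sd**2
    return [
        ShapeArchetype(
            shape_id=i + 1,
            latent_mean=_CENTROID_TEMPLATE[i] * separation,
            latent_cov=cov.copy(),
        )
        for i in range(k)
    ]


def default_dependency_graph() -> nx.DiGraph:
    """Planted signed dependency topology among shapes.

    A reconstruction of the consensus network reported on the screen: the
    migratory shape 5 sits at the top of the hierarchy; the spread shapes 6
    and 7 depend positively on it; the rounded/contractile/poorly-spread
    shapes 1, 3 and 4 depend negatively on it (driving the two anticorrelated
    blocks of shape space).  Shape 2 is deliberately left out: its abundance
    correlates with no other shape.  Edge attribute ``sign`` is +1 or -1.
    """
    g = nx.DiGraph()
    g.add_nodes_from(range(1, 8))
    g.add_edge(5, 6, sign=+1)
    g.add_edge(5, 7, sign=+1)
    g.add_edge(5, 1, sign=-1)
    g.add_edge(5, 3, sign=-1)
    g.add_edge(5, 4, sign=-1)
    return g


def generate_cells(
    archetypes: list[ShapeArchetype],
    conditions: list[ConditionSpec],
    n_features: int = 145,
    loading_seed: int = 0,
    noise_sd: float = 0.1,
    cell_seed: int = 0,
) -> tuple[FeatureTable, np.ndarray]:
    """Sample a feature table plus the hidden true shape labels.

    Per condition, each cell draws a shape class from the condition's mixture
    weights and a latent 3-vector from its archetype.  Features are
    ``exp(A z + b + noise)`` where the lift ``A`` (entries N(0, 1/3)) and
    intercept ``b`` are drawn once from ``loading_seed`` and then fixed, so
    the same loading seed always produces the same feature geometry.  The
    exponential keeps every value strictly positive, exercising the
    offset/log preprocessing end to end.
    """
    if n_features < 3:
        raise ValueError("n_features must be at least 3")
    if not archetypes:
        raise ValueError("need at least one archetype")
    k = len(archetypes)
    ids = sorted(a.shape_id for a in archetypes)
    if ids != list(range(1, k + 1)):
        raise ValueError("archetype shape_ids must be contiguous 1..K")
    by_id = {a.shape_id: a for a in archetypes}
    for c in conditions:
        if len(c.shape_weights) != k:
            raise ValueError(
                f"condition {c.tc_id!r} has {len(c.shape_weights)} weights "
                f"for {k} archetypes"
            )
    load_rng = np.random.default_rng(loading_seed)
    A = load_rng.normal(0.0, 1.0 / np.sqrt(3.0), size=(n_features, 3))
    b = load_rng.normal(0.0, 0.5, size=n_features)
    rng = np.random.default_rng(cell_seed)
    cell_ids, tc_ids, labels, latents = [], [], [], []
    for c in conditions:
        drawn = rng.choice(np.arange(1, k + 1), size=c.n_cells, p=c.shape_weights)
        for j, s in enumerate(drawn):
            a = by_id[int(s)]
            z = rng.multivariate_normal(a.latent_mean, a.latent_cov)
            cell_ids.append(f"{c.tc_id}_c{j:05d}")
            tc_ids.append(c.tc_id)
            labels.append(int(s))
            latents.append(z)
    Z = np.vstack(latents)
    log_features = Z @ A.T + b
    if noise_sd > 0:
        log_features = log_features + rng.normal(0.0, noise_sd, size=log_features.shape)
    values = np.exp(log_features)
    table = FeatureTable(
        cell_ids=np.asarray(cell_ids, dtype=object),
        tc_ids=np.asarray(tc_ids, dtype=object),
        values=values,
        feature_names=[f"f{i + 1:03d}" for i in range(n_features)],
    )
    return table, np.asarray(labels, dtype=int)


def generate_condition_panel(
    n_tc: int,
    wildtype_weights: np.ndarray | None = None,
    dependency_graph: nx.DiGraph | None = None,
    effect_scale: float = 1.0,
    seed: int = 0,
    cells_per_tc: int = 47,
    perturbation_sd: float = 0.01,
    arc_weight: float = 0.8,
    rare_shape_prob: float = 0.08,
    rare_shape_max: float = 0.10,
    wildtype_id: str = "EGFP",
) -> list[ConditionSpec]:
    """One wild-type condition plus ``n_tc - 1`` perturbed conditions.

    Perturbations are generated ancestrally over the dependency graph: each
    shape in the wild-type support receives independent Gaussian noise (sd
    ``perturbation_sd``), to which each parent contributes
    ``sign * arc_weight`` times its own perturbation.  A shape absent from
    the wild type (shape 2 under the default weights) appears only in a
    small random subset of conditions (probability ``rare_shape_prob``), at
    a fraction below the enrichment threshold (at most ``rare_shape_max``)
    and independent of every other shape — so the panel spans all shape
    classes while that shape correlates with none.  The perturbation vector is centred to zero sum over the support
    (fraction vectors are compositional, and centring keeps the final
    renormalisation nearly inert), scaled by ``effect_scale``, added to the
    wild-type weights, clipped at 0 and renormalised.  The default
    ``perturbation_sd`` keeps perturbations within the linear range of the
    smallest wild-type fraction, so the planted correlations survive the
    clip.  With ``effect_scale=0`` every condition equals the wild type
    exactly.
    """
    if n_tc < 2:
        raise ValueError("n_tc must be at least 2")
    wt = (
        WILDTYPE_WEIGHTS.copy()
        if wildtype_weights is None
        else np.asarray(wildtype_weights, dtype=float)
    )
    if np.any(wt < 0) or abs(wt.sum() - 1.0) > 1e-9:
        raise ValueError("wildtype_weights must be a probability vector")
    k = len(wt)
    g = default_dependency_graph() if dependency_graph is None else dependency_graph
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("dependency graph must be acyclic (ancestral generator)")
    extra = [v for v in g.nodes if not 1 <= v <= k]
    if extra:
        raise ValueError(f"graph nodes {extra} outside shape range 1..{k}")
    order = list(nx.topological_sort(g))
    order += [s for s in range(1, k + 1) if s not in order]
    support = wt > 0
    rng = np.random.default_rng(seed)
    conditions = [
        ConditionSpec(
            tc_id=wildtype_id,
            n_cells=cells_per_tc,
            shape_weights=wt.copy(),
            is_wildtype=True,
        )
    ]
    for t in range(1, n_tc):
        delta = np.zeros(k)
        for s in order:
            if not support[s - 1]:
                continue
            delta[s - 1] = rng.normal(0.0, perturbation_sd)
            if s in g.nodes:
                for parent in g.predecessors(s):
                    sign = g.edges[parent, s].get("sign", 1)
                    delta[s - 1] += sign * arc_weight * delta[parent - 1]
        delta[support] -= delta[support].mean()  # stay compositional
        w = np.clip(wt + effect_scale * delta, 0.0, None)
        if w.sum() == 0:
            w = wt.copy()  # pathological draw; fall back to wild type
        w = w / w.sum()
        for s in range(1, k + 1):
            if not support[s - 1] and rng.random() < rare_shape_prob:
                f = min(1.0, effect_scale) * rng.uniform(
                    rare_shape_max / 3.0, rare_shape_max
                )
                w = w * (1.0 - f)
                w[s - 1] = f
        conditions.append(
            ConditionSpec(
                tc_id=f"TC{t:03d}", n_cells=cells_per_tc, shape_weights=w
            )
        )
    return conditions


def default_transition_matrix() -> np.ndarray:
    """Diagonal-dominant 7-shape transition matrix for trajectory emulation.

    Encodes the reported dynamics: shape 1 near-absorbing (the most stable
    shape), a 25% shape-5-to-6 and 15% shape-6-to-7 transition probability,
    relatively frequent 6/7-to-5 back-transitions, and rare crossings
    between the rounded block {1,2,3} and the spread block {5,6,7}.
    """
    P = np.array(
        [
            [0.970, 0.010, 0.010, 0.010, 0.000, 0.000, 0.000],
            [0.050, 0.850, 0.050, 0.040, 0.010, 0.000, 0.000],
            [0.040, 0.030, 0.850, 0.050, 0.020, 0.005, 0.005],
            [0.020, 0.010, 0.040, 0.850, 0.050, 0.020, 0.010],
            [0.000, 0.000, 0.010, 0.030, 0.700, 0.250, 0.010],
            [0.000, 0.000, 0.005, 0.015, 0.100, 0.730, 0.150],
            [0.000, 0.000, 0.005, 0.005, 0.120, 0.070, 0.800],
        ]
    )
    assert np.allclose(P.sum(axis=1), 1.0)
    return P


def generate_trajectories(
    cfg: TrajectoryConfig,
    initial_distribution: np.ndarray | None = None,
    seed: int = 0,
) -> TrajectorySet:
    """Independent first-order Markov chains of shape labels.

    The initial shape of each cell is drawn from ``initial_distribution``
    (default: the wild-type mixture truncated/renormalised to the matrix
    size).
    """
    P = cfg.transition_matrix
    k = P.shape[0]
    if initial_distribution is None:
        init = WILDTYPE_WEIGHTS[:k].copy()
        init = init / init.sum()
    else:
        init = np.asarray(initial_distribution, dtype=float)
        if len(init) != k:
            raise ValueError("initial_distribution length must match the matrix")
        if np.any(init < 0) or abs(init.sum() - 1.0) > 1e-9:
            raise ValueError("initial_distribution must be a probability vector")
    rng = np.random.default_rng(seed)
    rows = []
    shapes = np.arange(1, k + 1)
    for c in range(cfg.n_cells):
        state = int(rng.choice(shapes, p=init))
        for f in range(cfg.n_frames):
            rows.append((f"cell{c:04d}", f, state))
            if f < cfg.n_frames - 1:
                state = int(rng.choice(shapes, p=P[state - 1]))
    frames = pd.DataFrame(rows, columns=["cell_id", "frame_index", "shape_id"])
    return TrajectorySet(frames=frames, frame_interval_min=cfg.frame_interval_min)


def write_condition_panel_yaml(conditions: list[ConditionSpec], path: str | Path) -> None:
    doc = [
        {
            "tc_id": c.tc_id,
            "n_cells": c.n_cells,
            "shape_weights": [float(w) for w in c.shape_weights],
            "is_wildtype": c.is_wildtype,
        }
        for c in conditions
    ]
    Path(path).write_text(yaml.safe_dump(doc))


def read_condition_panel_yaml(path: str | Path) -> list[ConditionSpec]:
    doc = yaml.safe_load(Path(path).read_text())
    return [
        ConditionSpec(
            tc_id=d["tc_id"],
            n_cells=int(d["n_cells"]),
            shape_weights=np.asarray(d["shape_weights"], dtype=float),
            is_wildtype=bool(d.get("is_wildtype", False)),
        )
        for d in doc
    ]


def write_hidden_labels(
    table: FeatureTable, labels: np.ndarray, path: str | Path
) -> None:
    pd.DataFrame(
        {"cell_id": table.cell_ids, "true_shape": labels}
    ).to_csv(path, sep="\t", index=False)
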