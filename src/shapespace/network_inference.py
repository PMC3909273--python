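"""Consensus Bayesian dependency network between shapes across conditions.

Each shape's fraction across treatment conditions is one continuous variable;
a Bayesian network over these variables captures which shapes' abundances
depend on which.  Structures are scored with the BGe marginal likelihood (a
Gaussian model with a conjugate normal-Wishart prior), which is
score-equivalent: Markov-equivalent DAGs receive identical scores.  A single
run searches for a local score optimum by greedy hill climbing (add/delete/
reverse moves in randomised order).  The consensus procedure repeats the run
on bootstrap resamples of the conditions, keeps undirected edges that appear
in at least a retention fraction of runs, orients each kept edge by the
majority of its directed occurrences, and signs it by the Pearson correlation
of the two shapes over the full panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import multigammaln

from .heterogeneity import TCHP

__all__ = [
    "ProfilePanel",
    "ConsensusEdge",
    "ConsensusNetwork",
    "BGeScore",
    "rescale_panel",
    "score_network",
    "learn_structure",
    "consensus",
    "edge_signs",
]


@dataclass
class ProfilePanel:
    """Conditions x shapes matrix of column-rescaled shape fractions.

    Every non-constant column spans exactly [0, 1] after min-max rescaling.
    Constant columns (a shape absent or fixed everywhere) carry no signal and
    break a Gaussian score; they are zeroed and listed in
    ``excluded_shapes`` so learning can skip them.
    """

    tc_ids: list[str]
    shape_ids: list[int]
    values: np.ndarray
    excluded_shapes: list[int] = field(default_factory=list)

    @property
    def active_shapes(self) -> list[int]:
        return [s for s in self.shape_ids if s not in self.excluded_shapes]

    def active_values(self) -> np.ndarray:
        cols = [i for i, s in enumerate(self.shape_ids) if s not in self.excluded_shapes]
        return self.values[:, cols]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"shape_{s}" for s in self.shape_ids])
        df.insert(0, "tc_id", self.tc_ids)
        return df


def rescale_panel(profiles: list[TCHP]) -> ProfilePanel:
    """Column-wise min-max rescaling of raw shape fractions onto [0, 1]."""
    if len(profiles) < 3:
        raise ValueError("need at least 3 conditions to build a panel")
    k = profiles[0].n_shapes
    X = np.vstack([p.fractions for p in profiles]).astype(float)
    mins = X.min(axis=0)
    ranges = X.max(axis=0) - mins
    excluded = [i + 1 for i in range(k) if ranges[i] == 0]
    out = np.zeros_like(X)
    nz = ranges > 0
    out[:, nz] = (X[:, nz] - mins[nz]) / ranges[nz]
    return ProfilePanel(
        tc_ids=[p.tc_id for p in profiles],
        shape_ids=list(range(1, k + 1)),
        values=out,
        excluded_shapes=excluded,
    )


class BGeScore:
    """BGe marginal-likelihood score for Gaussian Bayesian networks.

    The joint prior is normal-Wishart with prior sample size ``alpha_mu``
    (default 1), degrees of freedom ``alpha_w`` (default d + 2) and prior
    mean equal to the column means (so the mean-correction term vanishes).
    The prior scale matrix defaults to the diagonal of empirical column
    variances: a fixed scale (e.g. the identity) that is large relative to
    the data scatter inverts the Occam penalty and lets independent columns
    acquire edges, so the prior is kept on the scale of the data it judges.
    The score decomposes per node; the local score of a node given its
    parents is the difference of two subset log-marginal-likelihoods, each a
    ratio of determinants and multivariate gamma functions.  Scores of
    Markov-equivalent DAGs coincide for any fixed scale matrix.
    """

    def __init__(
        self,
        data: np.ndarray,
        alpha_mu: float = 1.0,
        alpha_w: float | None = None,
        prior_mean: np.ndarray | None = None,
        prior_scale: np.ndarray | None = None,
    ):
        X = np.asarray(data, dtype=float)
        self.n, self.d = X.shape
        self.alpha_mu = float(alpha_mu)
        self.alpha_w = float(alpha_w) if alpha_w is not None else self.d + 2.0
        if self.alpha_w <= self.d - 1:
            raise ValueError("alpha_w must exceed d - 1")
        mean = X.mean(axis=0)
        mu0 = mean if prior_mean is None else np.asarray(prior_mean, dtype=float)
        if prior_scale is None:
            col_var = X.var(axis=0, ddof=1)
            floor = max(col_var.max(), 1.0) * 1e-12
            T = np.diag(np.maximum(col_var, floor))
        else:
            T = np.asarray(prior_scale, dtype=float)
        Xc = X - mean
        S = Xc.T @ Xc
        dm = (mean - mu0).reshape(-1, 1)
        self.R = T + S + (self.alpha_mu * self.n / (self.alpha_mu + self.n)) * (dm @ dm.T)
        self.T = T
        self._cache: dict[tuple[int, frozenset[int]], float] = {}
        self._subset_cache: dict[frozenset[int], float] = {}

    def _subset_logml(self, idx: frozenset[int]) -> float:
        """Log marginal likelihood of the data restricted to columns idx."""
        if not idx:
            return 0.0
        if idx in self._subset_cache:
            return self._subset_cache[idx]
        cols = sorted(idx)
        l = len(cols)
        n, d = self.n, self.d
        a = self.alpha_w - d + l
        T_sub = self.T[np.ix_(cols, cols)]
        R_sub = self.R[np.ix_(cols, cols)]
        val = (
            -0.5 * l * n * np.log(np.pi)
            + 0.5 * l * np.log(self.alpha_mu / (self.alpha_mu + n))
            + multigammaln((a + n) / 2.0, l)
            - multigammaln(a / 2.0, l)
            + 0.5 * a * np.linalg.slogdet(T_sub)[1]
            - 0.5 * (a + n) * np.linalg.slogdet(R_sub)[1]
        )
        self._subset_cache[idx] = val
        return val

    def local_score(self, node: int, parents: frozenset[int]) -> float:
        """log p(node | parents) as a difference of subset marginals."""
        key = (node, parents)
        if key not in self._cache:
            self._cache[key] = self._subset_logml(
                parents | {node}
            ) - self._subset_logml(parents)
        return self._cache[key]

    def network_score(self, dag: nx.DiGraph) -> float:
        if not nx.is_directed_acyclic_graph(dag):
            raise ValueError("graph must be acyclic")
        return sum(
            self.local_score(v, frozenset(dag.predecessors(v))) for v in dag.nodes
        )


def score_network(
    dag: nx.DiGraph, panel: ProfilePanel, hyperparams: dict | None = None
) -> float:
    """Score a DAG over shape nodes against a profile panel.

    Node names in the DAG must be shape ids present (and not excluded) in
    the panel.
    """
    active = panel.active_shapes
    col = {s: i for i, s in enumerate(active)}
    missing = [v for v in dag.nodes if v not in col]
    if missing:
        raise ValueError(f"DAG nodes {missing} not in the panel's active shapes")
    scorer = BGeScore(panel.active_values(), **(hyperparams or {}))
    relabeled = nx.relabel_nodes(dag, col, copy=True)
    for i in range(len(active)):  # isolated shapes still contribute
        if i not in relabeled:
            relabeled.add_node(i)
    return scorer.network_score(relabeled)


def _hill_climb(
    scorer: BGeScore, n_nodes: int, rng: np.random.Generator, eps: float = 1e-9
) -> nx.DiGraph:
    """Greedy search from the empty graph; first strictly improving move in
    a freshly shuffled move order, until a local optimum."""
    dag = nx.DiGraph()
    dag.add_nodes_from(range(n_nodes))
    local = {v: scorer.local_score(v, frozenset()) for v in range(n_nodes)}
    while True:
        moves = []
        edges = set(dag.edges)
        for u in range(n_nodes):
            for v in range(n_nodes):
                if u == v:
                    continue
                if (u, v) in edges:
                    moves.append(("del", u, v))
                    moves.append(("rev", u, v))
                elif (v, u) not in edges:
                    moves.append(("add", u, v))
        rng.shuffle(moves)
        applied = False
        for kind, u, v in moves:
            if kind == "add":
                if nx.has_path(dag, v, u):
                    continue
                pa = frozenset(dag.predecessors(v)) | {u}
                delta = scorer.local_score(v, pa) - local[v]
                if delta > eps:
                    dag.add_edge(u, v)
                    local[v] = scorer.local_score(v, pa)
                    applied = True
                    break
            elif kind == "del":
                pa = frozenset(dag.predecessors(v)) - {u}
                delta = scorer.local_score(v, pa) - local[v]
                if delta > eps:
                    dag.remove_edge(u, v)
                    local[v] = scorer.local_score(v, pa)
                    applied = True
                    break
            else:  # reverse u->v to v->u
                dag.remove_edge(u, v)
                if nx.has_path(dag, u, v):
                    dag.add_edge(u, v)
                    continue
                pa_v = frozenset(dag.predecessors(v))
                pa_u = frozenset(dag.predecessors(u)) | {v}
                delta = (
                    scorer.local_score(v, pa_v)
                    + scorer.local_score(u, pa_u)
                    - local[v]
                    - local[u]
                )
                if delta > eps:
                    dag.add_edge(v, u)
                    local[v] = scorer.local_score(v, pa_v)
                    local[u] = scorer.local_score(u, pa_u)
                    applied = True
                    break
                dag.add_edge(u, v)
        if not applied:
            return dag


def learn_structure(
    panel: ProfilePanel, seed: int = 0, hyperparams: dict | None = None
) -> nx.DiGraph:
    """One greedy structure-learning run; nodes are shape ids.

    Deterministic given the seed (the seed fixes the randomised move order).
    """
    active = panel.active_shapes
    scorer = BGeScore(panel.active_values(), **(hyperparams or {}))
    rng = np.random.default_rng(seed)
    dag = _hill_climb(scorer, len(active), rng)
    return nx.relabel_nodes(dag, dict(enumerate(active)), copy=True)


@dataclass
class ConsensusEdge:
    parent: int
    child: int
    frequency: float  # skeleton frequency across runs
    direction_frequency: float  # share of directed occurrences as parent->child
    sign: str  # "+", "-" or "0"


@dataclass
class ConsensusNetwork:
    """Signed directed shape-dependency graph aggregated over many runs.

    A consensus of DAGs need not itself be acyclic; ``is_acyclic`` reports
    (but never enforces) whether it is.
    """

    nodes: list[int]
    edges: list[ConsensusEdge]
    n_runs: int
    retention: float

    @property
    def is_acyclic(self) -> bool:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e.parent, e.child) for e in self.edges)
        return nx.is_directed_acyclic_graph(g)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(
                e.parent,
                e.child,
                frequency=e.frequency,
                direction_frequency=e.direction_frequency,
                sign=e.sign,
            )
        return g

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parent": e.parent,
                    "child": e.child,
                    "frequency": e.frequency,
                    "direction_frequency": e.direction_frequency,
                    "sign": e.sign,
                }
                for e in self.edges
            ]
        )


def _aggregate_runs(
    dags: list[nx.DiGraph], nodes: list[int], retention: float
) -> list[tuple[int, int, float, float]]:
    """Tally edge skeletons over runs; keep those at or above retention and
    orient each by the majority of its directed occurrences.

    Returns (parent, child, skeleton_frequency, direction_frequency) tuples.
    A skeleton occurrence is a run whose DAG contains the pair in either
    direction; ties in direction go to the lower-(u, v) ordering.
    """
    if not 0 < retention <= 1:
        raise ValueError("retention must be in (0, 1]")
    n_runs = len(dags)
    directed: dict[tuple[int, int], int] = {}
    for dag in dags:
        for u, v in dag.edges:
            directed[(u, v)] = directed.get((u, v), 0) + 1
    kept = []
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            f_uv = directed.get((u, v), 0)
            f_vu = directed.get((v, u), 0)
            skel = (f_uv + f_vu) / n_runs
            if skel >= retention:
                if f_uv >= f_vu:
                    kept.append((u, v, skel, f_uv / (f_uv + f_vu)))
                else:
                    kept.append((v, u, skel, f_vu / (f_uv + f_vu)))
    return kept


def _pearson_sign(x: np.ndarray, y: np.ndarray) -> str:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return "0"
    r = float(np.corrcoef(x, y)[0, 1])
    if r > 0:
        return "+"
    if r < 0:
        return "-"
    return "0"


def consensus(
    panel: ProfilePanel,
    n_runs: int = 500,
    retention: float = 0.60,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> ConsensusNetwork:
    """Bootstrap-consensus structure learning.

    Each run resamples conditions with replacement and learns a DAG with a
    fresh search seed.  Undirected edges present in at least ``retention`` of
    the runs are kept; a kept edge's direction is the more frequent of its
    two directed occurrences (even when neither direction alone reaches the
    retention threshold) and its sign is the Pearson correlation sign of the
    two shapes' columns on the full, unresampled panel.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not 0 < retention <= 1:
        raise ValueError("retention must be in (0, 1]")
    active = panel.active_shapes
    X = panel.active_values()
    rng = np.random.default_rng(seed)
    dags = []
    for _ in range(n_runs):
        rows = rng.integers(0, X.shape[0], size=X.shape[0])
        Xb = X[rows]
        if np.any(Xb.std(axis=0) == 0):  # degenerate resample; redraw
            rows = rng.integers(0, X.shape[0], size=X.shape[0])
            Xb = X[rows]
        scorer = BGeScore(Xb, **(hyperparams or {}))
        run_seed = int(rng.integers(0, 2**31 - 1))
        dag = _hill_climb(scorer, len(active), np.random.default_rng(run_seed))
        dags.append(nx.relabel_nodes(dag, dict(enumerate(active)), copy=True))
    kept = _aggregate_runs(dags, active, retention)
    col = {s: i for i, s in enumerate(active)}
    edges = [
        ConsensusEdge(
            parent=u,
            child=v,
            frequency=skel,
            direction_frequency=direction,
            sign=_pearson_sign(X[:, col[u]], X[:, col[v]]),
        )
        for u, v, skel, direction in kept
    ]
    return ConsensusNetwork(
        nodes=active, edges=edges, n_runs=n_runs, retention=retention
    )


def edge_signs(panel: ProfilePanel, network: ConsensusNetwork) -> ConsensusNetwork:
    """Re-derive every edge sign from Pearson correlations on the panel."""
    col = {s: i for i, s in enumerate(panel.active_shapes)}
    missing = [
        e for e in network.edges if e.parent not in col or e.child not in col
    ]
    if missing:
        raise ValueError("network nodes missing from the panel")
    X = panel.active_values()
    edges = [
        ConsensusEdge(
            parent=e.parent,
            child=e.child,
            frequency=e.frequency,
            direction_frequency=e.direction_frequency,
            sign=_pearson_sign(X[:, col[e.parent]], X[:, col[e.child]]),
        )
        for e in network.edges
    ]
    return ConsensusNetwork(
        nodes=network.nodes,
        edges=edges,
        n_runs=network.n_runs,
        retention=network.retention,
    )
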