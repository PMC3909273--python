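import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.special import gammaln

from shapespace.heterogeneity import TCHP
from shapespace.network_inference import (
    BGeScore,
    ConsensusEdge,
    ConsensusNetwork,
    ProfilePanel,
    _aggregate_runs,
    consensus,
    edge_signs,
    learn_structure,
    rescale_panel,
    score_network,
)


def panel_from_matrix(X):
    X = np.asarray(X, dtype=float)
    return ProfilePanel(
        tc_ids=[f"t{i}" for i in range(X.shape[0])],
        shape_ids=list(range(1, X.shape[1] + 1)),
        values=X,
    )


def all_dags(nodes):
    """Every labelled DAG over the nodes, by orienting each pair 3 ways."""
    pairs = list(itertools.combinations(nodes, 2))
    for choice in itertools.product((0, 1, 2), repeat=len(pairs)):
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for (u, v), c in zip(pairs, choice):
            if c == 1:
                g.add_edge(u, v)
            elif c == 2:
                g.add_edge(v, u)
        if nx.is_directed_acyclic_graph(g):
            yield g


def equivalence_key(g):
    """Markov-equivalence class key: skeleton plus v-structures."""
    skel = frozenset(frozenset(e) for e in g.edges)
    vstruct = set()
    for b in g.nodes:
        for a, c in itertools.combinations(sorted(g.predecessors(b)), 2):
            if not (g.has_edge(a, c) or g.has_edge(c, a)):
                vstruct.add((a, b, c))
    return skel, frozenset(vstruct)


class TestRescale:
    def test_column_rescaled(self):
        profiles = [
            TCHP(f"t{i}", np.array([f, 1 - f]), False, 10)
            for i, f in enumerate([0.0, 0.1, 0.2])
        ]
        panel = rescale_panel(profiles)
        np.testing.assert_allclose(panel.values[:, 0], [0, 0.5, 1])

    def test_idempotent(self, rng):
        X = rng.uniform(size=(10, 4))
        X[:, 0] = (X[:, 0] - X[:, 0].min()) / np.ptp(X[:, 0])
        p1 = panel_from_matrix(X)
        profiles = [
            TCHP(f"t{i}", row / row.sum(), False, 10) for i, row in enumerate(X + 0.1)
        ]
        panel = rescale_panel(profiles)
        again_vals = panel.values.copy()
        mins = again_vals.min(axis=0)
        rng_ = again_vals.max(axis=0) - mins
        np.testing.assert_allclose((again_vals - mins) / rng_, panel.values, atol=1e-12)
        assert p1.values.shape == X.shape

    def test_constant_column_excluded(self):
        profiles = [
            TCHP(f"t{i}", np.array([0.0, f, 1 - f]), False, 10)
            for i, f in enumerate([0.2, 0.5, 0.8])
        ]
        panel = rescale_panel(profiles)
        assert panel.excluded_shapes == [1]
        assert panel.active_shapes == [2, 3]
        np.testing.assert_array_equal(panel.values[:, 0], 0.0)

    def test_too_few_conditions(self):
        profiles = [TCHP("a", np.array([0.5, 0.5]), False, 5)] * 2
        with pytest.raises(ValueError):
            rescale_panel(profiles)


class TestBGeScore:
    def test_empty_graph_equals_univariate_closed_form(self, rng):
        """The empty-graph score is the sum over columns of the closed-form
        univariate normal-gamma marginal likelihood."""
        X = rng.normal(size=(40, 3))
        scorer = BGeScore(X)
        n, d = X.shape
        total = 0.0
        for j in range(d):
            x = X[:, j]
            t = np.var(x, ddof=1)  # default prior scale
            a = scorer.alpha_w - d + 1
            r = t + ((x - x.mean()) ** 2).sum()  # prior mean = sample mean
            total += (
                -0.5 * n * np.log(np.pi)
                + 0.5 * np.log(1.0 / (1.0 + n))
                + gammaln((a + n) / 2.0)
                - gammaln(a / 2.0)
                + 0.5 * a * np.log(t)
                - 0.5 * (a + n) * np.log(r)
            )
        empty = nx.DiGraph()
        empty.add_nodes_from(range(d))
        assert scorer.network_score(empty) == pytest.approx(total, rel=1e-10)

    def test_direction_reversal_scores_equal(self, rng):
        X = rng.normal(size=(30, 2))
        X[:, 1] += 0.7 * X[:, 0]
        scorer = BGeScore(X)
        ab = nx.DiGraph([(0, 1)])
        ba = nx.DiGraph([(1, 0)])
        assert scorer.network_score(ab) == pytest.approx(
            scorer.network_score(ba), rel=1e-12
        )

    def test_score_equivalence_over_enumerated_classes(self, rng):
        """All DAGs in each Markov-equivalence class (enumerated exhaustively
        on 4 nodes) receive the same BGe score."""
        X = rng.normal(size=(25, 4))
        X[:, 2] += 0.5 * X[:, 0]
        scorer = BGeScore(X)
        classes = {}
        for g in all_dags(range(4)):
            classes.setdefault(equivalence_key(g), []).append(
                scorer.network_score(g)
            )
        assert len(classes) > 50
        for scores in classes.values():
            assert max(scores) - min(scores) < 1e-8

    def test_copy_parent_raises_local_score(self, rng):
        X = rng.normal(size=(50, 2))
        X[:, 1] = X[:, 0] + 1e-6 * rng.normal(size=50)
        scorer = BGeScore(X)
        assert scorer.local_score(1, frozenset({0})) > scorer.local_score(
            1, frozenset()
        )

    def test_cyclic_graph_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        g = nx.DiGraph([(0, 1), (1, 0)])
        with pytest.raises(ValueError, match="acyclic"):
            BGeScore(X).network_score(g)

    def test_score_network_on_panel(self, rng):
        X = rng.uniform(size=(30, 3))
        panel = panel_from_matrix(X)
        g = nx.DiGraph()
        g.add_nodes_from([1, 2, 3])
        g.add_edge(1, 2)
        s = score_network(g, panel)
        assert np.isfinite(s)
        with pytest.raises(ValueError, match="acyclic"):
            score_network(nx.DiGraph([(1, 2), (2, 1)]), panel)


class TestStructureLearning:
    def test_independent_columns_give_empty_graph(self, rng):
        X = rng.uniform(size=(300, 3))
        dag = learn_structure(panel_from_matrix(X), seed=0)
        assert dag.number_of_edges() == 0

    def test_strong_dependency_gives_single_edge(self, rng):
        x = rng.uniform(size=(200,))
        y = x + 0.02 * rng.normal(size=200)
        dag = learn_structure(panel_from_matrix(np.column_stack([x, y])), seed=1)
        assert dag.number_of_edges() == 1
        assert set(map(frozenset, dag.edges)) == {frozenset({1, 2})}

    def test_seed_determinism(self, rng):
        X = rng.uniform(size=(100, 4))
        X[:, 3] += X[:, 0]
        panel = panel_from_matrix(X)
        d1 = learn_structure(panel, seed=42)
        d2 = learn_structure(panel, seed=42)
        assert set(d1.edges) == set(d2.edges)


class TestConsensusAggregation:
    def test_always_present_edge_retained_at_full_frequency(self):
        dags = [nx.DiGraph([(1, 2)]) for _ in range(10)]
        kept = _aggregate_runs(dags, [1, 2], retention=0.6)
        assert kept == [(1, 2, 1.0, 1.0)]

    def test_frequency_below_retention_dropped(self):
        dags = [nx.DiGraph([(1, 2)]) for _ in range(59)]
        empty = nx.DiGraph()
        empty.add_nodes_from([1, 2])
        dags += [empty] * 41
        assert _aggregate_runs(dags, [1, 2], retention=0.60) == []

    def test_direction_by_majority_of_directed_occurrences(self):
        """A 40% A->B / 30% B->A split keeps the edge (70% skeleton) and
        orients it A->B even though neither direction reaches retention."""
        dags = (
            [nx.DiGraph([(1, 2)]) for _ in range(40)]
            + [nx.DiGraph([(2, 1)]) for _ in range(30)]
        )
        empty = nx.DiGraph()
        empty.add_nodes_from([1, 2])
        dags += [empty] * 30
        kept = _aggregate_runs(dags, [1, 2], retention=0.6)
        assert kept == [(1, 2, 0.7, pytest.approx(4 / 7))]

    def test_invalid_retention(self):
        with pytest.raises(ValueError):
            _aggregate_runs([], [1], retention=0.0)


class TestSigns:
    def test_perfect_correlation_signs(self):
        x = np.linspace(0, 1, 20)
        panel = panel_from_matrix(np.column_stack([x, x, 1 - x]))
        net = ConsensusNetwork(
            nodes=[1, 2, 3],
            edges=[
                ConsensusEdge(1, 2, 1.0, 1.0, "?"),
                ConsensusEdge(1, 3, 1.0, 1.0, "?"),
            ],
            n_runs=1,
            retention=0.6,
        )
        out = edge_signs(panel, net)
        assert out.edges[0].sign == "+"
        assert out.edges[1].sign == "-"

    def test_sign_invariant_under_affine_column_rescale(self, rng):
        X = rng.uniform(size=(50, 2))
        X[:, 1] = -2 * X[:, 0] + rng.normal(scale=0.05, size=50)
        net = ConsensusNetwork(
            nodes=[1, 2],
            edges=[ConsensusEdge(1, 2, 1.0, 1.0, "?")],
            n_runs=1,
            retention=0.6,
        )
        s1 = edge_signs(panel_from_matrix(X), net).edges[0].sign
        s2 = edge_signs(panel_from_matrix(X * [3.0, 0.2] + [1, 5]), net).edges[0].sign
        assert s1 == s2 == "-"

    def test_consensus_on_strong_pair(self, rng):
        x = rng.uniform(size=(100,))
        y = 1 - x + 0.01 * rng.normal(size=100)
        panel = panel_from_matrix(np.column_stack([x, y]))
        net = consensus(panel, n_runs=25, retention=0.6, seed=0)
        assert len(net.edges) == 1
        assert net.edges[0].frequency == 1.0
        assert net.edges[0].sign == "-"
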