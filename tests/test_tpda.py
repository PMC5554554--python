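"""The three learning stages, cut-set machinery, orientation, and oracle checks."""

import itertools

import numpy as np
import pytest

from tpdanet.core_io import Network
from tpdanet.discretize import discretize_dataset
from tpdanet.errors import ParameterError, StructureError
from tpdanet.information import cmi_from_covariance
from tpdanet.synthetic import (
    analytic_covariance,
    dataset_from_covariance,
    make_spec,
    sample_linear_gaussian,
)
from tpdanet.tpda import (
    ThresholdTriple,
    draft,
    find_cut_set,
    learn,
    learn_stages,
    open_path_exists,
    orient,
    rank_pairs,
    thicken,
    thin,
)

EPS = ThresholdTriple(0.01, 0.01, 0.01)


def _discretized(ds, method="quantile", n=5):
    return discretize_dataset(ds, method=method, n=n)


@pytest.fixture(scope="module")
def chain_data():
    """Exact-covariance chain x -> z -> y, discretized wrapper kept with raw values."""
    names, cov = analytic_covariance(make_spec([("x", "z", 0.8), ("z", "y", 0.8)]))
    ds = dataset_from_covariance(names, cov, n_samples=400, seed=5)
    return _discretized(ds)


class TestRankPairs:
    def test_chain_ranking(self, chain_data):
        """Direct-edge MIs outrank the end-to-end pair (0.1114 nats).

        Closed form on the chain covariance: r(x,z) = 0.8/sqrt(1.64) gives
        0.24731 nats; r(z,y) = 0.8*sd(z)/sd(y) = 0.71554 gives 0.35885 nats;
        r(x,y) = 0.64/sqrt(2.0496) gives 0.11147 nats.
        """
        cands = rank_pairs(chain_data, eps=0.01, mi_on="raw")
        pairs = [(u, v) for u, v, _ in cands.pairs]
        assert set(pairs) == {("x", "z"), ("y", "z"), ("x", "y")}
        assert pairs[2] == ("x", "y")
        mi = {(u, v): m for u, v, m in cands.pairs}
        assert mi[("x", "z")] == pytest.approx(0.24731, abs=1e-4)
        assert mi[("y", "z")] == pytest.approx(0.35885, abs=1e-4)
        assert mi[("x", "y")] == pytest.approx(0.11147, abs=1e-4)

    def test_sorted_descending_with_lexicographic_ties(self, chain_data):
        cands = rank_pairs(chain_data, eps=0.01, mi_on="raw")
        keys = [(-m, u, v) for u, v, m in cands.pairs]
        assert keys == sorted(keys)

    def test_orthogonal_columns_empty(self):
        names, cov = ["a", "b", "c"], np.eye(3)
        ds = dataset_from_covariance(names, cov, 50, seed=1)
        assert rank_pairs(_discretized(ds), eps=0.01, mi_on="raw").pairs == []

    def test_threshold_dominates(self, chain_data):
        assert rank_pairs(chain_data, eps=10.0, mi_on="raw").pairs == []

    def test_threshold_monotonicity(self, chain_data):
        """Every pair ranked under a larger eps is ranked under a smaller one."""
        low = {(u, v) for u, v, _ in rank_pairs(chain_data, 0.01, mi_on="raw").pairs}
        high = {(u, v) for u, v, _ in rank_pairs(chain_data, 0.2, mi_on="raw").pairs}
        assert high <= low


class TestOpenPath:
    def test_edgeless(self):
        assert not open_path_exists(Network(["a", "b"]), "a", "b")

    def test_two_hop(self):
        net = Network(["a", "b", "c"])
        net.add_undirected("a", "c")
        net.add_undirected("c", "b")
        assert open_path_exists(net, "a", "b")

    def test_exclusion(self):
        net = Network(["a", "b"])
        net.add_undirected("a", "b")
        assert open_path_exists(net, "a", "b")
        assert not open_path_exists(net, "a", "b", exclude=("a", "b"))


class TestDraft:
    def test_chain_defers_endpoint_pair(self, chain_data):
        net, cands = draft(chain_data, eps=0.01, mi_on="raw")
        assert net.skeleton_edges() == {("x", "z"), ("y", "z")}
        assert [(u, v) for u, v, _ in cands.deferred] == [("x", "y")]

    def test_orthogonal_empty(self):
        ds = dataset_from_covariance(["a", "b"], np.eye(2), 40, seed=2)
        net, cands = draft(_discretized(ds), eps=0.01, mi_on="raw")
        assert net.skeleton_edges() == set()
        assert cands.deferred == []

    def test_star_hub_edges_first_leaves_deferred(self):
        """Hub-leaf correlations dominate, so leaf-leaf pairs are all deferred."""
        spec = make_spec([("h", "g1", 0.8), ("h", "g2", 0.8), ("h", "g3", 0.8)])
        names, cov = analytic_covariance(spec)
        ds = dataset_from_covariance(names, cov, 100, seed=3)
        net, cands = draft(_discretized(ds), eps=0.01, mi_on="raw")
        assert net.skeleton_edges() == {("g1", "h"), ("g2", "h"), ("g3", "h")}
        deferred_pairs = {(u, v) for u, v, _ in cands.deferred}
        assert deferred_pairs == {("g1", "g2"), ("g1", "g3"), ("g2", "g3")}


class TestFindCutSet:
    def test_chain_interior(self):
        net = Network(["a", "z", "b"])
        net.add_undirected("a", "z")
        net.add_undirected("z", "b")
        assert find_cut_set(net, "a", "b").nodes == {"z"}

    def test_parallel_paths(self):
        net = Network(["a", "u", "v", "b"])
        for mid in ("u", "v"):
            net.add_undirected("a", mid)
            net.add_undirected(mid, "b")
        cut = find_cut_set(net, "a", "b")
        assert cut.nodes == {"u", "v"}
        # removal disconnects (brute-force check)
        g = net.skeleton()
        g.remove_nodes_from(cut.nodes)
        import networkx as nx

        assert not nx.has_path(g, "a", "b")

    def test_direct_edge_must_be_removed_first(self):
        net = Network(["a", "b", "c"])
        net.add_undirected("a", "b")
        net.add_undirected("a", "c")
        net.add_undirected("c", "b")
        with pytest.raises(StructureError):
            find_cut_set(net, "a", "b")
        net.remove_undirected("a", "b")
        assert find_cut_set(net, "a", "b").nodes == {"c"}

    def test_no_open_path_is_error(self):
        with pytest.raises(StructureError):
            find_cut_set(Network(["a", "b"]), "a", "b")


class TestThicken:
    def test_chain_deferred_pair_stays_out(self, chain_data):
        net, cands = draft(chain_data, eps=0.01, mi_on="raw")
        out = thicken(net, cands, chain_data, eps=0.01, mi_on="raw")
        assert out.skeleton_edges() == net.skeleton_edges()

    def test_empty_deferred_is_noop(self, chain_data):
        net, _ = draft(chain_data, eps=0.01, mi_on="raw")
        out = thicken(net, [], chain_data, eps=0.01, mi_on="raw")
        assert out.skeleton_edges() == net.skeleton_edges()

    def test_collider_no_spurious_edge(self):
        """Marginally orthogonal collider parents never enter the deferred list."""
        spec = make_spec([("x", "w", 0.8), ("y", "w", 0.8)])
        names, cov = analytic_covariance(spec)
        ds = dataset_from_covariance(names, cov, 100, seed=4)
        data = _discretized(ds)
        net, cands = draft(data, eps=0.01, mi_on="raw")
        assert ("x", "y") not in {(u, v) for u, v, _ in cands.deferred}
        out = thicken(net, cands, data, eps=0.01, mi_on="raw")
        assert out.skeleton_edges() == {("w", "x"), ("w", "y")}

    def test_never_removes_edges(self, chain_data):
        net, cands = draft(chain_data, eps=0.01, mi_on="raw")
        out = thicken(net, cands, chain_data, eps=0.01, mi_on="raw")
        assert net.skeleton_edges() <= out.skeleton_edges()


class TestThin:
    def test_tree_unchanged(self, chain_data):
        net, cands = draft(chain_data, eps=0.01, mi_on="raw")
        out = thin(net, chain_data, eps=0.01, mi_on="raw")
        assert out.skeleton_edges() == net.skeleton_edges()

    def test_triangle_edge_deleted(self, chain_data):
        """A forced x-y edge on the chain triangle is cut by conditioning on z."""
        net = Network(["x", "y", "z"])
        net.add_undirected("x", "z", "draft", 0.25)
        net.add_undirected("y", "z", "draft", 0.25)
        net.add_undirected("x", "y", "draft", 0.11)
        out = thin(net, chain_data, eps=0.01, mi_on="raw")
        assert out.skeleton_edges() == {("x", "z"), ("y", "z")}

    def test_empty_network(self, chain_data):
        out = thin(Network(["x", "y", "z"]), chain_data, eps=0.01, mi_on="raw")
        assert out.skeleton_edges() == set()

    def test_subset_of_input(self, chain_data):
        net = Network(["x", "y", "z"])
        for u, v in (("x", "z"), ("y", "z"), ("x", "y")):
            net.add_undirected(u, v, "draft", 0.1)
        out = thin(net, chain_data, eps=0.01, mi_on="raw")
        assert out.skeleton_edges() <= net.skeleton_edges()


class TestOrient:
    def _roles(self):
        return {"AC": "trait", "BC": "trait", "g1": "gene", "g2": "gene"}

    def test_trait_gene_directed(self):
        net = Network(["AC", "g1"])
        net.add_undirected("AC", "g1", "draft", 0.2)
        out = orient(net, {"AC": "trait", "g1": "gene"})
        assert out.directed_edges == [("AC", "g1")]
        assert out.undirected_edges == []

    def test_gene_gene_stays_undirected(self):
        net = Network(["g1", "g2"])
        net.add_undirected("g1", "g2", "draft", 0.2)
        out = orient(net, self._roles())
        assert out.undirected_edges == [("g1", "g2")]

    def test_trait_trait_dropped_with_warning(self, caplog):
        net = Network(["AC", "BC"])
        net.add_undirected("AC", "BC", "draft", 0.2)
        with caplog.at_level("WARNING", logger="tpdanet.tpda"):
            out = orient(net, self._roles())
        assert out.skeleton_edges() == set()
        assert any("trait-trait" in rec.message for rec in caplog.records)


class TestLearn:
    def test_chain_recovery_quantile_codes(self):
        """A sampled 10-node chain is recovered exactly from discretized codes."""
        edges = [(f"n{i:02d}", f"n{i + 1:02d}", 0.8) for i in range(9)]
        spec = make_spec(edges, noise_sd=1.0, n_samples=2000, seed=21)
        ds = sample_linear_gaussian(spec)
        net = learn(ds, method="quantile", n=8, thresholds=EPS)
        truth = {tuple(sorted((u, v))) for u, v, _ in edges}
        assert net.skeleton_edges() == truth

    def test_determinism(self):
        spec = make_spec(
            [("a", "b", 0.7), ("b", "c", 0.7), ("a", "d", 0.7)],
            n_samples=300, seed=8,
        )
        ds = sample_linear_gaussian(spec)
        n1 = learn(ds, method="interval", n=4, thresholds=EPS)
        n2 = learn(ds, method="interval", n=4, thresholds=EPS)
        assert n1 == n2
        assert n1.undirected_edges == n2.undirected_edges

    def test_stage_monotonicity(self):
        spec = make_spec(
            [("a", "b", 0.8), ("a", "c", 0.8), ("b", "d", 0.8), ("c", "d", 0.8)],
            n_samples=500, seed=13,
        )
        ds = sample_linear_gaussian(spec)
        rec = learn_stages(ds, method="quantile", n=5, thresholds=EPS)
        assert rec.draft_network.skeleton_edges() <= rec.thicken_network.skeleton_edges()
        assert rec.thin_network.skeleton_edges() <= rec.thicken_network.skeleton_edges()

    def test_trait_in_degree_zero(self):
        from tpdanet.synthetic import generate_maize_like

        ds, _ = generate_maize_like(n_lines=200, n_background=20, seed=1)
        net = learn(ds, method="quantile", n=5, thresholds=EPS)
        for _, v in net.directed_edges:
            assert ds.roles[v] != "trait"
        for u, v in net.undirected_edges:
            assert ds.roles[u] != "trait" and ds.roles[v] != "trait"

    def test_invalid_thresholds(self):
        with pytest.raises(ParameterError):
            ThresholdTriple(0.0, 0.01, 0.01)


def exhaustive_ci_skeleton(names, cov, eps=0.01):
    """Brute-force constraint oracle: drop an edge iff ANY subset separates the pair."""
    idx = {n: i for i, n in enumerate(names)}
    edges = set()
    for u, v in itertools.combinations(sorted(names), 2):
        others = [n for n in names if n not in (u, v)]
        separated = False
        for r in range(len(others) + 1):
            for z in itertools.combinations(others, r):
                cmi = cmi_from_covariance(cov, idx[u], idx[v], [idx[w] for w in z])
                if cmi <= eps:
                    separated = True
                    break
            if separated:
                break
        if not separated:
            edges.add((u, v))
    return edges


def test_learn_matches_exhaustive_ci_oracle_on_chain():
    """On exact covariances the learner agrees with full CI enumeration."""
    spec = make_spec([("a", "b", 0.8), ("b", "c", 0.8), ("c", "d", 0.8)])
    names, cov = analytic_covariance(spec)
    ds = dataset_from_covariance(names, cov, 200, seed=17)
    net = learn(ds, thresholds=EPS, mi_on="raw")
    assert net.skeleton_edges() == exhaustive_ci_skeleton(names, cov)
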