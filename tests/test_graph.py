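import networkx as nx
import numpy as np
import pandas as pd
import pytest

import coexsig as cx
from coexsig.graph import louvain_communities


def power_iteration_centrality(g, tol=1e-13, max_iter=200_000):
    """Independent eigencentrality oracle: plain power iteration from the
    all-ones vector, rescaled to max 1. Iterates on A + I so the dominant
    eigenvalue is strictly dominant even on bipartite graphs (the shift
    leaves the eigenvector unchanged)."""
    nodes = list(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    if a.sum() == 0:
        return {n: 0.0 for n in nodes}
    a = a + np.eye(len(nodes))
    v = np.ones(len(nodes))
    for _ in range(max_iter):
        nv = a @ v
        nv = nv / np.linalg.norm(nv)
        if np.max(np.abs(nv - v)) < tol:
            v = nv
            break
        v = nv
    v = v / v.max()
    return {n: float(x) for n, x in zip(nodes, v)}


def exhaustive_best_modularity(g):
    """Maximum modularity over every partition of the nodes (Bell-number
    enumeration); only usable for small graphs."""
    nodes = list(g.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        first, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1:]
            yield [[first]] + part

    best = -np.inf
    for part in partitions(nodes):
        q = nx.community.modularity(g, [set(c) for c in part], weight=None)
        best = max(best, q)
    return best


def _logcpm_from(values, genes, samples=None):
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(values, index=genes,
                      columns=samples or [f"S{j}" for j in range(values.shape[1])])
    return cx.ExpressionMatrix(values=df, stage=cx.LOG_CPM)


class TestSpearmanMatrix:
    def test_identical_vectors_rho_one(self):
        m = _logcpm_from([[1, 2, 3, 4], [1, 2, 3, 4]], ["A", "B"])
        assert cx.spearman_matrix(m).loc["A", "B"] == pytest.approx(1.0)

    def test_rank_difference_closed_form(self):
        # x=(1,2,3,4), y=(1,3,2,4): rho = 1 - 6*2/(4*15) = 0.8
        m = _logcpm_from([[1, 2, 3, 4], [1, 3, 2, 4]], ["A", "B"])
        assert cx.spearman_matrix(m).loc["A", "B"] == pytest.approx(0.8)

    def test_reversed_vector_rho_minus_one(self):
        m = _logcpm_from([[1, 2, 3, 4], [4, 3, 2, 1]], ["A", "B"])
        assert cx.spearman_matrix(m).loc["A", "B"] == pytest.approx(-1.0)

    def test_absent_genes_dropped(self, toy_logcpm):
        corr = cx.spearman_matrix(toy_logcpm, ["G00", "G01", "NOT_THERE"])
        assert list(corr.index) == ["G00", "G01"]

    def test_symmetric_unit_diagonal(self, toy_logcpm):
        corr = cx.spearman_matrix(toy_logcpm).to_numpy()
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)


class TestThresholdGraph:
    def _corr(self, rho):
        return pd.DataFrame([[1.0, rho], [rho, 1.0]], index=["A", "B"], columns=["A", "B"])

    def test_below_cutoff_no_edge(self):
        g = cx.threshold_graph(self._corr(0.39), ccim=0.4)
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {"A", "B"}

    def test_at_cutoff_edge_kept(self):
        g = cx.threshold_graph(self._corr(0.40), ccim=0.4)
        assert g.has_edge("A", "B")

    def test_negative_correlation_never_an_edge(self):
        g = cx.threshold_graph(self._corr(-0.9), ccim=0.0)
        assert g.number_of_edges() == 0 or not g.has_edge("A", "B")

    def test_identity_matrix_all_isolated(self):
        corr = pd.DataFrame(np.eye(4), index=list("ABCD"), columns=list("ABCD"))
        g = cx.threshold_graph(corr, ccim=0.4)
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 4

    def test_invalid_ccim_rejected(self):
        with pytest.raises(ValueError):
            cx.threshold_graph(self._corr(0.5), ccim=1.5)


class TestEigenCentrality:
    def test_path_graph_closed_form(self):
        g = nx.path_graph(["A", "B", "C"])
        c = cx.eigen_centrality(g)
        assert c["B"] == pytest.approx(1.0)
        assert c["A"] == pytest.approx(1 / np.sqrt(2), abs=1e-10)
        assert c["C"] == pytest.approx(1 / np.sqrt(2), abs=1e-10)

    def test_complete_graph_all_one(self):
        c = cx.eigen_centrality(nx.complete_graph(4))
        assert all(v == pytest.approx(1.0) for v in c.values())

    def test_isolated_node_zero(self):
        g = nx.complete_graph(3)
        g.add_node("D")
        c = cx.eigen_centrality(g)
        assert c["D"] == 0.0
        assert max(c.values()) == pytest.approx(1.0)

    def test_edgeless_graph_all_zero(self):
        g = nx.empty_graph(5)
        assert set(cx.eigen_centrality(g).values()) == {0.0}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_power_iteration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            g = nx.gnp_random_graph(rng.integers(5, 30), rng.uniform(0.15, 0.5),
                                    seed=int(rng.integers(2**31)))
            a = nx.to_numpy_array(g)
            w = np.sort(np.linalg.eigvalsh(a))
            if g.number_of_edges() > 0 and w[-1] - w[-2] > 1e-2:
                break
        ours = cx.eigen_centrality(g)
        oracle = power_iteration_centrality(g)
        for n in g.nodes:
            assert ours[n] == pytest.approx(oracle[n], abs=1e-8)


class TestLouvain:
    def test_two_cliques_bridge_recovered(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_edge(0, 4)
        comm = louvain_communities(g, seed=17)
        assert {comm[i] for i in range(4)} != {comm[i] for i in range(4, 8)}
        assert len({comm[i] for i in range(4)}) == 1
        assert len({comm[i] for i in range(4, 8)}) == 1

    def test_two_cliques_match_exhaustive_optimum(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_edge(0, 4)
        comm = louvain_communities(g, seed=17)
        parts: dict[int, set] = {}
        for n, c in comm.items():
            parts.setdefault(c, set()).add(n)
        q = nx.community.modularity(g, list(parts.values()), weight=None)
        assert q >= exhaustive_best_modularity(g) - 1e-9

    def test_single_clique_one_community(self):
        comm = louvain_communities(nx.complete_graph(5), seed=17)
        assert len(set(comm.values())) == 1

    def test_edgeless_graph_singletons(self):
        comm = louvain_communities(nx.empty_graph(4), seed=17)
        assert len(set(comm.values())) == 4

    def test_deterministic_given_seed(self):
        g = nx.gnp_random_graph(25, 0.2, seed=3)
        assert louvain_communities(g, seed=17) == louvain_communities(g, seed=17)


class TestAdaptGeneSet:
    def test_small_community_not_retained(self, planted):
        # a pure-noise set has no community holding 20% of its genes at
        # the working correlation cutoff
        gs = planted["sets"]["SET_NOISE"]
        sigs = cx.adapt_gene_set(gs, planted["logcpm"], ccim=0.4, seed=17)
        assert sigs == []

    def test_planted_module_recovered(self, planted):
        gs = planted["sets"]["SET_M1"]
        sigs = cx.adapt_gene_set(gs, planted["logcpm"], ccim=0.4, seed=17)
        assert len(sigs) == 1
        sig = sigs[0]
        truth = planted["truth"]
        frac_true = np.mean([truth[g] == "module_1" for g in sig.genes])
        assert frac_true >= 0.9
        assert sig.community_fraction >= 0.20

    def test_core_rule_exact(self, planted):
        sig = cx.adapt_gene_set(planted["sets"]["SET_M1"], planted["logcpm"],
                                ccim=0.4, seed=17)[0]
        central = sig.central_eigenvalue
        for g, v in sig.members.items():
            assert (g in sig.core) == (v >= 0.9 * central - 1e-12)
        assert sig.name in sig.core

    def test_central_gene_has_max_centrality(self, planted):
        sig = cx.adapt_gene_set(planted["sets"]["SET_M1"], planted["logcpm"],
                                ccim=0.4, seed=17)[0]
        # centrality ties within 1e-12 count as equal-max (lexicographic pick)
        assert sig.members[sig.name] == pytest.approx(max(sig.members.values()), abs=1e-12)
        assert sig.members[sig.name] == pytest.approx(1.0)

    def test_twenty_percent_boundary(self):
        # 20 genes: a 10-gene clique (50%) passes, a 3-gene clique (15%)
        # does not
        rng = np.random.default_rng(0)
        n_samp = 60
        base1 = rng.normal(size=n_samp)
        base2 = rng.normal(size=n_samp)
        rows, genes = [], []
        for i in range(10):
            rows.append(base1 * 10 + rng.normal(scale=0.01, size=n_samp))
            genes.append(f"BIG{i}")
        for i in range(3):
            rows.append(base2 * 10 + rng.normal(scale=0.01, size=n_samp))
            genes.append(f"SMALL{i}")
        for i in range(7):
            rows.append(rng.normal(size=n_samp))
            genes.append(f"IND{i}")
        m = _logcpm_from(rows, genes)
        gs = cx.GeneSet(name="T", genes=tuple(genes))
        sigs = cx.adapt_gene_set(gs, m, ccim=0.9, min_fraction=0.20, seed=17)
        members = {g for s in sigs for g in s.genes}
        assert {f"BIG{i}" for i in range(10)} <= members
        assert not members & {f"SMALL{i}" for i in range(3)}

    def test_too_few_expressed_genes_raises(self, planted):
        gs = cx.GeneSet(name="ABSENT", genes=("NO_A", "NO_B", "NO_C"))
        with pytest.raises(ValueError, match="need >= 2"):
            cx.adapt_gene_set(gs, planted["logcpm"])

    def test_deterministic(self, planted):
        a = cx.adapt_gene_set(planted["sets"]["SET_M1"], planted["logcpm"], seed=17)
        b = cx.adapt_gene_set(planted["sets"]["SET_M1"], planted["logcpm"], seed=17)
        assert [(s.name, s.members) for s in a] == [(s.name, s.members) for s in b]


class TestMerge:
    def _sig(self, name, members, origins=("O1",)):
        return cx.AdaptedSignature(name=name, origins=origins, members=members,
                                   ccim=0.4, community_fraction=0.5)

    def test_union_arithmetic(self):
        a = self._sig("IDI1", {"IDI1": 1.0, "A": 0.5, "B": 0.6, "C": 0.7,
                               "D": 0.2, "E": 0.3}, origins=("O1",))
        # 6 and 8 members sharing 4 genes -> union of 10
        b = self._sig("IDI1", {"IDI1": 1.0, "A": 0.4, "B": 0.8, "C": 0.1, "F": 0.9,
                               "G": 0.2, "H": 0.3, "I": 0.25}, origins=("O2",))
        merged = cx.merge_by_central_gene([a, b])
        assert len(merged) == 1
        s = merged[0]
        assert len(s.members) == 10
        assert s.origins == ("O1", "O2")
        assert s.members["B"] == 0.8  # max per gene
        assert s.members["A"] == 0.5

    def test_disjoint_names_unchanged(self):
        a = self._sig("X", {"X": 1.0, "A": 0.5})
        b = self._sig("Y", {"Y": 1.0, "B": 0.5})
        assert cx.merge_by_central_gene([a, b]) == [a, b]

    def test_merged_core_obeys_rule(self):
        a = self._sig("X", {"X": 1.0, "A": 0.95, "B": 0.5})
        b = self._sig("X", {"X": 1.0, "B": 0.92, "C": 0.91}, origins=("O2",))
        s = cx.merge_by_central_gene([a, b])[0]
        assert set(s.core) == {"X", "A", "B", "C"}
        assert set(s.core) <= set(s.genes)


class TestDiagnostics:
    def test_median_of_pairwise(self):
        # three genes engineered to have pairwise spearman 1 and -1 mixes
        m = _logcpm_from([[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]], ["A", "B", "C"])
        d = cx.coexpression_diagnostics(cx.GeneSet(name="S", genes=("A", "B", "C")), m)
        assert d.mggc == pytest.approx(np.median([1.0, -1.0, -1.0]))

    def test_identical_genes(self):
        m = _logcpm_from([[1, 2, 3, 4]] * 3, ["A", "B", "C"])
        d = cx.coexpression_diagnostics(cx.GeneSet(name="S", genes=("A", "B", "C")), m)
        assert d.mggc == pytest.approx(1.0)
        assert d.mggv == pytest.approx(0.0)

    def test_adapted_beats_origin_on_planted_fixture(self, planted):
        gs = planted["sets"]["SET_M1"]
        sig = cx.adapt_gene_set(gs, planted["logcpm"], seed=17)[0]
        assert (cx.coexpression_diagnostics(sig, planted["logcpm"]).mggc
                > cx.coexpression_diagnostics(gs, planted["logcpm"]).mggc)


class TestCcimSweep:
    def test_sweep_shape_and_extremes(self, planted):
        coll = cx.GeneSetCollection(sets=[planted["sets"]["SET_M1"]])
        table = cx.ccim_sweep(coll, planted["logcpm"], grid=[0.0, 0.4, 0.99], seed=17)
        assert list(table.index) == [0.0, 0.4, 0.99]
        # no filtering: near-complete graph, one community holding all genes
        assert table.loc[0.0, "mean_size_retained_fraction"] >= 0.5
        # threshold above attainable correlations: nothing retained
        assert table.loc[0.99, "n_communities"] == 0
        assert table.loc[0.4, "n_communities"] >= 1

    def test_invalid_grid_rejected(self, planted):
        coll = cx.GeneSetCollection(sets=[planted["sets"]["SET_M1"]])
        with pytest.raises(ValueError):
            cx.ccim_sweep(coll, planted["logcpm"], grid=[0.2, 1.2])
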