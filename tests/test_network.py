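import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mobkit.io_core import OtuTable
from mobkit.network import (
    clr_transform,
    detect_modules,
    extract_subnetwork,
    filter_taxa,
    infer_network,
    module_abundance,
    module_function_regression,
    natural_connectivity,
    robustness,
    topology,
    zi_pi,
)
from mobkit.synthetic_data import NetworkSimConfig, simulate_network_counts

from conftest import random_table


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_betweenness(g):
    """Count shortest paths through each node by explicit enumeration."""
    out = {v: 0.0 for v in g}
    for s, t in itertools.combinations(sorted(g), 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in g:
            if v in (s, t):
                continue
            through = sum(v in p for p in paths)
            out[v] += through / len(paths)
    return out


def brute_clustering(g, v):
    nbrs = list(g.neighbors(v))
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(g.has_edge(a, b) for a, b in itertools.combinations(nbrs, 2))
    return 2 * links / (k * (k - 1))


def brute_modularity(g, partition):
    m = g.number_of_edges()
    q = 0.0
    deg = dict(g.degree())
    for u in g:
        for v in g:
            a = 1.0 if g.has_edge(u, v) else 0.0
            if partition[u] == partition[v]:
                q += a - deg[u] * deg[v] / (2 * m)
    return q / (2 * m)


# ---------------------------------------------------------------------------
# filtering and CLR
# ---------------------------------------------------------------------------

class TestFilterTaxa:
    def test_keep_everything_with_loosest_thresholds(self, toy_table):
        out = filter_taxa(toy_table, abundance_quantile=1.0,
                          occurrence_fraction=0.0)
        assert set(out.otu_ids) == set(toy_table.otu_ids)

    def test_hand_enumerated_survivors(self):
        # 10 OTUs over 4 samples; keep top 30% by total relative abundance
        # (3 OTUs) that occur in > 50% of samples (> 2 samples).
        counts = np.zeros((4, 10), dtype=int)
        counts[:, 0] = [50, 50, 50, 50]   # abundant, everywhere -> kept
        counts[:, 1] = [80, 80, 0, 0]     # abundant, half the samples -> cut
        counts[:, 2] = [30, 30, 30, 0]    # abundant, 3/4 samples -> kept
        counts[:, 3:] = 1                  # rare background
        table = OtuTable(counts, tuple(f"S{i}" for i in range(4)),
                         tuple(f"O{j}" for j in range(10)))
        out = filter_taxa(table, abundance_quantile=0.3,
                          occurrence_fraction=0.5)
        assert set(out.otu_ids) == {"O0", "O2"}

    def test_occurrence_threshold_is_strict(self):
        # an OTU present in exactly 25% of samples must be excluded
        counts = np.zeros((8, 2), dtype=int)
        counts[:, 0] = 10
        counts[:2, 1] = 10  # present in exactly 2/8 samples
        table = OtuTable(counts, tuple(f"S{i}" for i in range(8)), ("A", "B"))
        out = filter_taxa(table, abundance_quantile=1.0,
                          occurrence_fraction=0.25)
        assert out.otu_ids == ("A",)

    def test_no_survivor_rejected(self):
        counts = np.eye(4, dtype=int) * 5
        table = OtuTable(counts, tuple(f"S{i}" for i in range(4)),
                         tuple(f"O{j}" for j in range(4)))
        with pytest.raises(ValueError, match="no OTU"):
            filter_taxa(table, abundance_quantile=1.0, occurrence_fraction=0.9)


class TestClr:
    def test_uniform_sample_maps_to_zero(self):
        table = OtuTable(np.array([[7, 7, 7]]), ("S1",), ("A", "B", "C"))
        clr = clr_transform(table)
        assert np.allclose(clr.to_numpy(), 0.0)

    def test_rows_sum_to_zero(self, toy_table):
        clr = clr_transform(toy_table)
        assert np.allclose(clr.sum(axis=1), 0.0, atol=1e-12)

    def test_scale_invariance(self):
        a = OtuTable(np.array([[2, 4, 8]]), ("S1",), ("A", "B", "C"))
        b = OtuTable(np.array([[20, 40, 80]]), ("S1",), ("A", "B", "C"))
        # with a pseudocount scaled alongside the counts, CLR is identical
        ca = clr_transform(a, pseudocount=1.0)
        cb = clr_transform(b, pseudocount=10.0)
        assert np.allclose(ca.to_numpy(), cb.to_numpy(), atol=1e-12)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

class TestInferNetwork:
    def test_deterministic_given_seed(self):
        table, _ = simulate_network_counts(
            NetworkSimConfig(n_otus=20, n_samples=60, seed=4)
        )
        clr = clr_transform(table)
        g1 = infer_network(clr, seed=0)
        g2 = infer_network(clr, seed=0)
        assert set(g1.edges) == set(g2.edges)

    def test_planted_structure_recovered(self):
        cfg = NetworkSimConfig(seed=0)  # 40 OTUs x 200 samples
        table, adj = simulate_network_counts(cfg)
        g = infer_network(clr_transform(table), seed=0)
        idx = {o: i for i, o in enumerate(table.otu_ids)}
        pred = np.zeros_like(adj)
        for u, v in g.edges:
            pred[idx[u], idx[v]] = pred[idx[v], idx[u]] = True
        tp = (pred & adj).sum() / 2
        fp = (pred & ~adj).sum() / 2
        fn = (~pred & adj).sum() / 2
        f1 = 2 * tp / (2 * tp + fp + fn)
        assert f1 >= 0.6

    def test_independent_otus_stay_unconnected(self):
        cfg = NetworkSimConfig(n_otus=30, n_samples=150,
                               within_module_edge_prob=1e-12,
                               between_module_edge_prob=0.0, seed=1)
        table, adj = simulate_network_counts(cfg)
        assert adj.sum() == 0
        g = infer_network(clr_transform(table), seed=1)
        possible = 30 * 29 / 2
        assert g.number_of_edges() / possible <= 0.05

    def test_edge_signs_partition_edges(self):
        table, _ = simulate_network_counts(NetworkSimConfig(seed=2))
        g = infer_network(clr_transform(table), seed=2)
        signs = [d["sign"] for _, _, d in g.edges(data=True)]
        assert all(s in (-1, 1) for s in signs)
        pos = sum(s > 0 for s in signs)
        neg = sum(s < 0 for s in signs)
        assert pos + neg == g.number_of_edges()

    def test_increasing_lambda_path_rejected(self):
        table, _ = simulate_network_counts(
            NetworkSimConfig(n_otus=10, n_samples=30, seed=3)
        )
        with pytest.raises(ValueError, match="decreasing"):
            infer_network(clr_transform(table),
                          lambda_path=np.array([0.1, 0.2]))


class TestExtractSubnetwork:
    @pytest.fixture()
    def net_and_table(self):
        table, _ = simulate_network_counts(
            NetworkSimConfig(n_otus=25, n_samples=80, seed=6)
        )
        g = infer_network(clr_transform(table), seed=6)
        return g, table

    def test_full_subset_is_identity(self, net_and_table):
        g, table = net_and_table
        sub = extract_subnetwork(g, table, list(table.sample_ids))
        assert set(sub.edges) == set(g.edges)

    def test_absent_nodes_removed_and_edges_monotone(self, net_and_table):
        g, table = net_and_table
        sub = extract_subnetwork(g, table, list(table.sample_ids[:10]))
        present = table.select_samples(table.sample_ids[:10]).presence().any(0)
        absent = {o for o, p in zip(table.otu_ids, present) if not p}
        assert not (absent & set(sub.nodes))
        assert sub.number_of_edges() <= g.number_of_edges()


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

class TestTopology:
    def test_path_graph_by_enumeration(self):
        g = nx.path_graph(["A", "B", "C"])
        nodes, stats = topology(g)
        assert list(nodes["degree"]) == [1, 2, 1]
        assert list(nodes["betweenness"]) == [0.0, 1.0, 0.0]

    def test_complete_graph_symmetry(self):
        g = nx.complete_graph(4)
        nodes, stats = topology(g)
        assert stats["clustering_coefficient"] == pytest.approx(1.0)
        assert stats["degree_centralization"] == pytest.approx(0.0)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(1e6)))
            nodes, stats = topology(g)
            bb = brute_betweenness(g)
            for v in g:
                assert nodes.loc[v, "betweenness"] == pytest.approx(
                    bb[v], abs=1e-10
                )
                assert nodes.loc[v, "clustering"] == pytest.approx(
                    brute_clustering(g, v), abs=1e-10
                )


# ---------------------------------------------------------------------------
# modules and roles
# ---------------------------------------------------------------------------

class TestModules:
    def test_two_cliques_found_exactly(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        modules, q = detect_modules(g, seed=0)
        assert len(set(modules.values())) == 2
        assert len({modules[v] for v in range(5)}) == 1
        assert len({modules[v] for v in range(5, 10)}) == 1

    def test_complete_graph_single_module(self):
        modules, q = detect_modules(nx.complete_graph(6), seed=0)
        assert len(set(modules.values())) == 1

    def test_q_matches_direct_formula(self):
        g = nx.gnp_random_graph(15, 0.3, seed=11)
        if g.number_of_edges() == 0:
            pytest.skip("degenerate random draw")
        modules, q = detect_modules(g, seed=1)
        assert q == pytest.approx(brute_modularity(g, modules), abs=1e-10)

    def test_edgeless_graph(self):
        g = nx.empty_graph(4)
        modules, q = detect_modules(g, seed=0)
        assert q == 0.0
        assert len(set(modules.values())) == 4


class TestZiPi:
    def test_internal_node_has_zero_pi(self):
        g = nx.complete_graph(5)
        modules = {v: 1 for v in g}
        res = zi_pi(g, modules)
        assert (res["pi"] == 0.0).all()

    def test_even_split_gives_half(self):
        g = nx.Graph([("x", "a"), ("x", "b"), ("x", "c"), ("x", "d")])
        modules = {"x": 1, "a": 1, "b": 1, "c": 2, "d": 2}
        res = zi_pi(g, modules)
        assert res.loc["x", "pi"] == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "zi,pi,role",
        [
            (3.0, 0.7, "network_hub"),
            (3.0, 0.5, "module_hub"),
            (1.0, 0.7, "connector"),
            (1.0, 0.5, "peripheral"),
        ],
    )
    def test_role_quadrants(self, zi, pi, role):
        from mobkit.network import role_for

        assert role_for(zi, pi) == role

    def test_roles_partition_nodes(self):
        table, _ = simulate_network_counts(
            NetworkSimConfig(n_otus=30, n_samples=120, seed=9)
        )
        g = infer_network(clr_transform(table), seed=9)
        modules, _ = detect_modules(g, seed=0)
        res = zi_pi(g, modules)
        assert set(res["role"]).issubset(
            {"network_hub", "module_hub", "connector", "peripheral"}
        )
        assert len(res) == g.number_of_nodes()

    def test_isolated_node_peripheral(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])
        g.add_edge("a", "b")
        g.add_node("lonely")
        res = zi_pi(g, {"a": 1, "b": 1, "lonely": 2})
        assert res.loc["lonely", "role"] == "peripheral"
        assert res.loc["lonely", "pi"] == 0.0


class TestModuleAbundance:
    def test_single_otu_module_equals_z_profile(self, toy_table):
        modules = {"A": 1}
        prof = module_abundance(toy_table, modules)
        rel = toy_table.relative_abundance()[:, 0]
        z = (rel - rel.mean()) / rel.std(ddof=1)
        assert np.allclose(prof["module_1"], z)

    def test_profiles_have_zero_mean(self, toy_table):
        modules = {"A": 1, "B": 1, "C": 2, "D": 2}
        prof = module_abundance(toy_table, modules)
        assert np.allclose(prof.mean(axis=0), 0.0, atol=1e-9)

    def test_correlated_members_average_to_member_profile(self):
        # A and B share the same relative-abundance profile across samples
        counts = np.array([[10, 10, 80], [20, 20, 60], [40, 40, 20]])
        table = OtuTable(counts, ("S1", "S2", "S3"), ("A", "B", "C"))
        prof = module_abundance(table, {"A": 1, "B": 1})
        rel = table.relative_abundance()[:, 0]
        z = (rel - rel.mean()) / rel.std(ddof=1)
        assert np.allclose(prof["module_1"], z)


class TestModuleRegression:
    def test_affine_profile_r2_one(self):
        mop = pd.Series([5.0, 10.0, 20.0, 30.0], index=list("abcd"))
        prof = pd.DataFrame({"module_1": 2 * mop + 3}, index=list("abcd"))
        res = module_function_regression(prof, mop)
        assert res.loc["module_1", "r_squared"] == pytest.approx(1.0)

    def test_zero_variance_profile_rejected(self):
        mop = pd.Series([5.0, 10.0, 20.0], index=list("abc"))
        prof = pd.DataFrame({"module_1": [1.0, 1.0, 1.0]}, index=list("abc"))
        with pytest.raises(ValueError):
            module_function_regression(prof, mop)


# ---------------------------------------------------------------------------
# robustness
# ---------------------------------------------------------------------------

class TestRobustness:
    def test_k3_closed_form(self):
        expected = np.log((np.e**2 + 2 * np.e**-1) / 3)
        assert natural_connectivity(nx.complete_graph(3)) == pytest.approx(
            expected, abs=1e-10
        )

    def test_kn_closed_form(self):
        for n in (4, 7):
            expected = np.log(
                (np.exp(n - 1) + (n - 1) * np.exp(-1)) / n
            )
            assert natural_connectivity(nx.complete_graph(n)) == pytest.approx(
                expected, abs=1e-10
            )

    def test_edgeless_graph_zero(self):
        assert natural_connectivity(nx.empty_graph(5)) == pytest.approx(0.0)

    def test_targeted_removal_at_least_as_damaging(self):
        rng = np.random.default_rng(0)
        worse = 0
        for s in range(10):
            g = nx.barabasi_albert_graph(40, 2, seed=s)
            fr = np.arange(0.0, 0.61, 0.2)
            tgt = robustness(g, "targeted_degree", fractions=fr, seed=s)
            rnd = robustness(g, "random", fractions=fr, n_repeats=20, seed=s)
            n = min(len(tgt.natural_connectivity), len(rnd.natural_connectivity))
            worse += (
                tgt.natural_connectivity[1:n]
                <= rnd.natural_connectivity[1:n] + 1e-9
            ).all()
        assert worse >= 9

    def test_curve_shapes(self):
        g = nx.barabasi_albert_graph(30, 2, seed=1)
        curve = robustness(g, "random", n_repeats=5, seed=0)
        assert len(curve.removed_fraction) == len(curve.natural_connectivity)
        assert (np.diff(curve.removed_fraction) > 0).all()
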