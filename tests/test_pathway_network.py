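"""MRF inference exactness, permutation contrast, and network operations."""

import io

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from nbscreen.pathway_network import (
    NetworkError,
    PermutationConfig,
    build_mrf,
    build_zscore_network,
    cluster_subnetworks,
    compare_networks,
    enrich_modules,
    impact_scores,
    infer_impact,
    load_fi_network,
    overlay_drugs,
    permutation_null,
    rank_normal_scores,
    select_impacted_genes,
    synthetic_fi_network,
)


def chain(n, w=1.0):
    g = nx.Graph()
    for i in range(n - 1):
        g.add_edge(f"g{i}", f"g{i+1}", fi_weight=w)
    return g


def star(n_leaves, w=1.0):
    g = nx.Graph()
    for i in range(n_leaves):
        g.add_edge("hub", f"leaf{i}", fi_weight=w)
    return g


def obs_frame(values: dict, samples=("S1",)):
    return pd.DataFrame(
        {s: [v if np.isscalar(v) else v[i] for v in values.values()]
         for i, s in enumerate(samples)},
        index=list(values.keys()),
    )


def manual_posterior(graph, obs, coupling, tau=1.0):
    """Independent construction of the Gaussian posterior (test oracle)."""
    nodes = sorted(set(graph.nodes) | set(obs.index))
    idx = {n: i for i, n in enumerate(nodes)}
    J = np.eye(len(nodes))
    for g in obs.index:
        J[idx[g], idx[g]] += tau
    for u, v, d in graph.edges(data=True):
        c = coupling * d["fi_weight"]
        J[idx[u], idx[u]] += c
        J[idx[v], idx[v]] += c
        J[idx[u], idx[v]] -= c
        J[idx[v], idx[u]] -= c
    h = np.zeros((len(nodes), obs.shape[1]))
    for g in obs.index:
        h[idx[g]] = tau * obs.loc[g].to_numpy()
    return pd.DataFrame(np.linalg.solve(J, h), index=nodes, columns=obs.columns)


class TestInference:
    def test_zero_coupling_decouples_genes(self):
        g = chain(4)
        obs = obs_frame({f"g{i}": float(i) for i in range(4)})
        model = build_mrf(g, obs, coupling_scale=0.0)
        out = infer_impact(model, obs)
        # posterior mean = tau/(1+tau) * y gene by gene
        for i in range(4):
            assert out.loc[f"g{i}", "S1"] == pytest.approx(0.5 * i, abs=1e-12)

    def test_two_node_chain_matches_closed_form(self):
        g = chain(2, w=0.7)
        obs = obs_frame({"g0": 1.3, "g1": -0.4})
        model = build_mrf(g, obs, coupling_scale=1.5)
        out = infer_impact(model, obs)
        oracle = manual_posterior(g, obs, coupling=1.5)
        assert np.allclose(out.to_numpy(), oracle.to_numpy(), atol=1e-8)

    def test_five_node_star_matches_closed_form(self):
        g = star(4, w=0.9)
        obs = obs_frame({"hub": 2.0, **{f"leaf{i}": 0.0 for i in range(4)}})
        model = build_mrf(g, obs, coupling_scale=1.0)
        out = infer_impact(model, obs)
        oracle = manual_posterior(g, obs, coupling=1.0)
        assert np.allclose(out.to_numpy(), oracle.to_numpy(), atol=1e-8)
        # propagation: amplified hub dominates, leaves still lifted above zero
        hub = out.loc["hub", "S1"]
        leaves = out.loc[[f"leaf{i}" for i in range(4)], "S1"]
        assert (hub > leaves).all() and (leaves > 0).all()

    def test_all_zero_observations_give_zero_impact(self):
        g = chain(3)
        obs = obs_frame({"g0": 0.0, "g1": 0.0, "g2": 0.0})
        model = build_mrf(g, obs)
        assert np.allclose(infer_impact(model, obs).to_numpy(), 0.0)

    def test_impact_is_odd_in_observation_sign(self):
        g = chain(3, w=0.4)
        obs = obs_frame({"g0": 1.0, "g1": -0.5, "g2": 0.2})
        model = build_mrf(g, obs)
        a = infer_impact(model, obs)
        b = infer_impact(model, -obs)
        assert np.allclose(a.to_numpy(), -b.to_numpy(), atol=1e-12)

    def test_relabeling_isomorphism(self):
        g = chain(3, w=0.8)
        obs = obs_frame({"g0": 1.0, "g1": 0.3, "g2": -0.7})
        out = infer_impact(build_mrf(g, obs), obs)
        relabel = {f"g{i}": f"x{i}" for i in range(3)}
        g2 = nx.relabel_nodes(g, relabel)
        obs2 = obs.rename(index=relabel)
        out2 = infer_impact(build_mrf(g2, obs2), obs2)
        for old, new in relabel.items():
            assert out.loc[old, "S1"] == pytest.approx(out2.loc[new, "S1"], abs=1e-12)

    def test_disjoint_network_and_profile_is_an_error(self):
        with pytest.raises(NetworkError, match="share no genes"):
            build_mrf(chain(2), obs_frame({"zz": 1.0}))


class TestRankNormalScores:
    def test_constant_row_maps_to_zero(self):
        scores = rank_normal_scores(pd.DataFrame([[5.0, 5.0, 5.0]], index=["g"]))
        assert np.allclose(scores.to_numpy(), 0.0)

    def test_depends_only_on_ranks(self):
        a = rank_normal_scores(pd.DataFrame([[1.0, 2.0, 10.0]], index=["g"]))
        b = rank_normal_scores(pd.DataFrame([[1.0, 5.0, 6.0]], index=["g"]))
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_rows_are_centered(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 13)))
        scores = rank_normal_scores(df)
        assert np.allclose(scores.to_numpy().sum(axis=1), 0.0, atol=1e-9)


class TestPermutationContrast:
    def test_constant_profile_has_zero_diff(self):
        g = chain(3)
        profile = pd.DataFrame(
            np.ones((3, 6)), index=["g0", "g1", "g2"],
            columns=[f"S{i}" for i in range(6)],
        )
        scores = rank_normal_scores(profile)
        model = build_mrf(g, scores)
        real = np.abs(infer_impact(model, scores).to_numpy()).mean(axis=1)
        perm = permutation_null(model, scores, PermutationConfig(10, seed=0))
        assert np.allclose(real, 0.0) and np.allclose(perm.to_numpy(), 0.0)

    def test_fixed_seed_reproduces_permuted_means(self, rng):
        g = chain(5)
        profile = pd.DataFrame(
            rng.normal(size=(5, 13)), index=[f"g{i}" for i in range(5)],
            columns=[f"S{i}" for i in range(13)],
        )
        scores = rank_normal_scores(profile)
        model = build_mrf(g, scores)
        a = permutation_null(model, scores, PermutationConfig(20, seed=7))
        b = permutation_null(model, scores, PermutationConfig(20, seed=7))
        assert np.allclose(a.to_numpy(), b.to_numpy())
        c = permutation_null(model, scores, PermutationConfig(20, seed=8))
        assert not np.allclose(a.to_numpy(), c.to_numpy())

    def test_null_profile_diffs_centered_at_zero(self):
        # i.i.d. CNV: real alignment is exchangeable with the permuted one,
        # so per-profile mean diffs across genes center at 0
        g = synthetic_fi_network(
            __import__("nbscreen.genomic_profiling", fromlist=["core_panel"])
            .core_panel()[:20],
            seed=3,
        )
        means = []
        for i in range(30):
            rng = np.random.default_rng(100 + i)
            profile = pd.DataFrame(
                rng.normal(size=(20, 13)),
                index=[n for n in sorted(g.nodes)][:20],
                columns=[f"S{j}" for j in range(13)],
            )
            out = impact_scores(g, profile, PermutationConfig(40, seed=i))
            means.append(out["diff"].mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) <= 3 * se + 1e-4


class TestSelection:
    def test_strict_threshold_band(self):
        scores = pd.DataFrame(
            {"real_mean": [0, 0, 0, 0], "perm_mean": [0, 0, 0, 0],
             "diff": [0.005, 0.02, -0.01, -0.0101], "selected": False},
            index=["a", "b", "c", "d"],
        )
        assert select_impacted_genes(scores) == ["b", "d"]

    def test_no_cnv_genes_removed_before_scoring(self):
        g = chain(3)
        profile = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 2.0, 2.0], [0.5, 1.5, 0.7, 2.5]],
            index=["g0", "g1", "g2"], columns=list("ABCD"),
        )
        out = impact_scores(g, profile, PermutationConfig(5, seed=0))
        assert "g1" not in out.index and {"g0", "g2"} <= set(out.index)

    def test_empty_profile_yields_empty_summary(self):
        g = chain(2)
        profile = pd.DataFrame(
            [[1.0, 1.0], [3.0, 3.0]], index=["g0", "g1"], columns=["A", "B"]
        )
        out = impact_scores(g, profile, PermutationConfig(2, seed=0))
        assert out.empty


class TestNetworkOps:
    def test_overlay_with_empty_annotation_is_identity(self):
        g = chain(3)
        out = overlay_drugs(g, {})
        assert set(out.nodes) == set(g.nodes) and out.size() == g.size()

    def test_drug_targeting_two_selected_genes_has_degree_two(self):
        g = chain(3)
        out = overlay_drugs(g, {"drugA": ["g0", "g2", "absent"]})
        assert out.degree["drugA"] == 2
        assert out.nodes["drugA"]["kind"] == "drug"

    def test_toy_overlay_matches_hand_enumeration(self):
        g = nx.Graph()
        g.add_nodes_from([f"g{i}" for i in range(5)])
        targets = {"d1": ["g0", "g1"], "d2": ["g4"], "d3": ["zz"]}
        out = overlay_drugs(g, targets)
        drug_edges = {frozenset(e) for e in out.edges
                      if e[0].startswith("d") or e[1].startswith("d")}
        assert drug_edges == {frozenset({"d1", "g0"}), frozenset({"d1", "g1"}),
                              frozenset({"d2", "g4"})}
        assert "d3" not in out

    def test_zscore_network_edges_mirror_significant_pairs(self):
        table = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "drug_id": ["d1", "d1", "d2"],
                "z": [1.2, -0.8, 0.5],
                "significant": [True, True, False],
            }
        )
        g = build_zscore_network(table, {"d1": 40.0, "d2": 70.0})
        assert g.number_of_edges() == 2
        assert g["a"]["d1"]["z"] == pytest.approx(1.2)
        assert g.nodes["d1"]["mean_cytotoxicity"] == pytest.approx(40.0)

    def test_no_significant_pairs_empty_network(self):
        table = pd.DataFrame(
            {"gene_id": ["a"], "drug_id": ["d"], "z": [0.1], "significant": [False]}
        )
        assert build_zscore_network(table, {}).number_of_edges() == 0


class TestClustering:
    def test_two_disconnected_cliques_become_two_modules(self):
        g = nx.Graph()
        for block, names in enumerate(("abcd", "wxyz")):
            for i, u in enumerate(names):
                for v in names[i + 1:]:
                    g.add_edge(u, v, fi_weight=1.0)
        assignment, summary = cluster_subnetworks(g)
        assert len(summary) == 2
        assert len({assignment[c] for c in "abcd"}) == 1
        assert assignment["a"] != assignment["w"]

    def test_single_edge_single_module(self):
        g = nx.Graph()
        g.add_edge("a", "b", fi_weight=1.0)
        assignment, summary = cluster_subnetworks(g)
        assert len(summary) == 1 and assignment["a"] == assignment["b"] == 0

    def test_planted_two_block_graph_recovered(self):
        rng = np.random.default_rng(5)
        blocks = {f"a{i}": 0 for i in range(10)}
        blocks.update({f"b{i}": 1 for i in range(10)})
        names = list(blocks)
        g = nx.Graph()
        g.add_nodes_from(names)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                p = 0.9 if blocks[names[i]] == blocks[names[j]] else 0.05
                if rng.random() < p:
                    g.add_edge(names[i], names[j], fi_weight=1.0)
        assignment, summary = cluster_subnetworks(g)
        assert len(summary) == 2
        for block in (0, 1):
            members = [n for n in names if blocks[n] == block]
            assert len({assignment[m] for m in members}) == 1

    def test_module_enrichment_flags_planted_set(self):
        g = nx.Graph()
        for i in range(5):
            for j in range(i + 1, 5):
                g.add_edge(f"a{i}", f"a{j}", fi_weight=1.0)
                g.add_edge(f"b{i}", f"b{j}", fi_weight=1.0)
        assignment, _ = cluster_subnetworks(g)
        universe = list(assignment)
        sets = {"setA": [f"a{i}" for i in range(5)], "rand": ["a0", "b3"]}
        out = enrich_modules(assignment, sets, universe)
        hit = out[(out["gene_set"] == "setA") & (out["overlap"] == 5)]
        assert not hit.empty and (hit["q"] < 0.05).all()


class TestComparison:
    def build(self, edges):
        g = nx.Graph()
        for d, genes in edges.items():
            g.add_node(d, kind="drug")
            for gene in genes:
                g.add_node(gene, kind="gene")
                g.add_edge(d, gene)
        return g

    def test_identical_networks_jaccard_one(self):
        g = self.build({"d1": ["a", "b"]})
        out = compare_networks(g, g.copy(), ["d1"])
        assert out.loc[0, "jaccard"] == pytest.approx(1.0)

    def test_disjoint_neighbors_jaccard_zero(self):
        a = self.build({"d1": ["a", "b"]})
        b = self.build({"d1": ["c", "d"]})
        assert compare_networks(a, b, ["d1"]).loc[0, "jaccard"] == 0.0

    def test_partial_overlap(self):
        a = self.build({"d1": ["A", "B", "C"]})
        b = self.build({"d1": ["B", "C", "D"]})
        assert compare_networks(a, b, ["d1"]).loc[0, "jaccard"] == pytest.approx(0.5)

    def test_absent_drug_warned_and_skipped(self):
        a = self.build({"d1": ["A"]})
        with pytest.warns(UserWarning, match="absent"):
            out = compare_networks(a, a, ["d1", "ghost"])
        assert list(out["drug_id"]) == ["d1"]


class TestEdgeListIO:
    def test_rejects_self_loop_duplicate_and_bad_weight(self):
        def load(text):
            return load_fi_network(io.StringIO(text))

        with pytest.raises(NetworkError, match="self-loop"):
            load("gene_a\tgene_b\tfi_weight\na\ta\t1.0\n")
        with pytest.raises(NetworkError, match="duplicate"):
            load("gene_a\tgene_b\tfi_weight\na\tb\t1.0\nb\ta\t0.5\n")
        with pytest.raises(NetworkError, match="positive"):
            load("gene_a\tgene_b\tfi_weight\na\tb\t-1.0\n")

    def test_loads_simple_graph(self):
        g = load_fi_network(io.StringIO("gene_a\tgene_b\tfi_weight\na\tb\t0.9\n"))
        assert g["a"]["b"]["fi_weight"] == pytest.approx(0.9)
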