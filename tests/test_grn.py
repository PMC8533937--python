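import networkx as nx
import numpy as np
import pandas as pd
import pytest

from imglkit.grn import (
    build_grn,
    compute_mri,
    propagate_cascade,
    rank_tfs,
    significant_mask,
    tf_set,
)

SGN = {"up": 1, "down": -1}


def make_net(edges, statuses):
    """edges: (src, tgt, sign); statuses: node -> up/down."""
    net = nx.DiGraph()
    for n, s in statuses.items():
        net.add_node(n, status=s)
    for s, t, sign in edges:
        net.add_edge(s, t, sign=sign)
    return net


def oracle_coherent(net, seed):
    """Independent oracle: a node is coherent iff SOME simple path from the
    seed predicts the observed status of every node along it (enumeration
    over all simple paths, no reachability shortcuts)."""
    if seed not in net or net.nodes[seed].get("status") not in SGN:
        return set()
    s0 = SGN[net.nodes[seed]["status"]]
    out = set()
    for v in net.nodes:
        if v == seed:
            continue
        for path in nx.all_simple_paths(net, seed, v):
            pred, ok = s0, True
            for u, w in zip(path, path[1:]):
                pred = pred * net.edges[u, w]["sign"]
                if pred != SGN[net.nodes[w]["status"]]:
                    ok = False
                    break
            if ok:
                out.add(v)
                break
    return out


def random_signed_net(rng, n_max=10):
    n = int(rng.integers(3, n_max + 1))
    nodes = [f"n{i}" for i in range(n)]
    statuses = {v: ("up" if rng.random() < 0.5 else "down") for v in nodes}
    edges = []
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < 0.3:
                edges.append((nodes[i], nodes[j], 1 if rng.random() < 0.6 else -1))
    return make_net(edges, statuses)


class TestBuildGrn:
    def edges(self, *pairs):
        return pd.DataFrame(list(pairs), columns=["source", "target", "sign"])

    def de(self, lfc):
        return pd.DataFrame(
            {"log2fc": pd.Series(lfc), "pvalue": 0.0, "padj": 0.0, "status": "ns"}
        )

    def test_both_endpoints_above_threshold_retained_with_status(self):
        net = build_grn(self.edges(("A", "B", 1)), self.de({"A": 3.0, "B": -2.5}))
        assert net.nodes["A"]["status"] == "up"
        assert net.nodes["B"]["status"] == "down"
        assert net.has_edge("A", "B")

    def test_weak_endpoint_drops_edge_and_node(self):
        net = build_grn(self.edges(("A", "B", 1)), self.de({"A": 3.0, "B": 1.0}))
        assert "B" not in net and net.number_of_edges() == 0

    def test_empty_de_gives_empty_network(self):
        net = build_grn(self.edges(("A", "B", 1)), self.de({}))
        assert net.number_of_nodes() == 0


class TestPropagate:
    def test_activating_chain_all_coherent(self):
        net = make_net(
            [("T", "A", 1), ("A", "B", 1)], {"T": "up", "A": "up", "B": "up"}
        )
        assert propagate_cascade(net, "T") == {"A", "B"}

    def test_double_repression_restores_sign(self):
        statuses = {"T": "up", "A": "down", "B": "up"}
        net = make_net([("T", "A", -1), ("A", "B", -1)], statuses)
        assert propagate_cascade(net, "T") == {"A", "B"}
        # observed B flipped: incoherent, and A still reached
        statuses["B"] = "down"
        net2 = make_net([("T", "A", -1), ("A", "B", -1)], statuses)
        assert propagate_cascade(net2, "T") == {"A"}

    def test_incoherent_node_absorbs_signal(self):
        net = make_net(
            [("T", "A", 1), ("A", "B", 1)], {"T": "up", "A": "down", "B": "up"}
        )
        assert propagate_cascade(net, "T") == set()

    def test_cycle_terminates(self):
        net = make_net([("T", "A", 1), ("A", "T", 1)], {"T": "up", "A": "up"})
        assert propagate_cascade(net, "T") == {"A"}

    def test_absent_seed_empty(self):
        net = make_net([], {"A": "up"})
        assert propagate_cascade(net, "missing") == set()

    def test_matches_exhaustive_path_oracle_on_random_ensemble(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            net = random_signed_net(rng)
            for seed in net.nodes:
                assert propagate_cascade(net, seed) == oracle_coherent(net, seed)

    def test_adding_coherent_edge_never_shrinks_reach(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            net = random_signed_net(rng)
            tfs = tf_set(net)
            if not tfs:
                continue
            tf = tfs[int(rng.integers(len(tfs)))]
            before = propagate_cascade(net, tf)
            pool_src = sorted(before | {tf})
            pool_tgt = sorted(set(net.nodes) - before - {tf})
            if not pool_tgt:
                continue
            u = pool_src[int(rng.integers(len(pool_src)))]
            v = pool_tgt[int(rng.integers(len(pool_tgt)))]
            if net.has_edge(u, v):
                continue
            s0 = SGN[net.nodes[tf]["status"]]
            sign = (SGN[net.nodes[u]["status"]] * s0) * (SGN[net.nodes[v]["status"]] * s0)
            net.add_edge(u, v, sign=sign)
            after = propagate_cascade(net, tf)
            assert before <= after and v in after
            for other in tf_set(net):
                assert propagate_cascade(net, other) >= set()  # terminates


class TestMRI:
    def test_two_of_five_nodes_is_forty_percent(self):
        net = make_net(
            [("T", "A", 1), ("T", "B", 1)],
            {"T": "up", "A": "up", "B": "up", "C": "up", "D": "down"},
        )
        rec = compute_mri(net, "T")
        assert rec.n_coherent == 2 and rec.total_nodes == 5 and rec.mri_pct == 40.0

    def test_tf_without_out_edges_scores_zero(self):
        net = make_net([("T", "A", 1)], {"T": "up", "A": "up"})
        assert compute_mri(net, "A").mri_pct == 0.0

    def test_mri_always_below_hundred(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            net = random_signed_net(rng)
            for tf in tf_set(net):
                assert 0 <= compute_mri(net, tf).mri_pct < 100


class TestRankTfs:
    def test_star_hub_outranks_leaves(self):
        statuses = {f"n{i}": "up" for i in range(6)}
        edges = [("n0", f"n{i}", 1) for i in range(1, 6)] + [("n1", "n2", 1)]
        table = rank_tfs(make_net(edges, statuses))
        assert table.iloc[0]["tf"] == "n0"

    def test_ties_broken_by_gene_id(self):
        statuses = {"zTF": "up", "aTF": "up", "x": "up", "y": "up"}
        edges = [("zTF", "x", 1), ("aTF", "y", 1)]
        table = rank_tfs(make_net(edges, statuses))
        pair = list(table["tf"][:2])
        assert pair == ["aTF", "zTF"]

    def test_planted_masters_outrank_everything_in_nonfocal_protocols(
        self, default_analysis
    ):
        truth, res = default_analysis
        masters = truth.expected_masters[truth.focal_protocol]  # the planted pair
        for prot, table in res.mri_tables.items():
            if prot == truth.focal_protocol:
                continue
            top = list(table["tf"][: len(masters)])
            assert set(top) == set(masters)

    def test_significance_rule(self):
        table = pd.DataFrame(
            {"tf": ["a", "b", "c"], "status": ["up"] * 3,
             "n_coherent": [10, 4, 10], "total_nodes": [100] * 3,
             "mri_pct": [10.0, 4.0, 0.5]}
        )
        assert significant_mask(table).tolist() == [True, False, False]
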