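import numpy as np
import pandas as pd
import pytest

from transomic.io_formats import DiffTable, NetworkEdgeList, NodeAnnotation
from transomic.master_regulator import (
    KeyNodeResult,
    empirical_null,
    keynode_score,
    significant_candidates,
    total_rank,
    upstream_reach,
)
from transomic.synthetic_data import SyntheticSpec, gen_network


def chain_network() -> NetworkEdgeList:
    return NetworkEdgeList(
        edges=[("A", "B", ""), ("B", "TF1", "")],
        node_annotations={
            "A": NodeAnnotation(("A",), False),
            "B": NodeAnnotation(("B",), False),
            "TF1": NodeAnnotation(("TF1",), True),
        },
    )


def random_network(rng: np.random.Generator, n_nodes: int, edge_prob: float) -> NetworkEdgeList:
    nodes = [f"V{i}" for i in range(n_nodes)]
    edges = [
        (nodes[i], nodes[j], "")
        for i in range(n_nodes)
        for j in range(n_nodes)
        if i != j and rng.uniform() < edge_prob
    ]
    ann = {n: NodeAnnotation((n,), i < max(2, n_nodes // 3)) for i, n in enumerate(nodes)}
    return NetworkEdgeList(edges=edges, node_annotations=ann)


def oracle_distances(network: NetworkEdgeList, targets, radius):
    """Independent oracle: boolean adjacency powers give min path length."""
    nodes = network.nodes
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    for a, b, _ in network.edges:
        adj[idx[a], idx[b]] = True
    dist = {}
    reach = np.eye(n, dtype=bool)
    current = np.eye(n, dtype=bool)
    for d in range(1, radius + 1):
        current = current @ adj
        for t in targets:
            for i, node in enumerate(nodes):
                if node != t and current[i, idx[t]] and (node, t) not in dist:
                    dist[(node, t)] = d
    return dist


class TestUpstreamReach:
    def test_chain_radius_12(self):
        reach = upstream_reach(chain_network(), ["TF1"], max_radius=12)
        assert reach["A"] == {"TF1": 2}
        assert reach["B"] == {"TF1": 1}

    def test_chain_radius_1(self):
        reach = upstream_reach(chain_network(), ["TF1"], max_radius=1)
        assert reach["A"] == {}
        assert reach["B"] == {"TF1": 1}

    def test_node_not_own_regulator(self):
        reach = upstream_reach(chain_network(), ["TF1"], max_radius=12)
        assert "TF1" not in reach["TF1"]

    def test_matches_path_enumeration_oracle(self):
        # DERIVED: adjacency-power oracle on small random graphs
        rng = np.random.default_rng(3)
        for _ in range(20):
            net = random_network(rng, int(rng.integers(4, 13)), 0.25)
            tfs = net.tf_nodes()[:3]
            if not tfs:
                continue
            reach = upstream_reach(net, tfs, max_radius=12)
            oracle = oracle_distances(net, tfs, 12)
            got = {(n, t): d for n, dd in reach.items() for t, d in dd.items()}
            assert got == oracle

    def test_missing_tfs_skipped_error_when_none(self):
        net = chain_network()
        with pytest.raises(ValueError):
            upstream_reach(net, ["GHOST"])

    def test_radius_monotone_superset(self):
        rng = np.random.default_rng(8)
        net = random_network(rng, 10, 0.3)
        tfs = net.tf_nodes()[:2]
        prev: dict[str, set] = {}
        for radius in (1, 3, 6, 12):
            reach = upstream_reach(net, tfs, max_radius=radius)
            for node, dd in reach.items():
                assert prev.get(node, set()) <= set(dd)
            prev = {n: set(dd) for n, dd in reach.items()}


class TestKeynodeScore:
    def test_direct_upstream_of_k_tfs(self):
        assert keynode_score({f"T{i}": 1 for i in range(5)}) == pytest.approx(2.5)

    def test_one_tf_at_max_distance(self):
        assert keynode_score({"T": 12}) == pytest.approx(1 / 13)

    def test_additional_tf_strictly_increases(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            k = int(rng.integers(1, 6))
            dists = {f"T{i}": int(rng.integers(1, 13)) for i in range(k)}
            base = keynode_score(dists)
            dists[f"T{k}"] = int(rng.integers(1, 13))
            assert keynode_score(dists) > base


class TestEmpiricalNull:
    def test_hub_reaching_all_universe_tfs_has_p_one(self):
        # node upstream of every TF at d=1: every null set scores the same
        tfs = [f"T{i}" for i in range(5)]
        edges = [("HUB", t, "") for t in tfs]
        ann = {"HUB": NodeAnnotation(("HUB",), False)}
        ann.update({t: NodeAnnotation((t,), True) for t in tfs})
        net = NetworkEdgeList(edges=edges, node_annotations=ann)
        res = empirical_null(net, tfs[:2], n_runs=200, seed=0)
        hub = next(r for r in res if r.node == "HUB")
        assert hub.empirical_p == pytest.approx(1.0)
        assert np.isnan(hub.z_score)  # null sd is zero

    def test_empirical_p_floor(self):
        res_p = 1.0 / (1000 + 1)
        spec = SyntheticSpec(seed=0, n_network_nodes=200, n_tf_nodes=40,
                             max_path_len=3, edge_prob=0.004,
                             planted_tfs=("TF_A", "TF_B", "TF_C", "TF_D", "TF_E"))
        net, truth = gen_network(spec)
        res = empirical_null(net, list(spec.planted_tfs), n_runs=1000, seed=0)
        planted = next(r for r in res if r.node == truth["planted_regulator"])
        assert planted.empirical_p >= res_p  # formula lower bound with +1 smoothing

    def test_fewer_tf_nodes_than_set_size(self):
        net = chain_network()  # B is present but only TF1 is TF-annotated
        with pytest.raises(ValueError, match="fewer"):
            empirical_null(net, ["TF1", "B"], n_runs=10, seed=0)

    def test_determinism(self):
        spec = SyntheticSpec(seed=5, n_network_nodes=100, n_tf_nodes=10)
        net, _ = gen_network(spec)
        a = empirical_null(net, list(spec.planted_tfs), n_runs=200, seed=9)
        b = empirical_null(net, list(spec.planted_tfs), n_runs=200, seed=9)
        assert [(r.node, r.empirical_p, r.fdr) for r in a] == [
            (r.node, r.empirical_p, r.fdr) for r in b
        ]

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        net = random_network(rng, 9, 0.3)
        tfs = net.tf_nodes()[:2]
        res = empirical_null(net, tfs, n_runs=300, seed=4)
        mapping = {n: f"X_{n}" for n in net.nodes}
        net2 = NetworkEdgeList(
            edges=[(mapping[a], mapping[b], l) for a, b, l in net.edges],
            node_annotations={mapping[n]: a for n, a in net.node_annotations.items()},
        )
        res2 = empirical_null(net2, [mapping[t] for t in tfs], n_runs=300, seed=4)
        scores1 = {r.node: r.keynode_score for r in res}
        scores2 = {r.node: r.keynode_score for r in res2}
        assert scores2 == {mapping[n]: s for n, s in scores1.items()}


class TestTotalRank:
    def _tables(self):
        tx = DiffTable(
            layer="transcriptome",
            frame=pd.DataFrame(
                {"feature_id": ["GA", "GB"], "log_fc": [2.0, 0.5], "p_value": [0.01, 0.01]}
            ),
        )
        prot = DiffTable(
            layer="proteome",
            frame=pd.DataFrame(
                {"feature_id": ["GA"], "log_fc": [1.0], "p_value": [0.01]}
            ),
        )
        return tx, prot

    def _candidate(self, node, score, tfs=("T1",)):
        return KeyNodeResult(
            node=node, keynode_score=score, reached_tfs=tfs, mean_distance=1.0,
            z_score=3.0, empirical_p=0.001, fdr=0.01,
        )

    def test_single_candidate_total_four(self):
        tx, prot = self._tables()
        ranked = total_rank(
            [self._candidate("A", 2.0)], {"T1": 1.0}, tx, prot, {"A": ["GA"]}
        )
        assert ranked[0].total_rank == pytest.approx(4.0)

    def test_two_candidates_arithmetic(self):
        # candidate ranked 1st,2nd,1st,2nd of 2 -> total 6
        tx, prot = self._tables()
        cands = [self._candidate("A", 2.0, ("T1",)), self._candidate("B", 1.0, ("T2",))]
        ranked = total_rank(
            cands, {"T1": 0.5, "T2": 1.5}, tx, prot, {"A": ["GA"], "B": ["GB"]}
        )
        by = {c.node: c for c in ranked}
        # A: keynode 1st, cma 2nd, tx 1st (|2.0|), prot 1st (only A has protein)
        assert by["A"].ranks["keynode_rank"] == 1
        assert by["A"].ranks["cma_rank"] == 2
        assert by["A"].ranks["tx_lfc_rank"] == 1
        assert by["A"].total_rank < by["B"].total_rank

    def test_missing_component_midpoint(self):
        tx, prot = self._tables()
        cands = [self._candidate("A", 2.0), self._candidate("B", 1.0)]
        ranked = total_rank(cands, {"T1": 1.0}, tx, prot, {"A": ["GA"], "B": ["GB"]})
        by = {c.node: c for c in ranked}
        # B's gene GB is absent from the proteome -> midpoint rank (2+1)/2
        assert by["B"].ranks["prot_lfc_rank"] == pytest.approx(1.5)

    def test_empty_candidates(self):
        tx, prot = self._tables()
        assert total_rank([], {}, tx, prot, {}) == []

    def test_null_fdr_control(self):
        # no planted structure: flagged node fraction stays near/below 0.05
        fracs = []
        for seed in range(10):
            spec = SyntheticSpec(seed=seed + 900, n_network_nodes=150, n_tf_nodes=15)
            net, _ = gen_network(spec)
            rng = np.random.default_rng(seed)
            obs = list(rng.choice(net.tf_nodes(), size=4, replace=False))
            res = empirical_null(net, obs, n_runs=500, seed=seed)
            fracs.append(
                np.mean([r.fdr < 0.05 for r in res]) if res else 0.0
            )
        assert np.mean(fracs) <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / max(len(fracs), 1))
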