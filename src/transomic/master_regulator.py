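"""Upstream master-regulator search on a directed signaling network.

For every node, find the subset of input transcription factors reachable by
directed paths of bounded length and score the node by summed
inverse-distance coverage.  Significance comes from an empirical null built
by resampling same-size TF sets from the network's TF nodes, with BH
control over the per-node empirical p-values.  Candidates are fused with
composite-module and omics evidence into a total rank.

The key-node formula sum(1/(1+d)) rewards covering many input TFs at short
upstream distance; it is deliberately isolated in one function so alternate
scores can be swapped in.  A node is not counted as its own upstream
regulator (only distances >= 1 contribute).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from ._util import bh_adjust
from .io_formats import DiffTable, NetworkEdgeList

logger = logging.getLogger(__name__)


@dataclass
class KeyNodeResult:
    node: str
    keynode_score: float
    reached_tfs: tuple[str, ...]
    mean_distance: float
    z_score: float  # nan when the null sd is zero
    empirical_p: float
    fdr: float
    ranks: dict[str, float] = field(default_factory=dict)
    total_rank: float = float("nan")


# ---------------------------------------------------------------------------
# reachability
# ---------------------------------------------------------------------------


def _distances_to_targets(
    graph: nx.DiGraph, targets: Sequence[str], max_radius: int
) -> dict[str, dict[str, int]]:
    """Shortest directed distance node -> target for d in [1, max_radius]."""
    reversed_graph = graph.reverse(copy=False)
    out: dict[str, dict[str, int]] = {n: {} for n in graph.nodes}
    for tf in targets:
        lengths = nx.single_source_shortest_path_length(reversed_graph, tf, cutoff=max_radius)
        for node, d in lengths.items():
            if d >= 1:
                out[node][tf] = d
    return out


def upstream_reach(
    network: NetworkEdgeList, tf_nodes: Sequence[str], max_radius: int = 12
) -> dict[str, dict[str, int]]:
    """Map node -> {reached input TF -> shortest directed distance <= radius}.

    Input TFs missing from the network are logged and skipped; an error is
    raised when none remain.
    """
    graph = network.to_networkx()
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    present = [t for t in tf_nodes if t in graph]
    missing = sorted(set(tf_nodes) - set(present))
    if missing:
        logger.warning("input TFs absent from network, skipped: %s", missing)
    if not present:
        raise ValueError("no input TFs present in the network")
    return _distances_to_targets(graph, present, max_radius)


def keynode_score(distances: Mapping[str, int]) -> float:
    """sum over reached TFs of 1/(1+distance)."""
    return float(sum(1.0 / (1.0 + d) for d in distances.values()))


# ---------------------------------------------------------------------------
# empirical null
# ---------------------------------------------------------------------------


def empirical_null(
    network: NetworkEdgeList,
    tf_nodes: Sequence[str],
    max_radius: int = 12,
    n_runs: int = 10_000,
    seed: int = 0,
    fdr_threshold: float = 0.05,
) -> list[KeyNodeResult]:
    """Score every node against a resampled-TF-set null.

    Null sets are drawn without replacement from the network's TF-annotated
    nodes, same size as the observed set.  empirical_p uses +1 smoothing;
    BH over per-node empirical p gives the fdr column.  Only nodes reaching
    at least one observed TF are scored.
    """
    graph = network.to_networkx()
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    observed_reach = upstream_reach(network, tf_nodes, max_radius)
    observed_tfs = [t for t in tf_nodes if t in graph]
    set_size = len(observed_tfs)

    universe = sorted(network.tf_nodes())
    if len(universe) < set_size:
        raise ValueError(
            f"network has {len(universe)} TF nodes, fewer than set size {set_size}"
        )

    # distance matrix from every node to every universe TF; inf = unreachable
    node_index = {n: i for i, n in enumerate(graph.nodes)}
    dist = _distances_to_targets(graph, universe, max_radius)
    contrib = np.zeros((len(node_index), len(universe)))
    for node, per_tf in dist.items():
        i = node_index[node]
        for j, tf in enumerate(universe):
            if tf in per_tf:
                contrib[i, j] = 1.0 / (1.0 + per_tf[tf])

    rng = np.random.default_rng([seed, 21])
    n_nodes = len(node_index)
    null_sum = np.zeros(n_nodes)
    null_sq = np.zeros(n_nodes)
    observed_scores = np.array(
        [keynode_score(observed_reach[n]) for n in graph.nodes]
    )
    ge_count = np.zeros(n_nodes)
    for _ in range(n_runs):
        cols = rng.choice(len(universe), size=set_size, replace=False)
        run = contrib[:, cols].sum(axis=1)
        null_sum += run
        null_sq += run * run
        ge_count += run >= observed_scores
    mean = null_sum / n_runs
    var = np.maximum(null_sq / n_runs - mean * mean, 0.0)
    sd = np.sqrt(var)
    emp_p = (1.0 + ge_count) / (1.0 + n_runs)

    scored_nodes = [n for n in graph.nodes if observed_reach[n]]
    if not scored_nodes:
        return []
    idx = [node_index[n] for n in scored_nodes]
    fdr = bh_adjust(emp_p[idx])
    results = []
    for n, i, q in zip(scored_nodes, idx, fdr):
        distances = observed_reach[n]
        z = (observed_scores[i] - mean[i]) / sd[i] if sd[i] > 0 else float("nan")
        results.append(
            KeyNodeResult(
                node=n,
                keynode_score=float(observed_scores[i]),
                reached_tfs=tuple(sorted(distances)),
                mean_distance=float(np.mean(list(distances.values()))),
                z_score=float(z),
                empirical_p=float(emp_p[i]),
                fdr=float(q),
            )
        )
    results.sort(key=lambda r: (-r.keynode_score, r.node))
    return results


def significant_candidates(
    results: Sequence[KeyNodeResult], fdr_threshold: float = 0.05
) -> list[KeyNodeResult]:
    return [r for r in results if r.fdr < fdr_threshold]


# ---------------------------------------------------------------------------
# total rank
# ---------------------------------------------------------------------------


def _rank_descending(values: list[float | None], n_total: int) -> list[float]:
    """Competition-free average ranks, descending; None -> midpoint (N+1)/2."""
    from scipy.stats import rankdata

    present = [i for i, v in enumerate(values) if v is not None]
    ranks = [float(n_total + 1) / 2.0] * len(values)
    if present:
        arr = np.array([-values[i] for i in present], dtype=float)
        for i, r in zip(present, rankdata(arr, method="average")):
            ranks[i] = float(r)
    return ranks


def total_rank(
    candidates: Sequence[KeyNodeResult],
    tf_regulatory_scores: Mapping[str, float],
    tx_table: DiffTable,
    prot_table: DiffTable,
    node_genes: Mapping[str, Sequence[str]],
) -> list[KeyNodeResult]:
    """Fuse four component rankings into an ascending total rank.

    Components: key-node score (desc); best regulatory score among reached
    TFs (desc); |transcriptome logFC| (desc); |proteome logFC| (desc), each
    evaluated on the best (largest |logFC|) gene symbol mapped to the node.
    Missing components take the midpoint rank (N+1)/2.  Ties in the final
    ordering break by key-node rank then node name.
    """
    cands = list(candidates)
    n = len(cands)
    if n == 0:
        return []

    def best_lfc(node: str, table: DiffTable) -> float | None:
        best: float | None = None
        for gene in node_genes.get(node, ()):  # best mapped symbol, logged decision
            hit = table.lookup(gene)
            if hit is not None and (best is None or abs(hit[0]) > abs(best)):
                best = hit[0]
        return best

    key_vals: list[float | None] = [c.keynode_score for c in cands]
    cma_vals: list[float | None] = []
    tx_vals: list[float | None] = []
    prot_vals: list[float | None] = []
    for c in cands:
        reg = [tf_regulatory_scores[t] for t in c.reached_tfs if t in tf_regulatory_scores]
        cma_vals.append(max(reg) if reg else None)
        tx_vals.append(abs(v) if (v := best_lfc(c.node, tx_table)) is not None else None)
        prot_vals.append(abs(v) if (v := best_lfc(c.node, prot_table)) is not None else None)

    key_rank = _rank_descending(key_vals, n)
    cma_rank = _rank_descending(cma_vals, n)
    tx_rank = _rank_descending(tx_vals, n)
    prot_rank = _rank_descending(prot_vals, n)
    for i, c in enumerate(cands):
        c.ranks = {
            "keynode_rank": key_rank[i],
            "cma_rank": cma_rank[i],
            "tx_lfc_rank": tx_rank[i],
            "prot_lfc_rank": prot_rank[i],
        }
        c.total_rank = key_rank[i] + cma_rank[i] + tx_rank[i] + prot_rank[i]
    cands.sort(key=lambda c: (c.total_rank, c.ranks["keynode_rank"], c.node))
    return cands
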