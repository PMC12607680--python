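"""Significance calling, transcript-protein concordance classes and top-N selection.

Significance applies Benjamini-Hochberg control to the supplied per-feature
p-values (the pipeline consumes differential tables, it does not recompute
group tests).  Concordance partitions features detected in at least one
layer into five mutually exclusive classes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._util import bh_adjust
from .io_formats import DiffTable

CONCORDANCE_CLASSES = (
    "concordant_up",
    "concordant_down",
    "discordant_up_gene_down_protein",
    "discordant_down_gene_up_protein",
    "single_layer_only",
)


@dataclass(frozen=True)
class SignificanceCall:
    feature_id: str
    layer: str
    direction: str  # 'up' | 'down' | 'unchanged'
    significant: bool
    log_fc: float
    p_value: float
    adj_p: float


@dataclass(frozen=True)
class ConcordanceRecord:
    feature_id: str
    concordance_class: str


def call_significance(
    table: DiffTable, alpha: float = 0.05, lfc_min: float = 0.0
) -> list[SignificanceCall]:
    """BH-adjust p over all table rows; significant iff adj_p <= alpha and
    |log_fc| >= lfc_min; direction follows the sign of log_fc."""
    if len(table) == 0:
        raise ValueError("empty differential table")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha={alpha} outside (0,1)")
    if lfc_min < 0:
        raise ValueError("lfc_min must be >= 0")
    adj = bh_adjust(table.frame["p_value"].to_numpy(dtype=float))
    calls = []
    for row, q in zip(table.frame.itertuples(index=False), adj):
        lfc = float(row.log_fc)
        significant = bool(q <= alpha and abs(lfc) >= lfc_min)
        if significant and lfc > 0:
            direction = "up"
        elif significant and lfc < 0:
            direction = "down"
        else:
            direction = "unchanged"
        calls.append(
            SignificanceCall(
                feature_id=str(row.feature_id),
                layer=table.layer,
                direction=direction,
                significant=significant,
                log_fc=lfc,
                p_value=float(row.p_value),
                adj_p=float(q),
            )
        )
    return calls


def classify_concordance(
    tx_calls: list[SignificanceCall], prot_calls: list[SignificanceCall]
) -> tuple[list[ConcordanceRecord], dict[str, int]]:
    """Classify every feature significant in at least one layer.

    Both-layer-significant features are concordant when directions agree,
    discordant otherwise; features significant in exactly one layer fall in
    ``single_layer_only``.  Returns (records, class counts).
    """
    tx = {c.feature_id: c for c in tx_calls if c.significant}
    prot = {c.feature_id: c for c in prot_calls if c.significant}
    records: list[ConcordanceRecord] = []
    for fid in sorted(set(tx) | set(prot)):
        in_tx, in_prot = fid in tx, fid in prot
        if in_tx and in_prot:
            t_dir, p_dir = tx[fid].direction, prot[fid].direction
            if t_dir == p_dir:
                cls = "concordant_up" if t_dir == "up" else "concordant_down"
            elif t_dir == "up":
                cls = "discordant_up_gene_down_protein"
            else:
                cls = "discordant_down_gene_up_protein"
        else:
            cls = "single_layer_only"
        records.append(ConcordanceRecord(feature_id=fid, concordance_class=cls))
    counts = Counter(r.concordance_class for r in records)
    summary = {cls: counts.get(cls, 0) for cls in CONCORDANCE_CLASSES}
    return records, summary


def top_n_by_significance(calls: list[SignificanceCall], n: int = 300) -> list[str]:
    """Top-n significant features by ascending p, ties by descending |logFC|
    then lexicographic ID; fewer when fewer are significant."""
    if n < 1:
        raise ValueError("n must be >= 1")
    significant = [c for c in calls if c.significant]
    significant.sort(key=lambda c: (c.p_value, -abs(c.log_fc), c.feature_id))
    return [c.feature_id for c in significant[:n]]
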