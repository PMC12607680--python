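"""Seeded generators for every pipeline input.

Each generator is a pure function of (spec, optional library): the same
seed yields byte-identical outputs.  Truth labels are returned alongside so
recovery tests can score the downstream stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .io_formats import (
    CompoundActivityTable,
    DiffTable,
    DrugTargetTable,
    NetworkEdgeList,
    NodeAnnotation,
    PromoterRecord,
    PromoterSet,
    PWMatrix,
    PROMOTER_LEN,
)
from .motif_enrichment import reverse_complement

import pandas as pd


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic trans-omic benchmark."""

    seed: int = 0
    # differential tables
    n_genes: int = 500
    frac_up: float = 0.1
    frac_down: float = 0.1
    effect_mu: float = 1.5
    effect_sigma: float = 0.4
    null_sigma: float = 0.15
    signal_p_max: float = 1e-4
    discordance_frac: float = 0.0
    # promoters
    n_yes: int = 50
    n_no: int = 50
    planted_tfs: tuple[str, ...] = ("TF_A", "TF_B", "TF_C")
    site_prob: float = 0.9
    module_window: int = 250
    gc_content: float = 0.45
    # network
    n_network_nodes: int = 200
    n_tf_nodes: int = 40
    planted_regulator: str = "REG1"
    max_path_len: int = 3
    edge_prob: float = 0.004
    # drug tables
    drugs_per_target: dict[str, int] = field(default_factory=dict)
    n_decoy_compounds: int = 10

    def __post_init__(self) -> None:
        for name in ("frac_up", "frac_down", "discordance_frac", "site_prob", "gc_content"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.frac_up + self.frac_down > 1.0:
            raise ValueError("frac_up + frac_down must not exceed 1")
        if not 1 <= self.module_window <= 300:
            raise ValueError("module_window must be in [1, 300]")
        if not 1 <= self.max_path_len <= 12:
            raise ValueError("max_path_len must be in [1, 12]")
        self.planted_tfs = tuple(self.planted_tfs)


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


# ---------------------------------------------------------------------------
# differential tables
# ---------------------------------------------------------------------------


def gen_diff_tables(spec: SyntheticSpec) -> tuple[DiffTable, DiffTable, dict[str, dict]]:
    """Two-layer differential tables with planted up/down signal.

    Signal genes draw |logFC| ~ Normal(effect_mu, effect_sigma) with tiny p;
    nulls draw logFC ~ Normal(0, null_sigma) with uniform p.  A
    ``discordance_frac`` of signal genes flips the proteome logFC sign.
    Returns (transcriptome, proteome, truth) where truth maps gene ->
    {direction, discordant}.
    """
    rng = _rng(spec, 1)
    n = spec.n_genes
    n_up = int(round(spec.frac_up * n))
    n_down = int(round(spec.frac_down * n))
    genes = [f"G{i:05d}" for i in range(n)]
    directions = np.array([1] * n_up + [-1] * n_down + [0] * (n - n_up - n_down))

    def layer_values(signs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        signal = signs != 0
        lfc = rng.normal(0.0, spec.null_sigma, size=n)
        mag = np.abs(rng.normal(spec.effect_mu, spec.effect_sigma, size=n))
        lfc[signal] = signs[signal] * mag[signal]
        p = rng.uniform(0.0, 1.0, size=n)
        p[signal] = rng.uniform(0.0, spec.signal_p_max, size=int(signal.sum()))
        return lfc, p

    tx_lfc, tx_p = layer_values(directions)
    flip = rng.uniform(size=n) < spec.discordance_frac
    prot_signs = np.where(flip & (directions != 0), -directions, directions)
    prot_lfc, prot_p = layer_values(prot_signs)

    tx = DiffTable(
        layer="transcriptome",
        frame=pd.DataFrame({"feature_id": genes, "log_fc": tx_lfc, "p_value": tx_p}),
    )
    prot = DiffTable(
        layer="proteome",
        frame=pd.DataFrame({"feature_id": genes, "log_fc": prot_lfc, "p_value": prot_p}),
    )
    truth = {
        g: {
            "direction": {1: "up", -1: "down", 0: "null"}[int(d)],
            "discordant": bool(f and d != 0),
        }
        for g, d, f in zip(genes, directions, flip)
    }
    return tx, prot, truth


# ---------------------------------------------------------------------------
# PWM library
# ---------------------------------------------------------------------------


def gen_pwm_library(
    tf_symbols: Sequence[str],
    seed: int = 0,
    length_range: tuple[int, int] = (8, 12),
    sharpness: float = 10.0,
    cutoff: float = 0.85,
) -> list[PWMatrix]:
    """One random matrix per TF symbol: count ``sharpness`` at a random
    consensus base per position and 1 elsewhere."""
    rng = np.random.default_rng([seed, 99])
    matrices = []
    for i, sym in enumerate(tf_symbols):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        consensus = rng.integers(0, 4, size=length)
        counts = np.ones((length, 4))
        counts[np.arange(length), consensus] = sharpness
        matrices.append(
            PWMatrix(matrix_id=f"M{i:03d}_{sym}", tf_symbols=(sym,), counts=counts, cutoff=cutoff)
        )
    return matrices


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def gen_promoters(
    spec: SyntheticSpec,
    pwm_library: Sequence[PWMatrix],
    yes_ids: Sequence[str] | None = None,
    no_ids: Sequence[str] | None = None,
) -> PromoterSet:
    """Yes/No promoter sets with planted co-occurring consensus sites.

    No promoters are i.i.d. background at ``gc_content``.  Each planted TF
    independently implants one max-scoring (consensus) site into a Yes
    promoter with probability ``site_prob``; all implanted sites of one
    promoter share a uniformly placed window of ``module_window`` bp,
    strands uniform, sites non-overlapping (rejection-sampled).  Per-TF
    independence means a multi-TF composite separates Yes from No strictly
    better than any single matrix once site_prob < 1.
    """
    by_symbol = {}
    for mat in pwm_library:
        for sym in mat.tf_symbols:
            by_symbol.setdefault(sym, mat)
    missing = [tf for tf in spec.planted_tfs if tf not in by_symbol]
    if missing:
        raise ValueError(f"planted TFs lacking a matrix: {missing}")
    planted = [by_symbol[tf] for tf in spec.planted_tfs]
    if yes_ids is None:
        yes_ids = [f"YES{i:04d}" for i in range(spec.n_yes)]
    if no_ids is None:
        no_ids = [f"NO{i:04d}" for i in range(spec.n_no)]

    rng = _rng(spec, 2)
    records: list[PromoterRecord] = []
    for gene_id in yes_ids:
        seq = list(_random_sequence(rng, PROMOTER_LEN, spec.gc_content))
        implant = [rng.uniform() < spec.site_prob for _ in planted]
        if any(implant):
            win_len = min(spec.module_window, PROMOTER_LEN)
            win_start = int(rng.integers(0, PROMOTER_LEN - win_len + 1))
            placed: list[tuple[int, int]] = []
            for mat, keep in zip(planted, implant):
                if not keep:
                    continue
                site = mat.consensus()
                if rng.uniform() < 0.5:
                    site = reverse_complement(site)
                for _ in range(1000):  # rejection-sample a non-overlapping slot
                    pos = int(rng.integers(win_start, win_start + win_len - len(site) + 1))
                    if all(pos + len(site) <= s or pos >= s + l for s, l in placed):
                        placed.append((pos, len(site)))
                        seq[pos : pos + len(site)] = list(site)
                        break
                else:
                    raise RuntimeError("could not place non-overlapping sites; widen module_window")
        records.append(PromoterRecord(gene_id=gene_id, sequence="".join(seq), label="yes"))
    for gene_id in no_ids:
        records.append(
            PromoterRecord(
                gene_id=gene_id,
                sequence=_random_sequence(rng, PROMOTER_LEN, spec.gc_content),
                label="no",
            )
        )
    return PromoterSet(records=records)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


def gen_network(
    spec: SyntheticSpec, tf_symbols: Sequence[str] | None = None
) -> tuple[NetworkEdgeList, dict]:
    """Random directed graph with a planted regulator wired to every planted TF.

    TF symbols become TF-annotated nodes (planted TFs plus decoys up to
    ``n_tf_nodes``); directed paths of length <= ``max_path_len`` from
    ``planted_regulator`` to each planted TF are guaranteed.  Acyclicity is
    not enforced.  Returns (network, truth) with the planted node name.
    """
    if tf_symbols is None:
        tf_symbols = spec.planted_tfs
    tf_symbols = list(tf_symbols)
    n_decoy_tfs = max(0, spec.n_tf_nodes - len(tf_symbols))
    decoy_tfs = [f"TFX{i:03d}" for i in range(n_decoy_tfs)]
    n_plain = spec.n_network_nodes - len(tf_symbols) - n_decoy_tfs - 1
    if n_plain < 1:
        raise ValueError("n_network_nodes too small for requested TF count")
    plain = [f"N{i:04d}" for i in range(n_plain)]
    nodes = [spec.planted_regulator] + tf_symbols + decoy_tfs + plain

    annotations = {spec.planted_regulator: NodeAnnotation((spec.planted_regulator,), False)}
    for sym in tf_symbols + decoy_tfs:
        annotations[sym] = NodeAnnotation((sym,), True)
    for node in plain:
        annotations[node] = NodeAnnotation((node,), False)

    rng = _rng(spec, 3)
    edges: set[tuple[str, str]] = set()
    n_nodes = len(nodes)
    mask = rng.uniform(size=(n_nodes, n_nodes)) < spec.edge_prob
    np.fill_diagonal(mask, False)
    for i, j in zip(*np.nonzero(mask)):
        edges.add((nodes[i], nodes[j]))
    # guaranteed planted paths regulator -> ... -> TF of length <= max_path_len
    for tf in tf_symbols:
        path_len = int(rng.integers(1, spec.max_path_len + 1))
        hops = [spec.planted_regulator]
        if path_len > 1:
            via = rng.choice(len(plain), size=path_len - 1, replace=False)
            hops += [plain[i] for i in via]
        hops.append(tf)
        for a, b in zip(hops[:-1], hops[1:]):
            edges.add((a, b))
    edge_list = [(a, b, "regulates") for a, b in sorted(edges)]
    network = NetworkEdgeList(edges=edge_list, node_annotations=annotations)
    truth = {"planted_regulator": spec.planted_regulator, "planted_tfs": list(tf_symbols)}
    return network, truth


# ---------------------------------------------------------------------------
# drug tables
# ---------------------------------------------------------------------------


def gen_drug_tables(spec: SyntheticSpec) -> tuple[DrugTargetTable, CompoundActivityTable, dict]:
    """Toy curated and predicted drug tables.

    ``spec.drugs_per_target`` maps gene -> number of distinct curated
    compounds; the curated druggability of that gene is that count by
    construction.  The predicted table gives every compound mechanism /
    disease-effect / toxicity rows with seeded Pa draws.  Truth records the
    intended curated druggability ordering.
    """
    rng = _rng(spec, 4)
    targets = dict(spec.drugs_per_target)
    if not targets:
        targets = {spec.planted_regulator: 5, "TF_A": 2}
    rows = []
    activity_rows = []
    compound_idx = 0
    for gene in sorted(targets):
        for _ in range(targets[gene]):
            cid = f"CPD{compound_idx:04d}"
            compound_idx += 1
            phase = int(rng.integers(0, 5))
            rows.append((cid, gene, "DIS01", phase))
            partner = sorted(targets)[int(rng.integers(0, len(targets)))]
            genes = tuple(sorted({gene, partner}))
            activity_rows.append((cid, f"inhibits_{gene}", "mechanism",
                                  float(rng.uniform(0.5, 1.0)), genes))
            activity_rows.append((cid, "DIS01", "disease_effect",
                                  float(rng.uniform(0.3, 1.0)), ()))
            activity_rows.append((cid, "tox_generic", "toxicity",
                                  float(rng.uniform(0.0, 0.6)), ()))
    for _ in range(spec.n_decoy_compounds):
        cid = f"CPD{compound_idx:04d}"
        compound_idx += 1
        gene = sorted(targets)[int(rng.integers(0, len(targets)))]
        activity_rows.append((cid, f"inhibits_{gene}", "mechanism",
                              float(rng.uniform(0.0, 1.0)), (gene,)))
        activity_rows.append((cid, "tox_generic", "toxicity",
                              float(rng.uniform(0.0, 1.0)), ()))
    drug_table = DrugTargetTable(
        frame=pd.DataFrame(rows, columns=["compound_id", "target_gene", "disease_id",
                                          "max_trial_phase"])
    )
    genes = sorted(targets)
    activity = CompoundActivityTable(
        frame=pd.DataFrame(
            activity_rows,
            columns=["compound_id", "activity_name", "activity_class", "pa", "mapped_genes"],
        ),
        iap={g: 1.0 for g in genes},
        opt_weight={g: 1.0 for g in genes},
    )
    truth = {"curated_druggability": {g: targets[g] for g in genes}}
    return drug_table, activity, truth


def spec_to_dict(spec: SyntheticSpec) -> dict:
    return asdict(spec)
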