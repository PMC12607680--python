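"""Druggability scoring: curated drug ranking and predicted compound filtering.

Curated mode ranks compounds by three components — target activity score,
disease activity score and clinical validity — and counts distinct drugs
per target as the druggability score.  Predicted mode filters compounds by
toxicity / disease-effect / target-count thresholds on precomputed activity
probabilities (Pa) and aggregates Pa-weighted mechanism evidence per gene.

The curated target-activity formula is a reconstruction (the source formula
is typographically ambiguous): score =
-(|T| / (|T| + w*(|AT| - |T|))) * sum_{t in T} log10(rank(t) / (1 + maxRank(T))),
which is positive whenever T is non-empty and rank-monotone.  All threshold
inequalities are strict.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.stats import rankdata

from .io_formats import CompoundActivityTable, DrugTargetTable

logger = logging.getLogger(__name__)


@dataclass
class CuratedDrugScores:
    compound_id: str
    t_score_psd: float
    d_score_psd: float
    clinical_validity_score: int
    drug_rank: float = float("nan")


@dataclass
class PredictedCompoundScores:
    compound_id: str
    toxicity_score: float
    disease_activity_score: float
    t_score: float
    passes_filter: bool


@dataclass(frozen=True)
class TargetDruggability:
    gene: str
    mode: str  # 'curated' | 'predicted'
    druggability_score: float


# ---------------------------------------------------------------------------
# curated (HumanPSD-style)
# ---------------------------------------------------------------------------


def t_score_psd(
    compound_targets: Sequence[str],
    input_ranks: Mapping[str, float],
    w: float = 1.0,
) -> float | None:
    """Target activity score; None (compound excluded) when no compound
    target intersects the input list."""
    all_targets = set(compound_targets)
    hit = all_targets & set(input_ranks)
    if not hit:
        logger.info("compound excluded: no target in the input list")
        return None
    n_hit, n_all = len(hit), len(all_targets)
    max_rank = max(input_ranks[t] for t in hit)
    coverage = n_hit / (n_hit + w * (n_all - n_hit))
    total = sum(math.log10(input_ranks[t] / (1.0 + max_rank)) for t in hit)
    return -coverage * total


def d_score_psd(
    compound_id: str,
    selected_diseases: Sequence[str],
    trial_table: DrugTargetTable,
) -> float:
    """Sum over selected diseases of the phase numbers with a known trial."""
    if not selected_diseases:
        return 0.0
    sub = trial_table.frame[trial_table.frame["compound_id"] == compound_id]
    score = 0.0
    for disease in selected_diseases:
        phases = {
            int(p)
            for p in sub.loc[sub["disease_id"] == disease, "max_trial_phase"]
            if int(p) > 0
        }
        score += sum(phases)
    return score


def clinical_validity(compound_id: str, trial_table: DrugTargetTable) -> int:
    """Highest trial phase (1-4) over any pathology; 0 when never tested."""
    sub = trial_table.frame[trial_table.frame["compound_id"] == compound_id]
    if sub.empty:
        return 0
    return int(sub["max_trial_phase"].max())


def drug_rank(compounds: Sequence[CuratedDrugScores]) -> list[CuratedDrugScores]:
    """Rank each component descending (best score = rank 1), sum the three
    ranks, and order ascending; ties break by compound_id."""
    if not compounds:
        return []
    comps = list(compounds)

    def ranks(values: list[float]) -> list[float]:
        return [float(r) for r in rankdata([-v for v in values], method="average")]

    r1 = ranks([c.t_score_psd for c in comps])
    r2 = ranks([c.d_score_psd for c in comps])
    r3 = ranks([float(c.clinical_validity_score) for c in comps])
    for c, a, b, d in zip(comps, r1, r2, r3):
        c.drug_rank = a + b + d
    comps.sort(key=lambda c: (c.drug_rank, c.compound_id))
    return comps


def score_curated(
    trial_table: DrugTargetTable,
    input_ranks: Mapping[str, float],
    selected_diseases: Sequence[str],
    w: float = 1.0,
) -> list[CuratedDrugScores]:
    """Full curated scoring for every compound with >= 1 input-list target."""
    out = []
    for cid in trial_table.compounds():
        t = t_score_psd(sorted(trial_table.targets_of(cid)), input_ranks, w=w)
        if t is None:
            continue
        out.append(
            CuratedDrugScores(
                compound_id=cid,
                t_score_psd=t,
                d_score_psd=d_score_psd(cid, selected_diseases, trial_table),
                clinical_validity_score=clinical_validity(cid, trial_table),
            )
        )
    return drug_rank(out)


def curated_druggability(gene: str, drug_target_table: DrugTargetTable) -> int:
    """Count of distinct compounds targeting the gene."""
    sub = drug_target_table.frame[drug_target_table.frame["target_gene"] == gene]
    return int(sub["compound_id"].nunique())


# ---------------------------------------------------------------------------
# predicted (PASS-style)
# ---------------------------------------------------------------------------


def _mechanism_targets(rows, target_threshold: float) -> set[str]:
    genes: set[str] = set()
    for row in rows.itertuples(index=False):
        if row.activity_class == "mechanism" and row.pa > target_threshold:
            genes.update(row.mapped_genes)
    return genes


def filter_predicted(
    compound_table: CompoundActivityTable,
    tox_threshold: float,
    effect_threshold: float,
    target_threshold: float,
    diseases: Sequence[str],
) -> list[PredictedCompoundScores]:
    """Apply the three strict-inequality filters to every compound.

    passes_filter requires: max toxicity Pa < tox_threshold; every
    disease-matched effect Pa > effect_threshold (vacuously true with no
    matching effect rows, as printed); and >= 2 distinct mechanism target
    genes with Pa > target_threshold.  toxicity_score is the max toxicity
    Pa (0 with no toxicity rows); disease_activity_score is the max Pa over
    disease-matched effects.
    """
    disease_set = set(diseases)
    out = []
    for cid in compound_table.compounds():
        rows = compound_table.rows_for(cid)
        tox = [r.pa for r in rows.itertuples(index=False) if r.activity_class == "toxicity"]
        toxicity_score = max(tox) if tox else 0.0
        effects = [
            r.pa
            for r in rows.itertuples(index=False)
            if r.activity_class == "disease_effect" and r.activity_name in disease_set
        ]
        disease_activity_score = max(effects) if effects else 0.0
        targets = _mechanism_targets(rows, target_threshold)
        passes = (
            toxicity_score < tox_threshold
            and all(pa > effect_threshold for pa in effects)
            and len(targets) >= 2
        )
        mech_pa = sum(
            r.pa
            for r in rows.itertuples(index=False)
            if r.activity_class == "mechanism" and r.pa > target_threshold
        )
        out.append(
            PredictedCompoundScores(
                compound_id=cid,
                toxicity_score=float(toxicity_score),
                disease_activity_score=float(disease_activity_score),
                t_score=float(mech_pa),  # refined by t_score_pass when input targets given
                passes_filter=bool(passes),
            )
        )
    return out


def t_score_pass(
    compound_rows,
    input_targets: Sequence[str],
    iap: Mapping[str, float],
    opt_weight: Mapping[str, float],
    w: float = 1.0,
    target_threshold: float = 0.0,
) -> float | None:
    """Predicted target-activity score for one compound's activity rows.

    Mechanisms are the mechanism rows with Pa above the target threshold;
    T is the union of their mapped genes intersected with the input list.
    Returns None (compound excluded) when T is empty.
    """
    mechanisms = [
        r
        for r in compound_rows.itertuples(index=False)
        if r.activity_class == "mechanism" and r.pa > target_threshold
    ]
    all_targets: set[str] = set()
    for m in mechanisms:
        all_targets.update(m.mapped_genes)
    hit = all_targets & set(input_targets)
    if not hit:
        return None
    n_hit, n_all = len(hit), len(all_targets)
    coverage = n_hit / (n_hit + w * (n_all - n_hit))
    total = sum(
        m.pa * sum(iap.get(g, 1.0) * opt_weight.get(g, 1.0) for g in m.mapped_genes)
        for m in mechanisms
    )
    return coverage * total


def d_score_pass(
    gene: str,
    compound_table: CompoundActivityTable,
    passing_compounds: Sequence[str],
    target_threshold: float = 0.0,
) -> float:
    """IAP(g) * sum over passing compounds targeting g of their mechanism Pa
    values that map to g."""
    iap = compound_table.iap.get(gene, 1.0)
    total = 0.0
    for cid in passing_compounds:
        rows = compound_table.rows_for(cid)
        for row in rows.itertuples(index=False):
            if (
                row.activity_class == "mechanism"
                and row.pa > target_threshold
                and gene in row.mapped_genes
            ):
                total += row.pa
    return iap * total


def predicted_druggability(
    genes: Sequence[str],
    compound_table: CompoundActivityTable,
    tox_threshold: float = 0.5,
    effect_threshold: float = 0.0,
    target_threshold: float = 0.0,
    diseases: Sequence[str] = (),
) -> list[TargetDruggability]:
    """Filter compounds, then aggregate d_score_pass per gene."""
    scored = filter_predicted(
        compound_table, tox_threshold, effect_threshold, target_threshold, diseases
    )
    passing = [c.compound_id for c in scored if c.passes_filter]
    return [
        TargetDruggability(
            gene=g,
            mode="predicted",
            druggability_score=d_score_pass(g, compound_table, passing, target_threshold),
        )
        for g in genes
    ]
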