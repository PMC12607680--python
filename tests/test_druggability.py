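import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transomic.druggability import (
    CuratedDrugScores,
    clinical_validity,
    curated_druggability,
    d_score_pass,
    d_score_psd,
    drug_rank,
    filter_predicted,
    predicted_druggability,
    t_score_pass,
    t_score_psd,
)
from transomic.io_formats import CompoundActivityTable, DrugTargetTable


def drug_table(rows):
    return DrugTargetTable(
        frame=pd.DataFrame(
            rows, columns=["compound_id", "target_gene", "disease_id", "max_trial_phase"]
        )
    )


def activity_table(rows, iap=None, opt=None):
    return CompoundActivityTable(
        frame=pd.DataFrame(
            rows,
            columns=["compound_id", "activity_name", "activity_class", "pa", "mapped_genes"],
        ),
        iap=iap or {},
        opt_weight=opt or {},
    )


class TestTScorePsd:
    def test_single_target_rank_one(self):
        # |T|=|AT|=1, rank=1, maxRank=1 -> -log10(1/2) ~ 0.30103
        score = t_score_psd(["G1"], {"G1": 1})
        assert score == pytest.approx(-math.log10(0.5), abs=1e-12)

    def test_w_monotone_decreasing(self):
        ranks = {"G1": 1}
        targets = ["G1", "G2", "G3"]  # |AT|=3 > |T|=1
        assert t_score_psd(targets, ranks, w=2.0) < t_score_psd(targets, ranks, w=1.0)

    def test_hand_recomputation_three_targets(self):
        # DERIVED: spreadsheet-style recomputation
        ranks = {"G1": 1, "G2": 3, "G3": 7}
        targets = ["G1", "G2", "G3", "G4"]  # one off-list target
        w = 1.0
        coverage = 3 / (3 + w * (4 - 3))
        expected = -coverage * sum(
            math.log10(r / (1 + 7)) for r in (1, 3, 7)
        )
        assert t_score_psd(targets, ranks, w=w) == pytest.approx(expected, abs=1e-9)

    def test_no_overlap_excluded(self):
        assert t_score_psd(["G9"], {"G1": 1}) is None

    def test_positive_whenever_t_nonempty(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 6))
            ranks = {f"G{i}": int(rng.integers(1, 50)) for i in range(n)}
            extra = [f"X{i}" for i in range(int(rng.integers(0, 4)))]
            score = t_score_psd(list(ranks) + extra, ranks, w=float(rng.uniform(0.1, 3)))
            assert score > 0


class TestDScorePsd:
    def _table(self):
        return drug_table(
            [
                ("C1", "G1", "DA", 1),
                ("C1", "G2", "DA", 3),
                ("C1", "G1", "DB", 2),
                ("C2", "G1", "DA", 4),
            ]
        )

    def test_empty_disease_set_zero(self):
        assert d_score_psd("C1", [], self._table()) == 0.0

    def test_phases_one_and_three_sum_four(self):
        assert d_score_psd("C1", ["DA"], self._table()) == pytest.approx(4.0)

    def test_two_diseases_twelve(self):
        table = drug_table(
            [
                ("C1", "G1", "DA", 2),
                ("C1", "G1", "DB", 1),
                ("C1", "G2", "DB", 2),
                ("C1", "G3", "DB", 3),
                ("C1", "G4", "DB", 4),
            ]
        )
        assert d_score_psd("C1", ["DA", "DB"], table) == pytest.approx(12.0)


class TestClinicalValidity:
    def test_untested_zero(self):
        assert clinical_validity("GHOST", drug_table([("C1", "G1", "DA", 1)])) == 0

    def test_max_phase_across_pathologies(self):
        table = drug_table([("C1", "G1", "DA", 1), ("C1", "G1", "DB", 3)])
        assert clinical_validity("C1", table) == 3

    def test_bounded_by_four(self):
        table = drug_table([("C1", "G1", "DA", 4)])
        assert clinical_validity("C1", table) <= 4


class TestDrugRank:
    def test_single_compound_rank_three(self):
        [c] = drug_rank([CuratedDrugScores("C1", 1.0, 2.0, 3)])
        assert c.drug_rank == pytest.approx(3.0)

    def test_best_on_all_three(self):
        a = CuratedDrugScores("A", 2.0, 5.0, 4)
        b = CuratedDrugScores("B", 1.0, 2.0, 1)
        ranked = drug_rank([a, b])
        assert ranked[0].compound_id == "A" and ranked[0].drug_rank == pytest.approx(3.0)
        assert ranked[1].drug_rank == pytest.approx(6.0)

    def test_rank_sums_invariant_to_order(self):
        rng = np.random.default_rng(1)
        comps = [
            CuratedDrugScores(f"C{i}", float(rng.uniform()), float(rng.uniform()),
                              int(rng.integers(0, 5)))
            for i in range(6)
        ]
        ref = {c.compound_id: c.drug_rank for c in drug_rank([c for c in comps])}
        for _ in range(5):
            perm = list(rng.permutation(6))
            shuffled = [
                CuratedDrugScores(comps[i].compound_id, comps[i].t_score_psd,
                                  comps[i].d_score_psd, comps[i].clinical_validity_score)
                for i in perm
            ]
            got = {c.compound_id: c.drug_rank for c in drug_rank(shuffled)}
            assert got == ref


class TestFilterPredicted:
    def _table(self):
        return activity_table(
            [
                ("C1", "mech1", "mechanism", 0.9, ("G1",)),
                ("C1", "mech2", "mechanism", 0.8, ("G2",)),
                ("C1", "DIS", "disease_effect", 0.7, ()),
                ("C1", "tox", "toxicity", 0.2, ()),
                ("C2", "mech1", "mechanism", 0.9, ("G1",)),  # only 1 target
                ("C2", "DIS", "disease_effect", 0.7, ()),
                ("C3", "mech1", "mechanism", 0.9, ("G1", "G2")),
                ("C3", "tox", "toxicity", 0.9, ()),  # too toxic
            ]
        )

    def test_one_target_fails(self):
        scored = {c.compound_id: c for c in
                  filter_predicted(self._table(), 0.5, 0.5, 0.5, ["DIS"])}
        assert not scored["C2"].passes_filter

    def test_no_toxicity_rows_scores_zero(self):
        table = activity_table([("C1", "m1", "mechanism", 0.9, ("G1", "G2"))])
        [c] = filter_predicted(table, 0.5, 0.0, 0.5, [])
        assert c.toxicity_score == 0.0 and c.passes_filter

    def test_toxic_compound_fails(self):
        scored = {c.compound_id: c for c in
                  filter_predicted(self._table(), 0.5, 0.5, 0.5, ["DIS"])}
        assert not scored["C3"].passes_filter
        assert scored["C1"].passes_filter

    def test_five_compound_hand_enumeration(self):
        # DERIVED: hand evaluation of each clause per compound
        table = activity_table(
            [
                ("A", "m", "mechanism", 0.9, ("G1", "G2")),   # passes
                ("B", "m", "mechanism", 0.9, ("G1",)),        # 1 target
                ("C", "m", "mechanism", 0.3, ("G1", "G2")),   # pa below target thr
                ("D", "m", "mechanism", 0.9, ("G1", "G2")),
                ("D", "t", "toxicity", 0.8, ()),              # toxic
                ("E", "m", "mechanism", 0.9, ("G1", "G2")),
                ("E", "DIS", "disease_effect", 0.1, ()),      # weak effect
            ]
        )
        result = {c.compound_id: c.passes_filter
                  for c in filter_predicted(table, 0.5, 0.4, 0.5, ["DIS"])}
        assert result == {"A": True, "B": False, "C": False, "D": False, "E": False}

    def test_boundary_semantics_strict(self):
        # tox=1, effect=0, target=0 passes everything with >=2 mechanism targets
        table = self._table()
        scored = {c.compound_id: c.passes_filter
                  for c in filter_predicted(table, 1.0, 0.0, 0.0, ["DIS"])}
        assert scored == {"C1": True, "C2": False, "C3": True}


class TestTScorePass:
    def test_direct_evaluation(self):
        table = activity_table([("C1", "m", "mechanism", 0.5, ("G1",))],
                               iap={"G1": 1.0}, opt={"G1": 1.0})
        rows = table.rows_for("C1")
        score = t_score_pass(rows, ["G1"], table.iap, table.opt_weight, w=1.0)
        assert score == pytest.approx(0.5)

    def test_zero_iap_zeroes_score(self):
        table = activity_table([("C1", "m", "mechanism", 0.5, ("G1",))],
                               iap={"G1": 0.0})
        rows = table.rows_for("C1")
        assert t_score_pass(rows, ["G1"], table.iap, table.opt_weight) == pytest.approx(0.0)

    def test_two_mechanism_hand_oracle(self):
        # DERIVED: hand recomputation with two mechanisms and weights
        iap = {"G1": 0.9, "G2": 0.8}
        opt = {"G1": 1.5, "G2": 1.0}
        table = activity_table(
            [
                ("C1", "m1", "mechanism", 0.6, ("G1",)),
                ("C1", "m2", "mechanism", 0.4, ("G1", "G2")),
            ],
            iap=iap, opt=opt,
        )
        rows = table.rows_for("C1")
        # T = {G1} (input), AT = {G1, G2}; coverage = 1/(1+1*(2-1)) = 0.5
        expected = 0.5 * (0.6 * (0.9 * 1.5) + 0.4 * (0.9 * 1.5 + 0.8 * 1.0))
        got = t_score_pass(rows, ["G1"], iap, opt, w=1.0)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_excluded_without_input_overlap(self):
        table = activity_table([("C1", "m", "mechanism", 0.5, ("G1",))])
        assert t_score_pass(table.rows_for("C1"), ["OTHER"], {}, {}) is None


class TestDScorePass:
    def test_empty_structures_zero(self):
        table = activity_table([("C1", "m", "mechanism", 0.5, ("G1",))])
        assert d_score_pass("G1", table, []) == 0.0

    def test_direct_sum(self):
        table = activity_table(
            [
                ("C1", "m1", "mechanism", 0.5, ("G1",)),
                ("C1", "m2", "mechanism", 0.3, ("G1",)),
            ],
            iap={"G1": 1.0},
        )
        assert d_score_pass("G1", table, ["C1"]) == pytest.approx(0.8)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=4),
           st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=4))
    def test_additive_over_disjoint_structure_sets(self, pas1, pas2):
        rows = [("A", f"m{i}", "mechanism", pa, ("G1",)) for i, pa in enumerate(pas1)]
        rows += [("B", f"m{i}", "mechanism", pa, ("G1",)) for i, pa in enumerate(pas2)]
        table = activity_table(rows, iap={"G1": 0.7})
        joint = d_score_pass("G1", table, ["A", "B"])
        split = d_score_pass("G1", table, ["A"]) + d_score_pass("G1", table, ["B"])
        assert joint == pytest.approx(split, abs=1e-9)


class TestCuratedDruggability:
    def test_zero_drugs(self):
        assert curated_druggability("G9", drug_table([("C1", "G1", "DA", 1)])) == 0

    def test_distinct_compound_count(self):
        table = drug_table(
            [("C1", "G1", "DA", 1), ("C2", "G1", "DA", 2), ("C1", "G1", "DB", 1)]
        )
        assert curated_druggability("G1", table) == 2


class TestPredictedDruggability:
    def test_passing_compounds_aggregate(self):
        table = activity_table(
            [
                ("C1", "m1", "mechanism", 0.9, ("G1", "G2")),
                ("C2", "m1", "mechanism", 0.8, ("G1",)),  # fails: 1 target
            ],
            iap={"G1": 1.0, "G2": 1.0},
        )
        out = {t.gene: t.druggability_score
               for t in predicted_druggability(["G1", "G2"], table,
                                               tox_threshold=0.5, target_threshold=0.5)}
        assert out["G1"] == pytest.approx(0.9)
        assert out["G2"] == pytest.approx(0.9)
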