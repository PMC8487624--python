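import numpy as np
import pandas as pd
import pytest

from aeroscore.consensus_taxonomy import (assignment_stats, consistency_at_genus,
                                          genus_overlap, merge_assignments)
from aeroscore.io_formats import RANKS, UNASSIGNED, AsvTable, TaxonomyTable
from aeroscore.synthetic_data import (expected_tier_fractions,
                                      generate_taxonomy_pair,
                                      taxonomy_pair_from_counts)


def _tax(genera: dict[str, str], source_db: str = "db") -> TaxonomyTable:
    rows = {}
    for asv, genus in genera.items():
        lin = {r: UNASSIGNED for r in RANKS[:-1]}
        if genus != UNASSIGNED:
            lin.update(domain="Bacteria", phylum="P", **{"class": "C"},
                       order="O", family="F", genus=genus)
        rows[asv] = lin
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index"),
                         source_db=source_db)


class TestMerge:
    def test_tier_assignment_cases(self):
        prim = _tax({"A1": "Pseudomonas", "A2": "Ralstonia", "A3": UNASSIGNED,
                     "A4": UNASSIGNED}, "RDP")
        sec = _tax({"A1": "Pseudomonas", "A2": "Burkholderia",
                    "A3": "Sphingomonas", "A4": UNASSIGNED}, "SILVA")
        cons = merge_assignments(prim, sec)
        row = cons.assignments
        assert row.loc["A1", ["confidence", "source", "genus"]].tolist() == \
            ["high", "both", "Pseudomonas"]
        # primary database preferred on conflict; the alternative is kept
        assert row.loc["A2", ["confidence", "source", "genus",
                              "alternative_genus"]].tolist() == \
            ["medium", "primary_db", "Ralstonia", "Burkholderia"]
        assert row.loc["A3", ["confidence", "source", "genus"]].tolist() == \
            ["low", "secondary_db", "Sphingomonas"]
        assert row.loc["A4", "confidence"] == "unassigned"

    def test_case_insensitive_and_candidatus_agreement(self):
        prim = _tax({"A1": "pseudomonas"}, "RDP")
        sec = _tax({"A1": "Candidatus Pseudomonas"}, "SILVA")
        cons = merge_assignments(prim, sec)
        assert cons.assignments.loc["A1", "confidence"] == "high"

    def test_absent_from_both_warns_not_raises(self):
        prim = _tax({"A1": "Bacillus"})
        sec = _tax({"A1": "Bacillus"})
        with pytest.warns(UserWarning, match="absent from both"):
            cons = merge_assignments(prim, sec, asv_ids=["A1", "GHOST"])
        assert cons.assignments.loc["GHOST", "confidence"] == "unassigned"

    def test_unassigned_keeps_deepest_primary_prefix(self):
        prim = TaxonomyTable(pd.DataFrame(
            {"domain": ["Bacteria"], "phylum": ["Firmicutes"],
             "class": [UNASSIGNED], "order": [UNASSIGNED],
             "family": [UNASSIGNED], "genus": [UNASSIGNED]}, index=["A1"]), "RDP")
        sec = _tax({"A1": UNASSIGNED}, "SILVA")
        cons = merge_assignments(prim, sec)
        assert cons.assignments.loc["A1", "phylum"] == "Firmicutes"
        assert cons.assignments.loc["A1", "confidence"] == "unassigned"

    def test_tier_partition_sums_to_total(self):
        tax1, tax2 = generate_taxonomy_pair([f"A{i}" for i in range(400)],
                                            c1=0.5, c2=0.7, agreement=0.6, seed=1)
        cons = merge_assignments(tax1, tax2)
        assert sum(cons.tier_counts().values()) == cons.n_asvs == 400


class TestAssignmentStats:
    def test_rates_from_exact_margins(self):
        tax1, tax2, ids = taxonomy_pair_from_counts(200, 120, 80, 50, seed=0)
        cons = merge_assignments(tax1, tax2, asv_ids=ids)
        st = assignment_stats(cons, tax1, tax2)
        assert st.unassigned_primary == 120 and st.unassigned_secondary == 80
        assert st.unassigned_combined == 50
        assert st.pct_unassigned_primary == pytest.approx(60.0)
        assert st.pct_unassigned_combined == pytest.approx(25.0)

    def test_complementary_databases_leave_nothing_unassigned(self):
        prim = _tax({"A1": "Bacillus", "A2": UNASSIGNED})
        sec = _tax({"A1": UNASSIGNED, "A2": "Massilia"})
        cons = merge_assignments(prim, sec)
        st = assignment_stats(cons, prim, sec)
        assert st.unassigned_combined == 0
        assert st.pct_assigned_combined == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_combined_never_exceeds_single_database(self, seed):
        tax1, tax2 = generate_taxonomy_pair([f"A{i}" for i in range(300)],
                                            c1=0.4, c2=0.6, agreement=0.5, seed=seed)
        cons = merge_assignments(tax1, tax2)
        st = assignment_stats(cons, tax1, tax2)
        assert st.unassigned_combined <= min(st.unassigned_primary,
                                             st.unassigned_secondary)


class TestGenusOverlap:
    def test_identical_and_disjoint_sets(self):
        a = _tax({"A1": "Bacillus", "A2": "Massilia"})
        assert genus_overlap(a, a).n_only_primary == 0
        b = _tax({"A1": "Hymenobacter", "A2": "Deinococcus"})
        assert genus_overlap(a, b).n_shared == 0

    def test_generator_truth_counts(self):
        tax1, tax2 = generate_taxonomy_pair([f"A{i}" for i in range(500)],
                                            c1=0.6, c2=0.6, agreement=0.5, seed=4)
        ov = genus_overlap(tax1, tax2)
        g1, g2 = tax1.genus_names(), tax2.genus_names()
        assert ov.n_shared == len(g1 & g2)
        assert ov.n_only_primary == len(g1 - g2)
        assert ov.n_only_secondary == len(g2 - g1)


class TestConsistency:
    def test_full_agreement_and_degenerate(self):
        a = _tax({"A1": "Bacillus", "A2": "Massilia"})
        table = AsvTable(pd.DataFrame({"A1": [5], "A2": [3]}, index=["S1"]))
        out = consistency_at_genus(a, a, table)
        assert out["overall_fraction"] == 1.0 and out["top_n_fraction"] == 1.0
        empty = _tax({"A1": UNASSIGNED, "A2": UNASSIGNED})
        out2 = consistency_at_genus(a, empty, table)
        assert out2["overall_fraction"] == 0.0 and out2["no_co_assigned_asvs"]

    def test_top_n_ranking_by_reads(self):
        prim = _tax({"A1": "Bacillus", "A2": "Massilia", "A3": "Hymenobacter"})
        sec = _tax({"A1": "Bacillus", "A2": "Other", "A3": "Hymenobacter"})
        table = AsvTable(pd.DataFrame({"A1": [100], "A2": [50], "A3": [1]},
                                      index=["S1"]))
        out = consistency_at_genus(prim, sec, table, top_n=2)
        assert out["top_n_fraction"] == pytest.approx(0.5)   # A1 agrees, A2 not
        assert out["overall_fraction"] == pytest.approx(2 / 3)

    def test_agreement_rate_recovered_within_binomial_ci(self):
        a = 0.5
        ids = [f"A{i}" for i in range(2000)]
        tax1, tax2 = generate_taxonomy_pair(ids, c1=1.0, c2=1.0, agreement=a, seed=8)
        table = AsvTable(pd.DataFrame({i: [1] for i in ids}, index=["S1"]))
        out = consistency_at_genus(tax1, tax2, table, top_n=100)
        se = np.sqrt(a * (1 - a) / 2000)
        assert abs(out["overall_fraction"] - a) < 1.96 * se * 1.5


class TestClosedFormRecovery:
    def test_tier_fractions_near_expectation(self):
        c1, c2, agr = 0.44, 0.62, 0.5
        ids = [f"A{i}" for i in range(3000)]
        tax1, tax2 = generate_taxonomy_pair(ids, c1=c1, c2=c2, agreement=agr, seed=2)
        cons = merge_assignments(tax1, tax2)
        obs = cons.tier_fractions()
        exp = expected_tier_fractions(c1, c2, agr)
        for tier, e in exp.items():
            ci = 1.96 * np.sqrt(e * (1 - e) / len(ids))
            assert abs(obs[tier] - e) < 1.5 * ci, tier
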