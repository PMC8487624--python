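import numpy as np
import pandas as pd
import pytest

from aeroscore.errors import ValidationError
from aeroscore.io_formats import (read_asv_table, read_fasta, read_metadata,
                                  read_taxonomy, write_asv_table, write_fasta,
                                  write_metadata, write_taxonomy)
from aeroscore.synthetic_data import (CommunityConfig, PipelinePairConfig,
                                      generate_community, generate_pipeline_pair,
                                      generate_taxonomy_pair,
                                      overlap_pair_from_counts,
                                      taxonomy_pair_from_counts)


class TestCommunity:
    def test_same_seed_is_byte_identical(self):
        a = generate_community(seed=7)
        b = generate_community(seed=7)
        pd.testing.assert_frame_equal(a.contaminated.counts, b.contaminated.counts)
        pd.testing.assert_frame_equal(a.metadata.frame, b.metadata.frame)
        assert a.sequences == b.sequences

    def test_zero_contamination_tables_are_equal(self):
        cfg = CommunityConfig(n_lab_contaminants=0, n_sampling_contaminants=0,
                              n_dual=0)
        t = generate_community(cfg, seed=1)
        pd.testing.assert_frame_equal(t.contaminated.counts, t.uncontaminated.counts)

    def test_study_shape_defaults(self, community):
        types = community.metadata.frame["sample_type"].value_counts()
        assert types["sample"] == 66
        assert types["sampling_control"] + types["laboratory_control"] == 33
        assert community.metadata.locations()[
            community.metadata.true_samples()].nunique() == 11

    def test_laboratory_controls_carry_contaminants_only(self, community):
        lab = community.metadata.negative_controls("laboratory_only")
        true_cols = community.contaminated.counts.loc[lab, community.true_asvs]
        assert true_cols.to_numpy().sum() == 0

    def test_realized_totals_within_multinomial_ci(self):
        t = generate_community(seed=11)
        samples = t.metadata.true_samples()
        clean = t.uncontaminated.counts.loc[samples, t.true_asvs]
        n_total = clean.to_numpy().sum()
        # per-sample location effects perturb props; check the heaviest ASVs
        # against a conservative 6-sigma binomial band around expectation
        props = t.true_props.sort_values(ascending=False)
        for asv in props.index[t.config.n_dual:12]:
            p = props[asv]
            mean, sd = n_total * p, np.sqrt(n_total * p * (1 - p))
            realized = clean[asv].sum()
            assert abs(realized - mean) < 6 * sd + 0.3 * mean

    def test_concentration_tracks_contamination_inversely(self, community):
        samples = community.metadata.true_samples()
        conc = community.metadata.frame.loc[samples, "dna_concentration"]
        lam = community.contaminant_fraction.loc[samples]
        assert conc.corr(lam, method="spearman") < -0.5

    def test_infeasible_configs_rejected(self):
        with pytest.raises(ValidationError):
            generate_community(CommunityConfig(n_samples=5, n_locations=11), seed=0)
        with pytest.raises(ValidationError):
            generate_community(CommunityConfig(n_dual=4, dual_profile_weight=0.3),
                               seed=0)

    def test_generated_files_validate_under_readers(self, community, tmp_path):
        pair = generate_pipeline_pair(community, seed=2)
        tax1, tax2 = generate_taxonomy_pair(pair.table_a.asv_ids, seed=3)
        write_asv_table(pair.table_a, tmp_path / "t.tsv")
        write_fasta(pair.seqs_a, tmp_path / "s.fasta")
        write_taxonomy(tax1, tmp_path / "x1.tsv")
        write_metadata(community.metadata, tmp_path / "m.tsv")
        meta = read_metadata(tmp_path / "m.tsv")
        table = read_asv_table(tmp_path / "t.tsv", sample_ids=meta.sample_ids)
        assert table.n_asvs == pair.table_a.n_asvs
        assert set(read_fasta(tmp_path / "s.fasta")) == set(pair.seqs_a)
        assert read_taxonomy(tmp_path / "x1.tsv").asv_ids == tax1.asv_ids

    def test_provenance_audit_round_trips(self, community, tmp_path):
        audit = community.provenance()
        p = tmp_path / "audit.tsv"
        audit.to_csv(p, sep="\t")
        again = pd.read_csv(p, sep="\t", index_col=0)
        assert (again["is_dual"].sum() == len(community.dual_asvs))
        assert list(again.index) == community.contaminated.asv_ids


class TestPipelinePair:
    def test_identical_parameters_full_overlap_on_true_asvs(self, community):
        cfg = PipelinePairConfig(retention_a=1.0, retention_b=1.0,
                                 sensitivity_a=1.0, sensitivity_b=1.0,
                                 n_spurious_a=0, n_spurious_b=0)
        pair = generate_pipeline_pair(community, cfg, seed=1)
        assert pair.seqs_a == pair.seqs_b
        pd.testing.assert_frame_equal(pair.table_a.counts, pair.table_b.counts)

    def test_spurious_bookkeeping_is_exact(self, community):
        cfg = PipelinePairConfig(n_spurious_a=40, n_spurious_b=90)
        pair = generate_pipeline_pair(community, cfg, seed=6)
        assert len(pair.spurious_a) == 40 and len(pair.spurious_b) == 90
        assert set(pair.spurious_a) <= set(pair.table_a.asv_ids)
        assert not set(pair.spurious_a) & set(pair.table_b.asv_ids)

    def test_retention_ratio_matches_binomial_thinning(self, community):
        cfg = PipelinePairConfig(retention_a=1.0, retention_b=0.75,
                                 sensitivity_a=1.0, sensitivity_b=1.0,
                                 n_spurious_a=0, n_spurious_b=0)
        pair = generate_pipeline_pair(community, cfg, seed=4)
        ratio = pair.table_a.total_reads / pair.table_b.total_reads
        assert ratio == pytest.approx(4 / 3, rel=0.02)

    def test_shared_true_asvs_carry_identical_sequences(self, community):
        pair = generate_pipeline_pair(community, seed=8)
        shared = set(pair.detected_a) & set(pair.detected_b)
        assert shared
        for asv in list(shared)[:20]:
            assert pair.seqs_a[asv] == pair.seqs_b[asv]


class TestTaxonomyPair:
    def test_full_coverage_full_agreement(self):
        ids = [f"A{i}" for i in range(50)]
        t1, t2 = generate_taxonomy_pair(ids, c1=1.0, c2=1.0, agreement=1.0, seed=0)
        assert (t1.genus() == t2.genus()).all()
        assert t1.assigned_at_genus().all()

    def test_zero_coverage_all_unassigned(self):
        ids = [f"A{i}" for i in range(50)]
        t1, t2 = generate_taxonomy_pair(ids, c1=0.0, c2=0.0, seed=0)
        assert not t1.assigned_at_genus().any()
        assert not t2.assigned_at_genus().any()

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValidationError):
            generate_taxonomy_pair(["A1"], c1=1.5)


class TestCountStructuredFixtures:
    def test_overlap_fixture_margins(self):
        sa, sb = overlap_pair_from_counts(10, 4, 6, seed=0)
        assert len(sa) == 14 and len(sb) == 16
        assert len(set(sa.values()) & set(sb.values())) == 10

    def test_taxonomy_fixture_margins(self):
        t1, t2, ids = taxonomy_pair_from_counts(100, 40, 30, 20, seed=0)
        assert (~t1.assigned_at_genus()).sum() == 40
        assert (~t2.assigned_at_genus()).sum() == 30
        both = (~t1.assigned_at_genus()) & (~t2.assigned_at_genus())
        assert both.sum() == 20

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValidationError):
            taxonomy_pair_from_counts(100, 40, 30, 35, seed=0)
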