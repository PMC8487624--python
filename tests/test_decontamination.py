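import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from aeroscore.community_metrics import bray_curtis
from aeroscore.decontamination import (combination_flags, compare_strategies,
                                       frequency_scores, prevalence_scores,
                                       run_decontamination, subtract_background)
from aeroscore.errors import ValidationError
from aeroscore.io_formats import AsvTable, SampleMetadata
from aeroscore.synthetic_data import CommunityConfig, generate_community


def _meta(samples, controls, control_type="sampling_control", conc=None):
    rows = []
    for i, s in enumerate(samples):
        rows.append({"sample_id": s, "location": "parkA", "sample_type": "sample",
                     "dna_concentration": (conc[i] if conc is not None else np.nan)})
    for c in controls:
        rows.append({"sample_id": c, "location": "control",
                     "sample_type": control_type, "dna_concentration": np.nan})
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))


class TestPrevalence:
    def test_control_exclusive_asv_is_flagged(self):
        n_ctrl, n_samp = 20, 46
        counts = pd.DataFrame(
            {"contam": [5] * n_ctrl + [0] * n_samp,
             "true": [0] * n_ctrl + [9] * n_samp},
            index=[f"C{i}" for i in range(n_ctrl)] + [f"S{i}" for i in range(n_samp)])
        meta = _meta([f"S{i}" for i in range(n_samp)], [f"C{i}" for i in range(n_ctrl)])
        p = prevalence_scores(AsvTable(counts), meta)
        assert p["contam"] < 1e-6
        assert p["true"] == pytest.approx(1.0)

    def test_everywhere_present_asv_not_flagged(self):
        counts = pd.DataFrame({"ubiquitous": [4, 5, 6, 7]},
                              index=["C1", "C2", "S1", "S2"])
        meta = _meta(["S1", "S2"], ["C1", "C2"])
        p = prevalence_scores(AsvTable(counts), meta)
        assert p["ubiquitous"] == pytest.approx(1.0)

    def test_no_controls_is_an_error(self):
        counts = pd.DataFrame({"a": [1, 2]}, index=["S1", "S2"])
        meta = _meta(["S1", "S2"], [])
        with pytest.raises(ValidationError, match="negative control"):
            prevalence_scores(AsvTable(counts), meta)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_fisher_exact_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_ctrl, n_samp = 8, 15
        counts = pd.DataFrame(rng.integers(0, 2, (n_ctrl + n_samp, 12)),
                              index=[f"C{i}" for i in range(n_ctrl)]
                              + [f"S{i}" for i in range(n_samp)],
                              columns=[f"A{j}" for j in range(12)])
        meta = _meta([f"S{i}" for i in range(n_samp)], [f"C{i}" for i in range(n_ctrl)])
        table = AsvTable(counts)
        ours = prevalence_scores(table, meta)
        present = counts > 0
        for a in table.asv_ids:
            k_c = int(present.loc[[f"C{i}" for i in range(n_ctrl)], a].sum())
            k_s = int(present.loc[[f"S{i}" for i in range(n_samp)], a].sum())
            _, p_ref = fisher_exact([[k_c, n_ctrl - k_c], [k_s, n_samp - k_s]],
                                    alternative="greater")
            assert ours[a] == pytest.approx(p_ref, abs=1e-10)


class TestFrequency:
    def test_inverse_relationship_is_flagged(self):
        n = 20
        conc = np.linspace(1, 10, n)
        contam = (1000 / conc).astype(int)
        other = np.full(n, 500)
        counts = pd.DataFrame({"contam": contam, "other": other},
                              index=[f"S{i}" for i in range(n)])
        meta = _meta(list(counts.index), [], conc=conc)
        p = frequency_scores(AsvTable(counts), meta)
        assert p["contam"] < 0.01
        assert p["other"] > 0.1

    def test_presence_minimum_gives_absent_score(self):
        conc = np.linspace(1, 5, 8)
        counts = pd.DataFrame({"rare": [3, 2, 1, 0, 0, 0, 0, 0],
                               "common": [5] * 8},
                              index=[f"S{i}" for i in range(8)])
        meta = _meta(list(counts.index), [], conc=conc)
        p = frequency_scores(AsvTable(counts), meta)
        assert np.isnan(p["rare"]) and not np.isnan(p["common"])

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(0)
        n, n_asvs = 40, 150
        counts = pd.DataFrame(rng.integers(1, 50, (n, n_asvs)),
                              index=[f"S{i}" for i in range(n)],
                              columns=[f"A{j}" for j in range(n_asvs)])
        meta = _meta(list(counts.index), [], conc=rng.uniform(1, 10, n))
        p = frequency_scores(AsvTable(counts), meta).dropna()
        assert 0.35 < p.mean() < 0.65
        assert (p < 0.1).mean() < 0.2

    def test_missing_concentrations_is_an_error(self):
        counts = pd.DataFrame({"a": [1] * 6}, index=[f"S{i}" for i in range(6)])
        meta = _meta(list(counts.index), [])
        with pytest.raises(ValidationError, match="concentration"):
            frequency_scores(AsvTable(counts), meta)


class TestCombination:
    def test_reference_values(self):
        prev = pd.Series({"a": 0.5, "b": 1.0, "c": 1e-6})
        freq = pd.Series({"a": 0.5, "b": 1.0, "c": np.nan})
        out = combination_flags(prev, freq, threshold=0.1)
        # chi^2_4 tail of -2(ln .5 + ln .5) = 2.7726
        assert out.loc["a", "combined_p"] == pytest.approx(0.5965735902799727)
        assert not out.loc["a", "flagged"]
        assert out.loc["b", "combined_p"] == pytest.approx(1.0)
        assert out.loc["c", "combined_p"] == pytest.approx(1e-6)   # pass-through
        assert out.loc["c", "flagged"]


class TestSubtraction:
    def test_zero_background_is_identity_on_samples(self):
        counts = pd.DataFrame({"a": [10, 20, 0], "b": [1, 2, 0]},
                              index=["S1", "S2", "C1"])
        meta = _meta(["S1", "S2"], ["C1"])
        with pytest.warns(UserWarning, match="zero-read control"):
            res = subtract_background(AsvTable(counts), meta)
        pd.testing.assert_frame_equal(res.corrected.counts,
                                      counts.loc[["S1", "S2"]],
                                      check_names=False)
        assert res.total_removed() == 0

    def test_profile_scaling_and_floor(self):
        # control profile: ASV a at 10%; sample S1 has 1000 reads, 150 of them a
        counts = pd.DataFrame(
            {"a": [150, 80, 10], "b": [850, 920, 90]},
            index=["S1", "S2", "C1"])
        meta = _meta(["S1", "S2"], ["C1"])
        res = subtract_background(AsvTable(counts), meta)
        assert res.corrected.counts.loc["S1", "a"] == 50    # 150 - 0.1*1000
        assert res.corrected.counts.loc["S2", "a"] == 0     # 80 - 100 floored
        assert res.reads_removed["a"] == 100 + 80

    def test_never_increases_and_conserves_reads(self, community):
        res = subtract_background(community.contaminated, community.metadata)
        samples = [s for s in community.metadata.true_samples()]
        before = community.contaminated.counts.loc[samples]
        after = res.corrected.counts.reindex(columns=before.columns, fill_value=0)
        assert (after.to_numpy() <= before.to_numpy()).all()
        assert res.total_removed() == before.to_numpy().sum() - after.to_numpy().sum()
        assert set(res.corrected.sample_ids) == set(samples)

    def test_no_controls_is_an_error(self):
        counts = pd.DataFrame({"a": [1, 2]}, index=["S1", "S2"])
        with pytest.raises(ValidationError, match="control"):
            subtract_background(AsvTable(counts), _meta(["S1", "S2"], []))


class TestComparator:
    def test_fully_adjusted_flags_leave_no_missed_contaminants(self):
        counts = pd.DataFrame({"contam": [100, 120, 300, 280],
                               "true": [900, 880, 0, 0]},
                              index=["S1", "S2", "C1", "C2"])
        meta = _meta(["S1", "S2"], ["C1", "C2"])
        table = AsvTable(counts)
        sub = subtract_background(table, meta)
        flags = pd.Series({"contam": True, "true": False})
        comp = compare_strategies(flags, sub, table, meta,
                                  high_abundance_threshold=400)
        assert comp.missed_high_abundance == []
        assert comp.n_flagged_by_both == 1

    def test_generator_truth_lab_only_and_dual(self, community):
        res = run_decontamination(community.contaminated, community.metadata)
        # pure laboratory contaminants surface as deletion candidates
        assert set(community.lab_only_contaminants) <= set(
            res.comparison.laboratory_deletion_candidates)
        # dual-membership ASVs: flagged for removal, partially reduced only
        for d in community.dual_asvs:
            assert res.scores.loc[d, "flagged"]
            assert res.subtraction.reads_removed[d] > 0
            assert res.subtraction.corrected.counts[d].sum() > 0

    def test_subtraction_moves_samples_toward_truth(self, community):
        res = subtract_background(community.contaminated, community.metadata)
        clean = community.uncontaminated.counts
        corrected = res.corrected.counts.reindex(
            columns=community.contaminated.asv_ids, fill_value=0)
        improved = 0
        samples = community.metadata.true_samples()
        for s in samples:
            bc_contam = bray_curtis(community.contaminated.counts.loc[s], clean.loc[s])
            bc_corr = bray_curtis(corrected.loc[s], clean.loc[s])
            improved += bc_corr < bc_contam
        assert improved >= 0.9 * len(samples)

    def test_null_contamination_has_low_false_positive_rate(self):
        cfg = CommunityConfig(n_lab_contaminants=0, n_sampling_contaminants=0,
                              n_dual=0)
        truth = generate_community(cfg, seed=3)
        res = run_decontamination(truth.contaminated, truth.metadata)
        fp = res.scores.loc[truth.true_asvs, "flagged"].mean()
        assert fp < 0.05
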