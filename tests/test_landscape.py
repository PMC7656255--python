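"""Frequency tables, hotspot detection, mutation load and VAF statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from oncopanel.landscape import (
    cnv_frequency,
    detect_hotspots,
    gene_frequency,
    mutation_load,
    vaf_summary,
)
from oncopanel.model import ClinicalSample, Cohort, CopyNumberCall, SomaticMutation


def _sample(i, subtype_kwargs=None):
    kw = subtype_kwargs or dict(er_positive=True, pr_positive=True,
                                her2_positive=False, ki67_fraction=0.10)
    return ClinicalSample(f"S{i}", f"P{i}", **kw)


def _mut(sid, gene="TP53", pchange=None, vaf_counts=(30, 70), pos=100):
    return SomaticMutation(sid, gene, "1", pos, "G", "A", protein_change=pchange,
                           t_alt_count=vaf_counts[0], t_ref_count=vaf_counts[1])


class TestGeneFrequency:
    def test_601_of_1134_reports_53_percent(self):
        samples = [_sample(i) for i in range(1134)]
        somatic = [_mut(f"S{i}") for i in range(601)]
        freq = gene_frequency(Cohort(samples=samples, somatic=somatic))
        f = freq.loc[freq.feature == "TP53", "frequency"].item()
        assert f == pytest.approx(601 / 1134)
        assert round(100 * f, 1) == 53.0

    def test_gene_absent_from_group_keeps_zero_row(self):
        tn = dict(er_positive=False, pr_positive=False, her2_positive=False)
        samples = [_sample(0), ClinicalSample("S1", "P1", **tn)]
        freq = gene_frequency(Cohort(samples=samples, somatic=[_mut("S0")]), "subtype")
        tn_row = freq[(freq.feature == "TP53") & (freq.group == "triple_negative")]
        assert tn_row["n_altered"].item() == 0 and tn_row["frequency"].item() == 0.0

    def test_single_group_equals_ungrouped(self):
        cohort = Cohort(samples=[_sample(i) for i in range(10)],
                        somatic=[_mut("S0"), _mut("S1")])
        by_subtype = gene_frequency(cohort, "subtype")
        ungrouped = gene_frequency(cohort, "none")
        assert by_subtype["frequency"].tolist() == ungrouped["frequency"].tolist()

    def test_empty_cohort_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            gene_frequency(Cohort(samples=[]))

    def test_row_order_invariant_under_input_permutation(self, small_cohort):
        shuffled = Cohort(samples=small_cohort.samples,
                          somatic=list(reversed(small_cohort.somatic)))
        a = gene_frequency(small_cohort, "subtype")
        b = gene_frequency(shuffled, "subtype")
        assert a.equals(b)


class TestHotspots:
    def test_threshold_rule(self):
        muts = [_mut(f"S{i}", "PIK3CA", "p.H1047R") for i in range(30)]
        muts += [_mut(f"T{i}", "AKT1", "p.E17K") for i in range(10)]
        hs = detect_hotspots(muts, 1000, 0.02)
        assert [(h.gene_symbol, h.n_samples) for h in hs] == [("PIK3CA", 30)]
        assert hs[0].frequency == pytest.approx(0.03)

    def test_duplicate_calls_in_one_sample_count_once(self):
        muts = [_mut("S1", "PIK3CA", "p.H1047R", pos=100),
                _mut("S1", "PIK3CA", "p.H1047R", pos=100)]
        hs = detect_hotspots(muts, 10, 0.02)
        assert hs[0].n_samples == 1

    def test_monotone_in_threshold(self, small_cohort):
        n = len(small_cohort.samples)
        loose = {(h.gene_symbol, h.protein_change)
                 for h in detect_hotspots(small_cohort.somatic, n, 0.02)}
        strict = {(h.gene_symbol, h.protein_change)
                  for h in detect_hotspots(small_cohort.somatic, n, 0.05)}
        assert strict <= loose

    def test_sorted_by_frequency_then_name(self):
        muts = [_mut(f"S{i}", "B", "p.A1V") for i in range(5)]
        muts += [_mut(f"S{i}", "A", "p.A2V") for i in range(5)]
        muts += [_mut(f"S{i}", "C", "p.A3V") for i in range(9)]
        hs = detect_hotspots(muts, 100, 0.02)
        assert [(h.gene_symbol) for h in hs] == ["C", "A", "B"]


class TestMutationLoad:
    def test_identical_groups_give_p_one(self):
        lum = dict(er_positive=True, pr_positive=True, her2_positive=False,
                   ki67_fraction=0.10)
        tn = dict(er_positive=False, pr_positive=False, her2_positive=False)
        samples = ([ClinicalSample(f"A{i}", f"A{i}", **lum) for i in range(3)]
                   + [ClinicalSample(f"B{i}", f"B{i}", **tn) for i in range(3)])
        somatic = [_mut(s.sample_id, gene=g, pos=p)
                   for s in samples for g, p in (("G1", 1), ("G2", 2))]
        _, summary = mutation_load(Cohort(samples=samples, somatic=somatic))
        assert summary["p_value"] == pytest.approx(1.0)
        assert set(summary["medians"].values()) == {2.0}

    def test_separated_groups_match_rank_statistic_oracle(self):
        """Kruskal-Wallis H for {1,1,1} vs {10,10,10} against direct rank arithmetic."""
        lum = dict(er_positive=True, pr_positive=True, her2_positive=False,
                   ki67_fraction=0.10)
        tn = dict(er_positive=False, pr_positive=False, her2_positive=False)
        samples = ([ClinicalSample(f"A{i}", f"A{i}", **lum) for i in range(3)]
                   + [ClinicalSample(f"B{i}", f"B{i}", **tn) for i in range(3)])
        somatic = [_mut(s.sample_id, gene="G1", pos=1) for s in samples]
        for s in samples[3:]:
            somatic += [_mut(s.sample_id, gene=f"G{k}", pos=k) for k in range(2, 11)]
        _, summary = mutation_load(Cohort(samples=samples, somatic=somatic))
        # oracle: ranks are {2,2,2} and {5,5,5}; H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2,
        # tie-corrected by 1 - sum(t^3-t)/(N^3-N) with two tie groups of size 3
        h_raw = 12 / (6 * 7) * (3 * 1.5**2 + 3 * 1.5**2)
        h = h_raw / (1 - (2 * (27 - 3)) / (216 - 6))
        assert summary["p_value"] == pytest.approx(float(sps.chi2.sf(h, df=1)), rel=1e-9)
        assert summary["medians"] == {"luminal_A": 1.0, "triple_negative": 10.0}

    def test_single_group_marked_not_applicable(self):
        cohort = Cohort(samples=[_sample(i) for i in range(3)], somatic=[_mut("S0")])
        _, summary = mutation_load(cohort)
        assert summary["p_value"] is None and "not applicable" in summary["note"]

    def test_empty_cohort_is_error(self):
        with pytest.raises(ValueError):
            mutation_load(Cohort(samples=[]))


class TestVafSummary:
    def test_single_gene_median(self):
        muts = [_mut("S1", "G", vaf_counts=(10, 90)), _mut("S2", "G", vaf_counts=(30, 70)),
                _mut("S3", "G", vaf_counts=(50, 50))]
        table, p = vaf_summary(muts, ["G"])
        assert table.loc[0, "median"] == pytest.approx(0.30)
        assert p is None

    def test_identical_multisets_give_p_one(self):
        muts = [_mut(f"S{i}", "G1", vaf_counts=(k, 100 - k)) for i, k in enumerate((10, 30, 50))]
        muts += [_mut(f"T{i}", "G2", vaf_counts=(k, 100 - k)) for i, k in enumerate((10, 30, 50))]
        _, p = vaf_summary(muts, ["G1", "G2"])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_shifted_sets_match_hand_h_statistic(self):
        """Three genes with disjoint VAF ranges: p from the H formula directly."""
        sets = {"G1": (5, 10, 15), "G2": (40, 45, 50), "G3": (80, 85, 90)}
        muts = [_mut(f"{g}{i}", g, vaf_counts=(k, 100 - k))
                for g, ks in sets.items() for i, k in enumerate(ks)]
        _, p = vaf_summary(muts, list(sets))
        # no ties: ranks are 1..9 in known blocks; H = 12/(N(N+1)) sum n R^2/n - 3(N+1)
        rank_sums = {"G1": 1 + 2 + 3, "G2": 4 + 5 + 6, "G3": 7 + 8 + 9}
        h = 12 / (9 * 10) * sum(r**2 / 3 for r in rank_sums.values()) - 3 * 10
        assert p == pytest.approx(float(sps.chi2.sf(h, df=2)), rel=1e-9)

    def test_gene_without_mutations_listed_empty_and_excluded(self):
        muts = [_mut("S1", "G1", vaf_counts=(30, 70))]
        table, p = vaf_summary(muts, ["G1", "G2"])
        empty = table[table.gene == "G2"].iloc[0]
        assert empty["n"] == 0 and np.isnan(empty["median"])

    def test_empty_gene_list_is_error(self):
        with pytest.raises(ValueError):
            vaf_summary([], [])


class TestCnvFrequency:
    def test_fraction_of_evaluable_samples(self):
        samples = [_sample(i) for i in range(100)]
        calls = [CopyNumberCall(f"S{i}", "ERBB2", "amplification") for i in range(25)]
        freq = cnv_frequency(calls, samples)
        amp = freq[(freq.feature == "ERBB2") & (freq.call == "amplification")]
        assert amp["frequency"].item() == pytest.approx(0.25)

    def test_deletion_only_gene_reports_zero_amplification(self):
        samples = [_sample(i) for i in range(10)]
        calls = [CopyNumberCall("S0", "PTEN", "deletion")]
        freq = cnv_frequency(calls, samples)
        amp = freq[(freq.feature == "PTEN") & (freq.call == "amplification")]
        assert amp["frequency"].item() == 0.0

    def test_denominator_is_evaluable_subset(self):
        samples = [_sample(i) for i in range(20)]
        evaluable = {f"S{i}" for i in range(10)}
        calls = [CopyNumberCall(f"S{i}", "MYC", "amplification") for i in range(5)]
        freq = cnv_frequency(calls, samples, evaluable_ids=evaluable)
        amp = freq[(freq.feature == "MYC") & (freq.call == "amplification")]
        assert amp["n_total"].item() == 10
        assert amp["frequency"].item() == pytest.approx(0.5)
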