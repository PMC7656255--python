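"""Rare-variant prefilter, evidence scoring, classification and cohort summaries."""

import numpy as np
import pytest
from scipy import stats as sps

from oncopanel.germline import (
    GeneContext,
    _rx2_exact_p,
    carrier_summary,
    classify,
    classify_variants,
    germline_cohort_compare,
    prefilter_rare,
    score_evidence,
)
from oncopanel.model import Classification, ClinvarStatus, Consequence, GermlineVariant
from oncopanel.simulate import golden_germline_set


def _variant(**kw):
    base = dict(patient_id="p1", gene_symbol="BRCA1", chrom="17", pos=100, ref="A", alt="T",
                consequence=Consequence.missense)
    base.update(kw)
    return GermlineVariant(**base)


class TestPrefilterRare:
    def test_threshold_semantics(self):
        common = _variant(af_eas=0.006)
        rare = _variant(af_eas=0.004)
        missing = _variant(af_eas=None)
        boundary = _variant(af_eas=0.005)
        kept, removed = prefilter_rare([common, rare, missing, boundary])
        assert removed == [common, boundary]  # af >= 0.5% is not rare
        assert kept == [rare, missing]  # absence from the database implies rarity

    def test_order_independence(self):
        variants = [_variant(af_eas=v) for v in (0.01, 0.001, None, 0.004, 0.2)]
        kept_fwd, _ = prefilter_rare(variants)
        kept_rev, _ = prefilter_rare(list(reversed(variants)))
        assert {id(v) for v in kept_fwd} == {id(v) for v in kept_rev}

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            prefilter_rare([], max_eas_af=0.0)


LOF = GeneContext("g", is_cancer_gene=True, lof_mechanism=True)


class TestScoreEvidence:
    def test_truncating_in_lof_cancer_gene_fires_pvs1(self):
        v = _variant(consequence=Consequence.frameshift)
        evidence, score = score_evidence(v, LOF)
        assert ("PVS1", 8) in evidence and score >= 8

    def test_unsupported_missense_scores_zero(self):
        evidence, score = score_evidence(_variant(), LOF)
        assert evidence == [] and score == 0

    def test_pm5_fires_without_ps1_for_novel_missense_at_known_residue(self):
        v = _variant(same_residue_known_pathogenic=True)
        evidence, score = score_evidence(v, LOF)
        codes = [c for c, _ in evidence]
        assert codes == ["PM5"] and score == 2

    def test_ps1_preempts_pm5(self):
        v = _variant(same_aa_known_pathogenic=True, same_residue_known_pathogenic=True)
        evidence, score = score_evidence(v, LOF)
        assert [c for c, _ in evidence] == ["PS1"] and score == 7

    def test_pm2_never_fires(self):
        for golden_variant, ctx, _expected in golden_germline_set():
            evidence, _ = score_evidence(golden_variant, ctx)
            assert all(code != "PM2" for code, _ in evidence)

    def test_truncating_outside_lof_mechanism_does_not_fire(self):
        v = _variant(consequence=Consequence.stop_gained)
        _, score = score_evidence(v, GeneContext("g", True, False))
        assert score == 0


class TestClassify:
    def test_clinvar_cancer_pathogenic_wins_regardless_of_score(self):
        v = _variant(clinvar_status=ClinvarStatus.pathogenic_cancer)
        v.score = 0
        assert classify(v) is Classification.pathogenic

    def test_score_cutoff_is_strict(self):
        v = _variant()
        v.score = 8
        assert classify(v) is Classification.likely_pathogenic
        v.score = 7
        assert classify(v) is Classification.uncertain

    def test_monotone_in_score(self):
        rank = {Classification.uncertain: 0, Classification.likely_pathogenic: 1,
                Classification.pathogenic: 2}
        previous = -1
        for score in range(0, 12):
            v = _variant()
            v.score = score
            assert rank[classify(v)] >= previous
            previous = rank[classify(v)]

    def test_golden_set_classifies_exactly(self):
        for i, (variant, ctx, expected) in enumerate(golden_germline_set()):
            score_evidence(variant, ctx)
            assert classify(variant) is expected, f"golden case {i}"


class TestCarrierSummary:
    def test_printed_percent_arithmetic(self):
        variants = []
        for i in range(66):
            v = _variant(patient_id=f"P{i}", consequence=Consequence.frameshift)
            score_evidence(v, LOF)
            classify(v)
            variants.append(v)
        n, frac, per_gene = carrier_summary(variants, 1134)
        assert n == 66 and round(100 * frac, 1) == 5.8

    def test_zero_carriers(self):
        v = _variant()
        classify_variants([v], {"BRCA1": GeneContext("BRCA1", False, False)})
        n, frac, per_gene = carrier_summary([v], 10)
        assert (n, frac, per_gene) == (0, 0.0, {})

    def test_patient_with_two_genes_counts_once_overall(self):
        v1 = _variant(patient_id="P1", gene_symbol="BRCA1",
                      consequence=Consequence.frameshift)
        v2 = _variant(patient_id="P1", gene_symbol="TP53",
                      consequence=Consequence.frameshift)
        classify_variants([v1, v2], {"BRCA1": LOF, "TP53": LOF})
        n, _, per_gene = carrier_summary([v1, v2], 100)
        assert n == 1 and per_gene == {"BRCA1": 1, "TP53": 1}


class TestCohortCompare:
    def test_identical_frequencies_give_p_near_one(self):
        res = germline_cohort_compare({"BRCA2": [(10, 1000), (10, 1000), (10, 1000)]})
        assert res.iloc[0]["p_value"] > 0.99

    def test_contrast_matches_chi_square_oracle(self):
        ks, ns = (25, 23, 10), (1134, 1122, 515)
        res = germline_cohort_compare({"BRCA2": [(k, n) for k, n in zip(ks, ns)]})
        # hand-built Pearson chi-square on the 2x3 table
        table = np.array([ks, [n - k for k, n in zip(ks, ns)]], dtype=float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2 = ((table - expected) ** 2 / expected).sum()
        p_oracle = float(sps.chi2.sf(chi2, df=2))
        assert res.iloc[0]["method"] == "chi2"
        assert res.iloc[0]["p_value"] == pytest.approx(p_oracle, rel=1e-9)

    def test_exact_path_agrees_with_fisher_on_two_populations(self):
        res = germline_cohort_compare({"G": [(1, 20), (5, 9)]})
        assert res.iloc[0]["method"] == "freeman_halton"
        p_fisher = sps.fisher_exact([[1, 19], [5, 4]])[1]
        assert res.iloc[0]["p_value"] == pytest.approx(p_fisher, rel=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError, match="2 populations"):
            germline_cohort_compare({"G": [(1, 10)]})
        with pytest.raises(ValueError, match="n_total=0"):
            germline_cohort_compare({"G": [(1, 10), (0, 0)]})


def test_rx2_exact_matches_fisher_on_2x2_grid():
    """The Freeman-Halton enumeration reduces to Fisher's test for two groups."""
    for a, n1, b, n2 in [(1, 8, 5, 9), (0, 10, 4, 12), (3, 6, 3, 6), (2, 15, 9, 14)]:
        p = _rx2_exact_p([a, b], [n1, n2])
        p_ref = sps.fisher_exact([[a, n1 - a], [b, n2 - b]])[1]
        assert p == pytest.approx(p_ref, rel=1e-9), (a, n1, b, n2)
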