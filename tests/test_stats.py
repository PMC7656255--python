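"""Fisher/BH machinery against independent enumeration oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncopanel.model import ClinicalSample
from oncopanel.stats import (
    bh_fdr,
    cohort_compare,
    covariate_enrichment,
    fisher_exact_2x2,
    or_confidence_interval,
    subtype_enrichment,
)


def brute_force_fisher_p(a, b, c, d):
    """Oracle: enumerate every 2x2 table with the observed margins and sum
    the hypergeometric probabilities of tables no more likely than observed."""
    r1, c1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (math.comb(c1, x) * math.comb(n - c1, r1 - x)) / math.comb(n, r1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


class TestFisher:
    def test_symmetric_table(self):
        oddsr, p = fisher_exact_2x2(5, 5, 5, 5)
        assert oddsr == pytest.approx(1.0) and p == pytest.approx(1.0)

    def test_perfect_separation_closed_form(self):
        # only two equally extreme tables out of C(20,10) arrangements
        _, p = fisher_exact_2x2(10, 0, 0, 10)
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_cross_product_odds_ratio(self):
        oddsr, _ = fisher_exact_2x2(20, 80, 10, 90)
        assert oddsr == pytest.approx(2.25)

    def test_zero_cell_odds_ratios(self):
        assert fisher_exact_2x2(5, 0, 3, 10)[0] == np.inf
        assert fisher_exact_2x2(0, 5, 3, 10)[0] == 0.0
        assert np.isnan(fisher_exact_2x2(0, 5, 0, 10)[0])

    def test_all_zero_table_is_error(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 0, 0)

    def test_matches_enumeration_oracle_small_tables(self):
        """Exhaustive agreement with the hypergeometric oracle for N <= 14
        (the full N <= 40 sweep runs in the acceptance suite)."""
        worst = 0.0
        for n in range(1, 15):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        _, p = fisher_exact_2x2(a, b, c, d)
                        worst = max(worst, abs(p - brute_force_fisher_p(a, b, c, d)))
        assert worst < 1e-9

    @given(st.tuples(*(st.integers(0, 30),) * 4).filter(lambda t: sum(t) > 0))
    @settings(max_examples=150, deadline=None)
    def test_symmetry_invariance(self, table):
        """p is invariant under row swap, column swap and transpose."""
        a, b, c, d = table
        p = fisher_exact_2x2(a, b, c, d)[1]
        assert fisher_exact_2x2(c, d, a, b)[1] == pytest.approx(p, rel=1e-12)
        assert fisher_exact_2x2(b, a, d, c)[1] == pytest.approx(p, rel=1e-12)
        assert fisher_exact_2x2(a, c, b, d)[1] == pytest.approx(p, rel=1e-12)


class TestOrConfidenceInterval:
    def test_hand_evaluated_woolf_interval(self):
        # ln 2.25 +/- 1.96 * sqrt(1/20+1/80+1/10+1/90)
        lo, hi = or_confidence_interval(20, 80, 10, 90)
        assert lo == pytest.approx(0.9943, abs=2e-3)
        assert hi == pytest.approx(5.0917, abs=2e-3)

    def test_symmetric_table_contains_one(self):
        lo, hi = or_confidence_interval(5, 5, 5, 5)
        assert lo < 1 < hi

    def test_zero_cell_gives_finite_interval(self):
        lo, hi = or_confidence_interval(10, 0, 5, 15)
        assert np.isfinite(lo) and np.isfinite(hi) and lo > 0


class TestBhFdr:
    def test_single_p_is_identity(self):
        assert bh_fdr([0.03]).tolist() == [pytest.approx(0.03)]

    def test_hand_evaluated_step_up(self):
        # q_i = min over j>=i of p_(j) * m / j = 0.04 for every rank here
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx([0.04] * 4)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20),
           st.randoms(use_true_random=False))
    @settings(max_examples=100, deadline=None)
    def test_permutation_equivariance(self, ps, rnd):
        idx = list(range(len(ps)))
        rnd.shuffle(idx)
        q = bh_fdr(ps)
        q_shuffled = bh_fdr([ps[i] for i in idx])
        for orig_pos, new_pos in enumerate(idx):
            assert q_shuffled[orig_pos] == pytest.approx(q[new_pos], rel=1e-12)


def _subtyped(sid, subtype):
    ihc = {
        "luminal_A": dict(er_positive=True, pr_positive=True, her2_positive=False,
                          ki67_fraction=0.10),
        "triple_negative": dict(er_positive=False, pr_positive=False, her2_positive=False),
        "HER2pos": dict(er_positive=False, pr_positive=False, her2_positive=True),
    }[subtype]
    return ClinicalSample(sid, sid, **ihc)


class TestSubtypeEnrichment:
    def _matrix_and_samples(self, in_group, group_n, elsewhere, rest_n):
        import pandas as pd

        samples = ([_subtyped(f"A{i}", "triple_negative") for i in range(group_n)]
                   + [_subtyped(f"B{i}", "luminal_A") for i in range(rest_n)])
        values = [1] * in_group + [0] * (group_n - in_group) \
            + [1] * elsewhere + [0] * (rest_n - elsewhere)
        matrix = pd.DataFrame({"GENE": values},
                              index=[s.sample_id for s in samples]).astype("int8")
        return matrix, samples

    def test_strong_enrichment_flagged(self):
        matrix, samples = self._matrix_and_samples(30, 50, 5, 150)
        results = subtype_enrichment(matrix, samples, fdr_threshold=0.25)
        tn = [r for r in results if r.group_label == "triple_negative"][0]
        assert (tn.a, tn.b, tn.c, tn.d) == (30, 20, 5, 145)
        assert tn.significant and tn.odds_ratio > 1

    def test_uniform_frequency_not_flagged(self):
        matrix, samples = self._matrix_and_samples(10, 50, 30, 150)  # 20% everywhere
        results = subtype_enrichment(matrix, samples)
        assert not any(r.significant for r in results)

    def test_single_comparison_q_equals_p(self):
        import pandas as pd

        samples = [_subtyped("A0", "triple_negative"), _subtyped("B0", "luminal_A")]
        matrix = pd.DataFrame({"G": [1, 0]}, index=["A0", "B0"]).astype("int8")
        results = subtype_enrichment(matrix, samples)
        by_group = {r.group_label: r for r in results}
        # two symmetric one-vs-rest rows share the same p; BH over them keeps q >= p
        assert all(r.q_value == pytest.approx(max(x.p_value for x in results))
                   for r in results)


class TestCohortCompare:
    def _freq(self, rows):
        import pandas as pd

        return pd.DataFrame(rows, columns=["feature", "n_altered", "n_total"])

    def test_or_and_significance(self):
        res, unshared = cohort_compare(
            self._freq([("G", 20, 100)]), self._freq([("G", 5, 100)]))
        r = res[0]
        assert r.odds_ratio == pytest.approx((20 * 95) / (80 * 5))
        assert r.p_value == pytest.approx(brute_force_fisher_p(20, 80, 5, 95), rel=1e-9)

    def test_identical_cohorts_null(self):
        table = self._freq([("G1", 20, 100), ("G2", 5, 100)])
        res, _ = cohort_compare(table, table.copy())
        assert all(r.odds_ratio == pytest.approx(1.0) for r in res)
        assert not any(r.significant for r in res)

    def test_unshared_features_reported(self):
        res, unshared = cohort_compare(
            self._freq([("G1", 5, 50), ("ONLY_A", 3, 50)]),
            self._freq([("G1", 5, 50), ("ONLY_B", 2, 40)]))
        assert set(unshared.feature) == {"ONLY_A", "ONLY_B"}
        assert len(res) == 1


class TestCovariateEnrichment:
    def _samples(self, n_post, n_pre, n_missing=0):
        from oncopanel.model import Menopause

        out = []
        for i in range(n_post + n_pre + n_missing):
            s = _subtyped(f"S{i}", "luminal_A")
            s.menopause = (Menopause.post if i < n_post
                           else Menopause.pre if i < n_post + n_pre else Menopause.missing)
            out.append(s)
        return out

    def test_menopause_enrichment_flagged(self):
        import pandas as pd

        samples = self._samples(100, 100)
        values = [1] * 40 + [0] * 60 + [1] * 10 + [0] * 90
        matrix = pd.DataFrame({"PI3K_GENE": values},
                              index=[s.sample_id for s in samples]).astype("int8")
        results = covariate_enrichment(matrix, samples, "menopause")
        post = [r for r in results if r.group_label == "post"][0]
        assert post.significant and post.odds_ratio > 1

    def test_all_missing_covariate_is_error(self):
        import pandas as pd

        samples = self._samples(0, 0, 10)
        matrix = pd.DataFrame({"G": [0] * 10},
                              index=[s.sample_id for s in samples]).astype("int8")
        with pytest.raises(ValueError, match="fewer than 2"):
            covariate_enrichment(matrix, samples, "menopause")

    def test_one_empty_group_is_error(self):
        import pandas as pd

        samples = self._samples(5, 0)
        matrix = pd.DataFrame({"G": [1, 0, 1, 0, 0]},
                              index=[s.sample_id for s in samples]).astype("int8")
        with pytest.raises(ValueError):
            covariate_enrichment(matrix, samples, "menopause")
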