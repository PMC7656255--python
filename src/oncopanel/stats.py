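"""Inferential machinery: Fisher exact tests, odds-ratio confidence
intervals, Benjamini-Hochberg FDR, and the enrichment analyses built on
them (subtype enrichment one-vs-rest, two-cohort frequency comparison,
clinical-covariate enrichment).

Conventions: two-sided Fisher p sums all tables with point probability at
most that of the observed table; the odds ratio is the sample cross-product
(a*d)/(b*c) with +inf / 0 at zero cells; its 95% CI is the Woolf logit
interval with a Haldane-Anscombe +0.5 correction applied to every cell when
any cell is zero.  The odds ratio is oriented so that OR > 1 means enriched
in the first-named group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    feature: str
    group_label: str
    a: int  # altered in group
    b: int  # unaltered in group
    c: int  # altered elsewhere
    d: int  # unaltered elsewhere
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    q_value: float = np.nan
    significant: bool = False
    extra: dict = field(default_factory=dict)


def fisher_exact_2x2(a: int, b: int, c: int, d: int):
    """Two-sided Fisher exact test on a 2x2 table.

    Returns ``(odds_ratio, p_two_sided)`` where the odds ratio is the
    cross-product ratio: +inf when b*c == 0 with a*d > 0, 0 when a*d == 0
    with b*c > 0, and NaN when both products vanish.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells) or any(int(x) != x for x in cells):
        raise ValueError(f"cells must be nonnegative integers, got {cells}")
    if sum(cells) == 0:
        raise ValueError("all-zero 2x2 table")
    ad, bc = a * d, b * c
    if bc == 0:
        oddsr = np.nan if ad == 0 else np.inf
    else:
        oddsr = ad / bc
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(oddsr) if np.isfinite(oddsr) or np.isnan(oddsr) else np.inf, float(p)


def or_confidence_interval(a: int, b: int, c: int, d: int, level: float = 0.95):
    """Woolf logit confidence interval for the 2x2 odds ratio.

    With any zero cell, the Haldane-Anscombe correction adds 0.5 to all
    four cells first, keeping the interval finite.
    """
    z = stats.norm.ppf(0.5 + level / 2)
    aa, bb, cc, dd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if 0 in (a, b, c, d) else (a, b, c, d)
    )
    log_or = np.log((aa * dd) / (bb * cc))
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    return float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def bh_fdr(p_values):
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _one_vs_rest(matrix: pd.DataFrame, groups: dict, fdr_threshold: float) -> list:
    """Fisher one-vs-rest enrichment of each feature in each group; one BH family."""
    results = []
    all_ids = set(matrix.index)
    for label, ids in sorted(groups.items()):
        ids = [i for i in ids if i in all_ids]
        if not ids:
            log.info("enrichment: group %r has no samples, excluded", label)
            continue
        rest = sorted(all_ids - set(ids))
        in_group = matrix.loc[ids]
        out_group = matrix.loc[rest]
        for feature in matrix.columns:
            a = int(in_group[feature].sum())
            b = len(ids) - a
            c = int(out_group[feature].sum())
            d = len(rest) - c
            oddsr, p = fisher_exact_2x2(a, b, c, d)
            lo, hi = or_confidence_interval(a, b, c, d)
            results.append(EnrichmentResult(feature, str(label), a, b, c, d, oddsr, lo, hi, p))
    _attach_q(results, fdr_threshold)
    return results


def _attach_q(results: list, fdr_threshold: float) -> None:
    if not results:
        return
    q = bh_fdr([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
        r.significant = bool(qv < fdr_threshold)


def subtype_enrichment(matrix: pd.DataFrame, samples, fdr_threshold: float = 0.25) -> list:
    """Gene-vs-subtype enrichment, one-vs-rest, BH over all (gene, subtype) pairs."""
    groups: dict = {}
    for s in samples:
        groups.setdefault(s.subtype.value, []).append(s.sample_id)
    return _one_vs_rest(matrix, groups, fdr_threshold)


def covariate_enrichment(matrix: pd.DataFrame, samples, covariate: str,
                         fdr_threshold: float = 0.05) -> list:
    """Enrichment against a clinical covariate (stage, menopause, cohort_arm).

    Samples with a missing covariate are excluded pairwise with a logged
    count; fewer than two nonempty groups is an error.
    """
    getters = {
        "stage": lambda s: s.stage.value if s.stage else None,
        "menopause": lambda s: s.menopause.value if s.menopause.value != "missing" else None,
        "cohort_arm": lambda s: s.cohort_arm.value if s.cohort_arm else None,
    }
    if covariate not in getters:
        raise ValueError(f"unknown covariate: {covariate!r}")
    groups: dict = {}
    n_missing = 0
    for s in samples:
        label = getters[covariate](s)
        if label is None:
            n_missing += 1
            continue
        groups.setdefault(label, []).append(s.sample_id)
    if n_missing:
        log.info("covariate_enrichment(%s): %d samples missing, excluded", covariate, n_missing)
    groups = {k: v for k, v in groups.items() if v}
    if len(groups) < 2:
        raise ValueError(f"covariate {covariate!r} has fewer than 2 nonempty groups")
    keep = [i for ids in groups.values() for i in ids]
    return _one_vs_rest(matrix.loc[[i for i in matrix.index if i in set(keep)]], groups,
                        fdr_threshold)


def cohort_compare(freq_table_a: pd.DataFrame, freq_table_b: pd.DataFrame,
                   fdr_threshold: float = 0.05):
    """Per-feature comparison of two cohorts given as (feature, n_altered, n_total).

    Returns ``(results, unshared)``: Fisher/BH over the shared features (one
    family), with OR oriented so OR > 1 means enriched in cohort A;
    features present in only one table go to the unshared report rather
    than being silently dropped (panel-overlap caveat).
    """
    ta = freq_table_a.set_index("feature")
    tb = freq_table_b.set_index("feature")
    shared = sorted(set(ta.index) & set(tb.index))
    unshared = pd.DataFrame(
        {"feature": sorted(set(ta.index) ^ set(tb.index)),
         "present_in": ["A" if f in ta.index else "B"
                        for f in sorted(set(ta.index) ^ set(tb.index))]}
    )
    results = []
    for feature in shared:
        na, ta_tot = int(ta.loc[feature, "n_altered"]), int(ta.loc[feature, "n_total"])
        nb, tb_tot = int(tb.loc[feature, "n_altered"]), int(tb.loc[feature, "n_total"])
        if ta_tot == 0 or tb_tot == 0:
            log.info("cohort_compare: feature %r has zero denominator, excluded", feature)
            continue
        a, b, c, d = na, ta_tot - na, nb, tb_tot - nb
        oddsr, p = fisher_exact_2x2(a, b, c, d)
        lo, hi = or_confidence_interval(a, b, c, d)
        results.append(
            EnrichmentResult(feature, "A_vs_B", a, b, c, d, oddsr, lo, hi, p,
                             extra={"freq_a": na / ta_tot, "freq_b": nb / tb_tot})
        )
    _attach_q(results, fdr_threshold)
    return results, unshared


def enrichment_frame(results: list) -> pd.DataFrame:
    """Flatten EnrichmentResults to a table (all 2x2 cells, OR, CI, p, q, flag)."""
    rows = []
    for r in results:
        row = dict(feature=r.feature, group=r.group_label, a=r.a, b=r.b, c=r.c, d=r.d,
                   odds_ratio=r.odds_ratio, ci_low=r.ci_low, ci_high=r.ci_high,
                   p_value=r.p_value, q_value=r.q_value, significant=r.significant)
        row.update(r.extra)
        rows.append(row)
    return pd.DataFrame(rows)
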