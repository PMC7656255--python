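"""ACMG-guided germline classification with CharGer-style point scoring.

Variants are first restricted to rare alleles (East-Asian population
frequency below 0.5%), then scored by additive evidence modules: PVS1
(truncating consequence in a loss-of-function-mechanism cancer
susceptibility gene, 8 points), PS1 (same amino-acid change as a
cancer-related ClinVar-pathogenic variant, 7), PM4 (protein-length-changing
inframe event, 2), and PM5 (novel missense at a residue carrying a
cancer-related ClinVar-pathogenic missense, 2).  PM2 (absent/rare in
population databases) is deliberately disabled - rarity is already enforced
by the prefilter, so letting it score would double-count the same signal.
Classification: ClinVar cancer-pathogenic variants are pathogenic outright;
otherwise a score strictly greater than 7 is likely pathogenic, anything
else uncertain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .model import Classification, ClinvarStatus, Consequence, GermlineVariant

log = logging.getLogger(__name__)

#: Evidence point weights of the published CharGer scheme (exposed, not hard-wired).
DEFAULT_WEIGHTS = {"PVS1": 8, "PS1": 7, "PM4": 2, "PM5": 2}

#: Likely-pathogenic requires score strictly greater than this.
DEFAULT_SCORE_CUTOFF = 7

TRUNCATING = {
    Consequence.stop_gained,
    Consequence.frameshift,
    Consequence.canonical_splice,
    Consequence.start_lost,
}


@dataclass
class GeneContext:
    gene_symbol: str
    is_cancer_gene: bool = False
    lof_mechanism: bool = False


def read_gene_context_table(path) -> dict:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    need = {"gene", "is_cancer_gene", "lof_mechanism"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: gene context table needs columns {sorted(need)}")
    truthy = {"1", "true", "yes"}
    return {
        row["gene"]: GeneContext(
            row["gene"],
            str(row["is_cancer_gene"]).lower() in truthy,
            str(row["lof_mechanism"]).lower() in truthy,
        )
        for _, row in df.iterrows()
    }


def prefilter_rare(variants, max_eas_af: float = 0.005):
    """Keep only rare variants: East-Asian AF strictly below the threshold.

    A missing AF is treated as rare (absence from the population database
    implies rarity) and kept, with a logged count so the choice is
    auditable.  Returns ``(kept, removed)``.
    """
    if not 0 < max_eas_af <= 1:
        raise ValueError("max_eas_af must be in (0, 1]")
    kept, removed = [], []
    n_missing = 0
    for v in variants:
        if v.af_eas is None:
            n_missing += 1
            kept.append(v)
        elif v.af_eas >= max_eas_af:
            removed.append(v)
        else:
            kept.append(v)
    if n_missing:
        log.info("prefilter_rare: %d variants lacking af_eas retained as rare", n_missing)
    return kept, removed


def score_evidence(variant: GermlineVariant, gene_context: GeneContext,
                   weights: dict = None, extra_scorers=()) -> tuple:
    """Apply the active evidence modules; returns ``(evidence, score)``.

    ``evidence`` is a list of (code, points).  PM2 never fires.  Unknown
    consequences contribute nothing.  ``extra_scorers`` lets a caller gate
    in additional (supporting-level) modules as callables
    ``variant, context -> (code, points) | None``.
    """
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    evidence = []
    cons = variant.consequence
    if cons in TRUNCATING and gene_context.is_cancer_gene and gene_context.lof_mechanism:
        evidence.append(("PVS1", w["PVS1"]))
    ps1_fired = False
    if cons is Consequence.missense and variant.same_aa_known_pathogenic:
        evidence.append(("PS1", w["PS1"]))
        ps1_fired = True
    if cons is Consequence.inframe_indel:
        evidence.append(("PM4", w["PM4"]))
    if (cons is Consequence.missense and variant.same_residue_known_pathogenic
            and not ps1_fired):
        evidence.append(("PM5", w["PM5"]))
    for scorer in extra_scorers:
        fired = scorer(variant, gene_context)
        if fired is not None:
            evidence.append(fired)
    assert all(code != "PM2" for code, _ in evidence)
    variant.evidence = evidence
    variant.score = sum(points for _, points in evidence)
    return evidence, variant.score


def classify(variant: GermlineVariant, score_cutoff: int = DEFAULT_SCORE_CUTOFF) -> Classification:
    """Three-way call: ClinVar cancer-pathogenic > score cut-off > uncertain."""
    if variant.clinvar_status is ClinvarStatus.pathogenic_cancer:
        cls = Classification.pathogenic
    elif variant.score > score_cutoff:
        cls = Classification.likely_pathogenic
    else:
        cls = Classification.uncertain
    variant.classification = cls
    return cls


def classify_variants(variants, gene_contexts: dict,
                      score_cutoff: int = DEFAULT_SCORE_CUTOFF, weights: dict = None):
    """Score and classify every variant in place; returns the list."""
    default_ctx = GeneContext("?", False, False)
    for v in variants:
        score_evidence(v, gene_contexts.get(v.gene_symbol, default_ctx), weights)
        classify(v, score_cutoff)
    return variants


def carrier_summary(cohort_germline, n_patients: int):
    """Cohort carrier bookkeeping.

    A carrier is a patient with at least one pathogenic or likely
    pathogenic variant.  Per-gene counts tally patients (not variants): a
    patient with hits in two genes increments both genes but counts once
    overall.  Returns ``(n_carriers, fraction, per_gene_counts)``.
    """
    if n_patients <= 0:
        raise ValueError("n_patients must be > 0")
    carriers = set()
    per_gene: dict = {}
    for v in cohort_germline:
        if v.classification in (Classification.pathogenic, Classification.likely_pathogenic):
            carriers.add(v.patient_id)
            per_gene.setdefault(v.gene_symbol, set()).add(v.patient_id)
    counts = {g: len(p) for g, p in sorted(per_gene.items(), key=lambda kv: (-len(kv[1]), kv[0]))}
    return len(carriers), len(carriers) / n_patients, counts


def _rx2_exact_p(ks, ns):
    """Freeman-Halton exact test for an r x 2 table (carriers vs not, r groups).

    Enumerates all carrier allocations with the observed margins; the
    two-sided p sums the conditional (multivariate hypergeometric)
    probabilities of tables no more probable than the observed one.
    Feasible when the total carrier count is small.
    """
    ks, ns = list(ks), list(ns)
    total_k, total_n = sum(ks), sum(ns)

    def log_prob(alloc):
        lp = -(gammaln(total_n + 1) - gammaln(total_k + 1) - gammaln(total_n - total_k + 1))
        for a, n in zip(alloc, ns):
            lp += gammaln(n + 1) - gammaln(a + 1) - gammaln(n - a + 1)
        return lp

    obs_lp = log_prob(ks)
    p = 0.0

    def recurse(idx, remaining, alloc):
        nonlocal p
        if idx == len(ns) - 1:
            if remaining <= ns[idx]:
                lp = log_prob(alloc + [remaining])
                if lp <= obs_lp + 1e-9:
                    p += np.exp(lp)
            return
        tail_capacity = sum(ns[idx + 1:])
        lo = max(0, remaining - tail_capacity)
        hi = min(ns[idx], remaining)
        for a in range(lo, hi + 1):
            recurse(idx + 1, remaining - a, alloc + [a])

    recurse(0, total_k, [])
    return min(1.0, float(p))


def germline_cohort_compare(per_gene_counts: dict):
    """Compare per-gene carrier frequencies across populations.

    ``per_gene_counts`` maps gene -> list of (n_carriers, n_total), one
    entry per population.  Pearson chi-square is used unless any expected
    cell count falls below 5, in which case the Freeman-Halton exact test
    takes over.  Returns a DataFrame of per-gene p-values and frequencies.
    """
    rows = []
    for gene, pops in per_gene_counts.items():
        if len(pops) < 2:
            raise ValueError(f"gene {gene}: need at least 2 populations")
        ks = [int(k) for k, _ in pops]
        ns = [int(n) for _, n in pops]
        if any(n == 0 for n in ns):
            raise ValueError(f"gene {gene}: population with n_total=0")
        table = np.array([ks, [n - k for k, n in zip(ks, ns)]])
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any():
            if sum(ks) <= 200:
                p = _rx2_exact_p(ks, ns)
                method = "freeman_halton"
            else:
                p = float(stats.chi2_contingency(table, correction=False)[1])
                method = "chi2_low_expected"
        else:
            p = float(stats.chi2_contingency(table, correction=False)[1])
            method = "chi2"
        row = dict(gene=gene, p_value=p, method=method)
        for i, (k, n) in enumerate(zip(ks, ns)):
            row[f"freq_{i}"] = k / n
        rows.append(row)
    return pd.DataFrame(rows)


def germline_frame(variants) -> pd.DataFrame:
    """Per-variant output table with the full evidence trail."""
    return pd.DataFrame(
        [
            dict(patient_id=v.patient_id, gene_symbol=v.gene_symbol, chrom=v.chrom,
                 pos=v.pos, ref=v.ref, alt=v.alt, consequence=v.consequence.value,
                 af_eas=v.af_eas, clinvar_status=v.clinvar_status.value,
                 evidence=";".join(f"{c}:{p}" for c, p in v.evidence), score=v.score,
                 classification=v.classification.value if v.classification else "")
            for v in variants
        ]
    )
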