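"""Descriptive genomics over a panel-sequenced cohort.

Per-gene and per-group mutation frequencies, recurrent protein-change
(hotspot) detection at a cohort-frequency threshold, per-sample mutation
load with a Kruskal-Wallis comparison across subtypes, per-gene VAF
distributions, and CNV frequencies over the CNV-evaluable subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

GROUP_FIELDS = {
    "none": None,
    "subtype": lambda s: s.subtype.value,
    "coarse_subtype": lambda s: s.coarse_subtype.value,
    "stage": lambda s: s.stage.value if s.stage else None,
    "cohort_arm": lambda s: s.cohort_arm.value if s.cohort_arm else None,
}

#: Hotspot boundary tolerance: the 2% threshold admits entries whose raw
#: frequency sits a rounding hair below it (printed frequencies are
#: rounded to whole percent).
HOTSPOT_EPSILON = 5e-4


@dataclass
class Hotspot:
    gene_symbol: str
    protein_change: str
    n_samples: int
    frequency: float


def _group_of(sample, group_by: str):
    if group_by == "none":
        return "all"
    fn = GROUP_FIELDS[group_by]
    return fn(sample)


def _sample_groups(samples, group_by: str) -> dict:
    """Map group label -> list of sample_ids, dropping missing labels."""
    if group_by not in GROUP_FIELDS:
        raise ValueError(f"unknown group_by: {group_by!r}")
    groups: dict = {}
    n_missing = 0
    for s in samples:
        label = _group_of(s, group_by)
        if label is None:
            n_missing += 1
            continue
        groups.setdefault(label, []).append(s.sample_id)
    if n_missing:
        log.info("grouping by %s: %d samples with missing value excluded", group_by, n_missing)
    return groups


def gene_frequency(cohort, group_by: str = "none") -> pd.DataFrame:
    """Per-(gene, group) mutated-sample frequency table.

    Denominators are group sizes over all sequenced samples in the group,
    not just mutated ones; genes absent from a group keep a zero row.
    """
    if not cohort.samples:
        raise ValueError("empty cohort")
    groups = _sample_groups(cohort.samples, group_by)
    genes = sorted({m.gene_symbol for m in cohort.somatic})
    mutated: dict = {}
    for m in cohort.somatic:
        mutated.setdefault(m.gene_symbol, set()).add(m.sample_id)
    rows = []
    for group, ids in sorted(groups.items()):
        id_set = set(ids)
        for gene in genes:
            n_alt = len(mutated.get(gene, set()) & id_set)
            rows.append(
                dict(feature=gene, group=group, n_altered=n_alt, n_total=len(ids),
                     frequency=n_alt / len(ids))
            )
    return pd.DataFrame(rows)


def matrix_frequency(matrix: pd.DataFrame, samples, group_by: str = "none") -> pd.DataFrame:
    """Frequency table computed from a binary alteration matrix (any feature level)."""
    groups = _sample_groups(samples, group_by)
    rows = []
    for group, ids in sorted(groups.items()):
        ids = [i for i in ids if i in matrix.index]
        sub = matrix.loc[ids]
        for feature in matrix.columns:
            n_alt = int(sub[feature].sum())
            rows.append(
                dict(feature=feature, group=group, n_altered=n_alt, n_total=len(ids),
                     frequency=n_alt / len(ids) if ids else float("nan"))
            )
    return pd.DataFrame(rows)


def detect_hotspots(mutations, n_samples: int, min_frequency: float = 0.02):
    """Recurrent identical protein changes above a cohort-frequency threshold.

    Samples are counted once per (gene, protein_change) even with duplicate
    calls; mutations lacking a protein change are skipped (logged count).
    Result is sorted by frequency descending, ties by gene then protein
    change.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    carriers: dict = {}
    n_missing = 0
    for m in mutations:
        if not m.protein_change:
            n_missing += 1
            continue
        carriers.setdefault((m.gene_symbol, m.protein_change), set()).add(m.sample_id)
    if n_missing:
        log.info("detect_hotspots: %d mutations without protein_change skipped", n_missing)
    hotspots = [
        Hotspot(gene, pchange, len(ids), len(ids) / n_samples)
        for (gene, pchange), ids in carriers.items()
        if len(ids) / n_samples >= min_frequency - HOTSPOT_EPSILON
    ]
    hotspots.sort(key=lambda h: (-h.frequency, h.gene_symbol, h.protein_change))
    return hotspots


def mutation_load(cohort, group_by: str = "subtype"):
    """Somatic mutation count per sample, compared across groups.

    Returns ``(per_sample, summary)``: per-sample counts (zero-mutation
    samples included) and a dict with per-group medians and the
    Kruskal-Wallis p-value (``None`` with a note when fewer than two
    nonempty groups exist).
    """
    if not cohort.samples:
        raise ValueError("empty cohort")
    counts = {sid: 0 for sid in cohort.sample_ids}
    for m in cohort.somatic:
        counts[m.sample_id] += 1
    per_sample = pd.DataFrame(
        {"sample_id": list(counts), "n_mutations": list(counts.values())}
    )
    groups = _sample_groups(cohort.samples, group_by)
    group_counts = {g: [counts[i] for i in ids] for g, ids in groups.items() if ids}
    medians = {g: float(np.median(v)) for g, v in sorted(group_counts.items())}
    if len(group_counts) < 2:
        return per_sample, {"medians": medians, "p_value": None, "note": "not applicable: <2 groups"}
    values = list(group_counts.values())
    if all(len(set(v)) == 1 for v in values) and len({v[0] for v in values}) == 1:
        p = 1.0  # all observations identical: no evidence of any difference
    else:
        _, p = stats.kruskal(*values)
    return per_sample, {"medians": medians, "p_value": float(p)}


def vaf_summary(mutations, genes: Iterable[str]):
    """Per-gene VAF quartiles plus an across-gene Kruskal-Wallis test.

    Genes with no VAF-bearing mutations are listed with ``n=0`` and excluded
    from the test.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("genes must be nonempty")
    by_gene = {g: [] for g in genes}
    for m in mutations:
        if m.gene_symbol in by_gene and m.vaf is not None:
            by_gene[m.gene_symbol].append(m.vaf)
    rows = []
    for g in genes:
        v = np.asarray(by_gene[g], dtype=float)
        if v.size:
            rows.append(dict(gene=g, n=v.size, median=float(np.median(v)),
                             q1=float(np.percentile(v, 25)), q3=float(np.percentile(v, 75))))
        else:
            rows.append(dict(gene=g, n=0, median=np.nan, q1=np.nan, q3=np.nan))
    populated = [np.asarray(by_gene[g]) for g in genes if by_gene[g]]
    p = None
    if len(populated) >= 2:
        flat = np.concatenate(populated)
        if np.all(flat == flat[0]):
            p = 1.0
        else:
            try:
                _, p = stats.kruskal(*populated)
                p = float(p)
            except ValueError:  # all values identical within scipy's tie guard
                p = 1.0
    return pd.DataFrame(rows), p


def cnv_frequency(cnv_calls, samples, group_by: str = "none",
                  evaluable_ids: Optional[set] = None) -> pd.DataFrame:
    """Per-(gene, call, group) CNV frequency over CNV-evaluable samples.

    The denominator is the count of samples in which copy number could be
    determined (``evaluable_ids``), which may be smaller than the cohort;
    by default all provided samples are treated as evaluable.  Both call
    types get a row for every affected gene, so a deletion-only gene
    reports an explicit zero amplification frequency.
    """
    if evaluable_ids is None:
        evaluable_ids = {s.sample_id for s in samples}
    samples = [s for s in samples if s.sample_id in evaluable_ids]
    groups = _sample_groups(samples, group_by)
    genes = sorted({c.gene_symbol for c in cnv_calls})
    affected: dict = {}
    for c in cnv_calls:
        if c.sample_id in evaluable_ids:
            affected.setdefault((c.gene_symbol, c.call.value), set()).add(c.sample_id)
    rows = []
    for group, ids in sorted(groups.items()):
        id_set = set(ids)
        for gene in genes:
            for call in ("amplification", "deletion"):
                n_alt = len(affected.get((gene, call), set()) & id_set)
                rows.append(
                    dict(feature=gene, call=call, group=group, n_altered=n_alt,
                         n_total=len(ids), frequency=n_alt / len(ids) if ids else float("nan"))
                )
    return pd.DataFrame(rows)


def oncoprint_long(mutations) -> pd.DataFrame:
    """Plot-ready long table (sample, gene, variant_class) for external oncoprints."""
    return pd.DataFrame(
        [
            dict(sample_id=m.sample_id, gene_symbol=m.gene_symbol,
                 variant_class=m.variant_class.value)
            for m in mutations
        ]
    )
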