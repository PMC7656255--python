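"""Gene-to-pathway aggregation and pairwise exclusivity / co-occurrence.

Nine canonical oncogenic signaling pathways (cell cycle, Hippo, Notch,
PI3K, Wnt, RTK/RAS, p53, TGF-beta, Myc) are represented as replaceable
gene-membership sets; a curated default catalog restricted to common
breast-cancer panel genes ships with the package.  Pairwise association
between binary alteration features is scored by the 2x2 co-occurrence
odds ratio with a Fisher exact p-value and BH correction across all pairs;
log10(OR) is capped at +/-3 so fully exclusive (OR=0) and fully nested
(OR=inf) pairs stay on a finite color scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd

from .stats import bh_fdr, fisher_exact_2x2

log = logging.getLogger(__name__)

PATHWAY_NAMES = (
    "cell_cycle", "Hippo", "Notch", "PI3K", "Wnt", "RTK_RAS", "p53", "TGF_beta", "Myc",
)

LOG_OR_CAP = 3.0


@dataclass
class PairwiseAssociation:
    feature_i: str
    feature_j: str
    n11: int
    n10: int
    n01: int
    n00: int
    odds_ratio: float
    log10_or: float
    p_value: float
    q_value: float = np.nan
    pattern: str = "none"  # co_occurring | mutually_exclusive | none
    extra: dict = field(default_factory=dict)


def load_catalog(path) -> dict:
    """Read a (pathway, gene) TSV into a pathway -> gene-set mapping.

    Pathway names outside the nine canonical ones are an error; duplicate
    rows deduplicate silently (logged).  Genes not on the sequencing panel
    are retained - they simply never match an altered feature.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"pathway", "gene"}.issubset(df.columns):
        raise ValueError(f"{path}: catalog needs columns (pathway, gene)")
    catalog: dict = {}
    n_dup = 0
    for _, row in df.iterrows():
        pathway, gene = row["pathway"], row["gene"]
        if pathway not in PATHWAY_NAMES:
            raise ValueError(f"unknown pathway name {pathway!r}; expected one of {PATHWAY_NAMES}")
        members = catalog.setdefault(pathway, set())
        if gene in members:
            n_dup += 1
        members.add(gene)
    if n_dup:
        log.info("load_catalog: %d duplicate rows deduplicated", n_dup)
    empty = [p for p, genes in catalog.items() if not genes]
    if empty:
        raise ValueError(f"empty pathways in catalog: {empty}")
    return catalog


def default_catalog() -> dict:
    """The packaged nine-pathway membership catalog (user-replaceable)."""
    with resources.files("oncopanel.data").joinpath("pathways.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype=str)
    catalog: dict = {}
    for _, row in df.iterrows():
        catalog.setdefault(row["pathway"], set()).add(row["gene"])
    return catalog


def pathway_matrix(gene_matrix: pd.DataFrame, catalog: dict) -> pd.DataFrame:
    """Collapse a binary gene matrix to pathway level.

    A pathway cell is 1 iff at least one member gene cell is 1; genes
    belonging to several pathways contribute to each of them.
    """
    out = pd.DataFrame(0, index=gene_matrix.index,
                       columns=[p for p in PATHWAY_NAMES if p in catalog], dtype="int8")
    for pathway in out.columns:
        members = [g for g in catalog[pathway] if g in gene_matrix.columns]
        if members:
            out[pathway] = (gene_matrix[members].sum(axis=1) > 0).astype("int8")
    return out


def _capped_log10(oddsr: float) -> float:
    if np.isnan(oddsr):
        return np.nan
    if oddsr == 0:
        return -LOG_OR_CAP
    if np.isinf(oddsr):
        return LOG_OR_CAP
    return float(np.clip(np.log10(oddsr), -LOG_OR_CAP, LOG_OR_CAP))


def pairwise_association(matrix: pd.DataFrame, fdr_threshold: float = 0.05) -> list:
    """Mutual exclusivity / co-occurrence over all unordered feature pairs.

    Features altered in zero or all samples are skipped (degenerate 2x2
    margin, logged).  BH runs across all tested pairs as one family; among
    significant pairs, OR > 1 is labeled co-occurring and OR < 1 mutually
    exclusive.
    """
    if matrix.shape[1] < 2:
        raise ValueError("pairwise association needs at least 2 features")
    n = len(matrix)
    colsum = matrix.sum(axis=0)
    usable = [f for f in matrix.columns if 0 < colsum[f] < n]
    skipped = sorted(set(matrix.columns) - set(usable))
    if skipped:
        log.info("pairwise_association: skipped degenerate features %s", skipped)
    values = matrix[usable].to_numpy(dtype=np.int64)
    results = []
    for idx_i, idx_j in combinations(range(len(usable)), 2):
        vi, vj = values[:, idx_i], values[:, idx_j]
        n11 = int(np.sum(vi & vj))
        n10 = int(np.sum(vi & (1 - vj)))
        n01 = int(np.sum((1 - vi) & vj))
        n00 = n - n11 - n10 - n01
        oddsr, p = fisher_exact_2x2(n11, n10, n01, n00)
        results.append(
            PairwiseAssociation(usable[idx_i], usable[idx_j], n11, n10, n01, n00,
                                oddsr, _capped_log10(oddsr), p)
        )
    if results:
        q = bh_fdr([r.p_value for r in results])
        for r, qv in zip(results, q):
            r.q_value = float(qv)
            if qv < fdr_threshold:
                if r.odds_ratio > 1:
                    r.pattern = "co_occurring"
                elif r.odds_ratio < 1:
                    r.pattern = "mutually_exclusive"
    return results


def pathway_frequency(pathway_mat: pd.DataFrame, samples, group_by: str = "none") -> pd.DataFrame:
    """Per-(pathway, group) alteration frequency (denominator = group size)."""
    from .landscape import matrix_frequency

    return matrix_frequency(pathway_mat, samples, group_by)


def association_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(feature_i=r.feature_i, feature_j=r.feature_j, n11=r.n11, n10=r.n10,
                 n01=r.n01, n00=r.n00, odds_ratio=r.odds_ratio, log10_or=r.log10_or,
                 p_value=r.p_value, q_value=r.q_value, pattern=r.pattern)
            for r in results
        ]
    )


def cooccurrence_adjacency(results: list) -> pd.DataFrame:
    """Circos-style adjacency: co-altered sample counts for significant co-occurring pairs."""
    return pd.DataFrame(
        [
            dict(pathway_i=r.feature_i, pathway_j=r.feature_j, n_co_altered=r.n11)
            for r in results
            if r.pattern == "co_occurring"
        ]
    )
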