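"""Evidence-level tiering of alterations against an actionability knowledge base.

Levels follow the OncoKB convention: L1 FDA-recognized biomarkers, L2
standard-of-care, L3 investigational, each subdivided by whether the
evidence comes from the pertinent tumor type (A) or a different one (B),
and L4 for oncogenic biomarkers without a matched drug.  The knowledge
base itself is input data; a small curated breast-cancer table ships as a
replaceable default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import pandas as pd

from .model import CnvCall, VariantClass

#: Best-to-worst clinical evidence levels.
LEVEL_ORDER = ("L1", "L2A", "L2B", "L3A", "L3B", "L4")
_LEVEL_RANK = {lvl: i for i, lvl in enumerate(LEVEL_ORDER)}

MATCHERS = ("any_oncogenic", "exact_protein_change", "truncating", "amplification")

TRUNCATING_CLASSES = {VariantClass.nonsense, VariantClass.frameshift, VariantClass.splice_site}


@dataclass
class ActionabilityRecord:
    gene_symbol: str
    alteration_matcher: str
    level: str
    drugs: list
    tumor_context: str = "breast"
    protein_change: Optional[str] = None
    oncogenic_classes: Optional[set] = None  # allowlist for any_oncogenic rows

    def __post_init__(self) -> None:
        if self.level not in _LEVEL_RANK:
            raise ValueError(f"unknown evidence level {self.level!r}; expected {LEVEL_ORDER}")
        if self.alteration_matcher not in MATCHERS:
            raise ValueError(f"unknown matcher {self.alteration_matcher!r}")
        if self.alteration_matcher == "exact_protein_change" and not self.protein_change:
            raise ValueError(
                f"{self.gene_symbol}: exact_protein_change matcher needs a protein_change literal"
            )


@dataclass
class Match:
    alteration: str  # provenance: what matched, e.g. "PIK3CA p.H1047R" or "ERBB2 amplification"
    record: ActionabilityRecord
    level: str


@dataclass
class SampleActionability:
    sample_id: str
    matched: list = field(default_factory=list)
    best_level: Optional[str] = None


def _records_from_frame(df: pd.DataFrame, source) -> list:
    need = {"gene", "matcher", "level", "drugs"}
    if not need.issubset(df.columns):
        raise ValueError(f"{source}: knowledge base needs columns {sorted(need)}")
    records = []
    for _, row in df.iterrows():
        onc = row.get("oncogenic_classes", "")
        records.append(
            ActionabilityRecord(
                gene_symbol=row["gene"],
                alteration_matcher=row["matcher"],
                level=row["level"],
                drugs=[d for d in row["drugs"].split("|") if d],
                tumor_context=row.get("tumor_context", "breast") or "breast",
                protein_change=row.get("protein_change") or None,
                oncogenic_classes={VariantClass(c) for c in onc.split("|") if c} or None,
            )
        )
    return records


def load_kb(path) -> list:
    """Read the knowledge-base TSV into validated records.

    Columns: gene, matcher, protein_change, tumor_context, level, drugs
    ('|'-separated), oncogenic_classes ('|'-separated allowlist, optional).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    return _records_from_frame(df, path)


def default_kb() -> list:
    """The packaged curated breast-cancer knowledge base (user-replaceable)."""
    with resources.files("oncopanel.data").joinpath("actionability_kb.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype=str, keep_default_na=False)
    return _records_from_frame(df, "packaged kb")


def kb_audit(records) -> tuple:
    """(distinct gene count, distinct drug count) for bookkeeping audits."""
    genes = {r.gene_symbol for r in records}
    drugs = {d for r in records for d in r.drugs}
    return len(genes), len(drugs)


def match_alterations(mutations, cnv_calls, kb) -> list:
    """Match one sample's alterations against the knowledge base.

    Matcher semantics: exact_protein_change on (gene, protein change);
    truncating on nonsense/frameshift/splice; any_oncogenic on any
    non-silent somatic alteration in the gene, optionally restricted by the
    record's per-gene class allowlist; amplification on CNV amplification
    calls.  Every match retains its provenance.
    """
    matches = []
    for rec in kb:
        if rec.alteration_matcher == "amplification":
            for c in cnv_calls:
                if c.gene_symbol == rec.gene_symbol and c.call is CnvCall.amplification:
                    matches.append(Match(f"{c.gene_symbol} amplification", rec, rec.level))
        else:
            for m in mutations:
                if m.gene_symbol != rec.gene_symbol:
                    continue
                label = f"{m.gene_symbol} {m.protein_change or m.variant_class.value}"
                if rec.alteration_matcher == "exact_protein_change":
                    if m.protein_change == rec.protein_change:
                        matches.append(Match(label, rec, rec.level))
                elif rec.alteration_matcher == "truncating":
                    if m.variant_class in TRUNCATING_CLASSES:
                        matches.append(Match(label, rec, rec.level))
                elif rec.alteration_matcher == "any_oncogenic":
                    allowed = rec.oncogenic_classes
                    if allowed is None or m.variant_class in allowed:
                        matches.append(Match(label, rec, rec.level))
    return matches


def assign_best_level(matches) -> Optional[str]:
    """Highest evidence level among matches (L1 best); None when empty."""
    if not matches:
        return None
    return min((m.level for m in matches), key=_LEVEL_RANK.__getitem__)


def annotate_cohort(cohort, kb) -> list:
    """Per-sample actionability over a whole cohort."""
    mut_by_sample: dict = {}
    for m in cohort.somatic:
        mut_by_sample.setdefault(m.sample_id, []).append(m)
    cnv_by_sample: dict = {}
    for c in cohort.cnv:
        cnv_by_sample.setdefault(c.sample_id, []).append(c)
    out = []
    for sid in cohort.sample_ids:
        matches = match_alterations(mut_by_sample.get(sid, []), cnv_by_sample.get(sid, []), kb)
        out.append(SampleActionability(sid, matches, assign_best_level(matches)))
    return out


def actionability_summary(per_sample, samples, group_by: str = "subtype"):
    """Per-group fractions of samples at each best level (plus 'none').

    Also reports the fraction with at least one match and the distribution
    of per-sample distinct matched-alteration counts.  Level fractions per
    group, including the none bucket, sum to 1.
    """
    from .landscape import _sample_groups

    by_id = {p.sample_id: p for p in per_sample}
    groups = _sample_groups(samples, group_by)
    level_rows, count_rows = [], []
    for group, ids in sorted(groups.items()):
        entries = [by_id[i] for i in ids if i in by_id]
        n = len(entries)
        if n == 0:
            continue
        tally = {lvl: 0 for lvl in LEVEL_ORDER}
        tally["none"] = 0
        for e in entries:
            tally[e.best_level or "none"] += 1
        for lvl, k in tally.items():
            level_rows.append(dict(group=group, level=lvl, n=k, fraction=k / n))
        level_rows.append(
            dict(group=group, level="any_match", n=n - tally["none"],
                 fraction=(n - tally["none"]) / n)
        )
        for e in entries:
            count_rows.append(
                dict(group=group, sample_id=e.sample_id,
                     n_alterations=len({m.alteration for m in e.matched}))
            )
    return pd.DataFrame(level_rows), pd.DataFrame(count_rows)


def actionability_frame(per_sample) -> pd.DataFrame:
    rows = []
    for p in per_sample:
        for m in p.matched:
            rows.append(
                dict(sample_id=p.sample_id, alteration=m.alteration,
                     gene=m.record.gene_symbol, level=m.level,
                     drugs="|".join(m.record.drugs), best_level=p.best_level)
            )
        if not p.matched:
            rows.append(dict(sample_id=p.sample_id, alteration="", gene="", level="",
                             drugs="", best_level=""))
    return pd.DataFrame(rows)
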