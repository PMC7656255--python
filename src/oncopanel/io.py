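"""Readers and writers for the tabular formats the pipeline touches.

Somatic calls are ingested from TCGA-style MAF, a minimal TSV dialect, or a
small single-sample somatic VCF; clinical, CNV, panel-of-normals, germline
and gene-context tables are plain TSV.  Rows that fail validation are never
dropped silently: every reader returns a rejects table naming the reason.
All coordinates are 1-based inclusive (MAF/VCF convention).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .model import (
    ClinicalSample,
    CnvCall,
    CohortArm,
    Consequence,
    CopyNumberCall,
    ClinvarStatus,
    GermlineVariant,
    Menopause,
    SampleOrigin,
    SomaticMutation,
    Stage,
    VariantClass,
    derive_subtype,
)

log = logging.getLogger(__name__)

#: MAF Variant_Classification -> internal variant class.  Silent /
#: synonymous classes map to None and are excluded at read time with a
#: logged count (they carry no protein-altering signal on a coding panel).
MAF_CLASS_MAP = {
    "Missense_Mutation": VariantClass.missense,
    "Nonsense_Mutation": VariantClass.nonsense,
    "Frame_Shift_Del": VariantClass.frameshift,
    "Frame_Shift_Ins": VariantClass.frameshift,
    "Splice_Site": VariantClass.splice_site,
    "Splice_Region": VariantClass.splice_site,
    "In_Frame_Del": VariantClass.inframe_indel,
    "In_Frame_Ins": VariantClass.inframe_indel,
    "Nonstop_Mutation": VariantClass.other,
    "Translation_Start_Site": VariantClass.other,
    "Silent": None,
    "Synonymous": None,
}

MAF_COLUMNS = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Tumor_Sample_Barcode",
]

MINIMAL_COLUMNS = [
    "sample_id",
    "gene_symbol",
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "variant_class",
]

MISSING_MARKERS = {"", ".", "NA", "NaN", "nan", "None"}


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def _opt(value: Optional[str]):
    if value is None or str(value).strip() in MISSING_MARKERS:
        return None
    return str(value).strip()


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns: {missing}")


def read_somatic_table(path, dialect: str = "maf"):
    """Read somatic mutation calls.

    Returns ``(mutations, rejects)`` where rejects is a DataFrame with the
    offending row values and a ``reason`` column.  VAF is recomputed from
    alt/ref counts whenever both are present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "maf":
        return _read_maf(path)
    if dialect == "minimal_tsv":
        return _read_minimal(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown somatic dialect: {dialect!r} (expected maf, minimal_tsv, or vcf)")


def _build_mutation(rec: dict, rejects: list, raw: dict) -> Optional[SomaticMutation]:
    try:
        return SomaticMutation(**rec)
    except (ValueError, TypeError) as exc:
        reason = "zero depth" if "zero depth" in str(exc) else str(exc)
        rejects.append({**raw, "reason": reason})
        return None


def _read_maf(path):
    df = _read_tsv(path)
    _require_columns(df, MAF_COLUMNS, path)
    mutations, rejects = [], []
    n_silent = 0
    for _, row in df.iterrows():
        raw = row.to_dict()
        vclass_raw = row["Variant_Classification"]
        if vclass_raw not in MAF_CLASS_MAP:
            rejects.append({**raw, "reason": f"unknown Variant_Classification {vclass_raw!r}"})
            continue
        vclass = MAF_CLASS_MAP[vclass_raw]
        if vclass is None:
            n_silent += 1
            rejects.append({**raw, "reason": "silent"})
            continue
        alt_n = _opt(row.get("t_alt_count"))
        ref_n = _opt(row.get("t_ref_count"))
        rec = dict(
            sample_id=row["Tumor_Sample_Barcode"],
            gene_symbol=row["Hugo_Symbol"],
            chrom=str(row["Chromosome"]),
            pos=int(row["Start_Position"]),
            ref_allele=row["Reference_Allele"],
            alt_allele=row["Tumor_Seq_Allele2"],
            variant_class=vclass,
            protein_change=_opt(row.get("HGVSp_Short")),
            t_alt_count=int(alt_n) if alt_n is not None else None,
            t_ref_count=int(ref_n) if ref_n is not None else None,
        )
        mut = _build_mutation(rec, rejects, raw)
        if mut is not None:
            mutations.append(mut)
    if n_silent:
        log.info("read_somatic_table: excluded %d silent/synonymous rows", n_silent)
    return mutations, pd.DataFrame(rejects)


def _read_minimal(path):
    df = _read_tsv(path)
    _require_columns(df, MINIMAL_COLUMNS, path)
    mutations, rejects = [], []
    for _, row in df.iterrows():
        raw = row.to_dict()
        alt_n = _opt(row.get("t_alt_count"))
        ref_n = _opt(row.get("t_ref_count"))
        try:
            rec = dict(
                sample_id=row["sample_id"],
                gene_symbol=row["gene_symbol"],
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref_allele=row["ref_allele"],
                alt_allele=row["alt_allele"],
                variant_class=VariantClass(row["variant_class"]),
                protein_change=_opt(row.get("protein_change")),
                t_alt_count=int(alt_n) if alt_n is not None else None,
                t_ref_count=int(ref_n) if ref_n is not None else None,
            )
        except ValueError as exc:
            rejects.append({**raw, "reason": str(exc)})
            continue
        mut = _build_mutation(rec, rejects, raw)
        if mut is not None:
            mutations.append(mut)
    return mutations, pd.DataFrame(rejects)


def _read_vcf(path):
    """Minimal single-sample somatic VCF: INFO keys GENE, VC, AA; FORMAT AD."""
    mutations, rejects = [], []
    sample_name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                sample_name = fields[9] if len(fields) > 9 else None
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                rejects.append({"line": line, "reason": "truncated VCF row"})
                continue
            chrom, pos, _id, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            info = dict(
                kv.split("=", 1) if "=" in kv else (kv, "")
                for kv in parts[7].split(";")
                if kv
            )
            alt_n = ref_n = None
            if len(parts) > 9 and "AD" in parts[8].split(":"):
                ad_idx = parts[8].split(":").index("AD")
                ad = parts[9].split(":")[ad_idx].split(",")
                ref_n, alt_n = int(ad[0]), int(ad[1])
            rec = dict(
                sample_id=info.get("SAMPLE", sample_name or "sample"),
                gene_symbol=info.get("GENE", ""),
                chrom=chrom,
                pos=int(pos),
                ref_allele=ref,
                alt_allele=alt,
                variant_class=VariantClass(info.get("VC", "other")),
                protein_change=_opt(info.get("AA")),
                t_alt_count=alt_n,
                t_ref_count=ref_n,
            )
            mut = _build_mutation(rec, rejects, {"line": line})
            if mut is not None:
                mutations.append(mut)
    return mutations, pd.DataFrame(rejects)


def _parse_bool(value: str) -> bool:
    v = str(value).strip().lower()
    if v in {"1", "true", "pos", "positive", "yes", "+"}:
        return True
    if v in {"0", "false", "neg", "negative", "no", "-"}:
        return False
    raise ValueError(f"cannot parse boolean field value {value!r}")


def read_clinical_table(path):
    """Read the clinical sample TSV.

    Returns ``(samples, mismatches)``: when the table states a subtype it is
    cross-checked against the IHC-derived call and disagreements are
    reported (stated and derived values side by side), with the derived
    value retained.
    """
    path = Path(path)
    df = _read_tsv(path)
    _require_columns(df, ["sample_id", "patient_id", "er", "pr", "her2"], path)
    ids = df["sample_id"].tolist()
    dups = sorted({i for i in ids if ids.count(i) > 1})
    if dups:
        raise ValueError(f"{path}: duplicate sample_id values: {dups}")
    samples, mismatches = [], []
    for _, row in df.iterrows():
        ki67 = _opt(row.get("ki67"))
        sample = ClinicalSample(
            sample_id=row["sample_id"],
            patient_id=row["patient_id"],
            er_positive=_parse_bool(row["er"]),
            pr_positive=_parse_bool(row["pr"]),
            her2_positive=_parse_bool(row["her2"]),
            ki67_fraction=float(ki67) if ki67 is not None else None,
            stage=Stage(_opt(row.get("stage"))) if _opt(row.get("stage")) else None,
            cohort_arm=CohortArm(_opt(row.get("cohort_arm"))) if _opt(row.get("cohort_arm")) else None,
            sample_origin=SampleOrigin(_opt(row.get("sample_origin")) or "primary"),
            menopause=Menopause(_opt(row.get("menopause")) or "missing"),
            age_years=int(_opt(row.get("age"))) if _opt(row.get("age")) else None,
        )
        stated = _opt(row.get("subtype"))
        if stated is not None and stated != sample.subtype.value:
            mismatches.append(
                {"sample_id": sample.sample_id, "stated": stated, "derived": sample.subtype.value}
            )
        samples.append(sample)
    return samples, pd.DataFrame(mismatches)


def read_cnv_table(path):
    df = _read_tsv(path)
    _require_columns(df, ["sample_id", "gene_symbol", "call"], path)
    calls = [
        CopyNumberCall(row["sample_id"], row["gene_symbol"], CnvCall(row["call"]))
        for _, row in df.iterrows()
    ]
    # one record per (sample, gene, call)
    seen, unique = set(), []
    for c in calls:
        k = (c.sample_id, c.gene_symbol, c.call)
        if k not in seen:
            seen.add(k)
            unique.append(c)
    return unique


def read_pon_table(path) -> dict:
    """Panel-of-normals index: variant key -> count of normals carrying it."""
    df = _read_tsv(path)
    _require_columns(df, ["chrom", "pos", "ref", "alt", "n_normals"], path)
    index = {}
    for _, row in df.iterrows():
        n = int(row["n_normals"])
        if n < 0:
            raise ValueError(f"{path}: negative n_normals for {row['chrom']}:{row['pos']}")
        index[(str(row["chrom"]), int(row["pos"]), row["ref"], row["alt"])] = n
    return index


def read_germline_table(path):
    df = _read_tsv(path)
    _require_columns(
        df, ["patient_id", "gene_symbol", "chrom", "pos", "ref", "alt", "consequence"], path
    )
    variants = []
    for _, row in df.iterrows():
        af_eas = _opt(row.get("af_eas"))
        af_all = _opt(row.get("af_overall"))
        variants.append(
            GermlineVariant(
                patient_id=row["patient_id"],
                gene_symbol=row["gene_symbol"],
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                consequence=Consequence(row["consequence"])
                if row["consequence"] in Consequence._value2member_map_
                else Consequence.other,
                af_eas=float(af_eas) if af_eas is not None else None,
                af_overall=float(af_all) if af_all is not None else None,
                clinvar_status=ClinvarStatus(_opt(row.get("clinvar_status")) or "unreported"),
                same_aa_known_pathogenic=_parse_bool(row.get("same_aa_known_pathogenic", "0") or "0"),
                same_residue_known_pathogenic=_parse_bool(
                    row.get("same_residue_known_pathogenic", "0") or "0"
                ),
            )
        )
    return variants


def pon_filter(mutations, pon_index: dict, max_pon_count: int):
    """Split mutations into (kept, removed) by panel-of-normals recurrence.

    A mutation is removed iff its variant key was seen in more than
    ``max_pon_count`` normal samples; variants absent from the index count
    as 0.  Input order is preserved in both outputs.
    """
    if max_pon_count < 0:
        raise ValueError("max_pon_count must be >= 0")
    kept, removed = [], []
    for mut in mutations:
        if pon_index.get(mut.key, 0) > max_pon_count:
            removed.append(mut)
        else:
            kept.append(mut)
    return kept, removed


def build_alteration_matrix(cohort, feature_level: str = "gene", include_cnv: bool = False,
                            catalog=None) -> pd.DataFrame:
    """Binary samples x features alteration matrix.

    A cell is 1 iff the sample carries at least one somatic mutation in the
    feature (plus, when ``include_cnv``, a CNV call in it).  Samples with no
    alterations remain as all-zero rows.  ``feature_level='pathway'``
    aggregates through the pathway catalog.
    """
    if feature_level not in {"gene", "pathway"}:
        raise ValueError(f"unknown feature_level: {feature_level!r}")
    sample_ids = cohort.sample_ids
    genes = sorted({m.gene_symbol for m in cohort.somatic})
    if include_cnv:
        genes = sorted(set(genes) | {c.gene_symbol for c in cohort.cnv})
    matrix = pd.DataFrame(0, index=pd.Index(sample_ids, name="sample_id"),
                          columns=genes, dtype="int8")
    for m in cohort.somatic:
        matrix.loc[m.sample_id, m.gene_symbol] = 1
    if include_cnv:
        for c in cohort.cnv:
            if c.sample_id in matrix.index:
                matrix.loc[c.sample_id, c.gene_symbol] = 1
    if feature_level == "pathway":
        from .pathways import default_catalog, pathway_matrix

        return pathway_matrix(matrix, catalog or default_catalog())
    return matrix


def write_matrix(matrix: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    write_table(matrix.reset_index(), path, meta)


def read_matrix(path) -> pd.DataFrame:
    df = _read_tsv(path)
    out = df.set_index(df.columns[0])
    return out.astype("int8")


def matrix_long_format(matrix: pd.DataFrame) -> pd.DataFrame:
    """Long-format (sample_id, feature, altered=1) rows for external plotting."""
    stacked = matrix.stack()
    long = stacked[stacked > 0].reset_index()
    long.columns = ["sample_id", "feature", "altered"]
    return long


def write_table(df: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    """Write a TSV with '#'-prefixed header metadata lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
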