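"""End-to-end orchestration: ingest -> landscape -> enrichment -> pathways
-> germline -> actionability, with per-stage record-count logging,
stage-named failures, and byte-stable outputs across reruns on identical
inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
import pandas as pd
import yaml

from . import __version__
from .model import Cohort

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Inputs, thresholds and output location of one pipeline run."""

    somatic: str = ""
    somatic_dialect: str = "maf"
    clinical: str = ""
    cnv: str = ""
    cnv_evaluable: str = ""
    germline: str = ""
    gene_context: str = ""
    pon: str = ""
    catalog: str = ""
    kb: str = ""
    reference_genes: str = ""
    reference_pathways: str = ""
    outdir: str = "results"
    hotspot_min_frequency: float = 0.02
    subtype_fdr: float = 0.25
    compare_fdr: float = 0.05
    germline_max_eas_af: float = 0.005
    charger_score_cutoff: int = 7
    pon_max_count: int = 2
    include_cnv_in_matrix: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.hotspot_min_frequency <= 1:
            raise ValueError("hotspot_min_frequency must be in [0,1]")
        for name in ("subtype_fdr", "compare_fdr"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0,1]")
        if not 0 < self.germline_max_eas_af <= 1:
            raise ValueError("germline_max_eas_af must be in (0,1]")
        if self.pon_max_count < 0:
            raise ValueError("pon_max_count must be >= 0")
        for name in ("somatic", "clinical"):
            path = getattr(self, name)
            if not path:
                raise FileNotFoundError(f"required input {name!r} not configured")
        for name in ("somatic", "clinical", "cnv", "cnv_evaluable", "germline",
                     "gene_context", "pon", "catalog", "kb", "reference_genes",
                     "reference_pathways"):
            path = getattr(self, name)
            if path and not Path(path).exists():
                raise FileNotFoundError(f"input {name!r}: no such file {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        # outdir is excluded: where results land does not change what they are
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def for_simulated(cls, cohort_dir, outdir, **overrides) -> "RunConfig":
        """Config pointing at a directory written by ``simulate.generate``."""
        d = Path(cohort_dir)
        cfg = cls(
            somatic=str(d / "somatic.maf"), somatic_dialect="maf",
            clinical=str(d / "clinical.tsv"), cnv=str(d / "cnv.tsv"),
            cnv_evaluable=str(d / "cnv_evaluable.tsv"), germline=str(d / "germline.tsv"),
            gene_context=str(d / "gene_context.tsv"), pon=str(d / "pon.tsv"),
            catalog=str(d / "pathways.tsv"), kb=str(d / "actionability_kb.tsv"),
            reference_genes=str(d / "reference_genes.tsv"),
            reference_pathways=str(d / "reference_pathways.tsv"),
            outdir=str(outdir),
        )
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - surfaced with stage name
                raise PipelineError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a dict of output paths.

    Every stage logs record counts in and out; a failure halts with a
    stage-named :class:`PipelineError`.  Outputs are deterministic
    functions of the inputs and configuration.
    """
    from . import actionability as act
    from . import germline as germ
    from . import io as io_
    from . import landscape as ls
    from . import pathways as pw
    from . import stats as st

    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"tool": f"oncopanel {__version__}", "config": config.config_hash(),
            "seed": config.seed}
    outputs = {}

    def emit(name, df):
        path = outdir / name
        io_.write_table(df, path, meta)
        outputs[name] = str(path)

    # ---- ingest ----------------------------------------------------
    ingest = _stage("ingest")(_ingest)
    cohort, contexts, aux = ingest(config, io_, germ, emit)
    io_.write_matrix(aux["matrix"], outdir / "gene_matrix.tsv", meta)
    outputs["gene_matrix.tsv"] = str(outdir / "gene_matrix.tsv")
    emit("gene_matrix_long.tsv", io_.matrix_long_format(aux["matrix"]))

    # ---- landscape -------------------------------------------------
    @_stage("landscape")
    def _landscape():
        emit("gene_frequency.tsv", ls.gene_frequency(cohort, "none"))
        emit("gene_frequency_by_subtype.tsv", ls.gene_frequency(cohort, "subtype"))
        hotspots = ls.detect_hotspots(cohort.somatic, len(cohort.samples),
                                      config.hotspot_min_frequency)
        emit("hotspots.tsv", pd.DataFrame(
            [dict(gene_symbol=h.gene_symbol, protein_change=h.protein_change,
                  n_samples=h.n_samples, frequency=h.frequency) for h in hotspots]))
        per_sample, load = ls.mutation_load(cohort, "subtype")
        emit("mutation_load.tsv", per_sample)
        (outdir / "mutation_load_test.json").write_text(
            json.dumps(load, sort_keys=True) + "\n")
        top_genes = (ls.gene_frequency(cohort, "none").nlargest(8, "frequency")["feature"]
                     .tolist())
        vafs, vaf_p = ls.vaf_summary(cohort.somatic, sorted(top_genes))
        vafs["across_gene_p"] = vaf_p
        emit("vaf_summary.tsv", vafs)
        emit("cnv_frequency.tsv", ls.cnv_frequency(
            cohort.cnv, cohort.samples, "none", cohort.cnv_evaluable_ids))
        emit("oncoprint_long.tsv", ls.oncoprint_long(cohort.somatic))
    _landscape()

    # ---- enrichment ------------------------------------------------
    @_stage("enrichment")
    def _enrich():
        matrix = aux["matrix"]
        emit("subtype_enrichment.tsv", st.enrichment_frame(
            st.subtype_enrichment(matrix, cohort.samples, config.subtype_fdr)))
        for cov in ("menopause", "stage"):
            try:
                res = st.covariate_enrichment(matrix, cohort.samples, cov, config.compare_fdr)
                emit(f"enrichment_{cov}.tsv", st.enrichment_frame(res))
            except ValueError as exc:
                log.info("covariate %s skipped: %s", cov, exc)
    _enrich()

    # ---- pathways --------------------------------------------------
    @_stage("pathways")
    def _pathways():
        catalog = pw.load_catalog(config.catalog) if config.catalog else pw.default_catalog()
        pmat = pw.pathway_matrix(aux["matrix"], catalog)
        aux["pathway_matrix"] = pmat
        io_.write_matrix(pmat, outdir / "pathway_matrix.tsv", meta)
        outputs["pathway_matrix.tsv"] = str(outdir / "pathway_matrix.tsv")
        emit("pathway_frequency.tsv", pw.pathway_frequency(pmat, cohort.samples, "none"))
        emit("pathway_frequency_by_subtype.tsv",
             pw.pathway_frequency(pmat, cohort.samples, "subtype"))
        assoc = pw.pairwise_association(pmat, config.compare_fdr)
        emit("pathway_association.tsv", pw.association_frame(assoc))
        emit("pathway_cooccurrence_adjacency.tsv", pw.cooccurrence_adjacency(assoc))
    _pathways()

    # ---- cross-cohort comparison ------------------------------------
    @_stage("cohort_compare")
    def _compare():
        if config.reference_genes:
            ours = ls.gene_frequency(cohort, "none")[["feature", "n_altered", "n_total"]]
            ref = io_.read_table(config.reference_genes)
            res, unshared = st.cohort_compare(ours, ref, config.compare_fdr)
            emit("compare_genes.tsv", st.enrichment_frame(res))
            emit("compare_genes_unshared.tsv", unshared)
            scatter = pd.DataFrame(
                [dict(feature=r.feature, freq_cohort=r.extra["freq_a"],
                      freq_reference=r.extra["freq_b"], q_value=r.q_value,
                      significant=r.significant) for r in res])
            emit("compare_genes_scatter.tsv", scatter)
        if config.reference_pathways and "pathway_matrix" in aux:
            ours = pw.pathway_frequency(aux["pathway_matrix"], cohort.samples, "none")
            ours = ours[["feature", "n_altered", "n_total"]]
            ref = io_.read_table(config.reference_pathways)
            res, _ = st.cohort_compare(ours, ref, config.compare_fdr)
            emit("compare_pathways.tsv", st.enrichment_frame(res))
    _compare()

    # ---- germline ---------------------------------------------------
    @_stage("germline")
    def _germline():
        if not cohort.germline:
            return
        kept, removed = germ.prefilter_rare(cohort.germline, config.germline_max_eas_af)
        log.info("germline prefilter: %d in, %d kept, %d removed",
                 len(cohort.germline), len(kept), len(removed))
        germ.classify_variants(kept, contexts, config.charger_score_cutoff)
        emit("germline_classified.tsv", germ.germline_frame(kept))
        n_patients = len({s.patient_id for s in cohort.samples})
        n_car, frac, per_gene = germ.carrier_summary(kept, n_patients)
        emit("germline_summary.tsv", pd.DataFrame(
            [dict(n_carriers=n_car, n_patients=n_patients, fraction=frac,
                  percent=round(100 * frac, 1))]))
        emit("germline_per_gene.tsv", pd.DataFrame(
            [dict(gene=g, n_carriers=k, percent=round(100 * k / n_patients, 2))
             for g, k in per_gene.items()]))
    _germline()

    # ---- actionability ----------------------------------------------
    @_stage("actionability")
    def _actionability():
        kb = act.load_kb(config.kb) if config.kb else act.default_kb()
        n_genes, n_drugs = act.kb_audit(kb)
        log.info("knowledge base: %d genes, %d drugs", n_genes, n_drugs)
        per_sample = act.annotate_cohort(cohort, kb)
        emit("actionability_per_sample.tsv", act.actionability_frame(per_sample))
        levels, counts = act.actionability_summary(per_sample, cohort.samples, "subtype")
        emit("actionability_levels.tsv", levels)
        emit("actionability_counts.tsv", counts)
    _actionability()

    manifest = dict(tool="oncopanel", version=__version__, config_hash=config.config_hash(),
                    seed=config.seed, outputs=sorted(outputs))
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outputs


def _ingest(config: RunConfig, io_, germ, emit):
    samples, mismatches = io_.read_clinical_table(config.clinical)
    log.info("clinical: %d samples, %d subtype mismatches", len(samples), len(mismatches))
    emit("clinical_subtype_mismatches.tsv", mismatches if len(mismatches) else
         pd.DataFrame(columns=["sample_id", "stated", "derived"]))
    mutations, rejects = io_.read_somatic_table(config.somatic, config.somatic_dialect)
    emit("somatic_rejects.tsv", rejects if len(rejects) else pd.DataFrame(columns=["reason"]))
    n_in = len(mutations)
    if config.pon:
        pon = io_.read_pon_table(config.pon)
        mutations, removed = io_.pon_filter(mutations, pon, config.pon_max_count)
        log.info("pon_filter: %d in = %d kept + %d removed", n_in, len(mutations), len(removed))
        emit("pon_removed.tsv", pd.DataFrame(
            [dict(sample_id=m.sample_id, gene_symbol=m.gene_symbol, chrom=m.chrom,
                  pos=m.pos, ref=m.ref_allele, alt=m.alt_allele) for m in removed]))
    cnv = io_.read_cnv_table(config.cnv) if config.cnv else []
    evaluable = None
    if config.cnv_evaluable:
        evaluable = set(io_.read_table(config.cnv_evaluable)["sample_id"].astype(str))
    germline = io_.read_germline_table(config.germline) if config.germline else []
    contexts = (germ.read_gene_context_table(config.gene_context)
                if config.gene_context else {})
    cohort = Cohort(samples=samples, somatic=mutations, cnv=cnv, germline=germline,
                    cnv_evaluable_ids=evaluable)
    matrix = io_.build_alteration_matrix(cohort, "gene", config.include_cnv_in_matrix)
    return cohort, contexts, {"matrix": matrix}
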