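"""Seeded synthetic-cohort generator.

Produces full cohorts (clinical + somatic + CNV + germline + panel-of-
normals + reference-cohort tables) whose statistical structure mirrors a
large breast-cancer panel-sequencing study: per-subtype gene mutation
frequencies with a 53% TP53 / 32% PIK3CA mixture, recurrent protein-change
hotspots (PIK3CA p.H1047R at ~13% of the cohort), per-gene Beta-distributed
VAFs with read support from a mean-1000x depth model, CNV frequencies over
a CNV-evaluable subset, injected mutual-exclusivity/co-occurrence coupling
(including a fully exclusive ARID1A/PTEN pair), and a germline carrier
structure scaled from 66 distinct carriers per 1134 patients.

Everything is reproducible from (spec, seed): identical inputs give
byte-identical output files.  Categorical cohort structure (arms, subtypes)
is assigned by largest-remainder quota so the printed arm sizes
(419/606/109 scaled) are reproduced exactly, then shuffled.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .germline import GeneContext
from .model import (
    ClinicalSample,
    Classification,
    ClinvarStatus,
    CnvCall,
    Cohort,
    CohortArm,
    Consequence,
    CopyNumberCall,
    GermlineVariant,
    Menopause,
    SampleOrigin,
    SomaticMutation,
    Stage,
    Subtype,
    VariantClass,
)

SUBTYPES = [s.value for s in Subtype]

#: Cohort-arm quota (neoadjuvant, surgical, advanced) at the reference
#: cohort size of 1134; scaled proportionally for other sizes.
ARM_COUNTS_AT_1134 = {"neoadjuvant": 419, "surgical": 606, "advanced": 109}

#: Subtype mixture (luminal A, luminal B/HER2-, luminal B/HER2+, HER2+, TN).
DEFAULT_SUBTYPE_PROPORTIONS = (0.10, 0.45, 0.15, 0.12, 0.18)

#: Per-gene mutation probability; a tuple gives per-subtype values in the
#: order above, a scalar applies to every subtype.  TP53 and PIK3CA rows
#: are solved so the subtype mixture reproduces 53% / 32% overall.
DEFAULT_GENE_FREQS: dict = {
    "TP53": (0.17, 0.4126, 0.63, 0.74, 0.80),
    "PIK3CA": (0.35, 0.38, 0.30, 0.215, 0.24),
    "NF1": 0.10,
    "KMT2C": 0.09,
    "MAP3K1": 0.08,
    "KMT2D": 0.07,
    "GATA3": (0.10, 0.13, 0.02, 0.02, 0.02),
    "ARID1A": 0.06,
    "CDH1": 0.05,
    "AKT1": (0.12, 0.06, 0.01, 0.01, 0.01),
    "PTEN": (0.03, 0.03, 0.03, 0.03, 0.10),
    "SF3B1": (0.12, 0.02, 0.02, 0.02, 0.02),
    "SMO": (0.05, 0.005, 0.005, 0.005, 0.005),
    "CBFB": (0.05, 0.01, 0.01, 0.01, 0.01),
    "FAM47C": (0.01, 0.01, 0.01, 0.01, 0.06),
    "KDM6A": (0.01, 0.01, 0.01, 0.01, 0.05),
    "XDH": (0.01, 0.04, 0.01, 0.01, 0.01),
    "NOTCH1": 0.05, "NOTCH2": 0.03, "NOTCH3": 0.02, "FBXW7": 0.02,
    "SPEN": 0.03, "CREBBP": 0.02, "EP300": 0.02,
    "ATM": 0.02, "CHEK2": 0.01,
    "PIK3R1": 0.035, "MTOR": 0.025, "INPP4B": 0.02, "TSC2": 0.02, "STK11": 0.01,
    "ERBB2": 0.04, "ERBB3": 0.04, "FGFR1": 0.03, "FGFR2": 0.03,
    "KRAS": 0.02, "BRAF": 0.02, "EGFR": 0.03, "ALK": 0.02, "ROS1": 0.02, "RET": 0.02,
    "APC": 0.04, "CTNNB1": 0.02, "AXIN1": 0.01,
    "RB1": 0.04, "CDKN2A": 0.015, "CCND1": 0.01,
    "SMAD4": 0.01, "TGFBR2": 0.01,
    "MYC": 0.01,
    "NF2": 0.02,
    "ATRX": 0.03, "DNMT3A": 0.04, "MEN1": 0.02,
    "ESR1": 0.01, "RUNX1": 0.03,
}

#: Hotspot protein changes: gene -> {protein_change: (share of that gene's
#: mutations, variant class)}.  Shares back out the printed cohort-level
#: hotspot frequencies (e.g. PIK3CA p.H1047R 13% / 32% mutated ~ 0.41).
DEFAULT_HOTSPOT_FRACTIONS: dict = {
    "PIK3CA": {"p.H1047R": (0.41, "missense"), "p.E545K": (0.12, "missense"),
               "p.E542K": (0.06, "missense")},
    "AKT1": {"p.E17K": (0.92, "missense")},
    "KMT2C": {"p.K2797fs": (0.22, "frameshift")},
    "TP53": {"p.R248Q": (0.038, "missense"), "p.H179R": (0.030, "missense"),
             "p.R282W": (0.025, "missense"), "p.Y220C": (0.020, "missense"),
             "p.R213X": (0.018, "nonsense"), "p.Y163C": (0.015, "missense")},
    "SF3B1": {"p.K700E": (0.75, "missense")},
    "SMO": {"p.L23del": (0.80, "inframe_indel")},
    "GATA3": {"p.P409fs": (0.15, "frameshift")},
    "ESR1": {"p.D538G": (0.50, "missense")},
    "NF2": {"p.G240W": (0.15, "missense"), "p.Q324K": (0.15, "missense"),
            "p.L75I": (0.10, "missense"), "p.P257T": (0.08, "missense")},
}

#: Per-gene Beta(alpha, beta) VAF model; clonal heterozygous events at
#: high purity motivate the mode ~0.33 default.
DEFAULT_VAF_BETA: dict = {"default": (2.0, 3.0), "PIK3CA": (3.0, 2.6), "AKT1": (3.0, 2.6)}

#: (gene, call, frequency among CNV-evaluable samples).  The three 17q12
#: amplicon genes are drawn conditionally on HER2 IHC status instead.
DEFAULT_CNV_FREQS = [
    ("TRPS1", "amplification", 0.06), ("MYC", "amplification", 0.06),
    ("ERLIN2", "amplification", 0.06), ("PLPP5", "amplification", 0.06),
    ("NSD3", "amplification", 0.06), ("FGFR1", "amplification", 0.06),
    ("CCND1", "amplification", 0.05),
    ("PTEN", "deletion", 0.04), ("CDKN2A", "deletion", 0.03), ("RB1", "deletion", 0.02),
]
HER2_AMPLICON = ("ERBB2", "MIEN1", "GRB7")
HER2_AMPLICON_P = {"her2_pos": 0.85, "her2_neg": 0.02}

#: Injected pairwise coupling (feature_i, feature_j, target odds ratio);
#: the ARID1A/PTEN pair is fully exclusive by construction.
DEFAULT_COUPLING = [
    ("ARID1A", "PTEN", 0.0),
    ("NF1", "RUNX1", 5.0),
    ("NF1", "ATRX", 5.0),
    ("NF1", "DNMT3A", 4.0),
]

#: Germline carrier gene events at the reference size of 1134 (72 gene
#: events over 66 distinct carrier patients).
GERMLINE_GENE_COUNTS_AT_1134 = {
    "BRCA1": 22, "ALK": 5, "BRCA2": 5, "CHEK2": 5, "ATR": 4, "RB1": 4,
    "TP53": 3, "TSC2": 3, "APC": 3, "ETV6": 3, "BRAF": 2, "NF1": 2,
    "PTEN": 2, "SMARCA4": 2, "STK11": 2, "KRAS": 2, "MTAP": 2, "SMAD4": 1,
}
GERMLINE_CARRIERS_AT_1134 = 66
#: Oncogenes whose carrier variants are ClinVar cancer-pathogenic missense
#: rather than truncating loss-of-function events.
GERMLINE_NON_LOF = {"ALK", "BRAF", "KRAS"}

#: Reference (comparison) cohort frequency tables for cross-cohort tests;
#: pathway rows anchor to printed comparison values (p53 31%, RTK-RAS 18%,
#: Notch 11%, Wnt 1%, Hippo 0%), gene rows are representative Western
#: primary-breast-cancer frequencies.
REFERENCE_N = 869
REFERENCE_GENE_FREQS = {
    "TP53": 0.35, "PIK3CA": 0.33, "GATA3": 0.11, "CDH1": 0.09, "MAP3K1": 0.08,
    "KMT2C": 0.06, "ARID1A": 0.06, "PTEN": 0.05, "KMT2D": 0.05, "ESR1": 0.04,
    "NF1": 0.04, "AKT1": 0.03, "ERBB2": 0.03, "NOTCH1": 0.03, "RUNX1": 0.03,
    "RB1": 0.02, "SF3B1": 0.02, "CBFB": 0.02, "APC": 0.01, "KDM6A": 0.01,
    "FBXW7": 0.01, "SMAD4": 0.005, "CTNNB1": 0.004, "NF2": 0.002,
}
REFERENCE_PATHWAY_FREQS = {
    "p53": 0.31, "PI3K": 0.42, "RTK_RAS": 0.18, "Notch": 0.11, "cell_cycle": 0.09,
    "Wnt": 0.01, "TGF_beta": 0.01, "Myc": 0.004, "Hippo": 0.0,
}

#: Artifact variants recorded in the panel of normals (absent from the
#: per-gene frequency model; the PON filter should remove them).
PON_ARTIFACTS = [
    ("MUC16", "7", 5001000, "G", "A", 40),
    ("TTN", "2", 9002000, "C", "T", 25),
    ("FLG", "1", 3003000, "T", "C", 10),
]
ARTIFACT_SAMPLE_FRACTION = 0.02

NON_HOTSPOT_CLASS_P = {
    "missense": 0.62, "nonsense": 0.12, "frameshift": 0.14,
    "splice_site": 0.07, "inframe_indel": 0.03, "other": 0.02,
}

_AA = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort; the defaults are the study conditions."""

    n_samples: int = 1134
    seed: Optional[int] = None
    subtype_proportions: tuple = DEFAULT_SUBTYPE_PROPORTIONS
    gene_freqs: dict = dc_field(default_factory=lambda: dict(DEFAULT_GENE_FREQS))
    hotspot_fractions: dict = dc_field(default_factory=lambda: dict(DEFAULT_HOTSPOT_FRACTIONS))
    vaf_beta: dict = dc_field(default_factory=lambda: dict(DEFAULT_VAF_BETA))
    cnv_freqs: list = dc_field(default_factory=lambda: list(DEFAULT_CNV_FREQS))
    coupling: list = dc_field(default_factory=lambda: list(DEFAULT_COUPLING))
    germline_gene_counts: dict = dc_field(
        default_factory=lambda: dict(GERMLINE_GENE_COUNTS_AT_1134))
    mean_depth: float = 1000.0
    cnv_evaluable_fraction: float = 1114 / 1134

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducible generation")
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ValueError("subtype_proportions must sum to 1")
        for g, f in self.gene_freqs.items():
            vals = f if isinstance(f, tuple) else (f,)
            if any(not 0 <= v <= 1 for v in vals):
                raise ValueError(f"gene frequency out of [0,1] for {g}")


def largest_remainder(n: int, proportions) -> list:
    """Integer quotas summing to n, by the largest-remainder method."""
    raw = np.asarray(proportions, dtype=float) * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base))
    for i in order[:short]:
        base[i] += 1
    return base.tolist()


def solve_joint_cell(p_i: float, p_j: float, odds_ratio: float) -> float:
    """Co-occurrence cell probability p11 from two marginals and a target OR.

    Solves OR = p11*p00 / (p10*p01) via the standard quadratic root and
    raises on infeasible combinations (no valid probability).
    """
    lo, hi = max(0.0, p_i + p_j - 1.0), min(p_i, p_j)
    if odds_ratio == 1.0:
        p11 = p_i * p_j
    elif odds_ratio == 0.0:
        p11 = 0.0
    elif np.isinf(odds_ratio):
        p11 = hi
    else:
        s = 1.0 + (p_i + p_j) * (odds_ratio - 1.0)
        disc = s * s - 4.0 * odds_ratio * (odds_ratio - 1.0) * p_i * p_j
        if disc < 0:
            raise ValueError(f"infeasible coupling: OR={odds_ratio} with marginals {p_i}, {p_j}")
        p11 = (s - np.sqrt(disc)) / (2.0 * (odds_ratio - 1.0))
    if not (lo - 1e-12 <= p11 <= hi + 1e-12):
        raise ValueError(f"infeasible coupling: OR={odds_ratio} with marginals {p_i}, {p_j}")
    return float(np.clip(p11, lo, hi))


def _gene_chrom_base(gene: str) -> tuple:
    h = zlib.crc32(gene.encode())
    return str(h % 22 + 1), 1_000_000 + h % 100_000_000


def _residue_of(protein_change: str) -> int:
    digits = "".join(ch for ch in protein_change if ch.isdigit())
    return int(digits) if digits else 1


def _freq_vector(freq) -> np.ndarray:
    if isinstance(freq, tuple):
        return np.asarray(freq, dtype=float)
    return np.full(len(SUBTYPES), float(freq))


def _alleles(rng, variant_class: VariantClass) -> tuple:
    b = _BASES[rng.integers(4)]
    if variant_class is VariantClass.frameshift:
        return b + "A", b
    if variant_class is VariantClass.inframe_indel:
        return b + "AAA", b
    alt = _BASES[(rng.integers(1, 4) + _BASES.index(b)) % 4]
    return b, alt


def generate(spec: CohortSpec, outdir=None) -> Cohort:
    """Generate a cohort from a :class:`CohortSpec`; optionally write all input files.

    Returns the in-memory :class:`Cohort` (post panel-of-normals, i.e. the
    clean truth).  When ``outdir`` is given, writes the exact file dialects
    the readers consume - MAF (with PON artifacts injected), clinical,
    CNV, germline, gene-context, PON, pathway catalog, knowledge base and
    reference-cohort TSVs - plus a manifest recording spec and seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples

    samples = _make_samples(rng, spec)
    somatic = _make_somatic(rng, spec, samples)
    cnv, cnv_ids = _make_cnv(rng, spec, samples)
    germline, contexts = _make_germline(rng, spec, samples)
    cohort = Cohort(samples=samples, somatic=somatic, cnv=cnv, germline=germline,
                    cnv_evaluable_ids=cnv_ids)
    if outdir is not None:
        _write_cohort(Path(outdir), spec, cohort, contexts, rng)
    return cohort


def _make_samples(rng, spec: CohortSpec) -> list:
    n = spec.n_samples
    subtype_quota = largest_remainder(n, spec.subtype_proportions)
    subtype_idx = np.repeat(np.arange(5), subtype_quota)
    rng.shuffle(subtype_idx)
    arm_props = np.array([ARM_COUNTS_AT_1134[a] for a in ("neoadjuvant", "surgical", "advanced")],
                         dtype=float)
    arm_quota = largest_remainder(n, arm_props / arm_props.sum())
    arm_idx = np.repeat(np.arange(3), arm_quota)
    rng.shuffle(arm_idx)
    arms = ["neoadjuvant", "surgical", "advanced"]

    samples = []
    for i in range(n):
        sid = f"S{i + 1:04d}"
        st = Subtype(SUBTYPES[subtype_idx[i]])
        er = pr = her2 = False
        ki67 = None
        if st is Subtype.luminal_A:
            er = pr = True
            ki67 = round(float(rng.uniform(0.02, 0.14)), 3)
        elif st is Subtype.luminal_B_HER2neg:
            er = True
            pr = bool(rng.random() < 0.7)
            ki67 = round(float(rng.uniform(0.15, 0.90)), 3)
        elif st is Subtype.luminal_B_HER2pos:
            er = True
            pr = bool(rng.random() < 0.6)
            her2 = True
            ki67 = round(float(rng.uniform(0.05, 0.90)), 3) if rng.random() < 0.8 else None
        elif st is Subtype.HER2pos:
            her2 = True
            ki67 = round(float(rng.uniform(0.05, 0.90)), 3) if rng.random() < 0.8 else None
        else:  # triple negative
            ki67 = round(float(rng.uniform(0.05, 0.90)), 3) if rng.random() < 0.8 else None
        arm = CohortArm(arms[arm_idx[i]])
        if arm is CohortArm.advanced:
            stage = Stage.IV
            origin = SampleOrigin.metastatic if rng.random() < 0.31 else SampleOrigin.primary
        else:
            stage = Stage(["I", "II", "III"][rng.choice(3, p=[0.28, 0.38, 0.34])])
            origin = SampleOrigin.primary
        if rng.random() < 0.02:
            stage = None
        meno = Menopause(["pre", "post", "missing"][rng.choice(3, p=[0.45, 0.50, 0.05])])
        samples.append(
            ClinicalSample(
                sample_id=sid, patient_id=f"P{i + 1:04d}", er_positive=er, pr_positive=pr,
                her2_positive=her2, ki67_fraction=ki67, subtype=st, stage=stage,
                cohort_arm=arm, sample_origin=origin, menopause=meno,
                age_years=int(np.clip(rng.normal(50, 11), 22, 90)),
            )
        )
    return samples


def _make_somatic(rng, spec: CohortSpec, samples) -> list:
    n = len(samples)
    subtype_idx = np.array([SUBTYPES.index(s.subtype.value) for s in samples])
    coupled_genes = {g for pair in spec.coupling for g in pair[:2]}
    indicators: dict = {}
    # independent genes
    for gene in sorted(spec.gene_freqs):
        if gene in coupled_genes:
            continue
        p = _freq_vector(spec.gene_freqs[gene])[subtype_idx]
        indicators[gene] = rng.random(n) < p
    # coupled pairs: draw the joint 2x2 law per subtype.  A gene appearing in
    # several couplings (e.g. a hub like NF1) is drawn once; later partners
    # are drawn conditionally on it so every stated pairwise OR holds.
    for gene_i, gene_j, target_or in spec.coupling:
        p_i = _freq_vector(spec.gene_freqs[gene_i])[subtype_idx]
        p_j = _freq_vector(spec.gene_freqs[gene_j])[subtype_idx]
        p11 = np.array([solve_joint_cell(p_i[k], p_j[k], target_or) for k in range(n)])
        if gene_i in indicators or gene_j in indicators:
            if gene_j in indicators:  # orient so gene_i is the one already drawn
                gene_i, gene_j = gene_j, gene_i
                p_i, p_j = p_j, p_i
            vi = indicators[gene_i]
            cond = np.where(vi, p11 / p_i, (p_j - p11) / (1.0 - p_i))
            indicators[gene_j] = rng.random(n) < cond
        else:
            u = rng.random(n)
            vi = u < p_i
            vj = np.where(vi, u < p11, (u - p_i) < (p_j - p11))
            indicators[gene_i] = vi
            indicators[gene_j] = vj

    mutations = []
    for gene in sorted(indicators):
        carriers = np.flatnonzero(indicators[gene])
        if carriers.size == 0:
            continue
        chrom, base = _gene_chrom_base(gene)
        hotspots = spec.hotspot_fractions.get(gene, {})
        names = list(hotspots)
        shares = np.array([hotspots[h][0] for h in names], dtype=float)
        rest = 1.0 - shares.sum()
        if rest < 0:
            raise ValueError(f"hotspot shares for {gene} exceed 1")
        choice_p = np.concatenate([shares, [rest]])
        alpha, beta = spec.vaf_beta.get(gene, spec.vaf_beta.get("default", (2.0, 3.0)))
        picks = rng.choice(len(names) + 1, size=carriers.size, p=choice_p)
        vafs = rng.beta(alpha, beta, size=carriers.size)
        depths = np.maximum(30, rng.poisson(spec.mean_depth, size=carriers.size))
        for idx, samp_i in enumerate(carriers):
            if picks[idx] < len(names):
                pchange = names[picks[idx]]
                vclass = VariantClass(hotspots[pchange][1])
                residue = _residue_of(pchange)
                # hotspot alleles are a deterministic function of the site
                ref, alt = ("G", "A") if vclass is not VariantClass.frameshift else ("GA", "G")
            else:
                vclass = VariantClass(
                    list(NON_HOTSPOT_CLASS_P)[rng.choice(len(NON_HOTSPOT_CLASS_P),
                                                         p=list(NON_HOTSPOT_CLASS_P.values()))]
                )
                residue = int(rng.integers(1, 801))
                ref, alt = _alleles(rng, vclass)
                pchange = _protein_change(rng, vclass, residue)
            alt_count = max(1, int(rng.binomial(depths[idx], vafs[idx])))
            mutations.append(
                SomaticMutation(
                    sample_id=samples[samp_i].sample_id, gene_symbol=gene, chrom=chrom,
                    pos=base + residue * 3, ref_allele=ref, alt_allele=alt,
                    variant_class=vclass, protein_change=pchange,
                    t_alt_count=alt_count, t_ref_count=int(depths[idx]) - alt_count,
                )
            )
    mutations.sort(key=lambda m: (m.sample_id, m.gene_symbol, m.pos))
    return mutations


def _protein_change(rng, vclass: VariantClass, residue: int) -> Optional[str]:
    aa1 = _AA[rng.integers(len(_AA))]
    if vclass is VariantClass.missense:
        aa2 = _AA[(rng.integers(1, len(_AA)) + _AA.index(aa1)) % len(_AA)]
        return f"p.{aa1}{residue}{aa2}"
    if vclass is VariantClass.nonsense:
        return f"p.{aa1}{residue}X"
    if vclass is VariantClass.frameshift:
        return f"p.{aa1}{residue}fs"
    if vclass is VariantClass.inframe_indel:
        return f"p.{aa1}{residue}del"
    return None  # splice-site / other: no protein-level notation


def _make_cnv(rng, spec: CohortSpec, samples) -> tuple:
    n = len(samples)
    n_eval = int(round(n * spec.cnv_evaluable_fraction))
    eval_pos = rng.choice(n, size=n_eval, replace=False)
    eval_pos.sort()
    calls = []
    her2_status = np.array([s.her2_positive for s in samples])
    for gene in HER2_AMPLICON:
        p = np.where(her2_status[eval_pos], HER2_AMPLICON_P["her2_pos"],
                     HER2_AMPLICON_P["her2_neg"])
        hit = rng.random(n_eval) < p
        for i in np.flatnonzero(hit):
            calls.append(CopyNumberCall(samples[eval_pos[i]].sample_id, gene,
                                        CnvCall.amplification))
    for gene, call, freq in spec.cnv_freqs:
        hit = rng.random(n_eval) < freq
        for i in np.flatnonzero(hit):
            calls.append(CopyNumberCall(samples[eval_pos[i]].sample_id, gene, CnvCall(call)))
    calls.sort(key=lambda c: (c.sample_id, c.gene_symbol, c.call.value))
    return calls, {samples[i].sample_id for i in eval_pos}


def _make_germline(rng, spec: CohortSpec, samples) -> tuple:
    n = len(samples)
    scale = n / 1134
    events = []
    for gene in sorted(spec.germline_gene_counts):
        events += [gene] * int(round(spec.germline_gene_counts[gene] * scale))
    n_events = len(events)
    n_carriers = min(n_events, int(round(GERMLINE_CARRIERS_AT_1134 * scale)))
    n_carriers = min(n_carriers, n)
    order = rng.permutation(n_events)
    carrier_pos = rng.choice(n, size=n_carriers, replace=False)
    assignment = {}  # event index -> patient position
    for slot, ev in enumerate(order[:n_carriers]):
        assignment[ev] = carrier_pos[slot]
    leftover = order[n_carriers:]
    for ev in leftover:
        gene = events[ev]
        # second gene event for an existing carrier, never duplicating a gene
        for _ in range(50):
            cand = carrier_pos[rng.integers(n_carriers)]
            taken = {events[e] for e, p in assignment.items() if p == cand}
            if gene not in taken:
                assignment[ev] = cand
                break
        else:
            assignment[ev] = carrier_pos[rng.integers(n_carriers)]

    variants = []
    contexts = {}
    for gene in sorted(set(spec.germline_gene_counts) | {"MSH6", "PALB2", "RAD51C"}):
        contexts[gene] = GeneContext(gene, is_cancer_gene=True,
                                     lof_mechanism=gene not in GERMLINE_NON_LOF)
    for ev, patient_pos in sorted(assignment.items()):
        gene = events[ev]
        patient = samples[patient_pos].patient_id
        chrom, base = _gene_chrom_base(gene)
        residue = int(rng.integers(1, 801))
        af = round(float(rng.uniform(0, 0.004)), 5) if rng.random() < 0.7 else None
        if gene in GERMLINE_NON_LOF:
            variants.append(GermlineVariant(
                patient_id=patient, gene_symbol=gene, chrom=chrom, pos=base + residue * 3,
                ref="G", alt="A", consequence=Consequence.missense, af_eas=af,
                clinvar_status=ClinvarStatus.pathogenic_cancer))
        elif rng.random() < 0.5:
            variants.append(GermlineVariant(
                patient_id=patient, gene_symbol=gene, chrom=chrom, pos=base + residue * 3,
                ref="CA", alt="C", consequence=Consequence.frameshift, af_eas=af,
                clinvar_status=ClinvarStatus.pathogenic_cancer))
        else:
            variants.append(GermlineVariant(
                patient_id=patient, gene_symbol=gene, chrom=chrom, pos=base + residue * 3,
                ref="TA", alt="T", consequence=Consequence.frameshift, af_eas=af,
                clinvar_status=ClinvarStatus.unreported))
    # background: uncertain variants in non-carriers and a few common alleles
    background_genes = ["MSH6", "PALB2", "RAD51C"]
    n_vus = int(round(0.04 * n))
    vus_pos = rng.choice(n, size=n_vus, replace=False)
    for p_i in sorted(vus_pos):
        gene = background_genes[rng.integers(len(background_genes))]
        chrom, base = _gene_chrom_base(gene)
        residue = int(rng.integers(1, 801))
        variants.append(GermlineVariant(
            patient_id=samples[p_i].patient_id, gene_symbol=gene, chrom=chrom,
            pos=base + residue * 3, ref="C", alt="T", consequence=Consequence.missense,
            af_eas=round(float(rng.uniform(0, 0.004)), 5),
            clinvar_status=ClinvarStatus.vus))
    n_common = int(round(0.02 * n))
    common_pos = rng.choice(n, size=n_common, replace=False)
    for p_i in sorted(common_pos):
        gene = background_genes[rng.integers(len(background_genes))]
        chrom, base = _gene_chrom_base(gene)
        variants.append(GermlineVariant(
            patient_id=samples[p_i].patient_id, gene_symbol=gene, chrom=chrom,
            pos=base + 12, ref="A", alt="G", consequence=Consequence.missense,
            af_eas=round(float(rng.uniform(0.01, 0.2)), 4),
            clinvar_status=ClinvarStatus.benign))
    variants.sort(key=lambda v: (v.patient_id, v.gene_symbol, v.pos))
    return variants, contexts


def make_reference_cohort(freq_table: dict, n_total: int) -> pd.DataFrame:
    """Frequency dict -> integer (feature, n_altered, n_total) reference table.

    ``n_altered = floor(freq * n_total + 0.5)`` (round half up, documented).
    """
    rows = [
        dict(feature=f, n_altered=int(np.floor(freq * n_total + 0.5)), n_total=n_total)
        for f, freq in sorted(freq_table.items())
    ]
    return pd.DataFrame(rows)


def null_cohort(n_samples: int, n_features: int, base_freq: float, seed: int) -> pd.DataFrame:
    """Structure-free binary matrix: independent Bernoulli(base_freq) cells."""
    rng = np.random.default_rng(seed)
    values = (rng.random((n_samples, n_features)) < base_freq).astype("int8")
    return pd.DataFrame(
        values,
        index=pd.Index([f"S{i + 1:04d}" for i in range(n_samples)], name="sample_id"),
        columns=[f"F{j + 1:04d}" for j in range(n_features)],
    )


def golden_germline_set():
    """Twenty constructed germline variants with hand-derived expected classes.

    Each entry is (variant, gene_context, expected classification); the
    expectations were worked out rule by rule from the scoring scheme
    (PVS1=8, PS1=7, PM4=2, PM5=2; likely pathogenic iff score > 7;
    pathogenic iff ClinVar cancer-pathogenic).
    """
    C, K = Consequence, ClinvarStatus
    lof = GeneContext("x", True, True)
    onco = GeneContext("x", True, False)
    nogene = GeneContext("x", False, False)

    def v(gene, cons, clinvar=K.unreported, same_aa=False, same_res=False, af=None):
        return GermlineVariant(
            patient_id="px", gene_symbol=gene, chrom="1", pos=100, ref="A", alt="T",
            consequence=cons, af_eas=af, clinvar_status=clinvar,
            same_aa_known_pathogenic=same_aa, same_residue_known_pathogenic=same_res)

    P, LP, U = Classification.pathogenic, Classification.likely_pathogenic, Classification.uncertain
    return [
        (v("BRCA1", C.frameshift), lof, LP),                      # PVS1 -> 8
        (v("BRCA1", C.frameshift, clinvar=K.pathogenic_cancer), lof, P),
        (v("TP53", C.missense, clinvar=K.vus, same_aa=True), lof, U),   # PS1 alone -> 7
        (v("BRCA2", C.stop_gained), lof, LP),
        (v("PALB2", C.missense, same_res=True), lof, U),          # PM5 -> 2
        (v("CHEK2", C.inframe_indel), lof, U),                    # PM4 -> 2
        (v("ATM", C.canonical_splice), lof, LP),
        (v("GENE1", C.stop_gained), nogene, U),                   # not a cancer gene
        (v("ALK", C.stop_gained), onco, U),                       # no LOF mechanism
        (v("TP53", C.start_lost), lof, LP),
        (v("BRAF", C.missense, clinvar=K.pathogenic_cancer), onco, P),
        (v("PTEN", C.missense, clinvar=K.pathogenic_other), lof, U),
        (v("APC", C.missense, clinvar=K.benign), lof, U),
        (v("BRCA2", C.frameshift, same_res=True), lof, LP),       # flag irrelevant: not missense
        (v("TP53", C.inframe_indel, same_aa=True), lof, U),       # PS1 needs missense; PM4 -> 2
        (v("MSH2", C.other), lof, U),
        (v("STK11", C.canonical_splice, clinvar=K.pathogenic_cancer), lof, P),
        (v("TP53", C.missense, same_aa=True, same_res=True), lof, U),  # PS1 only -> 7
        (v("RAD51C", C.inframe_indel, clinvar=K.vus), nogene, U),
        (v("NF1", C.frameshift, af=0.004), lof, LP),
    ]


def _write_cohort(outdir: Path, spec: CohortSpec, cohort: Cohort, contexts: dict, rng) -> None:
    from importlib import resources

    from .io import write_table

    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"tool": f"oncopanel {__version__}", "seed": spec.seed}

    # somatic MAF, with PON artifacts injected on top of the clean calls
    maf_rows = []
    inv_class = {
        VariantClass.missense: "Missense_Mutation", VariantClass.nonsense: "Nonsense_Mutation",
        VariantClass.frameshift: "Frame_Shift_Del", VariantClass.splice_site: "Splice_Site",
        VariantClass.inframe_indel: "In_Frame_Del", VariantClass.other: "Nonstop_Mutation",
    }
    for m in cohort.somatic:
        maf_rows.append(dict(
            Hugo_Symbol=m.gene_symbol, Chromosome=m.chrom, Start_Position=m.pos,
            Reference_Allele=m.ref_allele, Tumor_Seq_Allele2=m.alt_allele,
            Variant_Classification=inv_class[m.variant_class],
            HGVSp_Short=m.protein_change or "", t_alt_count=m.t_alt_count,
            t_ref_count=m.t_ref_count, Tumor_Sample_Barcode=m.sample_id))
    n = spec.n_samples
    for gene, chrom, pos, ref, alt, _count in PON_ARTIFACTS:
        hit = rng.random(n) < ARTIFACT_SAMPLE_FRACTION
        for i in np.flatnonzero(hit):
            maf_rows.append(dict(
                Hugo_Symbol=gene, Chromosome=chrom, Start_Position=pos,
                Reference_Allele=ref, Tumor_Seq_Allele2=alt,
                Variant_Classification="Missense_Mutation", HGVSp_Short="p.A1V",
                t_alt_count=45, t_ref_count=955,
                Tumor_Sample_Barcode=cohort.samples[i].sample_id))
    maf = pd.DataFrame(maf_rows).sort_values(
        ["Tumor_Sample_Barcode", "Hugo_Symbol", "Start_Position"], kind="mergesort")
    write_table(maf, outdir / "somatic.maf", meta)

    clin_rows = []
    for s in cohort.samples:
        clin_rows.append(dict(
            sample_id=s.sample_id, patient_id=s.patient_id,
            er=int(s.er_positive), pr=int(s.pr_positive), her2=int(s.her2_positive),
            ki67="" if s.ki67_fraction is None else s.ki67_fraction,
            subtype=s.subtype.value, stage=s.stage.value if s.stage else "",
            cohort_arm=s.cohort_arm.value if s.cohort_arm else "",
            sample_origin=s.sample_origin.value, menopause=s.menopause.value,
            age="" if s.age_years is None else s.age_years))
    write_table(pd.DataFrame(clin_rows), outdir / "clinical.tsv", meta)

    write_table(pd.DataFrame(
        [dict(sample_id=c.sample_id, gene_symbol=c.gene_symbol, call=c.call.value)
         for c in cohort.cnv]), outdir / "cnv.tsv", meta)
    write_table(pd.DataFrame(
        [dict(sample_id=sid) for sid in sorted(cohort.cnv_evaluable_ids)]),
        outdir / "cnv_evaluable.tsv", meta)

    write_table(pd.DataFrame(
        [dict(patient_id=v.patient_id, gene_symbol=v.gene_symbol, chrom=v.chrom, pos=v.pos,
              ref=v.ref, alt=v.alt, consequence=v.consequence.value,
              af_eas="" if v.af_eas is None else v.af_eas,
              af_overall="" if v.af_overall is None else v.af_overall,
              clinvar_status=v.clinvar_status.value,
              same_aa_known_pathogenic=int(v.same_aa_known_pathogenic),
              same_residue_known_pathogenic=int(v.same_residue_known_pathogenic))
         for v in cohort.germline]), outdir / "germline.tsv", meta)

    write_table(pd.DataFrame(
        [dict(gene=c.gene_symbol, is_cancer_gene=int(c.is_cancer_gene),
              lof_mechanism=int(c.lof_mechanism)) for c in
         sorted(contexts.values(), key=lambda c: c.gene_symbol)]),
        outdir / "gene_context.tsv", meta)

    write_table(pd.DataFrame(
        [dict(chrom=chrom, pos=pos, ref=ref, alt=alt, n_normals=count)
         for _gene, chrom, pos, ref, alt, count in PON_ARTIFACTS]
        + [dict(chrom="1", pos=55, ref="A", alt="C", n_normals=1)]),
        outdir / "pon.tsv", meta)

    for name in ("pathways.tsv", "actionability_kb.tsv"):
        text = resources.files("oncopanel.data").joinpath(name).read_text()
        (outdir / name).write_text(text)

    write_table(make_reference_cohort(REFERENCE_GENE_FREQS, REFERENCE_N),
                outdir / "reference_genes.tsv", meta)
    write_table(make_reference_cohort(REFERENCE_PATHWAY_FREQS, REFERENCE_N),
                outdir / "reference_pathways.tsv", meta)

    manifest = dict(
        tool="oncopanel", version=__version__, seed=spec.seed, n_samples=spec.n_samples,
        subtype_proportions=list(spec.subtype_proportions),
        files=sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
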