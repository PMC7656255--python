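"""Domain types for panel-sequencing cohort interpretation.

The objects here mirror what a clinical sequencing pipeline hands downstream:
one clinical record per sequenced sample (immunohistochemistry receptor
status plus derived molecular subtype), one record per called somatic
mutation (with read support and variant allele fraction), gene-level copy
number calls, and annotated germline variants carrying their classification
evidence trail.

Molecular subtyping follows the St Gallen surrogate definitions used in
breast-cancer pathology: ER/PR/HER2 status from immunostaining and a Ki67
proliferation cut-off of 14% separate luminal A from luminal B/HER2−
disease; HER2-positive and triple-negative tumors are called regardless of
Ki67.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Subtype(str, Enum):
    luminal_A = "luminal_A"
    luminal_B_HER2neg = "luminal_B_HER2neg"
    luminal_B_HER2pos = "luminal_B_HER2pos"
    HER2pos = "HER2pos"
    triple_negative = "triple_negative"


class CoarseSubtype(str, Enum):
    HRpos_HER2neg = "HRpos_HER2neg"
    HRpos_HER2pos = "HRpos_HER2pos"
    HRneg_HER2pos = "HRneg_HER2pos"
    TNBC = "TNBC"


#: Deterministic collapse of the five IHC subtypes onto the four coarse
#: hormone-receptor / HER2 groups used for cross-cohort comparison.
COARSE_MAP = {
    Subtype.luminal_A: CoarseSubtype.HRpos_HER2neg,
    Subtype.luminal_B_HER2neg: CoarseSubtype.HRpos_HER2neg,
    Subtype.luminal_B_HER2pos: CoarseSubtype.HRpos_HER2pos,
    Subtype.HER2pos: CoarseSubtype.HRneg_HER2pos,
    Subtype.triple_negative: CoarseSubtype.TNBC,
}


class VariantClass(str, Enum):
    missense = "missense"
    nonsense = "nonsense"
    frameshift = "frameshift"
    splice_site = "splice_site"
    inframe_indel = "inframe_indel"
    other = "other"


class CnvCall(str, Enum):
    amplification = "amplification"
    deletion = "deletion"


class Stage(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


class CohortArm(str, Enum):
    neoadjuvant = "neoadjuvant"
    surgical = "surgical"
    advanced = "advanced"


class SampleOrigin(str, Enum):
    primary = "primary"
    metastatic = "metastatic"


class Menopause(str, Enum):
    pre = "pre"
    post = "post"
    missing = "missing"


#: Ki67 proliferation fraction at or below this value is "low"
#: (the 14% St Gallen cut-off; comparison is ``<=`` exactly).
KI67_LOW_MAX = 0.14


class SubtypeUndeterminableError(ValueError):
    """Raised when the subtype rules require a Ki67 value that is missing."""


def derive_subtype(
    er_positive: bool,
    pr_positive: bool,
    her2_positive: bool,
    ki67_fraction: Optional[float] = None,
) -> Subtype:
    """Call the molecular subtype from IHC receptor status.

    Rules: luminal A = ER+ and PR+, HER2−, Ki67 low; luminal B/HER2− = HR+
    (ER or PR), HER2−, otherwise (covers the high-Ki67 definition and the
    ER/PR-discordant corner so the five classes partition the space);
    luminal B/HER2+ = HR+, HER2+; HER2+ = ER−/PR−, HER2+; triple negative =
    all three negative.  Ki67 is consulted only for HER2−, HR+ tumors and a
    missing value there raises :class:`SubtypeUndeterminableError` rather
    than silently defaulting.
    """
    hr_positive = er_positive or pr_positive
    if her2_positive:
        return Subtype.luminal_B_HER2pos if hr_positive else Subtype.HER2pos
    if not hr_positive:
        return Subtype.triple_negative
    # HER2-negative, HR-positive: Ki67 decides luminal A vs B
    if ki67_fraction is None or (isinstance(ki67_fraction, float) and math.isnan(ki67_fraction)):
        raise SubtypeUndeterminableError(
            "Ki67 fraction is required to separate luminal A from luminal B/HER2- "
            "for an ER/PR-positive, HER2-negative tumor"
        )
    if er_positive and pr_positive and ki67_fraction <= KI67_LOW_MAX:
        return Subtype.luminal_A
    return Subtype.luminal_B_HER2neg


def coarse_subtype(subtype: Subtype) -> CoarseSubtype:
    return COARSE_MAP[Subtype(subtype)]


@dataclass
class ClinicalSample:
    sample_id: str
    patient_id: str
    er_positive: bool
    pr_positive: bool
    her2_positive: bool
    ki67_fraction: Optional[float] = None
    subtype: Optional[Subtype] = None
    stage: Optional[Stage] = None
    cohort_arm: Optional[CohortArm] = None
    sample_origin: SampleOrigin = SampleOrigin.primary
    menopause: Menopause = Menopause.missing
    age_years: Optional[int] = None

    def __post_init__(self) -> None:
        if self.subtype is None:
            self.subtype = derive_subtype(
                self.er_positive, self.pr_positive, self.her2_positive, self.ki67_fraction
            )
        else:
            self.subtype = Subtype(self.subtype)

    @property
    def coarse_subtype(self) -> CoarseSubtype:
        return coarse_subtype(self.subtype)


@dataclass
class SomaticMutation:
    sample_id: str
    gene_symbol: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_class: VariantClass = VariantClass.other
    protein_change: Optional[str] = None
    t_alt_count: Optional[int] = None
    t_ref_count: Optional[int] = None
    vaf: Optional[float] = None

    def __post_init__(self) -> None:
        self.variant_class = VariantClass(self.variant_class)
        if self.t_alt_count is not None and self.t_ref_count is not None:
            depth = self.t_alt_count + self.t_ref_count
            if depth <= 0:
                raise ValueError(
                    f"zero depth: t_alt_count + t_ref_count == 0 for {self.key}"
                )
            # VAF is recomputed from counts whenever both are present
            self.vaf = self.t_alt_count / depth

    @property
    def key(self) -> tuple:
        """Variant identity used by the panel-of-normals filter."""
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class CopyNumberCall:
    sample_id: str
    gene_symbol: str
    call: CnvCall

    def __post_init__(self) -> None:
        self.call = CnvCall(self.call)


class Consequence(str, Enum):
    stop_gained = "stop_gained"
    frameshift = "frameshift"
    canonical_splice = "canonical_splice"
    start_lost = "start_lost"
    missense = "missense"
    inframe_indel = "inframe_indel"
    other = "other"


class ClinvarStatus(str, Enum):
    pathogenic_cancer = "pathogenic_cancer"
    pathogenic_other = "pathogenic_other"
    benign = "benign"
    vus = "vus"
    unreported = "unreported"


class Classification(str, Enum):
    pathogenic = "pathogenic"
    likely_pathogenic = "likely_pathogenic"
    uncertain = "uncertain"


@dataclass
class GermlineVariant:
    patient_id: str
    gene_symbol: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Consequence = Consequence.other
    af_eas: Optional[float] = None
    af_overall: Optional[float] = None
    clinvar_status: ClinvarStatus = ClinvarStatus.unreported
    same_aa_known_pathogenic: bool = False
    same_residue_known_pathogenic: bool = False
    evidence: list = field(default_factory=list)
    score: int = 0
    classification: Optional[Classification] = None

    def __post_init__(self) -> None:
        self.consequence = Consequence(self.consequence)
        self.clinvar_status = ClinvarStatus(self.clinvar_status)


@dataclass
class Cohort:
    """A full analysis cohort: clinical samples plus all call tables."""

    samples: list
    somatic: list = field(default_factory=list)
    cnv: list = field(default_factory=list)
    germline: list = field(default_factory=list)
    cnv_evaluable_ids: Optional[set] = None

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        dup = {i for i in ids if ids.count(i) > 1} if len(ids) != len(set(ids)) else set()
        if dup:
            raise ValueError(f"duplicate sample_ids: {sorted(dup)}")
        known = set(ids)
        orphans = {m.sample_id for m in self.somatic if m.sample_id not in known}
        if orphans:
            raise ValueError(f"somatic mutations reference unknown samples: {sorted(orphans)[:5]}")

    @property
    def sample_ids(self) -> list:
        return [s.sample_id for s in self.samples]

    def samples_by_id(self) -> dict:
        return {s.sample_id: s for s in self.samples}
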