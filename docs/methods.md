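# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limitations of the package.

## Subtyping

Surrogate molecular subtypes follow the St Gallen IHC definitions: luminal A
requires ER+ and PR+, HER2− and Ki67 ≤ 14% (the comparison is `<=` on the
proportion 0.14 exactly); luminal B/HER2+ is any HR+ (ER or PR positive)
HER2+ tumor; HER2+ is HR−/HER2+; triple negative is ER−/PR−/HER2−, all
regardless of Ki67.  The verbal definitions leave one corner unassigned:
an ER/PR-discordant, HER2−, Ki67-low tumor is neither "ER+ and PR+" (luminal
A) nor "high Ki67" (the luminal B/HER2− wording).  We close the partition by
assigning every HR+/HER2− tumor that is not luminal A to luminal B/HER2−,
so the five classes are total and mutually exclusive over the IHC space.
Ki67 is consulted only on the HR+/HER2− branch; a missing value there is a
hard error (`SubtypeUndeterminableError`), never a silent default.

## Frequencies, hotspots, load and VAF

Mutation frequencies use the full group of sequenced samples as the
denominator, not just mutated ones; CNV frequencies use the CNV-evaluable
subset, which can be smaller than the cohort.  Hotspots are recurrent
identical protein changes; a sample counts once per (gene, protein change).
The reporting threshold is a cohort frequency of 2%, applied with a small
tolerance (5×10⁻⁴) below the cut so that entries whose printed
whole-percent value rounds to 2% are not dropped by floating-point
hair-splitting; the exact inclusion rule at the boundary is a convention,
and the threshold is a parameter.  Mutation load is the raw count of
somatic records per sample (zero-mutation samples included) compared across
subtypes with the tie-corrected Kruskal–Wallis test (chi-square
approximation; an all-identical degenerate input short-circuits to p = 1).
VAF summaries report per-gene quartiles and the same Kruskal–Wallis
machinery across genes.

## Enrichment machinery

All categorical association testing goes through one primitive: the
two-sided Fisher exact test, defined as the sum of hypergeometric
probabilities of all tables (at fixed margins) no more probable than the
observed one.  The implementation delegates to `scipy.stats.fisher_exact`;
the test suite verifies exact agreement with an independent brute-force
hypergeometric enumeration for every 2×2 table with N ≤ 40.  Odds ratios
are the sample cross-product (a·d)/(b·c), reported as +∞ / 0 / NaN at
degenerate cells; confidence intervals are Woolf logit intervals,
exp(ln OR ± z·√(1/a+1/b+1/c+1/d)), with the Haldane–Anscombe +0.5
correction applied to all four cells whenever any cell is zero, which keeps
intervals finite and plottable.  Multiple testing uses Benjamini–Hochberg
step-up (via statsmodels), with one family per analysis: all gene×subtype
pairs form one family in subtype enrichment, all shared features one family
in a cohort comparison, all feature pairs one family in the pairwise
association scan.  Subtype enrichment is one-vs-rest (each subtype against
all others); pairwise-subtype contrasts can be had by subsetting the
samples.  Odds ratios are oriented so OR > 1 means enriched in the
first-named group.

Default significance thresholds: FDR < 0.25 for subtype enrichment,
FDR < 0.05 for cohort comparisons, covariate enrichment and
exclusivity/co-occurrence patterns.  All are configurable; the 0.25 and
0.05 values mirror the conventions of the large published panel studies
this package is designed to re-analyze.

## Pathway aggregation and exclusivity

Nine canonical oncogenic signaling pathways (cell cycle, Hippo, Notch,
PI3K, Wnt, RTK/RAS, p53, TGF-β, Myc) are represented as gene-membership
sets.  The shipped catalog is a curation of the widely used TCGA pathway
templates restricted to genes commonly present on breast-cancer panels; it
is deliberately replaceable input (a two-column TSV), because membership
curation is itself a modeling decision.  A pathway is altered in a sample
iff at least one member gene is altered; genes in several pathways
contribute to each.  Pairwise association between binary features uses the
co-occurrence 2×2 table (n11 joint, n10/n01 single, n00 neither), Fisher p,
BH across all pairs, and labels significant pairs co-occurring (OR > 1) or
mutually exclusive (OR < 1).  log10(OR) is capped at ±3: a finite color
scale for fully exclusive (OR = 0) and fully nested (OR = ∞) pairs, chosen
to exceed any finite OR observable at cohort sizes near 1000 with nonzero
margins.  Features altered in zero or all samples are skipped (degenerate
margins) and logged.

## Germline classification

Variants are first restricted to rare alleles: East-Asian population
frequency strictly below 0.5%.  A variant absent from the population
database is treated as rare and retained (absence implies rarity); the
count of such variants is logged so the choice is auditable.  Scoring is
additive over evidence modules with the published CharGer point weights
(very strong 8, strong 7, moderate 2), exposed as configuration:

- **PVS1 (8)** — truncating consequence (stop gained, frameshift, canonical
  splice, start lost) in a cancer-susceptibility gene whose mechanism is
  loss of function;
- **PS1 (7)** — missense producing the same amino-acid change as a
  cancer-related ClinVar-pathogenic variant;
- **PM4 (2)** — protein-length-changing inframe event;
- **PM5 (2)** — novel missense at a residue carrying a different
  cancer-related ClinVar-pathogenic missense (suppressed when PS1 fires).

PM2 (absent/rare in population databases) is disabled by design: rarity is
already a hard prefilter here, and scoring it again would double-count the
same evidence.  Other supporting-level modules are off by default because
the input schema carries no annotations for them; callers can gate in
additional scorers.  Classification: ClinVar cancer-pathogenic variants are
pathogenic outright; otherwise a score strictly greater than 7 is likely
pathogenic; everything else is uncertain.  A consequence of the strict cut
is that PS1 alone (7 points) does not reach likely pathogenic — this is
intentional and covered by the golden-set tests.  "Cancer-related" for
PS1/PM5 is operationalized as a matched cancer-pathogenic ClinVar record,
supplied as boolean flags in the input table; no live database queries are
made.

Cross-population carrier comparisons use Pearson chi-square on the
populations × (carrier, non-carrier) table, switching to a Freeman–Halton
exact enumeration (multivariate hypergeometric, two-sided by point
probability) when any expected cell is below 5 and the total carrier count
is small enough to enumerate.

## Actionability

Evidence levels follow the OncoKB convention, ordered L1 > L2A > L2B >
L3A > L3B > L4, with A/B distinguishing evidence in the pertinent versus a
different tumor type.  Matching semantics: exact protein change on (gene,
HGVS p. short form); truncating on nonsense/frameshift/splice; any-oncogenic
on any non-silent alteration in the gene, optionally restricted by a
per-record class allowlist (truncating events for tumor suppressors,
missense for oncogenes); amplification on CNV amplification calls.  A
sample's best level is the maximum over its matches.  The shipped knowledge
base is a small curated breast-cancer table seeded from well-established
drug–gene pairs (PIK3CA hotspots → alpelisib, BRCA1/2 truncation →
PARP inhibitors, ERBB2 amplification → HER2-targeted agents, AKT1 p.E17K →
AKT inhibitors, and so on); it is synthetic in the sense of being assembled
for testing, and any production use should supply a current institutional
table.

## Synthetic cohort generator

The generator emulates the statistical structure of a large one-institution
breast-cancer panel study so that every stage has realistic, fully known
inputs.  Its defaults are the study conditions:

- **Cohort structure.** 1134 samples; treatment arms assigned by
  largest-remainder quota at 419 neoadjuvant / 606 surgical / 109 advanced
  (scaled for other sizes), then shuffled, so the printed arm sizes are
  exact; metastatic biopsies occur only in the advanced arm (31% of it,
  ≈ 3% of the cohort).  Subtype mixture (luminal A, luminal B/HER2−,
  luminal B/HER2+, HER2+, TN) = (0.10, 0.45, 0.15, 0.12, 0.18).  IHC
  fields are drawn consistently with the assigned subtype; Ki67 is missing
  in 20% of the samples whose subtype does not need it.
- **Somatic model.** Per-gene, per-subtype Bernoulli mutation indicators.
  TP53 per-subtype rates (0.17, 0.41, 0.63, 0.74, 0.80) and PIK3CA rates
  (0.35, 0.38, 0.30, 0.215, 0.24) are solved so the mixture reproduces 53%
  and 32% cohort-wide; roughly forty further genes carry representative
  panel frequencies (0.5–10%).  Protein changes are assigned by per-gene
  hotspot shares (e.g. p.H1047R as 41% of PIK3CA mutations ⇒ ≈13% of the
  cohort; p.E17K as 92% of AKT1; p.K2797fs as 22% of KMT2C), with the
  remainder drawn from a positional model.  VAFs are Beta(2, 3) per gene
  (mode ≈ 1/3, plausible for clonal heterozygous events at high purity),
  slightly right-shifted for PIK3CA and AKT1; read support is Poisson
  (mean 1000, floored at 30) total depth with binomial alt counts, so
  VAF = alt/(alt+ref) holds by construction.
- **Coupling.** Selected pairs are drawn from the joint 2×2 law solving the
  target odds ratio against both marginals (quadratic root in the
  co-occurrence cell; infeasible combinations are an error naming the
  pair).  A hub gene in several couplings is drawn once and its partners
  conditionally, preserving each stated pairwise OR.  Defaults: ARID1A/PTEN
  fully exclusive (OR = 0), NF1 positively coupled to RUNX1, ATRX and
  DNMT3A (OR 4–5).
- **CNV.** A CNV-evaluable subset of 1114/1134 of samples; the 17q12
  amplicon genes (ERBB2, MIEN1, GRB7) amplify at 85% in HER2+ samples and
  2% otherwise (≈25% overall); other genes carry flat 2–6% rates.
- **Germline.** 72 carrier gene events over 66 distinct carriers per 1134
  patients (six patients carry two genes), with the per-gene census led by
  BRCA1 (22); loss-of-function genes receive truncating variants (PVS1) or
  cancer-pathogenic ClinVar records, oncogenes (ALK, BRAF, KRAS) receive
  cancer-pathogenic missense records.  Background uncertain variants (4% of
  patients) and common alleles destined for the rare-variant prefilter (2%)
  are added on top.
- **Panel of normals.** Three artifact variants in artifact-prone genes
  (MUC16, TTN, FLG) are injected into the written MAF at 2% sample
  frequency with PON counts of 10–40, so the PON filter has real work; the
  in-memory cohort returned by `generate` is the clean truth.
- **Reference cohorts** for cross-cohort comparison are emitted as integer
  count tables (round half up) from representative Western
  primary-breast-cancer gene frequencies and pathway rates, at n = 869.

Everything derives from one `numpy` Generator seeded by the mandatory spec
seed; identical (spec, seed) gives byte-identical files.  What the
generator does **not** emulate: mutational signatures and trinucleotide
context, subclonal copy-number structure, panel capture dropout,
gene–gene correlation beyond the configured pairwise couplings, and any
survival/treatment-response structure.  Tests passing on synthetic cohorts
therefore validate the bookkeeping and the statistics, not biological
discovery on real data.

## Problem sizes used in tests

The default test run exercises the generator at 80–400 samples for unit
checks and at the full 1134 for acceptance-level recovery checks; the
exact-test oracle sweep covers all 2×2 tables with N ≤ 40 (deduplicated by
table symmetry); FDR control uses 20 null cohorts of 1000 features × 200
samples; exclusivity recovery uses 20 seeds of 1000-sample matrices.  These
sizes give stable statistical behavior while keeping the whole suite fast
on a single CPU.

## Known limitations

- Consequence and HGVS annotations are trusted as given; there is no
  re-annotation, liftover or normalization of indel representations.
- The pathway catalog and the actionability knowledge base are curated
  defaults for testing and demonstration, not clinical-grade resources.
- One-vs-rest enrichment is the only built-in subtype contrast; matched
  pairwise designs require subsetting by the caller.
- The Freeman–Halton exact path enumerates carrier allocations and is
  limited to small carrier totals (≤ 200); larger tables fall back to the
  chi-square approximation with a flag in the output.
- Germline classification implements exactly the evidence the input schema
  can support; co-segregation, de novo and functional-assay ACMG criteria
  are out of scope.
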