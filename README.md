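# oncopanel

Cohort-level interpretation of cancer panel sequencing, written for
translational researchers who receive *calls* (somatic mutations, gene-level
copy-number events, annotated germline variants) from an upstream pipeline
and need the downstream analysis layer: molecular subtyping, mutational
landscape and hotspot statistics, enrichment and cross-cohort comparison,
oncogenic-pathway aggregation with mutual-exclusivity analysis, ACMG-guided
germline classification, and clinical-actionability tiering.

The package grew out of breast-cancer panel studies and ships defaults for
that setting — IHC surrogate subtypes, a nine-pathway catalog, a curated
breast-cancer drug knowledge base — but every table is a replaceable TSV.

## What it computes

- **Subtyping** (`oncopanel.model`): St Gallen surrogate subtypes from
  ER/PR/HER2 and Ki67 (luminal A requires ER+ *and* PR+, HER2−, Ki67 ≤ 14%);
  a deterministic collapse onto HR±/HER2± coarse groups.
- **Landscape** (`oncopanel.landscape`): per-gene and per-subtype mutation
  frequencies over the full denominator of sequenced samples; recurrent
  protein-change hotspots above a cohort-frequency threshold (2% default);
  per-sample mutation load with a Kruskal–Wallis comparison; per-gene VAF
  quartiles; CNV frequencies over the CNV-evaluable subset.
- **Enrichment** (`oncopanel.stats`): two-sided Fisher exact tests on 2×2
  tables, odds ratios with Woolf logit 95% CIs (Haldane–Anscombe corrected
  at zero cells), Benjamini–Hochberg FDR per analysis family; one-vs-rest
  subtype enrichment (FDR < 0.25 by default), clinical-covariate enrichment,
  and two-cohort frequency comparison (FDR < 0.05).
- **Pathways** (`oncopanel.pathways`): aggregation onto the nine canonical
  oncogenic signaling pathways (cell cycle, Hippo, Notch, PI3K, Wnt,
  RTK/RAS, p53, TGF-β, Myc); pairwise co-occurrence / mutual exclusivity
  by the 2×2 odds ratio with log10(OR) capped at ±3 for plotting.
- **Germline** (`oncopanel.germline`): rare-variant prefilter (East-Asian
  population AF < 0.5%), CharGer-style additive evidence scoring
  (PVS1 = 8, PS1 = 7, PM4 = PM5 = 2; PM2 disabled), classification
  (ClinVar cancer-pathogenic → pathogenic; score > 7 → likely pathogenic),
  cohort carrier summaries and cross-population frequency tests.
- **Actionability** (`oncopanel.actionability`): OncoKB-convention evidence
  levels L1 > L2A > L2B > L3A > L3B > L4, matched per sample against a
  knowledge-base TSV, with per-subtype level distributions.
- **Simulation** (`oncopanel.simulate`): a seeded generator of complete
  synthetic cohorts (clinical + MAF + CNV + germline + panel-of-normals +
  reference tables) with controllable frequencies, hotspots, VAF models,
  pairwise coupling and germline carrier structure, so the entire pipeline
  is testable without any data download.

## Worked example

```python
from oncopanel.simulate import CohortSpec, GERMLINE_NON_LOF, generate
from oncopanel.landscape import gene_frequency, detect_hotspots
from oncopanel.io import build_alteration_matrix
from oncopanel.pathways import default_catalog, pathway_matrix, pairwise_association
from oncopanel.germline import (GeneContext, prefilter_rare,
                                classify_variants, carrier_summary)

cohort = generate(CohortSpec(n_samples=1134, seed=0))

freq = gene_frequency(cohort).set_index("feature")
for gene in ("TP53", "PIK3CA", "NF1"):
    print(f"{gene:7s} mutated in {100 * freq.loc[gene, 'frequency']:.1f}% of samples")

for h in detect_hotspots(cohort.somatic, len(cohort.samples))[:3]:
    print(f"hotspot {h.gene_symbol} {h.protein_change}: {100 * h.frequency:.1f}%")

matrix = build_alteration_matrix(cohort)
pathways = pathway_matrix(matrix, default_catalog())
print(f"p53 pathway altered in {100 * pathways['p53'].mean():.1f}% of samples")

associations = pairwise_association(matrix, 0.05)
for r in associations:
    if r.pattern != "none":
        print(f"{r.feature_i}/{r.feature_j}: {r.pattern}, "
              f"OR={r.odds_ratio:.1f}, q={r.q_value:.1e}")
arid = next(r for r in associations if {r.feature_i, r.feature_j} == {"ARID1A", "PTEN"})
print(f"ARID1A/PTEN co-mutated samples: {arid.n11}")

ctx = {g: GeneContext(g, True, g not in GERMLINE_NON_LOF)
       for g in {v.gene_symbol for v in cohort.germline}}
kept, _ = prefilter_rare(cohort.germline)
classify_variants(kept, ctx)
n, frac, per_gene = carrier_summary(kept, 1134)
print(f"germline carriers: {n}/1134 ({100 * frac:.1f}%), "
      f"top gene BRCA1 n={per_gene['BRCA1']}")
```

prints

```
TP53    mutated in 52.3% of samples
PIK3CA  mutated in 31.4% of samples
NF1     mutated in 9.7% of samples
hotspot PIK3CA p.H1047R: 12.3%
hotspot AKT1 p.E17K: 4.9%
hotspot PIK3CA p.E545K: 3.8%
p53 pathway altered in 54.0% of samples
NF1/RUNX1: co_occurring, OR=8.4, q=1.5e-04
ARID1A/PTEN co-mutated samples: 0
germline carriers: 66/1134 (5.8%), top gene BRCA1 n=22
```

The frequencies are the generator's study conditions recovered through the
analysis code: TP53 and PIK3CA land near their configured 53% / 32% cohort
rates, the PIK3CA p.H1047R hotspot near 13%, the p53 pathway near 55%, the
injected NF1/RUNX1 coupling is flagged as significantly co-occurring, the
ARID1A/PTEN pair is fully exclusive by construction, and exactly 66 of 1134
patients (5.8%) carry pathogenic or likely pathogenic germline variants,
led by BRCA1.

## Command line

```sh
oncopanel simulate --seed 1 -n 1134 --outdir cohort/
oncopanel run-all --cohort-dir cohort/ --outdir results/
```

`run-all` executes ingest (with panel-of-normals filtering) → landscape →
enrichment → pathways → cross-cohort comparison → germline →
actionability, writing one TSV per analysis with `#`-prefixed headers
recording tool version, configuration hash and seed.  Reruns on identical
inputs are byte-identical.  Exit codes: 0 success, 2 validation error,
3 stage failure.

## Layout

```
src/oncopanel/        library (model, io, landscape, stats, pathways,
                      germline, actionability, simulate, pipeline, cli)
src/oncopanel/data/   replaceable default pathway catalog and knowledge base
tests/                pytest suite, including tests/test_acceptance.py
docs/methods.md       models, assumptions, parameter choices, limitations
```
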