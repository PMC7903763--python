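# gliomareport

Catalog-driven prioritization and tiered clinical reporting of tumor/normal
whole-exome sequencing (WES) findings in diffuse glioma.

A single exome pair yields tens of thousands of called variants and thousands
of copy-number segments; almost none matter clinically. `gliomareport`
implements the interpretation layer that sits downstream of variant calling:
it filters called events with fixed clinical cutoffs, assigns survivors to
*sequential* curated tiers (an event is reported once, in the most specific
applicable subsection), computes summary biomarkers, and renders a
deterministic personalized Markdown report. It is written for
neuro-oncology analysts and bioinformaticians who consume caller output
(MAF-dialect variant tables, SEG copy-number segments, per-gene B-allele
frequencies) and need reproducible, auditable reports.

## What it computes

**Germline cascade** — keep variants with population MAF < 1% (max over
1000 Genomes / ExAC / ESP6500), not benign/likely-benign in ClinVar,
non-synonymous, not in FLAGS (frequently mutated passenger genes); report in
order: ACMG incidental-findings genes → Cancer Gene Census → cancer
predisposition genes → DNA-damage-repair genes, plus a Common Variants
section matching glioma GWAS SNPs by rsID against the *unfiltered* calls.
Clinically annotated alleles (pathogenic / likely pathogenic / drug
response) are exempt from the MAF cut.

**Somatic cascade** — keep variants with tumor VAF > 5%, non-synonymous,
non-FLAGS; report in order: established glioma genes → CGC hotspot variants
(gene in CGC *and* recurrent protein change) → other CGC variants → DNA
repair genes → selected KEGG pathway genes.

**Burden and biomarkers** — tumor mutational burden

    TMB = #{coding mutations: VAF > 5%, tumor depth > 20X, normal depth > 10X} / Mb

POLE-proofreading deficiency is predicted when SNVs/Mb > 60 **and**
SSR-indels/Mb < 0.18; MSI status is carried through from an external
predictor.

**Copy number** — segments retained at |log2(T/N)| ≥ 0.25; gene-level
Amp/Del calls (tiered: established glioma SCNAs → CGC); broad events at
cytoband / chromosome-arm / whole-chromosome scope, reported at the widest
qualifying scope; and four burden metrics, including the weighted genome
instability index

    wGII = mean over chromosomes c of (altered length on c / assayed length of c).

**LOH and double hits** — per-gene LOH when |BAF_tumor − BAF_normal| > 0.4;
double-hit genes carry a filter-passing somatic short variant *and* an SCNA
call and/or LOH event. Gene lists for downstream pathway enrichment are
exported (somatic SNV genes; genes with T/N ratio < 0.5 or > 1.5).

All thresholds live in a flat config (`AnalysisConfig`) and default to the
printed clinical cutoffs above.

## Worked example

```sh
python examples/05_full_report.py
```

generates a seeded synthetic tumor/normal case (miniature 4-chromosome
genome with planted ground truth) and runs the full pipeline:

```
germline: 187 called -> 45 pass -> 14 reported (+5 common SNPs)
somatic:  180 called -> 98 pass -> 15 reported in tiers {'glioma_established': 4,
          'cgc_hotspot': 2, 'cgc_other': 4, 'ddr': 2, 'kegg_selected': 3}
TMB 39.9/Mb | POLE not_deficient | 6 SCNA gene events | 4 LOH events | 4 double hits
```

The funnel lines mirror the report's audit trail: called → filter-passing →
reported-in-a-tier, with every excluded variant carrying its first failing
reason. The remaining examples (`examples/01_…` to `04_…`) demonstrate each
stage on a handful of hand-built records; the same machinery is available as
a CLI (`glioma-report --help`, or `glioma-report --demo --seed 7 --out-dir out/`).

## Layout

- `src/gliomareport/` — `model` (types, vocabularies, config), `io`
  (MAF/SEG/BED/cytoband/catalog dialects), `germline`, `somatic`, `burden`,
  `scna`, `loh`, `report`, `pipeline`, `cli`, `synthetic` (seeded case
  generator with truth manifests).
- `docs/methods.md` — model, assumptions, parameter defaults, numerical
  choices and limitations.
- `tests/` — unit, property (hypothesis) and end-to-end acceptance tests.
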