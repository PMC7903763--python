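# Methods

## Scope and model

`gliomareport` implements the clinical interpretation layer for one matched
tumor/normal whole-exome pair. It consumes the outputs of an upstream
calling pipeline — annotated short-variant tables (germline and somatic,
MAF dialect), copy-number segments with log2(tumor/normal) ratios (SEG),
and per-gene tumor/normal B-allele-frequency pairs — and produces a
personalized report. Variant calling, annotation, segmentation, MSI
prediction, mutational-signature fitting, purity/clonality estimation and
pathway enrichment are all upstream or downstream of this package: MSI
status, signature weights and contamination estimates are accepted as
inputs and echoed; enrichment receives exported gene lists only.

The core design is a pair of *sequential filter cascades*. Every called
variant ends in exactly one of three strata:

1. **excluded**, carrying the first failing filter as its reason;
2. **reported**, in exactly one tier (the first catalog, in a fixed order,
   containing its gene); or
3. **passed-but-unreported** (filter-passing, no catalog match).

Sequential tiering makes subsections disjoint and puts each finding in its
most specific clinical context. The per-stage counts written to
`run_log.json` form a conservation identity (called = excluded + reported +
unreported) that the test suite verifies at scale.

## Coordinates and dialects

All in-memory coordinates are 1-based, fully closed (MAF/SEG convention);
interval length is `end − start + 1`. BED gene models and UCSC-layout
cytoband files are converted from 0-based half-open on read. The variant
dialect's required and optional columns are listed in
`gliomareport.io.VARIANT_REQUIRED_COLUMNS` / `VARIANT_OPTIONAL_COLUMNS`;
tumor VAF is derived from `t_alt_count / (t_alt_count + t_ref_count)`.
Because no standard Funcotator column set encodes the three population-AF
sources, the dialect fixes them as `AF_1000G`, `AF_ExAC`, `AF_ESP6500`.

ClinVar significance strings are normalized onto a closed vocabulary
(pathogenic, likely_pathogenic, drug_response, conflicting, vus,
not_reported, likely_benign, benign). Unrecognized non-empty strings map to
`not_reported` with a logged warning — they are deliberately *not* assumed
to be VUS. Severity ranking uses the order above; the two benign classes
are placed below `not_reported` purely so the order is total — they are
removed by the germline filter before any ranking in practice.

## Thresholds (defaults, units, boundary semantics)

| Parameter | Default | Boundary |
| --- | --- | --- |
| `germline_max_maf` | 0.01 | strict `<` (MAF exactly 1% is excluded) |
| `somatic_min_vaf` | 0.05 | strict `>` (VAF exactly 5% is excluded) |
| `tmb_min_tumor_depth` / `tmb_min_normal_depth` | 20 / 10 reads | strict `>` |
| `scna_min_abs_log2` | 0.25 | inclusive `≥` |
| `loh_min_baf_diff` | 0.40 | strict `>` |
| `pole_min_snv_per_mb` | 60 /Mb | strict `>` |
| `pole_max_ssr_indel_per_mb` | 0.18 /Mb | strict `<` |
| `enrichment_del_ratio` / `enrichment_amp_ratio` | 0.5 / 1.5 (linear T/N) | strict |
| `hotspot_min_count` | 2 tumors | inclusive `≥` |
| `gene_min_overlap_fraction` | 0.5 | inclusive `≥` |
| `broad_min_covered_fraction` | 0.5 | inclusive `≥` |

Boundary semantics are pinned by dedicated tests and by boundary-valued
plants in the synthetic generator.

Choices made where the underlying definitions are open:

- **Effective population MAF** is the maximum over available sources; a
  variant with no recorded source has effective MAF 0 (conservative
  inclusion).
- **Clinical rescue**: germline variants annotated pathogenic / likely
  pathogenic / drug response are exempt from the MAF cut
  (`clinvar_rescue`, on by default), so clinically consequential common
  alleles — classically the TP53 p.P72R drug-response polymorphism — still
  surface. Toggleable for a strictly frequency-based report.
- **Exclusion-reason order** is fixed (MAF → benign → impact → FLAGS for
  germline; VAF → impact → FLAGS for somatic) so reports and logs are
  deterministic; the filter conjunction itself is order-independent.
- **TMB coding set** is the non-synonymous vocabulary *plus* Silent,
  reading "mutations in the coding region" literally;
  `tmb_include_silent=False` restricts to non-synonymous. The denominator
  `coding_mb` (assayed coding megabases) must be supplied — it is a property
  of the capture design, not of the data.
- **Hotspot matching** is exact string equality on (gene, protein change in
  short HGVS form); "observed in multiple tumors" is operationalized as a
  recurrence count ≥ 2. Variants without a protein-change annotation can
  never be hotspots and fall through to the generic CGC tier.
- **POLE assessability**: SSR (simple-sequence-repeat) provenance for
  indels comes from an `In_SSR` column. If any TMB-qualifying indel lacks
  it, the POLE call is `not_assessable`; a sample with *no* qualifying
  indels is assessable (its SSR-indel rate is exactly 0).

## Copy-number engine

Segments are retained at |log2| ≥ 0.25 and merged per direction
(overlapping or book-ended runs), making every downstream quantity
invariant to caller fragmentation — verified by property tests.

*Gene calls*: a gene is called Amp/Del when one direction's retained
segments cover ≥ 50% of its span; the supporting log2 is the
coverage-weighted mean. If both directions reach the fraction (possible
only with overlapping caller output) the better-covered direction wins and
an exact tie yields no call. Tiering: (gene, direction) in the curated
glioma-SCNA catalog → established tier; else gene in CGC → CGC tier; else
the call is kept but unreported.

*Broad events*: coverage is always measured within cytoband boundaries, so
band, arm and chromosome scopes aggregate the same quantity; an event is
reported at the widest qualifying scope and same-direction events at
narrower scopes are rolled up. One documented edge: on a perfectly
symmetric chromosome a fully covered arm is exactly half the chromosome and
the inclusive ≥ 0.5 rule rolls it up to chromosome scope; real (and our
synthetic) arm events are asserted at < 50% chromosome coverage.
`min_arm_assayed_len` (default 0 = disabled) can suppress arm calls on
arms with negligible assayed length, e.g. acrocentric p arms under exome
capture.

*Burden*: `total_altered_mb` is the union of merged runs;
`n_alterations` counts merged maximal runs per direction;
`avg_len_kb = total / n`; wGII averages the per-chromosome altered fraction
over **all** chromosomes of the genome model (assayed lengths derived from
the cytoband file in the pipeline), unweighted across chromosomes.

## LOH and double hits

LOH operates on per-gene BAF pairs (interval-level tracks must be
pre-aggregated by the caller). Double-hit genes require at least one
*filter-passing* somatic short variant (tier-reported not required — the
weaker, more sensitive reading) plus an SCNA call and/or LOH event on the
same gene; any-direction SCNA evidence qualifies by default, and
`doublehit_del_only` restricts to deletions for a tumor-suppressor-oriented
report.

## Report rendering

The report is Markdown with a fixed section sequence (patient/sample info,
quality, purity, germline tiers + common variants, somatic TMB/MSI-POLE +
five tiers, SCNA burden/gene/broad sections + plot data, LOH sections,
double hits, signatures, enrichment gene lists, config snapshot) and fixed
numeric formatting (VAF and log2 to 2 decimals, TMB to 1, wGII to 4).
Rendering the same bundle twice is byte-identical; per-section TSVs and the
plot data are emitted alongside, and figure rendering is deliberately left
to downstream tooling. Absent optional sections render as "not available";
empty sections carry an explicit notice.

## Synthetic data

`gliomareport.synthetic` generates complete cases on a miniature genome — 4
chromosomes × 10 Mb, 8 cytobands each, ~125 gene models of 100 kb — with a
`TruthSpec` declaring planted tier counts, exclusion reasons, SCNA calls,
broad events, LOH events, double-hit genes and the POLE quadrant. Catalogs
are synthetic stand-ins built from familiar cancer-gene symbols and are
deliberately overlapping so the sequential rules are exercised. Key
construction properties:

- every generated record is re-evaluated by generator-local predicates
  (independent of the analysis modules) to derive the truth manifest, so
  truth is computed, not asserted;
- planted retained segments are pairwise disjoint and non-adjacent, making
  manifest burden metrics plain sums;
- `coding_mb` is derived from the generated qualifying-SNV count so the
  planted POLE quadrant holds by construction (≈80 SNVs/Mb for "high",
  ≈30/Mb for "low");
- boundary-valued records (VAF 0.05, depth 20/10, |log2| 0.25, |ΔBAF| 0.40)
  are planted by default;
- a fixed seed reproduces every file byte-identically.

The generator emulates the *shapes and decision points* of real data, not
its biology: no realistic mutational spectrum, read-level noise, segment
jitter at gene boundaries, or subclonal structure. Passing tests therefore
demonstrate correctness of the filtering/tiering/metric logic and the
report contract on those shapes — not calling accuracy on real exomes.
Test problem sizes (20 cases of ~1000+ called variants for the cascade and
recovery properties; ≥200 randomized instances per operation for the
brute-force oracle comparisons) were chosen to exercise all code paths
within seconds.

## Known limitations

- Hotspot matching does not normalize alternative HGVS spellings.
- Gene-level SCNA weighting can double-count if same-direction caller
  segments overlap each other (callers emit disjoint segments in practice).
- TMB/POLE depend on an externally supplied `coding_mb`; molecular-subset
  labels for cohort context are inputs, not derived.
- No liftover, no raw VCF/BAM parsing, no pathogenicity prediction or
  ACMG/AMP criteria scoring.
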