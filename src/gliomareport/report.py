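"""Deterministic assembly of the personalized report.

The report is rendered as Markdown with a fixed section sequence and fixed
numeric formatting (VAF and log2 ratios to 2 decimals, TMB to 1 decimal),
so rendering the same bundle twice is byte-identical.  A one-page summary
of the somatic findings (TMB, reported short variants, reported SCNAs) is
produced alongside the full report.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

from .burden import PoleCall, TmbResult
from .loh import DoubleHit, LohEvent
from .model import (
    GERMLINE_TIER_ORDER,
    SOMATIC_TIER_ORDER,
    AnalysisConfig,
    AnnotatedVariant,
    ScnaSegment,
    TierAssignment,
)
from .scna import BroadScnaEvent, GeneScnaCall, ScnaBurden


class AssemblyError(ValueError):
    """A bundle section is malformed or missing where required."""


GERMLINE_TIER_TITLES = {
    "acmg_incidental": "ACMG Incidental Findings",
    "cgc": "Variants in Cancer Gene Census Genes",
    "predisposition": "Variants in Cancer Predisposition Genes",
    "ddr": "Variants in DNA Damage Repair Genes",
}

SOMATIC_TIER_TITLES = {
    "glioma_established": "Variants in Established Glioma Genes",
    "cgc_hotspot": "Hotspot Variants in Cancer Gene Census Genes",
    "cgc_other": "Other Variants in Cancer Gene Census Genes",
    "ddr": "Variants in DNA Damage Repair Genes",
    "kegg_selected": "Variants in Important KEGG Pathway Genes",
}


@dataclass
class ReportBundle:
    """Everything the renderer needs, already computed."""

    sample_id: str
    config: AnalysisConfig
    metadata: dict = field(default_factory=dict)
    quality: dict | None = None
    contamination: float | None = None
    germline_assignments: list[TierAssignment] = field(default_factory=list)
    germline_excluded: list[TierAssignment] = field(default_factory=list)
    common_matches: list[tuple[AnnotatedVariant, str]] = field(default_factory=list)
    somatic_assignments: list[TierAssignment] = field(default_factory=list)
    somatic_excluded: list[TierAssignment] = field(default_factory=list)
    tmb: TmbResult | None = None
    tmb_context: dict | None = None
    msi_status: str | None = None
    pole: PoleCall | None = None
    scna_burden: ScnaBurden | None = None
    gene_calls: list[GeneScnaCall] = field(default_factory=list)
    broad_events: list[BroadScnaEvent] = field(default_factory=list)
    plot_segments: list[ScnaSegment] = field(default_factory=list)
    loh_events: list[LohEvent] = field(default_factory=list)
    loh_somatic: list[tuple] = field(default_factory=list)
    double_hits: list[DoubleHit] = field(default_factory=list)
    signature_weights: dict[str, float] | None = None
    enrichment_snv_genes: list[str] = field(default_factory=list)
    enrichment_scna_genes: list[str] = field(default_factory=list)
    catalog_versions: dict[str, str] = field(default_factory=dict)


def select_enrichment_genes(
    somatic_passing: list[AnnotatedVariant],
    gene_calls: list[GeneScnaCall],
    cfg: AnalysisConfig,
) -> tuple[list[str], list[str]]:
    """Gene lists exported as pathway-enrichment input.

    The SNV list holds genes with any filter-passing somatic non-synonymous
    variant (VAF > 5%, non-FLAGS); the SCNA list holds genes with
    homozygous-deletion-range (tumor/normal ratio < 0.5) or multi-copy-
    amplification-range (ratio > 1.5) calls, both bounds strict.  Both
    lists are deduplicated and sorted.
    """
    snv_genes = sorted({v.gene for v in somatic_passing})
    scna_genes = sorted({
        c.gene for c in gene_calls
        if c.linear_ratio < cfg.enrichment_del_ratio
        or c.linear_ratio > cfg.enrichment_amp_ratio
    })
    return snv_genes, scna_genes


# ---------------------------------------------------------------------------
# Formatting helpers
# ---------------------------------------------------------------------------

def _f2(x: float | None) -> str:
    return "NA" if x is None else f"{x:.2f}"


def _f1(x: float | None) -> str:
    return "NA" if x is None else f"{x:.1f}"


def _table(headers: list[str], rows: list[list[str]]) -> str:
    if not rows:
        return "_No findings in this section._\n"
    out = ["| " + " | ".join(headers) + " |",
           "| " + " | ".join("---" for _ in headers) + " |"]
    out += ["| " + " | ".join(r) + " |" for r in rows]
    return "\n".join(out) + "\n"


def _variant_label(v: AnnotatedVariant) -> str:
    return v.genome_change or f"g.{v.chrom}:{v.pos}{v.ref}>{v.alt}"


def _germline_rows(assignments, tier):
    rows = []
    for a in assignments:
        if a.tier != tier:
            continue
        v = a.variant
        rows.append([v.gene, _variant_label(v), v.protein_change or "-", v.clinvar])
    rows.sort()
    return rows


def _somatic_rows(assignments, tier):
    rows = []
    for a in assignments:
        if a.tier != tier:
            continue
        v = a.variant
        rows.append([v.gene, v.classification, v.protein_change or "-",
                     _variant_label(v), _f2(v.tumor_vaf)])
    rows.sort()
    return rows


def _somatic_tier_tables(bundle) -> list[str]:
    parts = []
    for tier in SOMATIC_TIER_ORDER:
        parts.append(f"### {SOMATIC_TIER_TITLES[tier]}\n")
        parts.append(_table(
            ["Gene", "Classification", "Protein change", "Genome change", "Tumor VAF"],
            _somatic_rows(bundle.somatic_assignments, tier),
        ))
    return parts


def _tmb_block(bundle) -> list[str]:
    parts = ["### Tumor Mutational Burden\n"]
    if bundle.tmb is None:
        parts.append("_Not available._\n")
        return parts
    t = bundle.tmb
    parts.append(
        f"TMB: **{_f1(t.tmb)} mutations/Mb** "
        f"({t.n_qualifying} qualifying coding mutations over {t.denominator_mb:g} Mb).\n"
    )
    ctx = bundle.tmb_context
    if ctx and "overall_median" in ctx:
        parts.append(
            f"Cohort context (n={ctx['n_history']}): overall median TMB "
            f"{_f1(ctx['overall_median'])}/Mb; this tumor ranks {ctx['rank']} "
            "(1 = highest).\n"
        )
        rows = [[label, _f1(med)] for label, med in sorted(ctx["subset_medians"].items())]
        parts.append(_table(["Molecular subset", "Median TMB (/Mb)"], rows))
    return parts


def _msi_pole_block(bundle) -> list[str]:
    parts = ["### Microsatellite Instability and POLE Status\n"]
    msi = bundle.msi_status or "not available"
    parts.append(f"MSI status (external prediction): **{msi}**.\n")
    if bundle.pole is None:
        parts.append("POLE deficiency: **not assessable**.\n")
    else:
        p = bundle.pole
        ssr = "NA" if p.ssr_indel_per_mb is None else f"{p.ssr_indel_per_mb:.2f}"
        parts.append(
            f"POLE deficiency: **{p.status.replace('_', ' ')}** "
            f"(SNVs/Mb = {_f1(p.snv_per_mb)}, SSR indels/Mb = {ssr}).\n"
        )
    return parts


def _scna_section(bundle) -> list[str]:
    parts = ["## Somatic Copy Number Alterations\n"]
    parts.append("### SCNA Burden\n")
    if bundle.scna_burden is None:
        parts.append("_Not available._\n")
    else:
        b = bundle.scna_burden
        parts.append(_table(
            ["Metric", "Value"],
            [["Total altered length (Mb)", f"{b.total_altered_mb:.3f}"],
             ["Total number of alterations", str(b.n_alterations)],
             ["Average length of alterations (kb)", _f1(b.avg_len_kb)],
             ["Weighted Genome Instability Index", f"{b.wgii:.4f}"]],
        ))
    call_headers = ["Gene", "Type", "log2(T/N)", "Covered fraction"]

    def call_rows(tier):
        rows = [[c.gene, c.direction, _f2(c.log2_ratio), _f2(c.covered_fraction)]
                for c in bundle.gene_calls if c.tier == tier]
        rows.sort()
        return rows

    parts.append("### Established SCNAs in Glioma\n")
    parts.append(_table(call_headers, call_rows("glioma_established")))
    parts.append("### SCNAs in Cancer Gene Census Genes\n")
    parts.append(_table(call_headers, call_rows("cgc")))
    parts.append("### Broad SCNAs\n")
    rows = [[e.name, e.scope, e.direction, _f2(e.covered_fraction)]
            for e in bundle.broad_events]
    rows.sort()
    parts.append(_table(["Region", "Scope", "Type", "Covered fraction"], rows))
    parts.append("### Plots of SCNA Segments by Chromosome\n")
    parts.append(
        f"_Per-chromosome segment plot data ({len(bundle.plot_segments)} retained "
        "segments) are exported as scna_plot_data.tsv._\n"
    )
    return parts


def _loh_section(bundle) -> list[str]:
    parts = ["## Loss of Heterozygosity (LOH) Events\n", "### LOH Overview\n"]
    loh_headers = ["Gene", "Chromosome", "|dBAF|"]
    rows = sorted([[e.gene, e.chrom, _f2(e.baf_delta)] for e in bundle.loh_events])
    parts.append(_table(loh_headers, rows))
    parts.append("### LOH + Somatic SNV/indel\n")
    rows = sorted(
        [[g, str(len(events)), str(len(variants))] for g, events, variants in bundle.loh_somatic]
    )
    parts.append(_table(["Gene", "LOH events", "Reported somatic variants"], rows))
    parts.append("### LOH Events in CGC Genes\n")
    rows = sorted([[e.gene, e.chrom, _f2(e.baf_delta)]
                   for e in bundle.loh_events if e.in_cgc])
    parts.append(_table(loh_headers, rows))
    return parts


def assemble_report(bundle: ReportBundle) -> tuple[str, str]:
    """Render the full Markdown report and the one-page somatic summary.

    Sections appear in a fixed order; missing optional sections render as
    "not available"; a malformed bundle raises :class:`AssemblyError`
    naming the offending section.  Rendering is deterministic.
    """
    if bundle.config is None:
        raise AssemblyError("configuration section missing from bundle")
    for name in ("germline_assignments", "somatic_assignments"):
        section = getattr(bundle, name)
        if not isinstance(section, list):
            raise AssemblyError(f"malformed bundle section: {name}")

    parts: list[str] = [f"# Whole-Exome Sequencing Report — {bundle.sample_id}\n"]

    parts.append("## Patient and Sample Information\n")
    if bundle.metadata:
        parts.append(_table(
            ["Field", "Value"],
            [[k, str(v)] for k, v in sorted(bundle.metadata.items())],
        ))
    else:
        parts.append("_Not available._\n")

    parts.append("## Quality Metrics\n")
    if bundle.quality:
        parts.append(_table(
            ["Metric", "Value"],
            [[k, str(v)] for k, v in sorted(bundle.quality.items())],
        ))
    else:
        parts.append("_Not available._\n")
    parts.append("### Tumor Purity\n")
    if bundle.contamination is None:
        parts.append("_Not available._\n")
    else:
        parts.append(f"Cross-sample contamination estimate: {bundle.contamination:.4f}\n")

    parts.append("## Germline Alterations\n")
    for tier in GERMLINE_TIER_ORDER:
        parts.append(f"### {GERMLINE_TIER_TITLES[tier]}\n")
        parts.append(_table(
            ["Gene", "Variant", "Protein change", "ClinVar significance"],
            _germline_rows(bundle.germline_assignments, tier),
        ))
    parts.append("### Common Variants\n")
    rows = sorted(
        [[v.rsid or "-", gene, _variant_label(v), v.clinvar]
         for v, gene in bundle.common_matches]
    )
    parts.append(_table(["rsID", "Gene", "Variant", "ClinVar significance"], rows))

    parts.append("## Somatic SNV/indels\n")
    parts += _tmb_block(bundle)
    parts += _msi_pole_block(bundle)
    parts += _somatic_tier_tables(bundle)

    parts += _scna_section(bundle)
    parts += _loh_section(bundle)

    parts.append("## Genes with Double Hit\n")
    rows = [[h.gene, h.evidence_summary] for h in bundle.double_hits]
    parts.append(_table(["Gene", "Evidence"], rows))

    parts.append("## Mutational Signatures\n")
    if bundle.signature_weights:
        rows = [[sig, f"{w:.3f}"] for sig, w in sorted(bundle.signature_weights.items())]
        parts.append(_table(["Signature", "Weight"], rows))
    else:
        parts.append("_Not available._\n")

    parts.append("## Pathway Enrichment Input Gene Lists\n")
    parts.append("### High-impact Somatic SNV/indels\n")
    parts.append((", ".join(bundle.enrichment_snv_genes) or "_none_") + "\n")
    parts.append("### High-impact SCNAs\n")
    parts.append((", ".join(bundle.enrichment_scna_genes) or "_none_") + "\n")

    parts.append("## Analysis Configuration\n")
    parts.append("```json\n" + json.dumps(bundle.config.to_dict(), indent=2, sort_keys=True)
                 + "\n```\n")
    if bundle.catalog_versions:
        parts.append(_table(
            ["Catalog", "Version"],
            [[k, v] for k, v in sorted(bundle.catalog_versions.items())],
        ))

    report = "\n".join(parts)
    return report, _summary_page(bundle)


def _summary_page(bundle: ReportBundle) -> str:
    """One-page summary of somatic findings: TMB/MSI, short variants, SCNAs."""
    parts = [f"# Summary of Somatic WES Findings — {bundle.sample_id}\n"]
    if bundle.tmb is not None:
        parts.append(f"**TMB:** {_f1(bundle.tmb.tmb)} mutations/Mb  ")
    msi = bundle.msi_status or "not available"
    parts.append(f"**MSI status:** {msi}\n")
    parts.append("## Reported Somatic Short Variants\n")
    rows = []
    for tier in SOMATIC_TIER_ORDER:
        for r in _somatic_rows(bundle.somatic_assignments, tier):
            rows.append([SOMATIC_TIER_TITLES[tier]] + r)
    parts.append(_table(
        ["Category", "Gene", "Classification", "Protein change", "Genome change", "Tumor VAF"],
        rows,
    ))
    parts.append("## Reported Gene-level SCNAs\n")
    rows = sorted(
        [[("Established SCNAs in Glioma" if c.tier == "glioma_established"
           else "SCNAs in Cancer Gene Census Genes"),
          c.gene, c.direction, _f2(c.log2_ratio)]
         for c in bundle.gene_calls if c.tier in ("glioma_established", "cgc")]
    )
    parts.append(_table(["Category", "Gene", "Type", "log2(T/N)"], rows))
    return "\n".join(parts)
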