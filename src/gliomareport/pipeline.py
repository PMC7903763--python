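"""End-to-end orchestration: read inputs, run every cascade, write the report.

``analyze_case`` works on in-memory objects and returns a
:class:`~gliomareport.report.ReportBundle` plus a run log of cascade counts;
``run_pipeline`` is the file-level wrapper used by the CLI: it reads the
documented dialects, executes read -> filter -> tier -> burden -> SCNA ->
LOH -> double hit -> report and writes the report, per-section TSVs,
enrichment gene lists and a machine-readable run log.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as gio
from .burden import CohortTmbRecord, compute_tmb, predict_pole, tmb_context
from .germline import assign_germline_tiers, filter_germline, match_common_variants
from .loh import filter_loh, find_double_hits, intersect_loh_somatic
from .model import (
    GERMLINE_TIER_ORDER,
    SOMATIC_TIER_ORDER,
    AnalysisConfig,
    AnnotatedVariant,
    BafPair,
    ConfigurationError,
    Cytoband,
    GeneModel,
    ScnaSegment,
)
from .report import ReportBundle, assemble_report, select_enrichment_genes
from .scna import call_broad_events, call_gene_scnas, compute_scna_burden, threshold_segments
from .somatic import assign_somatic_tiers, filter_somatic

CATALOG_FILES = {
    "acmg": "acmg.tsv",
    "cgc": "cgc.tsv",
    "predisposition": "predisposition.tsv",
    "ddr": "ddr.tsv",
    "flags": "flags.tsv",
    "glioma_genes": "glioma_genes.tsv",
    "glioma_scnas": "glioma_scnas.tsv",
    "kegg_selected": "kegg_selected.tsv",
    "gwas_snps": "gwas_snps.tsv",
    "hotspots": "hotspots.tsv",
}


@dataclass
class CaseInputs:
    """In-memory inputs of one tumor/normal case."""

    germline: list[AnnotatedVariant]
    somatic: list[AnnotatedVariant]
    catalogs: dict
    cfg: AnalysisConfig
    segments: list[ScnaSegment] | None = None
    baf_pairs: list[BafPair] | None = None
    cytobands: list[Cytoband] | None = None
    gene_models: list[GeneModel] | None = None
    cohort_history: list[CohortTmbRecord] | None = None
    msi_status: str | None = None
    molecular_subset: str | None = None
    signature_weights: dict[str, float] | None = None
    sample_id: str = "sample"
    metadata: dict | None = None


def genome_model_from_cytobands(cytobands: list[Cytoband]) -> dict[str, int]:
    """Per-chromosome assayed length: the total cytoband-covered span."""
    model: dict[str, int] = {}
    for b in cytobands:
        model[b.chrom] = model.get(b.chrom, 0) + b.length
    return model


def analyze_case(inputs: CaseInputs) -> tuple[ReportBundle, dict]:
    """Run every cascade on one case; return the report bundle and run log."""
    cfg = inputs.cfg
    catalogs = inputs.catalogs
    if "flags" not in catalogs:
        raise ConfigurationError("missing required catalog 'flags'")

    # Germline cascade
    g_passing, g_excluded = filter_germline(inputs.germline, catalogs["flags"], cfg)
    g_assignments = assign_germline_tiers(g_passing, catalogs)
    common = (match_common_variants(inputs.germline, catalogs["gwas_snps"])
              if "gwas_snps" in catalogs else [])

    # Somatic cascade
    s_passing, s_excluded = filter_somatic(inputs.somatic, catalogs["flags"], cfg)
    s_assignments = assign_somatic_tiers(s_passing, catalogs, catalogs["hotspots"], cfg)

    # Mutation burden
    tmb = compute_tmb(inputs.somatic, cfg) if cfg.coding_mb else None
    pole = predict_pole(inputs.somatic, cfg) if cfg.coding_mb else None
    context = (tmb_context(inputs.cohort_history or [], tmb, inputs.molecular_subset)
               if tmb is not None else None)

    # SCNA engine
    retained: list[ScnaSegment] = []
    gene_calls = []
    broad_events = []
    burden = None
    if inputs.segments is not None:
        retained = threshold_segments(inputs.segments, cfg)
        if inputs.gene_models is not None:
            gene_calls = call_gene_scnas(retained, inputs.gene_models, catalogs, cfg)
        if inputs.cytobands is not None:
            broad_events = call_broad_events(retained, inputs.cytobands, cfg)
            burden = compute_scna_burden(
                retained, genome_model_from_cytobands(inputs.cytobands))

    # LOH and double hits
    loh_events = []
    if inputs.baf_pairs is not None:
        loh_events = filter_loh(inputs.baf_pairs, cfg, catalogs.get("cgc"))
    loh_somatic = intersect_loh_somatic(loh_events, s_assignments)
    double_hits = find_double_hits(s_passing, gene_calls, loh_events, cfg)

    snv_genes, scna_genes = select_enrichment_genes(s_passing, gene_calls, cfg)

    bundle = ReportBundle(
        sample_id=inputs.sample_id,
        config=cfg,
        metadata=inputs.metadata or {},
        germline_assignments=g_assignments,
        germline_excluded=g_excluded,
        common_matches=common,
        somatic_assignments=s_assignments,
        somatic_excluded=s_excluded,
        tmb=tmb,
        tmb_context=context,
        msi_status=inputs.msi_status,
        pole=pole,
        scna_burden=burden,
        gene_calls=gene_calls,
        broad_events=broad_events,
        plot_segments=retained,
        loh_events=loh_events,
        loh_somatic=loh_somatic,
        double_hits=double_hits,
        signature_weights=inputs.signature_weights,
        enrichment_snv_genes=snv_genes,
        enrichment_scna_genes=scna_genes,
    )
    run_log = _cascade_counts(inputs, bundle)
    return bundle, run_log


def _count_by(items, key) -> dict:
    out: dict = {}
    for item in items:
        k = key(item)
        out[k] = out.get(k, 0) + 1
    return {k: out[k] for k in sorted(out)}


def _cascade_counts(inputs: CaseInputs, bundle: ReportBundle) -> dict:
    """Stage counts mirroring the called -> filtered -> reported funnel."""
    g_tiers = _count_by([a for a in bundle.germline_assignments if a.tier], lambda a: a.tier)
    s_tiers = _count_by([a for a in bundle.somatic_assignments if a.tier], lambda a: a.tier)
    log = {
        "sample_id": inputs.sample_id,
        "germline": {
            "called": len(inputs.germline),
            "passing": len(bundle.germline_assignments),
            "excluded": _count_by(bundle.germline_excluded, lambda a: a.exclusion_reason),
            "tiers": {t: g_tiers.get(t, 0) for t in GERMLINE_TIER_ORDER},
            "unreported": sum(1 for a in bundle.germline_assignments if a.tier is None),
            "common_matches": len(bundle.common_matches),
        },
        "somatic": {
            "called": len(inputs.somatic),
            "passing": len(bundle.somatic_assignments),
            "excluded": _count_by(bundle.somatic_excluded, lambda a: a.exclusion_reason),
            "tiers": {t: s_tiers.get(t, 0) for t in SOMATIC_TIER_ORDER},
            "unreported": sum(1 for a in bundle.somatic_assignments if a.tier is None),
        },
        "scna": {
            "segments": len(inputs.segments) if inputs.segments is not None else 0,
            "retained": len(bundle.plot_segments),
            "gene_calls": len(bundle.gene_calls),
            "gene_calls_reported": sum(1 for c in bundle.gene_calls if c.tier != "none"),
            "broad_events": len(bundle.broad_events),
        },
        "loh": {
            "pairs": len(inputs.baf_pairs) if inputs.baf_pairs is not None else 0,
            "events": len(bundle.loh_events),
            "in_cgc": sum(1 for e in bundle.loh_events if e.in_cgc),
            "with_somatic": len(bundle.loh_somatic),
        },
        "double_hits": len(bundle.double_hits),
    }
    if bundle.tmb is not None:
        log["tmb"] = {
            "n_qualifying": bundle.tmb.n_qualifying,
            "denominator_mb": bundle.tmb.denominator_mb,
            "tmb": bundle.tmb.tmb,
        }
    if bundle.pole is not None:
        log["pole"] = {
            "status": bundle.pole.status,
            "snv_per_mb": bundle.pole.snv_per_mb,
            "ssr_indel_per_mb": bundle.pole.ssr_indel_per_mb,
        }
    return log


# ---------------------------------------------------------------------------
# Artifact writers
# ---------------------------------------------------------------------------

def write_artifacts(bundle: ReportBundle, run_log: dict, out_dir) -> list[str]:
    """Write the report, summary, per-section TSVs, enrichment lists and run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def _save(name: str, text: str):
        (out / name).write_text(text)
        written.append(name)

    def _tsv(name: str, headers, rows):
        lines = ["\t".join(headers)] + ["\t".join(str(c) for c in r) for r in rows]
        _save(name, "\n".join(lines) + "\n")

    report, summary = assemble_report(bundle)
    _save("report.md", report)
    _save("summary.md", summary)

    for tier in GERMLINE_TIER_ORDER:
        rows = sorted(
            [(a.variant.gene, a.variant.genome_change or "", a.variant.protein_change or "",
              a.variant.clinvar)
             for a in bundle.germline_assignments if a.tier == tier]
        )
        _tsv(f"germline_{tier}.tsv",
             ["Gene", "Genome_Change", "Protein_Change", "ClinVar"], rows)
    rows = sorted([(v.rsid or "", gene, v.clinvar) for v, gene in bundle.common_matches])
    _tsv("germline_common_variants.tsv", ["rsID", "Gene", "ClinVar"], rows)

    for tier in SOMATIC_TIER_ORDER:
        rows = sorted(
            [(a.variant.gene, a.variant.classification, a.variant.protein_change or "",
              a.variant.genome_change or "",
              "" if a.variant.tumor_vaf is None else f"{a.variant.tumor_vaf:.2f}")
             for a in bundle.somatic_assignments if a.tier == tier]
        )
        _tsv(f"somatic_{tier}.tsv",
             ["Gene", "Classification", "Protein_Change", "Genome_Change", "Tumor_VAF"],
             rows)

    rows = sorted(
        [(c.gene, c.direction, f"{c.log2_ratio:.2f}", c.tier, f"{c.covered_fraction:.2f}")
         for c in bundle.gene_calls]
    )
    _tsv("scna_gene_calls.tsv", ["Gene", "Type", "Log2_Ratio", "Tier", "Covered_Fraction"], rows)
    rows = sorted([(e.name, e.scope, e.direction, f"{e.covered_fraction:.2f}")
                   for e in bundle.broad_events])
    _tsv("scna_broad_events.tsv", ["Region", "Scope", "Type", "Covered_Fraction"], rows)
    if bundle.scna_burden is not None:
        b = bundle.scna_burden
        _tsv("scna_burden.tsv",
             ["Total_Altered_Mb", "N_Alterations", "Avg_Len_kb", "wGII"],
             [(f"{b.total_altered_mb:.3f}", b.n_alterations, f"{b.avg_len_kb:.1f}",
               f"{b.wgii:.4f}")])
    rows = [(s.chrom, s.start, s.end, f"{s.log2_ratio:.4f}") for s in bundle.plot_segments]
    _tsv("scna_plot_data.tsv", ["Chromosome", "Start", "End", "Log2_Ratio"], rows)

    rows = sorted([(e.gene, e.chrom, e.start, e.end, f"{e.baf_delta:.2f}", int(e.in_cgc))
                   for e in bundle.loh_events])
    _tsv("loh_overview.tsv", ["Gene", "Chromosome", "Start", "End", "BAF_Delta", "In_CGC"], rows)
    rows = sorted([(e.gene, e.chrom, f"{e.baf_delta:.2f}")
                   for e in bundle.loh_events if e.in_cgc])
    _tsv("loh_cgc.tsv", ["Gene", "Chromosome", "BAF_Delta"], rows)
    rows = sorted([(g, len(events), len(variants)) for g, events, variants in bundle.loh_somatic])
    _tsv("loh_somatic.tsv", ["Gene", "N_LOH_Events", "N_Somatic_Variants"], rows)

    rows = [(h.gene, h.evidence_summary) for h in bundle.double_hits]
    _tsv("double_hits.tsv", ["Gene", "Evidence"], rows)

    _save("enrichment_snv_genes.txt", "\n".join(bundle.enrichment_snv_genes) + "\n")
    _save("enrichment_scna_genes.txt", "\n".join(bundle.enrichment_scna_genes) + "\n")
    _save("run_log.json", json.dumps(run_log, indent=2, sort_keys=True) + "\n")
    return written


# ---------------------------------------------------------------------------
# File-level pipeline
# ---------------------------------------------------------------------------

def load_catalog_dir(catalog_dir) -> dict:
    catalog_dir = Path(catalog_dir)
    catalogs = {}
    for kind, fname in CATALOG_FILES.items():
        path = catalog_dir / fname
        if path.exists():
            catalogs[kind] = gio.read_catalog(path, kind)
    return catalogs


def read_cohort_history(path) -> list[CohortTmbRecord]:
    """Cohort TMB history TSV: Sample, TMB, Subset, Recurrent (0/1)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        records.append(CohortTmbRecord(
            sample=row.Sample, tmb=float(row.TMB), subset=row.Subset,
            recurrent=str(getattr(row, "Recurrent", "0")).strip() in ("1", "true", "True"),
        ))
    return records


def write_cohort_history(records, path) -> None:
    rows = [{"Sample": r.sample, "TMB": repr(r.tmb), "Subset": r.subset,
             "Recurrent": int(r.recurrent)} for r in records]
    pd.DataFrame(rows, columns=["Sample", "TMB", "Subset", "Recurrent"]).to_csv(
        path, sep="\t", index=False)


def read_signature_weights(path) -> dict[str, float]:
    weights = {}
    with open(path) as fh:
        header = fh.readline()  # Signature<TAB>Weight
        if "\t" not in header:
            raise gio.LoadError(f"{path}: expected Signature<TAB>Weight header")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            sig, w = line.split("\t")[:2]
            weights[sig] = float(w)
    return weights


def run_pipeline(
    germline_maf,
    somatic_maf,
    catalog_dir,
    out_dir,
    segments=None,
    baf=None,
    cytobands=None,
    gene_bed=None,
    config=None,
    cohort_history=None,
    msi_status=None,
    molecular_subset=None,
    signature_weights=None,
    sample_id="sample",
    require_scna=False,
) -> tuple[ReportBundle, dict]:
    """Read every input file, run the analysis and write all artifacts.

    Any stage failure raises with the stage named; callers (e.g. the CLI)
    map that to a nonzero exit status.
    """
    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    if require_scna and (segments is None or not Path(segments).exists()):
        raise FileNotFoundError(
            f"--require-scna set but segments file is missing: {segments}")

    cfg = _stage("config", gio.read_config, config) if config else AnalysisConfig()
    inputs = CaseInputs(
        germline=_stage("read_germline", gio.read_variants, germline_maf, "germline"),
        somatic=_stage("read_somatic", gio.read_variants, somatic_maf, "somatic"),
        catalogs=_stage("read_catalogs", load_catalog_dir, catalog_dir),
        cfg=cfg,
        segments=(_stage("read_segments", gio.read_segments, segments)
                  if segments and Path(segments).exists() else None),
        baf_pairs=(_stage("read_baf", gio.read_baf_pairs, baf)
                   if baf and Path(baf).exists() else None),
        cytobands=(_stage("read_cytobands", gio.read_cytobands, cytobands)
                   if cytobands and Path(cytobands).exists() else None),
        gene_models=(_stage("read_gene_bed", gio.read_gene_bed, gene_bed)
                     if gene_bed and Path(gene_bed).exists() else None),
        cohort_history=(_stage("read_cohort", read_cohort_history, cohort_history)
                        if cohort_history and Path(cohort_history).exists() else None),
        msi_status=msi_status,
        molecular_subset=molecular_subset,
        signature_weights=(_stage("read_signatures", read_signature_weights, signature_weights)
                           if signature_weights and Path(signature_weights).exists() else None),
        sample_id=sample_id,
    )
    bundle, run_log = _stage("analysis", analyze_case, inputs)
    _stage("write_artifacts", write_artifacts, bundle, run_log, out_dir)
    return bundle, run_log
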