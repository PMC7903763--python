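"""Synthetic matched tumor/normal case generator with planted ground truth.

Generates, for a miniature 4-chromosome genome (10 Mb per chromosome, 8
cytobands each), every input the pipeline consumes — germline and somatic
variant tables, copy-number segments, per-gene BAF pairs, cytobands, gene
models, curated catalogs and a config — together with a truth manifest
stating the expected fate of everything planted.  All catalogs are
synthetic stand-ins assembled from well-known cancer-gene symbols; they are
fixtures, not curation.

Ground truth is not merely asserted: every generated record is re-evaluated
by small generator-local predicate functions (deliberately independent of
the analysis modules), so the manifest is derived, and boundary-valued
plants (VAF exactly 0.05, |log2| exactly 0.25, |dBAF| exactly 0.40, depth
exactly at the cutoffs) pin strict-vs-inclusive threshold semantics.

The same seed always produces byte-identical files.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as gio
from .burden import CohortTmbRecord
from .model import (
    AnalysisConfig,
    AnnotatedVariant,
    BafPair,
    Cytoband,
    GeneCatalog,
    GeneModel,
    ScnaSegment,
)

# ---------------------------------------------------------------------------
# Miniature genome
# ---------------------------------------------------------------------------

CHROMS = ("chr1", "chr2", "chr3", "chr4")
CHROM_LEN = 10_000_000
BAND_NAMES = ("p14", "p13", "p12", "p11", "q11", "q12", "q13", "q14")
BAND_LEN = CHROM_LEN // len(BAND_NAMES)
GENE_LEN = 100_000
GENE_STRIDE = 200_000

# ---------------------------------------------------------------------------
# Synthetic catalogs (fixture stand-ins built from familiar symbols)
# ---------------------------------------------------------------------------

ACMG = ("APC", "BRCA1", "BRCA2", "MLH1", "MSH2", "PTEN", "RB1", "RET", "TP53", "VHL")
GLIOMA_GENES = ("ATRX", "CDKN2A", "CIC", "EGFR", "FUBP1", "IDH1", "IDH2", "NF1",
                "PDGFRA", "PIK3CA", "PTEN", "RB1", "TERT", "TP53")
CGC = tuple(sorted(set(GLIOMA_GENES) - {"TERT"}) + [
    "ALK", "APC", "BRAF", "BRCA1", "BRCA2", "CDK4", "CDK6", "EZH2", "FGFR1",
    "KIT", "KRAS", "MDM2", "MET", "MLH1", "MSH2", "NOTCH1", "RET", "SMARCA4", "VHL",
])
PREDISPOSITION = ("BAP1", "BRCA1", "BRCA2", "CHEK2", "MSH6", "NF1", "PALB2", "TP53")
DDR = ("BRCA1", "ERCC1", "ERCC4", "MLH1", "MSH2", "POLD1", "POLK", "XPA", "XPC")
FLAGS = ("AHNAK2", "DNAH17", "DST", "FLG", "MUC16", "MUC5B", "OBSCN", "PLEC",
         "SYNE1", "TTN")
KEGG_SELECTED = ("AKT1", "CCND1", "CCNE1", "CDK4", "E2F1", "MTOR", "RPS6KB1", "TSC1")
GWAS_SNPS = (("rs1110784", "ATP9B"), ("rs1468358", "PLOD3"), ("rs1760897", "TEP1"),
             ("rs1799782", "XRCC1"), ("rs3828550", "KDR"))
HOTSPOTS = (("BRAF", "p.V600E", 12), ("EGFR", "p.L858R", 20), ("IDH1", "p.R132H", 50),
            ("KRAS", "p.G12D", 30), ("PIK3CA", "p.E545K", 25), ("TP53", "p.R175H", 15))
GLIOMA_SCNAS = (("BRAF", "Amp"), ("CDK4", "Amp"), ("CDK6", "Amp"), ("CDKN2A", "Del"),
                ("EGFR", "Amp"), ("MDM2", "Amp"), ("MET", "Amp"), ("NF1", "Del"),
                ("PDGFRA", "Amp"), ("PTEN", "Del"), ("RB1", "Del"))

# Role pools: kept pairwise disjoint where an accidental overlap would plant
# an unintended double hit or tier.
SCNA_AMP_POOL = ("EGFR", "PDGFRA", "CDK6", "MDM2", "MET")          # glioma_established Amp
SCNA_DEL_POOL = ("PTEN", "CDKN2A", "RB1", "NF1")                   # glioma Del (double-hit capable)
SCNA_CGC_POOL = ("FGFR1", "VHL", "RET")                            # cgc-tier calls
VAR_GLIOMA_POOL = ("IDH1", "IDH2", "TP53", "ATRX", "CIC", "FUBP1", "PIK3CA")
VAR_HOTSPOT_POOL = (("BRAF", "p.V600E"), ("KRAS", "p.G12D"))
VAR_CGC_OTHER_POOL = ("EZH2", "APC", "BRCA2", "MSH2")
LOH_DH_POOL = ("NOTCH1", "ALK")                                    # chr3, CGC, double-hit via LOH
LOH_CGC_POOL = ("SMARCA4", "KIT")                                  # chr3, CGC, LOH only
VAR_DDR_POOL = ("POLK", "ERCC1", "ERCC4", "XPA")
VAR_KEGG_POOL = ("MTOR", "RPS6KB1", "AKT1", "E2F1")

N_FILLER_GENES = 60
SCNA_NONE_POOL = tuple(f"GENE{i:03d}" for i in range(1, 6))        # untiered SCNA calls
VAR_FILLER_POOL = tuple(f"GENE{i:03d}" for i in range(6, 39))      # filler variants (chr1/2)
LOH_FILLER_POOL = tuple(f"GENE{i:03d}" for i in range(39, 61))     # chr3, non-CGC LOH

NONSYN = ("Frame_Shift_Del", "Frame_Shift_Ins", "Splice_Site", "Translation_Start_Site",
          "Nonsense_Mutation", "Nonstop_Mutation", "In_Frame_Del", "In_Frame_Ins",
          "Missense_Mutation")
CODING = set(NONSYN) | {"Silent"}
_INDEL_CLASSES = {"Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins"}
_FILLER_CLASSES = ("Missense_Mutation", "Silent", "Intron", "3'UTR", "5'UTR",
                   "Frame_Shift_Del", "Nonsense_Mutation", "Splice_Site", "In_Frame_Ins")


def build_catalogs() -> dict[str, GeneCatalog]:
    return {
        "acmg": GeneCatalog("acmg", ACMG),
        "cgc": GeneCatalog("cgc", CGC),
        "predisposition": GeneCatalog("predisposition", PREDISPOSITION),
        "ddr": GeneCatalog("ddr", DDR),
        "flags": GeneCatalog("flags", FLAGS),
        "glioma_genes": GeneCatalog("glioma_genes", GLIOMA_GENES),
        "glioma_scnas": GeneCatalog("glioma_scnas", GLIOMA_SCNAS),
        "kegg_selected": GeneCatalog("kegg_selected", KEGG_SELECTED),
        "gwas_snps": GeneCatalog("gwas_snps", GWAS_SNPS),
        "hotspots": GeneCatalog("hotspots", HOTSPOTS),
    }


def build_cytobands() -> list[Cytoband]:
    bands = []
    for chrom in CHROMS:
        for i, name in enumerate(BAND_NAMES):
            start = i * BAND_LEN + 1
            bands.append(Cytoband(chrom=chrom, start=start, end=start + BAND_LEN - 1,
                                  band=name, arm=name[0]))
    return bands


def build_gene_models() -> dict[str, GeneModel]:
    """Deterministic placement: chr3 hosts the LOH pools, chr1/chr2 the rest."""
    chr3_genes = sorted(set(LOH_DH_POOL) | set(LOH_CGC_POOL) | set(LOH_FILLER_POOL))
    all_named = set().union(
        ACMG, CGC, GLIOMA_GENES, PREDISPOSITION, DDR, FLAGS, KEGG_SELECTED,
        (g for _, g in GWAS_SNPS),
        (f"GENE{i:03d}" for i in range(1, N_FILLER_GENES + 1)),
    )
    other = sorted(all_named - set(chr3_genes))
    per_chrom = CHROM_LEN // GENE_STRIDE
    if len(other) > 2 * per_chrom or len(chr3_genes) > per_chrom:
        raise AssertionError("gene pools exceed miniature genome capacity")
    models: dict[str, GeneModel] = {}

    def _place(genes, chrom):
        for slot, gene in enumerate(genes):
            start = slot * GENE_STRIDE + 50_001
            models[gene] = GeneModel(gene=gene, chrom=chrom, start=start,
                                     end=start + GENE_LEN - 1)

    _place(other[:per_chrom], "chr1")
    _place(other[per_chrom:], "chr2")
    _place(chr3_genes, "chr3")
    return models


# ---------------------------------------------------------------------------
# Truth specification
# ---------------------------------------------------------------------------

@dataclass
class TruthSpec:
    """Planted composition of one synthetic case."""

    seed: int = 0
    germline_tiers: dict = field(default_factory=lambda: {
        "acmg_incidental": 3, "cgc": 4, "predisposition": 3, "ddr": 3})
    n_germline_unreported: int = 5
    germline_excluded: dict = field(default_factory=lambda: {
        "maf_too_high": 4, "benign_clinvar": 3, "synonymous": 3, "flags_gene": 2})
    n_common: int = 5
    include_rescue_plant: bool = True
    somatic_tiers: dict = field(default_factory=lambda: {
        "glioma_established": 4, "cgc_hotspot": 2, "cgc_other": 4,
        "ddr": 2, "kegg_selected": 3})
    n_somatic_unreported: int = 4
    somatic_excluded: dict = field(default_factory=lambda: {
        "vaf_too_low": 3, "synonymous": 3, "flags_gene": 2})
    pole_snv_high: bool = False
    pole_ssr_high: bool = False
    scna_calls: dict = field(default_factory=lambda: {
        "glioma_established": 4, "cgc": 2, "none": 2})
    broad_events: tuple = (("arm", "Del"), ("band", "Amp"))
    n_double_hit_scna: int = 2
    n_double_hit_loh: int = 2
    n_loh_cgc_extra: int = 1
    n_loh_noncgc: int = 1
    n_filler_germline: int = 150
    n_filler_somatic: int = 150
    n_noise_segments: int = 30
    include_boundary_plants: bool = True

    def validate(self) -> None:
        for name, count in [*self.germline_tiers.items(), *self.somatic_tiers.items(),
                            *self.germline_excluded.items(), *self.somatic_excluded.items(),
                            *self.scna_calls.items()]:
            if count < 0:
                raise ValueError(f"infeasible spec: negative count for {name}")
        if self.n_common > len(GWAS_SNPS):
            raise ValueError("infeasible spec: more common-variant plants than GWAS SNPs")
        if self.n_double_hit_scna > min(self.somatic_tiers.get("glioma_established", 0),
                                        self.scna_calls.get("glioma_established", 0),
                                        len(SCNA_DEL_POOL)):
            raise ValueError("infeasible spec: double-hit-via-SCNA plants need matching "
                             "glioma-tier variants and deletion calls")
        if self.n_double_hit_loh > min(self.somatic_tiers.get("cgc_other", 0),
                                       len(LOH_DH_POOL)):
            raise ValueError("infeasible spec: double-hit-via-LOH plants need matching "
                             "cgc_other variants")
        if self.scna_calls.get("glioma_established", 0) - self.n_double_hit_scna > len(SCNA_AMP_POOL):
            raise ValueError("infeasible spec: too many glioma-tier amplification calls")
        if self.scna_calls.get("cgc", 0) > len(SCNA_CGC_POOL):
            raise ValueError("infeasible spec: too many cgc-tier SCNA calls")
        if self.scna_calls.get("none", 0) > len(SCNA_NONE_POOL):
            raise ValueError("infeasible spec: too many untiered SCNA calls")
        if self.n_loh_cgc_extra > len(LOH_CGC_POOL):
            raise ValueError("infeasible spec: too many CGC LOH plants")
        if self.n_loh_noncgc > len(LOH_FILLER_POOL):
            raise ValueError("infeasible spec: too many non-CGC LOH plants")
        if len(self.broad_events) > 0:
            scopes = [s for s, _ in self.broad_events]
            if "chromosome" in scopes and len(scopes) > 1:
                raise ValueError("infeasible spec: a chromosome-scope broad event "
                                 "must be the only broad plant")
            if scopes.count("arm") > 1 or scopes.count("band") > 1:
                raise ValueError("infeasible spec: at most one arm and one band broad plant")


# ---------------------------------------------------------------------------
# Generator-local fate evaluation (independent of the analysis modules)
# ---------------------------------------------------------------------------

def _local_germline_fate(v: AnnotatedVariant) -> tuple[str | None, str | None]:
    """(tier, exclusion_reason) mirror of the germline cascade, evaluated locally."""
    rescued = v.clinvar in ("pathogenic", "likely_pathogenic", "drug_response")
    if not rescued and not v.effective_maf < 0.01:
        return None, "maf_too_high"
    if v.clinvar in ("benign", "likely_benign"):
        return None, "benign_clinvar"
    if v.classification not in NONSYN:
        return None, "synonymous"
    if v.gene in FLAGS:
        return None, "flags_gene"
    for tier, genes in (("acmg_incidental", ACMG), ("cgc", CGC),
                        ("predisposition", PREDISPOSITION), ("ddr", DDR)):
        if v.gene in genes:
            return tier, None
    return None, "no_tier"


def _local_somatic_fate(v: AnnotatedVariant) -> tuple[str | None, str | None]:
    vaf = v.tumor_vaf or 0.0
    if not vaf > 0.05:
        return None, "vaf_too_low"
    if v.classification not in NONSYN:
        return None, "synonymous"
    if v.gene in FLAGS:
        return None, "flags_gene"
    if v.gene in GLIOMA_GENES:
        return "glioma_established", None
    if v.gene in CGC:
        hotspot = any(g == v.gene and pc == v.protein_change and c >= 2
                      for g, pc, c in HOTSPOTS)
        return ("cgc_hotspot" if hotspot else "cgc_other"), None
    if v.gene in DDR:
        return "ddr", None
    if v.gene in KEGG_SELECTED:
        return "kegg_selected", None
    return None, "no_tier"


def _local_tmb_qualifies(v: AnnotatedVariant) -> bool:
    vaf = v.tumor_vaf or 0.0
    return (v.classification in CODING and vaf > 0.05
            and v.tumor_depth > 20 and v.normal_depth > 10)


# ---------------------------------------------------------------------------
# Record factories
# ---------------------------------------------------------------------------

_BASES = ("A", "C", "G", "T")


def _alleles(rng: np.random.Generator, classification: str) -> tuple[str, str]:
    if classification in ("Frame_Shift_Del", "In_Frame_Del"):
        k = 3 if classification == "In_Frame_Del" else int(rng.integers(1, 4))
        return "".join(rng.choice(_BASES, size=k)), "-"
    if classification in ("Frame_Shift_Ins", "In_Frame_Ins"):
        k = 3 if classification == "In_Frame_Ins" else int(rng.integers(1, 4))
        return "-", "".join(rng.choice(_BASES, size=k))
    ref = str(rng.choice(_BASES))
    alt = str(rng.choice([b for b in _BASES if b != ref]))
    return ref, alt


def _variant(rng, models, gene, classification, origin, *, vaf=None, depth=100,
             n_depth=40, maf=None, clinvar="not_reported", rsid=None,
             protein_change=None, in_ssr=None, pos=None) -> AnnotatedVariant:
    model = models.get(gene)
    chrom = model.chrom if model else "chr1"
    if pos is None:
        if model:
            pos = int(rng.integers(model.start, model.end + 1))
        else:
            pos = int(rng.integers(1, CHROM_LEN))
    ref, alt = _alleles(rng, classification)
    t_alt = 0 if vaf is None else round(vaf * depth)
    pop_af = {}
    if maf is not None:
        pop_af["exac"] = maf
        if rng.random() < 0.5:
            pop_af["thousand_genomes"] = round(maf * float(rng.uniform(0.5, 1.0)), 6)
    if in_ssr is None and origin == "somatic" and classification in _INDEL_CLASSES:
        in_ssr = False
    return AnnotatedVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        classification=classification, origin=origin, rsid=rsid, pop_af=pop_af,
        clinvar=clinvar, protein_change=protein_change,
        genome_change=f"g.{chrom}:{pos}{ref}>{alt}",
        tumor_vaf=(t_alt / depth if vaf is not None else None),
        tumor_depth=depth if vaf is not None else 0,
        normal_depth=n_depth, in_ssr=in_ssr,
    )


def _pick(rng, pool, n):
    """n picks from pool, cycling deterministically when n exceeds the pool."""
    pool = list(pool)
    order = list(rng.permutation(len(pool)))
    return [pool[order[i % len(pool)]] for i in range(n)]


# ---------------------------------------------------------------------------
# Case generation
# ---------------------------------------------------------------------------

def generate_case(spec: TruthSpec, out_dir) -> dict:
    """Generate one case on disk and return its truth manifest.

    Writes germline.maf, somatic.maf, segments.seg, baf_pairs.tsv,
    cytoBand.txt, genes.bed, config.txt, catalogs/ and truth.json under
    ``out_dir``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    models = build_gene_models()
    catalogs = build_catalogs()
    cytobands = build_cytobands()

    germline: list[AnnotatedVariant] = []
    somatic: list[AnnotatedVariant] = []

    # ---- germline plants ---------------------------------------------------
    tier_pools = {
        "acmg_incidental": ACMG,
        "cgc": sorted(set(CGC) - set(ACMG)),
        "predisposition": sorted(set(PREDISPOSITION) - set(ACMG) - set(CGC)),
        "ddr": sorted(set(DDR) - set(ACMG) - set(CGC) - set(PREDISPOSITION)),
    }
    for tier, n in spec.germline_tiers.items():
        for gene in _pick(rng, tier_pools[tier], n):
            germline.append(_variant(
                rng, models, gene, "Missense_Mutation", "germline",
                maf=round(float(rng.uniform(0.0, 0.009)), 6),
                clinvar=str(rng.choice(["not_reported", "vus", "conflicting"])),
                protein_change=f"p.A{int(rng.integers(10, 900))}T"))
    for gene in _pick(rng, VAR_FILLER_POOL, spec.n_germline_unreported):
        germline.append(_variant(rng, models, gene, "Nonsense_Mutation", "germline",
                                 maf=0.0))
    for reason, n in spec.germline_excluded.items():
        for _ in range(n):
            gene = str(rng.choice(VAR_FILLER_POOL))
            if reason == "maf_too_high":
                germline.append(_variant(rng, models, gene, "Missense_Mutation",
                                         "germline",
                                         maf=round(float(rng.uniform(0.011, 0.2)), 6)))
            elif reason == "benign_clinvar":
                germline.append(_variant(rng, models, gene, "Missense_Mutation",
                                         "germline", maf=0.004,
                                         clinvar=str(rng.choice(["benign", "likely_benign"]))))
            elif reason == "synonymous":
                germline.append(_variant(rng, models, gene, "Silent", "germline", maf=0.0))
            elif reason == "flags_gene":
                germline.append(_variant(rng, models, str(rng.choice(FLAGS)),
                                         "Missense_Mutation", "germline", maf=0.0))
    if spec.include_rescue_plant:
        # clinically annotated common allele: exempt from the MAF cut
        germline.append(_variant(rng, models, "TP53", "Missense_Mutation", "germline",
                                 maf=0.42, clinvar="drug_response", rsid="rs1042522",
                                 protein_change="p.P72R"))
    for rsid, gene in list(GWAS_SNPS)[: spec.n_common]:
        germline.append(_variant(rng, models, gene, "Missense_Mutation", "germline",
                                 maf=round(float(rng.uniform(0.05, 0.45)), 6), rsid=rsid))
    if spec.include_boundary_plants:
        germline.append(_variant(rng, models, str(rng.choice(VAR_FILLER_POOL)),
                                 "Missense_Mutation", "germline", maf=0.01))
    for _ in range(spec.n_filler_germline):
        gene = str(rng.choice(VAR_FILLER_POOL))
        cls = str(rng.choice(_FILLER_CLASSES))
        maf = 0.0 if rng.random() < 0.5 else round(float(rng.uniform(0.0, 0.05)), 6)
        clinvar = str(rng.choice(["not_reported", "not_reported", "vus", "benign",
                                  "likely_benign"]))
        germline.append(_variant(rng, models, gene, cls, "germline",
                                 maf=maf, clinvar=clinvar))

    # ---- somatic plants ----------------------------------------------------
    dh_scna_genes = _pick(rng, SCNA_DEL_POOL, spec.n_double_hit_scna)
    dh_loh_genes = _pick(rng, LOH_DH_POOL, spec.n_double_hit_loh)

    def _passing_vaf():
        return round(float(rng.uniform(0.15, 0.6)), 2)

    for gene in dh_scna_genes:
        somatic.append(_variant(rng, models, gene, "Missense_Mutation", "somatic",
                                vaf=_passing_vaf(),
                                protein_change=f"p.G{int(rng.integers(10, 900))}D"))
    for gene in _pick(rng, VAR_GLIOMA_POOL,
                      spec.somatic_tiers.get("glioma_established", 0) - len(dh_scna_genes)):
        somatic.append(_variant(rng, models, gene, "Missense_Mutation", "somatic",
                                vaf=_passing_vaf(),
                                protein_change=f"p.G{int(rng.integers(10, 900))}D"))
    for gene, pchange in _pick(rng, VAR_HOTSPOT_POOL,
                               spec.somatic_tiers.get("cgc_hotspot", 0)):
        somatic.append(_variant(rng, models, gene, "Missense_Mutation", "somatic",
                                vaf=_passing_vaf(), protein_change=pchange))
    for gene in dh_loh_genes:
        somatic.append(_variant(rng, models, gene, "Nonsense_Mutation", "somatic",
                                vaf=_passing_vaf(),
                                protein_change=f"p.R{int(rng.integers(10, 900))}*"))
    for gene in _pick(rng, VAR_CGC_OTHER_POOL,
                      spec.somatic_tiers.get("cgc_other", 0) - len(dh_loh_genes)):
        somatic.append(_variant(rng, models, gene, "Missense_Mutation", "somatic",
                                vaf=_passing_vaf(),
                                protein_change=f"p.S{int(rng.integers(10, 900))}F"))
    for gene in _pick(rng, VAR_DDR_POOL, spec.somatic_tiers.get("ddr", 0)):
        somatic.append(_variant(rng, models, gene, "Missense_Mutation", "somatic",
                                vaf=_passing_vaf()))
    for gene in _pick(rng, VAR_KEGG_POOL, spec.somatic_tiers.get("kegg_selected", 0)):
        somatic.append(_variant(rng, models, gene, "Missense_Mutation", "somatic",
                                vaf=_passing_vaf()))
    for gene in _pick(rng, VAR_FILLER_POOL, spec.n_somatic_unreported):
        somatic.append(_variant(rng, models, gene, "Missense_Mutation", "somatic",
                                vaf=_passing_vaf()))
    for reason, n in spec.somatic_excluded.items():
        for _ in range(n):
            gene = str(rng.choice(VAR_FILLER_POOL))
            if reason == "vaf_too_low":
                somatic.append(_variant(rng, models, gene, "Missense_Mutation",
                                        "somatic", vaf=0.03))
            elif reason == "synonymous":
                somatic.append(_variant(rng, models, gene, "Silent", "somatic",
                                        vaf=_passing_vaf()))
            elif reason == "flags_gene":
                somatic.append(_variant(rng, models, str(rng.choice(FLAGS)),
                                        "Missense_Mutation", "somatic",
                                        vaf=_passing_vaf()))
    if spec.include_boundary_plants:
        # VAF exactly at the 5% cut (excluded, strict >)
        somatic.append(_variant(rng, models, str(rng.choice(VAR_FILLER_POOL)),
                                "Missense_Mutation", "somatic", vaf=0.05, depth=100))
        # tumor depth exactly 20 (passes the reporting filter, fails TMB)
        somatic.append(_variant(rng, models, str(rng.choice(VAR_FILLER_POOL)),
                                "Missense_Mutation", "somatic", vaf=0.5, depth=20))
        # normal depth exactly 10 (passes the reporting filter, fails TMB)
        somatic.append(_variant(rng, models, str(rng.choice(VAR_FILLER_POOL)),
                                "Missense_Mutation", "somatic", vaf=0.5, depth=100,
                                n_depth=10))
    for _ in range(spec.n_filler_somatic):
        gene = str(rng.choice(VAR_FILLER_POOL))
        cls = str(rng.choice(_FILLER_CLASSES))
        depth = int(rng.integers(10, 121))
        t_alt = int(rng.integers(0, depth + 1))
        somatic.append(_variant(rng, models, gene, cls, "somatic",
                                vaf=t_alt / depth, depth=depth,
                                n_depth=int(rng.integers(5, 61))))

    # ---- coding_mb derived from the planted POLE quadrant -------------------
    n_snv = sum(1 for v in somatic if _local_tmb_qualifies(v) and not v.is_indel)
    if n_snv == 0:
        raise ValueError("infeasible spec: no TMB-qualifying SNVs to anchor coding_mb")
    target_rate = 80.0 if spec.pole_snv_high else 30.0
    coding_mb = round(n_snv / target_rate, 4)
    if spec.pole_ssr_high:
        k = max(1, math.ceil(0.4 * coding_mb))
        for _ in range(k):
            somatic.append(_variant(rng, models, str(rng.choice(VAR_FILLER_POOL)),
                                    "Frame_Shift_Del", "somatic", vaf=0.3,
                                    in_ssr=True))

    rng.shuffle(germline)
    rng.shuffle(somatic)

    # ---- segments ----------------------------------------------------------
    segments: list[ScnaSegment] = []
    call_plan: list[tuple[str, str, float]] = []  # (gene, direction, log2)

    def _plant_call(gene, direction):
        log2 = (round(float(rng.uniform(0.4, 1.6)), 3) if direction == "Amp"
                else round(float(rng.uniform(-1.6, -0.4)), 3))
        m = models[gene]
        segments.append(ScnaSegment(chrom=m.chrom, start=m.start, end=m.end,
                                    log2_ratio=log2))
        call_plan.append((gene, direction, log2))

    for gene in dh_scna_genes:
        _plant_call(gene, "Del")
    for gene in _pick(rng, SCNA_AMP_POOL,
                      spec.scna_calls.get("glioma_established", 0) - len(dh_scna_genes)):
        _plant_call(gene, "Amp")
    for gene in _pick(rng, SCNA_CGC_POOL, spec.scna_calls.get("cgc", 0)):
        _plant_call(gene, "Amp")
    for gene in _pick(rng, SCNA_NONE_POOL, spec.scna_calls.get("none", 0)):
        _plant_call(gene, str(rng.choice(["Amp", "Del"])))

    broad_truth = []
    band_bounds = [(i * BAND_LEN + 1, (i + 1) * BAND_LEN) for i in range(len(BAND_NAMES))]
    for scope, direction in spec.broad_events:
        log2 = 0.7 if direction == "Amp" else -0.7
        if scope == "arm":
            start, end = band_bounds[0][0], band_bounds[2][1]  # 3 of 4 p bands
            name = "chr4p"
        elif scope == "band":
            start, end = band_bounds[5]  # q12
            name = "chr4q12"
        else:  # chromosome
            start, end = band_bounds[0][0], band_bounds[6][1]  # 7 of 8 bands
            name = "chr4"
        segments.append(ScnaSegment(chrom="chr4", start=start, end=end, log2_ratio=log2))
        broad_truth.append({"name": name, "scope": scope, "direction": direction})

    if spec.include_boundary_plants:
        # |log2| exactly at the 0.25 cut: retained (inclusive >=)
        segments.append(ScnaSegment(chrom="chr4", start=8_700_001, end=8_720_000,
                                    log2_ratio=0.25))
        # just below the cut: dropped
        segments.append(ScnaSegment(chrom="chr4", start=9_000_001, end=9_020_000,
                                    log2_ratio=-0.24))

    retained_planted = [s for s in segments if abs(s.log2_ratio) >= 0.25]
    _assert_disjoint(retained_planted)

    for _ in range(spec.n_noise_segments):
        chrom = str(rng.choice(CHROMS))
        start = int(rng.integers(1, CHROM_LEN - 100_000))
        segments.append(ScnaSegment(
            chrom=chrom, start=start, end=start + int(rng.integers(10_000, 80_000)),
            log2_ratio=round(float(rng.uniform(-0.2, 0.2)), 3)))
    rng.shuffle(segments)

    # ---- BAF pairs ---------------------------------------------------------
    baf_pairs: list[BafPair] = []
    loh_genes = list(dh_loh_genes)
    loh_genes += _pick(rng, LOH_CGC_POOL, spec.n_loh_cgc_extra)
    loh_genes += _pick(rng, LOH_FILLER_POOL, spec.n_loh_noncgc)
    for gene in loh_genes:
        m = models[gene]
        baf_pairs.append(BafPair(
            gene=gene, chrom=m.chrom, start=m.start, end=m.end,
            baf_tumor=round(float(rng.uniform(0.92, 0.99)), 3), baf_normal=0.5))
    quiet = [g for g in LOH_FILLER_POOL if g not in loh_genes][:5]
    for gene in quiet:
        m = models[gene]
        baf_pairs.append(BafPair(
            gene=gene, chrom=m.chrom, start=m.start, end=m.end,
            baf_tumor=round(0.5 + float(rng.uniform(0.0, 0.2)), 3), baf_normal=0.5))
    if spec.include_boundary_plants:
        gene = [g for g in LOH_FILLER_POOL if g not in loh_genes][5]
        m = models[gene]
        # |dBAF| exactly at the 0.4 cut: dropped (strict >)
        baf_pairs.append(BafPair(gene=gene, chrom=m.chrom, start=m.start, end=m.end,
                                 baf_tumor=0.9, baf_normal=0.5))
    rng.shuffle(baf_pairs)

    manifest = _derive_manifest(spec, germline, somatic, segments, baf_pairs,
                                call_plan, broad_truth, coding_mb, models)

    # ---- write everything --------------------------------------------------
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gio.write_variants(germline, out / "germline.maf")
    gio.write_variants(somatic, out / "somatic.maf")
    gio.write_segments(segments, out / "segments.seg")
    gio.write_baf_pairs(baf_pairs, out / "baf_pairs.tsv")
    gio.write_cytobands(cytobands, out / "cytoBand.txt")
    gio.write_gene_bed(sorted(models.values(), key=lambda m: (m.chrom, m.start)),
                       out / "genes.bed")
    (out / "catalogs").mkdir(exist_ok=True)
    for kind, catalog in catalogs.items():
        gio.write_catalog(catalog, out / "catalogs" / f"{kind}.tsv")
    gio.write_config(AnalysisConfig(coding_mb=coding_mb), out / "config.txt")
    (out / "truth.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _assert_disjoint(segments) -> None:
    by_chrom: dict[str, list[ScnaSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end + 1:
                raise AssertionError(f"planted segments touch on {chrom}: {a} / {b}")


def _derive_manifest(spec, germline, somatic, segments, baf_pairs, call_plan,
                     broad_truth, coding_mb, models) -> dict:
    """Re-derive the expected outputs from the generated records."""
    g_tiers: dict[str, int] = {}
    g_excluded: dict[str, int] = {}
    g_unreported = 0
    for v in germline:
        tier, reason = _local_germline_fate(v)
        if tier:
            g_tiers[tier] = g_tiers.get(tier, 0) + 1
        elif reason == "no_tier":
            g_unreported += 1
        else:
            g_excluded[reason] = g_excluded.get(reason, 0) + 1
    gwas_rsids = {r for r, _ in GWAS_SNPS}
    common_rsids = sorted({v.rsid for v in germline if v.rsid in gwas_rsids})

    s_tiers: dict[str, int] = {}
    s_excluded: dict[str, int] = {}
    s_unreported = 0
    passing_genes = set()
    for v in somatic:
        tier, reason = _local_somatic_fate(v)
        if tier or reason == "no_tier":
            passing_genes.add(v.gene)
        if tier:
            s_tiers[tier] = s_tiers.get(tier, 0) + 1
        elif reason == "no_tier":
            s_unreported += 1
        else:
            s_excluded[reason] = s_excluded.get(reason, 0) + 1

    qualifying = [v for v in somatic if _local_tmb_qualifies(v)]
    n_snv = sum(1 for v in qualifying if not v.is_indel)
    n_ssr = sum(1 for v in qualifying if v.is_indel and v.in_ssr)
    snv_rate = n_snv / coding_mb
    ssr_rate = n_ssr / coding_mb
    pole_status = ("deficient" if snv_rate > 60 and ssr_rate < 0.18 else "not_deficient")

    # planted gene calls double-checked by brute-force coverage over ALL
    # retained segments (catches accidental overlaps by construction bugs)
    retained = [s for s in segments if abs(s.log2_ratio) >= 0.25]
    planned = {g: (d, log2) for g, d, log2 in call_plan}
    for gene, model in models.items():
        for direction in ("Amp", "Del"):
            cov = sum(
                max(0, min(s.end, model.end) - max(s.start, model.start) + 1)
                for s in retained
                if s.chrom == model.chrom and (s.log2_ratio >= 0) == (direction == "Amp"))
            called = cov / model.length >= 0.5
            expected = gene in planned and planned[gene][0] == direction
            if called != expected:
                raise AssertionError(
                    f"construction error: gene {gene} {direction} call mismatch")

    def _call_tier(gene, direction):
        if (gene, direction) in set(GLIOMA_SCNAS):
            return "glioma_established"
        return "cgc" if gene in CGC else "none"

    gene_calls = sorted(
        ({"gene": g, "direction": d, "log2": log2, "tier": _call_tier(g, d)}
         for g, d, log2 in call_plan),
        key=lambda c: c["gene"])

    # burden truth: planted retained segments are pairwise disjoint and
    # non-adjacent, so the metrics are plain sums
    altered_by_chrom = {c: 0 for c in CHROMS}
    for s in retained:
        altered_by_chrom[s.chrom] += s.length
    total_altered_mb = sum(altered_by_chrom.values()) / 1e6
    n_alt = len(retained)
    burden = {
        "total_altered_mb": total_altered_mb,
        "n_alterations": n_alt,
        "avg_len_kb": (total_altered_mb * 1000 / n_alt) if n_alt else 0.0,
        "wgii": sum(v / CHROM_LEN for v in altered_by_chrom.values()) / len(CHROMS),
    }

    loh_genes = sorted({p.gene for p in baf_pairs if abs(p.baf_tumor - p.baf_normal) > 0.4})
    loh_cgc = sorted(g for g in loh_genes if g in CGC)
    scna_genes = {g for g, _, _ in call_plan}
    double_hits = sorted(passing_genes & (scna_genes | set(loh_genes)))

    enrichment_scna = sorted(
        g for g, _, log2 in call_plan if 2 ** log2 < 0.5 or 2 ** log2 > 1.5)

    return {
        "seed": spec.seed,
        "coding_mb": coding_mb,
        "germline": {
            "called": len(germline),
            "excluded": {k: g_excluded[k] for k in sorted(g_excluded)},
            "tiers": {k: g_tiers[k] for k in sorted(g_tiers)},
            "unreported": g_unreported,
            "passing": sum(g_tiers.values()) + g_unreported,
            "common_rsids": common_rsids,
        },
        "somatic": {
            "called": len(somatic),
            "excluded": {k: s_excluded[k] for k in sorted(s_excluded)},
            "tiers": {k: s_tiers[k] for k in sorted(s_tiers)},
            "unreported": s_unreported,
            "passing": sum(s_tiers.values()) + s_unreported,
        },
        "tmb": {"n_qualifying": len(qualifying), "tmb": len(qualifying) / coding_mb},
        "pole": {"status": pole_status, "snv_per_mb": snv_rate,
                 "ssr_indel_per_mb": ssr_rate},
        "scna": {
            "n_segments": len(segments),
            "n_retained": len(retained),
            "gene_calls": gene_calls,
            "broad_events": sorted(broad_truth, key=lambda e: e["name"]),
            "burden": burden,
        },
        "loh": {"genes": loh_genes, "cgc_genes": loh_cgc},
        "double_hits": double_hits,
        "enrichment": {
            "snv_genes": sorted(passing_genes),
            "scna_genes": enrichment_scna,
        },
    }


def generate_cohort(n: int, seed: int = 0) -> list[CohortTmbRecord]:
    """Synthetic TMB history with molecular-subset labels."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    subsets = ("IDH-mutant", "IDH-mutant-codel", "IDH-wild-type")
    records = []
    for i in range(n):
        records.append(CohortTmbRecord(
            sample=f"S{i + 1:03d}",
            tmb=round(float(rng.lognormal(mean=1.0, sigma=0.6)), 2),
            subset=subsets[i % len(subsets)],
            recurrent=bool(rng.random() < 0.2),
        ))
    return records
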