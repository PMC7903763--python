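"""Domain types for tumor/normal whole-exome report generation.

All genomic coordinates are 1-based, fully-closed intervals (the MAF/SEG
convention); the length of an interval is ``end - start + 1``.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields

logger = logging.getLogger(__name__)


class LoadError(ValueError):
    """An input file violates its documented dialect."""


class ConfigurationError(ValueError):
    """A required catalog, config key or resource is missing or malformed."""


class ContractViolation(ValueError):
    """A function was called outside its documented precondition."""


# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

#: Variant classifications with non-synonymous (protein-altering) impact.
NONSYNONYMOUS_CLASSIFICATIONS = frozenset({
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Splice_Site",
    "Translation_Start_Site",
    "Nonsense_Mutation",
    "Nonstop_Mutation",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Missense_Mutation",
})

#: Full closed vocabulary of accepted MAF-dialect classification tokens.
CLASSIFICATION_VOCABULARY = NONSYNONYMOUS_CLASSIFICATIONS | frozenset({
    "Silent",
    "Splice_Region",
    "Intron",
    "3'UTR",
    "5'UTR",
    "3'Flank",
    "5'Flank",
    "IGR",
    "RNA",
    "lincRNA",
    "Start_Codon_SNP",
    "De_novo_Start_InFrame",
    "De_novo_Start_OutOfFrame",
})

#: ClinVar significance tokens, ordered from most to least severe.  Benign
#: classes sort below "not_reported": they are removed by the germline filter
#: before any ranking, so their relative position only guarantees totality.
CLINVAR_SEVERITY_ORDER = (
    "pathogenic",
    "likely_pathogenic",
    "drug_response",
    "conflicting",
    "vus",
    "not_reported",
    "likely_benign",
    "benign",
)
CLINVAR_VOCABULARY = frozenset(CLINVAR_SEVERITY_ORDER)

#: ClinVar classes that exempt a germline variant from the population-MAF cut.
CLINVAR_RESCUE_CLASSES = frozenset({"pathogenic", "likely_pathogenic", "drug_response"})

POPULATION_AF_SOURCES = ("thousand_genomes", "exac", "esp6500")

GERMLINE_TIER_ORDER = ("acmg_incidental", "cgc", "predisposition", "ddr")
SOMATIC_TIER_ORDER = ("glioma_established", "cgc_hotspot", "cgc_other", "ddr", "kegg_selected")

CATALOG_KINDS = frozenset({
    "acmg", "cgc", "predisposition", "ddr", "flags", "glioma_genes",
    "glioma_scnas", "kegg_selected", "gwas_snps", "hotspots",
})

_CLINVAR_ALIASES = {
    "pathogenic": "pathogenic",
    "pathogenic/likely pathogenic": "pathogenic",
    "likely pathogenic": "likely_pathogenic",
    "likely_pathogenic": "likely_pathogenic",
    "drug response": "drug_response",
    "drug_response": "drug_response",
    "uncertain significance": "vus",
    "uncertain_significance": "vus",
    "vus": "vus",
    "benign": "benign",
    "likely benign": "likely_benign",
    "likely_benign": "likely_benign",
    "benign/likely benign": "likely_benign",
    "not_reported": "not_reported",
    "not reported": "not_reported",
    "not provided": "not_reported",
    "": "not_reported",
    ".": "not_reported",
    "na": "not_reported",
}


def normalize_clinvar(raw: str | None) -> str:
    """Map a free-text ClinVar significance string onto the closed vocabulary.

    Strings containing "conflicting" map to ``conflicting``.  Unrecognized
    non-empty strings map to ``not_reported`` with a logged warning (they are
    NOT assumed to be VUS).
    """
    if raw is None:
        return "not_reported"
    token = str(raw).strip().lower()
    if "conflicting" in token:
        return "conflicting"
    if token in _CLINVAR_ALIASES:
        return _CLINVAR_ALIASES[token]
    if token in CLINVAR_VOCABULARY:
        return token
    logger.warning("unrecognized ClinVar significance %r mapped to not_reported", raw)
    return "not_reported"


def _allele_len(allele: str) -> int:
    # MAF encodes the absent side of an indel as "-"
    return 0 if allele == "-" else len(allele)


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotatedVariant:
    """One germline or somatic short variant with its annotations.

    ``tumor_vaf`` is the fraction of tumor reads supporting the alternate
    allele (meaningful for somatic calls); ``pop_af`` maps population-source
    names to allele frequencies.  ``in_ssr`` records whether an indel lies in
    a simple sequence repeat; ``None`` means the annotation is unavailable.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    classification: str
    origin: str  # "germline" | "somatic"
    rsid: str | None = None
    pop_af: dict[str, float] = field(default_factory=dict)
    clinvar: str = "not_reported"
    protein_change: str | None = None
    genome_change: str | None = None
    tumor_vaf: float | None = None
    tumor_depth: int = 0
    normal_depth: int = 0
    in_ssr: bool | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.origin not in ("germline", "somatic"):
            raise ValueError(f"origin must be germline or somatic, got {self.origin!r}")
        if self.classification not in CLASSIFICATION_VOCABULARY:
            raise ValueError(f"unknown variant classification {self.classification!r}")
        if self.clinvar not in CLINVAR_VOCABULARY:
            raise ValueError(f"unknown ClinVar token {self.clinvar!r}")
        if self.tumor_vaf is not None and not 0.0 <= self.tumor_vaf <= 1.0:
            raise ValueError(f"tumor_vaf out of [0,1]: {self.tumor_vaf}")
        for src, af in self.pop_af.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"population AF for {src} out of [0,1]: {af}")
        if self.tumor_depth < 0 or self.normal_depth < 0:
            raise ValueError("read depths must be >= 0")

    @property
    def is_indel(self) -> bool:
        return _allele_len(self.ref) != _allele_len(self.alt)

    @property
    def effective_maf(self) -> float:
        """Population MAF: the maximum over available sources, 0 if none."""
        return max(self.pop_af.values(), default=0.0)

    @property
    def is_nonsynonymous(self) -> bool:
        return self.classification in NONSYNONYMOUS_CLASSIFICATIONS


@dataclass(frozen=True)
class ScnaSegment:
    """A copy-number segment with its log2(tumor/normal) ratio."""

    chrom: str
    start: int
    end: int
    log2_ratio: float
    sample: str = "sample"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if not math.isfinite(self.log2_ratio):
            raise ValueError("log2_ratio must be finite")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def direction(self) -> str:
        return "Amp" if self.log2_ratio >= 0 else "Del"


@dataclass(frozen=True)
class BafPair:
    """Tumor and normal B-allele frequencies aggregated over one gene."""

    gene: str
    chrom: str
    start: int
    end: int
    baf_tumor: float
    baf_normal: float

    def __post_init__(self) -> None:
        for name in ("baf_tumor", "baf_normal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")

    @property
    def baf_delta(self) -> float:
        return abs(self.baf_tumor - self.baf_normal)


@dataclass(frozen=True)
class GeneModel:
    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene model start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Cytoband:
    chrom: str
    start: int
    end: int
    band: str  # e.g. "p13.1"
    arm: str  # "p" | "q"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("cytoband start > end")
        if self.arm not in ("p", "q"):
            raise ValueError(f"arm must be p or q, got {self.arm!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneCatalog:
    """A named curated set driving tier assignment.

    ``entries`` holds, depending on ``kind``: gene symbols (most kinds);
    ``(rsid, gene)`` pairs for gwas_snps; ``(gene, direction)`` pairs for
    glioma_scnas; ``(gene, protein_change, count)`` for hotspots.
    """

    kind: str
    entries: tuple

    def __post_init__(self) -> None:
        if self.kind not in CATALOG_KINDS:
            raise ValueError(f"unknown catalog kind {self.kind!r}")
        if not self.entries:
            raise ValueError(f"catalog {self.kind} is empty")

    @property
    def genes(self) -> frozenset[str]:
        if self.kind == "gwas_snps":
            return frozenset(g for _, g in self.entries)
        if self.kind in ("glioma_scnas", "hotspots"):
            return frozenset(e[0] for e in self.entries)
        return frozenset(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    # -- kind-specific views -------------------------------------------------
    @property
    def rsids(self) -> dict[str, str]:
        """rsID -> gene (gwas_snps catalogs)."""
        if self.kind != "gwas_snps":
            raise ValueError("rsids view requires a gwas_snps catalog")
        return {rsid: gene for rsid, gene in self.entries}

    @property
    def scna_directions(self) -> frozenset[tuple[str, str]]:
        """(gene, Amp|Del) pairs (glioma_scnas catalogs)."""
        if self.kind != "glioma_scnas":
            raise ValueError("scna_directions view requires a glioma_scnas catalog")
        return frozenset((g, d) for g, d in self.entries)

    def hotspot_count(self, gene: str, protein_change: str | None) -> int:
        """Recurrence count for an exact (gene, protein change) hotspot, 0 if absent."""
        if self.kind != "hotspots":
            raise ValueError("hotspot_count requires a hotspots catalog")
        if protein_change is None:
            return 0
        for g, pc, count in self.entries:
            if g == gene and pc == protein_change:
                return count
        return 0


@dataclass(frozen=True)
class TierAssignment:
    """The fate of one variant in a cascade: a tier, or an exclusion reason.

    ``tier`` and ``exclusion_reason`` are mutually exclusive; a filter-passing
    variant matching no catalog carries ``tier=None, exclusion_reason='no_tier'``
    (the passed-but-unreported stratum).
    """

    variant: AnnotatedVariant
    tier: str | None = None
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if (self.tier is None) == (self.exclusion_reason is None):
            raise ValueError("exactly one of tier / exclusion_reason must be set")


@dataclass
class AnalysisConfig:
    """Tunable thresholds of the reporting cascades.

    Defaults mirror the printed clinical cutoffs: germline population MAF
    < 1%, somatic VAF > 5%, TMB depth > 20X tumor / > 10X normal, SCNA
    |log2 ratio| >= 0.25, LOH |dBAF| > 0.4, POLE-deficiency SNVs/Mb > 60
    with SSR-indels/Mb < 0.18, enrichment T/N ratio < 0.5 or > 1.5.
    """

    germline_max_maf: float = 0.01
    somatic_min_vaf: float = 0.05
    tmb_min_tumor_depth: int = 20
    tmb_min_normal_depth: int = 10
    scna_min_abs_log2: float = 0.25
    loh_min_baf_diff: float = 0.4
    pole_min_snv_per_mb: float = 60.0
    pole_max_ssr_indel_per_mb: float = 0.18
    enrichment_del_ratio: float = 0.5
    enrichment_amp_ratio: float = 1.5
    coding_mb: float | None = None
    hotspot_min_count: int = 2
    broad_min_covered_fraction: float = 0.5
    gene_min_overlap_fraction: float = 0.5
    clinvar_rescue: bool = True
    tmb_include_silent: bool = True
    doublehit_del_only: bool = False
    min_arm_assayed_len: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.germline_max_maf <= 1.0:
            raise ConfigurationError("germline_max_maf must be in [0,1]")
        if not 0.0 <= self.somatic_min_vaf <= 1.0:
            raise ConfigurationError("somatic_min_vaf must be in [0,1]")
        if self.scna_min_abs_log2 < 0:
            raise ConfigurationError("scna_min_abs_log2 must be >= 0")
        if not 0.0 <= self.loh_min_baf_diff <= 1.0:
            raise ConfigurationError("loh_min_baf_diff must be in [0,1]")
        if self.coding_mb is not None and self.coding_mb <= 0:
            raise ConfigurationError("coding_mb must be > 0")
        for name in ("broad_min_covered_fraction", "gene_min_overlap_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigurationError(f"{name} must be in (0,1]")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def rank_clinvar(tokens) -> str:
    """Return the most severe ClinVar token of a non-empty collection.

    Severity order: pathogenic > likely_pathogenic > drug_response >
    conflicting > vus > not_reported (> likely_benign > benign).
    """
    tokens = list(tokens)
    if not tokens:
        raise ContractViolation("rank_clinvar requires at least one token")
    for t in tokens:
        if t not in CLINVAR_VOCABULARY:
            raise ContractViolation(f"token {t!r} outside the ClinVar vocabulary")
    return min(tokens, key=CLINVAR_SEVERITY_ORDER.index)
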