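"""Germline reporting cascade.

A called germline variant is reported when its population MAF is below 1%,
it is not benign/likely-benign in ClinVar, it has non-synonymous impact and
its gene is not a FLAGS gene (frequently mutated, typically non-pathogenic
passengers).  Survivors are placed in the FIRST matching subsection of the
fixed sequence ACMG incidental findings -> Cancer Gene Census -> cancer
predisposition -> DNA damage repair; the Common Variants subsection matches
known GWAS SNPs by rsID against the unfiltered call set.
"""
from __future__ import annotations

from .model import (
    CLINVAR_RESCUE_CLASSES,
    GERMLINE_TIER_ORDER,
    AnalysisConfig,
    AnnotatedVariant,
    ConfigurationError,
    ContractViolation,
    GeneCatalog,
    TierAssignment,
)
from .model import rank_clinvar  # noqa: F401  (re-exported cascade utility)

#: Exclusion reasons, in the order the filter tests are applied.
GERMLINE_EXCLUSION_REASONS = ("maf_too_high", "benign_clinvar", "synonymous", "flags_gene")


def filter_germline(
    variants: list[AnnotatedVariant],
    flags: GeneCatalog,
    cfg: AnalysisConfig,
) -> tuple[list[AnnotatedVariant], list[TierAssignment]]:
    """Partition germline variants into filter survivors and exclusions.

    An excluded variant carries the first failing reason in the fixed order
    (population MAF, ClinVar benign, impact, FLAGS).  Variants with a
    pathogenic / likely-pathogenic / drug-response ClinVar class are exempt
    from the MAF cut when ``cfg.clinvar_rescue`` is on, so clinically
    annotated common alleles still surface in the report.
    """
    passing: list[AnnotatedVariant] = []
    excluded: list[TierAssignment] = []
    for v in variants:
        if v.origin != "germline":
            raise ContractViolation(f"filter_germline given a {v.origin} variant")
        reason = _germline_exclusion_reason(v, flags, cfg)
        if reason is None:
            passing.append(v)
        else:
            excluded.append(TierAssignment(variant=v, exclusion_reason=reason))
    return passing, excluded


def _germline_exclusion_reason(v: AnnotatedVariant, flags: GeneCatalog, cfg: AnalysisConfig):
    rescued = cfg.clinvar_rescue and v.clinvar in CLINVAR_RESCUE_CLASSES
    if not rescued and not v.effective_maf < cfg.germline_max_maf:
        return "maf_too_high"
    if v.clinvar in ("benign", "likely_benign"):
        return "benign_clinvar"
    if not v.is_nonsynonymous:
        return "synonymous"
    if v.gene in flags:
        return "flags_gene"
    return None


def assign_germline_tiers(
    passing: list[AnnotatedVariant],
    catalogs: dict[str, GeneCatalog],
) -> list[TierAssignment]:
    """Assign each filter-passing variant to its first matching tier.

    Tier order: acmg_incidental (acmg catalog), cgc, predisposition, ddr.
    A variant whose gene is in several catalogs lands only in the earliest
    tier; one matching no catalog is recorded with reason ``no_tier``.
    """
    tier_catalogs = {
        "acmg_incidental": "acmg",
        "cgc": "cgc",
        "predisposition": "predisposition",
        "ddr": "ddr",
    }
    for tier in GERMLINE_TIER_ORDER:
        if tier_catalogs[tier] not in catalogs:
            raise ConfigurationError(f"missing required catalog {tier_catalogs[tier]!r}")
    assignments = []
    for v in passing:
        tier = next(
            (t for t in GERMLINE_TIER_ORDER if v.gene in catalogs[tier_catalogs[t]]),
            None,
        )
        if tier is None:
            assignments.append(TierAssignment(variant=v, exclusion_reason="no_tier"))
        else:
            assignments.append(TierAssignment(variant=v, tier=tier))
    return assignments


def match_common_variants(
    all_variants: list[AnnotatedVariant],
    gwas: GeneCatalog,
) -> list[tuple[AnnotatedVariant, str]]:
    """Match known disease-associated GWAS SNPs by rsID.

    Runs against the UNFILTERED germline call set — common susceptibility
    alleles necessarily fail the 1% MAF cut, so this subsection is exempt
    from the reporting filter.  Returns (variant, catalog gene) pairs sorted
    by rsID.
    """
    rsids = gwas.rsids
    matches = [(v, rsids[v.rsid]) for v in all_variants if v.rsid and v.rsid in rsids]
    matches.sort(key=lambda m: (m[0].rsid, m[0].chrom, m[0].pos))
    return matches
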