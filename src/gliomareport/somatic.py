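"""Somatic short-variant reporting cascade.

Called somatic SNV/indels are reported when tumor VAF exceeds 5%, impact is
non-synonymous and the gene is not in FLAGS.  Survivors fall into the first
matching of five sequential subsections: established glioma genes, Cancer
Gene Census hotspots, other CGC variants, DNA-damage-repair genes, selected
KEGG pathway genes; survivors matching none are passed-but-unreported.
"""
from __future__ import annotations

import statistics

from .model import (
    SOMATIC_TIER_ORDER,
    AnalysisConfig,
    AnnotatedVariant,
    ConfigurationError,
    ContractViolation,
    GeneCatalog,
    TierAssignment,
)

SOMATIC_EXCLUSION_REASONS = ("vaf_too_low", "synonymous", "flags_gene")


def filter_somatic(
    variants: list[AnnotatedVariant],
    flags: GeneCatalog,
    cfg: AnalysisConfig,
) -> tuple[list[AnnotatedVariant], list[TierAssignment]]:
    """Partition somatic variants into filter survivors and exclusions.

    The VAF bound is strict: a variant at exactly ``somatic_min_vaf`` is
    excluded.  Exclusion reasons follow the fixed test order (VAF, impact,
    FLAGS).
    """
    passing: list[AnnotatedVariant] = []
    excluded: list[TierAssignment] = []
    for v in variants:
        if v.origin != "somatic":
            raise ContractViolation(f"filter_somatic given a {v.origin} variant")
        vaf = v.tumor_vaf if v.tumor_vaf is not None else 0.0
        if not vaf > cfg.somatic_min_vaf:
            excluded.append(TierAssignment(variant=v, exclusion_reason="vaf_too_low"))
        elif not v.is_nonsynonymous:
            excluded.append(TierAssignment(variant=v, exclusion_reason="synonymous"))
        elif v.gene in flags:
            excluded.append(TierAssignment(variant=v, exclusion_reason="flags_gene"))
        else:
            passing.append(v)
    return passing, excluded


def assign_somatic_tiers(
    passing: list[AnnotatedVariant],
    catalogs: dict[str, GeneCatalog],
    hotspots: GeneCatalog,
    cfg: AnalysisConfig,
) -> list[TierAssignment]:
    """First-match assignment over the five sequential somatic tiers.

    ``cgc_hotspot`` requires the gene in CGC AND an exact (gene, protein
    change) hotspot entry with recurrence count >= ``hotspot_min_count``;
    CGC genes without such a match fall to ``cgc_other``.  Survivors in no
    catalog are recorded with reason ``no_tier`` (passed-but-unreported).
    """
    for kind in ("glioma_genes", "cgc", "ddr", "kegg_selected"):
        if kind not in catalogs:
            raise ConfigurationError(f"missing required catalog {kind!r}")
    if hotspots.kind != "hotspots":
        raise ConfigurationError("hotspot catalog must have kind 'hotspots'")

    assignments = []
    for v in passing:
        tier = _somatic_tier(v, catalogs, hotspots, cfg)
        if tier is None:
            assignments.append(TierAssignment(variant=v, exclusion_reason="no_tier"))
        else:
            assignments.append(TierAssignment(variant=v, tier=tier))
    return assignments


def _somatic_tier(v, catalogs, hotspots, cfg):
    if v.gene in catalogs["glioma_genes"]:
        return "glioma_established"
    if v.gene in catalogs["cgc"]:
        if hotspots.hotspot_count(v.gene, v.protein_change) >= cfg.hotspot_min_count:
            return "cgc_hotspot"
        return "cgc_other"
    if v.gene in catalogs["ddr"]:
        return "ddr"
    if v.gene in catalogs["kegg_selected"]:
        return "kegg_selected"
    return None


def tier_vaf_summary(assignments: list[TierAssignment]) -> dict[str, dict[str, float]]:
    """Median and quartiles of tumor VAF per reported tier.

    Tiers with no variants are omitted.  Quartiles use the median-exclusive
    convention (lower/upper half medians).
    """
    by_tier: dict[str, list[float]] = {}
    for a in assignments:
        if a.tier is not None and a.variant.tumor_vaf is not None:
            by_tier.setdefault(a.tier, []).append(a.variant.tumor_vaf)
    summary = {}
    for tier in SOMATIC_TIER_ORDER:
        vafs = sorted(by_tier.get(tier, []))
        if not vafs:
            continue
        n = len(vafs)
        lower = vafs[: n // 2]
        upper = vafs[(n + 1) // 2:]
        summary[tier] = {
            "n": n,
            "median": statistics.median(vafs),
            "q1": statistics.median(lower) if lower else vafs[0],
            "q3": statistics.median(upper) if upper else vafs[-1],
        }
    return summary
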