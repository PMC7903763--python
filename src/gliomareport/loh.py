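"""Loss-of-heterozygosity detection and double-hit gene identification.

An LOH event is called when the absolute tumor-vs-normal B-allele-frequency
difference of a gene exceeds 0.4 (strict).  A double-hit gene carries at
least one filter-passing somatic short variant AND at least one gene-level
SCNA call and/or LOH event — the classical two-hit pattern of tumor
suppressor inactivation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    AnalysisConfig,
    AnnotatedVariant,
    BafPair,
    GeneCatalog,
    TierAssignment,
)
from .scna import GeneScnaCall


@dataclass(frozen=True)
class LohEvent:
    gene: str
    chrom: str
    start: int
    end: int
    baf_delta: float
    in_cgc: bool = False


@dataclass(frozen=True)
class DoubleHit:
    gene: str
    variants: tuple[AnnotatedVariant, ...]
    scna_calls: tuple[GeneScnaCall, ...] = ()
    loh_events: tuple[LohEvent, ...] = field(default=())

    @property
    def evidence_summary(self) -> str:
        parts = [f"{len(self.variants)} somatic SNV/indel"]
        if self.scna_calls:
            parts.append("+".join(sorted({c.direction for c in self.scna_calls})) + " SCNA")
        if self.loh_events:
            parts.append("LOH")
        return " + ".join(parts)


def filter_loh(
    pairs: list[BafPair],
    cfg: AnalysisConfig,
    cgc: GeneCatalog | None = None,
) -> list[LohEvent]:
    """Retain gene BAF pairs with |BAF_tumor - BAF_normal| strictly above the
    threshold; a delta of exactly 0.4 is dropped."""
    events = []
    for p in pairs:
        if p.baf_delta > cfg.loh_min_baf_diff:
            events.append(LohEvent(
                gene=p.gene, chrom=p.chrom, start=p.start, end=p.end,
                baf_delta=p.baf_delta,
                in_cgc=(cgc is not None and p.gene in cgc),
            ))
    return events


def intersect_loh_somatic(
    loh: list[LohEvent],
    somatic_reported: list[TierAssignment],
) -> list[tuple[str, list[LohEvent], list[AnnotatedVariant]]]:
    """Genes with both an LOH event and a reported somatic short variant.

    Matching is by gene symbol; one record per gene, sorted by gene.
    """
    loh_by_gene: dict[str, list[LohEvent]] = {}
    for e in loh:
        loh_by_gene.setdefault(e.gene, []).append(e)
    var_by_gene: dict[str, list[AnnotatedVariant]] = {}
    for a in somatic_reported:
        if a.tier is not None:
            var_by_gene.setdefault(a.variant.gene, []).append(a.variant)
    shared = sorted(set(loh_by_gene) & set(var_by_gene))
    return [(g, loh_by_gene[g], var_by_gene[g]) for g in shared]


def find_double_hits(
    somatic_passing: list[AnnotatedVariant],
    gene_calls: list[GeneScnaCall],
    loh: list[LohEvent],
    cfg: AnalysisConfig | None = None,
) -> list[DoubleHit]:
    """Genes with a filter-passing somatic short variant plus an SCNA call
    and/or LOH event.

    Any-direction SCNA evidence qualifies by default; with
    ``cfg.doublehit_del_only`` only deletions count (a tumor-suppressor-
    oriented reading).  Output is sorted by gene.
    """
    del_only = cfg is not None and cfg.doublehit_del_only
    vars_by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in somatic_passing:
        vars_by_gene.setdefault(v.gene, []).append(v)
    calls_by_gene: dict[str, list[GeneScnaCall]] = {}
    for c in gene_calls:
        if del_only and c.direction != "Del":
            continue
        calls_by_gene.setdefault(c.gene, []).append(c)
    loh_by_gene: dict[str, list[LohEvent]] = {}
    for e in loh:
        loh_by_gene.setdefault(e.gene, []).append(e)

    hits = []
    for gene in sorted(vars_by_gene):
        calls = calls_by_gene.get(gene, [])
        events = loh_by_gene.get(gene, [])
        if calls or events:
            hits.append(DoubleHit(
                gene=gene,
                variants=tuple(vars_by_gene[gene]),
                scna_calls=tuple(calls),
                loh_events=tuple(events),
            ))
    return hits
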