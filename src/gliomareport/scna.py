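"""Somatic copy-number alteration engine.

Segments are retained at |log2(tumor/normal)| >= 0.25 (inclusive).  Retained
segments drive three views: gene-level calls (a gene is amplified/deleted
when enough of its span is covered by sign-consistent segments), broad
events (cytoband / chromosome-arm / whole-chromosome scopes, reported once
at the widest qualifying scope) and four burden metrics, including the
weighted genome instability index (wGII): the unweighted mean over assayed
chromosomes of the altered fraction of each chromosome.

Intervals are 1-based inclusive throughout; merging joins overlapping or
book-ended (end + 1 == start) runs, so burden metrics are invariant to how
the upstream caller fragments an altered region.
"""
from __future__ import annotations

from dataclasses import dataclass

from .model import (
    AnalysisConfig,
    ConfigurationError,
    Cytoband,
    GeneCatalog,
    GeneModel,
    ScnaSegment,
)


@dataclass(frozen=True)
class GeneScnaCall:
    gene: str
    direction: str  # "Amp" | "Del"
    log2_ratio: float  # coverage-weighted mean of supporting segments
    tier: str  # "glioma_established" | "cgc" | "none"
    covered_fraction: float

    @property
    def linear_ratio(self) -> float:
        """Tumor/normal copy ratio on the linear scale (2**log2)."""
        return 2.0 ** self.log2_ratio


@dataclass(frozen=True)
class BroadScnaEvent:
    chrom: str
    scope: str  # "band" | "arm" | "chromosome"
    name: str  # e.g. "chr4", "chr4p", "chr4p13"
    direction: str
    covered_fraction: float


@dataclass(frozen=True)
class ScnaBurden:
    total_altered_mb: float
    n_alterations: int
    avg_len_kb: float
    wgii: float


# ---------------------------------------------------------------------------
# Interval primitives (1-based inclusive)
# ---------------------------------------------------------------------------

def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Merge overlapping or book-ended 1-based inclusive intervals."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def overlap_length(intervals, start: int, end: int) -> int:
    """Total overlap of a set of intervals with [start, end]."""
    total = 0
    for s, e in intervals:
        lo, hi = max(s, start), min(e, end)
        if lo <= hi:
            total += hi - lo + 1
    return total


def _by_chrom_direction(segments) -> dict[tuple[str, str], list[ScnaSegment]]:
    groups: dict[tuple[str, str], list[ScnaSegment]] = {}
    for s in segments:
        groups.setdefault((s.chrom, s.direction), []).append(s)
    return groups


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def threshold_segments(segments: list[ScnaSegment], cfg: AnalysisConfig) -> list[ScnaSegment]:
    """Keep high-confidence segments: |log2 ratio| >= threshold (inclusive)."""
    return [s for s in segments if abs(s.log2_ratio) >= cfg.scna_min_abs_log2]


def call_gene_scnas(
    retained: list[ScnaSegment],
    gene_models: list[GeneModel],
    catalogs: dict[str, GeneCatalog],
    cfg: AnalysisConfig,
) -> list[GeneScnaCall]:
    """Call gene-level SCNAs from retained segments and tier them.

    A gene is called when segments of one direction cover at least
    ``gene_min_overlap_fraction`` of its span; the supporting log2 ratio is
    the coverage-weighted mean over those segments.  If both directions
    reach the fraction (possible only with overlapping caller output) the
    better-covered one wins; an exact tie yields no call.  Tier:
    glioma_established when (gene, direction) is a curated glioma SCNA,
    else cgc when the gene is in the Cancer Gene Census, else none.
    """
    for kind in ("glioma_scnas", "cgc"):
        if kind not in catalogs:
            raise ConfigurationError(f"missing required catalog {kind!r}")
    seen: set[str] = set()
    for m in gene_models:
        if m.gene in seen:
            raise ConfigurationError(f"duplicate gene model for {m.gene!r}")
        seen.add(m.gene)

    groups = _by_chrom_direction(retained)
    glioma_dirs = catalogs["glioma_scnas"].scna_directions
    calls = []
    for m in gene_models:
        best = None  # (covered_len, direction, segments)
        for direction in ("Amp", "Del"):
            segs = groups.get((m.chrom, direction), [])
            merged = merge_intervals((s.start, s.end) for s in segs)
            cov = overlap_length(merged, m.start, m.end)
            if cov / m.length >= cfg.gene_min_overlap_fraction:
                if best is None or cov > best[0]:
                    best = (cov, direction, segs)
                elif cov == best[0]:
                    best = None  # ambiguous direction: no call
                    break
        if best is None:
            continue
        cov, direction, segs = best
        weight = 0
        weighted_log2 = 0.0
        for s in segs:
            w = overlap_length([(s.start, s.end)], m.start, m.end)
            weight += w
            weighted_log2 += w * s.log2_ratio
        log2 = weighted_log2 / weight
        if (m.gene, direction) in glioma_dirs:
            tier = "glioma_established"
        elif m.gene in catalogs["cgc"]:
            tier = "cgc"
        else:
            tier = "none"
        calls.append(GeneScnaCall(
            gene=m.gene, direction=direction, log2_ratio=log2, tier=tier,
            covered_fraction=cov / m.length,
        ))
    calls.sort(key=lambda c: c.gene)
    return calls


def call_broad_events(
    retained: list[ScnaSegment],
    cytobands: list[Cytoband],
    cfg: AnalysisConfig,
) -> list[BroadScnaEvent]:
    """Call cytoband/arm/chromosome-level events, rolled up to widest scope.

    A scope qualifies when segments of one direction cover at least
    ``broad_min_covered_fraction`` of its assayed (cytoband-covered) length;
    coverage is always measured within band boundaries, so band, arm and
    chromosome scopes aggregate the same quantity.  A band or arm event is
    suppressed when a same-direction event at a wider scope is reported.
    Arms shorter than ``min_arm_assayed_len`` are never called at arm scope.
    """
    bands_by_chrom: dict[str, list[Cytoband]] = {}
    for b in cytobands:
        bands_by_chrom.setdefault(b.chrom, []).append(b)
    for s in retained:
        if s.chrom not in bands_by_chrom:
            raise ConfigurationError(f"segment chromosome {s.chrom!r} absent from cytoband map")

    groups = _by_chrom_direction(retained)
    events: list[BroadScnaEvent] = []
    for chrom in sorted(bands_by_chrom, key=lambda c: (len(c), c)):
        bands = sorted(bands_by_chrom[chrom], key=lambda b: b.start)
        merged = {
            d: merge_intervals((s.start, s.end) for s in groups.get((chrom, d), []))
            for d in ("Amp", "Del")
        }
        # per-band covered length by direction
        cov = {
            d: {b.band: overlap_length(merged[d], b.start, b.end) for b in bands}
            for d in ("Amp", "Del")
        }
        band_len = {b.band: b.length for b in bands}
        chrom_len = sum(band_len.values())

        def _qualify(band_subset, min_len=0):
            """Winning direction and coverage fraction over a set of bands."""
            total = sum(band_len[b] for b in band_subset)
            if total == 0 or total < min_len:
                return None
            fracs = {
                d: sum(cov[d][b] for b in band_subset) / total for d in ("Amp", "Del")
            }
            qualifying = [d for d in ("Amp", "Del")
                          if fracs[d] >= cfg.broad_min_covered_fraction]
            if not qualifying:
                return None
            if len(qualifying) == 2:
                if fracs["Amp"] == fracs["Del"]:
                    return None
                qualifying = [max(qualifying, key=lambda d: fracs[d])]
            d = qualifying[0]
            return d, fracs[d]

        chrom_event = _qualify([b.band for b in bands])
        if chrom_event is not None:
            d, frac = chrom_event
            events.append(BroadScnaEvent(
                chrom=chrom, scope="chromosome", name=chrom, direction=d,
                covered_fraction=frac,
            ))
        arm_dirs: dict[str, str] = {}
        for arm in ("p", "q"):
            arm_bands = [b.band for b in bands if b.arm == arm]
            if not arm_bands:
                continue
            hit = _qualify(arm_bands, min_len=cfg.min_arm_assayed_len)
            if hit is None:
                continue
            d, frac = hit
            if chrom_event is not None and chrom_event[0] == d:
                continue  # rolled up into the chromosome event
            arm_dirs[arm] = d
            events.append(BroadScnaEvent(
                chrom=chrom, scope="arm", name=f"{chrom}{arm}", direction=d,
                covered_fraction=frac,
            ))
        for b in bands:
            hit = _qualify([b.band])
            if hit is None:
                continue
            d, frac = hit
            if chrom_event is not None and chrom_event[0] == d:
                continue
            if arm_dirs.get(b.arm) == d:
                continue  # rolled up into the arm event
            events.append(BroadScnaEvent(
                chrom=chrom, scope="band", name=f"{chrom}{b.band}", direction=d,
                covered_fraction=frac,
            ))
    return events


def compute_scna_burden(
    retained: list[ScnaSegment],
    genome_model: dict[str, int],
) -> ScnaBurden:
    """Compute the four burden metrics from retained segments.

    Segments are merged per direction first, so the metrics do not depend on
    caller granularity; the altered length of a chromosome is the union over
    both directions.  ``genome_model`` maps chromosome name to its assayed
    length in bp; wGII averages the per-chromosome altered fraction over ALL
    chromosomes of the model, including unaltered ones.
    """
    if not genome_model:
        raise ConfigurationError("genome model is empty")
    for s in retained:
        if s.chrom not in genome_model:
            raise ConfigurationError(f"segment chromosome {s.chrom!r} absent from genome model")

    groups = _by_chrom_direction(retained)
    n_alterations = 0
    altered_by_chrom: dict[str, int] = {c: 0 for c in genome_model}
    for chrom in genome_model:
        runs: list[tuple[int, int]] = []
        for d in ("Amp", "Del"):
            merged = merge_intervals(
                (s.start, s.end) for s in groups.get((chrom, d), [])
            )
            n_alterations += len(merged)
            runs.extend(merged)
        union = merge_intervals(runs)
        altered_by_chrom[chrom] = sum(e - s + 1 for s, e in union)

    total_altered = sum(altered_by_chrom.values())
    total_altered_mb = total_altered / 1e6
    avg_len_kb = (total_altered_mb * 1000.0) / n_alterations if n_alterations else 0.0
    wgii = sum(
        min(altered_by_chrom[c], genome_model[c]) / genome_model[c] for c in genome_model
    ) / len(genome_model)
    return ScnaBurden(
        total_altered_mb=total_altered_mb,
        n_alterations=n_alterations,
        avg_len_kb=avg_len_kb,
        wgii=wgii,
    )
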