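"""SCNA engine: thresholding, gene calls, broad events, burden metrics.

Brute-force oracles use per-base boolean coverage arrays on a miniature
coordinate space, independent of the interval-merging implementation.
"""
import numpy as np
import pytest

from gliomareport.model import AnalysisConfig, ConfigurationError, Cytoband, GeneModel, ScnaSegment
from gliomareport.scna import (
    ScnaBurden,
    call_broad_events,
    call_gene_scnas,
    compute_scna_burden,
    merge_intervals,
    threshold_segments,
)

CFG = AnalysisConfig()
CHROM_LEN = 100_000  # miniature space so boolean-array oracles stay cheap


def seg(start, end, log2, chrom="chr1"):
    return ScnaSegment(chrom=chrom, start=start, end=end, log2_ratio=log2)


def random_segments(rng, n, chroms=("chr1", "chr2")):
    out = []
    for _ in range(n):
        start = int(rng.integers(1, CHROM_LEN - 5000))
        out.append(seg(start, start + min(int(rng.integers(100, 20_000)), CHROM_LEN - start),
                       round(float(rng.uniform(-1.5, 1.5)), 3),
                       chrom=str(rng.choice(chroms))))
    return out


def coverage_mask(segments, chrom, direction):
    """Boolean per-base coverage: the independent oracle primitive."""
    mask = np.zeros(CHROM_LEN + 2, dtype=bool)
    for s in segments:
        if s.chrom == chrom and (s.log2_ratio >= 0) == (direction == "Amp"):
            mask[s.start: min(s.end, CHROM_LEN) + 1] = True
    return mask


def test_threshold_boundary_inclusive():
    segments = [seg(1, 10, 0.25), seg(20, 30, -0.24), seg(40, 50, -0.25), seg(60, 70, 0.1)]
    kept = threshold_segments(segments, CFG)
    assert kept == [segments[0], segments[2]]


def test_threshold_matches_predicate_oracle():
    rng = np.random.default_rng(73)
    segments = random_segments(rng, 300)
    kept = threshold_segments(segments, CFG)
    assert kept == [s for s in segments if abs(s.log2_ratio) >= 0.25]


def test_merge_intervals_handles_adjacency():
    assert merge_intervals([(1, 5), (6, 10), (20, 30), (25, 40)]) == [(1, 10), (20, 40)]
    assert merge_intervals([]) == []


def _models(*spans):
    return [GeneModel(gene=f"G{i}", chrom="chr1", start=s, end=e)
            for i, (s, e) in enumerate(spans)]


def test_gene_call_full_cover_and_tier(catalogs):
    model = GeneModel(gene="EGFR", chrom="chr1", start=1000, end=2000)
    calls = call_gene_scnas([seg(500, 2500, 1.2)], [model], catalogs, CFG)
    assert len(calls) == 1
    c = calls[0]
    assert (c.gene, c.direction, c.tier) == ("EGFR", "Amp", "glioma_established")
    assert c.log2_ratio == 1.2 and c.covered_fraction == 1.0


def test_gene_call_mixed_directions_yield_no_call(catalogs):
    model = GeneModel(gene="EGFR", chrom="chr1", start=1001, end=2000)
    half_amp = seg(1001, 1500, 0.8)
    half_del = seg(1501, 2000, -0.8)
    assert call_gene_scnas([half_amp, half_del], [model], catalogs, CFG) == []


def test_gene_call_weighted_mean_log2(catalogs):
    model = GeneModel(gene="EGFR", chrom="chr1", start=1, end=1000)
    calls = call_gene_scnas([seg(1, 600, 1.0), seg(601, 1000, 0.5)], [model],
                            catalogs, CFG)
    assert calls[0].log2_ratio == pytest.approx(0.6 * 1.0 + 0.4 * 0.5)


def test_gene_call_duplicate_model_rejected(catalogs):
    models = [GeneModel(gene="EGFR", chrom="chr1", start=1, end=10),
              GeneModel(gene="EGFR", chrom="chr2", start=1, end=10)]
    with pytest.raises(ConfigurationError, match="duplicate"):
        call_gene_scnas([], models, catalogs, CFG)


def test_gene_calls_match_coverage_oracle(catalogs):
    rng = np.random.default_rng(79)
    models = [GeneModel(gene=f"G{i:02d}", chrom=str(rng.choice(["chr1", "chr2"])),
                        start=(p := int(rng.integers(1, CHROM_LEN - 3000))),
                        end=p + int(rng.integers(500, 3000)))
              for i in range(50)]
    retained = threshold_segments(random_segments(rng, 60), CFG)
    calls = {c.gene: c.direction
             for c in call_gene_scnas(retained, models, catalogs, CFG)}
    for m in models:
        expected = None
        best_cov = -1
        for d in ("Amp", "Del"):
            cov = int(coverage_mask(retained, m.chrom, d)[m.start: m.end + 1].sum())
            if cov / m.length >= 0.5:
                if cov > best_cov:
                    expected, best_cov = d, cov
                elif cov == best_cov:
                    expected = None
        assert calls.get(m.gene) == expected


BANDS = [Cytoband(chrom="chr1", start=i * 12_500 + 1, end=(i + 1) * 12_500,
                  band=name, arm=name[0])
         for i, name in enumerate(["p14", "p13", "p12", "p11", "q11", "q12", "q13", "q14"])]


def test_broad_arm_rollup():
    """A deletion spanning most of the p arm reports once, at arm scope,
    with no per-band duplicates."""
    events = call_broad_events([seg(1, 37_500, -0.8)], BANDS, CFG)  # 3 of 4 p bands
    assert [(e.name, e.scope, e.direction) for e in events] == [("chr1p", "arm", "Del")]
    # on this symmetric miniature chromosome a fully covered arm is exactly
    # half the chromosome, so the inclusive threshold rolls it all the way up
    events = call_broad_events([seg(1, 50_000, -0.8)], BANDS, CFG)
    assert [(e.name, e.scope) for e in events] == [("chr1", "chromosome")]


def test_broad_whole_chromosome_rollup():
    events = call_broad_events([seg(1, 100_000, 0.8)], BANDS, CFG)
    assert [(e.name, e.scope, e.direction) for e in events] == [("chr1", "chromosome", "Amp")]


def test_broad_insufficient_coverage_no_event():
    # 40% of one band at the default 0.5 threshold
    assert call_broad_events([seg(1, 5_000, 0.8)], BANDS, CFG) == []


def test_broad_unknown_chromosome_errors():
    with pytest.raises(ConfigurationError, match="chrX"):
        call_broad_events([seg(1, 10, 0.5, chrom="chrX")], BANDS, CFG)


def test_broad_events_match_band_coverage_oracle():
    rng = np.random.default_rng(83)
    for _ in range(40):
        retained = threshold_segments(random_segments(rng, 8, chroms=("chr1",)), CFG)
        events = {(e.name, e.scope): e.direction
                  for e in call_broad_events(retained, BANDS, CFG)}
        # oracle: per-band covered fractions from boolean masks
        frac = {}
        for d in ("Amp", "Del"):
            mask = coverage_mask(retained, "chr1", d)
            for b in BANDS:
                frac[(b.band, d)] = mask[b.start: b.end + 1].sum() / b.length

        def winner(bands):
            scores = {d: sum(frac[(b.band, d)] * b.length for b in bands)
                      / sum(b.length for b in bands) for d in ("Amp", "Del")}
            qual = [d for d in scores if scores[d] >= 0.5]
            if len(qual) == 2:
                if scores["Amp"] == scores["Del"]:
                    return None
                qual = [max(qual, key=scores.get)]
            return qual[0] if qual else None

        chrom_dir = winner(BANDS)
        expected = {}
        if chrom_dir:
            expected[("chr1", "chromosome")] = chrom_dir
        arm_dir = {}
        for arm in ("p", "q"):
            arm_bands = [b for b in BANDS if b.arm == arm]
            d = winner(arm_bands)
            if d and d != chrom_dir:
                expected[(f"chr1{arm}", "arm")] = d
                arm_dir[arm] = d
        for b in BANDS:
            d = winner([b])
            if d and d != chrom_dir and arm_dir.get(b.arm) != d:
                expected[(f"chr1{b.band}", "band")] = d
        assert events == expected


def test_burden_closed_form_wgii():
    """One 1 Mb altered segment on a 10 Mb chromosome among 24 chromosomes."""
    genome = {f"chr{i}": 10_000_000 for i in range(1, 25)}
    burden = compute_scna_burden(
        [ScnaSegment(chrom="chr1", start=1, end=1_000_000, log2_ratio=0.5)], genome)
    assert burden.wgii == pytest.approx(0.1 / 24)
    assert burden.total_altered_mb == 1.0
    assert burden.n_alterations == 1
    assert burden.avg_len_kb == 1000.0


def test_burden_empty_is_zero():
    burden = compute_scna_burden([], {"chr1": 1000})
    assert burden == ScnaBurden(0.0, 0, 0.0, 0.0)


def test_burden_full_alteration_gives_wgii_one():
    genome = {"chr1": 1000, "chr2": 2000}
    segs = [seg(1, 1000, 0.5, "chr1"), seg(1, 2000, -0.5, "chr2")]
    assert compute_scna_burden(segs, genome).wgii == 1.0


def test_burden_invariant_under_split_and_order():
    """Splitting a segment into adjacent same-sign pieces changes nothing."""
    genome = {"chr1": CHROM_LEN}
    whole = [seg(101, 10_100, 0.7)]
    split = [seg(5001, 10_100, 0.7), seg(101, 5000, 0.7)]
    assert compute_scna_burden(whole, genome) == compute_scna_burden(split, genome)


def test_burden_matches_bruteforce_oracle():
    rng = np.random.default_rng(89)
    genome = {"chr1": CHROM_LEN, "chr2": CHROM_LEN, "chr3": CHROM_LEN}
    for _ in range(30):
        retained = threshold_segments(
            random_segments(rng, 12, chroms=tuple(genome)), CFG)
        burden = compute_scna_burden(retained, genome)
        total = 0
        n_runs = 0
        wgii_terms = []
        for chrom in genome:
            union = np.zeros(CHROM_LEN + 2, dtype=bool)
            for d in ("Amp", "Del"):
                mask = coverage_mask(retained, chrom, d)
                union |= mask
                # count maximal runs
                n_runs += int(np.sum(np.diff(mask.astype(int)) == 1))
            altered = int(union.sum())
            total += altered
            wgii_terms.append(altered / genome[chrom])
        assert burden.n_alterations == n_runs
        assert burden.total_altered_mb == pytest.approx(total / 1e6)
        assert burden.wgii == pytest.approx(np.mean(wgii_terms))
        if n_runs:
            assert burden.avg_len_kb == pytest.approx(burden.total_altered_mb * 1000 / n_runs)


def test_burden_unknown_chromosome_errors():
    with pytest.raises(ConfigurationError, match="chr9"):
        compute_scna_burden([seg(1, 10, 0.5, "chr9")], {"chr1": 100})
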