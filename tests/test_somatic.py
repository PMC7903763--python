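"""Somatic cascade: strict VAF boundary, five sequential tiers, VAF summaries."""
import statistics

import numpy as np
import pytest

from gliomareport.model import (
    AnalysisConfig,
    ContractViolation,
    NONSYNONYMOUS_CLASSIFICATIONS,
)
from gliomareport.somatic import assign_somatic_tiers, filter_somatic, tier_vaf_summary
from tests.conftest import make_variant


def s(**kw):
    return make_variant(origin="somatic", **kw)


def test_vaf_boundary_is_strict(catalogs, cfg):
    at = s(tumor_vaf=0.05)
    above = s(tumor_vaf=0.051)
    passing, excluded = filter_somatic([at, above], catalogs["flags"], cfg)
    assert passing == [above]
    assert excluded[0].exclusion_reason == "vaf_too_low"


def test_filter_rejects_germline_origin(catalogs, cfg):
    with pytest.raises(ContractViolation):
        filter_somatic([make_variant(origin="germline")], catalogs["flags"], cfg)


def test_filter_matches_bruteforce_predicate(catalogs, cfg):
    rng = np.random.default_rng(41)
    classes = sorted(NONSYNONYMOUS_CLASSIFICATIONS) + ["Silent", "Intron", "3'UTR"]
    variants = []
    for _ in range(1000):
        depth = int(rng.integers(10, 120))
        t_alt = int(rng.integers(0, depth + 1))
        gene = str(rng.choice(["TP53", "TTN", "GENE006", "EGFR", "MUC16"]))
        variants.append(s(gene=gene, tumor_vaf=t_alt / depth, tumor_depth=depth,
                          classification=str(rng.choice(classes))))
    passing, excluded = filter_somatic(variants, catalogs["flags"], cfg)
    expected = [v for v in variants
                if (v.tumor_vaf or 0) > 0.05
                and v.classification in NONSYNONYMOUS_CLASSIFICATIONS
                and v.gene not in catalogs["flags"].genes]
    assert passing == expected
    assert len(passing) + len(excluded) == len(variants)


def test_vaf_threshold_monotonicity(catalogs):
    rng = np.random.default_rng(43)
    variants = [s(tumor_vaf=round(float(rng.uniform(0, 0.3)), 4), gene="GENE006")
                for _ in range(200)]
    sizes = [len(filter_somatic(variants, catalogs["flags"],
                                AnalysisConfig(somatic_min_vaf=t))[0])
             for t in (0.01, 0.05, 0.1, 0.2)]
    assert sizes == sorted(sizes, reverse=True)


def test_tier_first_match(catalogs, cfg):
    variants = [
        s(gene="TP53"),                                     # glioma beats cgc
        s(gene="BRAF", protein_change="p.V600E"),           # cgc + recurrent hotspot
        s(gene="BRAF", protein_change="p.D594G"),           # cgc, not a hotspot
        s(gene="BRAF"),                                     # no protein change -> cgc_other
        s(gene="POLK"),                                     # ddr only
        s(gene="MTOR"),                                     # kegg only
        s(gene="GENE006"),                                  # no catalog
    ]
    assignments = assign_somatic_tiers(variants, catalogs, catalogs["hotspots"], cfg)
    assert [a.tier for a in assignments] == [
        "glioma_established", "cgc_hotspot", "cgc_other", "cgc_other",
        "ddr", "kegg_selected", None]


def test_hotspot_requires_min_recurrence(catalogs):
    v = s(gene="BRAF", protein_change="p.V600E")
    strict = AnalysisConfig(hotspot_min_count=13)  # V600E fixture count is 12
    a = assign_somatic_tiers([v], catalogs, catalogs["hotspots"], strict)
    assert a[0].tier == "cgc_other"


def test_tiers_match_bruteforce_first_match(catalogs, cfg):
    rng = np.random.default_rng(47)
    pool = sorted(set().union(catalogs["glioma_genes"].genes, catalogs["cgc"].genes,
                              catalogs["ddr"].genes, catalogs["kegg_selected"].genes) |
                  {f"GENE{i:03d}" for i in range(6, 30)})
    variants = [s(gene=pool[int(rng.integers(0, len(pool)))],
                  protein_change=str(rng.choice(["p.V600E", "p.G12D", "p.A100T", ""]))
                  or None)
                for _ in range(500)]
    assignments = assign_somatic_tiers(variants, catalogs, catalogs["hotspots"], cfg)
    for a in assignments:
        v = a.variant
        if v.gene in catalogs["glioma_genes"]:
            expected = "glioma_established"
        elif v.gene in catalogs["cgc"]:
            hot = catalogs["hotspots"].hotspot_count(v.gene, v.protein_change) >= 2
            expected = "cgc_hotspot" if hot else "cgc_other"
        elif v.gene in catalogs["ddr"]:
            expected = "ddr"
        elif v.gene in catalogs["kegg_selected"]:
            expected = "kegg_selected"
        else:
            expected = None
        assert a.tier == expected


def test_vaf_summary_medians(catalogs, cfg):
    variants = [s(gene="TP53", tumor_vaf=v) for v in (0.2, 0.38, 0.5)]
    assignments = assign_somatic_tiers(variants, catalogs, catalogs["hotspots"], cfg)
    summary = tier_vaf_summary(assignments)
    assert summary["glioma_established"]["median"] == 0.38
    assert "ddr" not in summary  # empty tiers omitted

    rng = np.random.default_rng(53)
    variants = [s(gene=str(rng.choice(["TP53", "EZH2", "POLK", "MTOR"])),
                  tumor_vaf=round(float(rng.uniform(0.06, 0.9)), 3))
                for _ in range(300)]
    assignments = assign_somatic_tiers(variants, catalogs, catalogs["hotspots"], cfg)
    summary = tier_vaf_summary(assignments)
    for tier, stats in summary.items():
        vafs = sorted(a.variant.tumor_vaf for a in assignments if a.tier == tier)
        assert stats["median"] == statistics.median(vafs)
        assert stats["n"] == len(vafs)
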