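"""Germline cascade: filter semantics, sequential tiers, common variants."""
import numpy as np
import pytest

from gliomareport.germline import (
    assign_germline_tiers,
    filter_germline,
    match_common_variants,
)
from gliomareport.model import (
    CLINVAR_SEVERITY_ORDER,
    AnalysisConfig,
    ConfigurationError,
    ContractViolation,
    GeneCatalog,
    rank_clinvar,
)
from tests.conftest import make_variant


def g(**kw):
    return make_variant(origin="germline", **kw)


def test_filter_first_failing_reason(catalogs, cfg):
    variants = [
        g(pop_af={"exac": 0.02}),                                # maf_too_high
        g(pop_af={"exac": 0.02}, clinvar="benign"),              # maf first
        g(clinvar="likely_benign"),                              # benign_clinvar
        g(classification="Silent"),                              # synonymous
        g(gene="TTN"),                                           # flags_gene
        g(gene="GENE006"),                                       # passes
    ]
    passing, excluded = filter_germline(variants, catalogs["flags"], cfg)
    assert [a.exclusion_reason for a in excluded] == [
        "maf_too_high", "maf_too_high", "benign_clinvar", "synonymous", "flags_gene"]
    assert passing == [variants[5]]
    assert len(passing) + len(excluded) == len(variants)


def test_clinvar_rescue_exempts_maf_cut(catalogs, cfg):
    """A drug-response allele carried by most of the population still reports."""
    v = g(gene="TP53", rsid="rs1042522", clinvar="drug_response",
          pop_af={"thousand_genomes": 0.54, "exac": 0.42})
    passing, excluded = filter_germline([v], catalogs["flags"], cfg)
    assert passing == [v]

    cfg_off = AnalysisConfig(coding_mb=30.0, clinvar_rescue=False)
    passing, excluded = filter_germline([v], catalogs["flags"], cfg_off)
    assert excluded[0].exclusion_reason == "maf_too_high"


def test_filter_rejects_somatic_origin(catalogs, cfg):
    with pytest.raises(ContractViolation):
        filter_germline([make_variant(origin="somatic")], catalogs["flags"], cfg)


def test_effective_maf_is_max_over_sources(catalogs, cfg):
    v = g(pop_af={"thousand_genomes": 0.002, "esp6500": 0.015})
    _, excluded = filter_germline([v], catalogs["flags"], cfg)
    assert excluded[0].exclusion_reason == "maf_too_high"
    assert g(pop_af={}).effective_maf == 0.0


def test_tiers_are_sequential_first_match(catalogs):
    # TP53 sits in acmg, cgc, predisposition and ddr-adjacent catalogs:
    # only the first tier claims it
    variants = [g(gene="TP53"), g(gene="EZH2"), g(gene="PALB2"), g(gene="POLK"),
                g(gene="GENE006")]
    assignments = assign_germline_tiers(variants, catalogs)
    assert [a.tier for a in assignments] == [
        "acmg_incidental", "cgc", "predisposition", "ddr", None]
    assert assignments[-1].exclusion_reason == "no_tier"


def test_missing_catalog_is_configuration_error(catalogs):
    partial = {k: v for k, v in catalogs.items() if k != "ddr"}
    with pytest.raises(ConfigurationError, match="ddr"):
        assign_germline_tiers([g(gene="TP53")], partial)


def test_tier_disjointness_against_bruteforce(catalogs):
    """No variant lands in two tiers; first-match agrees with independent
    evaluation of all catalog memberships."""
    rng = np.random.default_rng(17)
    pool = sorted(set().union(*(catalogs[k].genes for k in
                                ("acmg", "cgc", "predisposition", "ddr"))) |
                  {f"GENE{i:03d}" for i in range(6, 30)})
    variants = [g(gene=pool[int(rng.integers(0, len(pool)))]) for _ in range(300)]
    assignments = assign_germline_tiers(variants, catalogs)
    order = (("acmg_incidental", "acmg"), ("cgc", "cgc"),
             ("predisposition", "predisposition"), ("ddr", "ddr"))
    for a in assignments:
        memberships = [t for t, k in order if a.variant.gene in catalogs[k]]
        assert a.tier == (memberships[0] if memberships else None)


def test_common_variants_exempt_from_filter(catalogs):
    """GWAS SNPs are matched on the unfiltered set: a 40% MAF variant matches."""
    rng = np.random.default_rng(23)
    gwas = catalogs["gwas_snps"]
    planted = [g(gene=gene, rsid=rsid, pop_af={"exac": 0.4})
               for rsid, gene in gwas.entries]
    noise = [g(gene=f"GENE{int(rng.integers(6, 39)):03d}",
               rsid=(f"rs9{i}" if i % 3 else None)) for i in range(495)]
    matches = match_common_variants(noise + planted, gwas)
    assert sorted(m[0].rsid for m in matches) == sorted(r for r, _ in gwas.entries)
    assert all(m[0].rsid is not None for m in matches)


def test_maf_threshold_monotonicity(catalogs):
    rng = np.random.default_rng(31)
    variants = [g(pop_af={"exac": round(float(rng.uniform(0, 0.03)), 5)},
                  gene="GENE006") for _ in range(200)]
    sizes = []
    for maf in (0.02, 0.01, 0.005, 0.001):
        c = AnalysisConfig(germline_max_maf=maf)
        passing, _ = filter_germline(variants, catalogs["flags"], c)
        sizes.append(len(passing))
    assert sizes == sorted(sizes, reverse=True)


@pytest.mark.parametrize("tokens,expected", [
    (["vus", "drug_response"], "drug_response"),
    (["not_reported"], "not_reported"),
    (["conflicting", "pathogenic", "vus"], "pathogenic"),
    (["likely_pathogenic", "drug_response"], "likely_pathogenic"),
])
def test_rank_clinvar(tokens, expected):
    assert rank_clinvar(tokens) == expected


def test_rank_clinvar_total_order_properties():
    for t in CLINVAR_SEVERITY_ORDER:
        assert rank_clinvar([t]) == t
    with pytest.raises(ContractViolation):
        rank_clinvar([])
    with pytest.raises(ContractViolation):
        rank_clinvar(["bogus"])
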