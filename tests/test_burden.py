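"""TMB computation, POLE-deficiency prediction and cohort context."""
import statistics

import numpy as np
import pytest

from gliomareport.burden import (
    PoleCall,
    TmbResult,
    compute_tmb,
    predict_pole,
    tmb_context,
    tmb_qualifies,
)
from gliomareport.model import AnalysisConfig, ConfigurationError
from gliomareport.synthetic import generate_cohort
from tests.conftest import make_variant


def s(**kw):
    return make_variant(origin="somatic", **kw)


def qualifying(n):
    return [s(tumor_vaf=0.3, tumor_depth=100, normal_depth=40) for _ in range(n)]


def test_tmb_arithmetic():
    cfg = AnalysisConfig(coding_mb=32.0)
    result = compute_tmb(qualifying(64), cfg)
    assert result == TmbResult(n_qualifying=64, denominator_mb=32.0, tmb=2.0)


def test_tmb_depth_boundaries_are_strict(cfg):
    at_tumor = s(tumor_vaf=0.5, tumor_depth=20, normal_depth=40)
    at_normal = s(tumor_vaf=0.5, tumor_depth=100, normal_depth=10)
    at_vaf = s(tumor_vaf=0.05, tumor_depth=100, normal_depth=40)
    ok = s(tumor_vaf=0.06, tumor_depth=21, normal_depth=11)
    assert compute_tmb([at_tumor, at_normal, at_vaf, ok], cfg).n_qualifying == 1


def test_tmb_requires_coding_mb():
    with pytest.raises(ConfigurationError, match="coding_mb"):
        compute_tmb(qualifying(1), AnalysisConfig())


def test_tmb_matches_bruteforce_predicate(cfg):
    rng = np.random.default_rng(61)
    classes = ["Missense_Mutation", "Silent", "Intron", "Frame_Shift_Del", "3'UTR",
               "Nonsense_Mutation"]
    variants = []
    for _ in range(2000):
        depth = int(rng.integers(5, 120))
        t_alt = int(rng.integers(0, depth + 1))
        variants.append(s(classification=str(rng.choice(classes)),
                          tumor_vaf=t_alt / depth, tumor_depth=depth,
                          normal_depth=int(rng.integers(5, 60))))
    coding = {"Frame_Shift_Del", "Frame_Shift_Ins", "Splice_Site",
              "Translation_Start_Site", "Nonsense_Mutation", "Nonstop_Mutation",
              "In_Frame_Del", "In_Frame_Ins", "Missense_Mutation", "Silent"}
    expected = sum(
        1 for v in variants
        if v.classification in coding and v.tumor_vaf > 0.05
        and v.tumor_depth > 20 and v.normal_depth > 10)
    assert compute_tmb(variants, cfg).n_qualifying == expected


def test_tmb_scale_consistency():
    variants = qualifying(30)
    t1 = compute_tmb(variants, AnalysisConfig(coding_mb=10.0))
    t2 = compute_tmb(variants, AnalysisConfig(coding_mb=20.0))
    assert t2.tmb == t1.tmb / 2


def test_tmb_silent_inclusion_is_configurable():
    v = s(classification="Silent", tumor_vaf=0.3, tumor_depth=100, normal_depth=40)
    assert compute_tmb([v], AnalysisConfig(coding_mb=1.0)).n_qualifying == 1
    off = AnalysisConfig(coding_mb=1.0, tmb_include_silent=False)
    assert compute_tmb([v], off).n_qualifying == 0


def test_tmb_qualifying_variants_pass_somatic_vaf_bound(cfg):
    """Cross-module consistency: the TMB VAF cut equals the reporting cut."""
    rng = np.random.default_rng(67)
    for _ in range(200):
        depth = int(rng.integers(5, 120))
        v = s(tumor_vaf=int(rng.integers(0, depth + 1)) / depth, tumor_depth=depth)
        if tmb_qualifies(v, cfg):
            assert v.tumor_vaf > cfg.somatic_min_vaf


def _pole_fixture(n_snv, n_ssr_indel, coding_mb):
    variants = [s(tumor_vaf=0.3) for _ in range(n_snv)]
    variants += [s(classification="Frame_Shift_Del", ref="AC", alt="-",
                   tumor_vaf=0.3, in_ssr=True) for _ in range(n_ssr_indel)]
    return variants, AnalysisConfig(coding_mb=coding_mb)


@pytest.mark.parametrize("n_snv,n_ssr,expected", [
    (70, 0, "deficient"),        # snv high, ssr low
    (70, 1, "not_deficient"),    # snv high, ssr high (1/Mb > 0.18)
    (30, 0, "not_deficient"),    # snv low, ssr low
    (30, 1, "not_deficient"),    # snv low, ssr high
])
def test_pole_truth_table(n_snv, n_ssr, expected):
    variants, cfg = _pole_fixture(n_snv, n_ssr, coding_mb=1.0)
    call = predict_pole(variants, cfg)
    assert call.status == expected
    assert call.snv_per_mb == n_snv and call.ssr_indel_per_mb == n_ssr


def test_pole_snv_boundary_is_strict():
    variants, cfg = _pole_fixture(60, 0, coding_mb=1.0)
    assert predict_pole(variants, cfg).status == "not_deficient"


def test_pole_not_assessable_without_ssr_provenance():
    variants, cfg = _pole_fixture(70, 0, coding_mb=1.0)
    variants.append(s(classification="Frame_Shift_Ins", ref="-", alt="TT",
                      tumor_vaf=0.3, in_ssr=None))
    call = predict_pole(variants, cfg)
    assert call.status == "not_assessable" and call.ssr_indel_per_mb is None
    # but a sample with zero qualifying indels stays assessable
    snv_only, _ = _pole_fixture(70, 0, coding_mb=1.0)
    assert predict_pole(snv_only, cfg).status == "deficient"


def test_tmb_context_medians_match_sort_oracle():
    history = generate_cohort(50, seed=71)
    assert len({r.subset for r in history}) == 3
    current = TmbResult(n_qualifying=100, denominator_mb=20.0, tmb=5.0)
    ctx = tmb_context(history, current, subset="IDH-mutant")
    assert ctx["overall_median"] == statistics.median(r.tmb for r in history)
    for label, med in ctx["subset_medians"].items():
        assert med == statistics.median(r.tmb for r in history if r.subset == label)
    assert ctx["rank"] == 1 + sum(1 for r in history if r.tmb > 5.0)


def test_tmb_context_empty_history():
    current = TmbResult(n_qualifying=6, denominator_mb=3.0, tmb=2.0)
    ctx = tmb_context([], current, subset=None)
    assert ctx == {"current_tmb": 2.0, "current_subset": None}


def test_pole_call_deficient_property():
    assert PoleCall(snv_per_mb=80, ssr_indel_per_mb=0.0, status="deficient").deficient
    assert not PoleCall(snv_per_mb=80, ssr_indel_per_mb=None,
                        status="not_assessable").deficient
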