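"""Report assembly, enrichment export and end-to-end pipeline behavior."""
import json

import pytest

from gliomareport.model import AnalysisConfig
from gliomareport.pipeline import run_pipeline
from gliomareport.report import (
    AssemblyError,
    ReportBundle,
    assemble_report,
    select_enrichment_genes,
)
from gliomareport.scna import GeneScnaCall
from tests.conftest import make_variant


def _call(gene, log2):
    direction = "Amp" if log2 >= 0 else "Del"
    return GeneScnaCall(gene=gene, direction=direction, log2_ratio=log2,
                        tier="none", covered_fraction=1.0)


def test_enrichment_ratio_boundaries_strict(cfg):
    import math
    calls = [
        _call("DEEP_DEL", -1.1),                    # ratio ~0.466 -> in
        _call("AT_DEL", math.log2(0.5)),            # ratio exactly 0.5 -> out
        _call("AT_AMP", math.log2(1.5)),            # ratio exactly 1.5 -> out
        _call("HIGH_AMP", 1.0),                     # ratio 2.0 -> in
        _call("MILD", 0.3),                         # ratio ~1.23 -> out
    ]
    snv, scna = select_enrichment_genes([make_variant(gene="TP53")], calls, cfg)
    assert snv == ["TP53"]
    assert scna == ["DEEP_DEL", "HIGH_AMP"]


def test_enrichment_lists_deduplicated_sorted(cfg):
    variants = [make_variant(gene=g) for g in ("ZZZ", "AAA", "ZZZ")]
    snv, _ = select_enrichment_genes(variants, [], cfg)
    assert snv == ["AAA", "ZZZ"]


def test_empty_bundle_renders_with_notices():
    bundle = ReportBundle(sample_id="empty", config=AnalysisConfig())
    report, summary = assemble_report(bundle)
    assert "_No findings in this section._" in report
    assert "_Not available._" in report
    assert "empty" in summary


def test_malformed_bundle_names_section():
    bundle = ReportBundle(sample_id="x", config=AnalysisConfig())
    bundle.somatic_assignments = None
    with pytest.raises(AssemblyError, match="somatic_assignments"):
        assemble_report(bundle)


def test_render_is_deterministic():
    bundle = ReportBundle(sample_id="x", config=AnalysisConfig(),
                          metadata={"indication": "diffuse glioma"})
    assert assemble_report(bundle) == assemble_report(bundle)


def _run(case_dir, out, **kw):
    return run_pipeline(
        germline_maf=case_dir / "germline.maf", somatic_maf=case_dir / "somatic.maf",
        catalog_dir=case_dir / "catalogs", out_dir=out,
        segments=case_dir / "segments.seg", baf=case_dir / "baf_pairs.tsv",
        cytobands=case_dir / "cytoBand.txt", gene_bed=case_dir / "genes.bed",
        config=case_dir / "config.txt", **kw)


def test_end_to_end_writes_all_artifacts(default_case, tmp_path):
    case_dir, _ = default_case
    out = tmp_path / "out"
    bundle, run_log = _run(case_dir, out)
    for name in ("report.md", "summary.md", "run_log.json", "scna_burden.tsv",
                 "double_hits.tsv", "enrichment_snv_genes.txt"):
        assert (out / name).exists(), name
    assert json.loads((out / "run_log.json").read_text()) == json.loads(
        json.dumps(run_log))


def test_cascade_counts_are_conserved(default_case, tmp_path):
    """Raw -> filtered -> reported counts satisfy the funnel identities."""
    case_dir, _ = default_case
    _, log = _run(case_dir, tmp_path / "out")
    for side in ("germline", "somatic"):
        c = log[side]
        assert c["called"] == c["passing"] + sum(c["excluded"].values())
        assert c["passing"] == sum(c["tiers"].values()) + c["unreported"]
    assert log["scna"]["retained"] <= log["scna"]["segments"]


def test_every_reported_item_in_report_once(default_case, tmp_path):
    case_dir, manifest = default_case
    out = tmp_path / "out"
    bundle, _ = _run(case_dir, out)
    report = (out / "report.md").read_text()
    for c in manifest["scna"]["gene_calls"]:
        if c["tier"] != "none":
            row = f"| {c['gene']} | {c['direction']} |"
            assert report.count(row) == 1
    for gene in manifest["double_hits"]:
        assert gene in report


def test_tier_tsvs_match_report_counts(default_case, tmp_path):
    case_dir, manifest = default_case
    out = tmp_path / "out"
    _run(case_dir, out)
    for tier, n in manifest["somatic"]["tiers"].items():
        lines = (out / f"somatic_{tier}.tsv").read_text().strip().split("\n")
        assert len(lines) - 1 == n  # header + one row per variant
    for tier, n in manifest["germline"]["tiers"].items():
        name = {"acmg_incidental": "acmg_incidental"}.get(tier, tier)
        lines = (out / f"germline_{name}.tsv").read_text().strip().split("\n")
        assert len(lines) - 1 == n


def test_pipeline_runs_without_optional_inputs(default_case, tmp_path):
    case_dir, _ = default_case
    bundle, log = run_pipeline(
        germline_maf=case_dir / "germline.maf", somatic_maf=case_dir / "somatic.maf",
        catalog_dir=case_dir / "catalogs", out_dir=tmp_path / "out",
        config=case_dir / "config.txt")
    assert bundle.scna_burden is None and bundle.loh_events == []
    assert (tmp_path / "out" / "report.md").exists()


def test_require_scna_fails_on_missing_segments(default_case, tmp_path):
    case_dir, _ = default_case
    with pytest.raises(FileNotFoundError, match="segments"):
        run_pipeline(
            germline_maf=case_dir / "germline.maf",
            somatic_maf=case_dir / "somatic.maf",
            catalog_dir=case_dir / "catalogs", out_dir=tmp_path / "out",
            segments=case_dir / "missing.seg", require_scna=True)


def test_stage_errors_name_the_stage(default_case, tmp_path):
    case_dir, _ = default_case
    bad = tmp_path / "bad.maf"
    bad.write_text("Hugo_Symbol\tChromosome\nX\tchr1\n")
    with pytest.raises(RuntimeError, match="read_somatic"):
        run_pipeline(germline_maf=case_dir / "germline.maf", somatic_maf=bad,
                     catalog_dir=case_dir / "catalogs", out_dir=tmp_path / "out")


def test_cli_demo_mode(tmp_path):
    from click.testing import CliRunner

    from gliomareport.cli import main
    result = CliRunner().invoke(
        main, ["--demo", "--seed", "5", "--out-dir", str(tmp_path / "out")])
    assert result.exit_code == 0, result.output
    assert (tmp_path / "out" / "report.md").exists()
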