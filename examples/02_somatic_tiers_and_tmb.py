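"""Somatic tiering, tumor mutational burden and POLE-deficiency prediction.

Plants a hotspot variant, a glioma driver and background mutations, then
computes the five-tier assignment, TMB (qualifying mutations per megabase)
and the POLE call (> 60 SNVs/Mb with < 0.18 SSR-indels/Mb).
"""
from gliomareport import AnalysisConfig, AnnotatedVariant
from gliomareport.burden import compute_tmb, predict_pole
from gliomareport.somatic import assign_somatic_tiers, filter_somatic
from gliomareport.synthetic import build_catalogs


def v(gene, vaf, protein_change=None, classification="Missense_Mutation"):
    depth = 100
    return AnnotatedVariant(
        chrom="chr1", pos=5000, ref="C", alt="T", gene=gene,
        classification=classification, origin="somatic",
        protein_change=protein_change, tumor_vaf=vaf, tumor_depth=depth,
        normal_depth=40)


variants = [
    v("IDH1", 0.45, "p.R132H"),     # established glioma gene
    v("BRAF", 0.31, "p.V600E"),     # CGC gene at a recurrent hotspot
    v("MET", 0.28, "p.S100F"),      # CGC gene, not a hotspot
    v("MTOR", 0.22),                # selected KEGG pathway gene
    v("GENE006", 0.18),             # no catalog: passes but is unreported
    v("GENE007", 0.04),             # below the 5% VAF cut
]

catalogs = build_catalogs()
cfg = AnalysisConfig(coding_mb=0.05)  # tiny assayed footprint for the demo
passing, excluded = filter_somatic(variants, catalogs["flags"], cfg)
assignments = assign_somatic_tiers(passing, catalogs, catalogs["hotspots"], cfg)
for a in assignments:
    print(f"  {a.variant.gene:8s} VAF {a.variant.tumor_vaf:.2f} -> "
          f"{a.tier or 'passed-but-unreported'}")

tmb = compute_tmb(variants, cfg)
pole = predict_pole(variants, cfg)
print(f"TMB: {tmb.tmb:.1f} mutations/Mb "
      f"({tmb.n_qualifying} qualifying over {tmb.denominator_mb} Mb)")
print(f"POLE: {pole.status} (SNVs/Mb = {pole.snv_per_mb:.0f}, "
      f"SSR indels/Mb = {pole.ssr_indel_per_mb})")
print("The hotspot needs both CGC membership and a recurrent protein change; "
      "TMB counts coding mutations passing the VAF and depth cuts.")
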