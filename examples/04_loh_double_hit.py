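"""LOH detection from tumor/normal BAF pairs and double-hit genes.

A gene whose tumor B-allele frequency moves far from the heterozygous 0.5
(|dBAF| > 0.4) has lost an allele; combined with a somatic short variant on
the same gene this is the classical two-hit inactivation pattern.
"""
from gliomareport import AnalysisConfig, AnnotatedVariant, BafPair
from gliomareport.loh import filter_loh, find_double_hits
from gliomareport.scna import GeneScnaCall
from gliomareport.synthetic import build_catalogs

pairs = [
    BafPair(gene="NOTCH1", chrom="chr3", start=1, end=1000,
            baf_tumor=0.97, baf_normal=0.50),   # clear LOH
    BafPair(gene="GENE050", chrom="chr3", start=1, end=1000,
            baf_tumor=0.62, baf_normal=0.50),   # balanced enough: no event
]
cfg = AnalysisConfig()
catalogs = build_catalogs()
loh = filter_loh(pairs, cfg, cgc=catalogs["cgc"])
for e in loh:
    print(f"LOH: {e.gene} |dBAF| = {e.baf_delta:.2f} (CGC gene: {e.in_cgc})")

variants = [AnnotatedVariant(
    chrom="chr3", pos=100, ref="G", alt="T", gene="NOTCH1",
    classification="Nonsense_Mutation", origin="somatic",
    tumor_vaf=0.4, tumor_depth=80, normal_depth=30)]
pten_del = GeneScnaCall(gene="PTEN", direction="Del", log2_ratio=-1.2,
                        tier="glioma_established", covered_fraction=1.0)

hits = find_double_hits(variants, [pten_del], loh, cfg)
for h in hits:
    print(f"double hit: {h.gene} — {h.evidence_summary}")
print("NOTCH1 is a double hit (truncating variant + LOH); PTEN is not, "
      "because a deletion without a short variant is a single hit.")
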