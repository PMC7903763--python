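"""Readers and writers for the external file dialects.

Variant tables are tab-separated MAF dialect; segments are SEG; gene models
are 4-column BED (0-based half-open on disk, converted to 1-based inclusive
in memory); cytobands follow the UCSC cytoBand.txt layout; catalogs are
one-record-per-line TSV; configuration is a flat ``key = value`` file.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from .model import (
    POPULATION_AF_SOURCES,
    AnalysisConfig,
    AnnotatedVariant,
    BafPair,
    CLASSIFICATION_VOCABULARY,
    ConfigurationError,
    Cytoband,
    GeneCatalog,
    GeneModel,
    LoadError,
    ScnaSegment,
    normalize_clinvar,
)

#: Required columns of the variant-table dialect.
VARIANT_REQUIRED_COLUMNS = (
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "dbSNP_RS",
    "t_alt_count",
    "t_ref_count",
    "n_depth",
)

#: Optional columns: ClinVar significance, the three population-AF sources,
#: HGVS annotations and the simple-sequence-repeat flag for indels.
VARIANT_OPTIONAL_COLUMNS = (
    "ClinVar_Significance",
    "AF_1000G",
    "AF_ExAC",
    "AF_ESP6500",
    "Protein_Change",
    "Genome_Change",
    "In_SSR",
)

_AF_COLUMNS = dict(zip(("AF_1000G", "AF_ExAC", "AF_ESP6500"), POPULATION_AF_SOURCES))

SEG_COLUMNS = ("Sample", "Chromosome", "Start", "End", "Segment_Mean")
BAF_COLUMNS = ("Gene", "Chromosome", "Start", "End", "BAF_Tumor", "BAF_Normal")


def chrom_sort_key(chrom: str):
    """Natural chromosome order: chr1..chr22, chrX, chrY, then others."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if c.isdigit():
        return (0, int(c), "")
    if c in ("X", "Y", "M", "MT"):
        return (0, {"X": 23, "Y": 24, "M": 25, "MT": 25}[c], "")
    return (1, 0, c)


def _clean(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s if s not in ("", ".", "NA", "nan") else None


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

def read_variants(path, origin: str) -> list[AnnotatedVariant]:
    """Read a MAF-dialect variant table; row order is preserved.

    Raises :class:`LoadError` naming the first missing required column, or
    citing the (1-based data) row number for classification tokens outside
    the closed vocabulary.
    """
    if origin not in ("germline", "somatic"):
        raise ValueError(f"origin must be germline or somatic, got {origin!r}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in VARIANT_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise LoadError(f"{path}: missing required column {col!r}")
    variants = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        cls = r["Variant_Classification"].strip()
        if cls not in CLASSIFICATION_VOCABULARY:
            raise LoadError(
                f"{path}: row {i}: unknown Variant_Classification {cls!r}"
            )
        pop_af = {}
        for col, src in _AF_COLUMNS.items():
            v = _clean(r.get(col))
            if v is not None:
                pop_af[src] = float(v)
        t_alt = int(r["t_alt_count"]) if _clean(r["t_alt_count"]) else 0
        t_ref = int(r["t_ref_count"]) if _clean(r["t_ref_count"]) else 0
        tumor_depth = t_alt + t_ref
        vaf = t_alt / tumor_depth if tumor_depth > 0 else None
        in_ssr_raw = _clean(r.get("In_SSR"))
        in_ssr = None
        if in_ssr_raw is not None:
            in_ssr = in_ssr_raw.lower() in ("1", "true", "yes")
        try:
            variants.append(AnnotatedVariant(
                chrom=r["Chromosome"].strip(),
                pos=int(r["Start_Position"]),
                ref=r["Reference_Allele"].strip(),
                alt=r["Tumor_Seq_Allele2"].strip(),
                gene=r["Hugo_Symbol"].strip(),
                classification=cls,
                origin=origin,
                rsid=_clean(r["dbSNP_RS"]),
                pop_af=pop_af,
                clinvar=normalize_clinvar(r.get("ClinVar_Significance")),
                protein_change=_clean(r.get("Protein_Change")),
                genome_change=_clean(r.get("Genome_Change")),
                tumor_vaf=vaf,
                tumor_depth=tumor_depth,
                normal_depth=int(r["n_depth"]) if _clean(r["n_depth"]) else 0,
                in_ssr=in_ssr,
            ))
        except ValueError as exc:
            raise LoadError(f"{path}: row {i}: {exc}") from exc
    return variants


def write_variants(variants, path) -> None:
    """Write variants in the same dialect :func:`read_variants` consumes."""
    inv_af = {v: k for k, v in _AF_COLUMNS.items()}
    rows = []
    for v in variants:
        t_depth = v.tumor_depth
        t_alt = round(v.tumor_vaf * t_depth) if v.tumor_vaf is not None else 0
        row = {
            "Hugo_Symbol": v.gene,
            "Chromosome": v.chrom,
            "Start_Position": v.pos,
            "Reference_Allele": v.ref,
            "Tumor_Seq_Allele2": v.alt,
            "Variant_Classification": v.classification,
            "dbSNP_RS": v.rsid or "",
            "Protein_Change": v.protein_change or "",
            "Genome_Change": v.genome_change or "",
            "ClinVar_Significance": v.clinvar,
            "AF_1000G": "",
            "AF_ExAC": "",
            "AF_ESP6500": "",
            "t_alt_count": t_alt,
            "t_ref_count": t_depth - t_alt,
            "n_depth": v.normal_depth,
            "In_SSR": "" if v.in_ssr is None else int(v.in_ssr),
        }
        for src, af in v.pop_af.items():
            row[inv_af[src]] = repr(af)
        rows.append(row)
    cols = list(VARIANT_REQUIRED_COLUMNS[:7]) + list(VARIANT_OPTIONAL_COLUMNS[4:6]) + [
        "ClinVar_Significance", "AF_1000G", "AF_ExAC", "AF_ESP6500",
        "t_alt_count", "t_ref_count", "n_depth", "In_SSR",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Segments, BAF pairs
# ---------------------------------------------------------------------------

def read_segments(path) -> list[ScnaSegment]:
    """Read SEG-format copy-number segments, sorted by (chrom, start)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in SEG_COLUMNS:
        if col not in df.columns:
            raise LoadError(f"{path}: missing required column {col!r}")
    segments = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        start, end = int(row.Start), int(row.End)
        if start > end:
            raise LoadError(f"{path}: row {i}: segment start {start} > end {end}")
        segments.append(ScnaSegment(
            chrom=row.Chromosome.strip(), start=start, end=end,
            log2_ratio=float(row.Segment_Mean), sample=row.Sample.strip(),
        ))
    segments.sort(key=lambda s: (chrom_sort_key(s.chrom), s.start, s.end))
    return segments


def write_segments(segments, path) -> None:
    rows = [{
        "Sample": s.sample, "Chromosome": s.chrom, "Start": s.start,
        "End": s.end, "Segment_Mean": repr(s.log2_ratio),
    } for s in segments]
    pd.DataFrame(rows, columns=list(SEG_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_baf_pairs(path) -> list[BafPair]:
    """Read per-gene tumor/normal B-allele-frequency pairs."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in BAF_COLUMNS:
        if col not in df.columns:
            raise LoadError(f"{path}: missing required column {col!r}")
    pairs = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            pairs.append(BafPair(
                gene=row.Gene.strip(), chrom=row.Chromosome.strip(),
                start=int(row.Start), end=int(row.End),
                baf_tumor=float(row.BAF_Tumor), baf_normal=float(row.BAF_Normal),
            ))
        except ValueError as exc:
            raise LoadError(f"{path}: row {i}: {exc}") from exc
    return pairs


def write_baf_pairs(pairs, path) -> None:
    rows = [{
        "Gene": p.gene, "Chromosome": p.chrom, "Start": p.start, "End": p.end,
        "BAF_Tumor": repr(p.baf_tumor), "BAF_Normal": repr(p.baf_normal),
    } for p in pairs]
    pd.DataFrame(rows, columns=list(BAF_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cytobands, gene models
# ---------------------------------------------------------------------------

def read_cytobands(path) -> list[Cytoband]:
    """Read a UCSC cytoBand.txt-layout file (0-based half-open on disk)."""
    bands = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise LoadError(f"{path}: row {i}: expected >= 4 tab-separated fields")
            chrom, start0, end, band = parts[0], int(parts[1]), int(parts[2]), parts[3]
            arm = band[0] if band[:1] in ("p", "q") else ""
            if arm not in ("p", "q"):
                raise LoadError(f"{path}: row {i}: band name {band!r} lacks a p/q arm prefix")
            bands.append(Cytoband(chrom=chrom, start=start0 + 1, end=end, band=band, arm=arm))
    _check_band_layout(bands, path)
    bands.sort(key=lambda b: (chrom_sort_key(b.chrom), b.start))
    return bands


def _check_band_layout(bands, path) -> None:
    by_chrom: dict[str, list[Cytoband]] = {}
    for b in bands:
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom, bs in by_chrom.items():
        bs = sorted(bs, key=lambda b: b.start)
        for a, b in zip(bs, bs[1:]):
            if b.start <= a.end:
                raise LoadError(f"{path}: overlapping cytobands on {chrom}: {a.band}/{b.band}")


def write_cytobands(bands, path) -> None:
    with open(path, "w") as fh:
        for b in bands:
            fh.write(f"{b.chrom}\t{b.start - 1}\t{b.end}\t{b.band}\tgneg\n")


def read_gene_bed(path) -> list[GeneModel]:
    """Read 4-column BED gene models; one record per gene symbol."""
    models = []
    seen = set()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise LoadError(f"{path}: row {i}: expected 4 BED columns")
            chrom, start0, end, gene = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if gene in seen:
                raise ConfigurationError(f"{path}: duplicate gene model for {gene!r}")
            seen.add(gene)
            models.append(GeneModel(gene=gene, chrom=chrom, start=start0 + 1, end=end))
    models.sort(key=lambda m: (chrom_sort_key(m.chrom), m.start))
    return models


def write_gene_bed(models, path) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(f"{m.chrom}\t{m.start - 1}\t{m.end}\t{m.gene}\n")


# ---------------------------------------------------------------------------
# Catalogs
# ---------------------------------------------------------------------------

def read_catalog(path, kind: str) -> GeneCatalog:
    """Read a curated catalog; entries are deduplicated, symbol case kept.

    Schemas: plain gene lists (one symbol per line) for gene-set kinds;
    ``rsid<TAB>gene`` for gwas_snps; ``gene<TAB>Amp|Del`` for glioma_scnas;
    ``gene<TAB>protein_change<TAB>count`` for hotspots.  Conflicting hotspot
    rows (same gene and protein change, different counts) are a load error.
    """
    lines = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").strip()
            if not line or line.startswith("#"):
                continue
            lines.append((i, line))
    entries: list = []
    if kind == "gwas_snps":
        for i, line in lines:
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 2:
                raise LoadError(f"{path}: row {i}: expected rsid<TAB>gene")
            entries.append((parts[0], parts[1]))
    elif kind == "glioma_scnas":
        for i, line in lines:
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 2 or parts[1] not in ("Amp", "Del"):
                raise LoadError(f"{path}: row {i}: expected gene<TAB>Amp|Del")
            entries.append((parts[0], parts[1]))
    elif kind == "hotspots":
        counts: dict[tuple[str, str], int] = {}
        for i, line in lines:
            parts = [p.strip() for p in line.replace(", ", "\t").split("\t")]
            if len(parts) < 3:
                raise LoadError(f"{path}: row {i}: expected gene<TAB>protein_change<TAB>count")
            key, count = (parts[0], parts[1]), int(parts[2])
            if key in counts and counts[key] != count:
                raise LoadError(
                    f"{path}: row {i}: conflicting hotspot counts for {key[0]} {key[1]}"
                )
            counts[key] = count
        entries = [(g, pc, c) for (g, pc), c in counts.items()]
    else:
        for _, line in lines:
            entries.append(line.split("\t")[0].strip())
    # dedupe preserving first-seen order
    seen = set()
    unique = []
    for e in entries:
        if e not in seen:
            seen.add(e)
            unique.append(e)
    return GeneCatalog(kind=kind, entries=tuple(unique))


def write_catalog(catalog: GeneCatalog, path) -> None:
    with open(path, "w") as fh:
        for e in catalog.entries:
            if isinstance(e, tuple):
                fh.write("\t".join(str(x) for x in e) + "\n")
            else:
                fh.write(f"{e}\n")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def read_config(path) -> AnalysisConfig:
    """Read a flat ``key = value`` config file onto :class:`AnalysisConfig`."""
    known = {f.name: f for f in dataclasses.fields(AnalysisConfig)}
    kwargs = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}: row {i}: expected key = value")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ConfigurationError(f"{path}: row {i}: unknown config key {key!r}")
            kwargs[key] = _parse_config_value(value)
    return AnalysisConfig(**kwargs)


def _parse_config_value(value: str):
    low = value.lower()
    if low in ("true", "false"):
        return low == "true"
    if low in ("none", ""):
        return None
    try:
        return int(value)
    except ValueError:
        return float(value)


def write_config(cfg: AnalysisConfig, path) -> None:
    with open(path, "w") as fh:
        for key, value in cfg.to_dict().items():
            fh.write(f"{key} = {value}\n")
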