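"""Tumor mutational burden and polymerase-epsilon deficiency prediction.

TMB is the number of somatic coding mutations (SNVs and indels) per megabase
of assayed coding sequence, after keeping variants with tumor VAF > 5% and
sequencing depth > 20X in the tumor and > 10X in the normal.  POLE
proofreading deficiency is predicted from an ultra-high SNV rate (> 60
SNVs/Mb) combined with a LOW rate of indels in simple sequence repeats
(< 0.18/Mb) — the hypermutation pattern that distinguishes POLE-deficient
from microsatellite-unstable tumors.  MSI status itself comes from an
external predictor and is only carried through to the report.
"""
from __future__ import annotations

import statistics
from dataclasses import dataclass

from .model import (
    NONSYNONYMOUS_CLASSIFICATIONS,
    AnalysisConfig,
    AnnotatedVariant,
    ConfigurationError,
    ContractViolation,
)


@dataclass(frozen=True)
class TmbResult:
    n_qualifying: int
    denominator_mb: float
    tmb: float


@dataclass(frozen=True)
class PoleCall:
    """POLE-deficiency prediction; ``status`` is deficient / not_deficient /
    not_assessable (SSR provenance unavailable for qualifying indels)."""

    snv_per_mb: float
    ssr_indel_per_mb: float | None
    status: str

    @property
    def deficient(self) -> bool:
        return self.status == "deficient"


@dataclass(frozen=True)
class CohortTmbRecord:
    sample: str
    tmb: float
    subset: str
    recurrent: bool = False

    def __post_init__(self) -> None:
        if self.tmb < 0:
            raise ValueError("tmb must be >= 0")


def _coding_set(cfg: AnalysisConfig) -> frozenset[str]:
    if cfg.tmb_include_silent:
        return NONSYNONYMOUS_CLASSIFICATIONS | {"Silent"}
    return NONSYNONYMOUS_CLASSIFICATIONS


def tmb_qualifies(v: AnnotatedVariant, cfg: AnalysisConfig) -> bool:
    """The TMB inclusion predicate: coding class, VAF and depth cuts (all strict)."""
    vaf = v.tumor_vaf if v.tumor_vaf is not None else 0.0
    return (
        v.classification in _coding_set(cfg)
        and vaf > cfg.somatic_min_vaf
        and v.tumor_depth > cfg.tmb_min_tumor_depth
        and v.normal_depth > cfg.tmb_min_normal_depth
    )


def compute_tmb(somatic: list[AnnotatedVariant], cfg: AnalysisConfig) -> TmbResult:
    """Count qualifying somatic coding mutations per megabase."""
    if cfg.coding_mb is None:
        raise ConfigurationError("coding_mb is required to compute TMB")
    for v in somatic:
        if v.origin != "somatic":
            raise ContractViolation("compute_tmb requires somatic variants")
    n = sum(1 for v in somatic if tmb_qualifies(v, cfg))
    return TmbResult(n_qualifying=n, denominator_mb=cfg.coding_mb, tmb=n / cfg.coding_mb)


def predict_pole(somatic: list[AnnotatedVariant], cfg: AnalysisConfig) -> PoleCall:
    """Predict POLE deficiency from qualifying SNV and SSR-indel rates.

    Both conditions are strict: exactly 60 SNVs/Mb or exactly 0.18
    SSR-indels/Mb does not call deficiency.  If any qualifying indel lacks
    SSR provenance the call is not assessable (a sample with no qualifying
    indels has an SSR-indel rate of exactly 0 and stays assessable).
    """
    if cfg.coding_mb is None:
        raise ConfigurationError("coding_mb is required to predict POLE status")
    qualifying = [v for v in somatic if tmb_qualifies(v, cfg)]
    snvs = [v for v in qualifying if not v.is_indel]
    indels = [v for v in qualifying if v.is_indel]
    snv_per_mb = len(snvs) / cfg.coding_mb
    if any(v.in_ssr is None for v in indels):
        return PoleCall(snv_per_mb=snv_per_mb, ssr_indel_per_mb=None, status="not_assessable")
    ssr_per_mb = sum(1 for v in indels if v.in_ssr) / cfg.coding_mb
    deficient = snv_per_mb > cfg.pole_min_snv_per_mb and ssr_per_mb < cfg.pole_max_ssr_indel_per_mb
    return PoleCall(
        snv_per_mb=snv_per_mb,
        ssr_indel_per_mb=ssr_per_mb,
        status="deficient" if deficient else "not_deficient",
    )


def tmb_context(
    history: list[CohortTmbRecord],
    current: TmbResult,
    subset: str | None = None,
) -> dict:
    """Situate the current TMB among previously analyzed tumors.

    Returns the overall and per-subset medians plus the current sample's
    rank (1 + number of historical tumors with strictly higher TMB).  With
    an empty history only the current value is reported.
    """
    context: dict = {"current_tmb": current.tmb, "current_subset": subset}
    if not history:
        return context
    context["overall_median"] = statistics.median(r.tmb for r in history)
    subset_medians = {}
    for label in sorted({r.subset for r in history}):
        subset_medians[label] = statistics.median(r.tmb for r in history if r.subset == label)
    context["subset_medians"] = subset_medians
    context["rank"] = 1 + sum(1 for r in history if r.tmb > current.tmb)
    context["n_history"] = len(history)
    return context
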