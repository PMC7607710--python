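"""Variant retention filters with auditable per-variant decisions.

The retention cascade mirrors standard carrier-screening practice: keep a
variant only if its VCF filter status is PASS, its population minor allele
frequency is below a threshold (default: 1000 Genomes AF < 0.05), its
consequence is exonic or within the splice region, and its read depth is
strictly above a floor (default > 10x). A curated exclusion list handles
variants that pass every numeric rule but were judged to be population
polymorphisms on review (e.g. a coding variant at 0.5% local frequency seen
repeatedly in population NGS data).

Every variant receives exactly one :class:`FilterDecision`; a failing
variant is attributed to the *first* failing rule in the fixed order
quality -> maf -> consequence -> depth -> curation, so audit logs are
reproducible. A variant absent from every consulted frequency source is
treated as rare: missing evidence must not suppress a rare variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from carrierscreen.catalogue import AnnotatedVariant
from carrierscreen.errors import ValidationError
from carrierscreen.hgvs import VariantKind

logger = logging.getLogger(__name__)

__all__ = ["FilterConfig", "FilterDecision", "FilterReason", "apply_filters", "flag_local_common"]

FilterReason = str  # one of: none, quality, maf, consequence, depth, curation_exclusion


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the retention cascade.

    ``min_depth_exclusive`` is a strict bound (depth must be > it);
    ``maf_threshold`` is likewise strict (retained iff AF < threshold).
    ``max_intronic_offset`` widens "canonical splice site" to a splice
    region of that many intronic bases, so that functionally validated
    near-splice variants (e.g. a -6 acceptor-region substitution) survive.
    """

    maf_threshold: float = 0.05
    maf_sources: tuple[str, ...] = ("1000G",)
    min_depth_exclusive: int = 10
    require_pass: bool = True
    max_intronic_offset: int = 8
    exclusion_list: frozenset[str] = field(default_factory=frozenset)
    local_af_flag_threshold: float = 0.005

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_threshold < 1.0):
            raise ValidationError("maf_threshold must be in (0, 1)")
        if self.min_depth_exclusive < 0:
            raise ValidationError("min_depth_exclusive must be >= 0")
        if self.max_intronic_offset < 2:
            raise ValidationError("max_intronic_offset must cover the canonical +/-2 sites")
        object.__setattr__(self, "maf_sources", tuple(self.maf_sources))
        object.__setattr__(self, "exclusion_list", frozenset(self.exclusion_list))


@dataclass(frozen=True)
class FilterDecision:
    variant_id: str
    passed: bool
    reason: FilterReason

    def __post_init__(self) -> None:
        if self.passed != (self.reason == "none"):
            raise ValidationError("passed must hold exactly when reason is 'none'")


def _consulted_afs(variant: AnnotatedVariant, config: FilterConfig) -> list[float]:
    afs = []
    for source in config.maf_sources:
        if source in variant.pop_af:
            afs.append(variant.pop_af[source])
    return afs


def _decide(variant: AnnotatedVariant, config: FilterConfig) -> FilterDecision:
    if config.require_pass and variant.filter_status != "PASS":
        return FilterDecision(variant.variant_id, False, "quality")
    if any(af >= config.maf_threshold for af in _consulted_afs(variant, config)):
        return FilterDecision(variant.variant_id, False, "maf")
    kind = variant.kind_call
    if kind.kind is VariantKind.OTHER:
        return FilterDecision(variant.variant_id, False, "consequence")
    if kind.kind is VariantKind.SPLICE_REGION and kind.intronic_offset > config.max_intronic_offset:
        return FilterDecision(variant.variant_id, False, "consequence")
    if variant.depth <= config.min_depth_exclusive:
        return FilterDecision(variant.variant_id, False, "depth")
    if variant.variant_id in config.exclusion_list:
        return FilterDecision(variant.variant_id, False, "curation_exclusion")
    return FilterDecision(variant.variant_id, True, "none")


def apply_filters(
    variants: Sequence[AnnotatedVariant], config: FilterConfig | None = None
) -> list[FilterDecision]:
    """One decision per input variant, order-preserving and deterministic.

    Total: never raises on variant content. Source names configured but
    absent from a variant's frequency map are simply not consulted.
    """
    config = config or FilterConfig()
    return [_decide(v, config) for v in variants]


def flag_local_common(variant: AnnotatedVariant, config: FilterConfig | None = None) -> bool:
    """Advisory curation flag: seen at >= ``local_af_flag_threshold`` in a
    local/subcontinental source (``local`` or ``gnomAD_SAS``).

    High local frequency suggests a population polymorphism even when the
    global MAF filter passes. This never auto-drops a variant; it marks it
    for review (curated drops go through ``exclusion_list``).
    """
    config = config or FilterConfig()
    for source in ("local", "gnomAD_SAS"):
        af = variant.pop_af.get(source)
        if af is not None and af >= config.local_af_flag_threshold:
            return True
    return False


def decisions_to_rows(
    variants: Iterable[AnnotatedVariant],
    decisions: Iterable[FilterDecision],
    config: FilterConfig,
) -> list[dict]:
    """Audit-log rows: variant_id, passed, reason, and the consulted AFs."""
    rows = []
    for v, d in zip(variants, decisions, strict=True):
        if v.variant_id != d.variant_id:
            raise ValidationError("variants and decisions out of register")
        rows.append(
            {
                "variant_id": v.variant_id,
                "passed": d.passed,
                "reason": d.reason,
                "consulted_af": ";".join(
                    f"{s}={v.pop_af[s]:g}" for s in config.maf_sources if s in v.pop_af
                ),
            }
        )
    return rows
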