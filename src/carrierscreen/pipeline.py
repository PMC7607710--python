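"""End-to-end screening pipeline and report rendering.

Stage order is fixed — filter the catalogue, classify the retained
variants, call carriers, screen couples, then compute statistics — and the
analysis path is seed-free, so a run is deterministic for fixed inputs.
Every number in a rendered report traces to a stage output held on the
:class:`PipelineRun`, and the filter/confidence configuration is embedded
in the report itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

from carrierscreen.acmg import Classification, classify_catalogue
from carrierscreen.carriers import (
    AtRiskCouple,
    CarrierCall,
    GenotypeRecord,
    Individual,
    call_carriers,
    couple_screen,
    multiplicity_histogram,
)
from carrierscreen.catalogue import AnnotatedVariant
from carrierscreen.errors import CarrierScreenError, ValidationError
from carrierscreen.filters import FilterConfig, FilterDecision, apply_filters
from carrierscreen.panel import PanelGene
from carrierscreen.stats import CatalogueSummary, FrequencyEstimate, frequency_table, summarize_catalogue

__all__ = ["PipelineRun", "run_pipeline", "render_report"]


@dataclass(frozen=True)
class PipelineRun:
    """Outputs of one pipeline execution, stage by stage."""

    filter_config: FilterConfig
    conf: float
    n_individuals: int
    filter_decisions: tuple[FilterDecision, ...]
    classifications: dict[str, Classification]
    calls: tuple[CarrierCall, ...]
    at_risk_couples: tuple[AtRiskCouple, ...]
    frequencies: tuple[FrequencyEstimate, ...]
    catalogue_summary: CatalogueSummary
    multiplicity: dict[int, int]
    log: tuple[str, ...] = ()

    @property
    def n_carrier_individuals(self) -> int:
        return len({c.individual_id for c in self.calls if c.category == "carrier"})

    @property
    def n_calls(self) -> int:
        return sum(1 for c in self.calls if c.category == "carrier")


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except CarrierScreenError as exc:
        raise type(exc)(f"[stage: {name}] {exc}") from exc


def run_pipeline(
    panel: Sequence[PanelGene],
    catalogue: Sequence[AnnotatedVariant],
    individuals: Sequence[Individual],
    genotypes: Sequence[GenotypeRecord],
    filter_config: FilterConfig | None = None,
    conf: float = 0.95,
    couple_match: Literal["gene", "disorder"] = "gene",
) -> PipelineRun:
    """Filter -> classify -> call -> couple screen -> statistics.

    Genotypes over variants removed by filtration are dropped (with a log
    line); genotypes over unknown variants are a validation error. The
    catalogue summary covers the retained variants.
    """
    config = filter_config or FilterConfig()
    log: list[str] = []

    known = {v.variant_id for v in catalogue}
    dangling = sorted({g.variant_id for g in genotypes if g.variant_id not in known})
    if dangling:
        raise ValidationError(f"[stage: validate] genotypes over uncatalogued variants: {dangling}")

    decisions = _stage("filter", apply_filters, catalogue, config)
    retained = [v for v, d in zip(catalogue, decisions) if d.passed]
    log.append(f"filter: retained {len(retained)}/{len(catalogue)} variants")

    classifications = _stage("classify", classify_catalogue, retained)
    n_reportable = sum(1 for c in classifications.values() if c.reportable)
    log.append(f"classify: {n_reportable}/{len(retained)} retained variants reportable (P/LP)")

    retained_ids = {v.variant_id for v in retained}
    usable = [g for g in genotypes if g.variant_id in retained_ids]
    if len(usable) < len(genotypes):
        log.append(f"call: dropped {len(genotypes) - len(usable)} genotypes over filtered-out variants")
    variant_gene = {v.variant_id: v.gene for v in catalogue}
    calls = _stage("call", call_carriers, individuals, usable, classifications, panel, variant_gene)

    at_risk = _stage("couple_screen", couple_screen, individuals, calls, couple_match)
    freqs = _stage("stats", frequency_table, calls, len(individuals), panel, conf)
    summary = _stage("stats", summarize_catalogue, retained)
    hist = multiplicity_histogram(calls)

    return PipelineRun(
        filter_config=config,
        conf=conf,
        n_individuals=len(individuals),
        filter_decisions=tuple(decisions),
        classifications=classifications,
        calls=tuple(calls),
        at_risk_couples=tuple(at_risk),
        frequencies=tuple(freqs),
        catalogue_summary=summary,
        multiplicity=hist,
        log=tuple(log),
    )


def _payload(run: PipelineRun) -> dict:
    reasons: dict[str, int] = {}
    for d in run.filter_decisions:
        reasons[d.reason] = reasons.get(d.reason, 0) + 1
    return {
        "config": {
            "maf_threshold": run.filter_config.maf_threshold,
            "maf_sources": list(run.filter_config.maf_sources),
            "min_depth_exclusive": run.filter_config.min_depth_exclusive,
            "require_pass": run.filter_config.require_pass,
            "max_intronic_offset": run.filter_config.max_intronic_offset,
            "n_excluded_by_curation_list": len(run.filter_config.exclusion_list),
            "confidence_level": run.conf,
        },
        "cohort": {
            "n_individuals": run.n_individuals,
            "n_carrier_individuals": run.n_carrier_individuals,
            "carrier_pct": 100.0 * run.n_carrier_individuals / run.n_individuals,
            "n_carrier_calls": run.n_calls,
            "multiplicity_histogram": {str(k): v for k, v in run.multiplicity.items()},
            "n_at_risk_couples": len(run.at_risk_couples),
            "at_risk_couples": [
                {"couple_id": c.couple_id, "gene": c.gene, "disorder": c.disorder_name}
                for c in run.at_risk_couples
            ],
        },
        "filter_decisions_by_reason": dict(sorted(reasons.items())),
        "frequencies": [
            {
                "label": f.label,
                "n": f.n,
                "N": f.N,
                "pct": f.pct,
                "one_in": f.one_in,
                "ci_lower_pct": f.ci_lower_pct,
                "ci_upper_pct": f.ci_upper_pct,
            }
            for f in run.frequencies
        ],
        "catalogue": {
            "distinct_variants": run.catalogue_summary.distinct_variants,
            "total_occurrences": run.catalogue_summary.total_occurrences,
            "kind_pct": run.catalogue_summary.kind_pct,
            "novel_count": run.catalogue_summary.novel_count,
            "reported_subcontinent_pct": run.catalogue_summary.reported_subcontinent_pct,
        },
        "log": list(run.log),
    }


def _fmt(x) -> str:
    if x is None:
        return "-"
    if isinstance(x, bool):
        return str(x)
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def _render_tables(run: PipelineRun, markdown: bool) -> str:
    p = _payload(run)
    out: list[str] = []
    h = (lambda s: f"## {s}") if markdown else (lambda s: s.upper())
    out.append(h("Cohort"))
    c = p["cohort"]
    out.append(
        f"individuals: {c['n_individuals']}; carriers: {c['n_carrier_individuals']} "
        f"({_fmt(c['carrier_pct'])}%); carrier calls: {c['n_carrier_calls']}; "
        f"at-risk couples: {c['n_at_risk_couples']}"
    )
    out.append(
        "carriers by number of disorders: "
        + ", ".join(f"{k}: {v}" for k, v in c["multiplicity_histogram"].items())
    )
    out.append("")
    out.append(h("Carrier frequencies"))
    header = ["label", "n", "N", "pct", "1 in", "ci_lower_pct", "ci_upper_pct"]
    rows = [
        [r["label"], r["n"], r["N"], _fmt(r["pct"]), _fmt(r["one_in"]), _fmt(r["ci_lower_pct"]), _fmt(r["ci_upper_pct"])]
        for r in p["frequencies"]
    ]
    if markdown:
        out.append("| " + " | ".join(header) + " |")
        out.append("|" + "---|" * len(header))
        out += ["| " + " | ".join(map(str, row)) + " |" for row in rows]
    else:
        out.append("\t".join(header))
        out += ["\t".join(map(str, row)) for row in rows]
    out.append("")
    out.append(h("Variant catalogue"))
    cat = p["catalogue"]
    out.append(
        f"distinct variants: {cat['distinct_variants']}; observations: {cat['total_occurrences']}; "
        f"novel: {cat['novel_count']}; previously reported seen in subcontinent: "
        f"{_fmt(cat['reported_subcontinent_pct'])}%"
    )
    out.append("kinds: " + ", ".join(f"{k}: {_fmt(v)}%" for k, v in cat["kind_pct"].items()))
    out.append("")
    out.append(h("Filter decisions"))
    out.append(", ".join(f"{k}: {v}" for k, v in p["filter_decisions_by_reason"].items()))
    out.append("")
    out.append(h("Configuration"))
    out.append(", ".join(f"{k}={_fmt(v)}" for k, v in p["config"].items()))
    return "\n".join(out) + "\n"


def render_report(run: PipelineRun, format: Literal["text", "markdown", "json"] = "text") -> str:
    """Render a run as text, markdown or JSON; all three carry identical
    numeric content (floats printed to 6 significant digits in the
    human-readable forms)."""
    if format == "json":
        return json.dumps(_payload(run), indent=2) + "\n"
    if format == "markdown":
        return _render_tables(run, markdown=True)
    if format == "text":
        return _render_tables(run, markdown=False)
    raise ValidationError(f"unknown report format {format!r}")
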