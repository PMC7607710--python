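"""Carrier and couple-level risk calling.

Given per-individual genotypes over classified variants, emit one
:class:`CarrierCall` per (individual, gene) with reportable (P/LP)
findings. Category semantics follow screening convention:

* AR gene, single heterozygous variant -> ``carrier``;
* AR gene, homozygous or two distinct heterozygous variants (possible
  compound heterozygote; phase unresolved) -> ``affected_risk``;
* XL gene, heterozygous female -> ``carrier``; hemizygous male ->
  ``affected_risk`` (a hemizygous pathogenic genotype implies affected
  status, not carrier status); a heterozygous male on the X is a data
  error and is rejected;
* AD/AR gene, any reportable genotype -> ``affected_risk`` (a dominant
  allele is a finding for the individual, not a recessive carrier state),
  kept out of carrier-frequency tables.

VUS and benign variants never generate calls. Couple screening flags
couples where *both* partners hold a carrier-category call in the same
gene (gene-level matching by default: two partners carrying different
deafness genes are not an at-risk couple, consistent with locus
heterogeneity; disorder-level matching is available as an option).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

from carrierscreen.acmg import Classification
from carrierscreen.errors import ValidationError
from carrierscreen.panel import Inheritance, PanelGene

__all__ = [
    "Individual",
    "GenotypeRecord",
    "CarrierCall",
    "AtRiskCouple",
    "call_carriers",
    "couple_screen",
    "multiplicity_histogram",
    "residual_risk",
]

Zygosity = Literal["het", "hom", "hemi"]
Category = Literal["carrier", "affected_risk"]


@dataclass(frozen=True)
class Individual:
    id: str
    sex: Literal["male", "female"]
    couple_id: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"individual {self.id!r}: unknown sex {self.sex!r}")


@dataclass(frozen=True)
class GenotypeRecord:
    individual_id: str
    variant_id: str
    zygosity: Zygosity = "het"

    def __post_init__(self) -> None:
        if self.zygosity not in ("het", "hom", "hemi"):
            raise ValidationError(
                f"{self.individual_id}/{self.variant_id}: unknown zygosity {self.zygosity!r}"
            )


@dataclass(frozen=True)
class CarrierCall:
    individual_id: str
    gene: str
    disorder_name: str
    variant_ids: tuple[str, ...]
    category: Category

    def __post_init__(self) -> None:
        if not self.variant_ids:
            raise ValidationError("carrier call with no supporting variants")


@dataclass(frozen=True)
class AtRiskCouple:
    couple_id: str
    gene: str
    disorder_name: str
    member_ids: tuple[str, str]


def _validate_cohort(cohort: Sequence[Individual]) -> dict[str, Individual]:
    by_id: dict[str, Individual] = {}
    for ind in cohort:
        if ind.id in by_id:
            raise ValidationError(f"duplicate individual id {ind.id!r}")
        by_id[ind.id] = ind
    members: dict[str, list[str]] = defaultdict(list)
    for ind in cohort:
        if ind.couple_id is not None:
            members[ind.couple_id].append(ind.id)
    bad = {cid: ids for cid, ids in members.items() if len(ids) != 2}
    if bad:
        raise ValidationError(f"couple ids not shared by exactly two individuals: {sorted(bad)}")
    return by_id


def call_carriers(
    cohort: Sequence[Individual],
    genotypes: Sequence[GenotypeRecord],
    classifications: Mapping[str, Classification],
    panel: Sequence[PanelGene],
    variant_gene: Mapping[str, str],
) -> list[CarrierCall]:
    """Emit carrier / affected-risk calls, sorted by (individual, gene).

    ``variant_gene`` maps variant_id -> gene symbol (the catalogue index).
    Every genotype must reference a known individual and a classified
    variant on a panel gene; (individual, variant) pairs must be unique.
    Only reportable (P/LP) variants generate calls.
    """
    by_id = _validate_cohort(cohort)
    gene_info = {g.symbol: g for g in panel}

    seen_pairs: set[tuple[str, str]] = set()
    per_ind_gene: dict[tuple[str, str], list[GenotypeRecord]] = defaultdict(list)
    for rec in genotypes:
        if rec.individual_id not in by_id:
            raise ValidationError(f"genotype references unknown individual {rec.individual_id!r}")
        if rec.variant_id not in classifications:
            raise ValidationError(f"genotype references unclassified variant {rec.variant_id!r}")
        pair = (rec.individual_id, rec.variant_id)
        if pair in seen_pairs:
            raise ValidationError(f"duplicate genotype record for {pair}")
        seen_pairs.add(pair)
        if not classifications[rec.variant_id].reportable:
            continue
        gene = variant_gene.get(rec.variant_id)
        if gene is None:
            raise ValidationError(f"variant {rec.variant_id!r} missing from the catalogue index")
        if gene not in gene_info:
            raise ValidationError(f"variant {rec.variant_id!r} on off-panel gene {gene!r}")
        per_ind_gene[(rec.individual_id, gene)].append(rec)

    calls: list[CarrierCall] = []
    for (ind_id, gene), recs in per_ind_gene.items():
        ind = by_id[ind_id]
        info = gene_info[gene]
        zygosities = {r.zygosity for r in recs}
        if "hemi" in zygosities and (info.inheritance is not Inheritance.XL or ind.sex != "male"):
            raise ValidationError(
                f"{ind_id}/{gene}: hemizygous genotype outside male X-linked context"
            )
        if info.inheritance is Inheritance.XL:
            if ind.sex == "male":
                if "het" in zygosities:
                    raise ValidationError(
                        f"{ind_id}/{gene}: heterozygous male genotype on an X-linked gene"
                    )
                category: Category = "affected_risk"
            else:
                category = "affected_risk" if "hom" in zygosities else "carrier"
        elif info.inheritance is Inheritance.AD_AR:
            category = "affected_risk"
        else:  # AR
            if "hom" in zygosities or len(recs) > 1:
                category = "affected_risk"
            else:
                category = "carrier"
        calls.append(
            CarrierCall(
                individual_id=ind_id,
                gene=gene,
                disorder_name=info.disorder_name,
                variant_ids=tuple(sorted(r.variant_id for r in recs)),
                category=category,
            )
        )
    calls.sort(key=lambda c: (c.individual_id, c.gene))
    return calls


def couple_screen(
    cohort: Sequence[Individual],
    calls: Sequence[CarrierCall],
    level: Literal["gene", "disorder"] = "gene",
) -> list[AtRiskCouple]:
    """Couples where both partners carry (carrier category) in the same
    gene (default) or for the same disorder. Symmetric in partner order;
    singletons are ignored."""
    by_id = _validate_cohort(cohort)
    couple_of = {ind.id: ind.couple_id for ind in cohort if ind.couple_id is not None}

    def key(call: CarrierCall) -> str:
        return call.gene if level == "gene" else call.disorder_name

    held: dict[tuple[str, str], list[CarrierCall]] = defaultdict(list)
    for call in calls:
        if call.category != "carrier":
            continue
        cid = couple_of.get(call.individual_id)
        if cid is None:
            continue
        held[(cid, key(call))].append(call)

    at_risk = []
    for (cid, k), shared in sorted(held.items()):
        members = sorted({c.individual_id for c in shared})
        if len(members) == 2:
            at_risk.append(
                AtRiskCouple(
                    couple_id=cid,
                    gene=shared[0].gene if level == "gene" else "",
                    disorder_name=shared[0].disorder_name,
                    member_ids=(members[0], members[1]),
                )
            )
    return at_risk


def multiplicity_histogram(calls: Sequence[CarrierCall]) -> dict[int, int]:
    """Histogram of calls-per-individual (how many distinct disorders each
    called individual carries)."""
    per_ind: dict[str, int] = defaultdict(int)
    for call in calls:
        per_ind[call.individual_id] += 1
    hist: dict[int, int] = defaultdict(int)
    for n in per_ind.values():
        hist[n] += 1
    return dict(sorted(hist.items()))


def residual_risk(prior_carrier_freq: float, detection_rate: float) -> float:
    """Post-test carrier probability after a negative screen.

    Bayes with prior carrier frequency ``f`` and test detection rate ``d``:
    ``f(1-d) / (f(1-d) + (1-f))``. Monotone decreasing in ``d``; 0 for a
    perfect test (the f=1, d=1 corner is taken as its limit 0).
    """
    f, d = prior_carrier_freq, detection_rate
    if not (0.0 <= f <= 1.0 and 0.0 <= d <= 1.0):
        raise ValidationError("prior frequency and detection rate must lie in [0, 1]")
    missed = f * (1.0 - d)
    denom = missed + (1.0 - f)
    if denom == 0.0:
        return 0.0
    return missed / denom
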