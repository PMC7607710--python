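"""Seeded synthetic screening cohorts with known ground truth.

The simulator emulates the data a carrier-screening pipeline consumes —
individuals (couples plus singletons), heterozygous pathogenic/likely
pathogenic genotypes planted at configured per-gene carrier frequencies,
and distractor variants of the classes the retention filters and the ACMG
engine must reject — and returns the truth table alongside, so recovery can
be checked exactly.

Modelling choices, deliberately simple for rare recessive alleles: each
individual is independently a carrier of gene *g* with probability
``per_gene_carrier_freq[g]`` (independent Bernoulli per gene; Hardy-Weinberg
mating structure and linkage are ignored); the carried variant is drawn from
the catalogue entries for *g*, weighted by their reference occurrence
counts. On X-linked genes a planted male is hemizygous (an affected-risk
finding), a planted female heterozygous (a carrier); on AD/AR genes any
planted genotype is an affected-risk finding.

Distractor classes (counts per individual are Poisson with the configured
means): ``common`` (population AF >= 5%, should fail the MAF filter),
``non_pass`` (failed variant quality), ``low_depth`` (read depth <= 10),
``vus_evidence`` (clean QC but evidence combining to VUS) and
``benign_evidence`` (evidence combining to Benign). Each distractor is a
synthetic missense variant unique to one individual and must never survive
to a carrier call.

Identical seed and package version give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import io
import re
from dataclasses import dataclass, field
from os import PathLike
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from carrierscreen.carriers import GenotypeRecord, Individual
from carrierscreen.catalogue import AnnotatedVariant
from carrierscreen.errors import ValidationError
from carrierscreen.panel import Inheritance, PanelGene

__all__ = ["SimConfig", "PlantedCarrier", "TruthTable", "SimulatedCohort", "generate_cohort", "write_vcf"]

_DISTRACTOR_CLASSES = ("common", "non_pass", "low_depth", "vus_evidence", "benign_evidence")

# study-scale defaults: cohort of 200, 88% enrolled with a partner, and a
# light load of each distractor class per individual
_DEFAULT_DISTRACTOR_RATES: dict[str, float] = {
    "common": 2.0,
    "non_pass": 0.3,
    "low_depth": 0.3,
    "vus_evidence": 0.5,
    "benign_evidence": 0.5,
}


@dataclass(frozen=True)
class SimConfig:
    n_individuals: int = 200
    couple_fraction: float = 0.88
    per_gene_carrier_freq: Mapping[str, float] = field(default_factory=dict)
    distractor_rates: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_DISTRACTOR_RATES))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValidationError("n_individuals must be >= 1")
        if not (0.0 <= self.couple_fraction <= 1.0):
            raise ValidationError("couple_fraction must lie in [0, 1]")
        for gene, f in self.per_gene_carrier_freq.items():
            if not (0.0 <= f <= 1.0):
                raise ValidationError(f"carrier frequency for {gene!r} outside [0, 1]")
        unknown = set(self.distractor_rates) - set(_DISTRACTOR_CLASSES)
        if unknown:
            raise ValidationError(f"unknown distractor classes: {sorted(unknown)}")
        if any(r < 0 for r in self.distractor_rates.values()):
            raise ValidationError("distractor rates must be >= 0")


@dataclass(frozen=True)
class PlantedCarrier:
    individual_id: str
    gene: str
    variant_id: str
    zygosity: str
    expected_category: str  # carrier | affected_risk


@dataclass(frozen=True)
class TruthTable:
    planted: tuple[PlantedCarrier, ...]
    per_gene_freq: dict[str, float]

    def carriers_by_individual(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for p in self.planted:
            out.setdefault(p.individual_id, set()).add(p.gene)
        return out


@dataclass(frozen=True)
class SimulatedCohort:
    individuals: tuple[Individual, ...]
    genotypes: tuple[GenotypeRecord, ...]
    annotations: tuple[AnnotatedVariant, ...]
    truth: TruthTable
    config: SimConfig


def _make_individuals(config: SimConfig, rng: np.random.Generator) -> list[Individual]:
    n = config.n_individuals
    n_paired = int(n * config.couple_fraction)
    n_paired -= n_paired % 2  # paired individuals come in twos
    ids = [f"S{i + 1:04d}" for i in range(n)]
    order = rng.permutation(n)  # couples assigned randomly among the cohort
    paired = sorted(order[:n_paired])
    individuals: dict[int, Individual] = {}
    for c, (a, b) in enumerate(zip(paired[0::2], paired[1::2]), start=1):
        cid = f"SC{c:03d}"
        individuals[a] = Individual(id=ids[a], sex="male", couple_id=cid)
        individuals[b] = Individual(id=ids[b], sex="female", couple_id=cid)
    for i in range(n):
        if i not in individuals:
            sex = "male" if rng.random() < 0.5 else "female"
            individuals[i] = Individual(id=ids[i], sex=sex)
    return [individuals[i] for i in range(n)]


def _plant_carriers(
    config: SimConfig,
    individuals: Sequence[Individual],
    panel_by_symbol: Mapping[str, PanelGene],
    variants_by_gene: Mapping[str, list[AnnotatedVariant]],
    rng: np.random.Generator,
) -> tuple[list[GenotypeRecord], list[PlantedCarrier], dict[str, int]]:
    genotypes: list[GenotypeRecord] = []
    planted: list[PlantedCarrier] = []
    observed: dict[str, int] = {}
    for gene in sorted(config.per_gene_carrier_freq):
        freq = config.per_gene_carrier_freq[gene]
        if gene not in variants_by_gene:
            raise ValidationError(f"configured gene {gene!r} has no catalogue variants")
        mode = panel_by_symbol[gene].inheritance
        choices = variants_by_gene[gene]
        weights = np.array([max(v.occurrences, 1) for v in choices], dtype=float)
        weights /= weights.sum()
        hits = rng.random(len(individuals)) < freq
        for ind, hit in zip(individuals, hits):
            if not hit:
                continue
            variant = choices[int(rng.choice(len(choices), p=weights))]
            if mode is Inheritance.XL:
                zygosity = "hemi" if ind.sex == "male" else "het"
                category = "affected_risk" if ind.sex == "male" else "carrier"
            elif mode is Inheritance.AD_AR:
                zygosity, category = "het", "affected_risk"
            else:
                zygosity, category = "het", "carrier"
            genotypes.append(GenotypeRecord(ind.id, variant.variant_id, zygosity))
            planted.append(PlantedCarrier(ind.id, gene, variant.variant_id, zygosity, category))
            observed[variant.variant_id] = observed.get(variant.variant_id, 0) + 1
    return genotypes, planted, observed


def _distractor_variant(
    cls: str, index: int, gene: PanelGene, rng: np.random.Generator
) -> AnnotatedVariant:
    pos = int(rng.integers(100, 5000))
    aa = pos // 3 + 1
    common_fields = dict(
        variant_id=f"SIM-{cls}-{index:05d}",
        gene=gene.symbol,
        transcript=gene.transcript,
        chgvs=f"c.{pos}G>A",
        phgvs=f"p.Gly{aa}Ser",
        novel=False,
        subcontinent=False,
        occurrences=1,
    )
    from carrierscreen.acmg import parse_evidence  # local import avoids cycle

    if cls == "common":
        return AnnotatedVariant(
            filter_status="PASS",
            depth=60,
            pop_af={"1000G": round(float(rng.uniform(0.05, 0.5)), 4)},
            evidence=parse_evidence(""),
            **common_fields,
        )
    if cls == "non_pass":
        return AnnotatedVariant(
            filter_status="LowQual",
            depth=60,
            pop_af={"1000G": 0.001},
            evidence=parse_evidence("PM2 + PP3"),
            **common_fields,
        )
    if cls == "low_depth":
        return AnnotatedVariant(
            filter_status="PASS",
            depth=int(rng.integers(0, 11)),
            pop_af={"1000G": 0.001},
            evidence=parse_evidence("PM2 + PP3"),
            **common_fields,
        )
    if cls == "vus_evidence":
        return AnnotatedVariant(
            filter_status="PASS",
            depth=60,
            pop_af={"1000G": 0.001},
            evidence=parse_evidence("PM2 + PP3"),
            **common_fields,
        )
    if cls == "benign_evidence":
        return AnnotatedVariant(
            filter_status="PASS",
            depth=60,
            pop_af={"1000G": 0.001},
            evidence=parse_evidence("BS1 + BS2"),
            **common_fields,
        )
    raise ValidationError(f"unknown distractor class {cls!r}")


def generate_cohort(
    config: SimConfig,
    panel: Sequence[PanelGene],
    catalogue: Sequence[AnnotatedVariant],
) -> SimulatedCohort:
    """Generate a cohort under ``config``; same seed, same bytes.

    Raises if a configured gene is absent from the catalogue or the panel.
    """
    panel_by_symbol = {g.symbol: g for g in panel}
    for gene in config.per_gene_carrier_freq:
        if gene not in panel_by_symbol:
            raise ValidationError(f"configured gene {gene!r} not on the panel")
    variants_by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in catalogue:
        variants_by_gene.setdefault(v.gene, []).append(v)

    rng = np.random.default_rng(config.seed)
    individuals = _make_individuals(config, rng)
    genotypes, planted, observed = _plant_carriers(
        config, individuals, panel_by_symbol, variants_by_gene, rng
    )

    # annotation table: observed catalogue variants with simulated counts
    annotations = [
        dataclasses.replace(v, occurrences=observed[v.variant_id])
        for v in catalogue
        if v.variant_id in observed
    ]

    panel_list = [panel_by_symbol[s] for s in sorted(panel_by_symbol)]
    counter = 0
    for ind in individuals:
        for cls in _DISTRACTOR_CLASSES:
            rate = config.distractor_rates.get(cls, 0.0)
            if rate <= 0:
                continue
            for _ in range(int(rng.poisson(rate))):
                counter += 1
                gene = panel_list[int(rng.integers(0, len(panel_list)))]
                variant = _distractor_variant(cls, counter, gene, rng)
                annotations.append(variant)
                zyg = (
                    "hemi"
                    if gene.inheritance is Inheritance.XL and ind.sex == "male"
                    else "het"
                )
                genotypes.append(GenotypeRecord(ind.id, variant.variant_id, zyg))

    truth = TruthTable(planted=tuple(planted), per_gene_freq=dict(config.per_gene_carrier_freq))
    return SimulatedCohort(
        individuals=tuple(individuals),
        genotypes=tuple(genotypes),
        annotations=tuple(annotations),
        truth=truth,
        config=config,
    )


_SNV_RE = re.compile(r"([ACGT])>([ACGT])$")


def write_vcf(cohort: SimulatedCohort, path: str | PathLike | io.IOBase) -> None:
    """Minimal VCF v4.2 rendering of a simulated cohort.

    One pseudo-contig per gene (no real coordinates exist for the toy
    cohort); the annotation table remains authoritative. GT is the only
    FORMAT field; hemizygous genotypes are written haploid.
    """
    variants = list(cohort.annotations)
    samples = [ind.id for ind in cohort.individuals]
    gt: dict[tuple[str, str], str] = {}
    for rec in cohort.genotypes:
        code = {"het": "0/1", "hom": "1/1", "hemi": "1"}[rec.zygosity]
        gt[(rec.variant_id, rec.individual_id)] = code

    genes = sorted({v.gene for v in variants})
    pos_of = {v.variant_id: 1000 + 10 * i for i, v in enumerate(variants)}

    lines = ["##fileformat=VCFv4.2", "##source=carrierscreen-simulator"]
    lines += [f"##contig=<ID=ctg_{g},length=1000000>" for g in genes]
    lines.append('##INFO=<ID=VID,Number=1,Type=String,Description="Catalogue variant id">')
    lines.append('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t" + "FORMAT\t" + "\t".join(samples))
    for v in sorted(variants, key=lambda v: (v.gene, pos_of[v.variant_id])):
        m = _SNV_RE.search(v.chgvs.replace(" ", "")) if v.chgvs else None
        ref, alt = (m.group(1), m.group(2)) if m else ("N", "<ALT>")
        cells = [gt.get((v.variant_id, s), "0/0") for s in samples]
        lines.append(
            "\t".join(
                [
                    f"ctg_{v.gene}",
                    str(pos_of[v.variant_id]),
                    v.variant_id,
                    ref,
                    alt,
                    ".",
                    v.filter_status,
                    f"VID={v.variant_id};GENE={v.gene}",
                    "GT",
                ]
                + cells
            )
        )
    text = "\n".join(lines) + "\n"
    if isinstance(path, io.IOBase):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def genotypes_to_frame(cohort: SimulatedCohort) -> pd.DataFrame:
    """Flat genotype table (individual_id, variant_id, zygosity)."""
    return pd.DataFrame(
        [(g.individual_id, g.variant_id, g.zygosity) for g in cohort.genotypes],
        columns=["individual_id", "variant_id", "zygosity"],
    )
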