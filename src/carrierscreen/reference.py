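"""The bundled reference screening cohort and its deterministic genotypes.

This module ships the study conditions the package validates against: an
expanded carrier screen of 200 unrelated North Indian individuals (88
enrolled couples plus 24 singletons) over an 88-gene panel (72 AR, 7 XL,
9 AD/AR), whose curated catalogue holds 47 distinct pathogenic / likely
pathogenic variants observed 57 times in 52 carrier individuals (47
carriers of one disorder, 5 of two) with no couple sharing a gene.

Two data files back it:

``data/variant_catalogue.tsv``
    The 47 curated variants with their published HGVS descriptions, ACMG
    evidence sets, novelty / subcontinent provenance flags and per-variant
    occurrence counts. QC fields (PASS status, read depths > 30) and the
    small population allele frequencies are synthetic annotation consistent
    with the reported QC review, since per-variant QC values were not
    published.

``data/panel_synthetic.tsv``
    SYNTHETIC stand-in for the full panel document: the genes that actually
    appear in the catalogue (and the named X-linked disorders and familial
    hypercholesterolemia) are real, with their published transcripts and
    OMIM numbers; the remaining rows are representative filler genes with
    placeholder transcript/OMIM identifiers, included only so the panel has
    the documented 72/7/9 inheritance-mode composition.

The published tables give per-variant occurrence counts and marginal totals
but not which individual carried what, so the genotype assignment here is an
arbitrary *deterministic* choice preserving every printed marginal: the five
double carriers are singleton individuals P177-P181 with fixed gene pairs
(placing them outside couples makes the zero at-risk-couples result
structural), and each remaining observation goes to one member of a distinct
couple, in catalogue order.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from carrierscreen.carriers import GenotypeRecord, Individual
from carrierscreen.catalogue import AnnotatedVariant, load_catalogue
from carrierscreen.errors import ValidationError
from carrierscreen.panel import PanelGene, load_panel

__all__ = ["ReferenceCohort", "load_reference_panel", "load_reference_catalogue", "reference_cohort"]

N_INDIVIDUALS = 200
N_COUPLES = 88

# the five double-carrier individuals and their fixed variant pairs
_DOUBLE_CARRIERS: dict[str, tuple[str, str]] = {
    "P177": ("CFTR:c.223C>T", "SLC26A4:c.1001G>T"),
    "P178": ("CFTR:c.1646G>A", "GJB2:c.231G>A"),
    "P179": ("GAA:c.1933G>A", "SLC26A4:c.1001G>T"),
    "P180": ("TMPRSS3:c.323-6G>A", "MMAA:c.433C>T"),
    "P181": ("GALT:c.563A>G", "OCA2:c.1580T>G"),
}


@dataclass(frozen=True)
class ReferenceCohort:
    panel: tuple[PanelGene, ...]
    catalogue: tuple[AnnotatedVariant, ...]
    individuals: tuple[Individual, ...]
    genotypes: tuple[GenotypeRecord, ...]


def _data_path(name: str):
    return resources.files("carrierscreen.data").joinpath(name)


def load_reference_panel() -> list[PanelGene]:
    """The 88-gene panel (see module docstring for what is synthetic)."""
    with resources.as_file(_data_path("panel_synthetic.tsv")) as path:
        return load_panel(path)


def load_reference_catalogue(panel: list[PanelGene] | None = None) -> list[AnnotatedVariant]:
    """The 47-variant curated catalogue, validated against the panel."""
    if panel is None:
        panel = load_reference_panel()
    with resources.as_file(_data_path("variant_catalogue.tsv")) as path:
        return load_catalogue(path, panel=panel)


def _individuals() -> list[Individual]:
    people: list[Individual] = []
    # couples C001..C088: members P001/P002 .. P175/P176, male then female
    for k in range(1, N_COUPLES + 1):
        cid = f"C{k:03d}"
        people.append(Individual(id=f"P{2 * k - 1:03d}", sex="male", couple_id=cid))
        people.append(Individual(id=f"P{2 * k:03d}", sex="female", couple_id=cid))
    # 24 singletons: 13 male, 11 female (cohort totals 101 male / 99 female)
    for i in range(177, 190):
        people.append(Individual(id=f"P{i:03d}", sex="male"))
    for i in range(190, 201):
        people.append(Individual(id=f"P{i:03d}", sex="female"))
    return people


def reference_cohort() -> ReferenceCohort:
    """Panel, catalogue, individuals and the deterministic genotype table.

    Heterozygous genotypes reproduce every per-variant occurrence count.
    """
    panel = load_reference_panel()
    catalogue = load_reference_catalogue(panel)
    individuals = _individuals()

    remaining = {v.variant_id: v.occurrences for v in catalogue}
    genotypes: list[GenotypeRecord] = []
    for ind_id, pair in _DOUBLE_CARRIERS.items():
        for vid in pair:
            if remaining.get(vid, 0) < 1:
                raise ValidationError(f"double-carrier plan exceeds occurrences for {vid}")
            remaining[vid] -= 1
            genotypes.append(GenotypeRecord(individual_id=ind_id, variant_id=vid, zygosity="het"))

    # one single-carrier observation per couple, first member, catalogue order
    couple_index = 0
    for v in catalogue:
        for _ in range(remaining[v.variant_id]):
            couple_index += 1
            genotypes.append(
                GenotypeRecord(
                    individual_id=f"P{2 * couple_index - 1:03d}",
                    variant_id=v.variant_id,
                    zygosity="het",
                )
            )
        remaining[v.variant_id] = 0

    if couple_index > N_COUPLES:
        raise ValidationError("single-carrier assignments exceed available couples")
    return ReferenceCohort(
        panel=tuple(panel),
        catalogue=tuple(catalogue),
        individuals=tuple(individuals),
        genotypes=tuple(genotypes),
    )
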