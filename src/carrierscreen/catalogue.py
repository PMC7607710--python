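"""Variant catalogue data model and I/O.

An :class:`AnnotatedVariant` is one distinct variant as curated for a
screening cohort: HGVS description, QC fields (filter status, read depth),
population allele frequencies keyed by source name, its ACMG evidence set,
provenance flags (novel / previously described from the Indian
subcontinent), and the number of cohort individuals in whom it was observed.

Catalogues are keyed by ``variant_id`` (conventionally ``GENE:cHGVS``),
not genomic coordinates: printed variant tables rarely give positions, and
transcript-level HGVS is the stable citation form. Consequence kind is
derived from HGVS at load time via :func:`carrierscreen.hgvs.parse_hgvs_kind`.

Catalogues serialize to tab-separated text with one ``af_<source>`` column
per frequency source; loading and writing round-trip field-for-field.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Mapping

import pandas as pd

from carrierscreen.acmg import EvidenceSet, parse_evidence
from carrierscreen.errors import ParseError, ValidationError
from carrierscreen.hgvs import KindCall, VariantKind, parse_hgvs_kind
from carrierscreen.panel import PanelGene

__all__ = ["AnnotatedVariant", "load_catalogue", "write_catalogue", "catalogue_to_frame"]


@dataclass(frozen=True)
class AnnotatedVariant:
    variant_id: str
    gene: str
    transcript: str
    chgvs: str
    phgvs: str | None
    filter_status: str
    depth: int
    pop_af: Mapping[str, float]
    evidence: EvidenceSet
    novel: bool = False
    subcontinent: bool = False
    occurrences: int = 0
    kind_call: KindCall = field(init=False)

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise ValidationError("variant with empty variant_id")
        if self.depth < 0:
            raise ValidationError(f"{self.variant_id}: negative depth")
        if self.occurrences < 0:
            raise ValidationError(f"{self.variant_id}: negative occurrence count")
        for source, af in self.pop_af.items():
            if not (0.0 <= af <= 1.0):
                raise ValidationError(
                    f"{self.variant_id}: allele frequency {af} for {source!r} outside [0, 1]"
                )
        if self.novel and self.subcontinent:
            raise ValidationError(
                f"{self.variant_id}: a novel variant cannot also be previously "
                "described (subcontinent flag)"
            )
        object.__setattr__(self, "kind_call", parse_hgvs_kind(self.chgvs, self.phgvs))

    @property
    def kind(self) -> VariantKind:
        return self.kind_call.kind


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    token = str(value).strip().lower()
    if token in ("true", "1", "yes"):
        return True
    if token in ("false", "0", "no", "", "nan"):
        return False
    raise ParseError(f"unparseable boolean flag: {value!r}")


def load_catalogue(
    source: str | PathLike | io.IOBase | pd.DataFrame,
    panel: Iterable[PanelGene] | None = None,
) -> list[AnnotatedVariant]:
    """Load a variant catalogue from TSV or a DataFrame.

    Frequency columns are any column named ``af_<source>``; blank cells mean
    the source has no record of the variant (treated downstream as rare).
    If ``panel`` is given, every catalogued gene must be on it; offenders
    are listed in the :class:`ValidationError`.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", dtype=str, comment="#")
    if df.empty:
        return []
    af_cols = [c for c in df.columns if c.startswith("af_")]
    variants: list[AnnotatedVariant] = []
    for _, row in df.iterrows():
        pop_af = {}
        for col in af_cols:
            cell = row[col]
            if pd.notna(cell) and str(cell).strip() != "":
                pop_af[col[3:]] = float(cell)
        phgvs = row.get("phgvs")
        variants.append(
            AnnotatedVariant(
                variant_id=str(row["variant_id"]).strip(),
                gene=str(row["gene"]).strip(),
                transcript=str(row["transcript"]).strip(),
                chgvs="" if pd.isna(row.get("chgvs")) else str(row["chgvs"]).strip(),
                phgvs=None if pd.isna(phgvs) or str(phgvs).strip() == "" else str(phgvs).strip(),
                filter_status=str(row["filter_status"]).strip(),
                depth=int(row["depth"]),
                pop_af=pop_af,
                evidence=parse_evidence("" if pd.isna(row.get("evidence")) else row["evidence"]),
                novel=_parse_bool(row.get("novel", False)),
                subcontinent=_parse_bool(row.get("subcontinent", False)),
                occurrences=int(row.get("occurrences", 0)),
            )
        )
    ids = [v.variant_id for v in variants]
    dup = sorted({i for i in ids if ids.count(i) > 1})
    if dup:
        raise ValidationError(f"duplicate variant_id in catalogue: {dup}")
    if panel is not None:
        known = {g.symbol for g in panel}
        offenders = sorted({v.gene for v in variants if v.gene not in known})
        if offenders:
            raise ValidationError(f"catalogued genes not on the panel: {offenders}")
    return variants


def catalogue_to_frame(variants: Iterable[AnnotatedVariant]) -> pd.DataFrame:
    """Tabular view of a catalogue (the serialization schema)."""
    variants = list(variants)
    sources = sorted({s for v in variants for s in v.pop_af})
    rows = []
    for v in variants:
        row = {
            "variant_id": v.variant_id,
            "gene": v.gene,
            "transcript": v.transcript,
            "chgvs": v.chgvs,
            "phgvs": v.phgvs if v.phgvs is not None else "",
            "kind": v.kind.value,
            "filter_status": v.filter_status,
            "depth": v.depth,
            "evidence": v.evidence.canonical(),
            "novel": v.novel,
            "subcontinent": v.subcontinent,
            "occurrences": v.occurrences,
        }
        for s in sources:
            row[f"af_{s}"] = v.pop_af.get(s, math.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def write_catalogue(variants: Iterable[AnnotatedVariant], path: str | PathLike | io.IOBase) -> None:
    """Serialize a catalogue to TSV (round-trips with :func:`load_catalogue`)."""
    catalogue_to_frame(variants).to_csv(path, sep="\t", index=False)
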