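"""Gene panel data model and I/O.

A screening panel is a list of genes, each tied to one disorder, a
transcript, an OMIM number and an inheritance mode: autosomal recessive
(AR), X-linked (XL), or dual autosomal dominant / recessive (AD_AR, e.g.
familial hypercholesterolemia screened on a carrier panel because early
treatment is life-saving). Inheritance is taken verbatim from the panel
document — no gene-knowledge lookup — so runs are reproducible.

Panels are stored as tab-separated text with a header line::

    symbol  transcript  disorder_name  omim_id  inheritance
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from enum import Enum
from os import PathLike
from typing import Iterable

import pandas as pd

from carrierscreen.errors import ParseError, ValidationError

__all__ = ["Inheritance", "PanelGene", "load_panel", "write_panel", "mode_tally"]

_COLUMNS = ["symbol", "transcript", "disorder_name", "omim_id", "inheritance"]


class Inheritance(str, Enum):
    AR = "AR"
    XL = "XL"
    AD_AR = "AD_AR"


@dataclass(frozen=True)
class PanelGene:
    symbol: str
    transcript: str
    disorder_name: str
    omim_id: str
    inheritance: Inheritance

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValidationError("panel gene with empty symbol")
        if not isinstance(self.inheritance, Inheritance):
            object.__setattr__(self, "inheritance", _parse_mode(self.inheritance, self.symbol))


def _parse_mode(token: str, symbol: str) -> Inheritance:
    try:
        return Inheritance(str(token).strip().replace("/", "_").upper())
    except ValueError:
        raise ParseError(f"unknown inheritance token {token!r} for gene {symbol!r}") from None


def load_panel(source: str | PathLike | io.IOBase | pd.DataFrame) -> list[PanelGene]:
    """Load a panel from a TSV path/handle or a DataFrame.

    Raises :class:`ParseError` on malformed records (naming the record) and
    :class:`ValidationError` on duplicate gene symbols. An empty document
    yields an empty panel.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", dtype=str, comment="#")
    if df.empty:
        return []
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"panel document lacks columns: {missing}")
    genes: list[PanelGene] = []
    for _, row in df.iterrows():
        if row[_COLUMNS].isna().any():
            raise ParseError(f"malformed panel record: {row.to_dict()}")
        genes.append(
            PanelGene(
                symbol=str(row["symbol"]).strip(),
                transcript=str(row["transcript"]).strip(),
                disorder_name=str(row["disorder_name"]).strip(),
                omim_id=str(row["omim_id"]).strip(),
                inheritance=_parse_mode(row["inheritance"], row["symbol"]),
            )
        )
    seen: set[str] = set()
    dups = sorted({g.symbol for g in genes if g.symbol in seen or seen.add(g.symbol)})
    if dups:
        raise ValidationError(f"duplicate gene symbols in panel: {dups}")
    return genes


def write_panel(genes: Iterable[PanelGene], path: str | PathLike | io.IOBase) -> None:
    """Serialize a panel back to TSV (round-trips with :func:`load_panel`)."""
    df = pd.DataFrame(
        [
            {
                "symbol": g.symbol,
                "transcript": g.transcript,
                "disorder_name": g.disorder_name,
                "omim_id": g.omim_id,
                "inheritance": g.inheritance.value,
            }
            for g in genes
        ],
        columns=_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def mode_tally(genes: Iterable[PanelGene]) -> dict[Inheritance, int]:
    """Count of panel genes per inheritance mode."""
    tally = {mode: 0 for mode in Inheritance}
    for g in genes:
        tally[g.inheritance] += 1
    return tally
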