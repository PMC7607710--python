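"""HGVS-based variant consequence typing.

Carrier-screening reports describe variants by transcript-level HGVS
(cDNA and, when coding, protein change). For filtering purposes the pipeline
only needs a coarse consequence class; this module derives it from the HGVS
strings alone, with no reference-sequence validation.

The classifier is deliberately total: any string it cannot interpret maps to
``VariantKind.OTHER`` with a logged warning, never an exception, because a
screening run must not abort on one exotic description. It accepts both
canonical HGVS (``c.1001G>T``) and the spaced dialect common in printed
tables (``c.1001G > T``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum

logger = logging.getLogger(__name__)

__all__ = ["VariantKind", "KindCall", "parse_hgvs_kind"]


class VariantKind(str, Enum):
    """Coarse consequence class derived from HGVS nomenclature."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_REGION = "splice_region"
    OTHER = "other"


@dataclass(frozen=True)
class KindCall:
    """A consequence call; ``intronic_offset`` is set only for splice-region
    calls and gives the distance (in bases, >= 1) from the nearest exon edge."""

    kind: VariantKind
    intronic_offset: int | None = None

    def __post_init__(self) -> None:
        if self.kind is VariantKind.SPLICE_REGION:
            if self.intronic_offset is None or self.intronic_offset < 1:
                raise ValueError("splice_region requires intronic_offset >= 1")
        elif self.intronic_offset is not None:
            raise ValueError("intronic_offset only valid for splice_region")


# three-letter amino-acid codes (Sec/Pyl included; Xaa = unknown)
_AA3 = (
    "Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|"
    "Tyr|Val|Sec|Pyl|Xaa"
)

_P_SUB = re.compile(rf"^p\.\(?({_AA3})(\d+)({_AA3}|Ter|\*)\)?$")
_P_FS = re.compile(rf"^p\.\(?({_AA3})(\d+).*fs", re.IGNORECASE)
_P_INDEL = re.compile(
    rf"^p\.\(?({_AA3})(\d+)(_({_AA3})(\d+))?(del|dup|ins|delins)[A-Za-z]*\)?$"
)
# intronic cDNA position: c.123+5..., c.123-6G>A, also ranges c.123+1_123+4del
_C_INTRONIC = re.compile(r"^c\.\*?-?\d+([+-])(\d+)")


def _normalize(text: str) -> str:
    return re.sub(r"\s+", "", text.strip())


def parse_hgvs_kind(chgvs: str, phgvs: str | None = None) -> KindCall:
    """Classify a variant from its cDNA and (optional) protein HGVS.

    Protein-level evidence wins when present: a substitution to a residue is
    missense, to a stop (``Ter``/``*``) nonsense, an in-frame del/dup/ins an
    in-frame indel (frameshifts fall through to ``other``). Without a protein
    change, an intronic cDNA offset (``c.###+N`` / ``c.###-N``) yields
    ``splice_region`` with that offset. Anything else — including unparseable
    input — is ``other``.
    """
    p = _normalize(phgvs) if phgvs else ""
    c = _normalize(chgvs) if chgvs else ""

    if p:
        m = _P_SUB.match(p)
        if m:
            if m.group(3) in ("Ter", "*"):
                return KindCall(VariantKind.NONSENSE)
            return KindCall(VariantKind.MISSENSE)
        if _P_FS.match(p):
            return KindCall(VariantKind.OTHER)
        if _P_INDEL.match(p):
            return KindCall(VariantKind.INFRAME_INDEL)
        # protein string present but unrecognised: fall back to cDNA
        if not c:
            logger.warning("unrecognised protein HGVS %r; typed as other", phgvs)
            return KindCall(VariantKind.OTHER)

    if c:
        m = _C_INTRONIC.match(c)
        if m:
            return KindCall(VariantKind.SPLICE_REGION, intronic_offset=int(m.group(2)))

    if not p and not c:
        return KindCall(VariantKind.OTHER)
    logger.warning("could not type variant (c=%r, p=%r); typed as other", chgvs, phgvs)
    return KindCall(VariantKind.OTHER)
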