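"""ACMG/AMP evidence combination engine.

Evidence codes (PVS1, PS1-4, PM1-6, PP1-5 on the pathogenic side; BA1,
BS1-4, BP1-7 on the benign side) are parsed from ``+``-separated strings as
printed in variant tables, tallied by strength tier, and combined into the
five-tier classification (Pathogenic / Likely pathogenic / VUS / Likely
benign / Benign) by the standard combining rules. Only Pathogenic and
Likely pathogenic variants are reportable in carrier screening; VUS are
suppressed.

The engine consumes evidence codes as given — assigning evidence to a
variant is upstream curation and out of scope here.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from enum import Enum

from carrierscreen.errors import ParseError

__all__ = ["EvidenceSet", "Classification", "parse_evidence", "combine", "classify_catalogue"]

# code grammar: tier prefix + index within its allowed range
_CODE_RE = re.compile(r"^(PVS1|PS[1-4]|PM[1-6]|PP[1-5]|BA1|BS[1-4]|BP[1-7])$")

_TIER_OF = {"PVS": "pvs", "PS": "ps", "PM": "pm", "PP": "pp", "BA": "ba", "BS": "bs", "BP": "bp"}


class Classification(Enum):
    PATHOGENIC = "Pathogenic"
    LIKELY_PATHOGENIC = "Likely pathogenic"
    VUS = "VUS"
    LIKELY_BENIGN = "Likely benign"
    BENIGN = "Benign"

    @property
    def reportable(self) -> bool:
        """Carrier screening reports only P and LP findings."""
        return self in (Classification.PATHOGENIC, Classification.LIKELY_PATHOGENIC)


@dataclass(frozen=True)
class EvidenceSet:
    """A validated set of ACMG evidence codes with per-tier tallies."""

    codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen: Counter[str] = Counter(self.codes)
        for code, n in seen.items():
            if not _CODE_RE.match(code):
                raise ParseError(f"unknown ACMG evidence code: {code!r}")
            if n > 1:
                raise ParseError(f"duplicate ACMG evidence code: {code!r}")

    def _tier(self, code: str) -> str:
        return _TIER_OF[re.match(r"[A-Z]+", code).group(0)]

    def tier_counts(self) -> dict[str, int]:
        """Tallies keyed pvs/ps/pm/pp/ba/bs/bp."""
        counts = dict.fromkeys(("pvs", "ps", "pm", "pp", "ba", "bs", "bp"), 0)
        for code in self.codes:
            counts[self._tier(code)] += 1
        return counts

    @property
    def n_pvs(self) -> int:
        return self.tier_counts()["pvs"]

    @property
    def n_ps(self) -> int:
        return self.tier_counts()["ps"]

    @property
    def n_pm(self) -> int:
        return self.tier_counts()["pm"]

    @property
    def n_pp(self) -> int:
        return self.tier_counts()["pp"]

    @property
    def n_ba(self) -> int:
        return self.tier_counts()["ba"]

    @property
    def n_bs(self) -> int:
        return self.tier_counts()["bs"]

    @property
    def n_bp(self) -> int:
        return self.tier_counts()["bp"]

    def canonical(self) -> str:
        """Canonical rendering: codes sorted by tier strength then index,
        joined by `` + `` (the dialect printed in variant tables)."""
        order = {"PVS": 0, "PS": 1, "PM": 2, "PP": 3, "BA": 4, "BS": 5, "BP": 6}

        def key(code: str) -> tuple[int, int]:
            m = re.match(r"([A-Z]+)(\d+)", code)
            return order[m.group(1)], int(m.group(2))

        return " + ".join(sorted(self.codes, key=key))


def parse_evidence(text: str) -> EvidenceSet:
    """Parse a ``+``-separated evidence string (``"PVS1 + PS3 + PM1"``).

    Case-insensitive; arbitrary whitespace around tokens; the empty string
    yields an empty set. Unknown or duplicated codes raise :class:`ParseError`
    naming the offending token.
    """
    if text is None or not text.strip():
        return EvidenceSet()
    tokens = [t.strip().upper() for t in text.split("+")]
    if any(not t for t in tokens):
        raise ParseError(f"empty evidence token in {text!r}")
    return EvidenceSet(codes=tuple(tokens))


def combine(evidence: EvidenceSet) -> Classification:
    """Combine evidence tiers into a classification.

    Depends only on per-tier counts, never on which specific code within a
    tier. A satisfied pathogenic rule co-occurring with a satisfied benign
    rule is conflicting evidence and yields VUS; so does evidence satisfying
    no rule at all.
    """
    t = evidence.tier_counts()
    pvs, ps, pm, pp = t["pvs"], t["ps"], t["pm"], t["pp"]
    ba, bs, bp = t["ba"], t["bs"], t["bp"]

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs >= 1 and pm >= 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs == 1 and bp >= 1) or bp >= 2

    path_rule = pathogenic or likely_pathogenic
    benign_rule = benign or likely_benign
    if path_rule and benign_rule:
        return Classification.VUS
    if pathogenic:
        return Classification.PATHOGENIC
    if likely_pathogenic:
        return Classification.LIKELY_PATHOGENIC
    if benign:
        return Classification.BENIGN
    if likely_benign:
        return Classification.LIKELY_BENIGN
    return Classification.VUS


def classify_catalogue(variants) -> dict[str, Classification]:
    """Classify every variant in a catalogue; returns variant_id -> tier."""
    return {v.variant_id: combine(v.evidence) for v in variants}
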