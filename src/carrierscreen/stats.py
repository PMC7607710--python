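"""Carrier-frequency estimation and catalogue summary statistics.

Carrier frequencies are binomial proportions n/N over the screened cohort,
reported as a percentage, as the familiar "1 in N/n", and with a Wilson
score interval. The Wilson interval inverts the normal score test: with
p-hat = n/N and z the two-sided normal quantile,

    ( p-hat + z^2/2N  +/-  z * sqrt( p-hat(1-p-hat)/N + z^2/4N^2 ) )
    -----------------------------------------------------------------
                          1 + z^2/N

clamped to [0, 1]. It behaves well at the small counts typical of rare
carrier states (n of 1-9 in a cohort of 200), where the Wald interval
collapses or crosses zero. At 95% confidence z = 1.96 exactly (the
convention used in published screening tables); other levels use the
normal quantile.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import math

from scipy.stats import norm

from carrierscreen.carriers import CarrierCall
from carrierscreen.catalogue import AnnotatedVariant
from carrierscreen.errors import ValidationError
from carrierscreen.panel import PanelGene

__all__ = ["FrequencyEstimate", "CatalogueSummary", "wilson_ci", "frequency_table", "summarize_catalogue"]


def wilson_ci(n: int, N: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for n successes out of N, as fractions.

    Raises on N < 1, n outside [0, N], or conf outside (0, 1). The interval
    always contains the point estimate n/N and is clamped to [0, 1].
    """
    if N < 1:
        raise ValidationError("cohort size N must be >= 1")
    if not (0 <= n <= N):
        raise ValidationError("carrier count n must satisfy 0 <= n <= N")
    if not (0.0 < conf < 1.0):
        raise ValidationError("confidence level must lie in (0, 1)")
    z = 1.96 if conf == 0.95 else float(norm.ppf(0.5 + conf / 2.0))
    phat = n / N
    z2 = z * z
    denom = 1.0 + z2 / N
    center = phat + z2 / (2.0 * N)
    half = z * math.sqrt(phat * (1.0 - phat) / N + z2 / (4.0 * N * N))
    # n=0 and n=N endpoints are algebraically exact; avoid float residue
    lower = 0.0 if n == 0 else max(0.0, (center - half) / denom)
    upper = 1.0 if n == N else min(1.0, (center + half) / denom)
    return lower, upper


@dataclass(frozen=True)
class FrequencyEstimate:
    """One carrier-frequency row: n/N with percent, 1-in form and Wilson CI
    bounds on the percent scale."""

    label: str
    n: int
    N: int
    conf: float = 0.95

    def __post_init__(self) -> None:
        if not (0 <= self.n <= self.N):
            raise ValidationError(f"{self.label}: need 0 <= n <= N")

    @property
    def pct(self) -> float:
        return 100.0 * self.n / self.N

    @property
    def one_in(self) -> float | None:
        return None if self.n == 0 else self.N / self.n

    @property
    def ci_lower_pct(self) -> float:
        return 100.0 * wilson_ci(self.n, self.N, self.conf)[0]

    @property
    def ci_upper_pct(self) -> float:
        return 100.0 * wilson_ci(self.n, self.N, self.conf)[1]


@dataclass(frozen=True)
class CatalogueSummary:
    distinct_variants: int
    total_occurrences: int
    kind_pct: dict[str, float]
    novel_count: int
    reported_subcontinent_pct: float | None


def frequency_table(
    calls: Sequence[CarrierCall],
    cohort_size: int,
    panel: Sequence[PanelGene] | None = None,
    conf: float = 0.95,
    by_disorder: bool = False,
) -> list[FrequencyEstimate]:
    """Carrier-frequency rows per gene (default) or per disorder, plus a
    ``total`` row counting distinct carrier individuals.

    Only carrier-category calls enter the table — affected-risk findings
    (dominant alleles, hemizygotes, possible compound heterozygotes) are a
    different clinical statement and are reported separately. Rows are
    sorted by descending count then label.
    """
    if cohort_size < 1:
        raise ValidationError("cohort_size must be >= 1")
    carrier_calls = [c for c in calls if c.category == "carrier"]
    counts: dict[str, int] = defaultdict(int)
    for call in carrier_calls:
        counts[call.disorder_name if by_disorder else call.gene] += 1
    rows = [
        FrequencyEstimate(label=label, n=n, N=cohort_size, conf=conf)
        for label, n in counts.items()
    ]
    rows.sort(key=lambda r: (-r.n, r.label))
    total = len({c.individual_id for c in carrier_calls})
    rows.append(FrequencyEstimate(label="total", n=total, N=cohort_size, conf=conf))
    return rows


def summarize_catalogue(catalogue: Iterable[AnnotatedVariant]) -> CatalogueSummary:
    """Distinct-variant count, total observations, consequence-kind
    percentages, novel count, and the share of *previously reported*
    variants (denominator: distinct minus novel) already described from
    the Indian subcontinent."""
    variants = list(catalogue)
    distinct = len(variants)
    occurrences = sum(v.occurrences for v in variants)
    kind_counts: dict[str, int] = defaultdict(int)
    for v in variants:
        kind_counts[v.kind.value] += 1
    kind_pct = (
        {k: 100.0 * c / distinct for k, c in sorted(kind_counts.items())} if distinct else {}
    )
    novel = sum(v.novel for v in variants)
    reported = distinct - novel
    sub_pct = 100.0 * sum(v.subcontinent for v in variants) / reported if reported else None
    return CatalogueSummary(
        distinct_variants=distinct,
        total_occurrences=occurrences,
        kind_pct=kind_pct,
        novel_count=novel,
        reported_subcontinent_pct=sub_pct,
    )
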