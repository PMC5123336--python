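"""Allele-frequency estimators and public-resource threshold evaluation.

The central quantity is the ascertainment-corrected cohort allele frequency

    SGP_AF = no_het / (2 * (no_screened - no_hom))

which drops every homozygous-alternate individual from both numerator and
denominator.  Because a cohort recruited through diseased probands is
enriched for homozygous pathogenic genotypes, the naive allele count
(no_het + 2*no_hom) / (2*no_screened) overstates the population frequency;
removing homozygotes makes the estimate invariant to how many affected
homozygotes were ascertained.

Both estimators are computed in exact rational arithmetic
(:class:`fractions.Fraction`) so the homozygote-invariance property holds
bit-for-bit, not merely to floating-point tolerance.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

from .variant_io import CohortCounts, PublicFrequency

__all__ = [
    "DegenerateCountsError",
    "FreqSource",
    "FrequencyVerdict",
    "sgp_allele_frequency",
    "naive_allele_frequency",
    "evaluate_public",
]


class DegenerateCountsError(ValueError):
    """Raised when every screened individual is a homozygote, so the
    homozygote-excluding estimator has a zero denominator (an all-homozygote
    site carries no heterozygote information)."""


class FreqSource(enum.Enum):
    S1000G = "1000g"
    EXAC = "exac"
    KAVIAR = "kaviar"
    COHORT = "cohort"
    NONE = "none"


_ROLE_TO_SOURCE = {
    "1000g": FreqSource.S1000G,
    "exac": FreqSource.EXAC,
    "kaviar": FreqSource.KAVIAR,
}
_ROLE_TO_AF_FIELD = {"1000g": "af_1000g", "exac": "af_exac", "kaviar": "af_kaviar"}


def sgp_allele_frequency(counts: CohortCounts) -> Fraction:
    """Cohort allele frequency excluding homozygous-alternate individuals.

    Returns ``no_het / (2 * (no_screened - no_hom))`` as an exact
    :class:`~fractions.Fraction`.  Appending k homozygotes to the cohort
    (raising ``no_hom`` and ``no_screened`` by k each) leaves the value
    unchanged, which is the estimator's purpose: proband ascertainment adds
    homozygotes, not heterozygotes.

    Raises
    ------
    DegenerateCountsError
        If ``no_screened <= no_hom`` (all screened individuals homozygous).
    """
    denominator = counts.no_screened - counts.no_hom
    if denominator <= 0:
        raise DegenerateCountsError(
            f"all {counts.no_screened} screened individuals are homozygous at "
            f"{counts.key}; SGP_AF undefined"
        )
    value = Fraction(counts.no_het, 2 * denominator)
    # no_het <= no_screened - no_hom by the CohortCounts invariant, so <= 1/2
    assert 0 <= value <= 1
    return value


def naive_allele_frequency(counts: CohortCounts) -> Fraction:
    """Uncorrected allele count ``(no_het + 2*no_hom) / (2*no_screened)``.

    This is the estimator the homozygote-excluding form corrects: it rises
    monotonically as ascertained homozygotes are appended to the cohort.
    """
    if counts.no_screened <= 0:
        raise DegenerateCountsError(f"no screened individuals at {counts.key}")
    return Fraction(counts.no_het + 2 * counts.no_hom, 2 * counts.no_screened)


@dataclass(frozen=True)
class FrequencyVerdict:
    """Outcome of thresholding one variant against the public resources.

    ``source``/``value`` identify the first resource in the configured order
    whose frequency crossed the threshold (the resource that "caught" the
    variant); when none crossed they carry the maximum present frequency.
    ``max_af``/``max_source`` always carry the maximum, as provenance.
    ``crossed`` is True iff some resource reached the threshold, and
    ``hom_support`` is True iff a homozygote-reporting resource shows at
    least one homozygote.
    """

    value: Optional[float]
    source: FreqSource
    crossed: bool
    hom_support: bool
    max_af: Optional[float] = None
    max_source: FreqSource = FreqSource.NONE

    @property
    def missing(self) -> bool:
        return self.source is FreqSource.NONE


def evaluate_public(
    freq: Optional[PublicFrequency],
    threshold: float,
    order: Sequence[str] = ("1000g", "exac", "kaviar"),
) -> FrequencyVerdict:
    """Threshold a variant's public frequencies in sequential source order.

    Scans the resources in ``order`` and reports the first whose frequency is
    ``>= threshold``.  If none crosses, reports the maximum present frequency
    (ties broken by ``order``); with no frequency present at all, the verdict
    has source ``NONE`` and a missing value — a variant absent from public
    resources can never satisfy a frequency threshold.
    """
    if sorted(order) != ["1000g", "exac", "kaviar"]:
        raise ValueError(f"order must be a permutation of the three roles, got {order!r}")
    if freq is None:
        return FrequencyVerdict(
            value=None, source=FreqSource.NONE, crossed=False, hom_support=False
        )
    hom_support = any(
        count is not None and count >= 1 for count in (freq.hom_1000g, freq.hom_exac)
    )
    max_af: Optional[float] = None
    max_source = FreqSource.NONE
    for role in order:
        af = getattr(freq, _ROLE_TO_AF_FIELD[role])
        if af is not None and (max_af is None or af > max_af):
            max_af, max_source = af, _ROLE_TO_SOURCE[role]
    for role in order:
        af = getattr(freq, _ROLE_TO_AF_FIELD[role])
        if af is not None and af >= threshold:
            return FrequencyVerdict(
                value=af,
                source=_ROLE_TO_SOURCE[role],
                crossed=True,
                hom_support=hom_support,
                max_af=max_af,
                max_source=max_source,
            )
    if max_af is None:
        return FrequencyVerdict(
            value=None, source=FreqSource.NONE, crossed=False, hom_support=hom_support
        )
    return FrequencyVerdict(
        value=max_af,
        source=max_source,
        crossed=False,
        hom_support=hom_support,
        max_af=max_af,
        max_source=max_source,
    )
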