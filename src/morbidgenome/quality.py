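"""Two-route quality gate for cohort variant observations.

A cohort observation may contribute to reclassification only if it was
called on both sequencing platforms (Ion Proton and Illumina), or it is a
Proton-only SNV call meeting strict thresholds — quality score >= 1000,
depth >= 150 — and confirmed by Sanger sequencing.  Thresholds are
inclusive ("minimum" values).  Indels and multi-nucleotide substitutions
never pass the Proton-only route.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .variant_io import CohortCounts, QualityEvidence

__all__ = [
    "Route",
    "QualityDecision",
    "MIN_QUALITY_SCORE",
    "MIN_DEPTH",
    "passes_quality",
    "filter_cohort",
]

MIN_QUALITY_SCORE = 1000.0
MIN_DEPTH = 150


class Route(enum.Enum):
    BOTH_PLATFORMS = "both_platforms"
    PROTON_STRICT = "proton_strict"


@dataclass(frozen=True)
class QualityDecision:
    passed: bool
    route: Optional[Route]
    failed_conditions: tuple = ()


def passes_quality(ev: QualityEvidence) -> QualityDecision:
    """Evaluate the two acceptance routes for one quality record.

    Cross-platform concordance alone is sufficient; otherwise every strict
    Proton-only condition must hold.  The returned decision lists which
    strict conditions failed, for the exclusion log.
    """
    if ev.called_proton and ev.called_illumina:
        return QualityDecision(True, Route.BOTH_PLATFORMS)
    failed = []
    if not ev.called_proton:
        failed.append("not_called_on_proton")
    if not ev.is_snv:
        failed.append("not_snv")
    if ev.quality_score < MIN_QUALITY_SCORE:
        failed.append(f"quality_score<{MIN_QUALITY_SCORE:g}")
    if ev.depth < MIN_DEPTH:
        failed.append(f"depth<{MIN_DEPTH}")
    if not ev.sanger_confirmed:
        failed.append("no_sanger_confirmation")
    if not failed:
        return QualityDecision(True, Route.PROTON_STRICT)
    return QualityDecision(False, None, tuple(failed))


def filter_cohort(
    cohort: Sequence[CohortCounts],
    quality: Iterable[QualityEvidence] | Mapping,
    *,
    keep_unevidenced: bool = False,
):
    """Drop cohort rows whose observation fails the quality gate.

    Parameters
    ----------
    cohort
        Cohort count rows, in input order (preserved).
    quality
        Quality records, or a mapping from key to record.
    keep_unevidenced
        Cohort rows with no quality record are excluded by default; set True
        to retain them (they are then trusted without platform evidence).

    Returns
    -------
    (kept, exclusion_log, both_platform_fraction)
        ``kept`` is a subset of ``cohort`` in order; ``exclusion_log`` is a
        list of ``(key, reason)`` pairs; ``both_platform_fraction`` is the
        fraction of kept rows accepted via cross-platform concordance (None
        for an empty result) — around 0.99 in practice on dual-platform
        cohorts.
    """
    if isinstance(quality, Mapping):
        quality_index = dict(quality)
    else:
        quality_index = {q.key: q for q in quality}
    kept = []
    log = []
    n_both = 0
    for row in cohort:
        ev = quality_index.get(row.key)
        if ev is None:
            if keep_unevidenced:
                kept.append(row)
            else:
                log.append((row.key, "no evidence"))
            continue
        decision = passes_quality(ev)
        if decision.passed:
            kept.append(row)
            if decision.route is Route.BOTH_PLATFORMS:
                n_both += 1
        else:
            log.append((row.key, ";".join(decision.failed_conditions)))
    fraction = n_both / len(kept) if kept else None
    return kept, log, fraction
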