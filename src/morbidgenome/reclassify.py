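"""Reclassification engine: the four frequency/zygosity criteria, the
inheritance-aware advisory rule, the BRCA screen, and the reciprocal
pathogenic-homozygote check.

The four criteria are evaluated in fixed precedence, first match wins,
which makes them mutually exclusive strata:

* C1 — public allele frequency >= 5% in any of 1000 Genomes/ExAC/Kaviar
  (scanned in that order): benign outright.
* C2 — cohort frequency (homozygote-excluding SGP_AF) >= 5% while every
  public frequency is < 5% (a population-specific common allele the public
  resources under-sample): benign.
* C3 — cohort frequency >= 1% and at least one homozygote in an individual
  lacking the reported phenotype: benign.
* C4 — cohort frequency < 1% but still observed homozygous in a
  phenotype-free individual: designated "BS2-only" — benign-supporting
  zygosity evidence without the frequency evidence, deliberately not
  upgraded to (likely) benign.

A variant matching none of these is left unchanged.  A missing public
frequency can never cross a threshold; a missing cohort row contributes
neither frequency nor homozygote evidence.
"""
from __future__ import annotations

import enum
import hashlib
import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .frequency import (
    DegenerateCountsError,
    FreqSource,
    FrequencyVerdict,
    evaluate_public,
    naive_allele_frequency,
    sgp_allele_frequency,
)
from .quality import filter_cohort
from .variant_io import (
    AssertionClass,
    CohortCounts,
    JoinedRecord,
    MorbidAssertion,
    Source,
    ThresholdConfig,
    join_evidence,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Criterion",
    "Outcome",
    "BrcaCategory",
    "ReclassificationResult",
    "BrcaVerdict",
    "ReciprocalRecord",
    "RunResult",
    "evaluate_criteria",
    "acmg_inheritance_rule",
    "screen_brca",
    "reciprocal_pathogenic_check",
    "run_reclassification",
    "write_results_table",
    "read_results_table",
]


class Criterion(enum.Enum):
    C1 = "C1"
    C2 = "C2"
    C3 = "C3"
    C4 = "C4"
    NONE = "none"


class Outcome(enum.Enum):
    BENIGN = "benign"
    BS2_ONLY = "bs2_only"
    UNCHANGED = "unchanged"


_CRITERION_OUTCOME = {
    Criterion.C1: Outcome.BENIGN,
    Criterion.C2: Outcome.BENIGN,
    Criterion.C3: Outcome.BENIGN,
    Criterion.C4: Outcome.BS2_ONLY,
    Criterion.NONE: Outcome.UNCHANGED,
}

#: Assertion classes eligible for reclassification by default; HGMD DP/DFP
#: rows are parsed but excluded unless explicitly enabled.
ELIGIBLE_CLASSES = frozenset(
    {
        AssertionClass.DM,
        AssertionClass.DM_Q,
        AssertionClass.PATHOGENIC,
        AssertionClass.LIKELY_PATHOGENIC,
        AssertionClass.VOUS,
    }
)


@dataclass(frozen=True)
class ReclassificationResult:
    """Criterion match and outcome for one assertion, with evidence trail."""

    assertion: MorbidAssertion
    criterion: Criterion
    outcome: Outcome
    public_verdict: FrequencyVerdict
    sgp_af: Optional[Fraction] = None
    naive_af: Optional[Fraction] = None
    hom_phenotype_free: Optional[int] = None
    advisory_acmg: Optional[bool] = None
    evidence: dict = field(default_factory=dict)
    warning: Optional[str] = None

    def __post_init__(self) -> None:
        if _CRITERION_OUTCOME[self.criterion] is not self.outcome:
            raise ValueError(
                f"criterion {self.criterion.value} cannot carry outcome "
                f"{self.outcome.value}"
            )


class BrcaCategory(enum.Enum):
    BENIGN = "benign"
    FREQUENT_ONLY = "frequent_only"
    BS2_ONLY = "bs2_only"
    UNCHANGED = "unchanged"


@dataclass(frozen=True)
class BrcaVerdict:
    assertion: MorbidAssertion
    category: BrcaCategory
    sgp_af: Optional[Fraction] = None
    fanconi_free_hom: int = 0
    evidence: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ReciprocalRecord:
    """A pathogenic assertion observed homozygous in the cohort."""

    assertion: MorbidAssertion
    no_hom: int
    phenotype_free_hom: int
    is_violation: bool


def _frac(threshold) -> Fraction:
    """Exact rational view of a decimal threshold.

    Thresholds like 0.05 are decimal conventions (5%); comparing the exact
    rational cohort estimate against the binary float would misjudge the
    inclusive boundary, so floats are interpreted via their decimal string.
    """
    if isinstance(threshold, float):
        return Fraction(str(threshold))
    return Fraction(threshold)


def _cohort_frequencies(cohort: Optional[CohortCounts]):
    """(sgp_af, naive_af, warning) for a possibly absent/degenerate row."""
    if cohort is None:
        return None, None, None
    try:
        return sgp_allele_frequency(cohort), naive_allele_frequency(cohort), None
    except DegenerateCountsError as exc:
        return None, None, str(exc)


def evaluate_criteria(
    record: JoinedRecord,
    cfg: ThresholdConfig = ThresholdConfig(),
    *,
    include_dp_dfp: bool = False,
) -> ReclassificationResult:
    """Apply the four criteria, in precedence order, to one joined record.

    The record must have survived the quality gate (its cohort row, if any,
    is trusted here).  A degenerate cohort denominator (all screened
    individuals homozygous) yields criterion NONE with a warning rather than
    an error.
    """
    cls = record.assertion.assertion_class
    if cls not in ELIGIBLE_CLASSES and not include_dp_dfp:
        raise ValueError(
            f"assertion class {cls.value!r} is excluded from reclassification "
            "(enable include_dp_dfp to score DP/DFP rows)"
        )
    verdict = evaluate_public(record.public, cfg.af_benign_public, cfg.source_order)
    sgp, naive, warning = _cohort_frequencies(record.cohort)
    hom_free = record.cohort.hom_phenotype_free if record.cohort is not None else None

    if verdict.crossed:
        criterion = Criterion.C1
    elif sgp is not None and sgp >= _frac(cfg.af_cohort_common):
        # every public AF is < af_benign_public here (C1 did not fire;
        # missing public evidence counts as below threshold)
        criterion = Criterion.C2
    elif sgp is not None and sgp >= _frac(cfg.af_cohort_low) and (hom_free or 0) >= 1:
        criterion = Criterion.C3
    elif sgp is not None and sgp < _frac(cfg.af_cohort_low) and (hom_free or 0) >= 1:
        criterion = Criterion.C4
    else:
        criterion = Criterion.NONE

    evidence = {
        "public": {
            "max_af": verdict.max_af,
            "max_source": verdict.max_source.value,
            "crossed_at": cfg.af_benign_public if verdict.crossed else None,
            "caught_by": verdict.source.value if verdict.crossed else None,
            "hom_support": verdict.hom_support,
        },
        "cohort": {
            "sgp_af": float(sgp) if sgp is not None else None,
            "naive_af": float(naive) if naive is not None else None,
            "hom_phenotype_free": hom_free,
            "degenerate": warning is not None,
        },
        "thresholds": {
            "af_benign_public": cfg.af_benign_public,
            "af_cohort_common": cfg.af_cohort_common,
            "af_cohort_low": cfg.af_cohort_low,
        },
    }
    if warning is not None:
        evidence["warning"] = warning
    return ReclassificationResult(
        assertion=record.assertion,
        criterion=criterion,
        outcome=_CRITERION_OUTCOME[criterion],
        public_verdict=verdict,
        sgp_af=sgp,
        naive_af=naive,
        hom_phenotype_free=hom_free,
        advisory_acmg=acmg_inheritance_rule(record, cfg),
        evidence=evidence,
        warning=warning,
    )


def acmg_inheritance_rule(record: JoinedRecord, cfg: ThresholdConfig) -> bool:
    """Inheritance-aware public-frequency benign support (advisory only).

    Dominant alleles: public frequency > 1% suffices (a dominant disease
    allele cannot be that common in healthy populations).  Recessive alleles
    additionally require at least one reported homozygote, since healthy
    carriers are expected.  Unknown inheritance is treated as recessive (the
    stricter reading).  This column never overrides the four criteria.
    """
    verdict = evaluate_public(record.public, cfg.af_benign_public, cfg.source_order)
    if verdict.max_af is None or verdict.max_af <= cfg.af_acmg_inheritance:
        return False
    if record.assertion.inheritance.value == "dominant":
        return True
    return verdict.hom_support


def screen_brca(
    assertions: Sequence[MorbidAssertion],
    cohort: Iterable[CohortCounts] | Mapping,
    cfg: ThresholdConfig = ThresholdConfig(),
) -> list:
    """Triage BRCA1/BRCA2 VOUS and likely-pathogenic assertions.

    Uses the cohort frequency (strictly greater than the 1% screen
    threshold) together with homozygotes lacking the Fanconi anemia
    phenotype: biallelic pathogenic BRCA2 causes fully penetrant Fanconi
    anemia, so a Fanconi-free homozygote argues against pathogenicity.

    Categories: BENIGN (frequency and zygosity evidence), FREQUENT_ONLY
    (frequency alone), BS2_ONLY (zygosity alone), UNCHANGED (neither, or a
    pathogenic-class assertion, which is handled by the reciprocal check).
    """
    if isinstance(cohort, Mapping):
        cohort_index = dict(cohort)
    else:
        cohort_index = {c.key: c for c in cohort}
    verdicts = []
    for a in assertions:
        if a.source is not Source.BRCA_EXCHANGE:
            raise ValueError(
                f"screen_brca expects BRCA Exchange assertions, got {a.source.value}"
            )
        row = cohort_index.get(a.key)
        sgp, _, warning = _cohort_frequencies(row)
        fanconi_free = 0
        if row is not None and row.fanconi_free_hom is not None:
            fanconi_free = row.fanconi_free_hom
        if a.assertion_class is AssertionClass.PATHOGENIC:
            category = BrcaCategory.UNCHANGED
            note = "pathogenic class: see reciprocal check"
        else:
            frequent = sgp is not None and sgp > _frac(cfg.brca_maf)
            if frequent and fanconi_free >= 1:
                category = BrcaCategory.BENIGN
            elif frequent:
                category = BrcaCategory.FREQUENT_ONLY
            elif fanconi_free >= 1:
                category = BrcaCategory.BS2_ONLY
            else:
                category = BrcaCategory.UNCHANGED
            note = None
        evidence = {
            "sgp_af": float(sgp) if sgp is not None else None,
            "brca_maf": cfg.brca_maf,
            "fanconi_free_hom": fanconi_free,
        }
        if note:
            evidence["note"] = note
        if warning:
            evidence["warning"] = warning
        verdicts.append(
            BrcaVerdict(
                assertion=a,
                category=category,
                sgp_af=sgp,
                fanconi_free_hom=fanconi_free,
                evidence=evidence,
            )
        )
    return verdicts


def _is_brca_context(a: MorbidAssertion) -> bool:
    return a.source is Source.BRCA_EXCHANGE or a.gene.upper() in ("BRCA1", "BRCA2")


def reciprocal_pathogenic_check(
    assertions: Sequence[MorbidAssertion],
    cohort: Iterable[CohortCounts] | Mapping,
    *,
    include_dm: bool = False,
):
    """Flag pathogenic assertions observed homozygous in phenotype-free
    individuals.

    A truly pathogenic recessive allele should never be homozygous in an
    individual lacking the phenotype (for BRCA genes: lacking Fanconi
    anemia).  Returns ``(violations, consistent)``: violations need manual
    review; consistent records are pathogenic homozygotes in phenotype-
    positive individuals, which corroborate the assertion.
    """
    if isinstance(cohort, Mapping):
        cohort_index = dict(cohort)
    else:
        cohort_index = {c.key: c for c in cohort}
    classes = {AssertionClass.PATHOGENIC}
    if include_dm:
        classes.add(AssertionClass.DM)
    violations = []
    consistent = []
    for a in assertions:
        if a.assertion_class not in classes:
            continue
        row = cohort_index.get(a.key)
        if row is None or row.no_hom == 0:
            continue
        if _is_brca_context(a) and row.fanconi_free_hom is not None:
            free = row.fanconi_free_hom
        else:
            free = row.hom_phenotype_free
        record = ReciprocalRecord(
            assertion=a,
            no_hom=row.no_hom,
            phenotype_free_hom=free,
            is_violation=free >= 1,
        )
        (violations if record.is_violation else consistent).append(record)
    return violations, consistent


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass
class RunResult:
    results: list
    brca_verdicts: list
    violations: list
    consistent: list
    exclusion_log: list
    both_platform_fraction: Optional[float]
    config: ThresholdConfig
    run_log: list


def run_reclassification(
    assertions: Sequence[MorbidAssertion],
    public_fragments: Iterable = (),
    cohort: Sequence[CohortCounts] = (),
    annotations: Iterable = (),
    quality: Iterable = (),
    cfg: ThresholdConfig = ThresholdConfig(),
    *,
    include_dp_dfp: bool = False,
    include_dm_reciprocal: bool = False,
    keep_unevidenced_cohort: bool = False,
    out_dir=None,
    input_manifest: Optional[Mapping] = None,
) -> RunResult:
    """Run the full pipeline over in-memory evidence tables.

    Stages: quality-gate the cohort rows, join all evidence onto the
    assertions by normalized key, score the four criteria per assertion,
    screen BRCA Exchange assertions, run the reciprocal pathogenic check,
    and (when ``out_dir`` is given) write the results TSV, summary tables,
    exclusion log, violation report, and a run log echoing the
    configuration.  The run is deterministic: identical inputs produce
    byte-identical outputs.
    """
    annotations = list(annotations)
    quality = list(quality)
    kept_cohort, exclusion_log, both_fraction = filter_cohort(
        list(cohort), quality, keep_unevidenced=keep_unevidenced_cohort
    )
    records = join_evidence(assertions, public_fragments, kept_cohort, annotations, quality)

    results = []
    skipped_classes = 0
    for record in records:
        cls = record.assertion.assertion_class
        if cls not in ELIGIBLE_CLASSES and not include_dp_dfp:
            skipped_classes += 1
            verdict = evaluate_public(record.public, cfg.af_benign_public, cfg.source_order)
            results.append(
                ReclassificationResult(
                    assertion=record.assertion,
                    criterion=Criterion.NONE,
                    outcome=Outcome.UNCHANGED,
                    public_verdict=verdict,
                    evidence={"note": f"class {cls.value} excluded from scoring"},
                )
            )
            continue
        result = evaluate_criteria(record, cfg, include_dp_dfp=include_dp_dfp)
        if result.outcome is Outcome.BS2_ONLY:
            # definitional: BS2-only implies cohort frequency below the low
            # threshold
            assert result.sgp_af is not None and result.sgp_af < _frac(cfg.af_cohort_low)
        results.append(result)

    cohort_index = {c.key: c for c in kept_cohort}
    brca_assertions = [a for a in assertions if a.source is Source.BRCA_EXCHANGE]
    brca_verdicts = screen_brca(brca_assertions, cohort_index, cfg) if brca_assertions else []
    violations, consistent = reciprocal_pathogenic_check(
        assertions, cohort_index, include_dm=include_dm_reciprocal
    )

    run_log = ["morbidgenome reclassification run", "config:"]
    for k, v in sorted(cfg.as_dict().items()):
        run_log.append(f"  {k}: {v}")
    if input_manifest:
        run_log.append("inputs:")
        for name in sorted(input_manifest):
            path = input_manifest[name]
            digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
            run_log.append(f"  {name}: {path} sha256={digest}")
    run_log += [
        f"assertions: {len(assertions)}",
        f"cohort rows in: {len(list(cohort))}",
        f"cohort rows kept: {len(kept_cohort)}",
        f"cohort rows excluded: {len(exclusion_log)}",
        "both-platform fraction: "
        + (f"{both_fraction:.4f}" if both_fraction is not None else "NA"),
        f"classes excluded from scoring: {skipped_classes}",
        f"results: {len(results)}",
        f"brca verdicts: {len(brca_verdicts)}",
        f"reciprocal violations: {len(violations)}",
        f"reciprocal consistent: {len(consistent)}",
    ]

    run = RunResult(
        results=results,
        brca_verdicts=brca_verdicts,
        violations=violations,
        consistent=consistent,
        exclusion_log=exclusion_log,
        both_platform_fraction=both_fraction,
        config=cfg,
        run_log=run_log,
    )
    if out_dir is not None:
        _write_run_outputs(run, annotations, out_dir)
    return run


def _fmt_frac(value) -> str:
    if value is None:
        return "NA"
    return f"{float(value):.6g}"


RESULT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "source",
    "assertion_class",
    "criterion",
    "outcome",
    "sgp_af",
    "naive_af",
    "public_max_af",
    "public_source",
    "hom_phenotype_free",
    "advisory_acmg_rule",
    "evidence_json",
]


def write_results_table(results: Sequence[ReclassificationResult], path) -> None:
    """Serialize results to the documented TSV, one row per assertion."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(RESULT_COLUMNS)
        for r in results:
            a = r.assertion
            writer.writerow(
                [
                    a.key.chrom,
                    a.key.pos,
                    a.key.ref,
                    a.key.alt,
                    a.source.value,
                    a.assertion_class.value,
                    r.criterion.value,
                    r.outcome.value,
                    _fmt_frac(r.sgp_af),
                    _fmt_frac(r.naive_af),
                    _fmt_frac(r.public_verdict.max_af),
                    r.public_verdict.max_source.value,
                    r.hom_phenotype_free if r.hom_phenotype_free is not None else "NA",
                    "" if r.advisory_acmg is None else int(r.advisory_acmg),
                    json.dumps(r.evidence, sort_keys=True),
                ]
            )


def read_results_table(path):
    """Read a results TSV back as a pandas DataFrame (for reporting)."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)


def _write_run_outputs(run: RunResult, annotations, out_dir) -> None:
    import csv

    from .reporting import write_report

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_results_table(run.results, out_dir / "results.tsv")
    with open(out_dir / "exclusions.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chrom", "pos", "ref", "alt", "reason"])
        for key, reason in run.exclusion_log:
            writer.writerow([key.chrom, key.pos, key.ref, key.alt, reason])
    with open(out_dir / "violations.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["chrom", "pos", "ref", "alt", "source", "gene", "assertion_class",
             "no_hom", "phenotype_free_hom", "status"]
        )
        for rec in run.violations + run.consistent:
            a = rec.assertion
            writer.writerow(
                [a.key.chrom, a.key.pos, a.key.ref, a.key.alt, a.source.value,
                 a.gene, a.assertion_class.value, rec.no_hom,
                 rec.phenotype_free_hom,
                 "violation" if rec.is_violation else "consistent"]
            )
    with open(out_dir / "brca_verdicts.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["chrom", "pos", "ref", "alt", "gene", "assertion_class", "category",
             "sgp_af", "fanconi_free_hom"]
        )
        for v in run.brca_verdicts:
            a = v.assertion
            writer.writerow(
                [a.key.chrom, a.key.pos, a.key.ref, a.key.alt, a.gene,
                 a.assertion_class.value, v.category.value, _fmt_frac(v.sgp_af),
                 v.fanconi_free_hom]
            )
    write_report(run.results, annotations, run.config, out_dir)
    with open(out_dir / "run.log", "w") as fh:
        fh.write("\n".join(run.run_log) + "\n")
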