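"""Summary surfaces: per-criterion count matrices, in-silico prediction and
loss-of-function tallies, and the plain-text report.

The count matrix stratifies reclassified assertions by criterion (rows) and
source/class (columns).  The prediction summary counts, per criterion, how
many reclassified variants each of SIFT/PolyPhen2/MutationTaster/MetaSVM/
CADD calls damaging, and breaks down apparent loss-of-function variants
(stop-gain, frameshift, splicing) with their percentage of the criterion
total, formatted as ``a, b, c (pct%)`` in the text report.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .variant_io import (
    FunctionalClass,
    PredictorCall,
    ThresholdConfig,
    VariantAnnotation,
    normalize_variant,
)

logger = logging.getLogger(__name__)

__all__ = ["summarize_by_criterion", "summarize_predictions", "write_report"]

_CANONICAL_COLUMNS = [
    ("HGMD", "DM"),
    ("HGMD", "DM?"),
    ("CLINVAR", "Pathogenic"),
    ("CLINVAR", "Likely pathogenic"),
    ("CLINVAR", "VOUS"),
]
_CRITERIA = ["C1", "C2", "C3", "C4"]
_TOOLS = ["sift", "polyphen2", "mutationtaster", "metasvm", "cadd"]
_LOF_ORDER = ["stop_gain", "frameshift", "splicing"]


def _result_rows(results) -> list:
    """Normalize results (objects or DataFrame) to per-assertion tuples."""
    if isinstance(results, pd.DataFrame):
        return [
            (
                str(r["source"]),
                str(r["assertion_class"]),
                str(r["criterion"]),
                str(r["outcome"]),
                normalize_variant(r["chrom"], r["pos"], r["ref"], r["alt"]),
            )
            for _, r in results.iterrows()
        ]
    return [
        (
            r.assertion.source.value,
            r.assertion.assertion_class.value,
            r.criterion.value,
            r.outcome.value,
            r.assertion.key,
        )
        for r in results
    ]


def summarize_by_criterion(results) -> pd.DataFrame:
    """Count reclassified assertions per criterion and source/class stratum.

    Rows are the four criteria plus a ``total`` row; columns are
    ``SOURCE:class`` strata (the HGMD DM/DM? and ClinVar Pathogenic/Likely
    pathogenic/VOUS columns are always present, zero-filled when empty;
    further strata appear only when observed) plus a ``total`` column.
    Unchanged assertions are not counted anywhere, so the grand total equals
    the number of reclassified (benign or BS2-only) assertions.
    """
    rows = _result_rows(results)
    columns = list(_CANONICAL_COLUMNS)
    for source, cls, _, _, _ in rows:
        if (source, cls) not in columns:
            columns.append((source, cls))
    labels = [f"{s}:{c}" for s, c in columns]
    table = pd.DataFrame(0, index=_CRITERIA + ["total"], columns=labels + ["total"])
    for source, cls, criterion, outcome, _ in rows:
        if outcome == "unchanged":
            continue
        label = f"{source}:{cls}"
        table.loc[criterion, label] += 1
        table.loc[criterion, "total"] += 1
        table.loc["total", label] += 1
        table.loc["total", "total"] += 1
    return table


def _annotation_index(annotations) -> dict:
    if isinstance(annotations, Mapping):
        return dict(annotations)
    return {a.key: a for a in annotations}


def _damaging(annotation: Optional[VariantAnnotation], tool: str, cutoff: float) -> bool:
    if annotation is None:
        return False
    if tool == "cadd":
        return annotation.cadd_phred is not None and annotation.cadd_phred >= cutoff
    return getattr(annotation, tool) is PredictorCall.DAMAGING


def summarize_predictions(
    results,
    annotations,
    cfg: ThresholdConfig = ThresholdConfig(),
) -> pd.DataFrame:
    """Per-criterion damaging-call and loss-of-function tallies.

    CADD calls a variant damaging when its phred-scaled score is at or above
    ``cfg.cadd_damaging_cutoff``.  Reclassified variants without an
    annotation row count as missing for every tool (logged).  The
    ``lof_pct`` column is 100 x (stop-gain + frameshift + splicing) /
    criterion total, rounded to one decimal.
    """
    index = _annotation_index(annotations)
    table = pd.DataFrame(
        0,
        index=_CRITERIA,
        columns=["total"] + _TOOLS + _LOF_ORDER,
    )
    for source, cls, criterion, outcome, key in _result_rows(results):
        if outcome == "unchanged":
            continue
        annotation = index.get(key)
        if annotation is None:
            logger.warning("no annotation for reclassified variant %s; counted missing", key)
        table.loc[criterion, "total"] += 1
        for tool in _TOOLS:
            if _damaging(annotation, tool, cfg.cadd_damaging_cutoff):
                table.loc[criterion, tool] += 1
        if annotation is not None and annotation.is_lof:
            table.loc[criterion, annotation.functional_class.value] += 1
    lof = table[_LOF_ORDER].sum(axis=1)
    with pd.option_context("mode.chained_assignment", None):
        table["lof_pct"] = [
            round(100.0 * l / t, 1) if t else 0.0 for l, t in zip(lof, table["total"])
        ]
    return table


def _lof_cell(row) -> str:
    pct = row["lof_pct"]
    return (
        f"{int(row['stop_gain'])}, {int(row['frameshift'])}, "
        f"{int(row['splicing'])} ({pct:g}%)"
    )


def _prediction_cell(row) -> str:
    return ", ".join(str(int(row[t])) for t in _TOOLS)


def write_report(
    results,
    annotations,
    cfg: ThresholdConfig,
    out_dir,
) -> None:
    """Write ``summary_criteria.tsv``, ``summary_predictions.tsv`` and the
    human-readable ``report.txt`` into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    criteria = summarize_by_criterion(results)
    predictions = summarize_predictions(results, annotations, cfg)
    criteria.to_csv(out_dir / "summary_criteria.tsv", sep="\t", index_label="criterion")
    predictions.to_csv(
        out_dir / "summary_predictions.tsv", sep="\t", index_label="criterion"
    )
    lines = [
        "Reclassification summary",
        "========================",
        "",
        "Counts per criterion and assertion class",
        "----------------------------------------",
        criteria.to_string(),
        "",
        "Pathogenicity predictions (SIFT, PolyPhen2, MutationTaster, MetaSVM, CADD)",
        "and LOF breakdown (stop-gain, frameshift, splicing (pct of criterion))",
        f"CADD damaging cutoff: phred >= {cfg.cadd_damaging_cutoff:g} (convention)",
        "-" * 74,
    ]
    for criterion in _CRITERIA:
        row = predictions.loc[criterion]
        lines.append(
            f"{criterion}: total {int(row['total'])} | "
            f"predictions {_prediction_cell(row)} | LOF {_lof_cell(row)}"
        )
    with open(out_dir / "report.txt", "w") as fh:
        fh.write("\n".join(lines) + "\n")
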