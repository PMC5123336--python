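"""Synthetic consanguineous-cohort generator with planted ground truth.

Emulates the study conditions of an autozygosity-enriched national cohort:
thousands of individuals (default 5849, the Mendeliome-assay cohort size)
genotyped at independent biallelic sites, with genotype frequencies shifted
from Hardy-Weinberg by an inbreeding coefficient F (default 0.0625, the
expectation for offspring of first cousins), plus an optional block of
ascertained diseased probands appended as homozygous-alternate,
phenotype-positive individuals.

:func:`generate_fixture_bundle` emits every table the pipeline consumes —
morbid assertions, the three public-frequency resources, cohort counts,
annotations, quality evidence — together with a truth table assigning each
site the single reclassification criterion its evidence was constructed to
satisfy.  Everything is deterministic given the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .frequency import sgp_allele_frequency
from .variant_io import (
    AssertionClass,
    CohortCounts,
    FunctionalClass,
    Inheritance,
    MorbidAssertion,
    PredictorCall,
    QualityEvidence,
    Source,
    VariantAnnotation,
    VariantKey,
    write_annotation_table,
    write_cohort_table,
    write_morbid_table,
    write_quality_table,
)

__all__ = [
    "SimulationConfig",
    "FixtureBundle",
    "PLANTED_CLASSES",
    "TRUTH_EXPECTED",
    "genotype_probabilities",
    "simulate_site",
    "generate_fixture_bundle",
    "read_truth_table",
]

#: Ground-truth classes a site can be planted to realize.
PLANTED_CLASSES = ("C1", "C2", "C3", "C4", "NONE", "PATHOGENIC_CONSISTENT")

#: Expected (criterion, outcome) the engine should assign per planted class.
TRUTH_EXPECTED = {
    "C1": ("C1", "benign"),
    "C2": ("C2", "benign"),
    "C3": ("C3", "benign"),
    "C4": ("C4", "bs2_only"),
    "NONE": ("none", "unchanged"),
    "PATHOGENIC_CONSISTENT": ("none", "unchanged"),
}


class FixtureGenerationError(RuntimeError):
    """Rejection sampling exhausted its retry budget for one site."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the single-site inbreeding genotype model.

    p_true is the population alternate-allele frequency; f_inbreeding the
    inbreeding coefficient F; n_cohort the number of background individuals
    drawn from the genotype model; n_proband_hom the number of ascertained
    diseased homozygotes appended on top (phenotype-positive, so they never
    count as phenotype-free).  The seed fully determines every draw.
    """

    p_true: float = 0.01
    f_inbreeding: float = 0.0625
    n_cohort: int = 5849
    n_proband_hom: int = 0
    n_sites: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_true <= 1.0):
            raise ValueError(f"p_true={self.p_true} outside [0, 1]")
        if not (0.0 <= self.f_inbreeding <= 1.0):
            raise ValueError(f"f_inbreeding={self.f_inbreeding} outside [0, 1]")
        if self.n_cohort <= 0 or self.n_sites <= 0:
            raise ValueError("n_cohort and n_sites must be positive")
        if self.n_proband_hom < 0:
            raise ValueError("n_proband_hom must be non-negative")


def genotype_probabilities(p, F):
    """Genotype probabilities (hom_ref, het, hom_alt) under inbreeding.

    With inbreeding coefficient F, a fraction F of loci are identical by
    descent (genotype drawn as a single allele) and 1-F follow
    Hardy-Weinberg:

        hom_alt = p^2 + F p (1-p)
        het     = 2 p (1-p) (1-F)
        hom_ref = (1-p)^2 + F p (1-p)

    Returned as exact :class:`~fractions.Fraction` values so the triple sums
    to 1 exactly; F = 0 reduces to Hardy-Weinberg proportions.
    """
    p = Fraction(p)
    F = Fraction(F)
    if not (0 <= p <= 1) or not (0 <= F <= 1):
        raise ValueError(f"p={float(p)}, F={float(F)} must lie in [0, 1]")
    q = 1 - p
    ibd = F * p * q
    hom_alt = p * p + ibd
    het = 2 * p * q * (1 - F)
    hom_ref = q * q + ibd
    return hom_ref, het, hom_alt


def _draw_genotype_counts(rng: np.random.Generator, n: int, p, F):
    """Draw (n_hom_ref, n_het, n_hom_alt) for n individuals."""
    hom_ref, het, _ = (float(x) for x in genotype_probabilities(p, F))
    pvals = np.array([hom_ref, het, max(0.0, 1.0 - hom_ref - het)])
    counts = rng.multinomial(n, pvals / pvals.sum())
    return int(counts[0]), int(counts[1]), int(counts[2])


_BASES = ("A", "C", "G", "T")


def _site_key(rng: np.random.Generator, site_index: int) -> VariantKey:
    chrom = str(1 + site_index % 22)
    pos = 1_000_000 + site_index
    ref = _BASES[rng.integers(4)]
    alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(3)) % 4]
    return VariantKey(chrom=chrom, pos=pos, ref=ref, alt=alt)


def simulate_site(cfg: SimulationConfig, site_index: int = 0) -> CohortCounts:
    """Simulate genotype counts at one site.

    Draws ``n_cohort`` background genotypes from the inbreeding model, then
    appends ``n_proband_hom`` ascertained homozygous probands.  Background
    homozygotes are phenotype-free; probands are not, so
    ``hom_phenotype_free`` counts background homozygotes only.
    Deterministic given ``(cfg.seed, site_index)``.
    """
    rng = np.random.default_rng([cfg.seed, site_index])
    key = _site_key(rng, site_index)
    _, no_het, bg_hom = _draw_genotype_counts(
        rng, cfg.n_cohort, cfg.p_true, cfg.f_inbreeding
    )
    return CohortCounts(
        key=key,
        no_het=no_het,
        no_hom=bg_hom + cfg.n_proband_hom,
        no_screened=cfg.n_cohort + cfg.n_proband_hom,
        hom_phenotype_free=bg_hom,
    )


@dataclass
class FixtureBundle:
    """Paths of a generated fixture set plus its ground-truth table."""

    out_dir: Path
    morbid_hgmd: Path
    morbid_clinvar: Path
    public_1000g: Path
    public_exac: Path
    public_kaviar: Path
    cohort: Path
    annotations: Path
    quality: Path
    truth: Path
    retry_counts: dict = field(default_factory=dict)


def read_truth_table(path) -> dict:
    """Load a truth TSV as a mapping from VariantKey to planted class."""
    import csv

    truth = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            key = VariantKey(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            truth[key] = row["planted_class"]
    return truth


# class cycles for assigning assertion classes to sites; sites that may carry
# phenotype-free homozygotes never receive the Pathogenic class, so the
# reciprocal check flags nothing unless a violation is planted deliberately
_NONPATH_CYCLE = (
    (Source.HGMD, AssertionClass.DM),
    (Source.HGMD, AssertionClass.DM_Q),
    (Source.CLINVAR, AssertionClass.LIKELY_PATHOGENIC),
    (Source.CLINVAR, AssertionClass.VOUS),
)
_FULL_CYCLE = _NONPATH_CYCLE + ((Source.CLINVAR, AssertionClass.PATHOGENIC),)
_INHERITANCE_CYCLE = (Inheritance.RECESSIVE, Inheritance.DOMINANT, Inheritance.UNKNOWN)

_FUNCTIONAL_CLASSES = (
    FunctionalClass.MISSENSE,
    FunctionalClass.SYNONYMOUS,
    FunctionalClass.STOP_GAIN,
    FunctionalClass.FRAMESHIFT,
    FunctionalClass.SPLICING,
    FunctionalClass.OTHER,
)
_FUNCTIONAL_WEIGHTS = (0.55, 0.15, 0.10, 0.05, 0.05, 0.10)


def _plant_cohort(
    rng: np.random.Generator,
    planted: str,
    n_cohort: int,
    F: float,
    max_retries: int,
    key: VariantKey,
):
    """Rejection-sample genotype counts realizing the planted class.

    Returns (CohortCounts or None, retries used).  C1 plants no cohort
    constraint beyond rarity; PATHOGENIC_CONSISTENT appends two diseased
    proband homozygotes onto a background with none.
    """
    specs = {
        # p_true, acceptance predicate on (no_het, bg_hom)
        "C1": (0.002, lambda h, m: m == 0),
        "C2": (0.12, None),
        "C3": (0.03, None),
        "C4": (0.002, None),
        "NONE": (0.002, lambda h, m: m == 0),
        "PATHOGENIC_CONSISTENT": (0.0005, lambda h, m: m == 0),
    }
    p_true, simple_pred = specs[planted]
    for attempt in range(max_retries):
        _, no_het, bg_hom = _draw_genotype_counts(rng, n_cohort, p_true, F)
        counts = CohortCounts(
            key=key,
            no_het=no_het,
            no_hom=bg_hom,
            no_screened=n_cohort,
            hom_phenotype_free=bg_hom,
        )
        if simple_pred is not None:
            if simple_pred(no_het, bg_hom):
                if planted == "PATHOGENIC_CONSISTENT":
                    counts = CohortCounts(
                        key=key,
                        no_het=no_het,
                        no_hom=2,
                        no_screened=n_cohort + 2,
                        hom_phenotype_free=0,
                    )
                return counts, attempt
            continue
        sgp = sgp_allele_frequency(counts)
        if planted == "C2" and sgp >= Fraction(5, 100):
            return counts, attempt
        if planted == "C3" and Fraction(1, 100) <= sgp < Fraction(5, 100) and bg_hom >= 1:
            return counts, attempt
        if planted == "C4" and sgp < Fraction(1, 100) and bg_hom >= 1:
            return counts, attempt
    raise FixtureGenerationError(
        f"could not realize class {planted} at site {key} in {max_retries} draws"
    )


def generate_fixture_bundle(
    out_dir,
    planted: Sequence[str] | Mapping[str, int] | None = None,
    *,
    n_cohort: int = 5849,
    f_inbreeding: float = 0.0625,
    seed: int = 0,
    max_retries: int = 1000,
) -> FixtureBundle:
    """Write a complete fixture set with planted ground truth.

    Parameters
    ----------
    out_dir : path-like
        Directory to create the TSVs in.
    planted
        Either an explicit per-site class sequence, or a mapping from class
        name to site count (default: 10 sites per class).  Evidence at each
        site is constructed to satisfy exactly the planted criterion and no
        earlier one: C1 sites get a public frequency >= 5%; C2 sites a
        cohort frequency >= 5% with public < 5%; C3 sites a cohort
        frequency in [1%, 5%) with a phenotype-free homozygote; C4 sites a
        cohort frequency < 1% with a phenotype-free homozygote; NONE sites
        no homozygotes; PATHOGENIC_CONSISTENT sites two diseased proband
        homozygotes and no phenotype-free ones.  Realized counts are
        rejection-sampled within a bounded retry budget.

    Returns a :class:`FixtureBundle` with all file paths and per-site retry
    counts.  Byte-identical across runs with the same arguments.
    """
    if planted is None:
        planted = {c: 10 for c in PLANTED_CLASSES}
    if isinstance(planted, Mapping):
        site_classes = [c for c in PLANTED_CLASSES for _ in range(planted.get(c, 0))]
    else:
        site_classes = list(planted)
    for c in site_classes:
        if c not in PLANTED_CLASSES:
            raise ValueError(f"unknown planted class {c!r}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    hgmd_rows, clinvar_rows = [], []
    cohort_rows, annotation_rows, quality_rows = [], [], []
    public_rows = {"1000g": [], "exac": [], "kaviar": []}
    truth_rows = []
    retry_counts = {}
    cycle_positions = {"nonpath": 0, "full": 0}

    for i, planted_class in enumerate(site_classes):
        rng = np.random.default_rng([seed, i])
        key = _site_key(rng, i)
        counts, retries = _plant_cohort(
            rng, planted_class, n_cohort, f_inbreeding, max_retries, key
        )
        retry_counts[str(key)] = retries
        cohort_rows.append(counts)

        # public-frequency evidence per planted class
        if planted_class == "C1":
            af = round(float(rng.uniform(0.06, 0.50)), 4)
            public_rows["1000g"].append((key, af, int(rng.integers(0, 5))))
            if rng.random() < 0.5:
                public_rows["exac"].append((key, round(float(rng.uniform(0.05, 0.5)), 4), None))
        elif planted_class in ("C2", "C3") and rng.random() < 0.6:
            af = round(float(rng.uniform(0.001, 0.045)), 4)
            role = "exac" if rng.random() < 0.5 else "kaviar"
            public_rows[role].append((key, af, None))
        # C4/NONE/PATHOGENIC_CONSISTENT sites stay absent from public resources

        # assertion class assignment
        if planted_class == "PATHOGENIC_CONSISTENT":
            source, cls = Source.CLINVAR, AssertionClass.PATHOGENIC
        elif planted_class == "NONE":
            source, cls = _FULL_CYCLE[cycle_positions["full"] % len(_FULL_CYCLE)]
            cycle_positions["full"] += 1
        else:
            source, cls = _NONPATH_CYCLE[cycle_positions["nonpath"] % len(_NONPATH_CYCLE)]
            cycle_positions["nonpath"] += 1
        assertion = MorbidAssertion(
            key=key,
            source=source,
            assertion_class=cls,
            gene=f"GENE{i:04d}",
            inheritance=_INHERITANCE_CYCLE[i % 3],
            disease_label=f"synthetic disease {i}",
            hgvs=None,
        )
        (hgmd_rows if source is Source.HGMD else clinvar_rows).append(assertion)

        fc = _FUNCTIONAL_CLASSES[
            rng.choice(len(_FUNCTIONAL_CLASSES), p=_FUNCTIONAL_WEIGHTS)
        ]
        calls = [
            PredictorCall.DAMAGING if rng.random() < 0.4 else PredictorCall.TOLERATED
            for _ in range(4)
        ]
        annotation_rows.append(
            VariantAnnotation(
                key=key,
                functional_class=fc,
                sift=calls[0],
                polyphen2=calls[1],
                mutationtaster=calls[2],
                metasvm=calls[3],
                cadd_phred=round(float(rng.uniform(0.0, 40.0)), 2),
            )
        )

        # ~99% of observations concordant across both platforms, matching a
        # dual-platform cohort; the remainder pass the strict Proton route
        both = rng.random() < 0.99
        quality_rows.append(
            QualityEvidence(
                key=key,
                called_proton=True,
                called_illumina=both,
                is_snv=True,
                quality_score=float(rng.integers(1000, 5000)),
                depth=int(rng.integers(150, 600)),
                sanger_confirmed=not both,
            )
        )
        truth_rows.append((key, planted_class))

    bundle = FixtureBundle(
        out_dir=out_dir,
        morbid_hgmd=out_dir / "morbid_hgmd.tsv",
        morbid_clinvar=out_dir / "morbid_clinvar.tsv",
        public_1000g=out_dir / "public_1000g.tsv",
        public_exac=out_dir / "public_exac.tsv",
        public_kaviar=out_dir / "public_kaviar.tsv",
        cohort=out_dir / "cohort.tsv",
        annotations=out_dir / "annotations.tsv",
        quality=out_dir / "quality.tsv",
        truth=out_dir / "truth.tsv",
        retry_counts=retry_counts,
    )
    write_morbid_table(hgmd_rows, bundle.morbid_hgmd)
    write_morbid_table(clinvar_rows, bundle.morbid_clinvar)
    for role, path in (
        ("1000g", bundle.public_1000g),
        ("exac", bundle.public_exac),
        ("kaviar", bundle.public_kaviar),
    ):
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\taf\thom\n")
            for key, af, hom in public_rows[role]:
                hom_s = "" if hom is None else str(hom)
                fh.write(
                    f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t{af}\t{hom_s}\n"
                )
    write_cohort_table(cohort_rows, bundle.cohort)
    write_annotation_table(annotation_rows, bundle.annotations)
    write_quality_table(quality_rows, bundle.quality)
    with open(bundle.truth, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tplanted_class\n")
        for key, planted_class in truth_rows:
            fh.write(f"{key.chrom}\t{key.pos}\t{key.ref}\t{key.alt}\t{planted_class}\n")
    return bundle
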