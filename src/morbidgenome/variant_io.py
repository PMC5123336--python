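"""Domain types, tabular readers/writers, and variant-key normalization.

All pipeline stages exchange variants keyed by a normalized
:class:`VariantKey` (hg19 naming, 1-based, left-trimmed minimal
representation).  The tabular dialects are plain TSV with a header row;
public allele-frequency resources may alternatively be supplied as VCF.

Missing evidence is always represented as missing (``None``), never as a
fabricated zero: absence of a variant from a healthy-population resource is
not the same observation as a measured frequency of 0.
"""
from __future__ import annotations

import csv
import enum
import logging
import re
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "VariantKey",
    "Source",
    "AssertionClass",
    "Inheritance",
    "FunctionalClass",
    "PredictorCall",
    "MorbidAssertion",
    "PublicFrequency",
    "CohortCounts",
    "VariantAnnotation",
    "QualityEvidence",
    "ThresholdConfig",
    "JoinedRecord",
    "InvalidVariantError",
    "VariantFormatError",
    "DuplicateKeyError",
    "normalize_variant",
    "read_morbid_table",
    "write_morbid_table",
    "read_frequency_table",
    "read_cohort_table",
    "write_cohort_table",
    "read_annotation_table",
    "write_annotation_table",
    "read_quality_table",
    "write_quality_table",
    "merge_public_fragments",
    "join_evidence",
]


class InvalidVariantError(ValueError):
    """The chrom/pos/ref/alt quadruple does not describe a valid variant."""


class VariantFormatError(ValueError):
    """A tabular input file violates its documented dialect."""


class DuplicateKeyError(ValueError):
    """Two rows claim the same variant key where at most one is allowed."""


_VALID_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X", "Y", "MT"])
_ALLELE_RE = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized biallelic variant identifier (hg19, 1-based).

    Invariants: ``ref != alt``, both alleles non-empty uppercase strings over
    A/C/G/T, and the representation is minimal — shared leading/trailing
    bases are trimmed except that one anchor base is retained when an allele
    would otherwise become empty (the VCF indel convention).
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Return the left-trimmed minimal :class:`VariantKey` for an edit.

    Shared trailing bases are removed first, then shared leading bases
    (advancing ``pos``), stopping whenever either allele would become empty.
    The operation is idempotent and preserves the sequence edit the raw
    quadruple describes.

    Raises
    ------
    InvalidVariantError
        If ``ref == alt`` after case folding, or an allele contains a
        character outside A/C/G/T, or the chromosome label is not one of
        1-22/X/Y/MT (a leading ``chr`` prefix is stripped).
    """
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    if chrom == "M":
        chrom = "MT"
    if chrom not in _VALID_CHROMS:
        raise InvalidVariantError(f"unrecognized chromosome label {chrom!r}")
    ref = str(ref).strip().upper()
    alt = str(alt).strip().upper()
    if not _ALLELE_RE.match(ref) or not _ALLELE_RE.match(alt):
        raise InvalidVariantError(
            f"alleles must be non-empty strings over A/C/G/T, got ref={ref!r} alt={alt!r}"
        )
    if ref == alt:
        raise InvalidVariantError(f"ref and alt are identical ({ref!r}) at {chrom}:{pos}")
    pos = int(pos)
    if pos < 1:
        raise InvalidVariantError(f"position must be >= 1, got {pos}")
    # trim shared suffix, keeping at least one base on each allele
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim shared prefix, advancing pos
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom=chrom, pos=pos, ref=ref, alt=alt)


class Source(enum.Enum):
    HGMD = "HGMD"
    CLINVAR = "CLINVAR"
    BRCA_EXCHANGE = "BRCA_EXCHANGE"


class AssertionClass(enum.Enum):
    DM = "DM"
    DM_Q = "DM?"
    DP = "DP"
    DFP = "DFP"
    PATHOGENIC = "Pathogenic"
    LIKELY_PATHOGENIC = "Likely pathogenic"
    VOUS = "VOUS"


#: Assertion-class vocabulary permitted for each source database.
SOURCE_VOCABULARY: Mapping[Source, frozenset] = {
    Source.HGMD: frozenset(
        {AssertionClass.DM, AssertionClass.DM_Q, AssertionClass.DP, AssertionClass.DFP}
    ),
    Source.CLINVAR: frozenset(
        {AssertionClass.PATHOGENIC, AssertionClass.LIKELY_PATHOGENIC, AssertionClass.VOUS}
    ),
    Source.BRCA_EXCHANGE: frozenset(
        {AssertionClass.PATHOGENIC, AssertionClass.LIKELY_PATHOGENIC, AssertionClass.VOUS}
    ),
}

_CLASS_ALIASES = {
    "dm": AssertionClass.DM,
    "dm?": AssertionClass.DM_Q,
    "dp": AssertionClass.DP,
    "dfp": AssertionClass.DFP,
    "pathogenic": AssertionClass.PATHOGENIC,
    "likely pathogenic": AssertionClass.LIKELY_PATHOGENIC,
    "likely_pathogenic": AssertionClass.LIKELY_PATHOGENIC,
    "vous": AssertionClass.VOUS,
    "uncertain significance": AssertionClass.VOUS,
    "uncertain_significance": AssertionClass.VOUS,
}


class Inheritance(enum.Enum):
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    UNKNOWN = "unknown"


_INHERITANCE_ALIASES = {
    "dominant": Inheritance.DOMINANT,
    "ad": Inheritance.DOMINANT,
    "recessive": Inheritance.RECESSIVE,
    "ar": Inheritance.RECESSIVE,
    "unknown": Inheritance.UNKNOWN,
    "": Inheritance.UNKNOWN,
    ".": Inheritance.UNKNOWN,
}


class FunctionalClass(enum.Enum):
    MISSENSE = "missense"
    STOP_GAIN = "stop_gain"
    FRAMESHIFT = "frameshift"
    SPLICING = "splicing"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Loss-of-function functional classes (stop-gain, frameshift, splicing).
LOF_CLASSES = frozenset(
    {FunctionalClass.STOP_GAIN, FunctionalClass.FRAMESHIFT, FunctionalClass.SPLICING}
)


class PredictorCall(enum.Enum):
    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    MISSING = "missing"


@dataclass(frozen=True)
class MorbidAssertion:
    """One disease-mutation claim from a source database."""

    key: VariantKey
    source: Source
    assertion_class: AssertionClass
    gene: str
    inheritance: Inheritance = Inheritance.UNKNOWN
    disease_label: str = ""
    hgvs: Optional[str] = None

    def __post_init__(self) -> None:
        if self.assertion_class not in SOURCE_VOCABULARY[self.source]:
            raise VariantFormatError(
                f"class {self.assertion_class.value!r} is not in the "
                f"{self.source.value} vocabulary"
            )


@dataclass(frozen=True)
class PublicFrequency:
    """Per-variant allele frequency and homozygote evidence from the three
    public-resource roles (1000 Genomes, ExAC, Kaviar).

    A missing frequency means the variant was not observed in that resource;
    the Kaviar role reports no homozygote counts.
    """

    key: VariantKey
    af_1000g: Optional[float] = None
    af_exac: Optional[float] = None
    af_kaviar: Optional[float] = None
    hom_1000g: Optional[int] = None
    hom_exac: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("af_1000g", "af_exac", "af_kaviar"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise VariantFormatError(f"{name}={v} outside [0, 1] for {self.key}")
        for name in ("hom_1000g", "hom_exac"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise VariantFormatError(f"{name}={v} negative for {self.key}")


@dataclass(frozen=True)
class CohortCounts:
    """Genotype counts at one site in the autozygosity-enriched cohort.

    ``hom_phenotype_free`` counts homozygous-alternate individuals who lack
    the phenotype reported for the assertion; ``fanconi_free_hom`` is the
    analogous count for the BRCA2/Fanconi biallelic constraint and is only
    present where a BRCA screen is intended.
    """

    key: VariantKey
    no_het: int
    no_hom: int
    no_screened: int
    hom_phenotype_free: int = 0
    fanconi_free_hom: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.no_het, self.no_hom, self.hom_phenotype_free) < 0:
            raise VariantFormatError(f"negative genotype count at {self.key}")
        if self.no_screened <= 0:
            raise VariantFormatError(f"no_screened must be positive at {self.key}")
        if self.no_het + self.no_hom > self.no_screened:
            raise VariantFormatError(
                f"no_het + no_hom exceeds no_screened at {self.key}"
            )
        if self.hom_phenotype_free > self.no_hom:
            raise VariantFormatError(
                f"hom_phenotype_free exceeds no_hom at {self.key}"
            )
        if self.fanconi_free_hom is not None and not (
            0 <= self.fanconi_free_hom <= self.no_hom
        ):
            raise VariantFormatError(f"fanconi_free_hom out of range at {self.key}")


@dataclass(frozen=True)
class VariantAnnotation:
    """Functional class plus the five in-silico pathogenicity predictions."""

    key: VariantKey
    functional_class: FunctionalClass
    sift: PredictorCall = PredictorCall.MISSING
    polyphen2: PredictorCall = PredictorCall.MISSING
    mutationtaster: PredictorCall = PredictorCall.MISSING
    metasvm: PredictorCall = PredictorCall.MISSING
    cadd_phred: Optional[float] = None

    @property
    def is_lof(self) -> bool:
        return self.functional_class in LOF_CLASSES

    def __post_init__(self) -> None:
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise VariantFormatError(f"cadd_phred negative at {self.key}")


@dataclass(frozen=True)
class QualityEvidence:
    """Platform/quality evidence for one cohort variant call.

    ``quality_score`` and ``depth`` refer to the Ion Proton call when the
    variant was not also called on Illumina.
    """

    key: VariantKey
    called_proton: bool
    called_illumina: bool
    is_snv: bool
    quality_score: float = 0.0
    depth: int = 0
    sanger_confirmed: bool = False

    def __post_init__(self) -> None:
        if self.quality_score < 0 or self.depth < 0:
            raise VariantFormatError(f"negative quality_score/depth at {self.key}")


@dataclass(frozen=True)
class ThresholdConfig:
    """All tunable thresholds of the reclassification engine.

    Defaults follow the published rule set: a stand-alone 5% public-frequency
    benign threshold, 5%/1% cohort thresholds for the cohort-driven criteria,
    a 1% inheritance-aware advisory rule, a 1% BRCA screen threshold, and a
    CADD-phred damaging cutoff of 20 for the prediction summary.
    """

    af_benign_public: float = 0.05
    af_cohort_common: float = 0.05
    af_cohort_low: float = 0.01
    af_acmg_inheritance: float = 0.01
    brca_maf: float = 0.01
    cadd_damaging_cutoff: float = 20.0
    source_order: tuple = ("1000g", "exac", "kaviar")

    def __post_init__(self) -> None:
        for name in (
            "af_benign_public",
            "af_cohort_common",
            "af_cohort_low",
            "af_acmg_inheritance",
            "brca_maf",
        ):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v} outside (0, 1)")
        if not (self.af_cohort_low <= self.af_cohort_common):
            raise ValueError("af_cohort_low must not exceed af_cohort_common")
        if sorted(self.source_order) != ["1000g", "exac", "kaviar"]:
            raise ValueError(
                "source_order must be a permutation of ('1000g', 'exac', 'kaviar')"
            )
        object.__setattr__(self, "source_order", tuple(self.source_order))

    @classmethod
    def from_yaml(cls, path) -> "ThresholdConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "source_order" in data:
            data["source_order"] = tuple(data["source_order"])
        return cls(**data)

    def as_dict(self) -> dict:
        return {
            "af_benign_public": self.af_benign_public,
            "af_cohort_common": self.af_cohort_common,
            "af_cohort_low": self.af_cohort_low,
            "af_acmg_inheritance": self.af_acmg_inheritance,
            "brca_maf": self.brca_maf,
            "cadd_damaging_cutoff": self.cadd_damaging_cutoff,
            "source_order": list(self.source_order),
        }


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

_KEY_COLUMNS = ["chrom", "pos", "ref", "alt"]

MORBID_COLUMNS = _KEY_COLUMNS + ["gene", "class", "inheritance", "disease", "hgvs"]
FREQUENCY_COLUMNS = _KEY_COLUMNS + ["af"]
COHORT_COLUMNS = _KEY_COLUMNS + ["no_het", "no_hom", "no_screened", "hom_phenotype_free"]
ANNOTATION_COLUMNS = _KEY_COLUMNS + [
    "functional_class",
    "sift",
    "polyphen2",
    "mutationtaster",
    "metasvm",
    "cadd_phred",
]
QUALITY_COLUMNS = _KEY_COLUMNS + [
    "called_proton",
    "called_illumina",
    "is_snv",
    "quality_score",
    "depth",
    "sanger_confirmed",
]

_DIALECT_SOURCES = {
    "hgmd": Source.HGMD,
    "clinvar": Source.CLINVAR,
    "brca_exchange": Source.BRCA_EXCHANGE,
    "brca": Source.BRCA_EXCHANGE,
}


def _open_rows(path, required: Sequence[str], optional: Sequence[str] = ()):
    """Yield (line_number, row_dict) from a TSV, checking mandatory columns."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise VariantFormatError(f"{path}: empty file, header row expected")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise VariantFormatError(f"{path}: missing mandatory column(s) {missing}")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            rows.append((lineno, row))
    return rows


def _parse_bool(raw: str, path, lineno: int, column: str) -> bool:
    s = str(raw).strip().lower()
    if s in ("1", "true", "t", "yes"):
        return True
    if s in ("0", "false", "f", "no"):
        return False
    raise VariantFormatError(f"{path} line {lineno}: {column}={raw!r} is not a boolean")


def _parse_optional(raw) -> Optional[str]:
    if raw is None:
        return None
    s = str(raw).strip()
    return None if s in ("", ".", "NA", "nan") else s


def read_morbid_table(path, dialect: str) -> list:
    """Read a morbid-assertion TSV in the named dialect.

    Parameters
    ----------
    path : path-like
        TSV with columns ``chrom pos ref alt gene class inheritance disease
        hgvs``.
    dialect : {"hgmd", "clinvar", "brca_exchange"}
        Selects the source database and therefore the permitted ``class``
        vocabulary.  Rows whose class falls outside the dialect vocabulary
        are skipped with a logged reason; all other rows are returned in
        file order with normalized keys.
    """
    if dialect not in _DIALECT_SOURCES:
        raise ValueError(
            f"unknown dialect {dialect!r}; expected one of "
            f"{sorted(set(_DIALECT_SOURCES) - {'brca'})}"
        )
    source = _DIALECT_SOURCES[dialect]
    assertions = []
    for lineno, row in _open_rows(path, MORBID_COLUMNS[:-1]):
        raw_class = str(row["class"]).strip()
        cls = _CLASS_ALIASES.get(raw_class.lower())
        if cls is None or cls not in SOURCE_VOCABULARY[source]:
            logger.warning(
                "%s line %d: class %r not in %s vocabulary; row rejected",
                path,
                lineno,
                raw_class,
                source.value,
            )
            continue
        inh_raw = str(row.get("inheritance") or "").strip().lower()
        inheritance = _INHERITANCE_ALIASES.get(inh_raw)
        if inheritance is None:
            raise VariantFormatError(
                f"{path} line {lineno}: unknown inheritance {row['inheritance']!r}"
            )
        try:
            key = normalize_variant(row["chrom"], row["pos"], row["ref"], row["alt"])
        except InvalidVariantError as exc:
            raise VariantFormatError(f"{path} line {lineno}: {exc}") from exc
        assertions.append(
            MorbidAssertion(
                key=key,
                source=source,
                assertion_class=cls,
                gene=str(row["gene"]).strip(),
                inheritance=inheritance,
                disease_label=str(row["disease"]).strip(),
                hgvs=_parse_optional(row.get("hgvs")),
            )
        )
    return assertions


def write_morbid_table(assertions: Iterable[MorbidAssertion], path) -> None:
    """Write assertions back to the TSV dialect (inverse of the reader)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MORBID_COLUMNS)
        for a in assertions:
            writer.writerow(
                [
                    a.key.chrom,
                    a.key.pos,
                    a.key.ref,
                    a.key.alt,
                    a.gene,
                    a.assertion_class.value,
                    a.inheritance.value,
                    a.disease_label,
                    a.hgvs if a.hgvs is not None else "",
                ]
            )


_ROLE_FIELDS = {
    "1000g": ("af_1000g", "hom_1000g"),
    "exac": ("af_exac", "hom_exac"),
    "kaviar": ("af_kaviar", None),
}


def read_frequency_table(
    path,
    source_role: str,
    *,
    vcf_af_key: str = "AF",
    vcf_hom_key: str = "Hom",
) -> list:
    """Read one public-frequency resource as PublicFrequency fragments.

    ``source_role`` is one of ``1000g``, ``exac``, ``kaviar``.  The file is a
    TSV ``chrom pos ref alt af [hom]`` or, when the filename ends in
    ``.vcf``, a VCF v4.2 whose INFO carries the frequency (key ``AF``) and
    optionally a homozygote count (key ``Hom``).  The Kaviar role carries no
    homozygote counts; a ``hom`` column there is ignored.
    """
    if source_role not in _ROLE_FIELDS:
        raise ValueError(f"unknown source role {source_role!r}")
    af_field, hom_field = _ROLE_FIELDS[source_role]
    if str(path).endswith(".vcf"):
        return _read_frequency_vcf(path, af_field, hom_field, vcf_af_key, vcf_hom_key)
    fragments = []
    for lineno, row in _open_rows(path, FREQUENCY_COLUMNS):
        key = normalize_variant(row["chrom"], row["pos"], row["ref"], row["alt"])
        af = float(row["af"])
        if not (0.0 <= af <= 1.0):
            raise VariantFormatError(
                f"{path} line {lineno}: af={af} outside [0, 1]"
            )
        kwargs = {af_field: af}
        hom_raw = _parse_optional(row.get("hom"))
        if hom_raw is not None and hom_field is not None:
            kwargs[hom_field] = int(hom_raw)
        fragments.append(PublicFrequency(key=key, **kwargs))
    return fragments


def _read_frequency_vcf(path, af_field, hom_field, af_key, hom_key) -> list:
    from cyvcf2 import VCF

    fragments = []
    for record in VCF(str(path)):
        af = record.INFO.get(af_key)
        if af is None:
            continue
        for i, alt in enumerate(record.ALT):
            value = float(af[i]) if isinstance(af, tuple) else float(af)
            if not (0.0 <= value <= 1.0):
                raise VariantFormatError(
                    f"{path} {record.CHROM}:{record.POS}: AF={value} outside [0, 1]"
                )
            key = normalize_variant(record.CHROM, record.POS, record.REF, alt)
            kwargs = {af_field: value}
            hom = record.INFO.get(hom_key)
            if hom is not None and hom_field is not None:
                kwargs[hom_field] = int(hom[i] if isinstance(hom, tuple) else hom)
            fragments.append(PublicFrequency(key=key, **kwargs))
    return fragments


def read_cohort_table(path) -> list:
    """Read the cohort genotype-count TSV (optionally with fanconi_free_hom)."""
    counts = []
    for lineno, row in _open_rows(path, COHORT_COLUMNS):
        key = normalize_variant(row["chrom"], row["pos"], row["ref"], row["alt"])
        fanconi = _parse_optional(row.get("fanconi_free_hom"))
        try:
            counts.append(
                CohortCounts(
                    key=key,
                    no_het=int(row["no_het"]),
                    no_hom=int(row["no_hom"]),
                    no_screened=int(row["no_screened"]),
                    hom_phenotype_free=int(row["hom_phenotype_free"]),
                    fanconi_free_hom=int(fanconi) if fanconi is not None else None,
                )
            )
        except VariantFormatError as exc:
            raise VariantFormatError(f"{path} line {lineno}: {exc}") from exc
    return counts


def write_cohort_table(counts: Iterable[CohortCounts], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(COHORT_COLUMNS + ["fanconi_free_hom"])
        for c in counts:
            writer.writerow(
                [
                    c.key.chrom,
                    c.key.pos,
                    c.key.ref,
                    c.key.alt,
                    c.no_het,
                    c.no_hom,
                    c.no_screened,
                    c.hom_phenotype_free,
                    c.fanconi_free_hom if c.fanconi_free_hom is not None else "",
                ]
            )


_DAMAGING_TERMS = frozenset(
    {"damaging", "d", "deleterious", "probably_damaging", "possibly_damaging",
     "disease_causing", "a"}
)
_TOLERATED_TERMS = frozenset(
    {"tolerated", "t", "benign", "neutral", "polymorphism", "n", "p"}
)


def _parse_predictor(raw, path, lineno, column) -> PredictorCall:
    s = _parse_optional(raw)
    if s is None or s.lower() == "missing":
        return PredictorCall.MISSING
    s = s.lower()
    if s in _DAMAGING_TERMS:
        return PredictorCall.DAMAGING
    if s in _TOLERATED_TERMS:
        return PredictorCall.TOLERATED
    raise VariantFormatError(
        f"{path} line {lineno}: unrecognized {column} call {raw!r}"
    )


def read_annotation_table(path) -> list:
    """Read the per-variant annotation TSV.

    Predictor calls are mapped onto damaging/tolerated/missing through a
    fixed vocabulary (e.g. PolyPhen2 ``probably_damaging`` and
    ``possibly_damaging`` both count as damaging).
    """
    annotations = []
    for lineno, row in _open_rows(path, ANNOTATION_COLUMNS[:-1]):
        key = normalize_variant(row["chrom"], row["pos"], row["ref"], row["alt"])
        fc_raw = str(row["functional_class"]).strip().lower()
        try:
            fc = FunctionalClass(fc_raw)
        except ValueError as exc:
            raise VariantFormatError(
                f"{path} line {lineno}: unknown functional_class {row['functional_class']!r}"
            ) from exc
        cadd = _parse_optional(row.get("cadd_phred"))
        annotations.append(
            VariantAnnotation(
                key=key,
                functional_class=fc,
                sift=_parse_predictor(row["sift"], path, lineno, "sift"),
                polyphen2=_parse_predictor(row["polyphen2"], path, lineno, "polyphen2"),
                mutationtaster=_parse_predictor(
                    row["mutationtaster"], path, lineno, "mutationtaster"
                ),
                metasvm=_parse_predictor(row["metasvm"], path, lineno, "metasvm"),
                cadd_phred=float(cadd) if cadd is not None else None,
            )
        )
    return annotations


def write_annotation_table(annotations: Iterable[VariantAnnotation], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for a in annotations:
            writer.writerow(
                [
                    a.key.chrom,
                    a.key.pos,
                    a.key.ref,
                    a.key.alt,
                    a.functional_class.value,
                    a.sift.value,
                    a.polyphen2.value,
                    a.mutationtaster.value,
                    a.metasvm.value,
                    f"{a.cadd_phred:g}" if a.cadd_phred is not None else "",
                ]
            )


def read_quality_table(path) -> list:
    quality = []
    for lineno, row in _open_rows(path, QUALITY_COLUMNS):
        key = normalize_variant(row["chrom"], row["pos"], row["ref"], row["alt"])
        quality.append(
            QualityEvidence(
                key=key,
                called_proton=_parse_bool(row["called_proton"], path, lineno, "called_proton"),
                called_illumina=_parse_bool(
                    row["called_illumina"], path, lineno, "called_illumina"
                ),
                is_snv=_parse_bool(row["is_snv"], path, lineno, "is_snv"),
                quality_score=float(row["quality_score"]),
                depth=int(row["depth"]),
                sanger_confirmed=_parse_bool(
                    row["sanger_confirmed"], path, lineno, "sanger_confirmed"
                ),
            )
        )
    return quality


def write_quality_table(quality: Iterable[QualityEvidence], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(QUALITY_COLUMNS)
        for q in quality:
            writer.writerow(
                [
                    q.key.chrom,
                    q.key.pos,
                    q.key.ref,
                    q.key.alt,
                    int(q.called_proton),
                    int(q.called_illumina),
                    int(q.is_snv),
                    f"{q.quality_score:g}",
                    q.depth,
                    int(q.sanger_confirmed),
                ]
            )


# ---------------------------------------------------------------------------
# Joining
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JoinedRecord:
    """One assertion together with whatever evidence joined to its key.

    Absent evidence stays ``None`` — downstream rules treat a missing public
    frequency as "not observed", which fails every >= / > threshold test and
    satisfies every < threshold requirement.
    """

    assertion: MorbidAssertion
    public: Optional[PublicFrequency] = None
    cohort: Optional[CohortCounts] = None
    annotation: Optional[VariantAnnotation] = None
    quality: Optional[QualityEvidence] = None


def merge_public_fragments(fragments: Iterable[PublicFrequency]) -> dict:
    """Merge per-role fragments into one PublicFrequency per key.

    A later fragment for the same key and the same role is ignored with a
    logged warning (first occurrence wins); fragments for different roles
    combine into a single record.
    """
    merged: dict = {}
    for frag in fragments:
        existing = merged.get(frag.key)
        if existing is None:
            merged[frag.key] = frag
            continue
        updates = {}
        for f in ("af_1000g", "af_exac", "af_kaviar", "hom_1000g", "hom_exac"):
            new = getattr(frag, f)
            if new is None:
                continue
            if getattr(existing, f) is not None:
                logger.warning(
                    "duplicate public fragment for %s field %s; keeping first", frag.key, f
                )
                continue
            updates[f] = new
        if updates:
            merged[frag.key] = replace(existing, **updates)
    return merged


def _index_unique(items, what: str) -> dict:
    index: dict = {}
    for item in items:
        if item.key in index:
            raise DuplicateKeyError(f"duplicate {what} rows for key {item.key}")
        index[item.key] = item
    return index


def join_evidence(
    assertions: Sequence[MorbidAssertion],
    public_fragments: Iterable[PublicFrequency] = (),
    cohort_counts: Iterable[CohortCounts] = (),
    annotations: Iterable[VariantAnnotation] = (),
    quality: Iterable[QualityEvidence] = (),
) -> list:
    """Join all evidence tables onto the assertion list by normalized key.

    Returns one :class:`JoinedRecord` per assertion, in assertion order.
    Duplicate cohort (or annotation/quality) rows for one key raise
    :class:`DuplicateKeyError`; duplicate assertions are legitimate (multiple
    submissions per variant) and each receives its own joined record.
    """
    public_index = merge_public_fragments(public_fragments)
    cohort_index = _index_unique(cohort_counts, "cohort")
    annotation_index = _index_unique(annotations, "annotation")
    quality_index = _index_unique(quality, "quality")
    return [
        JoinedRecord(
            assertion=a,
            public=public_index.get(a.key),
            cohort=cohort_index.get(a.key),
            annotation=annotation_index.get(a.key),
            quality=quality_index.get(a.key),
        )
        for a in assertions
    ]
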