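"""Triage of BRCA1/BRCA2 variants of uncertain significance.

Biallelic pathogenic BRCA2 causes fully penetrant Fanconi anemia, so a
homozygote lacking that phenotype is evidence against pathogenicity.  The
screen combines the cohort allele frequency (strictly above 1%) with the
count of Fanconi-free homozygotes.
"""
import morbidgenome as mg

def vous(pos):
    return mg.MorbidAssertion(
        key=mg.VariantKey("13", pos, "A", "G"),
        source=mg.Source.BRCA_EXCHANGE,
        assertion_class=mg.AssertionClass.VOUS,
        gene="BRCA2",
        inheritance=mg.Inheritance.RECESSIVE,
        disease_label="Fanconi anemia",
    )

def cohort(pos, no_het, no_hom, fanconi_free):
    return mg.CohortCounts(
        key=mg.VariantKey("13", pos, "A", "G"),
        no_het=no_het, no_hom=no_hom, no_screened=5849,
        hom_phenotype_free=no_hom, fanconi_free_hom=fanconi_free,
    )

assertions = [vous(100), vous(200), vous(300), vous(400)]
rows = [
    cohort(100, no_het=300, no_hom=3, fanconi_free=3),   # common + free homs
    cohort(200, no_het=300, no_hom=0, fanconi_free=0),   # common, never homozygous
    cohort(300, no_het=40, no_hom=1, fanconi_free=1),    # rare but one free hom
    cohort(400, no_het=40, no_hom=0, fanconi_free=0),    # rare, no homs
]

for verdict in mg.screen_brca(assertions, rows):
    sgp = float(verdict.sgp_af)
    print(
        f"pos {verdict.assertion.key.pos}: SGP_AF={sgp:.5f} "
        f"fanconi_free_hom={verdict.fanconi_free_hom} -> {verdict.category.value}"
    )

print(
    "\nbenign needs both lines of evidence (AF > 1% and a Fanconi-free"
    "\nhomozygote); frequency or zygosity alone yields frequent_only or"
    "\nbs2_only, and a rare never-homozygous variant stays unchanged."
)
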