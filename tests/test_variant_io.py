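"""Variant-key normalization, tabular dialects, and evidence joining."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import morbidgenome as mg
from morbidgenome.variant_io import (
    DuplicateKeyError,
    InvalidVariantError,
    VariantFormatError,
    merge_public_fragments,
    write_morbid_table,
)

BASES = "ACGT"


class TestNormalizeVariant:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            (("1", 1000, "CT", "CA"), ("1", 1001, "T", "A")),
            (("2", 500, "A", "G"), ("2", 500, "A", "G")),
            (("chr3", 42, "a", "t"), ("3", 42, "A", "T")),
            # anchored indels keep one shared base
            (("1", 10, "C", "CA"), ("1", 10, "C", "CA")),
            (("1", 10, "CTT", "CT"), ("1", 10, "CT", "C")),
            # shared suffix trimmed before prefix
            (("4", 7, "AC", "AGC"), ("4", 7, "A", "AG")),
        ],
    )
    def test_examples(self, raw, expected):
        key = mg.normalize_variant(*raw)
        assert (key.chrom, key.pos, key.ref, key.alt) == expected

    @pytest.mark.parametrize(
        "raw",
        [
            ("3", 700, "A", "A"),
            ("1", 5, "AN", "A"),
            ("1", 5, "", "A"),
            ("99", 5, "A", "C"),
            ("1", 0, "A", "C"),
        ],
    )
    def test_invalid_inputs_rejected(self, raw):
        with pytest.raises(InvalidVariantError):
            mg.normalize_variant(*raw)

    @given(
        chrom=st.sampled_from([str(i) for i in range(1, 23)] + ["X", "Y", "MT"]),
        pos=st.integers(1, 10**6),
        ref=st.text(BASES, min_size=1, max_size=6),
        alt=st.text(BASES, min_size=1, max_size=6),
    )
    def test_idempotent(self, chrom, pos, ref, alt):
        if ref == alt:
            return
        key = mg.normalize_variant(chrom, pos, ref, alt)
        again = mg.normalize_variant(key.chrom, key.pos, key.ref, key.alt)
        assert again == key

    def test_normalization_preserves_the_edit(self):
        """Applying raw and normalized edits to a sequence must agree.

        Checked over 1000 random substitution/indel cases embedded in a
        random 50-bp sequence.
        """
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            seq = "".join(rng.choice(list(BASES), size=50))
            start = int(rng.integers(1, 40))  # 1-based
            ref_len = int(rng.integers(1, 6))
            ref = seq[start - 1 : start - 1 + ref_len]
            alt = "".join(rng.choice(list(BASES), size=int(rng.integers(1, 6))))
            if ref == alt:
                continue
            key = mg.normalize_variant("1", start, ref, alt)

            def apply(pos, r, a):
                assert seq[pos - 1 : pos - 1 + len(r)] == r
                return seq[: pos - 1] + a + seq[pos - 1 + len(r) :]

            assert apply(start, ref, alt) == apply(key.pos, key.ref, key.alt)


class TestMorbidTables:
    def _write(self, path, rows, header="chrom\tpos\tref\talt\tgene\tclass\tinheritance\tdisease\thgvs"):
        path.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))
        return path

    def test_hgmd_dialect_classes(self, tmp_path):
        path = self._write(
            tmp_path / "m.tsv",
            [
                "1\t100\tA\tG\tGJB2\tDM\trecessive\tdeafness\t.",
                "2\t200\tC\tT\tGJB2\tDM?\trecessive\tdeafness\t.",
                "3\t300\tG\tA\tTTN\tDP\tunknown\tcardiomyopathy\t.",
            ],
        )
        assertions = mg.read_morbid_table(path, "hgmd")
        assert [a.assertion_class.value for a in assertions] == ["DM", "DM?", "DP"]
        assert all(a.source is mg.Source.HGMD for a in assertions)

    def test_clinvar_uncertain_significance_maps_to_vous(self, tmp_path):
        path = self._write(
            tmp_path / "m.tsv",
            ["1\t100\tA\tG\tBRCA2\tUncertain significance\tunknown\tFanconi\t."],
        )
        (assertion,) = mg.read_morbid_table(path, "clinvar")
        assert assertion.assertion_class is mg.AssertionClass.VOUS

    def test_out_of_vocabulary_class_rejected_and_logged(self, tmp_path, caplog):
        path = self._write(
            tmp_path / "m.tsv",
            [
                "1\t100\tA\tG\tGJB2\tPathogenic\trecessive\tdeafness\t.",
                "2\t200\tC\tT\tGJB2\tDM\trecessive\tdeafness\t.",
            ],
        )
        with caplog.at_level("WARNING"):
            assertions = mg.read_morbid_table(path, "hgmd")
        assert len(assertions) == 1
        assert "rejected" in caplog.text

    def test_missing_column_names_the_column(self, tmp_path):
        path = (tmp_path / "m.tsv")
        path.write_text("chrom\tpos\tref\talt\tgene\tinheritance\tdisease\n")
        with pytest.raises(VariantFormatError, match="class"):
            mg.read_morbid_table(path, "hgmd")

    def test_unknown_dialect(self, tmp_path):
        path = self._write(tmp_path / "m.tsv", [])
        with pytest.raises(ValueError, match="dialect"):
            mg.read_morbid_table(path, "omim")

    def test_round_trip(self, tmp_path):
        path = self._write(
            tmp_path / "m.tsv",
            [
                "1\t100\tA\tG\tGJB2\tDM\trecessive\tdeafness\tNM_004004.5:c.35delG",
                "X\t999\tCT\tC\tF8\tDM?\tunknown\themophilia\t",
            ],
        )
        assertions = mg.read_morbid_table(path, "hgmd")
        out = tmp_path / "round.tsv"
        write_morbid_table(assertions, out)
        assert mg.read_morbid_table(out, "hgmd") == assertions


class TestFrequencyTables:
    def test_tsv_fragment(self, tmp_path):
        path = tmp_path / "f.tsv"
        path.write_text("chrom\tpos\tref\talt\taf\thom\n1\t100\tA\tG\t0.051\t3\n")
        (frag,) = mg.read_frequency_table(path, "exac")
        assert frag.af_exac == pytest.approx(0.051)
        assert frag.hom_exac == 3
        assert frag.af_1000g is None

    def test_kaviar_role_ignores_hom_column(self, tmp_path):
        path = tmp_path / "f.tsv"
        path.write_text("chrom\tpos\tref\talt\taf\thom\n1\t100\tA\tG\t0.2\t5\n")
        (frag,) = mg.read_frequency_table(path, "kaviar")
        assert frag.af_kaviar == pytest.approx(0.2)
        assert frag.hom_1000g is None and frag.hom_exac is None

    def test_af_out_of_range(self, tmp_path):
        path = tmp_path / "f.tsv"
        path.write_text("chrom\tpos\tref\talt\taf\n1\t100\tA\tG\t1.7\n")
        with pytest.raises(VariantFormatError, match="line 2"):
            mg.read_frequency_table(path, "1000g")

    def test_vcf_input(self, tmp_path):
        path = tmp_path / "f.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=AF,Number=A,Type=Float,Description="AF">\n'
            '##INFO=<ID=Hom,Number=A,Type=Integer,Description="hom count">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "1\t100\t.\tA\tG\t.\t.\tAF=0.5;Hom=3\n"
        )
        (frag,) = mg.read_frequency_table(path, "1000g")
        assert frag.af_1000g == pytest.approx(0.5)
        assert frag.hom_1000g == 3


class TestJoinEvidence:
    def _assertion(self, key):
        return mg.MorbidAssertion(
            key=key, source=mg.Source.HGMD, assertion_class=mg.AssertionClass.DM,
            gene="G", inheritance=mg.Inheritance.RECESSIVE, disease_label="d",
        )

    def test_output_count_matches_assertions(self, key):
        other = mg.VariantKey("2", 7, "C", "T")
        assertions = [self._assertion(key), self._assertion(key), self._assertion(other)]
        records = mg.join_evidence(assertions)
        assert len(records) == 3
        assert all(r.public is None and r.cohort is None for r in records)

    def test_fragments_merge_across_roles(self, key):
        frags = [
            mg.PublicFrequency(key=key, af_1000g=0.1),
            mg.PublicFrequency(key=key, af_exac=0.2, hom_exac=1),
            mg.PublicFrequency(key=key, af_kaviar=0.3),
        ]
        (record,) = mg.join_evidence([self._assertion(key)], frags)
        assert (record.public.af_1000g, record.public.af_exac, record.public.af_kaviar) == (
            0.1, 0.2, 0.3,
        )
        assert record.public.hom_exac == 1

    def test_duplicate_same_role_keeps_first(self, key, caplog):
        frags = [
            mg.PublicFrequency(key=key, af_exac=0.2),
            mg.PublicFrequency(key=key, af_exac=0.9),
        ]
        with caplog.at_level("WARNING"):
            merged = merge_public_fragments(frags)
        assert merged[key].af_exac == 0.2

    def test_duplicate_cohort_rows_error(self, key):
        rows = [
            mg.CohortCounts(key=key, no_het=1, no_hom=0, no_screened=10),
            mg.CohortCounts(key=key, no_het=2, no_hom=0, no_screened=10),
        ]
        with pytest.raises(DuplicateKeyError, match="12345"):
            mg.join_evidence([self._assertion(key)], cohort_counts=rows)


class TestTypeInvariants:
    def test_assertion_class_must_match_source_vocabulary(self, key):
        with pytest.raises(VariantFormatError):
            mg.MorbidAssertion(
                key=key, source=mg.Source.HGMD,
                assertion_class=mg.AssertionClass.PATHOGENIC, gene="G",
            )

    def test_cohort_counts_bounds(self, key):
        with pytest.raises(VariantFormatError):
            mg.CohortCounts(key=key, no_het=8, no_hom=3, no_screened=10)
        with pytest.raises(VariantFormatError):
            mg.CohortCounts(key=key, no_het=0, no_hom=1, no_screened=10,
                            hom_phenotype_free=2)

    def test_lof_derivation(self, key):
        lof = mg.VariantAnnotation(key=key, functional_class=mg.FunctionalClass.STOP_GAIN)
        assert lof.is_lof
        assert not mg.VariantAnnotation(
            key=key, functional_class=mg.FunctionalClass.MISSENSE
        ).is_lof

    def test_threshold_config_validation(self):
        with pytest.raises(ValueError):
            mg.ThresholdConfig(af_cohort_low=0.1, af_cohort_common=0.05)
        with pytest.raises(ValueError):
            mg.ThresholdConfig(source_order=("exac", "exac", "kaviar"))
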