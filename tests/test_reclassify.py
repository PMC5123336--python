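"""Criteria engine, advisory rule, BRCA screen, and reciprocal check."""
from fractions import Fraction

import numpy as np
import pytest

import morbidgenome as mg
from morbidgenome.reclassify import (
    BrcaCategory,
    Criterion,
    Outcome,
    ReclassificationResult,
    evaluate_criteria,
    reciprocal_pathogenic_check,
    screen_brca,
)
from morbidgenome.variant_io import JoinedRecord

KEY = mg.VariantKey("1", 100, "A", "G")


def assertion(source=mg.Source.HGMD, cls=mg.AssertionClass.DM, gene="G",
              inheritance=mg.Inheritance.RECESSIVE, key=KEY):
    return mg.MorbidAssertion(key=key, source=source, assertion_class=cls,
                              gene=gene, inheritance=inheritance, disease_label="d")


def record(public=None, cohort=None, **assertion_kwargs):
    return JoinedRecord(assertion=assertion(**assertion_kwargs), public=public,
                        cohort=cohort)


def public(af_1000g=None, af_exac=None, af_kaviar=None, hom_1000g=None, hom_exac=None):
    return mg.PublicFrequency(key=KEY, af_1000g=af_1000g, af_exac=af_exac,
                              af_kaviar=af_kaviar, hom_1000g=hom_1000g,
                              hom_exac=hom_exac)


def cohort_for(sgp, hom_free, screened=10000):
    """Construct counts realizing a target SGP_AF with given free homs."""
    no_hom = hom_free
    no_het = round(2 * sgp * (screened - no_hom))
    return mg.CohortCounts(key=KEY, no_het=no_het, no_hom=no_hom,
                           no_screened=screened, hom_phenotype_free=hom_free)


class TestEvaluateCriteria:
    def test_c1_public_frequency(self):
        r = evaluate_criteria(record(public=public(af_exac=0.06)))
        assert (r.criterion, r.outcome) == (Criterion.C1, Outcome.BENIGN)

    def test_c2_cohort_common_public_rare(self):
        r = evaluate_criteria(
            record(public=public(af_1000g=0.04), cohort=cohort_for(0.07, 0))
        )
        assert (r.criterion, r.outcome) == (Criterion.C2, Outcome.BENIGN)

    def test_c3_low_frequency_with_phenotype_free_hom(self):
        r = evaluate_criteria(record(cohort=cohort_for(0.02, 1)))
        assert (r.criterion, r.outcome) == (Criterion.C3, Outcome.BENIGN)

    def test_c4_rare_with_phenotype_free_hom_is_bs2_only(self):
        r = evaluate_criteria(record(cohort=cohort_for(0.005, 1)))
        assert (r.criterion, r.outcome) == (Criterion.C4, Outcome.BS2_ONLY)

    def test_rare_without_free_hom_unchanged(self):
        r = evaluate_criteria(record(cohort=cohort_for(0.005, 0)))
        assert (r.criterion, r.outcome) == (Criterion.NONE, Outcome.UNCHANGED)

    def test_c1_precedence_over_c2(self):
        r = evaluate_criteria(
            record(public=public(af_1000g=0.06), cohort=cohort_for(0.07, 0))
        )
        assert r.criterion is Criterion.C1

    def test_missing_public_counts_as_below_threshold(self):
        r = evaluate_criteria(record(cohort=cohort_for(0.07, 0)))
        assert r.criterion is Criterion.C2

    def test_inclusive_boundaries(self):
        assert evaluate_criteria(record(public=public(af_exac=0.05))).criterion is Criterion.C1
        assert evaluate_criteria(record(cohort=cohort_for(0.05, 0))).criterion is Criterion.C2
        assert evaluate_criteria(record(cohort=cohort_for(0.01, 1))).criterion is Criterion.C3

    def test_degenerate_cohort_becomes_none_with_warning(self):
        degenerate = mg.CohortCounts(key=KEY, no_het=0, no_hom=5, no_screened=5,
                                     hom_phenotype_free=5)
        r = evaluate_criteria(record(cohort=degenerate))
        assert r.criterion is Criterion.NONE
        assert r.warning is not None and r.evidence["cohort"]["degenerate"]

    def test_dp_class_rejected_unless_enabled(self):
        rec = record(cls=mg.AssertionClass.DP)
        with pytest.raises(ValueError):
            evaluate_criteria(rec)
        assert evaluate_criteria(rec, include_dp_dfp=True).criterion is Criterion.NONE

    def test_criterion_outcome_invariant_enforced(self):
        with pytest.raises(ValueError):
            ReclassificationResult(
                assertion=assertion(), criterion=Criterion.C4, outcome=Outcome.BENIGN,
                public_verdict=mg.evaluate_public(None, 0.05),
            )

    def test_threshold_monotonicity(self):
        """Lowering the benign thresholds never loses BENIGN outcomes."""
        rng = np.random.default_rng(42)
        records = []
        for _ in range(300):
            pub = public(
                af_1000g=round(float(rng.uniform(0, 0.1)), 4) if rng.random() < 0.5 else None,
                af_exac=round(float(rng.uniform(0, 0.1)), 4) if rng.random() < 0.5 else None,
            )
            coh = None
            if rng.random() < 0.7:
                hom_free = int(rng.integers(0, 3))
                coh = cohort_for(float(rng.uniform(0, 0.09)), hom_free)
            records.append(record(public=pub, cohort=coh))

        def benign_count(cfg):
            return sum(
                evaluate_criteria(r, cfg).outcome is Outcome.BENIGN for r in records
            )

        base = mg.ThresholdConfig()
        lower_public = mg.ThresholdConfig(af_benign_public=0.03)
        lower_cohort = mg.ThresholdConfig(af_cohort_low=0.005)
        assert benign_count(lower_public) >= benign_count(base)
        assert benign_count(lower_cohort) >= benign_count(base)

    def test_every_record_receives_exactly_one_criterion(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            pub = public(af_exac=round(float(rng.uniform(0, 0.1)), 4)) if rng.random() < 0.5 else None
            coh = cohort_for(float(rng.uniform(0, 0.08)), int(rng.integers(0, 2))) if rng.random() < 0.7 else None
            r = evaluate_criteria(record(public=pub, cohort=coh))
            assert r.criterion in set(Criterion)
            assert r.outcome in set(Outcome)


class TestAcmgInheritanceRule:
    def test_dominant_frequency_alone(self):
        rec = record(public=public(af_exac=0.02), inheritance=mg.Inheritance.DOMINANT)
        assert mg.acmg_inheritance_rule(rec, mg.ThresholdConfig())

    def test_recessive_needs_hom_support(self):
        cfg = mg.ThresholdConfig()
        no_hom = record(public=public(af_exac=0.02))
        assert not mg.acmg_inheritance_rule(no_hom, cfg)
        with_hom = record(public=public(af_exac=0.02, hom_exac=3))
        assert mg.acmg_inheritance_rule(with_hom, cfg)

    def test_unknown_treated_as_recessive(self):
        rec = record(public=public(af_exac=0.02), inheritance=mg.Inheritance.UNKNOWN)
        assert not mg.acmg_inheritance_rule(rec, mg.ThresholdConfig())

    def test_strict_inequality_at_one_percent(self):
        rec = record(public=public(af_exac=0.01), inheritance=mg.Inheritance.DOMINANT)
        assert not mg.acmg_inheritance_rule(rec, mg.ThresholdConfig())


def brca_assertion(cls=mg.AssertionClass.VOUS, key=KEY):
    return assertion(source=mg.Source.BRCA_EXCHANGE, cls=cls, gene="BRCA2", key=key)


def brca_cohort(sgp, fanconi_free, screened=10000):
    no_hom = max(fanconi_free, 0)
    no_het = round(2 * sgp * (screened - no_hom))
    return mg.CohortCounts(key=KEY, no_het=no_het, no_hom=no_hom,
                           no_screened=screened, hom_phenotype_free=no_hom,
                           fanconi_free_hom=fanconi_free)


class TestScreenBrca:
    @pytest.mark.parametrize(
        "sgp, fanconi_free, expected",
        [
            (0.02, 2, BrcaCategory.BENIGN),
            (0.02, 0, BrcaCategory.FREQUENT_ONLY),
            (0.004, 1, BrcaCategory.BS2_ONLY),
            (0.004, 0, BrcaCategory.UNCHANGED),
        ],
    )
    def test_rule_table(self, sgp, fanconi_free, expected):
        (verdict,) = screen_brca([brca_assertion()], [brca_cohort(sgp, fanconi_free)])
        assert verdict.category is expected

    def test_threshold_is_strict(self):
        (verdict,) = screen_brca([brca_assertion()], [brca_cohort(0.01, 0)])
        assert verdict.category is BrcaCategory.UNCHANGED

    def test_non_brca_source_rejected(self):
        with pytest.raises(ValueError):
            screen_brca([assertion()], [])

    def test_pathogenic_class_routed_to_reciprocal(self):
        (verdict,) = screen_brca(
            [brca_assertion(cls=mg.AssertionClass.PATHOGENIC)],
            [brca_cohort(0.02, 2)],
        )
        assert verdict.category is BrcaCategory.UNCHANGED

    def test_missing_cohort_row_unchanged(self):
        (verdict,) = screen_brca([brca_assertion()], [])
        assert verdict.category is BrcaCategory.UNCHANGED


class TestReciprocalCheck:
    def test_phenotype_free_hom_is_violation(self):
        a = brca_assertion(cls=mg.AssertionClass.PATHOGENIC)
        violations, consistent = reciprocal_pathogenic_check([a], [brca_cohort(0.001, 1)])
        assert len(violations) == 1 and violations[0].is_violation
        assert consistent == []

    def test_diseased_homozygotes_are_consistent(self):
        a = brca_assertion(cls=mg.AssertionClass.PATHOGENIC)
        row = mg.CohortCounts(key=KEY, no_het=3, no_hom=2, no_screened=10000,
                              hom_phenotype_free=2, fanconi_free_hom=0)
        violations, consistent = reciprocal_pathogenic_check([a], [row])
        assert violations == []
        assert len(consistent) == 1 and consistent[0].no_hom == 2

    def test_non_brca_uses_phenotype_free_count(self):
        a = assertion(source=mg.Source.CLINVAR, cls=mg.AssertionClass.PATHOGENIC)
        row = mg.CohortCounts(key=KEY, no_het=0, no_hom=1, no_screened=100,
                              hom_phenotype_free=1)
        violations, _ = reciprocal_pathogenic_check([a], [row])
        assert len(violations) == 1

    def test_empty_inputs(self):
        assert reciprocal_pathogenic_check([], []) == ([], [])

    def test_dm_included_only_on_request(self):
        a = assertion(cls=mg.AssertionClass.DM)
        row = mg.CohortCounts(key=KEY, no_het=0, no_hom=1, no_screened=100,
                              hom_phenotype_free=1)
        assert reciprocal_pathogenic_check([a], [row]) == ([], [])
        violations, _ = reciprocal_pathogenic_check([a], [row], include_dm=True)
        assert len(violations) == 1


class TestRunReclassification:
    def test_empty_inputs_produce_empty_outputs(self, tmp_path):
        run = mg.run_reclassification([], out_dir=tmp_path)
        assert run.results == [] and run.violations == []
        criteria = mg.summarize_by_criterion(run.results)
        assert int(criteria.loc["total", "total"]) == 0
        assert (tmp_path / "results.tsv").exists()

    def test_planted_bundle_recovered(self, small_bundle, small_bundle_data):
        from morbidgenome.simulate import TRUTH_EXPECTED, read_truth_table

        data = small_bundle_data
        run = mg.run_reclassification(
            data["assertions"], data["fragments"], data["cohort"],
            data["annotations"], data["quality"],
        )
        truth = read_truth_table(small_bundle.truth)
        assert len(run.results) == len(truth)
        for r in run.results:
            expected = TRUTH_EXPECTED[truth[r.assertion.key]]
            assert (r.criterion.value, r.outcome.value) == expected
        assert run.violations == []
        assert len(run.consistent) == sum(
            1 for c in truth.values() if c == "PATHOGENIC_CONSISTENT"
        )

    def test_bs2_only_never_at_or_above_low_threshold(self, small_bundle_data):
        data = small_bundle_data
        run = mg.run_reclassification(
            data["assertions"], data["fragments"], data["cohort"],
            data["annotations"], data["quality"],
        )
        for r in run.results:
            if r.outcome is Outcome.BS2_ONLY:
                assert r.sgp_af < Fraction(1, 100)
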