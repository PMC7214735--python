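"""Evidence-grading rubric, grouped columns and the heat-map matrix."""

import random

import pandas as pd
import pytest

from approvalmeta.corpus import (
    ApprovalRecord,
    ArmComparison,
    ArmRecord,
    ComparatorClass,
    DesignPhase,
    Hypothesis,
    NIVerdict,
)
from approvalmeta.grading import (
    EvidenceColumn,
    GradeCategory,
    TrialVerdict,
    derive_trial_effects,
    grade_approval,
    grade_corpus,
    grade_trial,
    heatmap_legend,
    heatmap_matrix,
)
from approvalmeta.corpus import TrialRecord


def _trial(tid, phase="initiation", hypothesis="superiority", d=None,
           comparator="placebo", compared=True, ni_verdict="not_applicable",
           nib=None, contrast=None, contrast_se=None, pooled=False):
    role = "active_comparator" if comparator == "active" else "placebo"
    arms = [
        ArmRecord(arm_id=f"{tid}_i", role="investigational", daily_dose=20.0,
                  n_randomised=100,
                  mean_change=d if d is not None else None,
                  sd_change=1.0 if d is not None else None),
        ArmRecord(arm_id=f"{tid}_c", role=role, n_randomised=100,
                  mean_change=0.0 if d is not None else None,
                  sd_change=1.0 if d is not None else None),
    ]
    comparisons = []
    if compared:
        comparisons.append(ArmComparison(
            trial_id=tid, investigational_arm_id=f"{tid}_i",
            comparator_arm_id=f"{tid}_c", comparator_class=comparator,
            reporting_tier="arm_stats" if d is not None else "insufficient",
            contrast_value=contrast, contrast_se=contrast_se,
        ))
    return TrialRecord(trial_id=tid, design_phase=phase, hypothesis=hypothesis,
                       reported_ni_verdict=ni_verdict,
                       non_inferiority_boundary=nib, pooled_analysis=pooled,
                       arms=arms, comparisons=comparisons)


def _verdict(trial, comparator=ComparatorClass.placebo):
    return grade_trial(trial, derive_trial_effects(trial), comparator)


class TestTrialVerdicts:
    def test_significant_in_favour_is_positive(self):
        # d = -0.5 at n=100/arm: p ~ 5e-4
        assert _verdict(_trial("t", d=-0.5)) is TrialVerdict.positive

    def test_nonsignificant_is_negative(self):
        assert _verdict(_trial("t", d=-0.05)) is TrialVerdict.negative

    def test_significant_against_drug_is_negative(self):
        assert _verdict(_trial("t", d=0.5)) is TrialVerdict.negative

    def test_comparator_arm_without_comparison_is_uncompared(self):
        """The 'internal positive control for assay sensitivity' pattern."""
        t = _trial("t", comparator="active", compared=False)
        assert _verdict(t, ComparatorClass.active) is TrialVerdict.uncompared

    def test_absent_comparator_class_not_applicable(self):
        assert _verdict(_trial("t", d=-0.5), ComparatorClass.active) \
            is TrialVerdict.not_applicable

    def test_ni_verdicts_taken_from_report(self):
        t = _trial("t", hypothesis="non_inferiority", comparator="active",
                   d=-0.05, ni_verdict="negative", nib=2.0)
        assert _verdict(t, ComparatorClass.active) is TrialVerdict.negative
        t = _trial("t", hypothesis="non_inferiority", comparator="active",
                   d=-0.05, ni_verdict="positive", nib=2.0)
        assert _verdict(t, ComparatorClass.active) is TrialVerdict.positive

    def test_ni_judged_from_ci_and_boundary_when_no_verdict(self):
        # upper CI bound 0.5 + 1.96*0.5 = 1.48 < NIB 2.0 -> non-inferior
        t = _trial("t", hypothesis="non_inferiority", comparator="active",
                   compared=True, nib=2.0, contrast=0.5, contrast_se=0.5)
        t.comparisons[0].reporting_tier = "contrast_only"
        assert _verdict(t, ComparatorClass.active) is TrialVerdict.positive
        # upper bound 1.0 + 1.96*1.0 = 2.96 > 2.0 -> not demonstrated
        t = _trial("t", hypothesis="non_inferiority", comparator="active",
                   compared=True, nib=2.0, contrast=1.0, contrast_se=1.0)
        t.comparisons[0].reporting_tier = "contrast_only"
        assert _verdict(t, ComparatorClass.active) is TrialVerdict.negative


def _approval(trials, **flags):
    fields = dict(approval_id="A", drug="d", route="oral", indication="i",
                  year=2010, approved_dose_min=10.0, approved_dose_max=40.0,
                  trials=trials)
    fields.update(flags)
    return ApprovalRecord(**fields)


def _grade(app, column):
    return next(g for g in grade_approval(app) if g.column is column)


class TestApprovalGrades:
    def test_two_positive_trials_are_robust(self):
        app = _approval([
            _trial("t1", d=-0.5, comparator="active"),
            _trial("t2", d=-0.6, comparator="active"),
        ])
        g = _grade(app, EvidenceColumn.superiority_vs_active_initiation)
        assert g.category is GradeCategory.robust
        assert g.n_positive == 2

    def test_one_positive_with_negatives_is_single(self):
        app = _approval([
            _trial("t1", hypothesis="non_inferiority", comparator="active",
                   d=-0.05, ni_verdict="positive", nib=2.0),
            _trial("t2", hypothesis="non_inferiority", comparator="active",
                   d=-0.05, ni_verdict="negative", nib=2.0),
            _trial("t3", hypothesis="non_inferiority", comparator="active",
                   d=-0.05, ni_verdict="negative", nib=2.0),
        ])
        g = _grade(app, EvidenceColumn.non_inferiority_vs_active)
        assert g.category is GradeCategory.single
        assert g.n_negative == 2

    def test_uncompared_only_is_none(self):
        app = _approval([_trial("t1", comparator="active", compared=False)])
        g = _grade(app, EvidenceColumn.superiority_vs_active_initiation)
        assert g.category is GradeCategory.none
        assert g.n_uncompared == 1

    def test_not_required_flags(self):
        app = _approval([_trial("t1", d=-0.5)],
                        comparative_evidence_required=False)
        for col in (EvidenceColumn.superiority_vs_active_initiation,
                    EvidenceColumn.non_inferiority_vs_active,
                    EvidenceColumn.continuation_vs_active,
                    EvidenceColumn.active_grouped):
            assert _grade(app, col).category is GradeCategory.not_required
        # the placebo column is still graded normally
        assert _grade(app, EvidenceColumn.superiority_vs_placebo_initiation) \
            .category is GradeCategory.single

    def test_pooled_analysis_counts_per_analysis(self):
        app = _approval([
            _trial("t1", hypothesis="non_inferiority", comparator="active",
                   compared=False, ni_verdict="positive", nib=2.0, pooled=True),
            _trial("t2", hypothesis="non_inferiority", comparator="active",
                   compared=False, ni_verdict="positive", nib=2.0, pooled=True),
        ])
        g = _grade(app, EvidenceColumn.non_inferiority_vs_active)
        assert g.category is GradeCategory.robust

    def test_grouped_is_max_evidence_not_count_sum(self):
        """One positive initiation + one positive continuation trial group to
        'single', not 'robust'."""
        app = _approval([
            _trial("t1", d=-0.5),
            _trial("t2", d=-0.5, phase="continuation"),
        ])
        g = _grade(app, EvidenceColumn.placebo_grouped)
        assert g.category is GradeCategory.single

    def test_grades_invariant_to_trial_order(self):
        trials = [
            _trial("t1", d=-0.5), _trial("t2", d=-0.05),
            _trial("t3", d=-0.6, comparator="active"),
            _trial("t4", d=-0.4, phase="continuation"),
        ]
        baseline = {(g.column, g.category, g.n_positive)
                    for g in grade_approval(_approval(trials))}
        rng = random.Random(3)
        for _ in range(5):
            shuffled = trials[:]
            rng.shuffle(shuffled)
            assert {(g.column, g.category, g.n_positive)
                    for g in grade_approval(_approval(shuffled))} == baseline


class TestHeatmap:
    def test_codes_and_na(self, fixture_corpus):
        grades = grade_corpus(fixture_corpus)
        m = heatmap_matrix(fixture_corpus, grades)
        assert m.shape == (27, 12)
        # olanzapine: robust superiority vs active and vs placebo
        assert m.loc["P01", "superiority_vs_active_initiation"] == 2
        assert m.loc["P01", "superiority_vs_placebo_initiation"] == 2
        # nalmefene: comparative evidence not required -> NA, never 0
        assert pd.isna(m.loc["P27", "superiority_vs_active_initiation"])
        # paliperidone: divergent opinion coded red
        assert m.loc["P05", "divergent_opinion"] == 0
        assert m.loc["P01", "divergent_opinion"] == 2

    def test_category_counts_sum_to_required_denominator(self, fixture_corpus):
        grades = grade_corpus(fixture_corpus)
        for col in EvidenceColumn:
            col_grades = [g for g in grades if g.column is col]
            required = [g for g in col_grades
                        if g.category is not GradeCategory.not_required]
            by_cat = {}
            for g in required:
                by_cat[g.category] = by_cat.get(g.category, 0) + 1
            assert sum(by_cat.values()) == len(required)
            assert len(col_grades) == 27

    def test_legend_covers_every_column_group(self):
        legend = heatmap_legend()
        assert set(legend) == {
            "evidence_columns", "subgroup_basis", "bias_assessment",
            "safety_issue", "tolerance_issue", "divergent_opinion",
        }


@pytest.fixture(scope="module")
def tallies(fixture_corpus):
    grades = grade_corpus(fixture_corpus)

    def tally(column):
        out = {c.value: 0 for c in GradeCategory}
        for g in grades:
            if g.column is column:
                out[g.category.value] += 1
        return out

    return {c: tally(c) for c in EvidenceColumn}, grades


class TestFixtureTallies:
    """The corpus reproduces every enumerated category count."""

    def test_superiority_vs_active(self, tallies):
        t, grades = tallies
        assert t[EvidenceColumn.superiority_vs_active_initiation] == {
            "robust": 2, "single": 3, "none": 21, "not_required": 1}
        # the 21 'none' split into 9 uncompared-only, 9 no-study, 3 negative
        none_grades = [
            g for g in grades
            if g.column is EvidenceColumn.superiority_vs_active_initiation
            and g.category is GradeCategory.none
        ]
        negative = sum(1 for g in none_grades if g.n_negative > 0)
        uncompared = sum(1 for g in none_grades
                         if g.n_negative == 0 and g.n_uncompared > 0)
        no_study = sum(1 for g in none_grades
                       if g.n_negative == 0 and g.n_uncompared == 0)
        assert (negative, uncompared, no_study) == (3, 9, 9)

    def test_non_inferiority_vs_active(self, tallies):
        t, _ = tallies
        assert t[EvidenceColumn.non_inferiority_vs_active] == {
            "robust": 1, "single": 8, "none": 17, "not_required": 1}

    def test_superiority_vs_placebo(self, tallies):
        t, _ = tallies
        assert t[EvidenceColumn.superiority_vs_placebo_initiation] == {
            "robust": 20, "single": 3, "none": 4, "not_required": 0}

    def test_continuation_columns(self, tallies):
        t, _ = tallies
        assert t[EvidenceColumn.continuation_vs_active] == {
            "robust": 0, "single": 1, "none": 20, "not_required": 6}
        assert t[EvidenceColumn.continuation_vs_placebo] == {
            "robust": 0, "single": 16, "none": 6, "not_required": 5}

    def test_grouped_placebo(self, tallies):
        t, _ = tallies
        assert t[EvidenceColumn.placebo_grouped] == {
            "robust": 20, "single": 7, "none": 0, "not_required": 0}
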