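"""Grade each approval's evidence base against the appraisal rubric.

The rubric classifies, per approval and per comparison class, how much
randomised evidence the dossier contains:

* ``robust`` — at least two positive studies;
* ``single`` — exactly one positive study (negatives allowed alongside);
* ``none`` — only negative studies, comparator arms never formally compared
  with the investigational drug ("internal positive control for assay
  sensitivity"), or no study at all;
* ``not_required`` — the dossier explicitly did not require that kind of
  evidence.

A superiority trial is *positive* when its primary comparison is statistically
significant (two-sided p < 0.05) in the investigational drug's favour;
*negative* when compared but not significant (or significant against the
drug); and *uncompared* when a comparator arm is present but no
drug-vs-comparator comparison is reported.  Non-inferiority trials are judged
by the dossier's reported verdict, or, failing that, by whether the
unfavourable bound of the contrast CI stays within the non-inferiority
boundary.  Pooled-analysis records count per analysis via their reported
verdict.

Seven evidence columns are graded; the two *grouped* columns take the
max-evidence category across the initiation and continuation columns of the
same comparator class.  Together with five dossier-level flag columns
(subgroup basis, bias assessment, safety issue, tolerance issue, divergent
opinion) they form the 12-column heat-map matrix.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import pandas as pd
from scipy import stats

from .corpus import (
    ApprovalRecord,
    ArmComparison,
    BetterIs,
    BiasAssessment,
    ComparatorClass,
    DesignPhase,
    Hypothesis,
    IssueFlag,
    NIVerdict,
    SubgroupBasis,
    TrialRecord,
)
from .effects import EffectEstimate, Unusable, derive_effect

__all__ = [
    "EvidenceColumn",
    "GradeCategory",
    "TrialVerdict",
    "EvidenceGrade",
    "derive_trial_effects",
    "grade_trial",
    "grade_approval",
    "grade_corpus",
    "heatmap_matrix",
    "heatmap_legend",
    "grades_to_frame",
]

_Z975 = float(stats.norm.ppf(0.975))


class EvidenceColumn(str, enum.Enum):
    superiority_vs_active_initiation = "superiority_vs_active_initiation"
    non_inferiority_vs_active = "non_inferiority_vs_active"
    superiority_vs_placebo_initiation = "superiority_vs_placebo_initiation"
    continuation_vs_active = "continuation_vs_active"
    continuation_vs_placebo = "continuation_vs_placebo"
    active_grouped = "active_grouped"
    placebo_grouped = "placebo_grouped"


class GradeCategory(str, enum.Enum):
    robust = "robust"
    single = "single"
    none = "none"
    not_required = "not_required"


_CATEGORY_STRENGTH = {
    GradeCategory.none: 0,
    GradeCategory.single: 1,
    GradeCategory.robust: 2,
}


class TrialVerdict(str, enum.Enum):
    positive = "positive"
    negative = "negative"
    uncompared = "uncompared"
    not_applicable = "not_applicable"


@dataclass(frozen=True)
class EvidenceGrade:
    approval_id: str
    column: EvidenceColumn
    category: GradeCategory
    n_positive: int = 0
    n_negative: int = 0
    n_uncompared: int = 0


EffectMap = Mapping[int, Union[EffectEstimate, Unusable]]


def derive_trial_effects(trial: TrialRecord, hedges: bool = False) -> Dict[int, Union[EffectEstimate, Unusable]]:
    """Effect estimates for every comparison of a trial, keyed by its index."""
    return {
        i: derive_effect(comp, trial, hedges=hedges)
        for i, comp in enumerate(trial.comparisons)
    }


def _ni_ci_positive(trial: TrialRecord, comp: ArmComparison) -> Optional[bool]:
    """Judge non-inferiority from the contrast CI vs the boundary; None if unjudgeable."""
    if (
        trial.non_inferiority_boundary is None
        or comp.contrast_value is None
        or comp.contrast_se is None
    ):
        return None
    nib = trial.non_inferiority_boundary
    if comp.better_is is BetterIs.lower:
        # unfavourable side is the upper bound of (investigational - comparator)
        return comp.contrast_value + _Z975 * comp.contrast_se < nib
    return comp.contrast_value - _Z975 * comp.contrast_se > nib


def grade_trial(
    trial: TrialRecord,
    effects: EffectMap,
    comparator_class: ComparatorClass,
    hypothesis: Optional[Hypothesis] = None,
) -> TrialVerdict:
    """Verdict of one trial against one comparator class.

    ``effects`` maps comparison index (within ``trial.comparisons``) to the
    derived estimate or unusable marker, as produced by
    :func:`derive_trial_effects`.
    """
    hypothesis = hypothesis or trial.hypothesis
    if not trial.comparator_arms(comparator_class):
        return TrialVerdict.not_applicable
    indices = [
        i
        for i, c in enumerate(trial.comparisons)
        if c.comparator_class is comparator_class
    ]
    if hypothesis is Hypothesis.non_inferiority:
        if trial.reported_ni_verdict is NIVerdict.positive:
            return TrialVerdict.positive
        if trial.reported_ni_verdict is NIVerdict.negative:
            return TrialVerdict.negative
        judged = [
            _ni_ci_positive(trial, trial.comparisons[i])
            for i in indices
        ]
        judged = [j for j in judged if j is not None]
        if judged:
            return TrialVerdict.positive if any(judged) else TrialVerdict.negative
        return TrialVerdict.uncompared if not indices else TrialVerdict.negative
    # superiority
    if not indices:
        return TrialVerdict.uncompared
    for i in indices:
        est = effects.get(i)
        if isinstance(est, EffectEstimate) and est.significant and est.favours_investigational:
            return TrialVerdict.positive
    return TrialVerdict.negative


def _column_trials(app: ApprovalRecord, column: EvidenceColumn):
    """(trial, comparator_class) members of one base evidence column."""
    for trial in app.trials:
        if column is EvidenceColumn.superiority_vs_active_initiation:
            if (
                trial.design_phase is DesignPhase.initiation
                and trial.hypothesis is Hypothesis.superiority
            ):
                yield trial, ComparatorClass.active
        elif column is EvidenceColumn.non_inferiority_vs_active:
            if (
                trial.design_phase is DesignPhase.initiation
                and trial.hypothesis is Hypothesis.non_inferiority
            ):
                yield trial, ComparatorClass.active
        elif column is EvidenceColumn.superiority_vs_placebo_initiation:
            if (
                trial.design_phase is DesignPhase.initiation
                and trial.hypothesis is Hypothesis.superiority
            ):
                yield trial, ComparatorClass.placebo
        elif column is EvidenceColumn.continuation_vs_active:
            if trial.design_phase is DesignPhase.continuation:
                yield trial, ComparatorClass.active
        elif column is EvidenceColumn.continuation_vs_placebo:
            if trial.design_phase is DesignPhase.continuation:
                yield trial, ComparatorClass.placebo


_ACTIVE_COLUMNS = {
    EvidenceColumn.superiority_vs_active_initiation,
    EvidenceColumn.non_inferiority_vs_active,
    EvidenceColumn.continuation_vs_active,
    EvidenceColumn.active_grouped,
}
_CONTINUATION_COLUMNS = {
    EvidenceColumn.continuation_vs_active,
    EvidenceColumn.continuation_vs_placebo,
}


def _not_required(app: ApprovalRecord, column: EvidenceColumn) -> bool:
    if column in _ACTIVE_COLUMNS and not app.comparative_evidence_required:
        return True
    if column in _CONTINUATION_COLUMNS and not app.continuation_evidence_required:
        return True
    if column is EvidenceColumn.active_grouped:
        return not app.comparative_evidence_required
    if column is EvidenceColumn.placebo_grouped:
        return False
    return False


def _category_from_counts(n_positive: int) -> GradeCategory:
    if n_positive >= 2:
        return GradeCategory.robust
    if n_positive == 1:
        return GradeCategory.single
    return GradeCategory.none


def _grade_base_column(
    app: ApprovalRecord,
    column: EvidenceColumn,
    effects_by_trial: Mapping[str, EffectMap],
) -> EvidenceGrade:
    if _not_required(app, column):
        return EvidenceGrade(app.approval_id, column, GradeCategory.not_required)
    n_pos = n_neg = n_unc = 0
    for trial, klass in _column_trials(app, column):
        verdict = grade_trial(
            trial, effects_by_trial.get(trial.trial_id, {}), klass
        )
        if verdict is TrialVerdict.positive:
            n_pos += 1
        elif verdict is TrialVerdict.negative:
            n_neg += 1
        elif verdict is TrialVerdict.uncompared:
            n_unc += 1
    return EvidenceGrade(
        app.approval_id, column, _category_from_counts(n_pos), n_pos, n_neg, n_unc
    )


def _grouped(
    app: ApprovalRecord,
    column: EvidenceColumn,
    initiation: EvidenceGrade,
    continuation: EvidenceGrade,
) -> EvidenceGrade:
    if _not_required(app, column):
        return EvidenceGrade(app.approval_id, column, GradeCategory.not_required)
    candidates = [
        g
        for g in (initiation, continuation)
        if g.category is not GradeCategory.not_required
    ]
    if not candidates:
        return EvidenceGrade(app.approval_id, column, GradeCategory.not_required)
    best = max(candidates, key=lambda g: _CATEGORY_STRENGTH[g.category])
    return EvidenceGrade(
        app.approval_id, column, best.category,
        best.n_positive, best.n_negative, best.n_uncompared,
    )


def grade_approval(
    app: ApprovalRecord,
    effects_by_trial: Optional[Mapping[str, EffectMap]] = None,
    hedges: bool = False,
) -> List[EvidenceGrade]:
    """One grade per evidence column for an approval.

    Grades are invariant to trial ordering: only per-trial verdict counts
    enter the category.
    """
    if effects_by_trial is None:
        effects_by_trial = {
            t.trial_id: derive_trial_effects(t, hedges=hedges) for t in app.trials
        }
    base = {
        col: _grade_base_column(app, col, effects_by_trial)
        for col in (
            EvidenceColumn.superiority_vs_active_initiation,
            EvidenceColumn.non_inferiority_vs_active,
            EvidenceColumn.superiority_vs_placebo_initiation,
            EvidenceColumn.continuation_vs_active,
            EvidenceColumn.continuation_vs_placebo,
        )
    }
    grades = list(base.values())
    grades.append(
        _grouped(
            app,
            EvidenceColumn.active_grouped,
            base[EvidenceColumn.superiority_vs_active_initiation],
            base[EvidenceColumn.continuation_vs_active],
        )
    )
    grades.append(
        _grouped(
            app,
            EvidenceColumn.placebo_grouped,
            base[EvidenceColumn.superiority_vs_placebo_initiation],
            base[EvidenceColumn.continuation_vs_placebo],
        )
    )
    return grades


def grade_corpus(
    corpus: Iterable[ApprovalRecord], hedges: bool = False
) -> List[EvidenceGrade]:
    grades: List[EvidenceGrade] = []
    for app in corpus:
        grades.extend(grade_approval(app, hedges=hedges))
    return grades


_EVIDENCE_CODE = {
    GradeCategory.robust: 2,
    GradeCategory.single: 1,
    GradeCategory.none: 0,
    GradeCategory.not_required: None,
}
_SUBGROUP_CODE = {
    SubgroupBasis.none: 2,
    SubgroupBasis.pre_specified: 1,
    SubgroupBasis.post_hoc: 0,
}
_BIAS_CODE = {
    BiasAssessment.reported_no_bias: 2,
    BiasAssessment.none_reported: 1,
    BiasAssessment.reported_bias_found: 0,
}
_ISSUE_CODE = {IssueFlag.no: 2, IssueFlag.possible: 1, IssueFlag.yes: 0}

_FLAG_COLUMNS = [
    "subgroup_basis",
    "bias_assessment",
    "safety_issue",
    "tolerance_issue",
    "divergent_opinion",
]


def heatmap_matrix(
    corpus: Sequence[ApprovalRecord], grades: Sequence[EvidenceGrade]
) -> pd.DataFrame:
    """Category-code matrix (rows = approvals, 12 columns) behind the heat map.

    Evidence columns code robust→2, single→1, none→0, not_required→NA; flag
    columns use the same green/orange/red ordering (2 best, 0 worst).
    """
    by_app: Dict[str, Dict[str, Optional[int]]] = {}
    for g in grades:
        by_app.setdefault(g.approval_id, {})[g.column.value] = _EVIDENCE_CODE[g.category]
    rows = []
    for app in corpus:
        row = dict(by_app.get(app.approval_id, {}))
        row["subgroup_basis"] = _SUBGROUP_CODE[app.subgroup_basis]
        row["bias_assessment"] = _BIAS_CODE[app.bias_assessment]
        row["safety_issue"] = _ISSUE_CODE[app.safety_issue]
        row["tolerance_issue"] = _ISSUE_CODE[app.tolerance_issue]
        row["divergent_opinion"] = 0 if app.divergent_opinion else 2
        rows.append(row)
    columns = [c.value for c in EvidenceColumn] + _FLAG_COLUMNS
    frame = pd.DataFrame(rows, index=[a.approval_id for a in corpus], columns=columns)
    frame.index.name = "approval_id"
    return frame.astype("Int64")


def heatmap_legend() -> dict:
    """Colour semantics of the heat-map codes, per column group."""
    return {
        "evidence_columns": {
            "2": "green: two or more positive studies",
            "1": "orange: one positive study",
            "0": "red: no positive study (only negative, uncompared, or none)",
            "NA": "white: evidence of this kind not required",
        },
        "subgroup_basis": {
            "2": "green: target population not based on subgroup analyses",
            "1": "orange: based on a pre-specified subgroup analysis",
            "0": "red: based on a post-hoc subgroup analysis",
        },
        "bias_assessment": {
            "2": "green: bias assessed, none identified",
            "1": "orange: bias assessment not presented",
            "0": "red: bias identified",
        },
        "safety_issue": {
            "2": "green: no safety issue identified",
            "1": "orange: safety issue presented as possible",
            "0": "red: safety issue identified",
        },
        "tolerance_issue": {
            "2": "green: no tolerance issue identified",
            "1": "orange: tolerance issue presented as possible",
            "0": "red: tolerance issue identified",
        },
        "divergent_opinion": {
            "2": "green: no divergent opinion",
            "0": "red: divergent opinion expressed",
        },
    }


def grades_to_frame(grades: Sequence[EvidenceGrade]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "approval_id": g.approval_id,
                "column": g.column.value,
                "category": g.category.value,
                "n_positive": g.n_positive,
                "n_negative": g.n_negative,
                "n_uncompared": g.n_uncompared,
            }
            for g in grades
        ],
        columns=[
            "approval_id", "column", "category",
            "n_positive", "n_negative", "n_uncompared",
        ],
    )
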