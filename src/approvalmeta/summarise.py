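"""Corpus-level descriptive outputs: grade tallies, reporting triage, significance
counts, pooled-effect medians and the d-vs-p scatter tables.

Percentages are rounded half-away-from-zero to integers and always accompanied
by the raw fraction, because rounding conventions differ between reports of
the same count.  Denominators exclude approvals for which the column's
evidence was not required.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .corpus import (
    ApprovalRecord,
    ComparatorClass,
    DesignPhase,
    ReportingTier,
)
from .effects import EffectEstimate, Unusable, derive_effect
from .grading import EvidenceColumn, EvidenceGrade, GradeCategory
from .pooling import (
    MedianSummary,
    PooledEstimate,
    median_pooled_effect,
    pool_corpus,
)

__all__ = [
    "round_half_away",
    "percent",
    "summarise_grades",
    "triage_report",
    "significance_tally",
    "scatter_export",
    "cohen_label",
    "summarise_corpus",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero (so 80.5 -> 81)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percent(count: int, denominator: int) -> Optional[int]:
    """Integer percentage, or None for a zero denominator."""
    if denominator == 0:
        return None
    return round_half_away(100.0 * count / denominator)


def cohen_label(d: float) -> str:
    """Qualitative benchmark for |d|: small 0.2, medium 0.5, large 0.8."""
    a = abs(d)
    if a < 0.2:
        return "trivial"
    if a < 0.5:
        return "small"
    if a < 0.8:
        return "medium"
    return "large"


def summarise_grades(grades: Sequence[EvidenceGrade]) -> pd.DataFrame:
    """Per-column category tallies with integer percentages and raw fractions.

    The percentage denominator excludes not_required approvals; not_required
    rows are still listed (count only, percent NA).
    """
    rows = []
    for column in EvidenceColumn:
        col_grades = [g for g in grades if g.column is column]
        if not col_grades:
            continue
        required = [g for g in col_grades if g.category is not GradeCategory.not_required]
        denom = len(required)
        for category in GradeCategory:
            count = sum(1 for g in col_grades if g.category is category)
            if category is GradeCategory.not_required:
                pct, frac = None, None
            else:
                pct = percent(count, denom)
                frac = count / denom if denom else None
            rows.append(
                {
                    "column": column.value,
                    "category": category.value,
                    "count": count,
                    "denominator": denom if category is not GradeCategory.not_required else None,
                    "percent": pct,
                    "fraction": frac,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["column", "category", "count", "denominator", "percent", "fraction"],
    )


def _included_comparisons(corpus: Iterable[ApprovalRecord], apply_dose_filter: bool):
    """Yield (approval, trial, comparison) after the approved-dose filter.

    Pooled-analysis records never count as studies or comparisons.
    """
    from .pooling import _dose_in_range  # shared filtering rule

    for app in corpus:
        for trial in app.trials:
            if trial.pooled_analysis:
                continue
            for comp in trial.comparisons:
                inv = trial.arm(comp.investigational_arm_id)
                if apply_dose_filter and not _dose_in_range(inv.daily_dose, app):
                    continue
                yield app, trial, comp


def triage_report(
    corpus: Sequence[ApprovalRecord],
    apply_dose_filter: bool = True,
    hedges: bool = False,
) -> dict:
    """Reporting-completeness triage of all arm comparisons.

    Each comparison is counted under its *effective* tier: the tier actually
    used by the derivation cascade, with comparisons that cannot be derived
    (including p-and-n reports lacking a direction) counted as insufficient.
    A study is analyzable when at least one of its comparisons is.
    """
    tier_counts: Dict[str, int] = {t.value: 0 for t in ReportingTier}
    study_any_usable: Dict[str, bool] = {}
    study_has_comparison: Dict[str, bool] = {}
    n_comparisons = 0
    for app, trial, comp in _included_comparisons(corpus, apply_dose_filter):
        n_comparisons += 1
        study_has_comparison.setdefault(trial.trial_id, True)
        est = derive_effect(comp, trial, hedges=hedges)
        if isinstance(est, Unusable):
            tier_counts[ReportingTier.insufficient.value] += 1
            study_any_usable.setdefault(trial.trial_id, False)
        else:
            tier_counts[est.tier_used.value] += 1
            study_any_usable[trial.trial_id] = True
    n_usable = n_comparisons - tier_counts[ReportingTier.insufficient.value]
    n_studies = len(study_has_comparison)
    n_studies_usable = sum(1 for v in study_any_usable.values() if v)
    return {
        "n_comparisons": n_comparisons,
        "tier_counts": tier_counts,
        "n_comparisons_analyzable": n_usable,
        "percent_comparisons_analyzable": percent(n_usable, n_comparisons),
        "fraction_comparisons_analyzable": (
            n_usable / n_comparisons if n_comparisons else None
        ),
        "n_studies": n_studies,
        "n_studies_analyzable": n_studies_usable,
        "percent_studies_analyzable": percent(n_studies_usable, n_studies),
    }


def significance_tally(
    results: Sequence[Union[EffectEstimate, PooledEstimate]],
) -> dict:
    """Count two-sided p < 0.05 results and their direction of favour."""
    n_total = len(results)
    n_sig = n_drug = n_comp = 0
    for r in results:
        d = r.d if isinstance(r, EffectEstimate) else r.d_pooled
        degenerate = getattr(r, "degenerate", False)
        if degenerate or not r.p_two_sided < 0.05:
            continue
        n_sig += 1
        if d < 0:
            n_drug += 1
        else:
            n_comp += 1
    return {
        "n_total": n_total,
        "n_significant": n_sig,
        "n_favour_drug": n_drug,
        "n_favour_comparator": n_comp,
    }


def effects_frame(
    corpus: Sequence[ApprovalRecord],
    apply_dose_filter: bool = True,
    hedges: bool = False,
) -> pd.DataFrame:
    """One row per arm comparison with its derived effect (or unusable reason)."""
    rows = []
    for app, trial, comp in _included_comparisons(corpus, apply_dose_filter):
        est = derive_effect(comp, trial, hedges=hedges)
        row = {
            "approval_id": app.approval_id,
            "trial_id": trial.trial_id,
            "investigational_arm_id": comp.investigational_arm_id,
            "comparator_arm_id": comp.comparator_arm_id,
            "design_phase": trial.design_phase.value,
            "comparator_class": comp.comparator_class.value,
            "reporting_tier": comp.reporting_tier.value,
        }
        if isinstance(est, Unusable):
            row.update(usable=False, reason=est.reason, d=None, se_d=None,
                       p_two_sided=None, tier_used=None)
        else:
            row.update(
                usable=not est.degenerate,
                reason="degenerate" if est.degenerate else None,
                d=est.d, se_d=est.se_d, p_two_sided=est.p_two_sided,
                tier_used=est.tier_used.value,
            )
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "approval_id", "trial_id", "investigational_arm_id",
            "comparator_arm_id", "design_phase", "comparator_class",
            "reporting_tier", "usable", "reason", "d", "se_d",
            "p_two_sided", "tier_used",
        ],
    )


def _strata(corpus, hedges: bool):
    """Study-level estimates keyed by (design phase, comparator class)."""
    out: Dict[Tuple[str, str], List[EffectEstimate]] = {}
    for app, trial, comp in _included_comparisons(corpus, apply_dose_filter=True):
        est = derive_effect(comp, trial, hedges=hedges)
        if isinstance(est, Unusable) or est.degenerate:
            continue
        key = (trial.design_phase.value, comp.comparator_class.value)
        out.setdefault(key, []).append(est)
    return out


def scatter_export(
    corpus: Sequence[ApprovalRecord],
    pooled: Optional[Sequence[PooledEstimate]] = None,
    hedges: bool = False,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """The two d-vs-p tables: one row per analyzable comparison (study level)
    and one per pooling key (meta-analysis level), stratified by design phase
    × comparator class.  Row order is deterministic."""
    if pooled is None:
        pooled = pool_corpus(corpus, hedges=hedges)
    study_rows = []
    for (phase, klass), ests in sorted(_strata(corpus, hedges).items()):
        for est in ests:
            study_rows.append(
                {
                    "design_phase": phase,
                    "comparator_class": klass,
                    "d": est.d,
                    "p": est.p_two_sided,
                    "tier": est.tier_used.value,
                    "magnitude": cohen_label(est.d),
                }
            )
    meta_rows = [
        {
            "design_phase": p.key.design_phase.value,
            "comparator_class": p.key.comparator_class.value,
            "drug": p.key.drug,
            "daily_dose": p.key.daily_dose,
            "k": p.k,
            "d": p.d_pooled,
            "p": p.p_two_sided,
            "magnitude": cohen_label(p.d_pooled),
        }
        for p in pooled
    ]
    study = pd.DataFrame(
        study_rows,
        columns=["design_phase", "comparator_class", "d", "p", "tier", "magnitude"],
    )
    meta = pd.DataFrame(
        meta_rows,
        columns=[
            "design_phase", "comparator_class", "drug", "daily_dose",
            "k", "d", "p", "magnitude",
        ],
    )
    return study, meta


def _median_dict(m: MedianSummary) -> dict:
    return {"n_keys": m.n_keys, "median": m.median, "min": m.min, "max": m.max}


def summarise_corpus(
    corpus: Sequence[ApprovalRecord],
    ignore_indication: bool = False,
    hedges: bool = False,
) -> dict:
    """Full descriptive summary of a corpus (the pipeline's summary JSON)."""
    from .grading import grade_corpus

    grades = grade_corpus(corpus, hedges=hedges)
    grade_table = summarise_grades(grades)
    pooled = pool_corpus(corpus, ignore_indication=ignore_indication, hedges=hedges)
    strata = _strata(corpus, hedges)
    tallies = {}
    medians = {}
    for phase in DesignPhase:
        for klass in ComparatorClass:
            name = f"{phase.value}_vs_{klass.value}"
            tallies[name] = {
                "study_level": significance_tally(strata.get((phase.value, klass.value), [])),
                "meta_level": significance_tally(
                    [
                        p
                        for p in pooled
                        if p.key.design_phase is phase
                        and p.key.comparator_class is klass
                    ]
                ),
            }
            medians[name] = _median_dict(median_pooled_effect(pooled, phase, klass))
    return {
        "n_approvals": len(corpus),
        "grade_summary": grade_table.to_dict(orient="records"),
        "triage": triage_report(corpus, hedges=hedges),
        "significance": tallies,
        "pooled_medians": medians,
        "n_pooling_keys": len(pooled),
    }
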