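"""Random-effects pooling of standardized effects per drug, dose, design and comparator.

Pooling follows the classic DerSimonian–Laird moment estimator, implemented
from first principles:

* fixed-effect weights ``w_i = 1/var_i`` and pooled mean ``d_FE``;
* heterogeneity statistic ``Q = sum w_i (d_i - d_FE)²``;
* ``tau² = max(0, (Q - (k-1)) / (sum w_i - sum w_i² / sum w_i))``;
* random-effect weights ``w*_i = 1/(var_i + tau²)``, pooled mean
  ``d_pooled = sum w*_i d_i / sum w*_i`` with ``se = 1/sqrt(sum w*_i)``;
* Wald (normal) 95% CI and two-sided p.

Each pooled estimate is classified at the two-sided 0.05 level:
``favours_drug`` (significant and negative, under the convention that negative
d favours the investigational drug), ``favours_comparator`` (significant and
positive) or ``no_evidence_of_difference``.

Pooling keys are (drug, daily dose, design phase, comparator class) — and, by
default, the approval's indication, since a drug may be approved in several
indications.  Only investigational arms whose daily dose lies within the
approved dose range contribute; arms dosed outside the range are excluded, and
approvals lacking dose bounds retain their arms with a logged warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from scipy import stats

from .corpus import ApprovalRecord, ComparatorClass, DesignPhase
from .effects import EffectEstimate, Unusable, derive_effect

__all__ = [
    "PoolKey",
    "PooledEstimate",
    "MedianSummary",
    "pool",
    "build_pooling_keys",
    "pool_corpus",
    "median_pooled_effect",
    "pooled_to_frame",
]

logger = logging.getLogger(__name__)

_Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class PoolKey:
    drug: str
    daily_dose: Optional[float]
    design_phase: DesignPhase
    comparator_class: ComparatorClass
    indication: Optional[str] = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        dose = "NA" if self.daily_dose is None else f"{self.daily_dose:g}"
        ind = f", {self.indication}" if self.indication else ""
        return (
            f"{self.drug} {dose}/day, {self.design_phase.value} vs "
            f"{self.comparator_class.value}{ind}"
        )


@dataclass(frozen=True)
class PooledEstimate:
    key: PoolKey
    k: int
    d_pooled: float
    se_pooled: float
    ci95: Tuple[float, float]
    p_two_sided: float
    tau2: float
    Q: float

    @property
    def classification(self) -> str:
        if self.p_two_sided < 0.05:
            return "favours_drug" if self.d_pooled < 0 else "favours_comparator"
        return "no_evidence_of_difference"


def pool(estimates: Sequence[EffectEstimate], key: PoolKey) -> PooledEstimate:
    """DerSimonian–Laird random-effects pooling of k >= 1 estimates."""
    if len(estimates) == 0:
        raise ValueError("cannot pool an empty list of estimates")
    d = [e.d for e in estimates]
    var = [e.var_d for e in estimates]
    if any(v <= 0 or not math.isfinite(v) for v in var):
        raise ValueError("all estimate variances must be positive and finite")
    k = len(d)
    w = [1.0 / v for v in var]
    sw = sum(w)
    d_fe = sum(wi * di for wi, di in zip(w, d)) / sw
    q = sum(wi * (di - d_fe) ** 2 for wi, di in zip(w, d))
    if k == 1:
        tau2 = 0.0
    else:
        c = sw - sum(wi * wi for wi in w) / sw
        tau2 = max(0.0, (q - (k - 1)) / c)
    w_star = [1.0 / (v + tau2) for v in var]
    sw_star = sum(w_star)
    d_pooled = sum(wi * di for wi, di in zip(w_star, d)) / sw_star
    se = 1.0 / math.sqrt(sw_star)
    z = d_pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return PooledEstimate(
        key=key,
        k=k,
        d_pooled=d_pooled,
        se_pooled=se,
        ci95=(d_pooled - _Z975 * se, d_pooled + _Z975 * se),
        p_two_sided=p,
        tau2=tau2,
        Q=q,
    )


def _dose_in_range(dose: Optional[float], app: ApprovalRecord) -> bool:
    lo, hi = app.approved_dose_min, app.approved_dose_max
    if lo is None and hi is None:
        logger.warning(
            "approval %s: no approved dose bounds; retaining dosed arms",
            app.approval_id,
        )
        return True
    if dose is None:
        logger.warning(
            "approval %s: arm without a daily dose retained", app.approval_id
        )
        return True
    if lo is not None and dose < lo:
        return False
    if hi is not None and dose > hi:
        return False
    return True


def build_pooling_keys(
    corpus: Iterable[ApprovalRecord],
    ignore_indication: bool = False,
    hedges: bool = False,
) -> Dict[PoolKey, List[EffectEstimate]]:
    """Derive effects for every comparison and group them into pooling keys.

    Applies the approved-dose filter (arms dosed outside the approval's dose
    range are excluded, with the exclusion logged), skips pooled-analysis
    records and unusable/degenerate estimates, and keys the rest by
    (drug, dose, phase, comparator class[, indication]).
    """
    keyed: Dict[PoolKey, List[EffectEstimate]] = {}
    for app in corpus:
        for trial in app.trials:
            if trial.pooled_analysis:
                continue
            for comp in trial.comparisons:
                inv = trial.arm(comp.investigational_arm_id)
                if not _dose_in_range(inv.daily_dose, app):
                    logger.info(
                        "approval %s trial %s: arm %s dose %s outside approved "
                        "range [%s, %s]; excluded from pooling",
                        app.approval_id, trial.trial_id, inv.arm_id,
                        inv.daily_dose, app.approved_dose_min,
                        app.approved_dose_max,
                    )
                    continue
                est = derive_effect(comp, trial, hedges=hedges)
                if isinstance(est, Unusable):
                    logger.info(
                        "approval %s trial %s: comparison %s -> %s unusable (%s)",
                        app.approval_id, trial.trial_id, inv.arm_id,
                        comp.comparator_arm_id, est.reason,
                    )
                    continue
                if est.degenerate:
                    logger.info(
                        "approval %s trial %s: degenerate binary comparison "
                        "excluded", app.approval_id, trial.trial_id,
                    )
                    continue
                key = PoolKey(
                    drug=app.drug,
                    daily_dose=inv.daily_dose,
                    design_phase=trial.design_phase,
                    comparator_class=comp.comparator_class,
                    indication=None if ignore_indication else app.indication,
                )
                keyed.setdefault(key, []).append(est)
    return keyed


def pool_corpus(
    corpus: Iterable[ApprovalRecord],
    ignore_indication: bool = False,
    hedges: bool = False,
) -> List[PooledEstimate]:
    """Pool every key of a corpus; deterministic key order."""
    keyed = build_pooling_keys(corpus, ignore_indication=ignore_indication, hedges=hedges)

    def _order(key: PoolKey):
        return (
            key.drug,
            key.indication or "",
            key.design_phase.value,
            key.comparator_class.value,
            key.daily_dose if key.daily_dose is not None else float("-inf"),
        )

    return [pool(keyed[key], key) for key in sorted(keyed, key=_order)]


@dataclass(frozen=True)
class MedianSummary:
    n_keys: int
    median: Optional[float]
    min: Optional[float]
    max: Optional[float]


def median_pooled_effect(
    pooled: Iterable[PooledEstimate],
    design_phase: DesignPhase,
    comparator_class: ComparatorClass,
) -> MedianSummary:
    """Median and range of pooled d within one design × comparator stratum.

    The sample median averages the two middle order statistics for even
    counts.  An empty stratum yields an explicit empty summary, never zero.
    """
    values = sorted(
        p.d_pooled
        for p in pooled
        if p.key.design_phase is design_phase
        and p.key.comparator_class is comparator_class
    )
    n = len(values)
    if n == 0:
        return MedianSummary(n_keys=0, median=None, min=None, max=None)
    mid = n // 2
    median = values[mid] if n % 2 else 0.5 * (values[mid - 1] + values[mid])
    return MedianSummary(n_keys=n, median=median, min=values[0], max=values[-1])


def pooled_to_frame(pooled: Sequence[PooledEstimate]) -> pd.DataFrame:
    """Flat one-row-per-key table of pooled estimates."""
    rows = []
    for p in pooled:
        rows.append(
            {
                "drug": p.key.drug,
                "daily_dose": p.key.daily_dose,
                "design_phase": p.key.design_phase.value,
                "comparator_class": p.key.comparator_class.value,
                "indication": p.key.indication,
                "k": p.k,
                "d_pooled": p.d_pooled,
                "se_pooled": p.se_pooled,
                "ci95_low": p.ci95[0],
                "ci95_high": p.ci95[1],
                "p_two_sided": p.p_two_sided,
                "tau2": p.tau2,
                "Q": p.Q,
                "classification": p.classification,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "drug", "daily_dose", "design_phase", "comparator_class",
            "indication", "k", "d_pooled", "se_pooled", "ci95_low",
            "ci95_high", "p_two_sided", "tau2", "Q", "classification",
        ],
    )
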