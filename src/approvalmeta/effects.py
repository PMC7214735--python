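"""Standardized effect sizes (Cohen's d) from heterogeneously reported trial results.

Dossiers report arm contrasts at very different levels of completeness, so a
single comparison may have to be standardized from (in priority order):

1. full arm statistics — means/SDs of change for continuous outcomes, event
   counts for binary outcomes (``arm_stats`` tier);
2. the arm contrast and its standard error (``contrast_only`` tier);
3. only a two-sided p-value, the group sizes and the direction of the result
   (``p_and_n_only`` tier), inverted through the central t distribution;
4. nothing usable (``insufficient`` tier) — the comparison is excluded.

Sign convention: **negative d favours the investigational drug** regardless of
the orientation of the outcome scale (``better_is``) or, for binary outcomes,
whether the event is desirable (``event_is_good``).

p-values are two-sided and computed from the two-sample t statistic
``t = d * sqrt(n1*n2/(n1+n2))`` on ``n1+n2-2`` degrees of freedom for the
continuous and contrast tiers, so that the p-and-n imputation tier inverts the
calculation exactly; the binary tier refers the Wald statistic on the log-odds
scale (equal to ``d/se_d``) to the same t distribution.

Binary outcomes are standardized through the logistic conversion
``d = ln(OR) * sqrt(3)/pi`` with ``var(d) = 3/pi² * (1/a + 1/b + 1/c + 1/d)``
and a 0.5 continuity correction added to all four cells only when a zero cell
occurs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Union

from scipy import stats

from .corpus import (
    ArmComparison,
    BetterIs,
    Direction,
    OutcomeType,
    ReportingTier,
    TrialRecord,
)

__all__ = [
    "EffectEstimate",
    "Unusable",
    "d_from_continuous_arms",
    "d_from_binary_arms",
    "d_from_contrast",
    "d_from_p_n",
    "derive_effect",
    "hedges_correction",
]

_SQRT3_OVER_PI = math.sqrt(3.0) / math.pi


@dataclass(frozen=True)
class EffectEstimate:
    """A standardized mean difference with its variance and two-sided p.

    ``d`` is oriented so that negative values favour the investigational arm.
    ``var_d`` is the large-sample variance
    ``(n1+n2)/(n1*n2) + d²/(2*(n1+n2))`` (for binary outcomes the
    log-odds-based variance); ``se_d = sqrt(var_d)``.
    """

    d: float
    var_d: float
    p_two_sided: float
    n_inv: int
    n_comp: int
    tier_used: ReportingTier
    outcome_type: OutcomeType
    degenerate: bool = False

    @property
    def se_d(self) -> float:
        return math.sqrt(self.var_d)

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_two_sided < 0.05

    @property
    def favours_investigational(self) -> bool:
        return self.d < 0


@dataclass(frozen=True)
class Unusable:
    """Marker for a comparison from which no effect size can be derived."""

    reason: str


def _check_n(n_inv: int, n_comp: int) -> None:
    if n_inv < 2 or n_comp < 2:
        raise ValueError(f"need at least 2 subjects per arm, got {n_inv}, {n_comp}")


def _smd_variance(d: float, n_inv: int, n_comp: int) -> float:
    n_total = n_inv + n_comp
    return n_total / (n_inv * n_comp) + d * d / (2.0 * n_total)


def _p_from_t(t: float, df: int) -> float:
    return float(2.0 * stats.t.sf(abs(t), df))


def d_from_continuous_arms(
    m_inv: float,
    sd_inv: float,
    n_inv: int,
    m_comp: float,
    sd_comp: float,
    n_comp: int,
    better_is: BetterIs = BetterIs.lower,
    hedges: bool = False,
) -> EffectEstimate:
    """Cohen's d from per-arm means and SDs of change (``arm_stats`` tier).

    d = (m_inv - m_comp) / s_pooled with the bias-free pooled SD; the sign is
    flipped for ``better_is='higher'`` scales so negative d always favours the
    investigational arm.  ``hedges=True`` applies the small-sample correction
    J = 1 - 3/(4*df - 1), yielding Hedges' g.
    """
    for name, x in (("m_inv", m_inv), ("sd_inv", sd_inv), ("m_comp", m_comp), ("sd_comp", sd_comp)):
        if not math.isfinite(x):
            raise ValueError(f"non-finite {name}: {x!r}")
    if sd_inv <= 0 or sd_comp <= 0:
        raise ValueError("standard deviations must be positive")
    _check_n(n_inv, n_comp)
    df = n_inv + n_comp - 2
    s_pooled = math.sqrt(
        ((n_inv - 1) * sd_inv**2 + (n_comp - 1) * sd_comp**2) / df
    )
    d = (m_inv - m_comp) / s_pooled
    if better_is is BetterIs.higher:
        d = -d
    t = d * math.sqrt(n_inv * n_comp / (n_inv + n_comp))
    est = EffectEstimate(
        d=d,
        var_d=_smd_variance(d, n_inv, n_comp),
        p_two_sided=_p_from_t(t, df),
        n_inv=n_inv,
        n_comp=n_comp,
        tier_used=ReportingTier.arm_stats,
        outcome_type=OutcomeType.continuous,
    )
    return hedges_correction(est) if hedges else est


def d_from_binary_arms(
    e_inv: int,
    n_inv: int,
    e_comp: int,
    n_comp: int,
    event_is_good: bool = False,
) -> EffectEstimate:
    """Cohen's d from 2x2 event counts via the logistic log-odds conversion.

    A 0.5 continuity correction is added to all four cells iff any cell is
    zero.  When both arms are all-events or both all-non-events the estimate
    carries no information and is flagged degenerate (excluded from pooling).
    """
    if not (0 <= e_inv <= n_inv and 0 <= e_comp <= n_comp):
        raise ValueError("event counts must satisfy 0 <= events <= n")
    _check_n(n_inv, n_comp)
    degenerate = (e_inv == 0 and e_comp == 0) or (e_inv == n_inv and e_comp == n_comp)
    a, b = float(e_inv), float(n_inv - e_inv)
    c, dd = float(e_comp), float(n_comp - e_comp)
    if min(a, b, c, dd) == 0.0:
        a, b, c, dd = a + 0.5, b + 0.5, c + 0.5, dd + 0.5
    log_or = math.log((a * dd) / (b * c))
    d = log_or * _SQRT3_OVER_PI
    if event_is_good:
        # higher event odds in the investigational arm favour the drug
        d = -d
    var_d = (3.0 / math.pi**2) * (1.0 / a + 1.0 / b + 1.0 / c + 1.0 / dd)
    df = n_inv + n_comp - 2
    p = 1.0 if degenerate else _p_from_t(d / math.sqrt(var_d), df)
    return EffectEstimate(
        d=d,
        var_d=var_d,
        p_two_sided=p,
        n_inv=n_inv,
        n_comp=n_comp,
        tier_used=ReportingTier.arm_stats,
        outcome_type=OutcomeType.binary,
        degenerate=degenerate,
    )


def d_from_contrast(
    contrast: float,
    se: float,
    n_inv: int,
    n_comp: int,
    better_is: BetterIs = BetterIs.lower,
) -> EffectEstimate:
    """Cohen's d from a reported arm contrast and its SE (``contrast_only`` tier).

    t = contrast/se; d = t * sqrt(1/n1 + 1/n2), sign-oriented so negative
    favours the investigational arm.
    """
    if not math.isfinite(contrast):
        raise ValueError(f"non-finite contrast: {contrast!r}")
    if not (math.isfinite(se) and se > 0):
        raise ValueError(f"contrast SE must be positive, got {se!r}")
    _check_n(n_inv, n_comp)
    df = n_inv + n_comp - 2
    t = contrast / se
    if better_is is BetterIs.higher:
        t = -t
    d = t * math.sqrt(1.0 / n_inv + 1.0 / n_comp)
    return EffectEstimate(
        d=d,
        var_d=_smd_variance(d, n_inv, n_comp),
        p_two_sided=_p_from_t(t, df),
        n_inv=n_inv,
        n_comp=n_comp,
        tier_used=ReportingTier.contrast_only,
        outcome_type=OutcomeType.continuous,
    )


def d_from_p_n(
    p_two_sided: float,
    n_inv: int,
    n_comp: int,
    direction: Direction,
) -> EffectEstimate:
    """Impute Cohen's d from a two-sided p and the group sizes.

    |t| is the upper p/2 quantile of the central t distribution on
    n1+n2-2 degrees of freedom; d = sign * |t| * sqrt(1/n1 + 1/n2) with the
    sign taken from the reported direction.  A comparison reported only as
    non-significant without a direction cannot be imputed (see
    :func:`derive_effect`).
    """
    if not (0.0 < p_two_sided <= 1.0):
        raise ValueError(f"p must lie in (0, 1], got {p_two_sided!r}")
    if direction is None or direction is Direction.null:
        raise ValueError("cannot impute an effect size without a direction")
    _check_n(n_inv, n_comp)
    df = n_inv + n_comp - 2
    t_abs = float(stats.t.isf(p_two_sided / 2.0, df))
    sign = -1.0 if direction is Direction.favours_investigational else 1.0
    d = sign * t_abs * math.sqrt(1.0 / n_inv + 1.0 / n_comp)
    return EffectEstimate(
        d=d,
        var_d=_smd_variance(d, n_inv, n_comp),
        p_two_sided=p_two_sided,
        n_inv=n_inv,
        n_comp=n_comp,
        tier_used=ReportingTier.p_and_n_only,
        outcome_type=OutcomeType.continuous,
    )


def hedges_correction(est: EffectEstimate) -> EffectEstimate:
    """Apply the small-sample correction J = 1 - 3/(4*df - 1) to an estimate."""
    df = est.n_inv + est.n_comp - 2
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    return replace(est, d=j * est.d, var_d=j * j * est.var_d)


def derive_effect(
    comparison: ArmComparison,
    trial: TrialRecord,
    hedges: bool = False,
) -> Union[EffectEstimate, Unusable]:
    """Dispatch one arm comparison to the highest usable derivation tier.

    Priority: arm_stats > contrast_only > p_and_n_only; the ``insufficient``
    tier (and a p-and-n comparison without a direction) yields an
    :class:`Unusable` marker.  A tier label inconsistent with the fields
    actually present raises ``ValueError``.
    """
    tier = comparison.reporting_tier
    if tier is ReportingTier.insufficient:
        return Unusable("reported information insufficient to derive Cohen's d")
    inv = trial.arm(comparison.investigational_arm_id)
    comp = trial.arm(comparison.comparator_arm_id)
    if tier is ReportingTier.arm_stats:
        if not (inv.has_outcome_stats() and comp.has_outcome_stats()):
            raise ValueError(
                f"trial {trial.trial_id}: arm_stats tier but outcome statistics "
                "are missing"
            )
        if inv.outcome_type is OutcomeType.binary:
            return d_from_binary_arms(
                inv.events, inv.n_randomised, comp.events, comp.n_randomised,
                event_is_good=comparison.better_is is BetterIs.higher,
            )
        est = d_from_continuous_arms(
            inv.mean_change, inv.sd_change, inv.n_randomised,
            comp.mean_change, comp.sd_change, comp.n_randomised,
            better_is=comparison.better_is,
        )
        return hedges_correction(est) if hedges else est
    if tier is ReportingTier.contrast_only:
        if comparison.contrast_value is None or comparison.contrast_se is None:
            raise ValueError(
                f"trial {trial.trial_id}: contrast_only tier but contrast or "
                "its SE is missing"
            )
        est = d_from_contrast(
            comparison.contrast_value, comparison.contrast_se,
            inv.n_randomised, comp.n_randomised, better_is=comparison.better_is,
        )
        return hedges_correction(est) if hedges else est
    # p_and_n_only
    if comparison.reported_p is None:
        raise ValueError(
            f"trial {trial.trial_id}: p_and_n_only tier but reported_p is missing"
        )
    if comparison.direction is None or comparison.direction is Direction.null:
        return Unusable("p-value reported without a direction")
    est = d_from_p_n(
        comparison.reported_p, inv.n_randomised, comp.n_randomised,
        comparison.direction,
    )
    return hedges_correction(est) if hedges else est
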