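"""Synthetic approval corpora with the statistical structure the pipeline assumes.

Two sources of corpora live here:

* :func:`generate` — a stochastic generator of approval → trial → arm records.
  Per trial a true standardized effect is drawn from
  ``Normal(true_effect[comparator], tau²)``; continuous arms report mean
  changes with unit population SD (sampling noise on both the mean and the
  SD), binary arms report event counts with the comparator event rate fixed
  and the investigational rate set so the log-odds conversion equals the true
  effect.  Reporting completeness is then censored stochastically into the
  four tiers (full arm statistics / contrast only / p and n only /
  insufficient).  Generation is reproducible from one root seed with
  per-approval substreams, so adding an approval never perturbs earlier ones;
  tier draws use their own substream, so the censored and uncensored views of
  one realisation share identical underlying data.

* :func:`reference_corpus` — a deterministic 27-approval corpus whose
  grade-category tallies, flag tallies and reporting-tier counts
  (158/29/12/67 over 266 post-dose-filter comparisons in 137 studies, one of
  which is excluded because all its doses fall below the approved minimum)
  match the published appraisal of psychotropic-drug approval dossiers.
  Individual approvals are schematic: only the evaluations the appraisal
  singles out by name (olanzapine and varenicline with robust superiority,
  paliperidone-IM with one positive and two negative non-inferiority trials,
  duloxetine's pooled non-inferiority analyses, nalmefene with comparative
  evidence not required) are modelled as such; all other drug names, and all
  per-approval flag values beyond the printed tallies, are arbitrary.
"""

from __future__ import annotations

import math
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .corpus import (
    ApprovalRecord,
    ArmComparison,
    ArmRecord,
    ArmRole,
    BetterIs,
    BiasAssessment,
    ComparatorClass,
    ComparisonReporting,
    Direction,
    DesignPhase,
    Hypothesis,
    IssueFlag,
    NIVerdict,
    OutcomeType,
    PrimaryOutcomeKind,
    ReportingTier,
    Route,
    SubgroupBasis,
    SuicidalExcluded,
    TrialRecord,
    validate_corpus,
)

__all__ = [
    "DistSpec",
    "GeneratorConfig",
    "generate",
    "generate_paired",
    "reference_corpus",
    "load_fixture_corpus",
]


def load_fixture_corpus() -> List[ApprovalRecord]:
    """Read the checked-in CSV bundle of :func:`reference_corpus`.

    The bundle is data shipped with the package so that downstream checks do
    not depend on generator internals; a test asserts it stays identical to
    what :func:`reference_corpus` builds.
    """
    from importlib.resources import files

    from .corpus import read_corpus

    return read_corpus(files("approvalmeta").joinpath("data/reference_corpus"))


class DistSpec(BaseModel):
    """Distribution of a per-record count: a fixed value or a truncated Poisson."""

    model_config = ConfigDict(extra="forbid")

    kind: Literal["fixed", "poisson"] = "fixed"
    value: float = 1
    minimum: int = 1

    def draw(self, rng: np.random.Generator) -> int:
        if self.kind == "fixed":
            return max(self.minimum, int(self.value))
        return max(self.minimum, int(rng.poisson(self.value)))

    @classmethod
    def fixed(cls, k: int) -> "DistSpec":
        return cls(kind="fixed", value=k, minimum=k)

    @classmethod
    def poisson(cls, mean: float, minimum: int = 1) -> "DistSpec":
        return cls(kind="poisson", value=mean, minimum=minimum)


class GeneratorConfig(BaseModel):
    """Study conditions for the synthetic corpus generator.

    Defaults emulate the published corpus: 27 approvals, around five trials
    each, ~100 subjects per arm, a small negative true effect against placebo
    (−0.3) and a null effect against active comparators, between-trial
    heterogeneity tau² = 0.05, 80% continuous outcomes, and the observed
    reporting-tier mix (roughly 0.6 / 0.1 / 0.05 / 0.25).
    """

    model_config = ConfigDict(extra="forbid")

    n_approvals: int = Field(default=27, ge=1)
    trials_per_approval: DistSpec = Field(
        default_factory=lambda: DistSpec.poisson(5.0, minimum=1)
    )
    arms_per_trial: int = Field(default=2, ge=2)
    n_per_arm: DistSpec = Field(default_factory=lambda: DistSpec.fixed(100))
    true_effect_by_comparator: Dict[ComparatorClass, float] = Field(
        default_factory=lambda: {
            ComparatorClass.placebo: -0.3,
            ComparatorClass.active: 0.0,
        }
    )
    tau2: float = Field(default=0.05, ge=0.0)
    outcome_mix: float = Field(default=0.8, ge=0.0, le=1.0)
    tier_probabilities: Dict[ReportingTier, float] = Field(
        default_factory=lambda: {
            ReportingTier.arm_stats: 0.6,
            ReportingTier.contrast_only: 0.1,
            ReportingTier.p_and_n_only: 0.05,
            ReportingTier.insufficient: 0.25,
        }
    )
    active_fraction: float = Field(default=0.3, ge=0.0, le=1.0)
    continuation_fraction: float = Field(default=0.1, ge=0.0, le=1.0)
    binary_event_rate: float = 0.4
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        probs = self.tier_probabilities
        if any(p < 0 for p in probs.values()):
            raise ValueError("tier probabilities must be non-negative")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("tier probabilities must sum to 1")
        if not (0.0 < self.binary_event_rate < 1.0):
            raise ValueError("binary_event_rate must lie strictly in (0, 1)")
        for klass in ComparatorClass:
            if klass not in self.true_effect_by_comparator:
                raise ValueError(f"true effect missing for comparator {klass.value}")
        return self


_TIER_ORDER = [
    ReportingTier.arm_stats,
    ReportingTier.contrast_only,
    ReportingTier.p_and_n_only,
    ReportingTier.insufficient,
]


def _sample_continuous_arm(rng, mu: float, n: int) -> Tuple[float, float]:
    """Observed mean and SD of n draws from Normal(mu, 1)."""
    mean = float(rng.normal(mu, 1.0 / math.sqrt(n)))
    sd = float(math.sqrt(rng.chisquare(n - 1) / (n - 1)))
    return mean, sd


def _pooled_sd(sd1: float, n1: int, sd2: float, n2: int) -> float:
    return math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))


def _direction_of(d: float) -> Direction:
    if d < 0:
        return Direction.favours_investigational
    if d > 0:
        return Direction.favours_comparator
    return Direction.null


def _two_sample_p(d: float, n1: int, n2: int) -> float:
    t = d * math.sqrt(n1 * n2 / (n1 + n2))
    return float(2.0 * stats.t.sf(abs(t), n1 + n2 - 2))


def _censor_trial(trial: TrialRecord, tiers: List[ReportingTier]) -> None:
    """Censor a fully reported trial in place according to per-comparison tiers.

    contrast_only keeps the arm contrast and its SE; p_and_n_only keeps the
    realised two-sided p, the group sizes and the direction; insufficient
    keeps neither.  An arm retains its outcome statistics only while some
    arm_stats comparison still needs it.
    """
    keep_stats = set()
    for comp, tier in zip(trial.comparisons, tiers):
        comp.reporting_tier = tier
        inv = trial.arm(comp.investigational_arm_id)
        cmp_arm = trial.arm(comp.comparator_arm_id)
        if tier is ReportingTier.arm_stats:
            keep_stats.add(inv.arm_id)
            keep_stats.add(cmp_arm.arm_id)
            continue
        if inv.outcome_type is OutcomeType.continuous:
            d = (inv.mean_change - cmp_arm.mean_change) / _pooled_sd(
                inv.sd_change, inv.n_randomised, cmp_arm.sd_change, cmp_arm.n_randomised
            )
            if comp.better_is is BetterIs.higher:
                d = -d
            if tier is ReportingTier.contrast_only:
                sp = _pooled_sd(
                    inv.sd_change, inv.n_randomised,
                    cmp_arm.sd_change, cmp_arm.n_randomised,
                )
                comp.contrast_value = inv.mean_change - cmp_arm.mean_change
                comp.contrast_se = sp * math.sqrt(
                    1.0 / inv.n_randomised + 1.0 / cmp_arm.n_randomised
                )
            elif tier is ReportingTier.p_and_n_only:
                comp.reported_p = _two_sample_p(
                    d, inv.n_randomised, cmp_arm.n_randomised
                )
                comp.direction = _direction_of(d)
        else:  # binary
            from .effects import d_from_binary_arms

            est = d_from_binary_arms(
                inv.events, inv.n_randomised, cmp_arm.events, cmp_arm.n_randomised,
                event_is_good=comp.better_is is BetterIs.higher,
            )
            if tier is ReportingTier.p_and_n_only:
                comp.reported_p = max(est.p_two_sided, 1e-300)
                comp.direction = _direction_of(est.d)
    for arm in trial.arms:
        if arm.arm_id not in keep_stats:
            arm.mean_change = None
            arm.sd_change = None
            arm.events = None


def _generate_one(
    config: GeneratorConfig, index: int
) -> Tuple[ApprovalRecord, List[List[ReportingTier]]]:
    """One fully reported approval plus the drawn per-trial comparison tiers."""
    data_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(index,))
    )
    tier_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(index, 1))
    )
    n_inv_arms = config.arms_per_trial - 1
    dose_min, dose_max = 10.0, 10.0 * n_inv_arms
    app = ApprovalRecord(
        approval_id=f"app_{index:03d}",
        drug=f"drug_{index:03d}",
        route=Route.oral,
        indication=f"indication_{index:03d}",
        year=2000 + index % 17,
        approved_dose_min=dose_min,
        approved_dose_max=dose_max,
    )
    tier_names = [t.value for t in _TIER_ORDER]
    tier_p = [config.tier_probabilities[t] for t in _TIER_ORDER]
    n_trials = config.trials_per_approval.draw(data_rng)
    tiers_by_trial: List[List[ReportingTier]] = []
    for t in range(n_trials):
        klass = (
            ComparatorClass.active
            if data_rng.random() < config.active_fraction
            else ComparatorClass.placebo
        )
        phase = (
            DesignPhase.continuation
            if data_rng.random() < config.continuation_fraction
            else DesignPhase.initiation
        )
        continuous = data_rng.random() < config.outcome_mix
        delta = float(
            data_rng.normal(
                config.true_effect_by_comparator[klass], math.sqrt(config.tau2)
            )
        )
        trial_id = f"app_{index:03d}_t{t:02d}"
        comp_role = (
            ArmRole.active_comparator
            if klass is ComparatorClass.active
            else ArmRole.placebo
        )
        n_comp = config.n_per_arm.draw(data_rng)
        arms: List[ArmRecord] = []
        comparisons: List[ArmComparison] = []
        if continuous:
            m, sd = _sample_continuous_arm(data_rng, 0.0, n_comp)
            comp_arm = ArmRecord(
                arm_id=f"{trial_id}_c", role=comp_role, n_randomised=n_comp,
                outcome_type=OutcomeType.continuous, mean_change=m, sd_change=sd,
                drug=None if klass is ComparatorClass.placebo else "comparator",
            )
        else:
            e = int(data_rng.binomial(n_comp, config.binary_event_rate))
            comp_arm = ArmRecord(
                arm_id=f"{trial_id}_c", role=comp_role, n_randomised=n_comp,
                outcome_type=OutcomeType.binary, events=e,
                drug=None if klass is ComparatorClass.placebo else "comparator",
            )
        arms.append(comp_arm)
        for j in range(n_inv_arms):
            n_inv = config.n_per_arm.draw(data_rng)
            arm_id = f"{trial_id}_i{j}"
            if continuous:
                # negative delta shifts the drug arm down: better_is=lower
                m, sd = _sample_continuous_arm(data_rng, delta, n_inv)
                arm = ArmRecord(
                    arm_id=arm_id, role=ArmRole.investigational, drug=app.drug,
                    daily_dose=10.0 * (j + 1), n_randomised=n_inv,
                    outcome_type=OutcomeType.continuous, mean_change=m, sd_change=sd,
                )
            else:
                logit = math.log(
                    config.binary_event_rate / (1.0 - config.binary_event_rate)
                ) + delta * math.pi / math.sqrt(3.0)
                p_inv = 1.0 / (1.0 + math.exp(-logit))
                arm = ArmRecord(
                    arm_id=arm_id, role=ArmRole.investigational, drug=app.drug,
                    daily_dose=10.0 * (j + 1), n_randomised=n_inv,
                    outcome_type=OutcomeType.binary,
                    events=int(data_rng.binomial(n_inv, p_inv)),
                )
            arms.append(arm)
            comparisons.append(
                ArmComparison(
                    trial_id=trial_id,
                    investigational_arm_id=arm_id,
                    comparator_arm_id=comp_arm.arm_id,
                    comparator_class=klass,
                    reporting_tier=ReportingTier.arm_stats,
                    better_is=BetterIs.lower,
                )
            )
        trial = TrialRecord(
            trial_id=trial_id,
            design_phase=phase,
            hypothesis=Hypothesis.superiority,
            duration_weeks=float(data_rng.integers(4, 53)),
            primary_outcome_kind=(
                PrimaryOutcomeKind.symptom_scale if continuous else PrimaryOutcomeKind.response
            ),
            arms=arms,
            comparisons=comparisons,
        )
        app.trials.append(trial)
        drawn = tier_rng.choice(tier_names, size=len(comparisons), p=tier_p)
        tiers = []
        for tier_name in drawn:
            tier = ReportingTier(tier_name)
            # a binary contrast has no continuous-scale difference to report
            if tier is ReportingTier.contrast_only and not continuous:
                tier = ReportingTier.arm_stats
            tiers.append(tier)
        tiers_by_trial.append(tiers)
    return app, tiers_by_trial


def generate_paired(
    config: GeneratorConfig,
) -> Tuple[List[ApprovalRecord], List[ApprovalRecord]]:
    """(censored, fully reported) views of the same simulated realisation."""
    censored: List[ApprovalRecord] = []
    full: List[ApprovalRecord] = []
    for i in range(config.n_approvals):
        app, tiers_by_trial = _generate_one(config, i)
        full.append(app)
        app_censored = app.model_copy(deep=True)
        for trial, tiers in zip(app_censored.trials, tiers_by_trial):
            _censor_trial(trial, tiers)
        censored.append(app_censored)
    validate_corpus(censored)
    validate_corpus(full)
    return censored, full


def generate(config: GeneratorConfig) -> List[ApprovalRecord]:
    """Generate a corpus under the configured study conditions."""
    return generate_paired(config)[0]


# ---------------------------------------------------------------------------
# the in-paper fixture corpus


class _FixtureBuilder:
    """Accumulates schematic trials, then assigns reporting tiers to match the
    published 158/29/12/67 comparison split."""

    # outcome-scale targets: means with unit SDs, so d equals the mean gap
    D_POSITIVE = -0.5
    D_POSITIVE_CONT = -0.6
    D_NEGATIVE = -0.05
    N_ARM = 120

    def __init__(self) -> None:
        self.approvals: List[ApprovalRecord] = []
        self.comp_specs: List[dict] = []  # one per comparison, in build order
        self._trial_counter = 0

    def add_approval(self, **kwargs) -> ApprovalRecord:
        kwargs.setdefault("approved_dose_min", 10.0)
        kwargs.setdefault("approved_dose_max", 60.0)
        app = ApprovalRecord(**kwargs)
        self.approvals.append(app)
        return app

    def add_trial(
        self,
        app: ApprovalRecord,
        phase: DesignPhase = DesignPhase.initiation,
        hypothesis: Hypothesis = Hypothesis.superiority,
        ni_verdict: NIVerdict = NIVerdict.not_applicable,
        nib: Optional[float] = None,
        pooled: bool = False,
        outcome: OutcomeType = OutcomeType.continuous,
        comparators: Tuple[Tuple[ComparatorClass, Optional[float]], ...] = (),
        inv_doses: Tuple[float, ...] = (20.0,),
        dose_excluded: bool = False,
        critical: bool = True,
    ) -> TrialRecord:
        """One trial; ``comparators`` holds (class, target d) pairs, with d=None
        meaning the comparator arm is present but never compared."""
        self._trial_counter += 1
        tid = f"{app.approval_id}_t{self._trial_counter:03d}"
        arms: List[ArmRecord] = []
        inv_arms: List[ArmRecord] = []
        doses = (5.0,) * len(inv_doses) if dose_excluded else inv_doses
        for j, dose in enumerate(doses):
            inv_arms.append(
                ArmRecord(
                    arm_id=f"{tid}_i{j}", role=ArmRole.investigational,
                    drug=app.drug, daily_dose=dose, n_randomised=self.N_ARM,
                    outcome_type=outcome,
                )
            )
        arms.extend(inv_arms)
        comparisons: List[ArmComparison] = []
        for klass, d_target in comparators:
            role = (
                ArmRole.active_comparator
                if klass is ComparatorClass.active
                else ArmRole.placebo
            )
            comp_arm = ArmRecord(
                arm_id=f"{tid}_{klass.value[:3]}", role=role,
                drug="comparator" if klass is ComparatorClass.active else None,
                n_randomised=self.N_ARM, outcome_type=outcome,
            )
            arms.append(comp_arm)
            if d_target is None:
                continue  # internal positive control: arm present, uncompared
            for j, inv_arm in enumerate(inv_arms):
                d_j = d_target if isinstance(d_target, float) else d_target[j]
                comp = ArmComparison(
                    trial_id=tid,
                    investigational_arm_id=inv_arm.arm_id,
                    comparator_arm_id=comp_arm.arm_id,
                    comparator_class=klass,
                    reporting_tier=ReportingTier.arm_stats,
                    better_is=BetterIs.lower,
                )
                comparisons.append(comp)
                self.comp_specs.append(
                    {
                        "comparison": comp,
                        "inv_arm": inv_arm,
                        "comp_arm": comp_arm,
                        "d": d_j,
                        "outcome": outcome,
                        "critical": critical or pooled,
                        "dose_excluded": dose_excluded,
                    }
                )
        trial = TrialRecord(
            trial_id=tid, design_phase=phase, hypothesis=hypothesis,
            duration_weeks=8.0, non_inferiority_boundary=nib,
            reported_ni_verdict=ni_verdict, pooled_analysis=pooled,
            arms=arms, comparisons=comparisons,
        )
        app.trials.append(trial)
        return trial

    def assign_tiers(
        self, n_insufficient: int, n_p_and_n: int, n_contrast: int
    ) -> None:
        """Critical comparisons stay at the top tier; the quota of degraded
        tiers is spread over the free ones in build order."""
        free = [
            s
            for s in self.comp_specs
            if not s["critical"] and not s["dose_excluded"]
            and s["outcome"] is OutcomeType.continuous
        ]
        if len(free) < n_insufficient + n_p_and_n + n_contrast:
            raise RuntimeError("not enough free comparisons for the tier quota")
        for spec in free[:n_insufficient]:
            spec["tier"] = ReportingTier.insufficient
        for spec in free[n_insufficient : n_insufficient + n_p_and_n]:
            spec["tier"] = ReportingTier.p_and_n_only
        for spec in free[
            n_insufficient + n_p_and_n : n_insufficient + n_p_and_n + n_contrast
        ]:
            spec["tier"] = ReportingTier.contrast_only
        for spec in self.comp_specs:
            spec.setdefault("tier", ReportingTier.arm_stats)

    def materialise(self) -> List[ApprovalRecord]:
        """Fill in arm statistics / contrast / p fields according to each
        comparison's tier, then blank statistics no arm_stats comparison needs."""
        n = self.N_ARM
        keep_stats: Dict[int, bool] = {}
        for spec in self.comp_specs:
            comp: ArmComparison = spec["comparison"]
            tier: ReportingTier = spec["tier"]
            comp.reporting_tier = tier
            d = spec["d"]
            if tier is ReportingTier.arm_stats:
                keep_stats[id(spec["inv_arm"])] = True
                keep_stats[id(spec["comp_arm"])] = True
                if spec["outcome"] is OutcomeType.continuous:
                    spec["inv_arm"].mean_change = d
                    spec["inv_arm"].sd_change = 1.0
                    spec["comp_arm"].mean_change = 0.0
                    spec["comp_arm"].sd_change = 1.0
                else:
                    # response event (good): drug arm responds more often
                    spec["comp_arm"].events = int(round(0.4 * n))
                    spec["inv_arm"].events = int(round(0.6 * n))
                    comp.better_is = BetterIs.higher
            elif tier is ReportingTier.contrast_only:
                comp.contrast_value = d
                comp.contrast_se = math.sqrt(2.0 / n)
            elif tier is ReportingTier.p_and_n_only:
                comp.reported_p = _two_sample_p(d, n, n)
                comp.direction = _direction_of(d)
        for app in self.approvals:
            for trial in app.trials:
                for arm in trial.arms:
                    if not keep_stats.get(id(arm), False):
                        arm.mean_change = None
                        arm.sd_change = None
                        arm.events = None
        return self.approvals


def reference_corpus() -> List[ApprovalRecord]:
    """The deterministic 27-approval corpus matching the published tallies.

    Evidence categories per column, non-inferiority verdicts, continuation
    evidence, the four named evaluations, the five agitation evaluations with
    continuation evidence not required, the safety/tolerance reporting
    tallies, the 48/137 trials excluding suicidal participants and the
    158/29/12/67 reporting-tier split over 266 dose-eligible comparisons are
    all reproduced; everything else (synthetic drug names, flag values of
    unnamed approvals, dose levels) is schematic.
    """
    b = _FixtureBuilder()
    PL, AC = ComparatorClass.placebo, ComparatorClass.active
    POS, NEG, CPOS = b.D_POSITIVE, b.D_NEGATIVE, b.D_POSITIVE_CONT

    meta = _fixture_approval_metadata()
    apps = [b.add_approval(**m) for m in meta]
    (p01, p02, p03, p04, p05, p06, p07, p08, p09, p10,
     p11, p12, p13, p14, p15, p16, p17, p18, p19, p20,
     p21, p22, p23, p24, p25, p26, p27) = apps

    def cont_placebo_pos(app):
        b.add_trial(app, phase=DesignPhase.continuation,
                    comparators=((PL, CPOS),))

    # P01 olanzapine oral / schizophrenia: robust superiority vs active,
    # plus the study whose doses all fall below the approved minimum.
    for app in (p01, p02):
        b.add_trial(app, comparators=((AC, POS), (PL, POS)))
        b.add_trial(app, comparators=((AC, POS), (PL, POS)))
        cont_placebo_pos(app)
    b.add_trial(p01, comparators=((PL, POS),), dose_excluded=True)

    # P03/P04 duloxetine: pooled non-inferiority analyses vs active
    for app, n_pooled in ((p03, 2), (p04, 1)):
        for _ in range(n_pooled):
            b.add_trial(app, hypothesis=Hypothesis.non_inferiority,
                        ni_verdict=NIVerdict.positive, nib=2.0, pooled=True,
                        comparators=((AC, None),))
        b.add_trial(app, comparators=((PL, POS),))
        b.add_trial(app, comparators=((PL, POS),))
        cont_placebo_pos(app)

    # P05 paliperidone IM maintenance: one positive, two negative NI trials
    for verdict in (NIVerdict.positive, NIVerdict.negative, NIVerdict.negative):
        b.add_trial(p05, hypothesis=Hypothesis.non_inferiority, ni_verdict=verdict,
                    nib=2.0, comparators=((AC, NEG),), critical=False)
    b.add_trial(p05, comparators=((PL, POS),))
    b.add_trial(p05, comparators=((PL, POS),))
    b.add_trial(p05, phase=DesignPhase.continuation, comparators=((AC, NEG),),
                critical=False)
    cont_placebo_pos(p05)

    # P06: the single positive continuation non-inferiority trial vs active
    b.add_trial(p06, phase=DesignPhase.continuation,
                hypothesis=Hypothesis.non_inferiority,
                ni_verdict=NIVerdict.positive, nib=2.0,
                comparators=((AC, NEG),), critical=False)
    b.add_trial(p06, comparators=((PL, POS),))
    b.add_trial(p06, comparators=((PL, POS),))
    cont_placebo_pos(p06)

    # P07: active arm never compared (the placebo contrast it anchors is
    # negative); one negative continuation trial vs active
    b.add_trial(p07, comparators=((PL, NEG), (AC, None)), critical=False)
    b.add_trial(p07, phase=DesignPhase.continuation, comparators=((AC, NEG),),
                critical=False)
    cont_placebo_pos(p07)

    # P08-P10: one positive superiority trial vs active (and one vs placebo)
    for app in (p08, p09, p10):
        b.add_trial(app, comparators=((AC, POS), (PL, POS)))
    cont_placebo_pos(p08)
    cont_placebo_pos(p09)

    # P11-P13: only negative superiority vs active; no placebo initiation trials
    for app in (p11, p12, p13):
        b.add_trial(app, comparators=((AC, NEG),), critical=False)
        cont_placebo_pos(app)

    # P14-P21: internal positive control only (active arm uncompared)
    for app in (p14, p15, p16, p17, p18, p19, p20, p21):
        b.add_trial(app, comparators=((PL, POS), (AC, None)))
        b.add_trial(app, comparators=((PL, POS), (AC, None)))
    for app in (p14, p15, p16, p17, p18, p19):
        b.add_trial(app, hypothesis=Hypothesis.non_inferiority,
                    ni_verdict=NIVerdict.positive, nib=2.0,
                    comparators=((AC, NEG),), critical=False)
    for app in (p14, p15, p16, p17):
        cont_placebo_pos(app)

    # P22-P26 agitation: continuation evidence not required; binary response
    for app in (p22, p23, p24, p25, p26):
        b.add_trial(app, outcome=OutcomeType.binary, comparators=((PL, POS),))
        b.add_trial(app, outcome=OutcomeType.binary, comparators=((PL, POS),))

    # P27 nalmefene: comparative effectiveness not required
    for _ in range(3):
        b.add_trial(p27, comparators=((PL, POS),))

    # filler placebo superiority trials (all negative) to reach 137 studies
    # and 266 dose-eligible comparisons
    robust_placebo = [p01, p02, p03, p04, p05, p06, p14, p15, p16, p17,
                      p18, p19, p20, p21, p22, p23, p24, p25, p26, p27]
    n_base_trials = sum(
        1 for app in b.approvals for t in app.trials if not t.pooled_analysis
    )
    n_base_comps = sum(
        1 for s in b.comp_specs if not s["dose_excluded"]
    )
    n_fillers = 137 - n_base_trials
    need = 266 - n_base_comps
    q, r = divmod(need, n_fillers)
    for f in range(n_fillers):
        app = robust_placebo[f % len(robust_placebo)]
        n_doses = q + 1 if f < r else q
        b.add_trial(
            app,
            comparators=((PL, NEG),),
            inv_doses=tuple(10.0 * (j + 1) for j in range(n_doses)),
            critical=False,
        )

    b.assign_tiers(n_insufficient=67, n_p_and_n=12, n_contrast=29)
    corpus = b.materialise()

    # 48 of the 137 trials explicitly excluded suicidal participants
    real_trials = [
        t for app in corpus for t in app.trials if not t.pooled_analysis
    ]
    for t in real_trials[:48]:
        t.suicidal_excluded = SuicidalExcluded.yes

    validate_corpus(corpus)
    return corpus


def _fixture_approval_metadata() -> List[dict]:
    """Per-approval identity and flag fields.

    Only the tallies are anchored in the published appraisal (safety and
    tolerance comparison reporting, the four named evaluations, the five
    agitation evaluations, routes 16 oral / 8 IM / 3 other, years 1996-2016
    with median 2008); individual flag assignments are otherwise arbitrary.
    """
    q, ql, ab = (
        ComparisonReporting.quantitative,
        ComparisonReporting.qualitative,
        ComparisonReporting.absent,
    )
    names = [
        ("olanzapine", "schizophrenia", Route.oral),
        ("varenicline", "smoking cessation", Route.oral),
        ("duloxetine", "major depressive disorder", Route.oral),
        ("duloxetine", "generalised anxiety disorder", Route.oral),
        ("paliperidone", "schizophrenia maintenance", Route.intramuscular),
        ("aripiprazole", "schizophrenia", Route.intramuscular),
        ("drug_a", "indication_07", Route.oral),
        ("drug_a", "indication_08", Route.oral),
        ("drug_b", "indication_09", Route.oral),
        ("drug_b", "indication_10", Route.oral),
        ("drug_c", "indication_11", Route.oral),
        ("drug_c", "indication_12", Route.oral),
        ("drug_c", "indication_13", Route.oral),
        ("drug_d", "indication_14", Route.intramuscular),
        ("drug_d", "indication_15", Route.oral),
        ("drug_d", "indication_16", Route.oral),
        ("drug_d", "indication_17", Route.oral),
        ("drug_e", "indication_18", Route.oral),
        ("drug_e", "indication_19", Route.inhalation),
        ("drug_e", "indication_20", Route.sublingual),
        ("drug_g", "indication_21", Route.inhalation),
        ("olanzapine", "agitation", Route.intramuscular),
        ("aripiprazole", "agitation", Route.intramuscular),
        ("drug_f", "agitation", Route.intramuscular),
        ("drug_f", "agitation (bipolar)", Route.intramuscular),
        ("drug_f", "agitation (dementia)", Route.intramuscular),
        ("nalmefene", "alcohol use disorder", Route.oral),
    ]
    years = [1996, 1997, 1998, 1999, 2000, 2001, 2002, 2003, 2004, 2005,
             2006, 2007, 2007, 2008, 2009, 2010, 2011, 2012, 2013, 2014,
             2015, 2016, 2016, 2016, 2016, 2016, 2016]
    metas: List[dict] = []
    for i, ((drug, indication, route), year) in enumerate(zip(names, years)):
        k = i + 1
        metas.append(
            {
                "approval_id": f"P{k:02d}",
                "drug": drug,
                "indication": indication,
                "route": route,
                "year": year,
                # safety vs active: 17 quantitative, 2 qualitative, 7 absent (of 26)
                "safety_comparison_active": q if k <= 17 else (ql if k <= 19 else ab),
                # tolerance vs active: 21 quantitative, 1 qualitative, 4 absent
                "tolerance_comparison_active": q if k <= 21 else (ql if k == 22 else ab),
                # safety vs placebo: 21 quantitative, 2 qualitative, 4 absent (of 27)
                "safety_comparison_placebo": q if k <= 21 else (ql if k <= 23 else ab),
                # tolerance vs placebo: 25 quantitative, 1 qualitative, 1 absent
                "tolerance_comparison_placebo": q if k <= 25 else (ql if k == 26 else ab),
                "subgroup_basis": (
                    SubgroupBasis.post_hoc if k in (11, 12)
                    else SubgroupBasis.pre_specified if k == 13
                    else SubgroupBasis.none
                ),
                "bias_assessment": (
                    BiasAssessment.reported_no_bias if k <= 5
                    else BiasAssessment.none_reported
                ),
                "safety_issue": IssueFlag.possible if k in (5, 11) else IssueFlag.no,
                "tolerance_issue": IssueFlag.yes if k == 11 else IssueFlag.no,
                "divergent_opinion": k == 5,
                "comparative_evidence_required": k != 27,
                "continuation_evidence_required": k not in (22, 23, 24, 25, 26),
                "n_exposed_presubmission": 1000 + 100 * k,
            }
        )
    return metas
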