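"""Cohen's d derivation cascade: hand oracles, sign conventions, round trips."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from approvalmeta.corpus import (
    ArmComparison,
    ArmRecord,
    BetterIs,
    Direction,
    ReportingTier,
    TrialRecord,
)
from approvalmeta.effects import (
    EffectEstimate,
    Unusable,
    d_from_binary_arms,
    d_from_continuous_arms,
    d_from_contrast,
    d_from_p_n,
    derive_effect,
    hedges_correction,
)

SQRT3_PI = math.sqrt(3.0) / math.pi


class TestContinuousArms:
    def test_hand_oracle(self):
        """m=10 vs 11, sd=2, n=50/50: d=-0.5, var=0.04+0.25/200."""
        e = d_from_continuous_arms(10, 2, 50, 11, 2, 50)
        assert e.d == pytest.approx(-0.5, abs=1e-10)
        assert e.var_d == pytest.approx(0.04125, abs=1e-10)
        assert e.se_d == pytest.approx(math.sqrt(0.04125), abs=1e-10)

    def test_equal_means_give_null_effect(self):
        e = d_from_continuous_arms(7.3, 1.5, 40, 7.3, 2.5, 60)
        assert e.d == 0.0
        assert e.p_two_sided == 1.0

    def test_swapping_arms_negates_d(self):
        a = d_from_continuous_arms(10, 2, 40, 12, 3, 60)
        b = d_from_continuous_arms(12, 3, 60, 10, 2, 40)
        assert b.d == pytest.approx(-a.d, abs=1e-12)
        assert b.var_d == pytest.approx(a.var_d, abs=1e-12)
        assert b.p_two_sided == pytest.approx(a.p_two_sided, abs=1e-12)

    def test_higher_is_better_flips_sign(self):
        lo = d_from_continuous_arms(10, 2, 50, 11, 2, 50, better_is=BetterIs.lower)
        hi = d_from_continuous_arms(10, 2, 50, 11, 2, 50, better_is=BetterIs.higher)
        assert hi.d == pytest.approx(-lo.d)
        # an investigational arm with better scores always favours the drug
        assert lo.d < 0 and hi.d > 0

    @given(
        m=st.floats(-50, 50),
        gap=st.floats(-5, 5),
        sd=st.floats(0.2, 10),
        scale=st.floats(0.01, 100),
        n1=st.integers(2, 500),
        n2=st.integers(2, 500),
    )
    @settings(max_examples=100, derandomize=True)
    def test_scale_invariance(self, m, gap, sd, scale, n1, n2):
        """Multiplying all means and SDs by a constant leaves d unchanged."""
        a = d_from_continuous_arms(m, sd, n1, m + gap, sd * 1.3, n2)
        b = d_from_continuous_arms(m * scale, sd * scale, n1,
                                   (m + gap) * scale, sd * 1.3 * scale, n2)
        assert b.d == pytest.approx(a.d, rel=1e-9, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            d_from_continuous_arms(float("nan"), 1, 50, 0, 1, 50)
        with pytest.raises(ValueError):
            d_from_continuous_arms(0, 1, 1, 0, 1, 50)
        with pytest.raises(ValueError):
            d_from_continuous_arms(0, -1, 50, 0, 1, 50)

    def test_hedges_shrinks_towards_zero(self):
        e = d_from_continuous_arms(10, 2, 10, 11, 2, 10)
        g = hedges_correction(e)
        assert abs(g.d) < abs(e.d)
        j = 1 - 3 / (4 * 18 - 1)
        assert g.d == pytest.approx(j * e.d)


class TestBinaryArms:
    def test_hand_oracle(self):
        """30/50 vs 20/50, good event: d = -(sqrt3/pi) ln(2.25)."""
        e = d_from_binary_arms(30, 50, 20, 50, event_is_good=True)
        assert e.d == pytest.approx(-SQRT3_PI * math.log((30 * 30) / (20 * 20)), abs=1e-10)
        expected_var = (3 / math.pi**2) * (1 / 30 + 1 / 20 + 1 / 20 + 1 / 30)
        assert e.var_d == pytest.approx(expected_var, abs=1e-10)

    def test_equal_proportions_give_zero(self):
        assert d_from_binary_arms(10, 50, 10, 50).d == 0.0

    def test_degenerate_no_events(self):
        e = d_from_binary_arms(0, 10, 0, 10)
        assert e.degenerate
        assert not e.significant

    def test_continuity_correction_only_with_zero_cell(self):
        corrected = d_from_binary_arms(0, 20, 5, 20)
        expected = SQRT3_PI * math.log((0.5 * 15.5) / (20.5 * 5.5))
        assert corrected.d == pytest.approx(expected, abs=1e-12)
        plain = d_from_binary_arms(1, 20, 5, 20)
        assert plain.d == pytest.approx(SQRT3_PI * math.log((1 * 15) / (19 * 5)), abs=1e-12)

    def test_event_orientation(self):
        # harmful event (relapse): fewer events in drug arm favours the drug
        e = d_from_binary_arms(10, 50, 20, 50, event_is_good=False)
        assert e.d < 0
        # beneficial event (response): more events favours the drug
        e = d_from_binary_arms(30, 50, 20, 50, event_is_good=True)
        assert e.d < 0

    def test_swapping_arms_negates_d(self):
        a = d_from_binary_arms(30, 50, 20, 60)
        b = d_from_binary_arms(20, 60, 30, 50)
        assert b.d == pytest.approx(-a.d, abs=1e-12)
        assert b.var_d == pytest.approx(a.var_d, abs=1e-12)

    def test_events_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            d_from_binary_arms(51, 50, 20, 50)


class TestContrast:
    def test_hand_oracle(self):
        """contrast=-2, se=1, n=50/50: t=-2, d=-2*sqrt(0.04)=-0.4."""
        e = d_from_contrast(-2, 1, 50, 50)
        assert e.d == pytest.approx(-0.4, abs=1e-10)

    def test_null_contrast(self):
        e = d_from_contrast(0.0, 2.0, 30, 30)
        assert e.d == 0.0 and e.p_two_sided == 1.0

    def test_agrees_with_arm_stats_path(self):
        """Computing the contrast and SE from the same arm statistics must give
        the same d and p as the direct arm-statistics path."""
        m1, s1, n1, m2, s2, n2 = 8.0, 2.0, 200, 9.0, 2.4, 180
        direct = d_from_continuous_arms(m1, s1, n1, m2, s2, n2)
        sp = math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
        via_contrast = d_from_contrast(m1 - m2, sp * math.sqrt(1 / n1 + 1 / n2), n1, n2)
        assert via_contrast.d == pytest.approx(direct.d, rel=1e-12)
        assert via_contrast.p_two_sided == pytest.approx(direct.p_two_sided, rel=1e-12)

    def test_bad_se(self):
        with pytest.raises(ValueError):
            d_from_contrast(1.0, 0.0, 50, 50)


class TestImputationFromPAndN:
    def test_p_of_one_gives_zero(self):
        assert d_from_p_n(1.0, 50, 50, Direction.favours_investigational).d == 0.0

    def test_t_quantile_oracle(self):
        """p=0.05, n=50/50: |t| = t_{0.975,98} = 1.98446745..., d = -0.39689..."""
        e = d_from_p_n(0.05, 50, 50, Direction.favours_investigational)
        assert e.d == pytest.approx(-1.9844674544266925 * math.sqrt(0.04), abs=1e-9)
        assert e.tier_used is ReportingTier.p_and_n_only

    @given(
        gap=st.floats(-3, 3),
        n1=st.integers(5, 400),
        n2=st.integers(5, 400),
    )
    @settings(max_examples=150, derandomize=True)
    def test_round_trip_recovers_d(self, gap, n1, n2):
        """Imputation from (p, n, direction) inverts the t-based p exactly."""
        src = d_from_continuous_arms(10 + gap, 2, n1, 10, 2, n2)
        if src.p_two_sided < 1e-12:  # quantile function loses precision
            return
        direction = (
            Direction.favours_investigational if src.d < 0
            else Direction.favours_comparator if src.d > 0
            else None
        )
        if direction is None:
            return
        back = d_from_p_n(src.p_two_sided, n1, n2, direction)
        assert back.d == pytest.approx(src.d, abs=1e-6)

    def test_missing_direction_rejected(self):
        with pytest.raises(ValueError):
            d_from_p_n(0.03, 50, 50, Direction.null)


def _two_arm_trial(tier, *, stats=True, reported_p=None, direction=None,
                   contrast=None, contrast_se=None):
    arms = [
        ArmRecord(arm_id="i", role="investigational", daily_dose=20.0,
                  n_randomised=50,
                  mean_change=-0.4 if stats else None,
                  sd_change=1.0 if stats else None),
        ArmRecord(arm_id="c", role="placebo", n_randomised=50,
                  mean_change=0.0 if stats else None,
                  sd_change=1.0 if stats else None),
    ]
    comp = ArmComparison(
        trial_id="t", investigational_arm_id="i", comparator_arm_id="c",
        comparator_class="placebo", reporting_tier=tier,
        reported_p=reported_p, direction=direction,
        contrast_value=contrast, contrast_se=contrast_se,
    )
    trial = TrialRecord(trial_id="t", design_phase="initiation",
                        hypothesis="superiority", arms=arms, comparisons=[comp])
    return comp, trial


class TestDerivationDispatch:
    def test_arm_stats_tier(self):
        est = derive_effect(*_two_arm_trial(ReportingTier.arm_stats))
        assert isinstance(est, EffectEstimate)
        assert est.tier_used is ReportingTier.arm_stats

    def test_p_and_n_tier(self):
        est = derive_effect(*_two_arm_trial(
            ReportingTier.p_and_n_only, stats=False, reported_p=0.04,
            direction=Direction.favours_investigational))
        assert isinstance(est, EffectEstimate)
        assert est.tier_used is ReportingTier.p_and_n_only
        assert est.d < 0

    def test_contrast_tier(self):
        est = derive_effect(*_two_arm_trial(
            ReportingTier.contrast_only, stats=False,
            contrast=-0.5, contrast_se=0.2))
        assert est.tier_used is ReportingTier.contrast_only

    def test_p_without_direction_is_unusable(self):
        est = derive_effect(*_two_arm_trial(
            ReportingTier.p_and_n_only, stats=False, reported_p=0.5,
            direction=Direction.null))
        assert isinstance(est, Unusable)

    def test_insufficient_is_unusable(self):
        est = derive_effect(*_two_arm_trial(ReportingTier.insufficient, stats=False))
        assert isinstance(est, Unusable)

    def test_inconsistent_tier_raises(self):
        comp, trial = _two_arm_trial(ReportingTier.contrast_only, stats=False)
        with pytest.raises(ValueError, match="contrast"):
            derive_effect(comp, trial)
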