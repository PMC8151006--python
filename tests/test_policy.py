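"""Effectiveness products, the prevalence-shift equation, scenario path."""

from fractions import Fraction

import pytest
from hypothesis import given, strategies as st

from tabsim import (
    BanLevel,
    PolicyDefinition,
    build_scenario_path,
    bundled_country,
    post_prevalence,
    reallocate_prevalence,
    status_quo_effectiveness,
)
from tabsim.policy import ReallocationMode, policy_schedule


class TestStatusQuoEffectiveness:
    @pytest.mark.parametrize(
        "level,compliance,expected",
        [
            (BanLevel.COMPREHENSIVE, 0.90, 0.081),  # Brazil
            (BanLevel.PARTIAL, 0.75, 0.0075),  # Argentina
            (BanLevel.COMPREHENSIVE, 0.75, 0.0675),  # Colombia
            (BanLevel.PARTIAL, 0.55, 0.0055),  # Bolivia
            (BanLevel.PARTIAL, 0.80, 0.008),  # Chile
            (BanLevel.ABSENT, 0.99, 0.0),
        ],
    )
    def test_published_effectiveness_products(self, level, compliance, expected):
        em = status_quo_effectiveness(PolicyDefinition(level, compliance))
        assert em == pytest.approx(expected, rel=1e-12)

    def test_effectiveness_multiplicative_in_compliance(self):
        full = status_quo_effectiveness(PolicyDefinition(BanLevel.COMPREHENSIVE, 1.0))
        half = status_quo_effectiveness(PolicyDefinition(BanLevel.COMPREHENSIVE, 0.5))
        assert half == full / 2

    def test_compliance_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="compliance"):
            PolicyDefinition(BanLevel.PARTIAL, 1.2)

    def test_from_country_uses_recorded_policy(self):
        pol = PolicyDefinition.from_country(bundled_country("co"))
        assert pol.ban_level is BanLevel.COMPREHENSIVE
        assert status_quo_effectiveness(pol) == pytest.approx(0.0675)

    def test_ranges_contain_central_values(self):
        pol = PolicyDefinition(BanLevel.COMPREHENSIVE, 1.0)
        for level, central in pol.central_effectiveness.items():
            lo, hi = pol.effectiveness_range[level]
            assert lo <= central <= hi


class TestPostPrevalence:
    def test_hand_arithmetic(self):
        assert post_prevalence(0.352, 0.09, 0.5) == pytest.approx(0.33616)

    def test_zero_effectiveness_is_identity(self):
        assert post_prevalence(0.25, 0.0, 0.5) == 0.25

    def test_full_effect_drives_prevalence_to_zero(self):
        assert post_prevalence(0.25, 1.0, 1.0) == pytest.approx(0.0)

    def test_inputs_outside_unit_interval_rejected(self):
        for bad in (dict(prev_pre=1.2, em=0.1, ip=0.5), dict(prev_pre=0.2, em=-0.1, ip=0.5)):
            with pytest.raises(ValueError):
                post_prevalence(**bad)

    @given(
        prev=st.floats(0, 1),
        em1=st.floats(0, 1),
        em2=st.floats(0, 1),
        ip=st.floats(0, 1),
    )
    def test_monotone_non_increasing_in_effectiveness(self, prev, em1, em2, ip):
        lo, hi = sorted((em1, em2))
        assert post_prevalence(prev, hi, ip) <= post_prevalence(prev, lo, ip) + 1e-15

    def test_matches_exact_rational_arithmetic_on_grid(self):
        for p in (0, 1, 7, 35):
            for em in (0, 9, 50, 100):
                for ip in (0, 50, 75, 100):
                    exact = Fraction(p, 100) * (1 - Fraction(em, 100) * Fraction(ip, 100))
                    got = post_prevalence(p / 100, em / 100, ip / 100)
                    assert got == pytest.approx(float(exact), abs=1e-15)


class TestScenarioPath:
    def test_short_and_long_term_ip_values(self):
        path = build_scenario_path()
        assert path.ip(1) == 0.5
        assert path.ip(5) == 0.5
        assert path.ip(10) == 0.75

    def test_year_eight_interpolates_linearly(self):
        assert build_scenario_path().ip(8) == pytest.approx(0.65)

    def test_intensity_benefit_phases_in_over_years_one_to_five(self):
        path = build_scenario_path()
        assert not path[1].intensity_adjustment_active
        weights = [path[t].intensity_weight for t in range(1, 6)]
        assert weights == pytest.approx([0.0, 0.25, 0.5, 0.75, 1.0])
        assert path[7].intensity_weight == 1.0

    def test_reallocation_switches_to_nonsmoker_in_second_half(self):
        path = build_scenario_path()
        assert path[5].reallocation_mode is ReallocationMode.TO_FORMER
        assert path[6].reallocation_mode is ReallocationMode.TO_NONSMOKER

    def test_long_horizon_holds_long_term_scenario(self):
        path = build_scenario_path(horizon=15)
        assert path.ip(15) == 0.75

    def test_nonpositive_horizon_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            build_scenario_path(horizon=0)


class TestReallocatePrevalence:
    def test_no_change_when_post_equals_baseline(self):
        base = (0.20, 0.10, 0.70)
        assert reallocate_prevalence(base, 0.20, "to_former") == base

    def test_quitters_join_former_pool(self):
        got = reallocate_prevalence((0.20, 0.10, 0.70), 0.18, "to_former")
        assert got == pytest.approx((0.18, 0.12, 0.70))

    def test_long_term_growth_goes_to_never_pool(self):
        got = reallocate_prevalence((0.20, 0.10, 0.70), 0.18, "to_nonsmoker")
        assert got == pytest.approx((0.18, 0.10, 0.72))

    def test_post_above_baseline_prevalence_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            reallocate_prevalence((0.20, 0.10, 0.70), 0.25, "to_former")

    @given(
        p_cur=st.floats(0.01, 0.5),
        p_for=st.floats(0, 0.4),
        shrink=st.floats(0, 1),
        mode=st.sampled_from(list(ReallocationMode)),
    )
    def test_total_mass_conserved(self, p_cur, p_for, shrink, mode):
        base = (p_cur, p_for, 1 - p_cur - p_for)
        out = reallocate_prevalence(base, p_cur * shrink, mode)
        assert sum(out) == pytest.approx(1.0, abs=1e-12)
        assert all(x >= -1e-15 for x in out)


class TestPolicySchedule:
    def test_zero_effectiveness_reproduces_baseline_exactly(self, ar):
        sched = policy_schedule(ar, em=0.0)
        base = ar.state_distribution()
        for ystate in sched:
            assert ystate.distribution == base
            assert ystate.consumption_reduction == 0.0

    def test_prevalence_shift_applied_to_baseline_not_compounded(self, ar):
        sched = policy_schedule(ar, em=0.09)
        base = ar.state_distribution()["male"][0]
        assert sched[0].distribution["male"][0] == pytest.approx(base * (1 - 0.09 * 0.5))
        assert sched[9].distribution["male"][0] == pytest.approx(base * (1 - 0.09 * 0.75))

    def test_consumption_reduction_ramps_with_intensity_weight(self, ar):
        sched = policy_schedule(ar, em=0.09)
        assert sched[0].consumption_reduction == 0.0
        assert sched[4].consumption_reduction == pytest.approx(0.09 * 0.5)
        assert sched[9].consumption_reduction == pytest.approx(0.09 * 0.5)
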