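"""Cohort engine: transition construction, conservation, reward accumulation.

The key check is oracle equivalence: for a short horizon the matrix engine
must agree with an exhaustive, independently coded enumeration over all state
paths, probability-weighted.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from renalcea.errors import DomainError
from renalcea.markov import (
    ModelSettings,
    TransitionSchedule,
    accumulate_outcomes,
    build_transition_row,
    discount_factor,
    run_arm,
    run_cohort,
    survival_to_death_probs,
)
from renalcea.parameters import draw_from_means, sample_draw

from conftest import TEST_SEED

CAPD_CURVE = (0.80, 0.72, 0.60, 0.57, 0.52)
HD_CURVE = (0.824, 0.706, 0.621, 0.580, 0.553)


class TestSurvivalConversion:
    @pytest.mark.parametrize(
        "curve, expected_first5",
        [
            # hand-computed 1 - S(t)/S(t-1)
            (CAPD_CURVE, [0.2, 0.1, 1 - 0.60 / 0.72, 1 - 0.57 / 0.60, 1 - 0.52 / 0.57]),
            (
                HD_CURVE,
                [
                    1 - 0.824,
                    1 - 0.706 / 0.824,
                    1 - 0.621 / 0.706,
                    1 - 0.580 / 0.621,
                    1 - 0.553 / 0.580,
                ],
            ),
        ],
    )
    def test_conditional_probabilities(self, curve, expected_first5):
        p = survival_to_death_probs(curve, horizon=40)
        assert p[:5] == pytest.approx(expected_first5, abs=1e-9)
        # final-year convention: constant tail equal to the year-5 value
        assert p[5:] == pytest.approx(np.full(35, expected_first5[-1]), abs=1e-9)

    def test_mean_hazard_tail(self):
        p = survival_to_death_probs(HD_CURVE, horizon=10, tail_rule="mean_hazard")
        expected_tail = 1 - (0.553 / 0.824) ** 0.25
        assert p[5:] == pytest.approx(np.full(5, expected_tail), abs=1e-12)
        # observed years unchanged by the tail rule
        assert p[0] == pytest.approx(1 - 0.824, abs=1e-12)

    def test_constant_curve_has_no_later_deaths(self):
        p = survival_to_death_probs([0.7] * 5, horizon=8)
        assert p[0] == pytest.approx(0.3)
        assert p[1:] == pytest.approx(np.zeros(7), abs=1e-12)

    def test_reconstructs_survivor_fractions(self):
        """Products of (1 - p) give back the cumulative curve."""
        p = survival_to_death_probs(CAPD_CURVE, horizon=5)
        assert np.cumprod(1 - p) == pytest.approx(CAPD_CURVE, abs=1e-12)

    @pytest.mark.parametrize(
        "bad", [[0.8, 0.9, 0.7, 0.6, 0.5], [0.8, 0.0, 0.0, 0.0, 0.0], [1.2, 0.9]]
    )
    def test_rejects_invalid_curves(self, bad):
        with pytest.raises(DomainError):
            survival_to_death_probs(bad)


class TestDiscounting:
    @pytest.mark.parametrize(
        "rate, cycle, expected",
        [(0.03, 0, 1.0), (0.03, 1, 1 / 1.03), (0.0, 10, 1.0), (0.05, 2, 1.05 ** -2)],
    )
    def test_factor(self, rate, cycle, expected):
        assert discount_factor(rate, cycle) == pytest.approx(expected, abs=1e-12)

    def test_negative_cycle_rejected(self):
        with pytest.raises(DomainError):
            discount_factor(0.03, -1)


class TestTransitionRows:
    def test_capd_year_one_at_base_means(self, base_draw):
        schedule = TransitionSchedule.from_draw(base_draw, 40, "final_year")
        row = build_transition_row("CAPD", 1, schedule)
        assert row == pytest.approx([0.7464, 0.0536, 0.2000], abs=1e-12)

    def test_dead_is_absorbing(self, base_draw):
        schedule = TransitionSchedule.from_draw(base_draw, 40)
        for year in (1, 7, 40):
            assert build_transition_row("Dead", year, schedule) == pytest.approx(
                [0.0, 0.0, 1.0]
            )

    def test_zero_switching_decouples_arms(self, base_draw):
        values = dict(base_draw.values, p_capd_to_hd=0.0, p_hd_to_capd=0.0)
        draw = type(base_draw)(values=values)
        schedule = TransitionSchedule.from_draw(draw, 40, "final_year")
        p_death = schedule.death_probs["CAPD"][0]
        row = build_transition_row("CAPD", 1, schedule)
        assert row == pytest.approx([1 - p_death, 0.0, p_death], abs=1e-15)

    def test_rows_sum_to_one(self, params):
        rng = np.random.default_rng(TEST_SEED)
        for i in range(20):
            schedule = TransitionSchedule.from_draw(sample_draw(params, rng), 15)
            for state in ("CAPD", "HD", "Dead"):
                for year in (1, 5, 6, 15):
                    row = build_transition_row(state, year, schedule)
                    assert row.sum() == pytest.approx(1.0, abs=1e-15)
                    assert np.all(row >= 0)


class TestCohortTrace:
    def test_first_cycle_equals_transition_row(self, base_draw):
        trace = run_cohort(base_draw, "CAPD", horizon=40, tail_rule="final_year")
        assert trace.occupancy[0] == pytest.approx([1.0, 0.0, 0.0])
        assert trace.occupancy[1] == pytest.approx([0.7464, 0.0536, 0.2000], abs=1e-12)

    def test_certain_death_absorbs_immediately(self, base_draw):
        values = dict(base_draw.values)
        for arm in ("capd", "hd"):
            for y in range(1, 6):
                values[f"surv_{arm}_{y}"] = 1e-12
        draw = type(base_draw)(values=values)
        trace = run_cohort(draw, "HD", horizon=4)
        for t in range(1, 5):
            assert trace.occupancy[t] == pytest.approx([0.0, 0.0, 1.0], abs=1e-9)

    def test_conservation_and_monotone_death(self, params):
        rng = np.random.default_rng(TEST_SEED)
        for i in range(20):
            draw = sample_draw(params, rng, index=i)
            for start in ("CAPD", "HD"):
                trace = run_cohort(draw, start, horizon=40)
                sums = trace.occupancy.sum(axis=1)
                assert np.allclose(sums, 1.0, atol=1e-12)
                dead = trace.occupancy[:, 2]
                assert np.all(np.diff(dead) >= -1e-15)
                assert np.all((trace.occupancy >= -1e-15) & (trace.occupancy <= 1 + 1e-15))


def enumerate_paths_outcomes(draw, start, horizon, settings):
    """Independent oracle: exhaustive probability-weighted path enumeration.

    Recomputes transition probabilities and rewards from first principles
    (death first, switch among survivors; end-of-cycle rewards).
    """
    states = ("CAPD", "HD", "Dead")
    death = {}
    for arm in ("CAPD", "HD"):
        S = list(draw.survival(arm))
        p = [1 - S[0]] + [1 - S[t] / S[t - 1] for t in range(1, 5)]
        if settings.tail_rule == "mean_hazard":
            tail = 1 - (S[4] / S[0]) ** 0.25
        else:
            tail = p[4]
        death[arm] = p + [tail] * max(0, horizon - 5)
    switch = {"CAPD": draw["p_capd_to_hd"], "HD": draw["p_hd_to_capd"]}

    def p_trans(a, b, year):
        if a == "Dead":
            return 1.0 if b == "Dead" else 0.0
        pd = death[a][year - 1]
        if b == "Dead":
            return pd
        other = "HD" if a == "CAPD" else "CAPD"
        if b == a:
            return (1 - pd) * (1 - switch[a])
        if b == other:
            return (1 - pd) * switch[a]
        return 0.0

    annual = {}
    util = {}
    for arm in ("CAPD", "HD"):
        pc = draw.p_complication(arm)
        c = (
            draw.cost("dmc", arm)
            + draw.cost("dnmc", arm)
            + draw.cost("id", arm)
            + pc * draw.cost("cc", arm)
        )
        if settings.setup_mode == "amortized":
            c += draw.cost("setup", arm)
        annual[arm] = c
        u = draw.utility(arm)
        if settings.blend_complication_utility:
            u = (1 - pc) * u + pc * draw.utility(arm, complicated=True)
        util[arm] = u

    r_c, r_e = draw["discount_cost"], draw["discount_effect"]
    total_cost = total_ly = total_qaly = 0.0
    for path in itertools.product(states, repeat=horizon):
        full = (start,) + path
        prob = 1.0
        for t in range(horizon):
            prob *= p_trans(full[t], full[t + 1], t + 1)
        if prob == 0.0:
            continue
        cost = ly = qaly = 0.0
        if settings.setup_mode in ("entry", "entry_and_switch"):
            cost += draw.cost("setup", start)
        for t in range(1, horizon + 1):
            s = full[t]
            if s == "Dead":
                continue
            extra = 0.0
            if settings.setup_mode == "entry_and_switch" and full[t - 1] != s:
                extra = draw.cost("setup", s)
            cost += (annual[s] + extra) * (1 + r_c) ** -t
            ly += (1 + r_e) ** -t
            qaly += util[s] * (1 + r_e) ** -t
        total_cost += prob * cost
        total_ly += prob * ly
        total_qaly += prob * qaly
    return total_cost, total_ly, total_qaly


class TestOutcomeAccumulation:
    @pytest.mark.parametrize(
        "settings",
        [
            ModelSettings(horizon_years=3),
            ModelSettings(horizon_years=3, tail_rule="final_year"),
            ModelSettings(horizon_years=3, blend_complication_utility=True),
            ModelSettings(horizon_years=3, setup_mode="entry"),
            ModelSettings(horizon_years=3, setup_mode="entry_and_switch"),
        ],
        ids=["default", "final-year-tail", "blended-utility", "setup-entry", "setup-switch"],
    )
    def test_engine_matches_path_enumeration(self, params, settings):
        """Matrix engine equals exhaustive 3-step path enumeration (20 draws)."""
        rng = np.random.default_rng(TEST_SEED)
        for i in range(20):
            draw = sample_draw(params, rng, index=i)
            for start in ("CAPD", "HD"):
                got = run_arm(draw, start, settings)
                cost, ly, qaly = enumerate_paths_outcomes(
                    draw, start, settings.horizon_years, settings
                )
                assert got.total_cost_discounted == pytest.approx(cost, rel=1e-9)
                assert got.total_ly_discounted == pytest.approx(ly, rel=1e-9)
                assert got.total_qaly_discounted == pytest.approx(qaly, rel=1e-9)

    def test_single_cycle_life_years(self, base_draw):
        """One CAPD year at base means leaves 0.8 of the cohort alive."""
        trace = run_cohort(base_draw, "CAPD", horizon=1)
        out = accumulate_outcomes(trace, base_draw, ModelSettings(horizon_years=1))
        assert out.total_ly_undiscounted == pytest.approx(0.8, abs=1e-12)

    def test_zero_rewards_give_zero_totals(self, base_draw):
        values = dict(base_draw.values)
        for n in list(values):
            if n.startswith(("u_", "dmc", "dnmc", "id_", "cc_", "setup")):
                values[n] = 0.0
        draw = type(base_draw)(values=values)
        out = run_arm(draw, "CAPD", ModelSettings(horizon_years=10))
        assert out.total_cost_discounted == 0.0
        assert out.total_qaly_discounted == 0.0
        assert out.total_ly_discounted > 0.0

    def test_unit_utilities_make_qaly_equal_lyg(self, base_draw):
        values = dict(base_draw.values)
        for n in ("u_capd", "u_hd", "u_capd_com", "u_hd_com"):
            values[n] = 1.0
        draw = type(base_draw)(values=values)
        for blend in (False, True):
            out = run_arm(
                draw, "HD", ModelSettings(blend_complication_utility=blend)
            )
            assert out.total_qaly_discounted == pytest.approx(
                out.total_ly_discounted, rel=1e-12
            )

    def test_discounting_monotone_in_rate(self, base_draw):
        totals = []
        for r in (0.0, 0.03, 0.05):
            values = dict(base_draw.values, discount_cost=r, discount_effect=r)
            out = run_arm(type(base_draw)(values=values), "CAPD")
            totals.append(
                (out.total_cost_discounted, out.total_qaly_discounted,
                 out.total_ly_discounted)
            )
        for a, b in zip(totals, totals[1:]):
            assert all(x >= y for x, y in zip(a, b))

    def test_discounted_never_exceeds_undiscounted(self, base_case):
        for out in (base_case.capd, base_case.hd):
            assert out.total_cost_discounted <= out.total_cost_undiscounted
            assert out.total_qaly_discounted <= out.total_qaly_undiscounted
            assert out.total_ly_discounted <= out.total_ly_undiscounted
            assert out.total_qaly_discounted <= out.total_ly_discounted

    def test_identical_arms_differ_only_via_survival(self, base_draw):
        """With no switching and shared rewards, outcome gaps trace to survival."""
        values = dict(base_draw.values, p_capd_to_hd=0.0, p_hd_to_capd=0.0)
        for comp in ("dmc", "dnmc", "id", "cc", "setup"):
            values[f"{comp}_hd"] = values[f"{comp}_capd"]
        values["u_hd"] = values["u_capd"]
        values["u_hd_com"] = values["u_capd_com"]
        values["p_vascular"] = values["p_peritonitis"]
        draw = type(base_draw)(values=values)
        capd = run_arm(draw, "CAPD")
        hd = run_arm(draw, "HD")
        # equalizing the survival inputs too removes every difference
        values2 = dict(values)
        for y in range(1, 6):
            values2[f"surv_hd_{y}"] = values2[f"surv_capd_{y}"]
        draw2 = type(base_draw)(values=values2)
        capd2 = run_arm(draw2, "CAPD")
        hd2 = run_arm(draw2, "HD")
        assert capd2.total_cost_discounted == pytest.approx(hd2.total_cost_discounted)
        assert capd2.total_qaly_discounted == pytest.approx(hd2.total_qaly_discounted)
        assert capd.total_qaly_discounted != hd.total_qaly_discounted

    @given(year=st.integers(0, 39), bump=st.floats(0.01, 0.5))
    def test_raising_mortality_weakly_decreases_lyg(self, params, year, bump):
        """Bumping one year's death probability never gains life-years."""
        base = draw_from_means(params)
        schedule = TransitionSchedule.from_draw(base, 40)

        def discounted_ly(sched):
            trace = run_cohort(base, "CAPD", 40, schedule=sched)
            df = (1 + base["discount_effect"]) ** -np.arange(41.0)
            alive = trace.alive()
            return float((alive * df)[1:].sum())

        bumped = {arm: probs.copy() for arm, probs in schedule.death_probs.items()}
        bumped["CAPD"][year] = min(1.0, bumped["CAPD"][year] + bump)
        worse = TransitionSchedule(death_probs=bumped, p_switch=schedule.p_switch)
        assert discounted_ly(worse) <= discounted_ly(schedule) + 1e-12
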