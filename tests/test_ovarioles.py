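"""Ovariole bank: maturation-time draws, round-robin loading, portion laying."""

import numpy as np
import pytest
from scipy import stats

from ovisim.ovarioles import (
    OvarioleBankState,
    OvarioleParams,
    draw_maturation_time,
    lay_eggs,
    load_ovarioles,
)


class TestMaturationDraw:
    def test_support_is_p1_to_pq(self, rng):
        params = OvarioleParams(J=10, M=5, p=0, q=4)
        draws = {draw_maturation_time(rng, params) for _ in range(2000)}
        assert draws == {1, 2, 3, 4}

    def test_degenerate_interval_is_constant(self, rng):
        params = OvarioleParams(J=10, M=5, p=2, q=1)
        assert all(draw_maturation_time(rng, params) == 3 for _ in range(100))

    def test_uniformity_chi_square(self):
        # chi-square GOF oracle on a fixed-seed sample of 1e5 draws
        rng = np.random.default_rng(2024)
        params = OvarioleParams(J=10, M=5, p=0, q=4)
        draws = np.array([draw_maturation_time(rng, params) for _ in range(100_000)])
        counts = np.bincount(draws, minlength=5)[1:5]
        assert counts.sum() == 100_000
        _, pvalue = stats.chisquare(counts)
        assert pvalue > 0.01

    def test_invalid_spread_rejected(self, rng):
        with pytest.raises(ValueError, match="q"):
            draw_maturation_time(rng, OvarioleParams(J=1, M=1, p=0, q=0))


class TestLoading:
    def test_nothing_to_load_leaves_state_unchanged(self, rng):
        params = OvarioleParams(J=3, M=5)
        state = OvarioleBankState.empty(params)
        load_ovarioles(state, 0.0, params, rng, k=1)
        assert state.portions == [] and state.ready_buffer == 0.0

    def test_abundant_yolk_fills_ovarioles_completely(self, rng):
        # J=2, M=10, buffer 25: two full portions of 10, 5 left over
        params = OvarioleParams(J=2, M=10, p=0, q=4)
        state = OvarioleBankState.empty(params)
        load_ovarioles(state, 25.0, params, rng, k=1)
        assert [p.size for p in state.portions] == [10, 10]
        assert state.x_ov == [10, 10]
        assert state.ready_buffer == pytest.approx(5.0)

    def test_sub_egg_remainder_carries_over(self, rng):
        params = OvarioleParams(J=2, M=10)
        state = OvarioleBankState.empty(params)
        load_ovarioles(state, 0.7, params, rng, k=1)
        assert state.portions == []
        assert state.ready_buffer == pytest.approx(0.7)

    def test_due_days_within_maturation_interval(self, rng):
        params = OvarioleParams(J=5, M=4, p=2, q=3)
        state = OvarioleBankState.empty(params)
        load_ovarioles(state, 20.0, params, rng, k=7)
        assert state.portions
        assert all(7 + 3 <= p.due_day <= 7 + 5 for p in state.portions)

    def test_round_robin_pointer_persists_across_days(self, rng):
        # scarce yolk: 1 egg/day must rotate across ovarioles, not favor j=0
        params = OvarioleParams(J=3, M=5, p=0, q=1)
        state = OvarioleBankState.empty(params)
        targets = []
        for k in range(1, 4):
            before = {id(p) for p in state.portions}
            load_ovarioles(state, 1.0, params, rng, k=k)
            new = [p for p in state.portions if id(p) not in before]
            targets.append(new[0].ovariole_id)
        assert targets == [0, 1, 2]

    def test_no_aging_inputs_reach_the_bank(self, rng):
        # the bank has no time-dependence beyond due dates: the same load on
        # day 1 and day 101 produces identical sizes and due-day offsets
        params = OvarioleParams(J=4, M=5, p=0, q=4)
        rng_a, rng_b = (np.random.default_rng(7) for _ in range(2))
        early = OvarioleBankState.empty(params)
        late = OvarioleBankState.empty(params)
        load_ovarioles(early, 12.0, params, rng_a, k=1)
        load_ovarioles(late, 12.0, params, rng_b, k=101)
        assert [p.size for p in early.portions] == [p.size for p in late.portions]
        assert [p.due_day - 1 for p in early.portions] == [
            p.due_day - 101 for p in late.portions
        ]


class TestLaying:
    def test_nothing_ripe_lays_nothing(self, rng):
        params = OvarioleParams(J=2, M=10, p=3, q=1)
        state = OvarioleBankState.empty(params)
        load_ovarioles(state, 20.0, params, rng, k=1)
        state, s = lay_eggs(state, k=2)
        assert s == 0

    def test_due_portions_laid_whole_and_loads_decremented(self, rng):
        from ovisim.ovarioles import Portion

        params = OvarioleParams(J=2, M=10)
        state = OvarioleBankState.empty(params)
        state.portions = [
            Portion(ovariole_id=0, size=10, due_day=5),
            Portion(ovariole_id=1, size=7, due_day=5),
            Portion(ovariole_id=1, size=2, due_day=6),
        ]
        state.x_ov = [10, 9]
        state, s = lay_eggs(state, k=5)
        assert s == 17
        assert state.x_ov == [0, 2]
        assert [p.size for p in state.portions] == [2]

    def test_daily_count_bounded_by_bank_size(self, rng):
        params = OvarioleParams(J=4, M=3, p=0, q=1)
        state = OvarioleBankState.empty(params)
        for k in range(1, 30):
            state, s = lay_eggs(state, k)
            assert 0 <= s <= params.J * params.M
            load_ovarioles(state, 50.0, params, rng, k)

    def test_egg_conservation_loaded_equals_outstanding_plus_laid(self, rng):
        params = OvarioleParams(J=6, M=5, p=0, q=4)
        state = OvarioleBankState.empty(params)
        rng_local = np.random.default_rng(99)
        poured = 0.0
        for k in range(1, 200):
            state, _ = lay_eggs(state, k)
            y = float(rng_local.uniform(0, 8))
            poured += y
            load_ovarioles(state, y, params, rng, k)
            outstanding = sum(p.size for p in state.portions)
            assert outstanding == sum(state.x_ov)
            assert state.cum_loaded == outstanding + state.cum_laid
            assert poured == pytest.approx(
                state.cum_loaded + state.ready_buffer, rel=1e-9, abs=1e-9
            )

    def test_deterministic_maturation_gives_constant_output(self, rng):
        # q=1: after the transient, constant input a=10 comes out as a
        # constant 10/day with zero day-to-day variance
        params = OvarioleParams(J=10, M=5, p=0, q=1)
        state = OvarioleBankState.empty(params)
        counts = []
        for k in range(1, 101):
            state, s = lay_eggs(state, k)
            counts.append(s)
            load_ovarioles(state, 10.0, params, rng, k)
        assert counts[50:] == [10] * 50
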