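import numpy as np
import pytest
from hypothesis import given, strategies as st

from gistcea import (
    MarkovCohortModel,
    ParameterSet,
    build_state_space,
    build_transition_matrix,
    discount_factor,
    make_toy_chain,
    run_cohort,
)
from gistcea.model import build_rewards
from gistcea.parameters import background_mortality, derive_secondary

UAPR_LABELS = {
    "UAPR_Yr1", "UAPR_Yr2", "UAPR_Yr3+",
    "Salvage Sx following LR1 post UAPR_Yr3+",
    "1st DR", "Mets disease 1st PD", "Mets disease 2nd PD",
    "Mets disease 3rd PD", "Dead",
}
CIUP_LABELS = {
    "CIUP", "APR following LR on CIUP", "Salvage Sx following LR1 post CIUP",
    "1st DR", "Mets disease 1st PD", "Mets disease 2nd PD",
    "Mets disease 3rd PD", "Dead",
}


class TestStateSpace:
    def test_uapr_reporting_labels(self, base_params):
        space = build_state_space("UAPR", base_params)
        assert set(space.labels) == UAPR_LABELS

    def test_ciup_has_no_uapr_states(self, base_params):
        space = build_state_space("CIUP", base_params)
        assert set(space.labels) == CIUP_LABELS
        assert not any(lbl.startswith("UAPR_Yr") for lbl in space.labels)

    def test_both_arms_cover_twelve_published_states(self, base_params):
        labels = set(build_state_space("UAPR", base_params).labels)
        labels |= set(build_state_space("CIUP", base_params).labels)
        assert len(labels) == 12

    def test_single_absorbing_dead_state(self, base_params):
        for strategy in ("UAPR", "CIUP"):
            space = build_state_space(strategy, base_params)
            absorbing = [s for s in space.states if s.absorbing]
            assert len(absorbing) == 1 and absorbing[0].label == "Dead"

    def test_unknown_strategy_rejected(self, base_params):
        with pytest.raises(ValueError, match="strategy"):
            build_state_space("WATCHFUL_WAITING", base_params)


class TestTransitionMatrix:
    @pytest.mark.parametrize("strategy", ["UAPR", "CIUP"])
    @pytest.mark.parametrize("cycle", [0, 7, 19])
    def test_rows_stochastic(self, strategy, cycle, base_params, life_table):
        M = build_transition_matrix(strategy, base_params, cycle, life_table)
        assert np.all(M >= 0)
        assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)

    def test_rows_stochastic_at_all_range_endpoints(self, base_params,
                                                    life_table):
        for name, (lo, hi, _fam) in base_params.ranges.items():
            for v in (lo, hi):
                ps = base_params.with_value(name, v)
                for strategy in ("UAPR", "CIUP"):
                    M = build_transition_matrix(strategy, ps, 0, life_table)
                    assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)

    def test_dead_row_is_identity(self, base_params, life_table):
        space = build_state_space("UAPR", base_params)
        M = build_transition_matrix("UAPR", base_params, 3, life_table,
                                    space=space)
        i = space.dead_index
        expected = np.zeros(len(space))
        expected[i] = 1.0
        assert np.array_equal(M[i], expected)

    def test_end_stage_death_uses_max_rule(self, base_params, life_table):
        """Disease mortality after regorafenib failure (0.405) dwarfs
        background mortality at all modelled ages."""
        space = build_state_space("UAPR", base_params)
        for cycle in (0, 19):
            q = background_mortality(life_table,
                                     base_params.start_age + cycle)
            assert q < 0.405
            M = build_transition_matrix("UAPR", base_params, cycle,
                                        life_table, space=space)
            assert M[space.index("mets_pd3"), space.dead_index] == pytest.approx(
                max(0.405, q))

    def test_surveillance_row_splits_recurrence(self, base_params, life_table):
        space = build_state_space("UAPR", base_params)
        M = build_transition_matrix("UAPR", base_params, 0, life_table,
                                    space=space)
        q = background_mortality(life_table, 60)
        i = space.index("uapr_surveillance")
        d = derive_secondary(base_params)
        assert M[i, space.index("salvage_uapr_yr1")] == pytest.approx(
            d["p_local_post_apr"] * (1 - q))
        assert M[i, space.index("first_dr")] == pytest.approx(
            d["p_distant_post_apr"] * (1 - q))
        assert M[i, i] == pytest.approx(
            (1 - base_params.p_rec_post_apr) * (1 - q))

    def test_no_tunnel_self_loops(self, base_params, life_table):
        for strategy in ("UAPR", "CIUP"):
            space = build_state_space(strategy, base_params)
            M = build_transition_matrix(strategy, base_params, 0, life_table,
                                        space=space)
            for i, s in enumerate(space.states):
                if s.tunnel:
                    assert M[i, i] == 0.0


class TestDiscounting:
    def test_cycle_zero_undiscounted(self):
        assert discount_factor(0, 0.03) == 1.0

    def test_one_cycle_at_three_percent(self):
        assert discount_factor(1, 0.03) == pytest.approx(0.970874, abs=1e-6)

    def test_zero_rate_is_identity(self):
        assert all(discount_factor(t, 0.0) == 1.0 for t in range(10))

    def test_rate_below_minus_one_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -1.5)


def _closed_form_totals(M, x0, utility, cost, horizon, rate):
    """Independent oracle: sum of matrix powers times reward vectors,
    start-of-cycle crediting."""
    qaly = cost_total = 0.0
    x = x0.copy()
    for t in range(horizon):
        df = (1 + rate) ** (-t)
        qaly += df * float(x @ utility)
        cost_total += df * float(x @ cost)
        x = x @ M
    return cost_total, qaly


class TestCohortEngineOracles:
    def test_two_state_geometric_chain(self):
        """Alive->Alive 0.5, utility 1, horizon 2, no discount: 1 + 0.5."""
        space, fn, rewards = make_toy_chain(
            [[0.5, 0.5], [0.0, 1.0]], [1.0, 0.0], [0.0, 0.0])
        out = MarkovCohortModel(space, fn, rewards, horizon=2,
                                discount_rate=0.0, entry_state="s0").run()
        assert out.qalys == pytest.approx(1.5)

    def test_stationary_cohort_accrues_u_times_h(self):
        space, fn, rewards = make_toy_chain(
            [[1.0, 0.0], [0.0, 1.0]], [0.0, 0.7], [0.0, 0.0],
            labels=["Dead", "Alive"])
        out = MarkovCohortModel(space, fn, rewards, horizon=12,
                                discount_rate=0.0, entry_state="s1").run()
        assert out.qalys == pytest.approx(0.7 * 12)

    def test_three_state_chain_matches_matrix_power_oracle(self):
        M = np.array([[0.6, 0.3, 0.1],
                      [0.0, 0.5, 0.5],
                      [0.0, 0.0, 1.0]])
        utility = np.array([0.9, 0.4, 0.0])
        cost = np.array([100.0, 250.0, 0.0])
        space, fn, rewards = make_toy_chain(M, utility, cost)
        out = MarkovCohortModel(space, fn, rewards, horizon=15,
                                discount_rate=0.03, entry_state="s0").run()
        x0 = np.array([1.0, 0.0, 0.0])
        exp_cost, exp_qaly = _closed_form_totals(M, x0, utility, cost, 15, 0.03)
        assert out.qalys == pytest.approx(exp_qaly, abs=1e-9)
        assert out.cost == pytest.approx(exp_cost, abs=1e-9)

    def test_half_cycle_correction_averages_boundaries(self):
        """Trapezoid totals equal the mean of start- and end-of-cycle sums."""
        M = np.array([[0.8, 0.2], [0.0, 1.0]])
        utility = np.array([1.0, 0.0])
        space, fn, rewards = make_toy_chain(M, utility, [0.0, 0.0])
        start = MarkovCohortModel(space, fn, rewards, horizon=5,
                                  discount_rate=0.0, entry_state="s0").run()
        hcc = MarkovCohortModel(space, fn, rewards, horizon=5,
                                discount_rate=0.0, entry_state="s0",
                                half_cycle_correction=True).run()
        # end-of-cycle sum = start-of-cycle shifted by one transition
        occ = start.trace.occupancy
        end_sum = float((occ[1:] @ utility).sum())
        assert hcc.qalys == pytest.approx(0.5 * (start.qalys + end_sum))


class TestStrategyRuns:
    @pytest.mark.parametrize("strategy", ["UAPR", "CIUP"])
    def test_trace_conserves_mass_and_absorbs(self, strategy, base_outcomes):
        out = base_outcomes[strategy]
        occ = out.trace.occupancy
        assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-10)
        dead = occ[:, out.space.dead_index]
        assert np.all(np.diff(dead) >= 0)

    @pytest.mark.parametrize("strategy", ["UAPR", "CIUP"])
    def test_mass_conserved_at_all_range_endpoints(self, strategy,
                                                   base_params, life_table):
        for name, (lo, hi, _fam) in base_params.ranges.items():
            for v in (lo, hi):
                out = run_cohort(strategy, base_params.with_value(name, v),
                                 life_table)
                assert np.allclose(out.trace.occupancy.sum(axis=1), 1.0,
                                   atol=1e-10)

    def test_discounting_strictly_reduces_totals(self, base_params,
                                                 life_table, base_outcomes):
        undiscounted = run_cohort("UAPR",
                                  base_params.with_value("discount_rate", 0.0),
                                  life_table)
        out = base_outcomes["UAPR"]
        assert out.qalys < undiscounted.qalys
        assert out.cost < undiscounted.cost
        assert out.trace.total_qalys <= float(out.trace.qaly_undisc.sum())

    def test_zero_utilities_give_zero_qalys(self, base_params, life_table):
        ps = base_params.with_values(u_post_apr=0.0, u_ciup=0.0,
                                     u_recurrence=0.0, u_met_pd=0.0)
        for strategy in ("UAPR", "CIUP"):
            assert run_cohort(strategy, ps, life_table).qalys == 0.0

    def test_base_case_dominance_direction(self, base_outcomes):
        uapr, ciup = base_outcomes["UAPR"], base_outcomes["CIUP"]
        assert uapr.qalys > ciup.qalys
        assert uapr.cost < ciup.cost

    def test_deterministic_bit_identical_reruns(self, base_params, life_table):
        a = run_cohort("CIUP", base_params, life_table)
        b = run_cohort("CIUP", base_params, life_table)
        assert a.cost == b.cost and a.qalys == b.qalys
        assert np.array_equal(a.trace.occupancy, b.trace.occupancy)

    @pytest.mark.parametrize("name", ["u_post_apr", "u_ciup", "u_recurrence",
                                      "u_met_pd"])
    def test_qalys_monotone_in_utilities(self, name, base_params, life_table):
        lo, hi, _ = base_params.ranges[name]
        values = [run_cohort(s, base_params.with_value(name, v), life_table).qalys
                  for v in (lo, (lo + hi) / 2, hi)
                  for s in ("UAPR", "CIUP")]
        uapr, ciup = values[0::2], values[1::2]
        assert uapr == sorted(uapr)
        assert ciup == sorted(ciup)

    @pytest.mark.parametrize("name", ["c_imatinib400", "c_sunitinib",
                                      "c_regorafenib", "c_apr", "c_salvage",
                                      "c_followup"])
    def test_cost_monotone_in_costs(self, name, base_params, life_table):
        lo, hi, _ = base_params.ranges[name]
        for strategy in ("UAPR", "CIUP"):
            costs = [run_cohort(strategy, base_params.with_value(name, v),
                                life_table).cost
                     for v in (lo, (lo + hi) / 2, hi)]
            assert costs == sorted(costs)

    def test_horizon_bounds_qalys(self, base_params, life_table):
        ps = base_params.with_value("horizon", 1)
        for strategy in ("UAPR", "CIUP"):
            out = run_cohort(strategy, ps, life_table)
            assert 0.0 <= out.qalys <= 1.0

    def test_trace_export_has_label_columns(self, base_outcomes):
        out = base_outcomes["UAPR"]
        df = out.trace.to_frame(out.space)
        assert "UAPR_Yr3+" in df.columns and "Dead" in df.columns
        assert len(df) == 21
        # occupancy columns still sum to 1 after label aggregation
        occ_cols = [c for c in df.columns
                    if c not in ("cycle", "cost_discounted", "qaly_discounted",
                                 "cost_undiscounted", "qaly_undiscounted")]
        assert np.allclose(df[occ_cols].sum(axis=1), 1.0, atol=1e-10)
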