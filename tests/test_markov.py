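"""Cohort propagation, half-cycle-corrected accrual, annualization."""

import numpy as np
import pytest

from renal_cea.markov import (
    CohortTrace,
    accumulate_outcomes,
    annualize,
    run_cohort,
    run_scenario,
)
from renal_cea.parameters import (
    HealthState,
    ModelConfig,
    SCENARIO_T,
    STATE_INDEX,
    assemble_matrix,
)

from conftest import FlatMortality, random_valid_inputs, toy_costs, toy_utilities

S = HealthState
TX = STATE_INDEX[S.TX]


def brute_force_trace(config, scenario, base, mortality):
    """Independent oracle: explicit per-cycle vector-matrix multiplication."""
    occ = [config.initial_occupancy_vector()]
    for t in range(config.horizon):
        M = assemble_matrix(base, scenario, mortality, config.start_age + t)
        occ.append(occ[-1] @ M)
    return np.array(occ)


def closed_form_hcc_life_years(q: float, r: float, horizon: int) -> float:
    """Analytic half-cycle-corrected discounted life-years of a 2-state
    constant-hazard model with one starting patient: geometric series
    sum_t v^t s^(t-1) (1+s)/2 with s = 1-q, v = 1/(1+r)."""
    s, v = 1.0 - q, 1.0 / (1.0 + r)
    if s * v == 1.0:
        series = float(horizon)
    else:
        series = (1.0 - (s * v) ** horizon) / (1.0 - s * v)
    return 0.5 * (1.0 + s) * v * series


class TestRunCohort:
    def test_identity_matrices_freeze_occupancy(self, no_exit_base):
        config = ModelConfig(cohort_size=1000.0, horizon=45,
                             initial_occupancy={s: (1.0 if s is S.TX else 0.0)
                                                for s in S})
        trace = run_cohort(config, SCENARIO_T, no_exit_base, FlatMortality(0.0))
        assert np.all(trace.occupancy[:, TX] == 1000.0)

    def test_two_state_toy_halving(self, two_state_config, no_exit_base):
        trace = run_cohort(two_state_config, SCENARIO_T, no_exit_base,
                           FlatMortality(0.5))
        np.testing.assert_allclose(trace.occupancy[:, TX], [1.0, 0.5, 0.25])

    def test_matches_brute_force_on_random_configs(self, rng):
        for _ in range(100):
            inputs = random_valid_inputs(rng)
            mort = inputs.mortality()
            trace = run_cohort(inputs.config, SCENARIO_T, inputs.transitions, mort)
            expected = brute_force_trace(inputs.config, SCENARIO_T,
                                         inputs.transitions, mort)
            np.testing.assert_allclose(trace.occupancy, expected, atol=1e-12)

    def test_conservation_and_absorption(self, rng):
        for _ in range(50):
            inputs = random_valid_inputs(rng)
            trace = run_cohort(inputs.config, SCENARIO_T, inputs.transitions,
                               inputs.mortality())
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1000.0,
                                       atol=1e-9)
            d = trace.occupancy[:, STATE_INDEX[S.D]]
            assert np.all(np.diff(d) >= -1e-9)
            assert np.all(trace.entrants >= 0)

    def test_entrant_bookkeeping(self, packaged):
        trace = run_cohort(packaged.config, SCENARIO_T, packaged.transitions,
                           packaged.mortality())
        # initial cohort counts as entrants at t = 0
        np.testing.assert_array_equal(trace.entrants[0],
                                      trace.occupancy[0])
        # cycle-1 inflow into HD is the timely-routed graft-failure mass
        assert trace.entrants[1][STATE_INDEX[S.HD]] == \
            pytest.approx(1000.0 * 0.0350)

    def test_infeasible_age_reports_cycle(self, two_state_config):
        from renal_cea.errors import InfeasibleModelError
        from renal_cea.parameters import BaseTransitions

        class ExplodingMortality(FlatMortality):
            def q_std(self, age):
                return 0.9 if age >= 41 else 0.0

        base = BaseTransitions(hd_to_pd=0.0, hd_to_tx=0.0, tx_exit_to_hd=0.2,
                               tx_exit_to_pd=0.0)
        with pytest.raises(InfeasibleModelError) as err:
            run_cohort(two_state_config, SCENARIO_T, base,
                       ExplodingMortality(0.0))
        assert err.value.cycle == 2


class TestAccumulateOutcomes:
    def test_two_state_toy_life_years(self, two_state_config, no_exit_base):
        trace = run_cohort(two_state_config, SCENARIO_T, no_exit_base,
                           FlatMortality(0.5))
        out = accumulate_outcomes(trace, toy_costs(), toy_utilities(), 0.0)
        assert out.total_qaly == pytest.approx(1.125, abs=1e-15)
        assert out.total_life_years == pytest.approx(1.125, abs=1e-15)

    @pytest.mark.parametrize("q", [0.1, 0.5, 0.9])
    @pytest.mark.parametrize("r", [0.0, 0.03, 0.05])
    def test_closed_form_geometric_series(self, q, r, no_exit_base):
        config = ModelConfig(cohort_size=1.0, horizon=30, discount_rate=r,
                             initial_occupancy={s: (1.0 if s is S.TX else 0.0)
                                                for s in S})
        trace = run_cohort(config, SCENARIO_T, no_exit_base, FlatMortality(q))
        out = accumulate_outcomes(trace, toy_costs(), toy_utilities(), r)
        assert out.total_qaly == pytest.approx(
            closed_form_hcc_life_years(q, r, 30), abs=1e-10)

    def test_zero_utilities_zero_qaly(self, two_state_config, no_exit_base):
        trace = run_cohort(two_state_config, SCENARIO_T, no_exit_base,
                           FlatMortality(0.5))
        out = accumulate_outcomes(trace, toy_costs(), toy_utilities(0.0), 0.03)
        assert out.total_qaly == 0.0
        assert out.total_life_years > 0

    def test_single_cycle_prevalence_cost_discounts_one_period(
            self, no_exit_base):
        config = ModelConfig(cohort_size=1.0, horizon=1, discount_rate=0.03,
                             initial_occupancy={s: (1.0 if s is S.HD else 0.0)
                                                for s in S})
        costs = toy_costs()
        costs.prevalence[S.HD] = 100.0
        costs.first_year[S.HD] = 0.0
        trace = run_cohort(config, SCENARIO_T, no_exit_base, FlatMortality(0.0))
        out = accumulate_outcomes(trace, costs, toy_utilities(), 0.03)
        assert out.total_cost == pytest.approx(100.0 / 1.03, rel=1e-12)

    def test_initial_cohort_first_year_cost_undiscounted(self, no_exit_base):
        config = ModelConfig(cohort_size=1.0, horizon=1, discount_rate=0.5,
                             initial_occupancy={s: (1.0 if s is S.HD else 0.0)
                                                for s in S})
        costs = toy_costs()  # first_year[HD] = 1, prevalence all 0
        trace = run_cohort(config, SCENARIO_T, no_exit_base, FlatMortality(0.0))
        out = accumulate_outcomes(trace, costs, toy_utilities(), 0.5)
        assert out.total_cost == pytest.approx(1.0)

    def test_discounted_below_undiscounted(self, packaged):
        _, summary = run_scenario(packaged, SCENARIO_T)
        assert summary.total_cost <= summary.total_cost_undiscounted
        assert summary.total_qaly <= summary.total_qaly_undiscounted

    def test_negative_trace_rejected(self, two_state_config):
        bad = CohortTrace(occupancy=np.full((3, 6), -1.0),
                          entrants=np.zeros((3, 6)), start_age=40.0)
        with pytest.raises(ValueError):
            accumulate_outcomes(bad, toy_costs(), toy_utilities(), 0.0)


class TestAnnualize:
    def test_direct_division(self):
        from renal_cea.markov import OutcomeSummary

        config = ModelConfig(cohort_size=1000.0, horizon=45)
        summary = OutcomeSummary(total_cost=90000.0, total_qaly=0.0,
                                 total_cost_undiscounted=90000.0,
                                 total_qaly_undiscounted=0.0,
                                 total_life_years=0.0, discount_rate=0.0)
        out = annualize(summary, config)
        assert out.per_patient_annual_cost == pytest.approx(2.0)
        assert out.per_patient_annual_qaly == 0.0

    def test_invariant_to_cohort_size(self, packaged):
        small = packaged.copy()
        small.config.cohort_size = 1.0
        _, a = run_scenario(packaged, SCENARIO_T)
        _, b = run_scenario(small, SCENARIO_T)
        assert a.per_patient_annual_cost == pytest.approx(
            b.per_patient_annual_cost, abs=1e-9)
        assert a.per_patient_annual_qaly == pytest.approx(
            b.per_patient_annual_qaly, abs=1e-12)

    def test_qaly_bounded_by_life_years(self, packaged):
        _, s = run_scenario(packaged, SCENARIO_T, discount_rate=0.0)
        assert s.total_qaly <= s.total_life_years
        assert s.total_life_years <= 1000.0 * 45
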