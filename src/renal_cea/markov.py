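"""Deterministic Markov cohort simulation and half-cycle-corrected accrual.

The cohort is a vector of expected patient counts over the six states,
propagated through an age-specific transition matrix once per one-year
cycle.  Outcomes accrue with the standard half-cycle correction:
prevalence costs and QALYs of cycle ``t`` (the year between boundaries
``t-1`` and ``t``) are evaluated on the trapezoidal average of the two
boundary occupancies, so transitions are effectively treated as mid-cycle
events.  First-year (transition) costs are one-off event costs attached in
full to the patients entering a state during the cycle — they are add-ons
(access surgery, transplant surgery), not year-long flows, so no trapezoid
applies.  Cycle-``t`` accrual is discounted by ``(1+r)^-t``; the initial
cohort's entry costs at ``t = 0`` are undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InfeasibleModelError
from .parameters import (
    ALIVE_STATES,
    BaseTransitions,
    CostSet,
    HealthState,
    ModelConfig,
    N_STATES,
    STATE_INDEX,
    STATES,
    ScenarioSpec,
    UtilitySet,
    assemble_matrix,
)

_D = STATE_INDEX[HealthState.D]


@dataclass
class CohortTrace:
    """State occupancy at cycle boundaries and per-cycle entrant flows.

    ``occupancy[t, s]`` is the expected count in state ``s`` at boundary
    ``t`` (t = 0..horizon); ``entrants[t, s]`` the expected inflow into
    ``s`` from other states during cycle ``t``, with the initial cohort
    counted as entrants at ``t = 0``.
    """

    occupancy: np.ndarray
    entrants: np.ndarray
    start_age: float

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def cohort_size(self) -> float:
        return float(self.occupancy[0].sum())

    def validate(self) -> None:
        if self.occupancy.min() < -1e-9 or self.entrants.min() < -1e-9:
            raise ValueError("negative occupancy or entrants in trace")
        totals = self.occupancy.sum(axis=1)
        if not np.allclose(totals, totals[0], atol=1e-9 * max(totals[0], 1.0)):
            raise ValueError("cohort size is not conserved across boundaries")
        if np.any(np.diff(self.occupancy[:, _D]) < -1e-9):
            raise ValueError("dead-state occupancy decreased")

    def deaths_per_cycle(self) -> np.ndarray:
        """Incremental deaths during cycles 1..horizon."""
        return np.diff(self.occupancy[:, _D])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.occupancy, columns=[s.value for s in STATES]
                            ).rename_axis("boundary")


@dataclass
class OutcomeSummary:
    """Total and per-patient-annual cost (€) and QALY for one scenario run."""

    total_cost: float
    total_qaly: float
    total_cost_undiscounted: float
    total_qaly_undiscounted: float
    total_life_years: float
    discount_rate: float
    per_patient_annual_cost: float | None = None
    per_patient_annual_qaly: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def run_cohort(config: ModelConfig, scenario: ScenarioSpec,
               base: BaseTransitions, mortality, *,
               on_infeasible: str = "error") -> CohortTrace:
    """Propagate the cohort through the age-specific transition matrices.

    The matrix of cycle ``t`` (boundaries ``t-1`` → ``t``) is assembled at
    age ``start_age + t - 1``, the cohort's age while the cycle elapses.
    """
    H = config.horizon
    occ = np.zeros((H + 1, N_STATES))
    ent = np.zeros((H + 1, N_STATES))
    occ[0] = config.initial_occupancy_vector()
    ent[0] = occ[0]
    for t in range(1, H + 1):
        age = config.start_age + (t - 1) * config.cycle_length
        try:
            M = assemble_matrix(base, scenario, mortality, age,
                                on_infeasible=on_infeasible)
        except InfeasibleModelError as err:
            raise InfeasibleModelError(err.state, err.age, err.residual,
                                       cycle=t) from None
        occ[t] = occ[t - 1] @ M
        inflow = occ[t - 1][:, None] * M
        np.fill_diagonal(inflow, 0.0)
        ent[t] = inflow.sum(axis=0)
    trace = CohortTrace(occupancy=occ, entrants=ent, start_age=config.start_age)
    trace.validate()
    return trace


def accumulate_outcomes(trace: CohortTrace, costs: CostSet,
                        utilities: UtilitySet, discount_rate: float
                        ) -> OutcomeSummary:
    """Half-cycle-corrected, discounted cost and QALY totals for a trace."""
    if discount_rate < 0:
        raise ValueError("discount_rate must be >= 0")
    trace.validate()
    H = trace.horizon
    v = (1.0 + discount_rate) ** -np.arange(H + 1)

    trapz = 0.5 * (trace.occupancy[:-1] + trace.occupancy[1:])  # cycle t row t-1
    prev_cost = trapz @ costs.prevalence_vector()
    qaly = trapz @ utilities.vector()
    fy_cost = trace.entrants @ costs.first_year_vector()

    alive = [STATE_INDEX[s] for s in ALIVE_STATES]
    return OutcomeSummary(
        total_cost=float(fy_cost @ v + prev_cost @ v[1:]),
        total_qaly=float(qaly @ v[1:]),
        total_cost_undiscounted=float(fy_cost.sum() + prev_cost.sum()),
        total_qaly_undiscounted=float(qaly.sum()),
        total_life_years=float(trapz[:, alive].sum()),
        discount_rate=discount_rate,
    )


def annualize(summary: OutcomeSummary, config: ModelConfig) -> OutcomeSummary:
    """Attach per-patient annual figures: total / (cohort_size × horizon)."""
    if config.horizon == 0:
        raise ZeroDivisionError("cannot annualize over a zero-cycle horizon")
    denom = config.cohort_size * config.horizon
    return replace(summary,
                   per_patient_annual_cost=summary.total_cost / denom,
                   per_patient_annual_qaly=summary.total_qaly / denom)


def run_scenario(inputs, scenario: ScenarioSpec, *,
                 discount_rate: float | None = None,
                 base: BaseTransitions | None = None,
                 mortality=None,
                 on_infeasible: str = "error"
                 ) -> tuple[CohortTrace, OutcomeSummary]:
    """Convenience pipeline: trace, accrue, annualize for one scenario.

    ``discount_rate``, ``base`` and ``mortality`` override the configured
    inputs; the sensitivity and PSA layers use these hooks.
    """
    base = base if base is not None else inputs.transitions
    mortality = mortality if mortality is not None else inputs.mortality()
    r = inputs.config.discount_rate if discount_rate is None else discount_rate
    trace = run_cohort(inputs.config, scenario, base, mortality,
                       on_infeasible=on_infeasible)
    summary = annualize(accumulate_outcomes(trace, inputs.costs,
                                            inputs.utilities, r), inputs.config)
    return trace, summary
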