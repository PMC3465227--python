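"""Deterministic sensitivity analyses.

One-way (tornado) analysis perturbs each scalar parameter by ±10 % with
everything else held at base, recomputes the ICER of timely versus late
referral and ranks parameters by the larger absolute ICER change.
Alternative-discount-rate runs and a sweep over the late-referral
proportion complete the deterministic robustness checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import IncrementalResult, incremental
from .errors import InfeasibleModelError
from .markov import run_scenario
from .parameters import ModelInputs, SCENARIO_L, SCENARIO_T, ScenarioSpec
from .paramspace import list_scalar_parameters


def deterministic_icer(inputs: ModelInputs,
                       comparator: ScenarioSpec = SCENARIO_T,
                       reference: ScenarioSpec = SCENARIO_L,
                       discount_rate: float | None = None) -> IncrementalResult:
    """Base-case incremental comparison of the two referral scenarios."""
    _, ref = run_scenario(inputs, reference, discount_rate=discount_rate)
    _, comp = run_scenario(inputs, comparator, discount_rate=discount_rate)
    return incremental(ref, comp, wtpt=inputs.config.wtpt)


@dataclass
class TornadoEntry:
    """ICER under the ±delta perturbation of a single parameter."""

    parameter_id: str
    base_value: float
    icer_low: float
    icer_high: float
    max_abs_pct_change: float
    infeasible: bool = False


def univariate_tornado(inputs: ModelInputs, delta: float = 0.10,
                       exclude: tuple[str, ...] = ()) -> list[TornadoEntry]:
    """One-way sensitivity of the ICER to ±``delta`` parameter changes.

    Each scalar parameter is scaled by ``1 ± delta`` in turn (utilities
    capped at 1; transition rows rebalanced through the residual-stay
    rule), the deterministic pipeline is re-run and the ICER recorded.
    Entries are sorted by the larger absolute percent ICER change.  A
    perturbation that makes the model infeasible flags the entry instead
    of aborting the analysis.
    """
    base = deterministic_icer(inputs)
    if base.icer is None:
        raise ValueError("base ICER undefined: scenarios have equal effectiveness")
    entries = []
    for param in list_scalar_parameters(inputs):
        if param.name in exclude:
            continue
        base_value = param.get(inputs)
        icers: list[float] = []
        infeasible = False
        for factor in (1.0 - delta, 1.0 + delta):
            perturbed = inputs.copy()
            value = base_value * factor
            if param.kind in ("probability", "utility"):
                value = min(value, 1.0)
            param.set(perturbed, value)
            try:
                res = deterministic_icer(perturbed)
                icers.append(np.nan if res.icer is None else res.icer)
            except InfeasibleModelError:
                icers.append(np.nan)
                infeasible = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            changes = [abs(i - base.icer) / abs(base.icer) * 100.0 for i in icers]
        max_change = float(np.nanmax(changes)) if not all(np.isnan(changes)) else np.nan
        entries.append(TornadoEntry(
            parameter_id=param.name, base_value=base_value,
            icer_low=icers[0], icer_high=icers[1],
            max_abs_pct_change=0.0 if np.isnan(max_change) else max_change,
            infeasible=infeasible))
    entries.sort(key=lambda e: e.max_abs_pct_change, reverse=True)
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in entries])


def discount_rate_scenarios(inputs: ModelInputs,
                            rates=(0.0, 0.03, 0.05)) -> dict[float, IncrementalResult]:
    """Full deterministic comparison at each (deduplicated) discount rate."""
    out: dict[float, IncrementalResult] = {}
    for rate in sorted(set(float(r) for r in rates)):
        if rate < 0:
            raise ValueError("discount rates must be >= 0")
        out[rate] = deterministic_icer(inputs, discount_rate=rate)
    return out


def sweep_late_referral_proportion(inputs: ModelInputs,
                                   p_grid) -> pd.DataFrame:
    """ICER of timely referral against a mixed current situation.

    For each late fraction ``p`` the current situation routes a fraction
    ``p`` of graft failures late; the comparator is always full timely
    referral (p = 0).  ``p = 0`` in the grid would compare timely with
    itself (ΔE = 0, ICER undefined) and is excluded with a warning;
    ``p = 1`` reproduces the baseline all-late versus all-timely
    comparison exactly.
    """
    _, timely = run_scenario(inputs, SCENARIO_T)
    rows = []
    for p in np.asarray(p_grid, dtype=float):
        if p == 0.0:
            warnings.warn("late fraction p = 0 excluded from sweep: "
                          "ICER undefined against the timely scenario")
            continue
        scenario = (SCENARIO_L if p == 1.0
                    else ScenarioSpec(f"p={p:g}", float(p)))
        _, mixed = run_scenario(inputs, scenario)
        res = incremental(mixed, timely, wtpt=inputs.config.wtpt)
        rows.append({"late_fraction": float(p),
                     "delta_cost": res.delta_cost,
                     "delta_qaly": res.delta_qaly,
                     "icer": res.icer,
                     "category": res.category.value})
    return pd.DataFrame(rows)
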