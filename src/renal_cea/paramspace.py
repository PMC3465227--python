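"""Registry of the scalar model parameters that sensitivity analyses vary.

Every tunable scalar — transition probabilities (including the mortality
curve's anchor points), first-year and prevalence costs, utilities and the
discount rate — is exposed as a named getter/setter pair over a
:class:`~renal_cea.parameters.ModelInputs` bundle, so the one-way tornado
and the probabilistic sensitivity analysis perturb exactly the same set.

Structural constants are never varied: cohort size, starting age, horizon,
the willingness-to-pay threshold and the uplift percentages (the uplifts
enter through the sampled late-referral cost totals).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .parameters import ALIVE_STATES, HealthState, ModelInputs

#: Parameter kinds; each maps to one distribution family in the PSA.
KINDS = ("probability", "cost", "utility", "rate")


@dataclass(frozen=True)
class ScalarParam:
    """One scalar model parameter with in-place access on a ModelInputs."""

    name: str
    kind: str
    get: Callable[[ModelInputs], float]
    set: Callable[[ModelInputs, float], None]


def _attr_param(name: str, kind: str, obj: str, attr: str) -> ScalarParam:
    return ScalarParam(
        name=name, kind=kind,
        get=lambda mi: getattr(getattr(mi, obj), attr),
        set=lambda mi, v: setattr(getattr(mi, obj), attr, v))


def _dict_param(name: str, kind: str, table: str, state: HealthState) -> ScalarParam:
    def get(mi: ModelInputs) -> float:
        owner = mi.costs if table != "utility" else mi.utilities
        return getattr(owner, table if table != "utility" else "utility")[state]

    def set_(mi: ModelInputs, v: float) -> None:
        owner = mi.costs if table != "utility" else mi.utilities
        getattr(owner, table if table != "utility" else "utility")[state] = v

    return ScalarParam(name=name, kind=kind, get=get, set=set_)


def _lr_death_param() -> ScalarParam:
    # sampled on the death-probability scale; stored as its survival complement
    return ScalarParam(
        name="mortality.lr_first_year_death", kind="probability",
        get=lambda mi: 1.0 - mi.mortality_params.lr_first_year_survival,
        set=lambda mi, v: setattr(mi.mortality_params, "lr_first_year_survival",
                                  1.0 - v))


def list_scalar_parameters(inputs: ModelInputs) -> list[ScalarParam]:
    """All tunable scalars of a configuration, in a stable order."""
    params: list[ScalarParam] = [
        _attr_param("transitions.HD.PD", "probability", "transitions", "hd_to_pd"),
        _attr_param("transitions.HD.Tx", "probability", "transitions", "hd_to_tx"),
        _attr_param("transitions.PD.HD", "probability", "transitions", "pd_to_hd"),
        _attr_param("transitions.PD.Tx", "probability", "transitions", "pd_to_tx"),
        _attr_param("transitions.Tx.exit_to_HD", "probability",
                    "transitions", "tx_exit_to_hd"),
        _attr_param("transitions.Tx.exit_to_PD", "probability",
                    "transitions", "tx_exit_to_pd"),
        _attr_param("mortality.q0", "probability", "mortality_params", "q0"),
        _lr_death_param(),
    ]
    for s in ALIVE_STATES:
        params.append(_dict_param(f"cost.first_year.{s.value}", "cost",
                                  "first_year", s))
    for s in ALIVE_STATES:
        params.append(_dict_param(f"cost.prevalence.{s.value}", "cost",
                                  "prevalence", s))
    for s in ALIVE_STATES:
        params.append(_dict_param(f"utility.{s.value}", "utility", "utility", s))
    params.append(ScalarParam(
        name="discount_rate", kind="rate",
        get=lambda mi: mi.config.discount_rate,
        set=lambda mi, v: setattr(mi.config, "discount_rate", v)))
    del inputs  # the registry is configuration-independent
    return params
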