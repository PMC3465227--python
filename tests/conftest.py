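"""Shared fixtures: packaged defaults, toy models, random valid configs."""

from __future__ import annotations

import numpy as np
import pytest

from renal_cea.parameters import (
    BaseTransitions,
    CostSet,
    HealthState,
    ModelConfig,
    ModelInputs,
    MortalityParams,
    UpliftSpec,
    UtilitySet,
)
from renal_cea.synthetic_data import default_inputs, generate_mortality_schedule

S = HealthState


class FlatMortality:
    """Age-independent mortality stub for hand-checkable toy models."""

    def __init__(self, q_std: float, q_lr: float | None = None):
        self._q_std = q_std
        self._q_lr = q_std if q_lr is None else q_lr

    def q_std(self, age):
        return self._q_std

    def q_lr(self, age):
        return self._q_lr


def toy_costs() -> CostSet:
    """Minimal valid cost set (late first-year must exceed timely)."""
    return CostSet(
        first_year={S.HD: 1.0, S.PD: 1.0, S.TX: 0.0, S.LRHD: 2.0,
                    S.LRPD: 2.0, S.D: 0.0},
        prevalence={s: 0.0 for s in S})


def toy_utilities(alive: float = 1.0) -> UtilitySet:
    return UtilitySet(utility={s: (0.0 if s is S.D else alive) for s in S})


@pytest.fixture(scope="session")
def packaged() -> ModelInputs:
    """The packaged, study-calibrated default configuration."""
    return default_inputs()


@pytest.fixture
def two_state_config() -> ModelConfig:
    """One patient starting in Tx with no exits: effectively {alive, dead}."""
    return ModelConfig(cohort_size=1.0, start_age=40.0, horizon=2,
                       discount_rate=0.0,
                       initial_occupancy={s: (1.0 if s is S.TX else 0.0)
                                          for s in S})


@pytest.fixture
def no_exit_base() -> BaseTransitions:
    return BaseTransitions(hd_to_pd=0.0, hd_to_tx=0.0, pd_to_hd=0.0,
                           pd_to_tx=0.0, tx_exit_to_hd=0.0,
                           tx_exit_to_pd=0.0, lr_tunnel=False)


def random_valid_inputs(rng: np.random.Generator, horizon: int = 8
                        ) -> ModelInputs:
    """A random configuration guaranteed feasible over its whole horizon."""
    base = BaseTransitions(
        hd_to_pd=rng.uniform(0.0, 0.1),
        hd_to_tx=rng.uniform(0.0, 0.1),
        pd_to_hd=rng.uniform(0.0, 0.1),
        pd_to_tx=rng.uniform(0.0, 0.1),
        tx_exit_to_hd=0.0350, tx_exit_to_pd=0.0035,
        lr_tunnel=bool(rng.integers(0, 2)))
    mortality_params = MortalityParams(
        q0=rng.uniform(0.01, 0.2),
        growth=rng.uniform(0.0, 0.08),
        lr_first_year_survival=rng.uniform(0.5, 0.9))
    start = {s: 0.0 for s in S}
    weights = rng.dirichlet(np.ones(3))
    for s, w in zip((S.HD, S.PD, S.TX), weights):
        start[s] = float(w)
    fy = {S.HD: rng.uniform(100, 5000), S.PD: rng.uniform(100, 5000),
          S.TX: rng.uniform(100, 50000), S.D: 0.0}
    fy[S.LRHD] = fy[S.HD] + rng.uniform(1, 5000)
    fy[S.LRPD] = fy[S.PD] + rng.uniform(1, 5000)
    prev = {s: (0.0 if s is S.D else rng.uniform(1000, 40000)) for s in S}
    util = {s: (0.0 if s is S.D else rng.uniform(0.1, 1.0)) for s in S}
    config = ModelConfig(cohort_size=1000.0, start_age=40.0, horizon=horizon,
                         discount_rate=rng.uniform(0.0, 0.05),
                         initial_occupancy=start)
    return ModelInputs(config=config, transitions=base,
                       costs=CostSet(first_year=fy, prevalence=prev),
                       utilities=UtilitySet(utility=util),
                       mortality_params=mortality_params,
                       uplifts=UpliftSpec())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
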