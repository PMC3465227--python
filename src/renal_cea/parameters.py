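"""Model parameters: typed containers, config I/O, scenario construction.

The model describes renal replacement therapy (RRT) after kidney-graft
failure with six health states: hemodialysis (HD), peritoneal dialysis
(PD), functioning transplant (Tx), late-referral hemodialysis (LRHD),
late-referral peritoneal dialysis (LRPD) and death (D).  A scenario is a
single number ``p`` — the fraction of graft-failure patients who restart
dialysis late: ``p = 1`` is the all-late scenario (L), ``p = 0`` the
all-timely scenario (T).

Costs are January-2012 euros; one model cycle is one year.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .errors import InfeasibleModelError, RangeError, ValidationError


class HealthState(str, Enum):
    """The six health states; D is absorbing."""

    HD = "HD"
    PD = "PD"
    TX = "Tx"
    LRHD = "LRHD"
    LRPD = "LRPD"
    D = "D"


#: Canonical state ordering used for every matrix and trace.
STATES: tuple[HealthState, ...] = (
    HealthState.HD,
    HealthState.PD,
    HealthState.TX,
    HealthState.LRHD,
    HealthState.LRPD,
    HealthState.D,
)
STATE_INDEX: dict[HealthState, int] = {s: i for i, s in enumerate(STATES)}
ALIVE_STATES: tuple[HealthState, ...] = STATES[:-1]
N_STATES = len(STATES)


def _check_prob(name: str, value: float) -> float:
    if not (0.0 <= value <= 1.0):
        raise RangeError(f"{name} = {value!r} is not a probability in [0, 1]")
    return float(value)


@dataclass
class BaseTransitions:
    """Per-cycle transition probabilities that do not depend on age or scenario.

    ``tx_exit_to_hd``/``tx_exit_to_pd`` are the total graft-failure exit
    probabilities; the scenario's late fraction decides how much of each is
    routed to the timely (HD/PD) versus late (LRHD/LRPD) states.

    ``lr_tunnel`` selects the late-referral state mechanics: if true
    (default) LRHD/LRPD are one-cycle tunnel states whose survivors move on
    to HD/PD — elevated costs, utilities and mortality are first-year
    phenomena; if false the labels are permanent.
    """

    hd_to_pd: float = 0.0
    hd_to_tx: float = 0.0
    pd_to_hd: float = 0.0
    pd_to_tx: float = 0.0
    tx_exit_to_hd: float = 0.0350
    tx_exit_to_pd: float = 0.0035
    lr_tunnel: bool = True

    def __post_init__(self) -> None:
        for name in ("hd_to_pd", "hd_to_tx", "pd_to_hd", "pd_to_tx",
                     "tx_exit_to_hd", "tx_exit_to_pd"):
            setattr(self, name, _check_prob(f"transitions.{name}", getattr(self, name)))
        for row, total in (("HD", self.hd_to_pd + self.hd_to_tx),
                           ("PD", self.pd_to_hd + self.pd_to_tx),
                           ("Tx", self.tx_exit_to_hd + self.tx_exit_to_pd)):
            if total > 1.0 + 1e-12:
                raise RangeError(f"off-diagonal exits of row {row} sum to {total} > 1")


@dataclass(frozen=True)
class ScenarioSpec:
    """A referral scenario: fraction ``late_fraction`` of Tx-failure patients
    restart dialysis late."""

    name: str
    late_fraction: float

    def __post_init__(self) -> None:
        _check_prob(f"scenario {self.name!r} late_fraction", self.late_fraction)


#: The two scenarios the study compares.
SCENARIO_L = ScenarioSpec("L", 1.0)  # current situation: all late
SCENARIO_T = ScenarioSpec("T", 0.0)  # ideal: all timely


@dataclass
class CostSet:
    """Per-state costs in euros.

    ``first_year`` is the one-off add-on cost of entering a state (vascular
    or peritoneal access, transplant surgery); ``prevalence`` is the
    recurring annual treatment cost of occupying it.
    """

    first_year: dict[HealthState, float]
    prevalence: dict[HealthState, float]

    def __post_init__(self) -> None:
        for label, table in (("first_year", self.first_year),
                             ("prevalence", self.prevalence)):
            for s in STATES:
                if s not in table:
                    raise ValidationError(f"costs.{label} missing state {s.value}")
                if table[s] < 0:
                    raise RangeError(f"costs.{label}[{s.value}] = {table[s]} < 0")
            if table[HealthState.D] != 0:
                raise RangeError(f"costs.{label}[D] must be 0")
        if self.first_year[HealthState.LRHD] <= self.first_year[HealthState.HD]:
            raise RangeError("first_year[LRHD] must exceed first_year[HD]")
        if self.first_year[HealthState.LRPD] <= self.first_year[HealthState.PD]:
            raise RangeError("first_year[LRPD] must exceed first_year[PD]")

    def first_year_vector(self) -> np.ndarray:
        return np.array([self.first_year[s] for s in STATES], dtype=float)

    def prevalence_vector(self) -> np.ndarray:
        return np.array([self.prevalence[s] for s in STATES], dtype=float)


@dataclass
class UtilitySet:
    """QALY weight of one year in each state, on [0, 1]; death weighs 0."""

    utility: dict[HealthState, float]

    def __post_init__(self) -> None:
        for s in STATES:
            if s not in self.utility:
                raise ValidationError(f"utilities missing state {s.value}")
            if not (0.0 <= self.utility[s] <= 1.0):
                raise RangeError(f"utilities[{s.value}] = {self.utility[s]} outside [0, 1]")
        if self.utility[HealthState.D] != 0:
            raise RangeError("utilities[D] must be 0")

    def vector(self) -> np.ndarray:
        return np.array([self.utility[s] for s in STATES], dtype=float)


@dataclass
class MortalityParams:
    """Parameters of the synthetic age-dependent mortality schedule.

    ``q0`` is the annual death probability of standard-care (HD/PD/Tx)
    patients at the cohort's starting age; ``growth`` the annual log-hazard
    increment of a Gompertz-type curve.  ``lr_first_year_survival`` anchors
    late-referral mortality: the schedule is scaled so a late-referral
    patient at the starting age survives the first year with this
    probability (0.73 by default).
    """

    q0: float = 0.022
    growth: float = 0.075
    lr_first_year_survival: float = 0.73

    def __post_init__(self) -> None:
        if not (0.0 < self.q0 < 1.0):
            raise RangeError(f"mortality.q0 = {self.q0} must lie in (0, 1)")
        if self.growth < 0:
            raise RangeError(f"mortality.growth = {self.growth} must be >= 0")
        if not (0.0 < self.lr_first_year_survival < 1.0):
            raise RangeError("mortality.lr_first_year_survival must lie in (0, 1)")


@dataclass
class ModelConfig:
    """Global run settings: cohort, horizon, discounting, PSA controls."""

    cohort_size: float = 1000.0
    start_age: float = 40.0
    horizon: int = 45
    cycle_length: float = 1.0
    discount_rate: float = 0.03
    wtpt: float = 45_000.0
    psa_replicates: int = 1000
    relative_sd: float = 0.10
    wtpt_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 90_001.0, 1000.0))
    initial_occupancy: dict[HealthState, float] = field(
        default_factory=lambda: {s: (1.0 if s is HealthState.TX else 0.0) for s in STATES})
    seed: int = 20120816

    def __post_init__(self) -> None:
        if self.cohort_size <= 0:
            raise RangeError("cohort_size must be > 0")
        if self.horizon < 1:
            raise RangeError("horizon must be >= 1")
        if self.discount_rate < 0:
            raise RangeError("discount_rate must be >= 0")
        if self.wtpt < 0:
            raise RangeError("wtpt must be >= 0")
        if self.psa_replicates < 1:
            raise RangeError("psa_replicates must be >= 1")
        self.wtpt_grid = np.asarray(self.wtpt_grid, dtype=float)
        occ = {s: float(self.initial_occupancy.get(s, 0.0)) for s in STATES}
        total = sum(occ.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"initial_occupancy sums to {total}, expected 1")
        self.initial_occupancy = occ

    def initial_occupancy_vector(self) -> np.ndarray:
        return self.cohort_size * np.array(
            [self.initial_occupancy[s] for s in STATES], dtype=float)


@dataclass
class UpliftSpec:
    """Relative first-year resource-use increases of late versus timely starters.

    Late starters spend 97 % more hospitalization days (access
    complications), need 69 % more erythropoietin and 47 % more intravenous
    iron during the first year.  ``nonscheduled_surcharge`` is the flat
    add-on cost of an urgent, unplanned dialysis start, applied per state
    when ``nonscheduled_start`` is set.
    """

    hospitalization_uplift: float = 0.97
    rhuepo_uplift: float = 0.69
    iv_iron_uplift: float = 0.47
    nonscheduled_start: bool = True
    nonscheduled_surcharge: dict[HealthState, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("hospitalization_uplift", "rhuepo_uplift", "iv_iron_uplift"):
            if getattr(self, name) < 0:
                raise RangeError(f"uplifts.{name} must be >= 0")
        for s, v in self.nonscheduled_surcharge.items():
            if v < 0:
                raise RangeError(f"uplifts.surcharge[{s.value}] = {v} < 0")


@dataclass
class ProductivityParams:
    """Societal-perspective extension: lost labor productivity per death-year."""

    loss_per_death_year: float = 29_345.0
    working_age_limit: float = 67.0
    enabled: bool = False

    def __post_init__(self) -> None:
        if self.loss_per_death_year < 0:
            raise RangeError("productivity.loss_per_death_year must be >= 0")


@dataclass
class ModelInputs:
    """The complete, validated parameter bundle a run needs."""

    config: ModelConfig
    transitions: BaseTransitions
    costs: CostSet
    utilities: UtilitySet
    mortality_params: MortalityParams
    uplifts: UpliftSpec
    cost_components: dict[HealthState, dict[str, float]] = field(default_factory=dict)
    productivity: ProductivityParams = field(default_factory=ProductivityParams)

    def mortality(self):
        """Build the age-dependent mortality schedule for this configuration."""
        from .synthetic_data import generate_mortality_schedule

        return generate_mortality_schedule(
            q0=self.mortality_params.q0,
            growth=self.mortality_params.growth,
            anchor=self.mortality_params.lr_first_year_survival,
            start_age=self.config.start_age,
            horizon=self.config.horizon,
        )

    def copy(self) -> "ModelInputs":
        return copy.deepcopy(self)


def build_tx_row(base: BaseTransitions, scenario: ScenarioSpec
                 ) -> tuple[float, float, float, float]:
    """Route the graft-failure exit mass by the scenario's late fraction.

    Returns the Tx-exit probabilities ``(to_HD, to_PD, to_LRHD, to_LRPD)``.
    The total dialysis-return mass ``tx_exit_to_hd + tx_exit_to_pd`` does
    not depend on the scenario; only its split between timely and late
    destinations does.
    """
    p = _check_prob("late_fraction", scenario.late_fraction)
    return ((1.0 - p) * base.tx_exit_to_hd,
            (1.0 - p) * base.tx_exit_to_pd,
            p * base.tx_exit_to_hd,
            p * base.tx_exit_to_pd)


def assemble_matrix(base: BaseTransitions, scenario: ScenarioSpec, mortality,
                    age: float, *, on_infeasible: str = "error") -> np.ndarray:
    """Assemble the 6x6 one-cycle transition matrix at a given age.

    Rows and columns follow :data:`STATES`.  The death column is
    age-dependent: standard-care states use ``mortality.q_std(age)``,
    late-referral states ``mortality.q_lr(age)``.  Each alive state's stay
    probability is the residual after exits and death; a negative residual
    raises :class:`InfeasibleModelError`, or — with
    ``on_infeasible="renormalize"`` — the row's off-diagonal entries are
    scaled to sum to one and the stay probability set to zero (the rule the
    probabilistic sensitivity analysis uses for extreme draws).
    """
    if on_infeasible not in ("error", "renormalize"):
        raise ValueError(f"unknown on_infeasible mode {on_infeasible!r}")
    q_std = _check_prob(f"q_std({age})", float(mortality.q_std(age)))
    q_lr = _check_prob(f"q_lr({age})", float(mortality.q_lr(age)))

    i = STATE_INDEX
    M = np.zeros((N_STATES, N_STATES), dtype=float)

    def fill_row(state: HealthState, exits: dict[HealthState, float], death: float) -> None:
        r = i[state]
        for to, p in exits.items():
            M[r, i[to]] = p
        M[r, i[HealthState.D]] = death
        residual = 1.0 - death - sum(exits.values())
        if residual < -1e-12:
            if on_infeasible == "renormalize":
                M[r] /= M[r].sum()
                return
            raise InfeasibleModelError(state.value, age, residual)
        M[r, r] += max(residual, 0.0)

    tx_hd, tx_pd, tx_lrhd, tx_lrpd = build_tx_row(base, scenario)
    fill_row(HealthState.HD,
             {HealthState.PD: base.hd_to_pd, HealthState.TX: base.hd_to_tx}, q_std)
    fill_row(HealthState.PD,
             {HealthState.HD: base.pd_to_hd, HealthState.TX: base.pd_to_tx}, q_std)
    fill_row(HealthState.TX,
             {HealthState.HD: tx_hd, HealthState.PD: tx_pd,
              HealthState.LRHD: tx_lrhd, HealthState.LRPD: tx_lrpd}, q_std)
    if base.lr_tunnel:
        # one-cycle tunnel: survivors migrate to the standard-care modality
        fill_row(HealthState.LRHD, {HealthState.HD: 1.0 - q_lr}, q_lr)
        fill_row(HealthState.LRPD, {HealthState.PD: 1.0 - q_lr}, q_lr)
    else:
        fill_row(HealthState.LRHD, {}, q_lr)
        fill_row(HealthState.LRPD, {}, q_lr)
    M[i[HealthState.D], i[HealthState.D]] = 1.0  # absorbing
    return M


# ---------------------------------------------------------------------------
# Config document I/O

_REQUIRED_SECTIONS = ("model", "transitions", "costs", "utilities", "mortality")


def _state_table(section: Mapping[str, Any], where: str) -> dict[HealthState, float]:
    out = {}
    for s in STATES:
        if s.value not in section:
            raise ValidationError(f"{where} missing state {s.value}")
        out[s] = float(section[s.value])
    return out


def _require(section: Mapping[str, Any], key: str, where: str) -> Any:
    if key not in section:
        raise ValidationError(f"missing key {where}.{key}")
    return section[key]


def config_from_dict(doc: Mapping[str, Any]) -> ModelInputs:
    """Validate a parsed configuration document into a :class:`ModelInputs`."""
    for sec in _REQUIRED_SECTIONS:
        if sec not in doc:
            raise ValidationError(f"missing section {sec!r}")

    m = doc["model"]
    psa = doc.get("psa", {})
    grid = psa.get("wtpt_grid", {"start": 0.0, "stop": 90_000.0, "step": 1000.0})
    config = ModelConfig(
        cohort_size=float(_require(m, "cohort_size", "model")),
        start_age=float(_require(m, "start_age", "model")),
        horizon=int(_require(m, "horizon", "model")),
        cycle_length=float(m.get("cycle_length", 1.0)),
        discount_rate=float(_require(m, "discount_rate", "model")),
        wtpt=float(_require(m, "wtpt", "model")),
        psa_replicates=int(psa.get("replicates", 1000)),
        relative_sd=float(psa.get("relative_sd", 0.10)),
        wtpt_grid=np.arange(float(grid["start"]),
                            float(grid["stop"]) + 0.5 * float(grid["step"]),
                            float(grid["step"])),
        initial_occupancy={HealthState(k): float(v)
                           for k, v in _require(m, "initial_occupancy", "model").items()},
        seed=int(m.get("seed", 20120816)),
    )

    t = doc["transitions"]
    transitions = BaseTransitions(
        hd_to_pd=float(_require(t.get("HD", {}), "PD", "transitions.HD")),
        hd_to_tx=float(_require(t.get("HD", {}), "Tx", "transitions.HD")),
        pd_to_hd=float(_require(t.get("PD", {}), "HD", "transitions.PD")),
        pd_to_tx=float(_require(t.get("PD", {}), "Tx", "transitions.PD")),
        tx_exit_to_hd=float(_require(t, "tx_exit_to_hd", "transitions")),
        tx_exit_to_pd=float(_require(t, "tx_exit_to_pd", "transitions")),
        lr_tunnel=bool(t.get("lr_tunnel", True)),
    )

    c = doc["costs"]
    costs = CostSet(
        first_year=_state_table(_require(c, "first_year", "costs"), "costs.first_year"),
        prevalence=_state_table(_require(c, "prevalence", "costs"), "costs.prevalence"),
    )
    components = {HealthState(state): {k: float(v) for k, v in comp.items()}
                  for state, comp in c.get("components", {}).items()}

    utilities = UtilitySet(utility=_state_table(doc["utilities"], "utilities"))

    mo = doc["mortality"]
    mortality_params = MortalityParams(
        q0=float(_require(mo, "q0", "mortality")),
        growth=float(_require(mo, "growth", "mortality")),
        lr_first_year_survival=float(_require(mo, "lr_first_year_survival", "mortality")),
    )

    u = doc.get("uplifts", {})
    uplifts = UpliftSpec(
        hospitalization_uplift=float(u.get("hospitalization", 0.97)),
        rhuepo_uplift=float(u.get("rhuepo", 0.69)),
        iv_iron_uplift=float(u.get("iv_iron", 0.47)),
        nonscheduled_start=bool(u.get("nonscheduled_start", True)),
        nonscheduled_surcharge={HealthState(k): float(v)
                                for k, v in u.get("surcharge", {}).items()},
    )

    pr = doc.get("productivity", {})
    productivity = ProductivityParams(
        loss_per_death_year=float(pr.get("loss_per_death_year", 29_345.0)),
        working_age_limit=float(pr.get("working_age_limit", 67.0)),
        enabled=bool(pr.get("enabled", False)),
    )

    return ModelInputs(config=config, transitions=transitions, costs=costs,
                       utilities=utilities, mortality_params=mortality_params,
                       uplifts=uplifts, cost_components=components,
                       productivity=productivity)


def config_to_dict(inputs: ModelInputs) -> dict[str, Any]:
    """Serialize a :class:`ModelInputs` back into a plain config document."""
    cfg = inputs.config
    grid = cfg.wtpt_grid
    step = float(grid[1] - grid[0]) if len(grid) > 1 else 1000.0
    return {
        "model": {
            "cohort_size": cfg.cohort_size,
            "start_age": cfg.start_age,
            "horizon": cfg.horizon,
            "cycle_length": cfg.cycle_length,
            "discount_rate": cfg.discount_rate,
            "wtpt": cfg.wtpt,
            "initial_occupancy": {s.value: cfg.initial_occupancy[s] for s in STATES},
            "seed": cfg.seed,
        },
        "transitions": {
            "HD": {"PD": inputs.transitions.hd_to_pd, "Tx": inputs.transitions.hd_to_tx},
            "PD": {"HD": inputs.transitions.pd_to_hd, "Tx": inputs.transitions.pd_to_tx},
            "tx_exit_to_hd": inputs.transitions.tx_exit_to_hd,
            "tx_exit_to_pd": inputs.transitions.tx_exit_to_pd,
            "lr_tunnel": inputs.transitions.lr_tunnel,
        },
        "costs": {
            "first_year": {s.value: inputs.costs.first_year[s] for s in STATES},
            "prevalence": {s.value: inputs.costs.prevalence[s] for s in STATES},
            "components": {s.value: dict(comp)
                           for s, comp in inputs.cost_components.items()},
        },
        "utilities": {s.value: inputs.utilities.utility[s] for s in STATES},
        "mortality": asdict(inputs.mortality_params),
        "uplifts": {
            "hospitalization": inputs.uplifts.hospitalization_uplift,
            "rhuepo": inputs.uplifts.rhuepo_uplift,
            "iv_iron": inputs.uplifts.iv_iron_uplift,
            "nonscheduled_start": inputs.uplifts.nonscheduled_start,
            "surcharge": {s.value: v
                          for s, v in inputs.uplifts.nonscheduled_surcharge.items()},
        },
        "psa": {
            "replicates": cfg.psa_replicates,
            "relative_sd": cfg.relative_sd,
            "wtpt_grid": {"start": float(grid[0]), "stop": float(grid[-1]), "step": step},
        },
        "productivity": asdict(inputs.productivity),
    }


def load_config(source: str | Path | Mapping[str, Any]) -> ModelInputs:
    """Load and validate a YAML/JSON configuration file (or parsed mapping)."""
    if isinstance(source, Mapping):
        return config_from_dict(source)
    path = Path(source)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ValidationError(f"config file {path} does not contain a mapping")
    return config_from_dict(doc)


def save_config(inputs: ModelInputs, path: str | Path) -> None:
    """Write a configuration that :func:`load_config` round-trips exactly."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(inputs), fh, sort_keys=False)


def load_default_config() -> ModelInputs:
    """Load the packaged default configuration.

    The packaged file encodes every printed cost, utility and probability of
    the study verbatim, plus the documented synthetic stand-ins for the
    unpublished transition and mortality inputs.
    """
    from importlib import resources

    ref = resources.files("renal_cea").joinpath("data/paper_calibrated.yaml")
    with resources.as_file(ref) as path:
        return load_config(path)
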