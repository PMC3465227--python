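"""Probabilistic sensitivity analysis by moment-matched Monte Carlo.

Each uncertain scalar receives a distribution by its kind — Beta for
transition probabilities, normal for utilities, log-normal for costs,
uniform for the discount rate — with parameters moment-matched to the
point estimate and a standard deviation of 10 % of the mean (the study's
dispersion assumption).  Every replicate draws all parameters
simultaneously and runs *both* referral scenarios under the same drawn
set, so the (ΔC, ΔE) pair isolates the scenario difference from the
parameter noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import category_frequencies, classify, restricted_acceptance
from .errors import InfeasibleModelError, RangeError
from .markov import run_scenario
from .parameters import (
    HealthState,
    ModelInputs,
    SCENARIO_L,
    SCENARIO_T,
    ScenarioSpec,
)
from .paramspace import ScalarParam, list_scalar_parameters
from .synthetic_data import generate_mortality_schedule

#: Distribution family used for each parameter kind.
FAMILY_OF_KIND = {"probability": "beta", "cost": "lognormal",
                  "utility": "normal", "rate": "uniform"}


@dataclass(frozen=True)
class DistributionSpec:
    """A moment-matched sampling distribution.

    ``natural_params`` hold the family's own parameters (α/β, μ/σ, bounds)
    derived so the analytic mean and sd equal the requested moments.
    """

    family: str
    mean: float
    sd: float
    natural_params: dict

    @property
    def analytic_mean(self) -> float:
        p = self.natural_params
        if self.family == "beta":
            return p["alpha"] / (p["alpha"] + p["beta"])
        if self.family == "normal":
            return p["loc"]
        if self.family == "lognormal":
            return math.exp(p["mu"] + 0.5 * p["sigma"] ** 2)
        if self.family == "uniform":
            return 0.5 * (p["low"] + p["high"])
        raise ValueError(self.family)

    @property
    def analytic_sd(self) -> float:
        p = self.natural_params
        if self.family == "beta":
            a, b = p["alpha"], p["beta"]
            return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        if self.family == "normal":
            return p["scale"]
        if self.family == "lognormal":
            s2 = p["sigma"] ** 2
            return math.exp(p["mu"] + 0.5 * s2) * math.sqrt(math.expm1(s2))
        if self.family == "uniform":
            return (p["high"] - p["low"]) / (2.0 * math.sqrt(3.0))
        raise ValueError(self.family)

    def rvs(self, rng: np.random.Generator, size=None):
        p = self.natural_params
        if self.family == "beta":
            return rng.beta(p["alpha"], p["beta"], size=size)
        if self.family == "normal":
            return rng.normal(p["loc"], p["scale"], size=size)
        if self.family == "lognormal":
            return rng.lognormal(p["mu"], p["sigma"], size=size)
        if self.family == "uniform":
            return rng.uniform(p["low"], p["high"], size=size)
        raise ValueError(self.family)


def make_distribution(family: str, mean: float, sd: float) -> DistributionSpec:
    """Moment-match a distribution of the given family to (mean, sd).

    Beta: ν = mean(1−mean)/sd² − 1, α = mean·ν, β = (1−mean)·ν.
    Log-normal: σ² = ln(1 + sd²/mean²), μ = ln(mean) − σ²/2.
    Uniform: bounds mean ± sd·√3.  Normal: direct.
    """
    if sd <= 0:
        raise RangeError(f"sd = {sd} must be > 0")
    if family == "beta":
        if not (0.0 < mean < 1.0):
            raise RangeError(f"beta mean {mean} must lie in (0, 1)")
        if sd * sd >= mean * (1.0 - mean):
            raise RangeError(
                f"beta with mean {mean} cannot have sd {sd}: "
                f"sd^2 >= mean(1-mean)")
        nu = mean * (1.0 - mean) / (sd * sd) - 1.0
        params = {"alpha": mean * nu, "beta": (1.0 - mean) * nu}
    elif family == "normal":
        params = {"loc": mean, "scale": sd}
    elif family == "lognormal":
        if mean <= 0:
            raise RangeError(f"lognormal mean {mean} must be > 0")
        sigma2 = math.log1p((sd / mean) ** 2)
        params = {"mu": math.log(mean) - 0.5 * sigma2,
                  "sigma": math.sqrt(sigma2)}
    elif family == "uniform":
        half = sd * math.sqrt(3.0)
        params = {"low": mean - half, "high": mean + half}
    else:
        raise ValueError(f"unknown family {family!r}")
    return DistributionSpec(family=family, mean=mean, sd=sd,
                            natural_params=params)


def build_parameter_specs(inputs: ModelInputs
                          ) -> dict[str, tuple[ScalarParam, DistributionSpec]]:
    """Distribution specs for every tunable scalar with a nonzero mean.

    Parameters whose point estimate is zero (an absent transition, a free
    state) carry no 10 %-of-mean uncertainty and stay fixed.
    """
    rel_sd = inputs.config.relative_sd
    specs = {}
    for param in list_scalar_parameters(inputs):
        mean = param.get(inputs)
        if mean <= 0:
            continue
        family = FAMILY_OF_KIND[param.kind]
        specs[param.name] = (param, make_distribution(family, mean,
                                                      rel_sd * mean))
    return specs


def sample_parameter_set(specs, rng: np.random.Generator,
                         inputs: ModelInputs) -> tuple[ModelInputs, dict[str, float]]:
    """Draw one joint parameter set; returns the modified inputs and draws.

    Each parameter is drawn independently from its spec.  Utilities are
    clamped to [0, 1]; probability rows whose exits outgrow the death
    probability are renormalized (residual-stay rule) at matrix-assembly
    time rather than here.
    """
    drawn_inputs = inputs.copy()
    draws: dict[str, float] = {}
    for name, (param, spec) in specs.items():
        value = float(spec.rvs(rng))
        if param.kind == "utility":
            value = min(max(value, 0.0), 1.0)
        param.set(drawn_inputs, value)
        draws[name] = value
    return drawn_inputs, draws


@dataclass
class PsaResult:
    """Replicate-level table plus summary statistics of one PSA run."""

    replicates: pd.DataFrame
    wtpt: float
    comparator: str = "T"
    reference: str = "L"
    seed: int | None = None

    @property
    def samples(self) -> np.ndarray:
        """(N, 2) array of per-patient annual (ΔC, ΔE) pairs."""
        return self.replicates[["delta_cost", "delta_qaly"]].to_numpy()

    def summary(self) -> dict:
        """Means, empirical 95 % percentile intervals (linear-interpolation
        rule) and category frequencies at the threshold."""
        rep = self.replicates

        def mean_ci(col: str) -> dict:
            x = rep[col].to_numpy()
            lo, hi = np.percentile(x, [2.5, 97.5])
            return {"mean": float(x.mean()), "ci_low": float(lo),
                    "ci_high": float(hi)}

        out = {
            "n": int(len(rep)),
            "cost": {self.reference: mean_ci(f"cost_{self.reference}"),
                     self.comparator: mean_ci(f"cost_{self.comparator}")},
            "qaly": {self.reference: mean_ci(f"qaly_{self.reference}"),
                     self.comparator: mean_ci(f"qaly_{self.comparator}")},
            "delta_cost": mean_ci("delta_cost"),
            "delta_qaly": mean_ci("delta_qaly"),
            "categories": category_frequencies(self.samples, self.wtpt,
                                               self.comparator, self.reference),
        }
        out["acceptance"] = {
            self.comparator: out["categories"][self.comparator]["acceptable"],
            self.reference: out["categories"][self.reference]["acceptable"],
        }
        try:
            out["acceptance_no_effectiveness_loss"] = restricted_acceptance(
                self.samples, self.wtpt, self.comparator, self.reference)
        except ValueError:
            out["acceptance_no_effectiveness_loss"] = None
        return out


def run_psa(inputs: ModelInputs, n: int | None = None, seed: int | None = None,
            comparator: ScenarioSpec = SCENARIO_T,
            reference: ScenarioSpec = SCENARIO_L,
            max_retries: int = 100) -> PsaResult:
    """Run the full probabilistic sensitivity analysis.

    Every replicate draws the whole parameter set once and runs both
    scenarios under it (common random parameters), recording per-patient
    annual discounted cost and QALY per scenario, their deltas and the
    cost-effectiveness category at the configured threshold.  A replicate
    whose draw yields an unusable model is logged and redrawn, up to
    ``max_retries`` attempts.
    """
    n = n if n is not None else inputs.config.psa_replicates
    if n < 1:
        raise ValueError("PSA needs at least one replicate")
    seed = seed if seed is not None else inputs.config.seed
    rng = np.random.default_rng(seed)
    specs = build_parameter_specs(inputs)

    rows = []
    for rep in range(n):
        for attempt in range(max_retries):
            drawn, draws = sample_parameter_set(specs, rng, inputs)
            mortality = generate_mortality_schedule(
                q0=drawn.mortality_params.q0,
                growth=drawn.mortality_params.growth,
                anchor=drawn.mortality_params.lr_first_year_survival,
                start_age=drawn.config.start_age,
                horizon=drawn.config.horizon)
            try:
                _, ref = run_scenario(drawn, reference, mortality=mortality,
                                      on_infeasible="renormalize")
                _, comp = run_scenario(drawn, comparator, mortality=mortality,
                                       on_infeasible="renormalize")
                break
            except InfeasibleModelError:  # pragma: no cover - renormalized away
                continue
        else:  # pragma: no cover
            raise InfeasibleModelError("any", drawn.config.start_age, -1.0)
        dc = comp.per_patient_annual_cost - ref.per_patient_annual_cost
        de = comp.per_patient_annual_qaly - ref.per_patient_annual_qaly
        rows.append({
            "replicate_id": rep,
            "discount_rate": drawn.config.discount_rate,
            f"cost_{reference.name}": ref.per_patient_annual_cost,
            f"qaly_{reference.name}": ref.per_patient_annual_qaly,
            f"cost_{comparator.name}": comp.per_patient_annual_cost,
            f"qaly_{comparator.name}": comp.per_patient_annual_qaly,
            "delta_cost": dc,
            "delta_qaly": de,
            "category": classify(dc, de, inputs.config.wtpt).value,
        })
    return PsaResult(replicates=pd.DataFrame(rows), wtpt=inputs.config.wtpt,
                     comparator=comparator.name, reference=reference.name,
                     seed=seed)
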