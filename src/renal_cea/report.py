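"""Run reports: the deterministic and probabilistic result blocks.

Mirrors the study's results table: per-patient annual cost and QALY per
scenario, undiscounted and at the configured discount rate, the ICERs,
and — when a PSA is attached — means, 95 % percentile intervals, category
frequencies and acceptance probabilities at the threshold.  Rendered
tables round to whole euros and four QALY decimals; exported CSV/JSON
keep full precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from . import __version__
from .cea import incremental
from .costing import productivity_loss
from .markov import run_scenario
from .parameters import ModelInputs, SCENARIO_L, SCENARIO_T, config_to_dict


def config_hash(inputs: ModelInputs) -> str:
    """Stable digest of the full configuration, for provenance."""
    doc = yaml.safe_dump(config_to_dict(inputs), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


def deterministic_block(inputs: ModelInputs, societal: bool = False) -> dict:
    """Both scenarios at 0 % and the configured rate, plus the ICERs."""
    r = inputs.config.discount_rate
    out: dict = {"discount_rate": r, "scenarios": {}, "comparative": {}}
    traces = {}
    for scen in (SCENARIO_L, SCENARIO_T):
        trace, disc = run_scenario(inputs, scen)
        _, undisc = run_scenario(inputs, scen, discount_rate=0.0)
        traces[scen.name] = trace
        out["scenarios"][scen.name] = {
            "per_patient_annual_cost": undisc.per_patient_annual_cost,
            "per_patient_annual_cost_discounted": disc.per_patient_annual_cost,
            "per_patient_annual_qaly": undisc.per_patient_annual_qaly,
            "per_patient_annual_qaly_discounted": disc.per_patient_annual_qaly,
            "life_years": disc.total_life_years,
        }
        _ = trace

    def _cmp(key_cost: str, key_qaly: str, rate: float) -> dict:
        _, ref = run_scenario(inputs, SCENARIO_L, discount_rate=rate)
        _, comp = run_scenario(inputs, SCENARIO_T, discount_rate=rate)
        res = incremental(ref, comp, wtpt=inputs.config.wtpt)
        block = {"delta_cost": res.delta_cost, "delta_qaly": res.delta_qaly,
                 "icer": res.icer, "category": res.category.value}
        if societal and inputs.productivity.loss_per_death_year > 0:
            # societal offset: productivity losses enter the incremental
            # comparison only, as savings of the more effective scenario
            denom = inputs.config.cohort_size * inputs.config.horizon
            loss_ref = productivity_loss(traces["L"], inputs.config,
                                         inputs.productivity) / denom
            loss_comp = productivity_loss(traces["T"], inputs.config,
                                          inputs.productivity) / denom
            dc = res.delta_cost + (loss_comp - loss_ref)
            block["delta_cost_societal"] = dc
            block["icer_societal"] = (dc / res.delta_qaly
                                      if res.delta_qaly else None)
        return block

    out["comparative"]["undiscounted"] = _cmp("cost", "qaly", 0.0)
    out["comparative"]["discounted"] = _cmp("cost", "qaly", r)
    return out


def run_report(inputs: ModelInputs, psa_result=None, seed: int | None = None,
               societal: bool = False) -> dict:
    """Full JSON-ready report with provenance."""
    report = {
        "provenance": {
            "config_hash": config_hash(inputs),
            "seed": seed if seed is not None else inputs.config.seed,
            "version": __version__,
        },
        "deterministic": deterministic_block(inputs, societal=societal),
    }
    if psa_result is not None:
        report["probabilistic"] = psa_result.summary()
    return report


def render_report(report: dict) -> str:
    """Text rendering of a report in the study's table layout."""
    det = report["deterministic"]
    lines = ["Results: Scenario L vs Scenario T",
             "=" * 50, "Deterministic analysis"]
    r = det["discount_rate"]
    L, T = det["scenarios"]["L"], det["scenarios"]["T"]
    cu, cd = det["comparative"]["undiscounted"], det["comparative"]["discounted"]
    rows = [
        ("Per-patient annual cost",
         f"{L['per_patient_annual_cost']:,.0f} EUR",
         f"{T['per_patient_annual_cost']:,.0f} EUR",
         f"{cu['delta_cost']:,.0f} EUR"),
        (f"Per-patient annual cost (discount rate {r:.0%})",
         f"{L['per_patient_annual_cost_discounted']:,.0f} EUR",
         f"{T['per_patient_annual_cost_discounted']:,.0f} EUR",
         f"{cd['delta_cost']:,.0f} EUR"),
        ("Per-patient annual QALY",
         f"{L['per_patient_annual_qaly']:.4f}",
         f"{T['per_patient_annual_qaly']:.4f}",
         f"{cu['delta_qaly']:.4f}"),
        (f"Per-patient annual QALY (discount rate {r:.0%})",
         f"{L['per_patient_annual_qaly_discounted']:.4f}",
         f"{T['per_patient_annual_qaly_discounted']:.4f}",
         f"{cd['delta_qaly']:.4f}"),
        ("ICER", "", "", f"{cu['icer']:,.0f} EUR/QALY" if cu["icer"] else "undefined"),
        (f"ICER (discount rate {r:.0%})", "", "",
         f"{cd['icer']:,.0f} EUR/QALY" if cd["icer"] else "undefined"),
    ]
    header = ("", "Scenario L", "Scenario T", "Comparative")
    widths = [max(len(str(row[i])) for row in rows + [header]) for i in range(4)]
    fmt = "  ".join(f"{{:<{w}}}" for w in widths)
    lines.append(fmt.format(*header))
    lines += [fmt.format(*row) for row in rows]

    if "probabilistic" in report:
        psa = report["probabilistic"]
        lines += ["", f"Probabilistic analysis (n = {psa['n']})"]
        for label in ("L", "T"):
            c, q = psa["cost"][label], psa["qaly"][label]
            lines.append(
                f"  Scenario {label}: cost {c['mean']:,.0f} EUR "
                f"({c['ci_low']:,.0f}; {c['ci_high']:,.0f}), "
                f"QALY {q['mean']:.4f} ({q['ci_low']:.4f}; {q['ci_high']:.4f})")
        acc = psa["acceptance"]
        lines.append(f"  Acceptable: L {acc['L']:.2%}, T {acc['T']:.2%}")
        rest = psa.get("acceptance_no_effectiveness_loss")
        if rest:
            lines.append("  Acceptable (without loss of effectiveness): "
                         f"L {rest['L']:.2%}, T {rest['T']:.2%}")
    return "\n".join(lines)


def write_report(report: dict, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
    (out_dir / "report.txt").write_text(render_report(report) + "\n")
    return path
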