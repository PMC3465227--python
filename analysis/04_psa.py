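"""Probabilistic sensitivity analysis.

1,000 Monte-Carlo replicates drawing every model parameter from its
moment-matched distribution (Beta for probabilities, log-normal for
costs, normal for utilities, uniform for the discount rate; sd = 10 % of
the mean), both scenarios run per draw.  Writes the replicate table,
summary, acceptability curves, cost-effectiveness plane and 95 %
confidence ellipse under results/psa/.
"""

import json
from pathlib import Path

from renal_cea.cea import ceac, confidence_ellipse
from renal_cea.plots import plot_ce_plane, plot_ceac
from renal_cea.psa import run_psa
from renal_cea.synthetic_data import default_inputs

OUT = Path(__file__).resolve().parent.parent / "results" / "psa"
OUT.mkdir(parents=True, exist_ok=True)

inputs = default_inputs()
result = run_psa(inputs, seed=inputs.config.seed)
result.replicates.to_csv(OUT / "psa_replicates.csv", index=False)

summary = result.summary()
with open(OUT / "psa_summary.json", "w") as fh:
    json.dump(summary, fh, indent=2)

curve = ceac(result.samples, inputs.config.wtpt_grid)
curve.to_frame().to_csv(OUT / "ceac.csv", index=False)
plot_ceac(curve, OUT / "ceac.png")

ellipse = confidence_ellipse(result.samples, level=0.95)
plot_ce_plane(result.samples, ellipse, OUT / "ce_plane.png",
              wtpt=inputs.config.wtpt)

acc = summary["acceptance"]
rest = summary["acceptance_no_effectiveness_loss"]
print(f"n = {summary['n']} replicates at WTPT 45,000 EUR/QALY")
print(f"mean incremental cost {summary['delta_cost']['mean']:,.0f} EUR "
      f"({summary['delta_cost']['ci_low']:,.0f}; "
      f"{summary['delta_cost']['ci_high']:,.0f})")
print(f"mean incremental QALY {summary['delta_qaly']['mean']:.4f} "
      f"({summary['delta_qaly']['ci_low']:.4f}; "
      f"{summary['delta_qaly']['ci_high']:.4f})")
print(f"acceptance: timely {acc['T']:.1%}, late {acc['L']:.1%}")
if rest:
    print(f"without loss of effectiveness: timely {rest['T']:.1%}, "
          f"late {rest['L']:.1%}")
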