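# Methods

## Model structure

The model is a discrete-time Markov cohort over six states — hemodialysis
(HD), peritoneal dialysis (PD), functioning kidney transplant (Tx),
late-referral hemodialysis (LRHD), late-referral peritoneal dialysis
(LRPD) and death (D) — with one-year cycles. A closed cohort of expected
counts (no microsimulation) is propagated through an age-specific
transition matrix for 45 cycles from age 40. D is absorbing; every other
row's stay probability is the residual after exits and death, and a
negative residual is a hard infeasibility error (except where the
probabilistic analysis explicitly renormalizes, below).

The two compared strategies differ *only* in the routing of the annual
graft-failure exit mass from Tx: probability 0.0350 returns to
hemodialysis and 0.0035 to peritoneal dialysis, routed to the timely
states (HD/PD) or the late-referral states (LRHD/LRPD) in proportion to
the scenario's late fraction *p*. This makes the total Tx-exit mass
invariant in *p* and the routing exactly linear in it.

### Starting state

The source material does not name the initial state distribution. The
packaged default places the whole cohort in Tx: the scenarios differ only
in Tx-exit routing, so a transplant-prevalent start maximises the signal
the comparison is about while keeping both arms identical at baseline.
Any other distribution can be configured (`model.initial_occupancy`).

### Late-referral states

Elevated late-referral costs, utilities and mortality are first-year
phenomena of an unplanned start. LRHD/LRPD are therefore modelled by
default as one-cycle *tunnel* states: survivors of the late-referral year
move to HD/PD respectively; setting `transitions.lr_tunnel: false` makes
the labels permanent instead. Death risk in a late-referral year uses the
late-referral mortality curve (below).

## Mortality

Standard-care mortality (HD, PD, Tx) is a Gompertz-type curve
`q_std(a) = min(1, q0 · exp(g · (a − a0)))` with `a0 = 40`. Late-referral
mortality is a constant multiplicative hazard scaling of the same curve,
anchored so that a late-referral patient at the starting age has a
first-year survival of 73 %: `q_lr(a) = min(1, k · q_std(a))` with
`k = 0.27 / q0`. The anchor value is published; the curve shape and its
extension across ages are this package's choices (the source derives its
schedule from a national registry it does not tabulate).

Defaults `q0 = 0.022`, `g = 0.075` are documented assumptions chosen
once: they give a median survival of roughly 16 years for a mixed
dialysis/transplant cohort starting renal replacement therapy at 40 and
keep every matrix row feasible across the whole 45-year horizon. They are
not registry estimates.

## Non-printed transitions and cost components

The non-transplant transition structure (HD↔PD switching, dialysis→Tx) is
published only diagrammatically. Packaged defaults — HD→PD 0.02,
HD→Tx 0.05, PD→HD 0.05, PD→Tx 0.06 per year — are plausible for a
European renal-replacement programme (transplant rates of 5–6 %/year
from dialysis, modality switches of a few percent) and are explicitly
assumptions. `synthetic_data.generate_base_transitions` can redraw them
from configurable ranges; the Tx-exit probabilities are never sampled.

First-year (entry) costs are one-off add-ons — vascular access for HD,
peritoneal access and training for PD, surgery for Tx. The late-referral
first-year totals are *constructed*: a timely modality's first-year total
is split into labelled components (hospitalization days, rHuEPO, IV iron,
access, other — default shares chosen once, access placement dominating),
the published relative uplifts are applied (hospitalization ×1.97,
rHuEPO ×1.69, IV iron ×1.47), and the residual against the published
late-referral total (6,627 € for LRHD, 3,748 € for LRPD) is attributed to
a flat non-scheduled-start surcharge (2,867 € and 1,199 € under the
default shares). The calibration is exact by construction, which the
tests enforce.

## Accrual conventions

- **Half-cycle correction**: prevalence costs and QALYs of cycle *t* use
  the trapezoidal occupancy `(occ[t−1] + occ[t]) / 2`, treating
  transitions as mid-cycle events.
- **First-year costs** attach in full to the entrants of a cycle, with no
  trapezoid — they are event costs, not year-long flows. Entrants into a
  state incur the first-year cost *in addition to* the cycle's prevalence
  cost, because the configured first-year values are add-ons, not
  full-year totals. The initial cohort pays its starting state's
  first-year cost at t = 0, undiscounted.
- **Discounting**: end-of-cycle, annual compounding — cycle-*t* accrual is
  multiplied by `(1 + r)^−t`; `r = 0` reduces to plain sums. The same rate
  applies to costs and QALYs.
- **Annualization**: per-patient annual figures divide totals by
  cohort_size × horizon (the published per-patient annual QALY magnitudes
  rule out division by person-years alive).

## Cost-effectiveness statistics

ΔC, ΔE and the ICER are computed on per-patient annual discounted
figures, comparator (timely) minus reference (late). The category
partition at threshold λ: *dominant* (no dearer, strictly more effective,
or strictly cheaper, no less effective), *dominated* (mirror image),
*efficient with higher effectiveness* (ΔC, ΔE > 0, ICER ≤ λ), *efficient
with lower cost* (ΔC, ΔE < 0, savings ≥ λ per QALY forgone), otherwise
*not acceptable*. Boundary conventions are fixed as above; under
continuous sampling they have probability ~0.

Acceptability is pairwise: the comparator's acceptance at λ is the
fraction of Monte-Carlo draws with positive net monetary benefit
`λ·ΔE − ΔC` (ties split equally), the reference takes the complement, so
the two curves sum to one. The *no-effectiveness-loss* variant
renormalizes over the draws in which either scenario is dominant or
efficient-with-higher-effectiveness. The 95 % confidence ellipse is the
normal-theory contour `(x − x̄)ᵀ S⁻¹ (x − x̄) = χ²₂(0.95) ≈ 5.9915` on the
sample mean and covariance of the (ΔE, ΔC) cloud.

## Sensitivity analyses

**One-way tornado**: every scalar parameter — the transition
probabilities (including the mortality anchors `q0` and the late-referral
first-year death probability), first-year and prevalence costs, utilities
and the discount rate — is scaled by 1 ± 10 % in turn (utilities capped
at 1; rows rebalanced through the residual-stay rule) and the ICER
recomputed; entries are ranked by the larger absolute percent change. A
perturbation that breaks feasibility flags the entry rather than aborting.
Structural constants (cohort size, horizon, threshold, the uplift
percentages) are never varied.

**Probabilistic analysis**: distribution families by kind — Beta
(probabilities), log-normal (costs), normal (utilities, clamped to
[0, 1]), uniform (discount rate) — moment-matched to mean and
sd = 10 % of mean: Beta `ν = m(1−m)/s² − 1, α = mν, β = (1−m)ν`;
log-normal `σ² = ln(1 + s²/m²), μ = ln m − σ²/2`; uniform bounds
`m ± s·√3` (the source states the family and sd rule but not the bounds).
Parameters with a zero point estimate stay fixed. All parameters are
drawn independently (the paired HD/LRHD prevalence costs included);
within a replicate both scenarios share the identical drawn set, so the
deltas isolate the routing difference. A drawn row whose exits exceed the
survival mass is renormalized to sum to one with zero stay probability.
Intervals are empirical 2.5/97.5 percentiles with linear interpolation.
The sampled discount rate applies to costs and QALYs alike.

**Discount rates and proportion sweep**: the deterministic pipeline is
re-run at 0/3/5 % and, in the sweep, a mixed current situation with late
fraction *p* is compared against full timely referral for each *p* in the
grid; *p* = 1 reproduces the baseline comparison bit-for-bit and *p* = 0
is excluded (ΔE = 0, ICER undefined).

## Productivity-loss extension (optional, default off)

From a societal perspective, each death during cycle *t* at an age below
the 67-year working-age limit forfeits 29,345 € per remaining working
year, accrued annually from the death cycle until age 67 and discounted
like other costs (an annuity-of-lost-years convention; the source states
only the per-death-year value). When enabled, the offset enters the
incremental comparison only, consistent with its exploratory framing.
Morbidity-related productivity losses are out of scope.

## What the synthetic defaults do and do not show

The packaged configuration reproduces every published input verbatim and
fills the unpublished inputs with the documented assumptions above. Test
results on these defaults therefore validate the *machinery* — engine
versus brute-force oracle to 1e-12, closed-form half-cycle discounting to
1e-10, conservation, calibration, distribution moments, ellipse coverage
— and the *qualitative* economics (timely referral gains QALYs at extra
cost, ICER below threshold, robustness to the late-referral proportion).
They do not reproduce the published headline numbers: those depend on the
unpublished transition diagram and registry mortality curve. Our packaged
defaults yield a discounted ICER near 31,500 €/QALY with a narrower PSA
spread than the source reports; the structural findings (one influential
parameter above the 10 % tornado threshold — the HD prevalence cost — and
threshold-independence of the conclusion) coincide.

## Problem sizes

Tests and the acceptance script use the full published scale where it is
cheap (1,000-patient cohort, 45 cycles, 1,000 PSA replicates, 10⁵-draw
moment checks, 10⁴-sample ellipse coverage) and small horizons (5–8
cycles) for the 1,000-configuration random-matrix oracles, which probe
per-cycle algebra rather than long-horizon behaviour.
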