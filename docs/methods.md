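# Methods

## Model structure and assumptions

The model is a discrete-time Markov cohort simulation with three mutually
exclusive states — CAPD, HD, Dead — an annual cycle, a 40-year horizon, and a
cohort entering at age 55 on one of the two dialysis modalities. Dead is
absorbing. Within a cycle, events are ordered **death first, then modality
switch among survivors**: from state *s* in model year *t*,

    P(Dead)  = p_death,s(t)
    P(other) = (1 − p_death,s(t)) · p_switch,s
    P(stay)  = remainder.

This keeps every transition row stochastic without renormalization and reads
the switch inputs as annual probabilities conditional on being alive. Switch
probabilities are constant over time. There is no age-dependent background
mortality beyond the survival curves, no transplantation state, and no
patient-level microsimulation.

### From survival curves to death probabilities

Cumulative survival is observed for years 1–5 per modality. Years 1–5 use the
conditional probabilities `p(1) = 1 − S(1)`, `p(t) = 1 − S(t)/S(t−1)`.
Beyond year 5 the annual death probability is constant; two conventions are
implemented (`ModelSettings.tail_rule`):

* **`mean_hazard` (default)** — the annualized average hazard across the
  observed curve, `p = 1 − (S(5)/S(1))^(1/4)`, i.e. the geometric mean of the
  four year-over-year conditional survival ratios. This is the reconstruction
  the package adopts: it is the only simple constant-tail rule under which the
  HD cohort's discounted life expectancy (6.431 years) and QALYs (4.22) match
  the reference analysis this package re-implements, and it avoids the
  artifact of the final-year rule, where HD's unusually flat year-4→5 segment
  (conditional death 0.047 vs CAPD's 0.088) would dominate 35 extrapolated
  years and *reverse the sign of the QALY difference* between the strategies.
* **`final_year`** — the year-5 conditional probability, the naive reading of
  "constant after year 5"; kept available because the original convention is
  not recoverable. `survival_to_death_probs` uses this as its own default
  (it is the function's documented contract); the engine's `ModelSettings`
  chooses explicitly.

In the PSA, each survival year is drawn from its own Beta distribution and the
curve is then monotonized by a running minimum within each arm before
conversion; the per-year uncertainties are published without a joint model,
and a non-monotone cumulative curve is meaningless.

### Rewards: costs, life-years, QALYs

Rewards are attributed to **end-of-cycle membership**: cycle *t* ≥ 1 rewards
the occupancy after the *t*-th transition, discounted by `(1+r)^−t` with
r = 3%/year for both costs and effects. No half-cycle correction is applied.
Per patient alive in state *s*, a cycle accrues:

* life-years: 1; QALYs: `U_s` (or the complication-blended value, below);
* costs (2020 IDR/year): `DMC_s + DNMC_s + ID_s + p_comp,s·CC_s`, plus the
  set-up charge per `setup_mode`.

**Complications** (peritonitis for CAPD, vascular access for HD) are annual
within-state events, not separate states: they add an expected cost
`p_comp·CC` and do not affect survival. Whether they also blend the utility,
`(1−p)·U_s + p·U_s,com`, is the `blend_complication_utility` switch. The
default is **off**: the reference QALY/LYG ratios (0.745 for CAPD, 0.656 for
HD) bracket the unblended utilities (0.81, 0.65) and are arithmetically
incompatible with blending (whose maximum attainable ratio is 0.710), and
with blending off the HD arm's QALYs reproduce the reference value
essentially exactly. The complication utilities remain first-class inputs and
participate in scenario analysis and PSA when blending is enabled.

**Set-up costs** ("pre-dialysis set-up": catheter placement / vascular
access) have no published timing. Three conventions are implemented
(`setup_mode`): `amortized` (default; charged annually while in the state),
`entry` (once, at model entry), and `entry_and_switch` (at entry and again on
each switch, charged to the switching mass). Amortized is the default because
it is the only convention under which the HD strategy's total cost exceeds
CAPD's, as the reference analysis reports; under the entry-based conventions
the cost difference flips sign (≈ +2 to +6M IDR) because the small switch
flow and near-equal set-up means cannot offset CAPD's higher annual total.

### Known gap: absolute cost totals

With the stated 3% discounting this implementation yields total costs of
≈ IDR 1.029bn (CAPD) and 1.032bn (HD), about 24% below the reference totals
(1.349/1.368bn). The gap is a documented reconstruction limit, not a tuning
target: the reference totals are numerically consistent only with an
*undiscounted* cost stream (which would give 1.326/1.345bn here, within 2%,
with a cost difference of −19.0M vs the reference −19.8M), while the stated
method discounts costs at 3%. The package keeps the stated 3% default and
reports the discrepancy rather than silently switching conventions; users can
set `discount_cost: 0` in the parameter table to reproduce the undiscounted
accumulation. The ICER magnitude inherits this gap (−9.4M IDR/QALY here at
3%). The sign structure — CAPD cheaper and more effective, i.e. the dominant
quadrant and a cost-saving verdict — is reproduced and is asserted
unconditionally in the test suite.

## Parameters and uncertainty

Every input is a mean with standard error, a deterministic range, and a
family: Beta for probabilities/utilities, Gamma for costs, `fixed` for
discount rates. Shapes are recovered by the method of moments

    Beta:  ν = m(1−m)/se² − 1,  α = mν,  β = (1−m)ν      (requires se² < m(1−m))
    Gamma: shape = m²/se²,  scale = se²/m,

so each matched distribution reproduces the printed mean and SE exactly (this
is asserted to 1e−9 for every row). The published "range" column bounds
deterministic scenarios only; PSA draws are never truncated to it. One
published range (HD→CAPD, 0.002–0.001) is reversed and excludes its mean; it
ships verbatim with a load-time warning, and `parameters_corrected.yaml`
offers a symmetric replacement (0.002–0.012). The IDR/USD rate in the config
(14,121) is back-derived for display only and never enters a decision.

PSA draws all quantities independently (no correlation structure is
published); independence and seed-determinism are property-tested. Failed
iterations are skipped rather than resampled so the draw stream stays aligned
with the seed.

## Sensitivity analyses

One-way scenarios perturb a single parameter's mean — ±5%, ±10%, or its range
bounds — and re-run both arms; the table is sorted by |ICER − base ICER|
(tornado order). The default scenario set covers every cost, utility, switch
and complication parameter; single survival years are excluded by default
because perturbing one year alone usually breaks curve monotonicity (explicit
survival scenarios are allowed and are marked `failed` when infeasible).
Perturbed probabilities/utilities are clipped to [0,1] with a logged warning.

The CEAC reports, on a willingness-to-pay grid (default 0–200M IDR/QALY, 41
points), the fraction of PSA draws with strictly positive net monetary
benefit; an exact zero counts as not cost-effective (a measure-zero
tie-break, fixed for determinism). Verdicts use the 1×/3× GDP-per-capita
thresholds (54.6M/163.8M IDR per QALY) with inclusive boundaries.

## EQ-5D-3L scoring and parameter derivation

Utilities come from five-digit EQ-5D-3L states scored with an additive value
set: anchor 1.0 minus per-dimension level decrements, with optional constant
and any-level-3 terms. The actual Thai tariff coefficients are not
redistributed here; the tariff is a pluggable YAML config, and the shipped
`tariff_toy.yaml` is a clearly labelled synthetic stand-in (uniform
decrements 0.10/0.30) used by tests and the generator. Costs recorded
monthly are annualized by ×12; older records are inflated by a CPI ratio
(shipped index is identity — inputs are already 2020 IDR). Per-arm summaries
use SE = sample SD/√n; complication costs are averaged among patients with an
event. Summary keys equal the model's parameter names, so a derived table
feeds the model directly.

## Synthetic cohort generator

The generator emulates the closed billing/interview dataset: 28 CAPD and 92
HD patients; Gamma-distributed cost components; Bernoulli complications
(0.200/0.100); EQ-5D-3L responses from a per-dimension level mixture whose
toy-tariff mean equals the target utilities (0.81/0.65) by construction.
Patient-level dispersions are not published and are back-solved as
SD = SE·√n with the study arm sizes (expected case counts for complication
costs) — an explicit assumption. Because the published means are the sample
statistics of that specific dataset, the generator by default also calibrates
each cost component multiplicatively so the generated sample mean equals the
target exactly, and fixes complication counts at their expectation
(`calibrate_means=False` restores plain sampling).

What the generator does **not** emulate: correlations between cost components
within a patient, regional tariff variation, longitudinal dialysis session
logs, or informative missingness. Passing recovery tests therefore show that
the derivation stage is unbiased and the pipeline closes — not that the model
is robust to those real-data features.

## Numerical choices and problem sizes

* Engine verification: exhaustive path enumeration at horizon 3 (all 3³
  state paths, 20 random parameter draws, agreement to 1e−9), plus
  conservation/absorption invariants at horizon 40.
* PSA: 1000 iterations in tests and the acceptance script (matching the
  reference analysis's iteration count); ~1–2 s on one CPU.
* Recovery tests: the study-sized cohort (28/92) against 3×SE bands, and
  5,000 per arm against 2% relative error.
* Degenerate inputs: `fixed` families pass means through; a fully `fixed`
  table makes PSA collapse to the base case exactly; zero-SD cost components
  generate identical records.

## Limitations

Beyond the cost-total gap above: the extrapolated tail hazard is a strong
assumption (half the horizon is extrapolation); utilities are treated as
time-constant; complications carry no mortality; and the two arms' survival
inputs come from different sources, so their small differences — which drive
the life-year results — are not a controlled comparison.
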