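# renalcea

Cost-utility modelling of dialysis modalities for end-stage renal disease
(ESRD) in Indonesia: continuous ambulatory peritoneal dialysis (CAPD) versus
hospital-based hemodialysis (HD), from a societal perspective.

The package is aimed at health-economics analysts who want a transparent,
tested re-implementation of the three-state Markov cohort model behind the
"CAPD-first" policy discussion — including the parameter-derivation stage
(EQ-5D-3L tariff scoring, cost annualization, per-arm summarization), the
cohort engine, incremental cost-effectiveness statistics, and deterministic
plus probabilistic sensitivity analysis. Because the underlying hospital
billing and interview data are closed, a synthetic-cohort generator emulates
their statistical structure so the whole pipeline runs end to end.

## The model

A cohort of 55-year-old ESRD patients starts on one modality and moves
between three mutually exclusive states — CAPD, HD, Dead — over 40 annual
cycles. Within a cycle death occurs first, then surviving patients may switch
modality with constant annual probabilities (CAPD→HD 0.067, HD→CAPD 0.007).
Annual death probabilities come from published cumulative five-year survival
curves, converted to conditional probabilities

    p(1) = 1 − S(1),   p(t) = 1 − S(t)/S(t−1)   for t = 2..5,

and held constant afterwards at the annualized average hazard over the
observed years, `1 − (S(5)/S(1))^(1/4)` (see `docs/methods.md` for why, and
for the alternative final-year convention).

Each cycle accrues, per patient alive in state *s*: life-years, utility
`U_s` (EQ-5D-3L, Thai-type tariff), and societal costs — direct medical,
direct non-medical, indirect, plus the expected complication cost
`p_comp,s · CC_s` (peritonitis for CAPD, vascular access for HD) and an
amortized pre-dialysis set-up cost. Costs and effects are discounted at 3%
per year. The two starting strategies are compared by

    ICER = ΔCost / ΔQALY,    NMB(λ) = λ·ΔQALY − ΔCost,

judged against a willingness-to-pay of 1–3× GDP per capita
(IDR 54.6M/QALY). Parameter uncertainty uses method-of-moments Beta
(probabilities, utilities) and Gamma (costs) distributions matched to each
input's mean and standard error; the probabilistic sensitivity analysis
(1000 Monte-Carlo iterations) yields a cost-effectiveness plane and
acceptability curve (CEAC).

## Worked example

```
$ renalcea run --out-dir out
Base case (discounted totals per patient, 2020 IDR)
                                      CAPD                HD
Total cost                   1,028,863,967     1,032,498,962
Life-years gained                    6.118             6.431
QALY                                  4.60              4.22

Incremental cost (CAPD - HD):  (3,634,994) IDR  (USD -257; display only)
Incremental QALY:              0.386
ICER:                          savings of 9,424,690 IDR/QALY
CE-plane quadrant:             dominant
Verdict at 1-3x GDP/capita (54,600,000 - 163,800,000 IDR/QALY): cost-saving
NMB at 1x GDP: 24,693,584 IDR; at 3x GDP: 66,810,764 IDR
```

Reading: over 40 years a CAPD-first patient costs IDR 1.029 billion and
gains 4.60 QALYs; an HD-first patient costs slightly more (IDR 1.032
billion) for fewer QALYs (4.22), because HD's small survival advantage is
outweighed by its lower quality-of-life weight (0.65 vs 0.81) and higher
transport/productivity costs. CAPD is therefore *dominant*: cheaper and more
effective, saving about IDR 9.4M per QALY gained. Negative monetary amounts
are shown in parentheses.

Other subcommands: `renalcea psa` (CE plane, CEAC, plots), `renalcea dsa`
(one-way scenario table in tornado order), `renalcea simulate` (synthetic
patient cohort), `renalcea derive` (patient records → parameter config).
All runs write a `manifest.json` with config hashes and seeds sufficient to
re-execute them exactly.

Inputs live in small YAML files: see
`src/renalcea/data/parameters_default.yaml` (every model input with its
mean, SE, scenario range and distribution family) and
`parameters_corrected.yaml` (same, with one typographical range fixed).
Point `--params` at a copy to run your own table.

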