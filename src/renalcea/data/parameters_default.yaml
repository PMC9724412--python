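# Default model inputs: annual switch and complication probabilities,
# cumulative survival (years 1-5) per modality, 2020-IDR annual cost
# components, EQ-5D-3L utilities, and discount rates.
# mean/se define the PSA distribution (method of moments); range bounds the
# deterministic scenario analysis only.
#
# Note: the HD->CAPD range is reproduced verbatim from the source table and is
# reversed (0.002-0.001, excluding the mean); loading warns about it.  See
# parameters_corrected.yaml for a usable symmetric range.
parameters:
  p_capd_to_hd:   {mean: 0.067, se: 0.020, family: beta, range: [0.058, 0.081]}
  p_hd_to_capd:   {mean: 0.007, se: 0.002, family: beta, range: [0.002, 0.001]}
  p_peritonitis:  {mean: 0.200, se: 0.010, family: beta, range: [0.180, 0.220]}
  p_vascular:     {mean: 0.100, se: 0.013, family: beta, range: [0.075, 0.125]}

  surv_capd_1: {mean: 0.800, se: 0.006, family: beta, range: [0.788, 0.812]}
  surv_capd_2: {mean: 0.720, se: 0.008, family: beta, range: [0.704, 0.736]}
  surv_capd_3: {mean: 0.600, se: 0.009, family: beta, range: [0.582, 0.617]}
  surv_capd_4: {mean: 0.570, se: 0.009, family: beta, range: [0.542, 0.577]}
  surv_capd_5: {mean: 0.520, se: 0.009, family: beta, range: [0.502, 0.537]}

  surv_hd_1: {mean: 0.824, se: 0.006, family: beta, range: [0.811, 0.837]}
  surv_hd_2: {mean: 0.706, se: 0.008, family: beta, range: [0.690, 0.722]}
  surv_hd_3: {mean: 0.621, se: 0.009, family: beta, range: [0.604, 0.638]}
  surv_hd_4: {mean: 0.580, se: 0.009, family: beta, range: [0.563, 0.598]}
  surv_hd_5: {mean: 0.553, se: 0.009, family: beta, range: [0.536, 0.571]}

  # one-time pre-dialysis set-up (catheter / vascular access placement)
  setup_capd: {mean: 16010564, se: 165562,  family: gamma, range: [15686062, 16335065]}
  setup_hd:   {mean: 16150823, se: 2337311, family: gamma, range: [11569693, 20731952]}
  # annual direct medical costs
  dmc_capd: {mean: 142328780, se: 6008598, family: gamma, range: [135173358, 149484201]}
  dmc_hd:   {mean: 120289134, se: 3650725, family: gamma, range: [108512280, 132065987]}
  # annual complication episode cost (peritonitis / vascular access)
  cc_capd: {mean: 9592093,  se: 4178178, family: gamma, range: [1402864, 17781321]}
  cc_hd:   {mean: 27173929, se: 7158016, family: gamma, range: [13144217, 41203640]}
  # annual direct non-medical costs (transport, lodging, caregiving)
  dnmc_capd: {mean: 5266455,  se: 1353606, family: gamma, range: [2613387, 7919522]}
  dnmc_hd:   {mean: 10083572, se: 950959,  family: gamma, range: [8219690, 11947453]}
  # annual indirect (productivity-loss) costs
  id_capd: {mean: 7196578,  se: 1535788, family: gamma, range: [4186434, 10206722]}
  id_hd:   {mean: 10858993, se: 968098,  family: gamma, range: [8961519, 12756466]}

  u_capd:     {mean: 0.81, se: 0.04, family: beta, range: [0.73, 0.88]}
  u_hd:       {mean: 0.65, se: 0.03, family: beta, range: [0.60, 0.71]}
  u_capd_com: {mean: 0.31, se: 0.09, family: beta, range: [0.13, 0.39]}
  u_hd_com:   {mean: 0.37, se: 0.11, family: beta, range: [0.15, 0.58]}

  discount_cost:   {mean: 0.03, family: fixed}
  discount_effect: {mean: 0.03, family: fixed}

settings:
  horizon_years: 40
  start_age: 55
  gdp_per_capita: 54600000        # 2020 IDR per capita, willingness-to-pay anchor
  exchange_rate_idr_per_usd: 14121  # back-derived, display only; not a published rate
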