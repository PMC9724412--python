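# SYNTHETIC toy EQ-5D-3L tariff for tests and examples.
# This is NOT a published value set: real analyses must supply the
# coefficients of a country tariff (the study scored with the Thai 3L set).
# Purely additive: utility = 1 - sum of per-dimension level decrements.
anchor: 1.0
constant: 0.0
any_level3: 0.0
decrements:
  mobility:           {2: 0.10, 3: 0.30}
  self_care:          {2: 0.10, 3: 0.30}
  usual_activities:   {2: 0.10, 3: 0.30}
  pain_discomfort:    {2: 0.10, 3: 0.30}
  anxiety_depression: {2: 0.10, 3: 0.30}
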