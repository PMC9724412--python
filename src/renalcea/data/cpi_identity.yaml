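# Default price index: identity (all inputs already at 2020 price level).
# Replace with actual CPI values to inflate older cost data.
2014: 1.0
2015: 1.0
2016: 1.0
2017: 1.0
2018: 1.0
2019: 1.0
2020: 1.0
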