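# Canonical gestational eGFR parameter set (version 1).
# bsc: baseline serum creatinine, umol/L, median of the pre-implantation (GW 0-3) interval.
# normal_gfr: absolute normal GFR, mL/min (110.1 mL/min/1.73 m2 de-indexed by BSA 1.62 m2).
# median_curve: ascending-power polynomial giving the median SCr (umol/L) per GW on [4, 41].
version: 1
bsc: 55.25
normal_gfr: 103.1
median_curve:
  coefficients: [56.7, -0.223, -0.113, 0.00545, -0.0000653]
  domain: [4, 41]
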