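# Illustrative photocycle rate sets at 290 and 250 K.
#
# NOT a transcription of any measured rate table. The 290 K intramolecular
# rate k_DA = 1e6 s^-1 is the measured His83 value; k_DA at 250 K is scaled
# down by the squared-coupling factor 1.88 (a less-than-2-fold decrease, the
# regime indicated by the pathway analysis), and the quenching rate is chosen
# an order of magnitude above k_DA so that excited-state quenching dominates.
# In this regime the steady-state charge-accumulation ratio 290/250 evaluates
# to ~1.8, the magnitude of the observed cross-temperature yield ratio.
#
# Run:  spinpath kinetics --config examples/kinetics_290_250.yaml --out out
kinetics:
  reference_temperature: 250.0
  rates:
    - temperature: 290.0
      k_exc: 1.0e+3
      k_DA: 1.0e+6
      k_AAg: 1.0e+7
      k_refill: 1.0e+8
      k_quench: 1.0e+7
    - temperature: 250.0
      k_exc: 1.0e+3
      k_DA: 5.319e+5   # = 1e6 / 1.88 (squared-coupling scaling)
      k_AAg: 1.0e+7
      k_refill: 1.0e+8
      k_quench: 1.0e+7
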