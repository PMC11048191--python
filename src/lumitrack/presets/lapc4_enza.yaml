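# LAPC4 + DHT + enzalutamide 10 uM: increased fraction drops to 35.4%,
# i.e. 64.6% responders.  Complete-shutdown weight is a package choice
# (no printed sub-fraction for this condition).
label: "LAPC4 DHT+Enza"
cell_line: LAPC4
treatment: "DHT 1 nM + Enza 10 uM"
population:
  n_cells: 2000
  mixture:
    p_responder: 0.646
    p_deep_given_responder: 0.30
  mobility:
    p_lost: 0.10
    p_displaced: 0.05
    jitter_sd: 2.0
    match_radius: 15.0
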