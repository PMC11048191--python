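# LAPC4 + DHT (1 nM agonist only), ECM-overlay mobility.
# Planted mixture: 91.2% non-responders (increased) / 8.8% responders.
label: "LAPC4 DHT"
cell_line: LAPC4
treatment: "DHT 1 nM"
population:
  n_cells: 2000
  mixture:
    p_responder: 0.088
    p_deep_given_responder: 0.0
  mobility:
    p_lost: 0.10
    p_displaced: 0.05
    jitter_sd: 2.0
    match_radius: 15.0
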