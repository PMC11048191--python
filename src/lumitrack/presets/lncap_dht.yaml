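# LNCaP + DHT (1 nM agonist only), ECM-overlay mobility.
# Planted mixture: 22.3% responders (decreased) / 77.7% non-responders.
label: "LNCaP DHT"
cell_line: LNCaP
treatment: "DHT 1 nM"
population:
  n_cells: 2000
  mixture:
    p_responder: 0.223
    p_deep_given_responder: 0.0
  mobility:
    p_lost: 0.10
    p_displaced: 0.05
    jitter_sd: 2.0
    match_radius: 15.0
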