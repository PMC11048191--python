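# LNCaP + DHT + enzalutamide 10 uM, ECM-overlay mobility.
# Planted mixture: 84.7% responders (decreased), of whom 48.7% shut the
# reporter off completely (no detectable signal at t1).
label: "LNCaP DHT+Enza"
cell_line: LNCaP
treatment: "DHT 1 nM + Enza 10 uM"
population:
  n_cells: 2000
  mixture:
    p_responder: 0.847
    p_deep_given_responder: 0.487
  mobility:
    p_lost: 0.10
    p_displaced: 0.05
    jitter_sd: 2.0
    match_radius: 15.0
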