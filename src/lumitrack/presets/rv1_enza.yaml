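# 22Rv1 + DHT + enzalutamide 10 uM: antiandrogen-resistant line; no
# significant bulk response, so a small responder fraction is planted.
# The 25% value is a package choice — no per-cell fraction is printed
# for this condition.
label: "22Rv1 DHT+Enza"
cell_line: 22Rv1
treatment: "DHT 1 nM + Enza 10 uM"
population:
  n_cells: 2000
  mixture:
    p_responder: 0.25
    p_deep_given_responder: 0.10
  mobility:
    p_lost: 0.10
    p_displaced: 0.05
    jitter_sd: 2.0
    match_radius: 15.0
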