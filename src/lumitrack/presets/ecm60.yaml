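# 10 uL overlay of 60% high-concentration Matrigel: retained fraction
# 0.63064 = 0.27419 * 2.3, i.e. 2.3-fold the no-overlay baseline.
label: "60% ECM-M HC overlay"
cell_line: LNCaP-GFP
treatment: "DHT 1 nM"
population:
  n_cells: 2000
  mixture:
    p_responder: 0.223
    p_deep_given_responder: 0.0
  mobility:
    p_lost: 0.25
    p_displaced: 0.11936
    jitter_sd: 2.0
    match_radius: 15.0
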