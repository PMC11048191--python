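# 10 uL overlay of 40% high-concentration Matrigel: cells largely
# immobilised between the two sessions (retained fraction 0.85),
# 3.1-fold the no-overlay baseline.
label: "40% ECM-M HC overlay"
cell_line: LNCaP-GFP
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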