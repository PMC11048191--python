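# Classical 2D culture, no Matrigel overlay: the media change between the
# two imaging sessions washes away or moves most poorly adherent cells.
# Retained fraction 0.27419 = 0.85 / 3.1, i.e. the 40% ECM overlay tracks
# 3.1-fold more cells than this baseline.
label: "2D no overlay"
cell_line: LNCaP-GFP
treatment: "DHT 1 nM"
population:
  n_cells: 2000
  mixture:
    p_responder: 0.223
    p_deep_given_responder: 0.0
  mobility:
    p_lost: 0.55
    p_displaced: 0.17581
    jitter_sd: 2.0
    match_radius: 15.0
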