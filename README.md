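# lumitrack

Single-cell bioluminescence microscopy analysis for androgen-receptor (AR)
activity biosensors in prostate cancer cells — plus a synthetic image
generator that plants per-cell ground truth so the whole pipeline can be
validated without any real microscopy data.

## The problem

AR-responsive luciferase reporters make the drug response of individual
prostate cancer cells visible: a cell that responds to an antiandrogen
(enzalutamide, apalutamide, darolutamide, bicalutamide) dims between a
baseline image and a second image taken 48 h after treatment, while a
non-responsive cell keeps or increases its signal.  Measuring this
cell-by-cell requires (i) finding the same cell in both imaging sessions —
hard for poorly adherent cells unless they are immobilised under a diluted
Matrigel (ECM-M) overlay — and (ii) deciding when "dimmer" actually means
"no detectable signal" rather than noise.

`lumitrack` implements the full analysis chain:

- **simgen** — ground-truth populations (positions, between-session fates,
  responder/non-responder mixtures with multiplicative treatment effects on
  the photon rate) rendered into paired 16-bit EM-CCD images
  (disc ⊗ Gaussian PSF, Poisson shot noise × gain, Gaussian read noise);
- **quantify** — detection of point-like cells and aperture photometry
  ("sum gray intensity per cell"), with a limit of detection
  LOD = k·σ_bg·√A for an aperture of A pixels;
- **trackcells** — one-to-one coordinate matching between the two sessions
  (max-cardinality, min-total-distance assignment within a match radius)
  and the operational tallies: tracked, displaced = n_t0 − tracked,
  lost = max(n_t0 − n_t1, 0);
- **response** — per-cell classification (increased iff I_t1 > I_t0, gated
  by the LOD gray zone), population heterogeneity summaries, bulk AR
  activity relative to the DHT-only control, Mann–Whitney / Wilcoxon
  comparisons with significance stars;
- **doseresponse** — viability normalisation, four-parameter logistic
  fitting r(d) = bottom + (top − bottom)/(1 + (d/IC50)^hill), and the
  Spearman correlation between IC50 and the non-responder fraction;
- **cli** — `lumitrack simulate|detect|track|classify|summarize|stats|fit4pl|run`.

Bundled presets (`lumitrack.list_presets()`) encode the study conditions:
`lncap_dht`, `lncap_enza`, `lncap_apa`, `lncap_daro`, `lapc4_dht`,
`lapc4_enza`, `rv1_enza` for the response mixtures, and `no_ecm`, `ecm40`,
`ecm60` for the overlay mobility contrast.

## Worked example

```python
from lumitrack.pipeline import run_condition

res = run_condition("lncap_enza", seed=42, n_cells=400,
                    population_overrides={"field_size": [1900, 1900]})
s, c = res.summary, res.counts
print(f"cells detected t0/t1 : {c.n_t0} / {c.n_t1}")
print(f"tracked / displaced / lost : {c.tracked} / {c.displaced} / {c.lost}")
print(f"limit of detection   : {res.lod.value:.0f} counts")
print(f"decreased            : {s.n_decreased} ({100*s.frac_decreased:.1f}%)")
print(f"no signal among decreased : {s.n_no_signal} "
      f"({100*s.frac_no_signal_among_decreased:.1f}%)")
```

prints

```
cells detected t0/t1 : 400 / 360
tracked / displaced / lost : 344 / 56 / 40
limit of detection   : 417 counts
decreased            : 295 (85.8%)
no signal among decreased : 142 (48.1%)
```

Reading: 400 cells were seeded and imaged under the enzalutamide preset,
whose planted truth makes 84.7% of cells responders and lets 10% be washed
away and 5% re-attach elsewhere between sessions.  344 cells were tracked
(found at the same coordinates in both images); of those, 85.8% dimmed
after treatment — recovering the planted responder fraction within its
binomial sampling error — and 48.1% of the dimmed cells fell below the
417-count limit of detection, i.e. lost all detectable reporter signal.

The same run from the shell:

```sh
lumitrack run --config cfg.yaml --out out/   # cfg.yaml: preset/seed/n_cells
```

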