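# Methods

This note records the models, parameter choices and numerical decisions
behind `lumitrack`, in the spirit of a package methods appendix.  Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Simulation model

**Population.**  A well contains `n_cells` (default 2000) point-like cells
placed uniformly at random on a `field_size` (default 4096 × 4096 px)
field, subject to a hard minimum separation (20 px) enforced by
grid-accelerated rejection sampling, and a placement margin (30 px) that
keeps every photometric aperture and background annulus inside the frame.
The pixel grid is 0-based, origin top-left, x rightward, y downward;
centroids are fractional.  The field of view and pixel scale of the real
instrument are not published, so the geometry is chosen for statistical
convenience: large enough that chance coincidences between unrelated cells
at the 15 px match radius are rare (see *Tracking*, below), small enough
that a full two-channel, two-timepoint condition simulates in ~20 s.

**Reporter rates.**  Baseline luminescence photon rates per exposure are
log-normal, ln rate ~ N(9.9, 0.5²) (median ≈ 2.0 × 10⁴ counts), spanning
roughly an order of magnitude across cells as single-cell reporter levels
do.  A constitutive GFP rate, ln rate ~ N(10.3, 0.3²), is carried per cell
and does not change with treatment.

**Treatment effect.**  Each cell is independently a *responder* with
probability `p_responder`, else a non-responder.  The post-treatment rate
is `rate_t0 · exp(logFC)`:

| class | logFC distribution | meaning |
|---|---|---|
| non-responder | N(+0.8, 0.25²) | signal maintained/increased (fold ≈ 2.2) |
| responder, moderate | N(−1.6, 0.3²) | suppressed ~5-fold, still detectable |
| responder, deep | N(−9.2, 0.5²) | complete shutdown, below the LOD |

A fraction `p_deep_given_responder` of responders draw from the deep
component; that weight is what plants the "no detectable signal" share.
The component means are placed so that, at the default optics, the strict
increase/decrease decision and the LOD gate misclassify a negligible
fraction of cells (the nearest 3σ tails clear the decision boundaries);
recovery of planted mixtures across p = 0.1…0.9 is verified in the tests.

**Between-session mobility.**  Fates are i.i.d. categorical:
`lost` (absent at t1), `displaced` (re-drawn uniformly, rejected within the
match radius of the origin, hence untrackable by construction), `retained`
(isotropic Gaussian jitter, sd 2 px, truncated at the match radius).
Response class is independent of fate, so the tracked subpopulation is an
unbiased sample of the mixture — a property tested by chi-square across
seeds.

**Camera.**  Each present cell stamps a uniform disc (radius 3 px,
sub-pixel accurate via 4× supersampling, integrated value = photon rate)
which is convolved with a Gaussian PSF (σ = 1.5 px).  The observed image is
`round(em_gain · Poisson(signal + bg/em_gain) + N(0, read_noise²))`,
clipped to [0, 65535].  Defaults: background 100 counts, read noise 3
counts, em_gain 1 (the EM excess-noise factor is folded into the read-noise
term rather than modelled as a gain cascade — one fewer parameter, adequate
for testing detection and classification).  Exposure (20 s) and substrate
concentration are metadata only.  A `noise=False` render returns the exact
expectation, used by the inverse-consistency tests (flux conservation to
<0.5%, limited only by PSF truncation).

**Presets.**  The named scenarios plant the printed study conditions as
ground truth: LNCaP responder fractions 0.223 (DHT), 0.847 (+Enza, with
deep weight 0.487), 0.902 (+Apa), 0.927 (+Daro); LAPC4 0.088 (DHT) and
0.646 (+Enza); and mobility presets with retained fractions 0.85 (40%
overlay), 0.631 (60%), 0.274 (none) — ratios of exactly 3.1 and 2.3.
Where a sub-fraction is not printed (deep weight for Apa/Daro and LAPC4,
the 22Rv1 mixture), the nearest printed condition's value or a stated
package choice is used, flagged in the preset file comments.  The
no-overlay lost/displaced split (0.55/0.176) is itself unprinted; it leans
towards "lost" because the media exchange washes poorly adherent cells out,
and because displaced cells landing by chance within the match radius of a
vacated position inflate the apparent tracked count (see *Tracking*).

**Substrate kinetics.**  `simulate_timecourse` models the per-cell signal
after substrate addition as rate·exp(−k·(t − t₀)) sampled every 10 min
from 30 to 230 min, with the camera noise aggregated over a photometric
aperture.  The null (k = 0) calibrates the paired Wilcoxon stability test:
its type-I error at α = 0.05 is verified at 5% ± 1.5% over 1000
simulations of 25 cells.

## Analysis pipeline

**Background estimation.**  Per-pixel background mean = image median;
sd = root-mean-square of deviations *below* the median (exactly unbiased
for symmetric noise, immune to the bright tail, and free of the integer
quantisation that pure quantile spreads suffer on count data).

**Detection and photometry.**  Cells are local maxima of the
Gaussian-smoothed image (σ = PSF σ) above mean + 5σ_bg, separated by ≥ 8 px
(the brighter peak wins a conflict — a known limit at high density).
Centroids are refined by the intensity-weighted mean inside the aperture.
Intensity is the aperture sum (radius = 3σ_PSF + cell radius = 7.5 px,
capturing >99% of the blurred disc) minus area × local background, where
the local background is a 3σ-clipped mean of a 10–25 px annulus.  The
clipped mean (not the median) matters: the background estimate enters the
result multiplied by the aperture area (177 px), so the median's ~π/2
efficiency loss inflates blank-aperture noise enough to break the LOD
budget below.  No segmentation is attempted; the fields are sparse
point-like sources for which fixed-aperture photometry is simpler, linear
(verified to 1%) and robust.

**Limit of detection.**  LOD = k·σ_bg·√A with k = 3 (configurable) and A
the aperture area — the k-sigma level of summed background noise; no mean
term appears because intensities are background-subtracted.  The measured
blank-aperture exceedance is ~0.3%, within the Gaussian-tail budget once
the annulus estimator noise is controlled as above.

**Tracking.**  Detection and tracking run on the GFP channel — which does
not vanish when the reporter shuts down — and luminescence is measured at
the matched GFP centroids; this mirrors locating reporter-dark cells by
complementary imaging and keeps the tracked set unbiased by response.
"Same coordinates" is one-to-one matching within 15 px.  The default
matcher maximises the number of within-radius pairs and then minimises the
total distance (rectangular assignment; ties broken by the deterministic
solver and input sorting); a single-pass mutual-nearest-neighbour variant
is available.  On sparse fields the two coincide; the assignment form is
order-independent and is validated against an exhaustive enumeration
oracle on 500 random small instances.  Chance coincidences — a displaced
cell landing within 15 px of a vacated coordinate — inflate tracked counts
by ~1–3% at the default density and are the main residual bias in the
overlay-fold contrast (measured mean ≈ 3.0 vs planted 3.1).

**Classification.**  Increased iff I_t1 > I_t0, strict; exact ties
(possible on integer counts) count as decreased — the conservative call
for an inhibition assay.  Cells below the LOD at both timepoints never
left the gray zone and are excluded from fractions (but retained in
output); below-LOD only at t1 is the "no detectable signal" phenotype;
below at t0 but above at t1 is increased.  Fractions are over classifiable
tracked cells.  Classification is invariant under joint rescaling of
intensities and LOD (property-tested).

**Bulk activity.**  Per condition, above-LOD ("positive") intensities are
summed per replicate well, averaged across wells, and expressed as % of
the reference (DHT-only) condition, which is 100 by construction.

**Statistics.**  Mann–Whitney for unpaired and Wilcoxon signed-rank for
paired comparisons, two-sided; stars at p ≤ 0.05/0.01/0.001/0.0001, "ns"
above.  No multiple-testing correction is applied by default, matching the
assay's reporting conventions.

**Dose–response.**  4PL on log₁₀ dose, bounded least squares
(bottom ≥ 0, span ≥ 0, hill free in sign) with multi-start over midpoint
quartiles × slope signs; convergence is reported honestly and a fit whose
midpoint falls outside the dosed range or whose span is not resolvable
against the residual scale is flagged unidentifiable (IC50 then only
bounds the truth — the resistant-profile case).  IC50 SE comes from the
Jacobian at the optimum.  Noise-free self-consistency is exact to 1e-6 and
the fit is dose-scale equivariant; no attempt is made to reproduce the
live-cell IC50 values themselves, which are not recomputable from any
deposited data.  The IC50 ↔ non-responder-fraction association uses
Spearman rank correlation, with the p-value suppressed below n = 5 lines.

## Problem sizes used in validation

Planted-fraction recovery runs at the full 2000 cells/well on the default
field (one run per condition; the overlay-fold contrast averages 10 paired
seeds).  Sweeps that repeat the pipeline many times (mixture grid,
monotonicity of tracking in mobility, type-I calibration) run at reduced
sizes — 300–400 cells on proportionally smaller fields, or detection-free
truth tracking — chosen so each sweep completes in about a minute while
binomial tolerances remain meaningful.

## What passing tests do and do not show

The generator plants exactly the effects the pipeline is designed to
measure: multiplicative reporter changes on well-separated, disc-shaped
cells with stationary background and independent fates.  Recovery of the
planted fractions therefore validates the *pipeline logic* — detection,
photometry linearity, LOD gating, tracking accounting, classification
arithmetic — not the biology or the instrument.  Real fields add
morphology, focus drift, uneven illumination, overlapping and dividing
cells, and ECM autofluorescence, none of which are modelled; conclusions
about real cells require the real assay.  Known limitations: merged peaks
closer than the minimum separation keep only the brighter cell; the lost
vs displaced split of untracked cells is identifiable only through the
second image's total count; and the simulator treats "lost" as absent
without distinguishing washed-away from dead cells.
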