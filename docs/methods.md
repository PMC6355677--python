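# Methods

## Overview

phenovol implements a pixel-count phenotyping pipeline for pot experiments:
RGB segmentation → digital biovolume (DB) → gravimetric water budget →
water-use efficiency (WUE) → ranking statistics.  Because raw greenhouse
imagery for the motivating trials is not publicly deposited, the package
ships a first-class synthetic-experiment generator whose ground truth
(projected areas, per-interval evaporation and transpiration, fresh weights,
pixel-exact masks) exercises every stage end to end.

## Digital biovolume

DB = s₀ + s₉₀ + log(s_top / d).  The published form of the index is
typographically ambiguous about the grouping of the top-view term; we
implement the literal reading log(top-sum ÷ divisor) with divisor d = 3 and
the natural log by default, both configurable (`DBConfig`).  Numerically the
log term is O(10) against side sums of O(10⁵), so the choice of base or
divisor cannot change any downstream ranking; we verified the formula itself
against a 50-digit decimal evaluation (max relative error 0 at double
precision, `scripts/acceptance.py`).  A top count of zero (pre-emergence)
omits the log term by default to keep early series finite; a strict mode
errors instead.

DBR is computed on cell means (treated mean / control mean per genotype per
day), not on paired replicates: the designs carry no replicate pairing.

## Segmentation

The original platform's foreground definition is proprietary; we use the
standard greenhouse-RGB baseline: excess green ExG = 2G − R − B (computed in
int16, no overflow), thresholded by Otsu's method or a fixed value, then a
morphological opening (3×3 cross, radius 1) and removal of connected
components below 25 px.  All surviving components are kept, not only the
largest — cereal canopies fragment into disconnected tillers in side view.

Otsu's threshold is floored at 0 in the default mode: the ExG index is
signed and a pixel with ExG ≤ 0 is not vegetation by the index's own
definition, whereas unconstrained Otsu drifts into the background cluster
when the plant covers a tiny fraction of the frame (early growth, top views).
The floor is a parameter (`SegmentationParams.otsu_floor`).

## Water budget

Losses are booked between consecutive weighings — loss_i = post-irrigation
weight at interval start minus pre-irrigation weight at interval end — which
conserves mass under partial refills (an alternative fixed-field-capacity
reference does not).  Negative losses (scale noise, condensation) are clipped
to zero and flagged, never propagated.  Bare-pot interval means give the
evaporation baseline; `cumulative_transpiration` supports both
`subtract_evap` (Tr_i = max(loss_i − evap_i, 0)) and `evapotranspiration`
(raw losses) because trials without bare pots can only report the latter.
The default is chosen automatically: subtract when bare pots exist, whole-pot
evapotranspiration otherwise.

WUE = (DB_tn − DB_t0)/ΣTr in pixels per gram; no absolute-biomass conversion
is applied.  t₀ defaults to the stress-imposition day and snaps forward to
the first imaging day at or after it (the wheat design images odd days while
stress starts on day 104).  WUE may legitimately be negative when biovolume
shrinks under late drought and is reported as-is; consequently the WUE ratio
is only guaranteed positive in the moderate-stress regime the published
0.52–1.32 range describes.  The class boundary ratio = 1 is assigned to
green (closed on the green side).

## Statistics

Two-way fixed-effects ANOVA is computed per imaging day (one model per day,
no repeated-measures structure) from the closed-form balanced decomposition;
unbalanced or singleton cells are rejected by contract, which also removes
the Type I/II/III sums-of-squares ambiguity.  The implementation is verified
in the tests against both an explicit mean-based recomputation and
statsmodels `anova_lm`.

Duncan's new multiple range test uses studentized-range quantiles at the
protection level (1 − α)^(p−1) for a stretch of p ordered means,
R_p = q·√(MSE/n); unequal n falls back to the harmonic mean and is flagged.
Letters are assigned to maximal homogeneous stretches of the descending
means (the widest non-significant span is never subdivided), which makes
letter groups contiguous by construction.  Quantiles come from
`scipy.stats.studentized_range` rather than printed tables.

`linear_fit` is ordinary least squares (scipy) with r² the squared Pearson
correlation; p-values are kept at full precision, with "p < 0.001"-style
formatting left to report rendering.

## Synthetic experiments

**Growth.**  Projected area follows a logistic K/(1 + e^(−r(t − t_mid))).
Stress at day s multiplies both K and r by a treatment factor f ∈ (0, 1],
continuing the logistic ODE dA/dt = rf·A(1 − A/(Kf)) from the stress-day
area, so the series is continuous at the changeover and — because the ODE
right-hand side rf·A − (r/K)A² is increasing in f — a smaller factor can
never produce a larger area (verified against independent `solve_ivp`
integration).  A plant already above the reduced asymptote Kf declines
toward it, reproducing the growth-then-decline shape of real drought
trajectories.

**Noise.**  Observation noise is multiplicative lognormal with coefficient of
variation `cv_noise` (default 0.05; 0 in oracle tests).  The noise stream is
keyed by (genotype, replicate, day) and shared across treatments — common
random numbers — so a drought plant and its control twin are *identical*
before stress imposition and every treatment contrast reflects the treatment
alone.  This mirrors the counterfactual reading of a treatment effect and
makes the pre-stress null exact rather than approximate.  Weight records
optionally carry additive Gaussian measurement noise (grams); ground truth
is stored exactly in either case.

**Water.**  Per interval, true loss = evap_rate·Δt + transp_coeff·mean
area·Δt (defaults 5 g/day and 3×10⁻⁴ g/px/day, giving realistic 30–100 g/day
pot losses); each weighing restores the pot to target · field-capacity
weight, by withholding only (never draining).  A dry-soil floor at 0.4·FC
truncates unphysical losses and flags the interval.  Fresh-weight truth is
c_fw·area (10⁻³ g/px) with its own small lognormal scatter (cv 0.03), which
yields the tight linear DB–fresh-weight relation by construction.

**Rendering.**  Masks for areas ≥ 25 px are built as unions of 3×3 cross
stamps grown by upward-biased random-walk strokes: such unions are exactly
invariant under the default morphological opening, so in clean mode the
segmenter recovers the requested pixel count *exactly*; areas below the
min-component cutoff use a compact raster block (they are filtered by the
analysis by design and asserted on masks only).  Foreground colors are
green-dominant (ExG ≥ 180), backgrounds gray-blue (ExG ≤ 0); optional
Gaussian pixel noise of stated σ degrades both.  Both side views carry the
full area; the top view carries 0.3× it (erect habit), configurable.

**Presets.**  `wheat_ssd`: 36 SSD + 3 named genotypes × {control, drought} ×
3 replicates, days 55–147 step 2, stress from day 104, irrigation targets
1.0/0.5 FC on a 1200 g pot, no bare pots; genotype drought factors span
0.5–1.0 and asymptotic sizes vary deterministically around 150 000 px.
`tomato_rwm`: 7 arms × 5 replicates at 0.7 FC on a 1800 g pot over 22 days,
10 bare pots; arm efficacy is modelled as asymptote multipliers 1.00–1.30
with prototype P2148 the clear top performer.  Weighing cadence
(`weigh_interval`, default 2 days, matching the imaging cadence) is exposed
rather than fixed because real trials differ.

**What the generator does not emulate:** photorealistic plant architecture,
senescent/yellow tissue (the segmenter is never stressed by hue overlap),
greenhouse microclimate gradients, datalogger artifacts, or conveyor/barcode
mechanics.  Passing tests therefore demonstrate the correctness of the
arithmetic and the statistical machinery under controlled conditions, not
robustness to real-world color calibration or occlusion problems.

## Problem sizes

Tests and the acceptance script run the full tomato design (35 plants + 10
bare pots) and wheat designs scaled to 6–10 genotypes for the repeated-run
pattern checks (100 runs for the treatment-F timing pattern, 20 for ranking
recovery); the full 39-genotype wheat bundle is exercised once end-to-end
through the pipeline.  These sizes were chosen so the whole validation suite
completes in minutes on a laptop while keeping every per-cell replicate
count identical to the study designs.

## Known limitations

* Segmentation assumes green-dominant foliage; senescent tissue would be
  undercounted (a configurable hue window is future work).
* Two-way ANOVA is balanced-only by contract; real trials with lost pots
  need cell-mean imputation upstream or a model-based approach out of scope
  here.
* WUE windows require a DB observation exactly at (the snapped) t₀; plants
  missing that day are skipped with a logged warning rather than
  interpolated.
* The water bookkeeping ignores plant fresh-weight gain inside the pot
  weight (a ~100 g effect on a ~1 kg pot at trial end, absorbed into the
  transpiration estimate).
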