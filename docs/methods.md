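# Methods

## Mass fractal dimension by box counting

The estimator treats the binarised hyphal network as a point set in the
plane. Grids of box side *s* are anchored at the image's top-left corner
(one fixed offset — no multi-offset minimisation), partial boxes at the
right/bottom borders count as full cells, and a box is *occupied* when any
pixel inside it is foreground. The dimension is the negative OLS slope of
ln N(s) on ln s (natural logs; the slope is base-invariant), with the sign
convention fixed so a filled square gives +2 and a 1-px line +1. The
intercept and R² are always reported; fits with R² < 0.95 are flagged but
not rejected, and estimates outside [0, 2] are flagged, never clipped.

The default size series 3, 6, 12, 24, 48, 96, 192, 384 px starts at the
scale of the thinnest resolvable filament and stops before N(s) saturates
at 1 for typical crops. Box sizes larger than both image dimensions are
skipped with a warning rather than failing, so one series can serve crops
of varying size. `fd_sensitivity` / `fd_rank_orders` refit the dimension
under alternative series: absolute FD shifts with the series, but the
ordering of specimens is preserved, which is the quantity comparative
experiments rely on.

Fewer than three usable scales is an error: a two-point log-log "fit" has
no residual and would report R² = 1 vacuously.

## Preprocessing chain

`kuwahara → sobel_magnitude → compute_threshold → binarize`, mirroring a
standard interactive workflow but fully scripted.

* **Kuwahara.** The *linear* variant (default) evaluates mean and variance
  along `n_orientations = 8` rasterised line segments of length
  `window = 5` px through each pixel at angles kπ/8, and outputs the mean
  of the minimum-variance segment; the classic four-quadrant variant
  (subwindows of side ⌈w/2⌉) is selectable. Oriented line windows suit
  1–3 px filaments: along a hypha some segment lies entirely on the
  filament, so edges survive smoothing unblurred. Ties in variance go to
  the lowest region index, making outputs bit-stable. Every output value
  is a mean of input values, so the output range never exceeds the input
  range.
* **Sobel.** Standard 3×3 kernels, magnitude √(Gx²+Gy²), replicate-padded
  borders (no artificial frame edges that would inflate box counts),
  clipped to [0, 255].
* **Threshold.** ISODATA (iterative intermeans) is the default binarisation
  after Sobel, matching the common toolbox default; Otsu, Huang and fixed
  are selectable. Automatic methods refuse constant images ("degenerate
  histogram"). All filters compute in float64 and quantize to 8 bits only
  at module boundaries, rounding half away from zero.

**Huang threshold.** For each candidate t the grey levels are given a
fuzzy membership μ(g) = 1/(1 + |g − m(g,t)|/C) to their class (m = class
mean, C = grey-level range), and t minimises the Shannon fuzziness
−Σ h(g)[μ ln μ + (1−μ) ln(1−μ)]; ties return the smallest t. The
implementation scans every candidate with cumulative histograms; the test
suite checks it against a naive re-derivation on random histograms.

## Colour quantification

RGB scenes are converted assuming sRGB/D65 to CIELAB and encoded to 8 bits
per plane with the neutral a\* axis at 128 (L\* scaled ×255/100, a\*, b\*
offset +128 and clipped). One Huang threshold is computed per image on the
whole a-plane histogram — not per drop — so all drops in a scene are
measured against the same criterion. A pixel is red when its encoded a\*
exceeds both the threshold and the neutral 128: red pigment has strictly
positive a\*, and the extra neutral gate prevents an automatic threshold
that lands in the green half-axis from promoting background to "red" in
pigment-free images. Components smaller than `min_particle_px`
(8-connectivity, default 0 = no filtering) are discarded. Drops whose ROI
is not fully inside the image are flagged `excluded` rather than dropped.

## Statistics

Measurement tables are long-format data frames. The factorial ANOVA uses
Type II sums of squares (via an OLS fit), the conventional choice for
mildly unbalanced designs when main effects are the target; the Tukey HSD
contrasts take their error mean square and residual df from the same
fitted model and use the studentized-range distribution with the
Tukey–Kramer standard error for unequal group sizes (with two groups this
reduces exactly to the pooled t test). The two-group comparison is Welch's
t by default — its Satterthwaite df are fractional, never exceeding
n₁+n₂−2 — with a pooled-variance variant available. Significance flags use
α = 0.05 but no decision is hard-coded into any computation.

## Synthetic data

* **Mycelium simulator.** Tips start evenly spaced on the left edge heading
  right, advance `step_len_px = 4` per step with heading jitter
  N(0, 0.25 rad), and branch with probability `branch_prob` per tip per
  step at ±0.6 rad. Tips leaving the 512×384 canvas die (bounded field of
  view); a carrying capacity of `max_tips = 150` live tips keeps density
  saturating rather than exponential, as it does in a real field of view.
  Defaults (100 steps, 5 initial tips, stroke width 2 px widened to the
  nearest odd width, foreground 200 on background 30, noise sd 8, linear
  illumination amplitude 20) give 2–40 % skeleton coverage across
  `branch_prob` ∈ [0.01, 0.15], visually similar to micrographs of hyphae
  bridging two drops. Parameters were chosen for visual plausibility —
  no published morphometry of *Fusarium* hyphal branching was available to
  calibrate against. The generator does **not** emulate anastomosis,
  nutrient fields, 3D growth, focus drift or uneven staining, so passing
  tests demonstrate correctness of the measurement chain, not biological
  realism of any particular FD value.
* **Analytic fixtures.** Line (FD 1), filled square (FD 2), Sierpiński
  carpet (FD log 8/log 3 ≈ 1.8928, size 3^level so counts are exactly
  8^(level−k)), and seeded random dust with an exact occupancy count.
* **Drop scenes.** Non-overlapping circles on a bright background;
  exactly ⌊red_fraction·|interior|⌋ interior pixels are painted the red
  pigment colour by seeded choice, so ground truth is exact by
  construction. Default colours (red (200,30,40), medium (235,235,200),
  background (250,250,250)) put pigment ≈ +63 a\* above an a\*-negative
  medium, the well-separated regime the method assumes; Gaussian RGB noise
  (sd 4) emulates camera noise.

All generators are pure functions of (params, seed) with no global RNG;
identical inputs give bit-identical rasters.

## Determinism and problem sizes

Batch runs derive one sub-seed per artifact from the config seed with a
fixed integer recurrence, so re-running a config reproduces every PNG and
CSV byte for byte. The bundled verification runs use 10 seeds per
branching level for the monotonicity check and 12 drops per pigment level
(36 drops) for recovery and ANOVA — sizes at which the expected effects
are unambiguous while a full run stays in the minutes range on one core.

## Known limitations

* The FD estimator uses a single grid origin; absolute FD values therefore
  carry a grid-placement bias that cancels in comparisons but differs from
  multi-offset estimators.
* ROIs use pixel-centre membership with boundary pixels counted inside;
  polygon areas in cm² inherit that half-pixel discretisation (bounded by
  the polygon perimeter).
* 16-bit inputs are linearly min–max rescaled to 8 bits; quantitative
  comparisons across images assume comparable acquisition settings.
* The colour stage assumes sRGB/D65 and one pigment on the +a\* axis; it
  performs no illumination correction or spectral unmixing.
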