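# Methods

This document records the exact geometric, numerical and statistical
conventions implemented in `woundhalve`, the synthetic study generator's
noise model and calibration, and known limitations.

## Coordinate and rasterization conventions

- Image coordinates are 0-based with x to the right and y down. The pixel
  at row `i`, column `j` has its **center** at `(x, y) = (j + 0.5, i + 0.5)`.
- An outline is a simple polygon given as an `(n ≥ 3, 2)` float vertex
  array in image coordinates; vertices must lie within the image bounds.
- Rasterization is **strictly interior**: a pixel is foreground when its
  center lies strictly inside the polygon. Pixel centers exactly on the
  boundary (a measure-zero event for real traced outlines) are background.
- Multiple outlines for one image combine by the **even-odd rule** (XOR of
  the per-polygon masks), so an outline drawn inside another cuts a hole.

## Minimum-area oriented bounding box

- The box is fitted to the foreground **pixel centers** with rotating
  calipers on their convex hull; the optimal box shares an edge direction
  with some hull edge, so the search over hull edges is exact (no
  orientation grid).
- The long axis `u` is the direction of the larger extent `L`; the short
  axis `v = rot90(u)` spans the width `W`. `L` and `W` are center-to-center
  extents; the reported box pixel area is `area_B = (L + 1)(W + 1)`,
  which always bounds the wound pixel count from above.
- Canonical axis sign: `u` is flipped to have positive x-component (positive
  y if x ≈ 0), making results reproducible across runs.
- Exact-square tie (`L = W`): the sweep axis is the candidate closer to the
  image x-axis.

## Strip sweep and line selection

- Strips are 1 pixel wide, perpendicular to the long axis. A pixel with
  projection offset `t = (p − low edge)·u ∈ [0, L]` belongs to strip
  `⌊t⌋ + 1`; there are `N = ⌊L⌋ + 1` strips.
- With `c[n]` the cumulative pixel count of the first `n` strips and `A`
  the total wound pixel count (`A ≥ 2` required), the selected count is
  `n* = argmin_n |c[n] − A/2|`; **ties break to the smallest `n`**.
- The one-side percentage is `100·c[n*]/A`; the other side is its exact
  complement. The halving line is drawn at offset `min(n*, L)` from the low
  edge along `u`, spanning the box across `±W/2` along `v`.

## Manual line evaluation

- A manual polyline is extended past the image border along its terminal
  segment directions, so a line drawn to the wound edge still separates.
- Each wound pixel is assigned by the sign of its signed distance to the
  nearest segment of the extended chain; pixels exactly **on** the line
  (signed distance 0) count toward side 1. For the algorithmic line this
  convention can differ from the strip accounting only for pixel centers
  exactly on the line — again measure-zero for real, rotated wounds.
- A line that leaves all wound pixels on one side is flagged
  `non_separating` rather than rejected.

## Statistics

- **Quantiles** (median, Q1, Q3) use the weighted-average-at-`(n+1)p`
  definition (`numpy` method `"weibull"`, R type 6), matching the HAVERAGE
  convention of common clinical statistics software; `"linear"` (R type 7)
  is available as an option.
- **ICC(A,1)** (two-way random, absolute agreement, single measurement) is
  computed from the two-way ANOVA mean squares,
  `r = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))`,
  with the McGraw–Wong F-based 95% CI using Satterthwaite degrees of
  freedom. Negative estimates are reported as-is. When the Satterthwaite
  df collapses (strongly negative estimates) the analytic limits of the
  bounds are used instead of a divergent F quantile. Qualitative bands:
  < 0.2 poor, 0.2–0.4 fair, 0.4–0.6 moderate, 0.6–0.8 good, ≥ 0.8
  excellent.
- **Wilcoxon signed-rank** (two-sided): zero differences are dropped;
  mid-ranks for tied magnitudes; statistic is `W+`. For ≤ 12 tie-free
  nonzero differences the p-value is exact (generating-function
  enumeration); otherwise a normal approximation with tie correction
  `Σ(t³−t)/48` and continuity correction. All-zero differences give a
  flagged degenerate result with p = 1.
- **Pairing for manual vs algorithm**: the default pairs each
  (image, assessor) manual deviation with the algorithmic deviation
  computed on *that assessor's* round-1 outline (n = images × assessors).
  The alternative `per-image-mean` first averages manual deviations per
  image (n = images), trading power for strict independence of pairs.
- Table "Algorithm" rows are grounded per assessor outline, so outline
  variability between assessors is reflected in the algorithm's (tiny)
  spread, exactly as when each assessor runs the tool on their own tracing.

## Synthetic wound generator

Wound shapes are star-convex radial perturbations of an ellipse:
`r(θ) = R · (1 + Σⱼ aⱼ cos((j+2)θ + φⱼ))`, stretched by the elongation
factor, rotated, and centered on the canvas.

Defaults (the simulated study conditions):

| parameter | default | units | rationale |
|---|---|---|---|
| image size | 768 × 768 | px | typical downscaled clinical photograph |
| number of wounds | 20 | — | study panel size |
| assessors × rounds | 6 × 2 | — | study design |
| box long axis | 250–500 | px | ≈ 5–15 cm² wounds at clinical photo scale; ≥ 250 px caps any 1-px strip below 0.5% of the area |
| elongation | 1.2–2.5 | — | wounds are rarely circular |
| harmonics | 4, each ≤ 0.07, Σ|aⱼ| < 0.35 | — | irregular but simple (non-self-intersecting) outlines |
| vertices per outline | 192 | — | sub-pixel outline fidelity |

Rater noise (applied to the ground-truth halving line and outline):

| parameter | default | units | meaning |
|---|---|---|---|
| `sigma_angle` | 3.0 | degrees | line rotation about its midpoint |
| `sigma_offset` | 0.022 | fraction of box length | axial displacement of the line |
| `sigma_outline` | 3.0 | px RMS | low-order radial jitter of the traced outline |
| `round2_scale` | 1.5 | — | noise inflation in the second round (recall drift) |

Calibration: the offset/angle defaults are chosen so the simulated manual
median absolute deviation lands in the 2–3 percentage-point band typical of
eyeballed halving lines (round 1 ≈ 2, round 2 ≈ 3 with the 1.5× inflation),
with IQRs of roughly 1–5 points. With all sigmas at 0 the manual lines
reproduce the algorithmic line exactly and every manual statistic collapses
onto the algorithm's — a built-in end-to-end check.

Randomness is namespaced through `SeedSequence` tuples — `(seed, 0, image)`
for shapes, `(seed, 1, image, rater, round)` for annotations,
`(seed, 2, rater, round)` for presentation order — so adding raters or
rounds never perturbs existing draws.

`estimate_sigma_offset` inverts the noise model: near the optimum the split
fraction is locally linear in the axial offset, so the offset noise is
recoverable from observed deviations via the local area-per-strip slope and
the half-normal mean relation `E|x| = σ√(2/π)`; the injected value is
recovered within 25% from 200 simulated lines.

## Limitations

- Synthetic wounds are star-convex with smooth low-order boundaries; real
  wounds can have concavities, islands and ambiguous edges. Holes are
  supported by the geometry (even-odd rule) but not produced by the
  generator.
- The rater noise model is Gaussian and independent across images; real
  assessors show correlated, skewed errors and learning effects beyond the
  single round-2 inflation factor.
- The halving line is constrained to be perpendicular to the box long axis,
  as specified; for nearly square wounds the chosen axis (closest to image
  x) is a convention, not an anatomical choice.
- ICC confidence intervals assume the two-way random-effects normal model;
  with n = 20 images they are wide, which the simulated studies reproduce.

## Problem sizes exercised

- Box oracle: 100 random blob masks up to 64 × 64, brute-force orientation
  grid at 0.05°.
- Strip selection: 1,000 random profiles including plateau/tie cases.
- ICC: 1,000 random matrices (n ∈ [2, 8], k ∈ [2, 5]) against a
  by-definition ANOVA oracle at 10⁻¹⁰; exact Wilcoxon against full 2ⁿ sign
  enumeration for all tie-free n ≤ 10; quantiles exhaustively for all
  multisets of size ≤ 6 over a 4-value alphabet.
- End-to-end: 20 images × 6 assessors × 2 rounds in ≈ 10 s on one CPU.
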