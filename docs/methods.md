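# Methods

## Model

The edge detector is a Mamdani fuzzy inference system over the eight
absolute neighbourhood differences `ΔP_j = |P_j − P|` of a 3×3 window.
Operators are the standard Mamdani triple: **min** t-norm for rule firing,
**clipping** implication, **max** aggregation across rules, and discretized
**centroid** defuzzification

    c = Σ_x q_x z_x / Σ_x q_x

on `N = 256` evenly spaced samples `z_x` of [0, 255] (`q_x` is the merged,
clipped output membership at `z_x`). The per-pixel crisp score `c` is
binarized at 127.5, the midpoint of the two output centres; the outermost
1-pixel frame is never flagged (no padding is invented at the border, since
padding manufactures artificial contrast).

### Fuzzy sets

| Variable | Set | MF | Parameters |
|---|---|---|---|
| each ΔP_j | Lower | trapezoid | (0, 0, 25, 75) |
| each ΔP_j | Higher | trapezoid | (25, 75, 255, 255) |
| output P | NonEdge | Gaussian | m = 10, d = 3.5 |
| output P | Edge | Gaussian | m = 245, d = 3.5 |

Trapezoids evaluate piecewise-linearly with degenerate plateaus (`r = s` or
`t = u`) handled without division by zero; Gaussians are
`exp(−(w−m)²/2d²)`, strictly positive, exactly 1 at the centre. Fuzzy-set
evaluation outside the universe clamps to the boundary degree.

### Rule base

Twelve rules, all with the Edge consequent; unlisted inputs are don't-care
and never enter the t-norm. Each rule pairs two `Higher` differences on one
flank — (P1,P2), (P1,P4), (P2,P3) or (P4,P6) — with a `Lower` difference on
the opposite flank (P8, P7 or P5 respectively for the three rule groups).
Under the row-major neighbour convention (P1=NW … P8=SE, config-exposed)
these are directional edge templates: an intensity interface activates the
rules on its south/east side, producing a one-pixel-wide response line,
while an isolated impulse — all eight differences `Higher` — activates
nothing.

Because no rule has a NonEdge consequent, the NonEdge aggregate receives
the implicit-else strength `1 − max(12 rule strengths)`. This guarantees a
non-empty output profile (so the centroid is always defined) and makes the
edge score a continuous, monotone function of the Edge activation. A
fallback (the NonEdge centre) covers the all-zero aggregate that the
implicit else makes unreachable.

## Contrast pre-stage

Smooth clinical images carry steps too weak for the `Higher` set: the
binarization threshold is reached only when the rule strength exceeds 0.5,
i.e. when the step amplitude exceeds ~50 grey levels. The pre-stage maps
each pixel independently through a three-rule system:

| Input set | MF | Output set | MF |
|---|---|---|---|
| Darker, trapezoid (0, 0, 60, 140) | → | Darkest | Gaussian m = 5, d = 15 |
| Grey, trapezoid (90, 125, 130, 165) | → | Grey | Gaussian m = 127.5, d = 15 |
| Brighter, trapezoid (115, 195, 255, 255) | → | Brightest | Gaussian m = 250, d = 15 |

The induced transfer function (crisp centroid per integer grey level,
rounded to nearest, ties to even) is a monotone S-curve, exactly symmetric
about mid-grey by construction (inputs and outputs mirror about 127.5), with
slope ≈ 1.9 at mid-grey and compressive plateaus at the extremes. It maps a
110/145 step to roughly 94/161 (Δ ≈ 68), which the edge rules detect. The
parameters were chosen for exactly this behaviour — classic fuzzy
intensification with enough central gain to lift sub-threshold clinical
contrasts past the rule threshold — and are fully config-exposed. A gentler
profile (wider Grey triangle, Darker/Brighter supports ending at mid-grey)
yields a mid-grey gain near 1.1 and fails to make low-amplitude steps
detectable, defeating the stage's purpose.

A note on "contrast expansion": a monotone map of [0,255] onto itself
cannot expand the range of *every* image (slope ≥ 1 everywhere forces the
identity). The stage expands ranges for images confined to the central band
(roughly 90–165), the regime smooth clinical images occupy, and compresses
near the extremes; the property tests assert exactly that.

## Noise model and calibration

Salt-and-pepper noise corrupts each pixel independently with probability
`p`, setting it to 0 or 255 with equal probability. `MSE` is the mean
squared intensity difference and `PSNR = 10·log₁₀(255²/MSE)` dB. The
protocol states noise as a PSNR target (25 dB for the standard experiment,
24 dB for the smooth-clinical one), so `calibrate_density` bisects on `p`:
one seeded uniform field is reused across probes, making the corrupted set
nested in `p` and the realized MSE monotone, hence the bisection well
posed. Default tolerance 0.25 dB; `tol_db = inf` accepts the first probe.
Every noise artifact records `(p, seed, MSE, PSNR)`.

## Baselines and evaluation

Sobel/Prewitt/Roberts use scikit-image gradient magnitudes thresholded by
Otsu's method by default (a fixed fraction-of-max threshold is available);
LoG flags 3×3 zero crossings of `scipy.ndimage.gaussian_laplace` gated at
0.75 × mean |response| (σ = 2 default); Canny is scikit-image's
implementation (σ = 1, hysteresis 0.1/0.2 on the unit-scaled gradient). All
detectors share the boolean-map contract with a cleared 1-pixel border so
false-edge counts are comparable.

A **false edge pixel** is flagged on the noisy image and absent from the
reference map — the analytic ground truth for synthetic fixtures, else the
same detector's clean-image output. Sensitivity `TP/(TP+FN)` and
specificity `TN/(TN+FP)` come from the strict pixel-wise confusion table;
an optional ±1-pixel tolerance band (off by default) redefines hits with
respect to dilated maps, with TP+FN anchored to the truth pixel count, to
accommodate detectors of differing edge thickness.

## Synthetic fixtures

Generators stand in for the unavailable clinical test images; all are pure
functions of their parameters (and a seed), bit-reproducible, with ground
truth marking **both** pixels flanking each generator discontinuity and
never touching the border frame.

* `make_rainbow` — 314×192 (width×height), five full-width 20-row stripes
  vertically centred on a uniform background: six horizontal boundary
  lines. Default levels (0, 80, 160, 55, 135) on background 240 give every
  interface a contrast ≥ 80 grey levels, saturating the `Higher` set; a
  contrast near 50 would park the edge score exactly on the binarization
  threshold, which is why lower-contrast defaults were rejected.
* `make_step`, `make_uniform`, `make_checkerboard` — analytic elementary
  fixtures for invariance and baseline tests.
* `make_smooth_phantom` — 270×290, a few soft elliptical blobs of
  amplitude ≤ 40 on a mid-grey field, Gaussian-blurred: emulates the
  intensity statistics (weak contrast, smooth gradients) of a smooth
  clinical MR slice. It does **not** emulate anatomy, scanner noise
  spectra, bias fields, or partial-volume effects — tests passing on it
  show the pipeline's behaviour under weak-contrast smooth intensity
  structure, not clinical performance.

## Numerical choices

* Output universe: 256 samples (the integer grey grid). Oracle tests
  integrate on a 10× denser grid; agreement is within 0.5 grey level.
* Scalar and whole-image paths share one batch defuzzification kernel, so
  the vectorized detector equals a naive per-pixel loop bit-for-bit.
* Contrast LUT rounding: nearest integer, ties to even.
* Degenerate inputs: images below 3×3 are rejected; uniform gradient
  images short-circuit the Otsu threshold (no edges); PSNR of identical
  images raises rather than returning infinity silently.
* Problem sizes in the shipped tests and the acceptance script (314×192
  band fixture, 270×290 phantom, 512×512 only for noise statistics) keep a
  full run in seconds on one CPU while leaving every quantity measured at
  the sizes the protocol names.

## Known limitations

* The published comparison counts on the original 512×512 standard image
  and the clinical MRIs are not reproducible — those images were never
  published; the comparison is reproduced as an ordering on synthetic
  fixtures instead.
* The rule base is deliberately one-sided (south/east response lines), so
  detected boundaries are one pixel wide on one flank of each interface;
  truth masks mark both flanks, and the ±1-pixel tolerance band exists for
  cross-detector scoring.
* Pairs of adjacent impulses can satisfy a rule (one impulse provides the
  other's `Lower` neighbour), so the false-edge count under heavy impulse
  noise is small but not zero.
* The contrast stage assumes grey conversion happens first; colour inputs
  are reduced by BT.601 luminance weights before any fuzzy processing.
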