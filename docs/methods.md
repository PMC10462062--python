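# Methods

## The generative model

A scene is a set of bundle *segments* (prongs) organized into Y/star
structures: each structure has one knot placed inside a gap between motor
stripes and 2–4 prongs anchored on the stripe pixels bounding that gap, with
at least one prong per side so the structure spans the gap. Each segment
carries

- `n` — its filament count, drawn from a discrete set (default 1, 2, 3, 4,
  6, 8) with weights ∝ 1/n, reflecting the prevalence of small bundles in
  entangled networks;
- `F_seg` — its total tension, in arbitrary force units. Only the ratio
  `F/n` is physically meaningful here, since no force calibration exists for
  the emulated assay.

### Tension model

The presupposition behind the per-filament-load mechanism is that motors
apply a total force to a segment that is *independent of its size*. We keep
that independence but do not make tensions strictly equal: each segment's
tension is drawn lognormally around the mean `F_seg` (mean-preserving,
coefficient of variation `F_seg_cv`, default 1.0; set 0 for strict
equality). The dispersion represents the stochastic number and cycling state
of the motors engaging each prong — order-of-magnitude single-digit engaged
motors imply a CV near 1 — and it is what lets individual small bundles
reach *absolutely* high binder intensities. With strictly equal tensions the
binding law is monotone in `n`, ABP and actin ranks coincide, and the
small-bundle quadrant can never populate; the observed enrichment phenomenon
requires force heterogeneity, which the real assay has in abundance.

### Binding law

Per-filament ABP occupancy follows

    rho(n) = k0 * (1 + beta * g(F_seg / n)),

with `g(x) = x` by default or the saturating form `g(x) = x / (x + x0)`.
`beta = 0` is the force-insensitive (C-terminally truncated mutant-like)
binder: occupancy is constant, total binding ∝ `n` (mass action). For
`beta > 0` with linear `g`, the total expected ABP on a segment is
`n*k0 + k0*beta*F_seg`: the force-dependent share is independent of `n`,
equalizing binder numbers across bundle sizes and enriching the ABP:actin
ratio on small bundles by exactly `k0*beta*F/n`.

Defaults: `k0 = 30` (baseline occupancy expressed directly in rendered
photons/px/filament, giving the ABP channel camera-comparable signal),
`beta = 2`, `F_seg = 6`. These place the force condition firmly in the
regime the assay exhibits: a ~13× ratio enhancement for single filaments,
greater-than-5-fold ratio spread among segments of equal size (through the
tension dispersion), and a clearly populated small-bundle quadrant, while
`beta = 0` gives the strictly linear regime. Actin brightness is
`a0 = 120` photons/px/filament; bundle intensity is strictly proportional to
`n` (no sub-resolution packing correction), matching the use of F-actin
intensity as the bundle-size proxy.

### Rendering

Paths are rasterized with anti-aliased line drawing, blurred with a Gaussian
PSF (default σ = 1 px at 0.267 µm/px, appropriate for a 60×/1.49 NA TIRF
objective with a 16 µm-pixel EMCCD), scaled by the camera gain, offset by a
uniform background (10 photons/px), then Poisson shot noise and additive
Gaussian read noise (σ = 2) are applied per frame. Bleaching is a per-frame
geometric decay of the pre-noise signal. Frames are 2 s apart. Rendering is
linear in brightness and gain before noise, and bit-identical given
(scene, parameters, seed).

### Rupture lifetimes

Paired-filament-complex lifetimes follow a two-component exponential
mixture parameterized by medians: the main population (median 27 s, the
middle of the observed 26–29 s range) plus a small long-lived tail
(fraction 0.05, median 300 s, representing complexes that persist for many
minutes). The census summarizes annotations with rupture time
`(last_intact_frame − 10) · frame_interval` and a Kaplan–Meier survival
curve over (optionally censored) records.

## Segmentation

`binarize → skeletonize → branch_points → split_segments → widen`:

- **Thresholding.** Otsu (between-class-variance maximization) or a fixed
  value; the threshold is always reported in the metadata, and a constant
  image under Otsu yields an all-background mask plus a warning flag.
- **Branch points** are skeleton pixels with ≥ 3 skeleton neighbors,
  computed by 3×3 neighbor-count convolution. This definition flags the
  whole junction neighborhood of axis-aligned 4-way crossings (the four arm
  pixels diagonally touching two arms each count ≥ 3), which is what the
  debranching step wants: the entire junction is removed.
- **Debranching** deletes branch pixels, labels the remainder by
  8-connectivity, discards components below `min_segment_px` (default 5),
  and orders labels by descending size (ties by smallest (row, col)).
- **Widening** dilates each arm with a Euclidean disk to the target odd
  width (default 5 px); contested pixels go to the nearest skeleton, exact
  ties to the lower label.

An optional region mask restricts segmentation to chosen stripe-gap
regions. Whether thresholding is global or per-region is configuration, not
hard-coded.

## Measurement

The canonical per-segment statistic is the **ratio of means**: mean ABP over
the segment mask divided by mean actin over the same mask, after optional
background subtraction. Ratio-of-means is far more robust to shot noise than
averaging per-pixel ratios; per-pixel ratio heatmaps are produced for
display only. Segments whose background-corrected actin mean is not positive
are flagged and excluded from ratio statistics.

Background is estimated per channel as the mean intensity outside the
6-px-dilated foreground (the mean, not the median, because the shot-noise
distribution is skewed and its median sits below the true level).

Measurements can exclude pixels near branch points (the validation studies
use a 6 px radius): within a couple of PSF widths of a knot, the blur of
crossing bundles mixes signals and biases dim arms toward their bright
neighbors' ratio. With this exclusion, noiseless ratio recovery is exact to
numerical precision.

Per-trial normalization divides each channel by its within-trial median
segment intensity (median, not max, for outlier robustness), making trials
with different illumination or gain comparable. Quadrant medians are
computed per analyzed table (per condition), and the quadrant uses strict
inequalities. State windows are primarily user-supplied; the automatic
detector (frame-difference z-score rule) is a convenience stand-in, not a
claim about how substantive transitions should be defined. Paired
before/after comparisons are keyed by stripe-gap region rather than by
segment, because segments rearrange under force. All p-values are
two-sided; no multiple-testing correction is applied.

## Validation studies and problem sizes

The frozen studies in `actnet.experiments` (used by both the test suite and
`scripts/acceptance.py`) run on a 192 × 160 px field of the 2.5/17.5 µm
pattern (two full gaps, 3 structures, ~10 segments per scene):

- *Segmentation recovery*: 100 noiseless scenes; exact segment-count
  agreement and per-mask IoU ≥ 0.5 against 5-px-wide rasterized true
  prongs. These studies use a fixed threshold (15 photons noiseless,
  background + 20 noisy) and `min_segment_px = 10`: with bundle brightness
  spanning ~20×, a global Otsu threshold falls *between* brightness classes
  and drops single filaments, while junction fragments are shorter than
  ~10 px and true prongs longer than ~18 px.
- *Binding recovery*: calibration scenes with fixed sizes (1,2,3,4,6,8) and
  `F_seg_cv = 0`; OLS of segment ratio on `1/n` estimates slope
  `k0*beta*F/a0` and intercept `k0/a0` (6 scenes noiseless, 20 noisy for
  ≥ 200 segments).
- *Qualitative regimes*: `beta = 0` noiseless linearity (8 scenes), and 100
  paired replicates of 8 noisy scenes per condition comparing quadrant
  fractions between `beta = 2` and `beta = 0`.
- *Statistics*: 2000 null simulations (n = 50 per group) for Welch type-I
  error; 10⁴ lifetime draws for the census round trip.

These sizes keep the full validation under about a minute while leaving
each assertion far from its tolerance.

## Known limitations

The generator emulates the *geometry and photometry* of the assay, not its
mechanochemistry: no motor kinetics, no filament polymerization or breakage
dynamics, no explicit end-linker capture kinetics, and no temporal network
rearrangement (scenes are static; states and rupture times are modeled
separately). Bundle sizes are discrete and bundle intensity exactly
proportional to filament count, whereas real bundles have continuous
intensity variation from labeling, packing and overlap; real backgrounds
are structured rather than uniform. Passing recovery tests therefore
demonstrates correctness of the measurement chain under the stated model,
not robustness to every artifact of real movies. Force units are arbitrary
throughout; only `F/n` ratios and the products `beta*F` are identifiable.
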