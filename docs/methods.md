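# Methods

## Rasters, grids, and coordinates

All rasters follow the north-up GeoTIFF convention: the geotransform origin
is the outer corner of the top-left pixel, world y decreases with the row
index, indices are 0-based `(row, col)`. Heights and distances are meters,
so only projected (metric) CRSs are accepted; a geographic (degree) CRS is a
hard error rather than a silently wrong computation. Projected vs geographic
is decided from the GeoTIFF model-type geokey on files, and from the EPSG
4000–4999 geographic band for bare EPSG ids.

Pixel membership in a plot polygon is **center-in-polygon** (boundary
counts as inside). This is deterministic, matches common zonal-statistics
defaults, and makes masks exactly reproducible; the alternative
(area-weighted membership) was rejected because every downstream count
(coverage denominators, volume-index denominators) would become fractional.
Pixel footprints are half-open (`[left, right) × (bottom, top]`), with a
1e-9-pixel epsilon inside the floor so that decimal coordinates written on
an edge land on the larger-index pixel regardless of binary representation.

When the DSM and orthomosaic grids differ, the DSM is resampled to the
orthomosaic grid by nearest-neighbor at pixel centers: no elevations are
invented, which matters because the height metrics are order statistics.

## Microplot grids

Plots are rotated rectangles laid out parametrically (anchor, angle,
plot length × width, counts, gaps) — the scriptable equivalent of dragging a
grid over the image. Numbering schemes: row-major (default), column-major,
and serpentine rows (common in breeding trials). `trim_margin` shrinks a
plot concentrically: a fraction *f* removes *f* of the chosen dimension in
total, split equally between the two opposing edges (so trimming 20% of the
width of a 9 m × 1.2 m plot leaves 9 m × 0.96 m). The default trimmed side
is the width because machinery tracks run along the plot's long axis.

Shapefile output writes polygon records (type 5) with clockwise outer rings
as the format requires and a single integer `plot_id` attribute; reading
normalizes rings back to counterclockwise starting at the stored first
vertex, so write→read is the identity on files this package wrote.

## Base plane

`fit_lsq_plane` minimizes vertical residuals Σ(z − ax − by − c)²; x/y are
centered before the solve for conditioning, and a rank check rejects
collinear samples. `shift_to_base` computes each sample's vertical downward
distance d = plane(x, y) − z (positive = below), excludes the ⌈f·N⌉ deepest
samples (default f = 0.05; ties broken deeper-first then input order via a
stable descending sort), and lowers the plane onto the deepest retained
sample when it is below the plane. Choices the underlying description
leaves open, fixed here:

- exclusion count is a **ceiling** of f·N (rounded at 1e-9 before the
  ceiling so f·N values representable only approximately in binary cannot
  spill over);
- at least one sample is always retained (the exclusion is capped at N−1);
- the plane is **never shifted upward**: if every retained sample is on or
  above the plane it is returned unchanged;
- "downward distance" means plane-minus-point, so the excluded anomalies are
  pits/noise below ground.

Under Gaussian elevation noise σ the shift aligns the plane to roughly the
5th-percentile residual, biasing all subsequent heights upward by ≈1.6σ
(≈8 mm at σ = 5 mm). This is inherent to the shift-to-deepest-point
definition, not an implementation artifact, and is visible in the worked
example.

The crest-line variant regresses elevation on the along-line coordinate
with one shared slope and a separate intercept per segment (crests share
slope, not offset); intercepts are averaged after the joint solve. The
returned plane's gradient is slope·(line direction), so the cross-line slope
is zero by construction — the stated assumption of the method, appropriate
when the field's fall line runs along the ridges. Multiple lines must be
parallel within 5° (one plane cannot honor two normal directions); the mean
direction is used. The default sampling half-width is one pixel. The plane
is serialized as `{"a":…,"b":…,"c":…,"crs":…}` and reused verbatim across
dates: one absolute reference for the whole series.

## Coverage classifier

Features per pixel: normalized R, G, B; HSV (hexcone, hue in [0,1), hue 0
when saturation 0); CIELAB under sRGB/D65 (the working space of consumer
cameras; the conversions are scikit-image's, verified in tests against an
independent implementation of the published formulas). Features are
standardized to zero mean/unit variance on the training set.

Training maximizes the L2-penalized multinomial log-likelihood

    (1/N) Σᵢ −log p(yᵢ|xᵢ; W) + (λ/2)‖W‖²,  intercepts unpenalized,

with λ = 1e-4 by default — small enough not to bias separable problems,
large enough to make the softmax solution unique. The contract is the
optimum, not any particular optimizer's trajectory; scikit-learn's lbfgs is
used, and an independent scipy solver of the same objective agrees with it
to 1e-4 in predicted probabilities in the test suite. Binary problems are
stored in the same per-class softmax form by pinning class 0 at zero.
Classification is per-pixel argmax with ties resolved toward the earlier
class; sample duplication does not change decisions (no class re-weighting).
Classes distinguishable only by texture or shape — not color — are out of
scope by design.

## Traits

HeightP = maximum height after discarding the ⌈(1−P/100)·N⌉ tallest pixels,
computed over **all** valid pixels of the (trimmed) plot — not vegetation
pixels only, since the tallest points of a covered plot are canopy anyway
and bare plots then degrade gracefully to ≈0. A vegetation-restricted
variant exists behind `heights_on_vegetation_only` but is off by default.
The exclusion count uses exact integer ceiling arithmetic. Negative heights
stay in the distribution (maxima ignore them); they are clipped to zero
inside the volume index so soil pits cannot subtract volume. The
volume-index denominator counts valid (non-nodata) pixels of the trimmed
plot; a pixel is valid when both the orthomosaic and DSM carry data there.

## Synthetic fields

The generator emulates the study conditions end to end: a planar sloped
ground (default slopes 0.01/−0.005, 5 mm i.i.d. Gaussian noise), optional
triangular-profile ridges running along the plot rows (default spacing
0.75 m, height 0.15 m) with crest lines placed exactly on pixel-center rows,
three 3 m × 2.25 m plots at 2.5 cm GSD, canopies of height 0.5 m covering
30% of each plot, and crop/soil colors (means 12 channel-σ apart, σ = 8) —
so cover fractions are exact up to pixel quantization and every estimate has
a closed-form truth. Canopy footprints are concentric rectangles (scaled by
√cover in both dimensions) or four non-overlapping quadrant discs. On
ridged fields the canopy **top** is flat at crest plane + canopy height, so
the true height above the crest reference equals the canopy height exactly;
and the ridged default scenario sets the cross-ridge ground slope to zero
because that is the crest-line method's modeling assumption. The base plane
should be estimated from a bare capture (cover 0) of the same field — crest
lines crossing a canopied plot would sample the canopy.

What the generator does **not** emulate: spatially correlated SfM error
(doming, melt), shadows and illumination gradients, mixed boundary pixels,
canopy height variation within a plot. Passing tests therefore demonstrate
the correctness of the extraction machinery under its stated model, not
field-grade accuracy of photogrammetry.

## Pipeline and determinism

A project is one YAML/JSON config: dated raster pairs, the plot Shapefile,
one base plane (serialized or derived from ground regions on a reference
date), a default and/or per-date coverage models, margin-trim settings.
Rows are ordered (date, plot_id); per-plot and per-date failures are logged
with reasons and skipped. CSV output fixes formatting (heights/VI in cm to
2 decimals, fractions to 4) and records the project seed in a leading
comment line, so reruns on identical inputs are byte-identical.

## Problem sizes

Synthetic validation uses 400×240-pixel fields (three ~10,800-pixel plots)
and 300×300-pixel plots for the coverage-recovery check, with 200 training
samples per class — sizes at which the quantization and noise terms are far
smaller than the acceptance tolerances while the whole suite runs in
seconds.

## Known limitations

- Ground must be planar; terraces, strong curvature, or per-ridge height
  drift violate the model (non-planar references are out of scope).
- The upward height bias from the base-plane shift grows with DSM noise.
- Only RGB color features: no texture, no NIR, no spatial context.
- Shapefile support covers the plot-polygon contract, not the full format
  (no multi-ring polygons, no M/Z geometries, plot_id is the only
  attribute).
- No CRS reprojection: all inputs must share one projected CRS.
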