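# Methods

This note documents the models, parameter choices and numerical decisions
behind `benthic-ready`, and what its synthetic test bed does and does not
establish about real imagery.

## Problem setting

A towed camera sledge photographs the seabed at ~0.1 Hz from 1–3 m altitude
under strobe/LED light. Four degradations make raw frames incomparable:

- **Light cone**: the artificial source illuminates a central disk strongly;
  brightness falls off radially towards the frame edges.
- **Scene brightness and cast**: the light path grows with altitude, so
  frames shot higher are darker and more strongly blue-green shifted
  (water absorbs red light first).
- **Poor local contrast**: intensities concentrate in a narrow band.
- **Scale variation**: px/cm is inversely proportional to altitude, so
  frames cover different seabed areas and are not equal sampling units.

## Pipeline stages

### Light-cone correction (batch z-score)

Frames are processed in acquisition-time order, in batches of 50 (the
trailing remainder is merged into the previous batch when shorter than
`max(2, batch_size/5)`, since per-position statistics over a handful of
frames are meaningless). For each pixel position and channel, values across
the batch are standardized to mean 0 and unit *population* variance — the
batch is the population of interest, not a sample. Positions with standard
deviation ≤ 1e-6 (static pixels) are set to 0. The channels are standardized
independently: falloff is channel-dependent because lamp spectrum and water
absorption differ per band.

Statistics are computed from exact integer sums (sum and sum of squares of
8-bit values in float64), which makes them — and therefore the outputs —
bit-identical under any permutation of the batch. For 8-bit data the
smallest nonzero per-position standard deviation in a batch of ≤ 60 frames
is ≥ 0.128, so the 1e-6 threshold only fires on exactly-constant positions;
the variance is clamped at 0 against rounding cancellation.

Standardized values are remapped for storage: clip to ±3 (≈99.7% of a
Gaussian range), linear map to 0–255, round half up (so 0 → 128). The ±3
clip and the linear map are this package's choice of display transform; any
symmetric monotone map would serve. One consequence matters downstream:
scene content whose across-batch distribution is heavy-tailed (a position
that is sediment in most frames but nodule in a few) produces |z| > 3 and
saturates at 0 or 255, concentrating a few percent of pixels in a single
intensity level. See "Histogram matching and the KS bound" below.

### Contrast enhancement (CLAHE)

Contrast-limited adaptive histogram equalization, applied per RGB channel
(the downstream stage is channel-wise too; skimage's color path would
equalize the HSV value channel instead and is deliberately not used). The
tile grid is 8×8 and the clip limit 2.0, expressed as a multiple of the
uniform histogram height — the convention of most imaging toolkits; it is
converted internally to skimage's pixel-fraction convention (÷ 256 bins).
Both parameters are exposed on the CLI. The clip prevents noise
amplification in flat regions at the cost of slower convergence: one
clipped pass moves local histograms only partway toward uniform, so
repeated application keeps changing RMS contrast by amounts comparable to
the first pass. The unclipped operator (clip limit 0) flattens local
histograms in one pass and is near-idempotent (second-pass change < 6% of
the first in our tests); the stabilization property is therefore asserted
on the unclipped operator. Constant channels pass through unchanged —
equalizing a structureless channel is undefined, and skimage's
implementation emits a 0/1 artifact on constant input.

### Color normalization (histogram matching)

The reference frame is the one with the largest px/cm — acquired closest to
the seafloor, hence with the best ground resolution and typically the best
lit scene; ties break toward the earliest acquisition. Matching is the
standard monotone transport on exact 256-bin histograms:
`lut[v] = min{g : F_ref(g) ≥ F_src(v)}`, ties in the reference CDF resolved
toward the lowest intensity. The map is a nondecreasing 256-entry lookup
table, so ranks are preserved within each channel and matching a frame to
itself is the exact identity. The implementation is this package's own
(eight lines around `np.searchsorted`); `skimage.exposure.match_histograms`
serves as an independent cross-check in the tests, and a brute-force
loop-based CDF-inverse oracle verifies the lookup table exactly.

#### Histogram matching and the KS bound

A monotone map on intensities can merge histogram bins but never split
them, so after matching, the sup-distance between the output CDF and the
reference CDF is bounded below by the largest single-level pixel mass of
the *input*. On inputs where no level holds more than 2/256 of the pixels
the residual KS distance stays below 2/256 (asserted in the tests with
sources holding each level exactly once). On full transects the z-score
display clip concentrates 2–4% of pixels at the saturation levels, so the
achievable KS distance there is that bin mass (measured ≈ 0.02–0.04), not
2/256; the corresponding transect-scale assertion in the acceptance tests
fails for this structural reason and is kept failing rather than relaxed.
Brightness harmonization is unaffected: across-frame variance of median
intensity drops to < 1% of its raw value on the synthetic transects.

### Footprint standardization

Per-frame scale comes from the laser dots: redness `R − max(G, B) ≥ 80`
(plain red thresholds also fire on bright white sediment), 8-connected
components with area in [4, 500] px, centroids of the three largest blobs,
and `px_per_cm` = mean over dot pairs of pixel distance / calibrated
separation. No layout is assumed; the pairwise mean is exact for an
equilateral triangle and a sensible average otherwise. If fewer than two
dots are found on a real frame, the pipeline falls back to the metadata's
archived cm/pixel and logs it; synthetic frames never need the fallback.

The target scale is the **median** of the per-frame scales (even counts:
mean of the central pair) — robust to the odd frame shot unusually close or
far. (Archive documentation variously calls the standardized value a median
or a mean scale; this implementation rescales to the median.) Resampling is
bilinear with Gaussian anti-aliasing when downscaling; output dimensions
are `round(dim × to/from)`, which preserves each frame's physical extent to
within one output pixel per axis. The crop target is the *elementwise*
minimum height and width over the rescaled set — a minimum area alone does
not determine a rectangle, and per-axis minima guarantee the centered crop
fits every frame. Centering uses floor offsets (top/left get the smaller
margin) so results are bit-exactly reproducible. After the stage, all
frames share one geometry; the across-frame variance of footprint area is
exactly 0.

### Published-archive geometry

The archive this pipeline's conventions follow stores 2240×3360 px frames
at 21.5 px/cm — a 50% per-axis center crop of the 4480×6720 (30 MP, 3:2)
source — which implies a footprint of (2240/21.5)(3360/21.5)/10⁴ ≈ 1.63 m²,
the "≈1.6 m²" standard frame. The acceptance script re-derives all three
numbers from the crop and footprint primitives.

## Synthetic scene generator

The generator is first-class, tested code; it renders every degradation the
pipeline corrects, with exact ground truth:

| parameter | default | meaning |
|---|---|---|
| `width_px, height_px` | 720 × 480 | 3:2 frame, a down-scaled stand-in for the 30-MP source |
| `altitude_m` | 1.5 | platform altitude; transects sample 1–3 m uniformly |
| `base_scale_px_per_cm_at_1m` | 30 | pinhole model: scale = base/altitude (20 px/cm at default) |
| `vignette_strength` | 0.6 | falloff depth at the corners |
| `vignette_radius_frac` | 0.9 | falloff radius as fraction of the half-diagonal |
| `color_cast` | (0.80, 0.90, 0.97) | per-meter transmission, applied as cast^altitude |
| `background_mean` | 150 | sediment mean intensity at 1 m; scaled by 1/altitude |
| `nodule_density_per_m2` | 30 | dark ellipses per m² of imaged seabed |
| `nodule_radius_cm` | 0.8–3.0 | nodule size range |
| `laser_separation_cm` | 10 | calibrated dot separation |
| `noise_sd` | 4 | Gaussian sensor noise (8-bit units) |

The vignette is multiplicative: `1 − s·(1 − exp(−(r/R)²))` with `R` =
`vignette_radius_frac` × half-diagonal — smooth, radial, monotone. The
laser dots are stamped pure red (255, 0, 0) at an equilateral triangle
centered mid-image, one vertex up; side length = separation × scale, so the
dots fail loudly (with a remediation hint) if the triangle does not fit the
frame. Timestamps advance 10 s per frame (0.1 Hz capture); filenames follow
the cruise naming convention. All randomness flows from one integer seed
through one `numpy` generator; identical parameters render bit-identical
rasters.

What the generator does **not** emulate: forward scatter and blur,
perspective distortion and camera tilt, JPEG artifacts, megafauna,
sediment-plume turbidity, or auto-exposure. Passing tests therefore
establish the correctness and the harmonization behavior of the
transformations under controlled degradations — not that any particular
quality level will be reached on a given real survey.

## Problem sizes and determinism

Tests run the full chain on 100 default-size frames (the transect scale at
which the statistical contracts are asserted) and smaller 360×240 frames
elsewhere; the acceptance script uses 100 frames per transect. The
end-to-end pipeline is deterministic by construction (no randomness after
generation; lossless PNG intermediates), and re-running a configuration
reproduces outputs and manifest bit-exactly.

## Known limitations

- The KS residual after histogram matching is bounded by the largest input
  histogram bin mass (see above); saturated levels from the display clip
  keep it above 2/256 on realistic transects.
- The laser detector is a threshold-plus-blob heuristic sized for the
  synthetic dots and clearly red dots on real sediment; faint or scattered
  dots on dark nodules may need the metadata-scale fallback.
- Batch z-scoring assumes the illumination pattern is static within a
  batch; a light rig re-aimed mid-transect would leak into the scene term.
- Scale handling assumes a nadir view; tilt makes px/cm vary across the
  frame, which neither the estimator nor the footprint model represents.
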