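# Methods

## Pixel classification model

Each pixel is classified independently from its own (R, G, B) triple;
no spatial context enters the decision. Features are the three 8-bit
channels divided by 255, so they lie in [0, 1]³ — RBF kernel-width
heuristics behave poorly on 0–255 ranges, and the scaling convention is
stored inside the model document so prediction is self-contained.

The decision rule is a three-class support vector machine:

* kernel: radial basis, K(u, v) = exp(−γ‖u−v‖²);
* regularization constant C = 1.0;
* kernel width γ by the "scale" heuristic, 1 / (n_features · Var(X)),
  resolved to a number at fit time and stored;
* multi-class reduction: one-vs-one voting over the three class pairs.

Fitting is delegated to scikit-learn's `SVC`; the fitted expansion
(support vectors, dual coefficients, intercepts, per-class support
counts, γ) is then extracted into `ClassifierModel`, which evaluates the
three pairwise decision functions itself and takes the vote winner.
Vote ties — which occur only in one-vs-one vote cycles, essentially in
color regions far from all training data — are broken by the summed
signed decision margin, then by the lowest class code. This differs
from scikit-learn's internal tie-break (normalized confidence sums), so
predictions can disagree with `SVC.predict` on a small fraction of
colors in no-man's-land; a test pins agreement at ≥ 99.95% near the
data distribution and ≥ 99% on uniformly random colors. The benefit is
that prediction is an explicit function of plain arrays: a model saved
to JSON (floats serialized via shortest round-tripping repr) and
reloaded anywhere predicts bit-identically, and training is
reproducible because samples are assembled in crop-list order, row-major
within each crop.

Training accuracy is reported on the training pixels themselves as a
3×3 confusion table (rows true, columns predicted); accuracy =
1 − errors/total. Pixels from different stain classes can genuinely
overlap in RGB space (dark areas especially), so sub-100% training
accuracy on real crops is expected behavior, not a defect.

An optional minimum-blob-area post-filter can reassign small isolated
adipogenic components (speckles the size of single lipid droplets) to
the negative class; it is off by default, keeping the per-pixel result
untouched.

## Ring profiling

A circular confinement of radius R (μm) is partitioned into coaxial
rings of thickness Δr (default 25 μm, the reference setup's value):

* distances are measured from pixel centers to the (continuous) circle
  center, times the pixel size in μm/px;
* ring k is the half-open interval [kΔr, (k+1)Δr); the outermost ring
  is truncated at R; pixels at distance ≥ R are OUTSIDE and excluded
  from every fraction;
* ring count = ⌈R/Δr⌉ (with a 1e-9 relative guard against float fuzz).

These conventions make the ring partition of the in-circle pixels exact
— disjoint, exhaustive, and checkable against brute-force per-pixel
enumeration, which the tests do. Per-ring class fractions are simple
count ratios, so non-empty rings sum to 1 to machine precision; empty
rings carry NaN (flagged, never a silent 0/0).

Replicates are aggregated per ring and class as the arithmetic mean and
sample SD (N−1 denominator) across images; a ring that is empty in some
replicate is excluded from that ring's sample rather than imputed as
zero, which would bias means toward zero. SD is reported as NaN when
fewer than two replicates contribute. Whether per-ring areas should be
normalized before or after averaging is genuinely open; averaging the
per-image fractions (each already normalized within its ring) was chosen
because it weights replicates equally regardless of slight differences
in ring pixel counts.

Exported tables always carry both radial coordinates — distance from the
confinement center and distance from the confining wall (R − mid-radius)
— because both conventions are in use for this kind of plot and the
choice of x-axis origin is presentation, not analysis.

Confinement geometry can be supplied explicitly (center, diameter, pixel
size) or auto-detected: the center is the centroid of the largest
connected foreground component (non-negative labels, or sub-Otsu gray
levels for raw images), which is robust to salt-and-pepper label noise;
the radius comes from the expected diameter when given (with a warning
if the detected foreground disagrees by more than 20%), else from the
foreground area. The pixel size (μm/px) cannot be inferred from an
image and is a required input for physical-unit profiles.

## Synthetic colony simulator

The simulator generates what the classifier and profiler need to be
validated end to end: images whose per-pixel class is known exactly.

* **Color model** — per class an isotropic Gaussian in RGB, clipped to
  [0, 255] and quantized. Defaults: adipogenic (180, 60, 60),
  osteogenic (60, 60, 180), negative (225, 225, 225), SD 10. These were
  chosen once to mimic the observed arrangement of the three stain
  clusters along the gray diagonal of RGB space (red-shifted,
  blue-shifted, near-white); real stain statistics are not published,
  so the numbers are the package's own defaults and fully configurable.
  The area outside the confinement is unstained surface and uses the
  negative class model unless overridden.
* **Radial layout** — adipogenic core (r < r_adipo), osteogenic belt
  (r_adipo ≤ r < r_osteo), undifferentiated rim (r ≥ r_osteo), either as
  a hard step or as logistic blends of width w (default 10 μm) giving
  per-radius class probabilities. Defaults r_adipo = 0.5 R and
  r_osteo = 0.85 R, i.e. 50 μm and 85 μm on a 200 μm confinement.
* **Sampling** — numpy's PCG64 generator with an explicit seed recorded
  in the sidecar metadata; the draw order (class uniforms, speckle
  positions, color noise) is fixed, so one seed fully determines image,
  labels and geometry, bitwise, across platforms.
* **Dark-area shading** — training crops can carry a multiplicative
  brightness attenuation on part of the crop, emulating the dark regions
  deliberately included in real reference crops.
* **Lipid-droplet speckles** — optionally, small adipogenic disks are
  stamped into the label map (default off); they exercise the blob-area
  filter.

What the simulator does **not** emulate: cell morphology and texture,
chromatic aberration and uneven illumination, stain co-localization
(purple pixels), partial-volume mixing at class boundaries, and any
correlation between neighboring pixels' colors. Passing tests therefore
demonstrate that the pipeline's machinery is correct (separable classes
are recovered, the geometry bookkeeping is exact, the statistics are
computed as stated) — not that any particular accuracy will be reached
on real micrographs, where class overlap in color space sets the
ceiling.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on simulated
data: training sets of ~1,000–10,000 pixels per class, colonies from
110×110 up to 512×512 px, and 12 replicates for the radial-recovery
measurement — sizes chosen so the full loop demonstrates every property
while a complete run stays fast on a single CPU. Prediction is chunked
(64k pixels per block) to bound the kernel-matrix memory. Degenerate
inputs: a class with no training pixels is a configuration error; two
classes sharing an identical feature set trains with a warning; empty
rings and single-replicate SDs are NaN, never fabricated numbers.

## Known limitations

* Per-pixel color classification cannot distinguish stain overlap or
  use spatial context; the deliberate scope is the simple, auditable
  rule.
* Auto-detection assumes one dominant circular colony per image;
  non-circular confinements are out of scope.
* The profiler's physical units are only as good as the user-supplied
  μm/px.
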