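# Methods

## Problem and approach

Long live-cell bright-field experiments lose focus as the stage drifts
(thermal expansion alone can move the objective by tens of µm over a day).
`zfocus` treats defocus estimation as *image classification*: the z-axis is
discretized into uniform bins spanning the acquisition range and a small
convolutional network predicts, from a single downsampled bright-field
image, which bin the image was acquired in.  The bin center is the defocus
estimate.  A deadband controller then corrects the objective whenever the
estimate leaves a tolerance band around the user-locked setpoint.

Classification (rather than regression) has two practical consequences this
package makes measurable:

* a quantization floor — an estimator that always returns the correct bin
  center still has MSE → width²/12 for z uniform over the span, so MSE must
  grow with bin width;
* a native confidence signal — the softmax over bins exposes ambiguous
  scenes (e.g. bimodal outputs when two cell populations occupy different
  planes).

## Coordinate conventions

Positive z means the image was acquired *above* the plane of best focus.
Slice indices are 0-based; the annotated in-focus slice has z = 0 exactly.
Bins are centers on a closed lattice `lo, lo+width, …, hi` with half-open
edges `[c − width/2, c + width/2)`, so a z exactly on a boundary belongs to
the upper bin and every covered z has exactly one label.  `−20..+20 µm`
with width 1 gives 41 categories; width 5 gives 9.  Out-of-coverage z
during training raises (surfacing annotation errors) rather than clamping.

## Network

Two convolution blocks (10×10 kernels, stride 1, zero padding preserving
size; ReLU; 5×5 max pooling with stride 5, floor on remainders) mapping
1 → 32 → 64 features, a 1024-unit fully connected layer with ReLU and
dropout p = 0.5 (training only), and a final linear layer to one unit per
bin, followed by a softmax (computed in log-space).  With a 1000-px crop,
4× downsampling (250-px input) and 41 bins this is 6,804,745 trainable
parameters.  Weights are initialized from a Gaussian (mean 0, sd 0.1)
truncated at ±2 sd; biases start at 0.1.

Because the 10×10 kernel is even, "same" padding is asymmetric: 4 px on the
leading edge, 5 on the trailing edge.  Pooling drops trailing rows/columns
that do not fill a window (needed e.g. for a 100-px input: 100 → 20 → 4).

The network is implemented directly in NumPy: convolutions are evaluated as
im2col + BLAS matrix multiplication in float32, the input gradient of a
stride-1 convolution is expressed as a convolution with the spatially
flipped, channel-transposed kernel, and max-pool gradients are scattered to
the cached argmax positions.  Backprop was validated against central finite
differences layer by layer.

## Training and evaluation protocol

Each mini-batch element is drawn uniformly over every (stack, slice) image
of the training split, then: random square crop → one of the 8 dihedral
transforms chosen uniformly (flips/rotations leave the label unchanged and
wash out illumination direction) → block-mean downsampling → per-image
min–max normalization to [0, 1].  The label is the z-bin of the slice's
annotated defocus.  Loss is mean cross entropy; the optimizer is Adam with
learning rate 1e-4, β₁ = 0.9, β₂ = 0.999, no schedule, no weight decay, no
early stopping.  Testing uses the *center* crop, no augmentation; the
estimate is the center of the argmax bin, ties broken toward the lower
index.

The full-scale preset (`paper`: 1000-px crops, 100,000 steps, batch 25) is
configuration only; the `desk` preset — 600-px synthetic fields, 256-px
crops, 4× downsampling (64-px network input), batch 16, 2,000 steps, 41
bins over ±20 µm — is the configuration the test battery and the
acceptance script actually run, sized for minutes on one CPU core.  The
desk experiment generates 125 stacks, splits 80/20 (100 train / 25 test)
and scores all 775 held-out slices.

Per-image min–max normalization and the lower-index tie-break are contract
choices (the upstream description is silent); both are stored with the
checkpoint so inference is self-describing.

## Synthetic data generator

The generator emulates yeast cells growing in a shallow microfluidic
chamber imaged in transmitted light at 60 nm/px: round cells of radius
2–3 µm, occasional 10-µm PDMS support pillars on a 50-µm grid, a
multiplicative illumination gradient (relative slope up to 0.15 across the
field), and additive Gaussian sensor noise (sd 0.01 on a [0, 1] intensity
scale).  A scene is frozen across its stack — the same cells appear in
every slice, as in real z-stack acquisition — and 31 slices are rendered at
Δz = 1 µm (a 51-slice, 12-µm-step variant covers the low-magnification
large-cell configuration).  Default cell count is 25–60 per 600-px field,
chosen so a 256-px crop contains roughly 4–11 cells — the typical per-crop
content of a growing colony; crops with only one or two cells are the
documented hard regime for this method, not the norm.

Image formation is phenomenological.  Each object contributes two sharp
maps — a narrow edge ring and a filled interior — blurred with a Gaussian
of width σ(z) = √(σ₀² + (s·z)²) (σ₀ = 0.8 px, s = 2.5 px/µm) and weighted
by two contrast terms:

* ring: −0.55 / (1 + (z/3 µm)²) + 0.18 · tanh(z / 2 µm) — a crisp dark
  outline at focus whose polarity drifts with z: above focus the ring
  lightens and turns bright (the classic bright-field halo), below focus
  it stays dark;
* interior: 0.35 · tanh(z / 2 µm) — *odd in z*: interiors render bright
  above focus and dark below it.

The sign asymmetries are the load-bearing design element: bright-field
images genuinely look different above vs. below focus, and without them no
classifier could learn the sign of the defocus; the polarity drift of the
ring also keeps the z → appearance map well separated *within* the dark
(below-focus) side.  The asymmetry magnitudes are free parameters, not fit
to any measurement.  Blur is applied in the
frequency domain (an analytic Gaussian transfer function on the rfft2 of
the component maps), making per-slice cost independent of blur width;
the boundary is therefore periodic, a visible but harmless artifact for
objects near the field edge.  Lateral drift in the closed-loop simulator is
a Fourier phase ramp, so a moving field costs nothing extra.

In two-population mode a fraction of cells sits on the chamber ceiling and
comes into focus `chamber_height_um` above the floor population (default
5 µm, the focal-plane gap between cells on the two chamber surfaces).
Mixed-sharpness slices and bimodal softmax outputs follow.

What the generator does *not* model: partially coherent image formation,
internal cell texture, cell motion or division within a single stack,
camera fixed-pattern noise, or real optical aberrations.  Passing tests on
this data therefore demonstrate that the pipeline learns and controls on
images whose defocus structure matches bright-field phenomenology — not
that any particular accuracy transfers to a specific microscope.

## Focus-score baselines

Three standard sharpness measures, all functions of intensity differences
(translation-invariant; zero on constant images):

* `brenner` — mean squared 2-px horizontal and vertical differences;
* `edge_density` — mean gradient magnitude over edge pixels, threshold
  picked per image by Otsu's method on the gradient-magnitude histogram;
* `iqa_detail` — fraction of non-DC spectral energy in the 0.05–0.35
  cycles/px band.  The image is Hann-windowed before the FFT: without
  tapering, the wrap-around discontinuity of any non-periodic content
  (e.g. an illumination gradient) leaks broadband energy and masks the
  true detail signal.

The method set is pluggable; these are standard instantiations of
edge-density/detail measures rather than transcriptions of any one
canonical formula.

Profile-based z-inference builds a global curve of normalized score vs. z
(per-stack max-normalization, peak aligned to 0, pointwise mean) and
inverts it by linear interpolation on the requested side of focus.  Two
structural handicaps are inherent and made explicit in the API: the
profile is even around its peak, so the *side* must be supplied
externally, and peak scores vary between stacks, so the per-stack maximum
must be supplied for normalization.  The comparison harness grants both
aids from ground truth, and errors are measured relative to each stack's
own peak-score slice.  Far from focus the profile sits on a flat noise
floor and carries no z information; inversion there is clamped and flagged
ambiguous.

## Closed-loop control

Time is abstracted into ticks.  Per tick: the stage drifts (linear trend
plus seeded Gaussian random walk), a slice is rendered at the current true
defocus, the estimator runs, and if |estimate − setpoint| exceeds the
deadband (default ±1 µm) the objective moves by gain × error (default
gain 1, a single full-error move).  After every applied correction the
estimate is re-measured from a freshly rendered image.  A failed estimate
holds position (fail-safe).  The bookkeeping identity

    final defocus = initial + Σ drift − Σ corrections

is asserted exactly on every session.  With a perfect estimator and gain 1
the true defocus provably never exceeds deadband + one-tick drift.  The
session used by the acceptance checks runs 500 ticks with a trend
accumulating 40 µm (0.08 µm/tick) plus a 0.02 µm/√tick walk, while the
colony grows from its initial count to ~100 cells and the field translates
slowly — the estimator must stay accurate as the scene it was never
trained on evolves.  The loop's renderer lifts the defocus model's
validated-range cap, since a misbehaving estimator may legitimately drive
the stage far from focus and the simulation must follow it there.

Softmax outputs with two local maxima each above 0.3 are flagged in the
session log (the two-population signature) but still acted on by argmax.

## Numerical choices and degenerate inputs

* float32 throughout the network; float64 for statistics.
* Splits use `round(fraction · N)` with half away from zero (431 → 345,
  136 → 109); membership is a seeded uniform permutation.
* Center-crop offsets are 0-based with floor division; a 2080×1552 frame
  center-cropped to 1000 px starts at (540, 276).
* Constant images normalize to all zeros and score 0 on every focus
  measure.
* All randomness flows through `numpy.random.Generator` seeded from
  explicit arguments; dataset generation, training and sessions are
  bit-reproducible given their seeds.

## Known limitations

* The CNN is trained and evaluated on synthetic data only; the desk-scale
  accuracy figures characterize the pipeline, not any physical microscope.
* 2,000 desk-scale steps leave the model undertrained: the smoothed loss
  is still decreasing at the end, train-split accuracy matches test-split
  accuracy (no overfitting), and roughly 45–50% of held-out slices land
  within ±1 µm depending on the seed.  Accuracy is excellent near focus
  (≈95% within ±1 µm for |z| ≤ 1) and visibly worse at |z| > 10 µm, where
  the slices are nearly featureless.  Longer training — the full-scale
  regime is 50× more steps — is the lever, not more stacks.
* The generator's defocus asymmetry magnitude is a free parameter; a real
  deployment would retrain on stacks from the target instrument, which is
  precisely the workflow the package automates.
* Checkpoints store raw parameter tensors (npz); no cross-version
  migration is attempted beyond a version field.
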