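# Methods

## The metric family

All eight box-similarity metrics share the skeleton `m = IoU − penalty`, with
the loss `1 − m`. Boxes are axis-aligned, stored as center/size
`(x_c, y_c, w, h)` in continuous feature-map cell units; corners are always
derived, never stored, so the two representations cannot drift apart. Nothing
in the loss or simulator path rounds to pixels.

* **IoU** — overlap over union; flat (zero gradient) for disjoint boxes.
* **GIoU** — subtracts the enclosing-box slack ratio; range (−1, 1].
* **DIoU** — subtracts squared center distance over the squared enclosing-box
  diagonal.
* **CIoU** — DIoU minus a weighted aspect-consistency term
  `ν = (4/π²)(atan(w_g/h_g) − atan(w_p/h_p))²` with trade-off weight
  `ν/(1 − IoU + ν)`. The weight is evaluated at the current point and treated
  as a constant during differentiation, the convention used when this loss is
  deployed in detectors; the finite-difference checks in the tests pin the
  weight accordingly.
* **EIoU** — DIoU minus squared width and height gaps normalized by the
  enclosing box's squared width and height.
* **SIoU** — IoU minus half the sum of an angle-modulated distance cost and a
  shape cost (θ = 4). The angle cost is `2·sinα·cosα` of the smaller axis
  angle of the center-to-center segment, computed algebraically (no trig
  calls); one fixed value is frozen in the tests as a golden regression
  anchor.
* **MPDIoU** — IoU minus both squared corner distances (top-left and
  bottom-right) over the squared feature-map diagonal `W² + H²`.
* **S-MPDIoU** — as MPDIoU but normalized by an angle-dependent baseline and
  amplified by a constant scale factor (below).

All metric values are symmetric in the two boxes and equal exactly 1 iff the
boxes coincide; every penalty is nonnegative, so `m ≤ IoU` always.

## S-MPDIoU specifics

With center gaps `C_w = |x_p − x_g|`, `C_h = |y_p − y_g|` and angle
`α = atan2(C_h, C_w) ∈ [0, π/2]`, the baseline is the chord of the map frame
at that angle: `C² = W²(1 + tan²α)` when `α < π/4`, `C² = H²(1 + cot²α)` when
`α ≥ π/4` (the boundary is assigned to the second branch; on square maps both
branches agree there, so the choice is observable only on non-square maps,
which are accepted with a warning). Implementation uses the ratios
`C_h/C_w` and `C_w/C_h` directly, avoiding trig and its edge cases.

Degenerate coincident centers leave α undefined; the baseline then falls back
to the full diagonal `√(W² + H²)`, the continuous limit along α = π/4 on
square maps, so the penalty stays defined.

The scale factor is `log₂(downsample)` with `downsample = input_ref / W`
(e.g. 640-pixel input on an 80×80 map: downsample 8, scale 3). It is a
constant per feature map: no gradient flows through it — which is also the
only consistent reading, as it does not depend on the boxes.

Both corner-distance fractions are subtracted. A variant that subtracts their
difference would cancel the penalty for symmetric displacements and *reward*
one corner's error, contradicting the corner-distance design this loss
descends from; the summed form also makes the diagonal-baseline/unit-scale
configuration reduce exactly to MPDIoU, which is regression-tested on random
pairs to machine precision.

## Differentiation

Gradients with respect to the predicted box's four parameters are computed by
an in-package vectorized forward-mode autodiff (`ioulab._dual`): dual numbers
with a fixed tangent width of 4, covering arithmetic, min/max/where
selections, abs, sqrt, exp and arctan. Selections propagate the tangent of
the active branch, which is the exact derivative almost everywhere for these
piecewise-smooth losses; exact ties resolve to the first argument. Two
deliberate exceptions:

* At an exactly identical pair every loss has a kinked minimum (one-sided
  derivatives disagree); the zero subgradient is returned so a
  gradient-descent iterate at the optimum stays put.
* Where a term is genuinely flat — the IoU of disjoint boxes — the clamp at
  zero overlap width yields a zero contribution, as it should.

Finite-difference agreement (central differences, step 1e-5, 1e-4 relative
tolerance, sampled away from branch boundaries) is asserted for all eight
losses in the test suite.

## The regression simulator

Plain per-case gradient descent, `θ ← θ − lr·∇(1 − m)`, no momentum or weight
decay — the minimal reading of a fixed learning rate (default 0.02). After
each step, width and height are clamped to a floor of 1e-4 cells to keep
iterates valid boxes. Convergence is declared on the L1 parameter gap
`Σ|θ_gt − θ|`, not on the training loss, at the first epoch where the gap
drops below the threshold. Converged cases are frozen by default: their
parameters stop updating but their residual gap still accumulates in the
per-epoch total-gap curve, which prevents oscillation artifacts around the
kinked minimum and keeps the aggregate curve monotone once the population
settles. A case whose parameters turn non-finite is aborted and recorded as
diverged, never silently dropped.

**Three-configuration experiment.** Ground truth centered at [1, 1] with
w = h = 0.5; predicted boxes of w = 1, h = 2 centered at [7, 1], [7, 7] and
[1, 7]; threshold 0.01; budget 100,000 epochs. The boxes live inside [0, 8]²
and no frame is inherent to the setup, so the canvas convention is this
package's choice: a 10×10 map with reference input 640 (scale log₂64 = 6),
chosen as the smallest round frame containing the boxes; both values are
config-exposed. Reported speedups are epoch ratios against MPDIoU.

**Randomized-population experiment.** On a 20×20 or 40×40 map (reference
input 640 → scale 5 or 4), 50 predicted-box centers and 5 ground-truth
centers are drawn uniformly from the inscribed circle. Ground-truth boxes
have unit area with aspect ratios 7:1, 4:1, 2:1, 1:1, 1:2, 1:4, 1:7;
predicted boxes take the same seven ratios and additionally seven area scales
0.5, 0.67, 0.75, 1, 1.33, 1.5, 2. The full cross-product of the stated
factors is 50·7·7·5·7 = 85,750 cases, generated reproducibly from a single
seed; threshold 0.5, budget 10,000 epochs. For desk-scale runs the population
is subsampled deterministically (first k after a seeded shuffle); the
acceptance checks use 2,000 cases and 2,000 epochs per loss, which preserves
the final-gap ordering the full run exhibits while keeping a laptop-friendly
runtime.

## MDA

The operator refines a C×H×W map with a channel stage (spatial mean → 1-D
convolution across channels → sigmoid → per-channel rescale) followed by a
directional stage (length-W and length-H directional means → sigmoid →
broadcast multiplication). All three poolings are arithmetic means. The
kernel size follows the efficient-channel-attention rule — nearest odd
integer to `log₂(C)/γ + b/γ` with γ = 2, b = 1, ties resolved downward — and
the convolution carries no bias, so the whole operator owns exactly k learned
scalars (5 for C = 256). The directional weights multiply the *refined* map,
applied by both branches in parallel, keeping the two directions
order-independent; multiplying the raw block input instead would be a
defensible alternative reading of the design, but the parallel-on-refined
form matches the staging of the operator. Kernel weights initialize to zeros
(the untrained operator is then a benign ×0.5 channel scaler with directional
weights in (0, 1)); a seeded random initialization is available.

Because every weight lies strictly in (0, 1), the operator is an elementwise
contraction and preserves signs — both are asserted, along with shape
preservation and determinism, by the invariant suite (`mda selftest`).

## Slide triage

The flow mirrors a count-and-flag auxiliary-diagnosis pipeline at desk scale:

1. **Background filter** — saturation-channel thresholding. The saturation
   image is clipped at 0.35 before an Otsu threshold is chosen on a
   downsampled copy, so the threshold separates white background from stained
   tissue rather than pale tissue from dark nuclei; pixels below a 0.02
   saturation floor are always background. The method is a standard choice
   for stained-tissue masking; only the step, not the algorithm, is fixed by
   the triage design.
2. **Tiling** — a regular non-overlapping grid (stride = patch size, default
   640 px); edge remainders are dropped so every patch is exactly square;
   patches under 5% tissue by mask are discarded (both config-exposed).
3. **Counting** — any callable `detector(patch_pixels, patch) -> int`. The
   shipped default is the synthetic-fixture oracle that reads the generator's
   ground-truth ledger; a connected-component blob counter is included for
   arbitrary rasters (it merges touching nuclei and is a stand-in, not a
   validated counter). A detector failure marks the patch invalid (−1) and is
   recorded, never silently zeroed.
4. **Flagging** — strictly `count > threshold` (default 50 cells/patch — a
   configuration default, no clinically fixed value exists).
5. **Overlay** — flagged patches are red-tinted and outlined; unflagged
   pixels are byte-identical to the input.

The synthetic slide generator emulates only what the pipeline exercises:
white background, pink tissue washes per patch, and dark-purple elliptical
cells whose exact centers are returned in a ledger. It does *not* emulate
stain variability, tissue morphology, out-of-focus regions, overlapping
nuclei populations or pyramidal WSI formats — so passing tests demonstrate
the pipeline's accounting (tiling, conservation, thresholding, rendering) on
clean inputs, not detection performance on real slides.

## Known limitations

* CIoU's gradient is the α-frozen one; differentiating through the trade-off
  weight would change it (both conventions exist in the wild).
* The experiment-1 canvas/scale convention is a documented package default;
  reported speedup ratios move with it.
* The randomized-population ordering results are asserted at the subsampled
  desk scale, not at the full 85,750×10,000 size.
* The blob counter undercounts touching nuclei by design; plugging in a real
  trained detector is the intended extension point.
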