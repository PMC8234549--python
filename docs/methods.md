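# Methods

## Problem and scope

The package reproduces, on synthetic data, a pipeline for fabricating
personalized 3D-printed thyroid models: segment the gland from axial
CT-like slices with a Dice-trained encoder–decoder, let a reviewer correct
the mask and mark surgically relevant nodules, rebuild the corrected
anatomy as a printable sphere-and-cylinder lattice, and export one STL per
printing material. A companion statistics module reproduces the design and
analysis of the randomized trial in which such models are evaluated
(sample size, block randomization, Welch and Fisher tests, questionnaire
scoring). Patient imaging, GUI interaction, and physical printing are out
of scope.

## Segmentation model

The network is the canonical U-Net pattern: `depth` encoder levels of two
(3×3 convolution → batch normalization → ReLU) blocks followed by 2×2
max-pooling; a two-block bottleneck; a mirrored decoder of 2× nearest
upsampling + 3×3 convolution, concatenation with the encoder skip, and two
more blocks; and a 1×1 sigmoid head. Input and output are one-channel
H×W maps with H, W divisible by 2^depth.

All layers, Adam, and the loss are implemented directly on float32 numpy
arrays (channels-last; convolutions as one GEMM per kernel offset). This
keeps the package dependency-light and the arithmetic fully inspectable;
it is sized for desk-scale models, not GPU-scale ones.

* **Dice metric.** DSC(y, y′) = 2|y∩y′|/(|y|+|y′|); two empty masks score
  1.0 (consistent with the prospective-DSC convention below). Note the
  denominator is the sum of the two mask sizes, not the union — the union
  form would score 2 for identical masks.
* **Loss.** Soft Dice, L = 1 − (2Σpy + ε)/(Σp + Σy + ε) with ε = 1.0 in
  numerator and denominator, averaged per sample over the batch; ε keeps
  the loss defined (and zero) on empty targets.
* **Selection.** After each epoch the mean per-volume hard DSC on the
  validation volumes is recorded; the returned model is the snapshot of
  the best validation epoch. Per-volume (not per-slice) averaging weights
  every case equally regardless of gland extent.
* **Unstated hyper-parameters.** Optimizer (Adam, lr 1e-3), channel
  widths, and threshold (0.5) are not dictated by the method and are
  exposed in `NetworkConfig`. The faithful configuration is 256×256,
  depth 4, 64 base channels, batch 16; `NetworkConfig.desk()` is the
  reduced 64×64 / depth 2 / 8-channel configuration used throughout the
  tests, batch 16, lr 3e-3, 10 epochs — on the 40-phantom training split
  the validation DSC reaches a stable plateau within the first half of
  the run, and a full training completes in roughly ten minutes on one
  CPU core.

## Augmentation

Each training slice is re-augmented every epoch. Four operations are
applied independently, each with probability 0.70, parameters uniform in
their ranges: per-axis scaling 0.70–1.30, rotation ±10°, shear ±10°, and
coarse dropout; a horizontal flip follows with probability 0.50.
Decisions fixed here because the scheme itself leaves them open:

* order is scale → rotate → shear → dropout → flip (reproducibility);
* geometric resampling is bilinear for images and nearest-neighbor for
  masks (binarity preserved), about the image center, zero-filled;
* coarse dropout is realized as one rectangular region whose area
  fraction is drawn from 0.10–0.20 (random aspect ratio 0.5–2), inside
  which each pixel is zeroed independently with probability drawn from
  0.05–0.10 — a literal reading of "per-pixel probability over a region
  of the image area"; scattered multi-patch dropout would also be
  defensible, and the single-region choice is the documented one;
* dropout touches the image only, never the mask.

## Synthetic phantoms

`PhantomSpec` renders a bilobed thyroid — two mirrored ellipsoidal lobes
(default semi-axes 8×11×15 mm at ±11 mm from the midline) bridged by an
anterior cylindrical isthmus (radius 4 mm; radius 0 omits it) — brighter
(0.65) than soft-tissue background (0.30), a dark tracheal tube (0.08),
optional hypodense nodules (0.45) that must lie inside a lobe, and
additive Gaussian noise (sd 0.05), on a 64×64×40 grid at 0.9 mm pixels
and 2.5 mm slices. The mask is the exact voxelization of lobes ∪ isthmus;
nodules are kept as geometric metadata, not burned into the mask, because
they become the second printing material. Cohorts jitter lobe semi-axes
(±15%), lobe offset, isthmus radius and noise per phantom, and are split
train/validation/test 3:1:1 by default (floor train and validation,
remainder to test); the segmentation surrogate uses a 60-phantom cohort
split 4:1:1 = 40/10/10.

What the phantom does *not* emulate: Hounsfield calibration, contrast
kinetics, neighboring organs other than the trachea, partial-volume
blurring, scanner artifacts. Passing the surrogate therefore shows the
pipeline machinery (loss, augmentation, training loop, inference) works
end to end — it does not certify performance on clinical CT, where
contrast is far poorer.

## Editing and prospective DSC

Corrections are an ordered, JSON-serializable script of per-slice polygon
or disk edits (`add` sets pixels to 1, `remove` to 0, applied in order).
Prospectively there is no annotated ground truth, so the corrected mask is
treated as truth and the *prospective DSC* is DSC(corrected, inferred);
an untouched inference scores exactly 1.000. Nodule marks are spheres in
volume-centered mm coordinates (the per-slice "circle" interpretation is a
sphere with circular cross-sections).

## Mesh-type model

Per-slice contours are traced by marching squares at level 0.5 on a
zero-padded slice (so edge-touching regions close), scaled to mm, then
resampled to `max(3, round(perimeter/spacing))` equally spaced nodes
(spacing default 3 mm). The lattice places a sphere (default radius
1.2 mm) at every node and cylinders (default radius 0.8 mm) between
consecutive ring nodes; with inter-slice linking on, each node also
connects to its nearest node on the adjacent slice's largest-overlap
contour (shapely intersection areas; ties to the lowest node index).
Nodules are rendered as one ring per slice plane the sphere crosses
(cross-section radius floored at a quarter of the nodule radius so polar
rings stay printable), or as solid spheres via a flag.

Export tessellates each primitive as a closed surface — 2·res·(res−1)
triangles per sphere and 4·res per cylinder (res = 16 by default; every
primitive satisfies V−E+F = 2) — and writes one binary (or ASCII) STL per
material in mm, scaled by `MeshParams.scale`. Overlapping shells are not
boolean-unioned: FDM slicers union overlapping solids, and exact CSG is
deliberately avoided. Contours too short to form a triangle are dropped.

## Trial statistics

* **Sample size.** d = diff/sd; n₀ is the smallest per-group n whose
  exact noncentral-t power of the two-sided two-sample t-test reaches the
  target; the allocation is ceil(n₀·(1+dropout)). Defaults d = 20/25,
  power 0.80, α 0.05, dropout 0.15 give n₀ = 26 → 30.
* **Randomization.** Permuted blocks (default size 4, two arms): each
  block is a uniform random permutation of a balanced arm multiset.
* **Welch's t** from summaries (mean, SD, n per group), Satterthwaite
  degrees of freedom, two-sided p; both-degenerate identical groups
  return p = 1.
* **Fisher's exact test** enumerates every r×c table with the observed
  margins and sums the probabilities of tables no more probable than the
  observed one (relative tolerance 1e-7) — the probability-ordering
  convention that published two-sided p-values use. Enumeration is capped
  (default 2·10⁶ tables) with an error advising Monte Carlo beyond it.
* **Questionnaires.** First form: 12 items (1–5), categories = items
  1–3 / 4–6 / 7–9 / 10–12 (knowledge, benefits, risks, satisfaction),
  category score the sum of its three items; arm comparison is Welch per
  category. Second form: 4 items plus a forced choice; percentages are
  100·count/total to one decimal.

## Numerical and degenerate-input choices

Coordinates are 0-based (slice, row, col) with pixel centers at integer
positions; even-size center crops start at (D−size)/2. Polygon
rasterization is boundary-inclusive (even-odd interior plus exact
on-edge test). Stored 8-bit stacks round-trip bit-exactly; intensity
windows map stored scales to [0, 1] for the network. All randomness flows
through explicit integer seeds (`numpy.random.default_rng`); identical
seeds give bit-identical phantoms, augmentations, splits, allocations and
training histories.

## Known limitations

The numpy network trains at desk scale only; no GPU path. The phantom's
simplicity inflates segmentation scores relative to clinical CT. The
inter-slice linking rule (nearest node on the largest-overlap contour) is
one reasonable choice among several and can produce long cylinders where
anatomy changes abruptly between slices. Fisher enumeration is exact but
exponential in table size; large sparse tables need the Monte Carlo
fallback the error message suggests. Raw patient-level questionnaire data
are not published, so arm comparisons are exercised on summaries and on
simulated responses.
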