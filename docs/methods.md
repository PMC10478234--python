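# Methods

## Problem and model

Coronary arteries occupy well under 5 % of a CCTA volume, thin out toward
their distal ends, and share their intensity range with other
contrast-filled structures (veins, the ascending aorta).  The package
segments such vessels with a four-level encoder/decoder network over
channel-first (C, D, H, W) feature grids, operating on fixed-depth slabs
(16 slices by default) of a windowed volume.

**Preprocessing.**  HU values are clamped to [−260, 760] — a window that
brackets contrast-enhanced blood while discarding air and dense bone — and
mapped linearly onto [0, 1].  Only the clamp window is externally
prescribed; the linear min–max rescaling is the simplest deterministic
choice and is monotone in HU, so ordering of tissues is preserved.

**Slab inference.**  Volumes deeper than the block depth are cut into
overlapping slabs (stride 8, i.e. half-overlap by default); per-slab class
probabilities are averaged on overlapping slices and the result is
arg-maxed, with exact probability ties resolving to background.  Volumes
shallower than one block are replicate-padded at the end and the padding is
stripped before any metric is computed.  Averaging probabilities rather than
votes keeps the stitched field smooth across slab seams.

**Dense residual blocks.**  Each stage applies H1, H2, H3 (3×3×3
convolution + ReLU, optionally with batch normalisation between convolution
and ReLU) and emits P(X) + A1 + A2 + A3 where A1 = H1(X), A2 = H2(A1),
A3 = H3(P(X) + A2), and P is a pointwise projection (identity at equal
channel widths).  The formula above — first residual: input plus the second
convolution's output; second residual: sum of the input and every
intermediate map — is this package's normative definition of the block, and
is exercised term-by-term by an independent scipy-based oracle in the
tests.

**Contextual attention on skips.**  Q = W_q∗X (1×1×1), K = W_k∗X and
V = W_v∗X (grouped k×k×k, k = 3, zero 'same' padding), attention
A = ReLU(W_f∗[K; Q]) with a single pointwise 2C→C convolution, output
softmax_C(A ⊙ V).  Three points were genuinely open and are fixed here as
package conventions:

* *Softmax axis*: the channel axis — it preserves shape without pooling and
  makes every voxel's channel vector a probability vector (the property the
  tests pin down).  It can be disabled (`channel_softmax=False`) for
  ablation.
* *Group count* of the k³ convolutions: 4, which divides every default
  level width; configurable.
* *Concatenation order*: (K, Q) along channels; fixed and documented, since
  either order defines a valid block.

With k = 1 and a single group the block degenerates exactly to plain
self-attention; the tests enforce this equivalence under shared weights.

**Network assembly.**  Encoder widths are base·2^level (base 16 by default,
8 in the desk preset); 2×2×2 max-pooling after the first three stages;
kernel-2 stride-2 transposed convolutions for decoder upsampling (the
classic 3D-UNet convention; the original figure is not legible on this
point).  Decoder stage i concatenates [attention(enc_i), enc_i,
up(dec_{i+1})] — or [enc_i, up(dec_{i+1})] with identity skips — and a
pointwise fusion convolution brings the concatenation back to the stage
width before the configured block runs.  The fusion layer keeps block
widths identical across skip variants, which makes the parameter cost of
the attention module independent of the block choice: the count deltas of
the two modules are exactly additive
(count(dr_lct) − count(dr) = count(lct) − count(unet)), and the qualitative
ordering unet < sa < lct and r < dr < dr_lct holds for every base width.
Absolute parameter counts depend on channel widths, which are not
externally prescribed, so no absolute count is asserted anywhere.

**Deep supervision.**  Four supervised outputs: the full-resolution head
(L1), the two deeper decoder stages (L2, L3) and the bottleneck (L4) —
there are only three decoder stages, so the fourth loss is carried by the
bottleneck.  Each head is a pointwise convolution + channel softmax; aux
probabilities are trilinearly upsampled to the input size (convex
interpolation keeps per-voxel sums at 1) and compared to the
full-resolution ground truth.  Total loss: L1 + α(L2 + L3 + L4).  The
grouping follows the stated intent that the *other* decoding layers
(plural) get the smaller weight.

**Objective.**  Soft Dice with smoothing constant 1e-5 (handles empty
masks); for binary predictions 1 − loss agrees with the set-based DSC to
within the smoothing term.

**Schedules.**  Epoch-indexed step functions with half-open-left intervals:
LR 1e-5/1e-6/1e-7 at epochs 0/100/160; α = 1, 0.8, 0.8², 0.8³, 0.8⁴ at
epochs 0/40/80/120/160; 180 epochs, batch 3, weight decay 5e-4.  Whether a
boundary epoch itself switches value is a convention; half-open-left is
adopted and tested.  `ScheduleConfig.scaled(n)` compresses the boundaries
proportionally for short runs.

## Numerical implementation

No GPU framework is used: `corovox._autograd` is a reverse-mode autodiff
engine over NumPy arrays implementing exactly the required primitives
(grouped 'same' 3-D convolution via sliding windows + matmul, 2× max
pooling, kernel-2/stride-2 transposed convolution as one einsum, separable
trilinear resizing, batch normalisation, channel softmax).  Every
primitive's gradient was verified against central finite differences.
Training runs in float32; algebraic unit tests run the same code in
float64.  Weight initialisation is He-normal, seeded; Adam carries its
moments in float64.  Batch normalisation defaults ON for training presets
(short CPU runs do not converge without it) and OFF in the algebraic block
tests, where the conv+ReLU unit is taken literally.

## The phantom generator

`phantom_gen` emulates the features of CCTA that make the task hard, not CT
physics:

* a bifurcating centerline tree (default: 2 trees, 3 bifurcation
  generations) whose segment radius shrinks by a fixed factor (0.72) per
  generation, starting from ~2.2 voxels — the rasterized foreground of the
  default 32×64×64 spec is ~1 % of voxels, matching the extreme class
  imbalance of vessel masks;
* tube rasterization by voxel-center-in-capsule, with no partial-volume
  weighting — exactly testable against a brute-force distance oracle;
* vessel intensity 350 HU, attenuated linearly with normalized arc length
  from the root by up to 40 % at the tips (the simplest monotone model of
  uneven contrast-medium distribution);
* a bright distractor tube (300 HU) that is *not* in the label,
  rejection-sampled to never overlap the tree, so intensity thresholding
  alone cannot solve the phantom;
* additive zero-mean Gaussian HU noise (σ = 20).

One integer seed drives separate sub-streams for topology, angles,
distractor placement and noise, so toggling noise leaves geometry
untouched.  Deliberately absent: beam hardening, partial volume, cardiac
anatomy, motion artifacts.  Passing tests on phantoms therefore demonstrate
that the pipeline learns thin bright tubular structure against distractors
at realistic class imbalance — not clinical-grade performance on real CCTA.

## Metrics

Boundary voxels are foreground voxels with a background-or-outside
6-neighbour (the boundary rule is a package convention; it is standard and
exactly testable).  Distances are Euclidean, in voxel units by default, per
axis multiplied by the spacing in mm mode.  The KD-tree implementation is
required by the tests to match brute-force all-pairs evaluation — the
brute-force definition is normative.  Empty masks raise typed errors
instead of returning sentinels, so batch summaries cannot silently absorb
degenerate predictions; `evaluate_case` records such fields as missing.

## Desk preset and problem sizes

The full-scale training regime (16×512×512 slabs, 180 epochs, GPU-class
compute) is far beyond a CPU session, so the package ships a first-class desk preset:
8 base channels, 16×32×32 phantoms, 16 training / 4 validation / 6 test
cases, a 16-epoch proportionally compressed schedule, batch 2, and
learning rates (3e-3, 1e-3, 3e-4) — the 1e-5-magnitude rates of the
full-scale schedule suit a long GPU run and do not move a 16-epoch run off
its initialisation.  The
tests and the acceptance script use these sizes; with them the full
pipeline (generation → training → slab inference → metrics) reaches mean
test DSC ≥ 0.9 in a few minutes on one core.

**Deep supervision at desk scale.**  With very few optimizer steps
(tens per run), the three auxiliary losses initially dilute the
full-resolution head's gradient, so the early-epoch validation-DSC
advantage of deep supervision only emerges once a run has enough steps per
epoch; the comparison test therefore uses depth-32 phantoms (three
overlapping slabs per case, ~24 steps/epoch) to probe the early phase at a
step count where the comparison is meaningful.  Long-run behaviour is
unaffected: with and without deep supervision the desk preset converges to
the same DSC range.

## Known limitations

* The phantom is a geometric emulation; no claim is made about clinical
  CCTA performance.
* Anisotropic pooling, multi-class labels, DICOM ingestion and
  registration are out of scope; NIfTI is the only on-disk format.
* Surface distances are plain ASSD/HD (no 95th-percentile variant, no
  centerline metrics).
* Single-device determinism only: results are bit-reproducible for a fixed
  seed on one machine, but BLAS differences may change low-order bits
  across platforms.
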