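# corovox

3-D segmentation of thin, branching, contrast-enhanced vessels — the
coronary-artery problem in CT angiography (CCTA) — as a tested, reusable
Python package.  It is aimed at medical-image-analysis researchers who want
the full method exercisable end to end on one CPU core: the network, its
training strategy, the evaluation metrics, and a synthetic vascular phantom
generator standing in for clinical data.

## The method

The segmenter is a four-level 3-D U-Net over fixed-depth slabs of a
HU-windowed volume (window [−260, 760] HU, rescaled linearly to [0, 1]),
with two architectural additions and one training strategy:

* **Dense residual (DR) blocks** in every encoder/decoder stage.  With
  H(·) = conv3×3×3 + ReLU and P(·) a pointwise projection (identity at equal
  widths), a block computes

      A1 = H1(X),  A2 = H2(A1),  R = P(X) + A2,  A3 = H3(R)
      Y  = P(X) + A1 + A2 + A3

  so shallow features (thin distal branches, faint boundaries) survive the
  convolution stack instead of washing out.

* **Local contextual transformer (LCT) attention** on the skip connections.
  Queries stay pointwise, Q = W_q ∗ X (1×1×1), while keys and values gather
  local context with grouped k×k×k convolutions, K = W_k ∗ X, V = W_v ∗ X
  (k = 3).  An attention map A = ReLU(W_f ∗ [K; Q]) gates the values
  element-wise, Y = softmax_C(A ⊙ V), emphasising vessel-adjacent regions and
  suppressing look-alike bright structures (veins, aorta) before the decoder
  consumes the encoder features.

* **Deep supervision with a Dice objective.**  Every supervised output o is
  scored with soft Dice, L = 1 − (2·Σ p·g + s)/(Σ p + Σ g + s), which is
  robust to the extreme foreground/background imbalance of vessel masks
  (< 5 % foreground).  The total loss is L1 + α(L2 + L3 + L4) over the
  full-resolution head, the two deeper decoder heads and the bottleneck head,
  with α stepping down 1 → 0.8 → 0.8² → 0.8³ → 0.8⁴ over training, under a
  piecewise learning-rate schedule (Adam, weight decay 5·10⁻⁴).

The network stack (tensors, reverse-mode autodiff, grouped 3-D convolution,
pooling, transposed convolution, trilinear resizing, batch normalisation,
Adam) is implemented in the package directly on NumPy — see
`corovox._autograd` and `corovox.nn` — so there is no GPU or deep-learning
framework dependency.

Evaluation uses the five standard metrics: DSC = 2TP/(2TP+FN+FP),
Recall = TP/(TP+FN), Precision = TP/(TP+FP), plus average symmetric surface
distance (ASSD) and Hausdorff distance (HD) between the 6-connectivity
boundary voxel sets.

## Worked example

Train the desk preset (8 base channels, 16×32×32 phantoms, 16-epoch
compressed schedule — a few minutes on one CPU core) and evaluate on held-out
phantoms:

```python
from corovox.runtime import desk_train_config, evaluate_on_cases, make_dataset, train

cfg = desk_train_config(seed=1, epochs=16, n_train=16, n_val=4, n_test=6)
result = train(cfg)
print(f"best validation DSC {result.best_val_dsc:.3f}")
_, _, test_cases = make_dataset(cfg)
print(evaluate_on_cases(result.net, test_cases).mean(numeric_only=True).round(3))
```

Output from this exact run:

```
best validation DSC 0.954
case         2.500
dsc          0.933
recall       0.890
precision    0.981
assd         0.117
hd           4.761
dtype: float64
```

The mean test DSC of 0.93 means the predicted vessel masks overlap the
ground-truth trees almost completely at this scale; precision near 0.98
shows the bright distractor tube is rejected, recall of 0.89 reflects
missed voxels at the thinnest distal tips, and the ASSD of ~0.1 voxels says
the predicted surfaces sit essentially on the true ones (the ~4.8-voxel HD
is the single worst distal miss).

The same pipeline is scriptable from the shell:

```bash
corovox simulate --out cases/ --n-cases 4 --seed 7
corovox train --ckpt model.npz --seed 1
corovox predict --ckpt model.npz --in cases/case000_image.nii.gz --out pred.nii.gz
corovox evaluate --pred pred.nii.gz --gt cases/case000_label.nii.gz
corovox ablate --variants unet,sa,lct,r,dr,dr_lct
```

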