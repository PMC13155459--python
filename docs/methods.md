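# Methods

This note documents the models, estimators and design choices behind `xakd`,
including what the synthetic world does and does not establish.

## Problem setting

A convolutional teacher and a vision-transformer student classify the same
labeled image patches (histopathology-style textures). The student is trained
with a composite objective that adds two forms of teacher supervision to
cross-entropy: response distillation on softened logits, and stage-level
feature distillation routed through automatically matched teacher–student
layer pairs.

## Similarity estimators

**Unbiased HSIC.** For Gram matrices `K, L` (n ≥ 4) with zeroed diagonals
`K̃, L̃`:

```
HSIC(K, L) = [ tr(K̃L̃) + (1ᵀK̃1)(1ᵀL̃1)/((n−1)(n−2)) − (2/(n−2))·1ᵀK̃L̃1 ] / (n(n−3))
```

The estimator is unbiased, hence occasionally slightly negative at small n;
values are *not* clamped — layer ranking uses raw numbers, and a degenerate
(constant) representation raises instead of silently scoring zero, because a
silent zero would corrupt candidate ranking.

**Linear CKA** normalizes by `sqrt(HSIC(K,K)·HSIC(L,L))`. The minibatch
variant accumulates the numerator and both self-terms across aligned batches
and normalizes once with the square-root-of-products form. (A sum-form
denominator sometimes seen in print would break the `[0,1]` bound that CKA is
defined to satisfy; the square-root form is the one implemented.) Single-batch
CKA on one probing batch of up to 240 samples is the default (k = 1).

**KCCA.** Views are compared through RBF kernels with per-view
median-heuristic bandwidths (deterministic given inputs). With centered Gram
matrices `K_X, K_Y` and ridge κ, the objective maximizes
`αᵀK_X K_Y β` under `αᵀ(K_X+κI)K_X α = βᵀ(K_Y+κI)K_Y β = 1`. Because a
centered Gram matrix commutes with itself, `M = K² + κK` is symmetric PSD, so
the solution is the SVD of `M_X^{−1/2} K_X K_Y M_Y^{−1/2}`, computed with a
pseudo-inverse square root (eigenvalues below `1e−12·λ_max` dropped). Numerical
round-off can push correlations marginally outside `[0,1]`; they are clipped by
default, with raw values retrievable. κ is an **absolute** ridge (κ = 1e−4 by
default, not scaled by n); the scalar score ρ̄ averages the top m = 10
correlations. With identical views the spectrum is `λ/(λ+κ)` over the Gram
eigenvalues, so ρ₁ → 1 as κ → 0 — the identity check used in tests.

## Layer matching

Both models are partitioned into early/mid/late thirds by depth (remainder
layers to the earlier stages — deterministic where "equal thirds" leaves a
choice). Stages are paired positionally; cross-stage pools are deliberately
not searched. Per stage, the top-3 CKA cells are candidates; KCCA picks the
argmax of ρ̄, with ties broken by higher CKA then smaller indices (an
invented but deterministic rule). The teacher representations come from the
post-warm-up weights, matching the protocol of computing similarity once
after warm-up and freezing it. Candidates whose KCCA solve fails are skipped
with a warning rather than aborting the run, so degenerate toy inputs cannot
kill the pipeline; failure of *all* candidates in a stage is an error.

## Distillation pathways

**Tokens.** Three learnable tokens (init N(0, 0.02), like patch embeddings)
are appended *after* the patch tokens so patch indices — and thus
attention-map extraction — are unchanged; their positional entries start at
zero. Tokens attend fully and propagate through every block; stage s is read
out (read-only) after the block of its bridge's student layer. The classifier
head reads the CLS slot only.

**Projectors.** Per bridge pair: GAP → linear(C→512) → LayerNorm → GELU →
linear(512→D) encoder, mirrored decoder back to C. D defaults to the student
embedding dimension (192 for a DeiT-scale student; 32 for the tiny fixture).
Projectors are trained jointly with everything else (no pre-training stage);
the decoder only serves the reconstruction loss and is unused at inference.
Teacher activations and logits enter the student objective as constants, so
no gradient flows from student-side losses into the teacher; the teacher
keeps fine-tuning on its own cross-entropy during distillation.

**Objective.** `L_total = α·L_cls + (1−α)·L_kd + γ·(L_feat + λ_rec·L_recon)`
with stage weights over the three cosine losses. Defaults α = 0.5, T = 4,
γ = 1, λ_rec = 1 and the primary stage preset (1, 1, 0) — the source protocol
does not state the scalar weights, so these are package defaults, all
config-exposed. KL uses natural log with batch-mean reduction, teacher
distribution first.

## Training protocol

SGD (momentum 0.9 — a package choice), weight decay 1e−3, batch size 16, step
scheduler (step 5, decay 0.1), learning rate 0.01 (unstated upstream;
config-exposed). Warm-up: 3 epochs of plain CE for both models, the
desk-scale substitute for pretrained-teacher initialization. The probing
batch is min(240, train size) drawn with a dedicated seed. Inputs are
standardized by fixed per-channel constants (frozen reference statistics of
the default generator — the synthetic analog of ImageNet mean/std
normalization); this step is load-bearing: without centered inputs the conv
teacher optimizes far slower than the LayerNorm-rich ViT and the
teacher-stronger-than-student premise of distillation fails. Conv stages
carry a single-group ChannelNorm as the stand-in for the batch normalization
every realistic teacher architecture has. Evaluation reports accuracy and
macro-averaged precision/recall (the averaging convention is a package
choice) with full confusion counts.

## Synthetic world

Each class is a field of Gaussian blobs (nucleus-like, dark purple hues) on
an eosin-pink background with low-frequency stain wobble and pixel noise;
adjacent classes share closely overlapping density/radius/hue parameters to
emulate fine-grained subtype structure. The generator is seed-deterministic
and split-stratified (60/20/20 by default). It does **not** emulate slide-
level context, magnification variation, patient-level correlation, staining
batch effects, or class imbalance — so a green end-to-end test establishes
that the machinery (matching, tokens, projectors, objective) behaves and that
distillation does not hurt at desk scale, not that the headline gains on real
histopathology benchmarks reproduce.

## Numerical and engine notes

All models run on `xakd.nn`, a small NumPy reverse-mode autodiff engine
(float64; conv via im2col; GELU in tanh approximation). Gradients of every
layer type are verified against central finite differences in
`tests/test_autodiff.py`. Gram symmetry is validated to 1e−8; attention maps
are min-max normalized with the all-equal map sent to zeros; softmax and
log-softmax use max-subtraction. Determinism: every stochastic component
(generator, splits, init, batch order, probing batch) derives from explicit
`numpy` Generators seeded from the run seed, so identical configs reproduce
identical bridge maps and confusion matrices.

## Known limitations

- Desk-scale only: the engine is single-threaded NumPy; models beyond a few
  hundred thousand parameters become impractical.
- ρ̄ under RBF kernels with small κ saturates near 1 for many layer pairs;
  discrimination rests on small differences (raising κ sharpens it, as the
  monotonicity test with κ = 1e−2 shows).
- The benefit criterion (distilled ≥ CE-only in mean) is evaluated near the
  fixture's accuracy ceiling; margins are small by construction.
- No augmentation is applied during training by default (determinism in
  tests); the augmentation hooks mirror mild rotation/flip/jitter/blur only.
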