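# xakd — cross-architecture knowledge distillation guided by representation similarity

`xakd` implements a knowledge-distillation framework for transferring the
inductive biases of a convolutional teacher into a vision-transformer student,
aimed at histopathology-style patch classification where ViTs underperform on
limited data. Its distinguishing component is *representation-similarity-guided
layer matching*: instead of pairing teacher and student layers by depth or by
hand, compatible layers are discovered from the models' own activations.

## Method

Both networks are partitioned by depth into three contiguous stages (early,
mid, late). On a fixed probing batch, every layer is summarized as an
`n × d` matrix — the CLS token state for transformer blocks, globally
average-pooled features for conv stages. For each stage:

1. **CKA candidate selection.** Linear centered kernel alignment between all
   teacher/student layer pairs of the stage,

   `CKA(X, Y) = HSIC(K, L) / sqrt(HSIC(K, K) · HSIC(L, L))`, `K = XXᵀ, L = YYᵀ`,

   using the unbiased three-term HSIC estimator on diagonal-zeroed Gram
   matrices. The top-3 pairs per stage are retained.
2. **KCCA refinement.** For each candidate, regularized kernel CCA with RBF
   kernels (median-heuristic bandwidth, ridge κ = 1e-4) yields canonical
   correlations ρ₁ ≥ ρ₂ ≥ …; the pair maximizing ρ̄, the mean of the top
   m = 10 correlations, becomes the stage's *bridge pair*. CKA captures
   geometric similarity of example organization; KCCA adds evidence of shared
   (possibly nonlinear) latent factors.

Matching runs once after a supervised warm-up and stays frozen. Distillation
then combines three signals into

`L_total = α·L_cls + (1−α)·L_kd + γ·(L_feat + λ_rec·L_recon)`

- `L_kd`: response distillation, `KL(softmax(z_t/T) ‖ softmax(z_s/T))·T²`;
- `L_feat`: stage-level feature distillation through three learnable
  *distillation tokens* appended to the student sequence (read out at their
  bridge layers, propagated through all blocks) and three teacher-side
  autoencoder projectors (GAP → C→512→D encoder, mirrored decoder), aligned
  by a scale-invariant cosine loss with stage weights (1, 1, 0) by default;
- `L_recon`: the projectors' reconstruction loss, trained jointly.

Models are implemented on a small NumPy reverse-mode autodiff engine
(`xakd.nn`), so the package has no deep-learning-framework dependency; the
engine's gradients are verified against finite differences in the test suite.

## Worked example

```python
from xakd.fixtures import SyntheticDatasetSpec
from xakd.training import RunConfig, run_pipeline

config = RunConfig(
    dataset=SyntheticDatasetSpec(n_classes=8, n_per_class=40, image_size=32, seed=1),
    warmup_epochs=3, distill_epochs=5, seed=1, out_dir="run",
)
results = run_pipeline(config)
print(results["bridges"]["early"])
print(results["student_test"]["accuracy"])
```

prints (values from this exact run):

```
{'teacher_layer': 1, 'student_layer': 1, 'cka': 0.7608443299999118, 'rho_bar': 0.9973787613965323}
0.8125
```

The bridge entry says stage-one distillation flows from teacher conv stage 1
into student block 1 — the pair with the highest mean canonical correlation
among the stage's top-CKA candidates — and the student reaches 81% test
accuracy on the held-out split of the 8-class synthetic fixture after five
distillation epochs. `run/` contains the frozen bridge map, per-stage CKA
matrices (CSV + heatmap), the per-step loss log, metrics, and a CLS
attention-map overlay.

The synthetic fixture emulates fine-grained stained-tissue subtypes: Gaussian
blob textures on an eosin-pink background whose density, radius and hue
differ only slightly between adjacent classes. `xakd generate / match /
distill / eval / attention` expose the same steps on the command line, and
class-per-folder image directories of real patches are accepted wherever the
synthetic spec is.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete pipeline from scratch — dataset synthesis, warm-up,
one-shot CKA+KCCA matching, joint distillation, evaluation — and writes the
results JSON; run artifacts are placed next to it for inspection.
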