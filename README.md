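# recalseg

Multi- and single-modality feature recalibration for 3D brain-tumor
segmentation.

## The problem

Gliomas are segmented from four co-registered MRI modalities (T1, T2, T1c,
Flair) into nested subregions: necrosis / non-enhancing core (NCR/NET,
label 1), edema (ED, label 2) and enhancing tumor (ET, label 4), evaluated
as whole tumor (WT = 1∪2∪4), tumor core (TC = 1∪4) and enhancing tumor
(ET = 4).  Each modality is sensitive to different subregions — edema is
bright on T2/Flair, the enhancing rim stands out against the necrotic core
on T1c, and the tumor as a whole is dark on T1.  A single multi-modality
network (MMN) fuses all four channels, but it does not exploit these
modality-specific relationships explicitly.

`recalseg` trains the MMN jointly with two lightweight single-modality
networks (SMNs) on T1c and Flair, each supervised on the label grouping its
modality shows best, and fuses the branches at every decoder scale with a
**Dual Recalibration Module (DRM)**:

* **Spatial recalibration (SR).**  Each branch's feature block
  `F_b ∈ R^{R×O×P×Q}` is compressed to one map by a 1×1×1 convolution; the
  per-branch maps are softmax-normalized *across branches* at every voxel,

  `w_b(x) = exp(z_b(x)) / Σ_k exp(z_k(x))`,  `F_b^SR = w_b ⊙ F_b`,

  so the branches share the voxel's unit weight budget.

* **Channel recalibration (CR).**  Global average pooling reduces every
  branch to an R-vector; the concatenated vectors feed three independent
  branch-specific fully-connected heads with a sigmoid,

  `u_b = σ(FC_b([GAP(F^SR_MMN); GAP(F^SR_T1c); GAP(F^SR_Flair)]))`,

  which rescale each branch's channels (squeeze-excitation across
  branches).

The fused feature `F_out = Σ_b u_b ⊙ (w_b ⊙ F_b)` replaces the MMN decoder
feature.  Training minimizes per network a compound Dice + cross-entropy
loss and combines the networks as

`L_T = λ·L_MMN + (1−λ)/2 · (L_SMN-T1c + L_SMN-Flair)`.

A seeded ellipsoid tumor-phantom generator reproduces the nested geometry
and the qualitative modality contrasts, so the complete pipeline — I/O,
preprocessing, training, sliding-window inference, BraTS-style metrics
(Dice, PPV, sensitivity, HD95 in mm) and the eight ablation variants —
runs and is tested on a CPU without any external imaging data.

The networks run on a compact numpy reverse-mode autodiff engine
(`recalseg.nn`) with 3D convolution, instance normalization, trilinear
upsampling and Adam/AdamW/SGD built in; gradient correctness is covered by
adjoint and finite-difference tests.

## Worked example

```python
import numpy as np
from recalseg.phantom import PhantomSpec, generate_phantom
from recalseg.engine import TrainConfig, train, predict
from recalseg.metrics import evaluate_labels

case = generate_phantom(PhantomSpec(seed=7))           # 32^3, 4 modalities
cfg = TrainConfig.desk_scale(smn_set="none", learning_rate=1e-3,
                             batch_size=1, patches_per_epoch=8, epochs=25,
                             do_augment=False, val_fraction=0.0, seed=3)
result = train([case], cfg)                            # 200 steps
print(round(result.history[0]["train_loss"], 3),
      round(result.history[-1]["train_loss"], 3))
report = evaluate_labels(predict(case[0], result.model), case[1])
print(round(report.wt.dice, 3), round(report.wt.hd95, 1))
```

prints

```
1.156 0.437
0.991 1.0
```

— the compound loss falls from 1.156 to 0.437 over 200 desk-scale training
steps, and the fitted model segments the phantom's whole-tumor region with
Dice 0.991 at a 95th-percentile surface distance of 1.0 mm.

The same pipeline is available from the shell:

```
recalseg phantom --out data --n 5 --shape 32 32 32 --seed 1
recalseg train   --data data --out run --desk-scale --seed 1
recalseg predict --case data/phantom_000 --checkpoint run/checkpoints/epoch_001.npz \
                 --config run/config.yaml --out pred.nii.gz
recalseg evaluate --pred pred.nii.gz --truth data/phantom_000/phantom_000_seg.nii.gz
recalseg ablate  --data data --out ablation --desk-scale --seed 1
```

`ablate` trains all eight architecture variants (MMN only; MMN + one or
both SMNs; SMNs on all labels; plain convolutional fusion; SR only; CR
only; full DRM) and writes a region-by-metric CSV.

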