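# se3refine

All-atom protein structure refinement with an SE(3)-equivariant graph
transformer, implemented in pure scientific Python (NumPy/SciPy), with its
own reverse-mode autodiff tape for training.

## The problem

Predicted protein structures — e.g. from template-free structure
predictors — are usually close to the native conformation but carry local
errors in backbone and especially side-chain geometry.  Refinement takes a
predicted model and moves its atomic coordinates toward the native
structure.  `se3refine` does this end to end: every heavy atom's 3D
position is adjusted directly by a learned per-atom shift,

    x_refined = x_initial + Δx(x_initial; θ),

with no fragment resampling, rotamer rebuilding, or molecular-dynamics
sampling.

## The model

A structure is encoded as a k-nearest-neighbour atom graph (default
k = 128).  Node features are a 37-way heavy-atom-type one-hot (the fixed
"atom37" vocabulary) concatenated with a 20-way residue-type one-hot.  Each
directed edge carries 49 rigid-motion-invariant scalars:

* **36 radial-basis distance bins** `exp(−((d − i·σ_d)/σ_d)²)`,
  i = 0…35, σ_d = 0.57 Å (grid spans 0–20 Å);
* **1 covalent-bond flag**: set when 0.4 Å < d < r_i + r_j + 0.56 Å with
  element covalent radii r (C 0.77, N 0.70, O 0.66, S 1.04 Å);
* **3 relative-position** components of the displacement expressed in the
  source residue's local frame (origin Cα, y toward N, z normal to the
  C–Cα–N plane, x = y × z);
* **9 relative-orientation** components: the destination residue's frame
  axes in the source residue's basis.

The network is an SE(3)-equivariant transformer: two attention blocks
(16 channels, 4 heads, embedding width 32), each followed by an equivariant
normalization layer.  Invariant scalars (type-0) and equivariant 3-vectors
(type-1) are carried per atom; vectors are only ever combined by channel
mixing and scalar gating of unit displacement vectors, so the predicted
shifts rotate exactly with the input and ignore translations.  The output
head is zero-initialized: an untrained model is the identity refiner.

Training regresses the per-atom shifts to the native structure after rigid
superposition (Kabsch) of native onto model — an MSE loss in Å², Adam with
β₁ = 0.9, β₂ = 0.999, weight decay 0.001, batch size 1, early stopping on
validation loss, k-fold cross-validation with selection of the
lowest-validation-loss checkpoints for ensemble inference.

Quality metrics included: GDT-TS / GDT-HA (cutoffs {1,2,4,8} / {0.5,1,2,4} Å,
exhaustive at small n), Cα-RMSD, and all-atom lDDT (15 Å inclusion radius,
{0.5,1,2,4} Å tolerances), plus best-of-ensemble selection by GDT-HA.

## Worked example

```python
import numpy as np
from se3refine import SE3Refiner, PerturbSpec, evaluate, make_dataset

pairs, manifest = make_dataset(50, spec=PerturbSpec(cartesian_sigma=0.5), seed=100)
train, test = pairs[:40], pairs[40:]

est = SE3Refiner(max_epochs=12, seed=0)
est.fit(train[:32], validation_data=train[32:])

for name, structs in [("initial", [p.initial for p in test]),
                      ("refined", est.transform([p.initial for p in test]))]:
    reps = [evaluate(s, p.native) for s, p in zip(structs, test)]
    print(name,
          "Cα-RMSD %.3f Å" % np.mean([r.rmsd_ca for r in reps]),
          "GDT-HA %.1f" % np.mean([r.gdt_ha for r in reps]))
```

prints (seeds as above):

```
initial Cα-RMSD 0.782 Å GDT-HA 81.1
refined Cα-RMSD 0.617 Å GDT-HA 87.6
```

i.e. on ten held-out synthetic models with 0.5 Å atomic jitter, twelve
training epochs cut the mean Cα deviation by ~0.17 Å and raise the mean
high-accuracy global distance score by ~6 points.

There is also a CLI covering the same pipeline:

```bash
se3refine fixtures --outdir runs/fx --n-pairs 20 --seed 0
se3refine train    --fixtures-dir runs/fx --outdir runs/tr --n-folds 2
se3refine refine   runs/fx/initial_000.pdb --outdir runs/rf \
                   --checkpoint runs/tr/model_0.npz
se3refine evaluate runs/rf/refined_0.pdb --native runs/fx/native_000.pdb \
                   --outdir runs/ev
```

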