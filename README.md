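# ordivox

Ordinal, voxel-based classification of 3D DaTSCAN SPECT volumes.

Parkinson's disease reduces the density of presynaptic dopamine transporters
in the striatum. A DaTSCAN (¹²³I-ioflupane) SPECT study images that density,
and clinicians grade the result on an ordered scale: no alteration of the
presynaptic nigrostriatal pathway (class 0), slight alteration — typically
one putamen affected (class 1), or severe alteration of both sides
(class 2). `ordivox` implements a complete machine-learning pipeline for
this *ordinal* grading problem that works on **every voxel** of the
spatially normalised volume rather than on pre-drawn regions of interest:

1. **Flattening** — each R×C×Z volume becomes a feature vector via the fixed
   bijection `index = layer·R·C + row·C + col`.
2. **Ordinal ReliefF (OReliefF)** — ReliefF attribute ranking with an
   ordinal miss penalty ρ: for a query pattern of class *y*, the
   contribution of nearest misses from class *l* is weighted by
   ρ = |y − l| / Σ<sub>l′≠y</sub>|y − l′|, so disagreement with far classes
   raises a voxel's quality more than disagreement with adjacent ones. The
   top fraction of the ranking (⌊p·S⌋ voxels) is kept as *informative
   voxels*.
3. **Macrovoxel distribution augmentation** — for each informative voxel,
   the values of its width-*w* macrovoxel (the surrounding cube,
   intersected with the informative set) are pooled across all training
   images of one class; four candidate location–scale families (alpha,
   generalised extreme value, Student's *t*, beta) are fitted by maximum
   likelihood and the family minimising the sum of squared errors against
   the density-normalised histogram is kept. New class-conditional images
   are sampled voxel-wise from these fits. Configurations CONF0–CONF5
   (which classes to duplicate/triplicate) and the noisy-replication
   baseline RAND are provided.
4. **Immediate-threshold ordinal logistic regression** — a latent score
   f(x) = w·x with ordered thresholds b₁ ≤ … ≤ b<sub>L−1</sub>; each
   training example is penalised with the logistic surrogate
   s(z) = log(1+e⁻ᶻ) only against the two thresholds bounding its own
   segment, plus a ridge term λ‖w‖².
5. **Ordinal evaluation** — CCR (accuracy), MAE, per-class MAE and
   MMAE = max<sub>l</sub> MAE<sub>l</sub>, the error of the worst-ranked
   class, which a majority-class classifier cannot hide on imbalanced data.
6. **Experiment protocol** — stratified 70–30 hold-out (per-class floor
   rule), 5-fold cross-validation over a feature-fraction grid, repeated
   augmentation studies, and non-parametric comparison
   (Kolmogorov–Smirnov normality, Kruskal–Wallis with average ranks,
   Mann–Whitney post hoc).

Because clinical SPECT datasets are private, the package ships a phantom
generator (`ordivox.phantom`) producing aligned 3D volumes with two
ellipsoidal "striatal" regions whose intensity decreases monotonically with
class, plus known ground truth, so the whole pipeline is testable offline.

## Worked example

```python
import numpy as np
from ordivox import (orelieff, select_top_fraction, stratified_holdout,
                     OrdinalLogit)
from ordivox.phantom import PhantomConfig, phantom_dataset

dataset, signal = phantom_dataset(PhantomConfig(), seed=42)   # 135 x 13,440
quality = orelieff(dataset, k=5, seed=1)
cols = select_top_fraction(quality, 0.15)                     # 2,016 voxels
print(f"signal voxels recovered: "
      f"{len(set(dataset.feature_indices[cols]) & set(signal)) / len(signal):.2%}")

tr, te = stratified_holdout(dataset.y, 0.7, seed=7)
train = dataset.subset(tr).select_features(cols)
test = dataset.subset(te).select_features(cols)
res = OrdinalLogit.from_dataset(train, penalty=1.0).fit()
m = res.evaluate(test.X, test.y)
print(f"test CCR {m.ccr:.4f}  MMAE {m.mmae:.4f}")
```

prints

```
signal voxels recovered: 100.00%
test CCR 0.9512  MMAE 0.2500
```

i.e. the ordinal ranking concentrates entirely on the true signal region,
the classifier grades 95% of unseen phantoms correctly, and the worst class
(slight alteration, the clinically confusable one) averages a quarter of a
grade of error. Triplicating that minority class with the macrovoxel
sampler (`CONF5` via `ordivox.experiment.run_augmentation_study`) lowers
the test MMAE below the unaugmented value on this phantom, mirroring the
behaviour of the method on clinical data.

A command-line interface mirrors the stages
(`ordivox phantom | flatten | select | augment | train | eval | experiment`).

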