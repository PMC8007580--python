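# Methods

This note documents the models and procedures implemented in `ordivox`,
their assumptions, the defaults and why, and the numerical choices that a
maintainer or reviewer would want spelled out.

## Problem setting

Input is a set of spatially normalised (pre-registered) 3D SPECT volumes
with ordinal labels 0 < 1 < 2 encoding the severity of presynaptic
dopaminergic deficit. The package assumes registration has already been
done by an external tool; no resampling, intensity normalisation or
registration is applied at load time. Each volume of dims (R, C, Z) is
flattened to an S = R·C·Z feature vector by the fixed 0-based bijection
`index = layer·R·C + row·C + col`. Any fixed bijection is equivalent for
the methods; this one is documented and stable so that feature indices,
macrovoxel geometry and exported masks always agree. Intensities are used
raw: an optional min–max rescaling exists upstream of ReliefF but is off by
default.

## Ordinal ReliefF

ReliefF estimates an attribute quality Q[A] by repeatedly sampling a query
pattern, finding its k nearest hits (same class) and, per other class, k
nearest misses, under Manhattan distance with the per-attribute term
`diff(A, x1, x2) = |x1[A] − x2[A]|`. The update subtracts the mean hit diff
and adds the prior-weighted mean miss diff, weight P(C_l)/(1 − P(C_query)).
The ordinal variant multiplies each class's miss contribution by
ρ_l = |y_q − y_l| / Σ_{l′≠q} |y_q − y_l′|, which sums to 1 over the other
classes and reduces to 1 when L = 2, so OReliefF coincides exactly with
ReliefF on binary problems.

Implementation details that matter:

* Iterations m default to the number of patterns N; queries are drawn
  uniformly without replacement when m ≤ N (with replacement otherwise),
  or can be supplied explicitly for a shared schedule.
* The per-iteration divisor is k; when a class has fewer than k available
  neighbours, all of them are used and the divisor is the actual count. A
  class with no other members contributes nothing (logged, not an error).
* Neighbour ties at equal distance break toward the lower pattern index,
  making the ranking fully deterministic given the schedule.
* A constant attribute accumulates zero diffs and so keeps Q = 0 exactly.
* `select_top_fraction(q, p)` keeps the ⌊p·S⌋ best attributes, descending
  by Q, ties toward the lower index.

## Macrovoxel distribution augmentation

The generative model: class-conditional voxel intensities are independent
across voxels, each following a parametric distribution estimated from the
voxel's *macrovoxel* — the width-w cube centred on it (default w = 3,
the smallest non-trivial neighbourhood; configurable), clipped at volume
borders and intersected with the informative-voxel set — pooled over all
training images of that class. Pooling the neighbourhood multiplies the
per-voxel sample size by up to w³, at the price of assuming local spatial
homogeneity at macrovoxel scale.

Candidate families are alpha, generalised extreme value, Student's t and
beta, all in location–scale form (densities implemented in closed form and
cross-checked against scipy). Parameters are estimated by maximum
likelihood per family (`scipy.stats.<dist>.fit`); the family is then chosen
by the smallest sum of squared errors between the fitted density and the
density-normalised histogram at bin centers. Numerical choices:

* Histogram: `max(10, floor(sqrt(|z|)))` bins spanning [min(z), max(z)]
  (square-root rule, stable for the pooled sizes involved); configurable.
* The beta family is fitted with its support anchored just outside the
  sample range (free four-parameter beta ML is ill-posed: the likelihood
  is unbounded as the support endpoints approach data extremes).
* A fit that fails or produces non-finite densities carries infinite SSE
  and is excluded; if all four fail the sample is reported degenerate.
  Fitting requires at least 8 values and a non-constant sample.
* SSE ties break in the fixed order alpha, GEV, t, beta.

Sampling draws one value per informative voxel independently from its
class's selected distribution. Because the heavy-tailed families can emit
physically implausible intensities, draws outside the pooled sample's
empirical [min, max] are redrawn (up to 100 rounds) and finally clamped:
voxel intensities are bounded physical measurements. Synthetic patterns
live in the reduced (informative-voxel) feature space only.

Study configurations: CONF0 (none), CONF1 (duplicate every class), CONF2
(duplicate classes 1 and 2), CONF3 (duplicate class 1), CONF4 (duplicate
class 2), CONF5 (triplicate class 1), and RAND — the noisy-replication
baseline (triplicate class 1 by duplicating randomly chosen patterns plus
N(0, 0.01) noise on every feature; the noise is applied to the intensities
as stored). Augmentation never modifies or removes original patterns, and
the per-voxel fits are estimated once per training set — repeated study
executions vary only the sampling seed.

## Immediate-threshold ordinal logistic regression

A threshold model: latent score f(x) = w·x and ordered thresholds
b₁ ≤ … ≤ b_{L−1} partition the real line into L class segments;
ŷ = #{j : f(x) > b_j}, with a boundary tie assigned to the lower class for
determinism. The fit minimises

    Σᵢ [ s(f(xᵢ) − b_{yᵢ}) + s(b_{yᵢ+1} − f(xᵢ)) ] + λ‖w‖²,

s(z) = log(1 + e⁻ᶻ), b₀ = −∞, b_L = +∞ (terms dropped) — each example is
penalised only against the two thresholds bounding its own segment. With
L = 2 this is exactly ridge-regularised binary logistic regression with
bias −b₁.

* Optimisation: L-BFGS-B with analytic gradients from a deterministic
  initialisation (zero weights, thresholds evenly spread on [−1, 1]), so
  fits are reproducible without any random state.
* Thresholds are optimised unconstrained; the immediate-threshold loss
  empirically preserves their order, and they are sorted defensively with
  a warning if an inversion occurs (it can, in degenerate cases such as
  constant features).
* λ defaults to 1.0. The ridge strength is a genuinely open choice in this
  design; it is exposed everywhere (`penalty=` / `--lambda`).

Metrics: CCR, MAE, per-class MAE and MMAE = max_l MAE_l. MAE is bounded by
L − 1 and decomposes as Σ_l (N_l/N)·MAE_l; CCR = 1 ⟺ MAE = 0 ⟺ MMAE = 0. A
class absent from the truth vector gets per-class MAE 0 by convention and
is flagged in the result.

## Experimental protocol

* Stratified hold-out: per class, ⌊fraction·N_l⌋ patterns to training
  (guarded against binary-float artefacts such as 0.7·90 = 62.999…),
  the remainder to test.
* Model selection: k-fold stratified CV (default 5) over the training set,
  methods {ReliefF, OReliefF, none} × fraction grid (default 1, 2, 5, 10,
  15, 20, 25, 50, 75 %). Ranking is re-run inside every fold on
  fold-training data only — no selection leakage; the ranking is computed
  once per fold and the fraction grid is swept over it. The operating
  point minimises mean MMAE, ties broken by higher mean CCR, then smaller
  fraction.
* Augmentation study: per configuration, augment the training set, refit,
  score the untouched test set; deterministic CONF0 runs once, stochastic
  configurations default to 30 repetitions.
* Statistics: per-sample one-sample Kolmogorov–Smirnov check against a
  normal with the sample's moments; Kruskal–Wallis omnibus with average
  ranks from a joint ranking (lower = better for MMAE, higher CCR ranked
  better); Mann–Whitney (two-sided) between the two best-ranked
  configurations. Degenerate cases (all values tied) report p = 1 rather
  than failing.
* Seeding: one master seed spawns per-stage seeds (split, CV, selection,
  study), making the full report bit-reproducible.

## Phantom generator

The phantom emulates the qualitative structure of a normalised DaTSCAN
study, not its anatomy: a uniform background with two ellipsoidal
high-uptake regions, on a 24×28×20 grid (13,440 voxels — the same order of
feature/sample imbalance as a clinical volume while keeping full-pipeline
runs to minutes; these sizes are the package's default study conditions).
Default class counts 80/25/30 echo a realistic imbalance with the slight
class scarcest. Intensity defaults follow typical DaTSCAN count
statistics:

* background mean 20, specific striatal amplitude 40 above background
  (striatal-to-background ratio ≈ 3);
* 40 % amplitude reduction per affected side (typical transporter loss at
  diagnosis); class 1 reduces exactly one side, chosen at random per
  image; class 2 reduces both;
* additive Gaussian noise sd 8 (≈ Poisson noise at these counts);
* a multiplicative per-image, per-side binding gain ~ N(1, 0.10),
  reflecting inter-subject uptake variability and physiological
  asymmetry — this is the component that makes the slight-alteration class
  genuinely confusable with its neighbours, as it is clinically;
* local-mean smoothing of radius 1 emulating scanner resolution.

What the phantom does *not* model: anatomy (caudate/putamen shape),
partial-volume effects, scatter/attenuation physics, registration error,
and spatial correlation beyond the smoothing kernel. Passing phantom tests
therefore demonstrates that the pipeline recovers known signal under
controlled ordinal structure and imbalance — not clinical performance.

## Known limitations

* Exact nearest-neighbour search makes (O)ReliefF O(m·N·S); full clinical
  volumes (5·10⁵ voxels) are feasible but slow in pure numpy.
* Voxel-independent generation ignores spatial correlation; augmented
  images are not visually realistic, they only match per-voxel marginals.
* Per-voxel ML fitting of four families dominates pipeline runtime
  (~seconds per hundred voxels); fits are estimated once per training set.
* The alpha family has a z⁻² tail; on moderate samples its best SSE fit is
  occasionally indistinguishable from a GEV fit, so family *identity*
  (unlike fit quality) is not always recoverable.
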