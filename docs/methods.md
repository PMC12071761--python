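# Methods

`nirdisc` classifies near-infrared (NIR) absorbance spectra of stored leafy
vegetables by storage time.  The pipeline is: scatter-correction
preprocessing → small-sample-size-safe discriminant feature extraction →
tree-based classification, evaluated under class-stratified five-fold
cross-validation.  This note records the models, the defaults and their
rationale, the numerical choices, and the known limitations — in
particular what the synthetic data generator can and cannot say about real
spectra.

## The statistical problem

A spectrum is a vector of p = 1577 absorbances on a fixed wavenumber grid
(4000 cm⁻¹ start, 3.856 cm⁻¹ spacing).  With five storage-time classes of
60 spectra each, a training fold holds n = 240 samples, so p ≫ n: the
within-class scatter matrix

    Sw = Σ_c Σ_{i∈c} (x_i − μ_c)(x_i − μ_c)ᵀ

has rank at most n − K = 235 and is singular.  Classical Fisher LDA
(maximize wᵀSb w / wᵀSw w) is undefined; the four extractors below are
standard remedies.  All of them return d = K − 1 = 4 discriminant
directions by default, deterministically (descending eigenvalue order;
each column's largest-magnitude entry is made positive).

## Synthetic data generator

No public storage-time spectra archive backs this package, so the
generator emulates the study design directly.  A class-c clean spectrum is
a sum of Gaussian absorption bands whose amplitudes decay geometrically
with storage step, `A_b (1−r_b)^c exp(−(ν−c_b)²/2w_b²)`.  The two default
bands model the chemistry that changes during storage:

| band | center | width (σ) | amplitude | decay/step | interpretation |
|------|--------|-----------|-----------|------------|----------------|
| water O–H combination | 5100 cm⁻¹ | 160 cm⁻¹ | 1.0 AU | 0.10 | water loss |
| N–H first overtone    | 6500 cm⁻¹ | 280 cm⁻¹ | 0.55 AU | 0.06 | protein degradation |

An observed sample is `gain·signal + slope·(ν−ν₀)/1000 + offset + ε` with
per-sample `gain ~ 1+N(0, 0.15)`, `slope ~ N(0, 0.03)` per 1000 cm⁻¹,
`offset ~ N(0, 0.05)` and iid per-point `ε ~ N(0, 0.003)` AU.  The
magnitudes were chosen once, on two grounds: (i) the multiplicative
scatter spread (15 %) exceeds the per-step class amplitude change (10 %),
so raw or SG-only spectra are genuinely confounded and SNV/MSC measurably
raise accuracy — the property the preprocessing comparison exists to
show; (ii) 0.003 AU additive noise is a plausible floor for multi-scan
averaged diffuse-reflectance FT-NIR of plant tissue.  All draws come from
one seeded stream in a fixed order (gains, slopes, offsets, noise), so a
config is bit-reproducible.

What the generator does **not** emulate: high-rank structured biological
within-class covariance (leaf-to-leaf chemistry), class differences beyond
band-amplitude decay, instrument line-shape effects, wavelength-correlated
noise.  The consequences matter and are discussed under *Limitations*.

## Preprocessing

* **SNV** standardizes each spectrum to mean 0, SD 1 (sample SD, n−1; a
  `snv_ddof` flag selects the population convention).
* **MSC** regresses each spectrum on a reference (OLS, `x ≈ a + b·ref`)
  and inverts the fit, `(x − a)/b`.  The reference is the **training-fold
  mean** — never the full-data mean — so no test information enters the
  fit; slopes below 1e−8 raise an error.
* **SG** (Savitzky–Golay) smooths with window 11, polynomial order 2 by
  default (the usual mild-smoothing choice for ~4 cm⁻¹-spaced NIR grids;
  both are configurable).  Boundaries are mirror-padded (reflection
  without repeating the edge point).

Combination names apply left to right: "SNV+MSC" = SNV then MSC, the MSC
reference being the mean of the SNV-transformed training fold.

## Feature extractors

* **ALDA** works in the range space of the total scatter St.  The reduced
  within-class scatter is eigendecomposed; its singular-value square roots
  D_W are made invertible by replacing entries below √tol·α with the
  largest root α, and W solves `S_α⁻¹ Ŝ_B w = λw`.  Numerically the
  eigenproblem is solved in the symmetric whitened form
  `D_α⁻¹U_WᵀŜ_BU_WD_α⁻¹`; the replacement threshold lives on the
  square-root scale so that round-off-level eigenvalues (≈ eps·λmax) are
  caught.
* **CLDA** removes the range-space component of one sample per class
  (`x_com = x − QQᵀx`, Q an orthonormal basis of range(Sw)); by the
  common-vector theorem every sample of a class gives the same result, so
  the choice of sample (the first) is immaterial — a test asserts this.
  W spans the nonzero eigenvectors of the common-vector scatter.  Both
  eigenproblems use the Gram-matrix trick (n×n, K×K) rather than p×p.
* **MLDA** clamps the pooled-covariance spectrum: eigenvalues of
  Sp = Sw/(n−K) below their average λ̄ (including the exact zeros of the
  singular case) are raised to λ̄, and W solves the Fisher criterion with
  the rebuilt Sw*.  The generalized eigenproblem is solved in the
  subspace spanned by range(Sw) and the class-mean deviations, which
  contains every solution with a nonzero criterion value — this avoids
  any p×p eigendecomposition and is oracle-checked densely at small p.
* **NLDA** projects Sb onto the null space of Sw, where within-class
  variance is exactly zero, and keeps the leading eigenvectors; if Sw has
  full rank it falls back to the eigenvectors of `(Sb+Sw)⁻¹Sb`.  The
  computation runs inside range(St): the part of null(Sw) orthogonal to
  the data carries no between-class scatter, so nothing is lost
  (oracle-checked).

Numerical rank everywhere uses `tol = max(p,n)·eps·σ_max`, with σ_max
anchored to the **total-scatter scale**: Sw ⪯ St in the PSD order, and
with exactly replicated class spectra Sw is pure round-off — a
self-anchored tolerance would misread that as full rank.  `rank_tolerance`
is overridable in every fitter.  When fewer than the requested d usable
directions exist, the available ones are returned with a recorded warning
rather than an error, so grid comparisons always complete.

## Classifiers

**CART** is grown by exhaustive Gini splitting (impurity 1 − Σp_k²;
candidate thresholds at midpoints of consecutive distinct values; ties to
the lowest feature index, then the smallest threshold; `x ≤ t` goes left).
Stopping: node Gini < 0.01, fewer than 2 samples, or depth 20.  Pruning is
weakest-link cost-complexity: β_t = (R(t) − R(T_t))/(N_{T_t} − 1) with
misclassification costs measured as proportions of the full training set
(the standard normalization), all β_min-attaining nodes collapsed per
step, and the subtree chosen by stratified 5-fold CV over the candidate
complexities (geometric means of consecutive β's); ties prefer the
smaller tree.

**Boosted stage**: a multiclass gradient-boosted decision-tree ensemble
(scikit-learn's histogram gradient boosting) behind a fixed contract —
deterministic given the seed, per-sample class probabilities summing
to 1.  Defaults: 500 iterations, depth 6, learning rate 0.1 — declared,
not tuned.  The ordered-target-statistic encoder
`x̂_k = (Σ_{j<k,x_j=x_k} y_j + a·p)/(#{j<k,x_j=x_k} + a)` is implemented
natively and exposed standalone (first-in-permutation samples encode to
the prior exactly; later targets can never influence earlier encodings).
It is not wired into the default pipeline because the discriminant scores
are continuous, not categorical.

## Evaluation protocol

Within each class, samples are shuffled (seeded) and dealt into five
near-equal parts; fold f tests on part f.  Per fold, preprocessing
(including the MSC reference), the extractor, and the classifier are all
refit on the training part only.  Test predictions are pooled into one
confusion matrix; reported metrics are per-fold and mean accuracy, the
sample (n−1) SD of fold accuracies (the denominator is recorded in the
output metadata), and macro-averaged precision/recall/F1 on the pooled
confusion matrix.  With balanced folds, macro recall equals pooled
accuracy — asserted to 1e−12.  Grid runs cache per-fold preprocessing and
projections across classifiers; a test verifies the cached path equals
independent per-combo runs bit for bit.

## Problem sizes

Default test runs use the full 300 × 1577 design for structural,
end-to-end and grid checks (the complete 6 × 4 × 2 grid evaluates in
roughly a minute on one CPU thanks to the subspace-based extractor
implementations), a 60 × 120 reduced design for fast pipeline unit tests,
and p ≤ 30, n ≤ 15 instances for the dense oracle comparisons.

## Limitations, and what the synthetic results do and do not show

The generator's multiplicative gain multiplies the class signal itself,
so the span of the class means lies inside the span of the within-class
gain directions for any positive gain SD.  Null-space methods therefore
annihilate the *first-order* class-mean structure and survive on the
consistent second-order residues of the preprocessing nonlinearity —
which is enough for near-perfect CART classification, but supports
essentially one strong discriminant direction.  With two absorption bands
the class-mean trajectory spans at most three affine dimensions with
geometrically decaying conditioning, so of the four returned components
the trailing ones are fold-specific estimation artifacts.  Because
null-space training scores are exactly point-degenerate per class (zero
within-class variance), every component separates the training classes
perfectly and a gradient-boosted ensemble cannot distinguish genuine from
artifact components from training data alone; its test accuracy on
NLDA/CLDA scores drops to ~0.4 at any noise level (the effect is
scale-free: both the genuine and the artifact between-class eigenvalues
scale as σ²).  CART is robust because its deterministic tie-break prefers
the leading (largest-eigenvalue) component and pruning removes the rest.
Real spectra, with hundreds of independently varying constituents, supply
many genuinely informative null-space directions, which is why boosted
ensembles on null-space scores behave very differently on real data.
Conclusions about *which extractor family wins under which classifier*
therefore do not transfer from this generator to real spectra; the
pipeline mechanics, contracts, and algebraic properties do.

In the noise-free limit the spurious eigenvalues vanish, the component
count truncates to the genuine rank, and the null-space pipelines recover
the classes exactly — the end-to-end recovery check uses this limit, the
default-noise margin over the chance baseline, and a shuffled-label
negative control.
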