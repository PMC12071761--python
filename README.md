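# nirdisc

Storage-time discrimination of leafy-vegetable NIR spectra: scatter
correction, small-sample-size discriminant analysis, and tree-based
classification.

## The problem

Near-infrared spectroscopy can grade stored produce non-destructively:
water and protein absorption bands weaken as leaves age, so a spectrum
carries the storage time.  But a diffuse-reflectance spectrum has p ≈ 1600
wavenumber points while a labeled training set has only a few hundred
samples, so the within-class scatter matrix Sw is singular and classical
Fisher discriminant analysis (maximize wᵀS_B w / wᵀS_W w) cannot be
applied.  `nirdisc` implements the standard remedies for this
small-sample-size (SSS) regime and the evaluation protocol to compare
them:

* **Preprocessing** — Savitzky–Golay smoothing (SG), standard normal
  variate (SNV), multiplicative scatter correction (MSC), and the
  combinations MSC+SG, SNV+SG, SNV+MSC, with a strict
  fit-on-train/apply-on-test contract.
* **Feature extraction** — four SSS-safe discriminant methods sharing one
  scatter-matrix foundation:
  * ALDA: approximate S_W⁻¹ via SVD with singular-value replacement,
  * CLDA: discriminative common vectors in the null space of S_W,
  * MLDA: maximum-uncertainty eigenvalue clamping of the pooled
    covariance,
  * NLDA: between-class scatter restricted to the null space of S_W.
* **Classification** — CART grown from scratch with Gini splitting
  (Gini(D) = 1 − Σ_k p_k²) and weakest-link cost-complexity pruning
  (β_t = (R(t) − R(T_t))/(N_{T_t} − 1), subtree chosen by CV), plus a
  seeded gradient-boosted tree ensemble and the ordered-target-statistic
  encoder x̂_k = (Σ_{j<k} y_j[x_j = x_k] + a·p)/(#{j<k: x_j = x_k} + a).
* **Evaluation** — class-stratified five-fold cross-validation; pooled
  confusion matrix; accuracy ± SD and macro precision/recall/F1.
* **Synthetic data** — a seeded generator of NIR-like spectra
  (class-decaying Gaussian absorption bands, multiplicative scatter,
  baseline drift, additive noise) emulating a 5-class × 60-sample,
  1577-point storage-time study, so the whole pipeline is testable
  without a proprietary dataset.

See `docs/methods.md` for the models, defaults, numerical choices and
limitations.

## Worked example

```python
import nirdisc as nd

data = nd.generate(nd.default_config())          # 300 x 1577 spectra
plan = nd.stratified_kfold(data.labels, 5, seed=7)
report = nd.run_combo_cv(
    data, nd.PreprocessSpec.from_name("SNV"), "NLDA", "CART", plan,
)
print(report.combo_label, report.mean_accuracy, report.accuracy_sd)
print(report.confusion)
```

prints

```
SNV-NLDA-CART 1.0 0.0
[[60  0  0  0  0]
 [ 0 60  0  0  0]
 [ 0  0 60  0  0]
 [ 0  0  0 60  0]
 [ 0  0  0  0 60]]
```

(rows/columns follow the sorted class labels: 0h, 12h, 18h, 24h, 6h)

— each of the five folds preprocesses its 240 training spectra with SNV,
fits null-space LDA (four discriminant directions), prunes a CART by
cross-validated cost-complexity, and classifies the held-out 60 spectra;
under the default synthetic conditions the SNV+NLDA+CART pipeline
separates all five storage times (mean accuracy 1.0, SD 0 across folds),
while the same pipeline without scatter correction (SG only) reaches
about 0.93 — the margin the scatter-correction stage exists to provide.

The same experiment from the shell:

```sh
nirdisc simulate -c config.yaml        # write the synthetic spectra CSV
nirdisc run -c config.yaml             # one combination -> metrics.json
nirdisc run -c config.yaml --grid      # full 6 x 4 x 2 grid -> grid.csv
```

with a YAML config naming the data source (synthetic block or an input
CSV), the treatment, extractor, classifier, CV folds and seeds; every run
writes a `run_manifest.json` sufficient to reproduce it exactly.

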