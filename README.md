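# kernelgp

Kernel mixed models for genomic prediction: **GBLUP**, **RR-BLUP** and
**RKHS (kernel ridge) regression** in one framework, with EM-REML
variance-component estimation, kernel hyperparameter tuning and a
repeated-holdout evaluation protocol — plus a synthetic SNP data
generator so everything is testable without external data.

## The problem

Genomic selection ranks breeding candidates by genetic merit predicted
from genome-wide SNP markers.  With a few hundred accessions and tens of
thousands of markers (p >> n), unpenalized regression interpolates the
phenotypes and learns nothing, so prediction methods are regularized.
Ridge regression, Bayesian ridge regression, RR-BLUP and GBLUP are the
same estimator seen in different coordinates, and the dual (kernel) view
generalizes it: replacing the linear Gram matrix K = XX' by a nonlinear
kernel turns GBLUP into RKHS regression, which can capture epistasis
(marker-by-marker interaction) without modeling it explicitly.  The
quadratic kernel illustrates the trick: squaring the entries of the
linear Gram matrix is exactly a ridge regression on all pairwise
interaction terms, computed without ever building them.

The model fitted throughout is

    Y = F beta + g + eps,   g ~ N(0, sigma2_g K),   eps ~ N(0, sigma2_e I)

with variance components estimated by EM-REML (one eigendecomposition of
K, O(n) iterations, monotone restricted likelihood).  Predictions for
new accessions are `F beta + K_cross alpha` with dual variables
`alpha = sigma2_g V^-1 (Y - F beta)`; for the linear kernel,
`beta_markers = X' alpha` recovers per-marker RR-BLUP effects.

Kernels: `linear`, `polynomial (⟨x,y⟩+c)^d`, `gaussian exp(-h‖x-y‖²)`,
`laplacian exp(-h‖x-y‖₁)`, `anova (Σⱼ exp(-h(xⱼ-yⱼ)²))^d`.  The Gaussian
rate of decay h is tuned by K-fold cross-validation inside each training
set.

Methods are compared by repeated random 2/3 train : 1/3 target splits,
scoring the Pearson correlation between predictions and observed target
phenotypes (relative prediction accuracy, RPA) and the signal-to-noise
ratio (SNR), reported as `mean (se) [snr]` rows.

## Worked example

```python
from kernelgp import (SimulationConfig, simulate_study, gram_matrix, KernelSpec,
                      em_reml_fit, make_splits, evaluate_method, MethodConfig, tpa)

cfg = SimulationConfig(n=200, p=2000, architecture="additive", n_causal=50,
                       heritability_target=0.6, seed=10)
study = simulate_study(cfg)
X, y = study.genotypes, study.phenotypes

K = gram_matrix(X.centered(), KernelSpec("linear"))
fit = em_reml_fit(K, y)
print(f"sigma2_g = {fit.sigma2_g:.4g}  sigma2_e = {fit.sigma2_e:.4g}  "
      f"lambda = {fit.lambda_hat:.4g}  ({fit.n_iter} EM iterations)")
print(f"in-sample accuracy vs true genetic values: "
      f"{tpa(fit.fitted, study.true_genetic_values):.3f}")

splits = make_splits(X.n, n_replicates=20, seed=1)
for method in (MethodConfig(family="linear", label="GBLUP"),
               MethodConfig(family="gaussian", decay_h=5e-4, label="RKHS (gaussian)")):
    report = evaluate_method(X, y, method, splits, trait_label="sim")
    print(f"{method.label:16s} {report.row()}")
```

prints

```
sigma2_g = 0.001898  sigma2_e = 0.3664  lambda = 193.1  (500 EM iterations)
in-sample accuracy vs true genetic values: 0.769
GBLUP            0.19 (0.02) [0.04]
RKHS (gaussian)  0.19 (0.02) [0.02]
```

`sigma2_g` is the genetic variance per unit of the (raw-scale `XX'`)
kernel and `lambda = sigma2_e/sigma2_g` the implied ridge penalty.  The
holdout rows read "mean RPA (standard error) [mean SNR]" over the 20
random 2/3–1/3 splits: both kernels predict this additive trait equally
well (about r = 0.19 against noisy phenotypes at heritability 0.6 with
independent markers), and the in-sample correlation with the *true*
genetic values, available because the data are simulated, is much
higher (0.77) — observed-phenotype correlations systematically
understate accuracy.

The same workflows are available from the shell:

```bash
kernelgp simulate --n 200 --p 2000 --heritability 0.6 --seed 10 --out sim/
kernelgp fit      --genotypes sim/genotypes.tsv --phenotypes sim/phenotypes.tsv \
                  --kernel linear --out fit/
kernelgp evaluate --genotypes sim/genotypes.tsv --phenotypes sim/phenotypes.tsv \
                  --kernel gaussian --decay 5e-4 --replicates 20 --seed 1 \
                  --out report.tsv
kernelgp tune     --genotypes sim/genotypes.tsv --phenotypes sim/phenotypes.tsv \
                  --grid 1e-6:1:15log --out cv.tsv
```

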