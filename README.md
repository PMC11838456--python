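# copulasim

Gaussian-copula simulation of omics count data with realistic gene–gene
dependence.

## The problem

Benchmarking omics pipelines (differential expression callers, circadian
phase inference, and the like) needs simulated data that looks like real
data.  Real transcriptomes have strong gene–gene correlation, but most
simulators draw genes independently: a full p×p correlation matrix cannot be
estimated from a handful of samples (the sample covariance has rank at most
n−1), and naive multivariate sampling costs O(p³).  `copulasim` fits a
reference genes × samples matrix and generates new samples that reproduce
both its per-gene (marginal) distributions and a low-rank approximation of
its dependence structure, in O(p·k) per sample.

## The model

Each gene i gets a marginal CDF F_i — normal, Poisson, negative binomial
with DESeq2-style median-of-ratios size factors, or empirical.  Observations
are mapped to a latent Gaussian score

    Z_ij = Φ⁻¹(F_i(X_ij)),

(discrete families use the jump midpoint (F(x⁻)+F(x))/2).  Dependence is
modelled on the Z scale by a covariance that splits into independent noise
plus k shared latent factors,

    Σ = diag(D²) + U·diag(W²)·Uᵀ,

and a new sample is Z′ = U(W∘u) + D∘v with u ~ N(0, I_k), v ~ N(0, I_p),
mapped back through X′_i = F_i⁻¹(Φ(Z′_i)).  Three estimators of (D, U, W)
are provided, plus an independence baseline:

| method | idea |
|---|---|
| `pca` | variance along the top-k principal directions of Z matches the reference exactly; per-gene residual variance absorbed into D |
| `wishart` | spiked-Wishart moment matching: E[singular values of a simulated n-sample dataset] ≈ the reference singular values, fitted by SGD with an O(m³) Gram-matrix sampler |
| `corpcor` | James–Stein shrinkage of the sample covariance (correlations toward 0, variances toward their median), expressed exactly in factorized form |
| `independent` | W = 0; per-gene variances only |

On top of the generator sit benchmark utilities: differential-expression
injection (a chosen fraction of genes gets its mean scaled by 2^β, |β| ~
Uniform over a log2-fold-change range, random sign), time-series simulation
with per-timepoint mean profiles, and evaluation statistics (mean/variance
agreement, gene-pair correlation QQ, PC spectra and projections, realized
false-discovery proportions, circular correlation for phase estimates).

## Worked example

```python
import copulasim as cs

counts, truth = cs.make_reference(p=2000, n=12, k_true=2,
                                  family="negbinom", seed=0)
model = cs.CopulaModel(counts, family="negbinom").fit(method="pca", seed=0)
print(model.summary())
sim = model.simulate(6, seed=1)
print(sim.to_dataframe().iloc[:4, :6].astype(int))
```

prints

```
Gaussian copula reference model
===============================================
genes (p):            2000
reference samples:    12
marginal family:      negbinom
covariance method:    pca
latent rank k:        2
seed:                 0
degenerate genes:     0
max |diag(Sigma)-1|:  0.7432
clamped_weights:      0
clamped_diag:         0

         sim_1  sim_2  sim_3  sim_4  sim_5  sim_6
gene_id
g1          20     17     26     23     21      7
g2          92     87     69     96    103     81
g3         406    918   1131    871    770    487
g4          97    114    104    129    114     84
```

The summary reports the fitted family, the latent rank, and diagnostics:
`max |diag(Sigma)-1|` measures how far the latent covariance diagonal sits
from the copula's unit-variance contract (large values at n = 12 reflect
small-sample noise in the normalized rows; at n = 100 it drops below 0.01
for this estimator), and the clamp counters report negative-variance
solutions truncated to zero.  The simulated counts reproduce the reference's
per-gene means closely (log-mean correlation 0.994 in this run) and inherit
its factor structure.

The same workflow from a shell:

```bash
copulasim make-fixture --p 2000 --n 12 --family negbinom --seed 0 --out ref.tsv
copulasim fit --counts ref.tsv --family negbinom --method pca --seed 0 --out model.npz
copulasim simulate --model model.npz --n-sim 6 --seed 1 --out sim.tsv
copulasim evaluate --real ref.tsv --sim sim.tsv --out report.json
```

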