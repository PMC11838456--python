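# Methods

## Model overview

`copulasim` treats a reference dataset X (p genes × n samples, columns
independent) as draws from a Gaussian copula: each gene has a univariate
marginal F_i, and dependence lives entirely in a latent multivariate normal
with covariance Σ.  Fitting proceeds in three stages — marginals, copula
normalization Z_ij = Φ⁻¹(F_i(X_ij)), covariance — and generation inverts
them: draw Z′ ~ N(0, Σ), output F_i⁻¹(Φ(Z′_i)).  Two structural assumptions
follow from this design and bound what the simulator can reproduce:

1. dependence is Gaussian on the latent scale (only monotone, elliptical
   association is captured; tail dependence and non-linear relations are
   not);
2. Σ is low-rank-plus-diagonal, Σ = diag(D²) + U·diag(W²)·Uᵀ with k ≪ p
   shared factors, which is both the only identifiable option at n ≪ p and
   what makes generation O(p(k+1)) per sample with no p×p object ever
   allocated.

The generator contract is exact by construction: for u ~ N(0, I_k),
v ~ N(0, I_p), the vector Z′ = U(W∘u) + D∘v has cov Z′ = Σ, and Σ is
positive semi-definite (non-negative diagonal plus a Gram matrix).

For the output to carry the *fitted* marginals, each diagonal entry of Σ
must be 1, since the generated latent score for gene i is N(0, Σ_ii) and
only a standard normal pushes forward through F_i⁻¹∘Φ to exactly F_i.  All
estimators approximate this; where they provably cannot achieve it per gene,
the limitation is documented below rather than papered over.

## Marginal families

* **normal** — per-gene mean and unbiased (n−1) standard deviation.  The
  unbiased choice makes the normalized rows have sample variance exactly 1,
  which the covariance stage relies on.
* **poisson** — per-gene mean.
* **negbinom** — DESeq2-style: median-of-ratios size factors s_j (median
  over genes, positive in every sample, of count / gene geometric mean),
  gene mean μ_i of the size-factor-normalized counts, and a
  method-of-moments dispersion α_i = max(0, (v_i − μ_i)/μ_i²) so that
  Var = μ + αμ².  α = 0 falls back to Poisson.  Gene i in sample j is
  NB with mean s_j·μ_i.  Method-of-moments was chosen over a
  likelihood/shrinkage dispersion fit (as DESeq2 itself performs) because
  the copula only needs a reasonable marginal shape — the normalized score,
  not the parametric tail, carries the dependence — and the estimator is
  closed-form and deterministic.  Exact parity with DESeq2's Cox–Reid
  dispersions is not claimed.
* **empirical** — the sorted observed values per gene; quantiles return
  observed values (suitable for ordinal data).

Genes constant across samples (including all-zero genes) are flagged
degenerate: their latent rows are set to 0, they are excluded from
covariance fitting, and simulation reproduces them as constants.

### Size factors for new samples

The reference's size factors describe *its* library depths; new samples
default to s = 1 (all genes simulated at the normalized scale), with options
to pass an explicit vector or to bootstrap-resample the reference's factors.

## Copula transforms

Discrete and empirical families have jump CDFs; an observation x is mapped
to the midpoint u = (F(x⁻) + F(x))/2 of its jump.  The midpoint choice makes
fitting deterministic and reproducible; a randomized distributional
transform (u uniform within the jump, which is exactly uniform marginally)
is available behind a flag for users who prefer distributional exactness
over determinism.  u is clipped to [1e−10, 1 − 1e−10] before Φ⁻¹, bounding
|Z| by about 6.4 and keeping every score finite while leaving tail behaviour
essentially intact.  The normal family bypasses the numeric path:
Z = (x − μ)/σ exactly.

A consequence of the midpoint transform worth knowing: with empirical
marginals and no ties, every gene's row of Z contains the same symmetric set
of normal scores Φ⁻¹((2r−1)/2n), so all rows sum to zero and the normalized
matrix has rank at most n−1 — its smallest singular value is numerically
zero.  The covariance estimators therefore work with the top n−1 singular
values throughout.

Generation truncates the normal family's small negative tail at zero so the
output remains a valid non-negative matrix; with realistic positive means
the truncated mass is negligible.

## Covariance estimators

All estimators operate on the row-centered normalized matrix (centering is
what makes the rank deficiency above exact and the per-gene variances
well-defined) and return the same factorization, so generation code is
method-agnostic.

### PCA (variance matching)

With u_1..u_k the top left singular vectors of centered Z, t_i = λ_i²/(n−1)
the sample variance of Z along u_i, and V_ℓℓ the per-gene sample variance,
solve the k×k system

    A s = B,  A_ij = δ_ij − Σ_ℓ U_ℓi² U_ℓj²,  B_i = t_i − Σ_ℓ U_ℓi² V_ℓℓ,

set W_i = √max(s_i, 0) and D_ℓ² = V_ℓℓ − Σ_i U_ℓi² W_i² (clamped at 0).
Substituting back shows u_iᵀΣu_i = t_i exactly whenever no clamp fired, and
the diagonal of Σ equals V_ℓℓ exactly — the two invariants the unit tests
pin against a dense oracle.  Negative solutions (possible when the top
directions' variance is not expressible with non-negative factor weights)
are clamped with a warning and counted in the diagnostics.  k must satisfy
k ≤ n−2: the fit consumes one rank for centering and must leave residual
variance to keep the simulated data full-rank.  Default k = min(2, n−2).

### Spiked Wishart (spectrum matching)

Rather than matching variances along the *reference's* directions, this
estimator asks that a simulated dataset of the same size have, on average,
the same singular-value spectrum as the reference under its own PCA.  The
model is a spiked covariance: k spike eigenvalues w_1..w_k above a flat bulk
c², with the reference's top singular vectors as spike directions.

**Sampler.**  The singular values of a p×m matrix Y with iid N(0, Σ) columns
(Σ diagonal wlog, by rotation invariance) are the square roots of the
eigenvalues of the m×m Gram matrix

    M = YᵀY = Σ_{i≤k} w_i h_i h_iᵀ + c² B,

with h_i iid standard normal m-vectors and B ~ Wishart_m(p−k, I) drawn via
the Bartlett decomposition (or an explicit Gaussian factor when p−k < m).
This is an exact reduction — it samples the singular-value law at
O(m³ + k·m²) with no p-sized allocation — and it reproduces the closed-form
trace identity E[Σλ′²] = m(c²(p−k) + Σw_i), which the tests verify by Monte
Carlo alongside a brute-force dense-sampler KS comparison at small p.

**Fitting.**  (w, c) minimize Σ_i (E[λ′_i] − λ_i)² by Adam-flavoured SGD on
log-parameters (positivity for free), learning rate 0.05, 1000 steps.  Each
step uses two independent Gram draws: one supplies the residual λ′ − λ, the
other the per-eigenvalue gradients via first-order perturbation
(∂eig_j/∂w_i = (q_j·h_i)², ∂eig_j/∂c² = q_jᵀBq_j, chained through the square
root).  The product of the two is an unbiased estimate of the gradient of
the population objective — a single draw would instead target
Σ E[(λ′−λ)²], whose variance term biases the spikes.  Log-parameters are
tail-averaged over the final quarter of the steps to shrink the SGD noise
ball, and the result is validated on fresh held-out draws (default 200),
reporting per-value relative errors and a convergence flag; a non-converged
fit is flagged, never silently returned.

**Initialization matters.**  The objective is nearly flat along a manifold
of (w, c) combinations with indistinguishable expected spectra (the bulk of
a sample spectrum can be explained either by the flat bulk c² or by many
moderate spikes), so the starting point decides which solution SGD reaches.
Initializing every spike at its sample value λ_i²/(n−1) overcounts — a
sample singular value is inflated above its population spike by the bulk —
and lands on solutions with inflated bulk spikes and a distorted diagonal.
We instead start c² at its trace-matched value Σλ²/(m·p) and each spike at
the first-order inversion of the spike-inflation map
T = w(1 + γc²/(w − c²)), γ = (p−k)/m, with sample values that invert below
the bulk starting exactly at c².  Fitted spikes are clamped to w_i ≥ c² and
converted to additive factor weights W_i = √(w_i − c²), so Σ's spectrum is
exactly (w_1..w_k, c², .., c²); the fitted w are interpreted as *total*
variances along the spike directions, which keeps u_iᵀΣu_i = w_i exact.
Default k = n−1 (all non-zero singular values).

### corpcor-style James–Stein shrinkage

The dense estimator shrinks correlations toward zero with intensity λ₁ and
variances toward their median with intensity λ₂:

    Σ_ii = v*_i = λ₂·v_med + (1−λ₂)·v_i,
    Σ_ij = (1−λ₁)·r_ij·√(v*_i v*_j)   (i ≠ j),

with both intensities estimated analytically from the data (the ratio of the
summed sampling variances of the entries to their summed squared magnitudes)
and clamped to [0, 1].  Because the shrunk matrix is a scaled sample
covariance plus a diagonal, it factorizes exactly: D_i = √(λ₁ v*_i),
U = √(1−λ₁)·S·Z_c/√(n−1) with S_ii = √(v*_i)/σ_i, W = 1 (k = n).  The
intensities are computed on the variance scale, and the implementation is
pinned by a test against an independently coded dense entry-by-entry
estimate (1e−10) rather than against the R package bit-for-bit; the
O(p²) pair sums are evaluated through n×n Gram identities so the fit costs
O(pn² + n³).

### Independence baseline

W = 0 and D_i the per-gene latent standard deviation — the comparator every
benchmark should include.

## Simulation utilities

* **Differential expression**: exactly ⌈fraction·p⌉ genes chosen without
  replacement (deterministic truth counts suit benchmarking; per-gene
  Bernoulli selection behind a flag), each mean multiplied by 2^β with
  |β| ~ Uniform(0.2, 2.0) by default and sign ± with probability ½; the
  covariance is untouched.  Empirical marginals have no parametric mean and
  are rejected.
* **Time series**: a p×T mean-profile matrix; at each timepoint the per-gene
  means are swapped in while dispersions/standard deviations and the
  covariance stay at the reference fit (no mean–variance re-coupling across
  timepoints).  Output carries true timepoint labels for scoring phase
  inference with the circular correlation ρ = Σ_{i<j} sin(X_i−X_j)
  sin(Y_i−Y_j) / (√Σ sin²(X_i−X_j)·√Σ sin²(Y_i−Y_j)).
* **Randomness**: one integer seed feeds named sub-streams (fit, de,
  simulate, timeseries, fixture), so each stage is independently
  reproducible and the full pipeline is byte-deterministic per seed.

## Synthetic reference generator

`make_reference` emulates a bulk RNA-seq compendium with known ground truth:
latent scores drawn from a known Σ = diag(D²) + U·diag(W²)·Uᵀ with *exactly*
unit diagonal, pushed through known marginals — log-normal mean expression
(median ≈ 100 reads), negative-binomial dispersions log-uniform on
[0.01, 0.5], size factors LogNormal(0, 0.2²).  Factor strengths default to
30% of total latent variance split 4:2:1 across factors, a realistic share
for the leading expression programs of a transcriptome; the default shape
p = 2000 × n = 12 mirrors a small bulk reference.

Loadings are delocalized: random-sign vectors, symmetrically
orthogonalized, so every gene draws a near-equal variance share from each
factor.  This is the regime in which a low-rank-plus-diagonal covariance can
have a uniform diagonal at all — with heavy-tailed (e.g. Haar) loadings the
per-gene factor share varies by an order of magnitude and the unit-diagonal
contract is unattainable for any estimator of the spiked form.  Real
transcriptomes sit between these extremes (co-expression modules concentrate
loadings); the generator therefore tests the estimators under their own
modelling assumption, not under worst-case module structure.

What it does not emulate: batch structure, covariate-dependent means,
zero-inflation/single-cell sparsity, gene-length effects, or library-size
heterogeneity beyond scalar size factors.  Passing tests on these fixtures
shows the estimators recover structure *of the assumed form*; it does not
certify behaviour under dependence the model cannot express.

## Numerical choices and test conditions

* Clipping: u ∈ [1e−10, 1−1e−10]; negative factor-weight solutions and
  residual variances clamped at 0 with warnings and diagnostic counters;
  spike weights clamped at the bulk.
* Singular values are sorted descending everywhere; exchangeable fitted
  spikes are sorted descending so w_i pairs with the i-th singular
  direction.
* Serialization keeps full binary precision (npz archive + JSON metadata,
  versioned); text outputs use 6 significant digits, integer matrices are
  written without decimals.
* Test problem sizes: dense-oracle checks at p ≤ 50; sampler KS at p = 8
  with 5000 draws per sampler; spectrum-recovery at p = 2000, m = 11, k = 3
  (the scale of a 12-sample reference); the unit-diagonal contract at
  p = 2000, n = 100; marginal-preservation at p = 150 genes × n = 500
  reference samples with 10,000 simulated values per gene.  The n = 500
  reference was chosen because marginal-preservation targets the copula
  machinery, and at small n the measured deviation is dominated by
  estimation noise in the fitted CDFs rather than by the simulator.

## Known limitations

* **The spiked-Wishart form cannot hold the unit diagonal per gene.**  With
  D = cI fixed, diag(Σ)_ℓ = c² + Σ_i U_ℓi²(w_i − c²), and the estimated
  singular vectors carry sampling noise whose per-gene magnitude is
  heterogeneous; at p = 2000, n = 100 with a ~30% factor share this leaves
  per-gene diagonal deviations of ±0.2 around a mean of 1.00 even though the
  expected-spectrum contract is met to ~2%.  The other two estimators absorb
  per-gene variance into D and hold the diagonal to machine precision.  In
  practice this means wishart-simulated marginals are mildly mis-scaled for
  high-loading genes.
* **Poisson marginals are not exactly preserved.**  The simulated latent
  variance for gene i is the sample variance of its normalized row; a
  Poisson fit pins only the mean, so the reference's empirical dispersion
  leaks into the simulated scale.  At 10,000 simulated values a 1%-level
  chi-square rejects for a substantial fraction of genes at any realistic
  reference size (28% at n = 500).  This is a real property of the pipeline
  — the simulator mimics the data's observed dispersion rather than the
  idealized fitted family — and is arguably desirable for mimicry; the
  negative-binomial family, whose dispersion parameter absorbs the observed
  variance, preserves marginals to within the test's resolution.
* Gene–gene correlation magnitudes: as in the comparison statistics, the PCA
  method tends to overshoot pairwise correlations (all shared variance is
  packed into k directions) while shrinkage methods undershoot; none
  reproduces the full correlation spectrum of a real dataset.
* The shrinkage intensities are this package's analytic implementation
  validated against its own dense oracle, not a bit-for-bit reproduction of
  the R corpcor package's edge-case conventions.
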