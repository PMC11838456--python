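"""Per-gene marginal distributions.

Supported families:

``normal``
    Gaussian with per-gene mean and unbiased (n-1) standard deviation.
``poisson``
    Poisson with per-gene rate.
``negbinom``
    Negative binomial with per-gene mean ``mu_i`` on the size-factor-normalized
    scale and dispersion ``alpha_i`` such that Var = mu + alpha * mu**2.  The
    distribution of gene i in sample j has mean ``s_j * mu_i``, with ``s_j``
    the DESeq2-style median-of-ratios size factor for that sample.  The
    dispersion is estimated by method of moments with a Poisson fallback
    (``alpha_i = 0``) when the normalized variance does not exceed the mean.
``empirical``
    The sorted observed values of each gene (the empirical CDF), suitable for
    arbitrary ordered data.

Genes that are constant across samples (including all-zero genes) are flagged
degenerate; they are carried through the copula as exact constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .counts import CountMatrix

FAMILIES = ("normal", "poisson", "negbinom", "empirical")


@dataclass
class SizeFactors:
    """Per-sample sequencing-depth scaling factors (all positive)."""

    s: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        if self.s.ndim != 1 or len(self.s) != len(self.sample_ids):
            raise ValueError("size factors must be 1-D and aligned to sample_ids")
        if np.any(self.s <= 0) or not np.all(np.isfinite(self.s)):
            raise ValueError("size factors must be positive and finite")


def fit_size_factors(counts: CountMatrix) -> SizeFactors:
    """DESeq2 median-of-ratios size factors.

    For each gene with a positive geometric mean across samples (i.e. positive
    in every sample), compute the ratio of each sample's count to that
    geometric mean; the size factor of a sample is the median ratio over those
    genes.
    """
    x = counts.values
    usable = np.all(x > 0, axis=1)
    if not np.any(usable):
        raise ValueError(
            "cannot estimate size factors: no gene is positive in every sample "
            "(all per-gene geometric means are zero)")
    logx = np.log(x[usable])
    geomean = np.exp(logx.mean(axis=1))
    ratios = x[usable] / geomean[:, None]
    s = np.median(ratios, axis=0)
    return SizeFactors(s, counts.sample_ids)


@dataclass
class MarginalModel:
    """Fitted per-gene marginal distributions of one family."""

    family: str
    gene_ids: np.ndarray
    degenerate: np.ndarray            # bool, per gene
    constant_value: np.ndarray        # value of each degenerate gene (0 otherwise)
    mu: Optional[np.ndarray] = None   # normal / negbinom mean; poisson rate alias
    sd: Optional[np.ndarray] = None   # normal only
    alpha: Optional[np.ndarray] = None  # negbinom dispersion
    values: Optional[np.ndarray] = None  # empirical: (p, n) sorted observations
    size_factors: Optional[SizeFactors] = None  # negbinom fit-time factors

    @property
    def p(self) -> int:
        return len(self.gene_ids)

    def copy(self) -> "MarginalModel":
        return MarginalModel(
            self.family, self.gene_ids.copy(), self.degenerate.copy(),
            self.constant_value.copy(),
            None if self.mu is None else self.mu.copy(),
            None if self.sd is None else self.sd.copy(),
            None if self.alpha is None else self.alpha.copy(),
            None if self.values is None else self.values.copy(),
            self.size_factors)


def fit_marginals(counts: CountMatrix, family: str,
                  size_factors: Optional[SizeFactors] = None) -> MarginalModel:
    """Fit one marginal distribution family to every gene of ``counts``."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    x = counts.values
    degenerate = x.max(axis=1) == x.min(axis=1)
    const = np.where(degenerate, x[:, 0], 0.0)
    m = MarginalModel(family, counts.gene_ids.copy(), degenerate, const)

    if family == "normal":
        m.mu = x.mean(axis=1)
        m.sd = x.std(axis=1, ddof=1)
    elif family == "poisson":
        m.mu = x.mean(axis=1)
    elif family == "negbinom":
        if size_factors is None:
            raise ValueError("negbinom marginals require size factors")
        if not np.array_equal(size_factors.sample_ids, counts.sample_ids):
            raise ValueError("size factor sample ids do not match counts")
        norm = x / size_factors.s[None, :]
        mu = norm.mean(axis=1)
        v = norm.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = np.where(mu > 0, (v - mu) / mu ** 2, 0.0)
        m.mu = mu
        m.alpha = np.clip(alpha, 0.0, None)
        m.size_factors = size_factors
    else:  # empirical
        m.values = np.sort(x, axis=1)
    return m


# ---------------------------------------------------------------------------
# scalar CDF / quantile interface (single gene, single sample)
# ---------------------------------------------------------------------------

def _nb_dist(mu: float, alpha: float):
    """Frozen count distribution with the given mean/dispersion."""
    if alpha <= 0:
        return stats.poisson(mu)
    r = 1.0 / alpha
    return stats.nbinom(r, r / (r + mu))


def _size_factor(model: MarginalModel, sample: int) -> float:
    if model.family == "negbinom":
        if model.size_factors is None:
            raise ValueError("negbinom model has no size factors")
        return float(model.size_factors.s[sample])
    return 1.0


def marginal_cdf(model: MarginalModel, gene: int, sample: int, x: float) -> float:
    """Right-continuous CDF F(x) of gene ``gene`` in sample ``sample``."""
    return _scalar_cdf(model, gene, _size_factor(model, sample), x, minus=False)


def marginal_cdf_minus(model: MarginalModel, gene: int, sample: int, x: float) -> float:
    """Left limit F(x-) = P(X < x); differs from F(x) only for discrete families."""
    return _scalar_cdf(model, gene, _size_factor(model, sample), x, minus=True)


def _scalar_cdf(model: MarginalModel, i: int, s: float, x: float, minus: bool) -> float:
    if model.degenerate[i]:
        c = model.constant_value[i]
        return float(x > c) if minus else float(x >= c)
    fam = model.family
    if fam == "normal":
        return float(stats.norm.cdf(x, model.mu[i], model.sd[i]))
    if fam in ("poisson", "negbinom"):
        mean = model.mu[i] * s if fam == "negbinom" else model.mu[i]
        alpha = model.alpha[i] if fam == "negbinom" else 0.0
        dist = _nb_dist(mean, alpha)
        if minus:
            # P(X < x): largest integer strictly below x
            k = np.ceil(x) - 1 if x == np.floor(x) else np.floor(x)
            return float(dist.cdf(k))
        return float(dist.cdf(np.floor(x)))
    # empirical
    row = model.values[i]
    side = "left" if minus else "right"
    return float(np.searchsorted(row, x, side=side)) / len(row)


def marginal_quantile(model: MarginalModel, gene: int, sample: int, u: float) -> float:
    """Generalized inverse CDF: smallest x with F(x) >= u, for u in (0, 1)."""
    if not (0.0 < u < 1.0):
        raise ValueError(f"u must be in (0, 1), got {u}")
    i = gene
    if model.degenerate[i]:
        return float(model.constant_value[i])
    s = _size_factor(model, sample)
    fam = model.family
    if fam == "normal":
        return float(stats.norm.ppf(u, model.mu[i], model.sd[i]))
    if fam in ("poisson", "negbinom"):
        mean = model.mu[i] * s if fam == "negbinom" else model.mu[i]
        alpha = model.alpha[i] if fam == "negbinom" else 0.0
        return float(_nb_dist(mean, alpha).ppf(u))
    row = model.values[i]
    n = len(row)
    idx = int(np.ceil(u * n)) - 1
    return float(row[min(max(idx, 0), n - 1)])


# ---------------------------------------------------------------------------
# vectorized matrix interface (used by the copula transforms)
# ---------------------------------------------------------------------------

def matrix_cdf(model: MarginalModel, X: np.ndarray, s: np.ndarray,
               minus: bool = False) -> np.ndarray:
    """Elementwise F(x) (or F(x-)) for a (p, n) matrix of observations."""
    p, n = X.shape
    out = np.empty_like(X, dtype=float)
    fam = model.family
    if fam == "normal":
        sd = np.where(model.sd > 0, model.sd, 1.0)
        out = stats.norm.cdf((X - model.mu[:, None]) / sd[:, None])
    elif fam in ("poisson", "negbinom"):
        if fam == "poisson":
            mean = np.broadcast_to(model.mu[:, None], X.shape)
            alpha = np.zeros(p)
        else:
            mean = model.mu[:, None] * s[None, :]
            alpha = model.alpha
        K = np.floor(X) - (1 if minus else 0)
        pois = alpha <= 0
        if np.any(pois):
            out[pois] = stats.poisson.cdf(K[pois], mean[pois])
        if np.any(~pois):
            rr = (1.0 / alpha[~pois])[:, None]
            mu_nb = mean[~pois]
            out[~pois] = stats.nbinom.cdf(K[~pois], rr, rr / (rr + mu_nb))
    else:  # empirical
        side = "left" if minus else "right"
        for i in range(p):
            out[i] = np.searchsorted(model.values[i], X[i], side=side) / n
    # degenerate genes: point mass at the constant
    if np.any(model.degenerate):
        d = model.degenerate
        c = model.constant_value[d][:, None]
        out[d] = (X[d] > c) if minus else (X[d] >= c)
    return out


def matrix_quantile(model: MarginalModel, U: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Elementwise generalized inverse CDF for a (p, n) matrix of u in (0,1)."""
    if np.any(U <= 0) or np.any(U >= 1):
        raise ValueError("quantile levels must lie strictly inside (0, 1)")
    p, n = U.shape
    out = np.empty_like(U, dtype=float)
    fam = model.family
    if fam == "normal":
        out = model.mu[:, None] + model.sd[:, None] * stats.norm.ppf(U)
    elif fam == "poisson":
        out = stats.poisson.ppf(U, model.mu[:, None])
    elif fam == "negbinom":
        mean = model.mu[:, None] * s[None, :]
        pois = model.alpha <= 0
        if np.any(pois):
            out[pois] = stats.poisson.ppf(U[pois], mean[pois])
        if np.any(~pois):
            r = 1.0 / model.alpha[~pois]
            mu_nb = mean[~pois]
            rr = r[:, None]
            out[~pois] = stats.nbinom.ppf(U[~pois], rr, rr / (rr + mu_nb))
    else:  # empirical
        nobs = model.values.shape[1]
        idx = np.clip(np.ceil(U * nobs).astype(int) - 1, 0, nobs - 1)
        out = np.take_along_axis(model.values, idx, axis=1)
    if np.any(model.degenerate):
        d = model.degenerate
        out[d] = model.constant_value[d][:, None]
    return out
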