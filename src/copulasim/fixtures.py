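"""Synthetic reference datasets with known ground truth.

``make_reference`` builds a counts matrix from a *known* low-rank-plus-
diagonal latent covariance pushed through known marginals, so that every
estimator in the package can be tested for parameter recovery without any
external download.  The latent covariance has exactly unit diagonal: factor
loadings come from a random orthonormal basis scaled by per-factor strengths,
rows whose factor share would exceed a cap are rescaled, and the diagonal
part absorbs the remaining variance.

Default marginal parameters emulate bulk RNA-seq: log-normally spread mean
expression (median around 100 reads), negative-binomial dispersions
log-uniform on [0.01, 0.5], and size factors LogNormal(0, 0.2^2) mimicking
modest library-size variation.  The default shape (p = 2000 genes, n = 12
samples) echoes a small bulk RNA-seq reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .counts import CountMatrix
from .marginals import SizeFactors

_FACTOR_SHARE = 0.3     # average fraction of latent variance from shared factors
_ROW_SHARE_CAP = 0.8    # per-gene cap on the factor share


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic reference."""

    D: np.ndarray          # (p,)
    U: np.ndarray          # (p, k): near-orthonormal factor directions
    W: np.ndarray          # (k,) factor strengths
    family: str
    params: dict           # true marginal parameters
    size_factors: Optional[SizeFactors]
    seed: int

    def sigma_dense(self) -> np.ndarray:
        """Materialize the true Sigma (small p only)."""
        return np.diag(self.D ** 2) + (self.U * self.W ** 2) @ self.U.T


def make_reference(p: int = 2000, n: int = 12, k_true: int = 2,
                   family: str = "negbinom", seed: int = 0,
                   factor_share: float = _FACTOR_SHARE):
    """Generate (CountMatrix, SyntheticTruth) with known latent structure."""
    if p < 10 or n < 3:
        raise ValueError("need p >= 10 and n >= 3")
    if not 0 <= k_true < n:
        raise ValueError("need 0 <= k_true < n")
    if not 0 <= factor_share < 1:
        raise ValueError("factor_share must be in [0, 1)")
    rng = np.random.default_rng([int(seed), 3])

    # Factor directions and strengths; total strength sums to factor_share * p.
    # Loadings are delocalized (random signs, symmetrically orthogonalized) so
    # that every gene draws a near-equal share of variance from the factors;
    # this is the regime in which a low-rank-plus-diagonal latent covariance
    # can have a (near-)uniform diagonal, which the copula contract requires.
    if k_true:
        S = rng.choice([-1.0, 1.0], size=(p, k_true)) / np.sqrt(p)
        gram = S.T @ S
        evals, evecs = np.linalg.eigh(gram)
        Q = S @ (evecs / np.sqrt(evals)) @ evecs.T   # S (S^T S)^{-1/2}
        raw = 2.0 ** -np.arange(k_true)
        W = np.sqrt(factor_share * p * raw / raw.sum())
        rowshare = (Q ** 2) @ (W ** 2)
        over = rowshare > _ROW_SHARE_CAP
        if np.any(over):
            Q[over] *= np.sqrt(_ROW_SHARE_CAP / rowshare[over])[:, None]
            rowshare = (Q ** 2) @ (W ** 2)
    else:
        Q = np.zeros((p, 0))
        W = np.zeros(0)
        rowshare = np.zeros(p)
    D = np.sqrt(1.0 - rowshare)   # exact unit diagonal of Sigma

    G = rng.standard_normal((k_true, n))
    E = rng.standard_normal((p, n))
    Z = Q @ (W[:, None] * G) + D[:, None] * E

    params: dict = {}
    size_factors = None
    if family == "normal" or family == "empirical":
        mu = np.exp(rng.normal(np.log(100.0), 1.0, size=p))
        sd = mu * np.exp(rng.normal(np.log(0.15), 0.3, size=p))
        x = mu[:, None] + sd[:, None] * Z
        x = np.clip(x, 0.0, None)   # counts container requires non-negative
        params = {"mu": mu, "sd": sd}
    elif family == "poisson":
        lam = np.exp(rng.normal(np.log(50.0), 1.2, size=p))
        u = np.clip(stats.norm.cdf(Z), 1e-12, 1 - 1e-12)
        x = stats.poisson.ppf(u, lam[:, None])
        params = {"lam": lam}
    elif family == "negbinom":
        mu = np.exp(rng.normal(np.log(100.0), 1.2, size=p))
        alpha = np.exp(rng.uniform(np.log(0.01), np.log(0.5), size=p))
        s = np.exp(rng.normal(0.0, 0.2, size=n))
        u = np.clip(stats.norm.cdf(Z), 1e-12, 1 - 1e-12)
        r = (1.0 / alpha)[:, None]
        mean = mu[:, None] * s[None, :]
        x = stats.nbinom.ppf(u, r, r / (r + mean))
        sample_ids = np.array([f"s{j + 1}" for j in range(n)])
        size_factors = SizeFactors(s, sample_ids)
        params = {"mu": mu, "alpha": alpha}
    else:
        raise ValueError(f"unknown family {family!r}")

    gene_ids = np.array([f"g{i + 1}" for i in range(p)])
    sample_ids = np.array([f"s{j + 1}" for j in range(n)])
    counts = CountMatrix(x, gene_ids, sample_ids)
    truth = SyntheticTruth(D, Q, W, family, params, size_factors, int(seed))
    return counts, truth


def make_phases(n: int, seed: Optional[int] = None, mode: str = "even") -> np.ndarray:
    """n phase angles in [0, 2*pi): evenly spaced or uniformly random."""
    if n < 3:
        raise ValueError("need n >= 3 phases")
    if mode == "even":
        return 2.0 * np.pi * np.arange(n) / n
    if mode == "random":
        rng = np.random.default_rng(None if seed is None else [int(seed), 5])
        return rng.uniform(0.0, 2.0 * np.pi, size=n)
    raise ValueError(f"unknown mode {mode!r}")
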