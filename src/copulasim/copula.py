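"""Latent-Gaussian (copula) transforms.

The NORTA / Gaussian-copula construction separates marginal distributions
from dependence: each observation is mapped through its fitted marginal CDF
to a uniform value u and then through the standard normal quantile function,
``Z_ij = Phi^{-1}(F_i(X_ij))``.  Dependence is modelled on the Z scale and
undone at generation time by the inverse map ``X'_ij = F_i^{-1}(Phi(Z'_ij))``.

For discrete (and empirical) families the CDF jumps; we place u at the
midpoint of the jump, ``u = (F(x-) + F(x)) / 2``, which is deterministic and
reproducible.  A randomized distributional transform (u uniform within the
jump) is available behind a flag.  u is clipped to ``[1e-10, 1 - 1e-10]``
before the normal quantile, bounding |Z| by about 6.4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .counts import CountMatrix
from .marginals import MarginalModel, SizeFactors, matrix_cdf, matrix_quantile

U_CLIP = 1e-10


@dataclass
class NormalizedMatrix:
    """Latent-Gaussian matrix Z with the same gene/sample ids as its source.

    Degenerate genes (constant in the reference) carry rows of exact zeros.
    """

    Z: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        if not np.all(np.isfinite(self.Z)):
            raise ValueError("normalized matrix must be finite")

    @property
    def p(self) -> int:
        return self.Z.shape[0]

    @property
    def n(self) -> int:
        return self.Z.shape[1]


def _sim_factors(model: MarginalModel, n: int,
                 size_factors: Optional[SizeFactors | np.ndarray]) -> np.ndarray:
    if size_factors is None:
        if model.family == "negbinom" and model.size_factors is not None:
            return np.asarray(model.size_factors.s, dtype=float)
        return np.ones(n)
    s = size_factors.s if isinstance(size_factors, SizeFactors) else np.asarray(size_factors, dtype=float)
    if len(s) != n:
        raise ValueError("size factor vector length does not match sample count")
    return s


def normalize(counts: CountMatrix, model: MarginalModel,
              size_factors: Optional[SizeFactors] = None,
              randomized: bool = False,
              rng: Optional[np.random.Generator] = None) -> NormalizedMatrix:
    """Copula-normalize counts to the latent Gaussian scale."""
    if not np.array_equal(counts.gene_ids, model.gene_ids):
        raise ValueError("gene ids of counts and marginal model do not match")
    x = counts.values
    s = _sim_factors(model, counts.n, size_factors)
    if model.family == "normal":
        sd = np.where(model.sd > 0, model.sd, 1.0)
        Z = (x - model.mu[:, None]) / sd[:, None]
    else:
        hi = matrix_cdf(model, x, s, minus=False)
        lo = matrix_cdf(model, x, s, minus=True)
        if randomized:
            if rng is None:
                rng = np.random.default_rng()
            u = lo + rng.uniform(size=x.shape) * (hi - lo)
        else:
            u = 0.5 * (lo + hi)
        u = np.clip(u, U_CLIP, 1.0 - U_CLIP)
        Z = stats.norm.ppf(u)
    Z[model.degenerate] = 0.0
    return NormalizedMatrix(Z, counts.gene_ids.copy(), counts.sample_ids.copy())


def denormalize(Zp: NormalizedMatrix, model: MarginalModel,
                sim_size_factors: Optional[SizeFactors | np.ndarray] = None) -> CountMatrix:
    """Map latent Gaussian samples back to the data scale (copula inversion)."""
    if not np.array_equal(Zp.gene_ids, model.gene_ids):
        raise ValueError("gene ids of Z and marginal model do not match")
    s = _sim_factors(model, Zp.n, sim_size_factors) if sim_size_factors is not None \
        else np.ones(Zp.n)
    u = stats.norm.cdf(Zp.Z)
    u = np.clip(u, U_CLIP, 1.0 - U_CLIP)
    x = matrix_quantile(model, u, s)
    if model.family in ("poisson", "negbinom"):
        x = np.rint(x)
    elif model.family == "normal":
        # a normal fit on non-negative data has a small negative tail;
        # truncate so the output remains a valid counts container
        x = np.clip(x, 0.0, None)
    return CountMatrix(x, Zp.gene_ids.copy(), Zp.sample_ids.copy())
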