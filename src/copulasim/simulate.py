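"""Sample generation from a fitted reference model.

Each simulated sample draws k factor scores u ~ N(0, I_k) and p independent
noise values v ~ N(0, I_p), forms the latent vector ``Z' = U (W * u) + D * v``
(cov Z' = Sigma by construction), and maps it back to the data scale through
the fitted marginals.  Cost is O(p (k + 1)) per sample plus the marginal
quantile evaluations; nothing of size p x p is ever allocated.

``inject_de`` perturbs a copy of the model for two-group differential
expression benchmarks: a fixed fraction of genes has its mean multiplied by
2**beta with |beta| uniform on a configured log2-fold-change range and a
random sign, while the dependence structure is left untouched.

``simulate_timeseries`` drives a time-course design: per timepoint the
per-gene means are replaced by a column of a mean-profile matrix while the
dispersions / standard deviations and the covariance stay at the reference
fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .copula import NormalizedMatrix, denormalize
from .counts import CountMatrix
from .marginals import SizeFactors


@dataclass
class DETruth:
    """Ground truth for an injected differential-expression design."""

    gene_ids: np.ndarray
    is_de: np.ndarray     # bool, per gene
    log2fc: np.ndarray    # 0 for non-DE genes; sign encodes direction

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_ids, "is_de": self.is_de,
                             "log2fc": self.log2fc})


def _require_covariance(model) -> None:
    if model.covariance is None:
        raise ValueError("model has no fitted covariance; cannot simulate")


def simulate(model, n_sim: int, rng: np.random.Generator,
             sim_size_factors: Optional[SizeFactors | np.ndarray] = None,
             sample_prefix: str = "sim") -> CountMatrix:
    """Draw ``n_sim`` independent samples from a fitted ReferenceModel."""
    _require_covariance(model)
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    fc = model.covariance
    u = rng.standard_normal((fc.k, n_sim))
    v = rng.standard_normal((fc.p, n_sim))
    Zp = fc.U @ (fc.W[:, None] * u) + fc.D[:, None] * v
    Zp[model.marginals.degenerate] = 0.0
    sample_ids = np.array([f"{sample_prefix}_{j + 1}" for j in range(n_sim)])
    nm = NormalizedMatrix(Zp, model.gene_ids.copy(), sample_ids)
    s = sim_size_factors
    if s is None:
        s = np.ones(n_sim)
    elif isinstance(s, SizeFactors):
        s = s.s
    else:
        s = np.asarray(s, dtype=float)
    if len(s) != n_sim:
        raise ValueError("sim size factor vector must have length n_sim")
    return denormalize(nm, model.marginals, s)


def resample_size_factors(model, n_sim: int, rng: np.random.Generator) -> np.ndarray:
    """Bootstrap new-sample size factors from the reference's fitted ones."""
    if model.size_factors is None:
        raise ValueError("model has no fitted size factors to resample")
    return rng.choice(model.size_factors.s, size=n_sim, replace=True)


def inject_de(model, fraction: float, lfc_lo: float = 0.2, lfc_hi: float = 2.0,
              rng: Optional[np.random.Generator] = None,
              exact_count: bool = True):
    """Return (perturbed model copy, DETruth) for a DE benchmark.

    A ``fraction`` of genes is selected uniformly at random (exactly
    ``ceil(fraction * p)`` genes by default, or per-gene Bernoulli when
    ``exact_count=False``); each selected gene's mean is multiplied by
    2**beta, |beta| ~ Uniform(lfc_lo, lfc_hi), up- or down-regulation chosen
    with probability 1/2.  The covariance is untouched.  Empirical marginals
    have no parametric mean to scale and raise.
    """
    if model.marginals.family == "empirical":
        raise ValueError("cannot inject differential expression into empirical "
                         "marginals: no parametric mean to scale")
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    if lfc_lo < 0 or lfc_hi < lfc_lo:
        raise ValueError("need 0 <= lfc_lo <= lfc_hi")
    if rng is None:
        rng = np.random.default_rng()
    p = len(model.gene_ids)
    is_de = np.zeros(p, dtype=bool)
    if fraction > 0:
        if exact_count:
            n_de = int(np.ceil(fraction * p))
            is_de[rng.choice(p, size=n_de, replace=False)] = True
        else:
            is_de = rng.uniform(size=p) < fraction
    log2fc = np.zeros(p)
    n_de = int(is_de.sum())
    beta = rng.uniform(lfc_lo, lfc_hi, size=n_de)
    sign = rng.choice([-1.0, 1.0], size=n_de)
    log2fc[is_de] = sign * beta

    new = model.copy()
    new.marginals.mu = new.marginals.mu * 2.0 ** log2fc
    truth = DETruth(model.gene_ids.copy(), is_de, log2fc)
    return new, truth


def simulate_timeseries(model, mean_profiles: np.ndarray,
                        samples_per_timepoint: int,
                        rng: np.random.Generator,
                        times: Optional[Sequence[float]] = None,
                        sim_size_factors=None):
    """Simulate a time course with per-timepoint means.

    ``mean_profiles`` is (p, T); column t replaces the per-gene means while
    dispersions / standard deviations and the covariance stay at the
    reference fit.  Returns (CountMatrix, true time per simulated sample).
    """
    if model.marginals.family == "empirical":
        raise ValueError("time-series simulation requires parametric means")
    _require_covariance(model)
    prof = np.asarray(mean_profiles, dtype=float)
    if prof.ndim != 2 or prof.shape[0] != len(model.gene_ids):
        raise ValueError("mean_profiles must be (p, T)")
    T = prof.shape[1]
    if T < 2:
        raise ValueError("need at least 2 timepoints")
    if np.any(prof < 0) or not np.all(np.isfinite(prof)):
        raise ValueError("mean profiles must be finite and non-negative")
    if times is None:
        times = np.arange(T, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(times) != T:
        raise ValueError("times must have length T")

    blocks, labels = [], []
    for t in range(T):
        mt = model.copy()
        mt.marginals.mu = prof[:, t].copy()
        block = simulate(mt, samples_per_timepoint, rng,
                         sim_size_factors=sim_size_factors,
                         sample_prefix=f"t{t}")
        blocks.append(block.values)
        labels.extend([times[t]] * samples_per_timepoint)
    values = np.concatenate(blocks, axis=1)
    sample_ids = np.array([f"t{t}_s{j + 1}" for t in range(T)
                           for j in range(samples_per_timepoint)])
    return (CountMatrix(values, model.gene_ids.copy(), sample_ids),
            np.asarray(labels))
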