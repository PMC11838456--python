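"""Model / results objects tying the pipeline together.

``CopulaModel`` holds a reference counts matrix and a marginal family;
``fit()`` estimates size factors (negative binomial only), the per-gene
marginals, the copula normalization and the factorized latent covariance by
the chosen method, and returns a :class:`ReferenceModel` results object.
The results object carries the estimates and diagnostics, prints a
``summary()``, and exposes ``simulate`` / ``inject_de`` /
``simulate_timeseries`` plus ``save``/``load``.

Randomness is organized as named sub-streams derived from one integer seed,
so fitting, DE injection and simulation are independently reproducible.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import simulate as _sim
from .copula import NormalizedMatrix, normalize
from .counts import CountMatrix
from .covariance import (FactorizedCovariance, fit_corpcor, fit_independent,
                         fit_pca)
from .marginals import (FAMILIES, MarginalModel, SizeFactors, fit_marginals,
                        fit_size_factors)
from .spiked_wishart import SGDConfig, fit_spiked, to_factorized

METHODS = ("independent", "pca", "wishart", "corpcor")

_STREAMS = {"fit": 0, "de": 1, "simulate": 2, "fixture": 3, "timeseries": 4}


def substream(seed: Optional[int], name: str) -> np.random.Generator:
    """Named, reproducible RNG sub-stream for one pipeline stage."""
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng([int(seed), _STREAMS[name]])


class CopulaModel:
    """Gaussian-copula dependence model of a reference counts matrix.

    Parameters
    ----------
    counts : CountMatrix
        Reference genes x samples matrix to mimic.
    family : str
        Marginal family: "normal", "poisson", "negbinom" or "empirical".
    """

    def __init__(self, counts: CountMatrix, family: str = "negbinom"):
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        self.counts = counts
        self.family = family

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, family: str = "negbinom") -> "CopulaModel":
        return cls(CountMatrix.from_dataframe(df), family)

    def fit(self, method: str = "pca", k: Optional[int] = None,
            seed: Optional[int] = 0,
            sgd_config: Optional[SGDConfig] = None) -> "ReferenceModel":
        """Fit marginals and the latent covariance; return a ReferenceModel.

        ``k`` defaults to min(2, n - 2) for the PCA method and to n - 1 for
        the spiked-Wishart method; it is ignored by the independent and
        corpcor methods.
        """
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
        counts, family = self.counts, self.family
        n = counts.n
        size_factors = fit_size_factors(counts) if family == "negbinom" else None
        marg = fit_marginals(counts, family, size_factors)
        Z = normalize(counts, marg, size_factors)

        nondeg = ~marg.degenerate
        Zsub = NormalizedMatrix(Z.Z[nondeg], Z.gene_ids[nondeg], Z.sample_ids)
        p_sub = Zsub.p

        if method == "independent":
            fc_sub = fit_independent(Zsub)
            k_used = 0
        elif method == "pca":
            k_used = min(2, n - 2) if k is None else int(k)
            fc_sub = fit_pca(Zsub, k_used)
        elif method == "corpcor":
            fc_sub = fit_corpcor(Zsub)
            k_used = fc_sub.k
        else:  # wishart
            rng = substream(seed, "fit")
            Zc = Zsub.Z - Zsub.Z.mean(axis=1, keepdims=True)
            Ufull, svals, _ = np.linalg.svd(Zc, full_matrices=False)
            # centering removes one rank, so at most n-1 (and at most p)
            # non-zero singular values remain
            m_avail = min(p_sub, n - 1)
            lam = svals[:m_avail]
            k_used = min(n - 1, m_avail, p_sub - 1) if k is None else int(k)
            sp = fit_spiked(lam, p_sub, k_used, rng, sgd_config)
            fc_sub = to_factorized(sp, Ufull[:, :k_used])

        # re-embed degenerate genes as zero rows
        p = counts.p
        D = np.zeros(p)
        U = np.zeros((p, fc_sub.k))
        D[nondeg] = fc_sub.D
        U[nondeg] = fc_sub.U
        fc = FactorizedCovariance(D, U, fc_sub.W, method=method,
                                  extra=dict(fc_sub.extra))

        diag = fc_sub.sigma_diag()
        diagnostics = {
            "max_abs_diag_dev": float(np.max(np.abs(diag - 1.0))) if p_sub else 0.0,
            "n_degenerate": int(np.sum(~nondeg)),
        }
        diagnostics.update({key: val for key, val in fc.extra.items()
                            if np.ndim(val) == 0})
        if method == "wishart":
            diagnostics["sgd_converged"] = bool(sp.report.converged)
            diagnostics["sgd_max_rel_err"] = float(sp.report.rel_err.max())

        meta = {"family": family, "method": method, "k": int(fc.k),
                "seed": seed, "p": int(p), "n": int(n)}
        return ReferenceModel(marg, fc, size_factors, counts.gene_ids.copy(),
                              meta, diagnostics)


@dataclass
class ReferenceModel:
    """Fitted reference model: marginals + factorized covariance + metadata."""

    marginals: MarginalModel
    covariance: Optional[FactorizedCovariance]
    size_factors: Optional[SizeFactors]
    gene_ids: np.ndarray
    metadata: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.gene_ids) != self.marginals.p:
            raise ValueError("gene dimension mismatch between parts")
        if self.covariance is not None and self.covariance.p != self.marginals.p:
            raise ValueError("gene dimension mismatch between parts")

    @property
    def p(self) -> int:
        return len(self.gene_ids)

    def copy(self) -> "ReferenceModel":
        return ReferenceModel(self.marginals.copy(),
                              _copy.deepcopy(self.covariance),
                              self.size_factors, self.gene_ids.copy(),
                              dict(self.metadata), dict(self.diagnostics))

    # -- generation ---------------------------------------------------------
    def simulate(self, n_sim: int, seed: Optional[int] = None,
                 size_factors=None, resample_size_factors: bool = False) -> CountMatrix:
        rng = substream(seed, "simulate")
        if resample_size_factors:
            if size_factors is not None:
                raise ValueError("pass either size_factors or resample_size_factors")
            size_factors = _sim.resample_size_factors(self, n_sim, rng)
        return _sim.simulate(self, n_sim, rng, sim_size_factors=size_factors)

    def inject_de(self, fraction: float, lfc_lo: float = 0.2,
                  lfc_hi: float = 2.0, seed: Optional[int] = None,
                  exact_count: bool = True):
        rng = substream(seed, "de")
        return _sim.inject_de(self, fraction, lfc_lo, lfc_hi, rng,
                              exact_count=exact_count)

    def simulate_timeseries(self, mean_profiles, samples_per_timepoint: int,
                            seed: Optional[int] = None, times=None,
                            size_factors=None):
        rng = substream(seed, "timeseries")
        return _sim.simulate_timeseries(self, mean_profiles,
                                        samples_per_timepoint, rng,
                                        times=times,
                                        sim_size_factors=size_factors)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        from .io import save_model
        save_model(self, path)

    @classmethod
    def load(cls, path) -> "ReferenceModel":
        from .io import load_model
        return load_model(path)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        meta, diag = self.metadata, self.diagnostics
        lines = [
            "Gaussian copula reference model",
            "=" * 47,
            f"genes (p):            {self.p}",
            f"reference samples:    {meta.get('n', '?')}",
            f"marginal family:      {self.marginals.family}",
            f"covariance method:    {meta.get('method', '?')}",
            f"latent rank k:        {meta.get('k', '?')}",
            f"seed:                 {meta.get('seed')}",
            f"degenerate genes:     {diag.get('n_degenerate', 0)}",
            f"max |diag(Sigma)-1|:  {diag.get('max_abs_diag_dev', float('nan')):.4f}",
        ]
        for key in ("lambda_corr", "lambda_var", "c", "sgd_converged",
                    "sgd_max_rel_err", "clamped_weights", "clamped_diag"):
            if key in diag:
                val = diag[key]
                sval = f"{val:.4f}" if isinstance(val, float) else str(val)
                lines.append(f"{key + ':':<22}{sval}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        meta = self.metadata
        return (f"<ReferenceModel p={self.p} family={self.marginals.family} "
                f"method={meta.get('method')} k={meta.get('k')}>")
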