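"""Low-rank-plus-diagonal covariance estimation.

All estimators share one canonical factorization:

    Sigma = diag(D**2) + U @ diag(W**2) @ U.T

so that a latent sample is generated as ``Z' = U (W * u) + D * v`` with
``u ~ N(0, I_k)`` and ``v ~ N(0, I_p)``; cov(Z') = Sigma by construction
and Sigma is positive semi-definite (a non-negative diagonal plus a Gram
matrix).  No p x p matrix is ever formed by the estimators.

Estimators
----------
``fit_pca``
    Matches the variance of the reference exactly along its top-k principal
    directions and on every coordinate axis, by solving a small k x k linear
    system for the factor weights.
``fit_corpcor``
    James-Stein shrinkage of the sample covariance (correlations shrunk
    toward zero, variances toward their median) with analytically estimated
    shrinkage intensities, expressed exactly in factorized form with k = n.
``fit_independent``
    The independence baseline: W = 0, D = per-gene standard deviation.

The spiked-Wishart estimator lives in :mod:`copulasim.spiked_wishart`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg

from .copula import NormalizedMatrix


@dataclass
class FactorizedCovariance:
    """Factors (D, U, W) of Sigma = diag(D^2) + U diag(W^2) U^T."""

    D: np.ndarray          # (p,) non-negative
    U: np.ndarray          # (p, k)
    W: np.ndarray          # (k,) non-negative
    method: str = "unknown"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if self.U.ndim != 2 or self.D.ndim != 1 or self.W.ndim != 1:
            raise ValueError("D and W must be vectors and U a matrix")
        if self.U.shape != (len(self.D), len(self.W)):
            raise ValueError("U must be (p, k) with p = len(D), k = len(W)")
        if np.any(self.D < 0) or np.any(self.W < 0):
            raise ValueError("D and W must be non-negative")

    @property
    def p(self) -> int:
        return len(self.D)

    @property
    def k(self) -> int:
        return len(self.W)

    def sigma_diag(self) -> np.ndarray:
        """Diagonal of Sigma without materializing it."""
        return self.D ** 2 + (self.U ** 2) @ (self.W ** 2)

    def dense(self) -> np.ndarray:
        """Materialize Sigma (tests / small p only)."""
        return np.diag(self.D ** 2) + (self.U * self.W ** 2) @ self.U.T


def sigma_quadform(fc: FactorizedCovariance, x: np.ndarray) -> float:
    """x^T Sigma x via the factors, never forming Sigma."""
    x = np.asarray(x, dtype=float)
    if x.shape != (fc.p,):
        raise ValueError(f"x must have shape ({fc.p},), got {x.shape}")
    t = fc.U.T @ x
    return float(np.sum((fc.D * x) ** 2) + np.sum((fc.W * t) ** 2))


def _centered(Z: np.ndarray) -> np.ndarray:
    return Z - Z.mean(axis=1, keepdims=True)


def fit_independent(Z: NormalizedMatrix) -> FactorizedCovariance:
    """Independence baseline: diagonal Sigma from per-gene latent variances."""
    Zc = _centered(Z.Z)
    D = np.sqrt((Zc ** 2).sum(axis=1) / (Z.n - 1))
    return FactorizedCovariance(D, np.zeros((Z.p, 0)), np.zeros(0), method="independent")


def fit_pca(Z: NormalizedMatrix, k: int) -> FactorizedCovariance:
    """Variance-matching PCA estimator.

    With ``u_i`` the top-k left singular vectors of the row-centered Z and
    ``t_i`` the sample variance of Z projected on ``u_i``, solves for factor
    weights ``s`` in ``A s = B`` (A_ij = delta_ij - sum_l U_li^2 U_lj^2,
    B_i = t_i - sum_l U_li^2 V_ll) so that ``u_i' Sigma u_i = t_i`` exactly,
    then absorbs the remaining per-gene variance into D so that the diagonal
    of Sigma equals the per-gene sample variance.  Negative solutions or
    negative remaining variances are clamped to zero with a warning.
    """
    p, n = Z.p, Z.n
    if not 1 <= k <= n - 2:
        raise ValueError(f"fit_pca requires 1 <= k <= n-2 (= {n - 2}), got k={k}")
    Zc = _centered(Z.Z)
    Ufull, svals, _ = linalg.svd(Zc, full_matrices=False)
    U = Ufull[:, :k]
    t = svals[:k] ** 2 / (n - 1)
    Vdiag = (Zc ** 2).sum(axis=1) / (n - 1)
    Usq = U ** 2
    A = np.eye(k) - Usq.T @ Usq
    B = t - Usq.T @ Vdiag
    try:
        s = linalg.solve(A, B)
    except linalg.LinAlgError:
        warnings.warn("singular system in fit_pca; falling back to least squares")
        s, *_ = linalg.lstsq(A, B)
    w_clamped = int(np.sum(s < -1e-12))
    W = np.sqrt(np.clip(s, 0.0, None))
    Dsq = Vdiag - Usq @ (W ** 2)
    d_clamped = int(np.sum(Dsq < -1e-12))
    D = np.sqrt(np.clip(Dsq, 0.0, None))
    if w_clamped or d_clamped:
        warnings.warn(
            f"fit_pca clamped {w_clamped} negative factor weights and "
            f"{d_clamped} negative residual variances to zero")
    return FactorizedCovariance(
        D, U, W, method="pca",
        extra={"k": k, "target_variances": t,
               "clamped_weights": w_clamped, "clamped_diag": d_clamped})


def _shrinkage_intensities(Zc: np.ndarray) -> tuple[float, float]:
    """Analytic James-Stein shrinkage intensities (correlation, variance).

    Computed from the centered data via n x n Gram identities, so the cost is
    O(p n^2 + n^3) and no p x p object is formed.  Both intensities are
    clamped to [0, 1].
    """
    p, n = Zc.shape
    v = (Zc ** 2).sum(axis=1) / (n - 1)
    sd = np.sqrt(v)

    # variance shrinkage toward the median variance
    z = Zc ** 2
    zbar = z.mean(axis=1)
    var_v = n / (n - 1) ** 3 * ((z - zbar[:, None]) ** 2).sum()
    vmed = float(np.median(v))
    den2 = float(((v - vmed) ** 2).sum())
    lam2 = 1.0 if den2 <= 0 else float(np.clip(var_v / den2, 0.0, 1.0))

    # correlation shrinkage toward zero, on standardized data
    y = Zc / sd[:, None]
    G = y.T @ y                        # n x n Gram over genes
    sum_Gkk2 = float(np.sum(np.diag(G) ** 2))
    sum_F = float(np.sum(G ** 2))
    total_num = sum_Gkk2 - sum_F / n   # sum over ALL (i, j) of sum_k (w - wbar)^2
    diag_num = float(np.sum(y ** 4)) - p * (n - 1) ** 2 / n
    off_num = n / (n - 1) ** 3 * (total_num - diag_num)
    off_den = sum_F / (n - 1) ** 2 - p  # sum_{i != j} r_ij^2
    lam1 = 1.0 if off_den <= 0 else float(np.clip(off_num / off_den, 0.0, 1.0))
    return lam1, lam2


def fit_corpcor(Z: NormalizedMatrix) -> FactorizedCovariance:
    """James-Stein shrinkage covariance in factorized form (k = n).

    The dense estimate it represents has diagonal ``v*_i = lam2 * v_med +
    (1 - lam2) * v_i`` and off-diagonal ``(1 - lam1) * r_ij *
    sqrt(v*_i v*_j)``; the factors reproduce it exactly:
    D_i = sqrt(lam1 * v*_i), U = sqrt(1 - lam1) * S Zc / sqrt(n - 1) with
    S_ii = sqrt(v*_i) / sd_i, and W = 1.

    Rows of exact zeros (degenerate genes) contribute zero factors; a
    constant non-zero row has no defined correlation and raises.
    """
    p, n = Z.p, Z.n
    if n < 3:
        raise ValueError("fit_corpcor requires at least 3 samples")
    zero = np.all(Z.Z == 0.0, axis=1)
    active = ~zero
    Za = Z.Z[active]
    Zc = _centered(Za)
    v = (Zc ** 2).sum(axis=1) / (n - 1)
    if np.any(v == 0):
        bad = Z.gene_ids[active][v == 0][0]
        raise ValueError(f"gene {bad!r} has zero variance on the latent scale "
                         "but is not a degenerate (all-zero) row")
    lam1, lam2 = _shrinkage_intensities(Zc)
    vmed = float(np.median(v))
    vstar = lam2 * vmed + (1.0 - lam2) * v
    Da = np.sqrt(lam1 * vstar)
    S = np.sqrt(vstar) / np.sqrt(v)
    Ua = np.sqrt(1.0 - lam1) * (Zc * S[:, None]) / np.sqrt(n - 1)
    D = np.zeros(p)
    U = np.zeros((p, n))
    D[active] = Da
    U[active] = Ua
    return FactorizedCovariance(
        D, U, np.ones(n), method="corpcor",
        extra={"lambda_corr": lam1, "lambda_var": lam2})
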