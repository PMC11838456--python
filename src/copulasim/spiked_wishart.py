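"""Spiked-Wishart spectrum sampling and moment-matching by SGD.

Model: a p x m matrix Y whose m columns are iid N(0, Sigma) with Sigma
diagonal up to rotation, having k "spike" eigenvalues w_1..w_k and a flat
bulk of p - k eigenvalues equal to c^2.  The singular values of Y are the
square roots of the eigenvalues of the m x m Gram matrix

    M = Y^T Y  =  sum_{i<=k} w_i h_i h_i^T  +  c^2 B,

with h_i iid standard normal m-vectors and B ~ Wishart_m(p - k, I) drawn by
the Bartlett decomposition.  This samples the exact singular-value law at
O(m^3 + k m^2) cost with no p-sized allocation.

``fit_spiked`` chooses (w, c) so that the expected sample singular values
match a given reference spectrum, E[lambda'_i] = lambda_i, by Adam-flavoured
stochastic gradient descent on log-parameters.  Per-eigenvalue gradients come
from first-order eigenvalue perturbation: for M's unit eigenvector q_j,
d eig_j / d w_i = (q_j . h_i)^2 and d eig_j / d c^2 = q_j^T B q_j.  The
residual is evaluated on a draw independent of the gradient draw, making the
stochastic gradient unbiased for the gradient of sum_i (E[lambda'_i] -
lambda_i)^2.  Log-parameters are tail-averaged over the final quarter of the
steps to reduce the SGD noise floor, and the fit is validated on fresh Monte
Carlo draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import linalg

from .covariance import FactorizedCovariance


@dataclass
class SGDConfig:
    """Tuning knobs for :func:`fit_spiked`."""

    steps: int = 1000
    lr: float = 0.05
    eval_reps: int = 200
    rel_tol: float = 0.05
    tail_frac: float = 0.25  # fraction of final steps averaged into the answer
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


@dataclass
class FitReport:
    converged: bool
    rel_err: np.ndarray       # per singular value, on held-out draws
    eval_mean: np.ndarray
    steps: int


@dataclass
class SpikedSpectrum:
    """Spike eigenvalues w (total, >= c^2 once clamped), bulk scale c, dims."""

    w: np.ndarray
    c: float
    p: int
    m: int
    report: Optional[FitReport] = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 1:
            raise ValueError("w must be a vector")
        if len(self.w) >= self.p:
            raise ValueError("need k < p")
        if self.m < 1 or self.c <= 0 or np.any(self.w <= 0):
            raise ValueError("m >= 1 and positive w, c required")

    @property
    def k(self) -> int:
        return len(self.w)


def _draw_gram(w: np.ndarray, c2: float, p: int, m: int,
               rng: np.random.Generator):
    """One draw of (M, B, H) for the Gram-matrix reduction."""
    k = len(w)
    df = p - k
    if df >= m:
        # Bartlett decomposition: O(m^2) normals + m chi-squares
        A = np.zeros((m, m))
        tri = np.tril_indices(m, -1)
        A[tri] = rng.standard_normal(len(tri[0]))
        A[np.diag_indices(m)] = np.sqrt(rng.chisquare(df - np.arange(m)))
        B = A @ A.T
    elif df > 0:
        # singular Wishart (df < m): explicit df x m Gaussian factor
        G = rng.standard_normal((df, m))
        B = G.T @ G
    else:
        B = np.zeros((m, m))
    if k:
        H = rng.standard_normal((k, m))
        M = c2 * B + (H * w[:, None]).T @ H
    else:
        H = np.zeros((0, m))
        M = c2 * B
    return M, B, H


def sample_singular_values(sp: SpikedSpectrum,
                           rng: np.random.Generator) -> np.ndarray:
    """Singular values (descending) of one p x m draw, via the Gram trick."""
    M, _, _ = _draw_gram(sp.w, sp.c ** 2, sp.p, sp.m, rng)
    eig = linalg.eigvalsh(M)
    return np.sqrt(np.clip(eig, 0.0, None))[::-1]


def expected_singular_values(sp: SpikedSpectrum, rng: np.random.Generator,
                             reps: int) -> np.ndarray:
    """Monte-Carlo estimate of E[lambda'_i] over ``reps`` fresh draws."""
    acc = np.zeros(sp.m)
    for _ in range(reps):
        acc += sample_singular_values(sp, rng)
    return acc / reps


def fit_spiked(ref_singular_values: np.ndarray, p: int, k: int,
               rng: np.random.Generator,
               config: Optional[SGDConfig] = None,
               init: Optional[tuple[np.ndarray, float]] = None) -> SpikedSpectrum:
    """Fit spike strengths and bulk scale so E[lambda'] matches the reference.

    Parameters
    ----------
    ref_singular_values : array, length m
        The non-zero singular values of the (centered) reference matrix,
        sorted descending.
    p : int
        Ambient dimension (number of genes).
    k : int
        Number of spikes, 0 <= k <= m.
    rng : numpy Generator
        Drives both training and the held-out convergence check.
    """
    cfg = config or SGDConfig()
    lam = np.sort(np.asarray(ref_singular_values, dtype=float))[::-1]
    m = len(lam)
    if k > m:
        raise ValueError(f"k = {k} exceeds the number of reference values m = {m}")
    if k >= p:
        raise ValueError("need k < p")
    if np.any(lam <= 0):
        raise ValueError("reference singular values must be positive")

    # Initialization.  The moment-matching objective is flat along a manifold
    # of (w, c) combinations with near-identical expected spectra, so the
    # starting point selects which solution SGD settles into.  We start at the
    # spectrum-consistent point: c^2 from trace matching, and each spike at
    # the population value whose expected sample eigenvalue (first-order
    # spike-inflation map T = w (1 + gamma c^2 / (w - c^2)), gamma = (p-k)/m)
    # reproduces the reference; sample values inside the bulk invert below
    # c^2 and start exactly at the bulk, keeping e_i' Sigma e_i near 1.
    if init is not None:
        w_init, c_init = init
        c2_init = float(c_init) ** 2
        w0 = np.asarray(w_init, dtype=float)
        if len(w0) != k:
            raise ValueError("init spike vector must have length k")
        theta = np.concatenate([np.log(w0), [np.log(c2_init)]])
        return _run_sgd(theta, lam, p, k, m, rng, cfg)
    c2_init = float(np.sum(lam ** 2) / (m * p))
    if k:
        T = lam[:k] ** 2 / m
        gamma = (p - k) / m
        b = T + c2_init * (1.0 - gamma)
        disc = b ** 2 - 4.0 * T * c2_init
        root = np.where(disc > 0, (b + np.sqrt(np.clip(disc, 0, None))) / 2.0,
                        c2_init)
        w0 = np.clip(root, c2_init, None)
    else:
        w0 = np.zeros(0)
    theta = np.concatenate([np.log(np.clip(w0, 1e-12, None)),
                            [np.log(c2_init)]])
    return _run_sgd(theta, lam, p, k, m, rng, cfg)


def _run_sgd(theta: np.ndarray, lam: np.ndarray, p: int, k: int, m: int,
             rng: np.random.Generator, cfg: SGDConfig) -> SpikedSpectrum:
    mom1 = np.zeros_like(theta)
    mom2 = np.zeros_like(theta)
    tail_start = cfg.steps - max(1, int(cfg.tail_frac * cfg.steps))
    tail_sum = np.zeros_like(theta)
    tail_n = 0

    for step in range(cfg.steps):
        w = np.exp(theta[:k])
        c2 = np.exp(theta[-1])
        # residual draw (independent of the gradient draw)
        M1, _, _ = _draw_gram(w, c2, p, m, rng)
        lam1 = np.sqrt(np.clip(linalg.eigvalsh(M1), 0.0, None))[::-1]
        resid = lam1 - lam
        # gradient draw
        M2, B2, H2 = _draw_gram(w, c2, p, m, rng)
        eig2, Q = linalg.eigh(M2)
        order = np.argsort(eig2)[::-1]
        eig2 = eig2[order]
        Q = Q[:, order]
        lam2 = np.sqrt(np.clip(eig2, 0.0, None))
        inv2 = 1.0 / np.clip(lam2, 1e-12, None)
        # d loss / d eig_j, chained through the square root
        gj = resid * inv2
        grad = np.empty_like(theta)
        if k:
            P = H2 @ Q                       # (k, m): h_i . q_j
            grad[:k] = (P ** 2) @ gj * w     # d/d log w_i
        qBq = np.sum(Q * (B2 @ Q), axis=0)   # q_j^T B q_j for each j
        grad[-1] = float(qBq @ gj) * c2      # d/d log c^2

        mom1 = cfg.beta1 * mom1 + (1 - cfg.beta1) * grad
        mom2 = cfg.beta2 * mom2 + (1 - cfg.beta2) * grad ** 2
        m1 = mom1 / (1 - cfg.beta1 ** (step + 1))
        m2 = mom2 / (1 - cfg.beta2 ** (step + 1))
        theta = theta - cfg.lr * m1 / (np.sqrt(m2) + cfg.eps)
        if step >= tail_start:
            tail_sum += theta
            tail_n += 1

    theta = tail_sum / tail_n
    c2 = float(np.exp(theta[-1]))
    c = float(np.sqrt(c2))
    # Spikes below the bulk carry no extra variance; clamp into the valid
    # region.  Spike labels are exchangeable in the objective, so sort
    # descending: w_i then pairs with the i-th reference singular direction.
    w = np.sort(np.maximum(np.exp(theta[:k]), c2))[::-1] if k else np.zeros(0)
    sp = SpikedSpectrum(w, c, p, m)

    eval_mean = expected_singular_values(sp, rng, cfg.eval_reps)
    rel_err = np.abs(eval_mean - lam) / lam
    sp.report = FitReport(bool(np.all(rel_err <= cfg.rel_tol)), rel_err,
                          eval_mean, cfg.steps)
    return sp


def to_factorized(sp: SpikedSpectrum, U: np.ndarray) -> FactorizedCovariance:
    """Convert a spiked spectrum plus spike directions to (D, U, W) factors.

    The fitted w_i are total eigenvalues of Sigma along u_i; the additive
    factor weights are W_i = sqrt(w_i - c^2), so Sigma's spectrum is exactly
    (w_1..w_k, c^2, ..., c^2).
    """
    U = np.asarray(U, dtype=float)
    if U.shape != (sp.p, sp.k):
        raise ValueError(f"U must be ({sp.p}, {sp.k}), got {U.shape}")
    if sp.k and not np.allclose(U.T @ U, np.eye(sp.k), atol=1e-6):
        raise ValueError("U must have orthonormal columns")
    D = np.full(sp.p, sp.c)
    W = np.sqrt(np.clip(sp.w - sp.c ** 2, 0.0, None))
    return FactorizedCovariance(D, U, W, method="wishart",
                                extra={"c": sp.c, "w": sp.w.copy(),
                                       "m": sp.m})
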