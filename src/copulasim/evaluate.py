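"""Comparison statistics between reference and simulated data.

These reproduce the standard faithfulness checks for a count simulator:
per-gene mean/variance agreement, quantile-quantile comparison of gene-pair
correlations among highly expressed genes, per-dataset principal-component
variance spectra, projections of every dataset onto the reference's top
principal components, realized false-discovery-proportion calibration for
differential-expression benchmarks, and the circular correlation coefficient
for benchmarking phase-inference methods on time-course data.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .counts import CountMatrix
from .simulate import DETruth


def circular_correlation(X: Sequence[float], Y: Sequence[float]) -> float:
    """Circular correlation between paired angle vectors (radians).

    rho = sum_{i<j} sin(X_i - X_j) sin(Y_i - Y_j) /
          sqrt(sum_{i<j} sin^2(X_i - X_j)) / sqrt(sum_{i<j} sin^2(Y_i - Y_j))

    Invariant to adding a constant to X or Y; negated when Y -> -Y; in
    [-1, 1], with |rho| near 1 meaning accurate phase recovery up to rotation
    and reflection of the circle.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 1 or len(X) < 3:
        raise ValueError("X and Y must be equal-length angle vectors, n >= 3")
    iu = np.triu_indices(len(X), 1)
    sx = np.sin(X[:, None] - X[None, :])[iu]
    sy = np.sin(Y[:, None] - Y[None, :])[iu]
    dx = np.sqrt(np.sum(sx ** 2))
    dy = np.sqrt(np.sum(sy ** 2))
    if dx == 0 or dy == 0:
        raise ValueError("circular correlation undefined: all pairwise sines "
                         "are zero (constant phases)")
    return float(np.sum(sx * sy) / (dx * dy))


def _aligned(real: CountMatrix, sim: CountMatrix) -> CountMatrix:
    if set(real.gene_ids) != set(sim.gene_ids):
        raise ValueError("real and simulated matrices must share their gene set")
    return sim.reindex_genes(real.gene_ids)


def corr_qq(real: CountMatrix, sim: CountMatrix, min_mean: float = 300.0,
            log_scale: bool = False):
    """Paired sorted gene-pair correlation vectors (real vs simulated).

    Restricts to genes whose mean in the *real* matrix is at least
    ``min_mean``, computes all pairwise Pearson correlations within each
    matrix, and returns both vectors sorted ascending (equal length, so they
    pair up as QQ points).  ``log_scale`` applies log1p before correlating.
    """
    sim = _aligned(real, sim)
    keep = real.values.mean(axis=1) >= min_mean
    if keep.sum() < 2:
        raise ValueError(f"fewer than 2 genes have mean >= {min_mean}")
    xr = real.values[keep]
    xs = sim.values[keep]
    if log_scale:
        xr, xs = np.log1p(xr), np.log1p(xs)
    iu = np.triu_indices(int(keep.sum()), 1)
    with np.errstate(invalid="ignore"):
        cr = np.corrcoef(xr)[iu]
        cs = np.corrcoef(xs)[iu]
    ok = np.isfinite(cr) & np.isfinite(cs)
    return np.sort(cr[ok]), np.sort(cs[ok])


def pc_spectrum(data: CountMatrix, n_components: int) -> np.ndarray:
    """Variances of the top principal components (genes centered, no scaling)."""
    p, n = data.p, data.n
    if n_components > min(p, n - 1):
        raise ValueError("n_components exceeds min(p, n-1)")
    Xc = data.values - data.values.mean(axis=1, keepdims=True)
    svals = np.linalg.svd(Xc, compute_uv=False)
    return svals[:n_components] ** 2 / (n - 1)


def project_onto(reference: CountMatrix, others: Iterable[CountMatrix],
                 n_components: int = 2) -> List[np.ndarray]:
    """Project datasets onto the reference's top principal components.

    PC weights and centering are fit on the reference only.  Returns one
    (n_components, n_samples) coordinate array per dataset, the reference
    first followed by ``others`` in order.
    """
    mean = reference.values.mean(axis=1, keepdims=True)
    Xc = reference.values - mean
    U, svals, _ = np.linalg.svd(Xc, full_matrices=False)
    Uk = U[:, :n_components]
    coords = [Uk.T @ Xc]
    for other in others:
        other = _aligned(reference, other)
        coords.append(Uk.T @ (other.values - mean))
    return coords


def fdr_calibration(reported_q: np.ndarray, truth: DETruth,
                    cutoffs: Sequence[float]) -> Dict[float, Optional[float]]:
    """Realized false discovery proportion at each reported-FDR cutoff.

    ``reported_q`` may contain NaN for untested genes (they are never called
    significant).  A cutoff with zero discoveries maps to None rather than 0,
    so calibration averages are not biased by empty calls.
    """
    q = np.asarray(reported_q, dtype=float)
    if len(q) != len(truth.gene_ids):
        raise ValueError("q-value vector length does not match truth")
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q-values must lie in [0, 1] (or be NaN)")
    out: Dict[float, Optional[float]] = {}
    tested = ~np.isnan(q)
    for c in cutoffs:
        sig = tested & (q <= c)
        n_sig = int(sig.sum())
        if n_sig == 0:
            out[float(c)] = None
        else:
            false = int(np.sum(sig & ~truth.is_de))
            out[float(c)] = false / n_sig
    return out


def mean_var_table(real: CountMatrix, sim: CountMatrix) -> pd.DataFrame:
    """Per-gene moments of both matrices, paired by gene id."""
    sim = _aligned(real, sim)
    return pd.DataFrame({
        "gene_id": real.gene_ids,
        "real_mean": real.values.mean(axis=1),
        "sim_mean": sim.values.mean(axis=1),
        "real_var": real.values.var(axis=1, ddof=1),
        "sim_var": sim.values.var(axis=1, ddof=1),
    })


def comparison_report(real: CountMatrix, sims: Dict[str, CountMatrix],
                      min_mean: float = 300.0, n_components: int = 2) -> dict:
    """JSON-serializable bundle of the comparison statistics above."""
    report: dict = {"n_genes": real.p, "n_real_samples": real.n,
                    "min_mean": min_mean, "methods": {}}
    ref_spectrum = pc_spectrum(real, min(n_components, real.n - 1))
    report["reference_pc_variances"] = ref_spectrum.tolist()
    coords = project_onto(real, list(sims.values()), n_components=min(n_components, real.n - 1))
    report["reference_projection_variance"] = coords[0].var(axis=1, ddof=1).tolist()
    for (name, sim), coord in zip(sims.items(), coords[1:]):
        entry: dict = {}
        mv = mean_var_table(real, sim)
        entry["mean_rmse_log"] = float(np.sqrt(np.mean(
            (np.log1p(mv.real_mean) - np.log1p(mv.sim_mean)) ** 2)))
        entry["var_rmse_log"] = float(np.sqrt(np.mean(
            (np.log1p(mv.real_var) - np.log1p(mv.sim_var)) ** 2)))
        try:
            rq, sq = corr_qq(real, sim, min_mean=min_mean)
            entry["corr_quantiles_real"] = np.quantile(rq, [0.05, 0.25, 0.5, 0.75, 0.95]).tolist()
            entry["corr_quantiles_sim"] = np.quantile(sq, [0.05, 0.25, 0.5, 0.75, 0.95]).tolist()
        except ValueError:
            entry["corr_quantiles_real"] = entry["corr_quantiles_sim"] = None
        entry["pc_variances"] = pc_spectrum(sim, min(n_components, sim.n - 1)).tolist()
        entry["projection_variance"] = coord.var(axis=1, ddof=1).tolist()
        report["methods"][name] = entry
    return report
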