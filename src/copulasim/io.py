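"""File input/output and model serialization.

Counts travel as TSV/CSV (first column gene ids, header row sample ids) or
MatrixMarket ``.mtx`` with sidecar ``<stem>.genes.txt`` / ``<stem>.samples.txt``
id files.  Fitted models are stored as a single ``.npz`` archive of named
numeric arrays plus a JSON metadata block; the format is versioned and
checked on load.  Text outputs use 6 significant digits; integer count
matrices are written without decimals; model arrays keep full binary
precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .counts import CountMatrix
from .covariance import FactorizedCovariance
from .marginals import MarginalModel, SizeFactors
from .model import ReferenceModel

MODEL_FORMAT_VERSION = 1


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "txt"):
        return "tsv"
    if suffix in ("csv", "mtx"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def _sidecars(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return (stem.with_suffix(".genes.txt"), stem.with_suffix(".samples.txt"))


def read_counts(path, fmt: Optional[str] = None) -> CountMatrix:
    """Read a counts matrix from TSV/CSV/MatrixMarket."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "mtx":
        mat = spio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        genes_path, samples_path = _sidecars(path)
        gene_ids = np.loadtxt(genes_path, dtype=str, ndmin=1)
        sample_ids = np.loadtxt(samples_path, dtype=str, ndmin=1)
        return CountMatrix(np.asarray(mat, dtype=float), gene_ids, sample_ids)
    sep = "\t" if fmt == "tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene id: {dup[0]!r}")
    if not all(np.issubdtype(t, np.number) for t in df.dtypes):
        bad = [c for c, t in df.dtypes.items() if not np.issubdtype(t, np.number)]
        raise ValueError(f"non-numeric values in column(s) {bad}")
    if df.isna().to_numpy().any():
        raise ValueError("missing/ragged values in counts file")
    if (df.to_numpy() < 0).any():
        raise ValueError("negative values in counts file")
    return CountMatrix.from_dataframe(df)


def write_counts(counts: CountMatrix, path, fmt: Optional[str] = None) -> None:
    """Write a counts matrix; integer matrices are written without decimals."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "mtx":
        spio.mmwrite(path, sparse.csr_matrix(counts.values))
        genes_path, samples_path = _sidecars(path)
        genes_path.write_text("\n".join(counts.gene_ids) + "\n")
        samples_path.write_text("\n".join(counts.sample_ids) + "\n")
        return
    sep = "\t" if fmt == "tsv" else ","
    df = counts.to_dataframe()
    if counts.is_integer():
        df = df.astype(np.int64)
        df.to_csv(path, sep=sep)
    else:
        df.to_csv(path, sep=sep, float_format="%.6g")


def save_model(model: ReferenceModel, path) -> None:
    """Serialize a ReferenceModel to a single .npz archive."""
    arrays: dict = {}
    marg = model.marginals
    arrays["gene_ids"] = model.gene_ids
    arrays["degenerate"] = marg.degenerate
    arrays["constant_value"] = marg.constant_value
    for name in ("mu", "sd", "alpha", "values"):
        val = getattr(marg, name)
        if val is not None:
            arrays[f"marg_{name}"] = val
    if marg.size_factors is not None:
        arrays["size_factors"] = marg.size_factors.s
        arrays["size_factor_sample_ids"] = marg.size_factors.sample_ids
    fc = model.covariance
    if fc is not None:
        arrays["cov_D"] = fc.D
        arrays["cov_U"] = fc.U
        arrays["cov_W"] = fc.W
    from . import __version__
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "package_version": __version__,
        "family": marg.family,
        "cov_method": None if fc is None else fc.method,
        "metadata": _jsonable(model.metadata),
        "diagnostics": _jsonable(model.diagnostics),
    }
    arrays["meta_json"] = np.array(json.dumps(meta))
    with open(path, "wb") as fh:   # exact path: np.savez would append ".npz"
        np.savez(fh, **arrays)


def _jsonable(d: dict) -> dict:
    out = {}
    for key, val in d.items():
        if isinstance(val, (np.integer,)):
            out[key] = int(val)
        elif isinstance(val, (np.floating,)):
            out[key] = float(val)
        elif isinstance(val, (np.bool_,)):
            out[key] = bool(val)
        elif isinstance(val, np.ndarray):
            out[key] = val.tolist()
        else:
            out[key] = val
    return out


def load_model(path) -> ReferenceModel:
    """Load a ReferenceModel saved by :func:`save_model`."""
    with np.load(path, allow_pickle=False) as archive:
        if "meta_json" not in archive:
            raise ValueError(f"{path}: not a copulasim model archive")
        meta = json.loads(str(archive["meta_json"]))
        version = meta.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model format version {version} is not supported "
                f"(expected {MODEL_FORMAT_VERSION})")
        gene_ids = archive["gene_ids"].astype(str)
        size_factors = None
        if "size_factors" in archive:
            size_factors = SizeFactors(archive["size_factors"],
                                       archive["size_factor_sample_ids"].astype(str))
        marg = MarginalModel(
            family=meta["family"],
            gene_ids=gene_ids,
            degenerate=archive["degenerate"].astype(bool),
            constant_value=archive["constant_value"],
            mu=archive["marg_mu"] if "marg_mu" in archive else None,
            sd=archive["marg_sd"] if "marg_sd" in archive else None,
            alpha=archive["marg_alpha"] if "marg_alpha" in archive else None,
            values=archive["marg_values"] if "marg_values" in archive else None,
            size_factors=size_factors)
        fc = None
        if "cov_D" in archive:
            fc = FactorizedCovariance(archive["cov_D"], archive["cov_U"],
                                      archive["cov_W"],
                                      method=meta.get("cov_method") or "unknown")
    return ReferenceModel(marg, fc, size_factors, gene_ids,
                          metadata=meta.get("metadata", {}),
                          diagnostics=meta.get("diagnostics", {}))
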