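"""Counts matrix container.

A :class:`CountMatrix` is a genes-by-samples matrix of non-negative values
with unique gene and sample identifiers.  It is both the reference input and
the simulator output.  Values may be integers (sequencing counts) or reals
(e.g. normalized abundances used with the normal or empirical families).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Genes x samples data matrix.

    Parameters
    ----------
    values : ndarray, shape (p, n)
        Non-negative measurements, one row per gene, one column per sample.
    gene_ids : sequence of str, length p
        Unique gene identifiers.
    sample_ids : sequence of str, length n
        Unique sample identifiers.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        p, n = self.values.shape
        if p < 1 or n < 2:
            raise ValueError(f"need at least 1 gene and 2 samples, got {p} x {n}")
        if len(self.gene_ids) != p:
            raise ValueError("gene_ids length does not match number of rows")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if np.any(self.values < 0):
            raise ValueError("values must be non-negative")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            uniq, counts = np.unique(ids, return_counts=True)
            if np.any(counts > 1):
                dup = uniq[counts > 1][0]
                raise ValueError(f"duplicate {name} id: {dup!r}")

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountMatrix":
        """Build from a DataFrame with genes as the index, samples as columns."""
        return cls(df.to_numpy(dtype=float), df.index.to_numpy(dtype=str),
                   df.columns.to_numpy(dtype=str))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.sample_ids)

    def reindex_genes(self, gene_ids) -> "CountMatrix":
        """Return a copy with rows re-ordered to ``gene_ids`` (must be a permutation)."""
        gene_ids = np.asarray(gene_ids, dtype=str)
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            idx = np.array([pos[g] for g in gene_ids])
        except KeyError as exc:
            raise ValueError(f"gene id {exc.args[0]!r} not present") from None
        if len(idx) != self.p:
            raise ValueError("gene_ids is not a permutation of this matrix's genes")
        return CountMatrix(self.values[idx], gene_ids, self.sample_ids)

    def is_integer(self) -> bool:
        return bool(np.all(self.values == np.floor(self.values)))
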