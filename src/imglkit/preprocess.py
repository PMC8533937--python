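"""Count-matrix assembly, cleaning, pseudocounting, and quantile normalization.

The multi-study matrix is assembled over the union of gene identifiers,
genes with no reads anywhere are dropped, a single pseudocount is added to
every remaining cell, and technical amplitude differences between samples
are removed by forcing every column onto one reference distribution
(rank-wise column averaging).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd


def assemble_matrix(per_sample_tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Outer-join per-sample (or per-study) count tables into one matrix.

    Genes missing from a table are filled with 0. A sample identifier
    appearing in more than one table is an error.
    """
    if not per_sample_tables:
        raise ValueError("no count tables given")
    seen: set = set()
    for t in per_sample_tables:
        for s in t.columns:
            if s in seen:
                raise ValueError(f"duplicate sample id across tables: {s!r}")
            seen.add(s)
    merged = pd.concat(per_sample_tables, axis=1, join="outer")
    return merged.fillna(0).astype(np.int64)


def clean_and_pseudocount(m: pd.DataFrame) -> pd.DataFrame:
    """Drop genes devoid of read counts, then add one read everywhere.

    Gene order is preserved. Raises if no gene survives cleaning.
    """
    keep = (m != 0).any(axis=1)
    if not keep.any():
        raise ValueError("empty matrix after cleaning: all genes devoid of read counts")
    return m.loc[keep] + 1


def quantile_normalize(m: pd.DataFrame, ties: str = "stable") -> pd.DataFrame:
    """Classic rank/mean quantile normalization.

    Each column is sorted, the reference distribution is the rank-wise mean
    across columns, and each value is mapped back through its within-column
    rank. ``ties="stable"`` assigns tied values consecutive reference values
    in stable input order, so every output column carries exactly the
    reference multiset; ``ties="average"`` gives tied values the mean of the
    reference values over their tied rank span.
    """
    if ties not in ("stable", "average"):
        raise ValueError(f"unknown tie policy {ties!r}")
    if m.shape[1] == 1:
        warnings.warn("single-sample matrix: quantile normalization is a no-op")
        return m.astype(float)
    X = m.to_numpy(dtype=float)
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty_like(ref)
        mapped[order] = ref
        if ties == "average":
            mapped = pd.Series(mapped).groupby(col).transform("mean").to_numpy()
        out[:, j] = mapped
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def preprocess_counts(m: pd.DataFrame, ties: str = "stable") -> pd.DataFrame:
    """clean -> pseudocount -> quantile normalize, in that order."""
    return quantile_normalize(clean_and_pseudocount(m), ties=ties)
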