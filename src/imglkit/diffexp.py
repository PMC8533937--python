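"""Two-group differential expression against the matched iPSC reference.

Each differentiated sample group is contrasted with its own protocol's iPSC
samples when those exist, falling back to a designated reference protocol's
iPSC otherwise. The test runs on the quantile-normalized pseudocounted
matrix (values rounded back to integers), reporting per-gene log2
fold-change, a p-value from Welch's t on log2 values, Benjamini-Hochberg
adjusted p-values, and an up/down/ns call at fold-change > ``fc_threshold``
and padj < ``padj_threshold``.

Running a count-model-style test on quantile-normalized values is
statistically unorthodox (normalization equalizes the marginal
distributions the test then compares) but is retained deliberately: the
pipeline's contract is calibration of the null p-values and near-complete
power on strong planted effects, both of which are enforced by tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "ns"


@dataclass(frozen=True)
class Contrast:
    """A test-vs-reference sample grouping, e.g. ``Muffat.iMGL vs Abud.iPSC``."""

    test: tuple
    reference: tuple
    label: str = ""

    def __post_init__(self):
        test, ref = set(self.test), set(self.reference)
        if not test or not ref:
            raise ValueError("contrast groups must be non-empty")
        if test & ref:
            raise ValueError(f"contrast groups overlap: {sorted(test & ref)}")


def select_reference(
    protocol: str, metadata: pd.DataFrame, fallback_protocol: str
) -> list:
    """iPSC sample ids for a protocol, falling back to a reference protocol.

    Mirrors the rule that protocols lacking their own iPSC transcriptomes are
    contrasted against the reference study's iPSC samples.
    """
    own = metadata[
        (metadata["protocol"] == protocol) & (metadata["cell_type"] == "iPSC")
    ]
    if len(own):
        return list(own["sample_id"])
    fb = metadata[
        (metadata["protocol"] == fallback_protocol) & (metadata["cell_type"] == "iPSC")
    ]
    if len(fb):
        return list(fb["sample_id"])
    raise ValueError(
        f"no iPSC samples for protocol {protocol!r} nor fallback {fallback_protocol!r}"
    )


def differential_test(
    norm_matrix: pd.DataFrame,
    contrast: Contrast,
    fc_threshold: float = 2.0,
    padj_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-gene two-group test on rounded quantile-normalized counts.

    Returns a DataFrame indexed by gene with columns ``log2fc``, ``pvalue``,
    ``padj``, ``status``. With a single sample per side no p-value exists:
    status is decided on fold-change alone and the result is flagged via
    ``attrs["fc_only"]``.
    """
    missing = [s for s in (*contrast.test, *contrast.reference) if s not in norm_matrix.columns]
    if missing:
        raise ValueError(f"contrast samples absent from matrix: {missing}")
    vals = np.rint(norm_matrix.to_numpy(dtype=float))
    vals = np.maximum(vals, 1.0)  # pseudocounted input stays >= 1 after rounding
    cols = {s: i for i, s in enumerate(norm_matrix.columns)}
    a = vals[:, [cols[s] for s in contrast.test]]
    b = vals[:, [cols[s] for s in contrast.reference]]

    log2fc = np.log2(a.mean(axis=1)) - np.log2(b.mean(axis=1))
    fc_only = a.shape[1] < 2 or b.shape[1] < 2
    if fc_only:
        pvalue = np.full(len(log2fc), np.nan)
        padj = np.full(len(log2fc), np.nan)
    else:
        la, lb = np.log2(a), np.log2(b)
        with np.errstate(divide="ignore", invalid="ignore"):
            tres = stats.ttest_ind(la, lb, axis=1, equal_var=False)
        pvalue = np.asarray(tres.pvalue, dtype=float)
        degenerate = (la.var(axis=1) == 0) & (lb.var(axis=1) == 0)
        same_mean = np.isclose(la.mean(axis=1), lb.mean(axis=1))
        pvalue[degenerate & same_mean] = 1.0
        pvalue[degenerate & ~same_mean] = 0.0
        pvalue = np.where(np.isnan(pvalue), 1.0, pvalue)
        padj = multipletests(pvalue, method="fdr_bh")[1]

    status = status_from(log2fc, padj, fc_threshold, padj_threshold)

    out = pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvalue, "padj": padj, "status": status},
        index=norm_matrix.index.copy(),
    )
    out.index.name = "gene_id"
    out.attrs["label"] = contrast.label
    out.attrs["fc_only"] = bool(fc_only)
    return out


def status_from(
    log2fc,
    padj,
    fc_threshold: float = 2.0,
    padj_threshold: float = 0.01,
) -> np.ndarray:
    """up/down/ns calls: fold-change > fc_threshold (resp. < 1/fc_threshold)
    AND padj < padj_threshold. Missing padj (single-replicate contrast)
    falls back to the fold-change rule alone."""
    log2fc = np.asarray(log2fc, dtype=float)
    padj = np.asarray(padj, dtype=float)
    fc = np.exp2(log2fc)
    sig = np.where(np.isnan(padj), True, padj < padj_threshold)
    status = np.full(len(log2fc), STATUS_NS, dtype=object)
    status[(fc > fc_threshold) & sig] = STATUS_UP
    status[(fc < 1.0 / fc_threshold) & sig] = STATUS_DOWN
    return status


def classify_de(de: pd.DataFrame) -> dict:
    """Partition tested genes into ``up`` / ``down`` / ``ns`` id sets."""
    return {
        s: set(de.index[de["status"] == s])
        for s in (STATUS_UP, STATUS_DOWN, STATUS_NS)
    }


def contrasts_from_metadata(
    metadata: pd.DataFrame,
    fallback_protocol: str,
    exclude_cell_types: Iterable[str] = ("iPSC",),
) -> list:
    """One contrast per (protocol, cell_type) group versus its iPSC reference."""
    excluded = set(exclude_cell_types)
    out = []
    for (protocol, cell_type), grp in metadata.groupby(
        ["protocol", "cell_type"], sort=True
    ):
        if cell_type in excluded:
            continue
        reference = select_reference(protocol, metadata, fallback_protocol)
        out.append(
            Contrast(
                test=tuple(grp["sample_id"]),
                reference=tuple(reference),
                label=f"{protocol}.{cell_type}",
            )
        )
    return out
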