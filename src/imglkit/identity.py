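"""Microglia-identity scoring for induced microglia-like (iMGL) groups.

Four read-outs: (i) %Common / %Divergence of each iMGL group's upregulated
genes against an in vivo microglia control, (ii) a microglia-specific
marker panel obtained by subtracting every negative-control up-program from
the fetal-microglia up-program, (iii) a PCA embedding of the log10
quantile-normalized matrix over a chosen gene subset, and (iv) the marker
log2 fold-change matrix ordered by Euclidean biclustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA


@dataclass(frozen=True)
class SimilarityScore:
    imgl_label: str
    control_label: str
    n_common: int
    n_up_imgl: int
    common_pct: float
    divergence_pct: float


@dataclass(frozen=True)
class MarkerSet:
    genes: frozenset
    provenance: str


def similarity(
    up_imgl: Iterable,
    up_control: Iterable,
    imgl_label: str = "iMGL",
    control_label: str = "control",
) -> SimilarityScore:
    """%Common = |up(iMGL) ∩ up(control)| / |up(iMGL)| x 100; %Divergence = 100 − %Common."""
    up_imgl, up_control = set(up_imgl), set(up_control)
    if not up_imgl:
        raise ValueError(f"empty upregulated set for {imgl_label!r}")
    n_common = len(up_imgl & up_control)
    common_pct = n_common / len(up_imgl) * 100.0
    return SimilarityScore(
        imgl_label=imgl_label,
        control_label=control_label,
        n_common=n_common,
        n_up_imgl=len(up_imgl),
        common_pct=common_pct,
        divergence_pct=100.0 - common_pct,
    )


def select_markers(
    up_sets_by_celltype: Mapping[str, Iterable],
    positive: str = "fetalMG",
    negatives: Sequence[str] = ("CD14M", "CD16M", "bloodDC", "NPC", "neuron"),
) -> MarkerSet:
    """Cell-type-specific markers: up(positive) minus the union of negative up-sets."""
    missing = [ct for ct in (positive, *negatives) if ct not in up_sets_by_celltype]
    if missing:
        raise KeyError(f"missing upregulated sets for cell types: {missing}")
    pos = set(up_sets_by_celltype[positive])
    neg_union: set = set()
    for ct in negatives:
        neg_union |= set(up_sets_by_celltype[ct])
    genes = pos - neg_union
    if not genes:
        warnings.warn(
            f"marker selection for {positive!r} is empty after subtraction"
        )
    return MarkerSet(
        genes=frozenset(genes),
        provenance=f"up({positive}) minus union of up({', '.join(negatives)})",
    )


def pca_embed(
    norm_matrix: pd.DataFrame, gene_subset: Iterable, n_components: int = 3
):
    """Centered PCA of samples over log10 normalized values of a gene subset.

    Returns (coordinates DataFrame: samples x PCs, variance fractions).
    """
    genes = [g for g in gene_subset if g in norm_matrix.index]
    if not genes:
        raise ValueError("gene subset is empty or absent from the matrix")
    X = np.log10(norm_matrix.loc[genes].to_numpy(dtype=float)).T  # samples x genes
    k = min(n_components, X.shape[0], X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(coords, index=norm_matrix.columns, columns=cols),
        pca.explained_variance_ratio_.copy(),
    )


@dataclass
class HeatmapResult:
    matrix: pd.DataFrame  # reordered log2fc, markers x groups
    row_linkage: np.ndarray
    col_linkage: np.ndarray | None
    missing: list = field(default_factory=list)  # (gene, group) not tested


def _leaf_order(linkage: np.ndarray) -> list:
    return list(hierarchy.leaves_list(linkage))


def marker_heatmap_matrix(
    de_results_by_group: Mapping[str, pd.DataFrame],
    marker_genes: Iterable,
    method: str = "average",
) -> HeatmapResult:
    """log2FC of marker genes across groups, biclustered (Euclidean distance).

    Marker genes untested in a contrast are recorded as 0 and flagged in
    ``missing``. Only the ordering changes; values are untouched.
    """
    markers = sorted(set(marker_genes))
    if not markers:
        raise ValueError("empty marker set")
    groups = list(de_results_by_group)
    mat = pd.DataFrame(0.0, index=markers, columns=groups)
    missing = []
    for grp, de in de_results_by_group.items():
        present = [g for g in markers if g in de.index]
        mat.loc[present, grp] = de.loc[present, "log2fc"].to_numpy()
        missing.extend((g, grp) for g in markers if g not in de.index)
    row_linkage = hierarchy.linkage(mat.to_numpy(), method=method, metric="euclidean")
    row_order = _leaf_order(row_linkage)
    col_linkage = None
    col_order = list(range(len(groups)))
    if len(groups) > 1:
        col_linkage = hierarchy.linkage(
            mat.to_numpy().T, method=method, metric="euclidean"
        )
        col_order = _leaf_order(col_linkage)
    ordered = mat.iloc[row_order, col_order]
    return HeatmapResult(
        matrix=ordered, row_linkage=row_linkage, col_linkage=col_linkage, missing=missing
    )
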