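"""Diagnostic data products: PCA, Ward/Euclidean clustering, volcano and
reproducibility curves.

Everything here is exported as plain tables (scores, leaf orders, curve
points); rendering is left to the caller and never affects results.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import ValidationError
from .rots import RotsOptimum


def pca_scores(values: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample PCA scores of the protein-centered matrix.

    Rows of ``values`` are proteins, columns samples; each protein is
    centered across samples before the SVD. Returns (scores, explained
    variance fractions), fractions non-increasing and summing to <= 1.
    """
    if values.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    x = values.to_numpy(dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    # samples as observations: rows = samples
    u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
    scores = u * s
    n_comp = min(values.shape[1], scores.shape[1])
    total_var = (centered ** 2).sum()
    explained = (s ** 2) / total_var if total_var > 0 else np.zeros_like(s)
    cols = [f"PC{i+1}" for i in range(n_comp)]
    return (
        pd.DataFrame(scores[:, :n_comp], index=values.columns, columns=cols),
        explained[:n_comp],
    )


def ward_clustering(
    values: pd.DataFrame, axis: str = "samples"
) -> tuple[np.ndarray, list[str]]:
    """Ward-linkage/Euclidean agglomerative clustering.

    ``axis`` selects whether samples (columns) or proteins (rows) are
    clustered. Returns the scipy linkage matrix and the dendrogram leaf
    order as labels.
    """
    if axis not in ("samples", "proteins"):
        raise ValidationError("axis must be 'samples' or 'proteins'")
    x = values.to_numpy(dtype=float)
    labels = list(values.columns) if axis == "samples" else list(values.index)
    if axis == "samples":
        x = x.T
    if x.shape[0] < 2:
        raise ValidationError("clustering needs at least 2 items")
    if not np.isfinite(x).all():
        raise ValidationError("non-finite values in clustering input")
    link = hierarchy.linkage(pdist(x, metric="euclidean"), method="ward")
    order = hierarchy.leaves_list(link)
    return link, [labels[i] for i in order]


def reproducibility_plot_data(optimum: RotsOptimum) -> pd.DataFrame:
    """Mean and SD of bootstrap top-k overlaps (observed vs permuted null)."""
    rows = []
    for j, k in enumerate(optimum.k_grid):
        rows.append(
            {
                "k": k,
                "overlap_mean": optimum.overlaps[:, j].mean(),
                "overlap_sd": optimum.overlaps[:, j].std(ddof=1),
                "null_mean": optimum.null_overlaps[:, j].mean(),
                "null_sd": optimum.null_overlaps[:, j].std(ddof=1),
            }
        )
    return pd.DataFrame(rows)


def volcano_data(result: pd.DataFrame) -> pd.DataFrame:
    """Mean difference vs -log10 p, the volcano-plot source table."""
    return pd.DataFrame(
        {
            "mean_diff": result["mean_diff"],
            "neg_log10_p": -np.log10(result["p"]),
            "selected": result.get("selected", False),
        },
        index=result.index,
    )
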