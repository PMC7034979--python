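"""NNLS deconvolution of bulk profiles against single-cell cluster means.

Single-cell counts are normalized to counts per million (CPM) per cell and
averaged within clusters. Genes informative about cluster identity are picked
reciprocally from both data sets (top-k enrichment of each column against the
mean and against the maximum of the other columns), and each bulk profile is
modeled as a non-negative weighted sum of cluster means via Lawson-Hanson
non-negative least squares. Cluster sizes can be compared with anatomical
counts through observed/expected ratios against a reference cell type.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

logger = logging.getLogger(__name__)


@dataclass
class ClusterProfileMatrix:
    """Mean CPM per single-cell cluster, with cluster sizes."""

    profiles: pd.DataFrame  # genes x clusters
    sizes: pd.Series  # cells per cluster


@dataclass
class DeconvolutionResult:
    """Per-bulk-profile NNLS coefficients over single-cell clusters."""

    coefficients: pd.DataFrame  # bulk profiles x clusters, raw (>= 0)
    normalized: pd.DataFrame  # each cluster column scaled to max 1 across profiles
    genes: list[str]  # selected gene set used for the regression
    residual_norms: pd.Series  # per bulk profile


def cluster_profiles(
    counts: pd.DataFrame, labels: pd.Series
) -> ClusterProfileMatrix:
    """Per-cell CPM normalization followed by per-cluster arithmetic means.

    ``counts`` is genes x cells (raw transcript counts or CPM); ``labels``
    maps each cell to a cluster. Empty clusters are dropped with a warning.
    """
    missing = [c for c in counts.columns if c not in labels.index]
    if missing:
        raise ValueError(f"cells without a cluster label: {missing[:5]}")
    lab = labels.reindex(counts.columns)
    depth = counts.sum(axis=0)
    zero = depth == 0
    if zero.any():
        warnings.warn(f"cells with zero counts dropped: {list(depth.index[zero])}")
        counts = counts.loc[:, ~zero]
        lab = lab[~zero]
        depth = depth[~zero]
    cpm = counts * (1e6 / depth)
    profiles = cpm.T.groupby(lab).mean().T
    sizes = lab.value_counts().reindex(profiles.columns)
    return ClusterProfileMatrix(profiles=profiles, sizes=sizes)


def select_enriched_genes(
    profiles_a: pd.DataFrame,
    profiles_b: pd.DataFrame,
    k: int = 50,
    pseudocount: float = 1.0,
) -> list[str]:
    """Union of per-column top-k enriched genes from both profile matrices.

    For every column of each matrix, genes are ranked by enrichment of that
    column against the mean of all other columns and, separately, against the
    maximum of all other columns (enrichment = (value + pseudocount) /
    (other + pseudocount)); the top-k of every ranking are pooled. Ties break
    by gene order, and k is capped at the gene count with a warning.
    """
    shared = profiles_a.index.intersection(profiles_b.index)
    if shared.empty:
        raise ValueError("profile matrices share no genes")
    if k > len(shared):
        warnings.warn(f"k={k} exceeds the {len(shared)} shared genes; capped")
        k = len(shared)
    selected: set[str] = set()
    n_used = 0
    for profiles in (profiles_a.loc[shared], profiles_b.loc[shared]):
        vals = profiles.to_numpy(dtype=float)
        n_col = vals.shape[1]
        if n_col < 2:
            # a single profile has no "other columns"; rank only the other side
            continue
        n_used += 1
        totals = vals.sum(axis=1, keepdims=True)
        for j in range(n_col):
            others = np.delete(vals, j, axis=1)
            mean_others = (totals[:, 0] - vals[:, j]) / (n_col - 1)
            max_others = others.max(axis=1)
            for other_stat in (mean_others, max_others):
                enrich = (vals[:, j] + pseudocount) / (other_stat + pseudocount)
                # stable top-k: sort by (-enrichment, gene position)
                order = np.lexsort((np.arange(len(enrich)), -enrich))[:k]
                selected.update(shared[i] for i in order)
    if n_used == 0:
        raise ValueError("need at least 2 columns in one matrix to define enrichment")
    return [g for g in shared if g in selected]


def nnls_solve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """argmin ||Ax - b||_2 subject to x >= 0 (Lawson-Hanson active set)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float).ravel()
    if a.ndim != 2 or a.shape[1] < 1:
        raise ValueError("A must be 2-D with at least one column")
    if a.shape[0] != b.size:
        raise ValueError("A and b dimensions do not conform")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite entries in the NNLS problem")
    x, _ = scipy.optimize.nnls(a, b)
    return x


def deconvolve(
    bulk: pd.DataFrame,
    clusters: ClusterProfileMatrix,
    k: int = 50,
    direction: str = "bulk~clusters",
) -> DeconvolutionResult:
    """Model each bulk profile as a non-negative combination of cluster means.

    Both matrices are restricted to the reciprocally enriched gene set before
    one NNLS solve per bulk profile. The ``normalized`` heatmap variant
    scales each cluster's coefficients to a maximum of one across bulk
    profiles. ``direction='clusters~bulk'`` swaps the roles (kept behind this
    flag: with collinear bulk profiles the reverse regression zeroes out
    whole profiles).
    """
    if direction not in ("bulk~clusters", "clusters~bulk"):
        raise ValueError(f"unknown direction {direction!r}")
    if direction == "clusters~bulk":
        swapped = deconvolve(
            clusters.profiles,
            ClusterProfileMatrix(bulk, pd.Series(1, index=bulk.columns)),
            k=k,
        )
        return swapped
    genes = select_enriched_genes(bulk, clusters.profiles, k=k)
    if not genes:
        raise ValueError("no shared enriched genes between bulk and clusters")
    a = clusters.profiles.loc[genes].to_numpy(dtype=float)
    coefs = np.zeros((bulk.shape[1], a.shape[1]))
    resid = np.zeros(bulk.shape[1])
    for j, col in enumerate(bulk.columns):
        b = bulk.loc[genes, col].to_numpy(dtype=float)
        coefs[j] = nnls_solve(a, b)
        resid[j] = float(np.linalg.norm(a @ coefs[j] - b))
    coefficients = pd.DataFrame(
        coefs, index=bulk.columns, columns=clusters.profiles.columns
    )
    col_max = coefficients.max(axis=0)
    normalized = coefficients / col_max.replace(0, np.nan)
    normalized = normalized.fillna(0.0)
    return DeconvolutionResult(
        coefficients=coefficients,
        normalized=normalized,
        genes=genes,
        residual_norms=pd.Series(resid, index=bulk.columns, name="residual_norm"),
    )


def observed_expected_ratio(
    cluster_sizes: pd.Series,
    true_counts: pd.Series,
    reference_id: str,
) -> pd.Series:
    """Cluster size relative to a reference, over the true-count ratio.

    ratio(X) = (size_X / size_ref) / (count_X / count_ref); the reference
    maps to exactly 1. Types without a true count get NaN.
    """
    if reference_id not in cluster_sizes.index or reference_id not in true_counts.index:
        raise ValueError(f"reference {reference_id!r} missing from sizes or counts")
    if cluster_sizes[reference_id] == 0 or true_counts[reference_id] == 0:
        raise ValueError(f"reference {reference_id!r} has a zero size or count")
    size_ratio = cluster_sizes / cluster_sizes[reference_id]
    count_ratio = true_counts.reindex(cluster_sizes.index) / true_counts[reference_id]
    out = size_ratio / count_ratio
    out.name = "observed_expected_ratio"
    return out
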