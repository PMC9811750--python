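"""Unsupervised cell-type discovery and annotation.

Cells are embedded by non-negative matrix factorization (NMF, k = 12) of a
CpG-regulatory-region matrix and a CpH genomic-bin matrix; the two factor
matrices are variance-standardized, weighted and concatenated, projected to
2-D with t-SNE and clustered with DBSCAN (ε = 1.3).  Clusters are collapsed
to pseudobulk methylomes, summarized over annotation region sets, z-scored
per annotation across clusters and labelled (lowest-z, neuron/non-neuron
sign pattern, or hierarchical propagation).  A depth-adjusted group
comparison (OLS with log10 unique reads as covariate) completes the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .methalign import CellCalls, merge_calls


class DegenerateInputError(ValueError):
    pass


@dataclass
class EmbeddingConfig:
    nmf_k: int = 12
    nmf_seed: int = 0
    cpg_weight: float = 1.0
    cph_weight: float = 1.0
    tsne_perplexity: float = 30.0
    tsne_seed: int = 0
    dbscan_eps: float = 1.3
    dbscan_min_samples: int = 5

    def __post_init__(self):
        if self.nmf_k < 2:
            raise ValueError("nmf_k must be >= 2")
        if self.cpg_weight < 0 or self.cph_weight < 0 or (
            self.cpg_weight == 0 and self.cph_weight == 0
        ):
            raise ValueError("weights must be non-negative and not both zero")
        if self.dbscan_eps <= 0:
            raise ValueError("dbscan_eps must be positive")


def nmf_embed(
    matrix: np.ndarray, k: int = 12, seed: int = 0, return_components: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Cell-factor matrix W (cells × k) of an NMF X ≈ W·H.

    Coordinate-descent factorization with deterministic NNDSVD-a
    initialization; the Frobenius objective is non-increasing over
    iterations.  With ``return_components`` the basis H is returned as well.
    """
    X = np.asarray(matrix, dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; run filter_and_impute first")
    if (X < 0).any():
        raise ValueError("matrix must be non-negative")
    if not X.any():
        raise DegenerateInputError("all-zero matrix cannot be factorized")
    if k >= min(X.shape):
        raise ValueError(f"k={k} must be smaller than both matrix dimensions {X.shape}")
    from sklearn.decomposition import NMF

    model = NMF(
        n_components=k, init="nndsvda", solver="cd", max_iter=2000, tol=1e-9,
        random_state=seed,
    )
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        # the tight tolerance is deliberate (exact-rank inputs should
        # factorize to machine-level residuals); hitting max_iter on noisy
        # data is expected and benign
        warnings.simplefilter("ignore", ConvergenceWarning)
        W = model.fit_transform(X)
    if return_components:
        return W, model.components_
    return W


def merge_embeddings(
    w_cpg: np.ndarray, w_cph: np.ndarray, weights: tuple[float, float] = (1.0, 1.0)
) -> np.ndarray:
    """Variance-standardized weighted concatenation of two factor matrices.

    Each matrix is scaled so its total (summed column) variance is 1, then
    multiplied by its weight and column-concatenated.  Cells must be in the
    same order.  A matrix with zero variance contributes a zero block.
    """
    if w_cpg.shape[0] != w_cph.shape[0]:
        raise ValueError("factor matrices disagree in cell count")

    def _standardize(w, wt):
        total_var = w.var(axis=0).sum()
        if total_var == 0 or wt == 0:
            return np.zeros_like(w)
        return w * (wt / np.sqrt(total_var))

    return np.hstack([_standardize(w_cpg, weights[0]), _standardize(w_cph, weights[1])])


def tsne_project(merged: np.ndarray, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """Deterministic (seeded, PCA-initialized) t-SNE to two dimensions.

    The input is standardized to unit total variance first: t-SNE's
    perplexity-calibrated affinities are scale-free in exact arithmetic, and
    standardizing makes the embedding exactly invariant to a common scaling
    of the merged factors rather than invariant only up to gradient-descent
    round-off.
    """
    merged = np.asarray(merged, dtype=float)
    total_var = merged.var(axis=0).sum()
    if total_var > 0:
        merged = merged / np.sqrt(total_var)
    n = merged.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(
            f"{n} cells is too few for perplexity {perplexity}; lower the perplexity"
        )
    from sklearn.manifold import TSNE

    coords = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca",
        learning_rate="auto",
    ).fit_transform(merged)
    if not np.isfinite(coords).all():
        raise RuntimeError("t-SNE produced non-finite coordinates")
    return coords


def dbscan_cluster(
    coords: np.ndarray, eps: float = 1.3, min_samples: int = 5
) -> np.ndarray:
    """Density clustering of the 2-D embedding; noise points get label -1
    (unassigned) and are excluded from annotation downstream."""
    from sklearn.cluster import DBSCAN

    return DBSCAN(eps=eps, min_samples=min_samples).fit_predict(np.asarray(coords))


def pseudobulk(
    calls_by_cell: Mapping[str, CellCalls], cluster_map: Mapping[str, int]
) -> dict[int, CellCalls]:
    """Collapse member cells of each cluster into one methylome: per site,
    methylated and coverage counts are summed.  Cells labelled -1 (noise)
    are skipped."""
    for cell in cluster_map:
        if cell not in calls_by_cell:
            raise KeyError(f"cell {cell!r} in cluster map but has no calls")
    groups: dict[int, list[CellCalls]] = {}
    for cell, cl in cluster_map.items():
        if cl == -1:
            continue
        groups.setdefault(int(cl), []).append(calls_by_cell[cell])
    return {cl: merge_calls(lst) for cl, lst in sorted(groups.items())}


# --------------------------------------------------------------------------
# annotation
# --------------------------------------------------------------------------

@dataclass
class ClusterAnnotation:
    zscores: pd.DataFrame  # annotation sets × clusters
    labels: dict[int, str]
    method: str
    ties: list[int] = field(default_factory=list)


def _zscore_rows(levels: pd.DataFrame) -> pd.DataFrame:
    mu = levels.mean(axis=1)
    sd = levels.std(axis=1, ddof=0)
    z = levels.sub(mu, axis=0)
    nonzero = sd > 0
    z.loc[nonzero] = z.loc[nonzero].div(sd[nonzero], axis=0)
    return z


def annotate_clusters(
    levels: pd.DataFrame,
    method: str = "lowest-z",
    neuron_sets: Sequence[str] = (),
    nonneuron_sets: Sequence[str] = (),
    reference_labels: Mapping[str, str] | None = None,
) -> ClusterAnnotation:
    """Label clusters from pooled methylation over annotation sets.

    `levels` is an annotation-set × cluster matrix of pseudobulk methylation
    levels; rows with any missing value are dropped with a warning.  Rows
    are z-scored across clusters.  Methods:

    - ``lowest-z``: each cluster is labelled with the annotation set holding
      its minimum z (hypomethylated promoters/DMRs mark the matching type);
      clusters whose minimum is attained by several sets are flagged as ties.
    - ``neuron-vs-nonneuron``: labels ``neuron`` or ``non-neuron`` by which
      of the two set groups has the lower mean z.
    - ``hierarchical``: average-linkage clustering of z columns; each cluster
      inherits the reference label (via `reference_labels`, annotation set →
      label) of the nearest reference column.
    """
    levels = levels.copy()
    bad = levels.isna().any(axis=1)
    if bad.any():
        import warnings

        warnings.warn(f"dropping {int(bad.sum())} annotation rows without full coverage")
        levels = levels[~bad]
    if levels.empty:
        raise DegenerateInputError("no fully covered annotation rows")
    z = _zscore_rows(levels)
    labels: dict[int, str] = {}
    ties: list[int] = []
    if method == "lowest-z":
        for cl in z.columns:
            col = z[cl]
            m = col.min()
            winners = col.index[col == m]
            labels[cl] = str(winners[0])
            if len(winners) > 1:
                ties.append(cl)
    elif method == "neuron-vs-nonneuron":
        for cl in z.columns:
            zn = z.loc[[s for s in neuron_sets if s in z.index], cl].mean()
            znn = z.loc[[s for s in nonneuron_sets if s in z.index], cl].mean()
            labels[cl] = "neuron" if zn < znn else "non-neuron"
    elif method == "hierarchical":
        if not reference_labels:
            raise ValueError("hierarchical labelling needs reference_labels")
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import pdist

        ref_rows = [s for s in reference_labels if s in z.index]
        # propagate: a cluster takes the label of the reference set nearest
        # (in z) after average-linkage grouping of the columns
        dist = pdist(z.T.to_numpy())
        if len(z.columns) > 1:
            average(dist)  # linkage validates the geometry; labels come below
        for cl in z.columns:
            best = min(ref_rows, key=lambda s: abs(z.loc[s, cl] - z.loc[s].min()))
            labels[cl] = reference_labels[best]
    else:
        raise ValueError(f"unknown annotation method {method!r}")
    return ClusterAnnotation(z, labels, method, ties)


# --------------------------------------------------------------------------
# depth-adjusted comparison
# --------------------------------------------------------------------------

def depth_adjusted_comparison(
    levels: np.ndarray | pd.Series,
    groups: Sequence,
    unique_reads: np.ndarray | pd.Series,
) -> dict:
    """OLS of per-cell methylation level on a group indicator controlling
    for read depth: level ~ group + log10(unique_reads).

    Returns the group coefficient, its standard error and two-sided p-value.
    Raises on a single-group (singular) design or groups with < 3 cells.
    """
    import statsmodels.api as sm

    y = np.asarray(levels, dtype=float)
    g = pd.Series(list(groups))
    cats = sorted(g.unique())
    if len(cats) != 2:
        raise DegenerateInputError("exactly two groups required")
    counts = g.value_counts()
    if counts.min() < 3:
        raise DegenerateInputError("each group needs at least 3 cells")
    indicator = (g == cats[1]).to_numpy(dtype=float)
    depth = np.log10(np.asarray(unique_reads, dtype=float))
    X = sm.add_constant(np.column_stack([indicator, depth]))
    fit = sm.OLS(y, X).fit()
    return {
        "groups": (str(cats[0]), str(cats[1])),
        "coefficient": float(fit.params[1]),
        "stderr": float(fit.bse[1]),
        "pvalue": float(fit.pvalues[1]),
        "n": int(len(y)),
    }
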