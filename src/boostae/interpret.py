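"""Post-training interpretation of sparse encoder weight matrices.

Covers: ranking a dimension's selected genes and cutting the ranking at
the largest gap between consecutive sorted absolute weights (change-point
criterion); matching latent dimensions to categorical cell labels by
quantile thresholding; k-nearest-neighbor label transfer in latent space;
gene selection stability counting across repeated runs; absolute Pearson
correlations between latent dimensions; and a supervised OLS/Bonferroni
regression baseline for gene selection given cluster and time labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "TopGenesEntry",
    "top_genes_changepoint",
    "top_genes_report",
    "quantile_label_correspondence",
    "knn_label_transfer",
    "selection_stability_counts",
    "latent_correlation_matrix",
    "regression_gene_selection",
]


@dataclass
class TopGenesEntry:
    """Ranked nonzero genes of one latent dimension.

    ``normalized_weights`` are the signed weights divided by the maximum
    absolute weight of the dimension, ordered by decreasing |weight|;
    ``change_point`` is the number of leading genes reported as top genes.
    """

    genes: list
    normalized_weights: list
    change_point: int

    @property
    def top_genes(self) -> list:
        return self.genes[: self.change_point]


def top_genes_changepoint(beta: np.ndarray, gene_ids: Optional[Sequence] = None):
    """Change-point ranking of one dimension's nonzero encoder weights.

    Nonzero weights are sorted by decreasing absolute value (ties broken
    toward the lower gene index); the change point sits at the largest
    difference between consecutive sorted absolute values, and the genes
    before it are the top genes.  A single nonzero weight, or all-equal
    absolute weights, yields one top gene.  Returns ``None`` with a
    warning for an all-zero dimension.
    """
    beta = np.asarray(beta, dtype=float)
    nz = np.flatnonzero(beta)
    if nz.size == 0:
        warnings.warn("all-zero weight column; no genes to rank", stacklevel=2)
        return None
    absw = np.abs(beta[nz])
    order = nz[np.lexsort((nz, -absw))]
    sorted_abs = np.abs(beta[order])
    if order.size == 1:
        cp = 1
    else:
        diffs = sorted_abs[:-1] - sorted_abs[1:]
        cp = int(np.argmax(diffs)) + 1
    ids = list(order) if gene_ids is None else [gene_ids[j] for j in order]
    normalized = list(beta[order] / sorted_abs[0])
    return TopGenesEntry(ids, normalized, cp)


def top_genes_report(B: np.ndarray, gene_ids: Optional[Sequence] = None) -> list:
    """Per-dimension change-point rankings for a whole encoder matrix."""
    B = np.asarray(B, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [top_genes_changepoint(B[:, l], gene_ids) for l in range(B.shape[1])]


def quantile_label_correspondence(Z: np.ndarray, labels: Sequence, p: float = 0.9) -> pd.DataFrame:
    """Match latent dimensions to labels by quantile thresholding.

    Per dimension j, cells strictly above the p-quantile (and strictly
    below the (1-p)-quantile) of z^(j) are collected; the label proportions
    among them identify the best-matching positive (negative) label.
    Quantiles use the linear-interpolation sample estimator.  Directions
    with no cells beyond the threshold are reported as undefined (NaN).
    """
    if not 0.5 < p < 1.0:
        raise ValueError("quantile level p must lie in (0.5, 1)")
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    labels = np.asarray(labels)
    if labels.shape[0] != Z.shape[0]:
        raise ValueError("labels must cover all cells")
    rows = []
    for j in range(Z.shape[1]):
        z = Z[:, j]
        q_pos = np.quantile(z, p)
        q_neg = np.quantile(z, 1.0 - p)
        for direction, mask in (("positive", z > q_pos), ("negative", z < q_neg)):
            if not mask.any():
                rows.append({"dimension": j, "direction": direction,
                             "label": None, "proportion": np.nan, "proportions": {}})
                continue
            vals, counts = np.unique(labels[mask], return_counts=True)
            best = int(np.argmax(counts))
            rows.append({"dimension": j, "direction": direction,
                         "label": vals[best],
                         "proportion": counts[best] / counts.sum(),
                         "proportions": dict(zip(vals, counts / counts.sum()))})
    return pd.DataFrame(rows)


def knn_label_transfer(Z_train: np.ndarray, labels: Sequence, Z_test: np.ndarray,
                       k: int = 10) -> np.ndarray:
    """Majority label among the k Euclidean nearest training cells.

    Majority ties resolve to the lexicographically smallest label;
    distance ties at the k boundary include the lower train-row index
    first.
    """
    Z_train = np.atleast_2d(np.asarray(Z_train, dtype=float))
    Z_test = np.atleast_2d(np.asarray(Z_test, dtype=float))
    labels = np.asarray(labels)
    if Z_train.shape[0] == 0:
        raise ValueError("empty training set")
    if not 1 <= k <= Z_train.shape[0]:
        raise ValueError(f"k must lie in [1, {Z_train.shape[0]}]")
    # brute force keeps neighbor order stable (lower index first on distance ties)
    nn = NearestNeighbors(n_neighbors=k, algorithm="brute").fit(Z_train)
    _, idx = nn.kneighbors(Z_test)
    preds = []
    for row in idx:
        vals, counts = np.unique(labels[row], return_counts=True)
        preds.append(vals[int(np.argmax(counts))])  # np.unique sorts: ties -> smallest label
    return np.asarray(preds)


def selection_stability_counts(B_runs: Sequence[np.ndarray]) -> np.ndarray:
    """Per-gene count of runs in which the gene has a nonzero weight in at
    least one latent dimension."""
    mats = [np.asarray(B) for B in B_runs]
    p = mats[0].shape[0]
    for B in mats:
        if B.shape[0] != p:
            raise ValueError("encoder matrices disagree on the number of genes")
    counts = np.zeros(p, dtype=int)
    for B in mats:
        counts += np.any(B != 0, axis=1).astype(int)
    return counts


def latent_correlation_matrix(Z: np.ndarray) -> np.ndarray:
    """Absolute sample Pearson correlation between all pairs of latent
    dimensions (diagonal 1).  Constant columns yield NaN entries and a
    warning."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    d = Z.shape[1]
    sd = Z.std(axis=0, ddof=1)
    constant = np.flatnonzero(~(sd > 0))
    if constant.size:
        warnings.warn(f"constant latent dimensions {constant.tolist()}; "
                      "correlation undefined", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.abs(np.corrcoef(Z, rowvar=False))
    C = np.atleast_2d(C)
    np.fill_diagonal(C, 1.0)
    for j in constant:
        C[j, :] = np.nan
        C[:, j] = np.nan
        C[j, j] = 1.0
    return C[:d, :d]


@dataclass
class RegressionSelection:
    """Selected genes of one (cluster, time) regression model."""

    cluster: object
    time: int
    selected: list
    pvalues_adjusted: np.ndarray
    degenerate: bool = False
    dropped_collinear: list = field(default_factory=list)


def _independent_columns(X: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent column subset via pivoted QR."""
    r = np.linalg.matrix_rank(X)
    if r == X.shape[1]:
        return np.arange(X.shape[1])
    _, _, piv = qr(X, mode="economic", pivoting=True)
    return np.sort(piv[:r])


def regression_gene_selection(X_by_time: Sequence[np.ndarray],
                              labels_by_time: Sequence[Sequence],
                              alpha: float = 0.05,
                              timebae_sets: Optional[dict] = None) -> list:
    """Supervised OLS baseline for gene selection per (cluster, time point).

    For each time point t and cluster c, the binary indicator of cluster
    membership is standardized and regressed without intercept on the
    standardized genes; each coefficient gets a two-sided t-test, p-values
    are Bonferroni-adjusted within the model, and genes with adjusted
    p < alpha are selected.  Singular designs drop collinear columns with
    a warning; an (essentially) zero-residual fit flags all p-values as 0
    with a degeneracy marker.  If ``timebae_sets`` maps dimension keys to
    gene index sets, the intersection of each selection with each set is
    reported in the entry's ``intersections`` attribute.
    """
    results = []
    for t, (X, lab) in enumerate(zip(X_by_time, labels_by_time)):
        X = np.asarray(X, dtype=float)
        lab = np.asarray(lab)
        for c in np.unique(lab):
            y = (lab == c).astype(float)
            if y.all() or not y.any():
                warnings.warn(f"cluster {c!r} empty or exhaustive at time point {t + 1}; "
                              "model skipped", stacklevel=2)
                continue
            y_std = (y - y.mean()) / y.std(ddof=1)
            cols = _independent_columns(X)
            dropped = sorted(set(range(X.shape[1])) - set(cols.tolist()))
            if dropped:
                warnings.warn(f"dropping {len(dropped)} collinear columns for "
                              f"cluster {c!r}, time point {t + 1}", stacklevel=2)
            fit = sm.OLS(y_std, X[:, cols]).fit()
            p_adj = np.full(X.shape[1], np.nan)
            degenerate = bool(fit.ssr < 1e-12)
            if degenerate:
                p_adj[cols] = 0.0
            else:
                p_adj[cols] = np.minimum(fit.pvalues * len(cols), 1.0)
            selected = sorted(int(j) for j in cols[np.asarray(p_adj[cols] < alpha)])
            entry = RegressionSelection(c, t, selected, p_adj, degenerate, dropped)
            if timebae_sets is not None:
                entry.intersections = {key: sorted(set(selected) & set(genes))
                                       for key, genes in timebae_sets.items()}
            results.append(entry)
    return results
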