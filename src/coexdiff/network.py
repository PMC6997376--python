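"""Signed weighted co-expression network construction and module detection.

Adjacency follows the signed convention a_ij = ((1 + r_ij)/2)^beta with
Pearson correlation r and soft-thresholding power beta (default 12), so
r = -1 maps to 0 and r = +1 to 1 while preserving the sign information.
Gene similarity for clustering is the topological overlap

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with connectivity k_i = sum_{j != i} a_ij, and modules come from
average-linkage clustering of the dissimilarity 1 - TOM with a
cohesion-based tree cut (see :func:`detect_modules`).  Genes not allocated to any module
carry label 0; modules 1..M are ranked by decreasing size.

Large gene sets are handled blockwise: genes are pre-clustered into blocks
of at most ``max_block_size`` and modules are detected within each block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

__all__ = [
    "pearson_correlation",
    "signed_adjacency",
    "topological_overlap",
    "detect_modules",
    "blockwise_partition",
    "module_assignment_frame",
    "export_edge_list",
    "SignedCoexpressionNetwork",
]


def pearson_correlation(expr: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Gene-gene Pearson correlation of a gene-major expression matrix.

    Zero-variance genes get correlation 0 to every other gene (diagonal
    stays 1) and trigger a warning.
    """
    X = np.asarray(expr, dtype=float)
    if X.shape[1] < 3:
        raise ValueError("at least 3 samples are required for correlations")
    sd = X.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance genes; their correlations are set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    if flat.any():
        r[flat, :] = 0.0
        r[:, flat] = 0.0
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def signed_adjacency(cor: np.ndarray, beta: float = 12) -> np.ndarray:
    """Signed adjacency ((1 + r)/2)^beta; unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    cor = np.asarray(cor, dtype=float)
    a = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix; the diagonal is excluded from the
    connectivity k_i and TOM_ii = 1."""
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    off = a.copy()
    np.fill_diagonal(off, 0.0)
    k = off.sum(axis=1)
    shared = off @ off  # sum_u a_iu a_uj over u != i, j plus nothing on diag
    num = shared + off
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - off
    tom = num / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def _collect_modules(
    Z: np.ndarray,
    tom: np.ndarray,
    n: int,
    min_size: int,
    min_cohesion: float,
    min_relative_gap: float,
) -> list[np.ndarray]:
    """Module subtrees of an average-linkage tree on 1 - TOM.

    A subtree qualifies as a module when (a) it holds at least ``min_size``
    leaves, (b) its mean within-subtree topological overlap is at least
    ``min_cohesion`` times its mean overlap with the remaining genes, and
    (c) its merge into the parent jumps by at least ``min_relative_gap`` of
    the subtree's remaining similarity scale, i.e.
    (h_parent - h_node) / (1 - h_node) >= min_relative_gap.

    Criterion (b) rejects the loosely chained subtrees that structureless
    data produces near the tree top; criterion (c) requires a clean
    separation from the surroundings.  Both are scale-free, which matters
    because soft thresholding compresses TOM dissimilarities toward 1.
    Among nested qualifying subtrees the one with the largest cohesion
    ratio wins: dropping true members raises the outside mean, absorbing
    background genes lowers the inside mean, so the ratio peaks at the true
    module boundary.  The root never qualifies, so data without separable
    structure yields no modules.
    """
    m = Z.shape[0]
    heights = np.concatenate([np.zeros(n), Z[:, 2]])
    counts = np.concatenate([np.ones(n, dtype=int), Z[:, 3].astype(int)])
    off = np.asarray(tom, dtype=float).copy()
    np.fill_diagonal(off, 0.0)
    row_sum = off.sum(axis=1)

    leaves: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n)}
    within_sum = np.zeros(n + m)  # sum of off[i, j] over ordered leaf pairs
    parent_height = np.full(n + m, np.nan)
    children: dict[int, tuple[int, int]] = {}
    for i in range(m):
        node = n + i
        left, right = int(Z[i, 0]), int(Z[i, 1])
        children[node] = (left, right)
        parent_height[left] = heights[node]
        parent_height[right] = heights[node]
        ll, rl = leaves[left], leaves[right]
        cross = off[np.ix_(ll, rl)].sum()
        within_sum[node] = within_sum[left] + within_sum[right] + 2.0 * cross
        leaves[node] = np.concatenate([ll, rl])

    def cohesion_ratio(node: int) -> float:
        c = counts[node]
        idx = leaves[node]
        mean_in = within_sum[node] / (c * (c - 1))
        out_sum = row_sum[idx].sum() - within_sum[node]
        n_out = c * (n - c)
        mean_out = out_sum / n_out if n_out else 0.0
        return mean_in / max(mean_out, 1e-300)

    def qualifies(node: int, ratio: float) -> bool:
        c = counts[node]
        if c < min_size or np.isnan(parent_height[node]):
            return False
        if ratio < min_cohesion:
            return False
        h = heights[node]
        scale = 1.0 - h
        if scale <= 0:
            return False
        return (parent_height[node] - h) / scale >= min_relative_gap

    # bottom-up: per node, the best qualifying clusters found so far and the
    # largest cohesion ratio among them
    best: dict[int, tuple[list[np.ndarray], float]] = {
        i: ([], -np.inf) for i in range(n)
    }
    for i in range(m):
        node = n + i
        left, right = children[node]
        l_clusters, l_max = best.pop(left)
        r_clusters, r_max = best.pop(right)
        sub = l_clusters + r_clusters
        sub_max = max(l_max, r_max)
        ratio = cohesion_ratio(node) if counts[node] >= min_size else -np.inf
        if qualifies(node, ratio) and ratio > sub_max:
            best[node] = ([leaves[node]], ratio)
        else:
            best[node] = (sub, sub_max)
    return best[n + m - 1][0]


def detect_modules(
    tom: np.ndarray,
    min_module_size: int = 20,
    cut: str = "cohesion",
    min_cohesion: float = 5.0,
    min_relative_gap: float = 1 / 3,
    static_cut_height: float = 0.95,
) -> np.ndarray:
    """Module labels from average-linkage clustering of 1 - TOM.

    ``cut='cohesion'`` (default) collects subtrees that are internally dense
    relative to the background and separate cleanly from their parent merge
    (see :func:`_collect_modules`); everything else is unassigned (label 0).
    ``cut='static'`` cuts the tree at ``static_cut_height`` and keeps
    clusters of at least ``min_module_size`` genes.  Labels 1..M are ranked
    by decreasing module size.
    """
    n = tom.shape[0]
    labels = np.zeros(n, dtype=int)
    if n < min_module_size:
        return labels
    dissim = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(dissim, 0.0)
    dissim = np.maximum((dissim + dissim.T) / 2.0, 0.0)
    Z = linkage(squareform(dissim, checks=False), method="average")
    if cut == "cohesion":
        clusters = _collect_modules(
            Z, tom, n, min_module_size, min_cohesion, min_relative_gap
        )
    elif cut == "static":
        flat = fcluster(Z, t=static_cut_height, criterion="distance")
        clusters = [
            np.flatnonzero(flat == c)
            for c in np.unique(flat)
            if (flat == c).sum() >= min_module_size
        ]
    else:
        raise ValueError(f"unknown cut method {cut!r}")
    clusters.sort(key=len, reverse=True)
    for label, members in enumerate(clusters, start=1):
        labels[members] = label
    return labels


def blockwise_partition(
    expr: pd.DataFrame | np.ndarray,
    max_block_size: int = 5000,
    seed: int = 0,
) -> list[np.ndarray]:
    """Split genes into blocks of at most ``max_block_size``.

    A single block if the gene set already fits; otherwise genes are
    pre-clustered by k-means on standardised expression profiles into
    ceil(n / max_block_size) centres, with oversized clusters trimmed to
    capacity (overflow genes move to the nearest centre with room).
    """
    X = np.asarray(expr, dtype=float)
    n = X.shape[0]
    if n <= max_block_size:
        return [np.arange(n)]
    n_blocks = int(np.ceil(n / max_block_size))
    sd = X.std(axis=1)
    Xs = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None]
    km = KMeans(n_clusters=n_blocks, random_state=seed, n_init=4).fit(Xs)
    dists = km.transform(Xs)
    order = np.argsort(dists.min(axis=1))  # confident genes claim space first
    capacity = np.full(n_blocks, max_block_size)
    assign = np.full(n, -1)
    for g in order:
        for b in np.argsort(dists[g]):
            if capacity[b] > 0:
                assign[g] = b
                capacity[b] -= 1
                break
    return [np.flatnonzero(assign == b) for b in range(n_blocks) if (assign == b).any()]


@dataclass
class NetworkParams:
    """Parameters of the signed network construction."""

    beta: float = 12.0
    min_module_size: int = 20
    max_block_size: int = 5000
    cut: str = "cohesion"
    min_cohesion: float = 5.0
    min_relative_gap: float = 1 / 3
    static_cut_height: float = 0.95

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


def module_assignment_frame(labels: np.ndarray, gene_ids) -> pd.Series:
    """Gene id -> module label series (0 = unassigned)."""
    return pd.Series(labels, index=pd.Index(gene_ids, name="gene"), name="module")


def export_edge_list(
    adjacency: np.ndarray,
    gene_ids,
    path,
    min_weight: float = 0.0,
) -> None:
    """Weighted edge list TSV (gene1, gene2, weight) with fixed 6-decimal
    formatting, for external graph viewers."""
    gene_ids = list(gene_ids)
    n = len(gene_ids)
    with open(path, "w", newline="\n") as fh:
        fh.write("gene1\tgene2\tweight\n")
        for i in range(n):
            for j in range(i + 1, n):
                w = adjacency[i, j]
                if w >= min_weight:
                    fh.write(f"{gene_ids[i]}\t{gene_ids[j]}\t{w:.6f}\n")


class SignedCoexpressionNetwork(BaseEstimator):
    """Signed network + module detection as a clustering-style estimator.

    ``fit(expr)`` with a gene-major log2 expression table computes, per
    block, correlation -> signed adjacency -> TOM -> average-linkage tree ->
    module cut, then relabels modules across blocks by decreasing size.
    Fitted attributes: ``labels_`` (array) and ``modules_`` (gene-indexed
    series).  Zero-variance genes are assigned module 0.
    """

    def __init__(
        self,
        beta: float = 12.0,
        min_module_size: int = 20,
        max_block_size: int = 5000,
        cut: str = "cohesion",
        min_cohesion: float = 5.0,
        min_relative_gap: float = 1 / 3,
        static_cut_height: float = 0.95,
        random_state: int = 0,
    ):
        self.beta = beta
        self.min_module_size = min_module_size
        self.max_block_size = max_block_size
        self.cut = cut
        self.min_cohesion = min_cohesion
        self.min_relative_gap = min_relative_gap
        self.static_cut_height = static_cut_height
        self.random_state = random_state

    def fit(self, expr: pd.DataFrame, y=None):
        NetworkParams(self.beta, self.min_module_size, self.max_block_size,
                      self.cut, self.min_cohesion, self.min_relative_gap,
                      self.static_cut_height)
        X = np.asarray(expr, dtype=float)
        n = X.shape[0]
        blocks = blockwise_partition(X, self.max_block_size, seed=self.random_state)
        self.blocks_ = blocks
        raw: list[np.ndarray] = []
        for block in blocks:
            cor = pearson_correlation(X[block])
            adj = signed_adjacency(cor, self.beta)
            tom = topological_overlap(adj)
            block_labels = detect_modules(
                tom,
                min_module_size=self.min_module_size,
                cut=self.cut,
                min_cohesion=self.min_cohesion,
                min_relative_gap=self.min_relative_gap,
                static_cut_height=self.static_cut_height,
            )
            for m in np.unique(block_labels):
                if m > 0:
                    raw.append(block[block_labels == m])
        raw.sort(key=len, reverse=True)
        labels = np.zeros(n, dtype=int)
        for lab, members in enumerate(raw, start=1):
            labels[members] = lab
        self.labels_ = labels
        index = expr.index if isinstance(expr, pd.DataFrame) else np.arange(n)
        self.modules_ = module_assignment_frame(labels, index)
        return self

    def fit_predict(self, expr: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(expr).labels_
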