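"""Density-aware constrained clustering of cells (SPADE-style).

Cells are partitioned into a fixed number of clusters (k = 6 for the study)
by agglomerative clustering — Ward linkage on Euclidean distances in Et gene
space by default, with the 2-D embedding coordinates available as an
alternative space.  An optional density-dependent downsampling stage (the
device SPADE uses to keep rare populations visible in 10^5+-cell cytometry
data) may precede the linkage; held-out cells are then assigned to the
nearest cluster centroid.  Clusters are relabeled 1..k by decreasing size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist, squareform

from .ct_io import ExpressionMatrix
from .tsne import EmbeddingResult

__all__ = [
    "ClusterAssignment",
    "DownsampleSettings",
    "density_downsample",
    "cluster_cells",
    "overlay_labels",
]


@dataclass(frozen=True)
class ClusterAssignment:
    """Per-cell labels in 1..k, size-ordered, with centroids in Et space."""

    labels: np.ndarray            # int, per cell
    k: int
    centroids: np.ndarray         # [k x n_genes] mean Et per cluster
    linkage_record: np.ndarray    # scipy linkage matrix of the clustered set
    cell_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        if labels.size and (labels.min() < 1 or labels.max() > self.k):
            raise ValueError(f"labels must lie in 1..{self.k}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "centroids", np.asarray(self.centroids, dtype=float))

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]

    @property
    def n_nonempty(self) -> int:
        return int((self.sizes > 0).sum())


@dataclass(frozen=True)
class DownsampleSettings:
    target_fraction: float = 1.0
    kernel_radius: float = 5.0
    seed: int = 0


def density_downsample(
    et: ExpressionMatrix | np.ndarray,
    target_fraction: float,
    kernel_radius: float,
    seed: int = 0,
) -> np.ndarray:
    """Density-dependent downsampling; returns sorted kept indices.

    Local density of a cell is the number of cells (itself included) within
    ``kernel_radius`` (Euclidean, Et space).  Cells are kept with probability
    min(1, c / density), with c chosen by bisection so the expected kept
    count is ``target_fraction * n`` — low-density (rare) cells are kept with
    probability 1, dense regions are thinned.
    """
    if not (0.0 < target_fraction <= 1.0):
        raise ValueError("target_fraction must be in (0, 1]")
    if kernel_radius <= 0:
        raise ValueError("kernel_radius must be positive")
    X = et.et if isinstance(et, ExpressionMatrix) else np.asarray(et, dtype=float)
    n = X.shape[0]
    if target_fraction == 1.0:
        return np.arange(n)

    D = squareform(pdist(X))
    density = (D <= kernel_radius).sum(axis=1).astype(float)  # includes self

    target = target_fraction * n
    lo, hi = 0.0, density.max()
    for _ in range(100):
        c = 0.5 * (lo + hi)
        expected = np.minimum(1.0, c / density).sum()
        if expected < target:
            lo = c
        else:
            hi = c
    keep_prob = np.minimum(1.0, 0.5 * (lo + hi) / density)

    rng = np.random.default_rng(seed)
    kept = np.flatnonzero(rng.random(n) < keep_prob)
    if kept.size == 0:  # degenerate tiny inputs: keep the sparsest cell
        kept = np.array([int(np.argmin(density))])
    return kept


def _space_matrix(
    et: ExpressionMatrix, space: str, embedding: EmbeddingResult | None
) -> np.ndarray:
    if space == "expression":
        return et.et
    if space == "embedding":
        if embedding is None:
            raise ValueError("space='embedding' requires an EmbeddingResult")
        return embedding.coords
    raise ValueError(f"unknown clustering space {space!r}")


def cluster_cells(
    et: ExpressionMatrix,
    k: int,
    downsample: DownsampleSettings | None = None,
    space: str = "expression",
    embedding: EmbeddingResult | None = None,
    linkage_method: str = "ward",
) -> ClusterAssignment:
    """Cut a Ward (by default) agglomerative tree at k clusters.

    With downsampling enabled, the tree is built on the retained subset and
    the held-out cells are assigned to the nearest centroid.  Labels are
    1..k by decreasing cluster size (ties by first occurrence).
    """
    X = np.asarray(_space_matrix(et, space, embedding), dtype=float)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds n_cells={n}")

    if downsample is not None and downsample.target_fraction < 1.0:
        kept = density_downsample(
            X, downsample.target_fraction, downsample.kernel_radius, downsample.seed
        )
        if kept.size < k:  # not enough survivors to cut at k
            kept = np.arange(n)
    else:
        kept = np.arange(n)

    Z = linkage(X[kept], method=linkage_method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = np.zeros(n, dtype=int)
    labels[kept] = raw

    holdout = np.setdiff1d(np.arange(n), kept, assume_unique=False)
    if holdout.size:
        cents = np.stack([X[kept][raw == c].mean(axis=0) for c in range(1, raw.max() + 1)])
        labels[holdout] = cdist(X[holdout], cents).argmin(axis=1) + 1

    # relabel by decreasing size
    found = np.unique(labels)
    sizes = {c: int((labels == c).sum()) for c in found}
    order = sorted(found, key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = np.array([remap[c] for c in labels])
    k_eff = len(order)

    centroids = np.stack([et.et[labels == c].mean(axis=0) for c in range(1, k_eff + 1)])
    return ClusterAssignment(
        labels=labels,
        k=k_eff,
        centroids=centroids,
        linkage_record=Z,
        cell_ids=tuple(et.cell_ids),
    )


def overlay_labels(
    assignment: ClusterAssignment, embedding: EmbeddingResult
) -> pd.DataFrame:
    """Join cluster labels onto embedding coordinates for map overlay."""
    if len(assignment.labels) != embedding.n_cells:
        raise ValueError(
            f"assignment covers {len(assignment.labels)} cells but embedding has "
            f"{embedding.n_cells}"
        )
    ids = assignment.cell_ids or embedding.cell_ids
    if ids is None:
        ids = tuple(f"cell{i:04d}" for i in range(embedding.n_cells))
    if embedding.cell_ids is not None and assignment.cell_ids is not None:
        if tuple(embedding.cell_ids) != tuple(assignment.cell_ids):
            raise ValueError("assignment and embedding refer to different cells")
    return pd.DataFrame(
        {
            "cell_id": list(ids),
            "cluster": assignment.labels,
            "tsne1": embedding.coords[:, 0],
            "tsne2": embedding.coords[:, 1],
        }
    )
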