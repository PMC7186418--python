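"""Projection of sorted-population bulk profiles onto the single-cell map.

Bulk transcriptional profiles of canonically sorted cell populations (e.g.
CD31+ endothelial cells) share only a subset of genes with the single-cell
panel.  To give the de-novo cell clusters provisional identities, both data
sets are restricted to the overlap genes and z-scored per gene within each
data set (absorbing platform scale differences), a bulk x cell Pearson
similarity matrix is computed across the overlap genes, and each bulk sample
is projected onto the tSNE map at the coordinates of its m most similar
cells.  Because a bulk population may straddle several clusters, identity is
reported per cell-type as a distribution over clusters alongside the modal
cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .cluster import ClusterAssignment
from .ct_io import ExpressionMatrix
from .simulate import BulkPanel
from .tsne import EmbeddingResult

__all__ = [
    "SimilarityMatrix",
    "ProjectionResult",
    "standardize_overlap",
    "similarity_matrix",
    "match_and_project",
    "cocluster_heatmap_order",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Bulk x cell Pearson similarities over the overlap genes."""

    values: np.ndarray            # [n_bulk x n_cells], in [-1, 1]
    bulk_ids: tuple[str, ...]
    cell_ids: tuple[str, ...]
    overlap_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.bulk_ids), len(self.cell_ids)):
            raise ValueError("similarity shape does not match labels")
        if v.size and (np.abs(v) > 1 + 1e-9).any():
            raise ValueError("similarities must lie in [-1, 1]")
        object.__setattr__(self, "values", np.clip(v, -1.0, 1.0))


@dataclass(frozen=True)
class ProjectionResult:
    """Matched cells, similarities and map coordinates per bulk sample."""

    #: rows: bulk_sample, cell_type, matched_cell_id, similarity, tsne1, tsne2
    matches: pd.DataFrame
    #: cell_type -> {cluster label: fraction of matched cells}
    cluster_distribution: dict[str, dict[int, float]]
    #: cell_type -> modal cluster label
    modal_cluster: dict[str, int]
    m: int


def standardize_overlap(
    et: ExpressionMatrix,
    bulk: BulkPanel,
    overlap_genes: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Restrict both data sets to the overlap genes and z-score per gene.

    Genes constant within either data set carry no matching information and
    are dropped from both (logged).  Returns (cells_z, bulk_z, genes_used)
    with a shared gene order.

    Raises ValueError if fewer than 3 usable genes remain.
    """
    overlap_genes = list(overlap_genes)
    if len(overlap_genes) < 3:
        raise ValueError("need at least 3 overlap genes")
    sc_idx = et.panel.index_of(overlap_genes)
    bulk_pos = {g: i for i, g in enumerate(bulk.genes)}
    missing = [g for g in overlap_genes if g not in bulk_pos]
    if missing:
        raise ValueError(f"overlap genes absent from bulk panel: {missing}")
    bk_idx = np.array([bulk_pos[g] for g in overlap_genes])

    sc = np.asarray(et.et, dtype=float)[:, sc_idx]
    bk = np.asarray(bulk.profiles, dtype=float)[:, bk_idx]

    usable = []
    for j, g in enumerate(overlap_genes):
        if sc[:, j].std() == 0.0 or bk[:, j].std() == 0.0:
            logger.warning("overlap gene %s constant in one data set; dropped from both", g)
        else:
            usable.append(j)
    if len(usable) < 3:
        raise ValueError(
            f"only {len(usable)} usable overlap genes after dropping constants; need >= 3"
        )
    sc, bk = sc[:, usable], bk[:, usable]
    genes_used = tuple(overlap_genes[j] for j in usable)

    def zscore(m: np.ndarray) -> np.ndarray:
        return (m - m.mean(axis=0)) / m.std(axis=0)

    return zscore(sc), zscore(bk), genes_used


def similarity_matrix(
    std_cells: np.ndarray,
    std_bulk: np.ndarray,
    cell_ids: Sequence[str],
    bulk_ids: Sequence[str],
    overlap_genes: Sequence[str],
) -> SimilarityMatrix:
    """Pearson correlation of every (bulk, cell) pair across overlap genes.

    Cells whose profile is constant across the overlap genes have undefined
    correlation; they are kept in the matrix with similarity 0 and a warning
    (so column indices still align with the cohort).
    """
    cells = np.asarray(std_cells, dtype=float)
    bulk = np.asarray(std_bulk, dtype=float)
    if cells.shape[1] != bulk.shape[1]:
        raise ValueError("cell and bulk matrices must share the gene axis")
    if cells.shape[0] == 0 or bulk.shape[0] == 0:
        raise ValueError("empty input to similarity_matrix")

    def center_norm(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = m - m.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(c, axis=1)
        return c, norm

    bc, bn = center_norm(bulk)
    cc, cn = center_norm(cells)
    flat = cn == 0.0
    if flat.any():
        logger.warning("%d cells constant across overlap genes; similarity set to 0", flat.sum())
    bad_bulk = bn == 0.0
    if bad_bulk.any():
        logger.warning("%d bulk samples constant across overlap genes", bad_bulk.sum())
    denom = np.outer(np.where(bn == 0, 1.0, bn), np.where(cn == 0, 1.0, cn))
    values = (bc @ cc.T) / denom
    values[:, flat] = 0.0
    values[bad_bulk, :] = 0.0
    return SimilarityMatrix(
        values=np.clip(values, -1.0, 1.0),
        bulk_ids=tuple(bulk_ids),
        cell_ids=tuple(cell_ids),
        overlap_genes=tuple(overlap_genes),
    )


def match_and_project(
    sim: SimilarityMatrix,
    embedding: EmbeddingResult,
    assignment: ClusterAssignment,
    bulk_cell_types: Sequence[str],
    m: int = 20,
) -> ProjectionResult:
    """Project each bulk sample at its m most similar cells' coordinates.

    Ties in similarity are broken by cell order (cell_id order of the
    cohort).  Per bulk cell-type, the distribution of cluster labels over all
    matched cells of all its samples gives the provisional identity; the
    modal cluster is the distribution's argmax (ties to the smaller label).
    """
    n_bulk, n_cells = sim.values.shape
    if n_bulk == 0 or n_cells == 0:
        raise ValueError("empty similarity matrix")
    if not (1 <= m <= n_cells):
        raise ValueError(f"m={m} must be in 1..{n_cells}")
    if embedding.n_cells != n_cells or len(assignment.labels) != n_cells:
        raise ValueError("similarity, embedding and assignment must cover the same cells")
    if len(bulk_cell_types) != n_bulk:
        raise ValueError("bulk_cell_types must align with similarity rows")

    rows = []
    per_type_labels: dict[str, list[int]] = {}
    for b in range(n_bulk):
        s = sim.values[b]
        # stable sort on (-similarity, index): ties broken by cell order
        top = np.lexsort((np.arange(n_cells), -s))[:m]
        ctype = bulk_cell_types[b]
        for c in top:
            rows.append(
                {
                    "bulk_sample": sim.bulk_ids[b],
                    "cell_type": ctype,
                    "matched_cell_id": sim.cell_ids[c],
                    "similarity": s[c],
                    "tsne1": embedding.coords[c, 0],
                    "tsne2": embedding.coords[c, 1],
                }
            )
            per_type_labels.setdefault(ctype, []).append(int(assignment.labels[c]))

    dist: dict[str, dict[int, float]] = {}
    modal: dict[str, int] = {}
    for ctype, labs in per_type_labels.items():
        counts = pd.Series(labs).value_counts().sort_index()
        frac = (counts / counts.sum()).to_dict()
        dist[ctype] = {int(k): float(v) for k, v in frac.items()}
        modal[ctype] = int(max(dist[ctype], key=lambda k: (dist[ctype][k], -k)))

    return ProjectionResult(
        matches=pd.DataFrame(rows),
        cluster_distribution=dist,
        modal_cluster=modal,
        m=m,
    )


def cocluster_heatmap_order(sim: SimilarityMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Row/column permutations from average-linkage correlation clustering.

    Returns (row_order, col_order) — dendrogram leaf orders for heatmap
    export.  Degenerate axes (size < 2) return the identity permutation.
    """
    def order(mat: np.ndarray) -> np.ndarray:
        if mat.shape[0] < 2:
            return np.arange(mat.shape[0])
        d = pdist(mat, metric="correlation")
        d = np.nan_to_num(d, nan=1.0)  # constant rows: treat as uncorrelated
        return leaves_list(linkage(d, method="average"))

    return order(sim.values), order(sim.values.T)
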