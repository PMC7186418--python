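"""Cluster-level statistics: frequency time courses, marker rankings,
pre/post-pneumonectomy differential expression, and per-gene map overlays.

Fold changes are differences of mean Et (Et is log2-scale, so a difference
of means IS a log2 fold-change, delta-delta-Ct style).  Group comparisons
use Welch's unequal-variance t-test with Satterthwaite degrees of freedom,
starred at p < 0.05 / 0.01 / 0.001; no multiple-testing correction is
applied to the stars (a Benjamini-Hochberg q-value column is emitted
additionally, as an extension).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cluster import ClusterAssignment
from .ct_io import CellMeta, ExpressionMatrix, GROUPS

__all__ = [
    "POST_PNX_GROUPS",
    "cluster_frequencies",
    "identify_emergent_cluster",
    "rank_markers",
    "welch_test",
    "prepost_comparison",
    "gene_overlay_scale",
    "stars_for_p",
]

#: Post-pneumonectomy timepoints pooled for the pre/post comparison.
POST_PNX_GROUPS = ("day1", "day3", "day7")

_STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars_for_p(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    for thr, s in _STAR_THRESHOLDS:
        if p < thr:
            return s
    return "ns"


# ---------------------------------------------------------------------------
# Cluster frequencies
# ---------------------------------------------------------------------------

def cluster_frequencies(
    assignment: ClusterAssignment, meta: Sequence[CellMeta]
) -> pd.DataFrame:
    """Per (group, cluster) cell counts and within-group fractions.

    Fractions are of the total number of cells in that group; groups with no
    cells are omitted.  Columns: group, cluster, n_cells, fraction.
    """
    if len(assignment.labels) != len(meta):
        raise ValueError("assignment does not cover the metadata")
    for c in meta:
        if c.group not in GROUPS:
            raise ValueError(f"unknown group {c.group!r}")
    df = pd.DataFrame({"group": [c.group for c in meta], "cluster": assignment.labels})
    rows = []
    for g in GROUPS:
        sub = df[df.group == g]
        if len(sub) == 0:
            continue
        counts = sub.cluster.value_counts()
        for c in range(1, assignment.k + 1):
            n = int(counts.get(c, 0))
            rows.append({"group": g, "cluster": c, "n_cells": n, "fraction": n / len(sub)})
    return pd.DataFrame(rows, columns=["group", "cluster", "n_cells", "fraction"])


def identify_emergent_cluster(freq: pd.DataFrame) -> int:
    """The cluster with the largest control-to-post-pneumonectomy gain.

    Control frequency is the mean fraction over the control groups present;
    post frequency the mean over day1/day3/day7.  Returns the cluster label
    maximizing (post - control).
    """
    control = [g for g in ("littermate_control", "surgical_control") if g in set(freq.group)]
    post = [g for g in POST_PNX_GROUPS if g in set(freq.group)]
    if not control or not post:
        raise ValueError("need both control and post-pneumonectomy groups")
    pivot = freq.pivot_table(index="cluster", columns="group", values="fraction", fill_value=0.0)
    gain = pivot[post].mean(axis=1) - pivot[control].mean(axis=1)
    return int(gain.idxmax())


# ---------------------------------------------------------------------------
# Marker ranking
# ---------------------------------------------------------------------------

def rank_markers(
    et: ExpressionMatrix, assignment: ClusterAssignment, top_n: int = 10
) -> pd.DataFrame:
    """Top-N genes per cluster by one-vs-rest log2 fold-change.

    log2fc(c, g) = mean Et of g in cluster c minus mean Et of g in all other
    clusters.  Within a cluster, genes sort by log2fc descending, ties
    alphabetically.  Columns: cluster, rank, gene, log2fc.
    """
    if assignment.k < 2:
        raise ValueError("marker ranking needs at least 2 clusters")
    if top_n > et.panel.size:
        raise ValueError(f"top_n={top_n} exceeds panel size {et.panel.size}")
    labels = assignment.labels
    empty = [c for c in range(1, assignment.k + 1) if (labels == c).sum() == 0]
    if empty:
        raise ValueError(f"cluster {empty[0]} is empty")
    rows = []
    for c in range(1, assignment.k + 1):
        inside = labels == c
        lfc = et.et[inside].mean(axis=0) - et.et[~inside].mean(axis=0)
        order = sorted(
            range(et.panel.size), key=lambda g: (-lfc[g], et.panel.gene_names[g])
        )[:top_n]
        for rank, g in enumerate(order, start=1):
            rows.append(
                {
                    "cluster": c,
                    "rank": rank,
                    "gene": et.panel.gene_names[g],
                    "log2fc": float(lfc[g]),
                }
            )
    return pd.DataFrame(rows, columns=["cluster", "rank", "gene", "log2fc"])


# ---------------------------------------------------------------------------
# Welch tests
# ---------------------------------------------------------------------------

def welch_test(a: np.ndarray, b: np.ndarray) -> dict:
    """Welch's unequal-variance t-test with Satterthwaite df and stars.

    Returns dict with mean_a, mean_b, t, df, p, stars.  Two samples with
    zero variance and equal means give t=0, p=1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples must be finite")

    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            t, df, p = 0.0, float(a.size + b.size - 2), 1.0
        else:
            t = np.inf if a.mean() > b.mean() else -np.inf
            df, p = float(a.size + b.size - 2), 0.0
    else:
        res = sps.ttest_ind(a, b, equal_var=False)
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "t": t,
        "df": df,
        "p": p,
        "stars": stars_for_p(p),
    }


def prepost_comparison(
    et: ExpressionMatrix,
    genes: Sequence[str] | None = None,
    include_surgical_controls: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch comparison of control vs post-pneumonectomy cells.

    Pool A: littermate controls (plus surgical controls when
    ``include_surgical_controls``); pool B: days 1+3+7 combined.  Emits one
    row per gene: gene, mean_ctrl, mean_pnx, t, df, p, stars, significant,
    bh_q (Benjamini-Hochberg, an extension beyond the per-gene stars) and a
    log10 display value pair for violin export (log10(Et + 1)).
    """
    genes = list(genes) if genes is not None else list(et.panel.gene_names)
    groups = et.groups
    ctrl_groups = ["littermate_control"] + (
        ["surgical_control"] if include_surgical_controls else []
    )
    in_a = np.isin(groups, ctrl_groups)
    in_b = np.isin(groups, POST_PNX_GROUPS)
    if in_a.sum() == 0 or in_b.sum() == 0:
        raise ValueError("both control and post-pneumonectomy pools must be non-empty")

    idx = et.panel.index_of(genes)
    rows = []
    for g, j in zip(genes, idx):
        r = welch_test(et.et[in_a, j], et.et[in_b, j])
        rows.append(
            {
                "gene": g,
                "mean_ctrl": r["mean_a"],
                "mean_pnx": r["mean_b"],
                "log10_ctrl": float(np.log10(r["mean_a"] + 1.0)),
                "log10_pnx": float(np.log10(r["mean_b"] + 1.0)),
                "t": r["t"],
                "df": r["df"],
                "p": r["p"],
                "stars": r["stars"],
                "significant": r["p"] < alpha,
            }
        )
    out = pd.DataFrame(rows)
    out["bh_q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Overlay scaling
# ---------------------------------------------------------------------------

def gene_overlay_scale(et: ExpressionMatrix, gene: str) -> np.ndarray:
    """Per-cell min-max scaling of one gene to [0, 1] for map heat overlays.

    A gene constant across cells maps to all zeros.
    """
    v = et.gene_values(gene)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)
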