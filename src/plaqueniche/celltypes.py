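"""Segmentation-based branch: filtering, Pearson-residual normalization,
clustering, gene-set scoring, cluster annotation, and cell-type locations
relative to plaques.

Normalization uses analytic Pearson residuals
``r = (x - mu) / sqrt(mu + mu^2/theta)`` with ``mu`` from row/column totals,
theta = 100 and clipping at sqrt(n_cells) — the established defaults for
this normalization.  A cluster is annotated with a cell type when the
separation score

    s = (mean(score | cluster) - mean(score | other cells))
        / (std(score | cluster) + std(score | other cells))

exceeds 1 (population std); among several qualifying types the argmax wins,
with all qualifying types reported.
"""
from __future__ import annotations

import dataclasses
import logging

import igraph
import leidenalg
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .coloc import DistanceProfile, plaque_distance_profile
from .io import CellMatrix
from .plaques import PlaqueField

log = logging.getLogger("plaqueniche")


# ---------------------------------------------------------------------------
# Filtering


def filter_matrix(
    raw: CellMatrix,
    max_missing_per_gene: int = 60000,
    min_counts_per_cell: int = 20,
) -> CellMatrix:
    """Marker-missingness and minimum-count filters.

    Genes with ``max_missing_per_gene`` or more missing values are removed;
    remaining missing values are set to 0; cells with total counts below
    ``min_counts_per_cell`` are removed (a total of exactly the minimum is
    kept).
    """
    missing = raw.missing_mask()
    gene_keep = missing.sum(axis=0) < max_missing_per_gene
    if not gene_keep.any():
        raise ValueError(
            f"every gene has >= {max_missing_per_gene} missing values; nothing left"
        )
    counts = raw.counts[:, gene_keep]
    counts = np.nan_to_num(counts, nan=0.0)
    cell_keep = counts.sum(axis=1) >= min_counts_per_cell
    if not cell_keep.any():
        raise ValueError(
            f"no cell reaches min_counts_per_cell={min_counts_per_cell}; nothing left"
        )
    log.info(
        "filter: genes %d -> %d, cells %d -> %d",
        raw.n_genes, int(gene_keep.sum()), raw.n_cells, int(cell_keep.sum()),
    )
    return CellMatrix(
        counts=counts[cell_keep],
        genes=[g for g, k in zip(raw.genes, gene_keep) if k],
        cells=raw.cells.loc[cell_keep].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# Normalization


@dataclasses.dataclass
class NormalizedMatrix:
    """Clipped analytic Pearson residuals of a count matrix."""

    residuals: np.ndarray
    genes: list[str]
    theta: float
    clip_bound: float


def pearson_residuals(
    counts: np.ndarray,
    genes: list[str] | None = None,
    theta: float = 100.0,
    clip: float | None = None,
) -> NormalizedMatrix:
    """Analytic Pearson residuals under the overdispersed null model.

    mu_ij = row_sum_i * col_sum_j / total;
    r_ij = (x_ij - mu_ij) / sqrt(mu_ij + mu_ij^2 / theta), clipped to
    +- sqrt(n_cells) by default.  Entries with x = mu give exactly 0, so a
    rank-1 count matrix normalizes to all zeros.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 cells and 2 genes")
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    row = x.sum(axis=1, keepdims=True)
    col = x.sum(axis=0, keepdims=True)
    zero_rows = np.flatnonzero(row.ravel() == 0)
    zero_cols = np.flatnonzero(col.ravel() == 0)
    if zero_rows.size or zero_cols.size:
        raise ValueError(
            f"all-zero rows {zero_rows.tolist()} / columns {zero_cols.tolist()}: "
            "mu undefined"
        )
    mu = row @ col / x.sum()
    r = (x - mu) / np.sqrt(mu + mu ** 2 / theta)
    bound = float(np.sqrt(x.shape[0])) if clip is None else float(clip)
    r = np.clip(r, -bound, bound)
    return NormalizedMatrix(
        residuals=r,
        genes=list(genes) if genes is not None else [],
        theta=theta,
        clip_bound=bound,
    )


# ---------------------------------------------------------------------------
# Dimensionality reduction + community detection


def reduce_and_cluster(
    norm: NormalizedMatrix | np.ndarray,
    n_pcs: int = 20,
    n_neighbors: int = 15,
    resolution: float = 0.1,
    seed: int = 0,
    embedding: np.ndarray | None = None,
) -> np.ndarray:
    """PCA on residuals, k-NN graph, Leiden community detection.

    ``embedding`` accepts a precomputed (e.g. batch-integrated) cell
    embedding, bypassing the internal PCA.  Returns integer cluster labels
    aligned to cells.
    """
    x = norm.residuals if isinstance(norm, NormalizedMatrix) else np.asarray(norm)
    if embedding is None:
        n_pcs = min(n_pcs, min(x.shape) - 1)
        if n_pcs < 1:
            raise ValueError("matrix too small for PCA")
        pca = PCA(n_components=n_pcs, random_state=seed)
        embedding = pca.fit_transform(x - x.mean(axis=0))
    n_cells = embedding.shape[0]
    if n_cells <= n_neighbors:
        raise ValueError(f"need more than {n_neighbors} cells for the k-NN graph")
    knn = kneighbors_graph(embedding, n_neighbors=n_neighbors, mode="connectivity")
    knn = knn.maximum(knn.T).tocoo()  # symmetrize
    g = igraph.Graph(
        n=n_cells, edges=list(zip(knn.row.tolist(), knn.col.tolist())), directed=False
    )
    g.simplify()
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


# ---------------------------------------------------------------------------
# Gene-set scoring


def score_gene_set(
    expr: np.ndarray,
    genes: list[str],
    set_genes: list[str],
    n_bins: int = 25,
    ctrl_size: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell gene-set score against an expression-matched control pool.

    score = mean(expr over set genes) - mean(expr over control genes), with
    control genes drawn (seeded) from bins of comparable mean expression —
    ``ctrl_size`` per occupied bin, defaulting to the set size.  A constant
    expression matrix scores exactly 0 for any set.
    """
    expr = np.asarray(expr, dtype=float)
    gene_idx = {g: i for i, g in enumerate(genes)}
    set_idx = [gene_idx[g] for g in set_genes if g in gene_idx]
    dropped = [g for g in set_genes if g not in gene_idx]
    if dropped:
        log.warning("set genes absent from panel, dropped: %s", dropped)
    if not set_idx:
        raise ValueError("no gene of the set is present in the panel")

    rng = np.random.default_rng(seed)
    mean_expr = expr.mean(axis=0)
    order = np.argsort(mean_expr, kind="stable")
    # equal-occupancy expression bins; keep >= 4 genes per bin so the
    # control pool is not just the set itself on small panels
    n_bins_eff = max(1, min(n_bins, len(genes) // 4))
    bins = np.array_split(order, n_bins_eff)
    bin_of = np.empty(len(genes), dtype=int)
    for b, members in enumerate(bins):
        bin_of[members] = b
    size = ctrl_size if ctrl_size is not None else len(set_idx)

    ctrl_idx: list[int] = []
    for b in sorted(set(bin_of[set_idx])):
        members = np.flatnonzero(bin_of == b)
        take = min(size, members.size)
        ctrl_idx.extend(rng.choice(members, size=take, replace=False))
    ctrl_idx = sorted(set(ctrl_idx))
    return expr[:, set_idx].mean(axis=1) - expr[:, ctrl_idx].mean(axis=1)


# ---------------------------------------------------------------------------
# Cluster annotation


def separation_score(scores: np.ndarray, in_cluster: np.ndarray) -> float:
    """(mean_in - mean_out) / (std_in + std_out), population std."""
    scores = np.asarray(scores, dtype=float)
    inside = scores[in_cluster]
    outside = scores[~in_cluster]
    if outside.size == 0:
        raise ValueError("cluster equals the whole dataset: no 'other cells'")
    denom = inside.std(ddof=0) + outside.std(ddof=0)
    if denom == 0:
        return np.inf if inside.mean() > outside.mean() else (
            -np.inf if inside.mean() < outside.mean() else 0.0
        )
    return float((inside.mean() - outside.mean()) / denom)


def annotate_clusters(
    type_scores: dict[str, np.ndarray],
    cluster_labels: np.ndarray,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Assign each cluster the cell type with maximal separation score > 1.

    Returns a table with one row per (cluster, type): the score, whether the
    type qualifies, and whether it is the assigned one.  Clusters with no
    qualifying type are ``unannotated`` (assigned column all-False).
    """
    cluster_labels = np.asarray(cluster_labels)
    rows = []
    for lc in np.unique(cluster_labels):
        in_cluster = cluster_labels == lc
        s_by_type = {
            ct: separation_score(scores, in_cluster)
            for ct, scores in type_scores.items()
        }
        qualifying = {ct: s for ct, s in s_by_type.items() if s > threshold}
        assigned = max(qualifying, key=qualifying.get) if qualifying else None
        if len(qualifying) > 1:
            log.info(
                "cluster %s: %d qualifying types %s, assigned %s",
                lc, len(qualifying), sorted(qualifying), assigned,
            )
        for ct, s in s_by_type.items():
            rows.append(
                {
                    "cluster": lc,
                    "type": ct,
                    "s": s,
                    "qualifies": s > threshold,
                    "assigned": ct == assigned,
                }
            )
    return pd.DataFrame(rows)


def cluster_assignments(annotation: pd.DataFrame) -> dict:
    """Map cluster -> assigned type (or 'unannotated')."""
    out = {}
    for lc, grp in annotation.groupby("cluster"):
        hit = grp.loc[grp["assigned"], "type"]
        out[lc] = hit.iloc[0] if len(hit) else "unannotated"
    return out


# ---------------------------------------------------------------------------
# Spatial location of annotated types


def celltype_distance_histogram(
    annotation: pd.DataFrame,
    cluster_labels: np.ndarray,
    centroids: np.ndarray,
    field: PlaqueField,
    bin_width: float = 5.0,
    max_range: float = 200.0,
) -> dict[str, DistanceProfile]:
    """Annulus-renormalized distance-to-plaque histogram per annotated type."""
    assign = cluster_assignments(annotation)
    cell_types = np.array([assign[lc] for lc in cluster_labels], dtype=object)
    if field.n_plaques == 0:
        log.warning("zero plaques: all distances infinite, empty profiles")
    profiles = {}
    for ct in sorted(set(assign.values())):
        if ct == "unannotated":
            continue
        pts = centroids[cell_types == ct]
        if len(pts) == 0:
            log.warning("annotated type %s has no cells; skipped", ct)
            continue
        profiles[ct] = plaque_distance_profile(
            pts, field, bin_width=bin_width, max_range=max_range
        )
    return profiles
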