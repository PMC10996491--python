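"""scRNA-seq cell filtering, normalization, gene-set scoring and clustering."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import CellMatrix, CountMatrix

__all__ = [
    "RnaQcThresholds",
    "ClusteringResult",
    "filter_cells_rna",
    "normalize_log",
    "score_gene_set",
    "cluster_cells",
    "rank_genes",
]


@dataclass
class RnaQcThresholds:
    """Cell-level RNA quality thresholds.

    Cells with fewer than ``min_transcripts`` total transcripts are low
    quality; cells above ``max_transcripts`` are putative multiplets;
    cells at or above ``max_mito_fraction`` mitochondrial reads are
    dying/damaged. All three classes are removed.
    """

    min_transcripts: int = 500
    max_transcripts: int = 100_000
    max_mito_fraction: float = 0.40

    def __post_init__(self):
        if not self.min_transcripts < self.max_transcripts:
            raise ValueError("min_transcripts must be < max_transcripts")
        if not 0 < self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in (0, 1]")


def filter_cells_rna(
    matrix: CountMatrix,
    mito_genes: Sequence[str],
    thresholds: RnaQcThresholds | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove low-count, multiplet, and high-mitochondrial cells.

    Returns the filtered matrix and a removal report listing each
    removed cell with the first rule it violates (checked in order
    low_count, high_count, high_mito).
    """
    if matrix.n_cells == 0:
        raise ValueError("empty matrix")
    t = thresholds or RnaQcThresholds()
    mito = [g for g in mito_genes if g in matrix.features]
    totals = matrix.cell_totals().astype(float)
    if mito:
        pos = matrix.features.get_indexer(mito)
        mito_counts = np.asarray(matrix.X[:, pos].sum(axis=1)).ravel().astype(float)
        mito_frac = np.divide(
            mito_counts, totals, out=np.zeros_like(totals), where=totals > 0
        )
    else:
        warnings.warn(
            "no mitochondrial genes found; mitochondrial filter vacuously passes",
            stacklevel=2,
        )
        mito_frac = np.zeros_like(totals)

    rule = pd.Series("", index=matrix.cells, dtype=object)
    rule[mito_frac >= t.max_mito_fraction] = "high_mito"
    rule[totals > t.max_transcripts] = "high_count"
    rule[totals < t.min_transcripts] = "low_count"  # highest priority written last
    removed = rule != ""
    report = pd.DataFrame(
        {
            "total_counts": totals[removed.to_numpy()],
            "mito_fraction": mito_frac[removed.to_numpy()],
            "rule": rule[removed],
        },
        index=matrix.cells[removed.to_numpy()],
    )
    filtered = matrix.subset_cells((~removed).to_numpy())
    return filtered, report


def normalize_log(matrix: CountMatrix, scale_total: float = 1e4) -> CellMatrix:
    """Depth normalization to ``scale_total`` counts per cell, then log1p.

    value = log(1 + count * scale_total / cell_total). Cells with zero
    total counts must have been removed by QC first.
    """
    totals = matrix.cell_totals().astype(float)
    if np.any(totals == 0):
        raise ValueError("cells with zero total counts must be filtered before normalization")
    X = matrix.X.astype(float).multiply(scale_total / totals[:, None]).tocsr()
    X.data = np.log1p(X.data)
    return CellMatrix(X, matrix.cells, matrix.features)


def score_gene_set(
    norm: CellMatrix,
    gene_set: Sequence[str],
    n_control_bins: int = 25,
    controls_per_gene: int = 50,
    seed: int = 0,
) -> pd.Series:
    """Expression-bin-matched gene-set (module) score per cell.

    Genes are binned by mean normalized expression into
    ``n_control_bins`` equal-size bins; for each set gene,
    ``controls_per_gene`` control genes are sampled (without
    replacement, capped at the bin size) from its bin. The score is the
    mean expression of the set genes minus the mean expression of the
    pooled control genes. Deterministic given the seed.
    """
    present = [g for g in gene_set if g in norm.features]
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    rng = np.random.default_rng(seed)
    gene_means = np.asarray(norm.X.mean(axis=0)).ravel()
    order = np.argsort(gene_means, kind="stable")
    n_bins = min(n_control_bins, norm.n_features)
    bin_of = np.empty(norm.n_features, dtype=int)
    bin_of[order] = np.arange(norm.n_features) * n_bins // norm.n_features
    bins = {b: np.flatnonzero(bin_of == b) for b in range(n_bins)}

    set_pos = norm.features.get_indexer(present)
    control = set()
    for p in set_pos:
        pool = bins[bin_of[p]]
        k = min(controls_per_gene, pool.size)
        control.update(rng.choice(pool, size=k, replace=False).tolist())
    control_pos = np.fromiter(sorted(control), dtype=int)

    set_mean = np.asarray(norm.X[:, set_pos].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(norm.X[:, control_pos].mean(axis=1)).ravel()
    return pd.Series(set_mean - ctrl_mean, index=norm.cells, name="score")


@dataclass
class ClusteringResult:
    labels: pd.Series  # per-cell cluster id, contiguous from 0
    chosen_resolution: float
    silhouette_by_resolution: pd.Series
    embedding: pd.DataFrame  # the PC space in which silhouettes were computed

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


def cluster_cells(
    norm: CellMatrix,
    n_pcs: int = 30,
    n_neighbors: int = 15,
    resolutions: Sequence[float] | None = None,
    seed: int = 0,
) -> ClusteringResult:
    """Leiden graph clustering with silhouette-based resolution selection.

    Clusters the PCA embedding at every resolution in ``resolutions``
    (default: ten values evenly spaced in [0.1, 1.0]), scores each
    clustering by silhouette in the same embedding, and keeps the
    argmax (ties and single-cluster solutions, scored -1, resolve to
    the lowest resolution).
    """
    import scanpy as sc
    from sklearn.metrics import silhouette_score

    if resolutions is None:
        resolutions = np.linspace(0.1, 1.0, 10).round(3).tolist()
    if norm.n_cells < 2 or len(resolutions) < 2:
        raise ValueError("need at least 2 cells and at least 2 resolutions")

    adata = norm.to_anndata()
    n_comps = min(n_pcs, norm.n_cells - 1, norm.n_features - 1)
    sc.pp.pca(adata, n_comps=n_comps, random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=min(n_neighbors, norm.n_cells - 1), random_state=seed)
    emb = adata.obsm["X_pca"]

    scores: dict[float, float] = {}
    labelings: dict[float, np.ndarray] = {}
    for res in resolutions:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            sc.tl.leiden(
                adata,
                resolution=float(res),
                key_added="_leiden",
                random_state=seed,
                flavor="igraph",
                n_iterations=2,
                directed=False,
            )
        lab = adata.obs["_leiden"].astype(int).to_numpy()
        labelings[res] = lab
        scores[res] = (
            float(silhouette_score(emb, lab)) if len(np.unique(lab)) > 1 else -1.0
        )

    sil = pd.Series(scores, name="silhouette")
    best = max(resolutions, key=lambda r: (scores[r], -r))
    labels = pd.Series(labelings[best], index=norm.cells, name="cluster")
    # contiguous relabeling from 0 in order of first appearance
    _, labels_contig = np.unique(labels.to_numpy(), return_inverse=True)
    labels = pd.Series(labels_contig, index=norm.cells, name="cluster")
    return ClusteringResult(
        labels=labels,
        chosen_resolution=float(best),
        silhouette_by_resolution=sil,
        embedding=pd.DataFrame(emb, index=norm.cells),
    )


def rank_genes(norm: CellMatrix, labels: pd.Series | Sequence) -> pd.DataFrame:
    """One-vs-rest rank-sum differential expression per cluster.

    For every group, each gene is tested with a one-sided ("greater")
    two-sample rank-sum test of the group's cells against all other
    cells (exact when both groups are small and tie-free, midrank
    normal approximation with continuity correction otherwise), BH
    adjusted across genes within the group, and the table is sorted by
    average log2 fold change descending.
    """
    labels = pd.Series(np.asarray(labels), index=norm.cells)
    groups = pd.unique(labels)
    if len(groups) < 2 or any((labels == g).sum() < 2 for g in groups):
        raise ValueError("need at least 2 groups with at least 2 cells each")
    dense = norm.to_dense()
    ln2 = np.log(2.0)
    frames = []
    for g in groups:
        mask = (labels == g).to_numpy()
        a, b = dense[mask], dense[~mask]
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(a, b, axis=0, alternative="greater", method="auto")
            pvals = np.asarray(res.pvalue, dtype=float)
        constant = np.ptp(dense, axis=0) == 0
        pvals[constant | ~np.isfinite(pvals)] = 1.0
        # average log2 fold change on the log-normalized scale
        lfc = (a.mean(axis=0) - b.mean(axis=0)) / ln2
        fdr = multipletests(pvals, method="fdr_bh")[1]
        frames.append(
            pd.DataFrame(
                {
                    "group": g,
                    "gene": norm.features,
                    "avg_log2fc": lfc,
                    "p_value": pvals,
                    "fdr": fdr,
                }
            ).sort_values("avg_log2fc", ascending=False)
        )
    return pd.concat(frames, ignore_index=True)
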