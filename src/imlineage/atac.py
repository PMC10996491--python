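"""scATAC-seq core: QC, LSI embedding, motif matching, accessibility deviations.

The deviation machinery follows the chromVAR construction: for a peak
set S (a motif annotation), the expected accessibility of cell i is
E_i = T_i * sum_{p in S} f_p, where T_i is the cell's total fragment
count and f_p the peak's fraction of all fragments. The raw deviation
y_i = (O_i - E_i) / E_i is standardized against the same statistic
computed on GC/accessibility-matched background peak sets, giving the
per-cell deviation z-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .matrix import CellMatrix, CountMatrix

__all__ = [
    "ETS_PREFIXES",
    "AtacQcThresholds",
    "MotifAnnotation",
    "DeviationResult",
    "LsiResult",
    "filter_cells_atac",
    "lsi_embed",
    "read_jaspar",
    "match_motifs",
    "sample_background_peaks",
    "compute_deviations",
    "differential_peaks",
    "retain_motifs",
    "celltype_motif_enrichment",
]

#: gene-symbol prefixes of the oncogenic ETS-family factors merged downstream
ETS_PREFIXES = ("ERG", "ETS", "ETV", "FLI")


@dataclass
class AtacQcThresholds:
    """Cell-level scATAC quality thresholds.

    Cells are kept when TSS enrichment >= ``min_tss_enrichment``, unique
    nuclear fragments >= ``min_fragments`` and total reads <=
    ``max_reads`` (larger cells are treated as putative multiplets).
    """

    min_tss_enrichment: float = 4.0
    min_fragments: int = 1000
    max_reads: int = 1_000_000

    def __post_init__(self):
        if min(self.min_tss_enrichment, self.min_fragments, self.max_reads) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class MotifAnnotation:
    """Boolean peak x motif incidence plus a motif -> gene-symbol map."""

    incidence: pd.DataFrame
    motif_to_gene: Mapping[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.incidence = self.incidence.astype(bool)
        if not self.motif_to_gene:
            self.motif_to_gene = {m: [m] for m in self.incidence.columns}
        for m in self.incidence.columns:
            genes = self.motif_to_gene.get(m, [])
            if not genes:
                raise ValueError(f"motif {m!r} maps to no gene symbol")

    @property
    def motifs(self) -> pd.Index:
        return self.incidence.columns

    @property
    def peaks(self) -> pd.Index:
        return self.incidence.index

    def peak_sets(self) -> dict[str, np.ndarray]:
        return {
            m: np.flatnonzero(self.incidence[m].to_numpy()) for m in self.incidence.columns
        }


@dataclass
class DeviationResult:
    """Per-motif, per-cell raw deviations and background-corrected z-scores."""

    raw: pd.DataFrame  # motifs x cells
    z: pd.DataFrame  # motifs x cells
    motif_to_gene: Mapping[str, list[str]] = field(default_factory=dict)

    @property
    def motifs(self) -> pd.Index:
        return self.raw.index

    @property
    def cells(self) -> pd.Index:
        return self.raw.columns


# -- QC --------------------------------------------------------------------

def filter_cells_atac(
    qc: pd.DataFrame, thresholds: AtacQcThresholds | None = None
) -> tuple[pd.Index, pd.DataFrame]:
    """Apply the TSS / fragment / read-count cell filters.

    Returns the retained cell index and a removal report listing, for
    each removed cell, the first rule it violates (checked in order
    low_tss, low_fragments, high_reads).
    """
    t = thresholds or AtacQcThresholds()
    for col in ("tss_enrichment", "n_fragments", "n_reads"):
        if col not in qc.columns:
            raise KeyError(f"QC table missing required field {col!r}")
    low_tss = qc["tss_enrichment"] < t.min_tss_enrichment
    low_frag = qc["n_fragments"] < t.min_fragments
    high_reads = qc["n_reads"] > t.max_reads
    rule = pd.Series("", index=qc.index, dtype=object)
    rule[high_reads] = "high_reads"
    rule[low_frag] = "low_fragments"
    rule[low_tss] = "low_tss"  # highest priority written last
    removed = rule != ""
    report = pd.DataFrame(
        {
            "tss_enrichment": qc.loc[removed, "tss_enrichment"],
            "n_fragments": qc.loc[removed, "n_fragments"],
            "n_reads": qc.loc[removed, "n_reads"],
            "rule": rule[removed],
        }
    )
    return qc.index[~removed], report


# -- LSI -------------------------------------------------------------------

@dataclass
class LsiResult:
    embedding: pd.DataFrame  # cells x retained components
    correlations: pd.Series  # per component |r| with cell depth
    excluded: list[str]
    singular_values: np.ndarray


def lsi_embed(
    matrix: CountMatrix,
    n_components: int = 30,
    depth_corr_cutoff: float = 0.75,
    binarize: bool = True,
    seed: int = 0,
) -> LsiResult:
    """TF-IDF + truncated SVD with exclusion of depth-correlated components.

    Counts are binarized by default (the usual treatment of
    near-binary accessibility data). Term frequency is the peak value
    over the cell total; the inverse document frequency is
    log(1 + N / (1 + df_p)) with df_p the number of cells in which the
    peak is open. Any component whose absolute Pearson correlation with
    per-cell total *counts* exceeds ``depth_corr_cutoff`` is dropped
    from the returned embedding (the standard guard against the
    sequencing-depth component).
    """
    n_cells, n_peaks = matrix.shape
    if n_components >= min(n_cells, n_peaks):
        raise ValueError("n_components must be < min(n_cells, n_peaks)")
    totals = matrix.cell_totals().astype(float)
    if np.any(totals == 0):
        raise ValueError("cells with zero counts must be filtered before LSI")
    X = (matrix.X > 0).astype(float) if binarize else matrix.X.astype(float)
    row_sums = np.asarray(X.sum(axis=1)).ravel()
    tf = X.multiply(1.0 / row_sums[:, None]).tocsr()
    df = np.asarray((X > 0).sum(axis=0)).ravel()
    idf = np.log1p(n_cells / (1.0 + df))
    tfidf = tf.multiply(idf[None, :]).tocsr()

    svd = TruncatedSVD(n_components=n_components, algorithm="arpack", random_state=seed)
    emb = svd.fit_transform(tfidf)

    corrs = np.zeros(n_components)
    if np.ptp(totals) > 0:
        for k in range(n_components):
            if np.ptp(emb[:, k]) > 0:
                corrs[k] = np.corrcoef(emb[:, k], totals)[0, 1]
    names = [f"LSI{k + 1}" for k in range(n_components)]
    keep = np.abs(corrs) <= depth_corr_cutoff
    excluded = [n for n, k in zip(names, keep) if not k]
    embedding = pd.DataFrame(emb[:, keep], index=matrix.cells, columns=np.array(names)[keep])
    return LsiResult(
        embedding=embedding,
        correlations=pd.Series(corrs, index=names, name="depth_correlation"),
        excluded=excluded,
        singular_values=svd.singular_values_,
    )


# -- motif matching --------------------------------------------------------

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


def read_jaspar(path: str) -> dict[str, np.ndarray]:
    """Parse a JASPAR-format PWM file into name -> 4 x L count matrices."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = {}
    for m in parsed:
        out[m.name or m.matrix_id] = np.array([m.counts[b] for b in _BASES], dtype=float)
    return out


def _pwm_threshold(logodds: np.ndarray, background: np.ndarray, pvalue: float, eps: float = 1e-3) -> float:
    """Exact score threshold at the given single-position match p-value.

    Convolves the per-column score distributions under the 0-order
    background on an ``eps`` grid and returns the smallest score whose
    upper-tail probability is <= pvalue.
    """
    scores = np.round(logodds / eps).astype(np.int64)  # 4 x L integer grid
    cur = np.array([1.0])
    cur_lo = 0
    for c in range(scores.shape[1]):
        col = scores[:, c]
        new_lo = cur_lo + int(col.min())
        new_hi = cur_lo + len(cur) - 1 + int(col.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            shift = cur_lo + int(col[b]) - new_lo
            new[shift : shift + len(cur)] += background[b] * cur
        cur, cur_lo = new, new_lo
    tail = np.cumsum(cur[::-1])[::-1]  # P(S >= grid point)
    above = np.flatnonzero(tail <= pvalue)
    if above.size == 0:
        return (cur_lo + len(cur)) * eps  # unattainable: no position can match
    return (cur_lo + above[0]) * eps


def _scan_sequence(seq: str, logodds: np.ndarray) -> float:
    """Maximum log-odds score over positions of one strand; -inf if too short."""
    L = logodds.shape[1]
    idx = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(idx.shape, -1, dtype=np.int64)
    for b, base in enumerate(_BASES):
        code[idx == ord(base)] = b
    n = len(seq) - L + 1
    if n <= 0:
        return -np.inf
    best = -np.inf
    col = np.arange(L)
    for start in range(n):
        window = code[start : start + L]
        if np.any(window < 0):  # ambiguous base
            continue
        s = logodds[window, col].sum()
        if s > best:
            best = s
    return best


def match_motifs(
    pwms: Mapping[str, np.ndarray] | None = None,
    sequences: Mapping[str, str] | None = None,
    incidence: pd.DataFrame | None = None,
    pvalue: float = 5e-5,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.1,
    motif_to_gene: Mapping[str, list[str]] | None = None,
) -> MotifAnnotation:
    """Annotate peaks with motif hits by log-odds scanning, or pass through.

    When ``incidence`` is given it is wrapped unchanged. Otherwise every
    PWM is scanned against every peak sequence on both strands against a
    0-order background (estimated from the sequences' base composition
    when not supplied); a peak is a hit when the best position score
    reaches the exact score threshold at the given match p-value.
    """
    if incidence is not None:
        return MotifAnnotation(incidence, dict(motif_to_gene or {}))
    if pwms is None or sequences is None:
        raise ValueError("either incidence or (pwms, sequences) must be provided")

    if background is None:
        comp = np.zeros(4)
        for seq in sequences.values():
            for b, base in enumerate(_BASES):
                comp[b] += seq.upper().count(base)
        background = comp / comp.sum() if comp.sum() else np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    background = background / background.sum()

    peak_ids = pd.Index(sequences.keys())
    hits = {}
    for name, pwm in pwms.items():
        pwm = np.asarray(pwm, dtype=float)
        if pwm.shape[0] != 4:
            raise ValueError(f"PWM {name!r} must have 4 rows (ACGT)")
        colsum = pwm.sum(axis=0)
        if np.any(colsum == 0):
            raise ValueError(f"PWM {name!r} has a zero column sum")
        prob = (pwm + pseudocount) / (colsum + 4 * pseudocount)
        logodds = np.log2(prob / background[:, None])
        thr = _pwm_threshold(logodds, background, pvalue)
        col = np.zeros(len(peak_ids), dtype=bool)
        for i, pid in enumerate(peak_ids):
            seq = sequences[pid]
            fwd = _scan_sequence(seq, logodds)
            rev = _scan_sequence(seq.translate(_COMP)[::-1], logodds)
            col[i] = max(fwd, rev) >= thr
        hits[name] = col
    return MotifAnnotation(
        pd.DataFrame(hits, index=peak_ids), dict(motif_to_gene or {})
    )


# -- background sampling and deviations ------------------------------------

def sample_background_peaks(
    peaks: pd.DataFrame,
    n_iterations: int = 50,
    n_neighbors: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """GC/accessibility-matched background peaks.

    For each peak, samples ``n_iterations`` peaks (with replacement)
    from its ``n_neighbors`` nearest neighbors in the standardized
    (GC fraction, mean accessibility) plane. Returns an integer array of
    shape (n_peaks, n_iterations) of peak positions.
    """
    n = len(peaks)
    if n < 2:
        raise ValueError("need at least 2 peaks to sample backgrounds")
    feats = peaks[["gc", "mean_accessibility"]].to_numpy(dtype=float)
    constant = np.ptp(feats, axis=0) == 0
    rng = np.random.default_rng(seed)
    if constant.all():
        # indistinguishable peaks: uniform sample of the whole set
        return rng.integers(0, n, size=(n, n_iterations))
    sd = feats.std(axis=0)
    std = (feats - feats.mean(axis=0)) / np.where(constant, 1.0, sd)
    k = min(n_neighbors, n)
    if k < n_neighbors:
        warnings.warn(
            f"only {n} peaks available; background neighbor pool shrunk to {k}",
            stacklevel=2,
        )
    nn = NearestNeighbors(n_neighbors=k).fit(std)
    _, idx = nn.kneighbors(std)
    sel = rng.integers(0, k, size=(n, n_iterations))
    return idx[np.arange(n)[:, None], sel]


def _annotation_deviations(
    counts: sp.csc_matrix,
    totals: np.ndarray,
    peak_totals: np.ndarray,
    grand: float,
    peak_set: np.ndarray,
    backgrounds: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw deviation and z-score vectors (per cell) for one peak set."""
    frac = peak_totals[peak_set].sum() / grand
    expected = totals * frac
    observed = np.asarray(counts[:, peak_set].sum(axis=1)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(expected > 0, (observed - expected) / expected, np.nan)

    n_bg = backgrounds.shape[1]
    bg_idx = backgrounds[peak_set, :]  # |S| x B
    # indicator matrix peaks x B carrying sampling multiplicities
    ind = sp.coo_matrix(
        (
            np.ones(bg_idx.size),
            (bg_idx.ravel(order="F"), np.repeat(np.arange(n_bg), len(peak_set))),
        ),
        shape=(counts.shape[1], n_bg),
    ).tocsc()
    obs_bg = np.asarray((counts @ ind).todense())  # cells x B
    frac_bg = peak_totals @ ind / grand  # length B
    exp_bg = totals[:, None] * frac_bg[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_bg = np.where(exp_bg > 0, (obs_bg - exp_bg) / exp_bg, np.nan)
        mean_bg = np.nanmean(raw_bg, axis=1)
        sd_bg = np.nanstd(raw_bg, axis=1, ddof=1)
        z = np.where(sd_bg > 0, (raw - mean_bg) / sd_bg, np.nan)
    return raw, z


def compute_deviations(
    matrix: CountMatrix,
    annotation: MotifAnnotation,
    backgrounds: np.ndarray,
) -> DeviationResult:
    """chromVAR-style accessibility deviations for every motif.

    ``backgrounds`` comes from :func:`sample_background_peaks` and must
    index peaks in the order of ``matrix.features``.
    """
    if annotation.incidence.shape[1] == 0:
        raise ValueError("annotation contains no motifs")
    inc = annotation.incidence.reindex(matrix.features, fill_value=False)
    counts = matrix.X.tocsc().astype(float)
    totals = matrix.cell_totals().astype(float)
    peak_totals = matrix.feature_totals().astype(float)
    grand = peak_totals.sum()
    if grand == 0:
        raise ValueError("empty count matrix")

    raw_rows, z_rows = [], []
    for motif in inc.columns:
        peak_set = np.flatnonzero(inc[motif].to_numpy())
        if peak_set.size == 0:
            raw_rows.append(np.full(matrix.n_cells, np.nan))
            z_rows.append(np.full(matrix.n_cells, np.nan))
            continue
        raw, z = _annotation_deviations(counts, totals, peak_totals, grand, peak_set, backgrounds)
        raw_rows.append(raw)
        z_rows.append(z)
    raw_df = pd.DataFrame(raw_rows, index=inc.columns, columns=matrix.cells)
    z_df = pd.DataFrame(z_rows, index=inc.columns, columns=matrix.cells)
    return DeviationResult(raw=raw_df, z=z_df, motif_to_gene=dict(annotation.motif_to_gene))


# -- differential accessibility --------------------------------------------

def differential_flag(
    fdr, log2fc, fdr_threshold: float = 0.05, lfc_threshold: float = 0.5
):
    """The compound differential-region rule: FDR < 0.05 AND |log2FC| >= 0.5."""
    return (np.asarray(fdr) < fdr_threshold) & (np.abs(log2fc) >= lfc_threshold)


def differential_peaks(
    matrix: CountMatrix,
    labels: pd.Series | Sequence,
    group,
    reference=None,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 0.5,
    scale_total: float = 1e4,
) -> pd.DataFrame:
    """Rank-sum differential accessibility on depth-normalized counts.

    A peak is flagged differential when FDR < ``fdr_threshold`` and
    |log2 fold change| >= ``lfc_threshold`` (pseudocount 1 on the
    normalized group means).
    """
    labels = pd.Series(np.asarray(labels), index=matrix.cells)
    in_group = (labels == group).to_numpy()
    in_ref = np.ones(len(labels), dtype=bool) & ~in_group if reference is None else (labels == reference).to_numpy()
    if in_group.sum() < 2 or in_ref.sum() < 2:
        raise ValueError("both groups need at least 2 cells")
    totals = matrix.cell_totals().astype(float)
    norm = matrix.X.multiply(scale_total / np.maximum(totals, 1)[:, None]).tocsr()
    a = np.asarray(norm[in_group].todense())
    b = np.asarray(norm[in_ref].todense())

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided", method="auto")
        pvals = np.asarray(res.pvalue, dtype=float)
    constant = np.array([np.ptp(np.concatenate([a[:, j], b[:, j]])) == 0 for j in range(a.shape[1])])
    pvals[constant | ~np.isfinite(pvals)] = 1.0
    lfc = np.log2(a.mean(axis=0) + 1.0) - np.log2(b.mean(axis=0) + 1.0)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "p_value": pvals,
            "fdr": fdr,
            "differential": differential_flag(fdr, lfc, fdr_threshold, lfc_threshold),
        },
        index=matrix.features,
    )
    return out.sort_values("log2_fold_change", ascending=False)


# -- motif retention and enrichment ----------------------------------------

def retain_motifs(
    dev: DeviationResult,
    expr_by_type: pd.DataFrame,
    gene_scores: pd.DataFrame,
    cell_labels: pd.Series,
    min_expression: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Expression and correlation filter on motifs, per cell type.

    A motif is retained for a cell type when (i) its mapped gene's
    normalized average expression in that type exceeds
    ``min_expression`` and (ii) the Spearman correlation between its
    per-cell deviation z-scores and its per-cell gene-activity scores,
    within cells of the type, is positive with BH-FDR < ``alpha``
    (one-sided test for positive association, adjusted across motifs
    within the type).
    """
    cell_labels = cell_labels.reindex(dev.cells)
    rows = []
    for ctype in pd.unique(cell_labels.dropna()):
        cells = dev.cells[(cell_labels == ctype).to_numpy()]
        recs = []
        for motif in dev.motifs:
            genes = [g for g in dev.motif_to_gene.get(motif, []) if g in expr_by_type.index]
            if not genes:
                warnings.warn(f"motif {motif!r}: mapped gene absent from expression table", stacklevel=2)
                recs.append((motif, np.nan, np.nan, np.nan))
                continue
            expr = float(expr_by_type.loc[genes, ctype].max())
            if motif not in gene_scores.columns:
                warnings.warn(f"motif {motif!r}: no gene-activity scores", stacklevel=2)
                recs.append((motif, expr, np.nan, np.nan))
                continue
            z = dev.z.loc[motif, cells].to_numpy(dtype=float)
            gs = gene_scores.loc[cells, motif].to_numpy(dtype=float)
            ok = np.isfinite(z) & np.isfinite(gs)
            if ok.sum() < 3 or np.ptp(z[ok]) == 0 or np.ptp(gs[ok]) == 0:
                recs.append((motif, expr, np.nan, np.nan))
                continue
            rho, p = stats.spearmanr(z[ok], gs[ok], alternative="greater")
            recs.append((motif, expr, rho, p))
        df = pd.DataFrame(recs, columns=["motif", "expression", "rho", "p_value"])
        df["cell_type"] = ctype
        valid = df["p_value"].notna()
        df["fdr"] = np.nan
        if valid.any():
            df.loc[valid, "fdr"] = multipletests(df.loc[valid, "p_value"], method="fdr_bh")[1]
        df["retained"] = (
            (df["expression"] > min_expression)
            & (df["rho"] > 0)
            & (df["fdr"] < alpha)
        ).fillna(False)
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    return out[["motif", "cell_type", "expression", "rho", "p_value", "fdr", "retained"]]


def celltype_motif_enrichment(
    dev: DeviationResult,
    cell_labels: pd.Series,
    z_threshold: float = 0.0,
    adj_threshold: float = 1e-20,
) -> pd.DataFrame:
    """Hypergeometric enrichment of motif accessibility within cell types.

    Cells are called accessible for a motif when the deviation z-score
    exceeds ``z_threshold``; for each motif and cell type, the
    upper-tail hypergeometric probability of the observed overlap
    between accessible cells and the type's cells (in the universe of
    all cells) is computed, BH-adjusted across all motif x type tests,
    and flagged at ``adj_threshold``.
    """
    cell_labels = cell_labels.reindex(dev.cells)
    types = pd.unique(cell_labels.dropna())
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    N = len(dev.cells)
    rows = []
    for motif in dev.motifs:
        z = dev.z.loc[motif].to_numpy(dtype=float)
        accessible = np.where(np.isfinite(z), z > z_threshold, False)
        K = int(accessible.sum())
        for ctype in types:
            members = (cell_labels == ctype).to_numpy()
            n = int(members.sum())
            if n == 0:
                raise ValueError(f"cell type {ctype!r} is empty")
            k = int((accessible & members).sum())
            p = stats.hypergeom.sf(k - 1, N, K, n)
            rows.append((motif, ctype, k, K, n, N, p))
    out = pd.DataFrame(
        rows, columns=["motif", "cell_type", "overlap", "n_accessible", "n_type", "n_cells", "p_value"]
    )
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["enriched"] = out["fdr"] < adj_threshold
    return out
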