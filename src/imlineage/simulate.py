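"""Synthetic scRNA and scATAC data with known ground truth.

The RNA generator draws negative-binomial counts (gamma-Poisson mixture)
for five cell populations: basal, two luminal subtypes (L1, L2), an
intermediate population expressing BOTH the basal and the luminal core
program, and a non-epithelial contaminant that lacks the Epcam gating
gene. The ATAC generator draws peak-by-cell fragment counts with
per-cell depth variation, per-peak GC content, Bernoulli motif
annotations, and an optional cooperativity effect: peaks carrying both
an ETS-family motif and a chosen partner motif are boosted in one target
cell type only.

Everything is deterministic given the config seed, and every generated
cell and peak has a ground-truth record, so downstream QC, clustering,
mixture-model and cooperativity code can be tested against planted
structure.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .atac import ETS_PREFIXES, MotifAnnotation
from .matrix import CountMatrix

__all__ = [
    "RnaSimConfig",
    "AtacSimConfig",
    "Cooperativity",
    "SyntheticTruth",
    "RnaDataset",
    "AtacDataset",
    "generate_rna",
    "generate_atac",
    "simulate_gene_scores",
    "write_rna_dataset",
    "write_atac_dataset",
]

RNA_TYPES = ("basal", "lumL1", "lumL2", "intermediate", "nonepithelial")
ATAC_TYPES = ("basal", "luminal", "intermediate")

#: gene programs each simulated RNA cell type switches on
_TYPE_PROGRAMS = {
    "basal": ("basal",),
    "lumL1": ("luminal", "l1"),
    "lumL2": ("luminal", "l2"),
    "intermediate": ("basal", "luminal"),
    "nonepithelial": ("nonepi",),
}


@dataclass
class RnaSimConfig:
    """Parameters of the RNA count simulator.

    ``planted_bad_cells`` maps QC-rule names (``low_count``,
    ``high_count``, ``high_mito``) to the number of extra cells violating
    exactly that rule; each planted cell violates one rule only.
    """

    n_cells_per_type: Mapping[str, int] = field(
        default_factory=lambda: {
            "basal": 500,
            "lumL1": 500,
            "lumL2": 300,
            "intermediate": 200,
            "nonepithelial": 300,
        }
    )
    n_genes: int = 2000
    marker_genes_per_program: int = 50
    program_logfc: float = 2.0  # log2 fold change of program genes over baseline
    baseline_mean: float = 1.0  # mean counts per gene per cell at depth 1
    dispersion: float = 0.3  # NB dispersion a: var = mu + a mu^2
    gene_lognormal_sigma: float = 0.5  # spread of per-gene baseline abundance
    mito_gene_count: int = 13
    mito_baseline_fraction: float = 0.05
    epcam_mean: float = 5.0  # Epcam mean counts in epithelial cells
    depth_lognormal_sigma: float = 0.35
    intermediate_attenuation: float = 1.0  # scales program_logfc in intermediate cells
    planted_bad_cells: Mapping[str, int] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or any(n < 0 for n in self.n_cells_per_type.values()):
            raise ValueError("non-positive dimensions")
        unknown = set(self.n_cells_per_type) - set(RNA_TYPES)
        if unknown:
            raise ValueError(f"unknown cell types: {sorted(unknown)}")
        n_special = 1 + 5 * self.marker_genes_per_program + self.mito_gene_count
        if n_special > self.n_genes:
            raise ValueError(
                f"program genes + mito genes + Epcam ({n_special}) exceed n_genes ({self.n_genes})"
            )
        bad = set(self.planted_bad_cells) - {"low_count", "high_count", "high_mito"}
        if bad:
            raise ValueError(f"unknown planted QC rules: {sorted(bad)}")
        if self.baseline_mean <= 0 or self.dispersion < 0:
            raise ValueError("baseline_mean must be > 0 and dispersion >= 0")


@dataclass
class Cooperativity:
    """A planted accessibility boost on peaks carrying partner AND ETS motifs."""

    partner: str
    cell_type: str = "intermediate"
    boost: float = 3.0

    def validate(self, catalog: Sequence[str], cell_types: Sequence[str]) -> None:
        if self.partner not in catalog:
            raise ValueError(f"cooperativity partner {self.partner!r} not in motif catalog")
        if self.cell_type not in cell_types:
            raise ValueError(f"cooperativity cell type {self.cell_type!r} not simulated")
        if self.boost < 1:
            raise ValueError("cooperativity boost must be >= 1")


@dataclass
class AtacSimConfig:
    n_cells_per_type: Mapping[str, int] = field(
        default_factory=lambda: {"basal": 300, "luminal": 400, "intermediate": 300}
    )
    n_peaks: int = 2000
    gc_beta_params: tuple[float, float] = (5.0, 5.0)
    motif_catalog: tuple[str, ...] = (
        "ERG",
        "ETV1",
        "FLI1",
        "NFKB2",
        "NFATC1",
        "STAT3",
        "KLF5",
        "GATA2",
        "FOXA1",
        "SOX9",
        "GRHL2",
        "CEBPB",
    )
    motif_peak_prob: float = 0.15
    cooperativity: Optional[Cooperativity] = None
    peak_mean: float = 1.0  # mean fragments per peak per cell at depth 1
    dispersion: float = 0.5  # gamma spread of per-peak base rates
    frac_type_specific: float = 0.3
    type_logfc: float = 1.0  # log2 boost of a type-specific peak in its own type
    depth_range: tuple[float, float] = (0.8, 2.5)  # log-uniform per-cell depth
    tss_mean: float = 8.0
    tss_sd: float = 1.5
    tss_floor: float = 4.5  # keep un-planted cells clear of the TSS<4 rule
    planted_bad_cells: Mapping[str, int] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_peaks <= 0 or any(n < 0 for n in self.n_cells_per_type.values()):
            raise ValueError("non-positive dimensions")
        if not all(a > 0 for a in self.gc_beta_params):
            raise ValueError("gc_beta_params must be positive")
        if not any(m.upper().startswith(ETS_PREFIXES) for m in self.motif_catalog):
            raise ValueError("motif catalog must contain at least one ETS-family motif")
        if self.cooperativity is not None:
            self.cooperativity.validate(self.motif_catalog, tuple(self.n_cells_per_type))
        bad = set(self.planted_bad_cells) - {"low_tss", "low_fragments", "high_reads"}
        if bad:
            raise ValueError(f"unknown planted QC rules: {sorted(bad)}")


@dataclass
class SyntheticTruth:
    """Ground truth for one generated dataset.

    cell_labels maps every cell to its true type; planted_violations is
    "none" except for cells generated to break exactly one QC rule.
    """

    cell_labels: pd.Series
    planted_violations: pd.Series
    config: dict
    depth: pd.Series
    gene_sets: dict[str, list[str]] | None = None
    gene_base_mean: pd.Series | None = None  # per-gene mean at depth 1 (baseline, no program)
    peak_motifs: MotifAnnotation | None = None
    coop_peaks: pd.Index | None = None  # peaks carrying partner AND ETS motifs
    peak_rate: pd.Series | None = None  # per-peak Poisson base rate at depth 1
    peak_specific_type: pd.Series | None = None  # "" for shared peaks


@dataclass
class RnaDataset:
    matrix: CountMatrix
    qc: pd.DataFrame
    truth: SyntheticTruth

    def __iter__(self):
        return iter((self.matrix, self.qc, self.truth))


@dataclass
class AtacDataset:
    matrix: CountMatrix
    qc: pd.DataFrame
    peaks: pd.DataFrame
    annotation: MotifAnnotation
    truth: SyntheticTruth

    def __iter__(self):
        return iter((self.matrix, self.qc, self.peaks, self.annotation, self.truth))


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    lam = np.zeros_like(mu)
    pos = mu > 0
    lam[pos] = rng.gamma(1.0 / dispersion, dispersion * mu[pos])
    return rng.poisson(lam)


def _config_echo(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    d["n_cells_per_type"] = dict(d["n_cells_per_type"])
    d["planted_bad_cells"] = dict(d["planted_bad_cells"])
    return d


def generate_rna(config: RnaSimConfig) -> RnaDataset:
    """Simulate an RNA count matrix with planted programs and QC violations."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.marker_genes_per_program
    n_mito = config.mito_gene_count

    # gene layout: Epcam, 5 marker programs, background, mito genes last
    gene_sets = {
        "basal": [f"bas_g{i:03d}" for i in range(m)],
        "luminal": [f"lum_g{i:03d}" for i in range(m)],
        "l1": [f"l1_g{i:03d}" for i in range(m)],
        "l2": [f"l2_g{i:03d}" for i in range(m)],
        "nonepi": [f"ne_g{i:03d}" for i in range(m)],
    }
    mito_genes = [f"mt-g{i:02d}" for i in range(n_mito)]
    n_bg = config.n_genes - 1 - 5 * m - n_mito
    bg_genes = [f"g{i:04d}" for i in range(n_bg)]
    genes = (
        ["Epcam"]
        + sum((gene_sets[k] for k in ("basal", "luminal", "l1", "l2", "nonepi")), [])
        + bg_genes
        + mito_genes
    )
    gene_index = pd.Index(genes)

    # relative baseline abundance; mito genes pinned to the target baseline share
    rel = rng.lognormal(0.0, config.gene_lognormal_sigma, size=config.n_genes)
    rel[0] = config.epcam_mean / config.baseline_mean
    f = config.mito_baseline_fraction
    mito_slice = slice(config.n_genes - n_mito, config.n_genes)
    rel[mito_slice] = f / (1 - f) * rel[: config.n_genes - n_mito].sum() / n_mito
    base_mean = config.baseline_mean * rel  # per-gene mean at depth 1, no program

    gene_pos = {g: i for i, g in enumerate(genes)}
    program_pos = {k: np.array([gene_pos[g] for g in v]) for k, v in gene_sets.items()}

    # per-type fold-change vectors
    fold = {}
    for t in RNA_TYPES:
        fv = np.ones(config.n_genes)
        eff = config.program_logfc
        if t == "intermediate":
            eff = config.program_logfc * config.intermediate_attenuation
        for prog in _TYPE_PROGRAMS[t]:
            fv[program_pos[prog]] = 2.0 ** eff
        if t == "nonepithelial":
            fv[0] = 0.0  # no Epcam
        fold[t] = fv

    labels, blocks, depths = [], [], []
    for t in RNA_TYPES:
        n = config.n_cells_per_type.get(t, 0)
        if n == 0:
            continue
        depth = rng.lognormal(0.0, config.depth_lognormal_sigma, size=n)
        mu = depth[:, None] * (base_mean * fold[t])[None, :]
        blocks.append(_nb_counts(rng, mu, config.dispersion))
        labels.extend([t] * n)
        depths.append(depth)

    # planted QC violations: each extra cell breaks exactly one rule
    epi_types = [t for t in RNA_TYPES if t != "nonepithelial"]
    typical_total = base_mean.sum()  # expected depth-1 total, programs aside
    bad_rows, bad_ids, bad_rules, bad_labels = [], [], [], []
    for rule, count in sorted(config.planted_bad_cells.items()):
        for k in range(count):
            t = epi_types[k % len(epi_types)]
            probs = base_mean * fold[t]
            probs = probs / probs.sum()
            if rule == "low_count":
                total = int(rng.integers(100, 500))
                row = rng.multinomial(total, probs)
            elif rule == "high_count":
                total = int(rng.integers(120_000, 200_001))
                row = rng.multinomial(total, probs)
            else:  # high_mito: normal depth, mito share pushed past 40%
                total = int(np.clip(rng.poisson(typical_total), 600, 90_000))
                frac = rng.uniform(0.45, 0.75)
                n_mt = int(round(frac * total))
                p_mt = probs[mito_slice] / probs[mito_slice].sum()
                p_rest = probs.copy()
                p_rest[mito_slice] = 0
                p_rest /= p_rest.sum()
                row = rng.multinomial(total - n_mt, p_rest)
                row[mito_slice] += rng.multinomial(n_mt, p_mt)
            bad_rows.append(row)
            bad_ids.append(f"bad_{rule}_{k:03d}")
            bad_rules.append(rule)
            bad_labels.append(t)

    counts = np.vstack(blocks) if blocks else np.empty((0, config.n_genes), dtype=np.int64)
    if bad_rows:
        counts = np.vstack([counts, np.array(bad_rows)])
    cell_ids = [f"c{i:05d}" for i in range(sum(len(b) for b in blocks))] + bad_ids
    labels = labels + bad_labels
    depth_all = np.concatenate(depths + [np.ones(len(bad_rows))]) if depths or bad_rows else np.array([])

    matrix = CountMatrix(sp.csr_matrix(counts), cell_ids, gene_index)
    totals = matrix.cell_totals()
    mito_counts = np.asarray(matrix.X[:, np.arange(config.n_genes)[mito_slice]].sum(axis=1)).ravel()
    violations = pd.Series("none", index=matrix.cells, name="planted_violation")
    violations.iloc[len(violations) - len(bad_rules) :] = bad_rules
    label_s = pd.Series(labels, index=matrix.cells, name="true_label")
    qc = pd.DataFrame(
        {
            "total_counts": totals,
            "mito_fraction": np.divide(mito_counts, totals, out=np.zeros_like(totals, dtype=float), where=totals > 0),
            "true_label": label_s,
            "planted_violation": violations,
        },
        index=matrix.cells,
    )
    truth = SyntheticTruth(
        cell_labels=label_s,
        planted_violations=violations,
        config=_config_echo(config),
        depth=pd.Series(depth_all, index=matrix.cells, name="depth"),
        gene_sets={**gene_sets, "mito": mito_genes, "epcam": ["Epcam"]},
        gene_base_mean=pd.Series(base_mean, index=gene_index, name="base_mean"),
    )
    return RnaDataset(matrix, qc, truth)


def generate_atac(config: AtacSimConfig) -> AtacDataset:
    """Simulate a peak-by-cell fragment count matrix with motif annotations."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_peaks = config.n_peaks
    peak_ids = pd.Index([f"peak_{i:05d}" for i in range(n_peaks)])
    motifs = list(config.motif_catalog)

    gc = rng.beta(*config.gc_beta_params, size=n_peaks)
    incidence = pd.DataFrame(
        rng.random((n_peaks, len(motifs))) < float(config.motif_peak_prob),
        index=peak_ids,
        columns=motifs,
    )
    annotation = MotifAnnotation(incidence, {name: [name] for name in motifs})
    is_ets = incidence.loc[:, [m for m in motifs if m.upper().startswith(ETS_PREFIXES)]].any(axis=1)

    # per-peak base rates; a gamma multiplier links GC loosely to accessibility
    rate = config.peak_mean * rng.gamma(1.0 / config.dispersion, config.dispersion, size=n_peaks)

    # a subset of peaks is more open in one cell type
    cell_types = [t for t in config.n_cells_per_type if config.n_cells_per_type[t] > 0]
    specific_type = np.full(n_peaks, "", dtype=object)
    spec_mask = rng.random(n_peaks) < config.frac_type_specific
    specific_type[spec_mask] = rng.choice(cell_types, size=spec_mask.sum())

    coop = config.cooperativity
    coop_mask = np.zeros(n_peaks, dtype=bool)
    if coop is not None:
        coop_mask = (incidence[coop.partner].to_numpy() & is_ets.to_numpy())

    lo, hi = config.depth_range
    labels, blocks, depths = [], [], []
    for t in cell_types:
        n = config.n_cells_per_type[t]
        depth = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
        mu = depth[:, None] * rate[None, :]
        boost = np.ones(n_peaks)
        boost[specific_type == t] = 2.0 ** config.type_logfc
        if coop is not None and t == coop.cell_type:
            boost = boost * np.where(coop_mask, coop.boost, 1.0)
        blocks.append(rng.poisson(mu * boost[None, :]))
        labels.extend([t] * n)
        depths.append(depth)

    # planted QC violations
    bad_rows, bad_ids, bad_rules, bad_labels, bad_tss, bad_reads = [], [], [], [], [], []
    probs = rate / rate.sum()
    for rule, count in sorted(config.planted_bad_cells.items()):
        for k in range(count):
            t = cell_types[k % len(cell_types)]
            if rule == "low_fragments":
                total = int(rng.integers(200, 1000))
                row = rng.multinomial(total, probs)
            else:
                row = rng.poisson(rate)
            bad_rows.append(row)
            bad_ids.append(f"bad_{rule}_{k:03d}")
            bad_rules.append(rule)
            bad_labels.append(t)
            bad_tss.append(rng.uniform(1.0, 3.9) if rule == "low_tss" else None)
            bad_reads.append(rng.uniform(1.2e6, 2.5e6) if rule == "high_reads" else None)

    counts = np.vstack(blocks) if blocks else np.empty((0, n_peaks), dtype=np.int64)
    if bad_rows:
        counts = np.vstack([counts, np.array(bad_rows)])
    cell_ids = [f"a{i:05d}" for i in range(sum(len(b) for b in blocks))] + bad_ids
    labels = labels + bad_labels
    depth_all = np.concatenate(depths + [np.ones(len(bad_rows))]) if depths or bad_rows else np.array([])

    matrix = CountMatrix(sp.csr_matrix(counts), cell_ids, peak_ids)
    totals = matrix.cell_totals().astype(float)

    # QC scalars: TSS enrichment simulated directly, reads ~ 2x fragments
    n_cells = matrix.n_cells
    tss = config.tss_mean + config.tss_sd * rng.standard_normal(n_cells)
    tss = np.maximum(tss, config.tss_floor)
    reads = totals * rng.uniform(1.6, 2.4, size=n_cells)
    offset = n_cells - len(bad_rules)
    for j, (t_override, r_override) in enumerate(zip(bad_tss, bad_reads)):
        if t_override is not None:
            tss[offset + j] = t_override
        if r_override is not None:
            reads[offset + j] = r_override

    violations = pd.Series("none", index=matrix.cells, name="planted_violation")
    violations.iloc[offset:] = bad_rules
    label_s = pd.Series(labels, index=matrix.cells, name="true_label")
    qc = pd.DataFrame(
        {
            "tss_enrichment": tss,
            "n_fragments": totals.astype(int),
            "n_reads": np.round(reads).astype(int),
            "true_label": label_s,
            "planted_violation": violations,
        },
        index=matrix.cells,
    )

    grand = matrix.feature_totals().sum()
    peaks = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_peaks) * 1000,
            "end": np.arange(n_peaks) * 1000 + 500,
            "name": peak_ids,
            "gc": gc,
            "mean_accessibility": matrix.feature_totals() / grand if grand > 0 else 0.0,
        },
        index=peak_ids,
    )
    truth = SyntheticTruth(
        cell_labels=label_s,
        planted_violations=violations,
        config=_config_echo(config),
        depth=pd.Series(depth_all, index=matrix.cells, name="depth"),
        peak_motifs=annotation,
        coop_peaks=peak_ids[coop_mask],
        peak_rate=pd.Series(rate, index=peak_ids, name="rate"),
        peak_specific_type=pd.Series(specific_type, index=peak_ids, name="specific_type"),
    )
    return AtacDataset(matrix, qc, peaks, annotation, truth)


def simulate_gene_scores(
    matrix: CountMatrix,
    annotation: MotifAnnotation,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell motif-gene activity scores (cells x motifs).

    A stand-in for fragment-derived gene-activity scores: the
    standardized log mean accessibility of each motif's peaks plus
    Gaussian noise, so a motif's activity tracks its true accessibility.
    """
    rng = np.random.default_rng(seed)
    totals = matrix.cell_totals().astype(float)
    norm = matrix.X.multiply(1e4 / np.maximum(totals, 1)[:, None]).tocsc()
    out = {}
    for motif in annotation.motifs:
        pos = np.flatnonzero(annotation.incidence[motif].to_numpy())
        if pos.size == 0:
            out[motif] = np.zeros(matrix.n_cells)
            continue
        mean_acc = np.log1p(np.asarray(norm[:, pos].mean(axis=1)).ravel())
        sd = mean_acc.std()
        z = (mean_acc - mean_acc.mean()) / (sd if sd > 0 else 1.0)
        out[motif] = z + noise_sd * rng.standard_normal(matrix.n_cells)
    return pd.DataFrame(out, index=matrix.cells)


# -- on-disk layout --------------------------------------------------------

def write_rna_dataset(data: RnaDataset, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    data.matrix.write_mtx_dir(os.path.join(out_dir, "counts"))
    data.qc.to_csv(os.path.join(out_dir, "cell_qc.tsv"), sep="\t")
    pd.DataFrame(
        {"cell": data.truth.cell_labels.index, "true_label": data.truth.cell_labels.values}
    ).to_csv(os.path.join(out_dir, "truth_labels.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "gene_sets.json"), "w") as fh:
        json.dump(data.truth.gene_sets, fh, indent=1)
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump(data.truth.config, fh, indent=1, default=str)


def write_atac_dataset(data: AtacDataset, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    data.matrix.write_mtx_dir(os.path.join(out_dir, "counts"))
    data.qc.to_csv(os.path.join(out_dir, "cell_qc.tsv"), sep="\t")
    # BED: chrom, 0-based half-open start/end, name, GC fraction in score column
    data.peaks[["chrom", "start", "end", "name", "gc"]].to_csv(
        os.path.join(out_dir, "peaks.bed"), sep="\t", header=False, index=False
    )
    data.annotation.incidence.astype(int).to_csv(
        os.path.join(out_dir, "motif_incidence.tsv"), sep="\t"
    )
    with open(os.path.join(out_dir, "motif_genes.json"), "w") as fh:
        json.dump(data.annotation.motif_to_gene, fh, indent=1)
    pd.DataFrame(
        {"cell": data.truth.cell_labels.index, "true_label": data.truth.cell_labels.values}
    ).to_csv(os.path.join(out_dir, "truth_labels.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump(data.truth.config, fh, indent=1, default=str)
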