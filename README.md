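# imlineage

Lineage identity and motif cooperativity for single-cell studies of
ERG-driven prostate cancer.

Prostate epithelium has two principal lineages — basal (Krt5/Trp63)
and luminal (Krt8/Krt18) — and ERG-driven tumors harbor a highly
proliferative *intermediate* population scoring high on **both** marker
programs. `imlineage` provides, for people analyzing such scRNA-seq and
scATAC-seq data:

- **Probabilistic lineage assignment.** Each cell's basal and luminal
  marker-program scores (expression-bin-matched module scores) are
  modeled with a 3-component bivariate Gaussian mixture,

  (s_bas, s_lum) ~ Σ_k π_k · N(μ_k, Σ_k),  k ∈ {basal, luminal, intermediate},

  fitted by EM with components mapped to labels from their mean
  contrasts. Posterior responsibilities give per-cell
  (p_basal, p_luminal, p_intermediate); the hard label is the argmax.

- **Motif cooperativity testing.** A chromVAR-style deviation machine
  — expected accessibility E_ij = T_i Σ_{p∈j} f_p, raw deviation
  (O−E)/E, z-scored against GC/accessibility-matched background peak
  sets — applied to peak partitions: for a candidate motif c, peaks
  carrying *both* c and an ETS-family motif (ERG/ETS/ETV/FLI collapsed
  to one identifier) versus peaks carrying only one. A one-sided
  Wilcoxon rank-sum test of the partition z-scores within a cell
  population asks whether co-occurring sites are more accessible than
  either motif's sites alone.

- The supporting stages: QC filters (RNA: ≥500 and ≤100K transcripts,
  <40% mitochondrial; ATAC: TSS enrichment ≥4, ≥1000 fragments, ≤1M
  reads), Leiden clustering with silhouette-based resolution selection,
  rank-sum differential expression/accessibility with BH-FDR, LSI with
  depth-component exclusion (|r| > 0.75), PWM motif scanning,
  hypergeometric motif × cell-type enrichment, and a synthetic-data
  generator with planted ground truth for every stage.

## Worked example

```python
import numpy as np
import pandas as pd
import imlineage as il

# 1. synthetic RNA data with planted populations; QC and normalization
rna = il.generate_rna(il.RnaSimConfig(seed=0))
counts, report = il.filter_cells_rna(rna.matrix, rna.truth.gene_sets["mito"])
norm = il.normalize_log(counts)

# 2. cluster, then gate epithelial clusters (>=50% Epcam+ cells)
clusters = il.cluster_cells(norm, seed=0)
sets = rna.truth.gene_sets
signatures = pd.DataFrame({
    "basal": il.score_gene_set(norm, sets["basal"], seed=1),
    "L1": il.score_gene_set(norm, sets["luminal"] + sets["l1"], seed=2),
    "L2": il.score_gene_set(norm, sets["luminal"] + sets["l2"], seed=3),
})
epcam = pd.Series(
    np.asarray(counts.X[:, counts.features.get_loc("Epcam")].todense()).ravel() > 0,
    index=counts.cells,
)
gate = il.gate_epithelial(clusters.labels, epcam, signatures, subtypes=("basal", "L1", "L2"))

# 3. fit the lineage mixture on the gated cells
basal = il.score_gene_set(norm, sets["basal"], seed=1)[gate.retained_cells]
luminal = il.score_gene_set(norm, sets["luminal"], seed=2)[gate.retained_cells]
fit = il.LineageMixture(basal, luminal).fit(seed=0)
print(fit.summary())
print(fit.posterior().labels.value_counts().to_string())
```

prints

```
Lineage Gaussian mixture (3 components, full covariance)

component       weight  basal mean  luminal mean
basal            0.333       1.045        -0.411
luminal          0.533      -0.351         0.841
intermediate     0.133       0.963         0.817

log-likelihood: 333.99   n = 1500
label
luminal         800
basal           500
intermediate    200
```

The generator planted 500 basal, 800 luminal (two subtypes) and 200
intermediate epithelial cells: the mixture recovers the populations
exactly, and the intermediate component sits high in *both* scores —
the defining signature of that state.

The cooperativity test on synthetic ATAC data with a planted 3× boost
on peaks carrying both STAT3 and an ETS motif (in intermediate cells
only):

```python
atac = il.generate_atac(il.AtacSimConfig(
    cooperativity=il.Cooperativity("STAT3", "intermediate", 3.0), seed=0))
bg = il.sample_background_peaks(atac.peaks, seed=0)
test = il.CooperativityTest(atac.matrix, atac.annotation, bg, atac.truth.cell_labels)
print(test.fit(candidates=["STAT3", "NFKB2", "NFATC1"], cell_type="intermediate").summary())
```

```
Motif co-accessibility vs ETS (cells: intermediate)

candidate  n_both  n_ets_only  n_candidate_only  median_z_both  median_z_ets_only  p_vs_ets_only  q_vs_ets_only
    STAT3     121         637               182          9.743             -1.589     5.275e-100      1.582e-99
    NFKB2     110         648               162          1.577              3.569              1              1
   NFATC1     119         639               175          1.133              3.765              1              1
```

Only the planted partner is called: its 121 co-occurring peaks are far
more accessible in intermediate cells than its ETS-only comparison set
(BH-adjusted p ≈ 1.6e-99), while the unboosted candidates are not.

## Command line

```bash
imlineage pipeline run --config cfg.yaml        # full RNA + ATAC + cooperativity run
imlineage simulate rna --out data/ --seed 1     # standalone synthetic datasets
imlineage rna qc|cluster|de ...                 # individual stages
imlineage atac qc|lsi|motifs|deviations|diffpeaks|enrich ...
imlineage coaccess --candidates NFKB2,NFATC1,STAT3 --cells intermediate ...
```

`pipeline run` executes every stage from one JSON/YAML config with
per-stage seeds and writes a machine-readable run report (per-stage
counts, every threshold with its provenance). Exit codes: 0 success,
2 config error, 3 stage failure.

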