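# Methods

`imlineage` implements two connected analyses for ERG-driven prostate
cancer single-cell data: (1) probabilistic assignment of epithelial
cells to basal, luminal, or intermediate identity from marker-program
scores, and (2) a chromatin-accessibility workflow that ends in a motif
co-accessibility (TF cooperativity) test against the ETS family. A
synthetic-data generator with known ground truth stands in for raw
mouse data, so every stage has a self-contained test surface.

## RNA quality control and normalization

Cells are removed when they have fewer than 500 transcripts (low
quality), more than 100,000 transcripts (putative multiplets), or 40%
or more mitochondrial reads. Boundaries are deliberate: 500 and 100,000
are retained, a mitochondrial fraction of exactly 0.40 is removed. The
removal report records the first violated rule per cell, checked in the
order low_count, high_count, high_mito, and filtering is idempotent.

Normalization is log1p of counts-per-10,000 (`scale_total`
configurable). A variance-stabilizing transform with covariate
regression would be the more elaborate alternative; the downstream
operations here (gene-set scores, rank-based tests, graph clustering)
depend only on a monotone per-cell-normalized scale, so the simpler
transform is used and stated.

## Gene-set (module) scores

The per-cell score of a gene set is the mean normalized expression of
the set genes minus the mean of expression-matched control genes: genes
are ranked by mean expression and cut into 25 equal-size bins, and each
set gene draws up to 50 controls from its own bin (without replacement,
seeded). Matching on expression level removes the depth/abundance
component that a plain mean would carry. With the set equal to the
whole transcriptome and full-bin controls the score is exactly zero.

## Clustering and resolution selection

Cells are embedded by PCA (default 30 components), connected by a
15-nearest-neighbor graph, and clustered with the Leiden algorithm at
ten resolutions evenly spaced in [0.1, 1.0] (the grid is configurable;
ten values is the stated protocol, the spacing is this package's
choice). Each clustering is scored by the mean silhouette width in the
same PC space; a single-cluster solution has no silhouette and scores
−1. The chosen resolution is the argmax, ties resolving to the lowest
resolution. On well-separated synthetic blobs this selection recovers
the planted cluster count in ≥95% of seeds (checked over 20).

## Differential expression

One-vs-rest two-sample rank-sum tests per gene, one-sided in the
direction of enrichment ("greater"), exact when both groups are small
and tie-free and otherwise the midrank normal approximation with
continuity correction (scipy's policy). Constant genes are assigned
p = 1 by convention. P-values are Benjamini–Hochberg adjusted across
genes within each group and tables are sorted by average log2 fold
change, computed as the difference of mean log-normalized expression
rescaled to log2 units.

## Epithelial gating and the lineage mixture

Clusters with ≥50% Epcam-positive cells are flagged epithelial
(positivity defaults to raw count > 0; the threshold is configurable
because positivity is not otherwise defined). Within flagged clusters
each cell's epithelial subtype is the argmax over its signature scores
(basal/L1/L2/L3 by default; the signature lists are user-supplied, and
the synthetic pipeline uses its three planted programs).

The lineage model is a three-component bivariate Gaussian mixture with
full covariances over per-cell (basal score, luminal score) pairs,
fitted by EM (k-means initialization, best of 10 starts by
log-likelihood, seeded; covariance regularization 1e-6 with one retry
at 1e-4 before failing). The feature space is the 2-D score plane, not
the full marker matrix: the two program scores are the model's
sufficient description of lineage, and the intermediate state is
defined by being high in both. Components are mapped to labels
deterministically from their means: luminal is the component maximizing
(luminal mean − basal mean), basal maximizes the opposite contrast
among the rest, and the remaining component is intermediate. Full
covariances matter because the intermediate component is correlated in
both scores.

Posterior responsibilities give (p_basal, p_luminal, p_intermediate)
per cell; the hard label is the argmax, with exact ties resolved to
intermediate so the rare state is flagged for review rather than
absorbed. For estimating the intermediate *fraction* of a population,
the hard-assignment fraction is the estimator of record: the mixing
weight of the intermediate component is biased upward when EM places a
broad component between blobs, while the hard fraction recovers planted
fractions of 0.02–0.25 within ±0.02 at n = 5000 (checked over 10
seeds).

## ATAC quality control and LSI

Cells are kept when TSS enrichment ≥ 4, unique nuclear fragments
≥ 1000, and total reads ≤ 1,000,000. The embedding is TF-IDF + truncated
SVD (LSI): counts are binarized (accessibility data are near-binary;
binarization also preserves the depth component the next rule must
catch), term frequency is the value over the cell total, and the IDF is
log(1 + N/(1 + df)). Any SVD component whose absolute Pearson
correlation with per-cell total counts exceeds 0.75 is excluded from
the returned embedding and logged; correlation against a constant depth
vector is taken as 0 (nothing excluded). The SVD uses ARPACK for
deterministic, permutation-stable results.

## Motif matching

PWMs (JASPAR text, parsed with Biopython) are column-normalized after a
pseudocount and scanned as log-odds against a 0-order background
(estimated from the scanned sequences' base composition unless given).
The hit threshold is the exact score whose upper-tail probability under
the background is ≤ 5e-5 per position, computed by convolving the
per-column score distributions on a 1e-3 grid. Both strands are
scanned; a uniform PWM can never match. A precomputed peak × motif
incidence matrix can be passed through unchanged, which is how the
synthetic pipeline supplies annotations.

## Accessibility deviations

For a peak set S, the expected accessibility of cell i is
E_i = T_i · Σ_{p∈S} f_p with T_i the cell total and f_p the peak's
fraction of all fragments (computed from the same matrix, so observed
and expected totals agree exactly and the all-peaks annotation has raw
deviation exactly 0). The raw deviation is y_i = (O_i − E_i)/E_i.
Each peak draws 50 background peaks per iteration (default 50
iterations) from its 50 nearest neighbors in the standardized
(GC fraction, mean accessibility) plane; the deviation z-score is y
standardized against the background iterations' deviations (sample sd,
ddof 1). Cells where E = 0 are recorded as missing. With randomly
placed annotations on homogeneous data, z is close to standard normal
(|mean| < 0.1, sd within [0.8, 1.2]). Peaks at the extremes of the GC
distribution necessarily match less well (the neighbor pool is
one-sided there); the typical peak's background mean GC is within 0.05
of its own.

## Differential accessibility, motif retention, enrichment

Differential regions: per-peak rank-sum on depth-normalized (CP10K)
counts, BH across peaks, flagged when FDR < 0.05 AND |log2FC| ≥ 0.5
(group-mean fold change with pseudocount 1). Motif retention per cell
type requires the motif's gene to have normalized average expression
> 1 in that type and a positive Spearman correlation (one-sided,
BH-FDR < 0.05 across motifs within the type) between the motif's
deviation z and its gene-activity score across the type's cells;
constant z or a missing gene drops the motif with a warning.
Gene-activity scores are consumed as an input table (the synthetic
generator supplies a noisy activity proxy); computing them from
fragments is out of scope. Cell-type enrichment binarizes accessibility
at z > 0 (configurable) and computes the upper-tail hypergeometric
probability of the accessible-cell / cell-type overlap, BH-adjusted
across all motif × type tests with the reporting flag at adjusted
p < 1e-20.

## The cooperativity (co-accessibility) test

ETS-family motifs (gene symbols starting with ERG/ETS/ETV/FLI —
prefix matching on the mapped gene, configurable for other databases)
are collapsed into a single "ETS" identifier whose incidence is the
union of the members (idempotent). For each candidate motif c, peaks
split into BOTH (c ∩ ETS), C_ONLY, and ETS_ONLY; each partition is
treated as a pseudo-annotation and scored with the deviation z per
cell, computed over all cells and then subset to the cell population of
interest. Within that subset, a one-sided ("greater") two-sample
rank-sum test compares BOTH z-scores against each exclusive set's
z-scores — BOTH vs ETS_ONLY is the headline comparison, both
directions are reported — and BH adjustment runs across the candidate
motifs within the one cell subset (recorded in the output metadata).
Partitions under 5 peaks skip the test with a logged reason (rank-sum
degeneracy below that).

Calibration and its limits: the test treats the per-cell z-scores of
two peak partitions as exchangeable samples. That holds when, absent a
cooperativity effect, accessibility is homogeneous across the
partitions; under that null the measured type-I error at α = 0.05 is
about 2–5% over 200 independent replicates — mildly conservative,
driven by the slight right-skew of deviations for the smaller (BOTH)
partition and the weak per-cell dependence between partitions. When
peak programs are genuinely cell-type-specific and uncorrelated with
motif content, random differences in how many type-specific peaks land
in each partition shift whole z distributions and inflate the type-I
error well above nominal; this is inherent to comparing partition
z-scores across cells and is the main caveat when interpreting small
p-values on real data. Power: a planted 3× boost on (partner ∩ ETS)
peaks in the intermediate population is detected at adjusted p < 0.01
in ≥9/10 seeds with no false positive among six decoy candidates, and
power is nondecreasing in the boost (checked at 1, 1.5, 2, 3 under the
homogeneous null).

## Synthetic data

RNA: negative-binomial counts via a gamma-Poisson mixture
(var = μ + a·μ², default dispersion a = 0.3), per-gene baseline
abundance log-normal (σ = 0.5) around a mean of 1 count/gene, per-cell
depth log-normal (σ = 0.35). Five populations (default
500/500/300/200/300 cells): basal, two luminal subtypes sharing a
luminal core program plus an L1- or L2-specific program, an
intermediate population expressing BOTH the basal and luminal core
programs at full effect (attenuation configurable), and a
non-epithelial contaminant with its own program and no Epcam
expression. Program genes (50 per program, disjoint) are boosted
2^2 = 4-fold by default. An Epcam-like gating gene (mean 5 in
epithelial cells, 0 in contaminants) and 13 mitochondrial genes pinned
to a 5% baseline share complete the layout. Planted QC violators are
extra cells constructed to break exactly one rule each (fixed-total
multinomials below 500 / above 120,000, or a mitochondrial share drawn
from [0.45, 0.75]); with default parameters no un-planted cell
violates any rule, which the tests rely on — shrunken test configs must
keep expected totals safely above the 500 floor.

ATAC: peak-by-cell Poisson counts with gamma-distributed per-peak base
rates (mean 1 fragment/peak/cell, dispersion 0.5), log-uniform per-cell
depth in [0.8, 2.5], Beta(5,5) per-peak GC, and three populations
(300/400/300). 30% of peaks are 2-fold more accessible in one randomly
assigned type. Motifs (a 12-name catalog with three ETS-family members
and candidate/decoy partners) land on peaks independently at
probability 0.15 each. The optional cooperativity effect multiplies the
rate of peaks carrying both the partner and an ETS motif by the boost
factor, in the target cell type only. TSS enrichment is simulated
directly as a per-cell scalar (the filter consumes only the scalar);
fragments equal in-peak totals and reads are ~2× fragments. What the
generator does not emulate: read-level data, doublets, batch effects,
peak-calling artifacts, chromosomal structure, or motif placement
correlated with sequence content — so passing tests demonstrate the
statistical machinery, not robustness to those real-data features.

## Numerical and design choices

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); same config + seed reproduces
  byte-identical outputs, including pipeline CSVs.
- Exact integer arithmetic for deviation expectations (peak-total
  sums before division) so the all-peaks annotation is exactly zero.
- Rank-sum tests use scipy's exact method for small tie-free samples
  and the corrected normal approximation otherwise; constant inputs
  yield p = 1 rather than NaN.
- The component→label map of the lineage mixture depends only on the
  fitted means, so it is invariant to component ordering and seed.
- Pipeline thresholds echo their provenance ("methods-default" for
  stated protocol rules vs "package-default" for this package's
  choices) in the run report.
- Problem sizes in the test-suite and acceptance checks (e.g. 1000
  cells × 2000 peaks per null replicate, 5000-cell mixture fits) were
  chosen as the smallest sizes at which the planted effects and
  calibration bands are stable.

## Known limitations

- The cooperativity test's exchangeability caveat above is the main
  interpretive limitation.
- The Epcam-positivity definition (count > 0) is a convention; shallow
  sequencing would need a calibrated threshold.
- Motif scanning uses a 0-order background and per-position exact
  threshold; no higher-order background or positional prior.
- Gene-activity scores for motif retention are inputs, not computed
  from fragments.
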