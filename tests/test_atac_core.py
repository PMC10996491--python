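import numpy as np
import pandas as pd
import pytest

import imlineage as il
from imlineage.matrix import CountMatrix


class TestFilterCellsAtac:
    def test_threshold_boundaries(self):
        qc = pd.DataFrame(
            {
                "tss_enrichment": [3.99, 4.0, 8.0, 8.0, 8.0],
                "n_fragments": [5000, 1000, 999, 5000, 1_000_000],
                "n_reads": [10_000, 10_000, 10_000, 1_000_001, 1_000_000],
            },
            index=list("abcde"),
        )
        retained, report = il.filter_cells_atac(qc)
        assert list(retained) == ["b", "e"]
        assert report.loc["a", "rule"] == "low_tss"
        assert report.loc["c", "rule"] == "low_fragments"
        assert report.loc["d", "rule"] == "high_reads"

    def test_only_planted_removed_and_conserving(self, atac_planted):
        retained, report = il.filter_cells_atac(atac_planted.qc)
        assert len(retained) + len(report) == atac_planted.matrix.n_cells
        planted = atac_planted.qc.query("planted_violation != 'none'")
        assert set(report.index) == set(planted.index)
        assert (report["rule"] == planted.loc[report.index, "planted_violation"]).all()
        # idempotent on the retained table
        retained2, report2 = il.filter_cells_atac(atac_planted.qc.loc[retained])
        assert len(report2) == 0 and list(retained2) == list(retained)

    def test_missing_field(self):
        with pytest.raises(KeyError, match="n_reads"):
            il.filter_cells_atac(
                pd.DataFrame({"tss_enrichment": [5], "n_fragments": [2000]})
            )


class TestLsiEmbed:
    def test_depth_component_excluded(self):
        cfg = il.AtacSimConfig(
            n_cells_per_type={"basal": 150, "luminal": 150},
            n_peaks=800,
            peak_mean=1.5,
            depth_range=(0.2, 5.0),  # strong depth gradient
            seed=2,
        )
        d = il.generate_atac(cfg)
        res = il.lsi_embed(d.matrix, n_components=10)
        assert len(res.excluded) >= 1
        assert (res.correlations[res.excluded].abs() > 0.75).all()
        assert res.embedding.shape[1] == 10 - len(res.excluded)

    def test_equal_totals_keeps_all_components(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(200))
        counts = np.vstack([rng.multinomial(2000, probs) for _ in range(80)])
        m = CountMatrix(counts, [f"c{i}" for i in range(80)], [f"p{j}" for j in range(200)])
        res = il.lsi_embed(m, n_components=5)
        assert res.excluded == []
        assert (res.correlations == 0).all()

    def test_cell_permutation_invariance(self, atac_planted):
        m = atac_planted.matrix
        res1 = il.lsi_embed(m, n_components=6)
        rng = np.random.default_rng(1)
        perm = rng.permutation(m.n_cells)
        res2 = il.lsi_embed(m.subset_cells(list(m.cells[perm])), n_components=6)
        # same geometry: compare pairwise distances on a cell subset
        sub = list(m.cells[:40])
        from scipy.spatial.distance import pdist

        d1 = pdist(res1.embedding.loc[sub].to_numpy())
        d2 = pdist(res2.embedding.loc[sub].to_numpy())
        np.testing.assert_allclose(d1, d2, rtol=1e-6, atol=1e-8)

    def test_component_count_bound(self, atac_planted):
        with pytest.raises(ValueError, match="n_components"):
            il.lsi_embed(atac_planted.matrix, n_components=10**6)


class TestMatchMotifs:
    CONSENSUS = "ACGTACGTAC"

    def _sharp_pwm(self):
        b2i = {b: i for i, b in enumerate("ACGT")}
        pwm = np.zeros((4, len(self.CONSENSUS)))
        for j, b in enumerate(self.CONSENSUS):
            pwm[b2i[b], j] = 100.0
        return pwm

    def test_consensus_hit_and_nonmatch(self):
        seqs = {"hit": "TT" + self.CONSENSUS + "GG", "miss": "T" * 20}
        ann = il.match_motifs({"M": self._sharp_pwm()}, seqs, background=[0.25] * 4)
        assert bool(ann.incidence.loc["hit", "M"])
        assert not bool(ann.incidence.loc["miss", "M"])

    def test_reverse_complement_invariance(self):
        rc = self.CONSENSUS.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        seqs = {"fwd": "TT" + self.CONSENSUS + "GG", "rev": "TT" + rc + "GG"}
        ann = il.match_motifs({"M": self._sharp_pwm()}, seqs, background=[0.25] * 4)
        assert bool(ann.incidence.loc["fwd", "M"]) == bool(ann.incidence.loc["rev", "M"]) == True

    def test_uniform_pwm_never_matches(self):
        seqs = {"s": "ACGT" * 10}
        ann = il.match_motifs({"U": np.full((4, 8), 1.0)}, seqs, background=[0.25] * 4)
        assert not ann.incidence["U"].any()

    def test_zero_column_rejected(self):
        pwm = self._sharp_pwm()
        pwm[:, 3] = 0.0
        with pytest.raises(ValueError, match="zero column"):
            il.match_motifs({"M": pwm}, {"s": "ACGTACGTACGT"})

    def test_incidence_passthrough(self):
        inc = pd.DataFrame({"M": [True, False]}, index=["p1", "p2"])
        ann = il.match_motifs(incidence=inc)
        pd.testing.assert_frame_equal(ann.incidence, inc)


class TestBackgroundPeaks:
    def test_deterministic_given_seed(self, atac_planted):
        a = il.sample_background_peaks(atac_planted.peaks, seed=3)
        b = il.sample_background_peaks(atac_planted.peaks, seed=3)
        np.testing.assert_array_equal(a, b)
        c = il.sample_background_peaks(atac_planted.peaks, seed=4)
        assert (a != c).any()

    def test_gc_matching_quality(self, atac_planted, atac_backgrounds):
        gc = atac_planted.peaks["gc"].to_numpy()
        diff = np.abs(gc[atac_backgrounds].mean(axis=1) - gc)
        assert np.quantile(diff, 0.95) < 0.05

    def test_identical_peaks_sample_uniformly(self):
        peaks = pd.DataFrame({"gc": 0.5, "mean_accessibility": 0.01}, index=range(100))
        bg = il.sample_background_peaks(peaks, n_iterations=200, seed=0)
        # the pool is the whole peak set, not a 50-neighborhood
        assert len(np.unique(bg)) == 100

    def test_small_pool_warns(self):
        peaks = pd.DataFrame(
            {"gc": np.linspace(0.2, 0.8, 10), "mean_accessibility": np.linspace(0, 1, 10)}
        )
        with pytest.warns(UserWarning, match="shrunk"):
            bg = il.sample_background_peaks(peaks, n_neighbors=50, seed=0)
        assert bg.shape == (10, 50)
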