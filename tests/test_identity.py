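import numpy as np
import pandas as pd
import pytest

import imlineage as il
from imlineage.identity import LineageMixture, LineageMixtureResults, _label_components


def _planted_scores(rng, n_per=1000, sd=0.4):
    means = {"basal": (2, 0), "luminal": (0, 2), "intermediate": (2, 2)}
    X = np.vstack([rng.normal(mu, sd, size=(n_per, 2)) for mu in means.values()])
    labels = np.repeat(list(means), n_per)
    return X, labels, means


class TestGateEpithelial:
    def _inputs(self, n_pos_in_a):
        # cluster A: 100 cells with n_pos_in_a Epcam+; cluster B: all negative
        cells = [f"c{i}" for i in range(150)]
        clusters = pd.Series(["A"] * 100 + ["B"] * 50, index=cells)
        pos = pd.Series([True] * n_pos_in_a + [False] * (150 - n_pos_in_a), index=cells)
        rng = np.random.default_rng(0)
        sigs = pd.DataFrame(
            rng.normal(size=(150, 4)), index=cells, columns=["basal", "L1", "L2", "L3"]
        )
        return clusters, pos, sigs

    def test_half_rule_boundary(self):
        clusters, pos, sigs = self._inputs(50)  # exactly 50% -> flagged
        gate = il.gate_epithelial(clusters, pos, sigs)
        assert bool(gate.flagged["A"]) and not bool(gate.flagged["B"])
        assert set(gate.subtype.index) == set(clusters.index[:100])

    def test_just_below_half_not_flagged(self):
        clusters, pos, sigs = self._inputs(49)
        gate = il.gate_epithelial(clusters, pos, sigs)
        assert not bool(gate.flagged["A"])
        assert len(gate.subtype) == 0

    def test_missing_signature_named(self):
        clusters, pos, sigs = self._inputs(50)
        with pytest.raises(ValueError, match="L3"):
            il.gate_epithelial(clusters, pos, sigs.drop(columns="L3"))

    def test_recall_on_synthetic_truth(self, rna_planted, rna_filtered, rna_norm):
        """Non-epithelial contaminants form unflagged clusters."""
        filtered, _ = rna_filtered
        res = il.cluster_cells(rna_norm, n_pcs=20, seed=0)
        sets = rna_planted.truth.gene_sets
        sigs = pd.DataFrame(
            {
                "basal": il.score_gene_set(rna_norm, sets["basal"], seed=1),
                "L1": il.score_gene_set(rna_norm, sets["luminal"] + sets["l1"], seed=2),
                "L2": il.score_gene_set(rna_norm, sets["luminal"] + sets["l2"], seed=3),
            }
        )
        epcam = pd.Series(
            np.asarray(
                filtered.X[:, filtered.features.get_loc("Epcam")].todense()
            ).ravel()
            > 0,
            index=filtered.cells,
        )
        gate = il.gate_epithelial(res.labels, epcam, sigs, subtypes=("basal", "L1", "L2"))
        truth = rna_planted.truth.cell_labels[rna_norm.cells]
        epithelial = truth.index[(truth != "nonepithelial").to_numpy()]
        recall = gate.retained_cells.isin(epithelial).sum() / len(epithelial)
        assert recall >= 0.98
        # contaminants stay out
        kept_nonepi = gate.retained_cells.isin(
            truth.index[(truth == "nonepithelial").to_numpy()]
        ).sum()
        assert kept_nonepi / max(len(gate.retained_cells), 1) < 0.02


class TestLineageMixture:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        X, _, means = _planted_scores(rng)
        res = LineageMixture(X[:, 0], X[:, 1]).fit(seed=0)
        for label, mu in means.items():
            np.testing.assert_allclose(
                res.means.loc[label].to_numpy(), mu, atol=0.1
            )
        assert res.weights.sum() == pytest.approx(1.0)

    def test_three_repeated_points_degenerate_fit(self):
        pts = np.array([[2.0, 0.0], [0.0, 2.0], [2.0, 2.0]])
        reps = (40, 30, 30)
        X = np.repeat(pts, reps, axis=0)
        res = LineageMixture(X[:, 0], X[:, 1]).fit(seed=0)
        for label, mu, w in zip(
            ("basal", "luminal", "intermediate"), pts, np.array(reps) / 100
        ):
            np.testing.assert_allclose(res.means.loc[label].to_numpy(), mu, atol=1e-2)
            assert res.weights[label] == pytest.approx(w, abs=1e-2)

    def test_label_map_invariant_to_seed(self):
        rng = np.random.default_rng(1)
        X, _, _ = _planted_scores(rng, n_per=400)
        fits = [LineageMixture(X[:, 0], X[:, 1]).fit(seed=s) for s in (0, 1, 2)]
        for res in fits[1:]:
            np.testing.assert_allclose(
                res.means.to_numpy(), fits[0].means.to_numpy(), atol=0.05
            )

    def test_label_map_rule_is_deterministic(self):
        # map depends only on means, however components are ordered
        means = np.array([[2.0, 2.0], [0.0, 2.0], [2.0, 0.0]])
        assert _label_components(means) == {0: "intermediate", 1: "luminal", 2: "basal"}
        perm = means[[2, 0, 1]]
        assert _label_components(perm) == {0: "basal", 1: "intermediate", 2: "luminal"}

    def test_too_few_cells(self):
        with pytest.raises(ValueError, match="30"):
            LineageMixture(np.zeros(10), np.zeros(10))


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(0)
    X, labels, _ = _planted_scores(rng)
    return LineageMixture(X[:, 0], X[:, 1]).fit(seed=0), labels


class TestLineagePosterior:

    def test_posteriors_sum_to_one(self, fitted):
        res, _ = fitted
        post = res.posterior()
        assert np.allclose(post.probabilities.sum(axis=1), 1.0, atol=1e-9)
        assert (post.probabilities.to_numpy() >= 0).all()

    def test_confident_at_component_means(self, fitted):
        res, _ = fitted
        for label in ("basal", "luminal", "intermediate"):
            mu = res.means.loc[label]
            post = res.posterior([mu["basal_score"]], [mu["luminal_score"]])
            assert post.probabilities.iloc[0][f"p_{label}"] > 0.99
            assert post.labels.iloc[0] == label

    def test_em_fixed_point(self, fitted):
        """Posterior-weighted means reproduce the fitted component means."""
        res, _ = fitted
        post = res.posterior()
        X = res.model.endog
        for label in ("basal", "luminal", "intermediate"):
            r = post.probabilities[f"p_{label}"].to_numpy()
            # EM stops at sklearn's lower-bound tolerance, so the
            # fixed-point identity holds to the convergence scale
            np.testing.assert_allclose(
                (r[:, None] * X).sum(axis=0) / r.sum(),
                res.means.loc[label].to_numpy(),
                atol=5e-3,
            )

    def test_symmetric_scores_give_equal_probabilities(self):
        from sklearn.mixture import GaussianMixture
        from sklearn.mixture._gaussian_mixture import _compute_precision_cholesky

        gmm = GaussianMixture(n_components=3, covariance_type="full")
        gmm.means_ = np.array([[2.0, 0.0], [0.0, 2.0], [2.0, 2.0]])
        gmm.covariances_ = np.tile(0.16 * np.eye(2), (3, 1, 1))
        gmm.weights_ = np.full(3, 1 / 3)
        gmm.precisions_cholesky_ = _compute_precision_cholesky(gmm.covariances_, "full")
        gmm.converged_ = True
        model = LineageMixture(np.linspace(0, 2, 30), np.linspace(2, 0, 30))
        res = LineageMixtureResults(model, gmm)
        post = res.posterior([1.0], [1.0])  # equidistant from basal and luminal
        p = post.probabilities.iloc[0]
        assert p["p_basal"] == pytest.approx(p["p_luminal"], abs=1e-12)

    def test_p_basal_monotone_along_basal_axis(self, fitted):
        res, _ = fitted
        basal = np.linspace(0.5, 4.0, 80)
        post = res.posterior(basal, np.zeros_like(basal))
        # the whole line lies far outside the luminal component's 99% ellipse;
        # small covariance differences between fitted components allow only
        # numerically negligible dips
        assert (np.diff(post.probabilities["p_basal"].to_numpy()) >= -1e-6).all()


def test_convenience_wrappers_match_methods():
    rng = np.random.default_rng(5)
    X, _, _ = _planted_scores(rng, n_per=200)
    res = il.fit_lineage_gmm(X[:, 0], X[:, 1], seed=0)
    post = il.lineage_posteriors(res)
    assert len(post.labels) == len(X)
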