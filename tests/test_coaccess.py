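import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import imlineage as il
from imlineage.atac import MotifAnnotation
from imlineage.coaccess import PeakPartition, _test_record


def _ann(incidence: dict, peaks=None) -> MotifAnnotation:
    n = len(next(iter(incidence.values())))
    index = peaks or [f"p{i}" for i in range(n)]
    return MotifAnnotation(pd.DataFrame(incidence, index=index))


class TestCollapseEts:
    def test_family_members_merge_into_union(self):
        ann = _ann(
            {
                "ERG": [1, 0, 0, 1],
                "ETV6": [0, 1, 0, 1],
                "FLI1": [0, 0, 1, 1],
                "NFKB2": [1, 1, 0, 0],
            }
        )
        out = il.collapse_ets(ann)
        assert set(out.motifs) == {"ETS", "NFKB2"}
        assert out.incidence["ETS"].tolist() == [True, True, True, True]
        assert out.incidence["NFKB2"].tolist() == [True, True, False, False]
        assert len(out.peaks) == len(ann.peaks)

    def test_idempotent(self):
        ann = _ann({"ETS": [1, 0], "STAT3": [0, 1]})
        out = il.collapse_ets(il.collapse_ets(ann))
        pd.testing.assert_frame_equal(out.incidence, il.collapse_ets(ann).incidence)

    def test_double_hit_counted_once(self):
        ann = _ann({"ERG": [1], "FLI1": [1], "STAT3": [0]})
        out = il.collapse_ets(ann)
        assert out.incidence["ETS"].sum() == 1

    def test_no_family_member_errors(self):
        with pytest.raises(ValueError, match="no motif matches"):
            il.collapse_ets(_ann({"NFKB2": [1, 0], "STAT3": [0, 1]}))


class TestPartitionPeaks:
    def test_candidate_subset_of_ets_flagged(self):
        ann = _ann({"ETS": [1, 1, 1], "STAT3": [1, 1, 0]})
        part = il.partition_peaks(ann, "STAT3")
        assert len(part.candidate_only) == 0
        assert "empty:candidate_only" in part.flags

    def test_disjoint_incidences_flagged(self):
        ann = _ann({"ETS": [1, 0], "STAT3": [0, 1]})
        part = il.partition_peaks(ann, "STAT3")
        assert len(part.both) == 0 and "empty:both" in part.flags

    def test_independent_incidences_expected_overlap(self):
        rng = np.random.default_rng(0)
        ann = _ann(
            {"ETS": rng.random(1000) < 0.3, "CAND": rng.random(1000) < 0.3}
        )
        part = il.partition_peaks(ann, "CAND")
        # E|BOTH| = 90, binomial sd ~ 9
        assert abs(len(part.both) - 90) < 40

    def test_absent_candidate(self):
        with pytest.raises(KeyError):
            il.partition_peaks(_ann({"ETS": [1]}), "NOPE")


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    st.lists(
        st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=60
    )
)
def test_partition_reconstructs_candidate_incidence(bits):
    """BOTH and C_ONLY are disjoint and union back to the candidate's peaks."""
    ann = _ann(
        {"ETS": [e for e, _ in bits], "CAND": [c for _, c in bits]}
    )
    part = il.partition_peaks(ann, "CAND")
    both, conly, eonly = (
        set(part.both),
        set(part.candidate_only),
        set(part.ets_only),
    )
    assert both.isdisjoint(conly) and both.isdisjoint(eonly) and conly.isdisjoint(eonly)
    cand_peaks = set(ann.peaks[ann.incidence["CAND"].to_numpy()])
    assert both | conly == cand_peaks


class TestCoaccessibilityTest:
    def test_exact_rank_sum_p(self):
        """{3,4,5} vs {1,2}: 1 of C(5,2)=10 orderings under 'greater'."""
        part = PeakPartition(
            candidate="X",
            both=pd.Index([f"b{i}" for i in range(6)]),
            candidate_only=pd.Index([f"c{i}" for i in range(6)]),
            ets_only=pd.Index([f"e{i}" for i in range(6)]),
        )
        z = pd.DataFrame(
            {
                "cell1": [3.0, np.nan, np.nan],
                "cell2": [4.0, np.nan, np.nan],
                "cell3": [5.0, np.nan, np.nan],
                "cell4": [np.nan, np.nan, 1.0],
                "cell5": [np.nan, np.nan, 2.0],
            },
            index=["both", "candidate_only", "ets_only"],
        )
        rec = _test_record(part, z, min_peaks=5)
        assert rec["p_vs_ets_only"] == pytest.approx(0.1)

    def test_small_partition_skipped_with_reason(self, atac_homogeneous):
        d = atac_homogeneous
        bg = il.sample_background_peaks(d.peaks, seed=0)
        inc = pd.DataFrame(
            {
                "ERG": [True] * 50 + [False] * (d.matrix.n_features - 50),
                "RARE": [True] * 2 + [False] * (d.matrix.n_features - 2),
            },
            index=d.matrix.features,
        )
        ann = il.collapse_ets(il.MotifAnnotation(inc))
        part = il.partition_peaks(ann, "RARE")
        rec = il.coaccessibility_test(d.matrix, part, bg)
        assert np.isnan(rec["p_vs_ets_only"])
        assert "minimum size" in rec["skip_p_vs_ets_only"]

    def test_planted_boost_detected_and_decoys_spared(self):
        cfg = il.AtacSimConfig(
            n_cells_per_type={"basal": 200, "luminal": 200, "intermediate": 300},
            cooperativity=il.Cooperativity("STAT3", "intermediate", 3.0),
            seed=1,
        )
        d = il.generate_atac(cfg)
        bg = il.sample_background_peaks(d.peaks, seed=2)
        test = il.CooperativityTest(d.matrix, d.annotation, bg, d.truth.cell_labels)
        res = test.fit(
            candidates=["STAT3", "NFKB2", "NFATC1", "KLF5", "GATA2", "FOXA1"],
            cell_type="intermediate",
        )
        t = res.table.set_index("candidate")
        assert t.loc["STAT3", "q_vs_ets_only"] < 0.01
        assert (t.drop(index="STAT3")["q_vs_ets_only"] > 0.05).all()
        assert "STAT3" in res.summary()

    def test_fdr_dominates_raw_p(self):
        cfg = il.AtacSimConfig(
            n_cells_per_type={"basal": 100, "intermediate": 100},
            n_peaks=800,
            peak_mean=1.5,
            seed=4,
        )
        d = il.generate_atac(cfg)
        bg = il.sample_background_peaks(d.peaks, seed=4)
        res = il.CooperativityTest(d.matrix, d.annotation, bg, d.truth.cell_labels).fit(
            cell_type="intermediate"
        )
        ok = res.table["p_vs_ets_only"].notna()
        assert (
            res.table.loc[ok, "q_vs_ets_only"]
            >= res.table.loc[ok, "p_vs_ets_only"] - 1e-12
        ).all()

    def test_power_monotone_in_boost(self):
        """Rejection power never decreases as the planted boost grows.

        Accessibility is homogeneous across cell types here so that the
        boost is the only structure separating the partitions; see the
        methods note on the exchangeability assumption of the test.
        """
        power = []
        for boost in (1.0, 1.5, 2.0, 3.0):
            hits = 0
            for seed in range(3):
                cfg = il.AtacSimConfig(
                    n_cells_per_type={"basal": 150, "luminal": 150, "intermediate": 200},
                    n_peaks=1500,
                    peak_mean=1.5,
                    frac_type_specific=0.0,
                    cooperativity=il.Cooperativity("STAT3", "intermediate", boost),
                    seed=100 + seed,
                )
                d = il.generate_atac(cfg)
                bg = il.sample_background_peaks(d.peaks, seed=200 + seed)
                ann = il.collapse_ets(d.annotation)
                part = il.partition_peaks(ann, "STAT3")
                im = d.matrix.cells[(d.truth.cell_labels == "intermediate").to_numpy()]
                rec = il.coaccessibility_test(d.matrix, part, bg, cells=im)
                hits += rec["p_vs_ets_only"] < 0.01
            power.append(hits)
        assert (np.diff(power) >= 0).all()
        assert power[0] == 0 and power[-1] == 3
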