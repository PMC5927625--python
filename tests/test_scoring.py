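"""MEP summarization, rescue/attenuation scoring and the t-test wrapper."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import memascreen as ms
from memascreen.errors import NumericalError
from memascreen.scoring import MEP_KEY


def spot_table(rows):
    """rows: (treatment, ecm, ligand, counts list)."""
    out = []
    for i, (tr, ecm, lig, counts) in enumerate(rows):
        for j, c in enumerate(counts):
            out.append(("CL", tr, ecm, lig, f"{tr}_{i}", j, 0, float(c), 0.2, 1.0, 1.0, 100.0, 0))
    return pd.DataFrame(out, columns=[
        "cell_line", "treatment", "ecm", "ligand", "array_id", "spot_row", "spot_col",
        "cell_count", "edu_fraction", "krt14_median", "krt19_median",
        "nuclear_area_median", "n_excluded"])


class TestSummarizeMep:
    def test_median_and_sem_arithmetic(self):
        spots = spot_table([("T", "E", "L", [10, 12, 14])])
        mep = ms.summarize_mep(spots)
        row = mep.iloc[0]
        assert row.median_cell_count == 12
        assert row.sem_cell_count == pytest.approx(2 / np.sqrt(3))
        assert row.n_replicates == 3

    def test_permutation_invariance(self, small_spots):
        a = ms.summarize_mep(small_spots)
        b = ms.summarize_mep(small_spots.sample(frac=1.0, random_state=3))
        pd.testing.assert_frame_equal(a, b)

    def test_matches_brute_force_groupby(self, small_spots):
        mep = ms.summarize_mep(small_spots).set_index(MEP_KEY)
        nz = small_spots[small_spots.cell_count > 0]
        for key, sub in list(nz.groupby(MEP_KEY))[::5]:
            assert mep.loc[key, "median_cell_count"] == pytest.approx(sub.cell_count.median())
            assert mep.loc[key, "n_replicates"] == len(sub)

    def test_empty_meps_reported_with_zero_n(self):
        spots = spot_table([("T", "E", "L", [0, 0])])
        mep = ms.summarize_mep(spots)
        assert mep.iloc[0].n_replicates == 0
        assert np.isnan(mep.iloc[0].median_cell_count)


class TestResponseRatio:
    def test_basic_and_identity(self):
        t = ms.summarize_mep(spot_table([("drug", "E", "L", [30, 30, 30])]))
        c = ms.summarize_mep(spot_table([("veh", "E", "L", [100, 100, 100])]))
        out = ms.response_ratio(t, c)
        assert out.ratio.iloc[0] == pytest.approx(0.30)
        same = ms.response_ratio(c, c)
        assert same.ratio.iloc[0] == 1.0

    def test_zero_control_yields_nan_with_warning(self):
        t = ms.summarize_mep(spot_table([("drug", "E", "L", [5, 5])]))
        c = t.copy()
        c["median_cell_count"] = 0.0
        with pytest.warns(UserWarning, match="zero control"):
            out = ms.response_ratio(t, c)
        assert np.isnan(out.ratio.iloc[0])


class TestRescueScore:
    def summary(self, t_lig, t_ref=30.0, c_ref=100.0):
        rows = [("lapatinib", "E", "L1", [t_lig] * 3),
                ("lapatinib", "E", "PBS", [t_ref] * 3),
                ("DMSO", "E", "L1", [90.0] * 3),
                ("DMSO", "E", "PBS", [c_ref] * 3)]
        return ms.summarize_mep(spot_table(rows))

    def test_no_rescue_scores_zero(self):
        hits = ms.rescue_score(self.summary(t_lig=30.0))
        assert hits.set_index("ligand").rescue_score["L1"] == 0.0
        assert hits.set_index("ligand").rescue_score["PBS"] == 0.0

    def test_full_restoration_scores_one(self):
        hits = ms.rescue_score(self.summary(t_lig=100.0))
        assert hits.set_index("ligand").rescue_score["L1"] == pytest.approx(1.0)
        assert hits.set_index("ligand")["rank"]["L1"] == 1

    def test_no_drug_effect_raises(self):
        with pytest.raises(NumericalError, match="no drug effect"):
            ms.rescue_score(self.summary(t_lig=50.0, t_ref=120.0, c_ref=100.0))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 10))
    def test_affine_invariance(self, shift, scale):
        """A common affine rescaling of all medians leaves S unchanged."""
        base = self.summary(t_lig=80.0)
        moved = base.copy()
        for col in ("median_cell_count", "median_edu_fraction"):
            moved[col] = moved[col] * scale + shift
        a = ms.rescue_score(base).rescue_score.to_numpy()
        b = ms.rescue_score(moved).rescue_score.to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestEcmModifierRank:
    def test_ties_ranked_by_label(self):
        spots = spot_table([("lapatinib", e, "L1", [20, 20, 20]) for e in ("B", "A", "C")])
        out = ms.ecm_modifier_rank(ms.summarize_mep(spots), "L1")
        cc = out[out.metric == "cell_count"]
        assert cc.ecm.tolist() == ["A", "B", "C"]
        assert (cc.deviation == 0).all()
        assert cc["rank"].tolist() == [1, 2, 3]

    def test_planted_strong_ecm_ranks_first(self):
        d = ms.fixture_design(11, cell_lines=("AU565",))
        p = ms.fixture_params(11, effect_sd=0.0)
        p.ecm_effects = {e: 1.0 for e in d.ecm_panel}
        p.ecm_effects["TNC"] = 1.5
        cells = ms.simulate_experiment(d, p)
        gated, _ = ms.gate_edu(cells)
        spots = ms.summarize_spots(gated, d)
        mep = ms.summarize_mep(spots)
        out = ms.ecm_modifier_rank(mep, "NRG1B", treatment="lapatinib")
        cc = out[out.metric == "cell_count"]
        assert cc.iloc[0].ecm == "TNC" and cc.iloc[0].deviation > 0

    def test_matches_brute_force_sort(self, small_spots):
        mep = ms.summarize_mep(small_spots)
        out = ms.ecm_modifier_rank(mep, "EGF", treatment="lapatinib")
        cc = out[out.metric == "cell_count"]
        sub = mep[(mep.ligand == "EGF") & (mep.treatment == "lapatinib")]
        expect = sub.sort_values(["median_cell_count", "ecm"],
                                 ascending=[False, True]).ecm.tolist()
        assert cc.ecm.tolist() == expect


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p = ms.two_sample_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_textbook_pooled_formula(self):
        a, b = np.array([2.1, 2.0, 1.9]), np.array([3.1, 3.0, 2.9])
        # hand-computed pooled-variance oracle
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        from scipy.stats import t as tdist
        p_hand = 2 * tdist.sf(abs(t_hand), len(a) + len(b) - 2)
        t, p = ms.two_sample_t(a, b)
        assert t == pytest.approx(t_hand, abs=1e-10)
        assert p == pytest.approx(p_hand, abs=1e-10)

    def test_zero_variance_diagnostic(self):
        with pytest.warns(UserWarning, match="pooled variance"):
            t, p = ms.two_sample_t([5, 5, 5], [7, 7, 7])
        assert np.isnan(t) and np.isnan(p)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ms.two_sample_t([1], [2, 3])


class TestExcludeConditions:
    def test_nidogen_style_exclusion(self, small_spots):
        mep = ms.summarize_mep(small_spots)
        out, audit = ms.exclude_conditions(mep, [("NID1", "cell_count")])
        nid = out[out.ecm == "NID1"]
        assert nid.median_cell_count.isna().all() and nid.sem_cell_count.isna().all()
        assert nid.median_edu_fraction.notna().any()  # EdU untouched
        masked = mep[(mep.ecm == "NID1")][["median_cell_count", "sem_cell_count"]].notna().sum().sum()
        assert len(audit) == masked

    def test_empty_list_is_identity(self, small_spots):
        mep = ms.summarize_mep(small_spots)
        out, audit = ms.exclude_conditions(mep, [])
        pd.testing.assert_frame_equal(out, mep)
        assert audit.empty

    def test_unknown_label_raises(self, small_spots):
        with pytest.raises(KeyError, match="NOPE"):
            ms.exclude_conditions(ms.summarize_mep(small_spots), [("NOPE", "cell_count")])
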