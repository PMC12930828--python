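import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bnorms import (
    assign_pubertal_stage,
    associate_pds,
    bh_adjust,
    default_atlas,
    lobe_deviation_counts,
    percentile_shift_analysis,
    stage_group_tests,
)
from bnorms.exceptions import ValidationError
from bnorms.puberty import dunn_posthoc
from conftest import make_table


def bh_bruteforce(p):
    """Independent step-up implementation of Benjamini-Hochberg."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def kruskal_oracle(groups):
    """Tie-corrected Kruskal-Wallis H from the rank-sum formula."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    idx = 0
    h = 0.0
    for g in groups:
        r = ranks[idx: idx + len(g)]
        idx += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


class TestBH:
    def test_hand_computed_example(self):
        adj = bh_adjust([0.001, 0.01, 0.02, 0.8])
        np.testing.assert_allclose(adj, [0.004, 0.02, 0.0266667, 0.8], atol=1e-6)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValidationError):
            bh_adjust([-0.1])

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_bruteforce_stepup(self, ps):
        np.testing.assert_allclose(bh_adjust(ps), bh_bruteforce(ps), atol=1e-12)


def _dev_and_cohort(n=60, n_roi=4, slope=1.0, noise=0.0, seed=0, sex="F"):
    """Deviation table plus minimal cohort where PDS = 2 + slope*z + noise."""
    rng = np.random.default_rng(seed)
    subjects = [f"S{i:03d}" for i in range(n)]
    rois = default_atlas(n_roi).roi_names
    dev_rows, coh_rows = [], []
    z_subj = {}
    for i, sid in enumerate(subjects):
        z_subj[sid] = rng.normal(0, 1, n_roi)
        for r, roi in enumerate(rois):
            dev_rows.append({
                "subject_id": sid, "sex": sex, "roi_name": roi, "timepoint": "y2",
                "y_obs": 2.5, "y_median_pred": 2.5, "s_w": 1.0,
                "z": z_subj[sid][r], "centile": 50.0,
            })
        pds = 2.0 + slope * z_subj[sid][0] + rng.normal(0, noise)
        for v, age in (("baseline", 118.0 + i * 0.01), ("y2", 142.0 + i * 0.01)):
            coh_rows.append({
                "subject_id": sid, "sex": sex, "visit": v, "age_months": age,
                "pds_mean": pds, "ses": rng.normal(), "ct_" + rois[0]: 2.5,
            })
    cohort = make_table(coh_rows)
    return pd.DataFrame(dev_rows), cohort, rois


class TestAssociation:
    def test_exact_linear_relation_recovered(self):
        dev, cohort, rois = _dev_and_cohort(slope=1.0, noise=0.0)
        out = associate_pds(dev, cohort, "bnorm")
        row = out[out.roi_name == rois[0]].iloc[0]
        assert row["slope"] == pytest.approx(1.0, abs=1e-8)
        assert row["p"] < 1e-20
        assert row["p_bh"] <= 1.0 and row["p_bh"] >= row["p"]

    def test_residual_df_is_n_minus_two(self):
        dev, cohort, _ = _dev_and_cohort(n=366, n_roi=2, noise=0.5)
        out = associate_pds(dev, cohort, "cnorm")
        assert (out["df_resid"] == 364).all()
        assert (out["df_model"] == 1).all()
        assert (out["n"] == 366).all()

    def test_small_cell_flagged_not_fitted(self):
        dev, cohort, _ = _dev_and_cohort(n=5, n_roi=1)
        out = associate_pds(dev, cohort, "bnorm")
        assert out["flagged"].all()
        assert out["slope"].isna().all()

    def test_covariate_variant_runs_full_factorial(self):
        dev, cohort, rois = _dev_and_cohort(n=80, noise=0.3, seed=2)
        cohort.df["bmi"] = np.random.default_rng(0).normal(18, 2, len(cohort.df))
        out = associate_pds(dev, cohort, "bnorm", variant="covariate")
        # intercept + z + bmi + ses + 3 two-way + 1 three-way = 8 params
        assert (out["df_resid"] == 80 - 8).all()

    def test_raw_diff_variant_uses_thickness_change(self):
        dev, cohort, rois = _dev_and_cohort(n=40, noise=0.2, seed=3, n_roi=1)
        df = cohort.df
        y2 = df["visit"] == "y2"
        # make thickness change exactly proportional to PDS
        df.loc[y2, "ct_" + rois[0]] = 2.5 + 0.1 * df.loc[y2, "pds_mean"]
        out = associate_pds(dev, cohort, "bnorm", variant="raw_diff")
        assert out.iloc[0]["slope"] == pytest.approx(10.0, abs=1e-6)

    def test_unknown_variant_rejected(self):
        dev, cohort, _ = _dev_and_cohort(n=12)
        with pytest.raises(ValidationError):
            associate_pds(dev, cohort, "bnorm", variant="quadratic")


class TestStages:
    def test_floor_and_ceiling(self):
        assert assign_pubertal_stage(1.0, "F") == "pre"
        assert assign_pubertal_stage(4.0, "M") == "post"

    def test_threshold_rule(self):
        assert assign_pubertal_stage(2.6, "F") == "mid"
        assert assign_pubertal_stage(1.5, "F") == "early"  # boundary goes up
        assert assign_pubertal_stage(3.9, "M") == "post"

    def test_missing_score_unstaged(self):
        assert assign_pubertal_stage(float("nan"), "F") is None


class TestLobeCounts:
    def test_counts_per_lobe(self):
        atlas = default_atlas(6)
        # pick the two ROIs in the same lobe_hemi? default atlas alternates; use all
        dev = pd.DataFrame({
            "subject_id": "S1", "sex": "F", "timepoint": "y2",
            "roi_name": atlas.roi_names,
            "z": [2.1, -2.5, 0.3, 1.96, -1.96, 5.0],
        })
        counts = lobe_deviation_counts(dev, atlas, threshold=1.96)
        total_pos = counts["pos_count"].sum()
        total_neg = counts["neg_count"].sum()
        assert total_pos == 2  # 2.1 and 5.0; +1.96 exactly is not extreme
        assert total_neg == 1  # -2.5; -1.96 exactly is not extreme

    def test_all_within_threshold_zero_counts(self):
        atlas = default_atlas(4)
        dev = pd.DataFrame({
            "subject_id": "S1", "sex": "F", "timepoint": "y2",
            "roi_name": atlas.roi_names, "z": [0.5, -0.5, 1.0, -1.9],
        })
        counts = lobe_deviation_counts(dev, atlas, threshold=1.96)
        assert counts["pos_count"].sum() == 0
        assert counts["neg_count"].sum() == 0

    def test_unknown_roi_rejected(self):
        atlas = default_atlas(2)
        dev = pd.DataFrame({
            "subject_id": "S1", "sex": "F", "timepoint": "y2",
            "roi_name": ["nope"], "z": [3.0],
        })
        with pytest.raises(Exception):
            lobe_deviation_counts(dev, atlas, threshold=1.96)


class TestKruskalWallis:
    def test_two_group_hand_example(self):
        counts = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(6)],
            "sex": "F", "lobe_hemi": "L_frontal", "model_kind": "bnorm",
            "timepoint": "y2",
            "stage": ["pre"] * 3 + ["mid"] * 3,
            "pos_count": [1, 2, 3, 4, 5, 6],
            "neg_count": [0] * 6,
        })
        omnibus, _ = stage_group_tests(counts)
        row = omnibus[omnibus["sign"] == "positive"].iloc[0]
        assert row["H"] == pytest.approx(3.8571, abs=1e-4)
        assert row["df"] == 1

    def test_identical_values_give_zero_h(self):
        counts = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(8)],
            "sex": "F", "lobe_hemi": "L_frontal", "model_kind": "bnorm",
            "timepoint": "y2",
            "stage": ["pre"] * 4 + ["mid"] * 4,
            "pos_count": [2] * 8, "neg_count": [0] * 8,
        })
        omnibus, _ = stage_group_tests(counts)
        assert (omnibus["H"] == 0).all()
        assert (omnibus["p"] == 1).all()

    @settings(deadline=None, max_examples=100)
    @given(
        sizes=st.lists(st.integers(2, 8), min_size=2, max_size=4),
        seed=st.integers(0, 10**6),
    )
    def test_h_matches_rank_formula_oracle(self, sizes, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.integers(0, 5, s).astype(float) for s in sizes]
        if np.all(np.concatenate(groups) == groups[0][0]):
            return
        h_scipy = stats.kruskal(*groups).statistic
        assert h_scipy == pytest.approx(kruskal_oracle(groups), abs=1e-10)

    def test_dunn_z_hand_check(self):
        groups = {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([4.0, 5.0, 6.0])}
        ph = dunn_posthoc(groups)
        # mean ranks 2 and 5; var_base = 6*7/12 = 3.5 (no ties)
        se = np.sqrt(3.5 * (1 / 3 + 1 / 3))
        assert ph.iloc[0]["z"] == pytest.approx((2 - 5) / se, abs=1e-12)
        assert ph.iloc[0]["p_bonf"] == pytest.approx(min(1, ph.iloc[0]["p"] * 1))

    def test_empty_stage_shrinks_df_and_small_cells_skipped(self):
        counts = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(9)],
            "sex": "F", "lobe_hemi": "L_frontal", "model_kind": "bnorm",
            "timepoint": "y2",
            "stage": ["pre"] * 3 + ["mid"] * 3 + ["late"] * 3,
            "pos_count": [1, 2, 3, 4, 5, 6, 7, 8, 9], "neg_count": [0] * 9,
        })
        omnibus, _ = stage_group_tests(counts)
        assert (omnibus[omnibus["sign"] == "positive"]["df"] == 2).all()
        only_one = counts[counts["stage"] != "mid"].copy()
        only_one = only_one[only_one["stage"] != "late"]
        with pytest.warns(UserWarning):
            out, _ = stage_group_tests(only_one)
        assert len(out) == 0 or (out["sign"] != "positive").all() or out.empty


class TestPercentileShifts:
    def _dev(self, z_map, tp):
        rows = []
        for sid, z in z_map.items():
            rows.append({"subject_id": sid, "sex": "F", "roi_name": "L_roi000",
                         "timepoint": tp, "y_obs": 2.5, "y_median_pred": 2.5,
                         "s_w": 1.0, "z": z, "centile": 50.0})
        return pd.DataFrame(rows)

    def _cohort(self, dpds):
        rows = []
        for sid, d in dpds.items():
            for v, age, pds in (("baseline", 118.0, 1.5), ("y2", 142.0, 2.0),
                                ("y4", 166.0, 2.0 + d)):
                rows.append({"subject_id": sid, "visit": v, "age_months": age,
                             "pds_mean": pds, "ct_L_roi000": 2.5})
        return make_table(rows)

    def test_group_assignment_and_boundary(self):
        z2 = {"A": 0.5, "B": 0.0, "C": 0.0, "D": 1.0}
        z4 = {"A": 2.0, "B": -1.0, "C": 0.5, "D": -1.5}
        # zDiff: A +1.5 positive, B -1.0 stable (closed boundary), C +0.5 stable,
        # D -2.5 negative
        dpds = {"A": 0.5, "B": 0.1, "C": 0.2, "D": 0.9}
        out = percentile_shift_analysis(self._dev(z2, "y2"), self._dev(z4, "y4"),
                                        self._cohort(dpds), threshold=1.0)
        row = out.iloc[0]
        assert row["n_positive"] == 1
        assert row["n_stable"] == 2
        assert row["n_negative"] == 1

    def test_constant_delta_pds_gives_zero_h(self):
        z2 = {s: 0.0 for s in "ABCDEF"}
        z4 = {"A": 2.0, "B": -2.0, "C": 0.0, "D": 0.0, "E": 1.5, "F": -1.5}
        dpds = {s: 0.3 for s in "ABCDEF"}
        out = percentile_shift_analysis(self._dev(z2, "y2"), self._dev(z4, "y4"),
                                        self._cohort(dpds), threshold=1.0)
        assert out.iloc[0]["H"] == 0.0
        assert out.iloc[0]["p_fdr"] == 1.0

    def test_single_group_skipped(self):
        z2 = {"A": 0.0, "B": 0.0}
        z4 = {"A": 0.1, "B": -0.1}
        dpds = {"A": 0.5, "B": 0.7}
        out = percentile_shift_analysis(self._dev(z2, "y2"), self._dev(z4, "y4"),
                                        self._cohort(dpds), threshold=1.0)
        assert np.isnan(out.iloc[0]["H"])
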