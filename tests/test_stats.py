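"""AUC metric, ROI pairs, windowed correlation, ANOVA, t-tests, FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirspipe.stats import (
    auc_abs,
    bh_fdr,
    demographic_summary,
    mixed_anova,
    roi_pairs,
    two_sample_t,
    windowed_pearson,
)

FS = 25.0


class TestAucAbs:
    def test_zero_curve(self):
        assert auc_abs(np.zeros(51)) == 0.0

    def test_constant_one_gives_50(self):
        assert auc_abs(np.ones(51)) == 50.0

    def test_alternating_signs_give_50(self):
        curve = np.array([(-1.0) ** j for j in range(51)])
        assert auc_abs(curve) == 50.0

    def test_positive_homogeneity_and_sign_symmetry(self):
        rng = np.random.default_rng(0)
        curve = rng.normal(size=51)
        for c in (0.5, 2.0, 7.3):
            assert auc_abs(c * curve) == pytest.approx(c * auc_abs(curve))
        assert auc_abs(-curve) == pytest.approx(auc_abs(curve))

    def test_nan_rejected(self):
        bad = np.ones(51)
        bad[10] = np.nan
        with pytest.raises(ValueError):
            auc_abs(bad)


class TestRoiPairs:
    def test_15_pairs_partitioned_3_3_9(self):
        pairs = roi_pairs()
        assert len(pairs) == 15
        by_label = {}
        for a, b, label in pairs:
            by_label.setdefault(label, []).append((a, b))
        assert len(by_label["PreFC"]) == 3
        assert len(by_label["S1"]) == 3
        assert len(by_label["PreFC/S1"]) == 9

    def test_pairs_are_unique_and_complete(self):
        pairs = roi_pairs()
        seen = {frozenset((a, b)) for a, b, _ in pairs}
        assert len(seen) == 15  # C(6,2), no duplicates

    def test_degenerate_two_rois(self):
        pairs = roi_pairs(prefc=("a",), s1=("b",))
        assert len(pairs) == 1
        assert pairs[0][2] == "PreFC/S1"

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            roi_pairs(prefc=("a", "b", "c"), s1=("a", "d", "e"))

    def test_total_mean_is_size_weighted_mean_of_subsets(self):
        """15 r_total = 3 r_PreFC + 3 r_S1 + 9 r_cross."""
        rng = np.random.default_rng(1)
        r = {(a, b): rng.uniform(-1, 1) for a, b, _ in roi_pairs()}
        by = {"PreFC": [], "S1": [], "PreFC/S1": []}
        for a, b, label in roi_pairs():
            by[label].append(r[(a, b)])
        total = np.mean(list(r.values()))
        weighted = (
            3 * np.mean(by["PreFC"]) + 3 * np.mean(by["S1"])
            + 9 * np.mean(by["PreFC/S1"])
        ) / 15
        assert total == pytest.approx(weighted)


class TestWindowedPearson:
    def test_identity_gives_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=1500)
        r = windowed_pearson(x, x, FS)
        assert r.shape == (51,)
        assert np.allclose(r, 1.0)

    def test_negative_affine_gives_minus_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=1500)
        r = windowed_pearson(x, -2.0 * x + 5.0, FS)
        assert np.allclose(r, -1.0)

    def test_matches_direct_formula_per_window(self):
        """Oracle: scipy's Pearson r computed independently per slice."""
        from scipy.stats import pearsonr

        rng = np.random.default_rng(4)
        x = rng.normal(size=1500)
        y = 0.4 * x + rng.normal(size=1500)
        r = windowed_pearson(x, y, FS)
        for j in range(51):
            sl = slice(j * 25, j * 25 + 250)
            assert r[j] == pytest.approx(pearsonr(x[sl], y[sl])[0], abs=1e-12)

    def test_zero_variance_window_is_missing(self):
        x = np.zeros(1500)
        x[300:] = np.random.default_rng(5).normal(size=1200)
        y = np.random.default_rng(6).normal(size=1500)
        r = windowed_pearson(x, y, FS)
        assert np.isnan(r[0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            windowed_pearson(np.zeros(100), np.zeros(101))


class TestMixedAnova:
    def test_single_within_level_reduces_to_one_way(self):
        """Between-group F equals the closed-form one-way ANOVA F."""
        rng = np.random.default_rng(7)
        groups = {"NB": rng.normal(0, 1, 6), "non-NB": rng.normal(1, 1, 5)}
        rows = []
        for g, vals in groups.items():
            for i, v in enumerate(vals):
                rows.append((f"{g}{i}", g, "P1", v))
        df = pd.DataFrame(rows, columns=["patient_id", "group", "epoch", "y"])
        out = mixed_anova(df, dv="y", between="group", within="epoch")
        assert len(out) == 1

        a, b = groups["NB"], groups["non-NB"]
        grand = np.concatenate([a, b]).mean()
        ss_b = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
        ss_w = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        f_oneway = (ss_b / 1) / (ss_w / (len(a) + len(b) - 2))
        assert out["F"].iloc[0] == pytest.approx(f_oneway, rel=1e-10)

    def test_unbalanced_split_plot_matches_R_aov(self):
        """Frozen oracle: R's aov(y ~ group*time + Error(subject/time)) on a
        seeded 5-vs-3 subject, 3-level fixture gives F = 0.438812 (group),
        15.343159 (time), 0.599716 (interaction)."""
        rng = np.random.default_rng(42)
        rows = []
        for g, n in (("A", 5), ("B", 3)):
            for i in range(n):
                subj_eff = rng.normal(0, 1)
                for t_ix, t in enumerate(["P0", "P1", "P2"]):
                    y = (
                        subj_eff + (1.0 if g == "A" else 0.0) * 0.8
                        + 0.3 * t_ix + rng.normal(0, 0.5)
                    )
                    rows.append((f"{g}{i}", g, t, round(y, 6)))
        df = pd.DataFrame(rows, columns=["patient_id", "group", "epoch", "y"])
        out = mixed_anova(df, dv="y", between="group", within="epoch")
        f = dict(zip(out["effect"], out["F"]))
        assert f["group"] == pytest.approx(0.438812, abs=1e-5)
        assert f["epoch"] == pytest.approx(15.343159, abs=1e-4)
        assert f["group * epoch"] == pytest.approx(0.599716, abs=1e-5)
        p = dict(zip(out["effect"], out["p"]))
        assert p["epoch"] == pytest.approx(0.000494, abs=1e-5)

    def test_balanced_matches_pingouin(self):
        """Cross-check against an independent mixed-ANOVA implementation."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        rows = []
        for g in ("NB", "non-NB"):
            for i in range(6):
                base = rng.normal()
                for t in ("P0", "P1", "P2"):
                    rows.append((f"{g}{i}", g, t, base + rng.normal()))
        df = pd.DataFrame(rows, columns=["patient_id", "group", "epoch", "y"])
        mine = mixed_anova(df, dv="y", between="group", within="epoch")
        theirs = pingouin.mixed_anova(
            df, dv="y", between="group", within="epoch", subject="patient_id"
        )
        mine_f = dict(zip(mine["effect"], mine["F"]))
        theirs_f = dict(zip(theirs["Source"], theirs["F"]))
        assert mine_f["group"] == pytest.approx(theirs_f["group"], rel=1e-8)
        assert mine_f["epoch"] == pytest.approx(theirs_f["epoch"], rel=1e-8)
        assert mine_f["group * epoch"] == pytest.approx(
            theirs_f["Interaction"], rel=1e-8
        )

    def test_balanced_toy_ss_decomposition(self):
        """2 groups x 3 levels, n=4 per group, integer dv: SS terms match a
        hand computation."""
        data = {
            ("A", 0): [3, 4, 5, 4], ("A", 1): [5, 6, 7, 6], ("A", 2): [7, 8, 9, 8],
            ("B", 0): [2, 3, 2, 3], ("B", 1): [3, 4, 3, 4], ("B", 2): [4, 5, 4, 5],
        }
        rows = []
        for (g, t), vals in data.items():
            for i, v in enumerate(vals):
                rows.append((f"{g}{i}", g, t, float(v)))
        df = pd.DataFrame(rows, columns=["patient_id", "group", "epoch", "y"])
        out = mixed_anova(df, dv="y", between="group", within="epoch")
        # hand computation: grand = 4.75; group means A=6, B=3.5;
        # SS_group = 12*(6-4.75)^2 + 12*(3.5-4.75)^2 = 37.5
        # time means: (3.25, 4.75, 6.25); SS_time = 8*((1.5)^2+(0)^2+(1.5)^2)=36
        # cell means A: 4,6,8; B: 2.5,3.5,4.5
        # interaction: A deviations (4-6-3.25+4.75)= -0.5, 0, 0.5; same magnitude B
        # SS_inter = 4*(0.25+0+0.25)*2 = 4.0... computed below directly
        grand = df["y"].mean()
        assert grand == pytest.approx(4.75)
        f = dict(zip(out["effect"], out["F"]))
        # subject means have zero within-group variance given the symmetric
        # construction? -> compute expected F directly from the SS identities
        t_levels, n_subj = 3, 8
        subj_means = df.groupby("patient_id")["y"].mean()
        group_means = df.groupby("group")["y"].mean()
        ss_group = t_levels * 4 * (
            (group_means["A"] - grand) ** 2 + (group_means["B"] - grand) ** 2
        )
        assert ss_group == pytest.approx(37.5)
        ss_subj = t_levels * ((subj_means - subj_means.groupby(
            df.set_index("patient_id")["group"].groupby(level=0).first()
        ).transform("mean")) ** 2).sum()
        f_group_expected = (ss_group / 1) / (ss_subj / 6)
        assert f["group"] == pytest.approx(f_group_expected)

    def test_constant_dv_reports_missing(self):
        rows = [
            (f"{g}{i}", g, t, 1.0)
            for g in ("A", "B") for i in range(3) for t in ("P0", "P1")
        ]
        df = pd.DataFrame(rows, columns=["patient_id", "group", "epoch", "y"])
        out = mixed_anova(df, dv="y", between="group", within="epoch")
        assert np.isnan(out["F"]).all()
        assert np.isnan(out["p"]).all()

    def test_small_group_rejected(self):
        rows = [("a1", "A", "P0", 1.0), ("b1", "B", "P0", 2.0),
                ("b2", "B", "P0", 3.0)]
        df = pd.DataFrame(rows, columns=["patient_id", "group", "epoch", "y"])
        with pytest.raises(ValueError, match="2 subjects"):
            mixed_anova(df, dv="y", between="group", within="epoch")

    def test_incomplete_subject_dropped_with_warning(self):
        rows = [
            (f"{g}{i}", g, t, np.random.default_rng(i).normal())
            for g in ("A", "B") for i in range(3) for t in ("P0", "P1")
        ]
        rows.append(("A9", "A", "P0", 1.0))  # missing P1
        df = pd.DataFrame(rows, columns=["patient_id", "group", "epoch", "y"])
        with pytest.warns(UserWarning, match="dropping 1"):
            out = mixed_anova(df, dv="y", between="group", within="epoch")
        assert out["df2"].iloc[0] == 4  # 6 subjects - 2 groups


class TestTwoSampleT:
    def test_identical_groups(self):
        t, df, p = two_sample_t(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        """{1,2,3} vs {4,5,6}: pooled t = -3.674, df = 4."""
        t, df, p = two_sample_t(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert t == pytest.approx(-3.674, abs=5e-4)
        assert df == 4

    def test_antisymmetry(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=8), rng.normal(1, 1, size=6)
        t1, _, p1 = two_sample_t(a, b)
        t2, _, p2 = two_sample_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_pooled_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            two_sample_t(np.array([1.0, 1, 1]), np.array([2.0, 2, 2]))

    def test_welch_flag(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(0, 1, 10), rng.normal(0, 5, 4)
        t_w, df_w, _ = two_sample_t(a, b, welch=True)
        _, df_p, _ = two_sample_t(a, b, welch=False)
        assert df_w < df_p  # Welch loses degrees of freedom


def _bh_bruteforce(p, alpha):
    """Oracle: largest k with p_(k) <= k*alpha/m; reject the k smallest."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestBhFdr:
    def test_all_small_p_rejected(self):
        adj, rej = bh_fdr(np.full(10, 0.001))
        assert rej.all()

    def test_hand_stepped_example(self):
        adj, rej = bh_fdr([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.5])
        assert list(rej) == [True, True, True, False]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10)
    )
    def test_rejection_set_matches_bruteforce(self, p):
        p = np.asarray(p)
        _, rej = bh_fdr(p, alpha=0.05)
        assert np.array_equal(rej, _bh_bruteforce(p, 0.05))

    def test_adjusted_p_monotone_in_rank(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=25)
        adj, _ = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestDemographics:
    def test_packaged_fixture_group_summaries(self):
        """Nerve-block group: age 17.6 +/- 3.59 (n=11, 6 F); no-block group:
        18.9 +/- 2.80 (n=8, 5 F)."""
        from nirspipe.io import load_patients

        demo = demographic_summary(load_patients())
        nb = demo.loc["NB"]
        non = demo.loc["non-NB"]
        assert nb["n"] == 11
        assert round(nb["age_mean"], 1) == 17.6
        assert round(nb["age_sd"], 2) == 3.59
        assert nb["n_female"] == 6
        assert non["n"] == 8
        assert round(non["age_mean"], 1) == 18.9
        assert round(non["age_sd"], 2) == 2.80
        assert non["n_female"] == 5
        assert nb["fraction"] == pytest.approx(11 / 19)

    def test_single_patient_group_sd_missing(self):
        from nirspipe.io import PatientRecord

        patients = [
            PatientRecord("1", 20, "F", "R", True, 2),
            PatientRecord("2", 22, "M", "L", False, 3),
            PatientRecord("3", 24, "M", "L", False, 3),
        ]
        demo = demographic_summary(patients)
        assert np.isnan(demo.loc["NB", "age_sd"])
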