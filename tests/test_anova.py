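"""Variance partitioning: R2, ICC, df bookkeeping, recovery, permutation null."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import morphoerror as me

# the six repeatability rows of the published summary: (SS_among, MS_among,
# SS_within, MS_within, printed R2 among/within, printed ICC)
PUBLISHED_ROWS = [
    ("size-all", 2548.6, 134.1, 61.3, 1.5, 98, 2, 0.98),
    ("size-bone", 1905.4, 100.3, 65.7, 1.6, 97, 3, 0.97),
    ("size-nose", 458.2, 24.1, 99.6, 2.5, 82, 18, 0.81),
    ("shape-all", 0.1467, 0.000203, 0.0566, 0.000037, 72, 28, 0.69),
    ("shape-bone", 0.1314, 0.000301, 0.0626, 0.000068, 68, 32, 0.63),
    ("shape-nose", 0.2995, 0.001970, 0.0660, 0.000206, 82, 18, 0.81),
]


class TestR2:
    @pytest.mark.parametrize(
        "name,ss_a,_ms_a,ss_w,_ms_w,r2_a,r2_w,_icc", PUBLISHED_ROWS
    )
    def test_published_rows_reproduced_at_rounding(
        self, name, ss_a, _ms_a, ss_w, _ms_w, r2_a, r2_w, _icc
    ):
        total = ss_a + ss_w
        assert round(me.r2_from_ss(ss_a, total)) == r2_a
        assert round(me.r2_from_ss(ss_w, total)) == r2_w

    def test_edges_and_errors(self):
        assert me.r2_from_ss(0.0, 5.0) == 0.0
        assert me.r2_from_ss(5.0, 5.0) == 100.0
        with pytest.raises(ValueError):
            me.r2_from_ss(1.0, 0.0)
        with pytest.raises(ValueError):
            me.r2_from_ss(2.0, 1.0)


class TestIcc:
    @pytest.mark.parametrize(
        "name,_ss_a,ms_a,_ss_w,ms_w,_r2a,_r2w,icc", PUBLISHED_ROWS
    )
    def test_published_iccs_reproduced(
        self, name, _ss_a, ms_a, _ss_w, ms_w, _r2a, _r2w, icc
    ):
        assert round(me.icc_from_ms(ms_a, ms_w).icc, 2) == icc

    def test_limits(self):
        assert me.icc_from_ms(3.0, 0.0).icc == 1.0
        assert me.icc_from_ms(3.0, 3.0).icc == 0.0
        with pytest.raises(ValueError):
            me.icc_from_ms(0.0, 0.0)

    def test_one_way_variant_differs(self):
        sym = me.icc_from_ms(134.1, 1.5).icc
        ow = me.icc_from_ms(134.1, 1.5, variant="one_way", k=3).icc
        assert ow < sym
        assert ow == pytest.approx((134.1 - 1.5) / (134.1 + 2 * 1.5))


class TestRepeatability:
    @pytest.mark.parametrize(
        "subset,df_ind,df_err", [("all", 722, 1520), ("bone", 437, 920), ("nose", 152, 320)]
    )
    def test_shape_df_bookkeeping(self, zero_noise_replica, subset, df_ind, df_err):
        ds, _ = zero_noise_replica
        sub = ds.select_subset(subset)
        fit = me.gpa_align(sub)
        table, _icc = me.repeatability_anova(fit, trait="shape")
        rows = table.rows.set_index("effect")
        assert rows.loc["individual", "df"] == df_ind
        assert rows.loc["residual", "df"] == df_err

    def test_zero_noise_perfect_repeatability(self, zero_noise_replica):
        ds, _ = zero_noise_replica
        fit = me.gpa_align(ds)
        table, icc = me.repeatability_anova(fit, trait="shape")
        assert table.r2("residual") == pytest.approx(0.0, abs=1e-9)
        assert icc.icc == pytest.approx(1.0, abs=1e-9)
        cs = np.array([me.centroid_size(r.coords) for r in ds.records])
        t2, icc2 = me.repeatability_anova(
            cs, ds.meta()["individual_id"].to_numpy(), trait="size"
        )
        assert t2.r2("residual") == pytest.approx(0.0, abs=1e-9)
        assert icc2.icc == pytest.approx(1.0, abs=1e-9)

    def test_unbalanced_design_rejected(self, replica):
        ds, _ = replica
        dropped = ds.filter(
            lambda r: not (r.individual_id == "ind01" and r.operator_id == "OP3")
        )
        fit = me.gpa_align(dropped)
        with pytest.raises(ValueError, match="balanced"):
            me.repeatability_anova(fit, trait="shape")

    def test_icc_monte_carlo_matches_variance_components(self):
        # sigma_b^2 = 9, sigma_w^2 = 1, n = 200, k = 3
        rng = np.random.default_rng(12)
        n, k = 200, 3
        mu = rng.normal(scale=3.0, size=n)
        y = (mu[:, None] + rng.normal(scale=1.0, size=(n, k))).ravel()
        ids = np.repeat([f"i{j}" for j in range(n)], k)
        _table, icc_ow = me.repeatability_anova(
            y, ids, trait="size", icc_variant="one_way"
        )
        assert abs(icc_ow.icc - 9.0 / 10.0) <= 0.05
        _t2, icc_sym = me.repeatability_anova(y, ids, trait="size")
        # symmetric form converges to k*sb^2 / (k*sb^2 + 2*sw^2)
        assert abs(icc_sym.icc - 27.0 / 29.0) <= 0.05

    def test_single_axis_shape_equals_classical_anova(self):
        rng = np.random.default_rng(13)
        n, k = 12, 3
        y = (rng.normal(scale=2.0, size=n)[:, None] + rng.normal(size=(n, k))).ravel()
        ids = np.repeat(np.arange(n), k)
        table, _ = me.repeatability_anova(
            y.reshape(-1, 1), ids, trait="shape", shape_dim=1
        )
        groups = [y[ids == i] for i in range(n)]
        f_ref, p_ref = stats.f_oneway(*groups)
        rows = table.rows.set_index("effect")
        assert rows.loc["individual", "F"] == pytest.approx(f_ref, rel=1e-10)
        assert rows.loc["individual", "P"] == pytest.approx(p_ref, rel=1e-8)

    def test_permutation_p_uniform_under_null(self):
        # pure-noise datasets: permutation p-values must be uniform
        rng = np.random.default_rng(14)
        n, k, b = 10, 2, 99
        pvals = []
        for rep in range(150):
            y = rng.normal(size=n * k)
            ids = np.repeat(np.arange(n), k)
            table, _ = me.repeatability_anova(
                y, ids, trait="size", n_permutations=b, seed=rep
            )
            pvals.append(table.rows.attrs["p_permutation"]["individual"])
        d, p = stats.kstest(pvals, "uniform")
        assert p > 0.001


class TestGrouping:
    def test_null_r2_matches_permutation_expectation(self, replica_fit):
        # exchangeable labels: E[R2] ~ 100 * (g-1)/(n-1)
        rng = np.random.default_rng(15)
        n = replica_fit.n
        labels = np.repeat(["A", "B", "C"], n // 3)
        r2s = []
        for _ in range(50):
            perm = rng.permutation(labels)
            t = me.grouping_anova(replica_fit, perm, trait="shape")
            r2s.append(t.r2("operator"))
        expected = 100.0 * 2 / (n - 1)
        assert np.mean(r2s) == pytest.approx(expected, abs=1.5)

    def test_zero_between_group_ss_for_identical_groups(self, zero_noise_replica):
        ds, _ = zero_noise_replica
        fit = me.gpa_align(ds)
        t = me.grouping_anova(fit, ds.meta()["operator_id"].to_numpy(), trait="shape")
        assert t.r2("operator") == pytest.approx(0.0, abs=1e-9)

    def test_recovers_designed_bias_share(self):
        diffs = []
        for seed in range(20):
            ds, truth = me.generate_replica_study(me.replica_spec(seed=300 + seed))
            fit = me.gpa_align(ds)
            t = me.grouping_anova(fit, ds.meta()["operator_id"].to_numpy(), trait="shape")
            diffs.append(t.r2("operator") / 100.0 - truth.design_fractions["operator"])
        assert abs(np.mean(diffs)) <= 0.05


class TestHierarchical:
    def test_r2_conservation(self, small_study):
        ds, _ = small_study
        meta = ds.meta()
        cs = np.array([me.centroid_size(r.coords) for r in ds.records])
        t = me.hierarchical_anova(
            cs, meta["sex"].to_numpy(), meta["operator_id"].to_numpy(), trait="size"
        )
        assert t.rows["R2"].sum() == pytest.approx(100.0, abs=1e-6)
        assert t.rows["SS"].sum() == pytest.approx(t.ss_total, rel=1e-12)

    def test_single_sex_reduces_to_grouping(self, replica):
        ds, _ = replica
        meta = ds.meta()
        cs = np.array([me.centroid_size(r.coords) for r in ds.records])
        h = me.hierarchical_anova(
            cs, meta["sex"].to_numpy(), meta["operator_id"].to_numpy(), trait="size"
        )
        g = me.grouping_anova(cs, meta["operator_id"].to_numpy(), trait="size")
        assert "sex" not in set(h.rows["effect"])
        assert h.r2("operator") == pytest.approx(g.r2("operator"), rel=1e-9)

    def test_matches_statsmodels_type1_sequential(self, small_study):
        statsmodels = pytest.importorskip("statsmodels.api")
        from statsmodels.formula.api import ols
        from statsmodels.stats.anova import anova_lm

        ds, _ = small_study
        meta = ds.meta()
        cs = np.array([me.centroid_size(r.coords) for r in ds.records])
        t = me.hierarchical_anova(
            cs, meta["sex"].to_numpy(), meta["operator_id"].to_numpy(), trait="size"
        )
        df = meta.assign(cs=cs)
        ref = anova_lm(ols("cs ~ C(sex) + C(operator_id)", data=df).fit(), typ=1)
        rows = t.rows.set_index("effect")
        assert rows.loc["sex", "SS"] == pytest.approx(ref.loc["C(sex)", "sum_sq"])
        assert rows.loc["operator", "SS"] == pytest.approx(
            ref.loc["C(operator_id)", "sum_sq"]
        )
        assert rows.loc["residual", "SS"] == pytest.approx(
            ref.loc["Residual", "sum_sq"]
        )

    def test_recovers_size_dimorphism_with_zero_bias(self):
        zero_bias = {op: np.zeros((15, 3)) for op in ("OP1", "OP2", "OP3")}
        sex_r2, op_r2 = [], []
        for seed in range(10):
            counts = {
                ("OP1", "F"): 26, ("OP1", "M"): 15, ("OP2", "F"): 27,
                ("OP2", "M"): 41, ("OP3", "F"): 63, ("OP3", "M"): 56,
            }
            spec = me.study_spec(
                seed=400 + seed, sex_counts=counts, n_individuals=228,
                operator_bias=zero_bias,
            )
            ds, _ = me.generate_study_sample(spec)
            meta = ds.meta()
            cs = np.array([me.centroid_size(r.coords) for r in ds.records])
            t = me.hierarchical_anova(
                cs, meta["sex"].to_numpy(), meta["operator_id"].to_numpy(), trait="size"
            )
            sex_r2.append(t.r2("sex"))
            op_r2.append(t.r2("operator"))
        # designed expectation: p(1-p) d^2 / (p(1-p) d^2 + sigma^2)
        p = 112 / 228
        d, sigma2 = 14.0, 36.0
        expected = 100 * p * (1 - p) * d**2 / (p * (1 - p) * d**2 + sigma2)
        assert np.mean(sex_r2) == pytest.approx(expected, abs=5.0)
        # bias-free: operator share shrinks to the null expectation
        # (g-1)/(n-1), i.e. well under one percent on average
        assert np.mean(op_r2) < 1.0

    def test_empty_cell_warns(self):
        rng = np.random.default_rng(16)
        y = rng.normal(size=20)
        sex = np.array(["F"] * 10 + ["M"] * 10)
        op = np.array(["OP1"] * 10 + ["OP2"] * 5 + ["OP3"] * 5)
        with pytest.warns(UserWarning, match="empty"):
            me.hierarchical_anova(y, sex, op, trait="size")


class TestBalancedSubsample:
    def test_n300_and_reproducibility(self, small_study):
        ds, _ = small_study
        t1, ids1 = me.balanced_subsample_r2(ds, 15, seed=7, trait="size")
        t2, ids2 = me.balanced_subsample_r2(ds, 15, seed=7, trait="size")
        assert len(ids1) == 90 and ids1 == ids2
        pd.testing.assert_frame_equal(t1.rows, t2.rows)
        t3, ids3 = me.balanced_subsample_r2(ds, 15, seed=8, trait="size")
        assert ids3 != ids1

    def test_insufficient_cell_names_it(self, small_study):
        ds, _ = small_study
        with pytest.raises(ValueError, match="OP1"):
            me.balanced_subsample_r2(ds, 50, seed=1, trait="size")

    def test_balanced_matches_unbalanced_without_bias(self):
        zero_bias = {op: np.zeros((15, 3)) for op in ("OP1", "OP2", "OP3")}
        deltas_sex, deltas_op = [], []
        for seed in range(10):
            counts = {
                ("OP1", "F"): 26, ("OP1", "M"): 15, ("OP2", "F"): 27,
                ("OP2", "M"): 41, ("OP3", "F"): 63, ("OP3", "M"): 56,
            }
            spec = me.study_spec(
                seed=500 + seed, sex_counts=counts, n_individuals=228,
                operator_bias=zero_bias,
            )
            ds, _ = me.generate_study_sample(spec)
            meta = ds.meta()
            cs = np.array([me.centroid_size(r.coords) for r in ds.records])
            unbal = me.hierarchical_anova(
                cs, meta["sex"].to_numpy(), meta["operator_id"].to_numpy(), trait="size"
            )
            bal, _ids = me.balanced_subsample_r2(ds, 15, seed=seed, trait="size")
            deltas_sex.append(bal.r2("sex") - unbal.r2("sex"))
            deltas_op.append(bal.r2("operator") - unbal.r2("operator"))
        assert abs(np.mean(deltas_sex)) <= 3.0
        assert abs(np.mean(deltas_op)) <= 3.0


def test_ss_additivity_enforced_by_table_type():
    rows = pd.DataFrame(
        [("a", 2.0, 1, 2.0, np.nan, np.nan, 50.0),
         ("residual", 2.0, 2, 1.0, np.nan, np.nan, 50.0)],
        columns=["effect", "SS", "df", "MS", "F", "P", "R2"],
    )
    me.AnovaTable(trait="size", rows=rows, shape_dim=1)  # valid
    bad = rows.copy()
    bad.loc[0, "R2"] = 70.0
    with pytest.raises(ValueError):
        me.AnovaTable(trait="size", rows=bad, shape_dim=1)
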