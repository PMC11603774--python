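import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ntaflow import diffstats, synth
from ntaflow.types import ValidationError

from conftest import build_table


def bh_oracle(p):
    """Textbook step-up: q_(k) = min_{j >= k} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        q[idx] = min(
            min(p[order[j - 1]] * m / j for j in range(rank, m + 1)), 1.0
        )
    return q


class TestBhAdjust:
    def test_hand_example(self):
        # 0.01*4/1=0.04, 0.02*4/2=0.04, 0.03*4/3=0.04, 0.04*4/4=0.04
        q = diffstats.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_empty(self):
        assert len(diffstats.bh_adjust(np.array([]))) == 0

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.uniform(size=500)
        q = diffstats.bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    @pytest.mark.parametrize("n", [1, 2, 10, 1000, 10_000])
    def test_matches_brute_force_oracle(self, n, rng):
        p = rng.uniform(size=n)
        np.testing.assert_allclose(diffstats.bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=777)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(diffstats.bh_adjust(p), q_sm, atol=1e-12)

    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_property_matches_oracle(self, p):
        p = np.array(p)
        np.testing.assert_allclose(diffstats.bh_adjust(p), bh_oracle(p), atol=1e-12)


class TestDifferentialTest:
    def make_table(self, n_features=20, n_per_group=10, effect=0.0, seed=0):
        rng = np.random.default_rng(seed)
        log_x = rng.normal(5.0, 0.3, (n_features, 2 * n_per_group))
        log_x[:, :n_per_group] += effect * np.log10(2)
        outcome = ["preterm"] * n_per_group + ["term"] * n_per_group
        return build_table(np.power(10.0, log_x), outcome=outcome)

    def test_matches_scipy_welch_per_feature(self):
        table = self.make_table()
        res = diffstats.differential_test(table)
        logx = table.log10_abundance()
        a = logx.iloc[:, :10].to_numpy()
        b = logx.iloc[:, 10:].to_numpy()
        for i, fid in enumerate(res.index):
            _, p = stats.ttest_ind(a[i], b[i], equal_var=False)
            assert res.loc[fid, "p"] == pytest.approx(p, rel=1e-10)

    def test_log2fc_from_linear_means(self):
        table = self.make_table()
        res = diffstats.differential_test(table)
        ab = table.abundance
        expected = np.log2(
            ab.iloc[:, :10].mean(axis=1) / ab.iloc[:, 10:].mean(axis=1)
        )
        np.testing.assert_allclose(res["log2fc"], expected)

    def test_planted_effect_recovered(self):
        table = self.make_table(n_features=100, n_per_group=47, effect=2.0, seed=3)
        res = diffstats.differential_test(table)
        assert res["log2fc"].median() == pytest.approx(2.0, abs=0.2)

    def test_null_pvalues_approximately_uniform(self):
        table = self.make_table(n_features=2000, n_per_group=30, effect=0.0, seed=5)
        res = diffstats.differential_test(table)
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_degenerate_group_raises(self):
        table = self.make_table(n_per_group=1)
        with pytest.raises(ValidationError):
            diffstats.differential_test(table)

    def test_missing_values_rejected(self):
        table = self.make_table()
        table.abundance.iloc[0, 0] = np.nan
        with pytest.raises(ValidationError):
            diffstats.differential_test(table)


class TestVolcanoClassify:
    def make_results(self, rows):
        return pd.DataFrame(rows, columns=["log2fc", "p"]).assign(q=lambda d: d["p"])

    def test_examples(self):
        res = diffstats.volcano_classify(
            self.make_results([(1.5, 0.01), (-1.3, 0.001), (2.0, 0.2), (0.5, 0.01)])
        )
        assert list(res["volcano_class"]) == ["up", "down", "not_significant", "not_significant"]

    def test_boundaries_exclusive(self):
        res = diffstats.volcano_classify(
            self.make_results([(1.2, 0.01), (1.21, 0.05), (1.21, 0.049)])
        )
        # fc exactly at cutoff -> not significant; p at cutoff -> not significant
        assert list(res["volcano_class"]) == [
            "not_significant", "not_significant", "up",
        ]

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=-10, max_value=10),
                st.floats(min_value=1e-12, max_value=1.0),
            ),
            min_size=1,
            max_size=50,
        ),
        st.floats(min_value=0.001, max_value=0.5),
        st.floats(min_value=0.1, max_value=5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_classes_partition_input(self, rows, p_cut, fc_cut):
        res = diffstats.volcano_classify(self.make_results(rows), p_cut, fc_cut)
        for _, row in res.iterrows():
            expected = "not_significant"
            if row["p"] < p_cut and row["log2fc"] > fc_cut:
                expected = "up"
            elif row["p"] < p_cut and row["log2fc"] < -fc_cut:
                expected = "down"
            assert row["volcano_class"] == expected


class TestRunPca:
    def test_planted_dominant_axis(self, rng):
        latent = rng.normal(size=30)
        loadings = rng.normal(size=50)
        log_x = 5 + 2.0 * np.outer(loadings, latent) + rng.normal(0, 0.05, (50, 30))
        table = build_table(np.power(10.0, log_x))
        pca = diffstats.run_pca(table)
        assert pca.variance_explained[0] > 0.9

    def test_batch_correlation_detected_and_reduced(self):
        from test_normalize import planted_batch_table
        from ntaflow import normalize

        table, _, _ = planted_batch_table(n_features=200, n_samples=120, seed=2)
        pre = diffstats.run_pca(table, covariates=("batch",))
        pre_r = pre.covariate_correlations
        # shifts are not monotone in batch index, so the one-way ANOVA is the
        # sensitive detector; the Pearson coding is still reported
        assert (pre_r.loc[pre_r["covariate"] == "batch", "anova_p"] < 0.01).any()
        corrected, _ = normalize.combat_correct(table)
        post = diffstats.run_pca(corrected, covariates=("batch",))
        post_r = post.covariate_correlations
        assert (
            post_r.loc[post_r["covariate"] == "batch", "r"].abs().max()
            < pre_r.loc[pre_r["covariate"] == "batch", "r"].abs().max()
        )

    def test_permuted_outcome_pvalues_uniform(self, rng):
        # under a permuted (null) labelling the PC1-outcome correlation
        # p-value should be uniform across replicates
        log_x = rng.normal(5, 0.3, (40, 30))
        table = build_table(np.power(10.0, log_x))
        pvals = []
        for _ in range(200):
            outcome = rng.permutation(["preterm"] * 15 + ["term"] * 15)
            table.samples["outcome"] = outcome
            pca = diffstats.run_pca(table, covariates=("outcome",))
            corr = pca.covariate_correlations
            pvals.append(float(corr.loc[corr["pc"] == "PC1", "p"].iloc[0]))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_constant_feature_excluded_with_warning(self):
        ab = np.power(10.0, np.random.default_rng(0).normal(5, 0.3, (10, 8)))
        ab[0, :] = 1e5
        table = build_table(ab)
        with pytest.warns(UserWarning, match="constant"):
            pca = diffstats.run_pca(table)
        assert pca.excluded_features == ["F001"]

    def test_too_few_samples(self):
        table = build_table(np.full((5, 2), 1e5))
        with pytest.raises(ValidationError):
            diffstats.run_pca(table)

    def test_variance_explained_nonincreasing(self, rng):
        table = build_table(np.power(10.0, rng.normal(5, 0.3, (30, 20))))
        pca = diffstats.run_pca(table)
        ve = pca.variance_explained
        assert (np.diff(ve) <= 1e-12).all()
        assert ((0 <= ve) & (ve <= 1)).all()


class TestClusterHeatmapMatrix:
    def test_identical_features_merge_at_zero(self, rng):
        base = rng.normal(5, 0.3, 12)
        ab = np.power(10.0, np.vstack([base, base, rng.normal(5, 0.3, 12)]))
        table = build_table(ab)
        out = diffstats.cluster_heatmap_matrix(table)
        # first merge joins the two identical features at distance ~0
        assert out.feature_linkage[0, 2] == pytest.approx(0.0, abs=1e-10)
        merged = {int(out.feature_linkage[0, 0]), int(out.feature_linkage[0, 1])}
        assert merged == {0, 1}

    def test_planted_blocks_separate_in_leaf_order(self, rng):
        n = 10
        f1 = rng.normal(size=24)
        f2 = rng.normal(size=24)
        block1 = 5 + 0.5 * np.vstack([f1] * n) + rng.normal(0, 0.05, (n, 24))
        block2 = 5 + 0.5 * np.vstack([f2] * n) + rng.normal(0, 0.05, (n, 24))
        table = build_table(np.power(10.0, np.vstack([block1, block2])))
        out = diffstats.cluster_heatmap_matrix(table)
        positions = {fid: i for i, fid in enumerate(out.feature_order)}
        block1_pos = sorted(positions[f"F{i + 1:03d}"] for i in range(n))
        # a planted block occupies a contiguous run of leaves
        assert block1_pos == list(range(block1_pos[0], block1_pos[0] + n))

    def test_leaf_order_stable_under_row_permutation(self, rng):
        ab = np.power(10.0, rng.normal(5, 0.5, (15, 10)))
        table = build_table(ab)
        out1 = diffstats.cluster_heatmap_matrix(table)
        perm = rng.permutation(15)
        table2 = table.subset_features([table.abundance.index[i] for i in perm])
        out2 = diffstats.cluster_heatmap_matrix(table2)
        order1 = list(out1.feature_order)
        order2 = list(out2.feature_order)
        assert order1 == order2 or order1 == order2[::-1] or set(order1) == set(order2)

    def test_degenerate_sizes_raise(self):
        with pytest.raises(ValidationError):
            diffstats.cluster_heatmap_matrix(build_table(np.full((1, 5), 1e5)))


class TestFdrCalibration:
    def test_null_plus_planted_fdr_controlled_small(self, rng):
        # reduced version of the headline calibration (full one in acceptance)
        fdps = []
        for _ in range(40):
            linear, groups, planted = synth.null_planted_matrix(
                rng, n_samples=60, n_features=400, n_planted=40, n_group_a=25
            )
            _, _, q = diffstats.welch_bh(linear, groups)
            discoveries = q < 0.05
            if discoveries.any():
                fdps.append((discoveries & ~planted).sum() / discoveries.sum())
            else:
                fdps.append(0.0)
        assert np.mean(fdps) <= 0.05 + 2 * np.std(fdps) / np.sqrt(len(fdps))
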