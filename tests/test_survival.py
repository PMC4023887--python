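"""KM, logrank, cut-point selection, clustering and Cox against hand oracles."""

import numpy as np
import pandas as pd
import pytest

from regrescue.survival import (
    cox_fit,
    km_estimate,
    logrank_test,
    single_gene_cutpoint,
    two_cluster_partition,
)


class TestKm:
    def test_product_limit_by_hand(self):
        c = km_estimate([1, 2], [True, True])
        assert c.at(1) == pytest.approx(0.5)
        assert c.at(2) == pytest.approx(0.0)
        assert c.at(0) == 1.0

    def test_censoring_freezes_curve(self):
        c = km_estimate([1, 2], [True, False])
        assert c.at(1) == pytest.approx(0.5)
        assert c.at(5) == pytest.approx(0.5)

    def test_all_censored_and_validation(self):
        c = km_estimate([3, 5, 7], [False, False, False])
        assert np.all(c.survival == 1.0)
        assert np.all(np.diff(km_estimate([1, 2, 2, 5], [1, 1, 0, 1]).survival) <= 0)
        with pytest.raises(ValueError, match="positive"):
            km_estimate([0, 1], [True, True])

    def test_matches_closed_form_on_random_instance(self):
        rng = np.random.default_rng(23)
        t = rng.exponential(10, 30).round(2) + 0.01
        e = rng.random(30) < 0.7
        curve = km_estimate(t, e)
        # independent product-limit computation
        s = 1.0
        for u in sorted(set(t[e])):
            n_at_risk = np.sum(t >= u)
            d = np.sum((t == u) & e)
            s *= 1 - d / n_at_risk
            assert curve.at(u) == pytest.approx(s)


class TestLogrank:
    def test_worked_example(self):
        # hand computation: O-E = 7/6, V = 17/36 -> chi2 = 49/17
        chi2, p = logrank_test([1, 2, 3, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])
        assert chi2 == pytest.approx(49 / 17, rel=1e-9)

    def test_identical_groups_are_null(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1] * 8
        chi2, p = logrank_test(t, e, ["A"] * 4 + ["B"] * 4)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_label_swap_invariance_and_validation(self):
        rng = np.random.default_rng(24)
        t = rng.exponential(5, 20) + 0.01
        e = rng.random(20) < 0.8
        g = np.array(["A", "B"] * 10)
        c1, _ = logrank_test(t, e, g)
        c2, _ = logrank_test(t, e, np.where(g == "A", "B", "A"))
        assert c1 == pytest.approx(c2)
        with pytest.raises(ValueError, match="no events"):
            logrank_test([1, 2], [0, 0], ["A", "B"])
        with pytest.raises(ValueError, match=">= 2 groups"):
            logrank_test([1, 2], [1, 1], ["A", "A"])


class TestCutpoint:
    def test_finds_gap_in_separated_toy(self):
        # low expression -> late events; high -> early events; gap at 5
        x = np.array([1, 2, 3, 3.5, 4, 6, 7, 8, 9, 9.5])
        t = np.array([50, 60, 55, 58, 52, 5, 6, 4, 7, 5], float)
        e = np.ones(10, bool)
        res = single_gene_cutpoint(x, t, e)
        assert 4 < res.threshold < 6
        assert (res.labels == np.where(x > res.threshold, "high", "low")).all()

    def test_optimum_dominates_fixed_thresholds(self):
        rng = np.random.default_rng(25)
        x = rng.normal(0, 1, 40)
        t = rng.exponential(10, 40) + 0.01
        e = rng.random(40) < 0.8
        res = single_gene_cutpoint(x, t, e)
        for q in (0.2, 0.4, 0.6, 0.8):
            thr = np.quantile(x, q)
            labels = np.where(x > thr, "high", "low")
            chi2, _ = logrank_test(t, e, labels)
            assert res.chi2 >= chi2 - 1e-9

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(26)
        x = rng.normal(0, 1, 30)
        t = rng.exponential(10, 30) + 0.01
        e = rng.random(30) < 0.8
        a = single_gene_cutpoint(x, t, e)
        b = single_gene_cutpoint(np.exp(x), t, e)
        assert (a.labels == b.labels).all()
        assert a.chi2 == pytest.approx(b.chi2)

    def test_constant_expression_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            single_gene_cutpoint(np.ones(12), np.arange(1, 13), np.ones(12, bool))

    def test_permutation_p_for_null_data_is_large(self):
        rng = np.random.default_rng(27)
        x = rng.normal(0, 1, 30)
        t = rng.exponential(10, 30) + 0.01
        e = np.ones(30, bool)
        res = single_gene_cutpoint(x, t, e, n_permutations=30, rng=rng)
        assert res.p_permutation is not None
        assert res.p_permutation > res.pvalue  # selection penalty


class TestTwoClusterPartition:
    def make_expr(self, rng, shift=3.0, n1=10, n2=8, genes=15):
        vals = rng.normal(0, 1, (genes, n1 + n2))
        vals[:, n1:] += shift
        cols = [f"s{j}" for j in range(n1 + n2)]
        return pd.DataFrame(vals, index=[f"g{i}" for i in range(genes)], columns=cols)

    def test_recovers_planted_blocks_exactly(self):
        rng = np.random.default_rng(28)
        expr = self.make_expr(rng)
        labels = two_cluster_partition(expr)
        assert set(labels.iloc[:10]) == {1}
        assert set(labels.iloc[10:]) == {2}  # higher-expression cluster labelled 2

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(29)
        expr = self.make_expr(rng)
        perm = rng.permutation(expr.columns)
        labels = two_cluster_partition(expr)
        labels_perm = two_cluster_partition(expr[perm])
        assert (labels_perm.loc[labels.index] == labels).all()

    def test_duplicated_samples_co_cluster(self):
        rng = np.random.default_rng(30)
        expr = self.make_expr(rng, n1=6, n2=5)
        dup = pd.concat([expr, expr.add_suffix("_dup", axis=1)], axis=1)
        labels = two_cluster_partition(dup)
        for s in expr.columns:
            assert labels[s] == labels[f"{s}_dup"]

    def test_too_few_genes_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=["a", "b", "c"])
        with pytest.raises(ValueError, match=">= 2 signature genes"):
            two_cluster_partition(expr)


class TestCox:
    def simulate(self, rng, n=500, log_hr=0.7, censor_frac=0.3):
        x = (rng.random(n) < 0.5).astype(float)
        rate = 0.02 * np.exp(log_hr * x)
        et = rng.exponential(1 / rate)
        ct = rng.exponential(1 / (censor_frac / (1 - censor_frac) * rate.mean()), n)
        return pd.DataFrame(
            {"time": np.minimum(et, ct), "event": (et <= ct).astype(int), "cluster2": x}
        )

    def test_recovers_planted_log_hr(self):
        rng = np.random.default_rng(31)
        est = np.mean([
            np.log(cox_fit(self.simulate(rng)).summary.loc["cluster2", "hr"])
            for _ in range(5)
        ])
        assert est == pytest.approx(0.7, abs=0.15)

    def test_null_covariate_has_small_coefficient(self):
        rng = np.random.default_rng(32)
        df = self.simulate(rng, log_hr=0.0)
        fit = cox_fit(df)
        assert abs(fit.summary.loc["cluster2", "coef"]) < 0.25
        assert fit.summary.loc["cluster2", "hr"] == pytest.approx(
            np.exp(fit.summary.loc["cluster2", "coef"])
        )

    def test_listwise_deletion_counted(self):
        rng = np.random.default_rng(33)
        df = self.simulate(rng, n=100)
        df.loc[df.index[:7], "cluster2"] = np.nan
        fit = cox_fit(df)
        assert fit.n_dropped == 7 and fit.n_used == 93

    def test_constant_covariate_rejected(self):
        rng = np.random.default_rng(34)
        df = self.simulate(rng, n=50)
        df["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df)

    def test_categorical_covariate_dummy_coded(self):
        rng = np.random.default_rng(35)
        df = self.simulate(rng, n=200)
        df["margin"] = np.where(rng.random(200) < 0.4, "positive", "negative")
        fit = cox_fit(df)
        assert "margin_positive" in fit.summary.index
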