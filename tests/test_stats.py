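"""Trait statistics: normality, correlation, UPGMA, group and two-sample tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import spikequad as sq


def naive_upgma(d):
    """O(n^3) reference agglomeration: average linkage on a distance matrix."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    active = list(range(n))
    d = d.copy().astype(float)
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    nxt = n
    while len(active) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: kv[1])
        merges.append((i, j, h, len(clusters[i]) + len(clusters[j])))
        clusters[nxt] = clusters[i] + clusters[j]
        active = [a for a in active if a not in (i, j)]
        new = {}
        for a in active:
            pa, pb = (min(a, i), max(a, i)), (min(a, j), max(a, j))
            da, db = dist[pa], dist[pb]
            wa, wb = len(clusters[i]), len(clusters[j])
            new[(a, nxt)] = (wa * da + wb * db) / (wa + wb)
        dist = {k: v for k, v in dist.items()
                if i not in k and j not in k}
        dist.update(new)
        active.append(nxt)
        nxt += 1
    return merges


class TestNormalityScan:
    def test_constant_vector_flagged(self):
        t = pd.DataFrame({"SL": [5.0] * 10})
        out = sq.normality_scan(t, traits=["SL"])
        assert not out.loc[0, "ok"]

    def test_small_n_skipped(self):
        t = pd.DataFrame({"SL": [1.0, 2.0]})
        out = sq.normality_scan(t, traits=["SL"])
        assert not out.loc[0, "ok"]

    def test_lognormal_rejected(self):
        rng = np.random.default_rng(4)
        t = pd.DataFrame({"SL": np.exp(rng.normal(0, 1, 100))})
        out = sq.normality_scan(t, traits=["SL"])
        assert out.loc[0, "p"] < 0.01

    def test_null_rejection_rate_calibrated(self):
        # Shapiro-Wilk on normal data rejects at about the nominal rate
        rng = np.random.default_rng(5)
        rejections = sum(
            sps.shapiro(rng.normal(0, 1, 50)).pvalue < 0.05 for _ in range(500)
        )
        assert 0.03 <= rejections / 500 <= 0.07


class TestCorrelationAndRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        slope, intercept, r = sq.pairwise_regression(x, 2 * x + 1)
        assert (slope, intercept, r) == pytest.approx((2.0, 1.0, 1.0))

    def test_anticorrelation(self):
        x = np.arange(10.0)
        assert sq.pairwise_regression(x, -x)[2] == pytest.approx(-1.0)

    def test_matrix_symmetric_unit_diagonal(self, population_table):
        r = sq.correlation_matrix(population_table,
                                  ["q_L", "q_S", "q_ym", "SL", "SDI"])
        assert np.allclose(r, r.T, equal_nan=True)
        assert np.allclose(np.diag(r), 1.0)

    def test_derived_trait_identity(self, population_table):
        # q_x2s == q_x2ns * q_L by construction
        t = population_table
        prod = t["q_x2ns"] * t["q_L"]
        r = np.corrcoef(t["q_x2s"], prod)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            sq.pairwise_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestTraitTree:
    def test_perfectly_correlated_merge_first(self):
        corr = pd.DataFrame(
            [[1.0, 1.0, 0.1], [1.0, 1.0, 0.1], [0.1, 0.1, 1.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        Z, leaves = sq.trait_tree(corr)
        assert leaves == list("ABC")
        assert Z[0, 2] == pytest.approx(0.0)
        assert set(Z[0, :2]) == {0.0, 1.0}

    def test_hand_computed_heights(self):
        corr = pd.DataFrame(
            [[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        Z, _ = sq.trait_tree(corr)
        assert Z[0, 2] == pytest.approx(0.1)   # d(A,B) = 1 - 0.9
        assert Z[1, 2] == pytest.approx(0.9)   # C joins at 1 - 0.1

    def test_matches_naive_agglomeration(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            n = rng.integers(4, 12)
            r = rng.uniform(-1, 1, (n, n))
            r = (r + r.T) / 2
            np.fill_diagonal(r, 1.0)
            corr = pd.DataFrame(r, index=[f"t{i}" for i in range(n)],
                                columns=[f"t{i}" for i in range(n)])
            Z, _ = sq.trait_tree(corr)
            merges = naive_upgma(1.0 - r)
            assert np.allclose(sorted(Z[:, 2]), sorted(m[2] for m in merges))

    def test_monotone_merge_heights(self, population_table):
        corr = sq.correlation_matrix(population_table)
        Z, leaves = sq.trait_tree(corr)
        assert set(leaves) <= set(population_table.columns)
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)


class TestGroupTests:
    def test_two_groups_F_equals_t_squared(self):
        rng = np.random.default_rng(7)
        t = pd.DataFrame({
            "species": ["A"] * 12 + ["B"] * 15,
            "q_L": np.concatenate([rng.normal(50, 5, 12), rng.normal(55, 5, 15)]),
        })
        out = sq.group_tests(t, "species", traits=["q_L"])
        a = t.loc[t.species == "A", "q_L"]
        b = t.loc[t.species == "B", "q_L"]
        tt = sps.ttest_ind(a, b)
        assert out.loc[0, "anova_F"] == pytest.approx(tt.statistic ** 2)
        assert out.loc[0, "anova_p"] == pytest.approx(tt.pvalue)

    def test_separated_groups_significant(self):
        t = pd.DataFrame({
            "species": list("AABBCC"),
            "q_L": [1.0, 2.0, 13.0, 14.0, 25.0, 26.0],
        })
        out = sq.group_tests(t, "species", traits=["q_L"])
        assert out.loc[0, "anova_p"] < 0.01
        # Kruskal-Wallis H is maximal for complete separation of ranks
        H = out.loc[0, "kruskal_H"]
        assert H == pytest.approx(sps.kruskal([1, 2], [13, 14], [25, 26])[0])

    def test_null_calibration_all_tests(self):
        rng = np.random.default_rng(8)
        alpha, reps = 0.05, 500
        rej = {"anova": 0, "levene": 0, "kruskal": 0}
        for _ in range(reps):
            groups = [rng.normal(0, 1, 20) for _ in range(3)]
            if sps.f_oneway(*groups).pvalue < alpha:
                rej["anova"] += 1
            if sps.levene(*groups, center="median").pvalue < alpha:
                rej["levene"] += 1
            if sps.kruskal(*groups).pvalue < alpha:
                rej["kruskal"] += 1
        for name, count in rej.items():
            assert 0.03 <= count / reps <= 0.07, name


class TestSummarize:
    def test_se_zero_for_identical(self):
        t = pd.DataFrame({"species": ["A"] * 4, "q_L": [7.0] * 4})
        out = sq.summarize_by_group(t, "species", traits=["q_L"])
        assert out.loc[0, "se"] == 0.0

    def test_extreme_flags(self):
        t = pd.DataFrame({"species": list("AABB"), "q_L": [1.0, 2.0, 9.0, 10.0]})
        out = sq.summarize_by_group(t, "species", traits=["q_L"])
        flags = dict(zip(out["group"], out["flag"]))
        assert flags == {"A": "min", "B": "max"}

    def test_class_means_recovered(self, population_table):
        out = sq.summarize_by_group(population_table, "species", traits=["q_L"])
        from spikequad.synthetic import SPECIES_TABLE

        for _, row in out.iterrows():
            ref = SPECIES_TABLE[row["group"]]
            mean_x = sum(ref[k][0] for k in ("q_x1s", "q_x2s", "q_x3s"))
            # sampled class mean close to the specified one (3 SE of n=25)
            assert abs(row["mean"] - mean_x) <= 3 * row["se"] + 0.05 * mean_x


class TestTwoSample:
    def test_summary_mode_matches_raw(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(10, 2, 8), rng.normal(12, 2, 9)
        t_raw, p_raw = sq.two_sample_from_summary(
            len(a), a.mean(), a.var(ddof=1), len(b), b.mean(), b.var(ddof=1)
        )
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert t_raw == pytest.approx(ref.statistic)
        assert p_raw == pytest.approx(ref.pvalue)

    def test_identical_groups(self):
        _, p = sq.two_sample_from_summary(10, 5.0, 2.0, 10, 5.0, 2.0)
        assert p == pytest.approx(1.0)
        F, _ = sq.variance_ratio_test(10, 2.0, 10, 2.0)
        assert F == pytest.approx(1.0)

    def test_group_order_swap_invariance(self):
        _, p1 = sq.two_sample_from_summary(8, 43.25, 13.36, 9, 60.44, 13.78)
        _, p2 = sq.two_sample_from_summary(9, 60.44, 13.78, 8, 43.25, 13.36)
        assert p1 == pytest.approx(p2)
        _, f1 = sq.variance_ratio_test(8, 13.36, 9, 13.78)
        _, f2 = sq.variance_ratio_test(9, 13.78, 8, 13.36)
        assert f1 == pytest.approx(f2)

    def test_mann_whitney_exact_enumeration(self):
        # all 20 orderings of {1,2,3} vs {4,5,6}: 2 are as extreme -> p = 0.1
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        u_obs = sum(x < y for x in a for y in b)
        count = 0
        pool = a + b
        for comb in itertools.combinations(range(6), 3):
            ga = [pool[i] for i in comb]
            gb = [pool[i] for i in range(6) if i not in comb]
            u = sum(x < y for x in ga for y in gb)
            if min(u, 9 - u) <= min(u_obs, 9 - u_obs):
                count += 1
        p_enum = count / 20
        assert p_enum == pytest.approx(0.1)
        _, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert p == pytest.approx(p_enum)

    def test_compare_accessions_raw_mode(self):
        rng = np.random.default_rng(10)
        t = pd.DataFrame({
            "accession": ["A"] * 8 + ["B"] * 9,
            "SL": np.concatenate([rng.normal(43, 3.6, 8), rng.normal(60, 3.7, 9)]),
            "q_L": np.concatenate([rng.normal(47, 14, 8), rng.normal(84, 10, 9)]),
        })
        out = sq.compare_accessions(t, "A", "B", traits=["SL", "q_L"])
        assert set(out["trait"]) == {"SL", "q_L"}
        assert ((out[["t_p", "f_p", "mw_p"]] >= 0)
                & (out[["t_p", "f_p", "mw_p"]] <= 1)).all().all()
        assert out.loc[out.trait == "SL", "t_p"].iloc[0] < 0.001

    def test_zero_variance_both_groups_flagged(self):
        t = pd.DataFrame({
            "accession": ["A"] * 3 + ["B"] * 3,
            "SL": [5.0, 5.0, 5.0, 5.0, 5.0, 5.0],
        })
        out = sq.compare_accessions(t, "A", "B", traits=["SL"])
        assert np.isnan(out.loc[0, "t_p"])
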