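import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from clockdiv.divergence_stats import (
    GroupSummary,
    RelativeRateRecord,
    ancova_group_effect,
    fisher_exact_2xk,
    focal_mean_distance,
    grand_mean_distance,
    group_summaries,
    mean_pairwise_distance,
    model_diversity_table,
    model_frequency_table,
    one_sample_t,
    records_from_table,
    regress_rate_on_length,
    relative_rates,
    residual_anova,
)
from clockdiv.io_formats import read_gene_table
from clockdiv.tree_build import DistanceMatrix


def const_dm(taxa, value):
    n = len(taxa)
    d = np.full((n, n), float(value))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(taxa), d)


def rec(gene, group, rate, nt=None, model=None):
    return RelativeRateRecord(gene, group, rate, rate, nt, model)


class TestFocalAndGrandMean:
    def test_focal_mean_is_arithmetic_mean(self):
        dm = DistanceMatrix(("W", "X", "Y"), np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], float))
        assert focal_mean_distance(dm, "W") == pytest.approx(2.0)

    def test_single_other_taxon(self):
        dm = const_dm(("W", "X"), 0.7)
        assert focal_mean_distance(dm, "W") == pytest.approx(0.7)

    def test_missing_focal_rejected(self):
        with pytest.raises(ValueError):
            focal_mean_distance(const_dm(("X", "Y"), 1), "W")

    def test_grand_mean_unweighted_over_genes(self):
        dms = [const_dm("WXY", 1.0), const_dm("WXY", 2.0)]
        assert grand_mean_distance(dms) == pytest.approx(1.5)

    def test_genes_with_missing_taxa_use_their_own_pairs(self):
        # third gene has 6 of 7 taxa; it contributes its own pair mean
        taxa7 = tuple("WABCDEF")
        dms = [const_dm(taxa7, 1.0), const_dm(taxa7, 3.0), const_dm(taxa7[:-1], 2.0)]
        assert grand_mean_distance(dms) == pytest.approx(2.0)

    def test_single_gene(self):
        assert grand_mean_distance([const_dm("WXY", 2.0)]) == pytest.approx(2.0)


class TestRelativeRates:
    def test_equal_distances_give_unit_rates(self):
        mats = {"g1": const_dm("WXY", 1.3), "g2": const_dm("WXY", 1.3)}
        recs = relative_rates(mats, "W")
        assert all(r.relative_rate == pytest.approx(1.0) for r in recs)

    def test_two_gene_hand_arithmetic(self):
        mats = {"g1": const_dm("WXY", 1.0), "g2": const_dm("WXY", 2.0)}
        rates = {r.gene: r.relative_rate for r in relative_rates(mats, "W")}
        assert rates["g1"] == pytest.approx(2 / 3)
        assert rates["g2"] == pytest.approx(4 / 3)

    def test_scale_invariance(self, rng):
        taxa = tuple("WABCDEF")
        mats = {}
        for g in range(5):
            d = rng.uniform(0.2, 2.0, (7, 7))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            mats[f"g{g}"] = DistanceMatrix(taxa, d)
        base = {r.gene: r.relative_rate for r in relative_rates(mats, "W")}
        scaled_mats = {k: DistanceMatrix(v.taxa, 7.3 * v.d) for k, v in mats.items()}
        scaled = {r.gene: r.relative_rate for r in relative_rates(scaled_mats, "W")}
        for g in base:
            assert scaled[g] == pytest.approx(base[g], rel=1e-12)

    def test_focal_equal_to_grand_mean_gives_exact_unit_rate(self):
        mats = {"g": const_dm("WXYZ", 0.8)}
        recs = relative_rates(mats, "W")
        assert recs[0].relative_rate == pytest.approx(1.0, rel=1e-12)

    def test_gene_without_focal_excluded_with_warning(self, caplog):
        mats = {"g1": const_dm("WXY", 1.0), "g2": const_dm("XYZ", 1.0)}
        recs = relative_rates(mats, "W")
        assert [r.gene for r in recs] == ["g1"]

    def test_zero_grand_mean_rejected(self):
        with pytest.raises(ValueError):
            relative_rates({"g": const_dm("WXY", 0.0)}, "W")


class TestOneSampleT:
    def test_closed_form_small_sample(self):
        s = one_sample_t([1.0, 2.0, 3.0], mu0=1.0)
        assert s.mean == pytest.approx(2.0)
        assert s.se == pytest.approx(1 / math.sqrt(3), abs=1e-4)
        assert s.t == pytest.approx(math.sqrt(3), abs=1e-4)
        assert s.df == 2

    def test_symmetric_values_give_t_zero(self):
        s = one_sample_t([0.5, 1.5], mu0=1.0)
        assert s.t == pytest.approx(0.0)
        assert s.p == pytest.approx(1.0)

    def test_matches_scipy(self, rng):
        x = rng.normal(1.1, 0.3, 12)
        s = one_sample_t(x, mu0=1.0)
        ref = sps.ttest_1samp(x, 1.0)
        assert s.t == pytest.approx(ref.statistic)
        assert s.p == pytest.approx(ref.pvalue)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0, 1.0, 1.0])


class TestGroupSummaries:
    def test_group_means_recombine(self):
        rows = read_gene_table()
        recs = records_from_table(rows)
        s = group_summaries(recs)
        lhs = (s["TTFL"].n * s["TTFL"].mean + s["PTM"].n * s["PTM"].mean) / s["combined"].n
        assert lhs == pytest.approx(s["combined"].mean, abs=1e-12)

    def test_identically_drawn_groups_have_close_means(self, rng):
        recs = [rec(f"a{i}", "TTFL", x) for i, x in enumerate(rng.normal(1, 0.2, 40))]
        recs += [rec(f"b{i}", "PTM", x) for i, x in enumerate(rng.normal(1, 0.2, 40))]
        s = group_summaries(recs)
        pooled_se = math.hypot(s["TTFL"].se, s["PTM"].se)
        assert abs(s["TTFL"].mean - s["PTM"].mean) < 3 * pooled_se

    def test_unlabeled_record_rejected(self):
        with pytest.raises(ValueError):
            group_summaries([rec("g", "", 1.0), rec("h", "TTFL", 1.1)])


class TestFisherExact:
    def test_diagonal_2x2_by_hand(self):
        # margins (2,2)/(2,2): three tables with probs 1/6, 4/6, 1/6
        assert fisher_exact_2xk([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_identical_rows_give_p_one(self):
        assert fisher_exact_2xk([[3, 2, 1], [3, 2, 1]]) == pytest.approx(1.0)

    def test_matches_scipy_on_random_2x2_tables(self, rng):
        for _ in range(50):
            t = rng.integers(0, 7, (2, 2))
            if t.sum() == 0:
                continue
            ours = fisher_exact_2xk(t)
            ref = sps.fisher_exact(t).pvalue
            assert ours == pytest.approx(ref, abs=1e-10), t

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2xk([[0, 0], [0, 0]])

    def test_study_model_table(self):
        recs = records_from_table(read_gene_table())
        table = model_frequency_table(recs)
        assert table.shape == (2, 8)
        assert table.loc["TTFL"].sum() == 9
        assert table.loc["PTM"].sum() == 8
        # full-string model table: identical to the r x c exact test
        assert fisher_exact_2xk(table.to_numpy()) == pytest.approx(0.7408, abs=2e-4)

    def test_study_model_diversity_matches_print(self):
        # 6 distinct models among 9 TTFL genes vs 5 among 8 PTM genes
        recs = records_from_table(read_gene_table())
        div = model_diversity_table(recs)
        np.testing.assert_array_equal(div, [[6, 3], [5, 3]])
        assert fisher_exact_2xk(div) == pytest.approx(1.000, abs=1e-9)


class TestRegression:
    def test_collinear_points(self):
        recs = [rec(f"g{i}", "TTFL", 0.1 * n, nt=n) for i, n in enumerate([100, 200, 300, 400])]
        slope, r, t, p = regress_rate_on_length(recs)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_null_pvalues_uniform(self, rng):
        pvals = []
        for _ in range(200):
            nts = rng.integers(300, 3000, 17)
            recs = [rec(f"g{i}", "TTFL", x, nt=int(n)) for i, (x, n) in enumerate(zip(rng.normal(1, 0.3, 17), nts))]
            pvals.append(regress_rate_on_length(recs)[3])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_length_variance_rejected(self):
        recs = [rec(f"g{i}", "TTFL", x, nt=500) for i, x in enumerate([0.5, 1.0, 1.5])]
        with pytest.raises(ValueError):
            regress_rate_on_length(recs)


class TestAncova:
    def test_identical_groups_give_t_zero(self):
        recs = [rec(f"a{i}", "TTFL", x, nt=n) for i, (x, n) in enumerate([(0.5, 100), (1.0, 200), (1.5, 300)])]
        recs += [rec(f"b{i}", "PTM", x, nt=n) for i, (x, n) in enumerate([(0.5, 100), (1.0, 200), (1.5, 300)])]
        t, p = ancova_group_effect(recs)
        assert t == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        """Six fabricated points solved via the explicit 3x3 normal equations."""
        data = [("a1", "TTFL", 0.9, 500), ("a2", "TTFL", 1.4, 900), ("a3", "TTFL", 1.1, 700),
                ("b1", "PTM", 0.5, 600), ("b2", "PTM", 0.8, 1100), ("b3", "PTM", 0.6, 800)]
        recs = [rec(*d) for d in data]
        y = np.array([d[2] for d in data])
        X = np.column_stack([np.ones(6), [1, 1, 1, 0, 0, 0], [d[3] for d in data]])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (6 - 3)
        se = math.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        t_expected = beta[1] / se
        t, p = ancova_group_effect(recs)
        assert t == pytest.approx(t_expected, abs=1e-10)
        assert p == pytest.approx(2 * sps.t.sf(abs(t_expected), 3), abs=1e-10)

    def test_group_coding_invariance_of_magnitude(self):
        recs = [rec(f"a{i}", "TTFL", x, nt=n) for i, (x, n) in enumerate([(0.9, 500), (1.4, 900), (1.1, 700)])]
        recs += [rec(f"b{i}", "PTM", x, nt=n) for i, (x, n) in enumerate([(0.5, 600), (0.8, 1100), (0.6, 800)])]
        flipped = [RelativeRateRecord(r.gene, "PTM" if r.group == "TTFL" else "TTFL", r.focal_mean,
                                      r.relative_rate, r.nucleotides, r.model_name) for r in recs]
        assert abs(ancova_group_effect(recs)[0]) == pytest.approx(abs(ancova_group_effect(flipped)[0]), abs=1e-10)


class TestResidualAnova:
    def test_identical_groups_give_f_zero(self):
        recs = [rec(f"a{i}", "TTFL", x, nt=n) for i, (x, n) in enumerate([(0.5, 100), (1.0, 200), (1.5, 300)])]
        recs += [rec(f"b{i}", "PTM", x, nt=n) for i, (x, n) in enumerate([(0.5, 100), (1.0, 200), (1.5, 300)])]
        F, p = residual_anova(recs)
        assert F == pytest.approx(0.0, abs=1e-12)

    def test_f_equals_squared_pooled_t(self, rng):
        recs = [rec(f"a{i}", "TTFL", x, nt=int(n)) for i, (x, n) in
                enumerate(zip(rng.normal(1.2, 0.3, 8), rng.integers(300, 3000, 8)))]
        recs += [rec(f"b{i}", "PTM", x, nt=int(n)) for i, (x, n) in
                 enumerate(zip(rng.normal(0.8, 0.3, 9), rng.integers(300, 3000, 9)))]
        F, _ = residual_anova(recs)
        y = np.array([r.relative_rate for r in recs])
        x = np.array([r.nucleotides for r in recs], float)
        res = sps.linregress(x, y)
        resid = y - (res.intercept + res.slope * x)
        g = np.array([r.group == "TTFL" for r in recs])
        t = sps.ttest_ind(resid[g], resid[~g]).statistic
        assert F == pytest.approx(t**2, abs=1e-10)

    def test_detects_group_shift(self, rng):
        """A one-sd group shift on the residual scale is detected most of the
        time at n = 40 (power check over 100 seeded replicates)."""
        hits = 0
        for _ in range(100):
            nts = rng.integers(300, 3000, 40)
            noise = rng.normal(0, 0.3, 40)
            shift = np.r_[np.full(20, 0.3), np.zeros(20)]
            recs = [
                rec(f"g{i}", "TTFL" if i < 20 else "PTM", 1.0 + noise[i] + shift[i], nt=int(nts[i]))
                for i in range(40)
            ]
            hits += residual_anova(recs)[1] < 0.05
        assert hits >= 80
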