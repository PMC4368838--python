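"""Correlation, regression, Ward clustering, ICC and ANOVA oracles."""

import itertools

import numpy as np
import pytest

import ivusecho as iv
from ivusecho.stats import ConstantInputError, pairwise_comparisons


def wss(points):
    pts = np.asarray(points, dtype=float)
    return float(((pts - pts.mean(axis=0)) ** 2).sum())


def brute_force_ward_merges(X):
    """Greedy minimal within-cluster-sum-of-squares increase, lowest pair on ties."""
    X = np.asarray(X, dtype=float)
    clusters = [(i,) for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            a, b = clusters[i], clusters[j]
            inc = wss(X[list(a + b)]) - wss(X[list(a)]) - wss(X[list(b)])
            key = (inc, tuple(sorted((a, b))))
            if best is None or key < best[0]:
                best = (key, i, j)
        (inc, _), i, j = best
        a, b = clusters[i], clusters[j]
        merges.append((frozenset([a, b]), inc))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(tuple(sorted(a + b)))
    return merges


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert iv.pearson_r(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert iv.pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_product_moment_formula(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r, _ = iv.pearson_r(x, y)
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert r == pytest.approx(num / den, rel=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(ConstantInputError):
            iv.pearson_r(np.ones(5), np.arange(5.0))

    def test_affine_invariance_with_sign(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=12), rng.normal(size=12)
        r0, _ = iv.pearson_r(x, y)
        assert iv.pearson_r(3 * x + 5, y)[0] == pytest.approx(r0)
        assert iv.pearson_r(-2 * x, y)[0] == pytest.approx(-r0)


class TestLinreg:
    def test_exact_line(self):
        x = np.linspace(0, 5, 8)
        fit = iv.linreg(x, 3 * x - 2)
        assert fit.slope == pytest.approx(3.0)
        assert fit.intercept == pytest.approx(-2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_orthogonal_predictor_gives_zero_r2(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = np.array([1.0, -1.0, 0.0, -1.0, 1.0])  # even function: cov(x, y) = 0
        assert iv.linreg(x, y).r_squared == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=15), rng.normal(size=15)
        fit = iv.linreg(x, y)
        A = np.column_stack([x, np.ones_like(x)])
        slope, intercept = np.linalg.solve(A.T @ A, A.T @ y)
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)
        sse = ((y - slope * x - intercept) ** 2).sum()
        sst = ((y - y.mean()) ** 2).sum()
        assert fit.r_squared == pytest.approx(1 - sse / sst, rel=1e-10)


class TestWard:
    def test_two_separated_clouds(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.2, size=(6, 2))
        b = rng.normal(10, 0.2, size=(5, 2))
        labels = iv.ward_cluster(np.vstack([a, b]), k=2)
        assert len(set(labels[:6])) == 1
        assert len(set(labels[6:])) == 1
        assert labels[0] != labels[6]

    def test_two_point_merge_cost_by_hand(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        labels, merges = iv.ward_cluster(X, k=1, return_merges=True)
        assert labels.tolist() == [0, 0]
        # Lance-Williams cost for two singletons is the squared Euclidean
        # distance (= 2x the WSS increase of the merge)
        assert merges[0][2] == pytest.approx(25.0)
        assert merges[0][2] / 2 == pytest.approx(wss(X))

    def test_merge_tree_matches_exhaustive_wss_oracle(self):
        rng = np.random.default_rng(4)
        for n in (5, 6, 8):
            X = rng.normal(size=(n, 2))
            _, merges = iv.ward_cluster(X, k=1, return_merges=True)
            oracle = brute_force_ward_merges(X)
            assert len(merges) == len(oracle)
            for (a, b, cost), (pair, inc) in zip(merges, oracle):
                assert frozenset([a, b]) == pair
                assert cost / 2 == pytest.approx(inc, rel=1e-9, abs=1e-12)

    def test_merge_costs_nondecreasing(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 2))
        _, merges = iv.ward_cluster(X, k=1, return_merges=True)
        costs = [m[2] for m in merges]
        assert all(c2 >= c1 - 1e-12 for c1, c2 in zip(costs, costs[1:]))

    def test_k_greater_than_n_errors(self):
        with pytest.raises(ValueError):
            iv.ward_cluster(np.zeros((3, 2)), k=4)


class TestICC:
    def test_identical_readings_give_one(self):
        rng = np.random.default_rng(6)
        r1 = rng.normal(size=20)
        assert iv.icc(np.column_stack([r1, r1])) == pytest.approx(1.0, abs=1e-9)

    def test_absolute_agreement_penalizes_offset(self):
        rng = np.random.default_rng(7)
        r1 = rng.normal(size=30)
        readings = np.column_stack([r1, r1 + 5.0])
        assert iv.icc(readings, model="ICC2") < iv.icc(readings, model="ICC3")

    def test_recovers_generating_icc_in_simulation(self):
        """Variance-component simulation: subject var 4, error var 1 -> ICC 0.8."""
        rng = np.random.default_rng(8)
        target = 4.0 / 5.0
        estimates = []
        for _ in range(50):
            subj = rng.normal(0, 2.0, size=200)
            readings = subj[:, None] + rng.normal(0, 1.0, size=(200, 2))
            estimates.append(iv.icc(readings))
        assert abs(np.mean(estimates) - target) < 0.05

    def test_constant_table_raises(self):
        with pytest.raises(ConstantInputError):
            iv.icc(np.ones((10, 2)))


class TestAnova:
    def test_identical_groups_f_zero(self):
        g = [1.0, 2.0, 3.0]
        f, p = iv.anova_oneway([g, list(g)])
        assert f == pytest.approx(0.0)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=12), rng.normal(0.5, 1, size=10)
        f, p = iv.anova_oneway([a, b])
        from scipy import stats as sps

        t, pt = sps.ttest_ind(a, b)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p == pytest.approx(pt, rel=1e-10)

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(10)
        groups = [rng.normal(m, 1, size=n) for m, n in [(0, 8), (1, 6), (0.5, 9)]]
        f, _ = iv.anova_oneway(groups)
        grand = np.concatenate(groups).mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        k, n = len(groups), sum(len(g) for g in groups)
        assert f == pytest.approx((ssb / (k - 1)) / (ssw / (n - k)), rel=1e-10)


class TestPairwise:
    def test_bonferroni_multiplies_by_number_of_pairs(self):
        rng = np.random.default_rng(11)
        groups = {k: rng.normal(size=10) for k in "abc"}
        df = pairwise_comparisons(groups)
        assert len(df) == 3
        assert np.allclose(df["p_adj"], np.minimum(df["p_raw"] * 3, 1.0))


class TestDegradationReport:
    def test_report_fields_finite_on_cohort(self):
        entries, mw = iv.generate_degradation_cohort(n_scaffolds_per_timepoint=1, seed=0)
        df = iv.analyze_cohort(entries, mw)
        report = iv.degradation_report(df)
        for key in ("hyper", "upper", "hyper_upper"):
            assert np.isfinite(report[key]["pearson_r"])
            assert np.isfinite(report[key]["r_squared"])

    def test_constant_schedule_raises_documented_error(self):
        entries, mw = iv.generate_degradation_cohort(
            n_scaffolds_per_timepoint=2, mw_schedule_kda=(50.0, 50.0, 50.0), seed=1
        )
        df = iv.analyze_cohort(entries, mw)
        with pytest.raises(ConstantInputError):
            iv.pearson_r(df["scaffold_vessel_hyper_upper_mm3"], df["molecular_weight_kda"])
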