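"""Representative curves, fit errors, and group-comparison statistics."""

import numpy as np
import pytest
from scipy import stats

import lactoclust as lc
from lactoclust.lc_models import LCParams

GRID = lc.DIM_GRID
WOOD_A = np.array([24.6645, 0.2142, 0.0039])


def wood_fit(params=WOOD_A):
    return LCParams(model="wood", params=np.asarray(params, dtype=float))


class TestRepresentative:
    def test_single_member_is_itself(self):
        m = np.random.default_rng(0).normal(size=(1, 20))
        np.testing.assert_array_equal(lc.representative_curve(m), m[0])

    def test_symmetric_pair_averages_to_constant(self):
        x = np.random.default_rng(1).normal(size=30)
        rep = lc.representative_curve(np.vstack([x, 2.0 - x]))
        np.testing.assert_allclose(rep, 1.0, atol=1e-12)

    def test_matches_loop_oracle(self):
        M = np.random.default_rng(2).normal(size=(5, 40))
        rep = lc.representative_curve(M)
        for j in range(40):
            assert rep[j] == pytest.approx(sum(M[:, j]) / 5, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            lc.representative_curve(np.empty((0, 10)))


class TestFitErrors:
    def test_eps_f_zero_for_self_generated_representative(self):
        rep = lc.eval_model("wood", WOOD_A, GRID)
        assert lc.epsilon_f(wood_fit(), rep) == pytest.approx(0.0, abs=1e-12)

    def test_eps_f_equals_constant_offset(self):
        rep = lc.eval_model("wood", WOOD_A, GRID) + 1.75
        assert lc.epsilon_f(wood_fit(), rep) == pytest.approx(1.75, abs=1e-9)

    def test_eps_f_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        rep = lc.eval_model("wood", WOOD_A, GRID) + rng.normal(0, 2, len(GRID))
        fitted = lc.eval_model("wood", WOOD_A, GRID)
        oracle = (sum((f - r) ** 2 for f, r in zip(fitted, rep)) / len(GRID)) ** 0.5
        assert lc.epsilon_f(wood_fit(), rep) == pytest.approx(oracle, abs=1e-12)

    def test_eps_c_invariant_to_positive_affine_members(self):
        base = lc.eval_model("wood", WOOD_A, GRID)
        members = np.vstack([2.0 * base + 5.0, 0.3 * base - 1.0, base])
        assert lc.epsilon_c(wood_fit(), members) == pytest.approx(0.0, abs=1e-9)

    def test_eps_c_matches_loop_oracle(self):
        rng = np.random.default_rng(4)
        members = lc.eval_model("wood", WOOD_A, GRID) + rng.normal(0, 3, (4, len(GRID)))
        zm = lc.znormalize(lc.eval_model("wood", WOOD_A, GRID))
        oracle = np.mean(
            [np.sqrt(np.mean((lc.znormalize(m) - zm) ** 2)) for m in members]
        )
        assert lc.epsilon_c(wood_fit(), members) == pytest.approx(oracle, abs=1e-12)

    def test_eps_c_skips_constant_member_with_warning(self):
        base = lc.eval_model("wood", WOOD_A, GRID)
        members = np.vstack([base, np.full(len(GRID), 30.0)])
        with pytest.warns(UserWarning, match="constant"):
            val = lc.epsilon_c(wood_fit(), members)
        assert val == pytest.approx(0.0, abs=1e-9)

    def test_member_order_invariance(self):
        rng = np.random.default_rng(5)
        members = lc.eval_model("wood", WOOD_A, GRID) + rng.normal(0, 2, (6, len(GRID)))
        fwd = lc.epsilon_c(wood_fit(), members)
        rev = lc.epsilon_c(wood_fit(), members[::-1])
        assert fwd == pytest.approx(rev, abs=1e-12)


class TestObservedPeak:
    def test_strictly_increasing_curve_peaks_at_window_end(self):
        curve = np.linspace(20, 50, len(GRID))
        _, dim = lc.observed_peak(curve)
        assert dim == 280

    def test_wood_curve_peaks_at_nearest_grid_day(self):
        curve = lc.eval_model("wood", WOOD_A, GRID.astype(float))
        peak_yield, peak_dim = lc.observed_peak(curve)
        assert peak_dim == 55  # closed-form peak at 54.92 days
        assert peak_yield == pytest.approx(46.957, abs=1e-2)

    def test_flat_curve_tie_resolves_to_earliest_day(self):
        _, dim = lc.observed_peak(np.full(len(GRID), 30.0))
        assert dim == 10


class TestAnova:
    def test_two_group_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        F, p = lc.anova_oneway([a, b])
        t, pt = stats.ttest_ind(a, b)
        assert F == pytest.approx(t**2, abs=1e-9)
        assert p == pytest.approx(pt, abs=1e-9)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(m, 1, n) for m, n in [(0, 8), (1, 12), (0.5, 9)]]
        F, p = lc.anova_oneway(groups)
        ref = stats.f_oneway(*groups)
        assert F == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_identical_groups_give_f_zero_p_one(self):
        g = [np.array([3.0, 3.0, 3.0]), np.array([3.0, 3.0])]
        assert lc.anova_oneway(g) == (0.0, 1.0)

    def test_zero_within_variance_unequal_means_gives_p_zero(self):
        g = [np.array([1.0, 1.0]), np.array([2.0, 2.0])]
        F, p = lc.anova_oneway(g)
        assert np.isinf(F) and p == 0.0

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(8)
        n_reps, alpha = 1000, 0.05
        rejections = sum(
            lc.anova_oneway([rng.normal(0, 1, 10) for _ in range(4)])[1] < alpha
            for _ in range(n_reps)
        )
        se = np.sqrt(alpha * (1 - alpha) / n_reps)
        assert abs(rejections / n_reps - alpha) <= 3 * se


class TestLSDLetters:
    def test_two_close_one_distant_group(self):
        # 10 vs 10.01 is far inside the LSD at this noise level; both
        # differ from 50 by hundreds of LSDs
        rng = np.random.default_rng(9)
        groups = [
            10.0 + rng.normal(0, 0.5, 10),
            10.01 + rng.normal(0, 0.5, 10),
            50.0 + rng.normal(0, 0.5, 10),
        ]
        assert lc.fisher_lsd_letters(groups) == ["b", "b", "a"]

    def test_identical_groups_share_a_letter(self):
        groups = [np.array([5.0, 5.0, 5.0])] * 4
        assert lc.fisher_lsd_letters(groups) == ["a", "a", "a", "a"]

    def test_single_group(self):
        assert lc.fisher_lsd_letters([np.array([1.0, 2.0])]) == ["a"]

    def test_order_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(10)
        groups = [rng.normal(m, 1, 12) for m in (0.0, 0.3, 3.0, 6.0)]
        fwd = lc.fisher_lsd_letters(groups)
        rev = lc.fisher_lsd_letters(groups[::-1])
        share_fwd = {
            (i, j): bool(set(fwd[i]) & set(fwd[j]))
            for i in range(4)
            for j in range(i + 1, 4)
        }
        share_rev = {
            (3 - j, 3 - i): bool(set(rev[i]) & set(rev[j]))
            for i in range(4)
            for j in range(i + 1, 4)
        }
        assert share_fwd == {(min(k), max(k)): v for k, v in share_rev.items()}

    def test_letters_reconstruct_pairwise_decisions(self):
        """Groups share a letter iff their LSD test is non-significant."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            g = int(rng.integers(3, 7))
            groups = [
                rng.normal(rng.uniform(0, 3), 1.0, int(rng.integers(5, 15)))
                for _ in range(g)
            ]
            letters = lc.fisher_lsd_letters(groups)
            ns = [len(x) for x in groups]
            means = [x.mean() for x in groups]
            ssw = sum(((x - x.mean()) ** 2).sum() for x in groups)
            df = sum(ns) - g
            msw = ssw / df
            tcrit = stats.t.ppf(0.975, df)
            for i in range(g):
                for j in range(i + 1, g):
                    lsd = tcrit * np.sqrt(msw * (1 / ns[i] + 1 / ns[j]))
                    significant = abs(means[i] - means[j]) > lsd
                    shared = bool(set(letters[i]) & set(letters[j]))
                    assert shared != significant, (i, j, letters)


class TestClusterSummary:
    @pytest.fixture
    def two_cluster_matrix(self):
        """3+3 records: low-yield typical curves vs high-yield typical curves."""
        records = []
        for i, scale in enumerate([0.8, 0.85, 0.9, 1.3, 1.35, 1.4]):
            a = WOOD_A.copy()
            a[0] *= scale
            curve = lc.eval_model("wood", a, np.arange(5, 301, dtype=float))
            records.append(
                lc.LactationRecord(
                    f"c{i}", 1 + (i >= 3), dict(zip(range(5, 301), curve))
                )
            )
        matrix = lc.build_curve_matrix(lc.filter_lactations(records).kept)
        labels = np.array([0, 0, 0, 1, 1, 1])
        return matrix, labels

    def test_means_and_ses_match_hand_computation(self, two_cluster_matrix):
        matrix, labels = two_cluster_matrix
        comps = {c.variable: c for c in lc.cluster_summary(matrix, labels)}
        daily = comps["daily_my_l"]
        for j in (0, 1):
            vals = matrix.raw[labels == j].mean(axis=1)
            assert daily.means[j] == pytest.approx(vals.mean(), abs=1e-12)
            assert daily.ses[j] == pytest.approx(
                vals.std(ddof=1) / np.sqrt(len(vals)), abs=1e-12
            )
        total = comps["total_my_l"]
        np.testing.assert_allclose(
            total.means, [matrix.raw[labels == j].sum(axis=1).mean() for j in (0, 1)]
        )

    def test_total_column_is_pooled_over_all_records(self, two_cluster_matrix):
        matrix, labels = two_cluster_matrix
        comps = {c.variable: c for c in lc.cluster_summary(matrix, labels)}
        assert comps["daily_my_l"].total_mean == pytest.approx(
            matrix.raw.mean(axis=1).mean(), abs=1e-12
        )

    def test_separated_clusters_get_distinct_letters(self, two_cluster_matrix):
        matrix, labels = two_cluster_matrix
        comps = {c.variable: c for c in lc.cluster_summary(matrix, labels)}
        daily = comps["daily_my_l"]
        assert daily.p < 0.05
        assert set(daily.letters) == {"a", "b"}

    def test_single_cluster_reports_without_tests(self, two_cluster_matrix):
        matrix, _ = two_cluster_matrix
        comps = lc.cluster_summary(matrix, np.zeros(6, dtype=int))
        for comp in comps:
            assert np.isnan(comp.F) and np.isnan(comp.p)
            assert comp.letters == [""]

    def test_summary_table_shape(self, two_cluster_matrix):
        matrix, labels = two_cluster_matrix
        table = lc.summary_table(lc.cluster_summary(matrix, labels))
        # 5 variables x (2 clusters + total row)
        assert len(table) == 15
        assert set(table["variable"]) == {
            "parity", "daily_my_l", "total_my_l", "peak_dim_days", "peak_my_l"
        }
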