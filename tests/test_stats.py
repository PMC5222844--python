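"""AUC/Youden, Kolmogorov–Smirnov, Bonferroni and the mixed-design ANOVA."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atonia import stats
from atonia.errors import InsufficientDataError


def auc_oracle(a, b):
    """Exhaustive pairwise Mann–Whitney probability in exact rationals."""
    num = Fraction(0)
    for x in a:
        for y in b:
            if y > x:
                num += 1
            elif y == x:
                num += Fraction(1, 2)
    return num / (len(a) * len(b))


class TestAUC:
    def test_identical_groups_give_half(self):
        res = stats.auc_analysis([1, 2, 3], [1, 2, 3], n_boot=100, seed=0)
        assert res.raw_auc == 0.5
        assert res.auc == 0.5
        assert res.effect_class == "none"

    def test_perfect_separation_gives_one(self):
        res = stats.auc_analysis([1, 2, 3], [4, 5, 6], n_boot=100, seed=0)
        assert res.auc == 1.0
        assert res.effect_class == "strong"

    def test_worked_example_seven_ninths_is_strong(self):
        res = stats.auc_analysis([1, 2, 3], [2, 3, 4], n_boot=100, seed=0)
        assert res.raw_auc == pytest.approx(7 / 9)
        assert res.effect_class == "strong"

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 20), min_size=2, max_size=12),
        st.lists(st.integers(0, 20), min_size=2, max_size=12),
    )
    def test_raw_auc_matches_exhaustive_pair_count(self, a, b):
        res = stats.auc_analysis(a, b, n_boot=10, seed=0)
        assert res.raw_auc == float(auc_oracle(a, b))

    def test_folding_symmetric_in_group_order(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 10)
        assert (
            stats.auc_analysis(a, b, n_boot=10, seed=0).auc
            == stats.auc_analysis(b, a, n_boot=10, seed=0).auc
        )

    def test_bootstrap_ci_reproducible_and_contains_estimate(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 8), rng.normal(1.2, 1, 10)
        r1 = stats.auc_analysis(a, b, n_boot=2000, seed=7)
        r2 = stats.auc_analysis(a, b, n_boot=2000, seed=7)
        assert (r1.ci_lo, r1.ci_hi) == (r2.ci_lo, r2.ci_hi)
        assert r1.ci_lo <= r1.auc <= r1.ci_hi

    def test_bootstrap_ci_coverage_near_95_percent(self):
        from scipy.stats import norm

        # normal two-group data, n=8/10; P(Y > X) for X~N(0,1), Y~N(d,1)
        # is Phi(d/sqrt(2))
        delta = 1.0
        true_auc = float(norm.cdf(delta / np.sqrt(2)))
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            a = rng.normal(0, 1, 8)
            b = rng.normal(delta, 1, 10)
            r = stats.auc_analysis(a, b, n_boot=400, seed=int(rng.integers(2**31)))
            hits += r.ci_lo <= true_auc <= r.ci_hi
        assert 0.92 - 0.03 <= hits / n_rep  # folding makes the interval conservative
        assert hits / n_rep <= 1.0

    def test_singleton_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            stats.auc_analysis([1.0], [2.0, 3.0])


class TestYouden:
    def test_perfect_separation(self):
        th, sens, spec = stats.youden_optimal(
            [1, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3
        )
        assert (sens, spec) == (1.0, 1.0)
        assert 3 < th < 10

    def test_identical_groups_have_zero_j(self):
        _, sens, spec = stats.youden_optimal([1, 2, 1, 2], [False, False, True, True])
        assert sens + spec - 1.0 == pytest.approx(0.0)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            values = rng.normal(size=20)
            labels = np.concatenate([np.zeros(10, bool), np.ones(10, bool)])
            values[labels] += 1.0
            th, sens, spec = stats.youden_optimal(values, labels)
            # brute force over every cut position of the sorted values
            best_j = -np.inf
            for cut in np.sort(np.unique(values)):
                for t in (cut - 1e-9, cut + 1e-9):
                    pred = values > t
                    j = (
                        np.mean(pred[labels]) + np.mean(~pred[~labels]) - 1.0
                    )
                    best_j = max(best_j, j)
            assert sens + spec - 1.0 == pytest.approx(best_j)

    def test_one_class_absent_rejected(self):
        with pytest.raises(InsufficientDataError):
            stats.youden_optimal([1, 2, 3], [True, True, True])


class TestKS:
    def test_identical_samples_zero_distance(self):
        assert stats.ks_two_sample([1, 2, 3], [1, 2, 3]).d == 0.0

    def test_disjoint_supports_distance_one(self):
        assert stats.ks_two_sample([1, 2], [5, 6]).d == 1.0

    def test_worked_ecdf_gap(self):
        assert stats.ks_two_sample([1, 2], [1.5, 2.5]).d == 0.5

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=40), rng.normal(0.5, 1.2, size=35)
        d0 = stats.ks_two_sample(x, y).d
        assert stats.ks_two_sample(np.exp(x), np.exp(y)).d == d0
        assert stats.ks_two_sample(x**3, y**3).d == d0

    def test_bonferroni_applied_to_p(self):
        r = stats.ks_two_sample([1, 2, 3], [1.1, 2.1, 3.1], m_comparisons=6)
        assert r.p_adjusted == min(1.0, 6 * r.p_raw)

    def test_empty_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            stats.ks_two_sample([], [1.0])


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected",
        [(0.01, 5, 0.05), (0.4, 5, 1.0), (0.2, 1, 0.2)],
    )
    def test_adjustment(self, p, m, expected):
        assert stats.bonferroni_adjust([p], m)[0] == pytest.approx(expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            stats.bonferroni_adjust([1.2], 2)


class TestMixedAnova:
    def test_worked_dataset_matches_manual_sums_of_squares(self):
        # 2 groups x 3 bins, hand-computable integers
        y = np.array(
            [
                [1.0, 2.0, 3.0],
                [3.0, 4.0, 5.0],
                [4.0, 6.0, 8.0],
                [2.0, 5.0, 6.0],
                [3.0, 4.0, 7.0],
            ]
        )
        groups = np.array(["a", "a", "b", "b", "b"])
        res = stats.mixed_anova(y, groups)
        # independent partition computed in exact rationals
        F = Fraction
        data = [[F(int(v)) for v in row] for row in y]
        t = 3
        grand = sum(sum(r) for r in data) / F(15)
        subj = [sum(r) / F(t) for r in data]
        ga = sum(subj[:2]) / 2
        gb = sum(subj[2:]) / 3
        ss_group = t * (2 * (ga - grand) ** 2 + 3 * (gb - grand) ** 2)
        ss_subj = t * (
            sum((s - ga) ** 2 for s in subj[:2])
            + sum((s - gb) ** 2 for s in subj[2:])
        )
        timem = [sum(data[i][j] for i in range(5)) / F(5) for j in range(t)]
        ss_time = 5 * sum((tm - grand) ** 2 for tm in timem)
        cell_a = [sum(data[i][j] for i in range(2)) / F(2) for j in range(t)]
        cell_b = [sum(data[i][j] for i in range(2, 5)) / F(3) for j in range(t)]
        ss_inter = sum(
            n_g * (cell[j] - gm - timem[j] + grand) ** 2
            for n_g, cell, gm in [(2, cell_a, ga), (3, cell_b, gb)]
            for j in range(t)
        )
        ss_err = sum(
            (data[i][j] - subj[i] - cell[j] + gm) ** 2
            for rows, cell, gm in [(range(2), cell_a, ga), (range(2, 5), cell_b, gb)]
            for i in rows
            for j in range(t)
        )
        assert res.effects.loc["group", "SS"] == pytest.approx(float(ss_group), abs=1e-10)
        assert res.effects.loc["time", "SS"] == pytest.approx(float(ss_time), abs=1e-10)
        assert res.effects.loc["interaction", "SS"] == pytest.approx(
            float(ss_inter), abs=1e-10
        )
        assert res.ss_subjects == pytest.approx(float(ss_subj), abs=1e-10)
        assert res.ss_error == pytest.approx(float(ss_err), abs=1e-10)

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        y = rng.normal(size=(9, 4)) + np.arange(4)
        groups = np.array(["a"] * 4 + ["b"] * 5)
        mine = stats.mixed_anova(y, groups)
        df = pd.DataFrame(
            {
                "y": y.ravel(),
                "subject": np.repeat(np.arange(9), 4),
                "time": np.tile(np.arange(4), 9),
                "group": np.repeat(groups, 4),
            }
        )
        ref = pg.mixed_anova(df, dv="y", within="time", subject="subject", between="group")
        ref = ref.set_index("Source")
        for mine_key, ref_key in [("group", "group"), ("time", "time"), ("interaction", "Interaction")]:
            assert mine.effects.loc[mine_key, "F"] == pytest.approx(
                ref.loc[ref_key, "F"], rel=1e-9
            )
            assert mine.effects.loc[mine_key, "p"] == pytest.approx(
                ref.loc[ref_key, "p_unc"], rel=1e-9
            )

    def test_pure_group_shift_loads_only_on_group_effect(self):
        base = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), (6, 1))
        y = base.copy()
        y[3:] += 5.0  # constant shift for group b, zero noise
        # tiny jitter in the between-subject direction keeps MS_subj nonzero
        y += np.linspace(0, 1e-6, 6)[:, None]
        groups = np.array(["a"] * 3 + ["b"] * 3)
        res = stats.mixed_anova(y, groups, posthoc=False)
        assert res.effects.loc["group", "p"] < 1e-9
        assert res.effects.loc["interaction", "SS"] == pytest.approx(0.0, abs=1e-9)

    def test_missing_cells_rejected(self):
        y = np.ones((4, 3))
        y[0, 1] = np.nan
        with pytest.raises(InsufficientDataError):
            stats.mixed_anova(y, ["a", "a", "b", "b"])

    def test_posthoc_bonferroni_never_below_raw(self):
        rng = np.random.default_rng(12)
        y = rng.normal(size=(10, 5))
        res = stats.mixed_anova(y, ["a"] * 5 + ["b"] * 5)
        assert (res.posthoc["p_adjusted"] >= res.posthoc["p_raw"] - 1e-15).all()
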