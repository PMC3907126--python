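"""Rank tests, ROC, reliability, discrimination index and factor analysis,
cross-checked against scipy, scikit-learn, pingouin and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score

import raads14 as r14
from raads14.errors import DegenerateDataError, UsageError
from raads14.psychometrics import (
    corrected_item_total,
    tucker_congruence,
    varimax,
)

int_scores = st.lists(st.integers(0, 10), min_size=2, max_size=60)


class TestMannWhitney:
    def test_complete_separation(self):
        c = r14.mann_whitney([1, 2, 3], [4, 5, 6])
        assert c.U == 0.0
        assert 0 <= c.U <= c.n1 * c.n2
        assert c.r <= abs(c.z)

    def test_permutation_symmetry(self, rng):
        x = rng.integers(0, 6, 25)
        y = rng.permutation(x)
        c = r14.mann_whitney(x, y)
        assert c.U == pytest.approx(25 * 25 / 2)
        assert abs(c.z) < 1e-9

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_scipy_asymptotic(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 8, 40)
        y = rng.integers(0, 10, 55)
        c = r14.mann_whitney(x, y)
        ref = mannwhitneyu(x, y, use_continuity=False, method="asymptotic")
        assert c.U == pytest.approx(min(ref.statistic, 40 * 55 - ref.statistic))
        assert c.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_all_tied(self):
        c = r14.mann_whitney([2, 2, 2], [2, 2])
        assert c.z == 0.0 and c.p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(UsageError):
            r14.mann_whitney([], [1, 2])


class TestEffectSize:
    def test_reported_value(self):
        # the large other-psychiatric vs autism comparison: z=-8.6, N=146
        assert round(r14.effect_size_r(-8.6, 146), 2) == 0.71

    def test_zero_deviate(self):
        assert r14.effect_size_r(0.0, 999) == 0.0

    def test_direct_formula(self):
        assert r14.effect_size_r(-11.6, 648) == pytest.approx(0.4557, abs=1e-4)

    def test_bad_n(self):
        with pytest.raises(UsageError):
            r14.effect_size_r(1.0, 0)


class TestROC:
    def test_perfect_separation(self):
        roc = r14.empirical_roc([2, 3, 0, 1], [True, True, False, False])
        assert roc.auc == pytest.approx(1.0)

    def test_identical_distributions(self):
        scores = [0, 1, 2, 3, 0, 1, 2, 3]
        labels = [True] * 4 + [False] * 4
        assert r14.empirical_roc(scores, labels).auc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_matches_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 6, 80).astype(float)
        labels = rng.random(80) < 0.4
        if labels.all() or not labels.any():
            pytest.skip("degenerate draw")
        mine = r14.empirical_roc(scores, labels).auc
        assert mine == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_monotone_sens_spec(self, rng):
        scores = rng.integers(0, 10, 200)
        labels = rng.random(200) < 0.5
        roc = r14.empirical_roc(scores, labels)
        assert np.all(np.diff(roc.sensitivity) <= 1e-12)
        assert np.all(np.diff(roc.specificity) >= -1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(UsageError):
            r14.empirical_roc([1, 2, 3], [True, True, True])


class TestAUCFromU:
    @pytest.mark.parametrize(
        "U,n1,n2,printed",
        [(467.5, 77, 69, 0.91), (2824, 77, 301, 0.88)],
    )
    def test_reported_aucs(self, U, n1, n2, printed):
        assert round(r14.auc_from_u(U, n1, n2), 2) == printed

    def test_midpoint(self):
        assert r14.auc_from_u(50 * 60 / 2, 50, 60) == 0.5

    def test_out_of_range(self):
        with pytest.raises(UsageError):
            r14.auc_from_u(1000.0, 10, 10)


class TestOperatingPoint:
    def test_perfect(self):
        sens, spec = r14.operating_point(
            [14, 15, 20, 0, 13], [True, True, True, False, False], 14
        )
        assert (sens, spec) == (1.0, 1.0)

    def test_inverted(self):
        sens, spec = r14.operating_point([13, 14], [True, False], 14)
        assert (sens, spec) == (0.0, 0.0)


def brute_force_cutoff(scores, labels, min_sens, rule="highest"):
    scores = np.asarray(scores, float)
    cases = scores[np.asarray(labels, bool)]
    lo, hi = int(np.floor(scores.min())), int(np.ceil(scores.max())) + 1
    ok = [t for t in range(lo, hi + 1) if (cases >= t).mean() >= min_sens]
    return max(ok) if rule == "highest" else min(ok)


class TestSelectCutoff:
    def test_all_cases_at_or_above_14(self):
        scores = [14, 15, 20, 29, 0, 5]
        labels = [True] * 4 + [False] * 2
        assert r14.select_cutoff(scores, labels, 0.93) == 14

    def test_constant_cases(self):
        scores = [5] * 10 + [1, 2]
        labels = [True] * 10 + [False] * 2
        assert r14.select_cutoff(scores, labels, 0.93) == 5

    def test_lowest_rule(self):
        scores = [14, 15, 20, 29, 0, 5]
        labels = [True] * 4 + [False] * 2
        assert r14.select_cutoff(scores, labels, 0.93, rule="lowest") == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_against_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 43, 150)
        labels = rng.random(150) < 0.4
        if not labels.any():
            pytest.skip("no cases drawn")
        for rule in ("highest", "lowest"):
            assert r14.select_cutoff(scores, labels, 0.93, rule=rule) == \
                brute_force_cutoff(scores, labels, 0.93, rule)

    def test_achieved_sensitivity_on_skewed_cases(self):
        cases = r14.draw_total_scores(30.8, 8.6, 1000, seed=4)
        controls = r14.draw_total_scores(12.6, 9.3, 1000, seed=5)
        scores = np.concatenate([cases, controls])
        labels = np.r_[np.ones(1000, bool), np.zeros(1000, bool)]
        t = r14.select_cutoff(scores, labels, 0.93)
        assert (cases >= t).mean() >= 0.93
        assert (cases >= t + 1).mean() < 0.93  # t is the highest qualifying

    def test_no_cases(self):
        with pytest.raises(UsageError):
            r14.select_cutoff([1, 2], [False, False], 0.9)


class TestCronbachAlpha:
    def test_two_item_closed_form(self, rng):
        # a permutation pair has exactly equal sample variances, so
        # alpha must equal 2r/(1+r) to machine precision
        a = rng.normal(size=400)
        b = rng.permutation(a)
        m = np.column_stack([a, b])
        r = np.corrcoef(a, b)[0, 1]
        assert r14.cronbach_alpha(m).alpha == pytest.approx(2 * r / (1 + r), abs=1e-12)

    def test_duplicated_item_alpha_one(self, rng):
        x = rng.integers(0, 4, 100).astype(float)
        m = np.column_stack([x, x, x])
        assert r14.cronbach_alpha(m).alpha == pytest.approx(1.0)

    def test_one_factor_spearman_brown(self):
        rng = np.random.default_rng(99)
        n, k, lam = 2000, 14, 0.7
        f = rng.standard_normal(n)
        m = lam * f[:, None] + np.sqrt(1 - lam**2) * rng.standard_normal((n, k))
        r0 = lam**2  # expected inter-item correlation
        expected = k * r0 / (1 + (k - 1) * r0)
        assert r14.cronbach_alpha(m).alpha == pytest.approx(expected, abs=0.02)

    @pytest.mark.parametrize("seed", [3, 8])
    def test_matches_pingouin(self, seed):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(seed)
        m = rng.integers(0, 4, size=(60, 6)).astype(float)
        mine = r14.cronbach_alpha(m).alpha
        ref = pg.cronbach_alpha(data=pd.DataFrame(m))[0]
        assert mine == pytest.approx(ref, abs=1e-10)

    def test_item_total_is_remainder_correlation(self, rng):
        m = rng.integers(0, 4, size=(50, 4)).astype(float)
        res = r14.cronbach_alpha(m)
        for j in range(4):
            rest = m.sum(axis=1) - m[:, j]
            assert res.item_total[j] == pytest.approx(
                np.corrcoef(m[:, j], rest)[0, 1]
            )

    def test_degenerate_and_usage_errors(self, rng):
        with pytest.raises(DegenerateDataError):
            r14.cronbach_alpha(np.ones((10, 3)))
        with pytest.raises(UsageError):
            r14.cronbach_alpha(rng.normal(size=(10, 1)))
        with pytest.raises(UsageError):
            r14.cronbach_alpha(rng.normal(size=(2, 3)))


class TestDiscriminationIndex:
    def test_identical_groups_zero(self):
        item = np.array([0, 1, 2, 3, 0, 1, 2, 3], float)
        flags = np.array([1, 1, 1, 1, 0, 0, 0, 0], bool)
        dm = np.column_stack([item, item[::-1]])
        s = r14.discrimination_index(item, flags, dm)
        assert s.r_pb == pytest.approx(0.0, abs=1e-12)
        assert s.index == pytest.approx(0.0, abs=1e-12)

    def test_index_is_product(self, rng):
        item = rng.integers(0, 4, 200).astype(float)
        flags = rng.random(200) < 0.5
        dm = np.column_stack([item, rng.integers(0, 4, 200), rng.integers(0, 4, 200)])
        s = r14.discrimination_index(item, flags, dm, item_key="i")
        assert s.index == pytest.approx(s.r_pb * s.r_it)
        assert abs(s.index) <= 1.0

    def test_zero_variance_flagged(self):
        item = np.ones(20)
        flags = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        s = r14.discrimination_index(item, flags, np.column_stack([item, item]))
        assert not s.defined
        assert np.isnan(s.index)


class TestFactorAnalysis:
    def test_one_factor_data(self):
        rng = np.random.default_rng(21)
        f = rng.standard_normal(1000)
        m = 0.7 * f[:, None] + np.sqrt(0.51) * rng.standard_normal((1000, 8))
        sol = r14.principal_factor_analysis(m)
        assert sol.n_factors == 1
        assert sol.eigenvalues[0] > 4 * abs(sol.eigenvalues[1])

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(17)
        n = 3000
        blocks = [0] * 7 + [1] * 4 + [2] * 3
        f = rng.standard_normal((n, 3))
        m = np.column_stack(
            [0.7 * f[:, b] + np.sqrt(0.51) * rng.standard_normal(n) for b in blocks]
        )
        sol = r14.principal_factor_analysis(m, n_factors=3)
        for b in range(3):
            target = np.array([0.7 if bb == b else 0.0 for bb in blocks])
            best = max(
                tucker_congruence(sol.loadings[:, j], target) for j in range(3)
            )
            assert best >= 0.9

    def test_noise_has_no_dominant_factor(self):
        rng = np.random.default_rng(4)
        m = rng.standard_normal((1500, 10))
        sol = r14.principal_factor_analysis(m, n_factors=3)
        assert np.all(sol.variance_explained < 0.1)

    def test_eigenvalues_descending(self, rng):
        m = rng.integers(0, 4, size=(300, 6)).astype(float)
        sol = r14.principal_factor_analysis(m, n_factors=2)
        assert np.all(np.diff(sol.eigenvalues) <= 1e-10)

    def test_degenerate_inputs(self, rng):
        x = rng.standard_normal(100)
        with pytest.raises(DegenerateDataError):
            r14.principal_factor_analysis(np.column_stack([x, x, x + 0 * x]))
        with pytest.raises(UsageError):
            r14.principal_factor_analysis(rng.standard_normal((4, 6)))

    def test_varimax_preserves_communalities(self, rng):
        L = rng.normal(size=(10, 3))
        R = varimax(L)
        assert np.allclose((L**2).sum(axis=1), (R**2).sum(axis=1))


# ---------------------------------------------------------------------------
# property suites
# ---------------------------------------------------------------------------

datasets = st.tuples(
    st.lists(st.integers(0, 8), min_size=2, max_size=40),
    st.lists(st.integers(0, 8), min_size=2, max_size=40),
)


class TestProperties:
    @given(data=datasets)
    @settings(max_examples=200, deadline=None)
    def test_u_auc_identity(self, data):
        """Trapezoidal ROC AUC equals the U-based AUC on any tied data."""
        x, y = data
        scores = np.array(x + y, float)
        labels = np.r_[np.ones(len(x), bool), np.zeros(len(y), bool)]
        comp = r14.mann_whitney(x, y)
        roc = r14.empirical_roc(scores, labels)
        assert roc.auc == pytest.approx(
            r14.auc_from_u(comp.u_case_loss, len(x), len(y)), abs=1e-9
        )

    @given(data=datasets)
    @settings(max_examples=100, deadline=None)
    def test_auc_invariant_under_monotone_transform(self, data):
        x, y = data
        scores = np.array(x + y, float)
        labels = np.r_[np.ones(len(x), bool), np.zeros(len(y), bool)]
        a1 = r14.empirical_roc(scores, labels).auc
        a2 = r14.empirical_roc(np.exp(scores / 3.0) + scores**3, labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    @given(
        scores=st.lists(st.integers(0, 42), min_size=4, max_size=80),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=100, deadline=None)
    def test_select_cutoff_equals_brute_force(self, scores, seed):
        rng = np.random.default_rng(seed)
        labels = rng.random(len(scores)) < 0.5
        if not labels.any():
            labels[0] = True
        assert r14.select_cutoff(scores, labels, 0.93) == brute_force_cutoff(
            scores, labels, 0.93
        )
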