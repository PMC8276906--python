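"""Confusion/classwise metrics and the nonparametric statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from stressbci.metrics import (
    ConfusionMatrix,
    classwise_report,
    confusion,
    precision_recall_points,
)
from stressbci.stats import (
    DegenerateTestError,
    mann_whitney_u,
    round_display,
    spearman_correlation,
    table_summaries,
    wilcoxon_signed_rank,
)


class TestConfusion:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 3, 0, 1])
        cm = confusion(y, y)
        assert cm.accuracy == 1.0
        assert np.array_equal(np.diag(cm.counts), [2, 2, 1, 1])
        assert cm.counts.sum() == np.trace(cm.counts)

    def test_collapsed_predictions_one_column(self):
        y = np.array([0, 1, 2, 3])
        cm = confusion(y, np.full(4, 2))
        assert cm.counts[:, 2].sum() == 4
        assert cm.counts.sum() == 4

    def test_hand_enumerated_example(self):
        # true = [A,A,B,B], pred = [A,B,B,B]
        cm = confusion([0, 0, 1, 1], [0, 1, 1, 1])
        rep = classwise_report(cm)
        assert cm.accuracy == 0.75
        assert rep.sensitivity["baseline"] == 0.5
        assert rep.sensitivity["stressor"] == 1.0

    @given(st_.lists(st_.tuples(st_.integers(0, 3), st_.integers(0, 3)),
                     min_size=1, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_accuracy_equals_match_fraction(self, pairs):
        t = [a for a, _ in pairs]
        p = [b for _, b in pairs]
        cm = confusion(t, p)
        assert cm.accuracy == pytest.approx(np.mean(np.array(t) == np.array(p)))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 5], [0, 1])


class TestClasswise:
    def test_diagonal_all_ones(self):
        rep = classwise_report(ConfusionMatrix(np.diag([5, 6, 7, 8])))
        assert all(v == 1.0 for v in rep.sensitivity.values())
        assert all(v == 1.0 for v in rep.specificity.values())

    def test_uniform_matrix_quarter_sensitivity(self):
        rep = classwise_report(ConfusionMatrix(np.full((4, 4), 3)))
        assert all(v == 0.25 for v in rep.sensitivity.values())

    def test_two_by_two_embedding(self):
        """[[90,10],[20,80]] embedded in 4x4: sens 0.9, spec 0.8 for class 1."""
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 0], counts[0, 1] = 90, 10
        counts[1, 0], counts[1, 1] = 20, 80
        rep = classwise_report(ConfusionMatrix(counts))
        assert rep.sensitivity["baseline"] == pytest.approx(0.9)
        assert rep.specificity["baseline"] == pytest.approx(0.8)

    def test_empty_row_is_nan_not_zero(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 0] = 10
        rep = classwise_report(ConfusionMatrix(counts))
        assert np.isnan(rep.sensitivity["guided"])

    def test_precision_recall_points_shape(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 4, 50)
        scores = rng.dirichlet(np.ones(4), 50)
        pts = precision_recall_points(y, scores)
        assert set(pts) == {"baseline", "stressor", "unguided", "guided"}
        for arr in pts.values():
            assert arr.ndim == 2 and arr.shape[1] == 2


def exact_signed_rank_p(d):
    """Exhaustive two-sided signed-rank p over all 2^n sign patterns."""
    from scipy.stats import rankdata

    d = np.asarray(d, dtype=float)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    mu = ranks.sum() / 2
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_unit_shift_matches_exhaustive_enumeration(self):
        pre = np.array([2, 3, 1, 2, 4, 2, 3, 2, 1, 3], dtype=float)
        post = pre + 1
        z, p = wilcoxon_signed_rank(pre, post, method="exact")
        assert p == pytest.approx(exact_signed_rank_p(post - pre))
        assert p == pytest.approx(2 / 1024)
        assert z < 0  # stress increase reported as negative Z

    def test_mixed_differences_match_enumeration(self):
        pre = np.array([2, 3, 1, 2, 4, 2, 3, 2], dtype=float)
        post = np.array([4, 3, 3, 1, 5, 4, 2, 4], dtype=float)
        z, p = wilcoxon_signed_rank(pre, post, method="exact")
        d = post - pre
        assert p == pytest.approx(exact_signed_rank_p(d[d != 0]))

    def test_antisymmetry(self):
        pre = [1, 2, 3, 2, 1, 4, 2, 3]
        post = [3, 3, 4, 1, 2, 5, 4, 3]
        z1, p1 = wilcoxon_signed_rank(pre, post)
        z2, p2 = wilcoxon_signed_rank(post, pre)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateTestError):
            wilcoxon_signed_rank([2, 2, 2], [2, 2, 2])


class TestMannWhitney:
    def test_disjoint_toy_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_exact_matches_enumeration(self):
        a = [1.0, 4.0, 2.5]
        b = [3.0, 5.0, 6.0, 0.5]
        u_obs, p = mann_whitney_u(a, b, method="exact")
        pooled = np.array(a + b)
        n_a = len(a)
        from scipy.stats import rankdata

        def u_of(idx):
            r = rankdata(pooled)
            return r[list(idx)].sum() - n_a * (n_a + 1) / 2

        mu = len(a) * len(b) / 2
        us = [u_of(c) for c in itertools.combinations(range(7), n_a)]
        p_enum = np.mean([abs(u - mu) >= abs(u_obs - mu) - 1e-12 for u in us])
        assert p == pytest.approx(p_enum)

    def test_group_swap_symmetry(self):
        a, b = [1, 5, 3, 8], [2, 9, 4]
        _, p1 = mann_whitney_u(a, b)
        _, p2 = mann_whitney_u(b, a)
        assert p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2])


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_correlation(x, [2, 4, 9, 16, 30]) == pytest.approx(1.0)
        assert spearman_correlation(x, [30, 16, 9, 4, 2]) == pytest.approx(-1.0)

    @given(st_.lists(st_.integers(-1000, 1000), min_size=4, max_size=20,
                     unique=True))
    @settings(max_examples=40, deadline=None)
    def test_invariant_under_monotone_transform(self, xs):
        xs = np.asarray(xs, dtype=float)
        ys = np.random.default_rng(0).permutation(len(xs)).astype(float)
        r1 = spearman_correlation(xs, ys)
        r2 = spearman_correlation(np.exp(xs / 100), ys)  # strictly monotone
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert -1.0 <= r1 <= 1.0

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateTestError):
            spearman_correlation([1, 1, 1], [1, 2, 3])


@pytest.fixture(scope="module")
def summ():
    return table_summaries()


class TestTableSummaries:
    def test_table1_column_means(self, summ):
        d = summ["display"]
        assert d["table1/guided_vs_stressor"] == 80.45
        assert d["table1/baseline_vs_stressor"] == 87.88
        assert d["table1/unguided_vs_guided"] == 80.57
        assert d["table1/unguided_vs_stressor"] == 78.28

    def test_table2_table3_means(self, summ):
        d = summ["display"]
        assert d["table2/deep_convnet"] == 58.80
        assert d["table2/shallow_convnet"] == 62.84
        assert d["table3/lstm1"] == 70.12
        assert d["table3/lstm2"] == 93.27
        assert d["table3/lstm_fcn"] == 62.97

    def test_table4_group_means_and_stats(self, summ):
        t4 = summ["table4"]
        assert round_display(t4["asd_mean"]) == 93.33
        assert t4["nt_mean"] == pytest.approx(93.155)
        assert t4["mann_whitney"][1] == pytest.approx(0.566, abs=5e-4)
        assert t4["spearman_rho"] == pytest.approx(0.0393, abs=5e-5)

    def test_inconsistencies_flagged_not_reconciled(self, summ):
        assert "table3/lstm3" in summ["inconsistent"]
        assert summ["inconsistent"]["table3/lstm3"]["recomputed"] == 72.25

    def test_missing_fixture_errors(self):
        from stressbci.tables import load_table

        with pytest.raises(FileNotFoundError):
            load_table("table9")


def test_round_display_half_away_from_zero():
    assert round_display(93.155) == 93.16
    assert round_display(72.2525) == 72.25
    # exact binary halves round away from zero in both directions
    assert round_display(0.125) == 0.13
    assert round_display(-0.125) == -0.13
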