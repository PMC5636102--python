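"""ROC estimator vs pair counting, DeLong behaviour, Spearman network."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirspec.io import ValidationError
from mirspec.evaluate import (
    auc_ci_over_runs,
    compare_models,
    delong_ci,
    delong_compare,
    roc_auc,
    spearman_network,
)


def pair_count_auc(scores, labels):
    """Brute-force oracle: concordant pairs, ties worth one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocAuc:
    def test_worked_example(self):
        r = roc_auc(np.array([0.8, 0.7, 0.6, 0.3]), np.array([1, 0, 1, 0]))
        assert r.auroc == pytest.approx(0.75)
        assert r.n_pos == 2 and r.n_neg == 2

    def test_extremes_and_ties(self):
        y = np.array([0, 0, 1, 1])
        assert roc_auc(np.array([1, 2, 3, 4.0]), y).auroc == 1.0
        assert roc_auc(np.array([4, 3, 2, 1.0]), y).auroc == 0.0
        assert roc_auc(np.full(4, 0.3), y).auroc == 0.5

    def test_curve_monotone(self):
        rng = np.random.default_rng(0)
        r = roc_auc(rng.random(50), (rng.random(50) < 0.4).astype(int))
        assert (np.diff(r.fpr) >= 0).all() and (np.diff(r.tpr) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_pair_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        labels = np.zeros(n, dtype=int)
        labels[rng.permutation(n)[: max(1, n // 3)]] = 1
        if labels.all() or not labels.any():
            return
        assert roc_auc(scores, labels).auroc == pytest.approx(
            pair_count_auc(scores, labels), abs=1e-12
        )


class TestAucCi:
    def test_constant_runs(self):
        mean, (lo, hi) = auc_ci_over_runs([0.9] * 100)
        assert (mean, lo, hi) == pytest.approx((0.9, 0.9, 0.9))

    def test_uniform_grid_quantiles(self):
        mean, (lo, hi) = auc_ci_over_runs(np.arange(1, 101) / 100)
        assert mean == pytest.approx(0.505)
        assert lo == pytest.approx(0.0347, abs=5e-3)
        assert hi == pytest.approx(0.9752, abs=5e-3)

    def test_two_runs(self):
        mean, _ = auc_ci_over_runs([0.8, 1.0])
        assert mean == pytest.approx(0.9)


class TestDelong:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(1)
        s = rng.random(40)
        y = (rng.random(40) < 0.4).astype(int)
        r = delong_compare(s, s, y)
        assert r.p == 1.0 and r.var_diff == 0.0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.random(30), rng.random(30)
        y = (rng.random(30) < 0.4).astype(int)
        r1, r2 = delong_compare(a, b, y), delong_compare(b, a, y)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p == pytest.approx(r2.p)
        assert r1.auc_a == r2.auc_b

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            delong_compare(np.zeros(5), np.zeros(6), np.r_[np.zeros(3, int), np.ones(3, int)])

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(3)
        y = (rng.random(80) < 0.3).astype(int)
        s = rng.random(80) + y
        auc, (lo, hi) = delong_ci(s, y)
        assert lo <= auc <= hi
        assert 0.0 <= lo and hi <= 1.0


class TestCompareModels:
    def test_self_comparison_p_one(self):
        rng = np.random.default_rng(4)
        y = (rng.random(40) < 0.4).astype(int)
        meld = rng.random(40)
        comp = compare_models({"a": meld, "b": meld}, y)
        assert comp.pairwise[0][2].p == 1.0

    def test_three_identical_models(self):
        rng = np.random.default_rng(5)
        y = (rng.random(40) < 0.4).astype(int)
        s = rng.random(40)
        comp = compare_models({"a": s, "b": s, "c": s}, y)
        assert len(comp.pairwise) == 3
        assert all(r.p == 1.0 for _, _, r in comp.pairwise)

    def test_stronger_score_usually_wins(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng([seed, 60])
            y = np.r_[np.ones(23, int), np.zeros(93, int)]
            strong = rng.standard_normal(116) + 1.8 * y
            weak = rng.standard_normal(116) + 0.8 * y
            comp = compare_models({"strong": strong, "weak": weak}, y)
            wins += comp.aucs["strong"] > comp.aucs["weak"]
        assert wins >= 9


class TestSpearmanNetwork:
    def test_worked_rank_example(self):
        sp = pd.DataFrame({"1468": [1, 2, 3, 4, 5] * 3})
        cl = pd.DataFrame({"bilirubin": [2, 1, 4, 3, 5] * 3})
        edges = spearman_network(sp, cl, alpha=0.5)
        assert len(edges) == 1
        assert edges[0].r == pytest.approx(0.8, abs=0.05)
        assert edges[0].sign == 1

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.random(30)
        yv = x + 0.1 * rng.random(30)
        sp = pd.DataFrame({"a": x})
        e1 = spearman_network(sp, pd.DataFrame({"c": yv}))
        e2 = spearman_network(sp, pd.DataFrame({"c": np.exp(5 * yv)}))
        assert e1[0].r == pytest.approx(e2[0].r, abs=1e-12)
        assert e1[0].p == pytest.approx(e2[0].p, abs=1e-12)

    def test_negative_monotone_r_minus_one(self):
        x = np.arange(15, dtype=float)
        edges = spearman_network(pd.DataFrame({"a": x}), pd.DataFrame({"c": -x}))
        assert edges[0].r == pytest.approx(-1.0)
        assert edges[0].sign == -1

    def test_spectral_spectral_pairs_included(self):
        rng = np.random.default_rng(7)
        x = rng.random(40)
        sp = pd.DataFrame({"a": x, "b": x + 0.01 * rng.random(40)})
        edges = spearman_network(sp, pd.DataFrame({"c": rng.random(40)}))
        assert any({e.node_a, e.node_b} == {"a", "b"} for e in edges)

    def test_constant_variable_skipped_with_warning(self):
        rng = np.random.default_rng(8)
        sp = pd.DataFrame({"a": rng.random(20), "flat": np.ones(20)})
        with pytest.warns(UserWarning):
            edges = spearman_network(sp, pd.DataFrame({"c": rng.random(20)}))
        assert all("flat" not in (e.node_a, e.node_b) for e in edges)

    def test_bh_adjustment_is_more_conservative(self):
        rng = np.random.default_rng(9)
        sp = pd.DataFrame(rng.random((25, 6)), columns=[f"v{i}" for i in range(6)])
        cl = pd.DataFrame(rng.random((25, 4)), columns=list("wxyz"))
        raw = spearman_network(sp, cl, alpha=0.3)
        adj = spearman_network(sp, cl, alpha=0.3, adjust="bh")
        assert len(adj) <= len(raw)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            spearman_network(pd.DataFrame({"a": [1.0, 2.0]}),
                             pd.DataFrame({"c": [3.0, 4.0]}))
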