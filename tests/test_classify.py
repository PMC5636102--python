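"""LDA closed forms, Youden scan vs oracle, Monte Carlo CV bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirspec.io import ValidationError
from mirspec.classify import (
    CVConfig,
    fit_lda,
    mc_cross_validate,
    score,
    youden_cutoff,
)
from mirspec._stats import rank_auc


def brute_force_youden(scores, labels):
    """Independent exhaustive scan: every candidate cut, max J, the spec's
    tie-breaks (higher specificity, then lower cutoff)."""
    u = np.unique(scores)
    cands = np.concatenate([[-np.inf], (u[:-1] + u[1:]) / 2, [np.inf]])
    best = None
    for c in cands:
        called = scores > c
        sens = called[labels == 1].mean()
        spec = 1.0 - called[labels == 0].mean()
        key = (sens + spec - 1.0, spec, -c)
        if best is None or key > best[0]:
            best = (key, c)
    return best[1], best[0][0]


class TestFitLda:
    def test_one_dimensional_closed_form(self):
        X = np.array([-1.0, 1.0, 3.0, 5.0])[:, None]
        y = np.array([0, 0, 1, 1])
        m = fit_lda(X, y)
        assert m.weights[0] == pytest.approx(2.0, abs=1e-6)
        # boundary at x = 2 with equal empirical priors
        assert score(m, np.array([[2.0]]))[0] == pytest.approx(0.5, abs=1e-9)

    def test_two_variable_weights_match_closed_form(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((200, 2)) @ np.array([[1.0, 0.4], [0.0, 0.9]])
        y = (rng.random(200) < 0.5).astype(int)
        X[y == 1] += [0.8, -0.5]
        m = fit_lda(X, y, ridge=0.0)
        mu0, mu1 = X[y == 0].mean(0), X[y == 1].mean(0)
        Xc = X - np.where(y[:, None] == 1, mu1, mu0)
        Sig = Xc.T @ Xc / (len(y) - 2)
        assert np.allclose(m.weights, np.linalg.solve(Sig, mu1 - mu0), atol=1e-10)

    def test_equal_class_means_give_prior_scores(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.standard_normal((40, 3))] * 2)
        y = np.r_[np.zeros(40, dtype=int), np.ones(40, dtype=int)]
        m = fit_lda(X, y)
        assert np.allclose(m.weights, 0.0, atol=1e-10)
        assert np.allclose(score(m, X), 0.5, atol=1e-10)

    def test_missing_class_rejected(self):
        with pytest.raises(ValidationError):
            fit_lda(np.zeros((6, 1)), np.zeros(6, dtype=int))

    def test_too_many_variables_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValidationError):
            fit_lda(rng.standard_normal((10, 9)), np.r_[np.zeros(5, int), np.ones(5, int)])


class TestScore:
    def test_class_one_mean_with_delta_two(self):
        # plug-in: at the deceased mean with Mahalanobis 2 and equal priors the
        # posterior is 1/(1+e^-2)
        rng = np.random.default_rng(0)
        X = np.r_[rng.normal(0, 1, 60000), rng.normal(2, 1, 60000)][:, None]
        y = np.r_[np.zeros(60000, int), np.ones(60000, int)]
        m = fit_lda(X, y, priors=(0.5, 0.5))
        assert score(m, np.array([[2.0]]))[0] == pytest.approx(1 / (1 + np.exp(-2)), abs=0.01)

    def test_prior_offset_shifts_midpoint(self):
        X = np.array([-1.0, 1.0, 3.0, 5.0])[:, None]
        m = fit_lda(X, np.array([0, 0, 1, 1]), priors=(0.8, 0.2))
        assert score(m, np.array([[2.0]]))[0] == pytest.approx(0.2, abs=1e-9)

    def test_dimension_mismatch_rejected(self):
        m = fit_lda(np.array([-1.0, 1.0, 3.0, 5.0])[:, None], np.array([0, 0, 1, 1]))
        with pytest.raises(ValidationError):
            score(m, np.zeros((3, 2)))


class TestYoudenCutoff:
    def test_worked_example(self):
        cut, J = youden_cutoff(np.array([0.1, 0.2, 0.6, 0.5, 0.9]),
                               np.array([0, 0, 0, 1, 1]))
        assert cut == pytest.approx(0.35)
        assert J == pytest.approx(2 / 3)

    def test_perfect_separation(self):
        _, J = youden_cutoff(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert J == pytest.approx(1.0)

    def test_identical_scores_no_discrimination(self):
        cut, J = youden_cutoff(np.full(6, 0.4), np.array([0, 0, 0, 1, 1, 1]))
        assert J == 0.0

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 25))
        scores = np.round(rng.random(n), 2)
        labels = np.zeros(n, dtype=int)
        labels[rng.permutation(n)[: max(1, n // 3)]] = 1
        if labels.all() or not labels.any():
            return
        got = youden_cutoff(scores, labels)
        want = brute_force_youden(scores, labels)
        assert got[0] == want[0] and got[1] == pytest.approx(want[1])


class TestMcCrossValidate:
    def test_holdout_allocation_at_study_size(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((116, 3))
        y = np.r_[np.ones(23, int), np.zeros(93, int)]
        X[y == 1] += 1.5
        rep = mc_cross_validate(X, y, CVConfig(n_runs=10, seed=2))
        # every run holds out 12 samples: 2 deceased + 10 alive
        assert rep.times_held_out.sum() == 10 * 12

    def test_separable_data_gives_perfect_auroc(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 2))
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        X[y == 1] += 20.0
        rep = mc_cross_validate(X, y, CVConfig(n_runs=25, seed=3))
        assert rep.mean_auroc == 1.0
        assert rep.auroc_ci == (1.0, 1.0)

    def test_misclassification_bookkeeping_conserved(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 2))
        y = (rng.random(40) < 0.4).astype(int)
        X[y == 1] += 1.0
        rep = mc_cross_validate(X, y, CVConfig(n_runs=30, seed=5))
        assert (rep.times_misclassified <= rep.times_held_out).all()
        assert (rep.times_misclassified[rep.times_held_out == 0] == 0).all()
        assert rep.run_sensitivity.min() >= 0 and rep.run_specificity.max() <= 1

    def test_converges_to_resubstitution_at_large_n(self):
        rng = np.random.default_rng(8)
        n = 2000
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        X = rng.standard_normal((n, 5))
        X[y == 1, :2] += 0.8
        rep = mc_cross_validate(X, y, CVConfig(n_runs=40, seed=8))
        m = fit_lda(X, y)
        resub = rank_auc(score(m, X), y)
        assert abs(rep.mean_auroc - resub) < 0.01

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValidationError):
            mc_cross_validate(np.zeros((10, 1)), np.r_[np.zeros(5, int), np.ones(5, int)])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((50, 2))
        y = (rng.random(50) < 0.3).astype(int)
        X[y == 1] += 1.0
        a = mc_cross_validate(X, y, CVConfig(n_runs=15, seed=4))
        b = mc_cross_validate(X, y, CVConfig(n_runs=15, seed=4))
        assert np.array_equal(a.run_auroc, b.run_auroc)
        assert a.mean_cutoff == b.mean_cutoff
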