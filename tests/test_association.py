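"""Spearman screen, logistic fits, stepwise selection and ROC analysis."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteoscreen import (
    ConvergenceError,
    ValidationError,
    candidate_filter,
    multivariate_logit,
    roc_auc,
    spearman,
    stepwise_select,
    univariate_logit,
)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [10, 20, 30]).rho == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_tied_ranks_average(self):
        # ranks x: 1, 2.5, 2.5, 4; ranks y: 1, 3, 2, 4 -> Pearson on ranks = 3/sqrt(10)
        res = spearman([1, 2, 2, 4], [1, 3, 2, 4])
        assert res.rho == pytest.approx(3 / np.sqrt(10), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            spearman([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            spearman([1, 2], [3, 4])

    @settings(max_examples=50, deadline=None)
    @given(
        xs=st.lists(st.integers(-50, 50), min_size=4, max_size=20, unique=True),
        seed=st.integers(0, 100),
    )
    def test_monotone_transform_invariance(self, xs, seed):
        rng = np.random.default_rng(seed)
        xs = np.asarray(xs, dtype=float)
        ys = rng.normal(size=len(xs))
        base = spearman(xs, ys).rho
        transformed = spearman(np.exp(xs / 25.0), ys).rho
        assert transformed == pytest.approx(base, abs=1e-12)


class TestUnivariateLogit:
    def test_null_case(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 40)
        x = rng.normal(size=80)  # independent of y
        fit = univariate_logit(y, x, label="noise")
        assert fit.odds_ratio == pytest.approx(1.0, abs=0.5)
        assert fit.p_value > 0.05

    def test_binary_x_matches_cross_ratio(self):
        # 2x2 table: exposed 3/1, unexposed 1/3 -> OR = (3*3)/(1*1) = 9
        y = np.array([1, 1, 1, 0, 1, 0, 0, 0])
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        fit = univariate_logit(y, x, label="bin")
        assert fit.odds_ratio == pytest.approx(9.0, rel=1e-4)

    def test_direction_sign_symmetry(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=120)
        y = (rng.random(120) < 1 / (1 + np.exp(-x))).astype(int)
        neg = univariate_logit(y, x, direction=-1, label="v")
        pos = univariate_logit(y, -x, direction=1, label="v")
        assert neg.odds_ratio == pytest.approx(pos.odds_ratio, rel=1e-6)
        assert neg.ci95 == pytest.approx(pos.ci95, rel=1e-6)

    def test_perfect_separation_flagged(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        x = np.array([1.0, 2, 3, 4, 10, 11, 12, 13])
        with pytest.raises(ConvergenceError):
            univariate_logit(y, x, label="sep")

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError):
            univariate_logit(np.zeros(10), np.arange(10.0), label="v")


class TestCandidateFilter:
    def test_published_pvalue_pattern(self):
        """p<0.2 keeps grip, one-leg, TST, age, BMI; drops knee, stand-up, Locomo25."""
        pvals = {
            "grip": 0.03,
            "knee_ext": 0.55,
            "one_leg": 0.01,
            "tst": 0.005,
            "standup": 0.50,
            "locomo25": 0.21,
            "age": 0.005,
            "bmi": 0.01,
        }
        fits = [_stub_fit(label, p) for label, p in pvals.items()]
        kept = candidate_filter(fits)
        assert set(kept) == {"grip", "one_leg", "tst", "age", "bmi"}

    def test_strict_inequality_at_threshold(self):
        assert candidate_filter([_stub_fit("x", 0.2)]) == []

    def test_empty_input(self):
        assert candidate_filter([]) == []


def _stub_fit(label, p):
    from osteoscreen.association import LogisticFit

    return LogisticFit(
        label=label, direction=1, coefficient=0.0, odds_ratio=1.0, ci95=(1.0, 1.0),
        p_value=p, intercept=0.0,
    )


class TestStepwise:
    def test_single_strong_candidate_selected(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=300)
        y = (rng.random(300) < 1 / (1 + np.exp(-2 * x))).astype(int)
        selected, fits = stepwise_select(y, pd.DataFrame({"x": x}))
        assert selected == ["x"]
        assert fits["x"].p_value < 0.01

    def test_noise_selection_is_subset(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
        y = rng.integers(0, 2, size=500)
        selected, _ = stepwise_select(y, X)
        assert set(selected) <= set("abcd")

    def test_true_effects_recovered(self):
        """Strong planted effects on two columns are retained, noise dropped."""
        rng = np.random.default_rng(4)
        n = 500
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=["tst", "bmi", "n1", "n2"])
        lp = -1.2 * X["tst"] - 0.9 * X["bmi"] - 1.5
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
        selected, _ = stepwise_select(y, X, directions={"tst": -1, "bmi": -1})
        assert {"tst", "bmi"} <= set(selected)

    def test_p_criterion_variant(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        y = (rng.random(300) < 1 / (1 + np.exp(-2 * x))).astype(int)
        X = pd.DataFrame({"x": x, "noise": rng.normal(size=300)})
        selected, _ = stepwise_select(y, X, criterion="p")
        assert "x" in selected and "noise" not in selected

    def test_requires_candidates(self):
        with pytest.raises(ValidationError):
            stepwise_select(np.array([0, 1, 0, 1]), pd.DataFrame(index=range(4)))


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0

    def test_all_ties(self):
        res = roc_auc([5.0] * 8, [0, 1, 0, 1, 0, 1, 0, 1])
        assert res.auc == 0.5

    def test_hand_counted_pairs(self):
        # cases (1, 3, 3, 6) vs controls (2, 3, 4, 5):
        # concordant pairs: 16 comparisons -> 6 wins, 2 ties, 8 losses
        res = roc_auc([1, 3, 3, 6, 2, 3, 4, 5], [1, 1, 1, 1, 0, 0, 0, 0])
        assert res.auc == pytest.approx((6 + 0.5 * 2) / 16, abs=1e-15)

    def test_delong_ci_matches_reference_implementation(self):
        """CI frozen from an independent DeLong implementation (pROC)."""
        scores = [0.2, 1.3, 0.8, 2.4, 3.1, 0.5, 1.1, 2.2, 0.9, 1.8, 2.9, 0.4,
                  1.45, 2.05, 0.75, 1.3]
        labels = [0, 1, 0, 1, 1, 0, 0, 1, 0, 1, 1, 0, 1, 1, 0, 0]
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(0.9921875, abs=1e-12)
        assert res.ci95[0] == pytest.approx(0.970532752745, abs=1e-9)
        assert res.ci95[1] == pytest.approx(1.0, abs=1e-12)

    def test_delong_ci_with_ties_matches_reference(self):
        scores = [1.2, 0.7, 1.2, 2.0, 0.3, 1.5, 0.9, 1.2, 0.4, 1.7, 0.8, 1.1,
                  1.9, 0.6, 1.0, 1.3, 0.5, 1.6, 1.2, 0.2]
        labels = [1, 0, 0, 1, 0, 1, 0, 1, 0, 1, 0, 0, 1, 0, 1, 0, 0, 1, 1, 0]
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(0.924242424242, abs=1e-9)
        assert res.ci95[0] == pytest.approx(0.814660339463, abs=1e-9)

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1.0, 2.0], [1, 1])

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 1000), n=st.integers(6, 30))
    def test_negation_symmetry(self, seed, n):
        """AUC(s) + AUC(-s) = 1."""
        rng = np.random.default_rng(seed)
        s = rng.normal(size=n).round(1)  # rounding forces ties
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            return
        assert roc_auc(s, y).auc + roc_auc(-s, y).auc == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=25)
        y = rng.integers(0, 2, size=25)
        if y.min() == y.max():
            return
        assert roc_auc(np.exp(s), y).auc == pytest.approx(roc_auc(s, y).auc, abs=1e-12)

    def test_curve_is_monotone_staircase(self):
        rng = np.random.default_rng(9)
        s = rng.normal(size=40).round(1)
        y = rng.integers(0, 2, size=40)
        curve = np.array(roc_auc(s, y).curve)
        assert (np.diff(curve[:, 0]) >= -1e-15).all()
        assert (np.diff(curve[:, 1]) >= -1e-15).all()
        assert tuple(curve[0]) == (0.0, 0.0)
        assert tuple(curve[-1]) == (1.0, 1.0)
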