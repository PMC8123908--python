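"""Likelihood-ratio matrices, contingency counting and rule extraction."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteoscreen import (
    DecisionRule,
    LrMatrix,
    Roster,
    TwoByTwo,
    ValidationError,
    contingency,
    extract_rules,
    likelihood_ratios,
    lr_matrix,
)
from osteoscreen.bmd import BmdCategory, classify_record

from .conftest import make_record, random_roster


def _exact_lr(t: TwoByTwo):
    """Independent oracle: exact rational sens/spec/LR+/LR-."""
    sens = Fraction(t.tp, t.tp + t.fn)
    spec = Fraction(t.tn, t.fp + t.tn)
    lr_pos = sens / (1 - spec) if spec < 1 else (math.inf if sens > 0 else 0.0)
    lr_neg = (1 - sens) / spec if spec > 0 else math.inf
    return sens, spec, lr_pos, lr_neg


class TestLikelihoodRatios:
    def test_hand_worked_table(self):
        cell = likelihood_ratios(TwoByTwo(tp=9, fn=3, fp=10, tn=40))
        assert cell.sens == pytest.approx(0.75)
        assert cell.spec == pytest.approx(0.8)
        assert cell.lr_pos == pytest.approx(3.75)
        assert cell.lr_neg == pytest.approx(0.3125)

    def test_perfect_test(self):
        cell = likelihood_ratios(TwoByTwo(tp=10, fn=0, fp=0, tn=10))
        assert cell.lr_pos == math.inf
        assert cell.lr_neg == 0.0

    def test_chance_line(self):
        # sens = 1 - spec = 0.5 -> LR+ = 1
        cell = likelihood_ratios(TwoByTwo(tp=5, fn=5, fp=5, tn=5))
        assert cell.lr_pos == pytest.approx(1.0)

    def test_haldane_correction(self):
        cell = likelihood_ratios(TwoByTwo(tp=10, fn=0, fp=0, tn=10), zero_cell="haldane")
        assert math.isfinite(cell.lr_pos)
        assert cell.lr_pos > 1

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValidationError):
            likelihood_ratios(TwoByTwo(tp=0, fn=0, fp=3, tn=4))

    @settings(max_examples=200, deadline=None)
    @given(
        tp=st.integers(0, 40), fn=st.integers(0, 40), fp=st.integers(0, 40), tn=st.integers(0, 40)
    )
    def test_matches_exact_rational_oracle(self, tp, fn, fp, tn):
        if tp + fn == 0 or fp + tn == 0:
            return
        t = TwoByTwo(tp, fn, fp, tn)
        cell = likelihood_ratios(t)
        sens, spec, lr_pos, lr_neg = _exact_lr(t)
        assert cell.sens == pytest.approx(float(sens), abs=1e-15)
        assert cell.spec == pytest.approx(float(spec), abs=1e-15)
        if math.isfinite(float(lr_pos)):
            assert cell.lr_pos == pytest.approx(float(lr_pos), rel=1e-12)
        else:
            assert cell.lr_pos == lr_pos
        if math.isfinite(float(lr_neg)):
            assert cell.lr_neg == pytest.approx(float(lr_neg), rel=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(
        tp=st.integers(0, 20), fn=st.integers(0, 20), fp=st.integers(0, 20),
        tn=st.integers(0, 20), k=st.integers(1, 7),
    )
    def test_prevalence_invariance_under_scaling(self, tp, fn, fp, tn, k):
        """Multiplying all counts by a positive integer leaves LR+/LR- unchanged."""
        if tp + fn == 0 or fp + tn == 0:
            return
        a = likelihood_ratios(TwoByTwo(tp, fn, fp, tn))
        b = likelihood_ratios(TwoByTwo(tp, fn, fp, tn).scaled(k))
        assert a.lr_pos == b.lr_pos
        if not math.isnan(a.lr_neg):  # LR- undefined when tn = 0 and sens = 1
            assert a.lr_neg == b.lr_neg
        else:
            assert math.isnan(b.lr_neg)

    @settings(max_examples=100, deadline=None)
    @given(
        tp=st.integers(1, 30), fn=st.integers(1, 30), fp=st.integers(1, 30), tn=st.integers(1, 30)
    )
    def test_lr_ordering_when_informative(self, tp, fn, fp, tn):
        cell = likelihood_ratios(TwoByTwo(tp, fn, fp, tn))
        if cell.sens + cell.spec > 1:
            assert cell.lr_pos > 1 > cell.lr_neg


class TestContingency:
    def test_all_positive_diseased(self):
        t = -3.0
        records = tuple(
            make_record(id=f"r{i}", bmi=20.0, tst=1.0, tscores=(t, t, t, t, t)) for i in range(5)
        )
        table = contingency(Roster(records=records), bmi_cut=25.0, tst_cut=1.5)
        assert (table.tp, table.fn, table.fp, table.tn) == (5, 0, 0, 0)

    def test_cutoffs_below_all_data(self):
        roster = random_roster(np.random.default_rng(0), n=20)
        table = contingency(roster, bmi_cut=5.0, tst_cut=0.1)
        assert table.tp == 0 and table.fp == 0
        assert table.tp + table.fn + table.fp + table.tn == 20

    def test_hand_enumerated_roster(self):
        spec = [
            # (bmi, tst, t_rep) -> positivity at (22.0, 1.30), disease at -2.5
            (21.0, 1.25, -3.0),  # tp
            (22.0, 1.30, -2.5),  # tp (boundary inclusive on all three)
            (23.0, 1.25, -3.0),  # fn (bmi above cut)
            (21.5, 1.40, -0.5),  # tn
            (21.5, 1.28, -1.5),  # fp
            (25.0, 1.50, -2.6),  # fn
        ]
        records = tuple(
            make_record(id=f"h{i}", bmi=b, tst=ts, tscores=(t, t, t, t, t))
            for i, (b, ts, t) in enumerate(spec)
        )
        table = contingency(Roster(records=records), bmi_cut=22.0, tst_cut=1.30)
        assert (table.tp, table.fn, table.fp, table.tn) == (2, 2, 1, 1)

    def test_missing_values_named(self):
        records = (
            make_record(id="ok"),
            make_record(id="gap", flags={"incomplete_tests"}, tst=None),
        )
        with pytest.raises(ValidationError, match="gap"):
            contingency(Roster(records=records), 22.0, 1.3)


class TestLrMatrix:
    def test_single_cell_equals_direct_computation(self):
        roster = random_roster(np.random.default_rng(1), n=60)
        m = lr_matrix(roster, (22.0,), (1.3,))
        direct = likelihood_ratios(contingency(roster, 22.0, 1.3))
        cell = m.cell(22.0, 1.3)
        assert cell.lr_pos == direct.lr_pos
        assert cell.lr_neg == direct.lr_neg

    def test_unsorted_grid_rejected(self):
        roster = random_roster(np.random.default_rng(2), n=20)
        with pytest.raises(ValidationError):
            lr_matrix(roster, (23.0, 22.0), (1.3,))

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_recount(self, seed):
        """Every cell equals an independent per-record enumeration."""
        rng = np.random.default_rng(seed)
        roster = random_roster(rng, n=40)
        bmi_grid = tuple(sorted(rng.uniform(18, 28, size=3)))
        tst_grid = tuple(sorted(rng.uniform(1.0, 1.6, size=3)))
        diseased = [classify_record(r) is BmdCategory.OSTEOPOROSIS for r in roster]
        try:
            m = lr_matrix(roster, bmi_grid, tst_grid)
        except ValidationError:
            return  # no diseased (or no healthy) subjects in this draw
        for b in bmi_grid:
            for t in tst_grid:
                tp = sum(1 for r, d in zip(roster, diseased) if d and r.tst <= t and r.bmi <= b)
                fn = sum(1 for r, d in zip(roster, diseased) if d and not (r.tst <= t and r.bmi <= b))
                fp = sum(1 for r, d in zip(roster, diseased) if not d and r.tst <= t and r.bmi <= b)
                tn = len(roster) - tp - fn - fp
                cell = m.cell(b, t)
                sens = tp / (tp + fn)
                spec = tn / (fp + tn)
                assert cell.sens == pytest.approx(sens, abs=1e-15)
                assert cell.spec == pytest.approx(spec, abs=1e-15)


class TestExtractRules:
    def test_published_matrix_rule_set(self, published_lr_matrix):
        """The published rule set emerges: (1.24, any), (1.30, 23.4),
        (1.32, 22.4), (1.34, 21.6); no exclude rules at threshold 0.2."""
        rules = extract_rules(published_lr_matrix, 5.0, 0.2)
        suspects = {(r.tst_cut, r.bmi_cut) for r in rules if r.kind == "suspect"}
        assert (1.24, None) in suspects
        assert (1.30, 23.4) in suspects
        assert (1.32, 22.4) in suspects
        assert (1.34, 21.6) in suspects
        assert not [r for r in rules if r.kind == "exclude"]

    def test_containment_prune_keeps_maximal_regions(self, published_lr_matrix):
        rules = extract_rules(published_lr_matrix, 5.0, 0.2, prune="containment")
        suspects = {(r.tst_cut, r.bmi_cut) for r in rules if r.kind == "suspect"}
        assert suspects == {(1.24, None), (1.30, 23.4), (1.32, 22.4), (1.36, 21.6)}

    def test_no_qualifying_cells(self):
        m = LrMatrix.from_values((21.0, 22.0), (1.3, 1.4), [[2.0, 1.5], [1.2, 1.1]],
                                 [[0.7, 0.8], [0.9, 0.9]])
        assert extract_rules(m, 5.0, 0.2) == []

    def test_single_qualifying_cell(self):
        m = LrMatrix.from_values(
            (21.0, 22.0), (1.3, 1.4), [[6.0, 2.0], [3.0, 1.0]], [[0.9, 0.9], [0.9, 0.9]]
        )
        rules = extract_rules(m, 5.0, 0.2)
        assert [(r.tst_cut, r.bmi_cut, r.kind) for r in rules] == [(1.3, 21.0, "suspect")]

    def test_pareto_prune_drops_strictly_redundant_rule(self):
        # column 1.4 covers column 1.3's region with an equal-or-better
        # worst-case LR, so (1.3, 21.0) is redundant
        m = LrMatrix.from_values(
            (21.0, 22.0), (1.3, 1.4), [[6.0, 7.0], [3.0, 2.0]], [[0.9] * 2] * 2
        )
        rules = extract_rules(m, 5.0, 0.2)
        assert [(r.tst_cut, r.bmi_cut) for r in rules] == [(1.4, 21.0)]

    def test_whole_column_becomes_any_bmi(self):
        m = LrMatrix.from_values((21.0, 22.0), (1.3,), [[8.0], [6.0]], [[0.9], [0.9]])
        rules = extract_rules(m, 5.0, 0.2)
        assert rules[0].bmi_cut is None
        assert rules[0].guaranteed_lr == 6.0

    def test_exclude_rules_extracted(self):
        m = LrMatrix.from_values(
            (21.0, 22.0), (1.3,), [[1.0], [1.0]], [[0.1], [0.3]]
        )
        rules = extract_rules(m, 5.0, 0.2)
        excludes = [(r.tst_cut, r.bmi_cut) for r in rules if r.kind == "exclude"]
        assert excludes == [(1.3, 21.0)]

    def test_rules_pareto_non_dominated(self, published_lr_matrix):
        """No kept suspect rule is contained in another with an at-least-as-
        strong worst-case LR guarantee."""
        rules = [r for r in extract_rules(published_lr_matrix, 5.0, 0.2) if r.kind == "suspect"]
        for a in rules:
            for b in rules:
                if b is a:
                    continue
                assert not (b.contains(a) and b.guaranteed_lr >= a.guaranteed_lr)

    def test_rule_region_membership(self):
        any_rule = DecisionRule(tst_cut=1.24, bmi_cut=None, kind="suspect", guaranteed_lr=5.0)
        assert any_rule.applies(tst=1.20, bmi=30.0)
        bounded = DecisionRule(tst_cut=1.30, bmi_cut=23.4, kind="suspect", guaranteed_lr=5.2)
        assert bounded.applies(tst=1.30, bmi=23.4)
        assert not bounded.applies(tst=1.31, bmi=20.0)
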