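"""Dual-cutoff likelihood-ratio matrices over BMI x two-step test (TST).

A candidate screening test is "positive" when a participant lies at or below
BOTH cutoffs (tst <= tst_cut AND bmi <= bmi_cut); disease is osteoporosis by
the five-site minimum T-score (<= -2.5).  For every cutoff pair on a grid we
form the 2x2 table against osteoporosis status and compute sensitivity,
specificity, LR+ = sens/(1-spec) and LR- = (1-sens)/spec.  Likelihood ratios
are prevalence-invariant: scaling all four counts leaves them unchanged.

Decision rules are read off the matrix column-wise (one column per TST
cutoff): the rule (tst_cut, b) qualifies as a "suspect" rule when EVERY cell
of that column with bmi_cut <= b reaches LR+ >= pos_threshold (the prefix
convention, which makes nested rule sets well defined); if the whole column
qualifies the BMI bound is "any".  "Exclude" rules are extracted analogously
with LR- <= neg_threshold.  Pruning (see :func:`extract_rules`) then removes
rules made redundant by a rule that both covers their region and guarantees
at least as strong a likelihood ratio.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bmd import BmdCategory, classify_record
from .cohort import Roster, ValidationError

__all__ = [
    "DEFAULT_BMI_GRID",
    "DEFAULT_TST_GRID",
    "TwoByTwo",
    "LrCell",
    "LrMatrix",
    "DecisionRule",
    "contingency",
    "likelihood_ratios",
    "lr_matrix",
    "extract_rules",
]

#: Default cutoff grids over which the matrices are evaluated.
DEFAULT_BMI_GRID = (21.0, 21.6, 22.2, 22.4, 23.0, 23.4, 23.8, 24.0)
DEFAULT_TST_GRID = (1.24, 1.26, 1.28, 1.30, 1.32, 1.34, 1.36, 1.38)


@dataclass(frozen=True)
class TwoByTwo:
    """Counts for one cutoff pair: tp = test-positive AND osteoporosis."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_nondiseased(self) -> int:
        return self.fp + self.tn

    def scaled(self, k: int) -> "TwoByTwo":
        return TwoByTwo(self.tp * k, self.fn * k, self.fp * k, self.tn * k)


@dataclass(frozen=True)
class LrCell:
    """Diagnostic summary at one (bmi_cut, tst_cut) pair.

    ``sens``/``spec`` may be None when the cell was entered directly from a
    published matrix rather than computed from counts.
    """

    bmi_cut: float
    tst_cut: float
    lr_pos: float
    lr_neg: float
    sens: Optional[float] = None
    spec: Optional[float] = None


def contingency(roster: Roster, bmi_cut: float, tst_cut: float) -> TwoByTwo:
    """2x2 counts of (tst <= tst_cut AND bmi <= bmi_cut) against osteoporosis."""
    tp = fn = fp = tn = 0
    bad = []
    for record in roster:
        if record.bmi is None or record.tst is None or not record.site_tscores:
            bad.append(record.id)
            continue
        positive = record.tst <= tst_cut and record.bmi <= bmi_cut
        diseased = classify_record(record) is BmdCategory.OSTEOPOROSIS
        if positive and diseased:
            tp += 1
        elif positive:
            fp += 1
        elif diseased:
            fn += 1
        else:
            tn += 1
    if bad:
        raise ValidationError(f"records missing BMI/TST/T-scores: {bad}")
    return TwoByTwo(tp=tp, fn=fn, fp=fp, tn=tn)


def likelihood_ratios(
    t: TwoByTwo, *, bmi_cut: float = math.nan, tst_cut: float = math.nan, zero_cell: str = "inf"
) -> LrCell:
    """Sens, spec, LR+ and LR- from a 2x2 table.

    ``zero_cell='inf'`` (default) reports LR+ = +inf when fp = 0 and sens > 0,
    and LR- on the raw counts; ``zero_cell='haldane'`` adds 0.5 to every count
    first (continuity correction).
    """
    if t.n_diseased == 0 or t.n_nondiseased == 0:
        raise ValidationError("both diseased and non-diseased subjects are required")
    if zero_cell == "haldane":
        tp, fn, fp, tn = (t.tp + 0.5, t.fn + 0.5, t.fp + 0.5, t.tn + 0.5)
    elif zero_cell == "inf":
        tp, fn, fp, tn = float(t.tp), float(t.fn), float(t.fp), float(t.tn)
    else:
        raise ValidationError(f"unknown zero_cell policy {zero_cell!r}")
    sens = tp / (tp + fn)
    spec = tn / (fp + tn)
    if spec < 1.0:
        lr_pos = sens / (1.0 - spec)
    else:
        lr_pos = math.inf if sens > 0 else 0.0
    if spec > 0.0:
        lr_neg = (1.0 - sens) / spec
    else:
        lr_neg = math.inf if sens < 1.0 else math.nan
    return LrCell(bmi_cut=bmi_cut, tst_cut=tst_cut, sens=sens, spec=spec, lr_pos=lr_pos, lr_neg=lr_neg)


@dataclass(frozen=True)
class LrMatrix:
    """Grid of :class:`LrCell` over ordered BMI (rows) and TST (columns) cutoffs."""

    bmi_cutoffs: tuple
    tst_cutoffs: tuple
    cells: tuple  # tuple of rows, each a tuple of LrCell

    def __post_init__(self) -> None:
        if len(self.cells) != len(self.bmi_cutoffs) or any(
            len(row) != len(self.tst_cutoffs) for row in self.cells
        ):
            raise ValidationError("grid dimensions must match the cutoff lists")

    def cell(self, bmi_cut: float, tst_cut: float) -> LrCell:
        i = self.bmi_cutoffs.index(bmi_cut)
        j = self.tst_cutoffs.index(tst_cut)
        return self.cells[i][j]

    @classmethod
    def from_values(
        cls,
        bmi_cutoffs: Sequence[float],
        tst_cutoffs: Sequence[float],
        lr_pos: Sequence[Sequence[float]],
        lr_neg: Sequence[Sequence[float]],
    ) -> "LrMatrix":
        """Build a matrix from published LR values (sens/spec unknown)."""
        bmi_cutoffs = tuple(float(b) for b in bmi_cutoffs)
        tst_cutoffs = tuple(float(t) for t in tst_cutoffs)
        cells = tuple(
            tuple(
                LrCell(bmi_cut=b, tst_cut=t, lr_pos=float(lr_pos[i][j]), lr_neg=float(lr_neg[i][j]))
                for j, t in enumerate(tst_cutoffs)
            )
            for i, b in enumerate(bmi_cutoffs)
        )
        return cls(bmi_cutoffs=bmi_cutoffs, tst_cutoffs=tst_cutoffs, cells=cells)

    def to_frame(self, which: str = "lr_pos", *, round_to: Optional[int] = None) -> pd.DataFrame:
        """Matrix as a DataFrame (BMI rows x TST columns); optional display rounding."""
        data = [[getattr(c, which) for c in row] for row in self.cells]
        df = pd.DataFrame(data, index=list(self.bmi_cutoffs), columns=list(self.tst_cutoffs))
        df.index.name = "bmi_cut"
        df.columns.name = "tst_cut"
        return df.round(round_to) if round_to is not None else df


def lr_matrix(
    roster: Roster,
    bmi_cutoffs: Sequence[float] = DEFAULT_BMI_GRID,
    tst_cutoffs: Sequence[float] = DEFAULT_TST_GRID,
    *,
    zero_cell: str = "inf",
) -> LrMatrix:
    """Likelihood-ratio matrix: one cell per (bmi_cut, tst_cut) pair."""
    bmi_cutoffs = tuple(float(b) for b in bmi_cutoffs)
    tst_cutoffs = tuple(float(t) for t in tst_cutoffs)
    if not bmi_cutoffs or not tst_cutoffs:
        raise ValidationError("cutoff lists must be non-empty")
    if list(bmi_cutoffs) != sorted(bmi_cutoffs) or list(tst_cutoffs) != sorted(tst_cutoffs):
        raise ValidationError("cutoff lists must be sorted ascending")
    cells = tuple(
        tuple(
            likelihood_ratios(contingency(roster, b, t), bmi_cut=b, tst_cut=t, zero_cell=zero_cell)
            for t in tst_cutoffs
        )
        for b in bmi_cutoffs
    )
    return LrMatrix(bmi_cutoffs=bmi_cutoffs, tst_cutoffs=tst_cutoffs, cells=cells)


@dataclass(frozen=True)
class DecisionRule:
    """A screening rule: flag when tst <= tst_cut and bmi <= bmi_cut.

    ``bmi_cut=None`` means "any BMI".  ``kind`` is ``suspect`` (rule-in, from
    LR+) or ``exclude`` (rule-out, from LR-).  ``guaranteed_lr`` is the
    worst cell value over the qualifying column prefix: the minimum LR+ for
    suspect rules, the maximum LR- for exclude rules.
    """

    tst_cut: float
    bmi_cut: Optional[float]
    kind: str
    guaranteed_lr: float

    @property
    def any_bmi(self) -> bool:
        return self.bmi_cut is None

    def contains(self, other: "DecisionRule") -> bool:
        """True when this rule's region contains the other's."""
        if other.tst_cut > self.tst_cut:
            return False
        return self.any_bmi or (not other.any_bmi and other.bmi_cut <= self.bmi_cut)

    def applies(self, tst: float, bmi: float) -> bool:
        return tst <= self.tst_cut and (self.any_bmi or bmi <= self.bmi_cut)

    def to_dict(self) -> dict:
        return {
            "tst_cut": self.tst_cut,
            "bmi_cut": "any" if self.any_bmi else self.bmi_cut,
            "kind": self.kind,
            "guaranteed_lr": self.guaranteed_lr,
        }


def _column_rules(m: LrMatrix, threshold: float, kind: str) -> list:
    """Per-column prefix qualification: the largest BMI bound whose whole
    prefix of cells meets the threshold."""
    rules = []
    for j, t in enumerate(m.tst_cutoffs):
        worst = None
        bound_idx = -1
        for i in range(len(m.bmi_cutoffs)):
            v = m.cells[i][j].lr_pos if kind == "suspect" else m.cells[i][j].lr_neg
            ok = v >= threshold if kind == "suspect" else v <= threshold
            if not ok:
                break
            worst = v if worst is None else (min(worst, v) if kind == "suspect" else max(worst, v))
            bound_idx = i
        if bound_idx >= 0:
            whole_column = bound_idx == len(m.bmi_cutoffs) - 1
            rules.append(
                DecisionRule(
                    tst_cut=m.tst_cutoffs[j],
                    bmi_cut=None if whole_column else m.bmi_cutoffs[bound_idx],
                    kind=kind,
                    guaranteed_lr=float(worst),
                )
            )
    return rules


def _prune(rules: list, kind: str, how: str) -> list:
    if how == "none":
        return list(rules)
    kept = []
    for a in rules:
        dominated = False
        for b in rules:
            if b is a or not b.contains(a):
                continue
            if how == "containment":
                dominated = True
            elif how == "lr_pareto":
                # redundant only if the covering rule's guarantee is at least as strong
                better = (
                    b.guaranteed_lr >= a.guaranteed_lr
                    if kind == "suspect"
                    else b.guaranteed_lr <= a.guaranteed_lr
                )
                dominated = better
            else:
                raise ValidationError(f"unknown prune policy {how!r}")
            if dominated:
                break
        if not dominated:
            kept.append(a)
    return kept


def extract_rules(
    m: LrMatrix,
    pos_threshold: float = 5.0,
    neg_threshold: float = 0.2,
    *,
    prune: str = "lr_pareto",
) -> list:
    """Suspect (LR+ >= pos_threshold) and exclude (LR- <= neg_threshold) rules.

    Qualification uses the column-prefix convention described in the module
    docstring.  ``prune`` controls redundancy removal:

    * ``'lr_pareto'`` (default): drop a rule only when another rule both
      contains its region and guarantees an at-least-as-strong worst-case LR
      over its prefix — a covered rule with a strictly better LR guarantee is
      kept, since it offers higher confirmatory value on its narrower region;
    * ``'containment'``: drop any rule whose region another rule contains;
    * ``'none'``: keep every qualifying column rule.
    """
    out = []
    out.extend(_prune(_column_rules(m, pos_threshold, "suspect"), "suspect", prune))
    out.extend(_prune(_column_rules(m, neg_threshold, "exclude"), "exclude", prune))
    return out


def rules_to_json(rules: Sequence[DecisionRule]) -> str:
    return json.dumps([r.to_dict() for r in rules], indent=2)
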