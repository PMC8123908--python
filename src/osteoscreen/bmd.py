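"""Representative T-score, WHO classification, prevalence, age standardization.

The representative bone status of a participant is the minimum T-score over
the five DXA sites (L2-4 spine, bilateral femoral neck, bilateral total hip).
WHO bands: T >= -1 healthy, -2.5 < T < -1 osteopenia, T <= -2.5 osteoporosis
(both boundaries inclusive on the outer bands).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .cohort import Roster, ValidationError

__all__ = [
    "AGE_STRATA",
    "BmdCategory",
    "PrevalenceTable",
    "representative_tscore",
    "classify_bmd",
    "stratum_label",
    "prevalence_table",
    "age_standardize",
]

#: Decade strata of the study design (inclusive bounds).
AGE_STRATA = ((50, 59), (60, 69), (70, 79), (80, 89))


class BmdCategory(enum.Enum):
    HEALTHY = "healthy"
    OSTEOPENIA = "osteopenia"
    OSTEOPOROSIS = "osteoporosis"


def representative_tscore(scores: Iterable[Optional[float]]) -> float:
    """Minimum of the provided (non-missing) site T-scores."""
    vals = [float(s) for s in scores if s is not None]
    if not vals:
        raise ValidationError("representative_tscore requires at least one non-missing score")
    if any(not math.isfinite(v) for v in vals):
        raise ValidationError("T-scores must be finite")
    return min(vals)


def classify_bmd(t: float) -> BmdCategory:
    """WHO band for a representative T-score (boundaries: -1 healthy, -2.5 osteoporosis)."""
    t = float(t)
    if not math.isfinite(t):
        raise ValidationError(f"T-score must be finite, got {t}")
    if t >= -1.0:
        return BmdCategory.HEALTHY
    if t <= -2.5:
        return BmdCategory.OSTEOPOROSIS
    return BmdCategory.OSTEOPENIA


def classify_record(record) -> BmdCategory:
    """Category from a participant's five-site minimum T-score."""
    return classify_bmd(representative_tscore(record.site_tscores))


def stratum_label(age: int) -> str:
    for lo, hi in AGE_STRATA:
        if lo <= age <= hi:
            return f"{lo}-{hi}"
    raise ValidationError(f"age {age} outside the 50-89 study range")


@dataclass(frozen=True)
class PrevalenceTable:
    """Per-stratum and pooled category counts with fractions.

    ``counts``: DataFrame indexed by stratum label (plus a ``total`` row),
    one column per :class:`BmdCategory` value, plus ``n``.
    """

    counts: pd.DataFrame

    @property
    def fractions(self) -> pd.DataFrame:
        cats = [c.value for c in BmdCategory]
        return self.counts[cats].div(self.counts["n"], axis=0)

    def pooled_fraction(self, category: BmdCategory) -> float:
        return float(self.counts.loc["total", category.value] / self.counts.loc["total", "n"])

    def stratum_fraction(self, stratum: str, category: BmdCategory) -> float:
        return float(self.counts.loc[stratum, category.value] / self.counts.loc[stratum, "n"])


def prevalence_table(roster: Roster) -> PrevalenceTable:
    """Counts of healthy / osteopenia / osteoporosis per decade stratum and pooled."""
    labels = [f"{lo}-{hi}" for lo, hi in AGE_STRATA]
    cats = [c.value for c in BmdCategory]
    counts = pd.DataFrame(0, index=labels + ["total"], columns=cats + ["n"])
    for record in roster:
        try:
            stratum = stratum_label(record.age)
        except ValidationError as exc:
            raise ValidationError(f"record {record.id}: {exc}") from exc
        cat = classify_record(record).value
        counts.loc[stratum, cat] += 1
        counts.loc[stratum, "n"] += 1
        counts.loc["total", cat] += 1
        counts.loc["total", "n"] += 1
    return PrevalenceTable(counts=counts)


def age_standardize(
    stratum_prevalences: Mapping[str, float], weights: Mapping[str, float]
) -> float:
    """Directly age-standardized prevalence, sum_s w_s * p_s.

    ``weights`` must cover exactly the strata of ``stratum_prevalences`` and
    sum to 1 (tolerance 1e-9).  No default reference population is shipped:
    reproducing a published age-adjusted rate requires the external standard
    population actually used.
    """
    if set(stratum_prevalences) != set(weights):
        raise ValidationError(
            f"strata mismatch: prevalences {sorted(stratum_prevalences)} vs weights {sorted(weights)}"
        )
    wsum = float(sum(weights.values()))
    if any(w < 0 for w in weights.values()):
        raise ValidationError("weights must be non-negative")
    if abs(wsum - 1.0) > 1e-9:
        raise ValidationError(f"weights must sum to 1, got {wsum!r}")
    return float(sum(weights[s] * stratum_prevalences[s] for s in stratum_prevalences))
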