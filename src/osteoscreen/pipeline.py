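"""End-to-end pipeline: cohort -> classification -> association -> LR rules.

``run_pipeline`` executes the full analysis sequence on a loaded or simulated
cohort and writes a deterministic report bundle:

* ``table1.csv``  baseline characteristics by age stratum
* ``table2.csv``  prevalence of the WHO categories by stratum (+ pooled row)
* ``table4.csv``  Spearman correlations of candidates vs site T-scores
* ``table5.csv``  univariate and multivariate (stepwise) odds ratios
* ``roc.csv`` / ``auc.json``  ROC points and AUC with DeLong CI
* ``table6.csv`` / ``table7.csv``  LR+ / LR- matrices (display-rounded, with
  ``*_full.csv`` companions at full precision)
* ``rules.json``  extracted screening rules
* ``run.json``    seed, config hash, library versions

Identical config + seed reproduce byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import bmd, screening
from .cohort import Roster, ValidationError, apply_eligibility, read_cohort_csv
from .synthetic import SyntheticCohortConfig, generate_cohort

logger = logging.getLogger("osteoscreen")
if not logger.handlers:  # stderr handler with machine-greppable warnings
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s:%(name)s:%(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "analysis_frame"]

#: Candidate variables in report order, with the per-unit direction used for
#: odds ratios (e.g. grip strength per -1 kg).
CANDIDATE_DIRECTIONS = {
    "grip": -1,
    "knee_ext": -1,
    "one_leg": -1,
    "tst": -1,
    "standup": -1,
    "locomo25": 1,
    "age": 1,
    "bmi": -1,
}


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline settings; exactly one of ``input_csv`` / ``simulate`` is set.

    ``offer_age`` controls whether age enters the stepwise candidate pool
    (default False: the screening model is derived from the modifiable
    performance measures plus BMI; age always appears in the univariate
    table).
    """

    input_csv: Optional[str] = None
    simulate: Optional[SyntheticCohortConfig] = None
    seed: int = 0
    bmi_grid: tuple = screening.DEFAULT_BMI_GRID
    tst_grid: tuple = screening.DEFAULT_TST_GRID
    pos_threshold: float = 5.0
    neg_threshold: float = 0.2
    zero_cell: str = "inf"
    prune: str = "lr_pareto"
    stepwise_criterion: str = "aic"
    p_entry: float = 0.2
    offer_age: bool = False
    ci_method: str = "delong"
    standardize_weights: Optional[tuple] = None  # ((stratum, weight), ...)
    outdir: str = "osteoscreen_out"

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.simulate is None):
            raise ValidationError("exactly one of input_csv / simulate must be provided")

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "simulate" in d and d["simulate"] is not None:
            sim = d["simulate"]
            if isinstance(sim, Mapping):
                sim = dict(sim)
                if "strata_sizes" in sim:
                    sim["strata_sizes"] = tuple(sim["strata_sizes"])
                sim = SyntheticCohortConfig(**sim)
            d["simulate"] = sim
        for key in ("bmi_grid", "tst_grid"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("standardize_weights") is not None and isinstance(d["standardize_weights"], Mapping):
            d["standardize_weights"] = tuple(sorted(d["standardize_weights"].items()))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass(frozen=True)
class PipelineResult:
    outdir: Path
    paths: dict
    roster: Roster
    selected: tuple
    auc: float
    rules: tuple


def analysis_frame(roster: Roster) -> pd.DataFrame:
    """Analysis table: derived columns plus representative T-score and status."""
    df = roster.to_frame()
    reps = []
    cats = []
    for r in roster:
        t = bmd.representative_tscore(r.site_tscores)
        reps.append(t)
        cats.append(bmd.classify_bmd(t).value)
    df["tscore_rep"] = reps
    df["category"] = cats
    df["osteoporosis"] = (df["category"] == "osteoporosis").astype(int)
    df["stratum"] = [bmd.stratum_label(a) for a in df["age"]]
    return df


def _table1(df: pd.DataFrame) -> pd.DataFrame:
    cols = ["height", "weight", "bmi", "tscore_l24", "tscore_neck", "tscore_hip"]
    rows = []
    strata = [f"{lo}-{hi}" for lo, hi in bmd.AGE_STRATA]
    for label in strata + ["total"]:
        sub = df if label == "total" else df[df["stratum"] == label]
        row = {"stratum": label, "n": len(sub)}
        for c in cols:
            row[f"{c}_mean"] = sub[c].mean()
            row[f"{c}_sd"] = sub[c].std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows)


def _table4(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for var in CANDIDATE_DIRECTIONS:
        for tvar in ("tscore_l24", "tscore_neck", "tscore_hip"):
            res = assoc.spearman(df[var], df[tvar], x_label=var, y_label=tvar)
            rows.append(
                {"variable": var, "against": tvar, "rho": res.rho, "p_value": res.p_value, "n": res.n}
            )
    return pd.DataFrame(rows)


def _fit_univariate(df: pd.DataFrame) -> list:
    fits = []
    for var, direction in CANDIDATE_DIRECTIONS.items():
        try:
            fits.append(
                assoc.univariate_logit(df["osteoporosis"], df[var], direction=direction, label=var)
            )
        except assoc.ConvergenceError as exc:
            logger.warning("WARNING: univariate fit for %s did not converge: %s", var, exc)
    return fits


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write the report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict = {}

    def stage(name: str):
        logger.info("stage: %s", name)

    # --- cohort ---------------------------------------------------------
    stage("cohort")
    if config.input_csv is not None:
        roster = read_cohort_csv(config.input_csv)
    else:
        roster = generate_cohort(config.simulate, seed=config.seed)
    roster, exclusion = apply_eligibility(roster)
    if len(roster) == 0:
        raise ValidationError("no records remain after the eligibility cascade")
    df = analysis_frame(roster)

    # --- descriptive tables --------------------------------------------
    stage("baseline")
    t1 = _table1(df)
    paths["table1"] = outdir / "table1.csv"
    t1.round(4).to_csv(paths["table1"], index=False)

    stage("prevalence")
    prev = bmd.prevalence_table(roster)
    t2 = prev.counts.copy()
    for cat in bmd.BmdCategory:
        t2[f"{cat.value}_pct"] = (100.0 * t2[cat.value] / t2["n"]).round(1)
    paths["table2"] = outdir / "table2.csv"
    t2.to_csv(paths["table2"], index_label="stratum")

    if config.standardize_weights is not None:
        weights = dict(config.standardize_weights)
        adjusted = {
            cat.value: bmd.age_standardize(
                {s: prev.stratum_fraction(s, cat) for s in weights}, weights
            )
            for cat in bmd.BmdCategory
        }
        paths["standardized"] = outdir / "standardized.json"
        paths["standardized"].write_text(json.dumps(adjusted, indent=2))

    # --- correlations ----------------------------------------------------
    stage("correlations")
    t4 = _table4(df)
    paths["table4"] = outdir / "table4.csv"
    t4.round(6).to_csv(paths["table4"], index=False)

    # --- logistic modelling ---------------------------------------------
    stage("univariate")
    fits = _fit_univariate(df)
    candidates = assoc.candidate_filter(fits, p_threshold=config.p_entry)
    if not config.offer_age:
        candidates = [c for c in candidates if c != "age"]

    stage("stepwise")
    if candidates:
        selected, mfits = assoc.stepwise_select(
            df["osteoporosis"],
            df[candidates],
            criterion=config.stepwise_criterion,
            directions=CANDIDATE_DIRECTIONS,
        )
    else:
        logger.warning("WARNING: no candidate passed the p<%s entry filter", config.p_entry)
        selected, mfits = [], {}
    rows = []
    for f in fits:
        m = mfits.get(f.label)
        rows.append(
            {
                "variable": f.label,
                "direction": f.direction,
                "uni_or": f.odds_ratio,
                "uni_ci_low": f.ci95[0],
                "uni_ci_high": f.ci95[1],
                "uni_p": f.p_value,
                "multi_or": m.odds_ratio if m else None,
                "multi_ci_low": m.ci95[0] if m else None,
                "multi_ci_high": m.ci95[1] if m else None,
                "multi_p": m.p_value if m else None,
            }
        )
    t5 = pd.DataFrame(rows)
    paths["table5"] = outdir / "table5.csv"
    t5.round(6).to_csv(paths["table5"], index=False)

    # --- ROC of the final screening model --------------------------------
    stage("roc")
    model_vars = selected if selected else ["bmi", "tst"]
    mv = assoc.multivariate_logit(df["osteoporosis"], df[model_vars])
    lp = sum(mv[v].coefficient * df[v] for v in model_vars)
    roc = assoc.roc_auc(lp.to_numpy(), df["osteoporosis"].to_numpy(), ci=config.ci_method)
    paths["roc"] = outdir / "roc.csv"
    pd.DataFrame(roc.curve, columns=["fpr", "tpr"]).round(6).to_csv(paths["roc"], index=False)
    paths["auc"] = outdir / "auc.json"
    paths["auc"].write_text(
        json.dumps(
            {
                "model": list(model_vars),
                "auc": round(roc.auc, 2),
                "auc_full": roc.auc,
                "ci95": [round(c, 2) for c in roc.ci95],
                "ci95_full": list(roc.ci95),
            },
            indent=2,
        )
    )

    # --- LR matrices and rules -------------------------------------------
    stage("lr-matrices")
    matrix = screening.lr_matrix(
        roster, config.bmi_grid, config.tst_grid, zero_cell=config.zero_cell
    )
    for which, name in (("lr_pos", "table6"), ("lr_neg", "table7")):
        paths[name] = outdir / f"{name}.csv"
        matrix.to_frame(which, round_to=1).to_csv(paths[name])
        paths[f"{name}_full"] = outdir / f"{name}_full.csv"
        matrix.to_frame(which).to_csv(paths[f"{name}_full"])

    stage("rules")
    rules = screening.extract_rules(
        matrix, config.pos_threshold, config.neg_threshold, prune=config.prune
    )
    paths["rules"] = outdir / "rules.json"
    paths["rules"].write_text(screening.rules_to_json(rules))

    # --- run metadata -----------------------------------------------------
    meta = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_input": exclusion.total_input,
        "n_included": exclusion.included_count,
        "exclusions": exclusion.counts,
        "selected": list(selected),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    paths["run"] = outdir / "run.json"
    paths["run"].write_text(json.dumps(meta, indent=2))

    return PipelineResult(
        outdir=outdir,
        paths=paths,
        roster=roster,
        selected=tuple(selected),
        auc=roc.auc,
        rules=tuple(rules),
    )
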