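"""Gaussian-copula synthetic cohorts with age-stratified margins.

The generator emulates the statistical structure the screening analysis
relies on: per-decade marginal means/SDs of the baseline and performance
tables, pooled Spearman correlations of every candidate with the three site
T-scores, and the prevalence gradient that the WHO classification induces.

Mechanism
---------
Within each decade stratum a latent multivariate normal vector is drawn with
a single shared correlation matrix and pushed through stratum-specific
marginal transforms (normal for most variables; censored normal on [0, 60]
for one-leg standing; a discretized normal on {1..8} for the stand-up score;
a rounded gamma for Locomo25; integer-uniform age within the decade).
Bilateral femoral-neck and total-hip T-scores are produced by adding small
independent site noise to the corresponding latent, so the five-site
minimum rule has bite.  Weight is derived from BMI and height.

Because the published correlations are POOLED over an age-stratified cohort
while the generator shifts margins per stratum, using them directly as
within-stratum correlations would overshoot.  The generator therefore
calibrates each printed pair's latent correlation so that the POOLED
Spearman of the mixture matches the target, computed semi-analytically with
Gauss-Hermite quadrature on mid-rank grades (exact in the limit of the
quadrature, including ties from censoring and discreteness).  Unprinted
pairs default to products of calibrated correlations through the total-hip
axis; T-score/T-score latent correlations are configuration constants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Mapping, Tuple

import numpy as np
import pandas as pd
import scipy.optimize as spo
import scipy.stats as sps
from statsmodels.stats.correlation_tools import corr_nearest

from .cohort import ParticipantRecord, Roster, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "VARIABLES",
    "T_VARIABLES",
    "SyntheticCohortConfig",
    "GeneratorReport",
    "pearson_from_spearman",
    "calibrate_latent_correlations",
    "generate_cohort",
    "validate_generator",
    "assign_exclusion_flags",
]

#: Latent-vector variable order.
VARIABLES = (
    "age",
    "height",
    "bmi",
    "t_l24",
    "t_neck",
    "t_hip",
    "grip",
    "knee_ext",
    "one_leg",
    "tst",
    "standup",
    "locomo25",
)
T_VARIABLES = ("t_l24", "t_neck", "t_hip")
STRATUM_LABELS = ("50-59", "60-69", "70-79", "80-89")

# Default per-stratum (mean, sd) margins, decades 50s/60s/70s/80s.
_DEFAULT_MARGINS: Dict[str, tuple] = {
    "height": ((158.1, 5.1), (153.0, 5.1), (150.3, 5.5), (145.4, 5.8)),
    "bmi": ((22.0, 3.9), (22.4, 2.8), (22.8, 3.1), (23.8, 3.1)),
    "t_l24": ((-0.2, 1.5), (-0.8, 1.5), (-0.9, 1.6), (-0.7, 1.8)),
    "t_neck": ((-0.9, 0.9), (-1.3, 0.9), (-1.6, 0.9), (-2.0, 0.7)),
    "t_hip": ((-0.6, 1.1), (-1.0, 0.9), (-1.1, 1.0), (-1.9, 0.8)),
    "grip": ((25.1, 4.7), (21.8, 3.7), (20.7, 4.2), (16.9, 3.9)),
    "knee_ext": ((1.37, 0.36), (1.22, 0.36), (0.94, 0.34), (0.73, 0.36)),
    "one_leg": ((47.6, 15.8), (44.2, 16.7), (24.6, 15.6), (9.1, 9.1)),
    "tst": ((1.54, 0.13), (1.45, 0.14), (1.36, 0.19), (1.05, 0.25)),
    "standup": ((4.4, 0.9), (4.4, 0.8), (3.5, 1.0), (3.0, 1.0)),
    "locomo25": ((5.0, 4.6), (4.4, 4.6), (9.9, 10.2), (20.4, 15.3)),
}

#: Derived-weight per-stratum means (informational target; weight follows BMI x height).
_WEIGHT_MEANS = (55.0, 52.4, 51.6, 50.4)

# Pooled Spearman targets of each candidate against the three site T-scores.
_DEFAULT_SPEARMAN: Dict[str, Tuple[float, float, float]] = {
    # (vs t_l24, vs t_neck, vs t_hip)
    "grip": (0.24, 0.38, 0.37),
    "knee_ext": (0.03, 0.25, 0.23),
    "one_leg": (0.02, 0.31, 0.25),
    "tst": (0.01, 0.39, 0.43),
    "standup": (-0.11, 0.12, 0.17),
    "locomo25": (0.10, -0.19, -0.22),
    "age": (-0.10, -0.40, -0.41),
    "bmi": (0.19, 0.11, 0.17),
}

# Latent correlations among the T-score sites (not published; femoral sites
# strongly correlated, lumbar weaker -- consistent with the published pattern
# of L2-4 being nearly uncorrelated with performance).
_DEFAULT_T_LATENT = {("t_l24", "t_neck"): 0.5, ("t_l24", "t_hip"): 0.5, ("t_neck", "t_hip"): 0.85}


def pearson_from_spearman(rho_s: float) -> float:
    """Gaussian-copula conversion of a Spearman rho to a latent Pearson r.

    r = 2 * sin(pi * rho_s / 6); odd, with |r| >= |rho_s|.
    """
    if not -1.0 <= rho_s <= 1.0:
        raise ValidationError(f"Spearman rho must be in [-1, 1], got {rho_s}")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


# ---------------------------------------------------------------------------
# Marginal families (each solves its parameters so the OBSERVED margin has
# the target mean/SD)
# ---------------------------------------------------------------------------

class _Margin:
    """Stratum margin: monotone transform of a standard normal plus CDFs."""

    mean: float
    sd: float

    def transform(self, z: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def cdf(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def cdf_left(self, x: np.ndarray) -> np.ndarray:
        """Left limit P(X < x); differs from cdf only at atoms."""
        return self.cdf(x)

    def mid_cdf(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * (self.cdf(x) + self.cdf_left(x))

    def kurtosis(self) -> float:
        """Kurtosis (non-excess) of the observed margin, via quadrature.

        Needed for the standard error of a sample SD, which is
        sd * sqrt((kappa - 1) / (4n)) and reduces to sd / sqrt(2n) only for
        normal margins.
        """
        z, w = np.polynomial.hermite_e.hermegauss(128)
        w = w / w.sum()
        x = np.asarray(self.transform(z), dtype=float)
        m1 = float(w @ x)
        m2 = float(w @ (x - m1) ** 2)
        m4 = float(w @ (x - m1) ** 4)
        return m4 / m2**2


class _NormalMargin(_Margin):
    def __init__(self, mean: float, sd: float):
        self.mean, self.sd = float(mean), float(sd)

    def transform(self, z):
        return self.mean + self.sd * np.asarray(z)

    def cdf(self, x):
        return sps.norm.cdf(x, loc=self.mean, scale=self.sd)


class _CensoredNormalMargin(_Margin):
    """clip(N(mu, sigma), lo, hi) with (mu, sigma) solved for target moments."""

    def __init__(self, mean: float, sd: float, lo: float, hi: float):
        self.mean, self.sd = float(mean), float(sd)
        self.lo, self.hi = float(lo), float(hi)
        sol = spo.root(self._moment_gap, x0=[self.mean, self.sd], method="hybr")
        if not sol.success:  # pragma: no cover - defensive
            raise ValidationError(f"censored-normal moment matching failed: {sol.message}")
        self.mu, self.sigma = float(sol.x[0]), float(abs(sol.x[1]))

    def _moments(self, mu: float, sigma: float) -> Tuple[float, float]:
        sigma = abs(sigma)
        a = (self.lo - mu) / sigma
        b = (self.hi - mu) / sigma
        Fa, Fb = sps.norm.cdf(a), sps.norm.cdf(b)
        fa, fb = sps.norm.pdf(a), sps.norm.pdf(b)
        mid = Fb - Fa
        e1 = self.lo * Fa + self.hi * (1 - Fb) + mu * mid + sigma * (fa - fb)
        e2 = (
            self.lo**2 * Fa
            + self.hi**2 * (1 - Fb)
            + (mu**2 + sigma**2) * mid
            + 2 * mu * sigma * (fa - fb)
            + sigma**2 * (a * fa - b * fb)
        )
        return e1, e2

    def _moment_gap(self, params):
        e1, e2 = self._moments(params[0], params[1])
        return [e1 - self.mean, (e2 - e1**2) - self.sd**2]

    def transform(self, z):
        return np.clip(self.mu + self.sigma * np.asarray(z), self.lo, self.hi)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        inner = sps.norm.cdf(x, loc=self.mu, scale=self.sigma)
        return np.where(x < self.lo, 0.0, np.where(x >= self.hi, 1.0, inner))

    def cdf_left(self, x):
        x = np.asarray(x, dtype=float)
        inner = sps.norm.cdf(x, loc=self.mu, scale=self.sigma)
        return np.where(x <= self.lo, 0.0, np.where(x > self.hi, 1.0, np.minimum(inner, sps.norm.cdf(self.hi, loc=self.mu, scale=self.sigma))))


class _DiscretizedNormalMargin(_Margin):
    """clip(round(N(mu, sigma)), lo, hi) on integers, moments solved exactly."""

    def __init__(self, mean: float, sd: float, lo: int, hi: int):
        self.mean, self.sd = float(mean), float(sd)
        self.lo, self.hi = int(lo), int(hi)
        sol = spo.root(self._moment_gap, x0=[self.mean, max(self.sd, 0.3)], method="hybr")
        if not sol.success:  # pragma: no cover - defensive
            raise ValidationError(f"discretized-normal moment matching failed: {sol.message}")
        self.mu, self.sigma = float(sol.x[0]), float(abs(sol.x[1]))

    def _pmf(self, mu: float, sigma: float) -> np.ndarray:
        sigma = abs(sigma)
        ks = np.arange(self.lo, self.hi + 1)
        upper = sps.norm.cdf(ks + 0.5, loc=mu, scale=sigma)
        lower = sps.norm.cdf(ks - 0.5, loc=mu, scale=sigma)
        p = upper - lower
        p[0] = upper[0]  # lower tail absorbed into lo
        p[-1] = 1.0 - lower[-1]  # upper tail absorbed into hi
        return p

    def _moment_gap(self, params):
        p = self._pmf(params[0], params[1])
        ks = np.arange(self.lo, self.hi + 1)
        e1 = float(p @ ks)
        var = float(p @ (ks - e1) ** 2)
        return [e1 - self.mean, var - self.sd**2]

    def transform(self, z):
        return np.clip(np.rint(self.mu + self.sigma * np.asarray(z)), self.lo, self.hi).astype(int)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        k = np.floor(x)
        inner = sps.norm.cdf(k + 0.5, loc=self.mu, scale=self.sigma)
        return np.where(x < self.lo, 0.0, np.where(x >= self.hi, 1.0, inner))

    def cdf_left(self, x):
        x = np.asarray(x, dtype=float)
        k = np.ceil(x) - 1.0
        inner = sps.norm.cdf(k + 0.5, loc=self.mu, scale=self.sigma)
        return np.where(x <= self.lo, 0.0, np.where(x > self.hi, 1.0, inner))


class _RoundedGammaMargin(_Margin):
    """round(Gamma) clipped to [0, cap]; shape/scale moment-matched.

    Rounding perturbs the moments by far less than a sampling SE at the
    problem sizes used, so shape/scale are matched on the continuous gamma.
    """

    def __init__(self, mean: float, sd: float, cap: float = 100.0):
        self.mean, self.sd = float(mean), float(sd)
        self.cap = float(cap)
        self.shape = (self.mean / self.sd) ** 2
        self.scale = self.sd**2 / self.mean

    def transform(self, z):
        u = sps.norm.cdf(np.asarray(z))
        x = sps.gamma.ppf(u, a=self.shape, scale=self.scale)
        return np.clip(np.rint(x), 0.0, self.cap)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        out = sps.gamma.cdf(np.floor(x) + 0.5, a=self.shape, scale=self.scale)
        return np.where(x < 0, 0.0, np.where(x >= self.cap, 1.0, out))

    def cdf_left(self, x):
        x = np.asarray(x, dtype=float)
        out = sps.gamma.cdf(np.ceil(x) - 0.5, a=self.shape, scale=self.scale)
        return np.where(x <= 0, 0.0, np.where(x > self.cap, 1.0, out))


class _AgeMargin(_Margin):
    """Integer age uniform on one decade {lo .. lo+9}."""

    def __init__(self, lo: int):
        self.lo = int(lo)
        self.mean = self.lo + 4.5
        self.sd = math.sqrt((100.0 - 1.0) / 12.0)

    def transform(self, z):
        u = sps.norm.cdf(np.asarray(z))
        return (self.lo + np.minimum(np.floor(10.0 * u), 9.0)).astype(int)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.clip((np.floor(x) - self.lo + 1.0) / 10.0, 0.0, 1.0)

    def cdf_left(self, x):
        x = np.asarray(x, dtype=float)
        return np.clip((np.ceil(x) - self.lo) / 10.0, 0.0, 1.0)


def _build_margins(config: "SyntheticCohortConfig") -> Dict[str, tuple]:
    margins: Dict[str, tuple] = {}
    for var in VARIABLES:
        per_stratum = []
        for s in range(4):
            if var == "age":
                per_stratum.append(_AgeMargin(lo=50 + 10 * s))
                continue
            mean, sd = config.margin(var, s)
            if var == "one_leg":
                per_stratum.append(_CensoredNormalMargin(mean, sd, lo=0.0, hi=60.0))
            elif var == "standup":
                per_stratum.append(_DiscretizedNormalMargin(mean, sd, lo=1, hi=8))
            elif var == "locomo25":
                per_stratum.append(_RoundedGammaMargin(mean, sd, cap=100.0))
            else:
                per_stratum.append(_NormalMargin(mean, sd))
        margins[var] = tuple(per_stratum)
    return margins


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _freeze(mapping: Mapping) -> tuple:
    return tuple(sorted((k, v) for k, v in mapping.items()))


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions for the generator (defaults = the published tables).

    ``strata_sizes`` are the decade sample sizes (default 42/58/39/29);
    ``margins`` maps variable -> 4 x (mean, sd); ``spearman_targets`` maps
    candidate -> pooled Spearman vs (L2-4, femoral neck, total hip);
    ``t_latent`` holds the latent T-score/T-score correlations;
    ``site_noise_sd`` is the bilateral site-noise SD in T-score units.
    """

    strata_sizes: tuple = (42, 58, 39, 29)
    margins: tuple = field(default_factory=lambda: _freeze(_DEFAULT_MARGINS))
    spearman_targets: tuple = field(default_factory=lambda: _freeze(_DEFAULT_SPEARMAN))
    t_latent: tuple = field(default_factory=lambda: _freeze(_DEFAULT_T_LATENT))
    site_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if len(self.strata_sizes) != 4 or any(n < 0 for n in self.strata_sizes):
            raise ValidationError("strata_sizes must be four non-negative counts")
        for var, per_stratum in self.margins:
            for mean, sd in per_stratum:
                if not sd > 0:
                    raise ValidationError(f"{var}: SDs must be positive, got {sd}")
        for pair, rho in list(self.spearman_targets) + list(self.t_latent):
            for r in np.atleast_1d(np.asarray(rho, dtype=float)):
                if not -1.0 <= r <= 1.0:
                    raise ValidationError(f"correlation target out of [-1, 1] for {pair}: {r}")

    def margin(self, var: str, stratum: int) -> Tuple[float, float]:
        return dict(self.margins)[var][stratum]

    def spearman_target(self, var: str, tvar: str) -> float:
        return dict(self.spearman_targets)[var][T_VARIABLES.index(tvar)]

    @property
    def weights(self) -> np.ndarray:
        n = np.asarray(self.strata_sizes, dtype=float)
        return n / n.sum()

    def scaled(self, total_n: int) -> "SyntheticCohortConfig":
        """Same conditions at a different cohort size (proportional strata)."""
        w = self.weights
        sizes = np.floor(w * total_n).astype(int)
        remainder = total_n - sizes.sum()
        order = np.argsort(-(w * total_n - sizes))
        for i in range(int(remainder)):
            sizes[order[i]] += 1
        return replace(self, strata_sizes=tuple(int(s) for s in sizes))


# ---------------------------------------------------------------------------
# Calibration of the latent correlation matrix
# ---------------------------------------------------------------------------

_GH_NODES = 64


def _gauss_hermite() -> Tuple[np.ndarray, np.ndarray]:
    z, w = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    return z, w / w.sum()


def _pooled_grade_fn(margins: Dict[str, tuple], var: str, weights: np.ndarray) -> Callable:
    """g_{var,s}(z): mid-rank grade of stratum-s values in the pooled margin."""
    per_stratum = margins[var]

    def grade(s: int, z: np.ndarray) -> np.ndarray:
        x = per_stratum[s].transform(z)
        g = np.zeros(np.shape(x), dtype=float)
        for t, wt in enumerate(weights):
            g += wt * per_stratum[t].mid_cdf(x)
        return g

    return grade


def _pair_moments(grade, weights, z, w):
    e = e2 = 0.0
    gs = []
    for s, ws in enumerate(weights):
        g = grade(s, z)
        gs.append(g)
        e += ws * float(w @ g)
        e2 += ws * float(w @ g**2)
    return e, e2, gs


def _pooled_spearman_model(r, gx, gy, weights, z, w, mom_x, mom_y, gx_nodes):
    ex, ex2, _ = mom_x
    ey, ey2, _ = mom_y
    rr = math.sqrt(max(0.0, 1.0 - r * r))
    exy = 0.0
    for s, ws in enumerate(weights):
        Z2 = r * z[:, None] + rr * z[None, :]
        Gy = gy(s, Z2)
        Gx = gx_nodes[s]
        exy += ws * float((w[:, None] * w[None, :] * Gx[:, None] * Gy).sum())
    num = exy - ex * ey
    den = math.sqrt((ex2 - ex**2) * (ey2 - ey**2))
    return num / den


def _calibrate(config: SyntheticCohortConfig) -> Tuple[pd.DataFrame, list]:
    margins = _build_margins(config)
    weights = config.weights
    z, w = _gauss_hermite()
    idx = {v: i for i, v in enumerate(VARIABLES)}
    R = np.eye(len(VARIABLES))
    repair_log: list = []

    grades = {v: _pooled_grade_fn(margins, v, weights) for v in VARIABLES}
    moments = {v: _pair_moments(grades[v], weights, z, w) for v in VARIABLES}

    # printed pooled targets: candidate variables vs the three T-scores
    for var, _targets in config.spearman_targets:
        for k, tvar in enumerate(T_VARIABLES):
            target = config.spearman_target(var, tvar)

            def gap(r, var=var, tvar=tvar, target=target):
                return (
                    _pooled_spearman_model(
                        r, grades[var], grades[tvar], weights, z, w,
                        moments[var], moments[tvar], moments[var][2],
                    )
                    - target
                )

            lo, hi = -0.995, 0.995
            glo, ghi = gap(lo), gap(hi)
            if glo > 0 or ghi < 0:  # target unreachable within the mixture
                r_hat = lo if glo > 0 else hi
                repair_log.append(
                    f"target rho({var},{tvar})={target} outside attainable range; clamped"
                )
            else:
                r_hat = spo.brentq(gap, lo, hi, xtol=1e-6)
            R[idx[var], idx[tvar]] = R[idx[tvar], idx[var]] = r_hat

    # latent T-score block (configuration constants)
    for (a, b), r in config.t_latent:
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r

    # unprinted pairs: products through the total-hip axis
    hip = idx["t_hip"]
    cand = [v for v in VARIABLES if v not in T_VARIABLES]
    for i, a in enumerate(cand):
        for b in cand[i + 1 :]:
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = R[idx[a], hip] * R[idx[b], hip]

    eigmin = float(np.linalg.eigvalsh(R).min())
    if eigmin < 1e-10:
        repaired = corr_nearest(R, threshold=1e-8, n_fact=200)
        shift = float(np.abs(repaired - R).max())
        repair_log.append(
            f"latent correlation matrix not PSD (min eig {eigmin:.2e}); "
            f"nearest-PSD projection applied (max |shift| {shift:.2e})"
        )
        logger.warning("WARNING: %s", repair_log[-1])
        R = repaired
    Rdf = pd.DataFrame(R, index=list(VARIABLES), columns=list(VARIABLES))
    return Rdf, repair_log


_CALIBRATION_CACHE: dict = {}


def _calibration_key(config: SyntheticCohortConfig) -> tuple:
    w = tuple(np.round(config.weights, 9))
    return (w, config.margins, config.spearman_targets, config.t_latent, config.site_noise_sd)


def calibrate_latent_correlations(config: SyntheticCohortConfig) -> Tuple[pd.DataFrame, list]:
    """Latent correlation matrix whose pooled Spearman matches the targets.

    Cached per configuration (the calibration depends on stratum weights and
    margins, not on absolute cohort size).
    """
    key = _calibration_key(config)
    if key not in _CALIBRATION_CACHE:
        _CALIBRATION_CACHE[key] = _calibrate(config)
    return _CALIBRATION_CACHE[key]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_cohort(config: SyntheticCohortConfig, seed: int) -> Roster:
    """Draw a reproducible synthetic cohort under the configured conditions."""
    rng = np.random.default_rng(seed)
    Rdf, _repair = calibrate_latent_correlations(config)
    R = Rdf.to_numpy()
    # tiny jitter guards the Cholesky against repaired matrices at eig ~ 0
    L = np.linalg.cholesky(R + 1e-10 * np.eye(len(VARIABLES)))
    margins = _build_margins(config)
    idx = {v: i for i, v in enumerate(VARIABLES)}

    records = []
    for s, n_s in enumerate(config.strata_sizes):
        if n_s == 0:
            continue
        Z = rng.standard_normal((n_s, len(VARIABLES))) @ L.T
        cols = {v: margins[v][s].transform(Z[:, idx[v]]) for v in VARIABLES}
        noise = rng.normal(0.0, config.site_noise_sd, size=(n_s, 4))
        height = np.asarray(cols["height"], dtype=float)
        bmi = np.clip(np.asarray(cols["bmi"], dtype=float), 10.0, None)
        weight = bmi * (height / 100.0) ** 2
        grip = np.maximum(np.asarray(cols["grip"], dtype=float), 0.1)
        knee = np.maximum(np.asarray(cols["knee_ext"], dtype=float), 0.01)
        tst = np.maximum(np.asarray(cols["tst"], dtype=float), 0.01)
        for i in range(n_s):
            records.append(
                ParticipantRecord(
                    id=f"S{s + 1}-{i + 1:05d}",
                    age=int(cols["age"][i]),
                    height=float(height[i]),
                    weight=float(weight[i]),
                    tscore_l24=float(cols["t_l24"][i]),
                    tscore_neck_left=float(cols["t_neck"][i] + noise[i, 0]),
                    tscore_neck_right=float(cols["t_neck"][i] + noise[i, 1]),
                    tscore_hip_left=float(cols["t_hip"][i] + noise[i, 2]),
                    tscore_hip_right=float(cols["t_hip"][i] + noise[i, 3]),
                    grip=float(grip[i]),
                    knee_ext=float(knee[i]),
                    one_leg=float(cols["one_leg"][i]),
                    tst=float(tst[i]),
                    standup=int(cols["standup"][i]),
                    locomo25=float(cols["locomo25"][i]),
                )
            )
    return Roster(records=tuple(records), provenance=f"synthetic(seed={seed})")


def assign_exclusion_flags(roster: Roster, counts: Mapping[str, int], seed: int) -> Roster:
    """Flag disjoint random subsets of records with the given exclusion reasons.

    Useful for exercising the eligibility cascade on synthetic rosters.
    """
    total = sum(counts.values())
    if total > len(roster):
        raise ValidationError(f"cannot flag {total} of {len(roster)} records")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(roster), size=total, replace=False)
    flag_of: Dict[int, str] = {}
    pos = 0
    for reason, k in counts.items():
        for j in range(k):
            flag_of[int(chosen[pos + j])] = reason
        pos += k
    new_records = []
    for i, r in enumerate(roster):
        if i in flag_of:
            new_records.append(replace(r, flags=frozenset({flag_of[i]})))
        else:
            new_records.append(r)
    return Roster(records=tuple(new_records), provenance=roster.provenance)


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorReport:
    """Achieved-vs-target margins and correlations with pass/fail columns."""

    margin_checks: pd.DataFrame
    correlation_checks: pd.DataFrame
    repair_log: tuple

    @property
    def passed(self) -> bool:
        return bool(self.margin_checks["passed"].all() and self.correlation_checks["passed"].all())

    def failures(self) -> pd.DataFrame:
        m = self.margin_checks[~self.margin_checks["passed"]]
        c = self.correlation_checks[~self.correlation_checks["passed"]]
        return pd.concat([m, c], ignore_index=True)


_FRAME_COLUMN = {
    "age": "age",
    "height": "height",
    "bmi": "bmi",
    "t_l24": "tscore_l24",
    "t_neck": "tscore_neck",
    "t_hip": "tscore_hip",
    "grip": "grip",
    "knee_ext": "knee_ext",
    "one_leg": "one_leg",
    "tst": "tst",
    "standup": "standup",
    "locomo25": "locomo25",
}


def validate_generator(
    roster: Roster, config: SyntheticCohortConfig, *, spearman_tol: float = 0.03, se_mult: float = 3.0
) -> GeneratorReport:
    """Compare achieved margins and pooled correlations against the targets.

    Margin means/SDs are checked per stratum at +/- ``se_mult`` standard
    errors (SE_mean = sd/sqrt(n), SE_sd = sd/sqrt(2n)); pooled Spearman
    correlations against the three T-scores at +/- ``spearman_tol``.  Derived
    weight is checked on its mean only (its SD follows from the BMI-height
    dependence and is not a controlled margin).
    """
    if len(roster) == 0:
        raise ValidationError("cannot validate an empty roster")
    df = roster.to_frame()
    df["stratum"] = pd.cut(
        df["age"], bins=[49, 59, 69, 79, 89], labels=list(STRATUM_LABELS)
    )

    margins = _build_margins(config)
    margin_rows = []
    for s, label in enumerate(STRATUM_LABELS):
        sub = df[df["stratum"] == label]
        n = len(sub)
        if n == 0:
            continue
        for var in VARIABLES:
            if var == "age":
                continue
            mean_t, sd_t = config.margin(var, s)
            kappa = margins[var][s].kurtosis()
            col = sub[_FRAME_COLUMN[var]]
            for stat, target, achieved, se in (
                ("mean", mean_t, float(col.mean()), sd_t / math.sqrt(n)),
                ("sd", sd_t, float(col.std(ddof=1)), sd_t * math.sqrt(max(kappa - 1.0, 0.5) / (4 * n))),
            ):
                margin_rows.append(
                    {
                        "stratum": label,
                        "variable": var,
                        "stat": stat,
                        "target": target,
                        "achieved": achieved,
                        "tolerance": se_mult * se,
                        "passed": abs(achieved - target) <= se_mult * se,
                    }
                )
        # derived weight: mean only
        wt = _WEIGHT_MEANS[s]
        achieved = float(sub["weight"].mean())
        se = 8.0 / math.sqrt(n)  # pooled-scale weight SD ~ 8 kg
        margin_rows.append(
            {
                "stratum": label,
                "variable": "weight",
                "stat": "mean",
                "target": wt,
                "achieved": achieved,
                "tolerance": se_mult * se,
                "passed": abs(achieved - wt) <= se_mult * se,
            }
        )

    corr_rows = []
    for var, _targets in config.spearman_targets:
        for tvar in T_VARIABLES:
            target = config.spearman_target(var, tvar)
            rho = float(
                sps.spearmanr(df[_FRAME_COLUMN[var]], df[_FRAME_COLUMN[tvar]]).statistic
            )
            corr_rows.append(
                {
                    "variable": var,
                    "against": tvar,
                    "target": target,
                    "achieved": rho,
                    "tolerance": spearman_tol,
                    "passed": abs(rho - target) <= spearman_tol,
                }
            )

    _, repair = calibrate_latent_correlations(config)
    return GeneratorReport(
        margin_checks=pd.DataFrame(margin_rows),
        correlation_checks=pd.DataFrame(corr_rows),
        repair_log=tuple(repair),
    )
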