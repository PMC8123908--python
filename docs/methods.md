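# Methods

## Scope and model

The package derives rule-in screening rules for osteoporosis from two cheap
measurements — the two-step test (TST, maximum two-stride distance divided
by height) and BMI — against a DXA-based reference standard.  Disease is
defined per participant as a representative T-score ≤ −2.5, where the
representative value is the **minimum** over five sites (L2–4 spine,
bilateral femoral neck, bilateral total hip).  WHO band boundaries are
assigned inclusively outward: T = −1 is healthy, T = −2.5 is osteoporosis,
osteopenia is the open interval between them.

A candidate screening test is the conjunction "TST ≤ t AND BMI ≤ b".  For
each (b, t) on a grid the 2×2 table against disease gives sensitivity,
specificity and the likelihood ratios LR+ = sens/(1−spec) and
LR− = (1−sens)/spec.  Likelihood ratios are prevalence-invariant, so rules
derived from them transfer across populations with different base rates
(under the usual assumption of transportable sens/spec).  Conventional
evidence thresholds are used: LR+ ≥ 5.0 supports ruling in, LR− ≤ 0.2
supports ruling out.

## Rule extraction

Within one TST column of the LR+ matrix, the rule (t, b) qualifies only if
**every** cell with BMI cutoff ≤ b reaches the threshold (the prefix
convention).  This makes rule sets well defined on non-monotone matrices:
a rule's `guaranteed_lr` is the minimum LR+ over its qualifying prefix, a
worst-case bound on the evidence a positive result provides anywhere in
the rule's region.  If an entire column qualifies, the BMI bound becomes
"any".

Redundancy pruning is deliberately conservative (`prune="lr_pareto"`,
the default): a rule is dropped only when another rule both contains its
region **and** guarantees an at-least-as-strong worst-case LR+.  A narrower
rule with a strictly better guarantee is kept, because it offers higher
confirmatory value on its sub-region.  Pure region-containment pruning
(`prune="containment"`, keeping only maximal regions) and no pruning are
available as alternatives; on published matrices the containment variant
can discard a narrower rule that the original investigators chose to
report, which is why it is not the default.  Positivity uses ≤ on both
axes; strictness at the smallest grid column is a matter of convention
since values below the grid's left edge are covered by any rule at that
column.

Zero cells default to exact arithmetic (LR+ = +∞ when fp = 0 with sens > 0;
LR− undefined only when tn = 0 and sens = 1); a Haldane +0.5 continuity
correction is available via `zero_cell="haldane"`.

## Association pipeline

* Spearman correlations use average ranks for ties and the two-sided
  t-approximation for p-values (scipy).
* Univariate logistic odds ratios carry a per-unit direction so that
  OR > 1 always reads as "risk rises as the measurement worsens"
  (direction −1 for grip, knee extension, one-leg standing, TST and
  stand-up score and for BMI; +1 for Locomo25 and age).  Perfect
  separation or non-convergence raises instead of returning silent output.
* Candidates enter the multivariable stage when their univariate p < 0.2
  (strict).  Stepwise selection is bidirectional, AIC-minimizing, starting
  from the full candidate model; a classic Wald-p enter/remove variant is
  available (`criterion="p"`).
* By default **age is not offered to the stepwise selection** (config
  `offer_age`).  Age is the design's stratification variable; in surrogate
  cohorts whose only age information is the stratum shift, offering age
  lets it absorb the between-stratum signal that in real data flows
  through the performance measures.  Age always appears in the univariate
  table.
* The screening model's score is the linear predictor of the final
  logistic model; AUC is the Mann–Whitney concordance probability (ties
  count ½) and its 95% CI uses the DeLong structural-component variance
  (validated against an independent reference implementation).

## Synthetic cohort generator

The generator emulates the study conditions: four decade strata (50s–80s)
of 42/58/39/29 women (scalable proportionally), per-stratum marginal
means/SDs for height, BMI, three site T-scores and six performance
measures, and the published pooled Spearman correlations of each candidate
against the three site T-scores.

Mechanism: one latent multivariate normal per stratum (shared correlation
matrix), pushed through stratum-specific marginal transforms —

* normal margins for height, BMI, T-scores, grip, knee extension, TST;
* a doubly censored normal on [0, 60] s for one-leg standing, with
  (μ, σ) solved so the **observed** censored margin matches the target
  mean/SD exactly (censoring is heavy: in the oldest stratum ~16% of the
  latent mass lies below 0);
* a rounded, clipped discretized normal on {1..8} for the stand-up score,
  with parameters solved against the exact discrete moments;
* a rounded gamma (shape/scale moment-matched) for Locomo25, capturing its
  non-negative right-skewed shape;
* integer age uniform within the decade.

Bilateral neck/hip T-scores add independent N(0, 0.1²) site noise to the
corresponding latent so the minimum-site rule has bite without distorting
the site means.  Weight is derived as BMI·(height/100)²; its per-stratum
means follow the targets, but its SD is a consequence of the (default
zero) within-stratum BMI–height correlation and is reported
informationally, not as a controlled margin.

**Pooled-Spearman calibration.**  The published correlations are pooled
over the age-stratified cohort, while the generator shifts margins per
stratum; between-stratum mean shifts therefore carry part of every pooled
correlation.  Using the pooled values directly as latent correlations
would overshoot (TST vs total hip would land near 0.54 instead of 0.43).
For each targeted pair the generator instead solves for the latent
correlation r such that the pooled Spearman of the mixture equals the
target.  The pooled Spearman is computed semi-analytically: mid-rank
grades g(z) (stratum value mapped through the pooled mid-CDF) evaluated on
a 64-node Gauss–Hermite grid, with E[g_x g_y] under correlation r obtained
by the Cholesky substitution z₂ = r·z₁ + √(1−r²)·z, and the root found by
Brent's method.  Mid-CDFs make the computation correct in the presence of
ties (censoring atoms, discrete scores, integer ages).  Targets that fall
outside the attainable range of the mixture are clamped with a logged
warning.  The standard Gaussian-copula conversion r = 2·sin(πρ/6) is
exposed as `pearson_from_spearman` and serves as the solver's conceptual
baseline.

Unprinted correlations: T-score/T-score latent correlations default to
0.5 (L2–4 vs either femoral site) and 0.85 (neck vs hip) — femoral sites
strongly coupled, lumbar weaker, consistent with the published pattern of
L2–4 being nearly uncorrelated with performance while femoral sites
correlate moderately.  All other pairs (performance–performance,
performance–age, anything–height) default to products of calibrated
correlations through the total-hip axis, i.e. a one-factor structure with
total-hip BMD as the shared axis; height is left uncorrelated within
stratum.  The assembled matrix is checked for positive semi-definiteness
and repaired by nearest-correlation projection if needed (none needed at
the defaults), with the repair logged in the generator report.

**What the generator does and does not emulate.**  It reproduces
second-order structure only: margins and pairwise pooled rank
correlations.  Real cohorts have joint features beyond this (nonlinear
dependence, tail clustering of very low TST with very low BMD in the
oldest women) that the published analysis plausibly exploited; the
surrogate therefore yields a weaker screening signal than the original
cohort.  Concretely, at n = 10,000 no grid cell reaches LR+ ≥ 5.0 in the
surrogate, and the BMI+TST model AUC averages ≈ 0.66 at n = 500 versus
the 0.73 reported on the real data.  Passing the pipeline-recovery tests
shows the machinery is correct and the synthetic conditions are faithful
to the published tables — not that the surrogate replicates the original
cohort's full joint distribution.

## Numerical choices and problem sizes

* Eligibility cascade: first-match attribution in the fixed order drugs →
  hormones → premenopausal → incomplete; idempotent by construction.
* CSV I/O: floats written with 17 significant digits and parsed with the
  round-trip parser, so write→read is lossless; missing cells permitted
  only on records flagged incomplete.
* Display rounding matches reporting practice (1 decimal for LR matrices,
  2 for ORs/AUC); full-precision companion files are always written.
* Default grids: BMI {21.0, 21.6, 22.2, 22.4, 23.0, 23.4, 23.8, 24.0},
  TST 1.24–1.38 in steps of 0.02.
* Moment-matching root solves use scipy's hybrid Powell method from the
  target moments as the starting point; calibration roots use Brent on
  (−0.995, 0.995) with xtol 1e-6, cached per configuration.
* Test problem sizes: generator fidelity is checked on one n = 10,000
  cohort (margin tolerance ±3 standard errors, with the SD tolerance using
  the kurtosis-correct SE of a sample SD; pooled Spearman ±0.03); the
  recovery experiment uses 50 cohorts of n = 500.  These sizes put Monte
  Carlo noise well inside the stated tolerances while keeping a full test
  run around half a minute.

## Known limitations

* FOSTA is included only as a comparator; its formula
  (truncate(0.2·(weight − age)), high risk < −4) is external to the
  screening derivation here.  FRAX is out of scope.
* Age standardization requires explicit reference weights; no national
  standard population is bundled, so published age-adjusted rates are
  reproducible only given the external standard actually used.
* The generator does not model participation bias, regional effects, or
  any joint structure beyond pairwise rank correlations, and its
  performance–performance dependence is an assumption (one-factor through
  total-hip BMD), not an estimate.
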