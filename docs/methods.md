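# Methods

## Model and scope

The package analyzes a non-adaptive (1:1:1) three-arm trial with a binary
outcome, summarized as a 3×2 table of counts `a_ij` (rows: shared
referent-control T0, treatments T1, T2; columns: unfavorable, favorable).
The per-arm unfavorable counts are treated as independent binomial variables
given the arm sizes.  Both relative risks are oriented
referent-over-treatment,

    RR1 = p0/p2,  RR2 = p0/p1,  pk = a_k1/a_k+,

so RR > 1 means the treatment reduces the unfavorable event, and
RLD = (RR1/RR2 − 1)×100 is positive when the new treatment (T2) outperforms
the standard one (T1).  Row order is semantic: the first row is always the
referent; file readers never reorder.

The target of inference is the interaction — whether the two treatment
effects differ — tested on the log-difference scale with the statistic

    zeta = (log RR1 − log RR2) / sqrt(Var1 + Var2 − 2 Cov),

whose null expectation of the numerator is zero (equal RRs).  Covariate
adjustment, GLM fitting, confidence intervals for the RR ratio, and designs
with more than three arms are out of scope.

## Delta-method moments

First-order Taylor expansion of `log RRk` around the binomial means gives

    Var(log RRk) = 1/a11 − 1/a1+ + 1/ak1 − 1/ak+,
    Cov(log RR1, log RR2) = 1/a11 − 1/a1+,

the covariance being exactly the referent-arm component of each variance —
the only shared term, since the two treatment arms are independent.  The
implementation computes these directly from the integer counts; the
closed-form p-value is `2(1 − Φ(|zeta|))`.  The absolute value matters:
without it the two-sided formula is valid only for positive zeta, and
exchanging the treatment rows (which negates zeta) would change the
p-value.

Zero event counts are an error (`DegenerateTableError`), not an occasion
for a continuity correction: a silent +0.5 would change every reported
value, and the method's reference results are defined on raw counts.  The
odds-ratio route requires all six cells positive and uses the Woolf
variances `1/a11 + 1/a12 + 1/ak1 + 1/ak2` with covariance `1/a11 + 1/a12`.

All internal computation is in full double precision; rounding to
significant digits (default 5) happens only in display blocks and reports.

## Simulated exact statistics

Conditioning on the total sample size n, the observed table induces a
single multinomial over the six cells with probabilities `a_ij/n` — one
multinomial, not three per-arm binomials, so row totals vary across
replicates.  For each replicate the two log RRs are recomputed; the run
reports their empirical variances and covariance (sample moments, ddof=1)
and `zeta_sim`, the observed log-difference divided by the simulated
standard deviation of the log-difference.

The distribution of the statistic is taken to be the per-replicate
log-difference standardized by the empirical mean and standard deviation of
that quantity across replicates.  This constant-scaling choice makes the
standardized sample approximately standard normal when the delta method is
adequate, and it is the definition under which the worked example's
reference shape values (right skew ≈ 0.187, excess kurtosis ≈ 0.193) and
exact p-value reproduce.  Studentizing each replicate by its own
delta-method standard error instead yields a *left*-skewed distribution
(the SE shrinks in the same draws that inflate the numerator) and roughly
halves the tail p; it is deliberately not used.  Centering at the empirical
mean rather than at the generating table's log-difference absorbs the small
finite-sample bias of the log-RR difference under resampling (≈ +0.0036 at
the worked example's scale).

The exact p-value is the right-tail area: the plain proportion of
standardized statistics at or above the threshold (so it can be exactly 0
at extreme inputs).  The default threshold is `zeta_sim`; a
`delta_method` option thresholds at the closed-form zeta instead, for users
who want the normal-theory statistic referred to the simulated
distribution.  Skewness and excess kurtosis use the bias-corrected sample
estimators (the common statistics-software default); at 10⁶–10⁷ replicates
the correction is immaterial.

Replicates where any arm's event count is zero leave a log RR undefined;
they are discarded and counted, with `n_used` reported and a warning when
more than half the draws are lost.  At the worked example's scale the
discarded fraction is ≈ 0 (the smallest event-cell expectation is 36); at
n = 30 it is ≈ 0.14%.

Draws are generated in fixed 10⁶-replicate batches (numpy PCG64, generator
name recorded in serialized results so seeds stay portable); only one
scalar per replicate is held across batches, so 10⁷ replicates need ~80 MB.
Retention of the standardized sample for plotting is opt-in
(`keep_sample`) and capped.

## Enumeration oracle

For n ≤ 40 the full support — every composition of n into six cells,
C(n+5,5) outcomes — is enumerated, each outcome weighted by its exact
multinomial probability (scipy's multinomial pmf).  The same moments as the
simulation are then exact weighted sums over the non-degenerate outcomes,
with the excluded probability mass reported.  This is the independent
check: on the worked example scaled down by six (n = 30, 324,632 outcomes)
the Monte-Carlo moments must sit within Monte-Carlo error of the enumerated
ones, which the test suite verifies with a 99.9% Student-t interval over
six independent simulation runs.

## Synthetic-data generator

`generate_table` draws per-arm unfavorable counts as Binomial(n_i, pi_i) —
the sampling model the closed-form moments assume.  Defaults in the
examples and tests mirror the worked example's conditions: 60 patients per
arm and true risks (0.9, 0.8, 0.6); null configurations use
(0.5, 0.5, 0.5).  The generator emulates only the randomized, concurrent
(1:1:1) design with fixed arm sizes: no covariates, no dropout or
censoring, no non-concurrent/pooled controls, no misclassification.
Passing tests therefore demonstrate correctness of the arithmetic and
calibration under the idealized design, not robustness to those real-data
features.

## Numerical and interface choices

- Natural logarithms throughout.
- Strict integer counts at the data-model level; fractional cells are
  rejected.
- Display uses significant-figure rounding (default 5), never fixed
  decimals; JSON reports carry full precision plus the rounded display
  block.
- CSV/TSV schema `arm,unfavorable,favorable`, three data rows, referent
  first; JSON mirrors the in-memory fields and round-trips exactly.
- The default simulation seed (180) is fixed and documented so shipped
  example output is reproducible byte for byte.
- Test problem sizes: the closed-form oracle check runs 1,000 random tables
  against an exact-rational/40-digit symbolic re-evaluation; calibration
  uses 10,000 simulated null trials; the exact-simulation reproduction test
  uses 10⁶ replicates with a-priori 4-standard-error Monte-Carlo bands
  (the full-scale reference values come from a 10⁷ run, which
  `scripts/acceptance.py` performs in full).

## Limitations

- The delta-method variances are first-order; for sparse tables or very
  small arms the normal approximation degrades, which is precisely when the
  simulated-exact route (or full enumeration) should be preferred.
- The exact p-value is one-sided by construction (right-tail area); a
  two-sided exact version would need a tail-ordering convention the method
  does not define.
- No confidence intervals for RR1/RR2 ratios, no power/sample-size
  calculations, no adjustment for covariates or for non-concurrent
  controls.
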