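# Methods

## The pair-level combined statistic

The package's central quantity scores a miRNA pair's *coordinated
differential expression*. Three evidence streams enter:

* `p_DE(miR1)`, `p_DE(miR2)` — two-sided paired t-test p-values for each
  member, testing the within-subject difference between the follow-up and
  baseline timepoints;
* `p_CC(miR1, miR2)` — the tail probability of the pair's Spearman rank
  correlation across all samples (both timepoints pooled).

Each p is mapped to a normal quantile `Z = Φ⁻¹(1 − p)` and combined as a
weighted Stouffer sum,

    Z(miR1, miR2) = (w_DE·Z_DE1 + w_DE·Z_DE2 + w_CC·Z_CC) / √(2·w_DE² + w_CC²),

with defaults `w_CC = 1`, `w_DE = 0.5` (denominator √1.5). The denominator
makes Z standard normal when the three streams are independent and uniform,
which the test suite verifies empirically (KS uniformity of the combined p
at 10⁵ idealized-null draws). Z converts back to an upper-tail p-value via
the normal survival function; Benjamini–Hochberg adjustment is applied over
the full all-pairs universe (all C(m, 2) scanned pairs, not only those
passing any differential-expression filter — filtering happens *after*
adjustment). Selection keeps pairs with FDR < 0.01 **and** min(p_DE1,
p_DE2) < 0.05.

### The Spearman tail convention

`p_CC` is one-sided **on |cc|**: `P(T_{n−2} > |t|)` with
`t = cc·√((n−2)/(1−cc²))`, i.e. half the two-sided p. Two consequences are
intended: anti-correlated pairs count as coordinated (the reference panel
contains one pair at cc = −0.812 that must score highly), and under truly
independent features `p_CC` is stochastically *smaller* than uniform
(halving a uniform two-sided p), so the realized pipeline null is
anti-conservative at the margin. The test suite asserts this direction
explicitly; the practical guard against it is the BH step over thousands of
pairs combined with the per-member p_DE condition, which together hold the
realized null selection rate near zero (see below).

At n = 22 the t-approximation reproduces the reference panel's printed tail
probabilities within the precision their 3-digit correlations permit
(propagated input rounding is 1–2.5% in p). An exact permutation-null
option (`method="exact"`, full n! enumeration) exists for n ≤ 10, where the
t-approximation is least trustworthy.

### Numerical conventions

* All Φ/Φ⁻¹ evaluations use survival-function forms (`norm.isf`,
  `norm.sf`); there is no `1 − CDF` cancellation, so p down to 1e−300 maps
  to finite, accurate z.
* Probabilities below 1e−300 are floored at 1e−300 and flagged, never
  returned as 0; |cc| = 1 (e.g. a duplicated assay) is flagged
  `perfect_correlation` and floored likewise.
* Degenerate t-tests (zero-variance differences) report p = 1 when the mean
  difference is also zero and the 1e−300-class floor when it is not, with a
  `degenerate` flag, so a scan never aborts mid-matrix.
* Component p-values entering the z-transform are clipped to
  [1e−300, 1 − 1e−12] (a degenerate p_DE = 1 would otherwise map to −∞).
* Pair enumeration is lexicographic in feature id and every resampling
  option is seeded, making outputs byte-for-byte reproducible.

## Preprocessing

Panel matrices carry an explicit missingness mask (qPCR non-detections).
The default pipeline applies, in order:

1. **Missingness filter** — drop features missing in strictly more than
   12/22 of samples (the fraction generalizes the 12-of-22 paired-panel
   rule to other sample counts; a feature exactly at the threshold is
   retained).
2. **Feature-mean imputation** — each missing cell takes its feature's mean
   over observed cells; observed cells are untouched bit-exactly.

The cross-sectional arm instead uses the detection filter (feature detected
in strictly more than 60% of samples). Normalization and batch correction
are out of scope: the pipeline consumes already-normalized log-scale values,
and both the t-tests and the rank correlation tolerate any monotone
log-scale transform. Whether incoming values are −ΔCt, log2 expression or
another monotone scale therefore does not affect p_DE or p_CC; it only
changes the fold-change units in the cross-sectional report (configurable
log base, default 2).

## Differential expression and clustering

The cross-sectional scan is a classical pooled-variance two-sample t-test
(the "parametric p-value" convention of array-analysis suites); Welch's
form is a flag. Fold change is `2^(mean_a − mean_b)` on log2 input, 1 = no
change. Sample clustering uses 1 − Pearson correlation distance with
average linkage, cut at two clusters, scored as the best-permutation
agreement with the known groups (so 0.5 is chance for balanced groups, 1.0
is perfect separation).

## The synthetic generator

`generate_paired` draws from

    X[g, s, t] = μ_g + A_s + λ_g·F[module(g), s, t] + δ_g·1[t = post]·R_s + ε

* `μ_g ~ N(10, 2²)` — per-feature baseline abundance, log2-scale values in
  the range typical of −ΔCt panel exports;
* `A_s ~ N(0, subject_sd²)` — a subject offset **shared by all features**.
  This is the global sample-level component that per-sample normalization
  removes; since the pipeline consumes normalized values its default is 0.
  Setting it positive deliberately injects the confounding it causes
  (background correlation between every pair, hence pair-level false
  discoveries) — useful for studying robustness, wrong as a default study
  condition;
* `F ~ N(0, factor_sd²)` — one latent factor draw per (module, subject,
  timepoint), loading λ_g on module members: the source of co-expression;
* `δ_g·R_s` — the exposure effect, applied at the post timepoint only and
  only in responder subjects (`R_s ~ Bernoulli(responder_fraction)`,
  default 0.5 — the heterogeneous-response regime that motivates pair-level
  analysis in the first place);
* `ε ~ N(0, 1)` — residual noise;
* cells are then masked completely at random (MCAR) at `missing_rate`
  (default 5%, a typical panel non-detection rate).

Defaults are 11 subjects × 2 timepoints (22 samples) and 120 features with
three 6-feature modules at λ = 1, δ = 1: within-module Spearman
correlations land in the 0.6–0.8 range seen in real panel hubs, and a
2-fold log2 shift is a moderate exposure effect. Identical config + seed
is bit-identical.

What the generator does **not** emulate: intensity-dependent
(non-ignorable) missingness — real Ct non-detections concentrate in
low-abundance miRNAs, but no mechanism is quantified for the motivating
design, and MCAR keeps the planted truth exactly computable; batch
structure; heavy-tailed or discrete measurement noise. Passing tests on
synthetic data therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to informative
missingness or batch effects.

Ground-truth scoring: *power* is the fraction of truly coupled
(same-module), truly shifted pairs selected; *false discovery proportion*
is the fraction of selected pairs not coupled in truth. One subtlety: when
several modules shift under full responder penetrance, shifted features
from *different* modules genuinely co-vary through the shared exposure
response; such selections count against FDP because no latent factor
couples them, which makes FDP a conservative metric in multi-module
strong-effect regimes.

## Problem sizes used in validation

The validation suite runs the full pipeline at study scale (120 features,
11 subjects, 7140 pairs per scan): 200 pure-noise replicates for the null
selection rate, and 100 replicates per effect size δ ∈ {0, 0.5, 1, 2} for
the power curve; the idealized-null calibration uses 10⁵ draws. The
acceptance script reports the same quantities at 200/50 replicates. These
sizes give Monte Carlo error comfortably below the effects being asserted
(the null bound of ≤ 2 mean selections sits an order of magnitude above
the observed ≈ 0.2; consecutive power-curve points differ by multiples).

## Open design choices, resolved

* **Hub rule.** The motivating analysis names two hubs, yet a third node
  reaches the same degree 3 in its own pair list. Rather than encode that
  editorial choice, the hub report flags *every* node at or above the
  degree threshold (default 3) and separately marks each multi-edge
  component's maximum-degree node as its "center" — which recovers exactly
  the two named hubs while keeping the third candidate visible.
* **FDR universe.** BH runs over all scanned pairs. The alternative
  (adjusting only pairs passing the p_DE filter) would make the adjusted
  values depend on an upstream threshold and is not what a
  combine-then-correct reading implies; published FDR magnitudes are
  consistent with a universe of thousands of pairs.
* **Equal-variance default** for the cross-sectional t; Welch via flag.
* **Missing sentinel** in files: empty cell or `NA`, configurable, since
  Ct-export conventions vary.
* **Ties** in ranks: average ranks (standard Spearman; normalized qPCR
  values rarely tie).

## Known limitations

* p_CC treats the pooled 22 samples as exchangeable, ignoring the pairing
  within subjects; this matches the motivating analysis but means p_CC is
  not calibrated against within-subject dependence.
* The Spearman t-approximation is used at n = 22 where it is accurate to
  ~1%; for very small panels use the exact option.
* The published FDR column of the reference panel cannot be reproduced
  exactly: its adjustment universe (the number of feature pairs surviving
  the study's missingness filter) is not recoverable. The package checks
  its own FDR for ordering consistency instead.
* No directionality classes (coherent up/up vs divergent up/down
  co-expression) and no combination rules other than weighted Stouffer.
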