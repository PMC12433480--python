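# Methods

This note documents the models, conventions and numerical choices behind
the package, in the order the pipeline runs them.

## Imaging summaries (`kinetics`)

**Baseline normalization** divides every confluence value by the well's
first scan, so curves are unitless fold changes with first value exactly 1.
Division (rather than subtraction) makes every downstream quantity invariant
to the instrument's absolute confluence scale and composes naturally with
the treated/untreated ratio; subtraction remains available via
`normalize_to_baseline(..., mode="subtract")` for instruments whose baseline
reflects debris rather than cells.  A non-positive baseline is a named
error (`BaselineError`), not a silent drop.

**AUC** is the trapezoid rule on the observed grid — exact for
piecewise-linear curves, no interpolation or extrapolation.  Technical
replicates are averaged *before* normalizing to the untreated mean of the
same biological repeat, so each repeat contributes one untreated-normalized
AUC per MOI and the untreated condition is exactly 1 per repeat.  Repeats
stay separate observations for the statistics.

**Death index** divides dead cells/mm² by confluence pointwise; timepoints
with non-positive confluence are dropped with a logged warning, and the
trapezoid AUC of the remainder summarizes cytotoxicity.

## Dose-response inference (`doseresp`)

Per cell line, the untreated-normalized AUCs (one per biological repeat and
MOI) are compared against the untreated condition with **Dunnett's
many-to-one test**.  The joint distribution of the statistics
T_j = (x̄_j − x̄_0)/(s√(1/n_j + 1/n_0)) has correlation
ρ_ij = λ_i λ_j, λ_j = √(n_j/(n_j + n_0)); the adjusted p-value
P(max_j |T_j| ≥ |t_i|) is evaluated by nested quadrature: 96-node
Gauss–Legendre over the shared control variate weighted by the standard
normal density, and 128-node Gauss–Legendre over the pooled-scale chi
distribution on a [1e−13, 1−1e−13] quantile window (the known-variance
limit skips the outer integral).  Absolute accuracy is ≲1e−5: with one
treatment the result matches the pooled t-test to ~1e−13, and on random
data it agrees with an independent multivariate-t implementation to a few
1e−5.  Degenerate data (zero pooled variance) reports p = 1 where the
observed difference is zero.  Unequal group sizes are supported; the study
design is balanced (n = 3 repeats).

Because the untreated values are exactly 1 per repeat (zero control
variance) while treated ratios carry the noise of both numerator and
denominator, the pooled-variance test is mildly **conservative** on true
nulls: on 500 simulated null lines (kmax = 0, α = 0.05) about 2% are
assigned a rank multiplier below 6, versus the 8% budget allowed for
family-wise error plus Monte-Carlo slack.

The **rank multiplier** is the 1-based rank of the lowest MOI (ascending
grid) with adjusted p ≤ α (inclusive threshold, default α = 0.05); 6 if no
MOI qualifies on the five-MOI grid (generally k+1 on a k-MOI grid).  The
**susceptibility score** is the sum of the per-MOI mean normalized AUCs
times the multiplier — strictly increasing in each AUC and in the
multiplier, so stronger inhibition can only lower the score.  Ranking is
ascending by score with deterministic tie-breaks (smaller AUC sum, then
name), so results are independent of input order.

The time × MOI factorial analysis is a **fixed-effects type-III two-way
ANOVA** via sum-to-zero contrasts and full-vs-reduced residual sums of
squares; for complete balanced data it equals the classical decomposition
(sums of squares add to the total within 1e−9 relative).  It is the
documented fixed-effects analog of the mixed-effects/repeated-measures
models that plate-analysis software fits; within-subject pairing is
deliberately ignored.  Pairwise post hoc adjustments (Sidák closed form,
Tukey via the studentized-range distribution, Fisher LSD with single pooled
variance) cover the remaining comparisons in the study design.

## Expression correlates (`expression`)

**Size factors** are median-of-ratios: reference = per-gene geometric mean
across samples over genes with strictly positive counts everywhere; a
sample's factor is the median ratio to the reference.  Depth-scaled copies
of one sample recover the scaling ratios with geometric-mean-1
normalization.  The transform is log2(count/factor + 1) — base and
pseudocount configurable — followed by per-gene z-scores (sample SD,
n−1 denominator; constant genes map to zeros).  The scaled matrix is what a
heatmap would display; plotting itself is out of scope.

**Correlation** aggregates log-normalized expression by arithmetic mean
over a line's replicate samples, then computes Spearman's ρ against the
integer susceptibility rank (1 = most susceptible).  Correlating against
the raw score would give identical Spearman output, since the rank is a
monotone function of the score.  For untied inputs the closed form
1 − 6Σd²/(n(n²−1)) is used and Σd² is reported; ties fall back to Pearson
on midranks.  P-values: exact enumeration of all n! permutations for
n ≤ 8, seeded Monte-Carlo permutation sampling (with standard error) for
larger n on request, or the t approximation t = r√((n−2)/(1−r²)), df = n−2
(the default above n = 8).  Exact small-n p-values from different software
differ in tie and rounding conventions, so reported p-values are
descriptive; estimates are the primary output.  Gene-level p-values are
unadjusted by default with an optional Benjamini–Hochberg column.

## Assay calibration (`assays`)

The **4PL** curve y = d + (a−d)/(1 + (x/c)^b) is fitted by unweighted least
squares (1/y² weighting optional) from the standard initialization (a, d
from the extreme responses, c at the geometric mid-concentration, b = 1)
plus three perturbed starts, keeping the best residual sum of squares.
Preconditions: ≥ 5 standards spanning ≥ 2 decades with monotone responses.
Inversion is analytic (x = c((a−d)/(y−d) − 1)^{1/b}), and evaluate/invert
round-trip to ≤ 1e−9 relative inside the standards' span.  Responses beyond
the response at the lowest/highest standard are flagged `below_fit` /
`above_fit` and substituted by LLOD/√2 or the upper limit respectively —
the substitution is idempotent.  The **hyperbolic** curve y = Bmax·x/(Kd+x)
works the same way for luminescence ATP assays.  Blank subtraction before
fitting is off by default (configurable upstream of the fit).

**Plaque titers** use mean countable plaques × dilution factor / infection
volume, with the countable window fixed at 5–50 isolated plaques per well
as a hard filter; if no well is countable the error lists the counts.

## Synthetic data (`simulate`)

The generator emulates the screen's raw inputs with a known ground truth:

- **Confluence**: logistic growth minus delayed Hill-type killing,
  C′ = gC(1 − C/K) − k(m)·C·1[t > τ], k(m) = kmax·m^h/(m^h + m50^h),
  k(0) = 0 — the simplest mechanism producing dose- and time-dependent
  suppression.  Euler integration with 4 substeps per 2 h sampling interval
  keeps the discretization error below 1% of the closed-form logistic at
  g = 0.05/h (a single 2 h step gives 3.4%); the observation grid is still
  every 2 h up to 170 h.  Noise is multiplicative lognormal per timepoint
  (confluence is strictly positive and heteroskedastic in practice), with
  σ = 0.05 by default — a typical well-to-well CV for imaging confluence;
  no published well-level variance exists, so this is a generator setting,
  not a claim about any particular instrument.  Values are clipped to
  [0, 100].
- **Dead cells**: γ × cumulative killed biomass ∫k(m)C(s)·1[s > τ]ds with
  γ = 1 cell/mm² per % killed (the scale cancels in the death index).  The
  onset gate matches the confluence ODE, so dead cells only accumulate once
  killing is active.  Note that at a fixed late timepoint a *higher* MOI
  need not give more cumulative death for extreme kill rates (fast collapse
  saturates the integral); in the default parameter regime the ordering
  holds and is tested numerically.
- **Secretion**: concentration = β × killed biomass at the sampled hours
  (default 24/48/72 h), zero for untreated wells, non-decreasing before
  noise.
- **Counts**: negative binomial with gene-wise dispersion (default 0.1) and
  lognormal per-sample depth factors (σ = 0.3) so size-factor estimation is
  genuinely exercised.  Planted "receptor" genes get log2 mean
  b0 − b1·z(score): susceptible lines (low score) express them more, so the
  planted signature is a negative Spearman estimate against the rank.
  Background genes draw a per-gene base mean (uniform on log2 3–10)
  independent of score.  A ground-truth table is returned alongside.

The **default panel** has 11 lines named for common melanoma, glioblastoma
and pancreatic-carcinoma models with kill parameters graded (kmax 0.10 →
0.01/h, m50 0.003 → 50 PFU/cell) so the most susceptible lines respond at
the lowest MOIs and the last line is nearly inert; `graded_panel(n)` builds
panels of other sizes with log-spaced m50.  The default design is the study
shape: five MOIs + untreated, triplicate wells, three biological repeats.
Every generator is deterministic given its seed; panel simulation uses
per-line child seeds from a `SeedSequence` spawn.

What the generator does *not* model: intracellular virus replication,
spatial plate effects, edge wells, secular drift, batch structure in the
counts, or immune-cell biology.  Passing tests on this synthetic data
demonstrate that the pipeline's arithmetic and inference behave as
specified under the stated noise model — not that any particular real panel
would reproduce a given ranking.

## Problem sizes used in the test suite

Monte-Carlo oracles use 2×10⁵ draws (Dunnett bivariate-normal check,
studentized-range check) or 10⁶ permutations (exact-Spearman check);
planted-effect recovery runs the full pipeline on 50 seeds of a 12-line
panel with 520 genes; null calibration simulates 500 single-line screens.
These sizes give comfortable Monte-Carlo margins relative to the tested
tolerances while keeping the suite quick on one CPU.

## Known limitations

- The Dunnett quadrature assumes the standard homoskedastic one-way model;
  it does not implement heteroskedasticity-robust or stepwise variants.
- REML mixed-effects / repeated-measures models are not implemented; the
  type-III fixed-effects ANOVA is the documented analog and is exact only
  for complete balanced data.
- Exact Spearman enumeration is capped at n = 8 (8! = 40,320 permutations);
  beyond that the seeded Monte-Carlo or t approximation applies.
- The 4PL fitter requires a monotone standard series and rejects designs
  spanning under two decades rather than attempting an ill-posed fit.
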