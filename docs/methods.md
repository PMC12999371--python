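# Methods notes

This note records the statistical model behind `cemeta`, the numerical
conventions it commits to, what the synthetic-data generator does and
does not emulate, and the design choices made where more than one
reasonable option existed.

## The estimation problem

A cost-effectiveness meta-analysis starts from M studies, each reporting
an incremental cost ΔC_j (treatment minus control, common currency), an
incremental effectiveness ΔE_j (larger is better after sign
normalisation), the combined-arms sample size N_j, and sometimes
standard errors.  The target quantities are the pooled differences and
their ratio, the ICER = ΔC_pooled/ΔE_pooled.  Cost and effectiveness are
pooled *separately* and combined only at the ratio stage: pooling
per-study ICERs directly mixes quadrants with opposite meanings (a
cheaper-but-worse study and a costlier-but-better study can have the
same ratio), and a ratio of averages is more stable than an average of
ratios.  Arithmetic means are used throughout — no medians, no log
transformation — matching prevailing CEA practice.  Only univariate CIs
are produced for ΔC and ΔE (no bivariate ellipse inference); the
cost–effect correlation enters the analysis through the paired bootstrap
instead.

## Scenario 1: ratio ("studies-at-random") estimators

With Y_j = N_jΔ_j and Z_j = N_j treated as an i.i.d. bivariate sample of
clusters, the pooled difference is Ȳ/Z̄ and its variance is the
Taylor-linearisation form

V² = [σ_y²/μ_z² + μ_y²σ_z²/μ_z⁴ − 2ρ_yz μ_yσ_yσ_z/μ_z³] / M.

Conventions the implementation commits to:

- **Moment estimators use the M−1 divisor** for variances and the
  covariance.  This is the sample-moments convention; with the bundled
  16-study dataset it reproduces the reference results to their printed
  precision, which the M-divisor does not.
- **Degrees of freedom**: t(M−2) for the random-N form (the ratio of two
  estimated means consumes two moments), t(M−1) for the constant-N
  variant V² = (ΣN_j²/(ΣN_j)²)·s²(Δ_j), whose s² is the *unweighted*
  sample variance of the Δ_j.
- **Degenerate inputs**: if Y or Z has zero sample variance the
  correlation is undefined; it is set to 0 with a warning, which zeroes
  the cross term.  Negative plug-in V² (possible in near-degenerate
  configurations) is truncated at 0.  M ≥ 3 is required (the moment
  estimates need it); datasets with M < 5 trigger a warning because the
  asymptotics are poor with so few clusters.
- Estimates are kept at full precision; rounding (integer currency,
  two-decimal effects) is presentation-layer only.

The two variants share the identical point estimate by construction;
the constant-N variant is usually, but not provably always, wider.

## Scenario 2: inverse-variance weighting

Standard fixed-effect pooling with w_j = 1/SE_j², Cochran's
Q = Σw_jES_j² − (Σw_jES_j)²/Σw_j, I² = max{(Q−df)/Q, 0} with df = M−1,
and the DerSimonian–Laird moment estimator
τ̂² = max{0, (Q−df)/(Σw_j − Σw_j²/Σw_j)} (truncation at 0 is standard —
the raw moment estimator can be negative).  Random-effects pooling
reruns the weighted mean with w_j* = 1/(SE_j² + τ̂²).  CIs use normal
quantiles for both FE and RE; no Knapp–Hartung small-sample adjustment
is applied.  Q and I² are always computed from FE weights, the usual
convention.  When SEs are only available as reported CIs,
`se_from_ci` backs them out from the interval width (normal or t
divisor).

Missing SEs cause an explicit refusal pointing at the scenario-1
methods; `complete_case=True` opts into subsetting to the studies that
report an SE, mirroring the common sensitivity re-analysis.

## The bootstrap wedge arc

Resampling: M studies are drawn with replacement; each draw keeps the
study's (ΔE, ΔC, N, SEs) together so the within-study cost–effect
dependence survives; the pooled pair is recomputed per replicate by the
same method as the point estimate.  Replicates are mapped to directions
θ = atan2(ΔC, ΔE); the slope tan θ is the replicate's ICER.

- **≤ 3 occupied quadrants**: at least one quadrant is empty, so the
  circle of directions has a replicate-free arc.  The implementation
  cuts at the midpoint of the *largest empty angular gap* and sorts
  counterclockwise from the cut; the k-th order statistic in from each
  end (k = ⌈Bα/2⌉, counting inclusive, ties broken by replicate index,
  with a 1e-9 guard against binary rounding of α) gives the clockwise
  bound (CB) and counterclockwise bound (CCB).  This angular formulation
  is equivalent to the bookkeeping description — sort slopes within each
  quadrant, then conjoin adjacent occupied quadrants across the ±∞
  discontinuities — and the equivalence is enforced by a
  cross-implementation test rather than assumed.  With one occupied
  quadrant it reduces to the ordinary bootstrap percentile interval on
  the slope.
- **4 occupied quadrants**: there is no empty arc and no natural cut, so
  the ordering is anchored at the point-estimate direction and the
  central 1−α of signed angular deviations is kept; the excluded mass
  sits antipodal to the estimate.  The anchor choice is a design
  decision (the inward-counting description does not name an origin);
  such arcs are flagged `informative=False`, since four-quadrant
  scatter means the direction is essentially unconstrained.
- Replicates exactly on an axis are assigned to the
  counterclockwise-adjacent quadrant (θ half-open binning); replicates
  at the exact origin carry no direction and are dropped with a warning.
- Defaults: B = 500 (500–1000 is the customary range); the seed is
  always explicit.  B must be ≥ 100 and ≥ 1/α.

Bounds are reported as slope + quadrant + angle: a slope alone is
ambiguous across antipodal quadrants.

The closed-form alternative (`taylor_icer_ci`) applies the ratio
machinery to Y_j = N_jΔC_j, Z_j = N_jΔE_j, giving ICER ± t(M−2)·V̂.  It
is symmetric in slope space and quadrant-blind, so it is offered only as
a comparison; it warns (reliable=False) whenever the pooled effect's
|t| fails the CI critical value, the regime where a ratio CI
degenerates.

## Decision rules on the CE plane

Quadrants follow the sign of (ΔE, ΔC): SE (more effective, cheaper) is
dominant and NW dominated regardless of any threshold.  Given a
willingness-to-pay λ, NE requires ICER ≤ λ; in SW the convention is
symmetric forgone-effect logic, requiring savings of at least λ per unit
of effectiveness given up (slope ≥ λ).  A pooled ΔE of exactly zero
yields an ±∞ ICER marker with a warning, never an exception.

## Synthetic-data generator

`generate_meta_dataset` draws N_j from a configurable distribution
(uniform integers by default, lognormal optional, floor 10) and then

(ΔC_j, ΔE_j) ~ BVN((μ_C, μ_E), SDs √(τ² + within²/N_j), corr ρ_CE),

the univariate random-effects model extended bivariately: τ_C, τ_E are
between-study SDs, and within_sd/√N_j is the within-study SE that the
study would report.  Defaults (M = 20, N_j ~ U{25..450}, μ_C = −2000,
μ_E = 0.2, τ_C = 4000, τ_E = 0.5, ρ_CE = −0.5, within 10 000 USD·√patient
and 1.5 QALY·√patient) were chosen once to resemble the bundled
wound-intervention data in scale and heterogeneity.  Two optional knobs
reflect features of real CEA data: a lognormal-cost mode (cost
distributions are right-skewed in practice) and a size–effect
correlation (study size may correlate with effect under the
studies-at-random sampling view; default off, implemented through a
Gaussian copula on the latent scores).

What the generator does *not* emulate: reporting heterogeneity (mixed
effectiveness scales, missing SEs, currency-year mismatch), publication
selection, non-normal effect distributions beyond the cost-skew option,
and within-study estimation error in N_j.  Passing coverage tests on
this generator therefore demonstrates correctness of the estimators
under their own assumptions, not robustness to real-world reporting
problems.

`run_coverage_sim` spawns one child RNG stream per replicate from a
master `SeedSequence`, so summaries are reproducible and independent of
which methods are requested.  Problem sizes used in the shipped tests —
2000 replications at M = 20 for coverage, 2000 at M = 50 for DL τ²
recovery, B = 500 with 20 seeds for the wedge — keep the whole suite in
the seconds-to-a-minute range while leaving Monte-Carlo error well below
the tested tolerances.

## Known limitations

- No currency conversion, discounting, time-horizon harmonisation, or
  combinability appraisal: inputs must arrive on a common scale, and
  whether studies *should* be pooled is a judgement outside this
  package.
- No Fieller-type ICER interval, no incremental-net-benefit pooling, no
  bivariate meta-analysis, meta-regression, or publication-bias tests.
- The wedge's frequentist calibration inherits the bootstrap's
  limitations for small M: with fewer than ~5 studies resampled ICERs
  tie heavily and the arc is unreliable (a warning is emitted).
- The DL τ̂² is a moment estimator; its known small-M bias and the
  controversies around RE-as-default apply here unchanged.
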