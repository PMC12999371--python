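# cemeta — meta-analysis of cost-effectiveness

`cemeta` pools the results of multiple cost-effectiveness analyses (CEA)
the way a conventional meta-analysis pools treatment effects, and deals
with the part that is genuinely different: the incremental
cost-effectiveness ratio (ICER) is a *ratio* of two pooled quantities
and lives on the four-quadrant cost-effectiveness (CE) plane, so its
confidence statement is an angular arc rather than an ordinary interval.

It is written for biostatisticians and health-economics researchers who
have a table of per-study summary results — incremental cost ΔC_j,
incremental effectiveness ΔE_j (e.g. QALYs), total sample size N_j, and
possibly standard errors — and want a pooled ΔC, ΔE and ICER with
defensible uncertainty, plus a publication-ready CE-plane figure.

## Methods in brief

**Scenario 1 — no SEs reported (common in CEA).** Each study is treated
as a sampled cluster ("studies at random") and the pooled difference is
the ratio of means

```
Δ̂ = Σ N_j Δ_j / Σ N_j = Ȳ / Z̄,     Y_j = N_j Δ_j,  Z_j = N_j
```

with Taylor-linearisation variance

```
V² = [σ_y²/μ_z² + μ_y² σ_z²/μ_z⁴ − 2 ρ_yz μ_y σ_y σ_z/μ_z³] / M
```

estimated by sample moments and a t(M−2) reference distribution.  A
variant treating the N_j as fixed uses V² = (Σ N_j²/(Σ N_j)²)·s²(Δ_j)
with t(M−1); it shares the identical point estimate and is typically
more conservative.

**Scenario 2 — SEs available.** Classical inverse-variance weighting:
fixed-effect weights w_j = 1/SE_j², or DerSimonian–Laird random effects
with w_j* = 1/(SE_j² + τ̂²), plus Cochran's Q, I² = max{(Q−df)/Q, 0} and
τ̂².  SEs can be backed out of reported CIs via their width.

**ICER and the bootstrap wedge.** The pooled ICER is the ratio of the
pooled differences, ΔC_pooled/ΔE_pooled — a slope through the origin of
the CE plane.  Its confidence arc resamples the M studies with
replacement B times (cost/effect pairs kept together), re-pools each
replicate, maps replicates to directions θ = atan2(ΔC, ΔE), and takes
the central 1−α of directions: a clockwise bound (CB) and a
counterclockwise bound (CCB), each reported as a slope with its quadrant
label.  When replicates span at most three quadrants the circle is cut
in the largest empty gap (one quadrant's worth is always empty) and the
procedure reduces to a percentile method that correctly conjoins
quadrants across ±∞ slope discontinuities; with all four quadrants
occupied the count is centred on the point estimate and the arc is
flagged as uninformative.  A closed-form Taylor CI for the ICER
(ratio method on Y_j = N_jΔC_j, Z_j = N_jΔE_j) is provided for
comparison, with a reliability warning when the pooled effect is not
clearly nonzero.

## Worked example

The package bundles a 16-study dataset from a systematic review of
complex-wound interventions (costs in 2013 USD, effectiveness on
QALY-like time scales, no SEs reported — scenario 1).
Running `python examples/pool_wound_interventions.py` prints:

```
16 studies, 3672 patients in total

pooled cost difference (2013 USD):
  ratio            -1972.52  95% CI (-4492.25, 547.20)
  ratio-constant   -1972.52  95% CI (-4688.96, 743.91)
pooled effect difference (QALY):
  ratio                0.21  95% CI (-0.03, 0.45)
  ratio-constant       0.21  95% CI (-0.25, 0.67)

pooled ICER = -9332 2013 USD/QALY (SE quadrant -> dominant)

per-study quadrant counts: {'NE': 5, 'NW': 1, 'SE': 10, 'SW': 0, 'on_axis': 0}
```

The pooled interventions save about $1973 per patient while gaining
0.21 QALYs: the ICER of −9332 lies in the southeast (dominant) quadrant.
`python examples/wedge_arc.py` adds the bootstrap wedge (with seed 42,
99.0% of the 500 replicates fall in SE; the 95% arc runs from
CB = −25341 to CCB = −1305, both in SE — dominance is robust), and
`python examples/ce_plane_figure.py` draws the full CE plane.
`examples/ivw_scenario2.py` and `examples/coverage_simulation.py`
demonstrate scenario-2 pooling and the Monte-Carlo coverage audit of all
four estimators on synthetic data.

The same functionality is exposed as a thin CLI:

```
cemeta pool                 # pooled differences on the bundled data
cemeta icer --seed 42       # ICER + wedge arc
cemeta plot --seed 42 --wtp 50000 --out plane.svg
cemeta simulate --seed 3 --reps 2000
```

`cemeta pool --input your_studies.csv` accepts a CSV with columns
`study_id, delta_c, delta_e, n` (optionally `se_delta_c, se_delta_e,
effect_direction`).

## Layout

- `src/cemeta/data.py` — study records, CSV/JSON I/O, bundled dataset
- `src/cemeta/ratio.py` — scenario-1 ratio pooling (Taylor variance)
- `src/cemeta/ivw.py` — scenario-2 IVW pooling, heterogeneity, DL τ²
- `src/cemeta/wedge.py` — ICER, quadrants, bootstrap wedge arc
- `src/cemeta/plane.py` — CE-plane figures
- `src/cemeta/simulate.py` — synthetic generator and coverage simulations
- `src/cemeta/cli.py` — `cemeta` command
- `docs/methods.md` — modelling assumptions, defaults and limitations
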