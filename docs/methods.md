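# Methods

This note records the models pcenet implements, the assumptions and
defaults behind them, and the design choices made where more than one
reasonable construction existed.

## Hydraulic model

The distribution system is a single steady snapshot: all consumers draw
water simultaneously at their annual demand rate, and that pattern stands
in for every time of day, season and year. Sources are fixed-head
reservoirs at a common reference head; elevations are flat (they vary
little in the coastal systems this model targets and no headloss data
survive to calibrate them); pressure-dependent demand, tanks, pumps and
valves are out of scope.

Headloss follows Hazen-Williams, `h = r·sign(Q)|Q|^n` with `n = 1.852`
and `r = 10.67 L / (C^1.852 d^4.871)` (SI units), with a single constant
roughness `C = 100` for all pipes by default — the historical roughness
of individual mains is unknowable, and because only resistance *ratios*
determine how flow divides among loops, a common constant is the neutral
choice. For the same reason the package's internal flow unit (volume per
year, in whatever unit the demands are given) never needs conversion.

The solver is a damped Newton iteration on junction heads: residuals are
net pipe inflow minus demand per junction; the head-flow law is
linearized below a tiny head drop (the loss at 10⁻⁷ of total demand) so
the Jacobian stays bounded through flow reversals and across dead-end
pipes carrying no flow; steps are backtracked until the residual norm
decreases. Defaults: relative tolerance 10⁻⁶ of total demand, 200
iterations; quadratic convergence typically reaches ~10⁻¹² within ten
iterations, and on tree networks the converged flows equal subtree demand
sums to machine precision. Zero total demand is rejected as degenerate
rather than solved trivially. `check_conservation` re-derives per-junction
residuals from the flow solution independent of the solver internals.

## Leaching and transport

The vinyl liner's residual PCE depletes by first-order kinetics: the
fraction of the initial areal load `m0` remaining `t` years after
installation is `e^(−t/R)`, with `R = 2.25` years as the central estimate
and `{0.025, 0.75, 2.25, 5, 10}` as the sensitivity grid spanning
implausibly fast to implausibly slow. The model gives only the continuous
decay; the annual discretization is this package's choice: the release in
the calendar year beginning `a` whole years after installation is the
exact integral `S·m0·(e^(−a/R) − e^(−(a+1)/R))`, `S = πdℓ`, so the
series telescopes — total release over all years equals `S·m0` for every
`R`, a conservation property the tests assert to 10⁻⁹.

Transport treats each year independently (steady state): orienting pipes
by flow direction yields a DAG; in topological order a junction's
concentration is the flow-weighted mean of its inflowing pipes' outlet
concentrations, and a pipe adds `J/|Q|` between inlet and outlet. Bulk
decay, dispersion, temperature effects and within-year dynamics are not
modeled. Pipes with |Q| below 10⁻⁹ of total demand are stagnant: a
steady-state model cannot represent accumulation in standing water, so
their leached mass is dropped from the balance with a logged warning
(mass conservation is asserted only over non-stagnant pipes).

Doses are *relative*: the annual dose at a node is its concentration
times one unit of standard consumption, so dose equals concentration
numerically and only the ordering across subjects carries meaning
(relative delivered dose, RDD). Whether the historical construction
normalized per household or per unit consumption is not recoverable; the
unit-consumption convention is adopted, and since every subject gets the
same unit it cannot rerank anyone. An absolute calibration — initial
load `m0_abs` (µg/m²) and per-demand-unit water use `demand_abs`
(m³/year) — rescales the relative field to µg/L point concentrations for
comparison with water samples. The synthetic default (`3×10⁷ µg/m²`,
`400 m³/year`) puts dead-end branch nodes in the hundreds-to-thousands
µg/L and looped mains in the tens, reproducing the historically observed
low-flow/high-flow contrast and the exceedance of the 40 µg/L action
level at dead ends only.

## Exposure histories

Accounting is by whole calendar years: the move-in and move-out years
both count, exposure is strictly before the reference year (diagnosis
year for cases, assigned index year for controls), and under a latency
assumption of `L` years only years ≤ reference − L count. Partial-year
handling is not specified by the underlying method; whole-year counting
with the inclusive conventions above is the simplest rule that makes
metrics additive when a residence span is split. Index years are drawn
from the empirical distribution of case diagnosis years so the two
groups share one calendar frame.

Metrics per subject and latency: cumulative RDD (sum over the window,
additive across residences), peak RDD (max), duration (count of positive
years), ever-exposed (duration > 0). Category cuts are the 50th/75th/90th
percentiles (linear interpolation between order statistics) of cumulative
RDD among *exposed controls*, per latency; a value exactly at the median
is "low". Cuts from fewer than 10 exposed controls are flagged unstable.
The referent group for every odds ratio is fixed as the women never
exposed during the entire study period (i.e., unexposed at latency 0),
not a latency-specific referent — the two conventions disagree in
published tabulations and the fixed referent is the one stated in the
source method's own description; the discrepancy is documented, not
resolved. Residences at nodes outside the supplied network either raise
or (configurably) contribute zero with a warning.

## Odds ratios, smoothing, screening

Crude ORs are `ad/bc` with Woolf intervals,
`exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`; zero cells yield an undefined
result (no Haldane correction), mirroring how sparse strata are reported
as missing. Adjusted ORs are the antilog of the exposure coefficient of
a maximum-likelihood logistic fit (statsmodels, Newton/IRLS) with Wald
intervals from the ML standard errors; on a single binary exposure with
no covariates this reproduces the 2×2 OR to 10⁻⁸ (asserted). Age and age
at first birth enter as continuous covariates (their original coding is
unstated; continuous is the minimal-assumption choice). Candidate
confounders beyond the core set are screened one at a time by the 10%
change-in-estimate rule; candidates that break convergence are flagged
and not kept.

The exposure-response shape is explored by LOESS (statsmodels lowess,
local-linear, fraction = span ∈ [0.1, 0.3]) of the 0/1 outcome on
continuous RDD — smoothing the indicator and logit-transforming the
clipped fit (clip [10⁻⁴, 1−10⁻⁴]) rather than local-likelihood logistic
fitting, matching the named procedure's default behavior and staying
deterministic. The curve is evaluated on a 200-point grid.

The high-exposure cut point is selected from the smoothed curve. The
naive rule — smallest grid RDD after which the curve is non-decreasing —
is exact on noise-free curves but measurably useless on sampled ones:
smooth sampling wiggles decline by tiny per-step amounts that defeat any
per-step slack, and cumulative-drawdown variants are dominated by
post-step plateau wiggles. The default rule therefore keeps the literal
behavior on monotone curves (first grid point for a rising curve; a
`None` sentinel for flat or falling ones) and, on non-monotone curves,
locates the regime change by the CUSUM change-point statistic — which in
simulation sits within ±4 RDD of a true risk step independent of the
smoothing span — then walks backward along the final non-decreasing
stretch, never below the halfway level of the rise. The rule is a
callable parameter, so any alternative can be substituted.

The Wilcoxon signed-rank test (paired exposure vectors from two
assessment methods) drops zero differences, uses the exact tie-aware null
distribution of the positive-rank sum (dynamic programming over doubled
ranks) for n ≤ 25 and the tie-corrected normal approximation beyond, and
returns p = 1 with a flag when all pairs are identical. It matches full
2ⁿ enumeration exactly in tests.

## Validation against water samples

Non-detects are substituted before analysis: the default reads "half the
detection limit of 0.5 µg/L" as DL = 0.5 → substitute 0.25; the alternate
reading (substitute 0.5) and arbitrary callables are configurable.
Agreement is summarized by Spearman's rank correlation on the raw scale
(rank agreement is what a relative dose model must deliver) and OLS on
ln-transformed pairs (concentrations are right-skewed), reporting R²,
slope and intercept; strata with fewer than 3 samples are skipped with a
note, and zero-variance inputs return a flagged undefined correlation.
No correction is applied for the known downward bias of head-space
assays; it is noted only.

## Synthetic data: what it emulates, what it does not

Towns are grid networks (default 8×8, 100 m spacing, 0.25 m mains) with
dead-end branches (default 6, 0.15 m) fed from one corner source. Each
junction hosts parcels (default 3) at unit demand. Vinyl-lined pipes are
grown as spatially contiguous "neighborhoods" (default 2 clusters
covering 15% of pipes) seeded in the half of the network farthest from
the source — liner installation followed street-by-street replacement and
expansion needs, and clustering away from the wellhead keeps the
contaminated downstream set from swallowing the whole town, yielding
ever-exposed fractions around 0.3–0.55 across seeds, matching the
roughly-half exposure prevalence of the study frame this emulates.
Install years are uniform over 1968–1980.

Cohorts default to 920 cases / 1293 controls with reference years uniform
over 1983–1993, 40-year residential histories with Poisson(0.4) extra
moves, and core covariates at the reported prevalences (occupational PCE
13%, regular bottled-water use 22%, family history 10%, deceased 15%).
Disease is injected by a logistic model: log-odds linear in the
top-category indicator (configurable `or_high`, default 1.3) and
configurable covariate effects, with pool-level baseline risk 0.42 —
deliberately high, because the design is case-control and the pool only
needs to supply the configured case count, not a realistic incidence.
Because the analysis defines "high" from the exposed-*control*
distribution, which exists only after disease is assigned, the injection
iterates the 90th-percentile cut to a fixed point (reusing the same
uniform draws, so the result stays a deterministic function of config and
seed); without this the injected and estimated categories straddle
different cuts and the recovered OR is biased low by construction rather
than by anything scientifically meaningful.

Sampling campaigns draw nodes with positive modeled concentration,
multiply truth by lognormal(0, σ) error (default σ = ln 2, matching
observed ~two-fold day-to-day fluctuations) and censor below 0.5 µg/L.
Stratum labels derive from the network (flow tertile, dead-end position,
installation era, junction-degree complexity) or are drawn at random
(season, fixture, personnel).

What passing tests on these data do **not** show: the towns are not
replicas of any real system (real networks have irregular geometry,
multiple sources, and decades of topology changes); covariates are
mutually independent given the configured effects, so realistic
confounding structure beyond the injected one is absent; residential
mobility is calendar-uniform; and measurement error is purely
multiplicative with no false negatives beyond censoring. Parameter
recovery on synthetic cohorts demonstrates the estimator chain is
consistent and correctly wired, not that the original study's estimates
are correct.

## Problem sizes and numerical defaults

Default analyses run on 8×8-grid towns (~75 nodes, ~120 pipes), 26
leaching years, and cohorts of 2000–4000 subjects; parameter-recovery
checks use 200 replicates of n = 2000 (900/1100), chosen to keep the
Monte Carlo error of the mean recovered OR near 0.025 while the whole
suite stays interactive. Solver tolerance 10⁻⁶ (tests tighten to 10⁻¹²
where exactness is asserted); stagnation threshold 10⁻⁹ of total demand;
LOESS grid 200 points; exact Wilcoxon up to n = 25; latencies
{0, 5, 7, 9, 11, 13, 15, 17, 19}; leaching-rate grid {0.025, 0.75, 2.25,
5, 10} years.

## Known limitations

- Steady-state flow cannot represent diurnal or seasonal flow reversals;
  exposure at nodes near flow divides is therefore less certain than the
  single snapshot suggests.
- Stagnant-pipe mass is dropped, understating exposure at true dead ends
  with zero modeled demand (real dead ends accumulate very high
  concentrations — the historical worst cases).
- Adjusted ORs on real tabulated data cannot be reproduced without
  individual-level covariates; they are exercised only synthetically.
- The LOESS cut-point rule, like any change-point estimator, needs a
  genuine two-regime structure; gradually increasing risk yields a cut
  near the start of the rise, not a uniquely defined threshold.
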