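# Methods

This note documents the statistical models the package implements, the
design choices made where more than one defensible option existed, and
what the synthetic validation experiments do and do not demonstrate.

## Data model

The unit of analysis is the 1°×1° latitude/longitude grid cell. Cell ids
are `(floor(lat), floor(lon))` — lower-left-closed, upper-right-open, so
latitude −0.0001 belongs to cell −1. A *sampling unit* is a cell
containing at least one record; `T` counts units per region and `Y_k` is
the number of distinct units occupied by species *k*. Abundance records
are degraded to presence before pooling, so a species×cell pair counts
once regardless of how many plot records or occurrence rows support it,
and incidence construction is idempotent. Region membership comes only
from the input's region column; geometry is never used to infer it.
Species names are compared after whitespace-trimming and case-folding
only — synonym resolution is out of scope, which is precisely why the
false-unique adjustment exists. Records with invalid coordinates or
blank names are rejected with per-reason counts; nothing is dropped
silently.

The degree grid stands in for a projected 100 km × 100 km equal-area
grid. At the scales analyzed the two are interchangeable for frequency
tallies, and the degree grid needs no projection machinery; the cell
convention above is fixed and tested. No antimeridian merging or
coordinate-precision filtering is attempted.

## Estimators

**Sample coverage.** The bias-reduced Good–Turing/Chao–Shen estimator
`C_n = 1 − (f1/n)[(n−1)f1/((n−1)f1 + 2f2)]`, read with
(singletons, doubletons, individuals) on abundance data and
(uniques, duplicates, total presences) on incidence data. `f1 = 0` gives
`C_n = 1` exactly. The coverage deficit equals the accumulation curve's
terminal slope per presence; the suite verifies this identity to ~10⁻⁴
on synthetic data.

**Chao2.** The bias-corrected form
`S_obs + ((T−1)/T)·Q1(Q1−1)/(2(Q2+1))`, finite for `Q2 = 0` by
construction. The variance attached to the CI is the standard
bias-corrected companion (the form EstimateS and the iNEXT family
distribute): with `A = (T−1)/T` and `d = Q2+1`,

```
var = A·Q1(Q1−1)/(2d) + A²·Q1(2Q1−1)²/(4d²) + A²·Q1²Q2(Q1−1)²/(4d⁴).
```

The 95% CI is log-normal on the excess `E = Chao2 − S_obs`:
`[S_obs + E/K, S_obs + E·K]` with `K = exp(z·√ln(1+var/E²))`, natural
log, `z = Φ⁻¹(0.975)` (any level is accepted). `E = 0` degenerates the
interval to `[S_obs, S_obs]`, and the lower bound can never fall below
`S_obs`.

**True uniques and Chao2_adj.** The unique count is predicted from the
duplicate–quadruplicate tail:

```
Q1̂ = A·2Q2²/(3Q3) + A²·Q2·(Q2/(2Q3) − Q3/(4Q4)).
```

The exponent placement on the leading factor is typographically
ambiguous in the literature this follows; the variant with `A²` on the
first term is available via `squared_first_term=True`, and for `T ≫ 1`
the two differ negligibly (for `T = 100` the toy example shifts from
37.051 to 36.754). Negative estimates clamp to 0 with a logged warning.
When `Q3 = 0` or `Q4 = 0` the estimator falls back to the observed `Q1`
with a flag — the conservative choice, making the adjusted estimate
coincide with the raw one. `Q1̂` is deliberately *not* capped at the
observed `Q1`: when duplicates outnumber uniques the adjustment can
revise richness upward. Chao2_adj substitutes `Q1̂` (possibly
fractional; values below 1 contribute nothing) into the same point,
variance, and CI code path, so `Q1̂ = Q1` reproduces plain Chao2 bit for
bit. On clean data with no misidentification Chao2_adj is *not* a better
estimator than Chao2 — it answers a different question (what Chao2 would
be if the unique count matched the tail) and should be preferred only
when false uniques are plausible.

**Fisher's log-series.** `α` solves `S_obs = α·ln(1 + n/α)` by Brent's
method on a bracketing interval, relative tolerance 10⁻⁹; an
all-singleton sample makes `α` unbounded and raises a distinct error.
The richness projection is the closed form `S = α·ln(1 + N/α)`. The
bootstrap CI resamples the `n` individuals with replacement
(multinomially over species; 1,000 replicates by default, seeded) and
refits per replicate. Resampling loses singletons, so replicate fits —
and hence the percentile interval — sit slightly below the full-sample
`α`; this bias is inherent to the scheme and is left visible rather than
corrected.

**Log-series goodness of fit.** The KS statistic compares the empirical
and fitted log-series CDFs *at the distinct observed abundance values*.
A sample-based KS distance is inflated under heavy ties (the jump at
abundance 1 alone can exceed 0.14 even for perfect log-series data);
comparing the two right-continuous step functions on the support removes
that artifact. The p value uses the asymptotic Kolmogorov distribution
with the number of compared support points as effective sample size — an
acknowledged approximation for discrete data that errs conservative
(simulated null rejection at p < 0.05 stays below 10%). Fewer than three
distinct abundance values refuse the test.

## Accumulation curves

Interpolation uses the exact hypergeometric expectation
`S(t) = Σ_k [1 − C(T−Y_k, t)/C(T, t)]`, the closed-form average of all
randomized accumulation orderings; binomial coefficients are evaluated
in log space. The suite verifies equality with exhaustive subset
enumeration for `T ≤ 8`. Extrapolation is Chao2-anchored:
`S(T+t*) = S_obs + Q̂0·[1 − (1 − Q1/(Q1+T·Q̂0))^t*]` with
`Q̂0 = Chao2 − S_obs`, monotone to the Chao2 asymptote; `Q1 = 0`
continues flat at `S_obs`.

Uncertainty bands bootstrap the sampling units: resample `T` units with
replacement, rebuild the incidence frequencies (units counted with
multiplicity), recompute the full curve, 200 replicates by default.
Unit resampling is biased low — duplicated units carry no new species,
so every replicate's right end sits below `S_obs` — and a raw percentile
envelope would therefore exclude the exact curve near `t = T`. The
replicate curves are recentered on the exact mean curve before taking
percentile envelopes, using the bootstrap only for spread. Curves are
evaluated on a log-spaced grid of 40 integer knots out to `2T`
(configurable).

## Rarity and partitioning

Rare species are the sum of (adjusted) singletons/uniques and
doubletons/duplicates; indices are reported in both modes — abundance
(stems pooled per species) and occurrence (cells per species) — along
with the rare fraction of `S_obs` and the `S1/S2` ratio (flagged
undefined when `S2 = 0`). "To be discovered" is
`round(Chao2_adj − S_obs)` half-up, clamped at 0 with a flag.

Partitioning pools incidences over every nonempty subset of the `R`
regions (regions must be disjoint in sampling units, so pooled `T` and
`Y` are sums) and applies the chosen estimator (Chao2 by default;
Chao2_adj and plain `S_obs` are also available — the latter turns the
machinery into an exact set-arithmetic oracle used by the tests). Venn
components come from Möbius inversion of
`M(A) = U(full) − U(full∖A)`; because the estimator is nonlinear, a
component can be slightly negative, in which case it is clamped to 0 and
the total clamped mass is reported as a residual alongside the table.
Endemic percentages are reported relative to each region's own estimate,
rounded half-up for display with unrounded values retained.

## The synthetic world

The generator reproduces only the statistical structure the estimators
consume, with ground truth retained for recovery tests:

- **Abundances.** Each region's pool of `S0` species receives iid
  abundance classes drawn from the log-series distribution with
  parameter `x = N/(N+α)` by inverse CDF on a support truncated where
  the remaining tail mass drops below 10⁻¹²; weights are the normalized
  classes. A separate helper draws whole log-series *communities* via
  the Poisson representation (species with abundance k ~
  Poisson(α·x^k/k)), for which the expected number of distinct species
  is exactly `α·ln(1 + n/α)` — the oracle behind the Fisher recovery
  experiments.
- **Geography.** Each region is a square lattice of 1° cells in its own
  longitude band (regions can never share sampling units). A species'
  range is the `max(1, round(c·(1+√k)))` cells nearest a uniformly drawn
  center (deterministic tie-breaking), where `k` is its abundance class
  and `c` the `range_clustering` knob: common species are widespread,
  rare species occupy compact blobs. At the default `c = 1` even the
  rarest species occupy two cells, so observed uniques arise from
  incomplete detection — the sampling process Chao2 models — rather than
  from genuinely single-cell ranges, which would violate the estimator's
  replicated-incidence assumption and push it above truth. Sub-unity
  clustering can still force single-cell ranges for targeted tests.
- **Surveys.** The abundance survey places `plots_per_cell` plots
  uniformly in every cell, splits the region's individual budget evenly
  over plots in covered cells, and draws each plot's stems multinomially
  over the covering species' weights; stems are conserved exactly. The
  occurrence survey reports each species×occupied-cell pair with
  probability `detection_prob`, coordinates at the cell center.
- **Sharing.** `sharing_matrix[i,j]` allocates
  `round(share·pool)` species to both regions' pools, pairwise;
  oversubscribed pools are a configuration error. Subset ground truth is
  the size of the pooled species union.
- **Misidentification.** For a fraction `misid_rate` of the species
  occurring in ≥ 2 cells, all records in one randomly chosen cell are
  relabeled to a fresh spurious name, and the spurious→true map is
  retained. Acting at the unit level — not per record — matches the
  error process the true-uniques adjustment targets: a duplicate becomes
  two false uniques.
- **Seeding.** One root seed; every stochastic operation derives its
  stream from `(seed, operation name, region)` via hashed
  `SeedSequence` keys, so any operation reproduces in isolation and
  whole runs are byte-identical under a fixed seed.

Default conditions: 400 species per region, Fisher α = 30, 30,000
individuals, a 12×12 cell grid, 2 plots per cell, detection probability
0.7. These sizes give per-region sample coverage around 98% — the
high-coverage regime in which the estimators are meant to operate — while
keeping a full multi-region run under a second. Smaller worlds are used
where an experiment loops over hundreds of seeds.

What the generator does *not* emulate: real plot networks and their
spatial bias, biome geometry, climate covariates, taxonomy (names are
synthetic labels), within-cell spatial structure beyond uniform plot
placement, or occurrence heaping at collection localities. Passing
recovery tests therefore show that the estimators invert the *assumed*
sampling process correctly — not that real survey data satisfy those
assumptions.

## Validation experiments and problem sizes

- Fisher recovery: 100 log-series communities at α = 50, n = 50,000;
  the mean fitted α lands within 10% of truth (observed: within ~1%).
- Misidentification recovery: 200 single-region worlds at default
  conditions with `misid_rate = 0.3`; `Q1̂` computed from corrupted
  tallies is closer to the clean unique count than the corrupted count
  is in ≥ 90% of seeds (observed ~94%), and mean |Chao2_adj − truth| <
  mean |Chao2 − truth| (observed roughly 180 vs 315 species).
- Chao2 behaves as a lower bound on clean data: over seeds, mean Chao2
  lies between mean `S_obs` and truth + 5% at default conditions.
- Rarefaction equals exhaustive enumeration on random toys with
  `T ≤ 8`; all formula implementations match independent high-precision
  oracles to 10⁻¹⁰ relative.

## Known limitations

- The adjusted estimator inherits the tail-ratio assumptions behind
  `Q1̂`; with very sparse tallies (`Q3` or `Q4` = 0) no adjustment is
  possible and the fallback silently equals Chao2 (the flag and exit
  code surface this).
- The log-normal CI attaches to whichever point estimate it is given;
  for Chao2_adj it treats `Q1̂` as known, understating uncertainty in
  the adjustment itself.
- Inclusion–exclusion on nonlinear estimates is not exactly additive;
  the clamped residual quantifies, but does not remove, the distortion.
- The KS p value for discrete data is approximate and conservative; it
  should be read as a sanity check on the log-series family, not a sharp
  test.
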