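# Methods

`periltools` estimates the *intrinsic* extinction vulnerability of
shallow-marine bivalve species — the sensitivity to perturbation implied by a
species' own traits and its clade's fossil history, as distinct from realized
external threat — and relates it to whether species are exploited by humans.
This note documents the models, the numerical conventions, the synthetic-data
generator that stands in for compiled occurrence/trait datasets, and the
limits of what the test suite demonstrates.

## The PERIL score

For species *i* with family extinction rate q̂, convex-hull geographic range
*r* (km²) and thermal range *T* (°C), the three raw components are

    q̂,   1 / ln r,   1 / T

Geographic and thermal range are inverted so that widespread, eurythermal
species score low: a range larger than the spatial reach of a perturbation,
or a wide realized thermal envelope, buffers a species against regional
environmental change. Each component is min–max rescaled to [0, 1] across
the full analyzed species set and the score is the **mean of the three
rescaled components**, keeping scores in [0, 1]. A `combine="sum"` switch
reports the raw sum (three times the mean) for users who prefer the additive
form; the ranking is identical.

Conventions that matter:

- **Rescaling context.** Components are always rescaled over the complete
  species set being analyzed; classifying any subset (e.g. only species in
  FAO production statistics) reuses the global scaling and the global score
  pool. A score is meaningful only relative to the species it was computed
  with.
- **Range floor.** Single-occurrence species take the operational
  100 km² (10 × 10 km) range; degenerate hulls (two points, collinear
  points) fall to the same floor, since a zero-area range is biologically
  meaningless and breaks 1/ln r. An `override` argument preserves
  independently known small ranges.
- **T = 0.** Species occupying a single grid cell have an undefined 1/T;
  they are assigned the largest raw 1/T observed among T > 0 species
  (maximally stenothermal) before rescaling, so they map to the top of the
  thermal-restriction axis rather than dropping out.
- **Thresholds.** "Vulnerable" means *strictly above* the linear-interpolation
  quantile (0.5 = median, 0.8 = top 20%) of the global pool or of the
  species' region pool; ties fall below. Regional membership of a species is
  the region holding the most of its occupied cells, ties broken
  alphabetically — a documented convention, since a range can span regions.

## Clade volatility (q̂)

q̂ is the per-capita extinction rate of a family's genera through the
Cenozoic, from first/last stage-level stratigraphic occurrences with the
boundary-crosser protocol: for each stage of duration Δt, with Nb genera
crossing its bottom boundary and Nbt crossing both boundaries,

    q = −ln(Nbt / Nb) / Δt.

Single-stage genera cross no boundary and are excluded from both counts —
the standard protocol, robust to within-stage sampling. Stages where every
crosser dies (Nbt = 0) have an undefined (infinite) rate and are dropped
from aggregation, with a prominent log entry. Aggregation across the
Cenozoic is the **duration-weighted mean** of defined per-stage rates,
Σ qᵢΔtᵢ / Σ Δtᵢ; a `pooled` switch divides the same numerator by the total
duration of all stages the family crosses into (including Nbt = 0 stages).
Note the stage abutting the present can never measure its own survival and
always drops out. A packaged ICS Cenozoic stage table (Danian–Holocene) is
the default; any contiguous scale is accepted. On records simulated under
time-homogeneous extinction the estimator recovers the generating rate
within ±0.02 per Myr at 1000 genera (tested; see `scripts/acceptance.py`).

## Phylogenetic signal

Three statistics on the time-scaled family tree:

- **D (binary trait, "family contains exploited species").** Nodal values of
  the 0/1 trait are estimated by a 1/branch-length-weighted average downpass;
  d_obs sums |v₁ − v₂| over bifurcations (and Σ|v_c − mean| at polytomies,
  which are preserved). D = (d_obs − mean_d_Brownian)/(mean_d_random −
  mean_d_Brownian), where the random null permutes the trait over tips and
  the Brownian null simulates a continuous trait on the tree and
  rank-thresholds it at the observed prevalence (keeping prevalence a fixed
  ancillary). By construction D calibrates to 1 under tip shuffling and 0
  under threshold-Brownian evolution; the calibration, not any particular
  nodal convention, is the contract, and is verified at 200 replicates on a
  64-tip tree (mean within ±0.1 of both anchors). p_random is the fraction
  of random-null d ≤ d_obs; p_Brownian the fraction of Brownian-null
  d ≥ d_obs.
- **Pagel's λ (continuous trait, proportion exploited).** ML over λ ∈ [0, 1],
  multiplying the off-diagonal phylogenetic covariance; mean and Brownian
  rate are profiled out analytically and the bounded scalar optimizer's
  result is compared against both boundary values. λ > 1 is not fit (it
  would require shrinking tip branches). The λ = 0 likelihood equals the
  star-tree likelihood with the same tip variances (tested to 1e-6). The
  implementation matches `phytools::phylosig` to ~1e-5 on a frozen fixture.
- **Blomberg's K** with a tip-permutation p-value (fraction of permutations
  with K ≥ observed, add-one corrected). K = 1 under Brownian motion
  (calibrated within ±0.2 on simulation means); star phylogenies are
  rejected as degenerate. Near-singular covariances from very short terminal
  branches get a 1e-8-scale ridge before failing.

## Exploitation–trait association

- Exploited/non-exploited trait distributions are compared with one- or
  two-sided two-sample Kolmogorov–Smirnov tests (asymptotic p at the
  effective sample size); the one-sided direction is always an explicit
  argument, never inferred from the data. Many species share a minimum
  bathymetry of 0 m; the ECDF convention handles ties naturally and is
  recorded in output metadata.
- Per-functional-category exploitation proportions carry exact
  Clopper–Pearson 95% intervals (beta-quantile identity).
- Regional body-size comparisons use Wilcoxon rank-sum tests: exact
  enumeration for small tie-free samples, normal approximation with
  continuity and midrank tie correction otherwise.
- The hierarchical model `exploited ~ traits + (1 | family)` is fit by
  deterministic marginal maximum likelihood: the family Gaussian intercept
  is integrated out with adaptive Gauss–Hermite quadrature (9 nodes by
  default, 1 node = Laplace) centred on each family's conditional mode,
  found by a vectorized Newton loop; the outer optimization is L-BFGS-B on
  (β, log σ) started from the unpenalized logistic fit. Continuous traits
  spanning orders of magnitude (shell size, range area, bathymetry + 1) are
  log10-transformed by default (a `none` switch exists) and all continuous
  predictors are z-standardized, so coefficients are log-odds per SD and
  comparable across traits. The fit matches `lme4::glmer` (nAGQ = 9) to
  ~1e-3 on a fixed dataset, collapses to ordinary logistic regression as
  σ → 0, flags complete separation (|β| > 15), and recovers generating
  coefficients within ±0.1 (means over 50 replicates of 5000 species in 60
  families) and a generating family SD of 1.0 within ±0.2.

## Geography

Hulls, grids and areas live in a Lambert cylindrical equal-area projection
on a spherical datum (km units); cell centroid latitude is recovered as
asin(y/R). A species occupies every 50 × 50 km cell its hull overlaps with
positive area (degenerate hulls: the cells they touch), and contributes to
every occupied cell regardless of where it is fished — maps bound the
broadest spatial impact exploitation could have. Region labels are supplied
as data (cell → region); the packaged default crosses latitudinal climate
bands (|lat| ≤ 23.44° tropical, ≤ 66.56° temperate, else polar) with a
coastline label when present. Ranges crossing the antimeridian should be
split at ±180° before projection; the synthetic grids never wrap, so this
is untested against real wrapped data.

## The synthetic-data generator

`simulate` produces every pipeline input with known ground truth. Default
conditions emulate the compiled data: ~13–17% of species exploited
(logistic intercept −2.2 with positive trait effects), 80 families with
lognormal richness, log10 range areas N(4.3, 1.0) truncated to
[100 km², 40% of the grid], shell sizes log-normal around 20 mm, 40% of
species intertidal (0 m) with exponential depths otherwise, ~10% of species
known from a single point, Cenozoic genus extinction rates lognormal with
median 0.1/Myr, and FAO-listed species a ~10% subset of exploited ones.
Exploitation is drawn from the same logistic model the `assoc` module fits
(effects: size +0.8, bathymetry −0.5, geographic range +0.5, thermal range
+0.5, attached +0.5 log-odds per SD; family SD 1.0), so parameter-recovery
tests are exact by construction.

Footprints are axis-aligned blocks of cells whose corner points' convex
hull reproduces the intended area, keeping the hull code on the hot path;
thermal range is always *derived* from the footprint and the SST field
(equator 28 °C, −0.9 °C per cell row, N(0, 0.3) noise), never drawn — and a
configurable fraction of species follows isotherms (wide range, narrow
thermal breadth), so range and thermal breadth correlate without being
redundant. `concentrate_region` builds the mapping test case: species of
top-quartile-volatility families get tenfold-smaller ranges placed on one
half of the grid. Birth–death family trees (birth 1.0, death 0.5) are
rescaled to 500 Myr depth, with terminal branches extended 2% past the
final speciation so no tip pair is exactly zero branches apart.

What the generator does **not** emulate: real coastline geometry and shelf
fragmentation, spatial sampling bias in occurrences, taxonomic error,
dispersal or niche processes, correlated functional-category structure, and
phylogenetic autocorrelation of the *trait* values themselves (traits are
drawn independently of the tree except through family membership). Passing
tests therefore demonstrate that the estimators and the pipeline are
correct and well calibrated under the stated generating processes — not
that any particular empirical dataset satisfies those processes.

## Numerical choices and degenerate inputs

- Quantiles use numpy's linear interpolation; recorded in layer metadata.
- Min–max rescaling of a constant component vector returns all zeros with a
  warning rather than dividing by zero.
- Branch lengths are floored at 1e-8 when inverted as downpass weights.
- Regions with fewer than 5 species produce thresholds flagged low-sample.
- Proportions with zero denominators are NaN, excluded from summaries.
- Rows with out-of-vocabulary categories are rejected individually (logged),
  never silently coerced; duplicated species or cell identifiers are errors.
- Missing values are empty CSV fields, never sentinels — 0 m bathymetry is
  data. Imputed bathymetries (5 m "subtidal"/"sublittoral", 10 m "shallow
  water") carry a flag so sensitivity runs can exclude them.

## Problem sizes

The calibration suite uses 1000 genera for rate recovery, 200 replicates on
64 tips for D, 100 replicates on 128 tips for λ, 50 replicates of 5000
species / 60 families for the hierarchical model, and 800–1200-species
faunas for pipeline and mapping checks — sizes at which every Monte-Carlo
acceptance band above is several standard errors wide.
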