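# Methods

This note documents the statistical models implemented in `synoptic`, the
choices made where the methodology is genuinely open, and what the synthetic
test surface does and does not establish about real data.

## Data model

The canonical table is long format: one row per (site, season), one column
per solute in mg/L. Missing concentrations propagate as nulls and are
dropped *pairwise* by each metric — different metrics therefore legitimately
use different site subsets per solute, mirroring how synoptic campaigns are
actually analyzed. Nothing is imputed. Replicate samples at one site within
a season are rejected by default; `aggregate_duplicates=True` averages them,
as an explicit caller decision rather than silent behavior.

A subwatershed area of 0 km² is legal and encodes a direct point source
(effluent outfall, field drain) sampled at the pipe. Such sites sort first
in the area ordering, where they contribute to small-scale variance; their
leverage is identically zero because leverage is area-weighted.

Category and season tokens are case-insensitive on input and canonical on
output. Concentrations are fixed in mg/L; there is no unit-conversion layer.

## Variance changepoints over area

Concentrations are z-scored (subtract mean, divide by the sample standard
deviation, n−1 denominator) over the full retained site set, then ordered by
subwatershed area (ties break by site id, deterministically). The default
scaling group pools seasons and networks — one series per solute — with
per-season and per-network restriction available, because a single
threshold-set-per-solute summary and per-tributary plots are both legitimate
framings of the same analysis.

Segments are modelled as zero-mean normal with segment-specific variance;
the mean is pinned at zero because the series is z-scored, which makes
variance the only segment parameter and the cost additive in O(1) via
prefix sums of squares:

    C(segment of length m) = m · (log 2π + log σ̂² + 1),
    σ̂² = max(mean of squared values, 1e-8).

The variance floor keeps the cost finite on constant runs. Penalties per
changepoint: BIC `β = 2 log n` (default), MBIC `β = 1.5 log n` plus a
`log(m/n)` term per segment, or any manual β. Because reasonable penalty
choices differ, the penalty actually used is always carried in the result
and printed by the CLI, and results should be reported together with it.

The minimizer is PELT with two exactness guards that are easy to get wrong:

1. **Lazy pruning.** With a minimum segment length `min_seg > 1`, a
   candidate dominated at time *t* may still be optimal for targets closer
   than `t + min_seg` (the domination argument routes through a boundary at
   *t*, which is inadmissible for those targets). Candidates are therefore
   retained for `min_seg − 1` further steps after first being dominated.
   Without this, pruning silently returns suboptimal segmentations at small
   penalties.
2. **Floor-aware pruning.** The pruning inequality relies on cost
   subadditivity, which the variance floor can locally break on
   near-constant data; candidates whose segment variance hits the floor are
   never pruned.

With these guards the pruned search is *identical* to unpruned optimal
partitioning — `brute_force_changepoints` (quadratic DP, capped at n = 40)
exists to verify exactly that, and the test suite additionally checks both
against a full enumeration of all admissible segmentations on a 12-point
series.

A reported changepoint "area" is the subwatershed area at the last index of
the upstream (left) segment; the convention is recorded in output metadata
since a boundary between two ordered sites has no unique area. `min_seg`
defaults to 2 (a variance needs two points).

## Subwatershed leverage

    leverage_conc = (C_sub − C_out) · (A_sub / A_out)      [mg/L]
    leverage_pct  = 100 · leverage_conc / C_out            [% of outlet flux]

Percent of outlet flux is the canonical reporting unit because the influence
thresholds are percentages: |pct| < 25 is low/moderate, pct > 100 highly
influential (critical source area). Thresholds are strict; boundary values
fall into the intermediate class. Negative leverage below −100% gets its own
`highly_influential_negative` class — an extension for symmetric reporting
of strong sinks, labelled as such.

Sign convention for group means: a **positive** mean implies net **removal**
within the surface-water network (tributaries carry more solute than the
outlet accounts for); a **negative** mean implies net production. The
opposite reading (positive = production) also circulates in the literature
and in figure captions; this package deliberately follows the flux-balance
reading above and does not attempt to reconcile the two — check the
`direction` column semantics before comparing with other work.

Outlet resolution defaults to the strict `"flagged"` rule (exactly one
`is_outlet` row per network and season). Valley-bottom tributaries that
discharge directly to the receiving lake never converge on a single outlet,
so leverage is undefined for them; they must be excluded upstream
(`exclude_valley_tributaries`, applied by default in `leverage_table`), and
an unflagged network fails loudly rather than guessing. `"max_area"` and
`"auto"` rules are available for tables without outlet flags; a silent
fallback from flagged to max-area is deliberately not the default because it
would mask exactly the non-convergence the exclusion rule encodes.

Leverage assumes uniform specific discharge (flux ∝ area × concentration).
The package does not compute discharge-weighted fluxes; where the
assumption made exact — conservative flux-weighted routing on subwatersheds
that partition the outlet — summed `leverage_conc` is zero to machine
precision, which the tests assert at 1e-9.

## Spatial persistence

Spearman's ρ (midranks on ties, via `scipy.stats.spearmanr`) between season
pairs, per land-use category and solute, pairing sites by id. Groups with
fewer than `min_overlap = 5` common sites are reported as null with a
reason, never silently dropped — ρ on fewer points is uninformative and
would distort range summaries. Category-level pooling across networks is
the default grouping; the key is configurable. Summaries report the mean
and range of ρ over the available pairs.

## Inferential layer

ANOVA uses Type-II sums of squares on fixed-effects linear models
(statsmodels), with an optional interaction term that requires every cell
occupied. Tukey HSD provides studentized-range-adjusted pairwise p-values.

Regression of concentration on season and land cover uses ordinary least
squares — the identity-structure special case of generalized least squares;
no correlation or variance structure is identifiable from a single synoptic
table, so none is modelled. Every subset of
{Season, forest, developed, impervious, herbaceous} is fit on the common
complete cases, ranked by

    AICc = −2 log L + 2k + 2k(k+1)/(n − k − 1),

with k the number of mean parameters (Season contributes its dummy columns).
Ties break toward fewer predictors, then lexicographically, making selection
deterministic and invariant to candidate order. Rank-deficient subsets are
skipped with a warning. Concentrations enter untransformed by default;
callers wanting log-scale regression can transform the response column
first. Note the selection-consistency caveat: AIC-family criteria retain a
scale-independent ≈15% chance of admitting any given spurious regressor, so
"exactly the true subset" is recovered only ~55–65% of the time even at
negligible noise; what is reliably recovered (≥90%, tested) is the presence
and sign of a genuinely predictive term.

## Synthetic watersheds

The generator produces the statistical structure the pipeline assumes, with
recorded ground truth:

* **Topology.** Random recursive bifurcation trees per network; leaf areas
  log-uniform; an internal node's area is exactly the sum of its children,
  so leaves partition each outlet watershed. Convergent networks (one per
  mountain/agricultural category) get one flagged outlet; valley networks
  are disjoint 2–6-site trees with no flag, so they exercise the exclusion
  rule. Land-cover fractions are Dirichlet draws around per-category
  profiles (valley networks much more developed/impervious); internal nodes
  inherit area-weighted means.
* **Concentrations.** Log-concentration = log baseline + log season factor
  + Σ(land-cover coefficients) + site effect + seasonal noise, exponentiated
  (lognormal noise: non-negative, right-skewed, like real water chemistry).
  Both random terms scale with `1/√(1 + A/A_mix)` (`A_mix` = 3 km²):
  tributary mixing averages terrestrial heterogeneity, producing the
  "funnel" variance collapse with area. Default baselines (DOC 3, TDN 0.8,
  DIN 0.5, PO4 0.05, Cl 50, SO4 40 mg/L) and a spring snowmelt maximum
  (seasonal factors 1.3/0.9/1.0) are realistic for a semiarid
  mountain-valley basin.
* **Hourglass.** When enabled (default), an extra site-level effect
  (sd 0.8 log units) applies to headwater sites (< 2 km²) and tailwater
  sites (area above 10% of the basin's largest subwatershed), re-inflating
  both ends of the area ordering. It is a *site-level* effect, not seasonal
  noise, because headwater/tailwater heterogeneity (geology, effluent,
  return flows, losing–gaining switches) is spatial and persistent;
  modelling it as temporal noise would wrongly destroy rank persistence.
  Flagged outlets are exempt: they are the flux references that every
  leverage value in their network is measured against.
* **Persistence tiers.** The site effect (sd 1.0) is reused across seasons
  in `"persistent"` mode and redrawn per season in `"scrambled"` mode.
  Seasonal noise scales per solute (conservative ions 0.4×, nutrients 1×,
  DOC/PO4 3× the base sd 0.3), producing the observed ordering: ions most
  rank-stable, reactive nutrients least.
* **Point sources.** 12% of each convergent network's sites (drawn from the
  larger, lowland half of its leaves, where effluent and drains sit)
  receive a concentration load calibrated against the realized outlet
  concentration so that a planted site's leverage is approximately
  `100 × strength × affinity` percent (default strength 3 → ≈300% for TDN
  and PO4, ≈150% for DOC, negligible for DIN/Cl/SO4 via affinity). Planting
  on positive-area leaves rather than area-0 pipe sites is deliberate: a
  zero-area site has identically zero leverage, so only subwatersheds
  *containing* sources can be critical source areas. In `"scrambled"` mode
  the planted identities are redrawn each season from all leaves —
  intermittent sources — so that mode is a genuine null for persistence.
* **Conservative routing.** Optionally, every internal node is overwritten
  with the flux-weighted mean of its children under uniform specific
  discharge; mass balance is then exact by construction and summed leaf
  leverage vanishes to rounding error.

`plant_variance_regime` overlays one or more variance boundaries on a
skeleton's area ordering for changepoint recovery tests. All generation is
deterministic under (seed, config).

### What the synthetic surface does not establish

The generator emulates marginal structure, not hydrology: no discharge time
series, no losing/gaining dynamics, no spatial autocorrelation beyond the
tree, no correlated measurement error between solutes, no in-lake
processes, and land cover is sampled rather than mapped. Passing recovery
tests therefore demonstrates that the estimators extract the structure they
target when it is present at realistic magnitudes — not that any particular
real watershed has that structure.

## Problem sizes and numerical choices

Simulation-based tests use the campaign-scale defaults: 200 sites × 3
seasons × 6 solutes; 200 replicates for changepoint recovery (n = 100,
tenfold sd contrast), 200 random series (n ≤ 30) for PELT–oracle
equivalence, 50 seeds for the critical-source fraction, 20 seeds for
persistence, 100 replicates for subset selection. Variance floor 1e-8;
leverage conservation asserted at 1e-9 absolute in mg/L; AICc ties at
exact equality break toward parsimony. The whole suite and the acceptance
script each run in well under a minute on one CPU.

## Known limitations

* The area at a changepoint is a convention (left-segment end), not an
  estimate of a physical boundary between the two adjacent sites.
* BIC/MBIC penalties are asymptotic; on short series (n < 20) manual
  penalties chosen by inspection of the penalty path are more defensible.
* Leverage requires a trusted outlet concentration; a single bad outlet
  sample biases every site in the network (consider `season_mean` first).
* The OLS layer ignores spatial nesting of sites within networks; p-values
  are anti-conservative to the extent sites share upstream area.
* Spearman persistence says nothing about magnitude stability, only ranks.
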