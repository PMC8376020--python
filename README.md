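# synoptic

Ecohydrological metrics for synoptic stream-network sampling in
human-modified, semiarid watersheds.

A synoptic campaign samples many points of a river network on a single day,
repeated across seasons. Given such a long-format site table (site,
tributary network, land-use category, subwatershed area, season, and
dissolved solute concentrations in mg/L for e.g. DOC, TDN, DIN, PO4, Cl,
SO4), `synoptic` computes the three network-scale diagnostics used to locate
and characterize solute sources:

* **Spatial variance thresholds.** Concentrations of each solute are
  z-scored, sites are ordered by subwatershed area *A*, and changes in the
  variance of the ordered series are located with an exact PELT (pruned
  exact linear time) search over a zero-mean Gaussian cost
  `m(log 2π + log σ̂² + 1)` per segment. The area at a changepoint is the
  scale where tributary mixing collapses (or human activity re-inflates)
  among-site variability. An unpruned dynamic program over all admissible
  segmentations is included as a verification oracle.
* **Subwatershed leverage.** For each site,
  `leverage = (C_sub − C_out) · (A_sub / A_out)`, expressed also as a
  percentage of outlet flux. Under uniform specific discharge this is the
  share of outlet flux attributable to the subwatershed; sites above +100%
  are highly influential critical source areas, and the network mean encodes
  net removal (positive) or production (negative) in the surface-water
  network.
* **Spatial persistence.** Spearman's ρ of site concentration ranks between
  season pairs (Spring–Summer, Summer–Fall, Spring–Fall), per land-use
  category and solute. ρ ≥ 0.7 means one synoptic snapshot already captures
  the bulk of the spatial pattern.

Around these sit the comparison layer (Type-II ANOVA with Tukey HSD post
hocs, and all-subsets OLS regression of concentration on season and land
cover selected by AICc) and a synthetic watershed generator that reproduces
the statistical structure such campaigns see — nested bifurcating networks
with additive areas, lognormal concentration noise that decays with
contributing area, planted point sources, seasonal rank persistence tiers,
and the "hourglass" variance profile of heavily modified basins — with full
ground truth, so the entire pipeline runs and is tested without any data
download.

## Worked example

```python
import synoptic as sy

cfg = sy.WatershedConfig(seed=7)            # ~200 sites, 3 seasons, 6 solutes
table, truth = sy.generate_watershed(cfg)

series = sy.order_by_area(table, "PO4")
res = sy.pelt_changepoints(series, penalty="bic")
print(res.penalty)                          # bic: 2*log(n) = 12.7939
print([round(a, 2) for a in res.changepoint_areas_km2][:5])
# [0.38, 0.38, 0.76, 0.76, 3.26]

recs = sy.leverage_table(table, solutes=["PO4"])
print((recs.influence_class == "highly_influential_positive").mean())
# 0.121

pers = sy.persistence_summary(sy.persistence_matrix(table))
print(pers.groupby("solute").mean_rho.mean().round(2))
# Cl 0.99  DIN 0.95  DOC 0.75  PO4 0.77  SO4 0.98  TDN 0.97
```

Reading the output: the PO4 variance changepoints sit at sub-10 km² areas —
point-source-dominated headwater heterogeneity that mixes away quickly —
while 12.1% of sites carry more than 100% of the outlet PO4 flux
(the generator planted sources at 12% of sites, `truth.planted_source_sites`
lists them). Conservative ions (Cl, SO4) keep almost identical spatial
rankings across seasons (ρ ≈ 0.98–0.99), whereas the reactive nutrients
(DOC, PO4) are markedly less persistent — the signature that distinguishes
geogenic from biologically processed solutes.

The same stages are available from the shell for CSV inputs:

```sh
synoptic simulate --seed 7 --out run/          # or bring your own site table
synoptic changepoints run/site_table.csv --penalty bic --out run/cp.csv
synoptic leverage run/site_table.csv --out run/lev.csv
synoptic persistence run/site_table.csv --out run/rho.csv
synoptic models run/site_table.csv --out run/models.csv
synoptic run --config config.yaml --out run/   # everything + manifest
```

Valley-bottom tributaries that drain to the lake without converging on a
single outlet are excluded from leverage automatically (the flagged-outlet
rule makes them fail loudly otherwise).

## Layout

| module                      | contents                                              |
| --------------------------- | ----------------------------------------------------- |
| `synoptic.data_io`          | site-table reading, validation, subsetting, season means |
| `synoptic.variance_scaling` | z-scoring, area ordering, PELT + exhaustive oracle    |
| `synoptic.leverage`         | leverage, influence classes, network summaries        |
| `synoptic.persistence`      | Spearman ρ matrices and summaries                     |
| `synoptic.inferential`      | ANOVA, Tukey HSD, AICc all-subsets regression         |
| `synoptic.synthetic`        | watershed generator with ground truth                 |
| `synoptic.cli`              | `synoptic` command-line pipeline                      |

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
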