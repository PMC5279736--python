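# riverpacs

Predictive bioassessment of river macroinvertebrate communities under
climate-change scenarios, in the RIVPACS / AUSRIVAS / MEDPACS tradition.

River bioassessment systems of this family classify minimally disturbed
*reference sites* into biological groups by their community composition,
learn to predict group membership from environmental predictors, and from
the two combine a *probability of capture* for every taxon at any new site.
`riverpacs` implements that machinery and uses it the other way around: the
environment of a raster of river grid cells is perturbed under
warming/flow-reduction scenarios, and the resulting changes in predicted
communities are summarized as range contractions and expansions,
elevational shifts, expected-richness declines and losses of ecological
status.  The package is aimed at freshwater ecologists and biomonitoring
practitioners who want a transparent, fully scriptable implementation of
this projection workflow, plus a synthetic-riverscape generator with known
truth for validating it.

## The model

Reference sites are clustered on Sørensen (presence/absence Bray–Curtis)
dissimilarity with average linkage into *k* biological groups.  Linear
discriminant models on standardized environmental predictors give, for any
environment **x**, the posterior membership probabilities

P(g | **x**) ∝ π_g · exp(−½ d²_g(**x**)),

where d²_g is the squared Mahalanobis distance to the group-g mean under the
pooled within-group covariance and π_g are group-size priors.  The
probability of capturing taxon *t* is the membership-weighted group
frequency

p_t(**x**) = Σ_g P(g | **x**) · f_{g,t},

with f_{g,t} the fraction of group-g reference sites containing *t*.
Expected richness at a cell counts taxa with p_t ≥ 0.5; the Ecological
Quality Ratio EQR = observed/expected richness compares each perturbed
scenario against the same cell's baseline, and is banded into the Water
Framework Directive status classes (High…Bad).  A cell whose environment is
flagged as an outlier (nearest-group Mahalanobis distance beyond the
χ² quantile at 1 − α) by at least 3 of the 5 best discriminant models, in
any scenario, is excluded from all statistics.  Scenarios add a temperature
delta to thermal predictors and multiply hydrological predictors by a flow
factor; the defaults are +1.70 °C/−10 %, +2.45 °C/−20 % and +3.30 °C/−30 %
on top of the unperturbed baseline.

Per-taxon downstream statistics: area of presence (occupied retained cells
and their percentage), percent change against baseline, area-of-presence
category (≥75 %, 50–75 %, 25–50 %, <25 %), unweighted mean altitude of
occupied cells and its shift, and a response strategy
(`reduce_up`, `reduce_down`, `expand_up`, `expand_down`, `stable`, `lost`,
`mixed`).  Community summaries include per-basin mean richness with 95 %
confidence intervals and two-way scenario × basin richness ANOVAs (type III).
The IBMWP/IASPT biotic indices (sum and mean of per-family sensitivity
scores) are available for any predicted community.

## Worked example

The `all` subcommand chains the whole pipeline on a synthetic riverscape —
2,000 grid cells over a 0–2,500 m elevation gradient in 9 basins, 40 taxa
with Gaussian-logit thermal/hydrological niches, 300 reference sites:

```bash
riverpacs all --seed 7 --out runs/demo
```

```
INFO riverpacs: built model: k=5 groups, 5 DF models (LOO acc 0.913..0.930)
INFO riverpacs.scenarios: scenario run: 2000 grids total, 1803 retained (90.2%), 197 excluded by the range rule
```

The run writes `grids.csv`, `sites.csv`, `occurrence.csv`, `model.json`,
`predictions_long.csv`, `grid_summary.csv`, the per-taxon `table2.csv`
(occupied-cell counts and percentages) and `table3.csv` (percent changes,
altitude shifts, categories, strategies), `basin_summary.csv`, `anova.csv`
and `strategy_counts.json`.  For this seed, mean retained-cell richness
falls 14.82 → 14.67 → 14.61 → 14.50 across the three scenarios, the share
of cells keeping High status falls 100 % → 95.1 % → 90.8 % → 85.3 %, and
the strategy counts are 13 taxa reducing (all moving upslope), 15 expanding,
2 stable — the cold-niche contraction and upslope drift the generator is
built to produce.  First rows of `table3.csv`:

```
taxon      ibmwp_score dif_pct_s1 dif_pct_s2 dif_pct_s3 mean_alt_s0 alt_shift_s3 ap_category strategy
taxon_000  3           32.15      44.76      61.46      556.15      207.76       3           expand_up
taxon_001  7           23.05      33.47      43.16      790.39      265.18       2           expand_up
taxon_002  10          -29.35     -40.77     -55.25     1999.50     237.33       3           reduce_up
```

The same report machinery runs directly on published per-taxon
occupied-grid tables (packaged under `src/riverpacs/data/`):

```bash
riverpacs report --table2 src/riverpacs/data/table2_paper.csv \
                 --table3 src/riverpacs/data/table3_paper.csv --out runs/report
```

which recomputes every percentage and percent-change cell from the raw
counts and writes the classification counts (47 taxa reducing, 10
enlarging, 8 stable, 4 lost; 40 moving upstream, 16 downstream) together
with `ap_discrepancies.csv`, the handful of taxa whose printed category is
inconsistent with the stated banding rule.

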