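# moultmap

Dual-isotope geographic assignment of seabird moulting grounds.

Pelagic seabirds such as storm-petrels replace their flight feathers at sea,
far from their breeding colonies, and the location of those moulting grounds
is largely invisible to direct observation. A feather grown at sea, however,
records the stable-isotope composition of the local food web: its carbon
isotope ratio (δ¹³C) tracks phytoplankton gradients — strongly latitudinal
in the Southern Ocean — and its oxygen isotope ratio (δ¹⁸O) tracks seawater
salinity and freshwater input. `moultmap` turns a table of per-bird feather
measurements (δ¹³C, δ¹⁵N, δ¹⁸O plus morphometrics) and gridded ocean
isoscapes into maps of where the birds most plausibly moulted, and scores
those maps against independent evidence.

## The method

1. **Filtering and corrections.** Birds missing δ¹³C or δ¹⁸O are dropped,
   as are flagged-species outliers with δ¹³C < −23 ‰. Feather values are
   moved onto the isoscape scales by exact shifts: δ¹³C − *L*·Δ (trophic
   enrichment Δ = 0.8 ‰ per level, *L* = 2 levels between plankton and
   storm-petrel, i.e. −1.6 ‰) and δ¹⁸O − δ<sub>water→feather</sub>
   (10.4 ‰ north, 13.0 ‰ south, estimable from known-origin feathers via
   `estimate_o18_discrimination`).
2. **Grouping.** A conditional inference tree with bivariate response
   (δ¹³C, δ¹⁸O) partitions the birds. At each node the linear statistic
   **T** = Σᵢ g(Xᵢ) h(Yᵢ)ᵀ is standardized by its permutation moments
   (Strasser–Weber) and its quadratic form referred to the asymptotic χ²
   distribution; p-values are Bonferroni-adjusted across covariates and
   splitting stops when min *p* > α (default 0.05, minimum node size 7).
   Terminal nodes are the moulting-niche groups, described further with
   Welch *t*, Pillai-trace MANOVA, ANOVA and Tukey HSD tests.
3. **Assignment.** For each bird and isotope, the probability of origin at
   ocean cell *c* is the normal density N(y; μ_c, σ_c) normalized over
   ocean cells, with σ_c² = σ²<sub>isoscape</sub> + σ²<sub>analytical</sub>
   (0.10 ‰ for δ¹³C, 0.50 ‰ for δ¹⁸O). Individual surfaces are averaged
   per group, each isotope's surface is z-scored over ocean cells, and the
   two scaled layers are summed into one combined origin score per cell.
   Combined scores are relative: they are read against quantiles of their
   own map, and maps are compared by the Jaccard index of their
   top-quantile cell sets.
4. **Validation.** Combined maps are checked against chlorophyll-a fields
   (Welch *t* between top-quantile and remaining cells), binned sighting
   locations (mean score within 1.1×10⁶ m great-circle buffers vs the
   map's 50 %/95 % quantiles), marine eco-realm polygons (per-region mean
   classified against the same quantiles), and the Southern-Ocean latitude
   relation δ¹³C = −8.52 − 0.26 × latitude (°S), valid south of the
   Subtropical Front (~44° S).

A fully seeded synthetic-data module generates isoscapes, feather records
with known true origins, chlorophyll fields, sightings and region polygons
with the statistical structure the analysis assumes, so every stage is
testable without any external download.

## Worked example

```sh
moultmap simulate   --out demo --n-per-group 30 --seed 7
moultmap preprocess demo/records.csv --out demo/corrected.csv --drop-log demo/drops.tsv
moultmap tree       demo/corrected.csv --out demo/labelled.csv --nodes-out demo/nodes.tsv
moultmap assign     demo/labelled.csv --isoscape-c demo/isoscape_c13.asc \
                    --isoscape-o demo/isoscape_o18.asc --out demo/maps
moultmap validate   demo/maps/combined_node_3.asc --chl demo/chlorophyll.asc \
                    --regions demo/regions.geojson --out demo/report.json
```

The `tree` step prints the terminal groups, here recovering the two
simulated species and a year effect within each:

```
terminal nodes: 3 (n=16), 4 (n=14), 6 (n=15), 7 (n=15)
```

with `nodes.tsv` showing the root split on species (adjusted
p ≈ 1.6×10⁻¹²) and year splits below it. `validate` reports, for the
node-3 combined map, its own quantiles and the chlorophyll contrast:

```
q50 = -0.82   q75 = 1.01   q95 = 2.23
chl_test: t = 8.74, df = 2100.2, p < 1e-17
```

i.e. cells in the top quartile of origin scores carry significantly higher
chlorophyll-a (the simulated hotspot was placed at the group's true
origin), and the per-region table classifies each synthetic eco-realm
against the map's 50 %/95 % quantiles. The same operations are available
as library functions (`moultmap.fit_cit`, `moultmap.origin_surface`,
`moultmap.combine_isotopes`, `moultmap.region_scores`, ...).

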