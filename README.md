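# betaspace

Beta-diversity partitioning and its environmental and spatial drivers, for
site-by-species incidence surveys at landscape scale (tens of sites, tens
of species) — the setting of island or fragmented-forest arthropod
inventories, and equally applicable to any presence/absence community
table.

## What it computes

For every pair of sites with `a` shared species and `b`, `c` species unique
to either site, total dissimilarity splits additively into a
species-replacement and a richness-difference component:

    β_total = (b + c)/(a + b + c)        (Jaccard dissimilarity)
    β_repl  = 2·min(b, c)/(a + b + c)    (species replacement)
    β_rich  = |b − c|/(a + b + c)        (richness difference)
    β_total = β_repl + β_rich            (exact identity)

The package then models each component's pairwise matrix:

* **Distance decay** — OLS of dissimilarity on inter-site distance (km)
  with Mantel permutation tests (exhaustive enumeration for n ≤ 7).
* **Environmental model** — standardised predictor matrix (field/soil
  variables, a correlation-matrix PCA of five collinear climate variables,
  a log-transformed landscape disturbance index), reduced by forward
  selection under the double stopping rule (global permutation gate at
  α, marginal permutation tests, adjusted-R² ceiling).
* **Spatial model** — Moran's eigenvector maps from 12 candidate spatial
  weighting schemes (MST, relative-neighbourhood, Gabriel, Delaunay graphs
  × binary, 1/d, 1 − d/d_max weights), positive-eigenvalue vectors only,
  selected by corrected AIC on a forward path.
* **Variation partitioning** — pure environmental [a], shared [b], pure
  spatial [c] and unexplained [d] adjusted-R² fractions from a series of
  constrained ordinations (CAP/db-RDA) of the dissimilarity matrix.

A synthetic-data module generates site tables and incidence matrices with
controllable environmental-niche and spatial-autocorrelation signal
(scenarios E, S, ES, N), so the full pipeline is testable against known
generating processes.

## Worked example

```python
from betaspace import (ScenarioConfig, simulate_sites, simulate_community,
                       beta_matrices, summarize_beta, RunConfig, run_all)

cfg = ScenarioConfig(scenario="ES", seed=7)   # 26 sites, 31 species, 30 km
sites = simulate_sites(cfg)
inc = simulate_community(sites, cfg)

for name, s in summarize_beta(beta_matrices(inc)).items():
    print(name, round(s["mean"], 3), round(s["sd"], 3))

report = run_all(inc, sites, RunConfig(seed=7, n_perm_selection=999,
                                       n_perm_mantel=999))
m = report["metrics"]
print(round(m["mantel_r_total"], 3), round(m["pure_spatial_repl"], 3))
```

prints

```
beta_total 0.664 0.201
beta_repl 0.387 0.249
beta_rich 0.277 0.187
0.479 0.097
```

Mean pairwise dissimilarity is 0.664 and most of it (0.387) is species
replacement rather than richness difference (0.277) — the generator's
niche and dispersal channels both reshuffle composition. Overall
dissimilarity increases with distance (Mantel r = 0.479), and after
forward selection of environmental predictors and AICc selection of a
spatial eigenvector model, a pure spatial fraction of 0.097 of the
replacement variation remains once the environment is controlled for.
The full `report` dict carries every stage's statistics (selection paths,
winning graph/weighting, decay regressions, variation fractions).

The same pipeline runs from the shell:

```sh
betaspace simulate --scenario ES --seed 7 --out-prefix sim_
betaspace partition --incidence sim_incidence.csv --out-prefix beta_
betaspace env --sites sim_sites.csv --out env.csv
betaspace mem --beta beta_repl.csv --sites sim_sites.csv --out mem.json
betaspace varpart --beta beta_repl.csv --env env.csv --spatial mem.csv
```

Real data enter as two CSVs: an incidence table (rows = sites, columns =
species, 0/1 cells) and a site table with `x,y` in km or `lon,lat` in
decimal degrees (projected internally) plus the raw environmental columns.

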