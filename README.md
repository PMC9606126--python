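# pollendiv

Calibration of pollen-based diversity against plant diversity in modern
landscapes: how well does the number of pollen types in a moss-polster sample
predict the plant species richness around it — and over what spatial scale?

`pollendiv` is a library for quantitative palaeoecologists working with
site-by-pollen-type count tables and radius-resolved floristic surveys. It
implements the full calibration pipeline:

- **Rarefaction** — every pollen sample is reduced to a common grain sum
  (default 943 grains) by random selection without replacement (a
  multivariate hypergeometric draw), repeated 100 times; the median taxon
  count is the sample's richness.
- **Pollen-productivity correction** — counts are divided by relative pollen
  productivity estimates (PPEs) to demote over-producing taxa, then resampled
  to 520 grains.
- **Total-variance beta diversity** — for a presence/absence table Y with
  Jaccard dissimilarities D (square-root transformed by default),

      SS_total = (1/n) Σ_{i<j} D_ij²,   BD_Total = SS_total / (n − 1),
      LCBD_i   = SS_i / SS_total,

  where SS_i is the diagonal of the Gower-centred matrix of −½D∘D. BD_Total
  is a variance per degree of freedom, comparable across different numbers of
  sites; LCBD significance comes from within-taxon column permutations.
- **Source-area estimation** — pollen diversity (richness, BD_Total or LCBD)
  is regressed by OLS against the matching plant diversity evaluated at each
  radius r of a grid from 0.5 to 1000 m; the radius with the highest adjusted
  R² (adj R² = 1 − (1 − R²)(n − 1)/(n − 2)) is the estimated source area.
- **Synthetic landscapes** — a generator with planted ground truth (species
  pools, habitat mosaics, an exponential dispersal kernel with closed-form
  effective source radius, many-to-one pollen taxonomy, PPEs, long-distance
  background, canopy interception) so the whole pipeline is testable without
  any field data.

## Worked example

```python
from pollendiv import partition_datasets, rarefy_dataset, report_mean_richness
from pollendiv.synthetic_data import simulate_study

pollen, survey, ppe, truth = simulate_study("two-region", seed=1)
partition = partition_datasets(pollen)
result = rarefy_dataset(pollen, depth=943, n_reps=100, rng_seed=1)
print(report_mean_richness(result.as_mapping(), partition))
```

prints (abridged) the mean rarefied richness of the four region/habitat
subsets:

```
region_poor_forest  33.8    region_poor_open  38.0
region_rich_forest  54.3    region_rich_open  63.6
```

Forest samples detect fewer pollen types than open-habitat samples because a
few high-productivity canopy trees monopolise their pollen rain, and the
species-poor region sits below the species-rich one — the rank order follows
the underlying species pools. The scripts in `examples/` walk through each
capability (rarefaction, PPE adjustment, BD_Total/LCBD, source-area
scanning, the full pipeline) and print what the numbers mean.

A thin CLI mirrors the library:

```sh
pollendiv simulate --preset two-region --seed 1 --outdir fixtures/
pollendiv rarefy --counts fixtures/pollen.csv --depth 943 --reps 100 --seed 1 --out richness.csv
pollendiv run --config run.yaml
```

File contracts are plain CSV/TSV: wide pollen counts
(`site_id, region, habitat, <taxa...>`), long plant surveys
(`site_id, species, first_distance_m, habitat`), two-column PPE tables.

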