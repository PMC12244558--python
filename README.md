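# stacksdm

Stacked species distribution modelling (SSDM) for assemblage-level
diversity mapping, built around a fully synthetic, truth-known
benchmark.

## The problem

Regional biodiversity compilations — for example basin-wide censuses of
benthic foraminifera — provide presence-only occurrence records for
hundreds of species plus gridded environmental layers. The question
those data are asked to answer is assemblage-level: where is species
richness concentrated, how does it follow environmental gradients, and
which environmental axes structure the fauna?

The standard approach models each species individually (a species
distribution model, SDM, per species), binarises each prediction, and
*stacks* the binary maps into a richness surface. Every step hides
methodological choices — pseudo-absence design, algorithm choice,
thresholding rule, ensemble weighting — whose effects are invisible on
real data because the truth is unknown. `stacksdm` implements the full
workflow *and* a virtual-species generator with known niches, occupancy
and richness, so every stage is validated against ground truth.

## What is implemented

| Module | Contents |
| --- | --- |
| `envgrid` | north-up grid geometry, layer stacks, bilinear resampling, cropping, collinearity screening |
| `raster_io` | ESRI ASCII grid (`.asc`) + YAML manifest read/write |
| `occurrences` | cleaning cascade, spatial thinning, rare-species filter, stratified pseudo-absences, composition summaries |
| `sdm_fit` | algorithm adapters (CTA, RF, GBM, SVM, GLM, ANN), confusion metrics, rank AUC, TSS thresholding, stratified CV, permutation importance |
| `ensemble` | weighted per-species ensembles, algorithm-combination search |
| `stack` | binary stacking to richness, uncertainty and weighted-endemism maps, community-level evaluation |
| `spatial_diversity` | regional ANOVA + Tukey HSD, richness gradients, Moran's I under rook weights |
| `niche_clusters` | PCA + Ward clustering of importance profiles (HCPC idiom) |
| `synthetic_data` | virtual landscapes, Gaussian-niche virtual species, presence-only sampling |
| `pipeline`, `cli` | configuration, stage orchestration, `stacksdm` command line |
| `datasets` | synthetic species-level census matching published Arabian Gulf foraminifera tallies |

Method details and parameter rationale are in
[docs/methods.md](docs/methods.md).

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
synthetic scenario (all artifacts land under `results/`):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_preprocess.py
python analysis/03_fit_stack.py --seed 1
python analysis/04_diversity_stats.py --seed 1
python analysis/05_importance_clusters.py
python analysis/06_census_composition.py
```

Output of that exact sequence:

```text
scenario written to results/scenario
  species: 20
  occurrence records: 1170
  layers: 15
records in: 1170, retained: 1170
species retained: 20
layers retained (15/15): bathymetry, sst_mean, sst_min, sst_max, bottom_temp_mean, salinity, chlorophyll_a, dissolved_oxygen, iron, silicate, phosphate, nitrate, ph, calcite, light_attenuation
fitted 20 species x 3 algorithms
mean CV AUC: 0.966, mean CV TSS: 0.914
richness range: 0..9
community prediction success: 84.2% over 1089 sites
latitude gradient: beta = +0.30 species/degree (R^2 = 0.011, p = 6.28e-22)
longitude gradient: beta = -1.01 species/degree (R^2 = 0.121, p = 4.09e-247)
Moran's I = 0.8958 (E[I] = -0.00042, z = 61.6)
band ANOVA: F(2,8772) = 143.3, p = 5.76e-62
PCA: 5 components retained (60.8% of variance)
clusters: k = 6
```

The same workflow is available as one command
(`stacksdm all --seed 1 --outdir results/run`) and as a library call
(`stacksdm.pipeline.run_pipeline(RunConfig(...))`).

The census composition summary reproduces the published shares of the
492-species compilation it encodes:

```text
census: 492 species

by order:
  Rotaliida         270   54.9%
  Miliolida         142   28.9%
  Lituolida          32    6.5%
  Textulariida       22    4.5%
  Nodosariida        11    2.2%
  Polymorphinida     11    2.2%
  Spirillinida        2    0.4%
  Astrorhizida        1    0.2%
  Robertinida         1    0.2%

by wall_type:
  hyaline           288   58.5%
  porcelaneous      142   28.9%
  agglutinated       62   12.6%
```

## Layout

```
src/stacksdm/       library modules
analysis/           numbered study scripts (simulate -> ... -> composition)
scripts/            acceptance.py (headline-quantity report)
tests/              unit + acceptance tests
docs/methods.md     modelling choices and rationale
```
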