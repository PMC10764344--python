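# urbanocc

Drivers of arthropod biodiversity in an urban ecosystem: a tested,
end-to-end pipeline for multi-species occupancy analysis of city-wide
Malaise-trap monitoring data.

Urban landscapes like the Greater Los Angeles Area stack steep gradients —
coast to mountains, dense development to protected chaparral, poor to
wealthy neighborhoods — into short distances, and arthropod communities
respond to all of them at once. This package implements the full analysis
chain needed to disentangle those drivers from detection/non-detection
data collected at backyard trap sites:

1. **Microclimate QC** (`urbanocc.microclimate`): a fixed-order cleaning
   sequence for 5-minute environmental logger streams — unit
   harmonization, physical range filters (temperature outside (−5, 50) °C,
   RH outside [0, 100] %), exclusion of broken-logger runs (> 60 °C),
   hourly Tmin/Tmax with a >10 % missing-slot rule, removal of hours
   missing at > 25 % of sites, and inverse-distance-weighted gap filling
   (3 nearest sites, power 1) — summarized per site as BIO1 (mean annual
   temperature), BIO2 (mean diurnal range) and mean RH.
2. **Covariate construction** (`urbanocc.covariates`): CPI-adjusted
   per-area residential land value and impervious surface averaged in
   0.25/0.5 km buffers, elevation, slope-weighted cost distance to the
   ocean (Dijkstra on the 8-connected grid), distance to protected areas
   ≥ 10 ha, and z-score standardization with persisted parameters.
3. **Causal model selection** (`urbanocc.causal`): per-group directed
   acyclic graphs over the covariates and occupancy, d-separation and
   implied-independency tests against data (partial correlations), and
   minimal backdoor adjustment sets that define a catalog of 37 occupancy
   model specifications (6 groups × 6 exposures + an RH model for
   Phoridae).
4. **Hierarchical occupancy fitting** (`urbanocc.occupancy`): the
   multi-species occupancy model below, fit by latent-state MCMC, with
   split-chain Gelman–Rubin diagnostics, effect summaries and
   marginal-effect curves.
5. **Richness interpolation** (`urbanocc.interpolation`): the
   all-covariate model projected over a 1-km grid (site-based
   standardization, re-centered climate bands, 3-SD clipping, contagious
   masking) and stacked into per-group and total richness maps from
   per-species posterior-median occupancies.
6. **Synthetic study system** (`urbanocc.synthetic`): a generator that
   emulates the monitoring design — 60 sites, six taxonomic groups
   (108/34/20/27/23/24 species), 12 monthly surveys, DAG-consistent
   landscape covariates, and corrupted logger streams — with known ground
   truth, so every stage is testable without restricted field data.

## The model

For species *i* at site *j* with standardized covariates *x*:

```
z_ij ~ Bernoulli(ψ_ij),        logit(ψ_ij) = ψ0 + a_i + Σ_t b_it x_jt
y_ijk ~ Bernoulli(z_ij p_ik),  logit(p_ik) = p0 + p_m2 · month²_k + c_i
```

with species effects drawn from group-level normals: `a_i ~ N(0, σ_a²)`,
`b_it ~ N(μ_t, σ_t²)`, `c_i ~ N(0, σ_c²)`. The month covariate is centered
and scaled before squaring, so a negative `p_m2` encodes a mid-year
detection peak. Which slopes `b_it` enter a given fit is decided by the
backdoor criterion on the group's DAG: each catalog model estimates one
exposure's marginal (deconfounded) effect `μ_t` on occupancy.

Fitting uses data augmentation: the latent presence `z` has a closed-form
Bernoulli conditional, group means and hierarchical SDs are Gibbs-updated,
remaining parameters use adaptive random-walk Metropolis, and joint
(effects, SD) scale moves handle the hierarchical funnel. Chains are
deterministic given a seed.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on the
synthetic study system (scaled-down group sizes, 60 sites):

```
python analysis/01_simulate.py
python analysis/02_clean_microclimate.py
python analysis/03_causal_catalog.py
python analysis/04_fit_occupancy.py
python analysis/05_interpolate_richness.py
```

Step 02 prints the QC ledger — every record is accounted for by a rule:

```
input records: 1028366; duplicates removed: 206; Fahrenheit converted: 197064
range filter removed 8385 temperature and 114 humidity records
site exclusions removed 288 records from ['S50']
60 sites summarized; max |BIO1 - true t_mean| = 0.277 C, ...
```

Step 04 fits the catalog models and summarizes group-level effects; the
star marks a 95 % credible interval excluding zero (here the generating
community mean for distance-to-ocean was 0, and species-level variation
produces the group spread):

```
group-level distance-to-ocean effects (mean [95% CI], * = CI excludes 0):
  Phoridae       -0.335 [-0.499, -0.175] *
  Syrphidae      -0.123 [-0.499, +0.256]
  Tipuloidea     +0.111 [-0.545, +0.732]
  ...
```

Step 05 writes ASCII-grid richness maps (plus PNG quick-looks) and checks
them against the generating truth:

```
prediction grid: 596 of 625 cells valid after 3-SD clipping and contagious masking
total richness: fitted range [14.5, 48.3] expected species out of 60 modelled
Spearman rho between fitted and generating-truth richness: 0.983 over 596 cells
```

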