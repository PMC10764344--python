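# Methods

This note documents the models, defaults and design choices behind
`urbanocc`, in the order the pipeline runs them.

## Synthetic study system

The generator emulates a city-wide Malaise-trap monitoring network: 60
residential sites sampled one week per month over one year, six taxonomic
groups with 108/34/20/27/23/24 species (total 236), paired 5-minute
environmental loggers, and landscape covariates shaped by the same causal
structure the analysis assumes.

**Landscape.** Covariates are generated on a regular km grid as a linear
structural equation model (SEM) over the covariate DAG: each node is the
coefficient-weighted sum of its parents plus spatially smoothed Gaussian
noise (unit SD on the latent scale; Gaussian smoothing with a 3-cell
kernel), and root nodes carry weak deterministic trends (elevation rises
northward, ocean distance eastward) scaled by the noise SD, so that
setting the noise to zero collapses every covariate to its intercept.
Latent fields map monotonically into physical units (logistic squashes
for percentages, log-normal for land value and distance to natural
areas), preserving the sign of every SEM edge. Default edge coefficients
(±0.25–0.6) produce moderate confounding (|r| ≈ 0.3–0.6 between connected
covariates), large enough that backdoor adjustment visibly matters in the
recovery experiments. Sites are grid cells sampled without replacement.

**Community and detections.** Species slopes are drawn from group-level
normals `b_it ~ N(μ_t, σ_t²)` with defaults σ_t = 0.3 and community means
of modest size (e.g. −0.4 for diurnal range, −0.2 for land value and
distance to natural areas, 0 for distance to ocean); species occupancy
intercepts use σ_a = 0.75 and detection effects σ_c = 0.4 around a
detection intercept of 0 (mean p ≈ 0.5) with a month-squared coefficient
of −0.4 (mid-year detection peak). Latent presence and monthly detections
are Bernoulli draws from the model; missing visits are
missing-completely-at-random at a configurable rate (default 0 — the
design aims for complete monthly coverage), with at least one surveyed
visit retained per site.

**Logger streams.** Per-site air temperature follows a sinusoidal diurnal
cycle around the site mean with amplitude half the site's diurnal range
(mid-afternoon peak) plus 0.03 °C instrument noise (logger-resolution
scale, so annual summaries are dominated by the diurnal signal); RH swings
in antiphase with a 5 % amplitude. Injected artifacts — each exercising
one cleaning rule — are whole-site Fahrenheit recordings (25 % of sites),
out-of-range spikes (2×10⁻⁴ per record), duplicated rows, 6-hour missing
blocks, and one site with a 30-day run near 65 °C emulating a failed
logger.

What the generator does *not* emulate: real Los Angeles geography, the
multi-phase 2014–2018 sampling design (a single exchangeable year is
assumed), spatial autocorrelation in occupancy beyond what the covariates
induce, species interactions, and non-random visit missingness. Passing
tests therefore demonstrate the *machinery* recovers known truth under
the stated design, not that the field estimates themselves are
reproduced: real detection data for systems like this is typically
restricted, which is why the generator exists.

## Microclimate QC

The cleaning order is fixed and each step reports removed+retained counts
that must reconcile to its input:

1. De-duplicate on (site, timestamp, variable), keep first; convert °F to
   °C.
2. Keep air temperature and relative humidity only.
3. Range filters as strict inequalities: remove temperature < −5 °C or > 50 °C, RH < 0 or > 100 %.
4. Site/variable/interval exclusions. Rather than hard-coding one known
   bad logger, a detector flags any site whose month contains more than
   12 readings above 60 °C (one hour's worth — distinguishing a broken
   sensor from isolated spikes, which step 3 already removes) and
   excludes the whole span of flagged months.
5. Hourly Tmin/Tmax and mean RH from the 12 expected 5-minute slots; an
   hour is missing when more than 10 % of slots are absent (i.e. at 12
   slots, 2 or more missing).
6. A date-time × variable is removed for *all* sites when more than 25 %
   of sites are missing it.
7. Remaining gaps are filled by inverse-distance weighting over the three
   nearest sites with valid values that hour (weights 1/d, Euclidean
   distance in projected km coordinates, nearest-neighbor ties broken by
   site id; fewer donors are used if fewer exist, none leaves the gap
   with a warning). Fills are convex combinations of donor values.
8. BIO1 is the mean of hourly (Tmin+Tmax)/2 midpoints — the natural
   estimate from hourly extremes; a `daily_extremes` alternative
   ((daily max + daily min)/2 over complete days) sits behind a switch
   since either reading of the definition is defensible. BIO2 is the mean
   over complete days (all 24 hours present, which drops partial
   first/last days) of daily max(Tmax) − min(Tmin).

## Covariates

Land value: residential parcels only, values scaled by CPI_now/CPI_year,
divided by parcel area, and filtered below a threshold (default: the 1st
percentile, making "unreasonably low" explicit). Buffer membership is by
parcel centroid (order-independent and simple); buffer radii are 0.25 km
for the poor dispersers (Phoridae, Araneae) and 0.5 km for the rest.
Cost distance to the ocean accumulates over the 8-connected grid with
step cost = step length × mean endpoint cost and cost surface 1 + slope,
so flat terrain still accrues distance; the uniform-cost limit reduces to
plain grid distance, and the implementation (scipy sparse-graph Dijkstra)
is checked against an independent shortest-path oracle. Distance to
natural areas drops protected polygons under 10 ha and measures Euclidean
distance to the nearest retained boundary (0 inside). Standardization
optionally log-transforms (default: land value only, for its heavy right
tail) then z-scores with *site* means/SDs, which are persisted and reused
verbatim on prediction grids.

All geometry lives in a projected metric CRS with km units; rasters are
plain-text ASCII grids (values printed at full float64 precision, so
round trips are bitwise) handled by a small in-package container, with
shapely for polygon work.

## Causal analysis

Each group's DAG covers the seven occupancy covariates (plus RH for
Phoridae) and the occupancy outcome. The shipped defaults encode the
urban-gradient story — elevation and ocean proximity drive land value and
development, natural areas sit in high terrain, inland cells swing harder
diurnally, humidity responds to temperature, marine influence, terrain
and development — and are constructed so that each exposure's *unique
minimal* backdoor set equals the adjustment covariates of the
corresponding single-exposure model form (e.g. distance-to-natural-areas
adjusts for elevation; the joint impervious/land-value model adjusts for
elevation, ocean distance and natural-area distance). DAGs are
user-replaceable via DOT or edge-list CSV.

d-separation uses networkx's standard implementation; implied
independencies enumerate all minimal separating sets per non-adjacent
pair (exponential search, fine at ≤ 9 nodes); consistency testing uses
linear-Gaussian partial correlation (pingouin) at α = 0.05. Note the
partial-correlation test assumes exchangeable rows: on spatially
autocorrelated site covariates it runs anti-conservative, which the
analysis script demonstrates by contrast with iid SEM draws. Backdoor
search enumerates subsets of non-descendants and tests d-separation in
the graph with the exposure's out-edges removed, returning minimal sets.

The catalog holds one entry per group × exposure. The impervious-surface
and land-value entries share a single joint fit (they appear in one model
form together) but are counted as two catalog rows, one per exposure of
interest: 6 groups × 6 exposures + 1 Phoridae RH model = 37. An all-covariate "Model All" per
group exists outside the catalog for prediction.

## Occupancy model and sampler

The model is as in the README; two reading choices deserve note. The
month covariate is calendar month centered at 6.5, scaled by the SD of
1..12, then squared — a visit-level covariate, encoding the assumed
mid-year detection peak. "Flat, uninformative priors" are realized as
proper but weak choices on the standardized scale: N(0, 10²) on location
parameters and Uniform(0, 10) on SDs, both config-visible constants.

The sampler is Metropolis-within-Gibbs with latent-z augmentation:

- `z_ij` Gibbs from its Bernoulli conditional (forced to 1 where the
  species was detected);
- species intercepts/slopes and detection effects by vectorized
  random-walk Metropolis, one block per parameter vector, with step sizes
  initialized from rough Fisher-information heuristics and adapted toward
  35 % acceptance every 100 burn-in iterations (frozen afterwards, so
  chains are reproducible from the seed);
- group means `μ_t` and the global/species intercept *splits*
  (ψ0 vs mean a, p0 vs mean c, which the likelihood cannot separate) by
  exact Gibbs draws;
- hierarchical SDs by Gibbs from truncated inverse-gamma conditionals
  (floored at 10⁻³ to keep precisions finite when data pin an SD at 0);
- joint (effects, SD) scale moves — multiply a random-effect vector and
  its SD by a common log-normal factor; after the prior cancels against
  the Jacobian the acceptance ratio is the likelihood change plus log k —
  which walk the hierarchical funnel that plain random-walk updates mix
  through too slowly (visible as R-hat > 1.1 on σ_c before this move was
  added).

Default settings are 100 000 iterations, 1 000 burn-in, thinning 100 and
3 chains (2 970 retained draws). Tests and the acceptance experiment use
5 000/500/10 × 3, which the recovery experiment shows is enough for
R-hat < 1.1 on every parameter at the 60 × 30 × 12 design. The marginal
likelihood (latent state summed out) is implemented separately and
checked against exhaustive latent enumeration to 10⁻¹⁰; the sampler
itself is validated against a fine-grid numerical posterior on a tiny
intercept-only model and by rank-uniformity calibration across 50 seeded
replicates.

Split-chain R-hat is computed per scalar parameter; convergence reports
flag R-hat ≥ 1.1. Summaries are posterior means with equal-tailed 95 %
intervals (linear-interpolation quantiles); a slope is starred when its
interval excludes zero. Marginal-effect curves evaluate ψ along one
standardized predictor with the others at 0 (their mean), using
posterior-mean coefficients, and carry each species' significance class.

## Interpolation

Prediction bands are standardized with the stored *site* parameters;
gridded climate bands are first re-centered by the additive difference
between site-logger means and the grid values at the site cells (assuming
the gridded climatology scales linearly with site-level differences).
Standardized values strictly beyond 3 SDs become missing — the boundary
value 3.0 is retained — and a cell missing any band is masked in every
output (contagious, idempotent masking). Richness is the per-cell sum of
each species' *posterior median* ψ (median over draws, per species — not
a median across species), accumulated by group and in total; it is an
expected species count bounded by the species total. Elevation stays in
the prediction model since the all-covariate model contains it.

## Numerical choices and limitations

- Strict inequalities everywhere a threshold is worded "less/more than";
  boundary conventions are asserted in tests.
- Species order is fixed by sorted name; IDW and nearest-neighbor ties
  break by site id; all stochastic code takes numpy `Generator` seeds and
  identical seeds give byte-identical outputs.
- Scaled-down problem sizes in tests and scripts (e.g. 20–30 species,
  4 000–5 000 iterations, 25×25 km grids) were chosen so the full suite
  and the acceptance run complete in minutes on one CPU while keeping
  every qualitative behaviour of the full-size design; the package
  defaults remain the full-size settings above.
- The cost-distance surface (1 + slope) is one reasonable mapping; GIS
  cost-distance tools differ in their exact cost scaling, so only the
  uniform-cost limit and oracle equivalence are asserted.
- No temporal occupancy dynamics, no spatial random fields, no model
  averaging — single-season, spatially independent sites by design.
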