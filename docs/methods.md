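# Methods

This note records the models, conventions and numerical choices behind
`nhbd-lab`, and what the synthetic validation does and does not show.

## Coordinate and grid conventions

All coordinates are planar meters, x east, y north. Grids are addressed
`(row, col)` with row 0 at the bottom; values sit at cell centers, so
cell `(r, c)` of a grid with origin `(x0, y0)` and resolution `res` is
centered at `(x0 + (c + 0.5)·res, y0 + (r + 0.5)·res)`. No CRS handling
is attempted: inputs are assumed already projected. Rasters are written
as multi-band TIFF with the grid metadata (band names, resolution,
origin, row order) in the image description tag; study areas as GeoJSON
in the same planar coordinates.

## Synthetic landscapes

Each band is a stationary Gaussian random field built by smoothing white
noise with a Gaussian kernel and rescaling to the configured marginal
mean/sd. `autocorr_range_m` is the *practical variogram range*: the lag
at which the semivariogram reaches ≈95% of its sill. For a Gaussian
smoother of width σ the spatial correlation is `exp(−d²/4σ²)`, which
drops to 0.05 at `d = 2σ√(ln 20)`; σ is set accordingly
(`σ = range / (2√(ln 20))`). `range = 0` gives white noise. Smoothing
uses wrapped boundaries so the field stays stationary to the edge.

The six land-cover fractions are compositional: six independent fields
enter a softmax whose offsets are the log target shares, so per-cell
fractions close to 1 exactly. Default shares emulate a boreal,
forest-dominated mosaic (forest 0.60, mire 0.10, mountain 0.10, water
0.08, agricultural 0.07, human-dominated 0.05). Bounded bands
(densities ≥ 0, bear index in [0, 1]) are clipped to their support;
default sds are small relative to means so clipping is rare and the
configured marginals are effectively preserved.

## Disperser populations and the NHBD ground truth

Natal centers are uniform over the study area. Each disperser draws a
dispersal distance from a configurable kernel (default log-normal,
median 50 km, log-sd 1, which populates all three distance categories)
and a uniform direction, then chooses among `n_candidate_sites`
(default 20) candidate sites placed **on the arc at exactly the drawn
distance**, with angular scatter of roughly 1.5 territory radii of arc
length (floor 0.5 rad, capped at π). Keeping candidates equidistant
from the natal center makes the settled dispersal distance follow the
kernel by construction; the angular scatter makes alternatives differ
in territory-scale habitat. Settlement probability is
`∝ exp(nhbd_strength × similarity)`, where similarity is the negative
Euclidean distance between standardized *territory-scale* habitat
features — per-band disc means over the 1000 km² territory radius —
divided by √n_bands, so one unit is about one per-band sd. Preference
therefore operates at the spatial scale a territory occupies, the same
scale the feature-extraction stage measures; `nhbd_strength = 0` is
settlement indifferent to natal habitat. Settled territories are
registered under the establishment year (uniform over 1998–2012 by
default); dispersers with no in-area candidate after bounded retries
are dropped with a logged warning.

Reference trajectories are correlated random walks: i.i.d. step lengths
(default log-normal, median 2 km, log-sd 0.75) and von Mises turning
angles (default concentration 2). The default pool of 13 trajectories
matches one profile per reference animal. These tracks carry no GPS
error, no habitat response and no behavioral phases; they exist to
donate realistic step/turn distributions to the availability stage.

## Feature extraction

Land-cover percentages use a 3×3 moving window over the dominant-class
grid (argmax of the fraction bands); windows shrink at edges so
percentages always close to 100. Slope is the arctangent of the
central-difference gradient magnitude; roughness is max − min elevation
over a 3×3 neighborhood (window size exposed; the 3×3 "cell plus 8
neighbors" definition is the default). Territory features are means
over cells whose centers fall in the circle of radius
`r = √(A/π)` ≈ 17 841 m for the default 1000 km² territory; partial
raster coverage is allowed and recorded, a circle fully off-grid is an
error. Wolf-pair density is the *count* of same-year registry centers
within 40 km inclusive (a density proxy — the area is constant across
matched records), excluding the focal disperser's own natal and
established territories; the establishment year is used for all 13
records of a disperser. Distance categories use
[0, 40 km) / [40, 200 km] / (200 km, ∞). All layers are computed at the
single landscape resolution; the multi-resolution sources of real GIS
stacks are out of scope.

## Availability

**Conditioned CRWs.** A free walk is resampled (with replacement) from
one reference profile's step lengths and turning angles, then rigidly
translated, rotated and uniformly scaled so its endpoints hit the natal
and established centers. A similarity transform preserves the entire
turning-angle sequence and all step-length ratios, so the walk keeps
the donor's movement signature; endpoint error is < 1e-6 m by
construction. A degenerate free walk (coincident endpoints) is
resimulated. One availability point is drawn uniformly among the
*admissible interior vertices* of each walk (arc-length sampling is
available behind a flag); 11 points come from 11 distinct profiles
chosen without replacement from the pool, with up to 20 resimulations
per profile before an unused profile is substituted. Admissible means:
inside the study area, at least one exclusion radius (default: one
territory radius) from every same-year registered pair, and at least
that far from the focal natal and established centers.

**Buffers.** 11 points rejection-sampled uniformly from the
intersection of the straight natal–established segment's buffer with
the study area, subject to the same admissibility; radii from 25 to
300 km are swept as a sensitivity axis. Sampling fails loudly if the
acceptance rate collapses.

## Similarity

Feature vectors of all natal, available and established records are
pooled, standardized once (mean 0, sd 1 per column), and the
establishment year appended as a continuous column. PCA retains 5
components (component signs fixed by making each component's
largest-magnitude loading positive). Clustering methods: k-means with
25 seeded restarts; k-medoids seeded with random medoids and refined by
alternating (Voronoi) iterations on the precomputed distance matrix — a
scalable variant of classic medoid partitioning; Ward hierarchical
clustering cut at k. k defaults to 6 and sweeps 4–10. The NHBD
indicator of a record is 1 iff its cluster equals its disperser's natal
cluster, which makes it invariant to cluster relabeling. The continuous
alternative is the Euclidean distance to the natal record in PC space
(larger = less similar); when used as the model covariate its
coefficients are reported ×100 for readability. No "optimal k" is
selected — k is a sensitivity dimension, not an estimand.

## Conditional logistic regression

The matched likelihood `∏ exp(x_case·β)/Σ_j exp(x_j·β)` is maximized by
Newton–Raphson with the exact score and observed information,
step-halving to keep the log-likelihood monotone, convergence when the
largest score component is below 1e-8, and at most 100 iterations. Wald
SEs come from the inverse information; 95% intervals are β ± 1.96 SE.
Strata must have exactly one used record. Covariates constant within
every stratum, and covariates linearly dependent after within-stratum
centering (e.g. a full set of compositional percentages), cancel from
or alias the likelihood and are rejected by name (the model suite drops
them with a log instead). Quasi-complete separation drives a
coefficient toward ±∞ along a flattening likelihood; any fit whose
largest |β| exceeds 15 is flagged as separated, marked non-converged
and reports no intervals — genuine effects on this package's covariate
scales are an order of magnitude smaller.

The correlation screen iteratively removes, from each pair with
|Pearson r| above 0.6, the member ranked lower on an explicit
keep-priority list (defaulting to the model-variable set: forest,
water, mountain percentages, main-road density, bear index, slope,
human accessibility, moose harvest, human density, wolf-pair density);
unlisted variables rank below all listed ones. The pipeline fits
models on the screened variables restricted to that declared model set,
which both mirrors the reference model specification and avoids the
exact collinearity of the six land-cover percentages.

The model suite fits each sex × distance-category cell, each category
over both sexes (sex is stratum-constant, so those fits are legitimate
and better powered), and one pooled model with `NHBD × wolf density`
and `NHBD × sex` (F = 1, M = 0) interactions; cells with < 2 strata or
impossible designs are skipped with a logged reason. Significance is
flagged at p < 0.05.

## Pipeline, determinism, artifacts

One master seed drives everything: child seeds are spawned
deterministically per stage (landscape, trajectories, population,
availability, clustering), so a rerun is bit-identical — including the
CSV artifacts, which are written with `%.17g` floats and re-read with
round-trip parsing precisely so that the staged CLI workflow reproduces
the in-memory one exactly. Every CSV carries the config hash and seed
in a `#` header comment. Stage failures abort with the stage name;
per-disperser availability failures and skipped model cells are logged,
not fatal.

## Validation: what is measured, at what size

The test suite and `scripts/acceptance.py` compute, from scratch:

* likelihood identity against direct evaluation on ~60 random toy
  strata (tolerance 1e-12) and the Newton MLE against a grid-search
  maximizer (|Δβ| < 1e-3);
* the exact 1/12 per-stratum case probability and `n·log(1/12)`
  log-likelihood at β = 0;
* type-I error of the NHBD Wald test over 500 datasets of 100 strata
  simulated from the matched design with β_NHBD = 0 (model-level
  simulation; the acceptance band is 3–8% at α = 0.05);
* recovery of β_NHBD = 1 over 100 replicates of 200 strata (mean β̂ and
  empirical 95% CI coverage);
* end-to-end power: 150×150 km landscape at 1 km resolution,
  autocorrelation range 20 km, 140 dispersers, log-normal dispersal
  kernel (median 25 km, log-sd 0.8) and `nhbd_strength = 4` — a
  strong-preference regime in which the short-disperser cell should
  show β̂ > 0 at p < 0.05 in the large majority of replicate seeds
  (50 seeds in the test, 25 in the script);
* the buffer-size trend: Spearman ρ of β̂_NHBD against radius
  {25, 100, 300} km averaged over replicate seeds (20 in the test, 10
  in the script), expected positive;
* conditioned-CRW invariants over 500–1000 walks and the sampling
  uniformity χ²;
* the geometry closed forms (territory radius for 1000 km², slope of a
  1-in-25 plane ≈ 2.291°, roughness of the 1–9 grid = 8 m).

These sizes are deliberately desk-scale; they are the package's
validation conditions, not estimates of any field system.

## What passing does not show

The generator's habitat fields are stationary Gaussian surrogates: real
land-cover mosaics have sharp boundaries, anisotropy and long-range
gradients that can make clustering either easier or harder than here.
Reference trajectories lack behavioral structure, so CRW availability
is "right" by construction in a way real GPS-informed CRWs are not.
The settlement model is the same family the estimator assumes (softmax
in habitat similarity), so parameter recovery demonstrates internal
consistency of the inference chain, not robustness to model
misspecification. Finally, the availability-proximity confound — natal
-like habitat is more available near home — is present and visible
(short vs. medium/long contrasts), but no correction for it is
attempted beyond the matched design itself.

## Known limitations

* Endpoint conditioning by translate–rotate–scale changes absolute step
  lengths for walks whose free chord differs from the natal–established
  distance; for very short dispersal the scaled walks hug the endpoint
  keep-out discs and a minority of dispersers can fail availability and
  drop out (logged).
* k-medoids uses alternating iterations, not the full swap search;
  with 5 restarts it can settle in a local optimum of the medoid cost.
* Wald inference only; no profile-likelihood or exact conditional
  intervals for near-separated cells.
* The wolf-pair registry holds settlement-year snapshots only; no
  territory turnover or persistence model.
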