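# nhbd-lab

Matched use–availability analysis of **natal habitat-biased dispersal
(NHBD)** — the hypothesis that dispersing animals preferentially settle
in habitat resembling their natal territory — built around the study
design used for territorial large carnivores such as the grey wolf: a
known natal territory, a known established territory, and a
reconstruction of what was *available* in between.

The package is aimed at movement and spatial ecologists who want to

* test NHBD on paired natal/established territory centers when the
  actual dispersal route is unknown,
* experiment with availability definitions (endpoint-conditioned
  correlated random walks vs. straight-line buffers of varying radius),
* and validate the whole inference chain on synthetic landscapes with a
  *known, tunable* settlement preference.

## The design and the model

For each disperser *i* the established territory (used, `y = 1`) is
matched with 11 available territories (`y = 0`) sampled along the
dispersal route; the 12 records form one stratum. Habitat similarity is
defined by clustering standardized territory feature vectors (PCA to 5
components, then k-means / k-medoids / Ward's hierarchical clustering,
k = 4…10): the binary covariate `NHBD` is 1 when a record falls in the
same habitat cluster as the natal territory. Selection is estimated by
**conditional logistic regression**, whose likelihood conditions on one
used record per stratum and so eliminates all stratum-level intercepts:

```
L(β) = ∏ᵢ  exp(x_{i,used}·β) / Σ_{j ∈ stratum i} exp(x_{ij}·β)
```

`β_NHBD > 0` means natal-like habitat is settled more than expected
from availability. The model is fitted by Newton–Raphson on the exact
gradient and observed information (with step-halving); Wald standard
errors, z scores, p values and 95% intervals come from the inverse
information. Covariates that are constant within every stratum (e.g.
sex) cancel from the likelihood and are rejected by name; sex instead
enters through an `NHBD × sex` interaction (coded F = 1, M = 0), and
density dependence through `NHBD × wolf density`. Models are fitted per
sex × dispersal-distance category (short < 40 km, medium 40–200 km,
long > 200 km), per category over both sexes, and pooled with the
interactions.

Everything upstream of the regression is part of the package too:

* `synthetic` — spatially autocorrelated multi-band landscapes
  (compositional land cover, terrain, prey/competitor/human
  covariates), GPS-like reference trajectories, and a disperser
  population whose settlement preference
  `P(site) ∝ exp(strength × similarity(natal, site))` is the ground
  truth being estimated;
* `features` — moving-window land-cover percentages, slope/roughness,
  zonal means over the 1000 km² territory circle, wolf-pair counts
  within 40 km;
* `availability` — endpoint-conditioned correlated random walks (CRWs)
  resampled from reference movement profiles, admissibility rules, and
  buffer sampling;
* `similarity` — pooled standardization, PCA, three clustering methods,
  NHBD indicator and a continuous natal-distance metric;
* `clogit` — the conditional logistic regression, correlation
  screening, and the per-group model suite;
* `pipeline` / `cli` — the end-to-end experiment driver and the
  `nhbd-lab` command.

## Worked example

Simulate a landscape with a strong settlement preference
(`nhbd_strength = 3`), run the full analysis, and look at the NHBD
coefficient per dispersal-distance category:

```python
from nhbd_lab import pipeline

cfg = pipeline.ExperimentConfig(
    seed=42, resolution_m=1000.0, extent_cells=(120, 120),
    autocorr_range_m=15_000.0, n_dispersers=80, nhbd_strength=3.0,
    dispersal_kernel={"distribution": "lognormal", "median": 25_000.0, "sigma": 0.8},
    cluster_methods=("kmeans",), k_values=(6,),
)
grid = pipeline.run_nhbd_analysis(cfg)
print(grid[(grid.variable == "nhbd")
           & grid.group.isin(["all/short", "all/medium", "pooled"])]
      [["group", "beta", "se", "z", "p", "ci_lo", "ci_hi", "n_strata"]]
      .round(3).to_string(index=False))
```

prints

```
     group   beta    se      z     p  ci_lo  ci_hi  n_strata
all/medium -1.232 0.849 -1.451 0.147 -2.895  0.432        14
 all/short  0.804 0.365  2.201 0.028  0.088  1.521        53
    pooled -0.117 0.544 -0.215 0.830 -1.183  0.950        67
```

Short-distance dispersers show significant selection for natal-like
habitat (β = 0.80, p = 0.028) while medium-distance dispersers do not —
natal-like habitat is simply scarcer far from home, so the preference
only has room to express itself nearby. The pooled fit also reports the
habitat control variables and the `NHBD × sex` / `NHBD × wolf density`
interactions in the same tidy table.

The same experiment runs from the shell, stage by stage or at once:

```bash
nhbd-lab run-all --config config.yaml --seed 42 --out results/run1
nhbd-lab sweep-buffers --config config.yaml --out results/sweep \
         --radii 25000,100000,300000
```

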