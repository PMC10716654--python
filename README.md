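# wisent

Process-explicit reconstruction of late-Quaternary range and population
dynamics of the European bison (*Bison bonasus*): a niche-hypervolume
habitat model, human-pressure surfaces, a stochastic spatially explicit
population model (SEPM) with harvest, pattern-oriented ABC calibration
against fossil-derived targets, counterfactual attribution of range loss,
and smooth-regression driver analysis.

## Who this is for

Paleoecologists and macroecologists who want to confront mechanistic range
models with sparse fossil and historical evidence: the package couples the
whole chain — environment → demography → validation → inference — in one
tested toolkit, and ships a synthetic-data generator with known truth so
every stage can be exercised and checked for parameter recovery before any
real data are touched.

## The model

The landscape is a grid of equal-area cells (86.6 km × 75.6 km) stepped at
one bison generation (10 years) from 21 ka BP to 100 BP. Each cell carries

- **Habitat suitability** `S ∈ [0, 1]`: a Gaussian kernel-density
  hypervolume fitted in a four-dimensional environmental space (annual
  precipitation, winter temperature, spring–summer evapotranspiration,
  land-use-adjusted forage biomass) to quality-filtered fossil occurrences
  (age quality score > 10), projected per generation and scaled by the
  pooled 95th percentile. Realized niches truncate the density at the level
  enclosing a *niche volume* fraction of total mass and displace the
  centroid by a *marginality* shift.
- **Carrying capacity** `K = S · D_max · A` with maximum density `D_max`
  (0.3 bison km⁻² ≈ 2000 bison per cell at `S = 1`).
- **Growth**: stochastic Ricker, `N' = N exp(r_t (1 − N/K))`,
  `r_t ~ N(r_max, r_sd)` per cell per generation.
- **Harvest**: generalized Holling offtake
  `O = min(h_max N, h_max · H · N · N^q/(θ^q + N^q))` where `H ∈ [0, 1]` is
  relative human abundance sampled within ±1 s.d. of a demographic-model
  surface (window centre ω is itself calibrated), and `q ∈ [1, 2]`
  interpolates a type II (q = 1) and type III (q = 2) functional response.
- **Dispersal**: a fixed fraction emigrates per generation over an
  exponential distance kernel truncated at a maximum distance, weighted by
  a friction landscape (0 on ice; reduced under land use); mass-conserving.
- **Allee threshold**: cells falling strictly below a fixed abundance are
  locally extirpated.

Calibration is pattern-oriented ABC: Latin-hypercube rounds of simulations
are summarized by (i) the fraction of fossils matched in space-time (cell ±
its Moore neighbourhood, within ±2 s.d. of the calibrated age), (ii) years
of premature extirpation in named refugia relative to 1850 CE, and (iii)
the deviation of the number of 8-connected refugial populations at 1850 CE
from its target. The closest simulations are accepted (0.25% at the full
55 000-run schedule), priors are iteratively refined, and the accepted
ensemble is averaged with inverse-distance weights. Counterfactual reruns
(no hunting / no land use / neither, under common random numbers) attribute
each lost cell to a cause, and a post-1500 CE harvest-escalation scan is
validated against the historical 1870 CE estimate of 3560 bison.

## Worked example

A desk-scale experiment on a synthetic world with known truth
(`h_max = 0.12`, `volume_fraction = 0.65`), 300 + 2×200 simulations:

```python
from wisent.config import RunConfig
from wisent.pipeline import build_model_from_config
from wisent.scenarios import harvest_scan

cfg = RunConfig.desk_profile(seed=1)
model, bundle = build_model_from_config(cfg)   # synthetic truth bundle
fit = model.fit(round_sizes=cfg.round_sizes, tolerance=cfg.tolerance, seed=1)
print(fit)
```

```
Pattern-oriented fit of the range-dynamics model
  rounds: [300, 200, 200] (700 simulations), accepted: 40
  converged (overlap >= 0.8): False

                    post_mean  post_min  post_max  prior_lo  prior_hi
parameter
r_max                  0.2352   0.07108    0.3995      0.05       0.4
...
h_max                  0.1426  0.004426    0.2982         0       0.3
...
volume_fraction        0.6527    0.3231    0.9643       0.3         1
```

The accepted min–max ranges bracket the generating values (`h_max` 0.12
inside [0.004, 0.298]; `volume_fraction` 0.65 inside [0.323, 0.964]) and the
weighted posterior means sit close to them; at 700 simulations the posterior
is honest but wide, and the overlap diagnostic correctly reports that two
desk-scale rounds have not yet converged. `fit.gof()` returns a
goodness-of-fit p-value (1.0 here: the target is typical of the accepted
cloud), and the harvest scan reports ensemble 1870 CE totals against the
historical constant:

```python
scan = harvest_scan(fit)
print(scan[["multiplier", "weighted_final_total", "validation_total_1870"]].head(4))
```

```
 multiplier  weighted_final_total  validation_total_1870
        0.1         421111.712578                 3560.0
        0.2         411017.124353                 3560.0
        0.3         401417.437960                 3560.0
        0.4         392317.344647                 3560.0
```

Totals decline monotonically in the escalation multiplier (the synthetic
world is far more benign than the real one, hence the large absolute
numbers). The same pipeline runs end-to-end from a YAML config:

```bash
wisent pipeline --profile desk --seed 1 --out pipeline_out
```

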