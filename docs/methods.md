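# Methods

This note documents the models implemented in `wisent`, their assumptions,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that a maintainer
would otherwise have to reverse-engineer.

## Grid and calendars

Simulations run on a rectangular lattice of equal-area cells (defaults
86.6 km × 75.6 km, an Albers equal-area resolution appropriate for
continental-scale megafauna modelling) at generational 10-year steps. Time
is indexed 0-based from the oldest step; ages are years BP (before 1950
CE), and `year_CE = 1950 − year_BP` everywhere (so 450 BP is 1500 CE and
100 BP is 1850 CE). A grid is valid only if its span divides evenly by the
step.

## Ecological niche (Gaussian hypervolume)

Occurrences are fossil records filtered to dating-quality scores strictly
greater than 10, intersected with per-generation environmental layers: one
environmental point per (cell, generation) bin within ±2 s.d. of the
calibrated age, duplicates collapsed. Sub-generational climate series are
first averaged to the 10-year step with a centred 30-year sliding window
(truncated at the series edges).

The full potential niche is a product-Gaussian KDE over four standardized
axes. Bandwidths are a single multiplier on the per-axis s.d., selected by
K-fold (K = 5) least-squares cross-validation — the estimator of the
integrated squared error, with the ∫f̂² term in closed form — over a
log-spaced multiplier grid (0.25×–4× the Silverman value, 13 points).
Axis standardization makes the bandwidths unit-free and the marginality
shift interpretable in s.d. units.

Realized niches are generated by two knobs:

- **volume_fraction v ∈ (0, 1]** — the density is truncated at the level
  enclosing `v` of total density mass. The threshold is the (1 − v)
  quantile of the density of points sampled from the KDE itself (20 000
  seeded samples), since P(f(X) ≥ t_v) = v for X ~ f.
- **marginality m ≥ 0** — the centroid is displaced by `m` per-axis s.d.
  along a seeded random unit direction. The subsampling literature this
  emulates does not fix a shift geometry; an isotropic random direction is
  the least-informative choice and is documented as such.

Projection evaluates the (shifted, untruncated) density at every
(generation, cell) environmental point, scales the pooled distribution over
*all* generations and cells by its 95th percentile (clipping at 1), then
zeroes cells below the truncation threshold. Two deliberate choices:

- *Pooled* rather than per-generation scaling, so suitability — and hence
  carrying capacity — is comparable across time; per-generation scaling
  would erase the climate signal the demographic model needs.
- The scale comes from the *untruncated* density, so shrinking the niche
  volume only removes cells and can never raise a surviving cell's
  suitability (a monotonicity the calibration relies on).

`truncate_density_map` applies the identical volume-fraction semantics
directly to a cached projected density map; it is the fast path used when
thousands of parametrizations vary the niche volume over a fixed
environment (the threshold is then a mass quantile of the map itself, with
cells weighted by their own density).

## Human pressure

Effective-population-size surfaces (mean and per-cell s.d., 25-year native
step) are used as a relative-abundance proxy: scaled to [0, 1] by the
pooled 95th percentile (clipping), linearly interpolated in time to the
10-year step. One *realization* per simulation draws each (cell,
generation) from a lognormal with median `mean + ω·sd` — the window-centre
ω ∈ [−1, 1] is a calibrated parameter — and shape `σ = asinh(sd/median)`,
so one log-unit spans the half-window; draws are rejection-truncated to
`[max(0, mean − sd), mean + sd]`. Degenerate cells (sd = 0 or nonpositive
median) return the clipped window centre. The source publication does not
print its lognormal parametrization; median/shape matching is the simplest
construction that (a) is exact for sd → 0, (b) is monotone in ω in
distribution, and (c) respects the stated ±1 s.d. envelope, and the
envelope bound is asserted exactly in tests.

## Population model (SEPM)

Per generation, in order: carrying-capacity update → Ricker growth →
harvest → dispersal → Allee threshold. The ordering is a modelling choice
(the source is silent): harvest acts on post-breeding abundance, and the
Allee rule comes last so that hunting plus emigration can trigger local
extirpation. Abundance is real-valued; the Allee threshold supplies the
discreteness of small-population collapse.

- **Carrying capacity** `K = S · D_max · A` (linear in suitability).
- **Growth** `N' = N exp(r_t (1 − N/K))`, `r_t ~ N(r_max, r_sd)` i.i.d.
  per cell per generation; `K = 0` collapses the cell. The whole noise
  field is pre-drawn indexed by generation, so a run branched from a saved
  mid-series state (harvest scans) experiences exactly the same noise as
  its parent — the common-random-numbers contract that makes
  counterfactual differences attributable to the intervention alone.
- **Harvest** `O = min(h_max N, h_max · H · N · N^q/(θ^q + N^q))`. The
  exponent `q ∈ [1, 2]` interpolates type II and type III functional
  responses (`q = 1` gives `N/(θ + N)`; `q = 2` gives `N²/(θ² + N²)`); θ is
  the half-saturation abundance in animals per cell. Offtake is clipped to
  available abundance.
- **Dispersal** moves a fixed fraction of each cell's animals among
  destinations within `d_max` km (grid-Euclidean with the cell dimensions),
  weighted by `exp(−d/λ) · friction(dest)` with `λ = d_max/3` (the kernel
  decays to e⁻³ ≈ 5% at the maximum distance). Ice has friction 0 and
  blocks settlement; sources with no reachable destination keep their
  movers; the default deterministic mode moves expected mass and conserves
  total abundance to machine precision (an integer multinomial mode exists
  for small-population studies). Self-destination is excluded, so a
  two-cell open landscape transfers exactly the dispersal fraction.
- **Allee**: strictly-below-threshold cells drop to zero (a cell exactly at
  the threshold survives).

Extirpation bookkeeping records, per cell, the first generation after which
it stays empty to the end (−1 = extant at the end, −2 = never occupied).

A caveat asserted only under the conditions tested: monotonicity of totals
in `h_max` under shared noise holds in the Ricker regime the calibration
explores (`N ≲ K/r`); strong overcompensation could in principle break it.

## Pattern-oriented ABC

Summaries per simulation: occurrence match ∈ [0, 1] (a fossil matches if
its cell or any Moore neighbour is occupied at any generation within ±2
s.d. of its age; sightings with zero dating error use only their deposition
step), persistence penalty in years (per refugium, `max(0, 1850 CE − last
occupied year)`; never-occupied refugia count from the simulation start),
and |refugia count − expected| with refugia as 8-connected occupied patches
at the 1850 CE step. Components are scaled by the across-simulation MAD
(×1.4826; fallback s.d., then 1) before the Euclidean distance — without
standardization the year-scale penalty would dominate a fraction and a
count.

Rejection keeps the `⌈n·tol⌉` smallest distances with stable index-order
tie-breaking. Prior refinement expands the accepted min–max by 10% about
its midpoint and intersects with the original bounds. Convergence between
rounds is a per-parameter histogram overlap coefficient (10 shared bins;
converged when the minimum overlap ≥ 0.8) — a transparent stand-in for the
Bayes-factor criterion of the source, whose statistic is not printed.
Goodness of fit is a leave-one-out null: pseudo-observations are accepted
summaries, each measured against the centroid of the rest; p is the
fraction of null distances at least as large as the real target's distance.
Ensemble estimates weight accepted runs by normalized inverse distance
(zero distances floored at 10⁻⁶ × the smallest positive distance).

Schedules: the **full** profile is 25 000 + 3×10 000 simulations at 0.25%
tolerance. The **desk** profile (20×20 grid, 300-generation span, 300 +
2×200 simulations) uses tolerance 0.20: at desk scale the three-component
summary is coarse and many simulations reproduce the target exactly, so
the acceptance set must be at least as large as this tie plateau —
otherwise the index-order tie-break, not the data, decides which
behaviourally equivalent models define the posterior ranges.

## Scenarios and attribution

Counterfactuals: *no hunting* (h_max = 0 throughout), *no land use*
(unmodified biomass and suitability, land-use friction 1), *no human
pressures* (both), all under common random numbers. The harvest scan
branches each accepted run from its saved 1500 CE state with
`h_max → (1 + m)·h_max` for m = 0.1 … 1.0 and runs to 1870 CE (clamped to
the grid's final step if the span ends earlier), reporting per-model and
inverse-distance-weighted finals beside the historical 3560-animal
estimate (2000 Caucasus + 1560 Białowieża). The escalation is read as
*additive* (new rate = (1 + m)·h_max); the alternative reading (a rate of
m·h_max) would reduce hunting and cannot deplete the population, which is
the scan's purpose.

Attribution labels each cell extirpated in the baseline ensemble by 1500 CE
(ensemble occupancy agreement below 25%) with the mildest counterfactual
under which it survives: *hunting* if occupied with hunting removed, else
*land use* if occupied with land use removed, else *human combined* if only
the joint removal saves it, else *climate*. Labels partition the
extirpated cells by construction. Map products mask cells below 25% model
agreement and flag ensemble abundance under 50 animals as "very low".

## Driver analysis

Ensemble series are aggregated to 100-year bins (10 generations) per
accepted model: mean abundance, and three covariates averaged over that
model's occupied cells per generation — mean annual temperature, scaled
relative human abundance, and land-use change as the fractional biomass
reduction (raw − adjusted)/raw. Epochs partition the span at 11.7 ka,
4.25 ka and 450 BP, boundaries belonging to the older epoch.

The regression is a penalized additive Gaussian model written for this
package: cubic B-spline smooths (8 basis functions per covariate, centered)
with a double penalty per smooth — a second-difference wiggliness penalty
plus a separate penalty on its null space — so an uninformative covariate
can be shrunk to exactly flat; model ID enters as a ridge-shrunk dummy
block (a random effect). Smoothing parameters are selected by GCV with
coordinate descent over a log-spaced grid (10⁻³–10⁵, two passes).
Reported quantities: the maximized Gaussian profile log-likelihood (the ML
criterion), effective degrees of freedom (trace of the hat matrix), and
centered partial-effect curves.

Model comparison follows the χ² recipe: statistic = 2 × |ΔML| between
nested fits with and without interactions, df = difference in effective
parameters, p from the χ² tail. Two choices keep this test calibrated:
the interaction block is an *unpenalized* fixed-df basis (products of
centered linear and quadratic covariate transforms, 4 columns per pair, 12
for three covariates), and the interaction fit reuses the null fit's
smoothing parameters, so the comparison is a classical nested likelihood
ratio. Under a simulated additive null the test rejects at ≈ 5%
(measured 5.5% over 200 replicates in the acceptance suite).

## Synthetic study conditions

The generator produces worlds with the statistical structure the analysis
assumes, not physical emulations of climate, vegetation or human-demography
models:

- **Suitability**: a smooth spatial field (Gaussian-blurred white noise,
  radius 2 cells, rescaled to [0.15, 0.95]) modulated in time by an abrupt
  collapse at a configurable step with linear recovery — the analogue of a
  rapid warming event that cuts carrying capacity — plus 2% slow temporal
  noise. The collapse severity varies *spatially* (a second smooth field,
  normalized so the mean drop equals `collapse_depth`): a spatially uniform
  drop interacting with the niche's global density threshold would
  extirpate every cell at once, which is neither realistic nor what the
  fossil record shows; uneven severity creates the refugia the validation
  targets rely on. The blur radius is a fixture choice — the real spatial
  autocorrelation of suitability at model resolution is not known.
- **Ice**: covers the northern 30% of rows at the start and retreats
  poleward monotonically, clearing halfway through the series.
- **Land use**: from a configurable onset step, a contiguous western block
  (one third of columns) has its biomass multiplier decline linearly to
  0.4 and its friction reduced to 0.6.
- **Temperature**: a latitudinal gradient plus a warming excursion tied to
  the collapse profile (so the driver analysis has a real climate signal).
- **Humans**: per-cell logistic growth toward a *spatially heterogeneous*
  ceiling (a smooth field spanning 0.1–1 of the nominal level) with
  log-normal heterogeneity in starting levels; the s.d. layer is a fixed
  fraction (default 0.2) of the mean. Persistent spatial structure in
  late-series human pressure is what allows low-pressure refugia to exist.
- **Fossils**: sampled from the occupied (generation, cell) pairs of a
  known-truth simulation, with detection probability proportional to
  abundance, Gaussian dating error, and integer quality scores uniform on a
  configurable range (quality scoring itself is exogenous and not
  reproduced). Default 120 records at the full scale, 60 at desk scale,
  dating s.d. 30 years.
- **Truth bundles** default to the posterior central estimates as
  generating values (r_max 0.18, D_max 0.3 km⁻², Allee 9, dispersal 5% to
  110 km, h_max 0.12, niche volume 0.65) and regenerate with a fresh
  substream (up to 25 attempts) if the truth population collapses before
  10% of the span or fails to persist to the end.

What passing the synthetic suite does **not** show: that the pipeline
recovers parameters from *real* fossil compilations (real dating error is
non-Gaussian and calibrated, detection is taphonomically biased, and the
environmental fields have structure far richer than blurred noise), nor
that the desk-scale posterior ranges have the coverage of the full 55 000-
run schedule. The recovery experiment shows identifiability under the
stated conditions, no more.

## Randomness and reproducibility

One master seed spawns named substreams (`SeedSequence` spawn keys) per
operation and per (round, simulation) pair; appending to — never replacing
— an existing spawn key keeps retries and nested operations independent.
All stochastic outputs are bit-reproducible for a fixed seed; the pipeline
writes a manifest with hashes of its tabular outputs, identical across
repeated runs of the same configuration.

## I/O

NetCDF (dims time/row/col, time in years BP, via xarray's scipy backend)
for landscapes, human fields and simulation results; CSV for fossils
(`cell_id,lon,lat,age_bp,age_sd,quality,kind`), posteriors and scan tables;
YAML for configurations and manifests. The categorical extirpation-cause
map is written as CSV (integer codes documented in `scenarios.CAUSE_LABELS`).

## Known limitations

- No age/sex structure, genetics or within-generation seasonality; the
  scalar Ricker-with-threshold abstraction is the modelling contract.
- Deterministic dispersal ignores demographic stochasticity of small
  moving groups (the multinomial mode exists but is not the default).
- The desk profile's wide posterior ranges reflect genuinely weak
  identification from three coarse summaries at 700 simulations — the
  convergence diagnostic honestly reports non-convergence at that scale.
- The LSCV bandwidth criterion is noisy for small occurrence sets; the
  cross-validated multiplier is constrained to a factor-of-4 window around
  the Silverman value.
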