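# Methods

## The model

`ddcrop` predicts county-scale maize grain yield with a deterministic
daily-time-step growth engine,

    yhat(t, c) = f(W_tc, M_tc, S_c, g_tc, s_c),

where `W` is daily weather for county `c` in year `t`, `M` is management
(planting/harvest day-of-year, stand density, planted area), `S` static
soil descriptors, `g` a vector of genotypic parameters defined to be
independent of the environment, and `s` a small set of calibrated county
soil parameters.  All seeds grown in one county in one year are represented
by a single composite genotype; `g_tc` is therefore a county-year average
of the commercially planted varieties, not an individual cultivar.

The daily loop couples seven processes:

1. **Phenology.** Thermal time accumulates as the mean of the
   [tbase, tcap]-clipped daily extremes minus tbase (tbase = 10 degC,
   tcap = 30 degC).  The crop is vegetative until cumulative GDD reaches
   `gdd_flower`, fills grain until `gdd_mature`, then stops.  Transitions
   are one-way; the season ends at min(harvest, maturity).
2. **Water uptake.** Potential uptake is `u_max * root_mass * VPD`
   (L/plant/day); actual uptake is capped by the water stored above a
   wilting level (10% of effective capacity), converted per plant through
   the ground area per plant (10^4/density m^2; 1 mm over 1 m^2 = 1 L).
   The ratio actual/potential is the drought factor.
3. **Soil water.** A single bucket: rain minus a fixed runoff fraction
   enters; uptake and bare-soil evaporation
   (`evap_coeff * VPD * (1 - cover) * wetness`) leave; overflow above the
   effective capacity (`capacity * sw_cap_scale`) runs off.  The balance is
   exact to float round-off and is audited in tests.
4. **Radiation interception.** Beer-Lambert, `1 - exp(-k * LAI)` with
   k = 0.6 and `LAI = leaf_mass * sla / plant_area`; proportional to LAI
   when the canopy is open, bounded at closure.
5. **Stress.** Heat: linear ramp from 1 at `t_heat` to 0 at
   `t_heat + 10 degC` on daily tmax.  Flooding: a flat 0.5 penalty after
   3 consecutive days at saturation.  Drought enters through the uptake
   ratio.  Stresses multiply the radiation-limited branch.
6. **Growth and respiration.** Gross growth is the minimum of a
   radiation-limited branch (`rue * f_int * srad * plant_area`, discounted
   by the stress multipliers) and a water-limited branch
   (`te * uptake / max(VPD, 0.1 kPa)`).  Maintenance respiration is a Q10
   form, `m0 * total_mass * 2^((Tavg-20)/10)` with m0 = 0.008/day.
7. **Partitioning.** Vegetative gains split to leaf/root/stem by
   (`p_leaf`, `p_root`, remainder); during grain fill everything goes to
   grain; a net loss is debited from stem then leaf, never grain or root,
   so grain mass is non-decreasing.  Yield is
   `grain_mass * density * 1e-6` Mg/ha, with no moisture adjustment.

VPD uses the Tetens saturation curve evaluated at tmax and tmin, averaged,
minus ambient vapour pressure.  Rainfed conditions and adequate fertility
are hard-coded assumptions; an irrigation hook (added mm/day) exists and
defaults to zero.

### Choice of functional forms

The qualitative dependency structure (what drives what) is fixed by the
modelling framework; the concrete algebra here is in each case the simplest
standard agronomic form honouring it: Tetens for saturation vapour
pressure, Beer-Lambert canopy optics, co-limitation by min(radiation,
water) in the spirit of crop models that bound growth by the scarcest
resource, Q10 respiration, a linear heat ramp, and a saturation-day flood
counter.  Stress is applied multiplicatively on the radiation branch (not
inside the min) — a modelling choice, documented here because alternatives
(min-combination of stresses) are equally defensible.

### Genotype vector, bounds and constants

The calibrated genotype is 9-dimensional: `gdd_flower`, `gdd_mature`
(degC day), `rue` (g/MJ), `te` (g kPa/L), `sla` (m^2/g), `p_leaf`,
`p_root` (fractions), `u_max` (L/g/kPa/day), `t_heat` (degC).  Each
component carries a biological bound (see `ddcrop.params.GENOTYPE_BOUNDS`)
spanning the ranges reported for dent maize; everything else (extinction
coefficient, Q10 pair, wilting and saturation fractions, seed organ
masses, flood parameters) is a fixed constant in `SimConstants`, keeping
the calibrated vector low-dimensional.

One structural caveat: with uptake potential linear in root mass and a
constant `u_max`, a plant cannot both bootstrap from a tiny seedling root
and keep peak transpiration bounded.  The defaults resolve this with a
2 g seedling root, a small root partition (`p_root` = 0.06) and
`u_max` = 0.055, which keeps peak potential uptake near 6-8 mm/day —
realistic canopy-scale transpiration — while leaving early growth
radiation-limited.  Outside this neighbourhood the engine degenerates into
a sharply water-limited regime; the bounds tables reflect that.

## Calibration

Parameters are fit by minimising the planting-area-weighted RMSE

    sqrt( sum_k a_k^2 (y_k - yhat_k)^2 / sum_k a_k^2 ),

with squared-area weights (the printed form of the objective; note it
differs from the more common linear-area weighting) subject to pairwise
ratio constraints with bound rho = 1.25 on every genotype component:
within a county across years and within a year across counties, no two
values may differ by more than the factor rho.  The constraints regularise
the fit and encode that commercial genotypes change gradually in space and
time.  Soil parameters `s_c` are bounded but not ratio-constrained (the
constraints are defined on `g` only).

The simulator is not differentiable in any useful sense, so the solver is
a derivative-free block-coordinate scheme:

1. **Shared genotype block.** Nelder-Mead on the log of the free
   components' shared values.  When at most three components are free, a
   coarse log-space grid over the bounds seeds the simplex — the objective
   has compensation ridges (e.g. radiation-use efficiency against
   flowering time) that can strand a locally started simplex.
2. **Soil block.** The squared-area-weighted squared error decomposes by
   county, so each county's three soil parameters are fit by their own
   small Nelder-Mead on that county's residuals.
3. **Per-cell deviations.** A greedy sweep perturbs each county-year's
   free components by +/-5% in log space, re-projects the whole table onto
   the ratio band, and keeps strict improvements.
4. Repeat until the relative objective improvement falls below 1e-4.

Every accepted iterate is feasible (the projection runs inside every
candidate evaluation) and the accepted-objective trace is non-increasing;
the incumbent is kept on ties.  Initialisation is the geometric midpoint
of each bound interval (genotypes) and nominal values (soil), so runs are
reproducible; all phases are deterministic and the seed is reserved for
stochastic search variants.

The feasibility projection works per component in log space, alternately
clipping each county's across-year values and each year's across-county
values into a +/- ln(rho)/2 interval and then into bounds, iterated to a
fixed point.  The interval is centred on the slice midrange (the geometric
mean of the slice extremes) rather than the full geometric mean: midrange
centring makes every already-feasible slice an exact fixed point, which
the calibration loop relies on.

## Evaluation designs

* **Spatial extrapolation**: each county in turn is removed entirely and
  the model refit on the remainder.  The held-out county's genotype for
  year t is the area-weighted geometric mean of the fitted genotypes of
  the k = 3 nearest training counties in that year (Euclidean distance
  between centroids); its soil parameters are the geometric mean over the
  same neighbours — the ratio band implies nearby parameters are similar,
  which is what makes this transfer defensible.  The naive benchmark
  predicts each county-year with the nearest county's observed yield that
  year (ties to the smaller county id, falling back past counties with no
  data).
* **Temporal extrapolation**: each year is removed; the held-out genotype
  is the geometric mean of the county's fitted genotypes in the adjacent
  years; the benchmark averages the county's observed yields in t-1 and
  t+1 (one of them at the boundary).
* Errors are area-weighted RMSEs per held-out unit, aggregated with
  planted-area weights; RRMSE divides by a reference mean yield
  (configurable; default: the last year's area-weighted mean observed
  yield).

The shipped extrapolation experiments run the holdout refits with a
deliberately regularised optimizer setting (one outer iteration, an
early-stopped simplex, no per-cell deviation sweeps).  Per-cell freedom in
a refit mostly absorbs observation noise, and since the held-out unit's
parameters are neighbour aggregates, that noise degrades the transfer; the
milder refit consistently extrapolates better in the synthetic
experiments.

Holdout hygiene is enforced structurally — the held-out unit's
observations never enter the refit objective — and verified by a poisoning
test: perturbing held-out yields must not move any fitted parameter.

## What-if analyses

The genotype-by-environment matrix grows every calibrated genotype year
under every environment year: cell (t1, t2) is the area-weighted county
mean of f(W_{t2,c}, M_{t2,c}, S_c, g_{t1,c}, s_c).  Its diagonal equals
the aggregated fitted training yields by construction.

Seed selection picks, for a target (county c, year t), the source pair
(d, r) maximising either the predicted yield under the realized year-t
weather (known-weather scenario; r ranges from the first data year through
t) or the mean predicted yield over all historical weather years in c
(unknown-weather scenario; r starts one year later, as the two printed
admissible ranges differ — both are implemented as printed, with an
override).  Both optimizers are exhaustive enumerations; ties break to the
earlier source year, then the smaller county id.  The target county keeps
its own soil throughout.  Gain summaries report both conventions — against
observed yields and against the model-predicted own-genotype reference;
only the latter is non-negative by construction.

## Synthetic data

The generator emulates the four public-source table shapes (county yield
survey, gridded daily weather, soil survey water-holding summary,
state-level management) so the pipeline runs with no download, and exposes
the generating truth for recovery experiments.  Daily weather: sinusoidal
seasonal temperature (annual mean 10 degC, amplitude 15 degC, peak near
day 205) with 2 degC Gaussian daily noise and an 8 degC diurnal range;
wet days are Bernoulli(0.35) with exponential depths (mean 12 mm, about
4.2 mm/day — a humid Corn Belt season); radiation is a clear-sky annual
cosine (6-28 MJ m-2 day-1) times a U(0.55, 1) cloudiness factor; vapour
pressure is the Tetens value at tmin (dew point ~ tmin).  Counties get
multiplicative log-normal offsets on soil capacity and rainfall and jittered
planar grid coordinates, so spatial extrapolation is non-trivial.  True
genotypes perturb a mid-range maize genotype cell-wise in log space
(sd 0.04, inside the rho = 1.25 band by construction, with an optional
upward RUE drift capped by the band); observed yields are the simulator's
output under the truth plus N(0, 0.5 Mg/ha) noise, floored at zero.
Default sizes (5 counties, 6 years, 160-day season from day 120, 75,000
plants/ha, ~20,000 ha planted) give yields around 9-15 Mg/ha.

What the generator does **not** emulate: spatially correlated weather
between counties, trends or autocorrelation across years, irrigation,
heteroscedastic or non-Gaussian survey error, and real geography.  Passing
tests therefore demonstrate internal correctness (conservation, recovery,
ranking of model vs naive benchmarks under heterogeneity) — not skill on
real county data.  Observation noise is placed on yield only, matching the
calibration's implicit error model, which penalises yield residuals alone;
the noise law is a test-harness convention, not a claim about surveys.

## Numerical choices and degenerate inputs

* Exact water balance is maintained by absorbing float round-off (< 1e-9 mm)
  into the evaporation term rather than clamping storage.
* `growing_degree_days` and `vapor_pressure_deficit` reject tmax < tmin;
  weather series validate contiguity, and a gap inside the management
  season raises a missing-data error.
* Structural genotype constraints (flowering before maturity, partitions
  summing below 1) are nudged, not errored, during optimisation proposals
  (`gdd_flower <- 0.95 * gdd_mature`; proportional rescale of the
  partition pair).
* The drought factor is defined as 1 when potential uptake is zero.
* A zero-radiation or zero-available-water season yields exactly 0.
* Problem sizes in the shipped experiments (3-5 counties, 3-6 years) are
  the package's default desk-scale configuration; everything scales to
  larger tables through the same API.

## Known limitations

* No nitrogen/fertility dynamics, pests, senescence beyond stage gating,
  sub-daily steps, or layered soil.
* The min(radiation, water) branch with stress multiplied into the
  radiation side double-counts drought in strongly water-limited regimes,
  making yields sharply sensitive to `u_max` there.
* The calibration is a heuristic: monotone descent and feasibility are
  guaranteed, global optimality is not; recovery accuracy is demonstrated
  for reduced free dimensions.
* Grain is reported as simulated dry mass times density; no standard
  moisture correction is applied.
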