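# ddcrop — a data-driven maize crop model

`ddcrop` is for agronomists and modellers who want process-based maize
yield prediction at county scale **without experimental trait calibration**:
a daily mechanistic growth simulator whose genotypic and soil parameters
are fit directly to historical county-year yield tables by constrained
optimization, plus the downstream analyses that this separation of
genotype from environment enables — leave-one-out extrapolation against
naive benchmarks, genotype-by-environment what-if matrices, and optimal
seed selection.

## The model

Predicted yield for county *c* in year *t* is

    ŷ_tc = f(W_tc, M_tc, S_c, g_tc, s_c)

where *f* is a deterministic daily simulator (GDD phenology clock,
bucket soil-water balance, Beer–Lambert light interception, growth as
min(radiation-limited, water-limited) with RUE and transpiration-efficiency
coefficients, Q10 maintenance respiration, heat/drought/flood stress,
stage-dependent organ partitioning), *W/M/S* are weather, management and
soil data, and *g*, *s* are the parameters to calibrate.  Calibration
minimises the planting-area-weighted RMSE

    min_{g,s} √( Σ_tc a_tc² (y_tc − ŷ_tc)² / Σ_tc a_tc² )
    s.t.      g_{t₁,c} ≤ ρ·g_{t₂,c}   ∀ c, t₁, t₂      (temporal band)
              g_{t,c₁} ≤ ρ·g_{t,c₂}   ∀ t, c₁, c₂      (spatial band)

with ρ = 1.25, via a derivative-free block-coordinate search (Nelder–Mead
on shared components, per-county soil blocks, projected per-cell
deviations).  Because *g* is defined to be environment-independent, a
fitted genotype can be re-grown in silico under any other year's weather —
the basis of the G×E and seed-selection analyses.  See `docs/methods.md`
for the full model description and design rationale.

A seeded synthetic-data generator (`ddcrop.synth`) emulates the four input
tables (county yields + planted areas, daily weather, soil water-holding
summaries, management) with known ground truth, so the entire pipeline
runs and is testable with no external downloads.

## Worked example

Recover known genotype parameters from a noise-free synthetic yield table
(`examples/02_calibrate.py`):

```python
from ddcrop import CalibrationProblem, FitOptions, fit
from ddcrop.params import DEFAULT_GENOTYPE_VALUES
from ddcrop.synth import SynthConfig, generate_dataset

dataset = generate_dataset(SynthConfig(n_counties=3, years=(2001, 2003),
                                       yield_noise_sd=0.0,
                                       genotype_spread=0.0, rng_seed=7))
truth = dataset.true_genotypes[dataset.keys()[0]]
problem = CalibrationProblem(
    dataset,
    fixed_components={n: getattr(truth, n) for n in DEFAULT_GENOTYPE_VALUES
                      if n not in ("rue", "gdd_flower")},
    fixed_soil=dataset.true_soil_params)
result = fit(problem, FitOptions(max_outer=2, nm_maxiter=150, cell_sweeps=0))
```

prints

```
objective (area-weighted RMSE): 0.0318 Mg/ha
trace of accepted objectives:   [1.129, 0.032, 0.032]
rue         truth 3.000  fitted 3.067
gdd_flower  truth 800.0  fitted 826.6
```

The objective falls monotonically from the midpoint initialisation
(1.13 Mg/ha) to 0.03 Mg/ha, and the two freed genotype components —
radiation-use efficiency (g biomass per MJ intercepted) and the thermal
time to flowering (°C·day) — come back within ~3% of the values that
generated the data.  `examples/` holds one short script per capability:
single-season simulation with a daily trace, calibration, extrapolation
benchmarks, and G×E / seed selection.

A thin CLI wraps the same functions
(`ddcrop synth|fit|evaluate|gxe|select-seed ... --out DIR`), writing CSV
tables and a JSON-lines run log with the seed and config hash.

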