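"""Leave-one-out extrapolation against the naive benchmarks.

Holds out each county (then each year), refits the model on the remainder,
transfers parameters to the held-out unit, and compares the model's error
to the nearest-county / nearest-year benchmark predictions.
"""
from ddcrop import FitOptions, spatial_extrapolation, temporal_extrapolation
from ddcrop.synth import SynthConfig, generate_dataset

dataset = generate_dataset(SynthConfig(n_counties=4, years=(2001, 2004), rng_seed=11))
options = FitOptions(max_outer=1, nm_maxiter=60, soil_nm_maxiter=30, cell_sweeps=0)

for name, runner in [("spatial", spatial_extrapolation),
                     ("temporal", temporal_extrapolation)]:
    report = runner(dataset, options)
    s = report.summary
    print(f"{name} extrapolation (reference yield "
          f"{report.reference_yield:.2f} Mg/ha):")
    print(f"  model     RMSE {s['model_rmse_avg']:.2f} Mg/ha "
          f"(RRMSE {s['model_rrmse_pct']:.1f}%)")
    print(f"  benchmark RMSE {s['benchmark_rmse_avg']:.2f} Mg/ha "
          f"(RRMSE {s['benchmark_rrmse_pct']:.1f}%)")
    print(f"  training  RMSE {s['training_rmse_avg']:.2f} Mg/ha")
# A model that captures weather and soil effects should beat the naive
# benchmark on held-out units while its training error stays lower still.
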