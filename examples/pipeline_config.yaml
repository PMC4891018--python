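# Full pipeline run on a simulated study-parameter cohort:
#   mrsurv run-all --config examples/pipeline_config.yaml
output_dir: results/example_run
synthetic:
  n_patients: 500
  metabolite_names: [Valine, SMC24, Lysine, TG15, SDMA]
  means: [249.84, 23.93, 200.53, 8.46, 0.76]     # umol/L
  sds: [98.57, 20.67, 51.73, 2.88, 0.62]
  betas: [-0.005, 0.047, -0.020, -0.483, 1.314]  # per umol/L
  lambda0: 1.7376       # baseline Weibull scale (per year)
  gamma0: 1.0769        # baseline Weibull shape
  censor_time_max: 1.25 # administrative censoring horizon (years)
  missing_rates: [0.10, 0.0, 0.0, 0.0, 0.0]
  n_noise_covariates: 5
  seed: 202
n_trees: 1000
importance_threshold: 0.20
p_enter: 0.10
p_stay: 0.05
n_boot: 1000
horizon: 1.0
seeds:
  forest: 1
  bootstrap: 2
  evaluation: 3
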