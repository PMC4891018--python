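# mrsurv

Building and validating a **Metabolites Risk Score (MRS)** — a one-year
mortality probability for pancreatic-cancer patients computed from serum
metabolite concentrations — and the statistical pipeline around it:
random-survival-forest variable screening, Weibull proportional-hazards
modelling with stepwise selection and fractional-polynomial linearity
checks, bootstrap-stabilized score weights, RECPAM risk-class discovery and
censored-data discrimination metrics.

The score has the form

    MRS = 1 − S0(1)^exp{ Σᵢ βᵢ (Xᵢ − X̄ᵢ) },      S0(t) = exp{−(λt)^γ},

where (λ, γ) come from the empty Weibull model, βᵢ are the multivariable
Weibull coefficients of the selected metabolites and X̄ᵢ their sample
means. With the published estimates λ = 1.7376 and γ = 1.0769 the baseline
term is S0(1) = 0.1632, so a patient at the mean metabolite profile has
MRS = 1 − 0.1632 = 0.8368.

Because the underlying patient-level data (27 pancreatic-cancer patients,
18 deaths within one year) are not publicly deposited, the package ships a
synthetic cohort generator that reproduces the study's statistical
structure — Weibull-PH event times driven by five metabolites with the
published means, SDs and coefficients, administrative censoring, MCAR
missingness, copula-correlated clinical covariates — so every stage is
testable end to end. See `docs/methods.md` for the full model account.

## Worked example

```python
from mrsurv import MRSModel, compute_mrs

model = MRSModel(
    names=["Valine", "SMC24", "Lysine", "TG15", "SDMA"],
    means=[249.84, 23.93, 200.53, 8.46, 0.76],   # umol/L
    betas=[-0.005, 0.047, -0.020, -0.483, 1.314],  # per umol/L
    lambda_=1.7376, gamma=1.0769,                # empty-model Weibull fit
)
print(round(model.baseline_term, 4))   # 0.1632
at_means = dict(zip(model.names, model.means))
print(round(compute_mrs(model, at_means), 4))                      # 0.8368
print(round(compute_mrs(model, {**at_means, "SDMA": 0.76 + 0.62}), 4))  # 0.9833
```

A patient one SD of SDMA above the mean moves from 84% to 98% predicted
one-year mortality; one SD of Valine above the mean lowers it to 0.6696.

Running the full pipeline on a simulated cohort:

```python
from mrsurv import PipelineConfig, run_pipeline
from mrsurv.synthetic import (STUDY_BETAS, STUDY_MEANS, STUDY_METABOLITES,
                              STUDY_SDS)

config = PipelineConfig(
    output_dir="run1",
    synthetic=dict(
        n_patients=500, metabolite_names=list(STUDY_METABOLITES),
        means=list(STUDY_MEANS), sds=list(STUDY_SDS), betas=list(STUDY_BETAS),
        lambda0=1.7376, gamma0=1.0769, censor_time_max=1.25,
        n_noise_covariates=5, seed=202),
    n_trees=1000, n_boot=10_000,
)
report = run_pipeline(config)
```

On this cohort the forest screen retains TG15, Lysine, SMC24 and SDMA
(relative importances 1.00, 0.52, 0.30, 0.20; the Valine-strength signal
sits below the 20% screen at this effect ratio), stepwise keeps all four,
fractional polynomials call every association linear, the RECPAM
interaction check reports "additive adequate", and the score reaches a
censored c-statistic of 0.83 (95% CI 0.80–0.85) against 0.66 for an
LDH+age clinical comparator (paired bootstrap p = 0.001).

## Analysis scripts

The `analysis/` drivers replay the study's workflow on synthetic cohorts,
writing tables under `results/`:

```bash
python analysis/01_simulate_cohort.py    # cohorts (paper-scale n=27, desk n=500)
python analysis/02_forest_screening.py   # Step 1: missingness screen, RSF, importance
python analysis/03_weibull_model.py      # Step 2: stepwise fit, FP2, log-log, RECPAM check
python analysis/04_build_score.py        # Step 3: MRS + 10,000-resample bootstrap
python analysis/05_risk_classes.py       # RECPAM classes on the score, KM by class
python analysis/06_evaluate.py           # c-statistics, incidence, associations
```

There is also a CLI (`mrsurv simulate|screen|forest|select|score|classify|
evaluate|run-all|plot`) for running the same stages from a shell with YAML
configs; exit codes are 0/1/2 for ok/validation/runtime.

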