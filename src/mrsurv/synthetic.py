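"""Synthetic survival cohorts with the structure the analysis assumes.

Event times follow a Weibull proportional-hazards law driven by a linear
predictor over metabolite concentrations: S(t|x) = exp{-(lambda0 t)^gamma0
e^{x_c beta}} with x_c mean-centered at the specification means.  Times are
drawn by inversion, censoring is uniform administrative, metabolite
concentrations are zero-truncated normal, and missingness is MCAR.

The default specification (:func:`study_cohort_spec`) carries the study-like
conditions: five prognostic serum metabolites with means 249.84, 23.93,
200.53, 8.46 and 0.76 umol/L, SDs 98.57, 20.67, 51.73, 2.88 and 0.62,
coefficients -0.005, 0.047, -0.020, -0.483 and 1.314 per umol/L, and
baseline Weibull scale/shape 1.7376/1.0769 per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import SurvivalDataset, ValidationError

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "inject_clinical",
    "study_cohort_spec",
    "STUDY_METABOLITES",
    "STUDY_MEANS",
    "STUDY_SDS",
    "STUDY_BETAS",
    "STUDY_LAMBDA",
    "STUDY_GAMMA",
]

STUDY_METABOLITES = ["Valine", "SMC24", "Lysine", "TG15", "SDMA"]
STUDY_MEANS = [249.84, 23.93, 200.53, 8.46, 0.76]
STUDY_SDS = [98.57, 20.67, 51.73, 2.88, 0.62]
STUDY_BETAS = [-0.005, 0.047, -0.020, -0.483, 1.314]
STUDY_LAMBDA = 1.7376
STUDY_GAMMA = 1.0769


@dataclass
class CohortSpec:
    """Ground-truth description of a cohort to simulate.

    ``betas`` are per-umol/L proportional-hazards coefficients applied to the
    mean-centered concentrations; ``lambda0``/``gamma0`` parameterise the
    baseline survivor S0(t)=exp{-(lambda0 t)^gamma0} (per-year scale).
    """

    n_patients: int
    metabolite_names: list[str]
    means: list[float]
    sds: list[float]
    betas: list[float]
    lambda0: float
    gamma0: float
    censor_time_max: float = 1.25
    missing_rates: list[float] = field(default_factory=list)
    n_noise_covariates: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValidationError("n_patients must be positive")
        p = len(self.metabolite_names)
        if not self.missing_rates:
            self.missing_rates = [0.0] * p
        lengths = {p, len(self.means), len(self.sds), len(self.betas), len(self.missing_rates)}
        if len(lengths) != 1:
            raise ValidationError(
                "metabolite_names, means, sds, betas and missing_rates must have equal length"
            )
        if any(s <= 0 for s in self.sds):
            raise ValidationError("sds must be strictly positive")
        if any(not (0 <= r < 1) for r in self.missing_rates):
            raise ValidationError("missing_rates must lie in [0, 1)")
        if self.lambda0 <= 0 or self.gamma0 <= 0:
            raise ValidationError("lambda0 and gamma0 must be strictly positive")
        if self.censor_time_max <= 0:
            raise ValidationError("censor_time_max must be positive")
        if self.n_noise_covariates < 0:
            raise ValidationError("n_noise_covariates must be non-negative")

    def with_(self, **kwargs) -> "CohortSpec":
        return replace(self, **kwargs)


def study_cohort_spec(n_patients: int = 27, seed: int = 0, **overrides) -> CohortSpec:
    """Specification matching the study-like five-metabolite cohort."""
    spec = CohortSpec(
        n_patients=n_patients,
        metabolite_names=list(STUDY_METABOLITES),
        means=list(STUDY_MEANS),
        sds=list(STUDY_SDS),
        betas=list(STUDY_BETAS),
        lambda0=STUDY_LAMBDA,
        gamma0=STUDY_GAMMA,
        seed=seed,
    )
    return spec.with_(**overrides) if overrides else spec


@dataclass
class SyntheticCohort:
    """Generated cohort plus the ground truth used to create it."""

    dataset: SurvivalDataset
    true_linear_predictor: np.ndarray
    true_event_time: np.ndarray
    spec: CohortSpec


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw one cohort from ``spec``; identical seed gives an identical cohort.

    Concentrations are Normal(mean, sd) truncated at zero, event times come
    from inverting S(t|x) -- t = (1/lambda0) * (-ln U * e^{-x_c beta})^(1/gamma0)
    -- censoring is Uniform(0, censor_time_max], and the MCAR mask is punched
    after outcome generation so missingness is independent of everything.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    p = len(spec.metabolite_names)
    means = np.asarray(spec.means, float)
    sds = np.asarray(spec.sds, float)
    betas = np.asarray(spec.betas, float)

    a = (0.0 - means) / sds  # truncation of concentrations at zero
    X = stats.truncnorm.rvs(a[None, :], np.inf, loc=means[None, :], scale=sds[None, :],
                            size=(n, p), random_state=rng)
    lp = (X - means) @ betas
    u = rng.uniform(size=n)
    true_t = (1.0 / spec.lambda0) * (-np.log(u) * np.exp(-lp)) ** (1.0 / spec.gamma0)
    # uniform administrative censoring on (0, horizon]
    cens = spec.censor_time_max * (1.0 - rng.uniform(size=n))
    time = np.minimum(true_t, cens)
    event = (true_t <= cens).astype(int)

    cov = pd.DataFrame(X, columns=spec.metabolite_names)
    for k in range(spec.n_noise_covariates):
        cov[f"noise_{k + 1}"] = rng.normal(size=n)
    for j, rate in enumerate(spec.missing_rates):
        if rate > 0:
            holes = rng.uniform(size=n) < rate
            cov.iloc[holes, j] = np.nan

    dataset = SurvivalDataset(time=time, event=event, covariates=cov)
    return SyntheticCohort(
        dataset=dataset, true_linear_predictor=lp, true_event_time=true_t, spec=spec
    )


def _gaussian_scores(values: np.ndarray) -> np.ndarray:
    """Normal scores of the ranks (mid-ranks for ties)."""
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf(ranks / (len(values) + 1.0))


def inject_clinical(cohort: SyntheticCohort,
                    target_correlations: dict[str, float] | None = None,
                    seed: int = 0) -> SurvivalDataset:
    """Append LDH, age, smoking and alcohol columns to a generated cohort.

    LDH is built through a Gaussian copula on the metabolite rank scores so
    that its Spearman correlation with each named metabolite approaches the
    requested target as n grows; its marginal is log-normal around a typical
    serum activity of 200 U/L.  Age, smoking and alcohol are independent
    draws with plausible oncology-cohort frequencies; none of the appended
    columns feeds back into the event times.
    """
    target_correlations = dict(target_correlations or {})
    ds = cohort.dataset
    for name in target_correlations:
        if name not in ds.covariates.columns:
            raise ValidationError(f"metabolite '{name}' not present in cohort")
    if any(abs(r) >= 1 for r in target_correlations.values()):
        raise ValidationError("target Spearman correlations must satisfy |rho| < 1")
    rng = np.random.default_rng(seed)
    n = ds.n

    if target_correlations:
        names = list(target_correlations)
        # Spearman target -> Pearson correlation of the latent normals
        r_vec = np.array([2.0 * np.sin(np.pi * target_correlations[m] / 6.0) for m in names])
        Z = np.column_stack([
            _gaussian_scores(ds.covariates[m].fillna(ds.covariates[m].mean()).to_numpy())
            for m in names
        ])
        Szz = np.corrcoef(Z, rowvar=False) if len(names) > 1 else np.array([[1.0]])
        w = np.linalg.solve(Szz, r_vec)
        resid_var = max(1.0 - float(r_vec @ w), 1e-6)
        z_ldh = Z @ w + np.sqrt(resid_var) * rng.normal(size=n)
        z_ldh = z_ldh / max(np.std(z_ldh), 1e-12)
    else:
        z_ldh = rng.normal(size=n)
    # log-normal LDH marginal (median 200 U/L); Spearman is rank-invariant
    ldh = np.exp(np.log(200.0) + 0.35 * stats.norm.ppf(
        stats.rankdata(z_ldh) / (n + 1.0)))

    out = ds.covariates.copy()
    out["LDH"] = ldh
    out["age"] = np.clip(rng.normal(67.0, 9.0, size=n), 30.0, 95.0)
    out["smoking"] = rng.binomial(1, 0.45, size=n)
    out["alcohol"] = rng.binomial(1, 0.35, size=n)
    return SurvivalDataset(time=ds.time, event=ds.event, covariates=out)
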