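"""The Metabolites Risk Score (MRS).

MRS(x) = 1 - S0(t)^exp{sum_i beta_i (X_i - Xbar_i)} with S0(t) =
exp{-(lambda t)^gamma}: the predicted probability of death within the horizon
t (default one year), anchored at the cohort's mean metabolite profile.
lambda and gamma come from the empty (covariate-free) Weibull model, the
weights beta_i from the final multivariable Weibull fit, and the centering
constants Xbar_i are the sample means of the selected metabolites.

Weight stability is assessed by patient-level bootstrap: the multivariable
model is refitted on each resample and percentile 95% intervals of each
coefficient's empirical distribution are reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import SurvivalDataset, ValidationError
from .weibull import ConvergenceError, WeibullPHFit, baseline_survivor, fit_weibull_ph

__all__ = ["MRSModel", "build_mrs", "compute_mrs", "bootstrap_weights", "BootstrapWeights"]

SCHEMA_VERSION = 1


@dataclass
class MRSModel:
    """A fitted risk score: names, centering means, weights and baseline."""

    names: list[str]
    means: np.ndarray
    betas: np.ndarray
    lambda_: float
    gamma: float
    t: float = 1.0
    boot_ci: dict[str, tuple[float, float]] | None = None
    n_boot: int = 0

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, float)
        self.betas = np.asarray(self.betas, float)
        if not (len(self.names) == self.means.size == self.betas.size):
            raise ValidationError("names, means and betas must align")
        if self.lambda_ <= 0 or self.gamma <= 0:
            raise ValidationError("baseline scale and shape must be positive")
        if self.t <= 0:
            raise ValidationError("horizon must be positive")

    @property
    def baseline_term(self) -> float:
        """S0(t), the constant the linear predictor exponent acts on."""
        return float(baseline_survivor(self.lambda_, self.gamma, self.t))

    def linear_predictor(self, values) -> np.ndarray:
        df = self._as_frame(values)
        X = df[self.names].to_numpy(dtype=float)
        if np.isnan(X).any() or not np.isfinite(X).all():
            raise ValidationError("all score metabolites must be present and finite")
        return (X - self.means) @ self.betas

    def _as_frame(self, values) -> pd.DataFrame:
        if isinstance(values, pd.DataFrame):
            df = values
        elif isinstance(values, (dict, pd.Series)):
            df = pd.DataFrame([values])
        else:
            raise ValidationError("values must be a mapping, Series or DataFrame")
        missing = [n for n in self.names if n not in df.columns]
        if missing:
            raise ValidationError(f"missing score metabolites: {missing}")
        return df

    def score(self, values) -> np.ndarray | float:
        """MRS = 1 - S0(t)^exp(linear predictor), strictly inside (0,1).

        Extreme linear predictors would saturate to exactly 0 or 1 in floating
        point; the result is nudged to the nearest representable interior
        value so the open-interval contract holds numerically.
        """
        lp = self.linear_predictor(values)
        out = 1.0 - self.baseline_term ** np.exp(np.clip(lp, -700.0, 700.0))
        out = np.clip(out, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
        return float(out[0]) if out.size == 1 and not isinstance(values, pd.DataFrame) else out

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "names": self.names,
            "means": list(map(float, self.means)),
            "betas": list(map(float, self.betas)),
            "lambda": self.lambda_,
            "gamma": self.gamma,
            "t": self.t,
            "boot_ci": {k: list(v) for k, v in self.boot_ci.items()} if self.boot_ci else None,
            "n_boot": self.n_boot,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, obj: dict) -> "MRSModel":
        return cls(
            names=list(obj["names"]),
            means=np.asarray(obj["means"], float),
            betas=np.asarray(obj["betas"], float),
            lambda_=float(obj["lambda"]),
            gamma=float(obj["gamma"]),
            t=float(obj.get("t", 1.0)),
            boot_ci={k: tuple(v) for k, v in obj["boot_ci"].items()} if obj.get("boot_ci") else None,
            n_boot=int(obj.get("n_boot", 0)),
        )

    @classmethod
    def from_json(cls, path) -> "MRSModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_mrs(empty_fit: WeibullPHFit, multivariable_fit: WeibullPHFit,
              sample_means: dict[str, float], t: float = 1.0,
              boot: "BootstrapWeights | None" = None) -> MRSModel:
    """Assemble the score from the empty-model baseline and the final weights.

    The empty fit contributes (lambda, gamma); the multivariable fit
    contributes the point coefficients, taken verbatim as the score weights;
    ``sample_means`` are the centering constants.
    """
    if empty_fit.names:
        raise ValidationError("empty_fit must have no covariates")
    names = list(multivariable_fit.names)
    if set(names) != set(sample_means):
        raise ValidationError(
            f"sample_means keys {sorted(sample_means)} do not match fit covariates {sorted(names)}"
        )
    return MRSModel(
        names=names,
        means=np.array([sample_means[n] for n in names]),
        betas=multivariable_fit.beta.copy(),
        lambda_=empty_fit.lambda_,
        gamma=empty_fit.gamma,
        t=t,
        boot_ci=None if boot is None else boot.ci,
        n_boot=0 if boot is None else boot.n_boot,
    )


def compute_mrs(model: MRSModel, values) -> np.ndarray | float:
    """Evaluate the score; every score metabolite must be supplied."""
    return model.score(values)


@dataclass
class BootstrapWeights:
    """Empirical bootstrap distribution of the score weights."""

    names: list[str]
    draws: np.ndarray                       # (n_boot, p)
    n_boot: int
    n_redrawn: int
    ci: dict[str, tuple[float, float]] = field(init=False)

    def __post_init__(self) -> None:
        lo = np.percentile(self.draws, 2.5, axis=0)
        hi = np.percentile(self.draws, 97.5, axis=0)
        self.ci = {n: (float(a), float(b)) for n, a, b in zip(self.names, lo, hi)}

    def hr_ci_per_sd(self, sds: dict[str, float]) -> pd.DataFrame:
        """Per-SD hazard-ratio CIs by exponentiating the weight distribution."""
        rows = []
        for j, n in enumerate(self.names):
            hr = np.exp(self.draws[:, j] * sds[n])
            rows.append({"metabolite": n,
                         "hr_low": float(np.percentile(hr, 2.5)),
                         "hr_high": float(np.percentile(hr, 97.5))})
        return pd.DataFrame(rows).set_index("metabolite")


def bootstrap_weights(dataset: SurvivalDataset, metabolites: list[str],
                      n_boot: int = 10_000, seed: int = 0,
                      max_redraw_frac: float = 0.20) -> BootstrapWeights:
    """Patient-level bootstrap of the multivariable Weibull coefficients.

    Resamples with zero events or a non-converged fit are redrawn (counted);
    if more than ``max_redraw_frac`` of the attempts fail the procedure aborts
    with diagnostics rather than report a biased distribution.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be at least 100")
    data = dataset.complete_cases(metabolites)
    if data.n_events < 1:
        raise ValidationError("at least one event required")
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, len(metabolites)))
    n_redrawn = 0
    kept = 0
    attempts = 0
    while kept < n_boot:
        attempts += 1
        if n_redrawn > max_redraw_frac * max(attempts, n_boot):
            raise ConvergenceError(
                f"bootstrap aborted: {n_redrawn} failed resamples in {attempts} attempts"
            )
        idx = rng.integers(0, data.n, size=data.n)
        boot = data.subset(idx)
        if boot.n_events == 0:
            n_redrawn += 1
            continue
        try:
            fit = fit_weibull_ph(boot, metabolites)
        except (ConvergenceError, np.linalg.LinAlgError):
            n_redrawn += 1
            continue
        draws[kept] = fit.beta
        kept += 1
    return BootstrapWeights(names=list(metabolites), draws=draws,
                           n_boot=n_boot, n_redrawn=n_redrawn)
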