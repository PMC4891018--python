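"""Weibull proportional-hazards regression by maximum likelihood.

The model: hazard h(t|x) = gamma * lambda^gamma * t^(gamma-1) * exp(x beta),
so the survivor function is S(t|x) = exp{-(lambda t)^gamma e^{x beta}} and the
baseline survivor S0(t) = exp{-(lambda t)^gamma}.  The scale is tied to the
regression intercept through lambda = 1/exp(beta0).

Fitting is by Newton-Raphson on the unconstrained parameterisation
(ln lambda, ln gamma, beta) with analytic gradient and Hessian, falling back
to BFGS when Newton stalls.  The covariance matrix comes from the observed
information at the optimum.

Also here: per-SD hazard ratios, AIC-guided forward-stepwise selection with
backward Wald checks, a two-order fractional-polynomial linearity check, and
the log(-log KM) vs log(time) graphical diagnostic.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataset import SurvivalDataset, ValidationError

__all__ = [
    "WeibullPHFit",
    "ConvergenceError",
    "fit_weibull_ph",
    "baseline_survivor",
    "hazard_ratio_per_sd",
    "stepwise_select",
    "StepwiseResult",
    "fp2_linearity_check",
    "FPCheckResult",
    "weibull_loglog_diagnostic",
    "LogLogDiagnostic",
    "FP_POWERS",
]

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


class ConvergenceError(RuntimeError):
    """Maximum-likelihood fit failed to converge; message carries diagnostics."""


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _loglik(theta: np.ndarray, t: np.ndarray, d: np.ndarray, X: np.ndarray,
            logt: np.ndarray) -> float:
    c, s = theta[0], min(theta[1], 30.0)  # cap ln(gamma); beyond is -inf-like
    beta = theta[2:]
    gamma = np.exp(s)
    u = gamma * (c + logt) + (X @ beta if beta.size else 0.0)
    u = np.clip(u, -300.0, 300.0)
    z = np.exp(u)
    return float(np.sum(d * (s + u - logt)) - np.sum(z))


def _grad_hess(theta, t, d, X, logt):
    c, s = theta[0], min(theta[1], 30.0)
    beta = theta[2:]
    p = beta.size
    gamma = np.exp(s)
    m = c + logt
    u = gamma * m + (X @ beta if p else 0.0)
    u = np.clip(u, -300.0, 300.0)
    z = np.exp(u)
    r = d - z
    grad = np.empty(2 + p)
    grad[0] = gamma * r.sum()
    grad[1] = d.sum() + gamma * (r * m).sum()
    if p:
        grad[2:] = X.T @ r
    H = np.empty((2 + p, 2 + p))
    zm = z * m
    H[0, 0] = -gamma * gamma * z.sum()
    H[0, 1] = H[1, 0] = gamma * r.sum() - gamma * gamma * zm.sum()
    H[1, 1] = gamma * (r * m).sum() - gamma * gamma * (zm * m).sum()
    if p:
        Xz = X * z[:, None]
        H[0, 2:] = H[2:, 0] = -gamma * Xz.sum(axis=0)
        H[1, 2:] = H[2:, 1] = -gamma * (X * zm[:, None]).sum(axis=0)
        H[2:, 2:] = -(X.T @ Xz)
    return grad, H


def _fit_mle(t, d, X, init=None, max_iter=60, tol=1e-9):
    """Newton with step-halving; returns (theta, loglik, hessian)."""
    t = np.asarray(t, float)
    d = np.asarray(d, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    logt = np.log(t)
    if init is None:
        rate = max(d.sum(), 0.5) / t.sum()  # exponential moment start
        init = np.r_[np.log(rate), 0.0, np.zeros(p)]
    theta = np.asarray(init, float).copy()
    ll = _loglik(theta, t, d, X, logt)
    converged = False
    for _ in range(max_iter):
        grad, H = _grad_hess(theta, t, d, X, logt)
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            break
        # walk uphill; halve until the likelihood improves
        lam = 1.0
        for _ in range(40):
            cand = theta + lam * step
            ll_new = _loglik(cand, t, d, X, logt)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            lam *= 0.5
        else:
            break
        moved = np.max(np.abs(lam * step))
        theta, ll = cand, ll_new
        if np.max(np.abs(grad)) < tol * (1.0 + abs(ll)) and moved < 1e-8:
            converged = True
            break
    if not converged:
        grad, _ = _grad_hess(theta, t, d, X, logt)
        if np.max(np.abs(grad)) < 1e-4 * (1.0 + abs(ll)):
            converged = True
    if not converged:  # quasi-Newton rescue from the same start
        with np.errstate(over="ignore", invalid="ignore"):
            res = optimize.minimize(
                lambda th: -_loglik(th, t, d, X, logt),
                theta,
                jac=lambda th: -_grad_hess(th, t, d, X, logt)[0],
                method="BFGS",
                options={"maxiter": 500, "gtol": 1e-7},
            )
        if not res.success and np.max(np.abs(res.jac)) > 1e-3 * (1.0 + abs(res.fun)):
            raise ConvergenceError(
                f"Weibull MLE did not converge: {res.message}; |grad|={np.max(np.abs(res.jac)):.3g}"
            )
        theta = res.x
        ll = -res.fun
    _, H = _grad_hess(theta, t, d, X, logt)
    return theta, ll, H


# ---------------------------------------------------------------------------
# fit object
# ---------------------------------------------------------------------------

@dataclass
class WeibullPHFit:
    """A converged Weibull proportional-hazards fit.

    ``params`` are ordered (beta0, ln gamma, beta...), with
    lambda = 1/exp(beta0).  ``cov`` is the observed-information covariance on
    that parameterisation.  ``centering`` holds the covariate means subtracted
    before fitting (empty dict when the fit was uncentered).
    """

    names: list[str]
    beta: np.ndarray
    beta0: float
    log_gamma: float
    loglik: float
    cov: np.ndarray
    n_used: int
    n_events: int
    centering: dict[str, float] = field(default_factory=dict)

    @property
    def lambda_(self) -> float:
        return float(np.exp(-self.beta0))

    @property
    def gamma(self) -> float:
        return float(np.exp(self.log_gamma))

    @property
    def n_params(self) -> int:
        return 2 + len(self.names)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def se_beta(self) -> np.ndarray:
        if not self.names:
            return np.empty(0)
        return np.sqrt(np.diag(self.cov)[2:])

    def wald_p(self) -> pd.Series:
        """Two-sided Wald p-value per covariate."""
        se = self.se_beta
        zval = np.divide(self.beta, se, out=np.zeros_like(se), where=se > 0)
        return pd.Series(2.0 * stats.norm.sf(np.abs(zval)), index=self.names)

    def hazard_ratios(self, sds: dict[str, float] | None = None) -> pd.DataFrame:
        """HRs with Wald 95% CIs, per unit or per SD when ``sds`` given."""
        scale = np.array([1.0 if sds is None else sds[n] for n in self.names])
        b, se = self.beta * scale, self.se_beta * scale
        return pd.DataFrame(
            {
                "hr": np.exp(b),
                "ci_low": np.exp(b - 1.959963984540054 * se),
                "ci_high": np.exp(b + 1.959963984540054 * se),
                "p": self.wald_p().to_numpy(),
            },
            index=self.names,
        )

    # -- prediction --------------------------------------------------------
    def linear_predictor(self, covariates: pd.DataFrame) -> np.ndarray:
        X = covariates[self.names].to_numpy(dtype=float)
        if self.centering:
            X = X - np.array([self.centering[n] for n in self.names])
        return X @ self.beta if self.names else np.zeros(len(covariates))

    def predict_survival(self, t: float, covariates: pd.DataFrame) -> np.ndarray:
        """S(t|x) = exp{-(lambda t)^gamma e^{x beta}} at a single horizon."""
        lp = self.linear_predictor(covariates)
        return np.exp(-((self.lambda_ * t) ** self.gamma) * np.exp(lp))

    def predict_risk(self, t: float, covariates: pd.DataFrame) -> np.ndarray:
        """Probability of death by horizon ``t``."""
        return 1.0 - self.predict_survival(t, covariates)

    # -- serialization: the portable model format --------------------------
    def to_dict(self) -> dict:
        return {
            "names": self.names,
            "beta": list(map(float, self.beta)),
            "beta0": self.beta0,
            "log_gamma": self.log_gamma,
            "lambda": self.lambda_,
            "gamma": self.gamma,
            "loglik": self.loglik,
            "aic": self.aic,
            "cov": self.cov.tolist(),
            "n_used": self.n_used,
            "n_events": self.n_events,
            "centering": self.centering,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, obj: dict) -> "WeibullPHFit":
        return cls(
            names=list(obj["names"]),
            beta=np.asarray(obj["beta"], float),
            beta0=float(obj["beta0"]),
            log_gamma=float(obj["log_gamma"]),
            loglik=float(obj["loglik"]),
            cov=np.asarray(obj["cov"], float),
            n_used=int(obj["n_used"]),
            n_events=int(obj["n_events"]),
            centering={k: float(v) for k, v in obj.get("centering", {}).items()},
        )

    @classmethod
    def from_json(cls, path) -> "WeibullPHFit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _fit_arrays(t, d, X, names, centering, init=None) -> WeibullPHFit:
    theta, ll, H = _fit_mle(t, d, X, init=init)
    k = 2 + (X.shape[1] if X.ndim == 2 else (0 if X.size == 0 else 1))
    try:
        cov_int = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        cov_int = np.full((k, k), np.nan)
    # internal order (c=ln lambda, s=ln gamma, beta) -> reported (beta0=-c, s, beta)
    J = np.eye(k)
    J[0, 0] = -1.0
    cov = J @ cov_int @ J
    return WeibullPHFit(
        names=list(names),
        beta=theta[2:].copy(),
        beta0=float(-theta[0]),
        log_gamma=float(theta[1]),
        loglik=ll,
        cov=cov,
        n_used=len(t),
        n_events=int(np.sum(d)),
        centering=dict(centering),
    )


def fit_weibull_ph(dataset: SurvivalDataset, covariate_names: list[str] | None = None,
                   center: bool = False) -> WeibullPHFit:
    """Fit the Weibull PH model by maximum likelihood.

    Requested covariates must be complete (impute or drop beforehand).  With
    ``center=True`` the covariates are mean-centered and the constants stored
    on the fit, so predictions and the risk score can be expressed around the
    sample means.
    """
    names = list(covariate_names or [])
    dataset.require_columns(names)
    if dataset.n_events < 1:
        raise ValidationError("at least one event is required to fit a survival model")
    X = dataset.matrix(names) if names else np.empty((dataset.n, 0))
    if np.isnan(X).any():
        raise ValidationError(
            "missing values among requested covariates; impute or take complete cases first"
        )
    centering: dict[str, float] = {}
    if center and names:
        means = X.mean(axis=0)
        centering = {n: float(mu) for n, mu in zip(names, means)}
        X = X - means
    return _fit_arrays(dataset.time, dataset.event.astype(float), X, names, centering)


# ---------------------------------------------------------------------------
# elementary quantities
# ---------------------------------------------------------------------------

def baseline_survivor(lambda_: float, gamma: float, t) -> np.ndarray | float:
    """S0(t) = exp{-(lambda t)^gamma}."""
    if lambda_ <= 0 or gamma <= 0:
        raise ValidationError("lambda and gamma must be strictly positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("time must be non-negative")
    out = np.exp(-((lambda_ * t_arr) ** gamma))
    return float(out) if np.isscalar(t) or out.ndim == 0 else out


def hazard_ratio_per_sd(beta: float, sd: float) -> float:
    """Hazard ratio for a one-SD increase of the covariate: exp(beta*sd)."""
    if sd <= 0:
        raise ValidationError("sd must be strictly positive")
    return float(np.exp(beta * sd))


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

@dataclass
class StepwiseResult:
    selected: list[str]
    fit: WeibullPHFit
    trace: pd.DataFrame  # one row per step: action, variable, aic, p


def stepwise_select(dataset: SurvivalDataset, candidates: list[str],
                    p_enter: float = 0.10, p_stay: float = 0.05) -> StepwiseResult:
    """Forward stepwise with backward Wald checks.

    At each forward step every not-yet-included candidate is test-fitted; those
    whose Wald p-value is below ``p_enter`` are eligible and the eligible
    candidate minimising AIC enters.  After each entry, included variables with
    Wald p above ``p_stay`` are removed (worst first).  Ties in AIC break by
    candidate order, so the procedure is deterministic.  Complete cases over
    all candidates are used throughout so AICs are comparable.
    """
    dataset.require_columns(candidates)
    data = dataset.complete_cases(candidates) if candidates else dataset
    if candidates and data.n < 2 * len(candidates):
        warnings.warn(
            f"only {data.n} complete cases for {len(candidates)} candidates; "
            "stepwise selection may be unstable",
            stacklevel=2,
        )
    included: list[str] = []
    rows = []
    seen_states = {tuple()}
    while True:
        best = None  # (aic, order, name, fit, p)
        for k, name in enumerate(c for c in candidates if c not in included):
            try:
                fit = fit_weibull_ph(data, included + [name])
            except ConvergenceError:
                continue
            p = float(fit.wald_p()[name])
            if p < p_enter and (best is None or fit.aic < best[0] - 1e-12):
                best = (fit.aic, k, name, fit, p)
        if best is None:
            break
        _, _, name, fit, p = best
        included.append(name)
        rows.append({"action": "enter", "variable": name, "aic": fit.aic, "p": p})
        # backward purge
        while included:
            pvals = fit.wald_p()[included]
            worst = pvals.idxmax()
            if pvals[worst] <= p_stay:
                break
            included.remove(worst)
            fit = fit_weibull_ph(data, included)
            rows.append({"action": "remove", "variable": worst, "aic": fit.aic,
                         "p": float(pvals[worst])})
        state = tuple(sorted(included))
        if state in seen_states:  # cycling guard
            break
        seen_states.add(state)
    final = fit_weibull_ph(data, included)
    trace = pd.DataFrame(rows, columns=["action", "variable", "aic", "p"])
    return StepwiseResult(selected=included, fit=final, trace=trace)


# ---------------------------------------------------------------------------
# fractional polynomials
# ---------------------------------------------------------------------------

def _fp_terms(x: np.ndarray, powers: tuple[float, ...]) -> np.ndarray:
    """FP basis columns; power 0 means log, a repeated power brings x^p*ln x."""
    cols = []
    prev = None
    for p in powers:
        base = np.log(x) if p == 0 else x ** p
        if prev is not None and p == prev:
            base = base * np.log(x)
        cols.append(base)
        prev = p
    return np.column_stack(cols)


@dataclass
class FPCheckResult:
    verdict: str               # "linear" | "FP1" | "FP2"
    deviance_table: pd.DataFrame
    p_fp2_vs_linear: float
    p_fp2_vs_fp1: float
    best_fp1: tuple[float, ...]
    best_fp2: tuple[float, ...]
    shift: float
    scale: float


def fp2_linearity_check(dataset: SurvivalDataset, covariate: str,
                        alpha: float = 0.05) -> FPCheckResult:
    """Closed test of linearity against one- and two-term fractional polynomials.

    All candidate transforms x^p, p in {-2,-1,-0.5,0,0.5,1,2,3} (0 = log,
    repeated power p gives x^p ln x) are fitted inside the Weibull PH
    likelihood.  First the best FP2 is compared with the linear model (3 df);
    if that is significant, FP2 is compared with the best FP1 (2 df).
    """
    data = dataset.complete_cases([covariate])
    if data.n_events < 10:
        raise ValidationError(
            f"only {data.n_events} events; fractional-polynomial comparison needs >=10"
        )
    x = data.matrix([covariate])[:, 0]
    if np.ptp(x) == 0:
        raise ValidationError(f"covariate '{covariate}' is constant; no functional form to test")
    shift = 0.0
    if x.min() <= 0:
        pos = np.sort(np.unique(x))
        incr = np.min(np.diff(pos)) if pos.size > 1 else 1.0
        shift = float(incr - x.min())
        x = x + shift
    scale = float(10.0 ** np.round(np.log10(np.median(x))))
    x = x / scale

    t, d = data.time, data.event.astype(float)

    def deviance(powers: tuple[float, ...]) -> float:
        fit = _fit_arrays(t, d, _fp_terms(x, powers), [f"fp{p}" for p in powers], {})
        return -2.0 * fit.loglik

    records = []
    dev_lin = deviance((1.0,))
    best1 = min(((deviance((p,)), (p,)) for p in FP_POWERS), key=lambda z: z[0])
    combos = [tuple(c) for c in itertools.combinations_with_replacement(FP_POWERS, 2)]
    best2 = min(((deviance(c), c) for c in combos), key=lambda z: z[0])
    records.append({"model": "linear", "powers": (1.0,), "deviance": dev_lin})
    records.append({"model": "FP1", "powers": best1[1], "deviance": best1[0]})
    records.append({"model": "FP2", "powers": best2[1], "deviance": best2[0]})

    p_lin = stats.chi2.sf(max(dev_lin - best2[0], 0.0), df=3)
    p_fp1 = stats.chi2.sf(max(best1[0] - best2[0], 0.0), df=2)
    if p_lin >= alpha:
        verdict = "linear"
    elif p_fp1 < alpha:
        verdict = "FP2"
    else:
        verdict = "FP1"
    return FPCheckResult(
        verdict=verdict,
        deviance_table=pd.DataFrame(records),
        p_fp2_vs_linear=float(p_lin),
        p_fp2_vs_fp1=float(p_fp1),
        best_fp1=best1[1],
        best_fp2=best2[1],
        shift=shift,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# log(-log) diagnostic
# ---------------------------------------------------------------------------

@dataclass
class LogLogDiagnostic:
    log_time: np.ndarray
    loglog_survival: np.ndarray
    slope: float
    intercept: float
    r_squared: float


def weibull_loglog_diagnostic(dataset: SurvivalDataset) -> LogLogDiagnostic:
    """ln(-ln KM) against ln(t): near-linear with slope gamma under Weibull."""
    from lifelines import KaplanMeierFitter

    if dataset.n_events == 0:
        raise ValidationError("no events; cannot form the log(-log) diagnostic")
    event_times = np.unique(dataset.time[dataset.event == 1])
    if event_times.size < 2:
        raise ValidationError("need at least 2 distinct event times")
    km = KaplanMeierFitter().fit(dataset.time, dataset.event)
    s = km.survival_function_at_times(event_times).to_numpy()
    keep = (s > 0) & (s < 1)
    if keep.sum() < 2:
        raise ValidationError("KM estimate degenerate; diagnostic undefined")
    x = np.log(event_times[keep])
    y = np.log(-np.log(s[keep]))
    slope, intercept, r, _, _ = stats.linregress(x, y)
    return LogLogDiagnostic(
        log_time=x, loglog_survival=y,
        slope=float(slope), intercept=float(intercept), r_squared=float(r * r),
    )
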