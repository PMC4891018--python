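"""Discrimination and descriptive statistics for censored survival data.

The discrimination measure is a Harrell-type concordance on predicted
one-year mortality probabilities: a pair of patients is usable when the
shorter observed time ends in an event, concordant when the higher predicted
risk belongs to the patient who failed earlier, and risk ties count one half.
Confidence intervals and model comparisons use patient-level bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import SurvivalDataset, ValidationError

__all__ = [
    "ConcordanceResult",
    "cstat_censored",
    "compare_cstats",
    "CStatComparison",
    "kaplan_meier",
    "KaplanMeierCurve",
    "mortality_rate",
    "MortalityRate",
    "clinical_associations",
]


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def _concordance_counts(time: np.ndarray, event: np.ndarray, risk: np.ndarray):
    """(concordant + 0.5*ties, usable pairs, risk-tie count) over usable pairs.

    Vectorised over all n^2 ordered pairs: pair (i, j) with t_i < t_j is
    usable iff patient i died; equal observed times are usable when exactly
    one of the two died (the death is taken as the earlier failure).
    """
    n = len(time)
    t_i = time[:, None]
    t_j = time[None, :]
    d_i = event[:, None].astype(bool)
    d_j = event[None, :].astype(bool)
    r_i = risk[:, None]
    r_j = risk[None, :]
    # i is the earlier, observed failure
    usable = (d_i & (t_i < t_j)) | (d_i & ~d_j & (t_i == t_j))
    conc = usable & (r_i > r_j)
    ties = usable & (r_i == r_j)
    n_usable = int(usable.sum())
    n_conc = conc.sum() + 0.5 * ties.sum()
    return float(n_conc), n_usable, int(ties.sum())


@dataclass
class ConcordanceResult:
    cstat: float
    ci_low: float
    ci_high: float
    n_usable_pairs: int
    n_risk_ties: int


def cstat_censored(risk: np.ndarray, dataset: SurvivalDataset,
                   n_boot: int = 1000, seed: int = 0) -> ConcordanceResult:
    """Censoring-aware concordance of predicted risks, with bootstrap 95% CI."""
    risk = np.asarray(risk, float)
    if risk.shape != dataset.time.shape:
        raise ValidationError("risk vector length must match the dataset")
    if not np.all(np.isfinite(risk)):
        raise ValidationError("risk values must be finite")
    num, n_pairs, n_ties = _concordance_counts(dataset.time, dataset.event, risk)
    if n_pairs == 0:
        raise ValidationError("no usable pairs (no events?); concordance undefined")
    c = num / n_pairs
    from .forest import _concordance_error  # numba kernel for the resamples

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, dataset.n, size=dataset.n)
        if dataset.event[idx].sum() > 0:
            boots.append(1.0 - _concordance_error(
                dataset.time[idx], dataset.event[idx].astype(np.int64), risk[idx]))
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan))
    return ConcordanceResult(
        cstat=float(c),
        ci_low=float(np.clip(lo, 0, 1)),
        ci_high=float(np.clip(hi, 0, 1)),
        n_usable_pairs=n_pairs,
        n_risk_ties=n_ties,
    )


@dataclass
class CStatComparison:
    cstat_a: float
    cstat_b: float
    difference: float
    ci_low: float
    ci_high: float
    p_value: float


def compare_cstats(risk_a: np.ndarray, risk_b: np.ndarray, dataset: SurvivalDataset,
                   n_boot: int = 1000, seed: int = 0) -> CStatComparison:
    """Paired bootstrap comparison of two predictors' concordance.

    The two-sided p-value comes from the empirical distribution of the
    bootstrap differences centered at the observed difference.
    """
    risk_a = np.asarray(risk_a, float)
    risk_b = np.asarray(risk_b, float)
    if risk_a.shape != risk_b.shape or risk_a.shape != dataset.time.shape:
        raise ValidationError("risk vectors must match the dataset length")
    ca = cstat_censored(risk_a, dataset, n_boot=0)
    cb = cstat_censored(risk_b, dataset, n_boot=0)
    diff = ca.cstat - cb.cstat
    from .forest import _concordance_error  # numba kernel for the resamples

    rng = np.random.default_rng(seed)
    diffs = []
    for _ in range(n_boot):
        idx = rng.integers(0, dataset.n, size=dataset.n)
        t, e = dataset.time[idx], dataset.event[idx].astype(np.int64)
        if e.sum() == 0:
            continue
        diffs.append((1.0 - _concordance_error(t, e, risk_a[idx]))
                     - (1.0 - _concordance_error(t, e, risk_b[idx])))
    diffs = np.asarray(diffs)
    if diffs.size == 0:
        raise ValidationError("bootstrap produced no usable resamples")
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    centered = diffs - diffs.mean()
    p = (np.sum(np.abs(centered) >= abs(diff)) + 1.0) / (diffs.size + 1.0)
    return CStatComparison(
        cstat_a=ca.cstat, cstat_b=cb.cstat, difference=float(diff),
        ci_low=float(lo), ci_high=float(hi), p_value=float(min(p, 1.0)),
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KaplanMeierCurve:
    """Product-limit estimate with its risk table; optionally per stratum."""

    table: pd.DataFrame  # columns: stratum, time, at_risk, events, censored, survival

    def survival_at(self, t: float, stratum=None) -> float:
        tab = self.table if stratum is None else self.table[self.table["stratum"] == stratum]
        tab = tab[tab["time"] <= t]
        return float(tab["survival"].iloc[-1]) if len(tab) else 1.0

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def kaplan_meier(dataset: SurvivalDataset, strata: np.ndarray | None = None) -> KaplanMeierCurve:
    """Kaplan-Meier estimate, stratified when class labels are supplied."""
    if dataset.n == 0:
        raise ValidationError("empty dataset")
    from lifelines import KaplanMeierFitter

    labels = np.zeros(dataset.n, int) if strata is None else np.asarray(strata)
    rows = []
    for lab in np.unique(labels):
        mask = labels == lab
        km = KaplanMeierFitter().fit(dataset.time[mask], dataset.event[mask])
        tab = km.event_table.iloc[1:] if 0.0 in km.event_table.index and \
            km.event_table.loc[0.0, "observed"] == 0 and km.event_table.loc[0.0, "censored"] == 0 \
            else km.event_table
        surv = km.survival_function_at_times(tab.index).to_numpy()
        for t, at_risk, obs, cen, s in zip(tab.index, tab["at_risk"], tab["observed"],
                                           tab["censored"], surv):
            rows.append({"stratum": lab, "time": float(t), "at_risk": int(at_risk),
                         "events": int(obs), "censored": int(cen), "survival": float(s)})
    return KaplanMeierCurve(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# incidence
# ---------------------------------------------------------------------------

@dataclass
class MortalityRate:
    events: int
    person_years: float
    rate_per_100py: float


def mortality_rate(dataset: SurvivalDataset, horizon: float | None = None) -> MortalityRate:
    """Events per 100 person-years, optionally truncating follow-up at a horizon."""
    if horizon is not None and horizon <= 0:
        raise ValidationError("horizon must be positive")
    time = dataset.time
    event = dataset.event.astype(bool)
    if horizon is not None:
        event = event & (time <= horizon)
        time = np.minimum(time, horizon)
    py = float(time.sum())
    if py <= 0:
        raise ValidationError("zero total person-years")
    ev = int(event.sum())
    return MortalityRate(events=ev, person_years=py, rate_per_100py=100.0 * ev / py)


# ---------------------------------------------------------------------------
# clinical associations
# ---------------------------------------------------------------------------

def clinical_associations(dataset: SurvivalDataset, clinical_vars: list[str],
                          metabolites: list[str], fdr: bool = False,
                          max_levels_categorical: int = 6) -> pd.DataFrame:
    """Rank-based association screen between clinical variables and metabolites.

    Continuous-continuous pairs use Spearman correlation; a clinical variable
    with few distinct values is treated as a grouping factor and tested by
    Mann-Whitney (2 groups) or Kruskal-Wallis (3+).  Raw p-values are reported;
    ``fdr=True`` appends Benjamini-Hochberg adjusted ones.
    """
    dataset.require_columns(list(clinical_vars) + list(metabolites))
    rows = []
    for cv in clinical_vars:
        cvals = dataset.covariates[cv]
        n_levels = cvals.dropna().nunique()
        for met in metabolites:
            mvals = dataset.covariates[met]
            ok = cvals.notna() & mvals.notna()
            x, y = cvals[ok].to_numpy(), mvals[ok].to_numpy()
            if n_levels <= 1 or np.ptp(y) == 0 or len(x) < 3:
                rows.append({"variable": cv, "metabolite": met, "test": "undefined",
                             "estimate": np.nan, "p": np.nan})
                continue
            if n_levels == 2:
                g = np.unique(x)
                stat, p = stats.mannwhitneyu(y[x == g[0]], y[x == g[1]],
                                             alternative="two-sided")
                rows.append({"variable": cv, "metabolite": met, "test": "mann-whitney",
                             "estimate": float(stat), "p": float(p)})
            elif n_levels <= max_levels_categorical:
                groups = [y[x == g] for g in np.unique(x)]
                stat, p = stats.kruskal(*groups)
                rows.append({"variable": cv, "metabolite": met, "test": "kruskal-wallis",
                             "estimate": float(stat), "p": float(p)})
            else:
                rho, p = stats.spearmanr(x, y)
                rows.append({"variable": cv, "metabolite": met, "test": "spearman",
                             "estimate": float(rho), "p": float(p)})
    out = pd.DataFrame(rows)
    if fdr and len(out):
        out["p_bh"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    mask = np.isfinite(p)
    q = np.full_like(p, np.nan, dtype=float)
    pm = p[mask]
    m = pm.size
    order = np.argsort(pm)
    ranked = pm[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    vals = np.empty(m)
    vals[order] = np.clip(ranked, 0, 1)
    q[mask] = vals
    return q
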