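#!/usr/bin/env python
"""Discrimination, incidence and clinical-association summaries.

Compares the score's censored c-statistic against a clinical comparator
(an LDH+age Weibull model's one-year predicted probabilities), reports the
one-year mortality rate per 100 person-years, and screens clinical variables
against the score metabolites with rank tests / Spearman correlations.
"""

from pathlib import Path

import pandas as pd

from mrsurv.dataset import SurvivalDataset
from mrsurv.evaluation import (
    clinical_associations,
    compare_cstats,
    cstat_censored,
    mortality_rate,
)
from mrsurv.weibull import fit_weibull_ph

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "analysis"

scored = pd.read_csv(OUT / "scored_cohort.csv")
cohort = SurvivalDataset.from_csv(ROOT / "cohorts" / "cohort_desk.csv")
risk_mrs = scored["mrs"].to_numpy()

res = cstat_censored(risk_mrs, cohort, seed=3)
print(f"MRS c-statistic: {res.cstat:.3f} "
      f"(95% CI {res.ci_low:.3f}-{res.ci_high:.3f}; "
      f"{res.n_usable_pairs} usable pairs)")

clin = cohort.complete_cases(["LDH", "age"])
clin_fit = fit_weibull_ph(clin, ["LDH", "age"])
risk_clin = clin_fit.predict_risk(1.0, cohort.covariates)
cmp = compare_cstats(risk_mrs, risk_clin, cohort, seed=4)
print(f"clinical comparator c-statistic: {cmp.cstat_b:.3f}; "
      f"difference {cmp.difference:+.3f} (p = {cmp.p_value:.4f})")

rate = mortality_rate(cohort, horizon=1.0)
print(f"one-year mortality: {rate.events}/{rate.person_years:.0f} py "
      f"({rate.rate_per_100py:.1f} per 100 py)")

assoc = clinical_associations(
    cohort, ["LDH", "smoking", "alcohol"],
    [c for c in cohort.covariate_names if not c.startswith(("noise", "LDH"))
     and c not in ("age", "smoking", "alcohol")])
assoc.round(4).to_csv(OUT / "clinical_associations.csv", index=False)
sig = assoc[assoc["p"] < 0.05]
print(f"clinical associations: {len(sig)}/{len(assoc)} significant at 0.05")
print(sig.round(3).to_string(index=False))

pd.DataFrame({
    "metric": ["cstat_mrs", "cstat_clinical", "cstat_diff_p",
               "mortality_rate_per_100py"],
    "value": [res.cstat, cmp.cstat_b, cmp.p_value, rate.rate_per_100py],
}).to_csv(OUT / "evaluation_metrics.csv", index=False)
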