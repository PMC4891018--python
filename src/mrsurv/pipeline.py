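"""End-to-end orchestration of the three-step score-building procedure.

Step 1: exclude covariates with more than 25% missingness, impute the rest
inside a random survival forest and rank covariates by permutation
importance.  Step 2: keep metabolites with at least 20% relative importance,
run AIC-guided stepwise Weibull selection, check linearity with fractional
polynomials and interactions with RECPAM.  Step 3: build the risk score from
the final coefficients, bootstrap the weights, discover risk classes by
RECPAM on the score, and evaluate discrimination.

Every stage is a pure function of (input data, config, seeds); artifacts are
written as CSV/JSON with a checksum manifest, so two runs from the same
config are byte-identical apart from the timestamped run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, forest, recpam, score, synthetic, weibull
from .dataset import SurvivalDataset, ValidationError

__all__ = ["PipelineConfig", "PipelineError", "RunReport", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run (YAML-loadable).

    Exactly one of ``input_csv`` / ``synthetic`` must be given.  All stage
    seeds are explicit so the run is reproducible end to end.
    """

    output_dir: str
    input_csv: str | None = None
    synthetic: dict | None = None
    metabolites: list[str] | None = None   # default: all non-clinical covariates
    clinical: list[str] = field(default_factory=list)
    confounders: list[str] = field(default_factory=list)
    missing_rate_threshold: float = 0.25
    n_trees: int = 1000
    mtry: int | None = None
    min_terminal_events: int = 1
    importance_threshold: float = 0.20
    p_enter: float = 0.10
    p_stay: float = 0.05
    n_boot: int = 1000
    horizon: float = 1.0
    recpam_min_node_events: int = 3
    seeds: dict = field(default_factory=lambda: {"forest": 1, "bootstrap": 2, "evaluation": 3})

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.synthetic is None):
            raise ValidationError("exactly one of input_csv / synthetic must be set")
        for key in ("forest", "bootstrap", "evaluation"):
            if key not in self.seeds:
                raise ValidationError(f"seeds must name every stage; missing '{key}'")
        if self.synthetic is not None and "seed" not in self.synthetic:
            raise ValidationError("synthetic spec must carry an explicit seed")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh)
        return cls(**obj)


@dataclass
class RunReport:
    screen: forest.ScreenResult
    importance: forest.VariableImportance
    importance_selected: list[str]
    stepwise: weibull.StepwiseResult
    fp2_verdicts: dict[str, str]
    interaction: recpam.InteractionCheck | None
    empty_fit: weibull.WeibullPHFit
    final_fit: weibull.WeibullPHFit
    mrs_model: score.MRSModel
    bootstrap: score.BootstrapWeights | None
    risk: np.ndarray
    classes_tree: recpam.RecpamTree | None
    metrics: dict
    confounder_table: pd.DataFrame | None


def _load_data(config: PipelineConfig):
    if config.input_csv is not None:
        ds = SurvivalDataset.from_csv(config.input_csv)
        truth = None
    else:
        spec = synthetic.CohortSpec(**config.synthetic)
        cohort = synthetic.generate_cohort(spec)
        ds = cohort.dataset
        truth = cohort
    mets = config.metabolites
    if mets is None:
        mets = [c for c in ds.covariate_names
                if c not in set(config.clinical) | set(config.confounders)]
    ds.require_columns(mets + list(config.clinical) + list(config.confounders))
    return ds, mets, truth


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunReport:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(f"[{time.strftime('%Y-%m-%d %H:%M:%S')}] {msg}")

    def stage(name: str, fn):
        try:
            out = fn()
        except Exception as exc:  # halt with the stage name attached
            log(f"FAILED {name}: {exc}")
            (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
            raise PipelineError(name, exc) from exc
        log(f"completed {name}")
        return out

    artifacts: dict[str, Path] = {}

    def save_json(name: str, obj) -> None:
        p = outdir / name
        with open(p, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)
        artifacts[name] = p

    ds, mets, _truth = stage("load_data", lambda: _load_data(config))
    ds.to_csv(outdir / "cohort.csv")
    artifacts["cohort.csv"] = outdir / "cohort.csv"
    log(f"data: n={ds.n}, events={ds.n_events}, metabolites={len(mets)}")

    fcfg = forest.ForestConfig(
        n_trees=config.n_trees, mtry=config.mtry,
        min_terminal_events=config.min_terminal_events,
        seed=config.seeds["forest"],
        missing_rate_threshold=config.missing_rate_threshold,
    )

    # ---- Step 1: missingness screen, in-forest imputation, importance ----
    mets_ds = SurvivalDataset(ds.time, ds.event, ds.covariates[mets])
    scr = stage("screen", lambda: forest.screen_covariates(
        mets_ds, config.missing_rate_threshold))
    save_json("screen.json", {
        "retained": scr.retained, "removed": scr.removed,
        "missing_rates": {k: float(v) for k, v in scr.missing_rates.items()},
    })
    mets_kept = scr.retained
    ds_imp = stage("impute", lambda: forest.impute_missing_in_forest(
        SurvivalDataset(ds.time, ds.event, ds.covariates[mets_kept]), fcfg))

    fit_forest = stage("forest", lambda: forest.grow_forest(ds_imp, fcfg))
    vimp = stage("importance", lambda: forest.permutation_importance(fit_forest))
    vimp.to_csv(outdir / "importance.csv")
    artifacts["importance.csv"] = outdir / "importance.csv"
    selected_rsf = forest.apply_importance_screen(vimp, config.importance_threshold)
    log(f"forest OOB error {fit_forest.oob_error:.4f}; "
        f"{len(selected_rsf)} covariates pass the importance screen")

    # ---- Step 2: stepwise Weibull, linearity and interaction checks ------
    step = stage("stepwise", lambda: weibull.stepwise_select(
        ds_imp, selected_rsf, config.p_enter, config.p_stay))
    save_json("stepwise.json", {
        "selected": step.selected,
        "trace": step.trace.to_dict(orient="records"),
        "fit": step.fit.to_dict(),
    })
    fp2 = {}
    for met in step.selected:
        try:
            fp2[met] = weibull.fp2_linearity_check(ds_imp, met).verdict
        except ValidationError as exc:
            fp2[met] = f"not assessed ({exc})"
    save_json("fp2.json", fp2)
    inter = None
    if len(step.selected) >= 2:
        inter = stage("interaction_check", lambda: recpam.interaction_check(
            ds_imp, step.selected, min_node_events=config.recpam_min_node_events))
        save_json("interaction.json", {
            "verdict": inter.verdict, "additive_aic": inter.additive_aic,
            "tree_aic": inter.tree_aic,
        })

    # ---- Step 3: the score, bootstrap stability, risk classes ------------
    empty_fit = stage("empty_fit", lambda: weibull.fit_weibull_ph(ds_imp))
    final_fit = stage("final_fit", lambda: weibull.fit_weibull_ph(ds_imp, step.selected))
    boot = None
    if step.selected and config.n_boot >= 100:
        boot = stage("bootstrap_weights", lambda: score.bootstrap_weights(
            ds_imp, step.selected, n_boot=config.n_boot, seed=config.seeds["bootstrap"]))
    means = {m: float(ds_imp.covariates[m].mean()) for m in step.selected}
    mrs_model = stage("build_mrs", lambda: score.build_mrs(
        empty_fit, final_fit, means, t=config.horizon, boot=boot))
    mrs_model.to_json(outdir / "mrs_model.json")
    artifacts["mrs_model.json"] = outdir / "mrs_model.json"

    risk = np.asarray(score.compute_mrs(mrs_model, ds_imp.covariates)) \
        if step.selected else empty_fit.predict_risk(config.horizon, ds_imp.covariates)
    scored = ds.to_frame()
    scored["mrs"] = np.round(risk, 10)
    scored.to_csv(outdir / "scored_cohort.csv", index=False)
    artifacts["scored_cohort.csv"] = outdir / "scored_cohort.csv"

    tree = None
    labels = None
    score_ds = SurvivalDataset(ds.time, ds.event, pd.DataFrame({"mrs": risk}))
    try:
        tree = recpam.fit_recpam(score_ds, ["mrs"],
                                 min_node_events=config.recpam_min_node_events)
        tree.to_json(outdir / "recpam_tree.json")
        artifacts["recpam_tree.json"] = outdir / "recpam_tree.json"
        labels = tree.classify(pd.DataFrame({"mrs": risk}))
        log(f"RECPAM classes: {tree.n_classes}")
    except ValidationError as exc:
        log(f"RECPAM skipped: {exc}")

    # ---- evaluation ------------------------------------------------------
    eval_seed = config.seeds["evaluation"]
    conc = stage("cstat", lambda: evaluation.cstat_censored(
        risk, ds_imp, seed=eval_seed))
    mrate = evaluation.mortality_rate(ds_imp, horizon=config.horizon)
    km = evaluation.kaplan_meier(ds_imp, strata=labels)
    km.to_csv(outdir / "km_curves.csv")
    artifacts["km_curves.csv"] = outdir / "km_curves.csv"
    # score by survivor status for the boxplot analogue
    pd.DataFrame({"mrs": risk, "event": ds.event}).to_csv(
        outdir / "mrs_by_status.csv", index=False)
    artifacts["mrs_by_status.csv"] = outdir / "mrs_by_status.csv"

    metrics = {
        "oob_error": fit_forest.oob_error,
        "cstat": conc.cstat, "cstat_ci": [conc.ci_low, conc.ci_high],
        "mortality_rate_per_100py": mrate.rate_per_100py,
        "events": mrate.events, "person_years": mrate.person_years,
        "final_aic": final_fit.aic, "empty_lambda": empty_fit.lambda_,
        "empty_gamma": empty_fit.gamma,
        "n_classes": None if tree is None else tree.n_classes,
    }

    # confounder-adjusted refits: one by one and all together
    conf_tab = None
    if config.confounders and step.selected:
        rows = []
        base_hr = np.exp(final_fit.beta)
        for m, h in zip(step.selected, base_hr):
            rows.append({"model": "unadjusted", "metabolite": m, "hr": float(h)})
        sets = [[c] for c in config.confounders] + [list(config.confounders)]
        for cset in sets:
            label = "+".join(cset)
            try:
                adj = weibull.fit_weibull_ph(
                    ds.complete_cases(step.selected + cset), step.selected + cset)
                for m in step.selected:
                    hr = float(np.exp(adj.beta[adj.names.index(m)]))
                    rows.append({"model": f"adjusted:{label}", "metabolite": m, "hr": hr})
            except (ValidationError, weibull.ConvergenceError) as exc:
                log(f"confounder adjustment '{label}' skipped: {exc}")
        conf_tab = pd.DataFrame(rows)
        conf_tab.to_csv(outdir / "confounder_adjustment.csv", index=False)
        artifacts["confounder_adjustment.csv"] = outdir / "confounder_adjustment.csv"

    save_json("metrics.json", metrics)
    manifest = {
        "config": dataclasses.asdict(config),
        "artifacts": {name: _sha256(p) for name, p in sorted(artifacts.items())},
    }
    save_json("manifest.json", manifest)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")

    return RunReport(
        screen=scr, importance=vimp, importance_selected=selected_rsf,
        stepwise=step, fp2_verdicts=fp2, interaction=inter,
        empty_fit=empty_fit, final_fit=final_fit, mrs_model=mrs_model,
        bootstrap=boot, risk=risk, classes_tree=tree, metrics=metrics,
        confounder_table=conf_tab,
    )
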