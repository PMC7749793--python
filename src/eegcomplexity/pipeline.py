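"""End-to-end orchestration: features -> RCI -> imputation -> pooled models.

The central entry point is :func:`analyze_decline`, which regresses the
3-year overall reliable-change index of the patient group on each of the
four baseline EEG predictors (theta TE and theta relative BP, each in the
EC and EO condition), with multiply-imputed scores, per-imputation stepwise
confounder selection, a majority vote, Rubin-pooled coefficients and LMG
importance shares.  :func:`run_pipeline` wires the full analysis together
and writes every artifact (tables as CSV, structured results as JSON) with
the configuration echoed for provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cognition import RCIResult, ScorePanel, overall_rci
from .features import CANONICAL_BANDS, FeatureTable, TEConfig, compute_feature_table
from .group_stats import (
    compare_groups,
    extreme_groups,
    results_frame,
    te_bp_correlation,
    transition_contrast,
)
from .inference import (
    ImportanceShares,
    ImputedStack,
    PooledRegression,
    impute,
    lmg_importance,
    majority_vote,
    pooled_regression,
    stepwise_select,
)
from .simulate import Cohort, Coupling, SimulationConfig, simulate_cohort
from .stability import resample_global_te

logger = logging.getLogger(__name__)

#: Candidate confounders considered by the stepwise selection.
CONFOUNDERS = ("age", "education", "sex", "disease_duration", "led", "sleepiness")


@dataclass
class ModelResult:
    """One predictor x condition row of the pooled-regression table."""

    feature: str  # "te" or "bp"
    condition: str  # "EC" or "EO"
    pooled: PooledRegression
    importance: ImportanceShares
    consensus: list[str]

    @property
    def predictor_p(self) -> float:
        return float(self.pooled.p_values[self.pooled.predictor])

    @property
    def predictor_estimate(self) -> float:
        return float(self.pooled.estimates[self.pooled.predictor])


def _encode_confounders(subjects: pd.DataFrame) -> pd.DataFrame:
    """Numeric confounder block indexed by subject_id (sex coded f=1, m=0)."""
    conf = subjects.set_index("subject_id")[list(CONFOUNDERS)].copy()
    conf["sex"] = (subjects.set_index("subject_id")["sex"] == "f").astype(float)
    return conf


def _panel_wide_numeric(panel: ScorePanel) -> tuple[pd.DataFrame, list[tuple]]:
    wide = panel.wide()
    cols = list(wide.columns)
    flat = wide.copy()
    flat.columns = [f"{t}|{tp}" for t, tp in cols]
    return flat, cols


def _rci_from_completed(
    completed: pd.DataFrame, cols: list[tuple], panel: ScorePanel, horizon: str
) -> RCIResult:
    scores = completed.copy()
    scores.columns = pd.MultiIndex.from_tuples(cols, names=["test", "timepoint"])
    long = scores.stack(list(range(scores.columns.nlevels)), future_stack=True)
    long = long.rename("value").reset_index()
    long = long.rename(columns={long.columns[0]: "subject"})
    return overall_rci(
        ScorePanel(scores=long, tests=panel.tests), horizon=horizon
    )


def impute_scores(
    panel: ScorePanel,
    m: int = 20,
    seed: int = 0,
    n_iter: int = 5,
    horizon: str = "y3",
) -> tuple[ImputedStack, list[pd.Series]]:
    """Impute the raw score panel and derive one overall RCI per imputation.

    Imputation operates on the wide subject x (test, timepoint) matrix, so
    every available test at every visit informs the fill-in.  Returns the
    stack of completed score matrices and the per-imputation overall RCI.
    """
    flat, cols = _panel_wide_numeric(panel)
    stack = impute(flat, m=m, seed=seed, n_iter=n_iter)
    rcis = [
        _rci_from_completed(ds, cols, panel, horizon).overall
        for ds in stack.datasets
    ]
    return stack, rcis


def impute_rci(
    panel: ScorePanel,
    m: int = 20,
    seed: int = 0,
    n_iter: int = 5,
    horizon: str = "y3",
) -> list[pd.Series]:
    """Cheaper variant: impute per-test RCIs instead of raw scores.

    Per-test reliable change is computed from observed scores (missing where
    either visit is missing) and the 16 RCI columns are imputed jointly;
    domain and overall averages are then exact per imputation.  Statistically
    close to :func:`impute_scores` at a fraction of the cost; used for
    replicated simulations.
    """
    base = overall_rci(panel, horizon=horizon)
    per_test = base.per_test  # subjects x 16, NaN where unobserved
    stack = impute(per_test, m=m, seed=seed, n_iter=n_iter)
    domain_of = panel.tests.set_index("test")["domain"]
    rcis = []
    for ds in stack.datasets:
        per_domain = ds.T.groupby(domain_of).mean().T
        rcis.append(per_domain.mean(axis=1).rename(base.overall.name))
    return rcis


def analyze_decline(
    table: FeatureTable,
    panel: ScorePanel,
    subjects: pd.DataFrame,
    band: str = "theta",
    horizon: str = "y3",
    m: int = 20,
    seed: int = 0,
    alpha_enter: float = 0.05,
    candidates: Sequence[str] = CONFOUNDERS,
    imputation_level: str = "score",
    n_iter: int = 5,
    group: str = "PD",
) -> dict[str, ModelResult]:
    """The four pooled regressions of overall RCI on baseline EEG features.

    For each predictor (global median theta TE, global median theta relative
    BP) and condition (EC, EO): build per-imputation analysis datasets,
    run stepwise forward selection of confounders on each, take the strict
    majority vote, pool the final OLS fits by Rubin's rules, and decompose
    R^2 into LMG importance shares.  Returns a dict keyed ``"te_EC"``,
    ``"te_EO"``, ``"bp_EC"``, ``"bp_EO"``.
    """
    pd_subjects = subjects.loc[subjects["group"] == group, "subject_id"]
    conf = _encode_confounders(subjects[subjects["group"] == group])

    if imputation_level == "score":
        _, rcis = impute_scores(panel, m=m, seed=seed, n_iter=n_iter, horizon=horizon)
    elif imputation_level == "rci":
        rcis = impute_rci(panel, m=m, seed=seed, n_iter=n_iter, horizon=horizon)
    else:
        raise ValueError(f"unknown imputation_level {imputation_level!r}")

    results: dict[str, ModelResult] = {}
    for feature in ("te", "bp"):
        for condition in ("EC", "EO"):
            predictor = table.global_median(band, condition, feature)
            predictor.name = f"{feature}_{condition}"
            datasets = []
            for rci_i in rcis:
                ds = pd.DataFrame(
                    {
                        "overall_rci": rci_i,
                        predictor.name: predictor,
                    }
                ).join(conf)
                ds = ds.loc[ds.index.intersection(pd_subjects)]
                missing_pred = ds[predictor.name].isna()
                if missing_pred.any():
                    logger.info(
                        "%s_%s: excluding %d subjects without EEG features",
                        feature,
                        condition,
                        int(missing_pred.sum()),
                    )
                    ds = ds[~missing_pred]
                datasets.append(ds)
            stack = ImputedStack(datasets=datasets, seed=seed)
            selections = [
                stepwise_select(
                    ds, "overall_rci", [predictor.name], candidates, alpha_enter
                )
                for ds in stack.datasets
            ]
            consensus = majority_vote(selections)
            pooled = pooled_regression(
                stack, "overall_rci", predictor.name, consensus
            )
            importance = lmg_importance(
                stack, "overall_rci", [predictor.name, *consensus]
            )
            results[f"{feature}_{condition}"] = ModelResult(
                feature=feature,
                condition=condition,
                pooled=pooled,
                importance=importance,
                consensus=consensus,
            )
    return results


def regression_table(results: Mapping[str, ModelResult]) -> pd.DataFrame:
    """Human-readable pooled-regression table (one row per model)."""
    rows = []
    for key, res in results.items():
        row = {
            "model": key,
            "feature": res.feature,
            "condition": res.condition,
            "p_predictor": res.predictor_p,
            "estimate_predictor": res.predictor_estimate,
            "adj_r2": res.pooled.adj_r2,
            "m": res.pooled.m,
        }
        for conf in CONFOUNDERS:
            if conf in res.consensus:
                row[f"p_{conf}"] = float(res.pooled.p_values[conf])
            else:
                row[f"p_{conf}"] = np.nan  # "not included"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full synthetic-cohort analysis run."""

    out_dir: str = "results"
    seed: int = 0
    band: str = "theta"
    m: int = 20
    alpha: float = 0.05
    te: TEConfig = field(default_factory=TEConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    coupling: Coupling = field(default_factory=Coupling)
    imputation_level: str = "score"
    run_histograms: bool = True
    run_correlations: bool = True
    run_regression: bool = True
    run_extreme_groups: bool = True
    run_stability: bool = False
    stability_n: int = 100
    stability_epoch_s: float = 180.0


def run_pipeline(
    cfg: RunConfig, cohort: Cohort | None = None
) -> dict:
    """Run the full analysis on a (by default freshly simulated) cohort.

    Writes features, RCIs, group tests, transition contrasts, the pooled
    regression table and importance shares under ``cfg.out_dir``; every
    artifact carries the echoed configuration.  Returns the result bundle.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort = simulate_cohort(cfg.simulation, cfg.coupling)

    stage = "features"
    try:
        table = compute_feature_table(
            cohort.iter_recordings(),
            bands=CANONICAL_BANDS,
            te_config=cfg.te,
            groups=cohort.groups,
        )
        table.electrodes.to_csv(out / "features_electrodes.csv", index=False)
        table.global_summary.to_csv(out / "features_global.csv", index=False)

        stage = "rci"
        rci_observed = overall_rci(cohort.panel, horizon="y3")
        rci_observed.overall.rename("overall_rci_y3").to_csv(
            out / "overall_rci_y3.csv"
        )

        bundle: dict = {
            "version": __version__,
            "config": _jsonable(cfg),
            "n_subjects": int(len(cohort.subjects)),
        }

        if cfg.run_histograms:
            stage = "group_tests"
            tests = compare_groups(table.electrodes, alpha=cfg.alpha)
            results_frame(tests).to_csv(out / "group_tests.csv", index=False)
            bundle["group_tests"] = [vars(t) for t in tests]

        stage = "transition"
        contrast = transition_contrast(table, group="HC")
        contrast.to_csv(out / "transition_contrast_hc.csv", index=False)

        if cfg.run_correlations:
            stage = "correlations"
            corr = te_bp_correlation(table.electrodes)
            corr.to_csv(out / "te_bp_correlation.csv", index=False)

        if cfg.run_regression:
            stage = "regression"
            models = analyze_decline(
                table,
                cohort.panel,
                cohort.subjects,
                band=cfg.band,
                m=cfg.m,
                seed=cfg.seed,
                imputation_level=cfg.imputation_level,
            )
            reg = regression_table(models)
            reg.to_csv(out / "pooled_regression.csv", index=False)
            bundle["regression"] = {
                key: {
                    "p_predictor": res.predictor_p,
                    "estimate": res.predictor_estimate,
                    "adj_r2": res.pooled.adj_r2,
                    "selected_confounders": res.consensus,
                    "lmg_shares": res.importance.shares.to_dict(),
                    "m": res.pooled.m,
                }
                for key, res in models.items()
            }

        if cfg.run_extreme_groups:
            stage = "extreme_groups"
            k = min(10, len(rci_observed.overall.dropna()) // 2)
            extremes = extreme_groups(
                rci_observed.overall, table, k=k, band=cfg.band
            )
            extremes.to_csv(out / "extreme_groups.csv", index=False)

        if cfg.run_stability:
            stage = "stability"
            spec = cohort.specs[0]
            from .simulate import simulate_eeg

            rec = simulate_eeg(spec, "EO", cfg.simulation)
            report = resample_global_te(
                rec,
                band=cfg.band,
                te_config=cfg.te,
                n=cfg.stability_n,
                epoch_s=min(cfg.stability_epoch_s, rec.duration_s),
                seed=cfg.seed,
            )
            (out / "stability.json").write_text(json.dumps(report.to_dict(), indent=1))
            bundle["stability_cv"] = report.cv
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "results.json").write_text(json.dumps(bundle, indent=1, default=_default))
    return bundle


def _jsonable(obj) -> dict:
    d = asdict(obj)
    return json.loads(json.dumps(d, default=_default))


def _default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (pd.Series,)):
        return o.to_dict()
    return str(o)
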