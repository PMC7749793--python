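"""Replicated simulation studies of the decline-regression pipeline.

Two standing questions about the analysis chain are answered by Monte
Carlo over fresh synthetic cohorts:

* **Condition asymmetry (power)**: with the default planted coupling
  (3-year decline driven by the eyes-open theta-complexity latent only),
  how often is the TE-EO regression significant while TE-EC is not?
* **Type-I error**: with all coupling switched off, how often does the
  pipeline falsely reject at alpha = 0.05?

Replicates run at reduced channel count and sampling rate (the statistical
structure — subject numbers, missingness, coupling, m = 20 imputations —
is unchanged).  The type-I study drives the inference chain with the
latent complexity itself as predictor: under the null the EEG estimation
step (a monotone, separately-tested map of that latent) cannot create an
association, and skipping signal synthesis makes >= 400 replicates cheap.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .features import BAND_BY_NAME, TEConfig, compute_feature_table
from .inference import majority_vote, pooled_regression, stepwise_select, ImputedStack
from .pipeline import CONFOUNDERS, _encode_confounders, impute_rci
from .simulate import Coupling, SimulationConfig, reduced_config, simulate_cohort


def _pooled_p_for_predictor(
    predictor: pd.Series,
    rcis: list[pd.Series],
    conf: pd.DataFrame,
    alpha_enter: float = 0.05,
) -> float:
    datasets = []
    for rci_i in rcis:
        ds = pd.DataFrame({"overall_rci": rci_i, "x": predictor}).join(conf)
        datasets.append(ds.dropna(subset=["x"]))
    stack = ImputedStack(datasets=datasets)
    selections = [
        stepwise_select(ds, "overall_rci", ["x"], CONFOUNDERS, alpha_enter)
        for ds in stack.datasets
    ]
    consensus = majority_vote(selections)
    pooled = pooled_regression(stack, "overall_rci", "x", consensus)
    return float(pooled.p_values["x"])


def run_power_replicates(
    n_replicates: int = 50,
    seed: int = 0,
    cfg: SimulationConfig | None = None,
    coupling: Coupling | None = None,
    m: int = 20,
    alpha: float = 0.05,
    te_config: TEConfig | None = None,
) -> pd.DataFrame:
    """Replicated end-to-end TE-EO / TE-EC regressions on fresh cohorts.

    Each replicate simulates the default cohort (42 PD at reduced channel
    count), computes global median theta TE per condition from the signals,
    imputes the cognitive outcomes m times and pools the two regressions.
    Returns one row per replicate with columns ``p_eo``, ``p_ec``.
    """
    base = reduced_config(cfg)
    coupling = coupling or Coupling()
    te_config = te_config or TEConfig()
    theta = [BAND_BY_NAME["theta"]]
    rows = []
    for rep in range(n_replicates):
        rep_cfg = replace(base, seed=(seed * 100003 + rep) % (2**31 - 1))
        cohort = simulate_cohort(rep_cfg, coupling)
        table = compute_feature_table(
            cohort.iter_recordings(groups=("PD",)),
            bands=theta,
            te_config=te_config,
            groups=cohort.groups,
        )
        rcis = impute_rci(cohort.panel, m=m, seed=rep_cfg.seed)
        conf = _encode_confounders(
            cohort.subjects[cohort.subjects["group"] == "PD"]
        )
        p_eo = _pooled_p_for_predictor(
            table.global_median("theta", "EO"), rcis, conf
        )
        p_ec = _pooled_p_for_predictor(
            table.global_median("theta", "EC"), rcis, conf
        )
        rows.append({"replicate": rep, "p_eo": p_eo, "p_ec": p_ec})
    out = pd.DataFrame(rows)
    out.attrs["asymmetry_rate"] = float(
        ((out["p_eo"] < alpha) & (out["p_ec"] >= alpha)).mean()
    )
    return out


def run_type1_replicates(
    n_replicates: int = 400,
    seed: int = 0,
    cfg: SimulationConfig | None = None,
    m: int = 20,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Null-coupling replicates of the imputation + selection + pooling chain.

    All planted links are zeroed (``slope_eo = slope_ec = age_effect = 0``),
    so any predictor is null for the outcome; the standardized EO
    complexity latent stands in for its EEG estimate.  Returns one row per
    replicate with the pooled predictor p-value; the rejection rate at
    ``alpha`` estimates the chain's type-I error.
    """
    base = cfg or SimulationConfig()
    null = Coupling(slope_eo=0.0, slope_ec=0.0, age_effect=0.0)
    rows = []
    for rep in range(n_replicates):
        rep_cfg = replace(base, seed=(seed * 100003 + rep) % (2**31 - 1))
        cohort = simulate_cohort(rep_cfg, null)
        pd_subj = cohort.subjects["group"] == "PD"
        lat = cohort.latents[cohort.latents["group"] == "PD"]
        predictor = pd.Series(
            lat["theta_complexity_eo"].to_numpy(),
            index=lat["subject_id"].to_numpy(),
            name="x",
        )
        rcis = impute_rci(cohort.panel, m=m, seed=rep_cfg.seed)
        conf = _encode_confounders(cohort.subjects[pd_subj])
        p = _pooled_p_for_predictor(predictor, rcis, conf)
        rows.append({"replicate": rep, "p": p})
    out = pd.DataFrame(rows)
    out.attrs["rejection_rate"] = float((out["p"] < alpha).mean())
    return out
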