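"""Group-level descriptive statistics and hypothesis tests.

Covers the comparisons made between the patient and control groups:
normalized histograms of electrode-level features (groups of unequal size
become comparable as proportions), Mann-Whitney U and Welch t tests with
Holm-Sidak step-down correction across the band x condition family,
eyes-closed -> eyes-open transition contrasts per ROI, per-subject
correlation between entropy and band power over electrodes, and
extreme-group regional summaries (for which, deliberately, no hypothesis
tests are computed: conditioning on extreme outcomes inflates p-values).

Note: electrode-level pooled comparisons treat the ~213 electrodes of each
subject as observations; these are not independent within a subject.  The
pooled variant reproduces the target analysis and logs a warning; a
subject-median variant is available for conservative use.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureTable
from .io import ROI_LABELS

logger = logging.getLogger(__name__)


@dataclass
class GroupTestResult:
    band: str
    condition: str
    test_name: str  # "mann_whitney" or "welch_t"
    statistic: float
    p_raw: float
    p_adjusted: float | None
    significant: bool | None
    n_a: int
    n_b: int


# ---------------------------------------------------------------------------
# Histograms
# ---------------------------------------------------------------------------

def normalized_histogram(
    values: Sequence[float], bin_edges: Sequence[float]
) -> np.ndarray:
    """Bin proportions (summing to one) over given edges.

    Values outside the edges are clipped into the end bins, so unequal group
    sizes yield directly comparable proportions.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    clipped = np.clip(values, edges[0], np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(clipped, bins=edges)
    return counts / values.size


def shared_bin_edges(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> np.ndarray:
    """Freedman-Diaconis edges on the pooled sample (deterministic)."""
    pooled = np.concatenate([np.asarray(sample_a), np.asarray(sample_b)])
    q75, q25 = np.percentile(pooled, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        return np.linspace(pooled.min() - 0.5, pooled.max() + 0.5, 11)
    width = 2 * iqr / len(pooled) ** (1 / 3)
    n_bins = max(1, int(np.ceil((pooled.max() - pooled.min()) / width)))
    return np.linspace(pooled.min(), pooled.max(), n_bins + 1)


# ---------------------------------------------------------------------------
# Two-sample tests
# ---------------------------------------------------------------------------

def mann_whitney_u(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact p by enumeration for combined sample sizes up to 12 (without
    ties), normal approximation with tie correction otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size + b.size <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def welch_t(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float, float]:
    """Welch's t with Satterthwaite degrees of freedom, two-sided."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def holm_sidak(
    p_values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Holm-Sidak step-down correction.

    Sorting the raw p ascending, the i-th adjusted value is
    ``max_{j<=i} 1 - (1 - p_(j))**(m - j + 1)`` (monotonized); hypotheses
    are rejected while the adjusted value is <= alpha.  Returns (adjusted p,
    reject flags) in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted_sorted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        step = 1.0 - (1.0 - p[idx]) ** (m - i)
        running = max(running, step)
        adjusted_sorted[i] = running
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    # step-down rejection: stop at the first non-rejected sorted hypothesis
    reject = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):
        if adjusted_sorted[i] <= alpha:
            reject[idx] = True
        else:
            break
    return adjusted, reject


def compare_groups(
    features: pd.DataFrame,
    group_a: str = "HC",
    group_b: str = "PD",
    feature: str = "te",
    test: str = "mann_whitney",
    alpha: float = 0.05,
    pool_electrodes: bool = True,
) -> list[GroupTestResult]:
    """Group comparison per band x condition with Holm-Sidak over the family.

    With ``pool_electrodes`` (the default) all electrode-level values of a
    group form its sample; these are not independent within subjects, which
    is logged.  With ``pool_electrodes=False`` each subject contributes its
    median (conservative variant).
    """
    if pool_electrodes:
        logger.warning(
            "electrode-level pooling: values within a subject are not "
            "independent; p-values are descriptive"
        )
    results = []
    for (band, condition), chunk in features.groupby(
        ["band", "condition"], sort=True, observed=True
    ):
        if pool_electrodes:
            a = chunk.loc[chunk["group"] == group_a, feature].to_numpy()
            b = chunk.loc[chunk["group"] == group_b, feature].to_numpy()
        else:
            med = chunk.groupby(["group", "subject"], observed=True)[feature].median()
            a = med.loc[group_a].to_numpy()
            b = med.loc[group_b].to_numpy()
        if test == "mann_whitney":
            stat, p = mann_whitney_u(a, b)
        elif test == "welch_t":
            stat, _, p = welch_t(a, b)
        else:
            raise ValueError(f"unknown test {test!r}")
        results.append(
            GroupTestResult(
                band=band,
                condition=condition,
                test_name=test,
                statistic=stat,
                p_raw=p,
                p_adjusted=None,
                significant=None,
                n_a=len(a),
                n_b=len(b),
            )
        )
    adjusted, reject = holm_sidak([r.p_raw for r in results], alpha=alpha)
    for r, adj, rej in zip(results, adjusted, reject):
        r.p_adjusted = float(adj)
        r.significant = bool(rej)
    return results


def results_frame(results: Sequence[GroupTestResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


# ---------------------------------------------------------------------------
# EC -> EO transition contrasts
# ---------------------------------------------------------------------------

def transition_contrast(
    table: FeatureTable, group: str | None = None
) -> pd.DataFrame:
    """Cohort-mean EO - EC difference of ROI-mean TE and BP, per band x ROI.

    Per subject the ROI means of the two conditions are differenced, then
    averaged over subjects; subjects missing either condition are excluded
    (and logged).  Returns columns (band, roi, d_te, d_bp, n_subjects).
    """
    roi = table.roi
    if group is not None:
        roi = roi[roi["group"] == group]
    wide = roi.pivot_table(
        index=["subject", "band", "roi"],
        columns="condition",
        values=["roi_mean_te", "roi_mean_bp"],
    )
    have_both = wide.notna().all(axis=1)
    dropped = wide.index[~have_both].get_level_values("subject").unique()
    if len(dropped):
        logger.info(
            "transition contrast: excluded subjects missing a condition: %s",
            sorted(dropped),
        )
    wide = wide[have_both]
    diff = pd.DataFrame(
        {
            "d_te": wide[("roi_mean_te", "EO")] - wide[("roi_mean_te", "EC")],
            "d_bp": wide[("roi_mean_bp", "EO")] - wide[("roi_mean_bp", "EC")],
        }
    ).reset_index()
    out = (
        diff.groupby(["band", "roi"], sort=True, observed=True)
        .agg(d_te=("d_te", "mean"), d_bp=("d_bp", "mean"), n_subjects=("d_te", "size"))
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# TE-BP correlation over electrodes
# ---------------------------------------------------------------------------

def te_bp_correlation(features: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between TE and relative BP over a subject's electrodes.

    One r per (subject, group, band, condition); requires >= 3 electrodes
    and non-zero variance in both features.
    """
    rows = []
    for (subject, group, band, condition), chunk in features.groupby(
        ["subject", "group", "band", "condition"], sort=True, observed=True
    ):
        te = chunk["te"].to_numpy()
        bp = chunk["rel_bp"].to_numpy()
        if len(te) < 3:
            raise ValueError(
                f"subject {subject}: need >= 3 electrodes for correlation"
            )
        if te.std() == 0 or bp.std() == 0:
            raise ValueError(
                f"subject {subject}: zero variance in TE or BP ({band}, "
                f"{condition})"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = float(np.corrcoef(te, bp)[0, 1])
        rows.append(
            {
                "subject": subject,
                "group": group,
                "band": band,
                "condition": condition,
                "r": r,
            }
        )
    return pd.DataFrame(rows)


def compare_te_bp_correlations(
    correlations: pd.DataFrame,
    group_a: str = "HC",
    group_b: str = "PD",
    alpha: float = 0.05,
) -> list[GroupTestResult]:
    """Welch t on the per-subject TE-BP correlations, group A vs group B.

    One comparison per band x condition, Holm-Sidak corrected over the
    family.  Input is the frame produced by :func:`te_bp_correlation`.
    """
    results = []
    for (band, condition), chunk in correlations.groupby(
        ["band", "condition"], sort=True, observed=True
    ):
        a = chunk.loc[chunk["group"] == group_a, "r"].to_numpy()
        b = chunk.loc[chunk["group"] == group_b, "r"].to_numpy()
        stat, _, p = welch_t(a, b)
        results.append(
            GroupTestResult(
                band=band,
                condition=condition,
                test_name="welch_t",
                statistic=stat,
                p_raw=p,
                p_adjusted=None,
                significant=None,
                n_a=len(a),
                n_b=len(b),
            )
        )
    adjusted, reject = holm_sidak([r.p_raw for r in results], alpha=alpha)
    for r, adj, rej in zip(results, adjusted, reject):
        r.p_adjusted = float(adj)
        r.significant = bool(rej)
    return results


# ---------------------------------------------------------------------------
# Extreme groups
# ---------------------------------------------------------------------------

def extreme_groups(
    overall_rci: pd.Series,
    table: FeatureTable,
    k: int = 10,
    band: str = "theta",
    condition: str = "EO",
    hc_group: str = "HC",
) -> pd.DataFrame:
    """Regional median TE for top-k decliners, bottom-k stable, and controls.

    Subjects are ranked by overall RCI (decline-positive); ties at rank k
    are broken by subject id.  Per subject the ROI median TE is taken, then
    the median over each group's subjects.  No hypothesis tests are
    computed for the extreme groups: selecting on extreme outcomes inflates
    significance.
    """
    rci = overall_rci.dropna().sort_values(
        ascending=False, kind="stable"
    )
    # deterministic tie-break by subject id within equal RCI values
    rci = rci.iloc[
        np.lexsort((rci.index.to_numpy(), -rci.to_numpy()))
    ]
    if len(rci) < 2 * k:
        raise ValueError(
            f"need at least {2 * k} subjects with overall RCI, have {len(rci)}"
        )
    decliners = set(rci.index[:k])
    stable = set(rci.index[-k:])

    roi = table.roi
    sel = roi[(roi["band"] == band) & (roi["condition"] == condition)]

    def group_medians(subjects: set | None, label: str, group: str | None = None):
        if subjects is not None:
            part = sel[sel["subject"].isin(subjects)]
        else:
            part = sel[sel["group"] == group]
        med = (
            part.groupby("roi", observed=True)["roi_median_te"]
            .median()
            .reindex(list(ROI_LABELS))
        )
        return pd.DataFrame(
            {"group": label, "roi": med.index, "median_te": med.to_numpy()}
        )

    return pd.concat(
        [
            group_medians(decliners, "decliners"),
            group_medians(stable, "stable"),
            group_medians(None, "hc", group=hc_group),
        ],
        ignore_index=True,
    )
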