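"""Reliable change indices (RCI) from longitudinal neuropsychological scores.

For a single test, reliable change between baseline and a follow-up is the
raw difference standardized by the standard error of the difference:

    SE_M   = sd(baseline) * sqrt(1 - RS)
    S_diff = sqrt(2 * SE_M**2)
    RCI    = (follow-up - baseline) / S_diff

where RS is the test's reliability coefficient and sd(baseline) the
cohort-level baseline standard deviation for that test.  Because the RCI is
standardized, test RCIs are combined by simple averaging: first into the
four cognitive-domain scores (attention, executive, visuo-constructive,
working memory), then the overall RCI is the mean of the domain scores.

Sign convention: this package reports *decline-positive* RCIs.  Tests where
a higher score means better performance are sign-flipped before averaging,
so a positive overall RCI always means cognitive decline.  The convention
is recorded in the result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

TIMEPOINTS = ("baseline", "m6", "y3")
HORIZONS = ("m6", "y3")
DOMAINS = ("attention", "executive", "visuoconstructive", "working_memory")


@dataclass
class ScorePanel:
    """Longitudinal score panel with per-test metadata.

    Parameters
    ----------
    scores : DataFrame
        Long format with columns (subject, test, timepoint, value); missing
        observations are NaN values or absent rows.
    tests : DataFrame
        One row per test with columns (test, domain, higher_is_better,
        reliability).  ``reliability`` is the test-retest coefficient RS,
        strictly inside (0, 1).
    """

    scores: pd.DataFrame
    tests: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject", "test", "timepoint", "value"}
        if not required.issubset(self.scores.columns):
            raise ValueError(f"scores needs columns {sorted(required)}")
        req_meta = {"test", "domain", "higher_is_better", "reliability"}
        if not req_meta.issubset(self.tests.columns):
            raise ValueError(f"tests needs columns {sorted(req_meta)}")
        rs = self.tests["reliability"].to_numpy(dtype=float)
        if np.any(rs <= 0) or np.any(rs >= 1):
            raise ValueError(
                "reliability RS must lie strictly in (0, 1); RS = 1 makes "
                "the standard error of the difference zero"
            )
        unknown = set(self.tests["domain"]) - set(DOMAINS)
        if unknown:
            raise ValueError(f"unknown domains {sorted(unknown)}")
        missing_meta = set(self.scores["test"]) - set(self.tests["test"])
        if missing_meta:
            raise ValueError(f"tests without metadata: {sorted(missing_meta)}")

    def wide(self) -> pd.DataFrame:
        """Subjects x (test, timepoint) matrix with NaN for missing."""
        return self.scores.pivot_table(
            index="subject",
            columns=["test", "timepoint"],
            values="value",
            dropna=False,
        )

    def fraction_missing(self) -> float:
        """Fraction of missing cells over the full subject x test x time grid."""
        wide = self.wide().reindex(
            columns=pd.MultiIndex.from_product(
                [self.tests["test"], TIMEPOINTS], names=["test", "timepoint"]
            )
        )
        return float(wide.isna().to_numpy().mean())

    def baseline_sd(self) -> pd.Series:
        """Cohort baseline standard deviation per test (observed values)."""
        base = self.scores[self.scores["timepoint"] == "baseline"]
        return base.groupby("test")["value"].std(ddof=1)


@dataclass
class RCIResult:
    """Per-test, per-domain and overall RCIs for one follow-up horizon."""

    horizon: str
    per_test: pd.DataFrame  # subjects x tests, decline-positive
    per_domain: pd.DataFrame  # subjects x domains
    overall: pd.Series  # indexed by subject
    sign_convention: str = "positive_is_decline"
    baseline_sd: pd.Series = field(default_factory=pd.Series)


def rci(
    baseline: float | np.ndarray,
    followup: float | np.ndarray,
    sd_baseline: float,
    rs: float,
) -> float | np.ndarray:
    """Reliable change index for a single test.

    Raw convention: positive when the score increased.  NaN inputs
    propagate to NaN, never to zero.
    """
    if not 0 < rs < 1:
        raise ValueError("reliability RS must lie strictly in (0, 1)")
    if not sd_baseline > 0:
        raise ValueError("baseline standard deviation must be positive")
    se_m = sd_baseline * np.sqrt(1.0 - rs)
    s_diff = np.sqrt(2.0 * se_m**2)
    return (np.asarray(followup, dtype=float) - np.asarray(baseline, dtype=float)) / s_diff


def overall_rci(
    panel: ScorePanel,
    horizon: str = "y3",
    baseline_sd: pd.Series | None = None,
) -> RCIResult:
    """Per-test, domain and overall reliable change for one horizon.

    Baseline SDs default to the panel's own cohort (the analysis group);
    pass ``baseline_sd`` to use external norms instead.  Missing scores
    yield missing RCIs: a subject with no observed test in some domain has
    a missing overall RCI (imputation is a separate, explicit stage).
    """
    if horizon not in HORIZONS:
        raise ValueError(f"horizon must be one of {HORIZONS}")
    sds = panel.baseline_sd() if baseline_sd is None else baseline_sd
    wide = panel.wide()
    subjects = wide.index

    per_test = pd.DataFrame(index=subjects, dtype=float)
    for row in panel.tests.itertuples():
        test = row.test
        sd = float(sds.get(test, np.nan))
        if not np.isfinite(sd) or sd <= 0:
            raise ValueError(
                f"baseline SD for test {test!r} is unavailable or non-positive"
            )
        base = wide.get((test, "baseline"), pd.Series(np.nan, index=subjects))
        follow = wide.get((test, horizon), pd.Series(np.nan, index=subjects))
        raw = rci(base.to_numpy(), follow.to_numpy(), sd, float(row.reliability))
        # decline-positive harmonization: flip tests where higher = better
        per_test[test] = -raw if bool(row.higher_is_better) else raw

    domain_of = panel.tests.set_index("test")["domain"]
    per_domain = per_test.T.groupby(domain_of).mean().T
    per_domain = per_domain.reindex(columns=[d for d in DOMAINS if d in per_domain])
    # a subject missing an entire domain has no overall RCI
    overall = per_domain.mean(axis=1)
    overall[per_domain.isna().any(axis=1)] = np.nan
    overall.name = f"overall_rci_{horizon}"

    return RCIResult(
        horizon=horizon,
        per_test=per_test,
        per_domain=per_domain,
        overall=overall,
        baseline_sd=sds,
    )


def panel_from_frames(
    scores: pd.DataFrame, tests: pd.DataFrame
) -> ScorePanel:
    """Build and validate a panel from raw frames (CSV-loaded or synthetic)."""
    return ScorePanel(scores=scores.copy(), tests=tests.copy())


def read_panel(scores_csv, tests_csv) -> ScorePanel:
    """Load a panel from the two CSV files written by :func:`write_panel`."""
    return panel_from_frames(pd.read_csv(scores_csv), pd.read_csv(tests_csv))


def write_panel(panel: ScorePanel, scores_csv, tests_csv) -> None:
    panel.scores.to_csv(scores_csv, index=False)
    panel.tests.to_csv(tests_csv, index=False)
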