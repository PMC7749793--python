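import itertools

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from eegcomplexity.features import FeatureTable, TEConfig
from eegcomplexity.group_stats import (
    extreme_groups,
    holm_sidak,
    mann_whitney_u,
    normalized_histogram,
    shared_bin_edges,
    te_bp_correlation,
    transition_contrast,
    welch_t,
)
from eegcomplexity.io import ROI_LABELS


def _enumerated_mwu_p(a, b):
    """Oracle: exact two-sided p by full enumeration of rank assignments."""
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled)
    na, nb = len(a), len(b)
    centre = na * nb / 2.0

    def u_of(positions):
        ranks = np.empty(na + nb)
        ranks[order] = np.arange(1, na + nb + 1)
        ra = ranks[list(positions)].sum()
        return ra - na * (na + 1) / 2

    u_obs = u_of(range(na))
    count = total = 0
    for combo in itertools.combinations(range(na + nb), na):
        u = u_of(combo)
        total += 1
        if abs(u - centre) >= abs(u_obs - centre) - 1e-12:
            count += 1
    return count / total


class TestNormalizedHistogram:
    def test_one_value_per_bin(self):
        p = normalized_histogram([0.5, 1.5, 2.5, 3.5], [0, 1, 2, 3, 4])
        np.testing.assert_allclose(p, 0.25)

    def test_all_in_one_bin(self):
        p = normalized_histogram([1.1, 1.2, 1.3], [0, 1, 2, 3])
        np.testing.assert_allclose(p, [0, 1.0, 0])

    def test_unequal_group_sizes_comparable(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(8946)
        b = rng.standard_normal(5112)
        edges = shared_bin_edges(a, b)
        pa = normalized_histogram(a, edges)
        pb = normalized_histogram(b, edges)
        assert pa.sum() == pytest.approx(1.0)
        assert pb.sum() == pytest.approx(1.0)
        # identical distributions: max cumulative gap stays small
        assert np.abs(np.cumsum(pa) - np.cumsum(pb)).max() < 0.05

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalized_histogram([], [0, 1])


class TestMannWhitney:
    def test_separated_samples_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples(self):
        a = [1, 2, 2, 3, 5, 8, 9, 11, 12, 15]
        _, p = mann_whitney_u(a, a)
        assert p > 0.9

    @pytest.mark.parametrize("na,nb", [(2, 2), (3, 3), (4, 5), (6, 6), (2, 6)])
    def test_exact_p_matches_enumeration(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        for _ in range(3):
            pooled = rng.permutation(np.arange(1.0, na + nb + 1))
            a, b = pooled[:na], pooled[na:]
            _, p = mann_whitney_u(a, b)
            assert p == pytest.approx(_enumerated_mwu_p(a, b), abs=1e-10)

    def test_large_samples_match_reference(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(300)
        b = rng.standard_normal(300) + 0.4
        from scipy.stats import mannwhitneyu

        u, p = mann_whitney_u(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided")
        assert p == pytest.approx(ref.pvalue, abs=1e-8)


class TestWelch:
    def test_identical_groups(self):
        a = [1.0, 2.0, 3.0, 4.0]
        t, df, p = welch_t(a, a)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_clearly_separated_groups(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1e-3, 4)
        b = 1 + rng.normal(0, 1e-3, 4)
        _, _, p = welch_t(a, b)
        assert p < 0.01

    def test_equal_n_equal_variance_reduces_to_student(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(30)
        b = rng.standard_normal(30) + 0.3
        # force exactly equal sample variances by rescaling b
        b = b.mean() + (b - b.mean()) * a.std(ddof=1) / b.std(ddof=1)
        t, df, p = welch_t(a, b)
        from scipy.stats import ttest_ind

        ref = ttest_ind(a, b, equal_var=True)
        assert df == pytest.approx(2 * 30 - 2, abs=1e-9)
        assert t == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_zero_variance_both_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [2.0, 2.0])


class TestHolmSidak:
    def test_single_p(self):
        adj, rej = holm_sidak([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_two_p_hand_computed(self):
        # sorted: 1-(1-0.01)^2 = 0.0199; then max(0.0199, 0.04) = 0.04
        adj, rej = holm_sidak([0.04, 0.01])
        assert adj[1] == pytest.approx(1 - 0.99**2)
        assert adj[0] == pytest.approx(0.04)
        assert rej.tolist() == [True, True]

    def test_all_zero_all_rejected(self):
        adj, rej = holm_sidak([0.0] * 5)
        assert rej.all()

    def test_matches_statsmodels_reference(self):
        rng = np.random.default_rng(4)
        p = rng.random(10)
        adj, rej = holm_sidak(p, alpha=0.05)
        ref_rej, ref_adj, *_ = multipletests(p, alpha=0.05, method="holm-sidak")
        np.testing.assert_allclose(adj, ref_adj, atol=1e-12)
        np.testing.assert_array_equal(rej, ref_rej)

    def test_adjusted_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(5)
        p = rng.random(25)
        adj, _ = holm_sidak(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


def _toy_feature_table(values):
    """FeatureTable with explicit per-(subject, condition, roi) means."""
    rows = []
    for (subject, condition, roi), (te, bp) in values.items():
        rows.append(
            {
                "subject": subject,
                "group": "HC",
                "condition": condition,
                "band": "alpha",
                "roi": roi,
                "roi_mean_te": te,
                "roi_mean_bp": bp,
                "roi_median_te": te,
                "roi_median_bp": bp,
                "n_electrodes": 2,
            }
        )
    roi = pd.DataFrame(rows)
    return FeatureTable(
        electrodes=pd.DataFrame(),
        roi=roi,
        global_summary=pd.DataFrame(),
        te_config=TEConfig(),
    )


class TestTransitionContrast:
    def test_identical_conditions_give_zero(self):
        vals = {}
        for s in ("a", "b"):
            for c in ("EC", "EO"):
                vals[(s, c, "frontal_left")] = (0.5, 0.2)
        out = transition_contrast(_toy_feature_table(vals))
        assert np.allclose(out["d_te"], 0.0)
        assert np.allclose(out["d_bp"], 0.0)

    def test_hand_built_two_subject_means(self):
        vals = {
            ("a", "EC", "frontal_left"): (0.5, 0.30),
            ("a", "EO", "frontal_left"): (0.6, 0.10),
            ("b", "EC", "frontal_left"): (0.4, 0.20),
            ("b", "EO", "frontal_left"): (0.5, 0.16),
        }
        out = transition_contrast(_toy_feature_table(vals))
        assert out["d_te"].iloc[0] == pytest.approx(0.1)  # mean(0.1, 0.1)
        assert out["d_bp"].iloc[0] == pytest.approx((-0.2 - 0.04) / 2)

    def test_subject_missing_condition_excluded(self):
        vals = {
            ("a", "EC", "frontal_left"): (0.5, 0.3),
            ("a", "EO", "frontal_left"): (0.7, 0.1),
            ("b", "EC", "frontal_left"): (99.0, 99.0),  # no EO: must drop
        }
        out = transition_contrast(_toy_feature_table(vals))
        assert out["n_subjects"].iloc[0] == 1
        assert out["d_te"].iloc[0] == pytest.approx(0.2)


class TestTeBpCorrelation:
    def _electrodes(self, te, bp):
        return pd.DataFrame(
            {
                "subject": "s",
                "group": "PD",
                "condition": "EO",
                "band": "theta",
                "electrode": [f"e{i}" for i in range(len(te))],
                "roi": "frontal_left",
                "te": te,
                "rel_bp": bp,
            }
        )

    def test_exact_linear_relations(self):
        bp = np.linspace(0.1, 0.9, 20)
        out = te_bp_correlation(self._electrodes(2 * bp + 1, bp))
        assert out["r"].iloc[0] == pytest.approx(1.0)
        out = te_bp_correlation(self._electrodes(-bp, bp))
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_null_correlation_stays_small(self):
        rng = np.random.default_rng(6)
        hits = 0
        reps = 60
        for _ in range(reps):
            te = rng.standard_normal(213)
            bp = rng.standard_normal(213)
            r = te_bp_correlation(self._electrodes(te, bp))["r"].iloc[0]
            hits += abs(r) < 0.2
        assert hits / reps >= 0.95

    def test_too_few_electrodes_rejected(self):
        with pytest.raises(ValueError, match="3"):
            te_bp_correlation(self._electrodes([1.0, 2.0], [0.1, 0.2]))

    def test_group_comparison_of_correlations(self):
        from eegcomplexity.group_stats import compare_te_bp_correlations

        rng = np.random.default_rng(8)
        rows = []
        for group, mu in (("HC", 0.0), ("PD", -0.5)):
            for i in range(15):
                rows.append(
                    {
                        "subject": f"{group}{i}",
                        "group": group,
                        "band": "theta",
                        "condition": "EO",
                        "r": np.clip(mu + 0.1 * rng.standard_normal(), -1, 1),
                    }
                )
        out = compare_te_bp_correlations(pd.DataFrame(rows))
        assert len(out) == 1
        assert out[0].significant  # planted -0.5 shift in the PD group


class TestExtremeGroups:
    def _table_and_rci(self, n=24, seed=0):
        rng = np.random.default_rng(seed)
        subjects = [f"p{i:02d}" for i in range(n)]
        rci = pd.Series(np.linspace(-2, 2, n), index=subjects)
        rows = []
        for i, s in enumerate(subjects):
            for roi in ROI_LABELS:
                # decliners (high rci) get low entropy in every region
                te = 1.0 - 0.2 * (rci[s] > 0) + 0.01 * rng.standard_normal()
                rows.append(
                    {
                        "subject": s,
                        "group": "PD",
                        "condition": "EO",
                        "band": "theta",
                        "roi": roi,
                        "roi_mean_te": te,
                        "roi_median_te": te,
                        "roi_mean_bp": 0.2,
                        "roi_median_bp": 0.2,
                        "n_electrodes": 2,
                    }
                )
        for s in ("h1", "h2"):
            for roi in ROI_LABELS:
                rows.append(
                    {
                        "subject": s,
                        "group": "HC",
                        "condition": "EO",
                        "band": "theta",
                        "roi": roi,
                        "roi_mean_te": 1.0,
                        "roi_median_te": 1.0,
                        "roi_mean_bp": 0.2,
                        "roi_median_bp": 0.2,
                        "n_electrodes": 2,
                    }
                )
        table = FeatureTable(
            electrodes=pd.DataFrame(),
            roi=pd.DataFrame(rows),
            global_summary=pd.DataFrame(),
        )
        return table, rci

    def test_decliners_lower_in_every_roi(self):
        table, rci = self._table_and_rci()
        out = extreme_groups(rci, table, k=10)
        dec = out[out.group == "decliners"].set_index("roi")["median_te"]
        stab = out[out.group == "stable"].set_index("roi")["median_te"]
        assert (dec < stab).all()
        assert len(dec) == 10 and len(stab) == 10

    def test_k_too_large_rejected(self):
        table, rci = self._table_and_rci()
        with pytest.raises(ValueError, match="at least"):
            extreme_groups(rci, table, k=15)

    def test_identical_subjects_equal_medians(self):
        table, rci = self._table_and_rci()
        flat = pd.Series(0.0, index=rci.index)
        table.roi["roi_median_te"] = 0.7
        out = extreme_groups(flat, table, k=10)
        dec = out[out.group == "decliners"]["median_te"]
        stab = out[out.group == "stable"]["median_te"]
        np.testing.assert_allclose(dec, stab)
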