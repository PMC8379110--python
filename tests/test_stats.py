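import math

import numpy as np
import pytest
from scipy import stats as sps

from ablamargin.cohort import CohortRecord
from ablamargin.margins import CompletenessClass
from ablamargin.phantoms import CohortSimSpec, simulate_cohort
from ablamargin.reference import REFERENCE_CLASS_TOTALS, load_reference_cohort
from ablamargin.stats import (
    association_test,
    classification_table,
    cohort_values,
    compare_groups_continuous,
    covariate_screen,
    cumulative_table,
    fisher_exact_test,
    km_estimator,
    logrank_test,
    roc_analysis,
    sens100_threshold,
    zone_bands,
)

CLASSES = tuple(CompletenessClass)


def make_record(case_id, u_profile, ltp, time=12.0, residual=0.0, **cov):
    return CohortRecord(
        case_id=str(case_id),
        residual_pct=residual,
        unablated_pct_by_margin={float(m): u_profile for m in range(1, 11)}
        if np.isscalar(u_profile)
        else {float(m): u_profile[m - 1] for m in range(1, 11)},
        ltp=ltp,
        time_months=time,
        covariates=cov,
    )


# ---------------------------------------------------------------------------
# oracles


def fisher_two_sided_enumeration(a, b, c, d):
    """Exact two-sided Fisher p by integer hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    return sum(w for w in weights.values() if w <= w_obs) / math.comb(n, c1)


def auc_pairwise(values, labels):
    """Mann-Whitney concordant-pair count, ties counted 1/2."""
    pos = [v for v, y in zip(values, labels) if y == 1]
    neg = [v for v, y in zip(values, labels) if y == 0]
    score = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return score / (len(pos) * len(neg))


def logrank_oracle_p(times, events, groups):
    """Two-group log-rank chi-square from the O-E / V sums."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups, int)
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n, n1 = at_risk.sum(), (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return 1 - sps.chi2.cdf(chi2, 1)


# ---------------------------------------------------------------------------
# completeness tables


class TestClassificationTable:
    def test_reference_cohort_at_4mm(self):
        table = classification_table(load_reference_cohort(), 4)
        assert tuple(table.ltp_counts[c] for c in CLASSES) == (0, 1, 1, 5, 2)
        assert table.n == 9 and table.n_ltp == 9

    def test_empty_cohort_all_zero(self):
        table = classification_table([], 3, with_p=False)
        assert table.n == 0
        assert all(v == 0 for v in table.totals.values())

    def test_counts_match_brute_force_tally(self):
        cohort = simulate_cohort(CohortSimSpec(n_cases=50, seed=4))
        table = classification_table(cohort, 6)
        from ablamargin.margins import classify_ablation

        for cls in CLASSES:
            manual_total = sum(
                1
                for r in cohort
                if classify_ablation(min(r.residual_pct, 100.0), r.u(6)) is cls
            )
            manual_ltp = sum(
                1
                for r in cohort
                if r.ltp
                and classify_ablation(min(r.residual_pct, 100.0), r.u(6)) is cls
            )
            assert table.totals[cls] == manual_total
            assert table.ltp_counts[cls] == manual_ltp
        assert sum(table.totals.values()) == 50
        assert sum(table.ltp_counts.values()) == sum(r.ltp for r in cohort)

    def test_separated_cohort_low_p(self):
        cohort = [make_record(i, 0.0, False) for i in range(30)] + [
            make_record(100 + i, 50.0, True) for i in range(10)
        ]
        table = classification_table(cohort, 6)
        assert table.p_value < 0.001


class TestCumulativeTable:
    def test_prefix_sums_of_classification(self):
        cohort = simulate_cohort(CohortSimSpec(n_cases=60, seed=8))
        table = classification_table(cohort, 5, with_p=False)
        cum = cumulative_table(cohort, 5).set_index("group")
        running_total = running_ltp = 0
        for cls, label in zip(CLASSES, ("100%", ">95%", ">90%")):
            running_total += table.totals[cls]
            running_ltp += table.ltp_counts[cls]
            assert cum.loc[label, "total"] == running_total
            assert cum.loc[label, "ltp"] == running_ltp
        assert cum.loc["all", "total"] == 60

    def test_no_ltp_cohort_zero_percentages(self):
        cohort = [make_record(i, 20.0, False) for i in range(10)]
        cum = cumulative_table(cohort, 3)
        assert (cum["ltp_pct"] == 0).all()

    def test_reference_ge90_group_at_3mm_with_published_totals(self):
        """LTP share of the >=90%-coverage group at 3 mm: 4 events among
        the published group total of 71 tumors -> 5.6%."""
        cum = cumulative_table(load_reference_cohort(), 3).set_index("group")
        ltp_ge90 = int(cum.loc[">90%", "ltp"])
        assert ltp_ge90 == 4
        total_ge90 = sum(REFERENCE_CLASS_TOTALS[3][:3])
        assert total_ge90 == 71
        assert round(100 * ltp_ge90 / total_ge90, 1) == 5.6


# ---------------------------------------------------------------------------
# association tests


class TestAssociationTest:
    def test_identical_proportions_p_one(self):
        assert association_test([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_fisher_diagonal_table(self):
        # 2/20 of the fixed-margin tables are as extreme
        assert fisher_exact_test([[3, 0], [0, 3]]) == pytest.approx(0.1)

    def test_small_expected_counts_route_to_fisher(self):
        table = [[3, 0], [0, 3]]
        assert association_test(table) == pytest.approx(
            fisher_two_sided_enumeration(3, 0, 0, 3)
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_fisher_matches_enumeration_random_tables(self, seed):
        r = np.random.default_rng(seed)
        for _ in range(50):
            a, b, c, d = r.integers(0, 12, 4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            assert fisher_exact_test([[a, b], [c, d]]) == pytest.approx(
                fisher_two_sided_enumeration(a, b, c, d), rel=1e-9
            )

    def test_chisquare_matches_permutation_oracle(self):
        rng = np.random.default_rng(123)
        groups = np.repeat(np.arange(5), 100)
        y = (rng.random(500) < 0.3 + 0.04 * (groups >= 3)).astype(int)
        table = np.array([[((groups == g) & (y == k)).sum() for g in range(5)]
                          for k in (1, 0)])
        p_chi2 = association_test(table)

        # permutation of the binary outcome, margins fixed
        n_perm = 100_000
        keys = rng.random((n_perm, y.size)).argsort(axis=1)
        y_perm = y[keys]
        g_onehot = np.eye(5)[groups]
        s = y_perm @ g_onehot  # positives per group per permutation
        n_g = g_onehot.sum(axis=0)
        e1 = n_g * y.mean()
        e0 = n_g - e1
        stat = (((s - e1) ** 2) / e1 + ((n_g - s - e0) ** 2) / e0).sum(axis=1)
        obs = (((table[0] - e1) ** 2) / e1 + ((table[1] - e0) ** 2) / e0).sum()
        p_perm = (stat >= obs - 1e-9).mean()
        se = math.sqrt(p_perm * (1 - p_perm) / n_perm)
        # asymptotic vs exact: allow a small residual beyond Monte-Carlo error
        assert abs(p_chi2 - p_perm) < 4 * se + 0.005

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            association_test([[0, 0], [3, 4]])
        with pytest.raises(ValueError):
            association_test([[1.5, 2], [3, 4]])


class TestCompareGroupsContinuous:
    def test_identical_groups_p_one(self):
        assert compare_groups_continuous([2, 2, 2], [2, 2, 2]) == 1.0

    def test_hand_computed_pooled_t(self):
        # pooled s^2 = 1, t = -3/sqrt(2/3) = -3.674, df = 4
        p = compare_groups_continuous([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.0214, abs=5e-4)

    def test_degenerate_variance_unequal_means(self):
        assert compare_groups_continuous([1, 1, 1], [2, 2, 2]) == 0.0

    def test_requires_two_per_group(self):
        with pytest.raises(ValueError):
            compare_groups_continuous([1], [2, 3])

    def test_ltp_group_has_higher_unablated_percentages(self):
        cohort = simulate_cohort(CohortSimSpec(n_cases=200, seed=21))
        u, y = cohort_values(cohort, 6)
        p = compare_groups_continuous(u[y == 1], u[y == 0])
        assert p < 0.001


# ---------------------------------------------------------------------------
# survival


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        cohort = [make_record(i, 0.0, False, time=10 + i) for i in range(5)]
        curve = km_estimator(cohort)
        assert curve.times.size == 0
        assert curve.probability_at(100) == 1.0

    def test_all_events_product_limit(self):
        cohort = [make_record(i, 0.0, True, time=t) for i, t in enumerate((1, 2, 3))]
        curve = km_estimator(cohort)
        assert np.allclose(curve.times, [1, 2, 3])
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        assert np.allclose(curve.at_risk, [3, 2, 1])

    def test_censoring_removes_from_risk_set(self):
        # events at 1 and 3, censoring at 2: S(1)=2/3, S(3)=0
        cohort = [
            make_record(0, 0.0, True, time=1),
            make_record(1, 0.0, False, time=2),
            make_record(2, 0.0, True, time=3),
        ]
        curve = km_estimator(cohort)
        assert np.allclose(curve.times, [1, 3])
        assert np.allclose(curve.survival, [2 / 3, 0.0])

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(6)
        times = rng.uniform(1, 40, 25)
        cohort = [make_record(i, 0.0, True, time=t) for i, t in enumerate(times)]
        curve = km_estimator(cohort)
        for t in (5.0, 15.0, 30.0):
            assert curve.probability_at(t) == pytest.approx((times > t).mean())

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            km_estimator([])


class TestLogrank:
    def test_identical_groups_p_one(self):
        group = [make_record(i, 0.0, True, time=t) for i, t in enumerate((2, 5, 9))]
        assert logrank_test([group, list(group)]) == pytest.approx(1.0)

    def test_matches_hand_computed_statistic(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 1, 1, 1, 0, 1]
        groups = [0, 1, 0, 1, 0, 1]
        cohorts = [[], []]
        for i, (t, e, g) in enumerate(zip(times, events, groups)):
            cohorts[g].append(make_record(i, 0.0, bool(e), time=t))
        expected = logrank_oracle_p(times, events, groups)
        assert logrank_test(cohorts) == pytest.approx(expected, rel=1e-6)

    def test_p_decreases_with_sample_size_for_separated_groups(self):
        ps = []
        for n in (50, 100, 200):
            cohort = simulate_cohort(CohortSimSpec(n_cases=n, ltp_noise=0.0, seed=33))
            groups = [
                [r for r in cohort if r.u(6) <= 10],
                [r for r in cohort if r.u(6) > 10],
            ]
            ps.append(logrank_test(groups))
        assert ps[0] > ps[1] > ps[2]

    def test_requires_events(self):
        g1 = [make_record(0, 0.0, False, time=5)]
        g2 = [make_record(1, 0.0, False, time=6)]
        with pytest.raises(ValueError):
            logrank_test([g1, g2])


# ---------------------------------------------------------------------------
# ROC / thresholds / zones


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert roc.auc == pytest.approx(1.0)

    def test_interleaved_labels(self):
        assert roc_analysis([1, 2, 3, 4], [0, 0, 1, 1]).auc == pytest.approx(1.0)
        assert roc_analysis([1, 2, 3, 4], [0, 1, 0, 1]).auc == pytest.approx(0.75)

    def test_ties_count_half(self):
        assert roc_analysis([1, 1, 1, 1], [0, 1, 0, 1]).auc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_oracle_and_sklearn(self, seed):
        from sklearn.metrics import roc_auc_score

        r = np.random.default_rng(seed)
        n = int(r.integers(8, 50))
        values = np.round(r.uniform(0, 30, n), 1)  # rounding forces ties
        labels = r.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        roc = roc_analysis(values, labels)
        assert roc.auc == pytest.approx(auc_pairwise(values, labels), abs=1e-12)
        assert roc.auc == pytest.approx(roc_auc_score(labels, values), abs=1e-12)

    def test_sweep_monotone(self):
        r = np.random.default_rng(2)
        roc = roc_analysis(r.uniform(0, 20, 40), r.integers(0, 2, 40))
        assert (np.diff(roc.sensitivity) >= 0).all()
        assert (np.diff(roc.specificity) <= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2, 3], [1, 1, 1])


class TestSens100Threshold:
    def test_cutoff_strictly_below_min_ltp_value(self):
        cutoff, spec_ = sens100_threshold([3.3, 10.0, 25.0], [1, 1, 1])
        assert cutoff == pytest.approx(3.2)

    def test_value_on_grid_steps_down(self):
        cutoff, _ = sens100_threshold([5.0, 9.0], [1, 1])
        assert cutoff == pytest.approx(4.9)

    def test_grid_floor_at_zero(self):
        cutoff, _ = sens100_threshold([0.1], [1])
        assert cutoff == 0.0

    def test_specificity_counts_nonltp_at_or_below(self):
        cutoff, specificity = sens100_threshold(
            [0.0, 1.0, 2.0, 5.0, 20.0], [0, 0, 0, 1, 1]
        )
        assert cutoff == pytest.approx(4.9)
        assert specificity == 1.0

    def test_requires_positive_case(self):
        with pytest.raises(ValueError):
            sens100_threshold([1.0, 2.0], [0, 0])


class TestZoneBands:
    def test_reference_like_band_at_6mm(self):
        ltp_values = [rec.u(6) for rec in load_reference_cohort()]
        # synthetic non-LTP values; the largest is 19.3
        non_ltp = [0.0, 0.0, 2.5, 6.0, 9.8, 13.0, 19.3]
        values = np.concatenate([ltp_values, non_ltp])
        labels = np.array([1] * len(ltp_values) + [0] * len(non_ltp))
        bands = zone_bands(values, labels, margin_mm=6)
        assert bands.gray == pytest.approx((11.2, 19.3))

    def test_perfect_separation_empty_gray(self):
        bands = zone_bands([1, 2, 3, 20, 30], [0, 0, 0, 1, 1])
        assert bands.gray is None
        assert bands.green_upper > bands.red_lower

    def test_adjacent_green_red(self):
        bands = zone_bands([1.0, 2.0, 10.0, 20.0], [0, 0, 1, 1])
        assert bands.green_upper == pytest.approx(9.9)
        assert bands.red_lower == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# covariate screening


class TestCovariateScreen:
    def test_published_gender_counts_near_one(self):
        # 46/6 male vs 21/3 female (no LTP / LTP); reported p = 0.974
        p = association_test([[6, 46], [3, 21]], correction=False)
        assert p > 0.9

    def test_perfect_association_minimal_p(self):
        cohort = [
            make_record(i, 0.0, bool(i % 2), time=5, vessel=float(i % 2))
            for i in range(40)
        ]
        screen = covariate_screen(cohort, covariates=("vessel",))
        assert screen.loc[0, "p_value"] < 1e-6

    def test_null_covariates_rarely_significant(self):
        rates = []
        for seed in range(30):
            cohort = simulate_cohort(CohortSimSpec(n_cases=80, seed=seed))
            screen = covariate_screen(cohort)
            ps = screen["p_value"].dropna()
            rates.extend(p < 0.05 for p in ps)
        assert np.mean(rates) < 0.12  # near the nominal 5%, generous bound

    def test_continuous_covariates_dichotomized(self):
        cohort = [
            make_record(i, 0.0, i < 4, time=5, size_mm=20.0 + 20 * (i % 2), age=55.0 + (i % 3) * 10)
            for i in range(12)
        ]
        screen = covariate_screen(cohort, covariates=("size_mm", "age")).set_index("covariate")
        assert screen.loc["size_mm", ["pos_ltp", "pos_no_ltp", "neg_ltp", "neg_no_ltp"]].sum() == 12

    def test_constant_covariate_yields_nan(self):
        cohort = [make_record(i, 0.0, i < 2, time=5, organ=0.0) for i in range(6)]
        screen = covariate_screen(cohort, covariates=("organ",))
        assert np.isnan(screen.loc[0, "p_value"])
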