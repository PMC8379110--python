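"""Cohort-level statistics for margin-based treatment-success analysis.

Covers the full analysis battery applied to a cohort of margin-assessed
tumors: per-margin completeness tables with association tests,
Kaplan-Meier LTP-free survival with log-rank comparison, ROC analysis
of the unablated-margin percentage as an LTP predictor, discovery of
100%-sensitivity cut-offs on a one-decimal grid, and the green/gray/red
zone bands those cut-offs induce.

Conventions: the unit of analysis is the tumor (no patient-level
clustering adjustment); chi-square tests are uncorrected (Yates
available by flag), falling back to two-sided Fisher exact for 2x2
tables with small expected counts; ROC ties count 1/2 (Mann-Whitney);
raw p-values without multiplicity adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

from .cohort import CohortRecord, CohortSchemaError
from .margins import CompletenessClass, classify_ablation

__all__ = [
    "ClassificationTable",
    "SurvivalCurve",
    "RocResult",
    "ZoneBands",
    "classification_table",
    "cumulative_table",
    "association_test",
    "fisher_exact_test",
    "km_estimator",
    "logrank_test",
    "roc_analysis",
    "sens100_threshold",
    "zone_bands",
    "compare_groups_continuous",
    "covariate_screen",
]

CLASS_ORDER = tuple(CompletenessClass)


# ---------------------------------------------------------------------------
# completeness tables


@dataclass
class ClassificationTable:
    """Per-class totals and LTP tallies at one margin (one table row)."""

    margin_mm: float
    totals: dict[CompletenessClass, int]
    ltp_counts: dict[CompletenessClass, int]
    p_value: float | None = None

    @property
    def n(self) -> int:
        return sum(self.totals.values())

    @property
    def n_ltp(self) -> int:
        return sum(self.ltp_counts.values())

    def ltp_percent(self, cls: CompletenessClass) -> float:
        t = self.totals[cls]
        return 100.0 * self.ltp_counts[cls] / t if t else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": [c.name for c in CLASS_ORDER],
                "total": [self.totals[c] for c in CLASS_ORDER],
                "ltp": [self.ltp_counts[c] for c in CLASS_ORDER],
                "ltp_pct": [round(self.ltp_percent(c), 1) for c in CLASS_ORDER],
            }
        )


def _record_class(rec: CohortRecord, m: float) -> CompletenessClass:
    return classify_ablation(min(rec.residual_pct, 100.0), rec.u(m))


def classification_table(
    cohort: list[CohortRecord], m: float, *, with_p: bool = True
) -> ClassificationTable:
    """Tally the five completeness classes and their LTP counts at margin m."""
    totals = {c: 0 for c in CLASS_ORDER}
    ltp = {c: 0 for c in CLASS_ORDER}
    for rec in cohort:
        cls = _record_class(rec, m)
        totals[cls] += 1
        if rec.ltp:
            ltp[cls] += 1
    p = None
    if with_p and cohort:
        counts = np.array(
            [
                [ltp[c] for c in CLASS_ORDER],
                [totals[c] - ltp[c] for c in CLASS_ORDER],
            ]
        )
        keep = counts.sum(axis=0) > 0
        if keep.sum() >= 2 and counts.sum(axis=1).min() > 0:
            p = association_test(counts[:, keep])
    return ClassificationTable(float(m), totals, ltp, p)


#: nested coverage groups: class sets whose members count toward each group
CUMULATIVE_GROUPS = (
    ("100%", {CompletenessClass.SM100}),
    (">95%", {CompletenessClass.SM100, CompletenessClass.SM95_100}),
    (
        ">90%",
        {
            CompletenessClass.SM100,
            CompletenessClass.SM95_100,
            CompletenessClass.SM90_95,
        },
    ),
    ("all", set(CLASS_ORDER)),
)


def cumulative_table(cohort: list[CohortRecord], m: float) -> pd.DataFrame:
    """Nested completeness groups (100% / >95% / >90% / all) at margin m."""
    table = classification_table(cohort, m, with_p=False)
    rows = []
    for label, members in CUMULATIVE_GROUPS:
        total = sum(table.totals[c] for c in members)
        ltp = sum(table.ltp_counts[c] for c in members)
        rows.append(
            {
                "group": label,
                "total": total,
                "ltp": ltp,
                "ltp_pct": round(100.0 * ltp / total, 1) if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# association and group-comparison tests


def _validated_counts(table) -> np.ndarray:
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("table must hold non-negative integer counts")
    if counts.sum(axis=0).min() == 0 or counts.sum(axis=1).min() == 0:
        raise ValueError("degenerate table: a margin total is zero")
    return counts


def fisher_exact_test(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric tail sum)."""
    counts = _validated_counts(table)
    if counts.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    return float(sps.fisher_exact(counts.astype(int))[1])


def association_test(table, *, correction: bool = False) -> float:
    """Test independence of an r x c contingency table; returns the p-value.

    Chi-square by default (no continuity correction); a 2x2 table with
    any expected count below 5 is tested with the two-sided Fisher
    exact test instead.
    """
    counts = _validated_counts(table)
    if counts.shape == (2, 2):
        expected = sps.contingency.expected_freq(counts)
        if (expected < 5).any():
            return fisher_exact_test(counts)
    return float(sps.chi2_contingency(counts, correction=correction)[1])


def compare_groups_continuous(values_a, values_b) -> float:
    """Pooled-variance two-sided t test for two independent samples."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate: no within-group variance at all
        return 1.0 if a[0] == b[0] else 0.0
    return float(sps.ttest_ind(a, b, equal_var=True).pvalue)


# ---------------------------------------------------------------------------
# survival


@dataclass
class SurvivalCurve:
    """Product-limit LTP-free survival estimate."""

    times: np.ndarray  # ordered distinct event times
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # risk-set size just before each event time

    def probability_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimator(cohort: list[CohortRecord]) -> SurvivalCurve:
    """Kaplan-Meier estimate of LTP-free survival for a (sub)cohort."""
    if not cohort:
        raise ValueError("empty cohort")
    times = np.array([r.time_months for r in cohort])
    events = np.array([r.ltp for r in cohort], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    event_table = kmf.event_table
    rows = event_table[event_table["observed"] > 0]
    t = rows.index.to_numpy(dtype=float)
    surv = np.array([kmf.survival_function_at_times(x).iloc[0] for x in t])
    return SurvivalCurve(
        times=t, survival=surv, at_risk=rows["at_risk"].to_numpy(dtype=float)
    )


def logrank_test(groups: list[list[CohortRecord]]) -> float:
    """Log-rank comparison of LTP-free survival across >= 2 groups."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    times, events, labels = [], [], []
    for gi, g in enumerate(groups):
        for rec in g:
            times.append(rec.time_months)
            events.append(int(rec.ltp))
            labels.append(gi)
    if sum(events) == 0:
        raise ValueError("no events in any group")
    res = multivariate_logrank_test(
        np.array(times), np.array(labels), np.array(events)
    )
    return float(res.p_value)


# ---------------------------------------------------------------------------
# ROC and threshold discovery


@dataclass
class RocResult:
    """ROC sweep of U_m as an LTP predictor at one margin."""

    margin_mm: float
    auc: float
    thresholds: np.ndarray  # candidate cut-offs, descending
    sensitivity: np.ndarray  # P(U > thr | LTP)
    specificity: np.ndarray  # P(U <= thr | no LTP)
    sens100_threshold: float
    specificity_at_sens100: float


def roc_analysis(values, labels, margin_mm: float = float("nan")) -> RocResult:
    """ROC of "U above threshold predicts LTP" over all distinct cut-offs.

    AUC is the trapezoidal area of the sweep, which for this
    construction equals the Mann-Whitney concordance probability with
    ties counted 1/2.
    """
    u = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if u.shape != y.shape or u.ndim != 1:
        raise ValueError("values and labels must be equal-length 1D")
    if y.min() == y.max():
        raise ValueError("need both LTP and non-LTP cases")

    # thresholds at midpoints between distinct values, plus sentinels
    distinct = np.unique(u)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([distinct[-1] + 1.0], mids[::-1], [distinct[0] - 1.0]))
    pos, neg = u[y == 1], u[y == 0]
    sens = np.array([(pos > t).mean() for t in thresholds])
    spec = np.array([(neg <= t).mean() for t in thresholds])
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))

    cut, spec_at = sens100_threshold(u, y)
    return RocResult(
        margin_mm=margin_mm,
        auc=auc,
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        sens100_threshold=cut,
        specificity_at_sens100=spec_at,
    )


def sens100_threshold(values, labels, *, grid_step: float = 0.1) -> tuple[float, float]:
    """Largest one-decimal cut-off strictly below every LTP case's U value.

    A case is called LTP-prone when its U exceeds the cut-off, so a
    cut-off below the minimum LTP value flags every eventual LTP
    (100% sensitivity). Returns ``(cutoff, specificity)`` where
    specificity is the fraction of non-LTP cases at or below the
    cut-off. The cut-off is floored at 0.
    """
    u = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (y == 1).any():
        raise ValueError("no positive (LTP) cases")
    if grid_step <= 0:
        raise ValueError("grid step must be positive")
    u_min = float(u[y == 1].min())
    # largest grid multiple strictly below u_min (integer grid arithmetic
    # avoids 0.1-representation artifacts)
    k = math.floor(round(u_min / grid_step, 9))
    if k * grid_step >= u_min - 1e-12:
        k -= 1
    cutoff = max(k, 0) * grid_step
    neg = u[y == 0]
    specificity = float((neg <= cutoff + 1e-12).mean()) if neg.size else float("nan")
    return round(cutoff, 10), specificity


@dataclass
class ZoneBands:
    """Green / gray / red partition of U values at one margin.

    green: [0, g) — values seen only without LTP below every LTP value;
    gray:  [g, r] — values compatible with either outcome;
    red:   (r, 100] — above every non-LTP value.
    Gray is empty when the classes separate perfectly (g > r).
    """

    margin_mm: float
    green_upper: float  # g
    red_lower: float  # r

    @property
    def gray(self) -> tuple[float, float] | None:
        if self.green_upper <= self.red_lower:
            return (self.green_upper, self.red_lower)
        return None


def zone_bands(values, labels, margin_mm: float = float("nan")) -> ZoneBands:
    """Derive the zone bands: g from the 100%-sensitivity cut-off, r from
    the largest U observed without LTP."""
    u = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if y.min() == y.max():
        raise ValueError("need both LTP and non-LTP cases")
    g, _ = sens100_threshold(u, y)
    r = float(u[y == 0].max())
    return ZoneBands(margin_mm=margin_mm, green_upper=g, red_lower=r)


# ---------------------------------------------------------------------------
# covariate screening


#: dichotomization rules for continuous covariates
COVARIATE_SPLITS = {"size_mm": 30.0, "age": 60.0}


def covariate_screen(
    cohort: list[CohortRecord], covariates: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Univariate 2x2 association of each covariate with LTP.

    Continuous covariates are dichotomized (size at 30 mm, age at 60
    years); the rest are taken as binary flags. Returns one row per
    covariate with the 2x2 counts and p-value.
    """
    if not cohort:
        raise ValueError("empty cohort")
    if covariates is None:
        covariates = tuple(sorted(cohort[0].covariates))
    ltp = np.array([r.ltp for r in cohort], dtype=bool)
    rows = []
    for name in covariates:
        vals = np.array([r.covariates[name] for r in cohort], dtype=float)
        if name in COVARIATE_SPLITS:
            flag = vals >= COVARIATE_SPLITS[name]
        else:
            flag = vals != 0
        if flag.all() or not flag.any():
            rows.append({"covariate": name, "p_value": float("nan"),
                         "pos_ltp": int((flag & ltp).sum()),
                         "pos_no_ltp": int((flag & ~ltp).sum()),
                         "neg_ltp": int((~flag & ltp).sum()),
                         "neg_no_ltp": int((~flag & ~ltp).sum())})
            continue
        table = np.array(
            [
                [(flag & ltp).sum(), (flag & ~ltp).sum()],
                [(~flag & ltp).sum(), (~flag & ~ltp).sum()],
            ]
        )
        rows.append(
            {
                "covariate": name,
                "p_value": association_test(table),
                "pos_ltp": int(table[0, 0]),
                "pos_no_ltp": int(table[0, 1]),
                "neg_ltp": int(table[1, 0]),
                "neg_no_ltp": int(table[1, 1]),
            }
        )
    return pd.DataFrame(rows)


def cohort_values(cohort: list[CohortRecord], m: float) -> tuple[np.ndarray, np.ndarray]:
    """(U_m values, LTP labels) arrays for a cohort at one margin."""
    if not cohort:
        raise CohortSchemaError("empty cohort")
    u = np.array([r.u(m) for r in cohort])
    y = np.array([int(r.ltp) for r in cohort])
    return u, y
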