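"""Metric oracles: exhaustive-pair AUC, binomial-CI bisection, printed
Pearson formula, median conventions, variance-component ICC, partition
properties of the CV schemes, exact rank-test enumeration, progression."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from breathpd import evaluation as ev
from breathpd import synthetic_data as sd
from breathpd.breathing_io import SubjectRecord


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def auc_brute_force(scores, labels):
    """Exhaustive pairwise concordance with ties counted 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


@pytest.mark.parametrize("scores,labels", [
    ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]),            # perfect -> 1.0
    ([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]),            # all ties -> 0.5
    ([0.1, 0.4, 0.35, 0.8, 0.65, 0.4], [0, 0, 1, 1, 0, 1]),   # 6-point fixture
    ([0.3, 0.3, 0.7, 0.2, 0.9, 0.5, 0.3, 0.61], [0, 1, 1, 0, 1, 0, 0, 1]),
])
def test_auc_equals_exhaustive_concordance(scores, labels):
    _, auc = ev.roc_auc(scores, labels)
    assert abs(auc - auc_brute_force(scores, labels)) < 1e-12


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        ev.roc_auc([0.1, 0.2], [1, 1])


# ---------------------------------------------------------------------------
# sensitivity / specificity
# ---------------------------------------------------------------------------

def test_sens_spec_printed_formulas():
    r = ev.sens_spec(ev.ConfusionCounts(tp=8, fn=2, tn=0, fp=5))
    assert r.sensitivity == 0.8
    assert r.specificity == 0.0


def clopper_pearson_bisect(k, n, alpha=0.05, tol=1e-10):
    """Oracle: invert the binomial tails by bisection."""
    def solve(target, upper):
        lo, hi = 0.0, 1.0
        while hi - lo > tol:
            mid = (lo + hi) / 2
            if upper:
                tail = stats.binom.cdf(k, n, mid)        # P(X <= k)
                lo, hi = (lo, mid) if tail < target else (mid, hi)
            else:
                tail = stats.binom.sf(k - 1, n, mid)     # P(X >= k)
                lo, hi = (mid, hi) if tail < target else (lo, mid)
        return (lo + hi) / 2
    lo = 0.0 if k == 0 else solve(alpha / 2, upper=False)
    hi = 1.0 if k == n else solve(alpha / 2, upper=True)
    return lo, hi


def test_clopper_pearson_matches_bisection_oracle():
    r = ev.sens_spec(ev.ConfusionCounts(tp=73, fn=18, tn=50, fp=10))
    lo, hi = clopper_pearson_bisect(73, 91)
    assert abs(r.sens_ci[0] - lo) < 1e-6
    assert abs(r.sens_ci[1] - hi) < 1e-6
    lo, hi = clopper_pearson_bisect(50, 60)
    assert abs(r.spec_ci[0] - lo) < 1e-6
    assert abs(r.spec_ci[1] - hi) < 1e-6


def test_sens_spec_zero_denominator_and_wilson():
    with pytest.raises(ValueError):
        ev.sens_spec(ev.ConfusionCounts(tp=0, fn=0, tn=5, fp=1))
    r = ev.sens_spec(ev.ConfusionCounts(tp=8, fn=2, tn=9, fp=1),
                     ci_method="wilson")
    assert r.sens_ci[0] < 0.8 < r.sens_ci[1]


def test_threshold_half_is_strict():
    counts = ev.confusion_at_threshold([0.5, 0.51, 0.49, 0.7], [1, 1, 0, 0])
    assert (counts.tp, counts.fn, counts.tn, counts.fp) == (1, 1, 1, 1)


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------

def test_pearson_fixtures():
    u = np.array([3.0, 1.0, 4.0, 1.5])
    assert abs(ev.pearson(u, u) - 1.0) < 1e-12
    assert abs(ev.pearson(u, -u + 7.0) + 1.0) < 1e-12
    # hand computation of the definition on a 4-point fixture
    assert abs(ev.pearson([1, 2, 3, 4], [2, 1, 4, 3]) - 0.6) < 1e-12
    with pytest.raises(ValueError):
        ev.pearson([1, 2, 3], [5, 5, 5])


def test_pearson_agrees_with_scipy(rng):
    u = rng.normal(size=50)
    v = 0.3 * u + rng.normal(size=50)
    assert abs(ev.pearson(u, v) - stats.pearsonr(u, v).statistic) < 1e-12


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def _pred_frame(rows):
    return pd.DataFrame(rows, columns=["subject_id", "night_date", "pd_score"])


def test_aggregate_median_conventions():
    base = date(2023, 3, 1)
    rows = [("a", base + timedelta(days=i + 1), v)
            for i, v in enumerate([0.2, 0.9, 0.7])]
    rows += [("b", base + timedelta(days=1), 0.4)]
    rows += [("c", base + timedelta(days=1), 0.2),
             ("c", base + timedelta(days=2), 0.4)]
    agg = ev.aggregate_subject(_pred_frame(rows))
    assert agg["a"] == 0.7                  # odd count: middle value
    assert agg["b"] == 0.4                  # single night: itself
    assert abs(agg["c"] - 0.3) < 1e-12      # even count: mean of middle two
    # sorting oracle on a larger sample
    vals = [0.11, 0.93, 0.35, 0.62, 0.58, 0.27]
    rows = [("d", base + timedelta(days=i + 1), v) for i, v in enumerate(vals)]
    agg = ev.aggregate_subject(_pred_frame(rows))
    s = sorted(vals)
    assert abs(agg["d"] - (s[2] + s[3]) / 2) < 1e-12


def test_aggregate_window_filters_nights():
    base = date(2023, 3, 1)
    rows = [("a", base + timedelta(days=5), 0.9),
            ("a", base + timedelta(days=40), 0.1)]
    agg = ev.aggregate_subject(_pred_frame(rows), window=ev.month_window(base))
    assert agg["a"] == 0.9
    with pytest.raises(ValueError):
        ev.aggregate_subject(_pred_frame(rows),
                             window=(base + timedelta(days=100),
                                     base + timedelta(days=130)))


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def test_icc_identical_windows_is_one():
    m = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0], [5.0, 5.0]])
    assert abs(ev.icc_oneway(m) - 1.0) < 1e-12


def test_icc_pure_noise_near_zero():
    rng = np.random.default_rng(0)
    m = rng.normal(size=(50, 4))
    assert abs(ev.icc_oneway(m)) < 0.1


def test_icc_matches_variance_component_target():
    m = sd.simulate_variance_components(300, 4, var_between=9.0, var_within=1.0,
                                        seed=1)
    assert abs(ev.icc_oneway(m) - 0.9) < 0.05


def test_icc_agrees_with_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(2)
    m = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1)) * 2.0
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(12), 3),
        "rater": np.tile(np.arange(3), 12),
        "score": m.ravel()})
    ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                             ratings="score")
    icc1 = float(ref["ICC"].iloc[0])  # first row is the one-way ICC(1,1)
    assert abs(ev.icc_oneway(m) - icc1) < 1e-6


def test_test_retest_icc_windows():
    base = date(2023, 3, 1)
    rng = np.random.default_rng(3)
    rows = []
    for i in range(20):
        mu = rng.normal(0, 3)
        for k in range(8):
            rows.append((f"s{i}", base + timedelta(days=k + 1),
                         mu + rng.normal(0, 1)))
    df = _pred_frame(rows)
    pt = ev.test_retest_icc(df, window_n_nights=4, n_boot=100, seed=0)
    assert pt.n_windows == 2 and pt.n_subjects == 20
    assert pt.ci[0] <= pt.icc <= pt.ci[1]
    with pytest.raises(ValueError):
        ev.test_retest_icc(df, window_n_nights=5)  # only one window of 5 fits


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _subjects(n_pd, n_ctl, domain="wireless", institutions=None):
    out = []
    for i in range(n_pd + n_ctl):
        out.append(SubjectRecord(
            subject_id=f"s{i}", domain=domain,
            pd_status="PD" if i < n_pd else "control",
            institution=None if institutions is None else institutions[i]))
    return out


def test_kfold4_partitions_subjects_stratified():
    subjects = _subjects(4, 4)
    folds = ev.crossval(subjects, "kfold4", seed=0)
    assert len(folds) == 4
    all_test = [i for _, te in folds for i in te]
    assert sorted(all_test) == sorted(s.subject_id for s in subjects)
    status = {s.subject_id: s.pd_status for s in subjects}
    for train_ids, test_ids in folds:
        assert len(test_ids) == 2
        assert not set(train_ids) & set(test_ids)
        assert {status[i] for i in test_ids} == {"PD", "control"}


def test_loo_and_cross_institution():
    subjects = _subjects(2, 3, institutions=["A", "A", "B", "B", "C"])
    loo = ev.crossval(subjects, "loo")
    assert len(loo) == 5 and all(len(te) == 1 for _, te in loo)
    xi = ev.crossval(subjects, "cross_institution")
    assert len(xi) == 3
    for train_ids, test_ids in xi:
        insts = {s.institution for s in subjects if s.subject_id in set(test_ids)}
        assert len(insts) == 1
        assert insts.isdisjoint(
            {s.institution for s in subjects if s.subject_id in set(train_ids)})
    hold = ev.crossval(subjects, "external_holdout", test_institution="C")
    assert len(hold) == 1 and hold[0][1] == ["s4"]
    with pytest.raises(ValueError):
        ev.crossval(_subjects(2, 2), "cross_institution")  # untagged


# ---------------------------------------------------------------------------
# group comparisons (exact enumeration oracles)
# ---------------------------------------------------------------------------

def ranksum_exact_oracle(a, b):
    """One-tailed (a greater) p by enumerating all rank assignments."""
    from itertools import combinations
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    obs = ranks[: len(a)].sum()
    total = 0
    at_least = 0
    for comb in combinations(range(len(pooled)), len(a)):
        s = ranks[list(comb)].sum()
        total += 1
        if s >= obs - 1e-12:
            at_least += 1
    return at_least / total


def test_rank_sum_exact_small_sample():
    a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
    # b greater: p = 1/20
    _, p = ev.group_compare(b, a, test="rank_sum_one_tailed")
    assert abs(p - 0.05) < 1e-12
    assert abs(p - ranksum_exact_oracle(b, a)) < 1e-12
    # a greater is the complementary extreme
    _, p_rev = ev.group_compare(a, b, test="rank_sum_one_tailed")
    assert p_rev == 1.0
    # random fixture against the enumeration oracle
    rng = np.random.default_rng(4)
    x, y = rng.normal(size=5), rng.normal(0.5, 1.0, size=4)
    _, p = ev.group_compare(x, y, test="rank_sum_one_tailed")
    assert abs(p - ranksum_exact_oracle(x, y)) < 1e-12


def test_identical_groups_not_significant():
    vals = np.array([1.0, 2.0, 3.0, 4.0])
    _, p = ev.group_compare(vals, vals.copy(), test="rank_sum_one_tailed")
    assert p >= 0.5


def signed_rank_exact_oracle(x):
    """One-tailed p by enumerating all 2^n sign patterns."""
    from itertools import product
    ranks = stats.rankdata(np.abs(x))
    obs = ranks[x > 0].sum()
    count = 0
    patterns = list(product([0, 1], repeat=len(x)))
    for pat in patterns:
        s = sum(r for r, keep in zip(ranks, pat) if keep)
        if s >= obs - 1e-12:
            count += 1
    return count / len(patterns)


def test_signed_rank_exact_small_sample():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    _, p = ev.group_compare(x, test="signed_rank_one_sample")
    assert abs(p - 1.0 / 16.0) < 1e-12
    assert abs(p - signed_rank_exact_oracle(x)) < 1e-12
    rng = np.random.default_rng(5)
    y = rng.normal(0.4, 1.0, size=7)
    _, p = ev.group_compare(y, test="signed_rank_one_sample")
    assert abs(p - signed_rank_exact_oracle(y)) < 1e-12


def test_signed_rank_all_zero_changes():
    _, p = ev.group_compare(np.zeros(6), test="signed_rank_one_sample")
    assert p == 1.0


def test_kruskal_wallis_passthrough():
    g1, g2, g3 = [1, 2, 3], [2, 3, 4], [10, 11, 12]
    stat, p = ev.group_compare(None, test="kruskal_wallis", groups=[g1, g2, g3])
    ref = stats.kruskal(g1, g2, g3)
    assert stat == ref.statistic and p == ref.pvalue
    with pytest.raises(ValueError):
        ev.group_compare(None, test="kruskal_wallis", groups=[[], [1, 2]])


# ---------------------------------------------------------------------------
# progression
# ---------------------------------------------------------------------------

def _progression_fixture(deltas6):
    base = date(2023, 3, 1)
    subjects, rows = [], []
    for i, d6 in enumerate(deltas6):
        sid = f"p{i}"
        subjects.append(SubjectRecord(
            subject_id=sid, domain="wireless", pd_status="PD",
            mds_updrs_total=40.0, baseline_date=base,
            m6_date=base + timedelta(days=182), updrs_m6=40.0 + d6))
        for k in range(3):
            rows.append((sid, base + timedelta(days=k + 1), 40.0))
            rows.append((sid, base + timedelta(days=182 + k + 1), 40.0 + d6))
    df = pd.DataFrame(rows, columns=["subject_id", "night_date", "severity_pred"])
    return df, subjects


def test_progression_all_increasing_is_significant():
    df, subjects = _progression_fixture([2.0, 3.0, 4.0, 5.0, 6.0])
    res = ev.progression_analysis(df, subjects, months=(6,))
    r = res[6]
    assert r.n == 5
    np.testing.assert_allclose(sorted(r.model_changes), [2, 3, 4, 5, 6])
    assert r.model_p < 0.05   # all-positive differences, n = 5 -> p = 1/32
    assert abs(r.model_p - 1.0 / 32.0) < 1e-9
    assert r.clinician_p == r.model_p  # clinician changes identical here


def test_progression_zero_change_p_one():
    df, subjects = _progression_fixture([0.0] * 5)
    res = ev.progression_analysis(df, subjects, months=(6,))
    assert res[6].model_p == 1.0


def test_progression_sign_convention_later_minus_baseline():
    df, subjects = _progression_fixture([-3.0, -4.0, -5.0])
    res = ev.progression_analysis(df, subjects, months=(6,))
    assert (res[6].model_changes < 0).all()
    assert res[6].model_p > 0.5
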