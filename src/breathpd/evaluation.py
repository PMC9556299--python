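"""Metrics, resampling schemes and longitudinal statistics.

Covers the whole evaluation methodology: ROC/AUC, sensitivity and
specificity with binomial CIs at the 0.5 decision threshold, the Pearson
correlation (computed from its definition), median multi-night aggregation
within the month after baseline, one-way random-effects ICC(1,1) test-retest
reliability with subject-level bootstrap CIs, subject-level cross-validation
(stratified 4-fold, leave-one-out, cross-institution, external holdout),
nonparametric group comparisons (one-tailed Wilcoxon rank-sum,
Kruskal-Wallis, one-tailed one-sample signed-rank; exact small-sample
distributions), and the progression analysis comparing model-predicted and
clinician-scored MDS-UPDRS changes at months 6 and 12.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm
from statsmodels.stats.proportion import proportion_confint

from .breathing_io import SubjectRecord


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


def confusion_at_threshold(scores, labels, threshold: float = 0.5
                           ) -> ConfusionCounts:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores > threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (labels == 1))),
        fn=int(np.sum(~pred & (labels == 1))),
        tn=int(np.sum(~pred & (labels == 0))),
        fp=int(np.sum(pred & (labels == 0))))


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC curve and AUC (Mann-Whitney concordance; ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, thr = skm.roc_curve(labels, scores)
    auc = float(skm.roc_auc_score(labels, scores))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return curve, auc


@dataclass
class SensSpecResult:
    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    method: str


def sens_spec(counts: ConfusionCounts, ci_method: str = "clopper-pearson",
              alpha: float = 0.05) -> SensSpecResult:
    """Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), with 95% CIs.

    CI methods: Clopper-Pearson exact (default) or Wilson score.
    """
    if counts.positives == 0 or counts.negatives == 0:
        raise ValueError("sensitivity/specificity need nonzero denominators")
    method = {"clopper-pearson": "beta", "wilson": "wilson"}.get(ci_method)
    if method is None:
        raise ValueError(f"unknown CI method {ci_method!r}")
    sens = counts.tp / counts.positives
    spec = counts.tn / counts.negatives
    s_lo, s_hi = proportion_confint(counts.tp, counts.positives, alpha, method)
    p_lo, p_hi = proportion_confint(counts.tn, counts.negatives, alpha, method)
    return SensSpecResult(sensitivity=sens, specificity=spec,
                          sens_ci=(float(s_lo), float(s_hi)),
                          spec_ci=(float(p_lo), float(p_hi)),
                          method=ci_method)


def pearson(u, v) -> float:
    """Pearson correlation from its definition:
    sum((u-ubar)(v-vbar)) / (sqrt(sum((u-ubar)^2)) * sqrt(sum((v-vbar)^2)))."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.size != v.size or u.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    du = u - u.mean()
    dv = v - v.mean()
    denom = np.sqrt(np.sum(du ** 2)) * np.sqrt(np.sum(dv ** 2))
    if denom == 0:
        raise ValueError("zero variance in at least one input")
    return float(np.sum(du * dv) / denom)


# ---------------------------------------------------------------------------
# multi-night aggregation
# ---------------------------------------------------------------------------

def month_window(baseline: date, days: int = 30) -> tuple[date, date]:
    """The month immediately after the baseline visit: (baseline, baseline+30]."""
    return baseline, baseline + timedelta(days=days)


def aggregate_subject(records: pd.DataFrame,
                      window: tuple[date, date] | None = None,
                      stat: str = "median", col: str = "pd_score") -> pd.Series:
    """Per-subject aggregate of nightly values within a window.

    ``records`` needs columns subject_id, night_date and ``col``.  The window
    is (start, end]; even night counts use the mean-of-the-two-middle median
    convention.  Raises if no night falls in the window.
    """
    df = records
    if window is not None:
        start, end = window
        df = df[(df["night_date"] > start) & (df["night_date"] <= end)]
    if df.empty:
        raise ValueError("no nights fall inside the aggregation window")
    agg = {"median": "median", "mean": "mean"}.get(stat)
    if agg is None:
        raise ValueError(f"unknown aggregation stat {stat!r}")
    return df.groupby("subject_id")[col].agg(agg)


# ---------------------------------------------------------------------------
# test-retest reliability (ICC)
# ---------------------------------------------------------------------------

def icc_oneway(matrix: np.ndarray) -> float:
    """One-way random-effects, single-measurement ICC(1,1).

    Rows are subjects, columns repeated window measurements:
    ICC = (MSB - MSW) / (MSB + (k - 1) MSW) from the one-way ANOVA mean
    squares.  Negative estimates are possible (no truncation).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("ICC needs >= 2 subjects and >= 2 measurements")
    n, k = m.shape
    row_means = m.mean(axis=1)
    grand = m.mean()
    msb = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msw = np.sum((m - row_means[:, None]) ** 2) / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0:
        raise ValueError("zero total variance")
    return float((msb - msw) / denom)


@dataclass
class ReliabilityPoint:
    window_n_nights: int
    icc: float
    ci: tuple[float, float]
    n_subjects: int
    n_windows: int


def test_retest_icc(records: pd.DataFrame, window_n_nights: int,
                    col: str = "pd_score", n_boot: int = 1000, seed: int = 0,
                    min_subjects: int = 5) -> ReliabilityPoint:
    """ICC of window-aggregated predictions, windows as repeated measures.

    Each subject's nights (already restricted to the month after baseline,
    ordered by date) are split into consecutive non-overlapping windows of
    ``window_n_nights``; window medians form the subjects x windows matrix
    (every subject contributes the same number of windows — the minimum
    available — so the one-way design is balanced).  The CI is a
    subject-level bootstrap (percentile, ``n_boot`` resamples).
    """
    groups = []
    for _, g in records.sort_values("night_date").groupby("subject_id"):
        vals = g[col].to_numpy(dtype=float)
        n_win = vals.size // window_n_nights
        if n_win >= 2:
            meds = [np.median(vals[i * window_n_nights:(i + 1) * window_n_nights])
                    for i in range(n_win)]
            groups.append(meds)
    if len(groups) < min_subjects:
        raise ValueError(
            f"need >= {min_subjects} subjects with >= 2 windows of "
            f"{window_n_nights} nights; got {len(groups)}")
    k = min(len(g) for g in groups)
    m = np.asarray([g[:k] for g in groups])
    icc = icc_oneway(m)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, m.shape[0], size=m.shape[0])
        try:
            boots.append(icc_oneway(m[idx]))
        except ValueError:  # degenerate resample
            continue
    lo, hi = np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan)
    return ReliabilityPoint(window_n_nights=window_n_nights, icc=icc,
                            ci=(float(lo), float(hi)),
                            n_subjects=m.shape[0], n_windows=k)


def reliability_curve(records: pd.DataFrame, window_sizes, col: str = "pd_score",
                      n_boot: int = 200, seed: int = 0) -> list[ReliabilityPoint]:
    return [test_retest_icc(records, w, col=col, n_boot=n_boot, seed=seed)
            for w in window_sizes]


# ---------------------------------------------------------------------------
# cross-validation schemes
# ---------------------------------------------------------------------------

def crossval(subjects: list[SubjectRecord], scheme: str, n_folds: int = 4,
             seed: int = 0, test_institution: str | None = None
             ) -> list[tuple[list[str], list[str]]]:
    """Subject-level train/test partitions.

    * ``kfold4``: stratified by (pd_status, domain); every subject's nights
      stay in one fold.
    * ``loo``: leave-one-subject-out.
    * ``cross_institution``: one configuration per institution, testing on
      the held-out institution.
    * ``external_holdout``: single split testing on ``test_institution``.
    """
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    if scheme == "kfold4":
        rng = np.random.default_rng(seed)
        folds: list[list[str]] = [[] for _ in range(n_folds)]
        strata: dict[tuple[str, str], list[str]] = {}
        for s in subjects:
            strata.setdefault((s.pd_status, s.domain), []).append(s.subject_id)
        for key in sorted(strata):
            members = strata[key]
            rng.shuffle(members)
            for j, sid in enumerate(members):
                folds[j % n_folds].append(sid)
        return [([i for f, fold in enumerate(folds) if f != k for i in fold],
                 folds[k]) for k in range(n_folds)]
    if scheme == "loo":
        return [([i for i in ids if i != sid], [sid]) for sid in ids]
    if scheme in ("cross_institution", "external_holdout"):
        tags = {s.subject_id: s.institution for s in subjects}
        if any(t is None for t in tags.values()):
            raise ValueError(f"scheme {scheme!r} requires institution tags")
        institutions = sorted({t for t in tags.values()})
        if scheme == "external_holdout":
            if test_institution not in institutions:
                raise ValueError(f"unknown institution {test_institution!r}")
            institutions = [test_institution]
        return [([i for i in ids if tags[i] != inst],
                 [i for i in ids if tags[i] == inst]) for inst in institutions]
    raise ValueError(f"unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# nonparametric group comparisons
# ---------------------------------------------------------------------------

def _no_ties(*arrays) -> bool:
    pooled = np.concatenate(arrays)
    return np.unique(pooled).size == pooled.size


def group_compare(a, b=None, test: str = "rank_sum_one_tailed",
                  alternative: str = "greater", groups=None
                  ) -> tuple[float, float]:
    """Nonparametric comparisons with exact small-sample distributions.

    * ``rank_sum_one_tailed``: Wilcoxon rank-sum / Mann-Whitney on (a, b);
      ``alternative='greater'`` tests whether a stochastically exceeds b.
      Exact when both groups have n <= 10 and no ties, otherwise normal
      approximation with tie correction.
    * ``kruskal_wallis``: pass the samples via ``groups``.
    * ``signed_rank_one_sample``: one-sample Wilcoxon signed-rank of a
      against zero (drop-zeros convention; p = 1 when all values are zero).
    """
    if test == "rank_sum_one_tailed":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("rank-sum needs >= 2 values per group")
        method = ("exact" if max(a.size, b.size) <= 10 and _no_ties(a, b)
                  else "asymptotic")
        res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
        return float(res.statistic), float(res.pvalue)
    if test == "kruskal_wallis":
        gs = groups if groups is not None else [a, b]
        if any(len(g) == 0 for g in gs):
            raise ValueError("empty group in Kruskal-Wallis test")
        res = stats.kruskal(*gs)
        return float(res.statistic), float(res.pvalue)
    if test == "signed_rank_one_sample":
        x = np.asarray(a, dtype=float)
        if x.size < 1:
            raise ValueError("empty sample")
        nz = x[x != 0]
        if nz.size == 0:
            return 0.0, 1.0
        method = ("exact" if nz.size <= 10 and _no_ties(np.abs(nz))
                  else "approx")
        res = stats.wilcoxon(nz, alternative=alternative, method=method)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


# ---------------------------------------------------------------------------
# progression analysis
# ---------------------------------------------------------------------------

@dataclass
class ProgressionResult:
    month: int
    n: int
    model_changes: np.ndarray
    model_p: float
    clinician_changes: np.ndarray | None
    clinician_p: float | None


def progression_analysis(predictions: pd.DataFrame,
                         subjects: list[SubjectRecord],
                         months: tuple[int, ...] = (6, 12),
                         window_days: int = 30,
                         single_night: bool = False,
                         col: str = "severity_pred"
                         ) -> dict[int, ProgressionResult]:
    """Model-predicted and clinician-scored MDS-UPDRS change at follow-up.

    For each subject with a month-6 (or month-12) visit, the model change is
    the median nightly prediction over the month following that visit minus
    the median over the month following baseline (positive = worsening).
    ``single_night=True`` uses the first night of each window instead of the
    median.  Each set of changes gets a one-tailed one-sample Wilcoxon
    signed-rank p-value for an increase.
    """
    results: dict[int, ProgressionResult] = {}
    for month in months:
        model_changes, clin_changes = [], []
        for s in subjects:
            visit = s.m6_date if month == 6 else s.m12_date
            clin_score = s.updrs_m6 if month == 6 else s.updrs_m12
            if s.baseline_date is None or visit is None:
                continue
            sub = predictions[predictions["subject_id"] == s.subject_id]
            try:
                base = _window_value(sub, month_window(s.baseline_date, window_days),
                                     col, single_night)
                late = _window_value(sub, month_window(visit, window_days),
                                     col, single_night)
            except ValueError:
                continue
            model_changes.append(late - base)
            if clin_score is not None and s.mds_updrs_total is not None:
                clin_changes.append(clin_score - s.mds_updrs_total)
        if not model_changes:
            raise ValueError(f"no subject qualifies for the month-{month} analysis")
        _, model_p = group_compare(np.asarray(model_changes),
                                   test="signed_rank_one_sample",
                                   alternative="greater")
        clin_p = None
        if clin_changes:
            _, clin_p = group_compare(np.asarray(clin_changes),
                                      test="signed_rank_one_sample",
                                      alternative="greater")
        results[month] = ProgressionResult(
            month=month, n=len(model_changes),
            model_changes=np.asarray(model_changes), model_p=model_p,
            clinician_changes=np.asarray(clin_changes) if clin_changes else None,
            clinician_p=clin_p)
    return results


def _window_value(sub: pd.DataFrame, window: tuple[date, date], col: str,
                  single_night: bool) -> float:
    start, end = window
    w = sub[(sub["night_date"] > start) & (sub["night_date"] <= end)]
    if w.empty:
        raise ValueError("empty window")
    if single_night:
        return float(w.sort_values("night_date")[col].iloc[0])
    return float(w[col].median())


# ---------------------------------------------------------------------------
# predictions TSV
# ---------------------------------------------------------------------------

def save_predictions_tsv(df: pd.DataFrame, path):
    cols = ["subject_id", "night_date", "pd_score", "severity_pred"]
    df[cols].to_csv(path, sep="\t", index=False)
    return path


def load_predictions_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", parse_dates=["night_date"])
    df["night_date"] = df["night_date"].dt.date
    return df
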