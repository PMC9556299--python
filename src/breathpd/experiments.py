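"""End-to-end validation experiments on the synthetic polysomnography cohorts.

Each function runs one self-contained study at desk scale and returns its
headline numbers.  They are what the acceptance tests and the
``scripts/acceptance.py`` entry point execute:

* signal recovery — train the full multitask model on a strong-effect
  cohort (40+40 wireless subjects, three 30-min nights each, 30 epochs) and
  measure held-out subject-level AUC under stratified 4-fold CV, plus the
  same pipeline on a null cohort (all disease effects zero) as a leakage
  control;
* severity recovery — train one severity-weighted model and correlate
  3-night-median predictions with generating MDS-UPDRS on an independently
  simulated cohort (printed-formula Pearson);
* calibration recovery — Platt scaling recovers a known score transform;
* aggregation/reliability — accuracy and test-retest ICC versus the number
  of aggregated nights, and the variance-components ICC anchor;
* domain invariance — post-hoc domain probe accuracy with and without
  adversarial training on a two-domain cohort;
* consistency — within-subject spread of severity predictions with and
  without the transductive consistency term;
* progression power — detectability of a +6 points/year drift from
  month-window medians versus single nights.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from . import evaluation as ev
from . import synthetic_data as sd
from . import training as tr
from .breathing_io import impute_control_labels


def _kfold_predictions(cohort, tcfg, seed):
    impute_control_labels(cohort.subjects)
    train_set = tr.prepare_training_data(cohort.subjects, cohort.qeeg,
                                         screen=False)
    by_id = {s.subject_id: s for s in train_set}
    folds = ev.crossval(cohort.subjects, "kfold4", seed=seed)
    rows = []
    for k, (train_ids, test_ids) in enumerate(folds):
        model, _ = tr.train_model([by_id[i] for i in train_ids], tcfg,
                                  seed=(seed * 10 + k) % (2**31 - 1))
        test_recs = [s for s in cohort.subjects
                     if s.subject_id in set(test_ids)]
        rows.append(tr.predict_cohort(model, test_recs))
    import pandas as pd

    return pd.concat(rows, ignore_index=True)


def detection_experiment(seed: int = 1, n_per_class: int = 40, nights: int = 3,
                         night_s: float = 1800.0, epochs: int = 30,
                         null: bool = False) -> dict:
    """Held-out subject-level AUC of the full multitask pipeline (kfold4).

    ``null=True`` reruns the identical pipeline on a cohort with every
    disease effect set to zero; the resulting AUC should be chance, which
    guards against information leakage anywhere in the pipeline.
    """
    if null:
        cfg = sd.null_config(n_subjects={"wireless": (n_per_class, n_per_class)},
                             nights_per_subject=nights, night_s=night_s)
    else:
        cfg = sd.strong_effect_config(n_per_class, nights, night_s)
    cohort = sd.simulate_cohort(cfg, seed=seed)
    preds = _kfold_predictions(cohort, tr.TrainConfig(epochs=epochs), seed)
    labels = {s.subject_id: int(s.pd_status == "PD") for s in cohort.subjects}
    truth = {sid: p.severity for sid, p in cohort.params.items()}
    per = ev.aggregate_subject(preds)
    sev = ev.aggregate_subject(preds, col="severity_pred")
    y = [labels[s] for s in per.index]
    _, auc = ev.roc_auc(per.to_numpy(), y)
    r = ev.pearson([truth[s] for s in sev.index], sev.to_numpy())
    counts = ev.confusion_at_threshold(per.to_numpy(), np.asarray(y))
    ss = ev.sens_spec(counts)
    return {"auc": auc, "pearson_r_pooled": r, "n_subjects": len(y),
            "sensitivity": ss.sensitivity, "specificity": ss.specificity,
            "predictions": preds, "labels": labels, "truth": truth}


def severity_experiment(seed: int = 21, n_train_per_class: int = 40,
                        n_test_per_class: int = 20, nights: int = 3,
                        night_s: float = 1800.0, epochs: int = 45) -> dict:
    """Severity recovery: one severity-weighted model, independent test cohort.

    Trains with an emphasized regression term (w_sev = 2) and evaluates the
    Pearson correlation (printed formula) between generating MDS-UPDRS and
    3-night-median predictions on a separately simulated cohort.
    """
    train_cohort = sd.simulate_cohort(
        sd.strong_effect_config(n_train_per_class, nights, night_s), seed=seed)
    impute_control_labels(train_cohort.subjects)
    train_set = tr.prepare_training_data(train_cohort.subjects,
                                         train_cohort.qeeg, screen=False)
    model, _ = tr.train_model(train_set,
                              tr.TrainConfig(epochs=epochs, w_sev=2.0),
                              seed=(seed + 1) % (2**31 - 1))
    test_cohort = sd.simulate_cohort(
        sd.strong_effect_config(n_test_per_class, nights, night_s),
        seed=(seed + 1000) % (2**31 - 1))
    preds = tr.predict_cohort(model, test_cohort.subjects)
    sev = ev.aggregate_subject(preds, col="severity_pred")
    per = ev.aggregate_subject(preds)
    truth = {sid: p.severity for sid, p in test_cohort.params.items()}
    labels = {s.subject_id: int(s.pd_status == "PD")
              for s in test_cohort.subjects}
    t_all = np.array([truth[s] for s in sev.index])
    p_all = sev.to_numpy()
    y = np.array([labels[s] for s in per.index])
    r = ev.pearson(t_all, p_all)
    r_pd = ev.pearson(t_all[y == 1], p_all[y == 1])
    _, auc = ev.roc_auc(per.to_numpy(), y)
    return {"pearson_r": r, "pearson_r_pd_only": r_pd, "external_auc": auc,
            "n_subjects": int(y.size)}


def calibration_recovery(seed: int = 0, n: int = 2000) -> dict:
    """Platt-scaling oracle: recover a known generating transform.

    Logits are 2*z0 - 1 while labels follow Bernoulli(sigma(z0)), so the
    calibrator must find (A, B) = (0.5, 0.5); a second draw with calibrated
    logits must give (A, B) = (1, 0).  Calibrated cross-entropy can never
    exceed the uncalibrated one (the fit starts at the identity).
    """
    rng = np.random.default_rng(seed)
    z0 = rng.normal(0.0, 2.0, size=n)
    y = (rng.random(n) < expit(z0)).astype(float)
    cal = tr.platt_calibrate(2.0 * z0 - 1.0, y)
    z1 = rng.normal(0.0, 2.0, size=n)
    y1 = (rng.random(n) < expit(z1)).astype(float)
    cal_id = tr.platt_calibrate(z1, y1)
    ce_cal = tr._platt_ce(2.0 * z0 - 1.0, y, cal.A, cal.B)
    ce_raw = tr._platt_ce(2.0 * z0 - 1.0, y, 1.0, 0.0)
    return {"A": cal.A, "B": cal.B,
            "A_error": abs(cal.A - 0.5), "B_error": abs(cal.B - 0.5),
            "A_identity": cal_id.A, "B_identity": cal_id.B,
            "ce_calibrated": ce_cal, "ce_uncalibrated": ce_raw}


AGGREGATION_GRID = (1, 2, 4, 8, 15)


def aggregation_reliability_experiment(seed: int = 0, n_per_class: int = 100,
                                       n_nights: int = 30, n_seeds: int = 5
                                       ) -> dict:
    """Accuracy and ICC as functions of the aggregation window (medians over
    ``n_seeds`` independent cohorts), plus the 9:1 variance-components ICC."""
    acc_by_w = {w: [] for w in AGGREGATION_GRID}
    icc_by_w = {w: [] for w in AGGREGATION_GRID}
    for k in range(n_seeds):
        df, labels = sd.simulate_nightly_scores(
            n_per_class, n_nights, seed=(seed * 100 + k) % (2**31 - 1))
        for w in AGGREGATION_GRID:
            sub = df.groupby("subject_id").head(w)
            agg = sub.groupby("subject_id")["pd_score"].median()
            y = np.array([labels[s] for s in agg.index])
            acc_by_w[w].append(float(np.mean((agg.to_numpy() > 0.5) == y)))
            icc_by_w[w].append(
                ev.test_retest_icc(df, w, n_boot=10, seed=seed).icc)
    acc = [float(np.median(acc_by_w[w])) for w in AGGREGATION_GRID]
    icc = [float(np.median(icc_by_w[w])) for w in AGGREGATION_GRID]
    m = sd.simulate_variance_components(300, 4, 9.0, 1.0,
                                        seed=(seed + 11) % (2**31 - 1))
    return {"grid": AGGREGATION_GRID, "accuracy_medians": acc,
            "icc_medians": icc,
            "accuracy_monotone": all(b >= a for a, b in zip(acc, acc[1:])),
            "icc_monotone": all(b >= a for a, b in zip(icc, icc[1:])),
            "icc_9to1": ev.icc_oneway(m)}


def domain_invariance_experiment(seed: int = 5, n_per_cell: int = 16,
                                 nights: int = 3, night_s: float = 600.0,
                                 epochs: int = 30,
                                 train_seeds: tuple[int, ...] = (0, 1, 2)
                                 ) -> dict:
    """Domain-probe accuracy with vs without adversarial training.

    Same two-domain cohort and training conditions in both arms; the probe
    is a fresh logistic regression on pooled features scored by grouped CV.
    Reports the median over ``train_seeds``.
    """
    cohort = sd.simulate_cohort(
        sd.two_domain_config(n_per_cell, nights, night_s), seed=seed)
    impute_control_labels(cohort.subjects)
    train_set = tr.prepare_training_data(cohort.subjects, cohort.qeeg,
                                         screen=False)
    out = {}
    for label, adversarial in (("plain", False), ("adversarial", True)):
        accs = []
        for ts in train_seeds:
            cfg = tr.domain_adaptation_train_config(
                epochs=epochs, use_adversarial=adversarial)
            model, _ = tr.train_model(train_set, cfg, seed=ts)
            accs.append(tr.domain_probe_accuracy(model, train_set, seed=ts))
        out[f"probe_{label}"] = float(np.median(accs))
        out[f"probe_{label}_all"] = accs
    return out


def consistency_experiment(seed: int = 7, n_per_class: int = 16,
                           nights: int = 3, night_s: float = 600.0,
                           epochs: int = 15, w_cons: float = 25.0,
                           train_seeds: tuple[int, ...] = (0, 1, 2)) -> dict:
    """Within-subject sd of held-out severity predictions, +/- consistency.

    The consistency arm uses an emphatic weight (the within-subject variance
    is tiny on the standardized residual scale, so the effect would be
    invisible at token weights).  Reports per-arm medians over seeds.
    """
    cohort = sd.simulate_cohort(
        sd.strong_effect_config(n_per_class, nights, night_s), seed=seed)
    impute_control_labels(cohort.subjects)
    train_set = tr.prepare_training_data(cohort.subjects, cohort.qeeg,
                                         screen=False)
    by_id = {s.subject_id: s for s in train_set}
    train_ids, test_ids = ev.crossval(cohort.subjects, "kfold4", seed=seed)[0]
    test_recs = [s for s in cohort.subjects if s.subject_id in set(test_ids)]
    out = {}
    for label, (use, w) in (("plain", (False, 0.0)),
                            ("consistency", (True, w_cons))):
        sds = []
        for ts in train_seeds:
            cfg = tr.TrainConfig(epochs=epochs, use_consistency=use, w_cons=w)
            model, _ = tr.train_model([by_id[i] for i in train_ids], cfg,
                                      seed=ts)
            df = tr.predict_cohort(model, test_recs)
            sds.append(float(df.groupby("subject_id")["severity_pred"]
                             .std().mean()))
        out[f"within_subject_sd_{label}"] = float(np.median(sds))
        out[f"within_subject_sd_{label}_all"] = sds
    return out


def progression_power_experiment(seed: int = 0, n_replicates: int = 100,
                                 n_subjects: int = 12,
                                 drift_per_year: float = 6.0,
                                 noise_sd: float = 8.0,
                                 nights_per_window: int = 30,
                                 month: int = 6) -> dict:
    """Fraction of replicate cohorts where the month-window median change is
    detected (one-tailed signed-rank, p < 0.05), vs the single-night variant."""
    hits_median = hits_single = 0
    for rep in range(n_replicates):
        df, recs = sd.simulate_prediction_drift(
            n_subjects, drift_per_year, noise_sd, nights_per_window,
            seed=(seed * 1000 + rep) % (2**31 - 1))
        res = ev.progression_analysis(df, recs, months=(month,))
        hits_median += res[month].model_p < 0.05
        res1 = ev.progression_analysis(df, recs, months=(month,),
                                       single_night=True)
        hits_single += res1[month].model_p < 0.05
    return {"power_median_window": hits_median / n_replicates,
            "power_single_night": hits_single / n_replicates,
            "n_replicates": n_replicates}
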