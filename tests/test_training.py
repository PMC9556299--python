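"""Composite loss availability masking, consistency loss, Platt calibration
oracles, ensembling contracts and training-loop determinism."""

from datetime import date

import numpy as np
import pytest
from scipy.special import expit, logit as logit_fn

from breathpd import training as tr
from breathpd._nn import Tensor
from breathpd.model_core import ModelConfig, PDBreathingModel


# ---------------------------------------------------------------------------
# consistency loss
# ---------------------------------------------------------------------------

def _tensors(vals):
    return [Tensor(np.array(v), requires_grad=True) for v in vals]


def test_consistency_loss_values_and_invariance():
    loss, ok = tr.consistency_loss(_tensors([10.0, 10.0, 10.0]))
    assert ok and float(loss.data) == 0.0
    # population variance of [0, 2] is 1
    loss, _ = tr.consistency_loss(_tensors([0.0, 2.0]))
    assert float(loss.data) == 1.0
    a = float(tr.consistency_loss(_tensors([1.0, 5.0, 2.0]))[0].data)
    b = float(tr.consistency_loss(_tensors([2.0, 1.0, 5.0]))[0].data)
    assert a == b  # permutation invariant
    loss, ok = tr.consistency_loss(_tensors([3.0]))
    assert not ok and float(loss.data) == 0.0  # single night: not applicable


# ---------------------------------------------------------------------------
# composite loss
# ---------------------------------------------------------------------------

def _night_output(model, x, group="PD", adv=False):
    out = model.forward_night(x, parts=("total",), with_qeeg=True)
    if adv:
        out["disc_logit"] = model.discriminate(out["g"], group, reverse=True)
    return out


WEIGHTS = {"w_cls": 1.0, "w_sev": 0.05, "w_qeeg": 1.0, "w_adv": 0.1,
           "w_cons": 0.1}


def test_unavailable_terms_contribute_exactly_zero(rng):
    model = PDBreathingModel(ModelConfig(seed=1))
    outs = [_night_output(model, rng.normal(size=6400)) for _ in range(2)]
    labels = {"y": 1, "severity": None, "domain_y": 0,
              "qeeg_targets": [None, None], "qeeg_masks": [None, None]}
    avail = {"cls": True, "sev": False, "qeeg": False, "adv": False,
             "cons": True}
    total, bd = tr.composite_loss(outs, labels, avail, WEIGHTS)
    # total is exactly w_cls * l_cls + w_cons * l_cons
    assert abs(bd.total - (bd.l_cls + 0.1 * bd.l_cons)) < 1e-12
    assert bd.l_sev == 0.0 and bd.l_qeeg == 0.0 and bd.l_adv == 0.0


def test_missing_qeeg_label_propagates_no_gradient(rng):
    """Finite-difference check: with no qEEG label, perturbing a parameter
    that only the qEEG decoder uses leaves the total loss unchanged."""
    model = PDBreathingModel(ModelConfig(seed=2))
    x = rng.normal(size=6400)

    def total_loss():
        outs = [_night_output(model, x)]
        labels = {"y": 1, "severity": 50.0, "domain_y": 0,
                  "qeeg_targets": [None], "qeeg_masks": [None]}
        avail = {"cls": True, "sev": True, "qeeg": False, "adv": False,
                 "cons": False}
        t, _ = tr.composite_loss(outs, labels, avail, WEIGHTS)
        return float(t.data)

    base = total_loss()
    p = model.decoder.fc2.w
    p.data += 0.5
    assert total_loss() == base
    p.data -= 0.5
    # and backward deposits no gradient on decoder-only parameters
    outs = [_night_output(model, x)]
    labels = {"y": 1, "severity": 50.0, "domain_y": 0,
              "qeeg_targets": [None], "qeeg_masks": [None]}
    avail = {"cls": True, "sev": True, "qeeg": False, "adv": False,
             "cons": False}
    t, _ = tr.composite_loss(outs, labels, avail, WEIGHTS)
    model.zero_grad()
    t.backward()
    assert all(g is None for g in (q.grad for q in model.decoder.parameters()))


def test_perfect_predictions_zero_terms(rng):
    model = PDBreathingModel(ModelConfig(seed=3))
    x = rng.normal(size=6400)
    out = _night_output(model, x)
    # qEEG target equal to the prediction -> l_qeeg exactly 0
    tgt = out["qeeg_pred"].data.T.copy()
    labels = {"y": 1, "severity": float(out["severity"]["total"].data),
              "domain_y": 0, "qeeg_targets": [tgt], "qeeg_masks": [None]}
    avail = {"cls": True, "sev": True, "qeeg": True, "adv": False,
             "cons": False}
    _, bd = tr.composite_loss([out], labels, avail, WEIGHTS)
    assert bd.l_qeeg == 0.0
    assert bd.l_sev == 0.0  # severity target equals prediction


def test_all_terms_unavailable_is_an_error(rng):
    model = PDBreathingModel(ModelConfig(seed=3))
    out = _night_output(model, rng.normal(size=6400))
    with pytest.raises(ValueError):
        tr.composite_loss([out], {"y": 0}, {k: False for k in
                          ("cls", "sev", "qeeg", "adv", "cons")}, WEIGHTS)


# ---------------------------------------------------------------------------
# Platt calibration
# ---------------------------------------------------------------------------

def test_platt_recovers_generating_transform():
    # scores sigma(2 z0 - 1), labels ~ Bernoulli(sigma(z0)): the calibrator
    # must invert the transform, i.e. A ~ 0.5, B ~ 0.5 on logits z = 2 z0 - 1
    rng = np.random.default_rng(0)
    z0 = rng.normal(0.0, 2.0, size=2000)
    y = (rng.random(2000) < expit(z0)).astype(float)
    cal = tr.platt_calibrate(2.0 * z0 - 1.0, y)
    assert abs(cal.A - 0.5) < 0.1
    assert abs(cal.B - 0.5) < 0.1


def test_platt_identity_when_already_calibrated():
    rng = np.random.default_rng(0)
    z = rng.normal(0.0, 2.0, size=2000)
    y = (rng.random(2000) < expit(z)).astype(float)
    cal = tr.platt_calibrate(z, y)
    assert abs(cal.A - 1.0) < 0.1
    assert abs(cal.B - 0.0) < 0.1


def test_platt_never_increases_cross_entropy():
    rng = np.random.default_rng(2)
    for trial in range(5):
        z = rng.normal(0.0, 3.0, size=200)
        y = (rng.random(200) < expit(0.3 * z - 0.7)).astype(float)
        cal = tr.platt_calibrate(z, y)
        ce_cal = tr._platt_ce(z, y, cal.A, cal.B)
        ce_raw = tr._platt_ce(z, y, 1.0, 0.0)
        assert ce_cal <= ce_raw + 1e-12


def test_platt_single_class_errors():
    with pytest.raises(ValueError):
        tr.platt_calibrate(np.array([0.1, 0.2, 0.3]), np.array([1.0, 1.0, 1.0]))


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _train_set_from(cohort):
    from breathpd.breathing_io import impute_control_labels
    impute_control_labels(cohort.subjects)
    return tr.prepare_training_data(cohort.subjects, cohort.qeeg, screen=False)


def test_train_model_deterministic_given_seed(small_cohort):
    train_set = _train_set_from(small_cohort)
    cfg = tr.TrainConfig(epochs=1, crop_s=120.0)
    m1, log1 = tr.train_model(train_set, cfg, seed=5)
    m2, log2 = tr.train_model(train_set, cfg, seed=5)
    s1, s2 = m1.state_dict(), m2.state_dict()
    assert all(np.array_equal(s1[k], s2[k]) for k in s1)
    assert log1 == log2
    # training loss decreases over a few more epochs
    m3, log3 = tr.train_model(train_set, tr.TrainConfig(epochs=4, crop_s=120.0),
                              seed=5)
    assert log3[-1]["l_qeeg"] < log3[0]["l_qeeg"]


def test_train_model_needs_both_classes(small_cohort):
    train_set = [s for s in _train_set_from(small_cohort) if s.y == 1]
    with pytest.raises(ValueError):
        tr.train_model(train_set, tr.TrainConfig(epochs=1), seed=0)


def test_class_weights_inverse_frequency(small_cohort):
    # 2% prevalence weighting: positives upweighted by ~25x
    n_pos, n_neg = 2, 98
    w_pos = (n_pos + n_neg) / (2 * n_pos)
    w_neg = (n_pos + n_neg) / (2 * n_neg)
    assert w_pos / w_neg == n_neg / n_pos


# ---------------------------------------------------------------------------
# ensembling
# ---------------------------------------------------------------------------

def test_stratified_subsets_partition_subjects(small_cohort):
    train_set = _train_set_from(small_cohort)
    rng = np.random.default_rng(0)
    subsets = tr._stratified_subsets(train_set, 4, rng)
    flat = [i for sub in subsets for i in sub]
    assert sorted(flat) == list(range(len(train_set)))  # disjoint and complete
    sizes = [len(sub) for sub in subsets]
    assert max(sizes) - min(sizes) <= 1
    # class balance within one subject of even
    for sub in subsets:
        n_pd = sum(train_set[i].y for i in sub)
        assert abs(n_pd - len(sub) / 2) <= 1


def test_build_ensemble_small(small_cohort):
    train_set = _train_set_from(small_cohort)
    cfg = tr.TrainConfig(epochs=1, crop_s=120.0)
    bundle = tr.build_ensemble(train_set, cfg, seed=3)
    assert len(bundle.members) == 4
    assert sorted(c["fold_id"] for c in bundle.calibrations) == [0, 1, 2, 3]
    x = train_set[0].nights[0].x
    out = bundle.predict_night(x)
    assert 0.0 < out["pd_score"] < 1.0
    assert abs(out["pd_score"] - np.mean(out["member_scores"])) < 1e-12


def test_build_ensemble_requires_eight_subjects(small_cohort):
    with pytest.raises(ValueError):
        tr.build_ensemble(_train_set_from(small_cohort)[:6],
                          tr.TrainConfig(epochs=1), seed=0)
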