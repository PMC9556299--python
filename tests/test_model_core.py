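"""Network contracts: shapes, attention pooling against brute force,
hand-computed head forwards, qEEG decoder simplex output, discriminator
routing, determinism and serialization."""

import numpy as np
import pytest
from scipy.special import expit

from breathpd import model_core as mc
from breathpd._nn import Tensor, binary_cross_entropy_logit
from breathpd.model_core import (AttentionProfile, FeatureSequence, GlobalFeature,
                                 ModelBundle, ModelConfig, PDBreathingModel)


def test_config_stride_plan():
    cfg = ModelConfig()
    assert cfg.total_stride == 80
    assert cfg.feature_step_s == 8.0
    cfg.validate()
    with pytest.raises(ValueError):
        ModelConfig(stem_stride=4).validate()  # 64x stride breaks the 1 Hz plan


def test_encoder_shape_contract(tiny_model, rng):
    # 7,200-s night (72,000 samples) -> 900 feature steps
    f = mc.encode_breathing(tiny_model, rng.normal(size=72_000))
    assert f.time_steps == 900
    assert f.data.shape[1] == tiny_model.cfg.d
    # shape oracle over random lengths: steps == ceil(n / 80)
    for n in rng.integers(6400, 40_000, size=8):
        f = mc.encode_breathing(tiny_model, rng.normal(size=int(n)))
        assert f.time_steps == -(-int(n) // 80)
    # doubling input length doubles time_steps (lengths divisible by stride)
    for n in (8000, 12_000):
        t1 = mc.encode_breathing(tiny_model, rng.normal(size=n)).time_steps
        t2 = mc.encode_breathing(tiny_model, rng.normal(size=2 * n)).time_steps
        assert t2 == 2 * t1


def test_encoder_zero_input_finite(tiny_model):
    f = mc.encode_breathing(tiny_model, np.zeros(8000))
    assert np.isfinite(f.data).all()


def test_encoder_minimum_length(tiny_model):
    with pytest.raises(ValueError):
        tiny_model.encode(np.zeros(8 * 80 - 1))


def test_attention_pool_matches_brute_force(tiny_model, rng):
    f = mc.encode_breathing(tiny_model, rng.normal(size=8000))
    g, attn = mc.attend_pool(tiny_model, f)
    assert attn.weights.shape == (f.time_steps,)
    assert abs(attn.weights.sum() - 1.0) < 1e-6
    assert (attn.weights >= 0).all()
    # brute force: g == sum_t a_t * feature_t
    expected = (f.data * attn.weights[:, None]).sum(axis=0)
    np.testing.assert_allclose(g.vector, expected, atol=1e-9)


def test_uniform_attention_reduces_to_mean(rng):
    model = PDBreathingModel(ModelConfig(seed=3))
    # zero the second scoring convolution: constant scores -> uniform softmax
    model.pool.conv2.w.data[:] = 0.0
    model.pool.conv2.bias.data[:] = 0.0
    f = mc.encode_breathing(model, rng.normal(size=8000))
    g, attn = mc.attend_pool(model, f)
    np.testing.assert_allclose(attn.weights, 1.0 / f.time_steps, atol=1e-12)
    np.testing.assert_allclose(g.vector, f.data.mean(axis=0), atol=1e-9)


def test_one_hot_attention_selects_single_step(rng):
    # explicit weighted-sum contract on a 5-step toy profile
    feats = rng.normal(size=(5, 32))
    f = FeatureSequence(data=feats, step_s=8.0, _tensor=Tensor(feats.T))
    for k in range(5):
        w = np.zeros(5)
        w[k] = 1.0
        pooled = (feats * w[:, None]).sum(axis=0)
        np.testing.assert_allclose(pooled, feats[k], atol=1e-12)
    # random weights against the same oracle
    a = rng.dirichlet(np.ones(5))
    np.testing.assert_allclose((feats * a[:, None]).sum(axis=0), a @ feats,
                               atol=1e-12)


def test_classifier_hand_computed_forward(rng):
    model = PDBreathingModel(ModelConfig(seed=5))
    g = rng.normal(size=32)
    w = [layer.w.data for layer in model.classifier.layers]
    b = [layer.b.data for layer in model.classifier.layers]
    h = np.maximum(0, w[0] @ g + b[0])
    h = np.maximum(0, w[1] @ h + b[1])
    z = (w[2] @ h + b[2]).item()
    score = mc.classify_pd(model, GlobalFeature(vector=g))
    assert abs(score - expit(z)) < 1e-9
    assert 0.0 < score < 1.0


def test_classifier_logit_zero_gives_half():
    assert expit(0.0) == 0.5  # threshold anchor for the 0.5 decision rule
    # large logits approach but do not cross the (0, 1) bounds
    assert 0.0 < expit(-30.0) < expit(30.0) < 1.0


def test_severity_zero_head_and_missing_part(rng):
    model = PDBreathingModel(ModelConfig(seed=6))
    head = model.severity._parts["total"]
    for layer in head.layers:
        layer.w.data[:] = 0.0
        layer.b.data[:] = 0.0
    g = GlobalFeature(vector=rng.normal(size=32))
    assert mc.predict_severity(model, g, "total") == 0.0
    with pytest.raises(ValueError):
        mc.predict_severity(model, g, "II")  # head not trained


def test_subpart_heads_available_when_configured(rng):
    model = PDBreathingModel(ModelConfig(seed=6, severity_parts=("total", "III")))
    g = GlobalFeature(vector=rng.normal(size=32))
    assert np.isfinite(mc.predict_severity(model, g, "III"))


def test_qeeg_decoder_upsamples_8x_onto_simplex(tiny_model, rng):
    f = mc.encode_breathing(tiny_model, rng.normal(size=6000))
    pred = mc.predict_qeeg(tiny_model, f)
    assert pred.shape == (8 * f.time_steps, 4)
    np.testing.assert_allclose(pred.sum(axis=1), 1.0, atol=1e-5)
    # removing skip connections changes the output
    no_skip = mc.predict_qeeg(tiny_model, f, use_skips=False)
    assert np.abs(pred - no_skip).max() > 1e-8


def test_discriminator_zero_init_and_group_isolation(rng):
    model = PDBreathingModel(ModelConfig(seed=8))
    g = GlobalFeature(vector=rng.normal(size=32))
    disc = model._disc["PD"]
    for layer in disc.layers:
        layer.w.data[:] = 0.0
        layer.b.data[:] = 0.0
    assert mc.discriminate_domain(model, g, "PD") == 0.5
    # gradient isolation: a PD adversarial loss never touches D_Control
    model.zero_grad()
    logit = model.discriminate(Tensor(g.vector, requires_grad=True), "PD")
    binary_cross_entropy_logit(logit, 1.0).backward()
    assert all(p.grad is None for p in model._disc["control"].parameters())
    with pytest.raises(ValueError):
        model.discriminate(Tensor(g.vector), "patient")


def test_forward_deterministic_in_eval_mode(tiny_model, rng):
    x = rng.normal(size=9000)
    out1 = tiny_model.forward_night(x)
    out2 = tiny_model.forward_night(x)
    assert float(out1["logit"].data) == float(out2["logit"].data)
    np.testing.assert_array_equal(out1["qeeg_pred"].data, out2["qeeg_pred"].data)
    np.testing.assert_array_equal(out1["attention"].data, out2["attention"].data)


def test_bundle_round_trip_bit_identical(tmp_path, rng):
    cfg = ModelConfig(seed=9)
    members = [PDBreathingModel(ModelConfig(seed=9 + i)) for i in range(2)]
    cals = [{"A": 1.1, "B": -0.2, "fold_id": 0}, {"A": 0.9, "B": 0.1, "fold_id": 1}]
    bundle = ModelBundle(members=members, calibrations=cals, config=cfg)
    nights = [rng.normal(size=n) for n in (6400, 7000, 8000, 9000, 10_000)]
    before = [bundle.predict_night(x) for x in nights]
    bundle.save(tmp_path / "bundle")
    back = ModelBundle.load(tmp_path / "bundle")
    for x, ref in zip(nights, before):
        out = back.predict_night(x)
        assert out["pd_score"] == ref["pd_score"]
        assert out["severity"] == ref["severity"]
        np.testing.assert_array_equal(out["attention"], ref["attention"])


def test_bundle_ensemble_is_mean_of_calibrated_scores(rng):
    members = [PDBreathingModel(ModelConfig(seed=i)) for i in range(4)]
    cals = [{"A": 1.0, "B": 0.0, "fold_id": i} for i in range(4)]
    bundle = ModelBundle(members=members, calibrations=cals, config=members[0].cfg)
    x = rng.normal(size=6400)
    out = bundle.predict_night(x)
    assert abs(out["pd_score"] - np.mean(out["member_scores"])) < 1e-12
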