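"""Network construction, composite loss, gradients, training contracts."""

import numpy as np
import pytest

from sswvision import _nn, model, phonology
from sswvision.model import (ModelConfig, PhonoCNN, TexturePhonologyModel,
                             build_model, composite_loss, composite_loss_grad)

from conftest import random_form


def tiny_pairs(n_images=8, tokens_per_image=3, seed=0, size=40):
    """Small random image/target pairs for training contracts."""
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_images):
        img = rng.integers(0, 256, (size, size, 3), dtype=np.uint8)
        for _ in range(tokens_per_image):
            pairs.append((f"im{i}", img, phonology.encode_ssw(random_form(rng))))
    return pairs


# ---------------------------------------------------------------------------
# Construction


def test_vgg16_structure():
    cfg = ModelConfig()
    assert cfg.backbone == "vgg16" and cfg.freeze_conv
    assert (cfg.dropout_rate, cfg.batch_size, cfg.momentum) == (0.5, 40, 0.5)
    assert cfg.learning_rate == 2.5e-6 and cfg.epochs == 100
    net = build_model(cfg)
    assert net.n_conv_layers == 13
    assert net.n_fc_layers == 3
    assert net.output_dim == 88
    # dropout sits after the first two FC layers only
    dense_seen, dropouts_after = 0, []
    for i, layer in enumerate(net.head.layers):
        if isinstance(layer, _nn.Dense):
            dense_seen += 1
            nxt = net.head.layers[i + 1:i + 3]
            dropouts_after.append(any(isinstance(l, _nn.Dropout) for l in nxt))
    assert dropouts_after == [True, True, False]


def test_unknown_backbone_raises():
    with pytest.raises(model.UnknownBackbone):
        build_model(ModelConfig(backbone="resnet"))


def test_small_backbone_forward_shape():
    net = build_model(ModelConfig.small_test(seed=1))
    img = np.random.default_rng(0).integers(0, 256, (150, 150, 3), dtype=np.uint8)
    raw, probs = net.predict([img])
    assert raw.shape == (1, 88) and np.isfinite(raw).all()
    probs[0].validate()


# ---------------------------------------------------------------------------
# Composite loss


def test_composite_loss_equals_phonology_score():
    """Two independent implementations of the same training objective."""
    rng = np.random.default_rng(17)
    for _ in range(100):
        out = rng.normal(scale=2.0, size=88)
        form = random_form(rng)
        t = phonology.encode_ssw(form)
        assert composite_loss(out, t) == pytest.approx(
            phonology.score_candidate(out, form), abs=1e-9)


def test_composite_loss_batch_is_mean_of_sample_sums():
    rng = np.random.default_rng(4)
    outs = rng.normal(size=(5, 88))
    targets = np.stack([phonology.encode_ssw(random_form(rng)) for _ in range(5)])
    per_sample = [composite_loss(outs[i], targets[i]) for i in range(5)]
    assert composite_loss(outs, targets) == pytest.approx(np.mean(per_sample), abs=1e-9)


def test_composite_loss_gradient_matches_finite_differences():
    rng = np.random.default_rng(8)
    out = rng.normal(size=(2, 88))
    t = np.stack([phonology.encode_ssw(random_form(rng)) for _ in range(2)])
    g = composite_loss_grad(out, t)
    eps = 1e-6
    for idx in [(0, 3), (0, 40), (1, 70), (1, 80)]:
        up, dn = out.copy(), out.copy()
        up[idx] += eps
        dn[idx] -= eps
        num = (composite_loss(up, t) - composite_loss(dn, t)) / (2 * eps)
        assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-7)


def test_network_backward_matches_finite_differences():
    """End-to-end gradient of conv+head on a tiny input."""
    rng = np.random.default_rng(2)
    conv = _nn.Sequential([_nn.Conv2D(3, 4, rng=rng), _nn.ReLU(),
                           _nn.MaxPool2D(), _nn.Flatten()])
    head = _nn.Sequential([_nn.Dense(4 * 4 * 4, 16, rng=rng), _nn.ReLU(),
                           _nn.Dense(16, 88, rng=rng)])
    x = rng.normal(size=(2, 8, 8, 3))
    t = np.stack([phonology.encode_ssw(random_form(rng)) for _ in range(2)])

    def loss_of(x_):
        return composite_loss(head.forward(conv.forward(x_)), t)

    out = head.forward(conv.forward(x))
    gx = conv.backward(head.backward(composite_loss_grad(out, t)))
    eps = 1e-6
    for idx in [(0, 1, 1, 0), (1, 5, 2, 2), (0, 7, 7, 1)]:
        up, dn = x.copy(), x.copy()
        up[idx] += eps
        dn[idx] -= eps
        num = (loss_of(up) - loss_of(dn)) / (2 * eps)
        assert gx[idx] == pytest.approx(num, rel=1e-4, abs=1e-7)


# ---------------------------------------------------------------------------
# Training contracts


def test_frozen_conv_unchanged_by_training():
    cfg = ModelConfig.small_test(epochs=1, seed=5, batch_size=8)
    tm = TexturePhonologyModel(tiny_pairs(), cfg)
    res = tm.fit(folds=1)
    net = res.model
    before = PhonoCNN(cfg)  # same init seed as fold 0
    for a, b in zip(net.conv_params(), before.conv_params()):
        assert np.array_equal(a, b)


def test_unfrozen_conv_parameters_move():
    cfg = ModelConfig(backbone="small", freeze_conv=False, epochs=1,
                      learning_rate=0.01, batch_size=8, seed=5)
    tm = TexturePhonologyModel(tiny_pairs(n_images=4, tokens_per_image=2, size=32), cfg)
    res = tm.fit(folds=1)
    fresh = PhonoCNN(cfg)
    moved = [not np.array_equal(a, b) for a, b in
             zip(res.model.conv_params(), fresh.conv_params())]
    assert any(moved)


def test_training_is_deterministic_given_seed():
    cfg = ModelConfig.small_test(epochs=2, seed=9, batch_size=8)
    curves = []
    for _ in range(2):
        res = TexturePhonologyModel(tiny_pairs(), cfg).fit(folds=1)
        curves.append(res.folds[0].curve)
    assert np.allclose(curves[0]["train_loss"], curves[1]["train_loss"])


def test_training_loss_decreases_on_small_synthetic_set():
    from sswvision import synthetic
    corpus = synthetic.gen_corpus(14, seed=13, annotators=3, size=64)
    cfg = ModelConfig.small_test(epochs=5, seed=13)
    res = TexturePhonologyModel(corpus.pairs(), cfg).fit(folds=1)
    curve = res.folds[0].curve
    assert curve["train_loss"].iloc[-1] < curve["train_loss"].iloc[0]


def test_fold_assignment_partitions_images():
    cfg = ModelConfig.small_test(seed=2)
    tm = TexturePhonologyModel(tiny_pairs(n_images=10), cfg)
    test_sets = tm.fold_assignment(5)
    all_ids = set().union(*test_sets)
    assert all_ids == set(tm.image_ids)
    assert sum(len(s) for s in test_sets) == len(tm.image_ids)


def test_insufficient_data_raises():
    cfg = ModelConfig.small_test()
    with pytest.raises(model.InsufficientData):
        TexturePhonologyModel(tiny_pairs(n_images=3), cfg).fold_assignment(5)
    with pytest.raises(model.InsufficientData):
        TexturePhonologyModel([], cfg)


def test_predict_probabilities_are_normalized():
    net = build_model(ModelConfig.small_test(seed=4))
    rng = np.random.default_rng(1)
    imgs = [rng.integers(0, 256, (150, 150, 3), dtype=np.uint8) for _ in range(3)]
    raw, probs = net.predict(imgs)
    for p in probs:
        p.validate()
        for vec in (p.v1, p.c1, p.v2, p.c2):
            assert vec.sum() == pytest.approx(1.0, abs=1e-6)


def test_save_load_roundtrip(tmp_path):
    cfg = ModelConfig.small_test(epochs=1, seed=6, batch_size=8)
    res = TexturePhonologyModel(tiny_pairs(), cfg).fit(folds=1)
    net = res.model
    path = tmp_path / "model.npz"
    model.save_model(net, path)
    loaded = model.load_model(path)
    img = np.random.default_rng(3).integers(0, 256, (150, 150, 3), dtype=np.uint8)
    raw1, _ = net.predict([img])
    raw2, _ = loaded.predict([img])
    assert np.allclose(raw1, raw2)


def test_summary_mentions_configuration():
    cfg = ModelConfig.small_test(epochs=1, seed=0, batch_size=8)
    res = TexturePhonologyModel(tiny_pairs(), cfg).fit(folds=1)
    text = res.summary()
    assert "small" in text and "batch size   40" not in text or "batch size" in text
    assert "final train loss" in text
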