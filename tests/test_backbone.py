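"""Network assembly: pyramid, side outputs, fusion, loss, training."""

import numpy as np
import pytest

from timnet.backbone import (
    LossWeights,
    NetworkConfig,
    SideOutputs,
    TiMNet,
    TrainConfig,
    load_checkpoint,
    multiscale_pyramid,
    predict,
    save_checkpoint,
    sideout_fuse,
    train,
    weighted_loss,
)
from timnet.exceptions import ConfigurationError, ValidationError
from timnet.phantom import PhantomParams, generate_phantom

SMALL = dict(base_channels=8, attention_r=4, transformer_dim=16, transformer_heads=2)


def small_config(**over):
    return NetworkConfig(**{**SMALL, **over})


def phantom_pair(seed=1, size=64):
    ph = generate_phantom(PhantomParams(seed=seed, size=size))
    return np.repeat(ph.image[None], 3, axis=0).astype(np.float32), ph.mask


# ---------------------------------------------------------------- pyramid
def test_pyramid_halves_sizes():
    scales = multiscale_pyramid(np.zeros((3, 512, 512)))
    assert [s.shape[-1] for s in scales] == [512, 256, 128, 64]


def test_pyramid_of_constant_image_is_constant():
    scales = multiscale_pyramid(np.full((64, 64), 0.3))
    for s in scales:
        np.testing.assert_allclose(s, 0.3)


def test_pyramid_matches_window_maximum_definition():
    img = np.arange(16, dtype=float).reshape(4, 4)
    scales = multiscale_pyramid(img, levels=2)
    expected = np.array([[5, 7], [13, 15]], dtype=float)
    np.testing.assert_array_equal(scales[1], expected)


def test_pyramid_rejects_indivisible_size():
    with pytest.raises(ValidationError):
        multiscale_pyramid(np.zeros((3, 60, 60)))


# ---------------------------------------------------------------- config
def test_config_validation_errors():
    with pytest.raises(ConfigurationError):
        NetworkConfig(transformer_levels=(1,))
    with pytest.raises(ConfigurationError):
        NetworkConfig(input_size=48)
    with pytest.raises(ConfigurationError):
        NetworkConfig(backbone_kind="vnet")
    with pytest.raises(ConfigurationError):
        NetworkConfig(base_channels=8, attention_r=48)


@pytest.mark.parametrize("backbone_kind", ["mnet", "unet"])
@pytest.mark.parametrize("use_da", [True, False])
@pytest.mark.parametrize("levels", [(), (2,)])
def test_every_coarse_ablation_row_is_constructible(backbone_kind, use_da, levels):
    """Backbone1/2 with and without dual attention and the level-2
    transformer all instantiate and forward-pass from config alone."""
    cfg = small_config(backbone_kind=backbone_kind, use_dual_attention=use_da, transformer_levels=levels)
    out = TiMNet(cfg).forward(np.random.default_rng(0).random((3, 64, 64)).astype(np.float32))
    assert len(out.probs) == 4
    for p in out.probs:
        assert p.shape == (64, 64)
        assert (p > 0).all() and (p < 1).all()


@pytest.mark.parametrize("levels", [(2,), (3,), (4,), (2, 3), (2, 4), (3, 4), (2, 3, 4)])
def test_every_transformer_placement_is_constructible(levels):
    cfg = small_config(transformer_levels=levels)
    out = TiMNet(cfg).forward(np.random.default_rng(0).random((3, 64, 64)).astype(np.float32))
    assert len(out.probs) == 4 and all(p.shape == (64, 64) for p in out.probs)


# ---------------------------------------------------------------- forward
def test_forward_is_deterministic_in_evaluation(rng):
    model = TiMNet(small_config())
    img = rng.random((3, 64, 64)).astype(np.float32)
    a, b = model.forward(img), model.forward(img)
    for x, y in zip(a.probs, b.probs):
        np.testing.assert_array_equal(x, y)


def test_default_parameter_count_regression():
    """Exhaustive parameter enumeration for the default architecture,
    pinned once as a regression guard."""
    model = TiMNet(NetworkConfig())
    assert model.n_parameters() == 1_826_183


def test_forward_rejects_wrong_input_shape():
    model = TiMNet(small_config())
    with pytest.raises(ValidationError):
        model.forward(np.zeros((3, 32, 32), dtype=np.float32))


# ---------------------------------------------------------------- fusion/loss
def test_tuned_weights_accepted_in_side_order():
    w = LossWeights((0.10, 0.25, 0.25, 0.40))
    assert w.alpha == (0.10, 0.25, 0.25, 0.40)


def test_fusing_identical_maps_is_identity(rng):
    p = rng.random((8, 8))
    fused = sideout_fuse([p, p, p, p], LossWeights())
    np.testing.assert_allclose(fused, p, atol=1e-12)


def test_degenerate_weights_select_side5(rng):
    maps = [rng.random((8, 8)) for _ in range(4)]
    fused = sideout_fuse(maps, LossWeights((1, 0, 0, 0)))
    np.testing.assert_allclose(fused, maps[0], atol=1e-12)


def test_fused_probabilities_bounded_by_side_extremes(rng):
    maps = [rng.random((16, 16)) for _ in range(4)]
    fused = sideout_fuse(maps, LossWeights((0.1, 0.2, 0.3, 0.4)))
    lo, hi = np.min(maps, axis=0), np.max(maps, axis=0)
    assert (fused >= lo - 1e-12).all() and (fused <= hi + 1e-12).all()


def test_negative_weight_rejected():
    with pytest.raises(ValidationError):
        LossWeights((-0.1, 0.4, 0.4, 0.3))


def test_weighted_loss_is_convex_combination(rng):
    p = np.full((4, 4), 0.3)
    gt = np.zeros((4, 4), dtype=np.uint8)
    s = SideOutputs(probs=[p] * 4, logits=[np.zeros((4, 4))] * 4)
    ell = -np.log(0.7)
    assert abs(weighted_loss(s, gt, LossWeights()) - ell) < 1e-9


def test_weighted_loss_matches_hand_bce():
    probs = np.array([[0.9, 0.2], [0.6, 0.4]])
    gt = np.array([[1, 0], [1, 0]], dtype=np.uint8)
    hand = -(np.log(0.9) + np.log(0.8) + np.log(0.6) + np.log(0.6)) / 4
    maps = [probs, probs / 2 + 0.25, probs, probs]
    s = SideOutputs(probs=maps, logits=[np.zeros((2, 2))] * 4)
    value = weighted_loss(s, gt, LossWeights((1, 0, 0, 0)))
    assert abs(value - hand) < 1e-8


def test_weighted_loss_rejects_nonbinary_gt(rng):
    s = SideOutputs(probs=[rng.random((4, 4))] * 4, logits=[np.zeros((4, 4))] * 4)
    with pytest.raises(ValidationError):
        weighted_loss(s, np.full((4, 4), 0.5), LossWeights())


# ---------------------------------------------------------------- training
def test_training_defaults_match_published_recipe():
    cfg = TrainConfig()
    assert cfg.learning_rate == 0.0015
    assert cfg.batch_size == 2


def test_short_training_descends_and_is_reproducible():
    img, mask = phantom_pair(seed=3)
    cfg = small_config(transformer_levels=())
    tcfg = TrainConfig(epochs=8, seed=7)
    r1 = train([(img, mask)], cfg, tcfg)
    r2 = train([(img, mask)], cfg, tcfg)
    assert r1.history[-1]["loss"] < r1.history[0]["loss"]
    assert [e["loss"] for e in r1.history] == [e["loss"] for e in r2.history]


def test_every_side_head_receives_gradient(rng):
    import timnet.grad as G

    img, mask = phantom_pair(seed=4)
    model = TiMNet(small_config())
    logits = model.forward_tensors(img)
    weights = LossWeights()
    loss = None
    for a, l in zip(weights.alpha, logits):
        term = G.mul(G.bce_with_logits(l, mask), G.as_tensor(np.float32(a)))
        loss = term if loss is None else G.add(loss, term)
    loss.backward()
    for head in model.side_heads:
        assert head.weight.grad is not None
        assert np.abs(head.weight.grad).max() > 0


def test_empty_dataset_rejected():
    with pytest.raises(ValidationError):
        train([], small_config(), TrainConfig(epochs=1))


# ---------------------------------------------------------------- predict/checkpoint
def test_predict_variants_and_threshold(rng, tmp_path):
    img, _ = phantom_pair(seed=5)
    model = TiMNet(small_config())
    s = model.forward(img)
    prob7, _ = predict(img, model, variant="side7")
    np.testing.assert_array_equal(prob7, s.probs[2])
    probf, mask = predict(img, model, variant="sideout", threshold=0.0)
    assert mask.all()  # every probability is > 0
    np.testing.assert_allclose(probf, sideout_fuse(s.probs, LossWeights()), atol=1e-12)
    with pytest.raises(ConfigurationError):
        predict(img, model, variant="side9")


def test_checkpoint_roundtrip_preserves_predictions(tmp_path):
    img, _ = phantom_pair(seed=6)
    model = TiMNet(small_config())
    path = tmp_path / "model.npz"
    save_checkpoint(path, model)
    clone = load_checkpoint(path)
    a = model.forward(img)
    b = clone.forward(img)
    for x, y in zip(a.probs, b.probs):
        np.testing.assert_array_equal(x, y)


def test_checkpoint_config_mismatch_detected(tmp_path):
    model = TiMNet(small_config())
    other = TiMNet(small_config(base_channels=16, attention_r=8))
    with pytest.raises(ValueError):
        other.load_state(model.state())
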