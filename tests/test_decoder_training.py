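"""One-shot decoder, metrics, ablation grid, and the training loop."""

import numpy as np
import pytest

from surffold import nn
from surffold.model import (
    ModelConfig,
    N_CLASSES,
    OneShotDecoder,
    build_model,
    variant_config,
)
from surffold.training import (
    TrainConfig,
    evaluate,
    load_checkpoint,
    loss_and_perplexity,
    recovery,
    relative_difference,
    save_checkpoint,
    train,
)


# ------------------------------------------------------------------- decoder
def test_decoder_is_position_wise(rng):
    dec = OneShotDecoder(16, np.random.default_rng(0))
    fused = rng.normal(size=(9, 16))
    logits = dec(nn.Tensor(fused)).data
    assert logits.shape == (9, N_CLASSES)
    perm = rng.permutation(9)
    np.testing.assert_array_equal(dec(nn.Tensor(fused[perm])).data, logits[perm])
    dup = np.concatenate([fused, fused[:1]])
    np.testing.assert_array_equal(dec(nn.Tensor(dup)).data[-1], logits[0])


# ------------------------------------------------------------------- metrics
def test_uniform_logits_give_perplexity_twenty(rng):
    L = 37
    logits = nn.Tensor(np.full((L, N_CLASSES), 3.21))
    labels = rng.integers(0, N_CLASSES, size=L)
    _, ppl = loss_and_perplexity(logits, labels)
    assert ppl == pytest.approx(20.0, abs=1e-9)


def test_confident_correct_logits_approach_perplexity_one(rng):
    L = 10
    labels = rng.integers(0, N_CLASSES, size=L)
    raw = np.zeros((L, N_CLASSES))
    raw[np.arange(L), labels] = 200.0
    _, ppl = loss_and_perplexity(nn.Tensor(raw), labels)
    assert ppl == pytest.approx(1.0, abs=1e-9)


def test_loss_matches_naive_log_softmax_oracle(rng):
    L = 25
    raw = rng.normal(size=(L, N_CLASSES))
    labels = rng.integers(0, N_CLASSES, size=L)
    mask = rng.random(L) > 0.3
    labels[~mask] = -1
    loss, ppl = loss_and_perplexity(nn.Tensor(raw), labels, mask)
    # direct per-position evaluation
    nlls = []
    for i in range(L):
        if labels[i] < 0:
            continue
        z = raw[i] - raw[i].max()
        nlls.append(-(z[labels[i]] - np.log(np.exp(z).sum())))
    assert float(loss.data) == pytest.approx(np.mean(nlls), abs=1e-6)
    assert ppl == pytest.approx(np.exp(np.mean(nlls)), abs=1e-6)


def test_label_smoothing_changes_loss_not_perplexity(rng):
    raw = nn.Tensor(rng.normal(size=(12, N_CLASSES)))
    labels = rng.integers(0, N_CLASSES, size=12)
    l0, p0 = loss_and_perplexity(raw, labels, label_smoothing=0.0)
    l1, p1 = loss_and_perplexity(raw, labels, label_smoothing=0.1)
    assert p0 == p1
    assert float(l0.data) != float(l1.data)


def test_all_masked_raises(rng):
    with pytest.raises(ValueError):
        loss_and_perplexity(nn.Tensor(rng.normal(size=(4, N_CLASSES))),
                            np.full(4, -1))


def test_recovery_basic_cases():
    native = np.array([0, 1, 2, 3])
    assert recovery(native, native) == 100.0
    assert recovery(np.array([0, 1, 9, 9]), native) == 50.0


def test_recovery_random_predictions_near_five_percent(rng):
    L = 10_000
    native = rng.integers(0, N_CLASSES, size=L)
    pred = rng.integers(0, N_CLASSES, size=L)
    assert recovery(pred, native) == pytest.approx(5.0, abs=1.0)


def test_relative_difference():
    assert relative_difference(30.0, 30.0) == 0.0
    assert relative_difference(45.0, 30.0) == pytest.approx(0.5)
    for a, b in [(17.0, 42.0), (61.0, 33.0)]:
        assert relative_difference(a, b) == pytest.approx((a - b) / b)
    with pytest.raises(ValueError):
        relative_difference(10.0, 0.0)


# ------------------------------------------------------------- ablation grid
def test_invalid_flag_combinations_rejected():
    with pytest.raises(ValueError):
        ModelConfig(use_surface=False, use_cross_attention=True)
    with pytest.raises(ValueError):
        ModelConfig(use_surface=False, use_knn_alignment=True)
    with pytest.raises(ValueError):
        variant_config("model9")


def test_variant_grid_flags():
    assert not variant_config("model1").use_surface
    m2 = variant_config("model2")
    assert not m2.use_surface and not m2.use_sidechain
    assert not variant_config("model3").use_sidechain
    assert not variant_config("model4").use_cross_attention
    assert not variant_config("model5").use_knn_alignment
    full = variant_config("full")
    assert full.use_surface and full.use_sidechain


def test_full_model_has_more_parameters_than_backbone_only(small_config):
    full = build_model(small_config)
    from dataclasses import replace

    m1 = build_model(replace(small_config, use_surface=False,
                             use_knn_alignment=False, use_cross_attention=False))
    assert full.n_parameters() > m1.n_parameters()


@pytest.mark.parametrize("variant", ["model1", "model2", "model3", "model4", "model5", "full"])
def test_every_variant_runs_forward_and_backward(variant, small_config, featurized30):
    config = variant_config(variant, small_config)
    model = build_model(config)
    logits = model(featurized30, training=True, rng=np.random.default_rng(0))
    assert logits.shape == (featurized30.n_residues, N_CLASSES)
    loss, _ = loss_and_perplexity(logits, featurized30.labels, featurized30.mask)
    loss.backward()
    for p in model.parameters():
        assert p.grad is not None and np.isfinite(p.grad).all()


def test_surface_variant_requires_surface_features(small_config, featurized30):
    from dataclasses import replace
    import copy

    model = build_model(small_config)
    feats = copy.copy(featurized30)
    feats.surface = None
    with pytest.raises(ValueError, match="no surface"):
        model(feats)


# ------------------------------------------------------------------ training
@pytest.fixture(scope="module")
def tiny_dataset(small_config):
    from surffold.model import featurize_structure
    from surffold.structure import SyntheticSpec, make_synthetic_structure

    structures = [make_synthetic_structure(SyntheticSpec(n_residues=12, seed=s))
                  for s in (0, 1)]
    return [featurize_structure(s, small_config) for s in structures]


def test_epoch_zero_loss_deterministic(small_config, tiny_dataset):
    losses = []
    for _ in range(2):
        model = build_model(small_config)
        h = train(model, tiny_dataset, TrainConfig(epochs=1, seed=4))
        losses.append(h["loss"][0])
    assert losses[0] == losses[1]


def test_training_reduces_loss_and_logs(tmp_path, small_config, tiny_dataset):
    model = build_model(small_config)
    log = tmp_path / "log.jsonl"
    h = train(model, tiny_dataset,
              TrainConfig(epochs=20, lr=2e-3, seed=0, log_path=str(log)))
    assert h["loss"][-1] < h["loss"][0]
    assert len(log.read_text().splitlines()) == 20


def test_checkpoint_resume_reproduces_next_epoch(tmp_path, small_config, tiny_dataset):
    ckpt = str(tmp_path / "ck")
    model = build_model(small_config)
    cfg = TrainConfig(epochs=5, lr=1e-3, seed=9, checkpoint_path=ckpt)
    h1 = train(model, tiny_dataset, cfg)
    # continue the run without interruption as the reference
    cont = train(model, tiny_dataset,
                 TrainConfig(epochs=6, lr=1e-3, seed=9), start_epoch=5,
                 optimizer=h1["optimizer"], rng_state=h1["rng_state"])
    # a fresh model restored from the checkpoint must reproduce it
    model2 = build_model(small_config)
    opt2, epoch, rng_state = load_checkpoint(ckpt, model2, lr=1e-3)
    assert epoch == 5
    resumed = train(model2, tiny_dataset,
                    TrainConfig(epochs=6, lr=1e-3, seed=9),
                    optimizer=opt2, start_epoch=5, rng_state=rng_state)
    assert resumed["loss"][0] == pytest.approx(cont["loss"][0], abs=1e-5)


def test_empty_dataset_rejected(small_config):
    with pytest.raises(ValueError):
        train(build_model(small_config), [], TrainConfig(epochs=1))


# ---------------------------------------------------------------- evaluation
class _OracleModel:
    """Emits near-infinite-margin correct logits for every protein."""

    def __call__(self, feats, training=False, rng=None):
        raw = np.zeros((feats.n_residues, N_CLASSES))
        labels = np.where(feats.labels >= 0, feats.labels, 0)
        raw[np.arange(len(labels)), labels] = 500.0
        return nn.Tensor(raw)


class _UniformModel:
    def __call__(self, feats, training=False, rng=None):
        return nn.Tensor(np.zeros((feats.n_residues, N_CLASSES)))


def test_oracle_model_scores_perfectly(tiny_dataset):
    res = evaluate(_OracleModel(), tiny_dataset)
    pooled = res["all"]["pooled"]
    assert pooled.recovery == 100.0
    assert pooled.perplexity == pytest.approx(1.0, abs=1e-9)


def test_uniform_model_perplexity_twenty_per_split(tiny_dataset):
    spec = {"first": [tiny_dataset[0].identifier],
            "second": [tiny_dataset[1].identifier],
            "empty": ["nope"]}
    res = evaluate(_UniformModel(), tiny_dataset, spec)
    assert res["first"]["pooled"].perplexity == pytest.approx(20.0, abs=1e-9)
    assert res["second"]["pooled"].perplexity == pytest.approx(20.0, abs=1e-9)
    assert res["empty"]["skipped"]


def test_pooled_recovery_is_residue_weighted_mean(tiny_dataset, rng):
    class _NoisyModel:
        def __call__(self, feats, training=False, rng_=None):
            r = np.random.default_rng(abs(hash(feats.identifier)) % 2**31)
            return nn.Tensor(r.normal(size=(feats.n_residues, N_CLASSES)))

    res = evaluate(_NoisyModel(), tiny_dataset)
    per = res["all"]["per_protein"]
    num = sum(m.recovery * m.n_residues for m in per.values())
    den = sum(m.n_residues for m in per.values())
    assert res["all"]["pooled"].recovery == pytest.approx(num / den, abs=1e-9)
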