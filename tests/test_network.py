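import numpy as np
import pytest

from domseg.features import FeatureStack
from domseg.labels import AdjacencyLabel
from domseg.network import (
    NetworkConfig,
    TrainingConfig,
    _loss_and_grad,
    bce_loss,
    build_model,
    load_model,
    predict_soft_adjacency,
    save_model,
    train,
)
from domseg.synthetic import make_dataset, SyntheticSpec

TINY = NetworkConfig(n_blocks=2, n_filters=6, dilation_cycle=(1, 2))


def random_stack(L, seed=0):
    rng = np.random.default_rng(seed)
    return FeatureStack(rng.normal(size=(5, L, L)).astype(np.float32))


def random_adjacency(L, seed=0):
    rng = np.random.default_rng(seed)
    a = np.triu(rng.random((L, L)) < 0.5, k=1)
    return AdjacencyLabel((a + a.T).astype(np.uint8))


def test_fully_convolutional_one_weight_set_serves_all_lengths():
    model = build_model(TINY, seed=0)
    for L in (7, 16, 64, 200):
        out = predict_soft_adjacency(model, random_stack(L))
        assert out.matrix.shape == (L, L)


def test_output_logits_exactly_symmetric():
    model = build_model(TINY, seed=1)
    z = model.logits(random_stack(33, seed=2).tensor)
    assert np.array_equal(z, z.T)


def test_default_config_sizes():
    cfg = NetworkConfig()
    assert cfg.n_blocks == 31 and cfg.n_filters == 32
    model = build_model(cfg, seed=0)
    assert len(model.blocks) == 31
    assert model.blocks[0].conv1.W.shape == (32, 32, 3, 3)
    # dilation cycle repeats 1,2,4,8,16
    assert [b.conv1.dilation for b in model.blocks[:6]] == [1, 2, 4, 8, 16, 1]


def test_prediction_in_open_interval_and_symmetric():
    model = build_model(TINY, seed=3)
    soft = predict_soft_adjacency(model, random_stack(20, seed=4))
    assert np.array_equal(soft.matrix, soft.matrix.T)
    assert soft.matrix.min() >= 1e-4 and soft.matrix.max() <= 1 - 1e-4


def test_untrained_bce_near_ln2_on_random_labels():
    model = build_model(NetworkConfig(n_blocks=4, n_filters=8), seed=1)
    losses = [
        bce_loss(
            predict_soft_adjacency(model, random_stack(16, seed=s)),
            random_adjacency(16, seed=s),
        )
        for s in range(20)
    ]
    assert np.mean(losses) == pytest.approx(np.log(2), abs=0.05)


def test_bce_closed_forms():
    L = 10
    half = np.full((L, L), 0.5)
    zeros = AdjacencyLabel(np.zeros((L, L), dtype=np.uint8))
    assert bce_loss(half, zeros) == pytest.approx(np.log(2), abs=1e-12)
    pair = np.array([[0.5, 0.9], [0.9, 0.5]])
    target = AdjacencyLabel(np.array([[1, 1], [1, 1]], dtype=np.uint8))
    assert bce_loss(pair, target) == pytest.approx(-np.log(0.9), abs=1e-12)


def test_bce_perfect_prediction_limit():
    a = random_adjacency(8, seed=0)
    eps = 1e-4
    pred = np.clip(a.matrix.astype(float), eps, 1 - eps)
    assert bce_loss(pred, a) == pytest.approx(-np.log(1 - eps), rel=1e-6)


def test_gradients_match_finite_differences():
    model = build_model(TINY, seed=3, dtype=np.float64)
    rng = np.random.default_rng(0)
    x = rng.normal(size=(5, 6, 6))
    a = random_adjacency(6, seed=1).matrix.astype(float)
    _, grad = _loss_and_grad(model, x, a)
    model.backward(grad)
    analytic = {n: getattr(h, "d" + attr).copy() for n, h, attr in model.parameters()}
    eps = 1e-5
    for name, holder, attr in model.parameters():
        W = getattr(holder, attr)
        # check the largest-magnitude gradient entries of every tensor
        flat = np.argsort(-np.abs(analytic[name]).ravel())[:3]
        for idx in zip(*np.unravel_index(flat, W.shape)):
            orig = W[idx]
            W[idx] = orig + eps
            lp, _ = _loss_and_grad(model, x, a)
            W[idx] = orig - eps
            lm, _ = _loss_and_grad(model, x, a)
            W[idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - analytic[name][idx]) < 1e-7, name


def test_rigid_transform_gives_bitwise_identical_prediction():
    from scipy.stats import special_ortho_group
    from domseg.features import featurize
    from domseg.structure_io import ProteinChain
    from domseg.synthetic import generate_chain

    chain, _, ss = generate_chain(SyntheticSpec(n_domains=1, domain_sizes=(40,), seed=8))
    model = build_model(TINY, seed=0)
    ref = predict_soft_adjacency(model, featurize(chain, ss)).matrix
    R = -special_ortho_group.rvs(3, random_state=0)  # rotation + reflection
    moved = ProteinChain("A", chain.residues, chain.ca_coords @ R.T + 20.0)
    out = predict_soft_adjacency(model, featurize(moved, ss)).matrix
    assert np.array_equal(ref, out)


def small_dataset(n=6, seed=0):
    def spec_fn(rng, s):
        return SyntheticSpec(
            n_domains=int(rng.choice([1, 2])), size_range=(12, 20),
            centroid_separation=25.0, seed=s,
        )

    return make_dataset(n, seed=seed, spec_fn=spec_fn)


def test_training_reduces_loss_and_is_deterministic():
    dataset = small_dataset()
    cfg = TrainingConfig(epochs=4, seed=7)
    r1 = train(build_model(TINY, seed=2), dataset, cfg)
    r2 = train(build_model(TINY, seed=2), dataset, cfg)
    assert r1.loss_history == r2.loss_history
    assert np.mean(r1.loss_history[-6:]) < np.mean(r1.loss_history[:6])


def test_degenerate_sampling_p_multi_one():
    dataset = small_dataset(8, seed=3)
    cfg = TrainingConfig(p_multi=1.0, p_single=0.0, epochs=1, seed=0)
    result = train(build_model(TINY, seed=0), dataset, cfg)
    assert set(result.sampled_flags) == {"multi"}


def test_empty_dataset_rejected():
    with pytest.raises(ValueError):
        train(build_model(TINY, seed=0), [], TrainingConfig(epochs=1))


def test_training_config_validation():
    with pytest.raises(ValueError):
        TrainingConfig(p_multi=0.8, p_single=0.3)


def test_checkpoint_round_trip(tmp_path):
    model = build_model(TINY, seed=5)
    stack = random_stack(14, seed=6)
    ref = predict_soft_adjacency(model, stack).matrix
    path = tmp_path / "model.npz"
    save_model(model, path)
    loaded = load_model(path)
    assert loaded.config == model.config
    assert np.array_equal(predict_soft_adjacency(loaded, stack).matrix, ref)
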