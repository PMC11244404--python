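"""Classifier stack: shapes, batch norm, recurrent cells, splits, training."""

import numpy as np
import pytest

from hypnoseeg import nn
from hypnoseeg.errors import ConfigError, ValidationError
from hypnoseeg.models import (
    BatchNormParams,
    EEGNetConfig,
    Hyperparams,
    RecurrentConfig,
    RecurrentNet,
    batch_norm,
    build_eegnet,
    eegnet_forward,
    eegnet_time_dims,
    epochs_to_seq_batch,
    predict,
    recurrent_forward,
    split_dataset,
    train_model,
)


# --- shape contracts --------------------------------------------------------


def test_time_dims_from_config_alone():
    assert eegnet_time_dims(EEGNetConfig()) == [400, 400, 391, 97]


def test_forward_shapes_match_oracle(rng):
    cfg = EEGNetConfig()
    model = build_eegnet(cfg, seed=0)
    x = rng.standard_normal((3, 1, 8, 400))
    h = x
    seen = []
    for layer in model.layers:
        h = layer.forward(h, False)
        if h.ndim == 4:
            seen.append((h.shape[1], h.shape[3]))
    # block1 -> 16 x 400, depthwise -> 32 x 391, pool -> 32 x 97
    assert (16, 400) in seen
    assert (32, 391) in seen  # depthwise output channel count is 32
    assert (32, 97) in seen
    assert h.shape == (3, 2)


def test_padding_must_preserve_time_length():
    with pytest.raises(ConfigError, match="pad"):
        EEGNetConfig(conv1_kernel=51, conv1_pad=10)


def test_zero_weights_give_uniform_scores(rng):
    model = build_eegnet(EEGNetConfig(), seed=0)
    for p in model.params():
        p.value[...] = 0.0
    scores = eegnet_forward(rng.standard_normal((4, 1, 8, 400)), model, "eval")
    assert np.allclose(scores, scores[:, :1])  # equal class scores per sample

    rn = RecurrentNet(RecurrentConfig(cell="rnn"), seed=0)
    for p in rn.params():
        p.value[...] = 0.0
    scores = recurrent_forward(np.zeros((3, 4, 1000)), rn, "eval")
    assert np.allclose(scores, 0.0)


def test_depthwise_equals_naive_grouped_convolution(rng):
    """Depthwise layer vs an explicit per-channel convolution loop."""
    layer = nn.DepthwiseTemporalConv2d(4, 2, 5, rng)
    x = rng.standard_normal((3, 4, 2, 30))
    y = layer.forward(x, False)
    W, b = layer.W.value, layer.b.value
    naive = np.zeros_like(y)
    for n in range(3):
        for c in range(4):
            for m in range(2):
                for h in range(2):
                    for t in range(30 - 5 + 1):
                        naive[n, c * 2 + m, h, t] = (
                            x[n, c, h, t : t + 5] @ W[c, :, m] + b[c * 2 + m]
                        )
    assert np.max(np.abs(y - naive)) < 1e-6


# --- batch norm -------------------------------------------------------------


def test_batch_norm_standardizes(rng):
    m = 4096
    x = rng.standard_normal((m, 5)) * 3.0 + 7.0
    params = BatchNormParams(gamma=np.ones(5), beta=np.zeros(5))
    y = batch_norm(x, params, "train")
    assert np.allclose(y.mean(axis=0), 0.0, atol=3 / np.sqrt(m))
    assert np.allclose(y.var(axis=0), 1.0, atol=5 / np.sqrt(m))


def test_batch_norm_inverts_with_batch_statistics(rng):
    x = rng.standard_normal((256, 3)) * 2.0 + 1.0
    mu, sd = x.mean(axis=0), x.std(axis=0)
    params = BatchNormParams(gamma=sd, beta=mu)
    y = batch_norm(x, params, "train")
    assert np.allclose(y, x, atol=1e-4)  # exact up to the eps regularizer


def test_batch_norm_constant_feature_collapses_to_beta():
    x = np.full((64, 2), 3.3)
    params = BatchNormParams(gamma=np.ones(2), beta=np.array([0.5, -0.5]))
    y = batch_norm(x, params, "train")
    assert np.allclose(y, np.broadcast_to([0.5, -0.5], y.shape), atol=1e-6)


def test_batch_norm_needs_two_samples():
    params = BatchNormParams(gamma=np.ones(2), beta=np.zeros(2))
    with pytest.raises(ValidationError, match="2 samples"):
        batch_norm(np.ones((1, 2)), params, "train")


def test_batch_norm_eval_uses_running_stats(rng):
    layer = nn.BatchNorm(3)
    x = rng.standard_normal((512, 3)) * 4.0 + 2.0
    for _ in range(50):
        layer.forward(x, True)
    y = layer.forward(x, False)
    assert np.allclose(y.mean(axis=0), 0.0, atol=0.1)
    assert np.allclose(y.std(axis=0), 1.0, atol=0.1)


# --- recurrent nets ---------------------------------------------------------


def test_recurrent_hidden_dimensions():
    cfg = RecurrentConfig(cell="lstm")
    net = RecurrentNet(cfg, seed=0)
    assert len(net.Wih) == 2  # two layers
    assert net.Wih[0].value.shape == (4 * 128, 1000)
    assert net.Whh[1].value.shape == (4 * 128, 128)
    net.forward(np.zeros((2, 4, 1000)), False)
    for layer_cache in net._caches:
        assert layer_cache[0][1].shape == (2, 128)  # hidden size 128 per layer


def test_lstm_closed_gates_freeze_state(rng):
    """Forget gate ~1, input gate ~0, zero input: cell/hidden stay constant."""
    cfg = RecurrentConfig(cell="lstm", num_layers=1, input_size=6, hidden_size=4)
    net = RecurrentNet(cfg, seed=0)
    H = 4
    b = net.bias[0].value
    b[0:H] = -1000.0  # input gate -> 0
    b[H : 2 * H] = 1000.0  # forget gate -> 1
    net.forward(rng.standard_normal((2, 5, 6)) * 0.0, False)
    hiddens = [c[1] for c in net._caches[0]] + [net._top[:, -1]]
    for h in hiddens[1:]:
        assert np.allclose(h, hiddens[1])


def test_empty_sequence_rejected():
    net = RecurrentNet(RecurrentConfig(cell="rnn", input_size=8, hidden_size=4), seed=0)
    with pytest.raises(ValidationError):
        net.forward(np.zeros((2, 0, 8)), False)


def test_seq_batch_layout():
    data = np.arange(2 * 8 * 400, dtype=float).reshape(2, 8, 400)
    cfg = RecurrentConfig()
    seq = epochs_to_seq_batch(data, cfg)
    assert seq.shape == (2, 4, 1000)
    # first step holds channel-concatenated samples 0..99, zero-padded to 1000
    assert np.array_equal(seq[0, 0, :100], data[0, 0, :100])
    assert np.array_equal(seq[0, 0, 100:200], data[0, 1, :100])
    assert np.all(seq[:, :, 800:] == 0.0)


# --- splitting --------------------------------------------------------------


def test_split_100_is_60_20_20():
    labels = np.array(["RH"] * 50 + ["ND"] * 50)
    tr, va, te = split_dataset(labels, seed=0)
    assert (len(tr), len(va), len(te)) == (60, 20, 20)


def test_split_partitions_index_set():
    labels = np.array(["RH"] * 41 + ["ND"] * 62)
    tr, va, te = split_dataset(labels, seed=3)
    allidx = np.concatenate([tr, va, te])
    assert sorted(allidx) == list(range(103))
    assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))


def test_stratified_split_balance():
    labels = np.array(["RH"] * 50 + ["ND"] * 50)
    tr, va, te = split_dataset(labels, seed=1)
    for part in (tr, va, te):
        n_rh = np.sum(labels[part] == "RH")
        assert abs(n_rh - len(part) / 2) <= 0.5


def test_split_validation_errors():
    labels = np.array(["RH"] * 10 + ["ND"] * 10)
    with pytest.raises(ConfigError, match="sum to 1"):
        split_dataset(labels, ratios=(0.5, 0.2, 0.2))
    with pytest.raises(ValidationError, match=">=5"):
        split_dataset(np.array(["RH"] * 3 + ["ND"] * 20))
    tr1, *_ = split_dataset(labels, seed=7)
    tr2, *_ = split_dataset(labels, seed=7)
    assert np.array_equal(tr1, tr2)


# --- training and prediction ------------------------------------------------


def _toy_set(rng, n=24, c=2, t=50, gap=4.0):
    y = np.array(["RH", "ND"] * (n // 2))
    x = rng.standard_normal((n, c, t))
    x[y == "RH"] += gap  # linearly separable mean shift
    return x, y


def test_toy_separable_reaches_full_train_accuracy(rng):
    x, y = _toy_set(rng)
    trained = train_model(
        "eegnet",
        x,
        y,
        x,
        y,
        hyper=Hyperparams(max_epochs=30, patience=30, batch_size=8),
        seed=0,
    )
    pred, _ = predict(trained, x)
    assert np.mean(pred == y) == 1.0
    assert len(trained.history) > 0


@pytest.mark.parametrize("kind", ["rnn", "lstm"])
def test_recurrent_baselines_learn_toy_set(rng, kind):
    x, y = _toy_set(rng, t=40)
    cfg = RecurrentConfig(cell=kind, input_size=20, hidden_size=16, window=10)
    trained = train_model(
        kind, x, y, x, y, config=cfg,
        hyper=Hyperparams(max_epochs=40, patience=40, batch_size=8), seed=0,
    )
    pred, _ = predict(trained, x)
    assert np.mean(pred == y) == 1.0


def test_training_is_seed_deterministic(rng):
    x, y = _toy_set(rng)
    cfg = RecurrentConfig(cell="rnn", input_size=25, hidden_size=8, window=25)
    runs = [
        train_model("rnn", x, y, x, y, config=cfg,
                    hyper=Hyperparams(max_epochs=5, patience=5), seed=11)
        for _ in range(2)
    ]
    for p1, p2 in zip(runs[0].model.params(), runs[1].model.params()):
        assert np.array_equal(p1.value, p2.value)
    assert runs[0].history == runs[1].history


def test_predict_tie_breaks_to_nd(rng):
    x, y = _toy_set(rng)
    trained = train_model(
        "eegnet", x, y, x, y, hyper=Hyperparams(max_epochs=1, patience=1), seed=0
    )
    for p in trained.model.params():
        p.value[...] = 0.0  # forces exactly equal scores
    pred, scores = predict(trained, x[:4])
    assert np.allclose(scores, 0.5)
    assert list(pred) == ["ND"] * 4


def test_predictions_invariant_to_sample_order(rng):
    x, y = _toy_set(rng, n=16)
    trained = train_model(
        "eegnet", x, y, x, y, hyper=Hyperparams(max_epochs=3, patience=3), seed=0
    )
    pred, _ = predict(trained, x)
    perm = rng.permutation(len(x))
    pred_perm, _ = predict(trained, x[perm])
    assert np.array_equal(pred_perm, pred[perm])


def test_unknown_kind_and_empty_train():
    with pytest.raises(ConfigError):
        train_model("svm", np.zeros((2, 1, 8)), ["RH", "ND"], np.zeros((2, 1, 8)), ["RH", "ND"])
    with pytest.raises(ValidationError):
        train_model("rnn", np.zeros((0, 1, 8)), [], np.zeros((2, 1, 8)), ["RH", "ND"])


def test_model_checkpoint_roundtrip(tmp_path, rng):
    from hypnoseeg.models import load_model, save_model

    x, y = _toy_set(rng)
    trained = train_model(
        "eegnet", x, y, x, y, hyper=Hyperparams(max_epochs=3, patience=3), seed=0
    )
    save_model(trained, tmp_path / "model.h5")
    restored = load_model(tmp_path / "model.h5")
    p1, _ = predict(trained, x)
    p2, s2 = predict(restored, x)
    assert np.array_equal(p1, p2)
    assert restored.kind == "eegnet" and restored.history == trained.history
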