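import numpy as np
import pytest
from rdkit import Chem

from mflogp.data_io import DataError
from mflogp.dmpnn import (
    BatchGraph,
    EncoderConfig,
    TrainConfig,
    backward,
    embed,
    ensemble_predict,
    forward,
    init_edge_states,
    init_model,
    load_model,
    masked_mse_and_grad,
    message_pass,
    predict,
    save_model,
    train,
)
from mflogp.featurization import featurize_molecule
from conftest import SMALL_SMILES
from reference_dmpnn import reference_forward


def _batch(smiles, dtype=np.float32):
    return BatchGraph([featurize_molecule(s) for s in smiles], dtype=dtype)


# ---------------------------------------------------------------- forward ops


def test_init_edge_states_zero_weights_and_nonnegativity(rng):
    bg = _batch(["CCO", "c1ccccc1"])
    H = init_edge_states(bg, np.zeros((8, bg.edge_feats.shape[1]), dtype=np.float32))
    assert np.all(H == 0.0)
    W = rng.normal(size=(8, bg.edge_feats.shape[1])).astype(np.float32)
    assert np.all(init_edge_states(bg, W) >= 0.0)
    with pytest.raises(DataError):
        init_edge_states(bg, np.zeros((8, 3), dtype=np.float32))


def test_message_pass_depth_one_is_identity(rng):
    bg = _batch(["CC(=O)NC"])
    H0 = init_edge_states(bg, rng.normal(size=(8, bg.edge_feats.shape[1])).astype(np.float32))
    W_m = rng.normal(size=(8, 8)).astype(np.float32)
    np.testing.assert_array_equal(message_pass(bg, H0, W_m, depth=1), H0)


def test_message_pass_two_atom_molecule_states_frozen(rng):
    """One bond: each neighbor set minus the reverse edge is empty."""
    bg = _batch(["CO"])
    H0 = init_edge_states(bg, rng.normal(size=(8, bg.edge_feats.shape[1])).astype(np.float32))
    W_m = rng.normal(size=(8, 8)).astype(np.float32)
    for depth in (2, 3, 5):
        np.testing.assert_allclose(message_pass(bg, H0, W_m, depth), H0, atol=1e-6)


def test_forward_matches_unrolled_reference():
    """Vectorized forward vs the loop-unrolled oracle on small molecules."""
    cfg = EncoderConfig(hidden_size=12, depth=3, ffn_hidden=9, ffn_layers=2, n_targets=2)
    model = init_model(cfg, seed=5, dtype=np.float64)
    small = [s for s in SMALL_SMILES if Chem.MolFromSmiles(s).GetNumAtoms() <= 4]
    assert len(small) >= 8
    for smi in small:
        got = forward(model, _batch([smi], dtype=np.float64))[0]
        want = reference_forward(model, smi)
        np.testing.assert_allclose(got, want, atol=1e-6)


def test_forward_reference_agreement_with_extra_features(rng):
    cfg = EncoderConfig(hidden_size=6, depth=2, ffn_layers=3, ffn_hidden=5, extra_feature_dim=2)
    model = init_model(cfg, seed=9, dtype=np.float64)
    extra = rng.normal(size=(1, 2))
    got = forward(model, _batch(["CCO"], dtype=np.float64), extra=extra)[0]
    want = reference_forward(model, "CCO", extra=extra)
    np.testing.assert_allclose(got, want, atol=1e-6)


def test_embedding_permutation_invariance(rng):
    """Atom renumbering must not change the molecule embedding."""
    cfg = EncoderConfig(hidden_size=16, depth=3)
    model = init_model(cfg, seed=2, dtype=np.float64)
    mols = [s for s in SMALL_SMILES if featurize_molecule(s).n_atoms >= 2][:20]
    for smi in mols:
        mol = Chem.MolFromSmiles(smi)
        base = None
        for _ in range(3):
            perm = [int(i) for i in rng.permutation(mol.GetNumAtoms())]
            renum = Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)
            e = embed(model, [renum])  # float32 graph, float64 weights
            base = e if base is None else base
            np.testing.assert_allclose(e, base, atol=1e-6)


def test_single_atom_molecule_mean_equals_sum():
    cfg_mean = EncoderConfig(hidden_size=8, depth=3, aggregation="mean")
    cfg_sum = EncoderConfig(hidden_size=8, depth=3, aggregation="sum")
    m1 = init_model(cfg_mean, seed=4)
    m2 = init_model(cfg_sum, seed=4)
    np.testing.assert_allclose(embed(m1, ["O"]), embed(m2, ["O"]), atol=1e-7)


def test_ffn_head_shapes_and_zero_weights():
    cfg = EncoderConfig(hidden_size=8, n_targets=2, ffn_layers=2, ffn_hidden=4)
    model = init_model(cfg, seed=0)
    out = forward(model, _batch(["CCO", "O"]))
    assert out.shape == (2, 2)
    for k in model.weights:
        model.weights[k] = np.zeros_like(model.weights[k])
    np.testing.assert_array_equal(forward(model, _batch(["CCO", "O"])), 0.0)


# ---------------------------------------------------------------- gradients


def test_backward_matches_finite_differences(rng):
    cfg = EncoderConfig(
        hidden_size=7, depth=3, ffn_hidden=6, ffn_layers=2, n_targets=2, extra_feature_dim=1
    )
    model = init_model(cfg, seed=3, dtype=np.float64)
    bg = _batch(["CCO", "c1ccccc1O", "CC(=O)NC"], dtype=np.float64)
    extra = rng.normal(size=(3, 1))
    Y = rng.normal(size=(3, 2))
    M = np.array([[1, 0], [1, 1], [0, 1]], dtype=float)

    out, cache = forward(model, bg, extra=extra, return_cache=True)
    _, dout = masked_mse_and_grad(out, Y, M)
    grads = backward(model, bg, cache, dout)

    def loss():
        l, _ = masked_mse_and_grad(forward(model, bg, extra=extra), Y, M)
        return l

    eps = 1e-6
    for k, W in model.weights.items():
        flat = W.reshape(-1)
        for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = loss()
            flat[idx] = orig - eps
            lm = loss()
            flat[idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert grads[k].reshape(-1)[idx] == pytest.approx(fd, abs=1e-6, rel=1e-4)


# ---------------------------------------------------------------- train/predict


def test_predict_unscaling_and_determinism():
    model = init_model(EncoderConfig(hidden_size=8), seed=0)
    for k in model.weights:
        model.weights[k] = np.zeros_like(model.weights[k])
    model.scaler_mean = np.array([1.5])
    model.scaler_std = np.array([1.0])
    p1 = predict(model, ["CCO", "O", "c1ccccc1"])
    np.testing.assert_allclose(p1, 1.5, atol=1e-8)
    p2 = predict(model, ["CCO", "O", "c1ccccc1"])
    np.testing.assert_array_equal(p1, p2)
    # order independence per molecule
    p3 = predict(model, ["c1ccccc1", "CCO", "O"])
    np.testing.assert_allclose(sorted(p1.ravel()), sorted(p3.ravel()), atol=1e-8)


def test_train_overfits_small_set():
    smiles = SMALL_SMILES[:10]
    y = np.linspace(-1.0, 2.0, 10)[:, None]
    data = (smiles, y, None, None)
    model = init_model(EncoderConfig(hidden_size=64, ffn_hidden=64), seed=0)
    cfg = TrainConfig(max_epochs=200, batch_size=10, max_lr=5e-3, final_lr=5e-4, seed=0)
    model, log = train(model, data, data, cfg)
    pred = predict(model, smiles)
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    assert rmse < 0.05
    assert len(log) == 200  # patience 0 disables early stopping


def test_train_seed_reproducibility():
    smiles = SMALL_SMILES[:8]
    y = np.arange(8.0)[:, None]
    data = (smiles, y, None, None)
    outs = []
    for _ in range(2):
        model = init_model(EncoderConfig(hidden_size=16, ffn_hidden=16), seed=7)
        model, _ = train(model, data, data, TrainConfig(max_epochs=5, batch_size=4, seed=7))
        outs.append({k: v.copy() for k, v in model.weights.items()})
    for k in outs[0]:
        np.testing.assert_allclose(outs[0][k], outs[1][k], atol=1e-7)


def test_constant_label_round_trip():
    """z-scoring then unscaling recovers a constant label scale."""
    smiles = SMALL_SMILES[:6]
    y = np.full((6, 1), 2.5)
    data = (smiles, y, None, None)
    model = init_model(EncoderConfig(hidden_size=16, ffn_hidden=16), seed=1)
    model, _ = train(model, data, data, TrainConfig(max_epochs=30, batch_size=6, seed=1))
    np.testing.assert_allclose(predict(model, smiles), 2.5, atol=1e-3)


def test_early_stopping_patience():
    # hold-out val fold: once the model overfits train, val stops improving
    train_data = (SMALL_SMILES[:8], np.arange(8.0)[:, None], None, None)
    val_data = (SMALL_SMILES[8:12], np.array([[3.0], [-1.0], [2.0], [0.5]]), None, None)
    model = init_model(EncoderConfig(hidden_size=8, ffn_hidden=8), seed=0)
    model, log = train(
        model, train_data, val_data, TrainConfig(max_epochs=500, batch_size=8, patience=3, seed=0)
    )
    assert len(log) < 500


def test_ensemble_predict():
    def const_model(mean):
        m = init_model(EncoderConfig(hidden_size=4, ffn_hidden=4), seed=0)
        for k in m.weights:
            m.weights[k] = np.zeros_like(m.weights[k])
        m.scaler_mean = np.array([mean])
        m.scaler_std = np.array([1.0])
        return m

    one, three = const_model(1.0), const_model(3.0)
    np.testing.assert_allclose(ensemble_predict([one], ["CCO"]), predict(one, ["CCO"]))
    np.testing.assert_allclose(ensemble_predict([one, three], ["CCO", "O"]), 2.0, atol=1e-8)
    np.testing.assert_allclose(
        ensemble_predict([one, one, one], ["CCO"]), predict(one, ["CCO"]), atol=1e-8
    )
    two_head = init_model(EncoderConfig(hidden_size=4, n_targets=2), seed=0)
    with pytest.raises(DataError):
        ensemble_predict([one, two_head], ["CCO"])


def test_checkpoint_round_trip(tmp_path):
    cfg = EncoderConfig(hidden_size=10, depth=2, n_targets=2, ffn_layers=3, ffn_hidden=6)
    model = init_model(cfg, seed=12, mode="multi_target")
    model.scaler_mean = np.array([0.3, -1.2])
    model.scaler_std = np.array([1.1, 0.8])
    path = tmp_path / "model.npz"
    save_model(path, model)
    loaded = load_model(path)
    assert loaded.mode == "multi_target"
    assert loaded.config == cfg
    np.testing.assert_array_equal(loaded.scaler_mean, model.scaler_mean)
    smiles = ["CCO", "c1ccccc1"]
    np.testing.assert_array_equal(predict(loaded, smiles), predict(model, smiles))


def test_config_validation():
    with pytest.raises(DataError):
        EncoderConfig(depth=0)
    with pytest.raises(DataError):
        EncoderConfig(dropout=1.0)
    with pytest.raises(DataError):
        TrainConfig(batch_size=0)
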