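import numpy as np
import pytest

from mflogp import dmpnn
from mflogp.data_io import DataError
from mflogp.dmpnn import EncoderConfig, TrainConfig
from mflogp.strategies import (
    HF_COL,
    LF_COL,
    LabelMatrix,
    hyperparameter_search,
    load_result,
    masked_mse,
    merge_multifidelity,
    save_result,
    train_feature_augmented,
    train_multi_target,
    train_single_task,
    train_transfer,
)
from conftest import make_dataset

TINY_ENC = EncoderConfig(hidden_size=12, depth=2, ffn_hidden=8)
TINY_TRAIN = TrainConfig(max_epochs=3, batch_size=16, seed=0)


# ------------------------------------------------------------------ masked loss


def test_masked_mse_full_mask_is_mse():
    rng = np.random.default_rng(0)
    pred = rng.normal(size=(7, 1))
    vals = rng.normal(size=(7, 1))
    lm = LabelMatrix(vals, np.ones_like(vals))
    assert masked_mse(pred, lm) == pytest.approx(float(np.mean((pred - vals) ** 2)), abs=0)


def test_masked_mse_hand_value():
    lm = LabelMatrix(np.array([[1.0, 9.0], [3.0, 9.0]]), np.array([[1.0, 0.0], [1.0, 0.0]]))
    pred = np.array([[2.0, 0.0], [3.0, 0.0]])
    assert masked_mse(pred, lm) == pytest.approx(0.5, abs=0)
    assert masked_mse(lm.values, lm) == 0.0


def test_masked_mse_rejects_empty_mask_rows():
    with pytest.raises(DataError):
        LabelMatrix(np.zeros((2, 2)), np.array([[1.0, 0.0], [0.0, 0.0]]))


def test_masked_entries_do_not_touch_loss_or_gradients(rng):
    """Perturbing labels under a zero mask changes nothing, exactly."""
    cfg = EncoderConfig(hidden_size=6, depth=2, n_targets=2, ffn_hidden=4)
    model = dmpnn.init_model(cfg, seed=1, dtype=np.float64)
    from mflogp.featurization import featurize_molecule

    bg = dmpnn.BatchGraph(
        [featurize_molecule(s) for s in ["CCO", "c1ccccc1", "CCN"]], dtype=np.float64
    )
    Y = rng.normal(size=(3, 2))
    M = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 0.0]])
    out, cache = dmpnn.forward(model, bg, return_cache=True)
    loss1, dout1 = dmpnn.masked_mse_and_grad(out, Y, M)
    grads1 = dmpnn.backward(model, bg, cache, dout1)
    Y2 = Y.copy()
    Y2[M == 0.0] += rng.normal(size=int((M == 0).sum())) * 100.0
    loss2, dout2 = dmpnn.masked_mse_and_grad(out, Y2, M)
    grads2 = dmpnn.backward(model, bg, cache, dout2)
    assert loss1 == loss2
    for k in grads1:
        np.testing.assert_array_equal(grads1[k], grads2[k])


# ------------------------------------------------------------------ merging


def test_merge_multifidelity_masks():
    lf = make_dataset([("CCO", -0.1), ("c1ccccc1", 1.9), ("CCN", 0.0)], fidelity="LF")
    hf = make_dataset([("CCO", -0.05), ("CCCl", 1.0)], fidelity="HF")
    smiles, lm = merge_multifidelity(lf, hf)
    assert len(smiles) == 4
    i_ccO = smiles.index(lf.records[0].canonical_smiles)
    assert lm.mask[i_ccO].tolist() == [1.0, 1.0]  # present in both tiers
    assert lm.values[i_ccO, LF_COL] == -0.1 and lm.values[i_ccO, HF_COL] == -0.05
    i_benzene = smiles.index(lf.records[1].canonical_smiles)
    assert lm.mask[i_benzene].tolist() == [1.0, 0.0]  # LF only
    i_cl = smiles.index(hf.records[1].canonical_smiles)
    assert lm.mask[i_cl].tolist() == [0.0, 1.0]  # HF only


# ------------------------------------------------------------------ strategies


def test_single_task_runs_and_is_reproducible(tiny_bundle):
    r1 = train_single_task(tiny_bundle.hf_train, TINY_ENC, TINY_TRAIN)
    r2 = train_single_task(tiny_bundle.hf_train, TINY_ENC, TINY_TRAIN)
    smiles = tiny_bundle.hf_test.smiles[:10]
    np.testing.assert_allclose(r1.predict(smiles), r2.predict(smiles), atol=1e-7)
    assert r1.strategy == "single"
    assert np.isfinite(r1.val_rmse)


def test_transfer_zero_epoch_finetune_is_noop(tiny_bundle):
    pre = train_single_task(tiny_bundle.lf, TINY_ENC, TINY_TRAIN)
    lf_model = pre.models["model"]
    res = train_transfer(
        tiny_bundle.lf,
        tiny_bundle.hf_train,
        TINY_ENC,
        TINY_TRAIN,
        TrainConfig(max_epochs=0, seed=0),
        pretrained=lf_model,
    )
    smiles = tiny_bundle.hf_test.smiles[:15]
    np.testing.assert_allclose(
        res.predict(smiles), dmpnn.predict(lf_model, smiles)[:, 0], atol=1e-6
    )


def test_transfer_finetune_changes_weights_and_refits_scaler(tiny_bundle):
    pre = train_single_task(tiny_bundle.lf, TINY_ENC, TINY_TRAIN)
    lf_model = pre.models["model"]
    res = train_transfer(
        tiny_bundle.lf, tiny_bundle.hf_train, TINY_ENC, TINY_TRAIN, TINY_TRAIN,
        pretrained=lf_model,
    )
    ft = res.models["model"]
    assert ft.mode == "transfer"
    assert any(
        not np.array_equal(ft.weights[k], lf_model.weights[k]) for k in ft.weights
    )
    # pretrained model untouched (copied, not mutated)
    pre2 = train_single_task(tiny_bundle.lf, TINY_ENC, TINY_TRAIN)
    for k in lf_model.weights:
        np.testing.assert_array_equal(lf_model.weights[k], pre2.models["model"].weights[k])


def test_transfer_frozen_encoder_only_trains_head(tiny_bundle):
    pre = train_single_task(tiny_bundle.lf, TINY_ENC, TINY_TRAIN)
    lf_model = pre.models["model"]
    res = train_transfer(
        tiny_bundle.lf, tiny_bundle.hf_train, TINY_ENC, TINY_TRAIN, TINY_TRAIN,
        freeze_encoder=True, pretrained=lf_model,
    )
    ft = res.models["model"]
    for k in ("W_in", "W_m", "W_a", "b_a"):
        np.testing.assert_array_equal(ft.weights[k], lf_model.weights[k])
    assert any(
        not np.array_equal(ft.weights[k], lf_model.weights[k])
        for k in ft.weights if k.startswith("ffn_")
    )


def test_multi_target_trains_two_heads(tiny_bundle):
    res = train_multi_target(tiny_bundle.lf, tiny_bundle.hf_train, TINY_ENC, TINY_TRAIN)
    model = res.models["model"]
    assert model.config.n_targets == 2
    out = dmpnn.predict(model, tiny_bundle.hf_test.smiles[:5])
    assert out.shape == (5, 2)
    assert res.predict(tiny_bundle.hf_test.smiles[:5]).shape == (5,)


def test_feature_augmented_with_constant_stage_one(tiny_bundle):
    """A constant LF feature must not break stage-2 training (std floor)."""
    const = dmpnn.init_model(EncoderConfig(hidden_size=4, ffn_hidden=4), seed=0)
    for k in const.weights:
        const.weights[k] = np.zeros_like(const.weights[k])
    res = train_feature_augmented(
        tiny_bundle.lf, tiny_bundle.hf_train, TINY_ENC, TINY_TRAIN, lf_model=const
    )
    assert res.feature_std >= 1e-8
    preds = res.predict(tiny_bundle.hf_test.smiles[:5])
    assert np.all(np.isfinite(preds))


def test_feature_augmented_checkpoint_round_trip(tiny_bundle, tmp_path):
    res = train_feature_augmented(
        tiny_bundle.lf, tiny_bundle.hf_train, TINY_ENC, TINY_TRAIN
    )
    save_result(tmp_path / "fa", res)
    loaded = load_result(tmp_path / "fa")
    smiles = tiny_bundle.hf_test.smiles[:10]
    np.testing.assert_array_equal(res.predict(smiles), loaded.predict(smiles))


# ------------------------------------------------------------------ search


def test_hyperparameter_search_single_point_space(tiny_bundle):
    space = {"hidden_size": [10], "depth": [2]}
    best, trials = hyperparameter_search(
        space, budget=1, hf=tiny_bundle.hf_train, strategy="single",
        seed=0, base_cfg=TINY_ENC, train_cfg=TINY_TRAIN,
    )
    assert best.hidden_size == 10 and best.depth == 2
    assert len(trials) == 1


def test_hyperparameter_search_returns_argmin(tiny_bundle):
    space = {"hidden_size": [4, 8, 16], "depth": [2, 3]}
    best, trials = hyperparameter_search(
        space, budget=4, hf=tiny_bundle.hf_train, strategy="single",
        seed=3, base_cfg=TINY_ENC, train_cfg=TINY_TRAIN,
    )
    best_rmse = min(v for _, v in trials)
    assert any(c == best and v == best_rmse for c, v in trials)
    with pytest.raises(DataError):
        hyperparameter_search({"hidden_size": []}, budget=1, hf=tiny_bundle.hf_train)
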