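"""The four training regimes for mixing low- and high-fidelity logP labels.

* ``single``            — one model, one fidelity tier.
* ``transfer``          — pretrain on the LF tier, then fine-tune every weight
                          on the HF tier (sequential).
* ``multi_target``      — one model with two output heads (LF, HF) trained
                          jointly on the union of both tiers with a masked
                          loss that ignores missing entries (simultaneous).
* ``feature_augmented`` — an LF model's prediction becomes one extra input
                          feature of a fresh HF model (sequential).

Each trainer performs its own seeded 80-10-10 train/validation/test split and
keeps the weights of the epoch with the lowest validation RMSE (the HF column
when one exists).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import dmpnn
from .data_io import DataError, FidelityDataset, SplitSpec, ensure_canonical, random_split
from .dmpnn import EncoderConfig, ModelState, TrainConfig

STRATEGIES = ("single", "transfer", "multi_target", "feature_augmented")
LF_COL, HF_COL = 0, 1


@dataclass
class LabelMatrix:
    """Dense label matrix with an observation mask (1 = observed)."""

    values: np.ndarray  # (n, n_targets)
    mask: np.ndarray  # (n, n_targets)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=np.float64)
        if self.values.shape != self.mask.shape:
            raise DataError("label values and mask shapes differ")
        if (self.mask.sum(axis=1) == 0).any():
            raise DataError("every row needs at least one observed label")


@dataclass
class StrategyResult:
    """Trained model(s) plus the bookkeeping needed to predict and compare."""

    strategy: str
    models: dict[str, ModelState]
    logs: dict[str, list] = field(default_factory=dict)
    split_seed: int = 0
    val_rmse: float = float("nan")
    feature_mean: float = 0.0  # feature_augmented only
    feature_std: float = 1.0

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise DataError(f"unknown strategy {self.strategy!r}")

    def predict(self, smiles: Sequence[str]) -> np.ndarray:
        """High-fidelity-head prediction per molecule (shape (n,))."""
        if self.strategy == "feature_augmented":
            feat = dmpnn.predict(self.models["lf"], smiles)[:, 0]
            feat = (feat - self.feature_mean) / self.feature_std
            return dmpnn.predict(self.models["hf"], smiles, extra=feat[:, None])[:, 0]
        model = self.models["model"]
        out = dmpnn.predict(model, smiles)
        col = HF_COL if self.strategy == "multi_target" else 0
        return out[:, col]


def masked_mse(pred: np.ndarray, labels: LabelMatrix) -> float:
    """sum(mask * (pred - value)^2) / sum(mask); masked entries never count."""
    pred = np.asarray(pred, dtype=np.float64).reshape(labels.values.shape)
    loss, _ = dmpnn.masked_mse_and_grad(pred, labels.values, labels.mask)
    return loss


def _full_data(ds: FidelityDataset):
    ds = ensure_canonical(ds)
    smiles = ds.smiles
    y = ds.labels[:, None]
    return smiles, y, np.ones_like(y), None


def _best_val(log: list[dict]) -> float:
    return min((e["val_rmse"] for e in log), default=float("nan"))


def train_single_task(
    ds: FidelityDataset,
    enc_cfg: Optional[EncoderConfig] = None,
    train_cfg: Optional[TrainConfig] = None,
) -> StrategyResult:
    """Baseline: one n_targets=1 model on one fidelity tier."""
    enc_cfg = enc_cfg or EncoderConfig()
    train_cfg = train_cfg or TrainConfig()
    enc_cfg = replace(enc_cfg, n_targets=1, extra_feature_dim=0)
    tr, va, _ = random_split(ds, SplitSpec(seed=train_cfg.seed))
    model = dmpnn.init_model(enc_cfg, seed=train_cfg.seed, mode="single")
    model, log = dmpnn.train(model, _full_data(tr), _full_data(va), train_cfg)
    return StrategyResult(
        "single",
        {"model": model},
        logs={"train": log},
        split_seed=train_cfg.seed,
        val_rmse=_best_val(log),
    )


def train_transfer(
    lf: FidelityDataset,
    hf: FidelityDataset,
    enc_cfg: Optional[EncoderConfig] = None,
    pretrain_cfg: Optional[TrainConfig] = None,
    finetune_cfg: Optional[TrainConfig] = None,
    freeze_encoder: bool = False,
    pretrained: Optional[ModelState] = None,
) -> StrategyResult:
    """Sequential LF pretraining then HF fine-tuning of all weights.

    With ``finetune_cfg.max_epochs == 0`` the fine-tune is a no-op: the
    pretrained weights *and target scaler* are returned unchanged, so
    predictions equal the pretrained model's. With at least one epoch the
    scaler is refit on the HF training fold. ``pretrained`` short-circuits
    phase 1 with an existing LF model (it is copied, never mutated).
    """
    enc_cfg = enc_cfg or EncoderConfig()
    pretrain_cfg = pretrain_cfg or TrainConfig()
    finetune_cfg = finetune_cfg or TrainConfig()
    logs = {}
    if pretrained is None:
        stage1 = train_single_task(lf, enc_cfg, pretrain_cfg)
        pretrained = stage1.models["model"]
        logs["pretrain"] = stage1.logs["train"]
    model = pretrained.copy()
    model.mode = "transfer"
    tr, va, _ = random_split(hf, SplitSpec(seed=finetune_cfg.seed))
    trainable = None
    if freeze_encoder:
        trainable = {k for k in model.weights if k.startswith("ffn_")}
    model, log = dmpnn.train(
        model,
        _full_data(tr),
        _full_data(va),
        finetune_cfg,
        refit_scaler=finetune_cfg.max_epochs > 0,
        trainable=trainable,
    )
    logs["finetune"] = log
    return StrategyResult(
        "transfer",
        {"model": model},
        logs=logs,
        split_seed=finetune_cfg.seed,
        val_rmse=_best_val(log),
    )


def merge_multifidelity(lf: FidelityDataset, hf: FidelityDataset):
    """Union of both tiers keyed by canonical SMILES, as a 2-column LabelMatrix.

    Column 0 holds LF labels, column 1 HF labels; molecules present in both
    tiers keep both entries (no averaging — the discrepancy between tiers is
    exactly the signal multi-target learning exploits).
    """
    lf, hf = ensure_canonical(lf), ensure_canonical(hf)
    order: list[str] = []
    vals: dict[str, list] = {}
    for col, ds in ((LF_COL, lf), (HF_COL, hf)):
        for r in ds.records:
            key = r.canonical_smiles
            if key not in vals:
                vals[key] = [np.nan, np.nan]
                order.append(key)
            vals[key][col] = r.logp
    Y = np.array([vals[s] for s in order], dtype=np.float64)
    mask = np.isfinite(Y).astype(np.float64)
    Y = np.nan_to_num(Y)
    return order, LabelMatrix(Y, mask)


def train_multi_target(
    lf: FidelityDataset,
    hf: FidelityDataset,
    enc_cfg: Optional[EncoderConfig] = None,
    train_cfg: Optional[TrainConfig] = None,
    hf_weight: float = 1.0,
) -> StrategyResult:
    """Simultaneous training of one 2-head model on the merged LF+HF set.

    Missing entries are masked out of the loss, so the HF head receives
    gradient only from HF-labelled rows. ``hf_weight`` multiplies the weight
    of observed HF entries in the loss (1.0 = each observed entry counts
    once). Early stopping tracks the HF-column validation RMSE when the
    validation fold contains HF labels.
    """
    enc_cfg = enc_cfg or EncoderConfig()
    train_cfg = train_cfg or TrainConfig()
    enc_cfg = replace(enc_cfg, n_targets=2, extra_feature_dim=0)
    smiles, lm = merge_multifidelity(lf, hf)
    n = len(smiles)
    rng = np.random.default_rng(train_cfg.seed)
    perm = rng.permutation(n)
    n_tr, n_va = int(n * 0.8), int(n * 0.1)
    if n_tr == 0 or n_va == 0 or n - n_tr - n_va == 0:
        raise DataError("merged dataset too small for an 80-10-10 split")
    mask_w = lm.mask.copy()
    mask_w[:, HF_COL] *= hf_weight
    idx_tr, idx_va = perm[:n_tr], perm[n_tr : n_tr + n_va]
    data_tr = ([smiles[i] for i in idx_tr], lm.values[idx_tr], mask_w[idx_tr], None)
    data_va = ([smiles[i] for i in idx_va], lm.values[idx_va], lm.mask[idx_va], None)
    model = dmpnn.init_model(enc_cfg, seed=train_cfg.seed, mode="multi_target")
    model, log = dmpnn.train(model, data_tr, data_va, train_cfg, val_metric_col=HF_COL)
    return StrategyResult(
        "multi_target",
        {"model": model},
        logs={"train": log},
        split_seed=train_cfg.seed,
        val_rmse=_best_val(log),
    )


def train_feature_augmented(
    lf: FidelityDataset,
    hf: FidelityDataset,
    enc_cfg: Optional[EncoderConfig] = None,
    train_cfg: Optional[TrainConfig] = None,
    lf_model: Optional[ModelState] = None,
) -> StrategyResult:
    """Two-stage: an LF model's prediction feeds a fresh HF model as a feature.

    The stage-1 prediction is z-scored on the HF training fold (std floored at
    1e-8 so a constant feature cannot blow up the scale). Prediction on new
    molecules runs stage 1 then stage 2.
    """
    enc_cfg = enc_cfg or EncoderConfig()
    train_cfg = train_cfg or TrainConfig()
    logs = {}
    if lf_model is None:
        stage1 = train_single_task(lf, enc_cfg, train_cfg)
        lf_model = stage1.models["model"]
        logs["lf"] = stage1.logs["train"]
    tr, va, _ = random_split(hf, SplitSpec(seed=train_cfg.seed))
    feat_tr = dmpnn.predict(lf_model, tr.smiles)[:, 0]
    feat_va = dmpnn.predict(lf_model, va.smiles)[:, 0]
    f_mean = float(feat_tr.mean())
    f_std = max(float(feat_tr.std()), 1e-8)
    cfg2 = replace(enc_cfg, n_targets=1, extra_feature_dim=1)
    model = dmpnn.init_model(cfg2, seed=train_cfg.seed, mode="feature_augmented")
    data_tr = (tr.smiles, tr.labels[:, None], None, ((feat_tr - f_mean) / f_std)[:, None])
    data_va = (va.smiles, va.labels[:, None], None, ((feat_va - f_mean) / f_std)[:, None])
    model, log = dmpnn.train(model, data_tr, data_va, train_cfg)
    logs["hf"] = log
    return StrategyResult(
        "feature_augmented",
        {"lf": lf_model, "hf": model},
        logs=logs,
        split_seed=train_cfg.seed,
        val_rmse=_best_val(log),
        feature_mean=f_mean,
        feature_std=f_std,
    )


def save_result(outdir, result: StrategyResult) -> None:
    """Persist a strategy result as a directory: meta.json + one .npz per model."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "strategy": result.strategy,
        "split_seed": result.split_seed,
        "val_rmse": result.val_rmse,
        "feature_mean": result.feature_mean,
        "feature_std": result.feature_std,
        "models": sorted(result.models),
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2))
    for name, model in result.models.items():
        dmpnn.save_model(outdir / f"{name}.npz", model)
    (outdir / "logs.json").write_text(json.dumps(result.logs, indent=2))


def load_result(outdir) -> StrategyResult:
    import json
    from pathlib import Path

    outdir = Path(outdir)
    meta = json.loads((outdir / "meta.json").read_text())
    models = {name: dmpnn.load_model(outdir / f"{name}.npz") for name in meta["models"]}
    logs = {}
    if (outdir / "logs.json").exists():
        logs = json.loads((outdir / "logs.json").read_text())
    return StrategyResult(
        meta["strategy"],
        models,
        logs=logs,
        split_seed=meta["split_seed"],
        val_rmse=meta["val_rmse"],
        feature_mean=meta["feature_mean"],
        feature_std=meta["feature_std"],
    )


DEFAULT_SEARCH_SPACE = {
    "hidden_size": [64, 128, 256],
    "depth": [2, 3, 4],
    "dropout": [0.0, 0.1, 0.2],
    "ffn_layers": [1, 2, 3],
}


def hyperparameter_search(
    space: Optional[dict] = None,
    budget: int = 20,
    lf: Optional[FidelityDataset] = None,
    hf: Optional[FidelityDataset] = None,
    strategy: str = "single",
    seed: int = 0,
    base_cfg: Optional[EncoderConfig] = None,
    train_cfg: Optional[TrainConfig] = None,
):
    """Seeded random search over encoder hyperparameters by validation RMSE.

    Returns ``(best_config, trials)`` where trials is a list of
    ``(config, val_rmse)`` pairs. Candidates are drawn uniformly from the
    per-key value lists in ``space``.
    """
    space = space or DEFAULT_SEARCH_SPACE
    if budget < 1:
        raise DataError("search budget must be >= 1")
    if not space or any(len(v) == 0 for v in space.values()):
        raise DataError("empty search space")
    base_cfg = base_cfg or EncoderConfig()
    train_cfg = train_cfg or TrainConfig()
    rng = np.random.default_rng(seed)
    trials = []
    for _ in range(budget):
        params = {k: v[rng.integers(len(v))] for k, v in space.items()}
        cfg = replace(base_cfg, **params)
        if strategy == "single":
            ds = hf if hf is not None else lf
            res = train_single_task(ds, cfg, train_cfg)
        elif strategy == "transfer":
            res = train_transfer(lf, hf, cfg, train_cfg, train_cfg)
        elif strategy == "multi_target":
            res = train_multi_target(lf, hf, cfg, train_cfg)
        elif strategy == "feature_augmented":
            res = train_feature_augmented(lf, hf, cfg, train_cfg)
        else:
            raise DataError(f"unknown strategy {strategy!r}")
        trials.append((cfg, res.val_rmse))
    best = min(trials, key=lambda t: t[1])
    return best[0], trials
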