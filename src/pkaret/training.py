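"""Training protocol: MSE objective, Adam, multi-fidelity pretrain/fine-tune.

The multi-fidelity protocol pretrains the network on abundant low-fidelity
(computed-like) labels, then fine-tunes every layer on scarce high-fidelity
(experimental-like) labels — transferring knowledge from calculated to
experimental values.  Evaluation reports R^2, MAE and RMSE in pKa log units.
A single integer seed fixes weight initialization, data shuffling and
dropout, making loss traces bit-reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import data_pipeline
from .autodiff import Tensor
from .mpnn_model import ModelConfig, MoleculeTensors, PkaModel, featurize_molecule

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    batch_size: int = 64
    pretrain_epochs: int = 100
    finetune_epochs: int = 50
    learning_rate: float = 1e-3
    warmup_epochs: int = 2        # linear warmup, then exponential decay
    lr_decay: float = 0.99        # per-epoch multiplier after warmup
    seed: int = 0
    loss: str = "mse"
    target_train_mae: float | None = None  # optional early stop on train MAE
    n_restarts: int = 1

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.pretrain_epochs < 0 or self.finetune_epochs < 0:
            raise ValueError("epochs and batch size must be positive")
        if self.loss != "mse":
            raise ValueError("only the MSE loss is supported")


@dataclass
class Metrics:
    r2: float
    mae: float
    rmse: float

    def as_dict(self) -> dict[str, float]:
        return {"r2": self.r2, "mae": self.mae, "rmse": self.rmse}


def compute_metrics(y_true, y_pred) -> Metrics:
    """R^2 = 1 - SS_res/SS_tot, MAE, RMSE; R^2 is NaN (with a warning) when
    the labels have zero variance."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValueError("cannot compute metrics on empty input")
    err = y_pred - y_true
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err ** 2).mean()))
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0.0:
        warnings.warn("R^2 undefined: zero label variance", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - float((err ** 2).sum()) / ss_tot
    return Metrics(r2=r2, mae=mae, rmse=rmse)


class Adam:
    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad ** 2
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _prepare(df: pd.DataFrame, cache: dict[str, MoleculeTensors], use_qm: bool):
    """Featurize every molecule once; return (tensors, qm matrix, labels)."""
    mts, qms, ys = [], [], []
    qm_cols = [f"qm_{k}" for k in range(1, 6)]
    for _, row in df.iterrows():
        smi = row["smiles"]
        if smi not in cache:
            cache[smi] = featurize_molecule(smi)
        mts.append(cache[smi])
        qms.append(row[qm_cols].to_numpy(dtype=float) if use_qm else None)
        ys.append(float(row["pka"]))
    return mts, qms, np.array(ys)


def fit_qm_standardization(model: PkaModel, df: pd.DataFrame) -> None:
    """Store train-set z-score constants for the five QM scalars."""
    if not model.config.use_qm:
        return
    qm = df[[f"qm_{k}" for k in range(1, 6)]].to_numpy(dtype=float)
    model.qm_mean = qm.mean(axis=0)
    std = qm.std(axis=0)
    model.qm_std = np.where(std > 0, std, 1.0)


def train(model: PkaModel, train_df: pd.DataFrame, config: TrainConfig,
          val_df: pd.DataFrame | None = None, epochs: int | None = None,
          cache: dict[str, MoleculeTensors] | None = None,
          fit_qm: bool = True) -> dict:
    """Train with MSE loss; retains the best-validation-RMSE weights.

    Returns a history dict with per-epoch train loss (and val RMSE when a
    validation set is given).  Deterministic given ``config.seed``.
    """
    if len(train_df) == 0:
        raise ValueError("empty training split")
    epochs = config.pretrain_epochs if epochs is None else epochs
    cache = cache if cache is not None else {}
    if fit_qm:
        fit_qm_standardization(model, train_df)
    mts, qms, ys = _prepare(train_df, cache, model.config.use_qm)
    val = (_prepare(val_df, cache, model.config.use_qm)
           if val_df is not None and len(val_df) else None)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history: dict = {"train_loss": [], "val_rmse": [], "lr": []}
    best_rmse, best_state = np.inf, model.state_copy()
    n = len(mts)
    for epoch in range(epochs):
        if config.warmup_epochs and epoch < config.warmup_epochs:
            opt.lr = config.learning_rate * (epoch + 1) / config.warmup_epochs
        else:
            opt.lr = (config.learning_rate
                      * config.lr_decay ** max(0, epoch - config.warmup_epochs))
        order = rng.permutation(n)
        total, abs_err = 0.0, 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            loss = None
            for i in idx:
                pred = model.forward(mts[i], qms[i], rng=rng)
                sq = (pred - ys[i]) ** 2
                loss = sq if loss is None else loss + sq
                total += sq.data.item()
                abs_err += abs(pred.data.item() - ys[i])
            (loss * (1.0 / len(idx))).backward()
            opt.step()
        epoch_loss = total / n
        if not np.isfinite(epoch_loss):
            raise RuntimeError(
                f"NaN/inf loss at epoch {epoch}: diverged "
                f"(lr={opt.lr:.2e}); lower the learning rate")
        history["train_loss"].append(epoch_loss)
        history["lr"].append(opt.lr)
        if val is not None:
            vm = compute_metrics(val[2], np.array(
                [model.forward(mt, qm).data.item() for mt, qm in zip(val[0], val[1])]))
            history["val_rmse"].append(vm.rmse)
            if vm.rmse < best_rmse:
                best_rmse, best_state = vm.rmse, model.state_copy()
        log.debug("epoch %d loss %.4f", epoch, epoch_loss)
        if (config.target_train_mae is not None
                and abs_err / n < config.target_train_mae):
            break
    if val is not None and np.isfinite(best_rmse):
        model.load_state(best_state)
        history["best_val_rmse"] = best_rmse
    return history


def evaluate(model: PkaModel, df: pd.DataFrame,
             cache: dict[str, MoleculeTensors] | None = None
             ) -> tuple[Metrics, pd.DataFrame]:
    """Inference-mode metrics plus a per-molecule prediction table."""
    if "pka" not in df.columns or len(df) == 0:
        raise ValueError("evaluation requires a non-empty labeled dataset")
    cache = cache if cache is not None else {}
    mts, qms, ys = _prepare(df, cache, model.config.use_qm)
    preds = np.array([model.forward(mt, qm).data.item()
                      for mt, qm in zip(mts, qms)])
    table = pd.DataFrame({"smiles": df["smiles"].to_numpy(), "y_true": ys,
                          "y_pred": preds, "abs_error": np.abs(preds - ys)})
    return compute_metrics(ys, preds), table


def split_frames(df: pd.DataFrame, seed: int
                 ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    labels = data_pipeline.random_split(df, seed=seed)
    return tuple(df[labels == part].reset_index(drop=True)
                 for part in ("train", "val", "test"))


def multi_fidelity_run(pretrain_df: pd.DataFrame, finetune_df: pd.DataFrame,
                       config: TrainConfig, model_config: ModelConfig | None = None,
                       cache: dict[str, MoleculeTensors] | None = None) -> dict:
    """Pretrain on low-fidelity labels, then fine-tune all layers on
    high-fidelity labels.  Returns both checkpointed states and histories."""
    model_config = model_config or ModelConfig()
    for frame, name in ((pretrain_df, "pretrain"), (finetune_df, "finetune")):
        if model_config.use_qm and any(f"qm_{k}" not in frame.columns
                                       for k in range(1, 6)):
            raise ValueError(f"{name} dataset lacks QM columns required by the model")
    cache = cache if cache is not None else {}
    model = PkaModel(model_config, seed=config.seed)
    pre_tr, pre_val, _ = split_frames(pretrain_df, config.seed)
    pre_hist = train(model, pre_tr, config, val_df=pre_val,
                     epochs=config.pretrain_epochs, cache=cache)
    pretrain_state = model.state_copy()
    ft_tr, ft_val, ft_test = split_frames(finetune_df, config.seed)
    ft_hist = train(model, ft_tr, config, val_df=ft_val,
                    epochs=config.finetune_epochs, cache=cache, fit_qm=False)
    return {"model": model, "pretrain_state": pretrain_state,
            "pretrain_history": pre_hist, "finetune_history": ft_hist,
            "splits": {"train": ft_tr, "val": ft_val, "test": ft_test}}


ABLATION_VARIANTS = {
    # variant: (multi-fidelity, use_qm, use_retention)
    "N": (False, False, False),
    "Q": (True, False, False),
    "R": (True, True, False),
    "full": (True, True, True),
}


def ablate(pretrain_df: pd.DataFrame, finetune_df: pd.DataFrame,
           config: TrainConfig, base_model_config: ModelConfig | None = None,
           cache: dict[str, MoleculeTensors] | None = None) -> pd.DataFrame:
    """Variant grid: N (single-fidelity, no QM, attention), Q (+multi-
    fidelity), R (+QM), full (+retention).  Emits R^2/MAE/RMSE and the
    relative RMSE gain over variant N."""
    base = base_model_config or ModelConfig()
    cache = cache if cache is not None else {}
    rows = []
    base_rmse = None
    for name, (mfl, use_qm, use_ret) in ABLATION_VARIANTS.items():
        mc = ModelConfig(**{**base.__dict__, "use_qm": use_qm,
                            "use_retention": use_ret})
        if mfl:
            run = multi_fidelity_run(pretrain_df, finetune_df, config, mc, cache)
            model, test = run["model"], run["splits"]["test"]
        else:
            model = PkaModel(mc, seed=config.seed)
            tr, val, test = split_frames(finetune_df, config.seed)
            train(model, tr, config, val_df=val,
                  epochs=config.finetune_epochs, cache=cache)
        metrics, _ = evaluate(model, test, cache)
        if base_rmse is None:
            base_rmse = metrics.rmse
        gain = (base_rmse - metrics.rmse) / base_rmse * 100.0
        rows.append({"variant": name, **metrics.as_dict(),
                     "relative_rmse_gain_pct": gain})
    return pd.DataFrame(rows)
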