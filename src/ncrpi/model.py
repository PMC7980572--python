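"""The two-branch CNN+BLSTM interaction classifier.

Each branch takes one flat feature vector (ncRNA: 3141 elements, protein:
443) as a single-channel 1-D signal and applies three blocks of
[convolution -> ReLU -> max pooling -> batch normalization -> dropout]
with 45, 64 and 86 filters (kernels 6,5,5 for the ncRNA branch, 6,6,6 for
the protein branch), then a bidirectional LSTM (hidden size 45, final
states of both directions concatenated) and a fully-connected layer of 64
units.  The two 64-unit branch outputs are concatenated and passed through
fully-connected layers of 128, 64 and 2 units (dropout 0.25 and 0.3
between them) ending in a softmax; the loss is cross-entropy on the 2-way
softmax.

Training runs in two phases: Adam (lr 0.001) for fast convergence, then
SGD (lr 0.005) fine-tuning.  Inputs are standardized per feature using
training-set statistics (the raw feature scales span several orders of
magnitude, from 7-mer frequencies to solvent-accessibility averages).
Model selection and early stopping use the AUC on a stratified held-out
validation split — hyperparameter and epoch selection against a
discrimination metric on a validation set, with the cross-entropy loss
driving the gradients.  Fixed seeds give bit-identical runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from ._nn import (
    Adam,
    BatchNorm1d,
    BiLSTM,
    Conv1d,
    Dense,
    Dropout,
    Layer,
    MaxPool1d,
    Param,
    ReLU,
    SGD,
    Sequential,
    softmax,
    softmax_cross_entropy,
)
from .encode import PROTEIN_VECTOR_LENGTH, RNA_VECTOR_LENGTH


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier.

    Convolution filter counts, kernel sizes, conv dropout, BLSTM hidden
    size, branch/head fully-connected widths, head dropout and the two
    learning rates are the published operating point; pooling geometry,
    batch size, epoch budget, patience, validation fraction and the L2
    weight-decay strength are package defaults (see docs/methods.md).
    """

    rna_input_dim: int = RNA_VECTOR_LENGTH
    protein_input_dim: int = PROTEIN_VECTOR_LENGTH
    conv_filters: Tuple[int, int, int] = (45, 64, 86)
    rna_kernels: Tuple[int, int, int] = (6, 5, 5)
    protein_kernels: Tuple[int, int, int] = (6, 6, 6)
    conv_dropout: Tuple[float, float, float] = (0.2, 0.2, 0.2)
    blstm_hidden: int = 45
    branch_fc: int = 64
    head_fc: Tuple[int, int, int] = (128, 64, 2)
    head_dropout: Tuple[float, float] = (0.25, 0.3)
    adam_lr: float = 0.001
    sgd_lr: float = 0.005
    pool_size: int = 4
    batch_size: int = 16
    max_epochs: int = 40
    adam_fraction: float = 0.6
    patience: int = 10
    val_fraction: float = 0.15
    l2: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        dims = (
            self.rna_input_dim,
            self.protein_input_dim,
            *self.conv_filters,
            self.blstm_hidden,
            self.branch_fc,
            *self.head_fc,
            self.pool_size,
            self.batch_size,
            self.max_epochs,
        )
        if any(d <= 0 for d in dims):
            raise ValueError("all dimensions must be positive")
        if any(not (0.0 <= r < 1.0) for r in (*self.conv_dropout, *self.head_dropout)):
            raise ValueError("dropout rates must be in [0, 1)")
        if self.adam_lr <= 0 or self.sgd_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.head_fc[-1] != 2:
            raise ValueError("final head layer must have 2 units (binary softmax)")

    def to_dict(self) -> Dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Dict) -> "ModelConfig":
        d = dict(d)
        for key in ("conv_filters", "rna_kernels", "protein_kernels", "conv_dropout",
                    "head_fc", "head_dropout"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


class _Branch:
    """Conv stack + BLSTM + fully-connected projection for one molecule type."""

    def __init__(self, rng, input_dim: int, kernels, cfg: ModelConfig, dtype):
        f1, f2, f3 = cfg.conv_filters
        layers: List[Layer] = []
        c_in = 1
        for c_out, kernel, rate in zip(cfg.conv_filters, kernels, cfg.conv_dropout):
            layers += [
                Conv1d(rng, c_in, c_out, kernel, dtype=dtype),
                ReLU(),
                MaxPool1d(cfg.pool_size),
                BatchNorm1d(c_out, dtype=dtype),
                Dropout(rate, rng),
            ]
            c_in = c_out
        self.conv = Sequential(layers)
        self.blstm = BiLSTM(rng, f3, cfg.blstm_hidden, dtype=dtype)
        self.fc = Dense(rng, 2 * cfg.blstm_hidden, cfg.branch_fc, dtype=dtype)
        self.relu = ReLU()
        self.input_dim = input_dim

    def params(self) -> List[Param]:
        return self.conv.params() + self.blstm.params() + self.fc.params()

    def batchnorms(self) -> List[BatchNorm1d]:
        return [l for l in self.conv.layers if isinstance(l, BatchNorm1d)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.shape[1] != self.input_dim:
            raise ValueError(f"expected {self.input_dim} features, got {x.shape[1]}")
        h = self.conv.forward(x[:, :, None], training)       # (B, L, C)
        h = self.blstm.forward(h, training)                   # (B, 2H)
        return self.relu.forward(self.fc.forward(h, training), training)

    def backward(self, grad: np.ndarray) -> None:
        g = self.fc.backward(self.relu.backward(grad))
        g = self.blstm.backward(g)
        self.conv.backward(g)


class InteractionModel:
    """The full two-branch network; train with :func:`train`, score with :func:`predict`."""

    def __init__(self, config: ModelConfig, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        self.rng = np.random.default_rng(config.seed)
        rng = self.rng
        self.rna_branch = _Branch(rng, config.rna_input_dim, config.rna_kernels, config, dtype)
        self.prot_branch = _Branch(
            rng, config.protein_input_dim, config.protein_kernels, config, dtype
        )
        d1, d2, d_out = config.head_fc
        r1, r2 = config.head_dropout
        self.head = Sequential([
            Dense(rng, 2 * config.branch_fc, d1, dtype=dtype),
            ReLU(),
            Dropout(r1, rng),
            Dense(rng, d1, d2, dtype=dtype),
            ReLU(),
            Dropout(r2, rng),
            Dense(rng, d2, d_out, dtype=dtype),
        ])
        self.training_log: List[Dict] = []
        self._fitted = False
        # per-feature standardization fitted during training
        self._rna_scale: Optional[Tuple[np.ndarray, np.ndarray]] = None
        self._prot_scale: Optional[Tuple[np.ndarray, np.ndarray]] = None

    def fit_scalers(self, rna_X: np.ndarray, prot_X: np.ndarray) -> None:
        """Fit per-feature z-scaling on training rows (applied in forward)."""
        self._rna_scale = (rna_X.mean(axis=0), rna_X.std(axis=0) + 1e-8)
        self._prot_scale = (prot_X.mean(axis=0), prot_X.std(axis=0) + 1e-8)

    # -- plumbing ---------------------------------------------------------
    def params(self) -> List[Param]:
        return self.rna_branch.params() + self.prot_branch.params() + self.head.params()

    def _batchnorms(self) -> List[BatchNorm1d]:
        return self.rna_branch.batchnorms() + self.prot_branch.batchnorms()

    def _snapshot(self) -> Dict:
        return {
            "params": [p.value.copy() for p in self.params()],
            "bn": [(bn.running_mean.copy(), bn.running_var.copy())
                   for bn in self._batchnorms()],
        }

    def _restore(self, snap: Dict) -> None:
        for p, v in zip(self.params(), snap["params"]):
            p.value[...] = v
        for bn, (mean, var) in zip(self._batchnorms(), snap["bn"]):
            bn.running_mean[...] = mean
            bn.running_var[...] = var

    # -- forward/backward -------------------------------------------------
    def forward(self, rna_X: np.ndarray, prot_X: np.ndarray, training: bool) -> np.ndarray:
        if self._rna_scale is not None:
            rna_X = (rna_X - self._rna_scale[0]) / self._rna_scale[1]
            prot_X = (prot_X - self._prot_scale[0]) / self._prot_scale[1]
        rna_X = np.ascontiguousarray(rna_X, dtype=self.dtype)
        prot_X = np.ascontiguousarray(prot_X, dtype=self.dtype)
        h_rna = self.rna_branch.forward(rna_X, training)
        h_prot = self.prot_branch.forward(prot_X, training)
        self._split = h_rna.shape[1]
        h = np.concatenate([h_rna, h_prot], axis=1)
        return self.head.forward(h, training)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        self.rna_branch.backward(g[:, : self._split])
        self.prot_branch.backward(g[:, self._split :])

    # -- inference --------------------------------------------------------
    def predict_proba(self, rna_X: np.ndarray, prot_X: np.ndarray,
                      batch_size: Optional[int] = None) -> np.ndarray:
        if rna_X.shape[0] != prot_X.shape[0]:
            raise ValueError("row counts of the two feature matrices differ")
        bs = batch_size or self.config.batch_size
        chunks = []
        for start in range(0, rna_X.shape[0], bs):
            logits = self.forward(rna_X[start : start + bs], prot_X[start : start + bs],
                                  training=False)
            chunks.append(softmax(logits))
        if not chunks:
            return np.zeros((0, 2))
        return np.vstack(chunks)

    # -- persistence ------------------------------------------------------
    def save(self, path: Union[str, Path]) -> None:
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        for i, bn in enumerate(self._batchnorms()):
            arrays[f"bn_mean_{i}"] = bn.running_mean
            arrays[f"bn_var_{i}"] = bn.running_var
        arrays["config_json"] = np.array(json.dumps(self.config.to_dict()))
        if self._rna_scale is not None:
            arrays["rna_scale_mean"], arrays["rna_scale_std"] = self._rna_scale
            arrays["prot_scale_mean"], arrays["prot_scale_std"] = self._prot_scale
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "InteractionModel":
        data = np.load(path, allow_pickle=False)
        config = ModelConfig.from_dict(json.loads(str(data["config_json"])))
        model = cls(config)
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"param_{i}"]
        for i, bn in enumerate(model._batchnorms()):
            bn.running_mean[...] = data[f"bn_mean_{i}"]
            bn.running_var[...] = data[f"bn_var_{i}"]
        if "rna_scale_mean" in data:
            model._rna_scale = (data["rna_scale_mean"], data["rna_scale_std"])
            model._prot_scale = (data["prot_scale_mean"], data["prot_scale_std"])
        model._fitted = True
        return model


def build_model(config: Optional[ModelConfig] = None) -> InteractionModel:
    """Construct an untrained classifier from a configuration."""
    return InteractionModel(config or ModelConfig())


def _epoch_loss(model: InteractionModel, rna_X, prot_X, y, batch_size: int) -> float:
    total, n = 0.0, 0
    for start in range(0, len(y), batch_size):
        sl = slice(start, start + batch_size)
        logits = model.forward(rna_X[sl], prot_X[sl], training=False)
        loss, _ = softmax_cross_entropy(logits, y[sl])
        size = min(start + batch_size, len(y)) - start
        total += loss * size
        n += size
    return total / max(n, 1)


def train(
    model: InteractionModel,
    rna_X: np.ndarray,
    prot_X: np.ndarray,
    y: np.ndarray,
    config: Optional[ModelConfig] = None,
) -> InteractionModel:
    """Two-phase training (Adam then SGD) with validation-based selection.

    A stratified validation split is held out from the training rows; the
    feature scalers are fitted on the remaining rows.  After every epoch
    the validation AUC is computed; a phase stops early when it has not
    improved for ``patience`` epochs, and the best-validation parameters
    are restored before the next phase and at the end.  Deterministic for
    a fixed config seed.
    """
    cfg = config or model.config
    y = np.asarray(y, dtype=int)
    if not (rna_X.shape[0] == prot_X.shape[0] == len(y)):
        raise ValueError("row counts of features and labels disagree")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if not set(classes) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")

    idx_train, idx_val = train_test_split(
        np.arange(len(y)),
        test_size=cfg.val_fraction,
        stratify=y,
        random_state=cfg.seed % (2 ** 32),
    )
    model.fit_scalers(rna_X[idx_train], prot_X[idx_train])
    tr_rna, tr_prot, tr_y = rna_X[idx_train], prot_X[idx_train], y[idx_train]
    va_rna, va_prot, va_y = rna_X[idx_val], prot_X[idx_val], y[idx_val]

    adam_epochs = max(1, round(cfg.adam_fraction * cfg.max_epochs))
    sgd_epochs = max(0, cfg.max_epochs - adam_epochs)
    rng = np.random.default_rng(cfg.seed + 1)
    phases = [
        ("adam", Adam(model.params(), cfg.adam_lr, weight_decay=cfg.l2), adam_epochs),
        ("sgd", SGD(model.params(), cfg.sgd_lr, weight_decay=cfg.l2), sgd_epochs),
    ]
    best = model._snapshot()
    best_val_auc = -np.inf
    for phase_name, optimizer, n_epochs in phases:
        since_best = 0
        for epoch in range(n_epochs):
            order = rng.permutation(len(tr_y))
            epoch_loss, seen = 0.0, 0
            for start in range(0, len(order), cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                logits = model.forward(tr_rna[batch], tr_prot[batch], training=True)
                loss, dlogits = softmax_cross_entropy(logits, tr_y[batch])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss in phase {phase_name}, epoch {epoch}"
                    )
                optimizer.zero_grad()
                model.backward(dlogits)
                optimizer.step()
                epoch_loss += loss * len(batch)
                seen += len(batch)
            val_loss = _epoch_loss(model, va_rna, va_prot, va_y, cfg.batch_size)
            val_scores = model.predict_proba(va_rna, va_prot)[:, 1]
            val_auc = float(roc_auc_score(va_y, val_scores))
            model.training_log.append({
                "phase": phase_name,
                "epoch": epoch,
                "train_loss": epoch_loss / seen,
                "val_loss": val_loss,
                "val_auc": val_auc,
            })
            if val_auc > best_val_auc + 1e-9:
                best_val_auc = val_auc
                best = model._snapshot()
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        model._restore(best)
    model._fitted = True
    return model


def predict(model: InteractionModel, rna_X: np.ndarray, prot_X: np.ndarray) -> np.ndarray:
    """Positive-class probability for each row (softmax output for label 1)."""
    return model.predict_proba(rna_X, prot_X)[:, 1]
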