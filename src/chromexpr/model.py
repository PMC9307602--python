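"""The two-branch convolutional architecture for expression prediction.

One branch reads the L x m epigenetic signal matrix, the other the L x 4
one-hot sequence matrix.  Each branch is conv -> batch-norm -> ReLU ->
max-pool -> conv -> BN -> ReLU -> max-pool; the first convolution's kernel
spans ``l`` positions times all input channels (l x m and l x 4 kernels).
Both branches emit an L' x k2 representation (L' = L / (pool1 * pool2)).
The two representations are stacked as parallel columns and fused by a
convolution whose kernel spans ``l`` positions times both columns and all k2
channels, followed by BN, ReLU and a final max-pool; the flattened result
feeds four fully connected layers (ReLU + dropout between hidden layers) down
to a single scalar: the predicted expression on the training target scale.

Loss is mean squared error plus an L2 penalty ``lambda_l2 * sum(W^2)`` over
all convolutional and dense kernels.  A classification head (sigmoid output,
binary cross-entropy on above/below-median expression labels) is available
via ``task='classification'``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import (
    BatchNorm,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    Layer,
    MaxPool1D,
    ReLU,
    Sequential,
)

__all__ = ["ModelConfig", "Model", "build_model", "relu", "loss", "save_model", "load_model"]

_F32 = np.float32


def relu(x):
    """Rectified linear unit: x for x > 0, else 0."""
    return np.maximum(x, 0.0)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the selected configuration: 64 first-layer and 128
    second-layer kernels, kernel length 20 (spanning all input channels),
    dropout 0.5, L2 penalty 1e-4.  Pooling sizes 4 then 5 make L' = L/20; the
    fusion output is pooled once more by ``pool2`` before the four fully
    connected layers.
    """

    l: int = 20
    k1: int = 64
    k2: int = 128
    fusion_kernels: int = 64
    pool1: int = 4
    pool2: int = 5
    fc_widths: tuple[int, int, int, int] = (512, 256, 64, 1)
    dropout: float = 0.5
    lambda_l2: float = 1e-4
    task: str = "regression"

    def __post_init__(self) -> None:
        if len(self.fc_widths) != 4 or self.fc_widths[-1] != 1:
            raise ValueError("fc_widths must be four integers ending in 1")
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")

    def l_prime(self, L: int) -> int:
        """Rows entering fusion from each branch."""
        if L % (self.pool1 * self.pool2) != 0:
            raise ValueError(f"L={L} not divisible by pool1*pool2={self.pool1 * self.pool2}")
        return L // (self.pool1 * self.pool2)

    def flat_width(self, L: int) -> int:
        lp = self.l_prime(L)
        if lp % self.pool2 != 0:
            raise ValueError(f"L'={lp} not divisible by pool2={self.pool2}")
        return lp // self.pool2 * self.fusion_kernels

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fc_widths"] = list(self.fc_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["fc_widths"] = tuple(d["fc_widths"])
        return cls(**d)


def _branch(cfg: ModelConfig, c_in: int, rng: np.random.Generator) -> Sequential:
    return Sequential([
        Conv1D(cfg.l, c_in, cfg.k1, rng),
        BatchNorm(cfg.k1),
        ReLU(),
        MaxPool1D(cfg.pool1),
        Conv1D(cfg.l, cfg.k1, cfg.k2, rng),
        BatchNorm(cfg.k2),
        ReLU(),
        MaxPool1D(cfg.pool2),
    ])


class Model:
    """Differentiable prediction function F(epigenetic, sequence) -> scalar."""

    def __init__(self, cfg: ModelConfig, L: int, m: int, seed: int = 0) -> None:
        cfg.flat_width(L)  # validates the pooling arithmetic early
        self.cfg, self.L, self.m = cfg, L, m
        rng = np.random.default_rng(seed)
        self.branch_ep = _branch(cfg, m, rng)
        self.branch_seq = _branch(cfg, 4, rng)
        self.fusion = Sequential([
            Conv1D(cfg.l, 2 * cfg.k2, cfg.fusion_kernels, rng),
            BatchNorm(cfg.fusion_kernels),
            ReLU(),
            MaxPool1D(cfg.pool2),
            Flatten(),
        ])
        widths = [cfg.flat_width(L), *cfg.fc_widths]
        head: list[Layer] = []
        for i in range(4):
            head.append(Dense(widths[i], widths[i + 1], rng))
            if i < 3:  # hidden layers get ReLU + dropout; the output stays linear
                head.append(ReLU())
                head.append(Dropout(cfg.dropout))
        self.head = Sequential(head)
        self.sidecar: dict = {}

    # -- plumbing ----------------------------------------------------------

    def _modules(self) -> list[Sequential]:
        return [self.branch_ep, self.branch_seq, self.fusion, self.head]

    def param_handles(self) -> list[tuple[Layer, str]]:
        handles = []
        for mod in self._modules():
            for layer in mod.layers:
                for key in layer.params:
                    handles.append((layer, key))
        return handles

    def weight_handles(self) -> list[tuple[Layer, str]]:
        """Conv/dense kernels only — the W of the L2 penalty."""
        return [
            (layer, "w")
            for mod in self._modules()
            for layer in mod.layers
            if isinstance(layer, (Conv1D, Dense))
        ]

    def zero_grads(self) -> None:
        for mod in self._modules():
            mod.zero_grads()

    def get_weights(self) -> list[np.ndarray]:
        state = [layer.params[k].copy() for layer, k in self.param_handles()]
        for mod in self._modules():
            for layer in mod.layers:
                if isinstance(layer, BatchNorm):
                    state.append(layer.running_mean.copy())
                    state.append(layer.running_var.copy())
        return state

    def set_weights(self, state: list[np.ndarray]) -> None:
        it = iter(state)
        for layer, k in self.param_handles():
            layer.params[k][...] = next(it)
        for mod in self._modules():
            for layer in mod.layers:
                if isinstance(layer, BatchNorm):
                    layer.running_mean[...] = next(it)
                    layer.running_var[...] = next(it)

    def n_parameters(self) -> int:
        return sum(layer.params[k].size for layer, k in self.param_handles())

    # -- forward / backward ------------------------------------------------

    def forward(self, ep: np.ndarray, seq: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        ep = np.asarray(ep)
        seq = np.asarray(seq)
        if not np.issubdtype(ep.dtype, np.floating):
            ep = ep.astype(_F32)
        if not np.issubdtype(seq.dtype, np.floating):
            seq = seq.astype(_F32)
        ze = self.branch_ep.forward(ep, train, rng)
        zs = self.branch_seq.forward(seq, train, rng)
        if ze.shape != zs.shape:
            raise ValueError(f"branch outputs misaligned at fusion: {ze.shape} vs {zs.shape}")
        self._k2 = ze.shape[2]
        z = np.concatenate([ze, zs], axis=2)
        z = self.fusion.forward(z, train, rng)
        out = self.head.forward(z, train, rng)
        return out[:, 0]

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dz = self.head.backward(np.asarray(dout)[:, None])
        dz = self.fusion.backward(dz)
        dze, dzs = dz[:, :, : self._k2], dz[:, :, self._k2 :]
        dep = self.branch_ep.backward(np.ascontiguousarray(dze))
        dseq = self.branch_seq.backward(np.ascontiguousarray(dzs))
        return dep, dseq

    # -- user-facing -------------------------------------------------------

    def predict(self, ep: np.ndarray, seq: np.ndarray, batch: int = 256) -> np.ndarray:
        """Deterministic eval-mode predictions (dropout off, BN running stats)."""
        out = np.empty(ep.shape[0], dtype=_F32)
        for i in range(0, ep.shape[0], batch):
            out[i : i + batch] = self.forward(ep[i : i + batch], seq[i : i + batch], train=False)
        if self.cfg.task == "classification":
            out = 1.0 / (1.0 + np.exp(-out))
        return out

    def input_gradients(self, ep: np.ndarray, seq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """dF/d(epigenetic), dF/d(sequence), per sample, in eval mode."""
        self.forward(ep, seq, train=False)
        self.zero_grads()
        ones = np.ones(ep.shape[0], dtype=_F32)
        return self.backward(ones)


def build_model(cfg: ModelConfig, L: int, m: int, seed: int = 0) -> Model:
    """Construct an untrained model for input length L and m tracks."""
    return Model(cfg, L, m, seed=seed)


def loss(pred: np.ndarray, obs: np.ndarray, weights: list[np.ndarray] | None = None,
         lambda_l2: float = 0.0) -> float:
    """MSE plus L2 penalty: (1/N) sum (y - y')^2 + lambda * sum(W^2)."""
    pred = np.asarray(pred, dtype=np.float64)
    obs = np.asarray(obs, dtype=np.float64)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have equal length")
    if pred.size == 0:
        raise ValueError("loss undefined for empty vectors")
    mse = float(np.mean((pred - obs) ** 2))
    penalty = 0.0
    if lambda_l2 > 0 and weights:
        penalty = lambda_l2 * float(sum(np.sum(np.square(w, dtype=np.float64)) for w in weights))
    return mse + penalty


def save_model(model: Model, path, sidecar: dict | None = None) -> None:
    """Serialize weights (npz) plus a JSON sidecar so attribution runs are self-describing."""
    path = Path(path)
    state = model.get_weights()
    np.savez_compressed(path, *state)
    meta = {
        "model_config": model.cfg.to_dict(),
        "L": model.L,
        "m": model.m,
        "conv_padding": "zero, (l-1)//2 left and l//2 right (length-preserving)",
    }
    meta.update(sidecar or model.sidecar)
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_model(path) -> Model:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        meta = json.load(fh)
    cfg = ModelConfig.from_dict(meta["model_config"])
    model = Model(cfg, meta["L"], meta["m"])
    with np.load(path) as z:
        state = [z[k] for k in z.files]
    model.set_weights(state)
    model.sidecar = meta
    return model
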