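"""Training loop, evaluation metrics, and experiment drivers.

Training uses Adam on mini-batches of genes with an MSE + L2 loss, monitors
validation loss every epoch, and returns the weights of the best validation
epoch (early stopping).  Drivers cover the standard experiments: a
shuffled-expression negative control, single-modality ablations, and a scan
over candidate input-window combinations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import Model, ModelConfig, build_model
from .nn import Adam
from .preprocess import (
    GeneInput,
    RegionSpec,
    SplitDataset,
    as_arrays,
    assemble_dataset,
    build_trackset,
    split_dataset,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrainSpec",
    "EvalReport",
    "train",
    "evaluate",
    "shuffle_control",
    "ablation_run",
    "region_scan",
    "HYPERPARAMETER_GRID",
]

# The tuned search space: number of kernels, kernel length, L2 penalty, dropout.
HYPERPARAMETER_GRID = {
    "kernels": [16, 32, 64, 128],
    "kernel_length": [20, 50, 100],
    "lambda_l2": [0.0001, 0.01, 0.1, 1.0],
    "dropout": [0.1, 0.3, 0.5],
}


@dataclass(frozen=True)
class TrainSpec:
    """Optimization settings: 200 epochs, batch 100, Adam, early stopping."""

    epochs: int = 200
    batch: int = 100
    learning_rate: float = 1e-3
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience >= self.epochs:
            raise ValueError("patience must be smaller than epochs")


@dataclass
class EvalReport:
    """Test-set metrics: R^2 = 1 - SS_res/SS_tot and Pearson correlation."""

    r2: float
    pearson: float
    predictions: pd.DataFrame = field(repr=False)


def _bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    # numerically stable softplus form; gradient is (sigmoid(z) - y) / N
    z = logits.astype(np.float64)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = (1.0 / (1.0 + np.exp(-z)) - y) / z.size
    return loss, grad


def _batch_loss_grad(model: Model, ep, seq, y, lam) -> tuple[float, np.ndarray]:
    """Eval-mode loss of current weights on (ep, seq, y), without the L2 term."""
    pred = model.forward(ep, seq, train=False)
    if model.cfg.task == "classification":
        loss, _ = _bce_with_logits(pred, y)
        return loss, pred
    return float(np.mean((pred - y) ** 2)), pred


def train(model: Model, data: SplitDataset, spec: TrainSpec) -> tuple[Model, list[dict]]:
    """Fit the model; return it with the best-validation-epoch weights plus history.

    History has one record per epoch: train loss (MSE + L2 over the epoch's
    batches), validation loss, and whether the epoch improved.  Training stops
    once the validation loss has not improved for ``spec.patience`` epochs.
    """
    if not (data.train and data.validation):
        raise ValueError("train and validation splits must be non-empty")
    ep_tr, seq_tr, y_tr = as_arrays(data.train)
    ep_va, seq_va, y_va = as_arrays(data.validation)
    lam = model.cfg.lambda_l2
    # start the output at the training-target mean so the optimizer fits
    # structure, not the offset
    if model.cfg.task == "regression":
        out_bias = model.head.layers[-1].params["b"]
        if not out_bias.any():
            out_bias[...] = np.float32(y_tr.mean())
    rng = np.random.default_rng(spec.seed)
    drop_rng = np.random.default_rng(rng.integers(2**31))
    opt = Adam(model.param_handles(), lr=spec.learning_rate)
    n = len(y_tr)
    best_val = np.inf
    best_state: list[np.ndarray] | None = None
    best_epoch = -1
    history: list[dict] = []
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, spec.batch):
            idx = order[start : start + spec.batch]
            eb, sb, yb = ep_tr[idx], seq_tr[idx], y_tr[idx]
            pred = model.forward(eb, sb, train=True, rng=drop_rng)
            if model.cfg.task == "classification":
                batch_loss, dpred = _bce_with_logits(pred, yb)
            else:
                resid = pred.astype(np.float64) - yb
                batch_loss = float(np.mean(resid**2))
                dpred = 2.0 * resid / len(yb)
            if not np.isfinite(batch_loss):
                raise FloatingPointError(
                    f"non-finite training loss {batch_loss} at epoch {epoch}"
                )
            model.zero_grads()
            model.backward(dpred.astype(np.float32))
            if lam > 0:
                for layer, key in model.weight_handles():
                    layer.grads[key] += 2.0 * lam * layer.params[key]
                    batch_loss += lam * float(np.sum(np.square(layer.params[key], dtype=np.float64)))
            opt.step()
            epoch_loss += batch_loss * len(yb)
        val_loss, _ = _batch_loss_grad(model, ep_va, seq_va, y_va, lam)
        improved = val_loss < best_val
        if improved:
            best_val = val_loss
            best_state = model.get_weights()
            best_epoch = epoch
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / n,
                "val_loss": val_loss,
                "improved": improved,
            }
        )
        if epoch - best_epoch >= spec.patience:
            logger.info("early stop at epoch %d (best epoch %d)", epoch, best_epoch)
            break
    if best_state is not None:
        model.set_weights(best_state)
    return model, history


def evaluate(model: Model, genes: list[GeneInput]) -> EvalReport:
    """R^2 and Pearson correlation of predictions on the model's target scale."""
    if len(genes) < 3:
        raise ValueError("need at least 3 genes to evaluate")
    ep, seq, y = as_arrays(genes)
    pred = model.predict(ep, seq).astype(np.float64)
    y = y.astype(np.float64)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observations are constant; R^2 undefined")
    if np.all(pred == pred[0]):
        raise ValueError("predictions are constant; Pearson undefined")
    ss_res = float(np.sum((y - pred) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    pearson = float(stats.pearsonr(y, pred).statistic)
    table = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes], "observed": y, "predicted": pred}
    )
    return EvalReport(r2=r2, pearson=pearson, predictions=table)


def shuffle_control(data: SplitDataset, spec: TrainSpec, cfg: ModelConfig,
                    seed: int = 0) -> EvalReport:
    """Negative control: permute expression targets across all genes, retrain, evaluate.

    A model trained on shuffled targets should score near zero R^2 on the test
    set; anything else indicates leakage.
    """
    rng = np.random.default_rng(seed)
    all_genes = data.train + data.validation + data.test
    targets = np.array([g.target for g in all_genes])
    perm = rng.permutation(len(targets))
    shuffled = [_replace_target(g, float(t)) for g, t in zip(all_genes, targets[perm])]
    n_tr, n_va = len(data.train), len(data.validation)
    sdata = SplitDataset(
        train=shuffled[:n_tr],
        validation=shuffled[n_tr : n_tr + n_va],
        test=shuffled[n_tr + n_va :],
        fractions=data.fractions,
        seed=data.seed,
    )
    model = build_model(cfg, L=sdata.train[0].epigenetic.shape[0],
                        m=sdata.train[0].epigenetic.shape[1], seed=spec.seed)
    model, _ = train(model, sdata, spec)
    return evaluate(model, sdata.test)


def _replace_target(g: GeneInput, target: float) -> GeneInput:
    return GeneInput(
        gene_id=g.gene_id, epigenetic=g.epigenetic, sequence=g.sequence,
        target=target, tpm=g.tpm, chrom=g.chrom, coords=g.coords, strand=g.strand,
    )


def _mask_inputs(genes: list[GeneInput], track_names: list[str],
                 keep: set[str]) -> list[GeneInput]:
    """Zero the modalities not in ``keep`` ('sequence' keeps the sequence branch)."""
    keep_seq = "sequence" in keep
    keep_tracks = keep - {"sequence"}
    unknown = keep_tracks - set(track_names)
    if unknown:
        raise ValueError(f"unknown track name(s): {sorted(unknown)}")
    col = np.array([name in keep_tracks for name in track_names])
    out = []
    for g in genes:
        ep = g.epigenetic * col[None, :].astype(np.float32)
        seq = g.sequence if keep_seq else np.zeros_like(g.sequence)
        out.append(GeneInput(
            gene_id=g.gene_id, epigenetic=ep, sequence=seq, target=g.target,
            tpm=g.tpm, chrom=g.chrom, coords=g.coords, strand=g.strand,
        ))
    return out


def ablation_run(data: SplitDataset, track_names: list[str],
                 conditions: dict[str, set[str]], spec: TrainSpec,
                 cfg: ModelConfig) -> dict[str, EvalReport]:
    """Retrain with only a subset of modalities live, one model per condition.

    ``conditions`` maps a label to the set of modalities to keep (track names
    and/or 'sequence'); everything else is zeroed in train, validation and
    test inputs alike.
    """
    reports: dict[str, EvalReport] = {}
    for label, keep in conditions.items():
        if not keep:
            raise ValueError(f"condition {label!r}: keep set is empty")
        sdata = SplitDataset(
            train=_mask_inputs(data.train, track_names, keep),
            validation=_mask_inputs(data.validation, track_names, keep),
            test=_mask_inputs(data.test, track_names, keep),
            fractions=data.fractions,
            seed=data.seed,
        )
        model = build_model(cfg, L=sdata.train[0].epigenetic.shape[0],
                            m=sdata.train[0].epigenetic.shape[1], seed=spec.seed)
        model, _ = train(model, sdata, spec)
        reports[label] = evaluate(model, sdata.test)
    return reports


def region_scan(genes, raw_tracks, genome, candidate_specs: list[RegionSpec],
                spec: TrainSpec, cfg: ModelConfig, split_seed: int = 0,
                target_transform: str = "log1p") -> pd.DataFrame:
    """Train and evaluate one model per candidate window combination.

    Returns a table (one row per RegionSpec) sorted by test R^2, descending —
    the driver behind choosing the input-window combination.
    """
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    rows = []
    for i, rspec in enumerate(candidate_specs):
        tracks = build_trackset(raw_tracks, chrom_lengths, genes, rspec)
        inputs = assemble_dataset(genes, tracks, genome, rspec, target_transform)
        data = split_dataset(inputs, seed=split_seed)
        model = build_model(cfg, L=rspec.length, m=tracks.m, seed=spec.seed)
        model, _ = train(model, data, spec)
        report = evaluate(model, data.test)
        rows.append({
            "spec_index": i,
            "tss_up": rspec.tss_up, "tss_down": rspec.tss_down,
            "tts_up": rspec.tts_up, "tts_down": rspec.tts_down,
            "L": rspec.length,
            "test_r2": report.r2, "test_pearson": report.pearson,
        })
    return pd.DataFrame(rows).sort_values("test_r2", ascending=False).reset_index(drop=True)
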