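"""Losses, evaluation metrics, training loop and checkpointing.

The decoder is scored with masked cross-entropy; perplexity is always the
exponential of the unsmoothed mean per-residue negative log-likelihood over
scored positions, so a uniform predictor over the 20-letter vocabulary has
perplexity exactly 20.  Recovery is the percentage of argmax predictions
matching the native residue at scored positions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import nn
from .model import ModelConfig, N_CLASSES, ProteinFeatures, SurfFoldModel, build_model

logger = logging.getLogger(__name__)

__all__ = [
    "EvalMetrics",
    "TrainConfig",
    "loss_and_perplexity",
    "recovery",
    "relative_difference",
    "train",
    "evaluate",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class EvalMetrics:
    perplexity: float
    recovery: float  # percent
    n_residues: int

    def __post_init__(self):
        if self.n_residues > 0:
            assert self.perplexity >= 1.0 - 1e-9
            assert -1e-9 <= self.recovery <= 100.0 + 1e-9


def loss_and_perplexity(
    logits: nn.Tensor,
    native: np.ndarray,
    mask: np.ndarray | None = None,
    label_smoothing: float = 0.0,
) -> tuple[nn.Tensor, float]:
    """Masked cross-entropy loss and unsmoothed perplexity.

    ``native`` holds integer class codes; positions with ``mask`` False (or
    code < 0) are excluded.  The returned loss carries the autodiff tape; the
    perplexity is a plain float computed without label smoothing.
    """
    native = np.asarray(native)
    if logits.shape[0] != native.shape[0]:
        raise ValueError("logits and native lengths differ")
    mask = np.ones(len(native), dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    mask = mask & (native >= 0)
    if not mask.any():
        raise ValueError("all positions are masked out")
    idx = np.flatnonzero(mask)
    logp = nn.log_softmax(nn.take_rows(logits, idx), axis=-1)

    n = len(idx)
    onehot = np.zeros((n, N_CLASSES))
    onehot[np.arange(n), native[idx]] = 1.0
    target = onehot
    if label_smoothing > 0.0:
        target = (1.0 - label_smoothing) * onehot + label_smoothing / N_CLASSES
    loss = -(logp * nn.Tensor(target)).sum() * (1.0 / n)

    nll = -logp.data[np.arange(n), native[idx]].mean()
    return loss, float(np.exp(nll))


def recovery(predicted: np.ndarray, native: np.ndarray,
             mask: np.ndarray | None = None) -> float:
    """Percent of scored positions where the prediction matches the native code."""
    predicted = np.asarray(predicted)
    native = np.asarray(native)
    if predicted.shape != native.shape:
        raise ValueError("length mismatch")
    mask = np.ones(len(native), dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    mask = mask & (native >= 0)
    if not mask.any():
        raise ValueError("all positions are masked out")
    return 100.0 * float((predicted[mask] == native[mask]).mean())


def relative_difference(pred_identity: float, native_identity: float) -> float:
    """(predicted identity - native identity) / native identity."""
    if native_identity == 0:
        raise ValueError("relative difference undefined for zero native identity")
    return (pred_identity - native_identity) / native_identity


# ------------------------------------------------------------------ training
@dataclass
class TrainConfig:
    epochs: int = 200
    lr: float = 1e-3
    label_smoothing: float = 0.0
    grad_clip: float | None = None
    seed: int = 0
    checkpoint_path: str | None = None
    log_path: str | None = None
    log_every: int = 10
    lr_schedule: str = "constant"  # or "cosine"
    stop_at_recovery: float | None = None  # early stop once training recovery (%) reaches this

    def __post_init__(self):
        if self.epochs < 1 or self.lr <= 0:
            raise ValueError("epochs must be >= 1 and lr > 0")


def _epoch_lr(config: TrainConfig, epoch: int) -> float:
    if config.lr_schedule == "cosine":
        return config.lr * 0.5 * (1.0 + np.cos(np.pi * epoch / max(config.epochs - 1, 1)))
    return config.lr


def train(
    model: SurfFoldModel,
    dataset: Sequence[ProteinFeatures],
    config: TrainConfig,
    optimizer: nn.Adam | None = None,
    start_epoch: int = 0,
    rng_state: dict | None = None,
) -> dict:
    """Full-batch Adam training; seeded and resumable.

    Each epoch runs every protein forward, averages the residue-weighted
    cross-entropy, backpropagates once and takes one optimizer step.  Returns
    a history dict with per-epoch loss, perplexity and training recovery.
    """
    if not dataset:
        raise ValueError("empty dataset")
    if optimizer is None:
        optimizer = nn.Adam(model.parameters(), lr=config.lr, grad_clip=config.grad_clip)
    rng = np.random.default_rng(config.seed)
    if rng_state is not None:
        rng.bit_generator.state = rng_state

    history: dict = {"loss": [], "perplexity": [], "recovery": []}
    log_fh = open(config.log_path, "a") if config.log_path else None
    try:
        for epoch in range(start_epoch, config.epochs):
            optimizer.lr = _epoch_lr(config, epoch)
            model.zero_grad()
            total_loss = None
            total_res = 0
            nll_sum = 0.0
            match = 0
            for feats in dataset:
                logits = model(feats, training=True, rng=rng)
                loss, ppl = loss_and_perplexity(
                    logits, feats.labels, feats.mask,
                    label_smoothing=config.label_smoothing,
                )
                n = int(feats.mask.sum())
                weighted = loss * float(n)
                total_loss = weighted if total_loss is None else total_loss + weighted
                total_res += n
                nll_sum += np.log(ppl) * n
                pred = logits.data.argmax(axis=1)
                match += int((pred[feats.mask] == feats.labels[feats.mask]).sum())
            total_loss = total_loss * (1.0 / total_res)
            if not np.isfinite(total_loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {total_loss.data}"
                )
            total_loss.backward()
            optimizer.step()

            epoch_loss = float(total_loss.data)
            epoch_ppl = float(np.exp(nll_sum / total_res))
            epoch_rec = 100.0 * match / total_res
            history["loss"].append(epoch_loss)
            history["perplexity"].append(epoch_ppl)
            history["recovery"].append(epoch_rec)
            record = {"epoch": epoch, "loss": epoch_loss,
                      "perplexity": epoch_ppl, "recovery": epoch_rec}
            if log_fh:
                log_fh.write(json.dumps(record) + "\n")
            if epoch % config.log_every == 0:
                logger.info("epoch %d: loss %.4f ppl %.3f rec %.1f%%",
                            epoch, epoch_loss, epoch_ppl, epoch_rec)
            if config.stop_at_recovery is not None and epoch_rec >= config.stop_at_recovery:
                break
    finally:
        if log_fh:
            log_fh.close()

    if config.checkpoint_path:
        save_checkpoint(config.checkpoint_path, model, optimizer,
                        epoch=config.epochs, rng=rng, history=history)
    history["rng_state"] = rng.bit_generator.state
    history["optimizer"] = optimizer
    return history


def _ckpt_paths(path: str | Path) -> tuple[str, str]:
    base = str(path)
    npz = base if base.endswith(".npz") else base + ".npz"
    return npz, base + ".json"


def save_checkpoint(path: str | Path, model: SurfFoldModel, optimizer: nn.Adam,
                    epoch: int, rng: np.random.Generator, history: dict | None = None) -> None:
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_dict())}
    arrays.update({f"adam_m_{i}": m for i, m in enumerate(optimizer.m)})
    arrays.update({f"adam_v_{i}": v for i, v in enumerate(optimizer.v)})
    meta = {
        "epoch": epoch,
        "adam_t": optimizer.t,
        "rng_state": rng.bit_generator.state,
        "n_params": len(model.parameters()),
        "history": {k: v for k, v in (history or {}).items()
                    if isinstance(v, list)},
    }
    npz_path, json_path = _ckpt_paths(path)
    np.savez(npz_path, **arrays)
    Path(json_path).write_text(json.dumps(meta))


def load_checkpoint(path: str | Path, model: SurfFoldModel,
                    lr: float = 1e-3) -> tuple[nn.Adam, int, dict]:
    """Restore model + optimizer state; returns (optimizer, epoch, rng_state)."""
    npz_path, json_path = _ckpt_paths(path)
    data = np.load(npz_path)
    meta = json.loads(Path(json_path).read_text())
    n = meta["n_params"]
    model.load_state_dict([data[f"param_{i}"] for i in range(n)])
    optimizer = nn.Adam(model.parameters(), lr=lr)
    optimizer.t = meta["adam_t"]
    optimizer.m = [data[f"adam_m_{i}"].copy() for i in range(n)]
    optimizer.v = [data[f"adam_v_{i}"].copy() for i in range(n)]
    return optimizer, meta["epoch"], meta["rng_state"]


# ---------------------------------------------------------------- evaluation
def evaluate(
    model: SurfFoldModel,
    dataset: Sequence[ProteinFeatures],
    split_spec: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, dict]:
    """Metrics per split: pooled (residue-weighted) and per-protein averages.

    ``split_spec`` maps split names to protein identifiers; ``None`` scores
    everything as a single split named "all".  Empty splits are flagged and
    skipped.
    """
    by_id = {f.identifier: f for f in dataset}
    if split_spec is None:
        split_spec = {"all": list(by_id)}
    results: dict[str, dict] = {}
    for split, ids in split_spec.items():
        members = [by_id[i] for i in ids if i in by_id]
        if not members:
            logger.warning("split %r is empty; skipped", split)
            results[split] = {"skipped": True}
            continue
        nll_sum = 0.0
        match = 0
        total = 0
        per_protein = {}
        for feats in members:
            logits = model(feats, training=False)
            _, ppl = loss_and_perplexity(logits, feats.labels, feats.mask)
            pred = logits.data.argmax(axis=1)
            rec = recovery(pred, feats.labels, feats.mask)
            n = int(feats.mask.sum())
            per_protein[feats.identifier] = EvalMetrics(ppl, rec, n)
            nll_sum += np.log(ppl) * n
            match += int(round(rec / 100.0 * n))
            total += n
        pooled = EvalMetrics(float(np.exp(nll_sum / total)), 100.0 * match / total, total)
        results[split] = {
            "pooled": pooled,
            "mean_per_protein_recovery": float(
                np.mean([m.recovery for m in per_protein.values()])
            ),
            "per_protein": per_protein,
        }
    return results
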