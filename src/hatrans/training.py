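"""Optimization recipe and the fit/evaluate surface.

AdamW with decoupled weight decay; learning-rate schedule = linear warmup,
cosine annealing, plus optional multiplicative ×0.1 drops at the milestone
epochs (the published recipe describes both annealing and step reductions;
both are implemented and independently switchable).  Training is fully
seeded: data order, augmentation draws and parameter initialization are all
functions of the configured seeds.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from ._tensor import Parameter
from .branches import HATrans
from .config import LossWeights, ModelConfig, TrainConfig
from .evaluation import MetricsReport, clinical_panel, predict_labels, subset_accuracy
from .objectives import bce_loss, combined_loss, sigmoid, triplet_loss
from .synthetic import normalize_images

__all__ = ["build_schedule", "AdamW", "fit", "evaluate", "FitResult",
           "save_checkpoint", "load_checkpoint", "augment_batch"]


def build_schedule(config: TrainConfig) -> np.ndarray:
    """Per-epoch learning rates, length ``total_epochs``.

    Warmup epoch e (0-based) runs at lr·(e+1)/warmup; afterwards the rate
    follows cosine annealing to 0 over the remaining epochs, times an extra
    ``milestone_factor`` for every milestone epoch already passed.
    """
    lrs = np.empty(config.total_epochs)
    w, total = config.warmup_epochs, config.total_epochs
    for e in range(total):
        if e < w:
            lr = config.lr * (e + 1) / w
        else:
            if config.use_cosine:
                progress = (e - w) / max(total - w, 1)
                lr = config.lr * 0.5 * (1.0 + np.cos(np.pi * progress))
            else:
                lr = config.lr
            if config.use_milestones:
                drops = sum(1 for m in config.milestone_epochs if e >= m)
                lr *= config.milestone_factor**drops
        lrs[e] = lr
    return lrs


class AdamW(object):
    """AdamW with decoupled weight decay on the raw parameters."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.05):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            m_hat = self._m[i] / (1 - b1**self._t)
            v_hat = self._v[i] / (1 - b2**self._t)
            p.data = p.data - self.lr * (m_hat / (np.sqrt(v_hat) + self.eps)
                                         + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def augment_batch(images: np.ndarray, config: TrainConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Random pad-and-crop, horizontal flip (p=0.5) and colour jitter on a
    batch of [0,1] images."""
    out = np.array(images, dtype=np.float64, copy=True)
    b, h, w, _ = out.shape
    pad = config.crop_padding
    if config.augment_random_crop and pad > 0:
        padded = np.pad(out, ((0, 0), (pad, pad), (pad, pad), (0, 0)),
                        mode="reflect")
        offs = rng.integers(0, 2 * pad + 1, size=(b, 2))
        out = np.stack([padded[i, r:r + h, c:c + w]
                        for i, (r, c) in enumerate(offs)])
    if config.augment_horizontal_flip:
        flips = rng.random(b) < 0.5
        out[flips] = out[flips, :, ::-1]
    if config.augment_color_jitter:
        s = config.color_jitter_strength
        bright = rng.uniform(1 - s, 1 + s, size=(b, 1, 1, 1))
        contrast = rng.uniform(1 - s, 1 + s, size=(b, 1, 1, 1))
        sat = rng.uniform(1 - s, 1 + s, size=(b, 1, 1, 1))
        out = out * bright
        mean = out.mean(axis=(1, 2, 3), keepdims=True)
        out = (out - mean) * contrast + mean
        gray = out.mean(axis=3, keepdims=True)
        out = (out - gray) * sat + gray
    return np.clip(out, 0.0, 1.0)


@dataclass
class FitResult:
    """Results object returned by :func:`fit`.

    Carries the trained model, the per-epoch history (losses, learning rate,
    holdout subset accuracy), the best-by-subset-accuracy parameter state and
    a ``summary()`` table; ``evaluate`` scores a labelled image set with the
    full clinical panel.
    """

    model: HATrans
    history: pd.DataFrame
    best_state: dict[str, np.ndarray]
    best_epoch: int
    best_holdout_subset_accuracy: float
    train_config: TrainConfig

    def evaluate(self, images: np.ndarray, labels: np.ndarray,
                 use_best: bool = True, **kwargs) -> MetricsReport:
        if use_best:
            self.model.load_state_dict(self.best_state)
        return evaluate(self.model, images, labels, **kwargs)

    def summary(self) -> str:
        cfg = self.model.config
        last = self.history.iloc[-1]
        buf = io.StringIO()
        print("Hierarchical attention transformer — fit summary", file=buf)
        print("=" * 52, file=buf)
        print(f"variant: {cfg.variant}  depth={cfg.depth}  dim={cfg.embed_dim}  "
              f"heads={cfg.num_heads}  patches={cfg.num_patches}", file=buf)
        print(f"branches: region={cfg.use_region_branch}  "
              f"patch={cfg.use_patch_branches}  "
              f"contrastive={cfg.use_contrastive}", file=buf)
        print(f"epochs run: {len(self.history)}   "
              f"final L={last['loss_total']:.4f} "
              f"(LB={last['loss_bce']:.4f}, LT={last['loss_triplet']:.4f})", file=buf)
        print(f"best holdout subset accuracy: "
              f"{self.best_holdout_subset_accuracy:.4f} "
              f"(epoch {self.best_epoch})", file=buf)
        return buf.getvalue()


def fit(model: HATrans, images: np.ndarray, labels: np.ndarray,
        config: TrainConfig, holdout: tuple[np.ndarray, np.ndarray] | None = None,
        stop_at_subset_accuracy: float | None = None,
        log_stream=None) -> FitResult:
    """Mini-batch training of the combined objective L = λB·LB + λT·LT.

    ``images`` are raw [0,1] pixels; augmentation (if enabled) and
    normalization happen inside the loop.  ``holdout`` overrides the
    internal holdout split (pass the training set itself to monitor training
    accuracy).  ``stop_at_subset_accuracy`` ends training early once the
    monitored subset accuracy reaches the given level.
    """
    rng = np.random.default_rng(config.seed)
    images = np.asarray(images, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    n = images.shape[0]

    if holdout is None and config.holdout_fraction > 0 and n >= 5:
        n_hold = max(1, int(round(config.holdout_fraction * n)))
        perm = rng.permutation(n)
        hold_idx, train_idx = perm[:n_hold], perm[n_hold:]
        holdout = (images[hold_idx], labels[hold_idx])
        images, labels = images[train_idx], labels[train_idx]
        n = images.shape[0]
    elif holdout is None:
        holdout = (images, labels)

    weights = model.config.loss_weights
    schedule = build_schedule(config)
    optimizer = AdamW(model.parameters(), lr=config.lr,
                      betas=(config.beta1, config.beta2),
                      weight_decay=config.weight_decay)

    records = []
    best_state = model.state_dict()
    best_acc, best_epoch = -1.0, -1
    triplet_active = (model.config.use_contrastive
                      and model._patch_branches_active)
    for epoch in range(config.total_epochs):
        optimizer.lr = schedule[epoch]
        order = rng.permutation(n)
        lb_sum = lt_sum = total_sum = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = images[idx]
            if (config.augment_random_crop or config.augment_horizontal_flip
                    or config.augment_color_jitter):
                batch = augment_batch(batch, config, rng)
            out = model.forward(normalize_images(batch))
            probs = sigmoid(out.logits)
            lb = bce_loss(labels[idx], probs)
            if triplet_active and out.embeddings.z_fore is not None:
                lt = triplet_loss(out.embeddings, margin=weights.margin,
                                  orientation=model.config.triplet_orientation)
            else:
                lt = bce_loss(labels[idx], probs) * 0.0  # inert placeholder
            loss = combined_loss(lb, lt, weights,
                                 use_contrastive=model.config.use_contrastive)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch indices {idx[:8]}: "
                    f"LB={lb.data}, LT={lt.data}")
            model.zero_grad()
            loss.backward()
            optimizer.step()
            lb_sum += float(lb.data)
            lt_sum += float(lt.data)
            total_sum += float(loss.data)
            n_batches += 1

        hold_probs = model.predict_proba(normalize_images(holdout[0]))
        hold_acc = subset_accuracy(holdout[1], predict_labels(hold_probs))
        rec = {"epoch": epoch, "lr": schedule[epoch],
               "loss_bce": lb_sum / n_batches, "loss_triplet": lt_sum / n_batches,
               "loss_total": total_sum / n_batches,
               "holdout_subset_accuracy": hold_acc}
        records.append(rec)
        if log_stream is not None:
            print("\t".join(f"{rec[k]:.6g}" if k != "epoch" else str(rec[k])
                            for k in rec), file=log_stream, flush=True)
        if hold_acc > best_acc:
            best_acc, best_epoch = hold_acc, epoch
            best_state = model.state_dict()
        if (stop_at_subset_accuracy is not None
                and hold_acc >= stop_at_subset_accuracy):
            break

    history = pd.DataFrame.from_records(records)
    return FitResult(model=model, history=history, best_state=best_state,
                     best_epoch=best_epoch, best_holdout_subset_accuracy=best_acc,
                     train_config=config)


def evaluate(model: HATrans, images: np.ndarray, labels: np.ndarray,
             threshold: float = 0.5, label_names=None,
             roc_points: bool = False) -> MetricsReport:
    """Deterministic (no augmentation) evaluation with the clinical panel."""
    if images.shape[1] != model.config.image_size:
        raise ValueError(
            f"checkpoint expects {model.config.image_size}px images, "
            f"data is {images.shape[1]}px")
    probs = model.predict_proba(normalize_images(images))
    preds = predict_labels(probs, threshold)
    return clinical_panel(labels, preds, probs, label_names=label_names,
                          roc_points=roc_points)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

_CKPT_VERSION = 1


def save_checkpoint(model: HATrans, path, meta: dict | None = None) -> None:
    """Versioned checkpoint: every learnable parameter plus the model config."""
    cfg = asdict(model.config)
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    payload["__meta__"] = np.frombuffer(json.dumps({
        "version": _CKPT_VERSION, "config": cfg, "meta": meta or {},
    }).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[HATrans, dict]:
    """Rebuild the model (architecture from the stored config) and load all
    parameters; returns (model, meta)."""
    with np.load(path) as data:
        header = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
    cfg_dict = dict(header["config"])
    lw = cfg_dict.pop("loss_weights", None)
    cfg = ModelConfig(**cfg_dict)
    if lw:
        cfg.loss_weights = LossWeights(**lw)
    model = HATrans(cfg, rng=0)
    model.load_state_dict(state)
    return model, header.get("meta", {})
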