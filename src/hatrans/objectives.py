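"""Training objectives: binary cross-entropy over the k labels, a
cosine-similarity triplet loss over the three branch embeddings, and their
weighted combination L = λB·LB + λT·LT.

All operations accept either autodiff :class:`~hatrans._tensor.Tensor`
inputs (returning a Tensor on the graph) or plain arrays (returning floats),
so the same code serves training and the test oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor
from .config import LossWeights

__all__ = ["bce_loss", "cosine_similarity", "triplet_loss", "combined_loss",
           "BranchEmbeddings", "PROB_EPS"]

#: probabilities are clipped to [ε, 1−ε] before the logarithms
PROB_EPS = 1e-7


@dataclass
class BranchEmbeddings:
    """Final class-token features of the three branches.

    ``z_region`` anchors the triplet (it is also the classifier input);
    ``z_fore``/``z_back`` come from the foreground/background sub-branches.
    """

    z_region: Tensor
    z_fore: Tensor | None
    z_back: Tensor | None


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def bce_loss(y_true, y_prob) -> Tensor:
    """Mean over batch and labels of −[y·log p + (1−y)·log(1−p)].

    Probabilities are clipped to [ε, 1−ε] with ε=1e-7 so exact 0/1 inputs
    stay finite.  Averaging over the k labels (not just the batch) keeps the
    meaning of λB independent of batch size and label count.
    """
    y = _wrap(y_true)
    p = _wrap(y_prob).clip(PROB_EPS, 1.0 - PROB_EPS)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {p.shape}")
    term = y * p.log() + (1.0 - y) * (1.0 - p).log()
    return -term.mean()


def cosine_similarity(u, v) -> Tensor:
    """Row-wise cosine similarity u·v / (‖u‖‖v‖) ∈ [−1, 1].

    Accepts single vectors or B×D batches.  A zero vector has undefined
    direction; its similarity is defined as 0 (with a warning).
    """
    u, v = _wrap(u), _wrap(v)
    squeeze = u.ndim == 1
    if squeeze:
        u, v = u.reshape(1, -1), v.reshape(1, -1)
    nu = (u * u).sum(axis=-1)
    nv = (v * v).sum(axis=-1)
    degenerate = (nu.data == 0) | (nv.data == 0)
    if degenerate.any():
        warnings.warn("cosine similarity of a zero vector defined as 0",
                      RuntimeWarning, stacklevel=2)
    denom = ((nu * nv) + 1e-300) ** 0.5
    sim = (u * v).sum(axis=-1) / denom
    if degenerate.any():
        sim = sim * (~degenerate).astype(np.float64)
    return sim[0] if squeeze else sim


def triplet_loss(embeddings: BranchEmbeddings, margin: float = 0.3,
                 orientation: str = "conventional") -> Tensor:
    """Per-sample cosine triplet hinge, averaged over the batch.

    ``orientation="conventional"`` (default): max(sim(zR,zB) − sim(zR,zF) + α, 0)
    — pulls the foreground embedding toward the region anchor and pushes the
    background away, which is what the foreground branch's parameter sharing
    is for.  ``orientation="as_printed"``: max(sim(zR,zF) − sim(zR,zB) + α, 0),
    the literal published operand order (apparent sign inconsistency with the
    surrounding motivation; kept selectable rather than silently corrected).
    """
    if embeddings.z_fore is None or embeddings.z_back is None:
        raise ValueError("triplet loss requires both sub-branch embeddings")
    sim_f = cosine_similarity(embeddings.z_region, embeddings.z_fore)
    sim_b = cosine_similarity(embeddings.z_region, embeddings.z_back)
    if orientation == "conventional":
        gap = sim_b - sim_f
    elif orientation == "as_printed":
        gap = sim_f - sim_b
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return (gap + margin).relu().mean()


def combined_loss(lb, lt, weights: LossWeights,
                  use_contrastive: bool = True) -> Tensor:
    """L = λB·LB + λT·LT; with the contrastive ablation off, λT acts as 0."""
    lam_t = weights.lambda_triplet if use_contrastive else 0.0
    return _wrap(lb) * weights.lambda_bce + _wrap(lt) * lam_t


def sigmoid(x):
    """Numerically stable logistic function on arrays or Tensors."""
    if isinstance(x, Tensor):
        return 1.0 / (1.0 + (-x).exp())
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
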