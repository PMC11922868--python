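"""Region-recognition branch: accumulate per-layer attention by Hadamard
product, score patch tokens by the diagonal of the accumulated map, and
threshold the scores into complementary foreground/background partitions.

The mask computation is non-differentiable by construction (tokens are
routed, not re-weighted), so everything here operates on plain NumPy arrays;
:func:`split_tokens` is the only operation that touches the autodiff graph,
via index gathering on the encoded token tensor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, concat
from .config import ModelConfig

__all__ = ["reduce_heads", "accumulate_attention", "importance_scores",
           "threshold_mask", "split_tokens", "ForegroundPartition"]


@dataclass
class ForegroundPartition:
    """Foreground/background split of the N patch tokens of each sample.

    ``foreground_indices``/``background_indices`` hold 1-based token indices
    (the class token is index 0 and is never partitioned); ``mask_f`` and
    ``mask_b`` are B×N over patch tokens in patch order and satisfy
    ``mask_b = 1 - mask_f`` with both partitions non-empty.
    """

    scores: np.ndarray          # B×N diagonal importance scores g
    tau: np.ndarray             # per-sample threshold, shape B
    mask_f: np.ndarray          # B×N binary foreground mask
    mask_b: np.ndarray          # B×N binary background mask
    foreground_indices: list[np.ndarray]
    background_indices: list[np.ndarray]


def _as_array(maps) -> np.ndarray:
    if isinstance(maps, Tensor):
        return maps.data
    if isinstance(maps, (list, tuple)):
        return np.stack([m.data if isinstance(m, Tensor) else np.asarray(m)
                         for m in maps])
    return np.asarray(maps, dtype=np.float64)


def reduce_heads(stack) -> np.ndarray:
    """Average the head axis of an L×B×heads×T×T attention stack.

    The mean of row-stochastic maps is row-stochastic, so each layer map
    stays a probability distribution over keys.
    """
    arr = _as_array(stack)
    if arr.ndim != 5:
        raise ValueError(f"expected L×B×heads×T×T stack, got shape {arr.shape}")
    return arr.mean(axis=2)


def accumulate_attention(layer_maps) -> np.ndarray:
    """Element-wise (Hadamard) product of the L head-reduced layer maps.

    Am = A_0 ⊙ A_1 ⊙ … ⊙ A_{L-1}; no identity/residual mixing is added,
    unlike classic attention rollout.
    """
    arr = _as_array(layer_maps)
    if arr.ndim != 4:
        raise ValueError(f"expected L×B×T×T maps, got shape {arr.shape}")
    if arr.shape[0] == 0:
        raise ValueError("cannot accumulate an empty stack of attention maps")
    return np.prod(arr, axis=0)


def importance_scores(accumulated: np.ndarray) -> np.ndarray:
    """Diagonal self-attention scores of the patch tokens.

    Returns g of shape B×N where g[i] = Am[i+1, i+1]; the class-token
    diagonal entry is excluded — the class token is the classification
    anchor and always routes to the foreground sub-branch.
    """
    am = _as_array(accumulated)
    diag = np.diagonal(am, axis1=-2, axis2=-1)
    return np.ascontiguousarray(diag[..., 1:])


def threshold_mask(scores: np.ndarray, policy: str = "median",
                   tau: float | None = None) -> ForegroundPartition:
    """Threshold importance scores into foreground/background masks.

    Strict comparison as defined: MF[i] = 1 iff g[i] > τ, MB = 1 − MF.
    ``policy="median"`` sets τ per sample to the median of g (keeps both
    partitions populated across scales, since products of L stochastic maps
    shrink toward zero); ``policy="fixed"`` uses the global ``tau``.
    Degenerate-input rule: an empty foreground is repaired by promoting the
    single top-scoring token (lowest index on ties); an empty background
    symmetrically by demoting the single bottom-scoring token.
    """
    g = np.asarray(scores, dtype=np.float64)
    if g.ndim == 1:
        g = g[None, :]
    b, n = g.shape
    if n < 2:
        raise ValueError("need at least 2 patch tokens to form two partitions")
    if policy == "median":
        tau_vec = np.median(g, axis=1)
    elif policy == "fixed":
        if tau is None:
            raise ValueError("fixed policy requires tau")
        tau_vec = np.full(b, float(tau))
    else:
        raise ValueError(f"unknown threshold policy {policy!r}")

    mask_f = (g > tau_vec[:, None]).astype(np.int64)
    for i in range(b):
        if mask_f[i].sum() == 0:
            mask_f[i, int(np.argmax(g[i]))] = 1
        elif mask_f[i].sum() == n:
            mask_f[i, int(np.argmin(g[i]))] = 0
    mask_b = 1 - mask_f
    fg_idx = [np.flatnonzero(mask_f[i]) + 1 for i in range(b)]
    bg_idx = [np.flatnonzero(mask_b[i]) + 1 for i in range(b)]
    return ForegroundPartition(scores=g, tau=tau_vec, mask_f=mask_f,
                               mask_b=mask_b, foreground_indices=fg_idx,
                               background_indices=bg_idx)


def compute_partition(attention_stack, config: ModelConfig) -> ForegroundPartition:
    """Full region-branch pipeline: reduce heads → accumulate → score → mask."""
    layer_maps = reduce_heads(attention_stack)
    am = accumulate_attention(layer_maps)
    g = importance_scores(am)
    tau = config.threshold_value if config.threshold_policy == "fixed" else None
    return threshold_mask(g, policy=config.threshold_policy, tau=tau)


def _gather_padded(tokens: Tensor, index_lists: list[np.ndarray],
                   lead: Tensor) -> tuple[Tensor, np.ndarray]:
    """Gather per-sample ragged token subsets, prepending ``lead`` (B×1×D) at
    position 0, padding ragged tails (mask False ⇒ zero attention weight)."""
    b = tokens.shape[0]
    lengths = np.array([len(ix) for ix in index_lists])
    width = int(lengths.max()) if b else 0
    index = np.zeros((b, width), dtype=np.int64)
    key_mask = np.zeros((b, width + 1), dtype=bool)
    key_mask[:, 0] = True
    for i, ix in enumerate(index_lists):
        index[i, :len(ix)] = ix
        key_mask[i, 1:1 + len(ix)] = True
    gathered = tokens.take_tokens(index)
    return concat([lead, gathered], axis=1), key_mask


def split_tokens(tokens: Tensor, partition: ForegroundPartition,
                 background_cls: Tensor):
    """Route patch tokens into the two sub-branch input sequences.

    Foreground sequence: [main class token; foreground patch tokens in
    original order].  Background sequence: [independent learnable background
    class token; background patch tokens in original order].  Ragged lengths
    across the batch are padded; the returned boolean key masks give padded
    positions zero attention weight downstream.

    Returns ``(fg_tokens, fg_mask, bg_tokens, bg_mask)``.
    """
    b, t, d = tokens.shape
    n = partition.mask_f.shape[1]
    if t != n + 1:
        raise ValueError(f"token count {t} inconsistent with partition over {n} patches")
    main_cls = tokens[:, 0:1, :]
    fg_tokens, fg_mask = _gather_padded(tokens, partition.foreground_indices, main_cls)
    bg_lead = background_cls.reshape(1, 1, d) * np.ones((b, 1, 1))
    bg_tokens, bg_mask = _gather_padded(tokens, partition.background_indices, bg_lead)
    return fg_tokens, fg_mask, bg_tokens, bg_mask
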