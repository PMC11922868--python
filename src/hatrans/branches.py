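"""Patch-recognition sub-branches and the full hierarchical model.

The foreground sub-branch re-runs the *same* encoder layers (shared
parameter objects, not copies) on the foreground token subset; the
background sub-branch is an architecturally identical twin with its own
independently initialized parameters and its own learnable class token.
The classifier consumes the main branch's final class-token feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Parameter, Tensor, concat, no_grad
from .backbone import EncoderStack, ViTBackbone, patchify, _trunc_normal
from .config import ModelConfig
from .objectives import BranchEmbeddings
from .region import ForegroundPartition, compute_partition, split_tokens

__all__ = ["HATrans", "ForwardOutput", "forward_foreground", "forward_background"]


@dataclass
class ForwardOutput:
    """Everything one forward pass produces.

    ``last_tokens`` is the main branch's final-layer token tensor;
    ``block_inputs`` holds the token tensor entering each encoder block.
    All stay on the autodiff graph, so per-token gradients of any logit can
    be read off after a backward pass (the Grad-CAM++ saliency target is one
    of the ``block_inputs`` — final-layer patch tokens carry no gradient
    from the class logit, only the class token does).
    """

    logits: Tensor
    embeddings: BranchEmbeddings
    partition: ForegroundPartition | None
    attentions: list[Tensor]
    last_tokens: Tensor
    block_inputs: list[Tensor]


def forward_foreground(fg_tokens: Tensor, fg_mask: np.ndarray,
                       encoder: EncoderStack) -> Tensor:
    """Encode the foreground sequence with the main branch's own layers
    (parameters reused by reference) and return the class-token feature."""
    out, _ = encoder.forward(fg_tokens, key_mask=fg_mask)
    return out[:, 0, :]


def forward_background(bg_tokens: Tensor, bg_mask: np.ndarray,
                       encoder: EncoderStack) -> Tensor:
    """Encode the background sequence with the independent twin encoder and
    return its class-token feature."""
    out, _ = encoder.forward(bg_tokens, key_mask=bg_mask)
    return out[:, 0, :]


class HATrans:
    """Hierarchical attention transformer for multi-label image classification.

    A ViT backbone augmented with (a) a region-recognition branch that
    accumulates attention across layers by Hadamard product and thresholds
    the diagonal scores into foreground/background patch partitions, and
    (b) two patch-recognition sub-branches — foreground sharing the backbone
    parameters, background independently parameterized — whose class-token
    embeddings feed a cosine triplet loss against the backbone anchor.

    Ablation flags in :class:`~hatrans.config.ModelConfig` bypass stages:
    with ``use_region_branch=False`` the forward pass is a plain ViT; with
    ``use_patch_branches=False`` the partition is still computed but the
    sub-branches are skipped and the triplet term is disabled.

    Use :meth:`hatrans.training.fit` / :func:`hatrans.training.fit` to train;
    see :class:`hatrans.training.FitResult` for the statsmodels-style results
    object.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator | int = 0):
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        self.config = config
        self.backbone = ViTBackbone(config, rng)
        if config.use_patch_branches:
            self.background_encoder = EncoderStack(config, rng, prefix="bg")
            self.background_cls = Parameter(
                _trunc_normal(rng, (config.embed_dim,)), name="bg_cls_token")
        else:
            self.background_encoder = None
            self.background_cls = None

    # -- parameters -------------------------------------------------------

    def parameters(self) -> list[Parameter]:
        params = self.backbone.parameters()
        if self.background_encoder is not None:
            params = params + self.background_encoder.parameters()
            params.append(self.background_cls)
        return params

    def named_parameters(self) -> dict[str, Parameter]:
        return {p.name: p for p in self.parameters()}

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)[:5]} …")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{p.data.shape} vs {state[name].shape}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()

    # -- forward ----------------------------------------------------------

    @property
    def _patch_branches_active(self) -> bool:
        return (self.config.use_patch_branches and self.config.use_region_branch
                and self.background_encoder is not None)

    def forward(self, images: np.ndarray) -> ForwardOutput:
        """Full pipeline: tokenize → encode → accumulate attention →
        partition → sub-branches → classify."""
        cfg = self.config
        patches = patchify(images, cfg)
        tokens = self.backbone.embed(patches)
        tokens, attentions, states = self.backbone.encoder.forward(
            tokens, return_states=True)
        z_region = tokens[:, 0, :]

        partition = None
        z_fore = z_back = None
        if cfg.use_region_branch:
            with no_grad():
                partition = compute_partition(attentions, cfg)
            if self._patch_branches_active:
                fg_t, fg_m, bg_t, bg_m = split_tokens(
                    tokens, partition, self.background_cls)
                z_fore = forward_foreground(fg_t, fg_m, self.backbone.encoder)
                z_back = forward_background(bg_t, bg_m, self.background_encoder)

        if cfg.concat_foreground_feature and z_fore is not None:
            head_in = concat([z_region, z_fore], axis=1)
        else:
            head_in = z_region
        logits = self.backbone.classify(head_in)
        return ForwardOutput(
            logits=logits,
            embeddings=BranchEmbeddings(z_region=z_region, z_fore=z_fore,
                                        z_back=z_back),
            partition=partition,
            attentions=attentions,
            last_tokens=tokens,
            block_inputs=states,
        )

    def predict_proba(self, images: np.ndarray,
                      batch_size: int = 32) -> np.ndarray:
        """Label probabilities via the sigmoid of the logits (inference mode)."""
        from .objectives import sigmoid
        probs = []
        with no_grad():
            for start in range(0, images.shape[0], batch_size):
                out = self.forward(images[start:start + batch_size])
                probs.append(sigmoid(out.logits.data))
        return np.concatenate(probs, axis=0)
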