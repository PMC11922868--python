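"""Vision-Transformer backbone: patch tokenization, learnable class token and
position embeddings, pre-norm encoder blocks exposing per-layer attention maps,
and the linear multi-label classifier head.

Conventions (fixed, documented API contract):
  * patches are ordered row-major over the patch grid;
  * token index 0 is the class token, patch token i sits at index i (1…N);
  * attention maps are recorded post-softmax, one map per layer and head.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Parameter, Tensor, concat
from .config import ConfigError, ModelConfig

__all__ = ["patchify", "unpatchify", "EncoderStack", "ViTBackbone",
           "NumericsError", "parameter_count"]


class NumericsError(FloatingPointError):
    """Raised when activations become non-finite during encoding."""


def patchify(images: np.ndarray, config: ModelConfig) -> np.ndarray:
    """Split a B×H×W×C image batch into flattened P×P patches.

    Returns an array of shape B×N×(P²·C) where row i holds the pixels of
    patch i in row-major patch order.  The operation is lossless: patches
    tile the image exactly (see :func:`unpatchify`).
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 4:
        raise ConfigError(f"expected B×H×W×C images, got shape {images.shape}")
    b, h, w, c = images.shape
    p = config.patch_size
    for name, got, want in (("height", h, config.image_size),
                            ("width", w, config.image_size),
                            ("channels", c, config.channels)):
        if got != want:
            raise ConfigError(f"image {name} {got} does not match config {want}")
    gh, gw = h // p, w // p
    x = images.reshape(b, gh, p, gw, p, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)           # B×gh×gw×p×p×C
    return x.reshape(b, gh * gw, p * p * c)


def unpatchify(patches: np.ndarray, config: ModelConfig) -> np.ndarray:
    """Inverse of :func:`patchify` (used for round-trip verification)."""
    b, n, _ = patches.shape
    p, c = config.patch_size, config.channels
    g = config.grid_size
    x = patches.reshape(b, g, g, p, p, c).transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b, g * p, g * p, c)


def _trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2 * std, 2 * std)


class EncoderStack:
    """A stack of ``depth`` pre-norm transformer blocks.

    Each block applies the two residual recurrences
    ``z' = MHSA(LN(z)) + z`` and ``z_out = MLP(LN(z')) + z'``;
    attention maps are returned post-softmax for every layer.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator,
                 prefix: str = "enc"):
        self.config = config
        d, heads = config.embed_dim, config.num_heads
        hidden = int(round(d * config.mlp_ratio))
        self.layers: list[dict[str, Parameter]] = []
        for l in range(config.depth):
            p = {
                "ln1_w": Parameter(np.ones(d)),
                "ln1_b": Parameter(np.zeros(d)),
                "qkv_w": Parameter(_trunc_normal(rng, (d, 3 * d))),
                "qkv_b": Parameter(np.zeros(3 * d)),
                "proj_w": Parameter(_trunc_normal(rng, (d, d))),
                "proj_b": Parameter(np.zeros(d)),
                "ln2_w": Parameter(np.ones(d)),
                "ln2_b": Parameter(np.zeros(d)),
                "mlp_w1": Parameter(_trunc_normal(rng, (d, hidden))),
                "mlp_b1": Parameter(np.zeros(hidden)),
                "mlp_w2": Parameter(_trunc_normal(rng, (hidden, d))),
                "mlp_b2": Parameter(np.zeros(d)),
            }
            for k, v in p.items():
                v.name = f"{prefix}.{l}.{k}"
            self.layers.append(p)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.values()]

    def named_parameters(self) -> dict[str, Parameter]:
        return {p.name: p for p in self.parameters()}

    def _block(self, tokens: Tensor, layer: dict[str, Parameter],
               key_mask: np.ndarray | None) -> tuple[Tensor, Tensor]:
        cfg = self.config
        b, t, d = tokens.shape
        heads, hd = cfg.num_heads, cfg.head_dim

        normed = tokens.layer_norm(layer["ln1_w"], layer["ln1_b"])
        qkv = normed @ layer["qkv_w"] + layer["qkv_b"]       # B×T×3D
        qkv = qkv.reshape(b, t, 3, heads, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]                     # B×h×T×hd
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        if key_mask is not None:
            # padded key positions receive zero attention weight
            bias = np.where(key_mask[:, None, None, :], 0.0, -1e9)
            scores = scores + Tensor(bias)
        attn = scores.softmax(axis=-1)                       # B×h×T×T
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, d)
        tokens = tokens + (ctx @ layer["proj_w"] + layer["proj_b"])

        normed2 = tokens.layer_norm(layer["ln2_w"], layer["ln2_b"])
        hidden = (normed2 @ layer["mlp_w1"] + layer["mlp_b1"]).gelu()
        tokens = tokens + (hidden @ layer["mlp_w2"] + layer["mlp_b2"])
        return tokens, attn

    def forward(self, tokens: Tensor, key_mask: np.ndarray | None = None,
                return_states: bool = False):
        """Run all blocks; returns (final tokens, per-layer attention maps).

        With ``return_states`` also returns the token tensor *entering* each
        block (the last entry is the saliency target for Grad-CAM++: final-
        layer patch tokens do not influence the class logit, their inputs do).
        """
        attentions: list[Tensor] = []
        states: list[Tensor] = []
        for l, layer in enumerate(self.layers):
            states.append(tokens)
            tokens, attn = self._block(tokens, layer, key_mask)
            if not np.isfinite(tokens.data).all():
                raise NumericsError(f"non-finite activations at encoder layer {l}")
            attentions.append(attn)
        if return_states:
            return tokens, attentions, states
        return tokens, attentions


class ViTBackbone:
    """Patch embedding + class token + position embeddings + encoder + head."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | int = 0):
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        self.config = config
        d, n = config.embed_dim, config.num_patches
        in_dim = config.patch_size**2 * config.channels
        self.patch_w = Parameter(_trunc_normal(rng, (in_dim, d)), name="patch_w")
        self.patch_b = Parameter(np.zeros(d), name="patch_b")
        self.cls_token = Parameter(_trunc_normal(rng, (d,)), name="cls_token")
        self.pos_embed = Parameter(_trunc_normal(rng, (n + 1, d)), name="pos_embed")
        self.encoder = EncoderStack(config, rng, prefix="enc")
        head_in = 2 * d if config.concat_foreground_feature else d
        self.head_w = Parameter(_trunc_normal(rng, (head_in, config.num_labels)),
                                name="head_w")
        self.head_b = Parameter(np.zeros(config.num_labels), name="head_b")

    # -- parameter access -------------------------------------------------

    def parameters(self) -> list[Parameter]:
        own = [self.patch_w, self.patch_b, self.cls_token, self.pos_embed,
               self.head_w, self.head_b]
        return own + self.encoder.parameters()

    def named_parameters(self) -> dict[str, Parameter]:
        return {p.name: p for p in self.parameters()}

    # -- forward pieces ---------------------------------------------------

    def embed(self, patch_vectors: np.ndarray) -> Tensor:
        """Project patches, prepend the class token and add position embeddings.

        Implements z0 = [class; proj(patch_1); …; proj(patch_N)] + E_pos.
        """
        n = self.config.num_patches
        if patch_vectors.shape[1] != n:
            raise ConfigError(
                f"expected {n} patch rows, got {patch_vectors.shape[1]}")
        b = patch_vectors.shape[0]
        projected = Tensor(patch_vectors) @ self.patch_w + self.patch_b  # B×N×D
        cls = self.cls_token.reshape(1, 1, -1) * np.ones((b, 1, 1))
        tokens = concat([cls, projected], axis=1)
        return tokens + self.pos_embed.reshape(1, n + 1, -1)

    def encode(self, tokens: Tensor,
               key_mask: np.ndarray | None = None) -> tuple[Tensor, list[Tensor]]:
        if tokens.shape[-1] != self.config.embed_dim:
            raise ConfigError(
                f"token dim {tokens.shape[-1]} != embed_dim {self.config.embed_dim}")
        return self.encoder.forward(tokens, key_mask=key_mask)

    def classify(self, class_feature: Tensor) -> Tensor:
        """Single linear map from class-token features to k logits (no activation)."""
        return class_feature @ self.head_w + self.head_b

    def forward_plain(self, images: np.ndarray) -> tuple[Tensor, Tensor, list[Tensor]]:
        """Plain ViT path: tokenize, encode, return (logits, tokens, attentions)."""
        patches = patchify(images, self.config)
        tokens = self.embed(patches)
        tokens, attentions = self.encode(tokens)
        logits = self.classify(tokens[:, 0, :])
        return logits, tokens, attentions


def parameter_count(config: ModelConfig, include_background: bool = True) -> int:
    """Closed-form learnable-parameter count for a given configuration."""
    d, n, k = config.embed_dim, config.num_patches, config.num_labels
    hidden = int(round(d * config.mlp_ratio))
    in_dim = config.patch_size**2 * config.channels
    per_layer = (2 * d) + (d * 3 * d + 3 * d) + (d * d + d) + (2 * d) \
        + (d * hidden + hidden) + (hidden * d + d)
    head_in = 2 * d if config.concat_foreground_feature else d
    count = (in_dim * d + d) + d + (n + 1) * d \
        + config.depth * per_layer + (head_in * k + k)
    if include_background and config.use_patch_branches:
        count += config.depth * per_layer + d  # twin stack + background class token
    return count
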