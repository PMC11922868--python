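"""Model, loss, training and generator configuration.

Variant presets follow the published ViT shapes (Base: D=768, L=12, 12 heads;
Large: D=1024, L=24, 16 heads; Huge: D=1280, L=32, 16 heads); ``tiny`` is a
desk-scale preset for tests and experiments.  All fields round-trip through
YAML so runs are fully described by a single text file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "ModelConfig", "LossWeights", "TrainConfig", "GeneratorConfig",
    "VARIANT_PRESETS", "ConfigError",
]


class ConfigError(ValueError):
    """Raised when a configuration violates a structural invariant."""


#: (embed_dim D, depth L, num_heads, mlp_ratio) per variant
VARIANT_PRESETS: dict[str, tuple[int, int, int, float]] = {
    "tiny": (64, 4, 4, 4.0),
    "base": (768, 12, 12, 4.0),
    "large": (1024, 24, 16, 4.0),
    "huge": (1280, 32, 16, 4.0),
}


@dataclass
class LossWeights:
    """Weights of the combined objective L = λB·LB + λT·LT and triplet margin α.

    Nothing pins these externally; defaults are λB=1.0, λT=0.5, α=0.3.
    """

    lambda_bce: float = 1.0
    lambda_triplet: float = 0.5
    margin: float = 0.3

    def __post_init__(self) -> None:
        if self.lambda_bce < 0 or self.lambda_triplet < 0:
            raise ConfigError("loss weights must be non-negative")
        if not (0.0 <= self.margin <= 2.0):
            raise ConfigError(f"margin must lie in [0, 2], got {self.margin}")


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the hierarchical attention transformer.

    ``threshold_policy`` controls the foreground/background split of patch
    tokens: ``"median"`` sets the per-sample threshold τ to the median of the
    importance scores (both partitions guaranteed non-degenerate);
    ``"fixed"`` uses ``threshold_value`` globally.
    """

    image_size: int = 224
    channels: int = 3
    patch_size: int = 16
    embed_dim: int = 768
    depth: int = 12
    num_heads: int = 12
    mlp_ratio: float = 4.0
    num_labels: int = 4
    variant: str = "base"
    threshold_policy: str = "median"
    threshold_value: float = 0.5
    dropout: float = 0.0
    triplet_orientation: str = "conventional"  # or "as_printed"
    concat_foreground_feature: bool = False     # concat [zR; zF] before the head
    use_region_branch: bool = True
    use_patch_branches: bool = True
    use_contrastive: bool = True
    loss_weights: LossWeights = field(default_factory=LossWeights)

    @classmethod
    def from_variant(cls, variant: str, **overrides) -> "ModelConfig":
        if variant not in VARIANT_PRESETS:
            raise ConfigError(
                f"unknown variant {variant!r}; choose from {sorted(VARIANT_PRESETS)}")
        d, depth, heads, mlp = VARIANT_PRESETS[variant]
        defaults = dict(embed_dim=d, depth=depth, num_heads=heads,
                        mlp_ratio=mlp, variant=variant)
        if variant == "tiny":
            defaults.update(image_size=32, patch_size=8)
        defaults.update(overrides)
        return cls(**defaults)

    def __post_init__(self) -> None:
        if self.image_size % self.patch_size != 0:
            raise ConfigError(
                f"image_size {self.image_size} not divisible by patch_size {self.patch_size}")
        if self.embed_dim % self.num_heads != 0:
            raise ConfigError(
                f"embed_dim {self.embed_dim} not divisible by num_heads {self.num_heads}")
        if self.threshold_policy not in ("median", "fixed"):
            raise ConfigError(f"unknown threshold_policy {self.threshold_policy!r}")
        if self.triplet_orientation not in ("conventional", "as_printed"):
            raise ConfigError(f"unknown triplet_orientation {self.triplet_orientation!r}")
        if isinstance(self.loss_weights, dict):
            self.loss_weights = LossWeights(**self.loss_weights)

    @property
    def grid_size(self) -> int:
        return self.image_size // self.patch_size

    @property
    def num_patches(self) -> int:
        """N = H·W / P² patch tokens (class token excluded)."""
        return self.grid_size * self.grid_size

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.num_heads


@dataclass
class TrainConfig:
    """Optimization recipe: AdamW, linear warmup then cosine annealing with
    extra ×`milestone_factor` drops at the milestone epochs."""

    lr: float = 1e-4
    weight_decay: float = 0.05
    beta1: float = 0.9
    beta2: float = 0.999
    warmup_epochs: int = 10
    total_epochs: int = 100
    milestone_epochs: tuple[int, ...] = (60, 80)
    milestone_factor: float = 0.1
    use_cosine: bool = True
    use_milestones: bool = True
    batch_size: int = 16
    augment_random_crop: bool = True
    augment_horizontal_flip: bool = True
    augment_color_jitter: bool = True
    color_jitter_strength: float = 0.4
    crop_padding: int = 4
    holdout_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.warmup_epochs >= self.total_epochs:
            raise ConfigError("warmup_epochs must be < total_epochs")
        ms = tuple(self.milestone_epochs)
        if list(ms) != sorted(ms) or any(m >= self.total_epochs for m in ms):
            raise ConfigError("milestone_epochs must be ascending and < total_epochs")
        self.milestone_epochs = ms


#: image-count marginals 94/801/243/369 of 1507 for (bag, lid, lateral, medial)
DEFAULT_MARGINALS = (94 / 1507, 801 / 1507, 243 / 1507, 369 / 1507)
#: printed comorbidity rates: bag∧lid, medial∧lateral, medial∧lid, lid∧lateral
DEFAULT_PAIR_RATES = {
    ("bag", "lid"): 0.05,
    ("medial", "lateral"): 0.09,
    ("medial", "lid"): 0.16,
    ("lid", "lateral"): 0.11,
}

LABEL_NAMES = ("bag", "lid", "lateral", "medial")


@dataclass
class GeneratorConfig:
    """Synthetic periocular-style dataset generator settings.

    Marginals default to the cohort's per-indication image fractions and the
    four constrained pairwise co-occurrence rates to the printed comorbidity
    percentages; the joint is the max-entropy distribution matching them with
    zero mass on the all-negative vector (every sample carries at least one
    surgical indication).
    """

    n_images: int = 1507
    image_size: int = 224
    label_marginals: tuple[float, float, float, float] = DEFAULT_MARGINALS
    pairwise_rates: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_RATES))
    require_positive: bool = False
    noise_sd: float = 0.05
    background_amplitude: float = 0.10
    background_tone: float = 0.45
    glyph_intensity: float = 0.45
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0.0 <= m <= 1.0 for m in self.label_marginals):
            raise ConfigError("label marginals must lie in [0, 1]")
        marg = dict(zip(LABEL_NAMES, self.label_marginals))
        norm: dict[tuple[str, str], float] = {}
        for (a, b), r in self.pairwise_rates.items():
            if a not in LABEL_NAMES or b not in LABEL_NAMES or a == b:
                raise ConfigError(f"bad label pair ({a}, {b})")
            if r > min(marg[a], marg[b]) + 1e-12:
                raise ConfigError(
                    f"pair rate {r} for ({a}, {b}) exceeds min marginal "
                    f"{min(marg[a], marg[b]):.4f}")
            norm[tuple(sorted((a, b)))] = float(r)
        self.pairwise_rates = norm


def _asdict(cfg) -> dict:
    d = dataclasses.asdict(cfg)

    def clean(v):
        if isinstance(v, dict):
            return {("|".join(k) if isinstance(k, tuple) else k): clean(x)
                    for k, x in v.items()}
        if isinstance(v, tuple):
            return list(v)
        return v

    return {k: clean(v) for k, v in d.items()}


def save_config(cfg, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(
        {type(cfg).__name__: _asdict(cfg)}, sort_keys=False))


def load_config(path: str | Path):
    """Load any of the four config dataclasses from a one-section YAML file."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or len(doc) != 1:
        raise ConfigError(f"{path}: expected a single top-level config section")
    (kind, payload), = doc.items()
    classes = {c.__name__: c for c in
               (ModelConfig, TrainConfig, GeneratorConfig, LossWeights)}
    if kind not in classes:
        raise ConfigError(f"{path}: unknown config kind {kind!r}")
    if kind == "GeneratorConfig" and "pairwise_rates" in payload:
        payload["pairwise_rates"] = {
            tuple(k.split("|")): v for k, v in payload["pairwise_rates"].items()}
    for key in ("label_marginals", "milestone_epochs"):
        if key in payload and isinstance(payload[key], list):
            payload[key] = tuple(payload[key])
    return classes[kind](**payload)
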