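"""Synthetic periocular-style multi-label image dataset.

Emulates the structure of a four-indication surgical cohort: each image is a
stylized "eye" (ellipse + iris on a smoothly textured background) carrying
one distinct localized glyph per positive label — a crescent below the eye
(eye bag), a double arc above (upper-lid indication), a lateral tick (outer
canthus) and a medial wedge (inner canthus).  Label vectors are drawn from a
maximum-entropy joint over {0,1}⁴ fitted by iterative proportional fitting
(IPF) to the cohort's per-label marginals and four printed pairwise
comorbidity rates; the ``require_positive`` option conditions the joint on
at least one positive label (see :func:`fit_label_joint` for the trade-off).

The glyph boxes are ground-truth foreground regions, recorded in the
manifest, so localization behaviour of the model can be scored without any
human annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from scipy.ndimage import gaussian_filter

from .config import GeneratorConfig, LABEL_NAMES

__all__ = ["sample_labels", "render_image", "generate_dataset",
           "load_dataset", "detect_labels", "glyph_boxes", "SyntheticDataset"]


# ---------------------------------------------------------------------------
# label sampling
# ---------------------------------------------------------------------------

def _cell_bits(k: int = 4) -> np.ndarray:
    """(2^k)×k matrix of binary label vectors; cell index = Σ y_j·2^j."""
    cells = np.arange(2**k)
    return ((cells[:, None] >> np.arange(k)) & 1).astype(np.int64)


def fit_label_joint(config: GeneratorConfig, tol: float = 1e-12,
                    max_iter: int = 2000) -> np.ndarray:
    """Max-entropy joint over the 16 label cells matching the configured
    marginals and constrained pair rates.

    Fitted by IPF: each constraint is a two-bin partition of the cells and
    the corresponding bins are rescaled to their targets in turn.  The
    all-negative cell keeps whatever mass maximum entropy assigns it — the
    printed image-level marginals (which sum to ≈1) and the patient-level
    comorbidity rates are jointly incompatible with forbidding all-negative
    vectors, so matching the printed rates exactly requires admitting
    no-indication samples.  ``config.require_positive`` conditions the
    fitted joint on at least one positive label instead (the constraint
    targets then hold only up to that conditioning).
    """
    bits = _cell_bits()
    p = np.ones(16) / 16.0

    constraints: list[tuple[np.ndarray, float, str]] = []
    for j, m in enumerate(config.label_marginals):
        constraints.append((bits[:, j] == 1, float(m), f"marginal[{LABEL_NAMES[j]}]"))
    for (a, b), r in config.pairwise_rates.items():
        ja, jb = LABEL_NAMES.index(a), LABEL_NAMES.index(b)
        constraints.append(((bits[:, ja] == 1) & (bits[:, jb] == 1), float(r),
                            f"pair[{a}∧{b}]"))

    for _ in range(max_iter):
        worst = 0.0
        for sel, target, _name in constraints:
            cur = p[sel].sum()
            worst = max(worst, abs(cur - target))
            if target in (0.0, 1.0):
                p[sel if target == 0.0 else ~sel] = 0.0
                total = p.sum()
                if total > 0:
                    p /= total
                continue
            if cur > 0:
                p[sel] *= target / cur
            rest = p[~sel].sum()
            if rest > 0:
                p[~sel] *= (1.0 - target) / rest
        if worst < tol:
            break

    resid = [(name, abs(p[sel].sum() - t)) for sel, t, name in constraints]
    name, err = max(resid, key=lambda x: x[1])
    if err > 1e-6:
        raise ValueError(
            f"infeasible marginal/pair combination: constraint {name} "
            f"off by {err:.2e} after IPF")
    if config.require_positive and p[0] > 0:
        p = p.copy()
        p[0] = 0.0
        p /= p.sum()
    return p


def sample_labels(config: GeneratorConfig, n: int | None = None,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw n 4-bit label vectors from the fitted joint (columns follow
    ``LABEL_NAMES`` = (bag, lid, lateral, medial))."""
    n = config.n_images if n is None else int(n)
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    p = fit_label_joint(config)
    cells = rng.choice(16, size=n, p=p)
    return _cell_bits()[cells]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

#: per-label glyph boxes as (row0, row1, col0, col1) fractions of image size;
#: aligned to the quarter grid so each box is a whole number of patch cells
#: at the patch sizes this package uses (the ground-truth regions must be
#: resolvable at patch resolution to score localization), and clear of the
#: deterministic eye outline
_BOXES = {
    "bag": (0.75, 1.0, 0.25, 0.75),
    "lid": (0.0, 0.25, 0.25, 0.75),
    "lateral": (0.25, 0.75, 0.75, 1.0),
    "medial": (0.25, 0.75, 0.0, 0.25),
}


def glyph_boxes(image_size: int) -> dict[str, tuple[int, int, int, int]]:
    """Pixel-coordinate glyph boxes (r0, r1, c0, c1), half-open."""
    out = {}
    for name, (r0, r1, c0, c1) in _BOXES.items():
        out[name] = (int(round(r0 * image_size)), int(round(r1 * image_size)),
                     int(round(c0 * image_size)), int(round(c1 * image_size)))
    return out


def _glyph_mask(name: str, box: tuple[int, int, int, int], s: int) -> np.ndarray:
    """Binary glyph shape inside its box, on the full s×s canvas."""
    r0, r1, c0, c1 = box
    rows, cols = np.mgrid[0:s, 0:s].astype(np.float64)
    u = (rows - r0) / max(r1 - r0, 1)   # 0..1 inside the box vertically
    v = (cols - c0) / max(c1 - c0, 1)
    inside = (u >= 0) & (u < 1) & (v >= 0) & (v < 1)
    if name == "bag":       # crescent opening upward
        outer = ((u - 0.35) / 0.6) ** 2 + ((v - 0.5) / 0.55) ** 2 <= 1.0
        inner = ((u + 0.25) / 0.75) ** 2 + ((v - 0.5) / 0.5) ** 2 <= 1.0
        shape = outer & ~inner
    elif name == "lid":     # double arc: two horizontal bands
        shape = ((u > 0.15) & (u < 0.40)) | ((u > 0.60) & (u < 0.85))
    elif name == "lateral":  # rising tick
        shape = np.abs((1.0 - u) - v) < 0.22
    elif name == "medial":  # wedge narrowing to the right
        shape = np.abs(u - 0.5) < 0.5 * (1.0 - v)
    else:  # pragma: no cover
        raise KeyError(name)
    return (inside & shape).astype(np.float64)


def _base_scene(s: int) -> np.ndarray:
    """Deterministic eye scene: almond outline ring plus iris disc."""
    rows, cols = np.mgrid[0:s, 0:s].astype(np.float64)
    y = (rows - 0.5 * s) / (0.12 * s)
    x = (cols - 0.5 * s) / (0.23 * s)
    r2 = x**2 + y**2
    ring = (r2 <= 1.0) & (r2 >= 0.55)
    iris = ((rows - 0.5 * s) ** 2 + (cols - 0.5 * s) ** 2) <= (0.08 * s) ** 2
    scene = 0.25 * ring.astype(np.float64) - 0.20 * iris.astype(np.float64)
    return scene


def render_image(label_vector: np.ndarray, config: GeneratorConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Render one H×W×3 float image in [0, 1] for a 4-bit label vector.

    Stochastic components (smooth background texture, pixel noise) are drawn
    from ``rng`` *before* any glyph is placed, so toggling a label with the
    same substream changes pixels only inside that label's box.  Returns the
    image and the pixel glyph boxes.
    """
    label_vector = np.asarray(label_vector).astype(np.int64).ravel()
    if label_vector.shape != (4,) or not set(label_vector) <= {0, 1}:
        raise ValueError(f"expected a 4-bit label vector, got {label_vector}")
    s = config.image_size
    # correlation length ≈ s/32 keeps box-scale texture means small relative
    # to the glyph contrast, so the rendering task stays pixel-solvable
    texture = gaussian_filter(rng.normal(0.0, 1.0, size=(s, s)), sigma=s / 32.0)
    tex_sd = texture.std()
    if tex_sd > 0:
        texture *= config.background_amplitude / tex_sd
    noise = rng.normal(0.0, config.noise_sd, size=(s, s, 3))

    canvas = config.background_tone + texture + _base_scene(s)
    boxes = glyph_boxes(s)
    for j, name in enumerate(LABEL_NAMES):
        if label_vector[j]:
            canvas = canvas + config.glyph_intensity * _glyph_mask(name, boxes[name], s)
    image = np.clip(canvas[:, :, None] + noise, 0.0, 1.0)
    return image, boxes


def detect_labels(images: np.ndarray, config: GeneratorConfig,
                  contrast_threshold: float | None = None) -> np.ndarray:
    """Pixel-level oracle detector: a label is called positive when the mean
    intensity over its glyph's shape pixels exceeds the mean over the rest of
    its box by more than half the glyph contrast.  Verifies that the
    rendering task is solvable from pixels alone."""
    s = config.image_size
    if contrast_threshold is None:
        contrast_threshold = 0.5 * config.glyph_intensity
    boxes = glyph_boxes(s)
    calls = np.zeros((images.shape[0], 4), dtype=np.int64)
    for j, name in enumerate(LABEL_NAMES):
        shape = _glyph_mask(name, boxes[name], s) > 0
        r0, r1, c0, c1 = boxes[name]
        box = np.zeros((s, s), dtype=bool)
        box[r0:r1, c0:c1] = True
        rest = box & ~shape
        lum = images.mean(axis=-1)
        contrast = lum[:, shape].mean(axis=1) - lum[:, rest].mean(axis=1)
        calls[:, j] = contrast > contrast_threshold
    return calls


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """In-memory view of a generated dataset (images in [0,1], float64)."""

    images: np.ndarray            # n×H×W×3
    labels: np.ndarray            # n×4
    split: np.ndarray             # n array of "train"/"test"
    boxes: dict[str, tuple[int, int, int, int]]
    frame: pd.DataFrame           # path + label columns + split
    root: Path | None = None

    def subset(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.split == which
        return self.images[m], self.labels[m]


def _stratified_split(labels: np.ndarray, test_fraction: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-label-combination split hitting round(test_fraction·n) overall."""
    n = labels.shape[0]
    target = int(round(test_fraction * n))
    combos = labels @ (1 << np.arange(labels.shape[1]))
    split = np.array(["train"] * n, dtype=object)
    quotas: list[tuple[float, np.ndarray]] = []
    taken = 0
    for c in np.unique(combos):
        idx = np.flatnonzero(combos == c)
        idx = rng.permutation(idx)
        exact = test_fraction * len(idx)
        base = int(np.floor(exact))
        quotas.append((exact - base, idx))
        split[idx[:base]] = "test"
        taken += base
    # largest-remainder rounding to hit the overall target
    quotas.sort(key=lambda q: -q[0])
    for frac, idx in quotas:
        if taken >= target:
            break
        base = int(np.floor(test_fraction * len(idx)))
        if base < len(idx):
            split[idx[base]] = "test"
            taken += 1
    return split.astype(str)


def generate_dataset(config: GeneratorConfig,
                     output_dir: str | Path | None = None) -> SyntheticDataset:
    """Sample labels, render every image, and (optionally) write the dataset.

    When ``output_dir`` is given, writes ``images/img_#####.png``, a
    ``labels.csv`` table (``path,bag,lid,lateral,medial,split``) and a YAML
    ``manifest.yaml`` echoing the config and the ground-truth glyph boxes.
    Fully determined by (config, config.seed).
    """
    labels = sample_labels(config)
    split_rng = np.random.default_rng([config.seed, 2])
    split = _stratified_split(labels, config.test_fraction, split_rng)

    ss = np.random.SeedSequence([config.seed, 3])
    children = ss.spawn(config.n_images)
    images = np.empty((config.n_images, config.image_size, config.image_size, 3))
    boxes: dict[str, tuple[int, int, int, int]] = glyph_boxes(config.image_size)
    for i in range(config.n_images):
        images[i], _ = render_image(labels[i], config,
                                    np.random.default_rng(children[i]))

    paths = [f"images/img_{i:05d}.png" for i in range(config.n_images)]
    frame = pd.DataFrame({"path": paths})
    for j, name in enumerate(LABEL_NAMES):
        frame[name] = labels[:, j]
    frame["split"] = split

    root = None
    if output_dir is not None:
        root = Path(output_dir)
        try:
            (root / "images").mkdir(parents=True, exist_ok=True)
            for i, rel in enumerate(paths):
                arr = np.clip(np.round(images[i] * 255.0), 0, 255).astype(np.uint8)
                Image.fromarray(arr).save(root / rel)
            frame.to_csv(root / "labels.csv", index=False)
            manifest = {
                "generator": {
                    "n_images": config.n_images,
                    "image_size": config.image_size,
                    "label_marginals": [float(m) for m in config.label_marginals],
                    "pairwise_rates": {"|".join(k): float(v)
                                       for k, v in config.pairwise_rates.items()},
                    "noise_sd": config.noise_sd,
                    "background_amplitude": config.background_amplitude,
                    "background_tone": config.background_tone,
                    "glyph_intensity": config.glyph_intensity,
                    "test_fraction": config.test_fraction,
                    "seed": config.seed,
                },
                "label_names": list(LABEL_NAMES),
                "glyph_boxes": {k: list(v) for k, v in boxes.items()},
                "images": [{"path": paths[i],
                            "labels": [int(x) for x in labels[i]],
                            "split": str(split[i])}
                           for i in range(config.n_images)],
            }
            (root / "manifest.yaml").write_text(
                yaml.safe_dump(manifest, sort_keys=False))
        except OSError as exc:
            raise OSError(f"failed writing dataset under {root}: {exc}") from exc

    return SyntheticDataset(images=images, labels=labels, split=split,
                            boxes=boxes, frame=frame, root=root)


def load_dataset(root: str | Path) -> SyntheticDataset:
    """Read a folder+table dataset (labels.csv + PNG/JPEG images) back into
    memory; also serves as the ingestion path for real image folders."""
    root = Path(root)
    frame = pd.read_csv(root / "labels.csv")
    missing = [c for c in ("path", *LABEL_NAMES) if c not in frame.columns]
    if missing:
        raise ValueError(f"{root / 'labels.csv'} lacks columns {missing}")
    imgs = []
    for rel in frame["path"]:
        with Image.open(root / rel) as im:
            imgs.append(np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0)
    images = np.stack(imgs)
    labels = frame[list(LABEL_NAMES)].to_numpy(dtype=np.int64)
    split = (frame["split"].to_numpy(dtype=str) if "split" in frame.columns
             else np.array(["train"] * len(frame)))
    boxes = glyph_boxes(images.shape[1])
    manifest = root / "manifest.yaml"
    if manifest.exists():
        doc = yaml.safe_load(manifest.read_text())
        boxes = {k: tuple(v) for k, v in doc.get("glyph_boxes", {}).items()} or boxes
    return SyntheticDataset(images=images, labels=labels, split=split,
                            boxes=boxes, frame=frame, root=root)


def normalize_images(images: np.ndarray) -> np.ndarray:
    """Map [0,1] pixels to the zero-centred range the model consumes."""
    return (np.asarray(images, dtype=np.float64) - 0.5) / 0.5
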