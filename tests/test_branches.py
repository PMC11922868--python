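"""Sub-branch contracts: parameter sharing (foreground) vs independence
(background), ablation equivalences, pipeline composition, determinism, and
gradient routing."""

import numpy as np
import pytest

import hatrans as ht
from hatrans._tensor import Tensor
from hatrans.backbone import patchify
from hatrans.branches import HATrans, forward_background, forward_foreground
from hatrans.config import LossWeights, ModelConfig
from hatrans.region import compute_partition, split_tokens
from hatrans.synthetic import normalize_images
from hatrans.training import AdamW


@pytest.fixture
def micro_model(micro_config):
    return HATrans(micro_config, rng=11)


@pytest.fixture
def batch(micro_config, rng):
    return rng.random((3, micro_config.image_size, micro_config.image_size, 3))


def _loss(model, out, y, orientation=None):
    probs = ht.sigmoid(out.logits)
    lb = ht.bce_loss(y, probs)
    lt = ht.triplet_loss(out.embeddings, 0.3,
                         orientation or model.config.triplet_orientation)
    return ht.combined_loss(lb, lt, LossWeights())


class TestForegroundSharing:
    def test_full_foreground_equals_full_reencoding(self, micro_model, batch, rng):
        """Feeding the entire patch-token set through the foreground branch
        equals re-encoding the full sequence with the main encoder."""
        model = micro_model
        out = model.forward(normalize_images(batch))
        tokens = out.last_tokens
        n = model.config.num_patches
        from hatrans.region import ForegroundPartition
        all_fg = ForegroundPartition(
            scores=np.ones((3, n)), tau=np.zeros(3),
            mask_f=np.ones((3, n), int), mask_b=np.zeros((3, n), int),
            foreground_indices=[np.arange(1, n + 1)] * 3,
            background_indices=[np.array([], dtype=int)] * 3)
        fg, fg_m, _, _ = split_tokens(tokens, all_fg, model.background_cls)
        z_f = forward_foreground(fg, fg_m, model.backbone.encoder)
        ref, _ = model.backbone.encoder.forward(tokens)
        assert np.allclose(z_f.data, ref.data[:, 0, :], atol=1e-5)

    def test_shared_parameters_stay_identical_after_step(self, micro_model,
                                                         batch, rng):
        """The foreground branch reuses the main encoder's parameter objects,
        so after an optimizer step they are still bit-identical (they are the
        same arrays)."""
        model = micro_model
        y = rng.integers(0, 2, (3, 4))
        out = model.forward(normalize_images(batch))
        loss = _loss(model, out, y, orientation="as_printed")
        model.zero_grad()
        loss.backward()
        AdamW(model.parameters(), lr=1e-3).step()
        # one parameter list serves both branches — verify by object identity
        fg_params = model.backbone.encoder.named_parameters()
        for name, p in fg_params.items():
            assert model.named_parameters()[name] is p


class TestBackgroundIndependence:
    def test_copied_background_params_match_main_reencoding(self, micro_config, rng):
        """Control: with background parameters copied from the main encoder,
        both branches produce identical features on the same full token set
        (so any later divergence is attributable to training)."""
        model = HATrans(micro_config, rng=2)
        for src, dst in zip(model.backbone.encoder.parameters(),
                            model.background_encoder.parameters()):
            dst.data = src.data.copy()
        batch = rng.random((2, 16, 16, 3))
        out = model.forward(normalize_images(batch))
        via_bg, _ = model.background_encoder.forward(out.last_tokens)
        via_main, _ = model.backbone.encoder.forward(out.last_tokens)
        assert np.allclose(via_bg.data, via_main.data, atol=1e-10)

    def test_background_params_diverge_after_triplet_step(self, micro_config, rng):
        """A step on a non-zero triplet loss moves background parameters away
        from the (initially copied) main parameters."""
        model = HATrans(micro_config, rng=3)
        for src, dst in zip(model.backbone.encoder.parameters(),
                            model.background_encoder.parameters()):
            dst.data = src.data.copy()
        batch = rng.random((3, 16, 16, 3))
        out = model.forward(normalize_images(batch))
        lt = ht.triplet_loss(out.embeddings, 0.3, "as_printed")
        assert lt.data > 0
        model.zero_grad()
        lt.backward()
        AdamW(model.parameters(), lr=1e-2, weight_decay=0.0).step()
        diffs = [np.abs(s.data - d.data).max()
                 for s, d in zip(model.backbone.encoder.parameters(),
                                 model.background_encoder.parameters())]
        assert max(diffs) > 0

    def test_class_token_only_background_runs(self, micro_config, rng):
        """Degenerate minimum: a background sequence holding only its class
        token still yields a finite D-vector."""
        model = HATrans(micro_config, rng=4)
        d = micro_config.embed_dim
        bg = model.background_cls.reshape(1, 1, d) * np.ones((1, 1, 1))
        mask = np.ones((1, 1), dtype=bool)
        z_b = forward_background(bg, mask, model.background_encoder)
        assert z_b.shape == (1, d)
        assert np.isfinite(z_b.data).all()


class TestFullForward:
    def test_all_ablations_off_equals_plain_vit(self, rng):
        """With region and patch branches disabled the logits equal a plain
        ViT forward with the same weights."""
        cfg_full = ModelConfig(image_size=16, patch_size=8, embed_dim=16,
                               depth=2, num_heads=2)
        cfg_off = ModelConfig(image_size=16, patch_size=8, embed_dim=16,
                              depth=2, num_heads=2, use_region_branch=False,
                              use_patch_branches=False)
        full = HATrans(cfg_full, rng=7)
        off = HATrans(cfg_off, rng=0)
        off.backbone.load_state_dict = None  # unused
        state = {k: v for k, v in full.state_dict().items()
                 if not k.startswith("bg")}
        for name, p in off.backbone.named_parameters().items():
            p.data = state[name].copy()
        batch = normalize_images(rng.random((2, 16, 16, 3)))
        logits_full = full.forward(batch).logits.data
        logits_off = off.forward(batch).logits.data
        plain_logits, _, _ = full.backbone.forward_plain(batch)
        assert np.allclose(logits_off, plain_logits.data, atol=1e-5)
        assert np.allclose(logits_full, plain_logits.data, atol=1e-5)
        # the classifier consumes the main class token in every configuration,
        # so the sub-branches change training signals, not the forward logits

    def test_no_patch_branches_still_partitions(self, rng):
        cfg = ModelConfig(image_size=16, patch_size=8, embed_dim=16, depth=2,
                          num_heads=2, use_patch_branches=False)
        model = HATrans(cfg, rng=1)
        out = model.forward(normalize_images(rng.random((2, 16, 16, 3))))
        assert out.partition is not None
        assert out.embeddings.z_fore is None and out.embeddings.z_back is None

    def test_eval_mode_is_deterministic(self, micro_model, batch):
        a = micro_model.forward(normalize_images(batch)).logits.data
        b = micro_model.forward(normalize_images(batch)).logits.data
        assert np.array_equal(a, b)

    def test_pipeline_matches_manual_stage_composition(self, micro_model, batch):
        """forward() equals running patchify → embed → encode → partition →
        split → sub-branches by hand."""
        model = micro_model
        cfg = model.config
        x = normalize_images(batch)
        out = model.forward(x)

        tokens = model.backbone.embed(patchify(x, cfg))
        tokens, attns = model.backbone.encode(tokens)
        part = compute_partition(attns, cfg)
        fg, fg_m, bg, bg_m = split_tokens(tokens, part, model.background_cls)
        z_f = forward_foreground(fg, fg_m, model.backbone.encoder)
        z_b = forward_background(bg, bg_m, model.background_encoder)
        logits = model.backbone.classify(tokens[:, 0, :])

        assert np.allclose(out.logits.data, logits.data, atol=1e-12)
        assert np.allclose(out.embeddings.z_fore.data, z_f.data, atol=1e-12)
        assert np.allclose(out.embeddings.z_back.data, z_b.data, atol=1e-12)
        assert np.array_equal(out.partition.mask_f, part.mask_f)

    def test_gradient_routing(self, micro_model, batch, rng):
        """Triplet gradients reach the shared backbone (via zR and zF) and
        the background stack only via zB."""
        model = micro_model
        out = model.forward(normalize_images(batch))
        lt = ht.triplet_loss(out.embeddings, 0.3, "as_printed")
        model.zero_grad()
        lt.backward()
        main_grads = [p.grad is not None and np.abs(p.grad).sum() > 0
                      for p in model.backbone.encoder.parameters()]
        bg_grads = [p.grad is not None and np.abs(p.grad).sum() > 0
                    for p in model.background_encoder.parameters()]
        assert any(main_grads) and any(bg_grads)
        # BCE-only backward leaves the background stack untouched
        out = model.forward(normalize_images(batch))
        lb = ht.bce_loss(rng.integers(0, 2, (3, 4)), ht.sigmoid(out.logits))
        model.zero_grad()
        lb.backward()
        assert all(p.grad is None or np.abs(p.grad).sum() == 0
                   for p in model.background_encoder.parameters())
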