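"""Region-branch contracts: head reduction, Hadamard accumulation, diagonal
scoring, threshold masks with degeneracy rules, and token routing — each
against an explicit loop-based oracle."""

import numpy as np
import pytest

from hatrans._tensor import Parameter, Tensor
from hatrans.region import (ForegroundPartition, accumulate_attention,
                            importance_scores, reduce_heads, split_tokens,
                            threshold_mask)
from conftest import random_attention_stack


class TestReduceHeads:
    def test_single_head_unchanged(self, rng):
        stack = random_attention_stack(rng, 2, 3, 1, 5)
        assert np.allclose(reduce_heads(stack), stack[:, :, 0], atol=1e-15)

    def test_identical_heads_idempotent(self, rng):
        one = random_attention_stack(rng, 2, 2, 1, 4)
        stack = np.repeat(one, 3, axis=2)
        assert np.allclose(reduce_heads(stack), one[:, :, 0], atol=1e-15)

    def test_matches_loop_oracle_and_stays_stochastic(self, rng):
        stack = random_attention_stack(rng, 3, 2, 4, 6)
        got = reduce_heads(stack)
        oracle = np.zeros((3, 2, 6, 6))
        for l in range(3):
            for b in range(2):
                for h in range(4):
                    oracle[l, b] += stack[l, b, h]
        oracle /= 4
        assert np.allclose(got, oracle, atol=1e-7)
        assert np.allclose(got.sum(axis=-1), 1.0, atol=1e-9)


class TestAccumulate:
    def test_single_layer_identity(self, rng):
        maps = random_attention_stack(rng, 1, 2, 1, 5)[:, :, 0]
        assert np.allclose(accumulate_attention(maps), maps[0], atol=1e-15)

    def test_uniform_two_by_two(self):
        """Two uniform 2×2 maps multiply element-wise to all 0.25."""
        u = np.full((2, 1, 2, 2), 0.5)
        assert np.allclose(accumulate_attention(u), 0.25)

    def test_matches_nested_loop_oracle(self, rng):
        maps = rng.random((4, 2, 10, 10))
        got = accumulate_attention(maps)
        oracle = np.ones((2, 10, 10))
        for l in range(4):
            for b in range(2):
                oracle[b] *= maps[l, b]
        assert np.allclose(got, oracle, atol=1e-7)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            accumulate_attention(np.empty((0, 1, 3, 3)))

    def test_associativity_of_repeated_accumulation(self, rng):
        """Accumulating L layers at once equals repeated pairwise products."""
        maps = rng.random((5, 1, 6, 6))
        whole = accumulate_attention(maps)
        step = maps[0]
        for l in range(1, 5):
            step = accumulate_attention(np.stack([step, maps[l]]))
        assert np.allclose(whole, step, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        """Permuting patch order in every layer map permutes the accumulated
        map's rows and columns identically."""
        n = 6
        maps = rng.random((3, 1, n + 1, n + 1))
        perm = np.r_[0, 1 + rng.permutation(n)]  # class token stays at 0
        permuted = maps[:, :, perm][:, :, :, perm]
        am = accumulate_attention(maps)
        am_p = accumulate_attention(permuted)
        assert np.allclose(am_p, am[:, perm][:, :, perm], atol=1e-12)


class TestImportanceScores:
    def test_identity_map_scores_one(self):
        am = np.eye(5)[None]
        assert np.allclose(importance_scores(am), 1.0)

    def test_extracts_patch_diagonal_not_class(self):
        am = np.zeros((1, 4, 4))
        np.fill_diagonal(am[0], [0.9, 0.1, 0.8, 0.3])
        assert np.allclose(importance_scores(am), [[0.1, 0.8, 0.3]])

    def test_matches_lookup_oracle(self, rng):
        am = rng.random((3, 8, 8))
        g = importance_scores(am)
        for b in range(3):
            for i in range(7):
                assert g[b, i] == am[b, i + 1, i + 1]


class TestThresholdMask:
    def test_fixed_tau_strict_comparison(self):
        part = threshold_mask(np.array([[0.9, 0.1, 0.8]]), "fixed", tau=0.5)
        assert part.mask_f.tolist() == [[1, 0, 1]]
        assert part.mask_b.tolist() == [[0, 1, 0]]

    def test_tie_at_tau_goes_to_background(self):
        part = threshold_mask(np.array([[0.5, 0.7]]), "fixed", tau=0.5)
        assert part.mask_f.tolist() == [[0, 1]]

    def test_empty_foreground_promotes_top_scorer(self):
        part = threshold_mask(np.array([[0.1, 0.2]]), "fixed", tau=0.5)
        assert part.mask_f.tolist() == [[0, 1]]

    def test_empty_background_demotes_bottom_scorer(self):
        part = threshold_mask(np.array([[0.8, 0.9]]), "fixed", tau=0.1)
        assert part.mask_f.tolist() == [[0, 1]]

    def test_all_equal_scores_promotes_lowest_index(self):
        part = threshold_mask(np.array([[0.3, 0.3, 0.3]]), "median")
        assert part.mask_f.tolist() == [[1, 0, 0]]

    def test_single_patch_rejected(self):
        with pytest.raises(ValueError):
            threshold_mask(np.array([[0.5]]), "median")

    def test_complementarity_and_nonempty_over_random_sweep(self, rng):
        """1,000 random score vectors: MF + MB = 1 element-wise, both
        partitions non-empty, and MF matches a brute-force comparator
        wherever the degeneracy rule does not fire."""
        for _ in range(250):
            n = int(rng.integers(2, 17))
            g = rng.random((4, n))
            for policy, tau in (("median", None), ("fixed", float(rng.random()))):
                part = threshold_mask(g, policy, tau=tau)
                assert np.array_equal(part.mask_f + part.mask_b,
                                      np.ones((4, n), dtype=np.int64))
                fsizes = part.mask_f.sum(axis=1)
                assert ((fsizes >= 1) & (fsizes <= n - 1)).all()
                tau_vec = (np.median(g, axis=1) if policy == "median"
                           else np.full(4, tau))
                brute = (g > tau_vec[:, None]).astype(int)
                for b in range(4):
                    if 0 < brute[b].sum() < n:
                        assert np.array_equal(part.mask_f[b], brute[b])

    def test_raising_fixed_tau_never_grows_foreground(self, rng):
        g = rng.random((3, 12))
        sizes = []
        for tau in np.linspace(0, 1, 11):
            part = threshold_mask(g, "fixed", tau=tau)
            sizes.append(part.mask_f.sum(axis=1))
        sizes = np.array(sizes)
        assert (np.diff(sizes, axis=0) <= 0).all()


class TestSplitTokens:
    @staticmethod
    def _partition_from_masks(mask_f):
        mask_f = np.asarray(mask_f)
        mask_b = 1 - mask_f
        return ForegroundPartition(
            scores=mask_f.astype(float), tau=np.zeros(mask_f.shape[0]),
            mask_f=mask_f, mask_b=mask_b,
            foreground_indices=[np.flatnonzero(m) + 1 for m in mask_f],
            background_indices=[np.flatnonzero(1 - m) + 1 for m in mask_f])

    def test_counts_for_nearly_full_foreground(self, rng):
        n, d = 6, 8
        tokens = Tensor(rng.normal(size=(1, n + 1, d)))
        mask = np.ones((1, n), dtype=int)
        mask[0, 3] = 0
        part = self._partition_from_masks(mask)
        bg_cls = Parameter(rng.normal(size=(d,)))
        fg, fg_m, bg, bg_m = split_tokens(tokens, part, bg_cls)
        assert fg.shape[1] == n        # class token + 5 patches
        assert bg.shape[1] == 2        # background class token + 1 patch
        assert fg_m.all() and bg_m.all()

    def test_partition_roundtrip_recovers_patches(self, rng):
        n, d = 9, 4
        tokens = Tensor(rng.normal(size=(2, n + 1, d)))
        mask = (rng.random((2, n)) > 0.5).astype(int)
        mask[:, 0] = 1
        mask[:, -1] = 0  # keep both sides non-empty
        part = self._partition_from_masks(mask)
        fg, fg_m, bg, bg_m = split_tokens(tokens, part, Parameter(np.zeros(d)))
        for b in range(2):
            fg_idx = part.foreground_indices[b]
            bg_idx = part.background_indices[b]
            recovered = np.zeros((n, d))
            recovered[fg_idx - 1] = fg.data[b, 1:1 + len(fg_idx)]
            recovered[bg_idx - 1] = bg.data[b, 1:1 + len(bg_idx)]
            assert np.array_equal(recovered, tokens.data[b, 1:])

    def test_leads_are_main_and_background_class_tokens(self, rng):
        n, d = 4, 3
        tokens = Tensor(rng.normal(size=(1, n + 1, d)))
        mask = np.array([[1, 0, 1, 0]])
        part = self._partition_from_masks(mask)
        bg_cls = Parameter(rng.normal(size=(d,)))
        fg, _, bg, _ = split_tokens(tokens, part, bg_cls)
        assert np.array_equal(fg.data[0, 0], tokens.data[0, 0])
        assert np.array_equal(bg.data[0, 0], bg_cls.data)

    def test_gather_matches_index_oracle(self, rng):
        n, d = 7, 5
        tokens = Tensor(rng.normal(size=(3, n + 1, d)))
        mask = (rng.random((3, n)) > 0.4).astype(int)
        mask[:, 1] = 1
        mask[:, 2] = 0
        part = self._partition_from_masks(mask)
        fg, fg_m, _, _ = split_tokens(tokens, part, Parameter(np.zeros(d)))
        for b in range(3):
            for slot, tok_idx in enumerate(part.foreground_indices[b], start=1):
                assert np.array_equal(fg.data[b, slot], tokens.data[b, tok_idx])
            assert fg_m[b, :1 + len(part.foreground_indices[b])].all()
            assert not fg_m[b, 1 + len(part.foreground_indices[b]):].any()

    def test_inconsistent_sizes_rejected(self, rng):
        tokens = Tensor(rng.normal(size=(1, 5, 3)))
        part = self._partition_from_masks(np.array([[1, 0, 1]]))  # N=3 vs 4
        with pytest.raises(ValueError):
            split_tokens(tokens, part, Parameter(np.zeros(3)))
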