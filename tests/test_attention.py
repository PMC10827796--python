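"""Local and global attention: proposal counting, heatmap merging against a
per-cell oracle, gating identities, stitching, and the mutual-influence
property."""

import numpy as np
import pytest

from jawnet import nn
from jawnet.backbone import BlockFeatures
from jawnet.global_attention import GlobalAttention, reshape_to_image
from jawnet.local_attention import (LocalAttention, RegionProposalFPN,
                                    merge_proposals, soft_box_coverage)


def _fake_feats(rng, n=1, sizes=((12, 12), (6, 6), (3, 3)),
                chans=(8, 12, 16), deep=20):
    t = [nn.Tensor(rng.normal(size=(n, c, h, w)).astype(np.float32))
         for c, (h, w) in zip(chans, sizes)]
    b4 = nn.Tensor(rng.normal(size=(n, deep, *sizes[2])).astype(np.float32))
    return BlockFeatures(b1=t[0], b2=t[1], b3=t[2], b4=b4)


@pytest.fixture(scope="module")
def fpn():
    return RegionProposalFPN(tap_channels=(8, 12, 16), fpn_channels=8,
                             n_lesion_classes=3, patch_size=96,
                             rng=np.random.default_rng(0))


class TestProposals:
    def test_one_proposal_per_anchor_and_shape(self, fpn, rng):
        feats = _fake_feats(rng)
        props = fpn(feats)
        expect = 3 * (12 * 12 + 6 * 6 + 3 * 3)   # 3 box shapes per cell
        assert props.n_proposals == expect
        assert props.boxes.shape == (1, expect, 4)

    def test_zero_head_output_gives_half_objectness(self, rng):
        fpn0 = RegionProposalFPN((8, 12, 16), 8, 3, 96,
                                 np.random.default_rng(0))
        fpn0.head_out.weight.data[:] = 0.0
        fpn0.head_out.bias.data[:] = 0.0
        props = fpn0(_fake_feats(rng))
        np.testing.assert_allclose(props.objectness.data, 0.5, atol=1e-7)

    def test_boxes_clipped_to_patch(self, fpn, rng):
        props = fpn(_fake_feats(rng))
        assert props.boxes.min() >= 0.0 and props.boxes.max() <= 96.0

    def test_empty_features_rejected(self, fpn):
        empty = BlockFeatures(*(nn.Tensor(np.zeros((1, c, 0, 0), np.float32))
                                for c in (8, 12, 16, 20)))
        with pytest.raises(ValueError):
            fpn(empty)


class TestMergeProposals:
    def _props(self, boxes, scores):
        from jawnet.local_attention import ProposalSet
        boxes = np.asarray(boxes, np.float32)[None]
        return ProposalSet(
            boxes=boxes,
            objectness=nn.Tensor(np.asarray(scores, np.float32)[None]),
            cls_scores=np.zeros((1, len(scores), 3), np.float32),
            levels=np.zeros(len(scores), np.int32))

    def test_top_k_limits_contributors(self):
        """With 500 proposals and top_k=400, exactly the 400 best scores
        contribute to the merged map."""
        rng = np.random.default_rng(0)
        n = 500
        boxes = np.stack([np.zeros(n), np.zeros(n),
                          np.full(n, 8.0), np.full(n, 8.0)], -1)
        scores = rng.uniform(0.1, 0.9, n)
        props = self._props(boxes, scores)
        psi = merge_proposals(props, 400, (4, 4), 32)
        assert psi.data.max() == pytest.approx(1.0)
        # verify against explicit accumulation over exactly the top 400
        manual = np.zeros(16)
        order = np.argsort(-scores, kind="stable")[:400]
        covs = soft_box_coverage(boxes[order].astype(np.float32), (4, 4), 32)
        for s, c in zip(scores[order], covs):
            manual += s * c
        manual /= manual.max()
        np.testing.assert_allclose(psi.data[0, 0].ravel(), manual, rtol=1e-5)

    def test_single_full_cover_proposal_normalises_to_one(self):
        props = self._props([[0, 0, 32, 32]], [0.3])
        psi = merge_proposals(props, 10, (4, 4), 32)
        np.testing.assert_allclose(psi.data, 1.0, atol=1e-7)

    def test_overlapping_boxes_match_per_cell_oracle(self):
        boxes = [[0, 0, 16, 16], [8, 8, 24, 24], [0, 16, 32, 32]]
        scores = [0.9, 0.5, 0.7]
        props = self._props(boxes, scores)
        psi = merge_proposals(props, 3, (8, 8), 32)
        cell = 32 / 8
        manual = np.zeros((8, 8))
        for (x0, y0, x1, y1), s in zip(boxes, scores):
            for r in range(8):
                for c in range(8):
                    ox = max(0.0, min(x1, (c + 1) * cell) - max(x0, c * cell))
                    oy = max(0.0, min(y1, (r + 1) * cell) - max(y0, r * cell))
                    manual[r, c] += s * (ox / cell) * (oy / cell)
        manual /= manual.max()
        np.testing.assert_allclose(psi.data[0, 0], manual, rtol=1e-5, atol=1e-7)

    def test_score_increase_is_monotone_pre_normalization(self):
        boxes = [[0, 0, 16, 16], [8, 8, 24, 24]]
        for s2 in (0.3, 0.6):
            props = self._props(boxes, [0.5, s2])
            cov = soft_box_coverage(np.asarray(boxes, np.float32), (4, 4), 32)
            pre = (np.array([0.5, s2]) @ cov).reshape(4, 4)
            if s2 == 0.3:
                lo = pre
            else:
                assert np.all(pre >= lo - 1e-9)

    def test_zero_proposals_fall_back_to_uniform(self):
        props = self._props(np.zeros((3, 4)), [0.4, 0.2, 0.1])
        with pytest.warns(UserWarning, match="uniform"):
            psi = merge_proposals(props, 2, (4, 4), 32)
        np.testing.assert_array_equal(psi.data, 1.0)

    def test_gradient_flows_to_scores(self):
        from jawnet.local_attention import ProposalSet
        scores = nn.Tensor(np.array([[0.5, 0.2]], np.float32),
                           requires_grad=True)
        props = ProposalSet(
            boxes=np.array([[[0, 0, 16, 16], [16, 16, 32, 32]]], np.float32),
            objectness=scores, cls_scores=np.zeros((1, 2, 3), np.float32),
            levels=np.zeros(2, np.int32))
        psi = merge_proposals(props, 2, (4, 4), 32)
        psi.sum().backward()
        assert scores.grad is not None and np.any(scores.grad != 0)


class TestLocalGate:
    def test_uniform_heatmap_is_multiplicative_identity(self, rng):
        feats = _fake_feats(rng)
        att = LocalAttention(20, 8, np.random.default_rng(1))
        ones = nn.Tensor(np.ones((1, 1, 3, 3), np.float32))
        half = nn.Tensor(np.full((1, 1, 3, 3), 0.5, np.float32))
        out1 = att(feats.b4, ones)
        gate_ones = LocalAttention.gate(feats.b4, ones)
        gate_half = LocalAttention.gate(feats.b4, half)
        np.testing.assert_allclose(gate_half.data, gate_ones.data * 0.5,
                                   atol=1e-7)
        assert out1.shape == (1, 8, 3, 3)

    def test_zero_heatmap_zeroes_the_gated_activation(self, rng):
        feats = _fake_feats(rng)
        zeros = nn.Tensor(np.zeros((1, 1, 3, 3), np.float32))
        np.testing.assert_array_equal(
            LocalAttention.gate(feats.b4, zeros).data, 0.0)

    def test_gated_activation_bounded_unit_interval(self, rng):
        feats = _fake_feats(rng)
        psi = nn.Tensor(np.random.default_rng(0).uniform(
            size=(1, 1, 3, 3)).astype(np.float32))
        g = LocalAttention.gate(feats.b4, psi).data
        assert g.min() >= 0.0 and g.max() <= 1.0

    def test_mismatched_map_rejected(self, rng):
        feats = _fake_feats(rng)
        with pytest.raises(ValueError):
            LocalAttention.gate(feats.b4,
                                nn.Tensor(np.ones((1, 1, 5, 5), np.float32)))


class TestGlobalAttention:
    @pytest.fixture()
    def ga(self):
        return GlobalAttention(n_patches=4, attn_channels=8,
                               tap_channels=(8, 12, 16),
                               rng=np.random.default_rng(2))

    def test_global_map_shape(self, ga, rng):
        h_i = nn.Tensor(rng.normal(size=(4, 8, 3, 3)).astype(np.float32))
        assert ga.build_global_map(h_i).shape == (1, 8, 3, 3)

    def test_single_patch_degenerate(self, rng):
        ga1 = GlobalAttention(1, 8, (8, 12, 16), np.random.default_rng(2))
        h_i = nn.Tensor(rng.normal(size=(1, 8, 3, 3)).astype(np.float32))
        assert ga1.build_global_map(h_i).shape == (1, 8, 3, 3)

    def test_permuting_identical_patch_features_leaves_h_unchanged(self, ga, rng):
        one = rng.normal(size=(1, 8, 3, 3)).astype(np.float32)
        h_i = nn.Tensor(np.repeat(one, 4, axis=0))
        a = ga.build_global_map(h_i).data
        b = ga.build_global_map(nn.Tensor(np.repeat(one, 4, axis=0)[[1, 0, 2, 3]])).data
        np.testing.assert_array_equal(a, b)

    def test_attend_identity_and_annihilator(self, ga, rng):
        z = [nn.Tensor(rng.normal(size=(4, 8, 3, 3)).astype(np.float32))
             for _ in range(3)]
        ones = nn.Tensor(np.ones((1, 8, 3, 3), np.float32))
        zeros = nn.Tensor(np.zeros((1, 8, 3, 3), np.float32))
        zi = ga.attend_patch(z, ones)
        np.testing.assert_allclose(
            zi.data, np.concatenate([t.data for t in z], axis=1), atol=1e-7)
        np.testing.assert_array_equal(ga.attend_patch(z, zeros).data, 0.0)
        with pytest.raises(ValueError):
            ga.attend_patch(z[:2], ones)

    def test_layer_projections_reach_common_resolution(self, ga, rng):
        feats = _fake_feats(rng, n=4)
        for p in ga.project_layers(feats):
            assert p.shape == (4, 8, 3, 3)


class TestReshapeToImage:
    def test_reference_shape_and_block_exactness(self, rng):
        z = nn.Tensor(rng.normal(size=(8, 5, 11, 11)).astype(np.float32))
        zx = reshape_to_image(z, (4, 2))
        assert zx.shape == (1, 5, 22, 44)
        # cell (col=2, row=1) holds patch index 1*4+2=6, block-exactly
        np.testing.assert_array_equal(
            zx.data[0, :, 11:22, 22:33], z.data[6])

    def test_single_cell_grid_is_identity(self, rng):
        z = nn.Tensor(rng.normal(size=(1, 3, 4, 4)).astype(np.float32))
        np.testing.assert_array_equal(reshape_to_image(z, (1, 1)).data[0],
                                      z.data[0])

    def test_mismatched_grid_rejected(self, rng):
        z = nn.Tensor(rng.normal(size=(6, 3, 4, 4)).astype(np.float32))
        with pytest.raises(ValueError):
            reshape_to_image(z, (4, 2))


def test_mutual_influence_between_patches(tiny_cfg, tiny_model):
    """Perturbing the pixels of one patch changes the attended feature z_x
    in the region of a different patch (the reciprocal-calibration claim)."""
    rng = np.random.default_rng(0)
    x = rng.normal(size=(1, 1, 150, 300)).astype(np.float32)
    tiny_model.eval()
    with nn.no_grad():
        base = tiny_model(nn.Tensor(x)).z_x.data.copy()
        x2 = x.copy()
        x2[0, 0, :75, :75] += 0.5          # perturb patch (row 0, col 0) only
        pert = tiny_model(nn.Tensor(x2)).z_x.data
    g = base.shape[2] // 2                  # per-patch cell side in z_x
    # far-away patch (row 1, col 3) must change despite unchanged pixels
    far_base = base[0, :, g:, 3 * g:]
    far_pert = pert[0, :, g:, 3 * g:]
    assert np.abs(far_base - far_pert).max() > 1e-6
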