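"""Convolution layers: brute-force oracles, identities, gradient checks."""

import numpy as np
import pytest

from msstgcn import nn_core as nc
from msstgcn import skeleton_graph as sg
from msstgcn.network_layers import (
    MultiscaleTemporalConv,
    STGCNBlock,
    SpatialGraphConv,
)

from conftest import random_tree_layout

F64 = np.float64


def spatial_conv_per_node_oracle(x, subsets, masks, weights, bias):
    """Per-node neighborhood summation: the sampling/weight formulation.

    For every root joint ``q`` the output sums, over the three subsets and
    over the neighbors ``y`` that the subset contains, the neighbor's
    features mapped through the subset's channel transform and scaled by
    the masked normalized-adjacency weight.
    """
    n, t, v, c_in = x.shape
    c_out = weights.shape[2]
    out = np.zeros((n, t, v, c_out))
    for ni in range(n):
        for ti in range(t):
            for q in range(v):
                acc = np.zeros(c_out)
                for z in range(3):
                    for y in range(v):
                        w = subsets[z, q, y] * masks[z, q, y]
                        if w != 0.0:
                            acc += w * (x[ni, ti, y] @ weights[z])
                out[ni, ti, q] = acc + bias
    return out


def temporal_conv_direct_oracle(x, weight, bias, stride=1):
    """Direct convolution arithmetic: explicit loops over taps and frames."""
    n, t, v, c_in = x.shape
    k, _, c_out = weight.shape
    left = (k - 1 + 1) // 2
    right = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (left, right), (0, 0), (0, 0)))
    t_out = (t + left + right - k) // stride + 1
    out = np.zeros((n, t_out, v, c_out))
    for to in range(t_out):
        for i in range(k):
            out[:, to] += xp[:, to * stride + i] @ weight[i]
    return out + bias


class TestSpatialGraphConv:
    def test_identity_aggregation(self):
        """Identity subset, identity transform, all-ones mask: output == input."""
        v, c = 5, 3
        subsets = np.zeros((3, v, v))
        subsets[0] = np.eye(v)
        layer = SpatialGraphConv(c, c, subsets, dtype=F64)
        layer.weight.value[...] = 0.0
        layer.weight.value[0] = np.eye(c)
        x = np.random.default_rng(0).standard_normal((2, 4, v, c))
        np.testing.assert_allclose(layer.forward(x), x, atol=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_per_node_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = int(rng.integers(3, 11))
        layout = random_tree_layout(rng, v)
        graph = sg.build_graph(layout)
        layer = SpatialGraphConv(2, 2, graph.subsets, rng=rng, dtype=F64)
        layer.edge_masks.value[...] = rng.random((3, v, v)) + 0.5
        x = rng.standard_normal((1, 4, v, 2))
        expected = spatial_conv_per_node_oracle(
            x, graph.subsets, layer.edge_masks.value, layer.weight.value,
            layer.bias.value,
        )
        np.testing.assert_allclose(layer.forward(x), expected, atol=1e-5)

    def test_joint_permutation_equivariance(self, rng):
        v = 6
        layout = random_tree_layout(rng, v)
        graph = sg.build_graph(layout)
        layer = SpatialGraphConv(3, 4, graph.subsets, rng=rng, dtype=F64)
        x = rng.standard_normal((2, 5, v, 3))
        out = layer.forward(x)
        perm = rng.permutation(v)
        permuted_subsets = graph.subsets[:, perm][:, :, perm]
        layer_p = SpatialGraphConv(3, 4, permuted_subsets, rng=rng, dtype=F64)
        for p_dst, p_src in zip(layer_p.parameters(), layer.parameters()):
            if p_src.name == "edge_masks":
                p_dst.value[...] = p_src.value[:, perm][:, :, perm]
            else:
                p_dst.value[...] = p_src.value
        out_p = layer_p.forward(x[:, :, perm])
        np.testing.assert_allclose(out_p, out[:, :, perm], atol=1e-10)

    def test_zero_mask_blocks_neighbor(self, rng):
        """Zeroing a mask entry makes the root invariant to that neighbor."""
        layout = random_tree_layout(rng, 5)
        graph = sg.build_graph(layout)
        root, neighbor = layout.edges[0]
        layer = SpatialGraphConv(3, 3, graph.subsets, rng=rng, dtype=F64)
        layer.edge_masks.value[:, root, neighbor] = 0.0
        x = rng.standard_normal((1, 3, 5, 3))
        base = layer.forward(x).copy()
        x2 = x.copy()
        x2[:, :, neighbor] += rng.standard_normal(3)  # perturb the neighbor
        np.testing.assert_allclose(
            layer.forward(x2)[:, :, root], base[:, :, root], atol=1e-10
        )
        # sanity: without the zeroed mask the root does respond
        layer.edge_masks.value[...] = 1.0
        assert not np.allclose(
            layer.forward(x2)[:, :, root], layer.forward(x)[:, :, root]
        )

    def test_wrong_joint_count_rejected(self, graph20):
        layer = SpatialGraphConv(3, 3, graph20.subsets)
        with pytest.raises(ValueError, match="joints"):
            layer.forward(np.zeros((1, 4, 5, 3)))

    def test_wrong_subset_count_rejected(self):
        with pytest.raises(ValueError, match="3 partition subsets"):
            SpatialGraphConv(3, 3, np.zeros((2, 5, 5)))


class TestTemporalConv:
    @pytest.mark.parametrize("kernel,stride", [(3, 1), (8, 1), (16, 1), (3, 2)])
    def test_matches_direct_convolution(self, kernel, stride, rng):
        layer = nc.TemporalConv(3, 4, kernel, stride=stride, rng=rng, dtype=F64)
        x = rng.standard_normal((2, 25, 5, 3))
        expected = temporal_conv_direct_oracle(
            x, layer.weight.value, layer.bias.value, stride
        )
        np.testing.assert_allclose(layer.forward(x), expected, atol=1e-10)

    @pytest.mark.parametrize("kernel", [1, 3, 8, 16])
    def test_frame_count_conserved_at_stride_1(self, kernel, rng):
        layer = nc.TemporalConv(2, 2, kernel, rng=rng)
        out = layer.forward(rng.standard_normal((1, 25, 4, 2)).astype(np.float32))
        assert out.shape[1] == 25


class TestMultiscaleTemporalConv:
    def test_zero_filters_identity_on_nonnegative(self, rng):
        """With all filters and biases zero the block is the identity."""
        layer = MultiscaleTemporalConv(4, 3, rng=rng, dtype=F64)
        for p in layer.parameters():
            if p.name in ("weight", "bias"):
                p.value[...] = 0.0
        x = np.abs(rng.standard_normal((2, 10, 5, 4)))
        layer.train()
        np.testing.assert_allclose(layer.forward(x), x, atol=1e-12)
        layer.eval()
        np.testing.assert_allclose(layer.forward(x), x, atol=1e-12)

    @pytest.mark.parametrize("gamma", [3, 8])
    def test_frame_conservation_both_branches(self, gamma, rng):
        layer = MultiscaleTemporalConv(4, gamma, rng=rng)
        x = rng.standard_normal((1, 25, 5, 4)).astype(np.float32)
        assert layer.forward(x).shape == x.shape
        a = layer.branch_short.forward(x)
        b = layer.branch_long.forward(x)
        assert a.shape[1] == 25 and b.shape[1] == 25

    def test_branches_hold_half_the_channels_each(self, rng):
        layer = MultiscaleTemporalConv(8, 3, rng=rng)
        assert layer.branch_short.weight.value.shape == (3, 8, 4)
        assert layer.branch_long.weight.value.shape == (6, 8, 4)

    def test_single_scale_mode_is_plain_temporal_conv(self, rng):
        """The single-scale arm reduces to one full-width convolution."""
        layer = MultiscaleTemporalConv(4, 3, multiscale=False, rng=rng, dtype=F64)
        assert layer.branch_long is None
        assert layer.branch_short.weight.value.shape == (3, 4, 4)
        x = np.abs(rng.standard_normal((1, 9, 2, 4)))
        layer.eval()
        conv = temporal_conv_direct_oracle(
            x, layer.branch_short.weight.value, layer.branch_short.bias.value
        )
        eps = layer.bn.eps
        expected = np.maximum(conv / np.sqrt(1.0 + eps) + x, 0.0)
        np.testing.assert_allclose(layer.forward(x), expected, atol=1e-10)

    def test_multiscale_direct_arithmetic(self, rng):
        """Eval-mode block equals hand-written branch/concat/norm/residual math."""
        layer = MultiscaleTemporalConv(4, 2, rng=rng, dtype=F64)
        layer.eval()
        x = rng.standard_normal((2, 7, 3, 4))
        a = temporal_conv_direct_oracle(
            x, layer.branch_short.weight.value, layer.branch_short.bias.value
        )
        b = temporal_conv_direct_oracle(
            x, layer.branch_long.weight.value, layer.branch_long.bias.value
        )
        y = np.concatenate([a, b], axis=-1) / np.sqrt(1.0 + layer.bn.eps)
        np.testing.assert_allclose(layer.forward(x), np.maximum(y + x, 0.0), atol=1e-10)

    def test_odd_channels_rejected(self):
        with pytest.raises(ValueError, match="even"):
            MultiscaleTemporalConv(5, 3)

    def test_gamma_below_one_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            MultiscaleTemporalConv(4, 0)


# ---------------------------------------------------------------------------
# gradient checks
# ---------------------------------------------------------------------------

def numeric_grad(loss, array, eps=1e-6):
    g = np.zeros_like(array)
    it = np.nditer(array, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = array[i]
        array[i] = orig + eps
        fp = loss()
        array[i] = orig - eps
        fm = loss()
        array[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


def assert_gradients_match(layer, x, tol=1e-6):
    layer.train()
    out = layer.forward(x)
    probe = np.random.default_rng(1).standard_normal(out.shape)
    layer.zero_grad()
    gx = layer.backward(probe.copy())

    def loss():
        return float((layer.forward(x) * probe).sum())

    ngx = numeric_grad(loss, x)
    assert np.abs(gx - ngx).max() < tol * (1 + np.abs(ngx).max())
    for name, p in layer.named_parameters():
        ng = numeric_grad(loss, p.value)
        err = np.abs(p.grad - ng).max() / (1 + np.abs(ng).max())
        assert err < tol, f"parameter {name}: gradient error {err:.2e}"


@pytest.mark.parametrize(
    "factory,shape",
    [
        (lambda rng: nc.PointwiseConv(4, 3, rng=rng, dtype=F64), (2, 6, 5, 4)),
        (lambda rng: nc.PointwiseConv(4, 3, stride=2, rng=rng, dtype=F64), (2, 6, 5, 4)),
        (lambda rng: nc.TemporalConv(4, 3, 3, rng=rng, dtype=F64), (2, 6, 5, 4)),
        (lambda rng: nc.TemporalConv(4, 3, 6, rng=rng, dtype=F64), (2, 6, 5, 4)),
        (lambda rng: nc.TemporalConv(4, 4, 3, stride=2, rng=rng, dtype=F64), (2, 6, 5, 4)),
        (lambda rng: nc.BatchNorm(4, dtype=F64), (2, 6, 5, 4)),
        (lambda rng: MultiscaleTemporalConv(4, 2, rng=rng, dtype=F64), (2, 7, 5, 4)),
        (
            lambda rng: MultiscaleTemporalConv(4, 2, multiscale=False, rng=rng, dtype=F64),
            (2, 7, 5, 4),
        ),
    ],
    ids=["pointwise", "pointwise-s2", "tconv-k3", "tconv-k6", "tconv-s2",
         "batchnorm", "mstcn", "mstcn-single"],
)
def test_layer_gradients(factory, shape, rng):
    """Every backward pass agrees with central-difference numeric gradients."""
    assert_gradients_match(factory(rng), rng.standard_normal(shape))


def test_spatial_graph_conv_gradients(rng):
    layout = random_tree_layout(rng, 5)
    graph = sg.build_graph(layout)
    assert_gradients_match(
        SpatialGraphConv(3, 4, graph.subsets, rng=rng, dtype=F64),
        rng.standard_normal((2, 4, 5, 3)),
    )


@pytest.mark.parametrize("c_in,c_out,stride", [(4, 4, 1), (4, 6, 1), (4, 6, 2)])
def test_stgcn_block_gradients(c_in, c_out, stride, rng):
    layout = random_tree_layout(rng, 5)
    graph = sg.build_graph(layout)
    block = STGCNBlock(c_in, c_out, graph.subsets, 2, stride=stride, rng=rng, dtype=F64)
    assert_gradients_match(block, rng.standard_normal((2, 6, 5, c_in)))


def test_stgcn_block_shape_and_stacking(graph20, rng):
    """10 stacked blocks preserve the joint axis and contract frames by stride."""
    blocks = [STGCNBlock(3 if i == 0 else 4, 4, graph20.subsets, 2, rng=rng)
              for i in range(10)]
    x = rng.standard_normal((2, 25, 20, 3)).astype(np.float32)
    for b in blocks:
        x = b.forward(x)
        assert x.shape[2] == 20
    assert x.shape == (2, 25, 20, 4)
    strided = STGCNBlock(4, 6, graph20.subsets, 2, stride=2, rng=rng)
    assert strided.forward(x).shape == (2, 13, 20, 6)


def test_edge_mask_gradient_flows(graph20, rng):
    """After one backward pass every edge mask has a finite, nonzero gradient."""
    block = STGCNBlock(3, 4, graph20.subsets, 2, rng=rng, dtype=F64)
    block.train()
    x = rng.standard_normal((2, 8, 20, 3))
    out = block.forward(x)
    block.zero_grad()
    block.backward(np.ones_like(out))
    mask_grad = block.gcn.edge_masks.grad
    assert np.all(np.isfinite(mask_grad))
    assert np.abs(mask_grad).sum() > 0.0
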