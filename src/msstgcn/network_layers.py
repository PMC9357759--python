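"""Graph-convolution and multiscale temporal-convolution layers.

Two operations make up the network's backbone:

* **Subset-wise spatial graph convolution.**  With the three fixed
  partition matrices ``G_z`` (stationary / centripetal / centrifugal, see
  :mod:`msstgcn.skeleton_graph`), the layer computes

  .. math:: f_{out} = \\sum_{z=0}^{2} \\Theta_z\\big( (G_z \\odot W_z)\\, f_{in} \\big)

  where ``W_z`` is a learnable positive edge-importance mask (the network's
  spatial attention over bone connections, initialized to all ones so it
  starts as the plain partition) and ``Θ_z`` a per-subset 1×1 channel
  transform.  Aggregation runs root-wise: the output at joint ``x`` sums
  its labelled neighbors ``y`` with weight ``G_z[x, y]`` — exactly the
  per-node sampling/weight formulation that the test suite re-implements
  as a brute-force oracle.

* **Multiscale temporal convolution (MS-TCN).**  Two parallel banks of
  frame-axis filters, each holding half the output channels, with kernel
  extents ``γ`` (short movements) and ``2γ`` (long movements).  Branch
  outputs are concatenated, batch-normalized, added to the block input
  (residual) and passed through ReLU, so a zero-filter block is the
  identity on non-negative features.  A single-scale mode (all channels at
  extent ``γ``) is kept as an ablation arm.

Activations are channel-last ``(N, T, V, C)`` throughout.
"""

from __future__ import annotations

import numpy as np

from .nn_core import (
    BatchNorm,
    Module,
    PointwiseConv,
    ReLU,
    TemporalConv,
)

__all__ = ["SpatialGraphConv", "MultiscaleTemporalConv", "STGCNBlock"]


class SpatialGraphConv(Module):
    """Subset-wise graph convolution with learnable edge-importance masks.

    Parameters
    ----------
    c_in, c_out
        Feature channels before/after the layer.
    subsets
        ``(Z, V, V)`` partition of the normalized adjacency; ``Z`` must
        be 3 for the centroid-distance strategy.
    """

    def __init__(self, c_in, c_out, subsets, *, rng=None, dtype=np.float32):
        super().__init__()
        subsets = np.asarray(subsets, dtype=dtype)
        if subsets.ndim != 3 or subsets.shape[1] != subsets.shape[2]:
            raise ValueError(f"subsets must be (Z, V, V), got {subsets.shape}")
        if subsets.shape[0] != 3:
            raise ValueError(f"expected 3 partition subsets, got {subsets.shape[0]}")
        rng = rng or np.random.default_rng(0)
        self.subsets = subsets
        self.num_joints = subsets.shape[1]
        scale = np.sqrt(2.0 / (c_in * subsets.shape[0]))
        self.weight = self.register(
            "weight",
            (rng.standard_normal((subsets.shape[0], c_in, c_out)) * scale).astype(dtype),
        )
        self.edge_masks = self.register("edge_masks", np.ones_like(subsets))
        self.bias = self.register("bias", np.zeros(c_out, dtype=dtype))

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] != self.num_joints:
            raise ValueError(
                f"input has {x.shape[2]} joints, graph has {self.num_joints}"
            )
        n, t, v, c = x.shape
        z = self.subsets.shape[0]
        masked = self.subsets * self.edge_masks.value  # (Z, V, V)
        # joint aggregation as one GEMM: rows (n,t,c) times (V, Z·V)
        xt = np.ascontiguousarray(x.transpose(0, 1, 3, 2)).reshape(-1, v)
        aggt = xt @ masked.reshape(z * v, v).T  # (N·T·C, Z·V)
        # (Z, N·T·V, C) layout for the per-subset channel transforms
        agg = np.ascontiguousarray(
            aggt.reshape(n, t, c, z, v).transpose(3, 0, 1, 4, 2)
        ).reshape(z, n * t * v, c)
        w = self.weight.value
        y = agg[0] @ w[0]
        for i in range(1, z):
            y += agg[i] @ w[i]
        y = y.reshape(n, t, v, -1) + self.bias.value
        self._x, self._agg, self._masked = x, agg, masked
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, agg, masked = self._x, self._agg, self._masked
        n, t, v, c = x.shape
        z = self.subsets.shape[0]
        w = self.weight.value
        gflat = grad.reshape(n * t * v, -1)
        # per-subset channel-transform gradients and aggregated-feature grads
        g_agg = np.empty((z, n * t * v, c), dtype=grad.dtype)
        for i in range(z):
            self.weight.grad[i] += agg[i].T @ gflat
            g_agg[i] = gflat @ w[i].T
        self.bias.grad += gflat.sum(axis=0)
        # mask gradient: subsets ⊙ (g_agg ⋅ xᵀ over batch/frame/channel)
        ga_t = (
            g_agg.reshape(z, n, t, v, c)
            .transpose(0, 3, 1, 2, 4)
            .reshape(z * v, -1)
        )
        x_t = np.ascontiguousarray(x.transpose(2, 0, 1, 3)).reshape(v, -1)
        self.edge_masks.grad += self.subsets * (ga_t @ x_t.T).reshape(z, v, v)
        # input gradient: transpose of the aggregation
        gx = np.zeros((n * t * v, c), dtype=grad.dtype)
        ga_rows = g_agg.reshape(z, n, t, v, c)
        mt = masked.transpose(0, 2, 1)  # (Z, V, V): masked[z].T
        for i in range(z):
            gi = np.ascontiguousarray(ga_rows[i].transpose(0, 1, 3, 2)).reshape(-1, v)
            gx += (
                (gi @ mt[i].T).reshape(n, t, c, v).transpose(0, 1, 3, 2).reshape(-1, c)
            )
        gx = gx.reshape(n, t, v, c)
        del self._x, self._agg, self._masked
        return gx


class MultiscaleTemporalConv(Module):
    """Dual-kernel temporal convolution with residual and ReLU.

    In multiscale mode the block holds two filter banks of ``C/2`` output
    channels each, with kernel extents ``gamma`` and ``2·gamma``; their
    outputs are concatenated on the channel axis, batch-normalized, added
    to the (possibly strided) input and rectified.  In single-scale mode a
    single bank of ``C`` filters at extent ``gamma`` replaces the pair.
    """

    def __init__(self, channels, gamma, *, stride=1, multiscale=True,
                 rng=None, dtype=np.float32):
        super().__init__()
        if gamma < 1:
            raise ValueError("gamma must be >= 1")
        if multiscale and channels % 2 != 0:
            raise ValueError("multiscale mode needs an even channel count")
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.gamma = gamma
        self.stride = stride
        self.multiscale = multiscale
        if multiscale:
            half = channels // 2
            self.branch_short = self.add_module(
                "branch_short",
                TemporalConv(channels, half, gamma, stride=stride, rng=rng, dtype=dtype),
            )
            self.branch_long = self.add_module(
                "branch_long",
                TemporalConv(channels, half, 2 * gamma, stride=stride, rng=rng, dtype=dtype),
            )
        else:
            self.branch_short = self.add_module(
                "branch_short",
                TemporalConv(channels, channels, gamma, stride=stride, rng=rng, dtype=dtype),
            )
            self.branch_long = None
        self.bn = self.add_module("bn", BatchNorm(channels, dtype=dtype))
        self.relu = self.add_module("relu", ReLU())

    def forward(self, x: np.ndarray) -> np.ndarray:
        a = self.branch_short(x)
        if self.branch_long is not None:
            b = self.branch_long(x)
            y = np.concatenate([a, b], axis=-1)
        else:
            y = a
        y = self.bn(y)
        res = x[:, :: self.stride] if self.stride > 1 else x
        self._t_in = x.shape[1]
        return self.relu(y + res)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu.backward(grad)
        g_res = g
        gy = self.bn.backward(g)
        if self.branch_long is not None:
            half = self.channels // 2
            gx = self.branch_short.backward(gy[..., :half])
            gx += self.branch_long.backward(gy[..., half:])
        else:
            gx = self.branch_short.backward(gy)
        if self.stride > 1:
            gx[:, :: self.stride] += g_res
        else:
            gx += g_res
        return gx


class STGCNBlock(Module):
    """One backbone block: graph conv → BN → ReLU → MS-TCN, with residual.

    The block-level residual path is the identity when shapes allow, and a
    strided 1×1 channel map otherwise.  Output is rectified, so stacked
    blocks always exchange non-negative features — the regime in which the
    MS-TCN's own residual is exact.
    """

    def __init__(self, c_in, c_out, subsets, gamma, *, stride=1,
                 multiscale=True, residual=True, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.gcn = self.add_module(
            "gcn", SpatialGraphConv(c_in, c_out, subsets, rng=rng, dtype=dtype)
        )
        self.bn = self.add_module("bn", BatchNorm(c_out, dtype=dtype))
        self.relu = self.add_module("relu", ReLU())
        self.tcn = self.add_module(
            "tcn",
            MultiscaleTemporalConv(
                c_out, gamma, stride=stride, multiscale=multiscale, rng=rng, dtype=dtype
            ),
        )
        self.out_relu = self.add_module("out_relu", ReLU())
        if not residual:
            self.residual = None
            self._identity_res = False
        elif c_in == c_out and stride == 1:
            self.residual = None
            self._identity_res = True
        else:
            self.residual = self.add_module(
                "residual",
                PointwiseConv(c_in, c_out, stride=stride, rng=rng, dtype=dtype),
            )
            self._identity_res = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.tcn(self.relu(self.bn(self.gcn(x))))
        if self.residual is not None:
            h = h + self.residual(x)
        elif self._identity_res:
            h = h + x
        return self.out_relu(h)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.out_relu.backward(grad)
        gx = self.gcn.backward(self.bn.backward(self.relu.backward(self.tcn.backward(g))))
        if self.residual is not None:
            gx += self.residual.backward(g)
        elif self._identity_res:
            gx += g
        return gx
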