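"""Two-block weighted 3D convolutional classifier.

A 21x21x21 volume of interest is passed through two feature-extracting blocks
(3D convolution, batch normalization, ReLU, ceil-mode 2x2x2 max pooling). The
first block yields 11^3 feature maps, which are multiplied elementwise
(Hadamard product) by a fixed center-peaked Gaussian weight matrix before the
second block; the resulting 6^3 maps feed a fully connected layer and a
softmax, giving the probability that the input contains significant stenosis.

The network is implemented directly on NumPy arrays: parameters live in a
plain dict of float64 tensors and every layer has an analytic backward pass
(verified against finite differences in the test suite). The sizes involved
(two blocks, 16/32 channels, 21^3 inputs) keep CPU training practical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np


VOI_SIDE = 21
BLOCK1_SIDE = 11
BLOCK2_SIDE = 6

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def _pooled_side(n: int, size: int, stride: int) -> int:
    """Output side of ceil-mode max pooling (no padding)."""
    return math.ceil((n - size) / stride) + 1


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``gaussian_sd`` is the standard deviation, in voxels on the 11^3 feature
    map, of the fixed center-weighting matrix (default 0.75).
    """

    conv_kernel: int = 3
    channels_block1: int = 16
    channels_block2: int = 32
    pool_size: int = 2
    pool_stride: int = 2
    gaussian_sd: float = 0.75
    gaussian_peak: float = 1.0
    n_classes: int = 2
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.conv_kernel % 2 != 1 or self.conv_kernel < 1:
            raise ValueError("conv_kernel must be a positive odd integer")
        if self.gaussian_sd <= 0 or self.gaussian_peak <= 0:
            raise ValueError("gaussian_sd and gaussian_peak must be > 0")
        s1 = _pooled_side(VOI_SIDE, self.pool_size, self.pool_stride)
        s2 = _pooled_side(s1, self.pool_size, self.pool_stride)
        if (s1, s2) != (BLOCK1_SIDE, BLOCK2_SIDE):
            raise ValueError(
                "shape contract violated: pooling must map 21 -> 11 -> 6 "
                f"(got 21 -> {s1} -> {s2} for size={self.pool_size}, "
                f"stride={self.pool_stride})"
            )
        if self.n_classes != 2:
            raise ValueError("the classifier is binary (n_classes = 2)")

    @property
    def fc_in_features(self) -> int:
        return self.channels_block2 * BLOCK2_SIDE**3

    def to_dict(self) -> dict:
        return asdict(self)


def build_gaussian_weight(map_side: int, sd: float, peak: float = 1.0) -> np.ndarray:
    """Center-peaked Gaussian weight matrix for the Hadamard weighting layer.

    w[v] = peak * exp(-||v - c||^2 / (2 sd^2)) with c the center voxel; the
    maximum (= peak) sits at the center and the array is mirror-symmetric
    about it. ``map_side`` must be odd so the center voxel is well defined.
    """
    if map_side % 2 != 1:
        raise ValueError("map_side must be odd (center voxel ambiguous otherwise)")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    c = map_side // 2
    ax = np.arange(map_side) - c
    d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    return peak * np.exp(-d2 / (2.0 * sd * sd))


# ---------------------------------------------------------------------------
# layer primitives (functional, cache-returning)
# ---------------------------------------------------------------------------

def _im2col(x, k):
    """Columns for same-padded stride-1 conv: (B, Cin*k^3, P) with P = D*H*W.

    Built as one contiguous slice-copy per kernel offset, which is far
    cheaper than gathering the transposed sliding-window view.
    """
    B, Cin, D, H, W = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    P = D * H * W
    cols = np.empty((B, Cin, k**3, P), dtype=x.dtype)
    o = 0
    for dz in range(k):
        for dy in range(k):
            for dx_ in range(k):
                cols[:, :, o, :] = xp[
                    :, :, dz : dz + D, dy : dy + H, dx_ : dx_ + W
                ].reshape(B, Cin, P)
                o += 1
    return cols.reshape(B, Cin * k**3, P)


def conv3d_forward(x, weight, bias, need_cache=True):
    """Same-padded stride-1 3D convolution via im2col.

    x: (B, Cin, D, H, W); weight: (Cout, Cin, k, k, k); bias: (Cout,).
    """
    B, Cin, D, H, W = x.shape
    Cout, _, k, _, _ = weight.shape
    cols = _im2col(x, k)
    out = np.matmul(weight.reshape(Cout, -1), cols)  # (B, Cout, P)
    out = out.reshape(B, Cout, D, H, W) + bias.reshape(1, -1, 1, 1, 1)
    cache = (cols, x.shape, weight) if need_cache else None
    return out, cache


def conv3d_backward(dout, cache, need_dx=True):
    cols, xshape, weight = cache
    B, Cin, D, H, W = xshape
    Cout = weight.shape[0]
    dout_r = dout.reshape(B, Cout, -1)
    dweight = np.tensordot(dout_r, cols, axes=([0, 2], [0, 2])).reshape(weight.shape)
    dbias = dout.sum(axis=(0, 2, 3, 4))
    dx = None
    if need_dx:
        # input gradient = same-padded conv with channel-transposed, flipped kernels
        wt = np.ascontiguousarray(
            weight[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        )
        dx, _ = conv3d_forward(dout, wt, np.zeros(Cin, dtype=dout.dtype), need_cache=False)
    return dx, dweight, dbias


def batchnorm_forward(x, gamma, beta, running_mean, running_var, training):
    """Per-channel batch normalization over (B, D, H, W).

    In training mode the batch statistics are used and the running statistics
    (updated in place, momentum 0.1) accumulate for evaluation; eval mode uses
    the running statistics and is deterministic.
    """
    sh = (1, -1, 1, 1, 1)
    if training:
        axes = (0, 2, 3, 4)
        mean = x.mean(axis=axes)
        var = np.einsum("bcdhw,bcdhw->c", x, x) / (
            x.shape[0] * x.shape[2] * x.shape[3] * x.shape[4]
        ) - mean * mean
        np.maximum(var, 0.0, out=var)
        running_mean *= 1.0 - _BN_MOMENTUM
        running_mean += _BN_MOMENTUM * mean
        running_var *= 1.0 - _BN_MOMENTUM
        running_var += _BN_MOMENTUM * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (x - mean.reshape(sh)) * inv.reshape(sh)
    out = gamma.reshape(sh) * xhat + beta.reshape(sh)
    m = x.shape[0] * x.shape[2] * x.shape[3] * x.shape[4]
    cache = (xhat, inv, gamma, training, m)
    return out, cache


def batchnorm_backward(dout, cache):
    xhat, inv, gamma, training, m = cache
    sh = (1, -1, 1, 1, 1)
    axes = (0, 2, 3, 4)
    dgamma = (dout * xhat).sum(axis=axes)
    dbeta = dout.sum(axis=axes)
    dxhat = dout * gamma.reshape(sh)
    if training:
        dx = (
            inv.reshape(sh)
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=axes).reshape(sh)
                - xhat * (dxhat * xhat).sum(axis=axes).reshape(sh)
            )
        )
    else:
        dx = dxhat * inv.reshape(sh)
    return dx, dgamma, dbeta


def maxpool_forward(x):
    """Ceil-mode max pooling, size 2, stride 2 (right-padded with -inf)."""
    B, C, D, H, W = x.shape
    Do, Ho, Wo = (D + 1) // 2, (H + 1) // 2, (W + 1) // 2
    xp = np.pad(
        x,
        ((0, 0), (0, 0), (0, 2 * Do - D), (0, 2 * Ho - H), (0, 2 * Wo - W)),
        constant_values=-np.inf,
    )
    r = xp.reshape(B, C, Do, 2, Ho, 2, Wo, 2)
    r = np.ascontiguousarray(r.transpose(0, 1, 2, 4, 6, 3, 5, 7)).reshape(
        B, C, Do, Ho, Wo, 8
    )
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    cache = (idx, x.shape, (Do, Ho, Wo))
    return out, cache


def maxpool_backward(dout, cache):
    idx, xshape, (Do, Ho, Wo) = cache
    B, C, D, H, W = xshape
    dr = np.zeros((B, C, Do, Ho, Wo, 8), dtype=dout.dtype)
    np.put_along_axis(dr, idx[..., None], dout[..., None], axis=-1)
    dr = dr.reshape(B, C, Do, Ho, Wo, 2, 2, 2)
    dr = np.ascontiguousarray(dr.transpose(0, 1, 2, 5, 3, 6, 4, 7)).reshape(
        B, C, 2 * Do, 2 * Ho, 2 * Wo
    )
    return dr[:, :, :D, :H, :W]


def softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def init_params(config: NetworkConfig) -> dict[str, np.ndarray]:
    """He-uniform conv/FC weights, zero biases, identity batch norm; seeded."""
    rng = np.random.default_rng(config.init_seed)
    k = config.conv_kernel
    c1, c2 = config.channels_block1, config.channels_block2

    def he_uniform(shape, fan_in):
        limit = math.sqrt(6.0 / fan_in)
        return rng.uniform(-limit, limit, size=shape)

    params = {
        "conv1_w": he_uniform((c1, 1, k, k, k), fan_in=k**3),
        "conv1_b": np.zeros(c1),
        "bn1_gamma": np.ones(c1),
        "bn1_beta": np.zeros(c1),
        "bn1_mean": np.zeros(c1),
        "bn1_var": np.ones(c1),
        "conv2_w": he_uniform((c2, c1, k, k, k), fan_in=c1 * k**3),
        "conv2_b": np.zeros(c2),
        "bn2_gamma": np.ones(c2),
        "bn2_beta": np.zeros(c2),
        "bn2_mean": np.zeros(c2),
        "bn2_var": np.ones(c2),
        "fc_w": he_uniform((config.n_classes, config.fc_in_features),
                           fan_in=config.fc_in_features),
        "fc_b": np.zeros(config.n_classes),
    }
    return params


LEARNABLE_KEYS = (
    "conv1_w", "conv1_b", "bn1_gamma", "bn1_beta",
    "conv2_w", "conv2_b", "bn2_gamma", "bn2_beta",
    "fc_w", "fc_b",
)


def count_params(config: NetworkConfig) -> int:
    """Number of learnable scalars (batch-norm running statistics excluded)."""
    k3 = config.conv_kernel**3
    c1, c2 = config.channels_block1, config.channels_block2
    return (
        c1 * k3 + c1 + 2 * c1
        + c2 * c1 * k3 + c2 + 2 * c2
        + config.n_classes * config.fc_in_features + config.n_classes
    )


def _as_batch(x) -> np.ndarray:
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(float)
    if x.ndim == 3:
        x = x[None]
    if x.ndim == 4:
        x = x[:, None]
    if x.shape[2:] != (VOI_SIDE,) * 3 or x.shape[1] != 1:
        raise ValueError(f"input must be (batch of) {VOI_SIDE}^3 volumes, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    return x


def forward_block(x, params, config: NetworkConfig, block_index: int, training=False,
                  caches=None):
    """One feature-extracting block: conv -> batch norm -> ReLU -> max pool."""
    expected = VOI_SIDE if block_index == 1 else BLOCK1_SIDE
    if x.shape[2] != expected:
        raise ValueError(
            f"block {block_index} expects spatial side {expected}, got {x.shape[2]}"
        )
    b = f"bn{block_index}"
    c = f"conv{block_index}"
    out, c_cache = conv3d_forward(x, params[f"{c}_w"], params[f"{c}_b"],
                                  need_cache=caches is not None)
    out, b_cache = batchnorm_forward(
        out, params[f"{b}_gamma"], params[f"{b}_beta"],
        params[f"{b}_mean"], params[f"{b}_var"], training,
    )
    relu_mask = out > 0
    out = out * relu_mask
    out, p_cache = maxpool_forward(out)
    if caches is not None:
        caches[f"block{block_index}"] = (c_cache, b_cache, relu_mask, p_cache)
    return out


def _backward_block(dout, params, caches, block_index, need_dx=True):
    c_cache, b_cache, relu_mask, p_cache = caches[f"block{block_index}"]
    d = maxpool_backward(dout, p_cache)
    d = d * relu_mask
    d, dgamma, dbeta = batchnorm_backward(d, b_cache)
    d, dw, db = conv3d_backward(d, c_cache, need_dx=need_dx)
    grads = {
        f"conv{block_index}_w": dw,
        f"conv{block_index}_b": db,
        f"bn{block_index}_gamma": dgamma,
        f"bn{block_index}_beta": dbeta,
    }
    return d, grads


def forward(x, params, config: NetworkConfig, training=False, caches=None):
    """Full forward pass: probabilities (p_no_stenosis, p_stenosis).

    Accepts a single 21^3 volume or a batch; returns shape (2,) or (n, 2).
    Eval mode (training=False) uses batch-norm running statistics and is
    deterministic.
    """
    single = np.asarray(x).ndim == 3
    xb = _as_batch(x)
    h = forward_block(xb, params, config, 1, training, caches)
    g = build_gaussian_weight(
        BLOCK1_SIDE, config.gaussian_sd, config.gaussian_peak
    ).astype(h.dtype)
    h = h * g[None, None]
    h = forward_block(h, params, config, 2, training, caches)
    B = h.shape[0]
    flat = h.reshape(B, -1)
    logits = flat @ params["fc_w"].T + params["fc_b"]
    probs = softmax(logits)
    if caches is not None:
        caches["gaussian"] = g
        caches["flat"] = flat
        caches["h2_shape"] = h.shape
    return probs[0] if single else probs


def loss_and_grads(params, config: NetworkConfig, x, t_onehot, example_weights):
    """Weighted cross-entropy loss and analytic gradients for one batch.

    ``example_weights`` is the weight of each example's true class. Returns
    (loss, grads dict over LEARNABLE_KEYS). Runs the network in training mode.
    """
    from .training import wcee_loss  # local import to avoid a cycle

    caches: dict = {}
    probs = forward(x, params, config, training=True, caches=caches)
    n = probs.shape[0]
    loss = wcee_loss(probs, t_onehot, example_weights)
    # d(loss)/d(logits) of softmax + weighted CE
    dlogits = example_weights[:, None] * (probs - t_onehot) / n
    grads = {
        "fc_w": dlogits.T @ caches["flat"],
        "fc_b": dlogits.sum(axis=0),
    }
    dflat = dlogits @ params["fc_w"]
    d = dflat.reshape(caches["h2_shape"])
    d, g2 = _backward_block(d, params, caches, 2)
    d = d * caches["gaussian"][None, None]
    _, g1 = _backward_block(d, params, caches, 1, need_dx=False)
    grads.update(g2)
    grads.update(g1)
    return loss, grads


def predict_proba(x, params, config: NetworkConfig, batch_size: int = 64) -> np.ndarray:
    """Eval-mode stenosis probabilities for a stack of VOIs: shape (n,)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 3:
        x = x[None]
    out = []
    for i in range(0, x.shape[0], batch_size):
        out.append(forward(x[i : i + batch_size], params, config, training=False)[:, 1])
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# checkpoint I/O: one .npz file whose 'header' entry is a JSON string
# ---------------------------------------------------------------------------

def save_checkpoint(path, params: dict, config: NetworkConfig, **extra) -> None:
    header = json.dumps({"config": config.to_dict(), **extra})
    np.savez(path, header=np.array(header), **params)


def load_checkpoint(path) -> tuple[dict, NetworkConfig, dict]:
    with np.load(path) as data:
        header = json.loads(str(data["header"]))
        params = {k: data[k].copy() for k in data.files if k != "header"}
    config = NetworkConfig(**header.pop("config"))
    return params, config, header
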