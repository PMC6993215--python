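"""Encoder-decoder segmentation network with index-preserving pooling.

The network is fully convolutional: an encoder of ``depth`` blocks (two
3x3 same-padded convolutions + ReLU each) separated by 2x2
spatial-max-pooling, a two-convolution bottleneck, and a mirrored
decoder.  Spatial-max-pooling records, for every pooling window of every
feature map, the position of the maximum; the matching
spatial-max-unpooling layer in the decoder places each value back at its
recorded position (all other positions exactly zero), so boundary detail
lost to downsampling is restored at the original locations instead of
being smeared by interpolation.  Shortcut connections concatenate each
encoder block's output onto the corresponding decoder level.  A final
1x1 convolution and softmax emit a per-pixel probability simplex over
the four classes [background, NCR/NET, ED, ET].

Everything is implemented directly on numpy arrays (im2col convolutions,
manual backpropagation, Adam), which keeps inference and training exact,
deterministic and dependency-light at the problem sizes this package
targets.  Setting ``use_indices=False`` swaps the decoder's unpooling
for plain nearest-neighbor upsampling (the "plain max-pool + upsampling"
ablation baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .losses import LossConfig, compute_loss, static_weights_from_frequencies
from .patch_engine import Patch2D, PlaneSpec, augment, reorient, _get_plane
from .volume_io import MultiModalVolume


# ---------------------------------------------------------------------------
# Spatial max pooling / unpooling (the index-preserving primitive)

def spatial_max_pool(x: np.ndarray, pool_size: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Max-pool the trailing two axes, recording per-window argmax positions.

    ``x`` may carry any leading axes (batch, channels).  Returns the
    pooled array and an integer index array of the same pooled shape
    whose entries are the flat row-major position of the maximum inside
    its ``pool_size x pool_size`` window; ties resolve to the first
    position in row-major order (``argmax`` semantics), which makes the
    pool/unpool pair deterministic.
    """
    p = int(pool_size)
    *lead, H, W = x.shape
    if H % p or W % p:
        raise ValueError(f"spatial dims ({H},{W}) not divisible by pool size {p}")
    xr = x.reshape(*lead, H // p, p, W // p, p)
    xw = np.moveaxis(xr, -3, -2)  # (..., H/p, W/p, p, p)
    flat = xw.reshape(*lead, H // p, W // p, p * p)
    idx = flat.argmax(axis=-1)
    pooled = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return pooled, idx


def spatial_max_unpool(y: np.ndarray, idx: np.ndarray,
                       out_hw: tuple[int, int]) -> np.ndarray:
    """Place each pooled value at its recorded argmax position.

    Inverse of :func:`spatial_max_pool` on the retained positions: the
    output has ``y``'s values at the stored within-window positions and
    exact zeros elsewhere, so ``pool(unpool(y, idx)) == y``.
    """
    H, W = out_hw
    *lead, Hp, Wp = y.shape
    if idx.shape != y.shape:
        raise ValueError("index stack does not match pooled values")
    if H % Hp or W % Wp or H // Hp != W // Wp:
        raise ValueError(f"output shape ({H},{W}) incompatible with pooled ({Hp},{Wp})")
    p = H // Hp
    flat = np.zeros((*lead, Hp, Wp, p * p), dtype=y.dtype)
    np.put_along_axis(flat, idx[..., None], y[..., None], axis=-1)
    xw = flat.reshape(*lead, Hp, Wp, p, p)
    xr = np.moveaxis(xw, -2, -3)  # (..., Hp, p, Wp, p)
    return xr.reshape(*lead, H, W)


def _tile_idx(idx: np.ndarray, channels: int) -> np.ndarray:
    """Share pooling indices across decoder channel groups.

    The decoder tensor entering an unpooling layer carries a multiple of
    the feature maps recorded by the matching pooling layer (the
    bottleneck doubles the top encoder width); the recorded per-map
    argmax positions are reused by each group of decoder maps.
    """
    c_idx = idx.shape[1]
    if channels == c_idx:
        return idx
    if channels % c_idx:
        raise ValueError(f"{channels} channels not a multiple of {c_idx} index maps")
    return np.repeat(idx, channels // c_idx, axis=1)


def _unpool_gather(d_out: np.ndarray, idx: np.ndarray, p: int) -> np.ndarray:
    """Gather gradients from the argmax positions (backward of unpool)."""
    *lead, H, W = d_out.shape
    xr = d_out.reshape(*lead, H // p, p, W // p, p)
    xw = np.moveaxis(xr, -3, -2).reshape(*lead, H // p, W // p, p * p)
    return np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]


def _upsample_nearest(y: np.ndarray, p: int) -> np.ndarray:
    return y.repeat(p, axis=-2).repeat(p, axis=-1)


def _upsample_nearest_backward(d_out: np.ndarray, p: int) -> np.ndarray:
    *lead, H, W = d_out.shape
    xr = d_out.reshape(*lead, H // p, p, W // p, p)
    return xr.sum(axis=(-3, -1))


# ---------------------------------------------------------------------------
# Convolution (im2col) with manual backward

def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, k: int):
    """Same-padded correlation. x: (B,Cin,H,W); W: (Cout, Cin*k*k)."""
    B, Cin, H, Wd = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B,Cin,H,W,k,k)
    col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B * H * Wd, Cin * k * k
    )
    out = col @ W.T + b
    out = out.reshape(B, H, Wd, -1).transpose(0, 3, 1, 2)
    return out, (col, x.shape, k)


def _conv_backward(d_out: np.ndarray, W: np.ndarray, cache):
    col, x_shape, k = cache
    B, Cin, H, Wd = x_shape
    pad = k // 2
    Cout = d_out.shape[1]
    dcol_out = d_out.transpose(0, 2, 3, 1).reshape(-1, Cout)
    dW = dcol_out.T @ col
    db = dcol_out.sum(axis=0)
    dcol = (dcol_out @ W).reshape(B, H, Wd, Cin, k, k)
    dxp = np.zeros((B, Cin, H + 2 * pad, Wd + 2 * pad), dtype=d_out.dtype)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki:ki + H, kj:kj + Wd] += dcol[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
    dx = dxp[:, :, pad:pad + H, pad:pad + Wd] if pad else dxp
    return dx, dW, db


# ---------------------------------------------------------------------------
# Configuration and model

@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    The full-scale configuration is depth 4, base 32 filters (doubling
    each block, 512 at the bottleneck), 3x3 kernels and 2x2 pooling;
    the scaled-down test profile uses depth 2 with 8 base filters.
    Input H and W must be divisible by ``pool_size ** depth`` (whole-slice
    inference pads reflectively and crops the output back).
    """

    depth: int = 4
    base_filters: int = 32
    kernel_size: int = 3
    pool_size: int = 2
    n_classes: int = 4
    in_channels: int = 4
    use_indices: bool = True  # False -> plain pooling + nearest upsampling

    @property
    def divisor(self) -> int:
        return self.pool_size**self.depth


@dataclass
class TrainConfig:
    """Optimization hyperparameters: Adam with Xavier initialization.

    Full-scale defaults are learning rate 1e-4, batch 16, 20 epochs; the
    scaled-down profile raises the learning rate so a tiny network on a
    few hundred patches converges within a few epochs.
    """

    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    augment: bool = True
    seed: int = 0


class SpatialSegNet:
    """The encoder-bottleneck-decoder network, parameters held as numpy arrays."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        k, F = cfg.kernel_size, cfg.base_filters

        def add_conv(name, cin, cout, ksize):
            fan_in, fan_out = cin * ksize * ksize, cout * ksize * ksize
            a = np.sqrt(6.0 / (fan_in + fan_out))  # Xavier uniform
            self.params[f"{name}_W"] = rng.uniform(-a, a, (cout, cin * ksize * ksize)).astype(np.float32)
            self.params[f"{name}_b"] = np.zeros(cout, dtype=np.float32)

        cin = cfg.in_channels
        self._enc_channels = []
        for d in range(cfg.depth):
            cout = F * 2**d
            add_conv(f"enc{d}a", cin, cout, k)
            add_conv(f"enc{d}b", cout, cout, k)
            self._enc_channels.append(cout)
            cin = cout
        cbot = F * 2**cfg.depth
        add_conv("bota", cin, cbot, k)
        add_conv("botb", cbot, cbot, k)
        cin = cbot
        for d in reversed(range(cfg.depth)):
            cout = F * 2**d
            add_conv(f"dec{d}a", cin + self._enc_channels[d], cout, k)
            add_conv(f"dec{d}b", cout, cout, k)
            cin = cout
        add_conv("head", cin, cfg.n_classes, 1)
        self._adam_state = None

    # -- forward / backward -------------------------------------------------

    def _conv_relu(self, name, x, caches, relu=True):
        k = int(np.sqrt(self.params[f"{name}_W"].shape[1] // x.shape[1]))
        out, cc = _conv_forward(x, self.params[f"{name}_W"], self.params[f"{name}_b"], k)
        mask = None
        if relu:
            mask = out > 0
            out = out * mask
        caches.append((name, cc, mask))
        return out

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Run the network on a batch (B, C, H, W) -> probabilities (B, 4, H, W)."""
        cfg = self.cfg
        dtype = self.params["head_W"].dtype
        x = np.asarray(x, dtype=dtype)
        if x.ndim == 3:
            x = x[None]
        B, C, H, W = x.shape
        if H % cfg.divisor or W % cfg.divisor:
            raise ValueError(
                f"input {H}x{W} not divisible by pool^depth={cfg.divisor}; "
                "use predict_slices for automatic padding"
            )
        caches: list = []
        skips, pools = [], []
        for d in range(cfg.depth):
            x = self._conv_relu(f"enc{d}a", x, caches)
            x = self._conv_relu(f"enc{d}b", x, caches)
            skips.append(x)
            pooled, idx = spatial_max_pool(x, cfg.pool_size)
            pools.append((idx, x.shape[-2:]))
            x = pooled
        x = self._conv_relu("bota", x, caches)
        x = self._conv_relu("botb", x, caches)
        for d in reversed(range(cfg.depth)):
            idx, hw = pools[d]
            if cfg.use_indices:
                x = spatial_max_unpool(x, _tile_idx(idx, x.shape[1]), hw)
            else:
                x = _upsample_nearest(x, cfg.pool_size)
            x = np.concatenate([x, skips[d]], axis=1)
            x = self._conv_relu(f"dec{d}a", x, caches)
            x = self._conv_relu(f"dec{d}b", x, caches)
        logits = self._conv_relu("head", x, caches, relu=False)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=1, keepdims=True)
        if want_cache:
            return probs, {"caches": caches, "pools": pools, "probs": probs,
                           "skip_channels": [s.shape[1] for s in skips]}
        return probs

    def backward(self, cache, d_logits: np.ndarray) -> dict[str, np.ndarray]:
        """Backpropagate d(loss)/d(logits) through the graph; returns grads."""
        cfg = self.cfg
        caches = cache["caches"]
        pools = cache["pools"]
        skip_channels = cache["skip_channels"]
        grads: dict[str, np.ndarray] = {}
        pos = len(caches) - 1

        def back_conv(d, expect_name):
            nonlocal pos
            name, cc, mask = caches[pos]
            assert name == expect_name, (name, expect_name)
            pos -= 1
            if mask is not None:
                d = d * mask
            dx, dW, db = _conv_backward(d, self.params[f"{name}_W"], cc)
            grads[f"{name}_W"] = dW
            grads[f"{name}_b"] = db
            return dx

        d = back_conv(d_logits, "head")
        d_skips = [None] * cfg.depth
        for d_i in range(cfg.depth):
            d = back_conv(d, f"dec{d_i}b")
            d = back_conv(d, f"dec{d_i}a")
            n_skip = skip_channels[d_i]
            d_up, d_skip = d[:, :-n_skip], d[:, -n_skip:]
            d_skips[d_i] = d_skip
            idx, hw = pools[d_i]
            if cfg.use_indices:
                d = _unpool_gather(d_up, _tile_idx(idx, d_up.shape[1]), cfg.pool_size)
            else:
                d = _upsample_nearest_backward(d_up, cfg.pool_size)
        d = back_conv(d, "botb")
        d = back_conv(d, "bota")
        for d_i in reversed(range(cfg.depth)):
            idx, hw = pools[d_i]
            d = spatial_max_unpool(d, idx, hw)  # pooling backward routes to argmax
            d = d + d_skips[d_i]
            d = back_conv(d, f"enc{d_i}b")
            d = back_conv(d, f"enc{d_i}a")
        return grads

    # -- training -----------------------------------------------------------

    def loss_and_grads(self, x, G_onehot, loss_cfg: LossConfig):
        """Forward, evaluate the configured loss, backprop to parameter grads.

        ``G_onehot`` is (B, C, H, W).  The loss sees all batch pixels as
        one pixel population (adaptive Dice weights are computed per
        mini-batch from its ground truth).
        """
        probs, cache = self.forward(x, want_cache=True)
        B, C, H, W = probs.shape
        P = probs.transpose(1, 0, 2, 3).reshape(C, -1)
        G = np.asarray(G_onehot, dtype=np.float64).transpose(1, 0, 2, 3).reshape(C, -1)
        loss, dP = compute_loss(P, G, loss_cfg, grad=True)
        dP = np.asarray(dP, dtype=probs.dtype).reshape(C, B, H, W).transpose(1, 0, 2, 3)
        # chain through softmax: dz = P * (dP - sum_c P_c dP_c)
        inner = (probs * dP).sum(axis=1, keepdims=True)
        d_logits = probs * (dP - inner)
        grads = self.backward(cache, d_logits)
        return float(loss), grads

    def adam_step(self, grads, tc: TrainConfig):
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "m": {k: np.zeros_like(v) for k, v in self.params.items()},
                "v": {k: np.zeros_like(v) for k, v in self.params.items()},
            }
        st = self._adam_state
        st["t"] += 1
        t = st["t"]
        for k, g in grads.items():
            g = g.astype(self.params[k].dtype)
            st["m"][k] = tc.beta1 * st["m"][k] + (1 - tc.beta1) * g
            st["v"][k] = tc.beta2 * st["v"][k] + (1 - tc.beta2) * g * g
            mhat = st["m"][k] / (1 - tc.beta1**t)
            vhat = st["v"][k] / (1 - tc.beta2**t)
            self.params[k] -= tc.learning_rate * mhat / (np.sqrt(vhat) + tc.adam_eps)

    # -- persistence --------------------------------------------------------

    def save(self, path: str) -> None:
        meta = {f"cfg_{k}": np.asarray(v) for k, v in vars(self.cfg).items()}
        np.savez(path, **self.params, **meta)

    @classmethod
    def load(cls, path: str) -> "SpatialSegNet":
        data = np.load(path)
        cfg = NetworkConfig(
            depth=int(data["cfg_depth"]),
            base_filters=int(data["cfg_base_filters"]),
            kernel_size=int(data["cfg_kernel_size"]),
            pool_size=int(data["cfg_pool_size"]),
            n_classes=int(data["cfg_n_classes"]),
            in_channels=int(data["cfg_in_channels"]),
            use_indices=bool(data["cfg_use_indices"]),
        )
        net = cls(cfg, seed=0)
        for k in net.params:
            net.params[k] = data[k]
        return net


# ---------------------------------------------------------------------------
# Training loop

def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((labels.shape[0], n_classes) + labels.shape[1:], dtype=np.float32)
    for c in range(n_classes):
        out[:, c] = labels == c
    return out


def train_network(
    patches: list[Patch2D],
    cfg: NetworkConfig,
    loss_cfg: LossConfig | None = None,
    train_cfg: TrainConfig | None = None,
    val_patches: list[Patch2D] | None = None,
    compute_static_weights: bool = True,
) -> tuple[SpatialSegNet, list[dict]]:
    """Train a network on 2D patches; returns the net and a per-epoch log.

    Static class weights ``ws_c`` for the log-loss term are computed once
    from the training patches (inverse class frequency, mean 1) unless
    disabled.  Augmentation draws one random geometric transform per
    patch per epoch.  Fully deterministic under ``train_cfg.seed``.
    """
    loss_cfg = loss_cfg or LossConfig()
    tc = train_cfg or TrainConfig()
    if compute_static_weights and loss_cfg.variant in ("aggregated", "log_weighted"):
        counts = np.zeros(cfg.n_classes)
        for p in patches:
            counts += np.bincount(p.label.ravel(), minlength=cfg.n_classes)
        loss_cfg = replace(loss_cfg, static_weights=static_weights_from_frequencies(counts))
    rng = np.random.default_rng(tc.seed)
    net = SpatialSegNet(cfg, seed=int(rng.integers(0, 2**31 - 1)))
    history = []
    n = len(patches)
    for epoch in range(tc.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tc.batch_size):
            batch = [patches[i] for i in order[start:start + tc.batch_size]]
            if tc.augment:
                batch = [augment(p, rng) for p in batch]
            x = np.stack([p.image for p in batch])
            g = _one_hot(np.stack([p.label for p in batch]), cfg.n_classes)
            loss, grads = net.loss_and_grads(x, g, loss_cfg)
            net.adam_step(grads, tc)
            losses.append(loss)
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_patches:
            row["val_dice_fg"] = _validation_dice(net, val_patches)
        history.append(row)
    return net, history


def _validation_dice(net: SpatialSegNet, patches: list[Patch2D]) -> float:
    """Foreground (any tumor class) Dice over a patch set."""
    inter = p_sum = g_sum = 0.0
    for p in patches:
        pred = net.forward(p.image[None])[0].argmax(axis=0)
        pf, gf = pred > 0, p.label > 0
        inter += float((pf & gf).sum())
        p_sum += float(pf.sum())
        g_sum += float(gf.sum())
    return 2.0 * inter / max(p_sum + g_sum, 1.0)


# ---------------------------------------------------------------------------
# Whole-volume inference

def predict_slices(net: SpatialSegNet, slices: np.ndarray) -> np.ndarray:
    """Run full-resolution slices (B, C, H, W) with reflective padding."""
    m = net.cfg.divisor
    B, C, H, W = slices.shape
    ph, pw = (-H) % m, (-W) % m
    x = np.pad(slices, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect") if ph or pw else slices
    probs = net.forward(x)
    return probs[:, :, :H, :W]


def predict_volume(
    vol: MultiModalVolume,
    plane: str | PlaneSpec,
    net: SpatialSegNet,
    slice_batch: int = 8,
) -> np.ndarray:
    """Slice a volume along one plane, segment every slice, stack, return axial.

    The network is fully convolutional, so inference runs on whole
    slices at native resolution (no patching).  Output is a (4, S0, S1,
    S2) probability array in the axial frame, normalized per voxel.
    """
    from .patch_engine import reorient_array

    p = _get_plane(plane)
    v = reorient(vol, p)
    data = v.data  # (4, n_slices, H, W)
    n_slices = data.shape[1]
    out = np.empty((net.cfg.n_classes,) + v.shape, dtype=np.float32)
    for s0 in range(0, n_slices, slice_batch):
        batch = data[:, s0:s0 + slice_batch].transpose(1, 0, 2, 3)
        probs = predict_slices(net, batch)  # (b, 4, H, W)
        out[:, s0:s0 + probs.shape[0]] = probs.transpose(1, 0, 2, 3)
    return reorient_array(out, p, inverse=True)
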