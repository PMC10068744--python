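"""Lightweight multi-resolution 3D segmentation network.

The model segments vessels of very different calibres by feeding the *image*
(not the feature maps) to the network at several resolutions: the input
volume is average-pooled by 2^k for scale k, each pooled copy runs through a
narrow convolutional branch, the branch outputs are upsampled back to full
resolution by stride-2 transposed convolutions, concatenated, reweighted by
a convolutional block attention module (CBAM), and reduced to a single
sigmoid probability channel by two final convolutions.  Each branch is
Conv -> BottleConv -> LinkConv -> BottleConv, where

* ``BottleConv(W)`` is a residual bottleneck: 1x1x1 channel squeeze by
  ``bottleneck_ratio``, a 3^3 convolution at reduced width, 1x1x1 expand,
  plus the identity skip — depth at a fraction of the parameters;
* ``LinkConv(W)`` is a one-level U: pool /2, two 3^3 convolutions at
  ``linkconv_expansion`` times the width, transposed-conv back up, concat
  with the un-pooled skip, and a 3^3 fusion convolution.

With the reference widths (8, 12, 16) the whole three-scale network holds
about 0.15 M trainable parameters — roughly 1% of a standard 3D U-Net —
which is what makes blockwise inference over terabyte-scale volumes cheap.

Everything runs on the CPU through the package's numpy autodiff engine
(:mod:`vesselseg._autodiff`); training uses Adam on a per-voxel binary
cross-entropy with the staircase learning-rate schedule
``lr0 * lr_decay^floor(epoch / decay_every)``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from vesselseg import _autodiff as ad
from vesselseg._autodiff import Tensor

__all__ = [
    "NetConfig", "TrainConfig", "Network",
    "build_network", "count_parameters", "forward", "train", "predict_block",
    "normalize_block", "save_checkpoint", "load_checkpoint", "learning_rate_at",
]

CHECKPOINT_SCHEMA = 1
_DEFAULT_WIDTHS = {1: (8,), 2: (8, 12), 3: (8, 12, 16), 4: (8, 12, 16, 20)}


@dataclass(frozen=True)
class NetConfig:
    """Architecture description, including the ablation toggles.

    ``branch_widths`` gives the channel count of the branch at each scale
    (full resolution first).  Toggling ``use_linkconv``/``use_bottleconv``
    off replaces the module with a plain 3^3 convolution of equal width;
    ``use_cbam`` off makes the attention block an identity.
    """

    n_scales: int = 3
    branch_widths: tuple[int, ...] | None = None
    linkconv_expansion: int = 2
    bottleneck_ratio: int = 2
    cbam_reduction: int = 6
    head_width: int = 24
    use_linkconv: bool = True
    use_bottleconv: bool = True
    use_cbam: bool = True
    conv_kernel: int = 3
    pool_kernel: int = 2

    def __post_init__(self) -> None:
        if not 1 <= self.n_scales <= 4:
            raise ValueError(f"n_scales must be 1..4, got {self.n_scales}")
        if self.branch_widths is None:
            object.__setattr__(self, "branch_widths", _DEFAULT_WIDTHS[self.n_scales])
        widths = tuple(int(w) for w in self.branch_widths)
        object.__setattr__(self, "branch_widths", widths)
        if len(widths) != self.n_scales:
            raise ValueError(f"branch_widths {widths} must have n_scales={self.n_scales} entries")
        if any(w % self.bottleneck_ratio for w in widths):
            raise ValueError(f"branch widths {widths} must be divisible by bottleneck_ratio={self.bottleneck_ratio}")

    @property
    def divisibility(self) -> int:
        # deepest branch pools by 2^(n_scales-1), LinkConv pools once more
        return 2 ** self.n_scales

    def halved(self) -> "NetConfig":
        """Width-halved variant (same depth/topology, ~1/4 of the parameters)."""
        widths = tuple(max(self.bottleneck_ratio, w // 2) for w in self.branch_widths)
        return NetConfig(
            n_scales=self.n_scales, branch_widths=widths,
            linkconv_expansion=self.linkconv_expansion, bottleneck_ratio=self.bottleneck_ratio,
            cbam_reduction=self.cbam_reduction, head_width=max(2, self.head_width // 2),
            use_linkconv=self.use_linkconv, use_bottleconv=self.use_bottleconv,
            use_cbam=self.use_cbam,
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol: Adam, BCE loss, staircase learning-rate decay."""

    lr0: float = 1e-3
    lr_decay: float = 0.98
    decay_every: int = 10
    epochs: int = 30
    batch_size: int = 1
    patch_shape: tuple[int, int, int] = (24, 24, 24)
    augment: bool = True
    brightness_range: tuple[float, float] = (0.7, 1.3)
    fg_crop_prob: float = 0.5   # fraction of crops centered on a vessel voxel
    crops_per_epoch: int = 2    # training crops drawn from each block per epoch
    threshold: float = 0.5
    val_every: int = 1
    val_postprocess: bool = True  # validate at the pipeline operating point
    seed: int = 0


def learning_rate_at(tc: TrainConfig, epoch: int) -> float:
    """lr at a 0-based epoch: lr0 * lr_decay^floor(epoch / decay_every)."""
    return tc.lr0 * tc.lr_decay ** (epoch // tc.decay_every)


# ---------------------------------------------------------------------------
# layers


class _Layer:
    def params(self) -> list[Tensor]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor):
                out.append(v)
            elif isinstance(v, _Layer):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, _Layer):
                        out.extend(item.params())
                    elif isinstance(item, Tensor):
                        out.append(item)
        return out


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)
    t = Tensor(w, requires_grad=True)
    return t


class Conv3(_Layer):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.w = _he(rng, (cout, cin, k, k, k), cin * k ** 3)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv3d(x, self.w, self.b)


class TConv2(_Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = _he(rng, (cin, cout, 2, 2, 2), cin * 8)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.tconv2(x, self.w, self.b)


class Linear(_Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = _he(rng, (cout, cin), cin)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.linear(x, self.w, self.b)


class BottleConv(_Layer):
    """Residual bottleneck: 1x1x1 squeeze -> 3^3 conv -> 1x1x1 expand + skip."""

    def __init__(self, width: int, ratio: int, rng: np.random.Generator):
        mid = width // ratio
        self.squeeze = Conv3(width, mid, 1, rng)
        self.conv = Conv3(mid, mid, 3, rng)
        self.expand = Conv3(mid, width, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = ad.relu(self.squeeze(x))
        h = ad.relu(self.conv(h))
        h = self.expand(h)
        return ad.relu(ad.add(h, x))


class LinkConv(_Layer):
    """One-level U: pool /2, convolve wider, upsample, concat skip, fuse."""

    def __init__(self, width: int, expansion: int, rng: np.random.Generator):
        wide = width * expansion
        self.down1 = Conv3(width, wide, 3, rng)
        self.down2 = Conv3(wide, wide, 3, rng)
        self.up = TConv2(wide, width, rng)
        self.fuse = Conv3(2 * width, width, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = ad.avg_pool(x, 2)
        h = ad.relu(self.down1(h))
        h = ad.relu(self.down2(h))
        h = ad.relu(self.up(h))
        h = ad.concat([h, x], axis=0)
        return ad.relu(self.fuse(h))


class PlainConv(_Layer):
    """Equal-width 3^3 convolution; the ablation stand-in for LinkConv/BottleConv."""

    def __init__(self, width: int, rng: np.random.Generator):
        self.conv = Conv3(width, width, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.relu(self.conv(x))


class CBAM(_Layer):
    """Channel then spatial attention reweighting of a feature map."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self.spatial = Conv3(2, 1, 7, rng)

    def __call__(self, x: Tensor) -> Tensor:
        avg = self.fc2(ad.relu(self.fc1(ad.global_avg_pool(x))))
        mx = self.fc2(ad.relu(self.fc1(ad.global_max_pool(x))))
        ch_att = ad.sigmoid(ad.add(avg, mx))
        x = ad.mul(x, Reshape4(ch_att))
        smap = ad.concat([ad.channel_mean(x), ad.channel_max(x)], axis=0)
        sp_att = ad.sigmoid(self.spatial(smap))
        return ad.mul(x, sp_att)


def Reshape4(v: Tensor) -> Tensor:
    """View a channel vector (C,) as (C,1,1,1) for broadcasting."""
    out = v.data[:, None, None, None]

    def backward(g):
        ad._acc(v, g.reshape(v.data.shape))

    return ad._make(out, (v,), backward)


class Branch(_Layer):
    """One resolution branch: pool 2^k -> Conv -> BottleConv -> LinkConv -> BottleConv -> upsample."""

    def __init__(self, scale: int, width: int, cfg: NetConfig, rng: np.random.Generator):
        self.scale = scale
        self.stem = Conv3(1, width, 3, rng)
        mk_bottle = (lambda: BottleConv(width, cfg.bottleneck_ratio, rng)) if cfg.use_bottleconv \
            else (lambda: PlainConv(width, rng))
        self.block1 = mk_bottle()
        self.link = LinkConv(width, cfg.linkconv_expansion, rng) if cfg.use_linkconv \
            else PlainConv(width, rng)
        self.block2 = mk_bottle()
        self.ups = [TConv2(width, width, rng) for _ in range(scale)]

    def __call__(self, x: Tensor) -> Tensor:
        h = ad.avg_pool(x, 2 ** self.scale)
        h = ad.relu(self.stem(h))
        h = self.block1(h)
        h = self.link(h)
        h = self.block2(h)
        for up in self.ups:
            h = ad.relu(up(h))
        return h


class Network(_Layer):
    """The assembled multi-resolution segmentation network."""

    def __init__(self, config: NetConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.branches = [
            Branch(k, w, config, rng) for k, w in enumerate(config.branch_widths)
        ]
        total = sum(config.branch_widths)
        self.cbam = CBAM(total, config.cbam_reduction, rng) if config.use_cbam else None
        self.head1 = Conv3(total, config.head_width, 3, rng)
        self.head2 = Conv3(config.head_width, 1, 3, rng)
        # start near the background prior (vessels are a few percent of the
        # voxels) so early optimization is not spent collapsing the output
        self.head2.b.data[:] = -3.0

    def _check_shape(self, shape: tuple[int, ...]) -> None:
        div = self.config.divisibility
        if any(s % div for s in shape):
            raise ValueError(
                f"input spatial shape {shape} must be divisible by {div} "
                f"(2^n_scales with the in-branch pooling) for n_scales={self.config.n_scales}"
            )

    def forward_logits(self, block: np.ndarray) -> Tensor:
        arr = np.asarray(block, dtype=np.float32)
        if arr.ndim != 3:
            raise ValueError("expected a 3D block")
        self._check_shape(arr.shape)
        x = Tensor(arr[None])  # (1, D, H, W)
        feats = [br(x) for br in self.branches]
        h = ad.concat(feats, axis=0) if len(feats) > 1 else feats[0]
        if self.cbam is not None:
            h = self.cbam(h)
        h = ad.relu(self.head1(h))
        return self.head2(h)

    def __call__(self, block: np.ndarray) -> np.ndarray:
        """Inference forward pass to voxel probabilities in (0, 1); shape-preserving.

        Runs without tape recording; use :meth:`forward_logits` for training.
        """
        from scipy.special import expit

        with ad.no_grad():
            logits = self.forward_logits(block)
        return expit(logits.data[0])

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def load_state(self, state: Sequence[np.ndarray]) -> None:
        ps = self.params()
        if len(ps) != len(state):
            raise ValueError(f"state has {len(state)} arrays, network has {len(ps)} parameters")
        for p, arr in zip(ps, state):
            if p.data.shape != arr.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {arr.shape}")
            p.data = np.asarray(arr, dtype=np.float32).copy()


def build_network(config: NetConfig | None = None, seed: int = 0) -> Network:
    """Assemble the network with seeded He-initialized weights."""
    return Network(config or NetConfig(), seed=seed)


def count_parameters(net: Network) -> int:
    """Exact number of trainable scalars."""
    return int(sum(p.data.size for p in net.params()))


def forward(net: Network, block: np.ndarray) -> np.ndarray:
    """Inference forward pass (no tape): probabilities with the input's shape."""
    with ad.no_grad():
        return net(block)


def normalize_block(block: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Per-block min-max scaling to [0, 1] with a guard for constant blocks."""
    arr = np.asarray(block, dtype=np.float32)
    lo, hi = float(arr.min()), float(arr.max())
    return (arr - lo) / max(hi - lo, eps)


def predict_block(net: Network, block: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Normalize, forward, and binarize one image block (uint8 {0,1})."""
    probs = forward(net, normalize_block(block))
    return (probs > threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params: list[Tensor], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _augment(
    image: np.ndarray,
    truth: np.ndarray,
    patch: tuple[int, int, int],
    tc: TrainConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    # random crop to the training patch shape; with probability fg_crop_prob
    # the crop is centered on a random vessel voxel, so sparse foreground
    # (a few percent of real vessel-channel voxels) is seen often enough
    fg = np.argwhere(truth > 0)
    if len(fg) and rng.uniform() < tc.fg_crop_prob:
        center = fg[int(rng.integers(len(fg)))]
        off = [
            int(np.clip(c - p // 2, 0, max(s - p, 0)))
            for c, s, p in zip(center, image.shape, patch)
        ]
    else:
        off = [int(rng.integers(0, s - p + 1)) if s > p else 0 for s, p in zip(image.shape, patch)]
    sl = tuple(slice(o, o + p) for o, p in zip(off, patch))
    img, tr = image[sl].astype(np.float32), truth[sl]
    if tc.augment:
        perm = tuple(rng.permutation(3))
        img, tr = img.transpose(perm), tr.transpose(perm)
        img = img * float(rng.uniform(*tc.brightness_range))
    return np.ascontiguousarray(img), np.ascontiguousarray(tr)


def _dice(pred: np.ndarray, truth: np.ndarray) -> float:
    tp = float(np.logical_and(pred > 0, truth > 0).sum())
    denom = float((pred > 0).sum() + (truth > 0).sum())
    return 2 * tp / denom if denom else 1.0


def train(
    net: Network,
    dataset,
    tc: TrainConfig,
    log_path: str | Path | None = None,
    progress: Callable[[dict], None] | None = None,
) -> tuple[Network, list[dict]]:
    """Train on a phantom dataset's train split, track validation Dice.

    Returns the network loaded with the best-validation-Dice weights and the
    per-epoch log (epoch, lr, train_loss, val_dice).  Fully deterministic for
    a fixed ``tc.seed``.
    """
    train_pairs = dataset.split("train")
    val_pairs = dataset.split("val")
    if not train_pairs:
        raise ValueError("dataset has an empty train split")
    if not val_pairs:
        raise ValueError("dataset has an empty val split")
    rng = np.random.default_rng(tc.seed)
    opt = _Adam(net.params())
    log: list[dict] = []
    best = (-1.0, None)
    for epoch in range(tc.epochs):
        lr = learning_rate_at(tc, epoch)
        order = np.concatenate(
            [rng.permutation(len(train_pairs)) for _ in range(tc.crops_per_epoch)]
        )
        losses = []
        for idx in order:
            image, truth = train_pairs[int(idx)]
            img, tr = _augment(image, truth, tc.patch_shape, tc, rng)
            logits = net.forward_logits(normalize_block(img))
            loss = ad.bce_with_logits(logits, (tr > 0).astype(np.float32)[None])
            opt.zero_grad()
            loss.backward()
            opt.step(lr)
            losses.append(float(loss.data))
        val_dice = None
        if (epoch + 1) % tc.val_every == 0 or epoch == tc.epochs - 1:
            from vesselseg.postprocess import postprocess_mask

            with ad.no_grad():
                dices = []
                for img, tr in val_pairs:
                    pred = predict_block(net, img, tc.threshold)
                    if tc.val_postprocess:
                        pred = postprocess_mask(pred)
                    dices.append(_dice(pred, tr))
            val_dice = float(np.mean(dices))
            if val_dice > best[0]:
                best = (val_dice, net.state())
        entry = {
            "epoch": epoch,
            "lr": lr,
            "train_loss": float(np.mean(losses)),
            "val_dice": val_dice,
        }
        log.append(entry)
        if progress is not None:
            progress(entry)
    if best[1] is not None:
        net.load_state(best[1])
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["epoch", "lr", "train_loss", "val_dice"])
            writer.writeheader()
            writer.writerows(log)
    return net, log


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(net: Network, path: str | Path) -> None:
    """Write weights plus the embedded NetConfig and a schema version."""
    meta = {"schema": CHECKPOINT_SCHEMA, "config": asdict(net.config)}
    arrays = {f"param_{i:04d}": p.data for i, p in enumerate(net.params())}
    np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> Network:
    """Rebuild a network from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {meta.get('schema')}")
        cfg_dict = meta["config"]
        cfg_dict["branch_widths"] = tuple(cfg_dict["branch_widths"])
        cfg = NetConfig(**cfg_dict)
        net = build_network(cfg)
        keys = sorted(k for k in data.files if k.startswith("param_"))
        net.load_state([data[k] for k in keys])
    return net
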