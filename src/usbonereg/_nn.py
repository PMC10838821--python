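"""Compact CPU trainable encoder-decoder for bone-surface scoring.

A small U-style network (3x3 convolutions, 2x2 max-pooling, nearest
upsampling, skip concatenations, sigmoid output) implemented directly on
numpy with hand-written backpropagation and Adam.  It is sized for
desk-scale experiments (64x64 .. 128x128 frames, tens of images) and
exposes the same ``predict(frame, spacing) -> score_map`` contract as the
classical backend in :mod:`usbonereg.bone_segmentation`.

Loss is binary cross-entropy plus soft-Dice complement (``BCE + 1 - Dice``),
the standard choice for thin, class-imbalanced targets: BCE keeps the
background calibrated while the Dice term gives the sparse foreground a
gradient that does not vanish with class imbalance.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_EPS = 1e-7


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _cols(x: np.ndarray, k: int) -> np.ndarray:
    """Sliding kxk windows of a (N,C,H,W) tensor with 'same' zero padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    s = xp.strides
    N, C, H, W = x.shape
    return np.lib.stride_tricks.as_strided(
        xp, (N, C, H, W, k, k), (s[0], s[1], s[2], s[3], s[2], s[3])
    )


class _Conv:
    """Same-padded kxk convolution with He-initialised weights."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 bias_init: float = 0.0):
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = rng.normal(0.0, scale, size=(cout, cin, k, k))
        self.b = np.full(cout, bias_init, dtype=float)
        self.k = k
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = np.einsum("nchwij,ocij->nohw", _cols(x, self.k), self.W,
                      optimize=True)
        return y + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self.dW = np.einsum("nchwij,nohw->ocij", _cols(x, self.k), dy,
                            optimize=True)
        self.db = dy.sum(axis=(0, 2, 3))
        Wr = self.W[:, :, ::-1, ::-1]
        return np.einsum("nohwij,ocij->nchw", _cols(dy, self.k), Wr,
                         optimize=True)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class _ReLU:
    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, dy):
        return dy * self._m


class _MaxPool2:
    def forward(self, x):
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(N, C, H // 2, W // 2, 4)
        self._arg = flat.argmax(axis=-1)
        self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dy):
        N, C, H, W = self._shape
        out = np.zeros((N, C, H // 2, W // 2, 4))
        np.put_along_axis(out, self._arg[..., None], dy[..., None], axis=-1)
        out = out.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(N, C, H, W)


def _upsample2(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _downgrad2(dy):
    N, C, H, W = dy.shape
    return dy.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class UNetBackend:
    """Trained encoder-decoder; ``predict`` returns a [0,1] score map."""

    def __init__(self, depth: int, base_filters: int, seed: int):
        rng = np.random.default_rng(seed)
        self.depth = depth
        ch = [base_filters * 2**i for i in range(depth)]
        self.enc = [
            _Conv(1 if i == 0 else ch[i - 1], ch[i], 3, rng)
            for i in range(depth)
        ]
        self.dec = [
            _Conv(ch[i] + ch[i - 1], ch[i - 1], 3, rng)
            for i in range(depth - 1, 0, -1)
        ]
        # negative bias: sparse-foreground prior, keeps the initial
        # background probability low
        self.out = _Conv(ch[0], 1, 1, rng, bias_init=-2.0)
        self._relus_e = [_ReLU() for _ in range(depth)]
        self._relus_d = [_ReLU() for _ in range(depth - 1)]
        self._pools = [_MaxPool2() for _ in range(depth - 1)]
        self.loss_history: list[float] = []
        self.train_indices: np.ndarray | None = None
        self.test_indices: np.ndarray | None = None

    # forward producing logits -------------------------------------------
    def _forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        h = x
        for i in range(self.depth):
            h = self._relus_e[i].forward(self.enc[i].forward(h))
            if i < self.depth - 1:
                skips.append(h)
                h = self._pools[i].forward(h)
        self._skip_channels = []
        for j, conv in enumerate(self.dec):
            skip = skips[-(j + 1)]
            h = np.concatenate([_upsample2(h), skip], axis=1)
            self._skip_channels.append(h.shape[1] - skip.shape[1])
            h = self._relus_d[j].forward(conv.forward(h))
        return self.out.forward(h)

    def _backward(self, dz: np.ndarray) -> None:
        dh = self.out.backward(dz)
        dskips = []
        for j in reversed(range(len(self.dec))):
            d = self.dec[j].backward(self._relus_d[j].backward(dh))
            cup = self._skip_channels[j]
            dup, dskip = d[:, :cup], d[:, cup:]
            dskips.append(dskip)
            dh = _downgrad2(dup)
        # reversed decoder loop appends shallowest first: dskips[i] already
        # pairs with encoder level i
        for i in reversed(range(self.depth)):
            if i < self.depth - 1:
                dh = self._pools[i].backward(dh) + dskips[i]
            dh = self.enc[i].backward(self._relus_e[i].backward(dh))

    def _layers(self):
        return [*self.enc, *self.dec, self.out]

    # public API ----------------------------------------------------------
    def predict(self, frame: np.ndarray, spacing=(1.0, 1.0)) -> np.ndarray:
        x = _standardize(np.asarray(frame, dtype=float))
        H, W = x.shape
        m = 2 ** (self.depth - 1)
        ph, pw = (-H) % m, (-W) % m
        if ph or pw:
            x = np.pad(x, ((0, ph), (0, pw)), mode="reflect")
        z = self._forward(x[None, None])
        p = 1.0 / (1.0 + np.exp(-z[0, 0]))
        return p[:H, :W]


def _standardize(img: np.ndarray) -> np.ndarray:
    sd = img.std()
    if sd < 1e-9:
        return np.zeros_like(img)
    return (img - img.mean()) / sd


class _Adam:
    def __init__(self, layers, lr: float):
        self.layers = layers
        self.lr = lr
        self.t = 0
        self.state = {}

    def step(self):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for li, layer in enumerate(self.layers):
            for name, p, g in layer.params():
                key = (li, name)
                if key not in self.state:
                    self.state[key] = (np.zeros_like(p), np.zeros_like(p))
                m, v = self.state[key]
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                self.state[key] = (m, v)
                mh = m / (1 - b1**self.t)
                vh = v / (1 - b2**self.t)
                p -= self.lr * mh / (np.sqrt(vh) + eps)


def _bce_dice_loss_grad(z: np.ndarray, y: np.ndarray):
    """Loss value and gradient w.r.t. logits for BCE + (1 - soft Dice)."""
    p = 1.0 / (1.0 + np.exp(-z))
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    n = y.size
    bce = -np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc))
    inter = float((p * y).sum())
    S = float(p.sum() + y.sum()) + 1.0
    T = 2.0 * inter + 1.0
    dice_soft = T / S
    loss = bce + (1.0 - dice_soft)
    # d(bce)/dz = (p - y)/n ; d(dice)/dp_i = (2 y_i S - T) / S^2
    dz = (p - y) / n - (2.0 * y * S - T) / S**2 * p * (1 - p)
    return float(loss), dz


def train_unet(dataset, cfg) -> UNetBackend:
    """Train :class:`UNetBackend` on ``(frame, mask)`` pairs.

    Deterministic for a fixed ``cfg.seed``.  Raises ``ValueError`` for
    fewer than 8 labelled frames or single-class labels.
    """
    frames = [np.asarray(f, dtype=float) for f, _ in dataset]
    masks = [np.asarray(m).astype(float) for _, m in dataset]
    if len(frames) < 8:
        raise ValueError(f"need at least 8 labelled frames, got {len(frames)}")
    pos = sum(m.sum() for m in masks)
    neg = sum(m.size - m.sum() for m in masks)
    if pos == 0 or neg == 0:
        raise ValueError("labels are single-class; nothing to learn")
    shape = frames[0].shape
    if any(f.shape != shape or m.shape != shape
           for f, m in zip(frames, masks)):
        raise ValueError("all frames/masks must share one shape")

    rng = np.random.default_rng(cfg.seed)
    net = UNetBackend(cfg.depth, cfg.base_filters, seed=int(rng.integers(2**31)))
    n = len(frames)
    order = rng.permutation(n)
    n_train = max(1, int(round(cfg.split_ratio * n)))
    net.train_indices = order[:n_train]
    net.test_indices = order[n_train:]

    X = np.stack([_standardize(frames[i]) for i in net.train_indices])
    Y = np.stack([masks[i] for i in net.train_indices])
    opt = _Adam(net._layers(), cfg.learning_rate)

    for _epoch in range(cfg.epochs):
        Xe, Ye = X.copy(), Y.copy()
        n_aug = int(round(cfg.augment_fraction * n_train))
        blur_idx = rng.choice(n_train, size=n_aug, replace=False)
        for i in blur_idx:
            Xe[i] = ndimage.gaussian_filter(Xe[i], sigma=cfg.blur_sigma)
        flip_idx = rng.choice(n_train, size=n_aug, replace=False)
        Xe[flip_idx] = Xe[flip_idx, :, ::-1]
        Ye[flip_idx] = Ye[flip_idx, :, ::-1]

        perm = rng.permutation(n_train)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n_train, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            xb = Xe[idx][:, None]
            yb = Ye[idx][:, None]
            z = net._forward(xb)
            loss, dz = _bce_dice_loss_grad(z, yb)
            net._backward(dz)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        net.loss_history.append(epoch_loss / max(1, n_batches))
    return net
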