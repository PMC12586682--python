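"""A small convolutional classifier with explicit forward/backward passes.

The network is a 3-block CNN (conv3x3 -> ReLU -> 2x2 max-pool, channel widths
8/16/32) followed by global average pooling and a linear softmax head.  It is
sized for single-CPU training on melt-curve images, where the discriminative
signal is the position and shape of a handful of peaks rather than fine
texture.  Forward and backward passes are written out explicitly (im2col
convolutions), which keeps training fully deterministic under a fixed seed and
gives exact access to the feature-map gradients Grad-CAM needs.

Optimization uses decoupled weight decay (AdamW): the decay is applied
directly to the weights, not mixed into the adaptive gradient moments.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["SmallCNN", "AdamW", "softmax", "cross_entropy_grad"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(probs: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = probs.shape[0]
    loss = float(-np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean())
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*k*k) patches with zero padding 1, stride 1."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((n, c, k * k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i * k + j] = xp[:, :, i:i + h, j:j + w]
    return cols.transpose(0, 3, 4, 1, 2).reshape(n, h * w, c * k * k)


def _col2im(cols: np.ndarray, shape: tuple, k: int = 3) -> np.ndarray:
    """Adjoint of :func:`_im2col` (accumulates overlapping patches)."""
    n, c, h, w = shape
    cols = cols.reshape(n, h, w, c, k * k).transpose(0, 3, 4, 1, 2)
    xp = np.zeros((n, c, h + 2, w + 2), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + h, j:j + w] += cols[:, :, i * k + j]
    return xp[:, :, 1:-1, 1:-1]


class _Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 9
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_in * 9, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = _im2col(x)
        n, c, h, w = x.shape
        out = self._cols @ self.W + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c_out, h, w = grad_out.shape
        g = grad_out.transpose(0, 2, 3, 1).reshape(n, h * w, c_out)
        self.dW = np.einsum("npk,npc->kc", self._cols, g)
        self.db = g.sum(axis=(0, 1))
        grad_cols = g @ self.W.T
        return _col2im(grad_cols, self._shape)


def _maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    arg = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
    return out, arg


def _maxpool2_backward(grad_out: np.ndarray, arg: np.ndarray,
                       shape: tuple) -> np.ndarray:
    n, c, h, w = shape
    g = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad_out.dtype)
    np.put_along_axis(g, arg[..., None], grad_out[..., None], axis=-1)
    g = g.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return g.reshape(n, c, h, w)


class SmallCNN:
    """3-block CNN for ``input_size`` x ``input_size`` single-channel images.

    The final feature map is flattened — peak *position* along the temperature
    axis is the discriminative signal in melt images, so spatial layout is kept
    rather than average-pooled away — and projected to a ``latent_dim`` hidden
    layer whose activations serve as the model's latent features.
    """

    CHANNELS = (8, 16, 32)

    def __init__(self, n_classes: int, input_size: int = 48, seed: int = 0,
                 class_names: list[str] | None = None, latent_dim: int = 64):
        if input_size % 8 != 0:
            raise ValueError("input_size must be divisible by 8")
        rng = np.random.default_rng(seed)
        self.n_classes = n_classes
        self.input_size = input_size
        self.seed = seed
        self.class_names = class_names or [str(i) for i in range(n_classes)]
        c = [1, *self.CHANNELS]
        self.convs = [_Conv3x3(c[i], c[i + 1], rng) for i in range(3)]
        spatial = input_size // 8
        self.flat_dim = self.CHANNELS[-1] * spatial * spatial
        self.latent_dim = latent_dim
        self.fc1W = rng.normal(0.0, np.sqrt(2.0 / self.flat_dim),
                               size=(self.flat_dim, latent_dim)).astype(np.float32)
        self.fc1b = np.zeros(latent_dim, dtype=np.float32)
        self.fcW = rng.normal(0.0, np.sqrt(2.0 / latent_dim),
                              size=(latent_dim, n_classes)).astype(np.float32)
        self.fcb = np.zeros(n_classes, dtype=np.float32)

    # ---- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits for a batch of (N, 1, S, S) float32 images."""
        acts = []
        h = x.astype(np.float32)
        self._pool_args, self._relu_masks, self._pre_pool_shapes = [], [], []
        for conv in self.convs:
            z = conv.forward(h)
            mask = z > 0
            h = z * mask
            self._relu_masks.append(mask)
            acts.append(h)
            self._pre_pool_shapes.append(h.shape)
            h, arg = _maxpool2(h)
            self._pool_args.append(arg)
        self._acts = acts                       # post-ReLU, pre-pool activations
        self._last_conv_act = acts[-1]          # default Grad-CAM target
        self._map_shape = h.shape
        self._flat = h.reshape(h.shape[0], -1)
        z1 = self._flat @ self.fc1W + self.fc1b
        self._latent_mask = z1 > 0
        self._latent = z1 * self._latent_mask
        return self._latent @ self.fcW + self.fcb

    def latent(self, x: np.ndarray) -> np.ndarray:
        """Hidden-layer feature vector (N, latent_dim)."""
        self.forward(x)
        return self._latent.copy()

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[i:i + batch_size])))
        return np.concatenate(out, axis=0)

    def backward(self, grad_logits: np.ndarray,
                 stop_at_conv: int | None = None) -> np.ndarray | None:
        """Backpropagate from the logits; populates per-layer .dW/.db grads.

        With ``stop_at_conv=i`` the gradient at conv block ``i``'s post-ReLU
        feature map is returned without touching parameter gradients
        (the Grad-CAM path).
        """
        g = grad_logits.astype(np.float32)
        g_latent = (g @ self.fcW.T) * self._latent_mask
        if stop_at_conv is None:
            self.dfcW = self._latent.T @ g
            self.dfcb = g.sum(axis=0)
            self.dfc1W = self._flat.T @ g_latent
            self.dfc1b = g_latent.sum(axis=0)
        g_pool = (g_latent @ self.fc1W.T).reshape(self._map_shape)
        for idx in range(2, -1, -1):
            g_act = _maxpool2_backward(g_pool, self._pool_args[idx],
                                       self._pre_pool_shapes[idx])
            if stop_at_conv is not None and idx == stop_at_conv:
                return g_act
            g_z = g_act * self._relu_masks[idx]
            g_pool = self.convs[idx].backward(g_z)
        return None

    # ---- parameters ---------------------------------------------------------

    def parameters(self) -> list[tuple[str, np.ndarray, bool]]:
        """(name, array, decay?) triples; biases are exempt from weight decay."""
        out = []
        for i, conv in enumerate(self.convs):
            out.append((f"conv{i}.W", conv.W, True))
            out.append((f"conv{i}.b", conv.b, False))
        out.append(("fc1.W", self.fc1W, True))
        out.append(("fc1.b", self.fc1b, False))
        out.append(("fc.W", self.fcW, True))
        out.append(("fc.b", self.fcb, False))
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        g = {}
        for i, conv in enumerate(self.convs):
            g[f"conv{i}.W"] = conv.dW
            g[f"conv{i}.b"] = conv.db
        g["fc1.W"] = self.dfc1W
        g["fc1.b"] = self.dfc1b
        g["fc.W"] = self.dfcW
        g["fc.b"] = self.dfcb
        return g

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: arr.copy() for name, arr, _ in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, arr, _ in self.parameters():
            arr[...] = state[name]

    def weights_hash(self) -> str:
        import hashlib
        h = hashlib.sha256()
        for name, arr, _ in self.parameters():
            h.update(name.encode())
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()

    # ---- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.state_dict())
        meta = {"n_classes": self.n_classes, "input_size": self.input_size,
                "seed": self.seed, "class_names": self.class_names,
                "latent_dim": self.latent_dim, "architecture": "smallcnn"}
        (directory / "model.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "SmallCNN":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        model = cls(meta["n_classes"], meta["input_size"], meta["seed"],
                    meta["class_names"], meta.get("latent_dim", 64))
        with np.load(directory / "weights.npz") as npz:
            model.load_state_dict(dict(npz))
        return model


class AdamW:
    """Adam with decoupled weight decay.

    ``step`` consumes the model's current gradients; decay multiplies the
    decayed parameters directly by ``(1 - lr * weight_decay)``.
    """

    def __init__(self, model: SmallCNN, lr: float = 1e-3,
                 weight_decay: float = 0.0, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {name: np.zeros_like(arr) for name, arr, _ in model.parameters()}
        self.v = {name: np.zeros_like(arr) for name, arr, _ in model.parameters()}

    def step(self) -> None:
        self.t += 1
        grads = self.model.gradients()
        for name, arr, decay in self.model.parameters():
            g = grads[name].astype(np.float32)
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mhat = self.m[name] / (1 - self.b1 ** self.t)
            vhat = self.v[name] / (1 - self.b2 ** self.t)
            if decay and self.weight_decay:
                arr *= 1.0 - self.lr * self.weight_decay
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
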