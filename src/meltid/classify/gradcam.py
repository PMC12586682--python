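"""Gradient-weighted class activation mapping for the convolutional backbone.

For a chosen class, channel importance weights are the spatial means of the
class-score gradient at a convolutional feature map; the heatmap is the
rectified channel-weighted sum of activations, min-max normalized to [0, 1]
and upsampled to the input image size.  A constant activation map yields an
all-zero heatmap by convention.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

from .nn import SmallCNN

__all__ = ["gradcam"]


def gradcam(model: SmallCNN, image: np.ndarray, target_layer: int = 2,
            target_class: int | None = None) -> np.ndarray:
    """Heatmap of shape (input_size, input_size), values in [0, 1].

    ``image`` is a single (1, S, S) preprocessed array; ``target_layer``
    indexes the conv block (0-2, default the last).  ``target_class`` defaults
    to the model's own prediction.
    """
    if not isinstance(model, SmallCNN):
        raise TypeError(
            "gradcam requires a convolutional backbone with exposed feature "
            "maps; got " + type(model).__name__)
    if not 0 <= target_layer < len(model.convs):
        raise ValueError(f"target_layer must be in [0, {len(model.convs) - 1}]")
    x = image[None] if image.ndim == 3 else image
    logits = model.forward(x)
    cls = int(logits[0].argmax()) if target_class is None else int(target_class)
    grad = np.zeros_like(logits)
    grad[0, cls] = 1.0
    g_act = model.backward(grad, stop_at_conv=target_layer)
    activations = model._acts[target_layer][0]          # (C, h, w)
    weights = g_act[0].mean(axis=(1, 2))                # (C,)
    cam = np.maximum((weights[:, None, None] * activations).sum(axis=0), 0.0)
    img = Image.fromarray(cam.astype(np.float32), mode="F")
    img = img.resize((model.input_size, model.input_size), Image.BILINEAR)
    cam = np.asarray(img, dtype=np.float32)
    lo, hi = float(cam.min()), float(cam.max())
    if hi - lo < 1e-12:
        return np.zeros((model.input_size, model.input_size), dtype=np.float32)
    return (cam - lo) / (hi - lo)
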