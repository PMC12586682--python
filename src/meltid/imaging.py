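"""Deterministic rendering of curve representations into classifier images.

Every image of a given kind within one dataset shares identical axis limits,
so a 0.5 degC Tm shift moves the drawn curve by a fixed number of pixels —
absolute peak position is preserved as a visual feature.  Axis limits are
computed once from the training split only (5% padding), never per sample,
to keep test-set information out of the rendering.  No legend or species text
is drawn: label text in training images would leak class identity.

PNG encoding goes through Pillow with fixed settings and no timestamp or
software metadata, so identical inputs yield byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
from pathlib import Path
from typing import Iterable, Sequence

import matplotlib
matplotlib.use("Agg", force=True)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from PIL import Image

from .curves import CurveSet

__all__ = ["RenderStyle", "CURVE_KINDS", "compute_axis_limits", "render",
           "render_dataset", "manifest_hash"]

#: The three representations used as classifier inputs.
CURVE_KINDS = ("melt", "hrm", "derivative_hrm")

_KIND_ATTR = {"melt": "melt_derivative", "hrm": "hrm_normalized",
              "derivative_hrm": "derivative_hrm", "difference": "difference"}


@dataclasses.dataclass
class RenderStyle:
    """Fixed image geometry and global axis limits.

    ``axis_limits`` maps curve kind -> ((x_min, x_max), (y_min, y_max)); it
    must be identical for every image of that kind in a dataset.
    """

    width_px: int = 224
    height_px: int = 224
    line_width_px: float = 3.0
    axis_limits: dict = dataclasses.field(default_factory=dict)
    draw_axes: bool = True
    background: str = "white"
    dpi: int = 112

    def limits_for(self, kind: str) -> tuple[tuple[float, float], tuple[float, float]]:
        if kind not in self.axis_limits:
            raise ValueError(
                f"no axis limits set for kind {kind!r}; call compute_axis_limits first")
        return self.axis_limits[kind]


def compute_axis_limits(curvesets: Sequence[CurveSet],
                        kinds: Iterable[str] = CURVE_KINDS,
                        pad: float = 0.05) -> dict:
    """Global per-kind axis limits from a collection of curve sets.

    Intended to be called on the training split only; y-range is the pooled
    min/max padded by ``pad`` of the span, x-range is the shared grid.
    """
    if not curvesets:
        raise ValueError("need at least one curve set")
    limits = {}
    for kind in kinds:
        attr = _KIND_ATTR[kind]
        ys = [getattr(cs, attr) for cs in curvesets if getattr(cs, attr) is not None]
        if not ys:
            raise ValueError(f"no curves of kind {kind!r} present")
        lo = min(float(np.min(y)) for y in ys)
        hi = max(float(np.max(y)) for y in ys)
        span = (hi - lo) or 1.0
        grid = curvesets[0].grid
        limits[kind] = ((float(grid[0]), float(grid[-1])),
                        (lo - pad * span, hi + pad * span))
    return limits


def render(curves: CurveSet, kind: str, style: RenderStyle) -> bytes:
    """Render one representation to PNG bytes (RGB, fixed geometry).

    Deterministic: identical curve set + style produce byte-identical PNGs.
    """
    attr = _KIND_ATTR.get(kind)
    if attr is None:
        raise ValueError(f"unknown curve kind {kind!r}")
    y = getattr(curves, attr)
    if y is None:
        raise ValueError(f"curve kind {kind!r} missing from CurveSet {curves.run_id!r}")
    if not np.all(np.isfinite(y)):
        bad = np.flatnonzero(~np.isfinite(y))
        raise ValueError(f"non-finite values at indices {bad[:10].tolist()}")

    (x_lim, y_lim) = style.limits_for(kind)
    fig = plt.figure(figsize=(style.width_px / style.dpi, style.height_px / style.dpi),
                     dpi=style.dpi, facecolor=style.background)
    if style.draw_axes:
        ax = fig.add_axes((0.16, 0.13, 0.80, 0.83))
        ax.tick_params(labelsize=5)
    else:
        ax = fig.add_axes((0.0, 0.0, 1.0, 1.0))
        ax.set_axis_off()
    ax.set_facecolor(style.background)
    ax.plot(curves.grid, y, color="black", linewidth=style.line_width_px)
    ax.set_xlim(*x_lim)
    ax.set_ylim(*y_lim)

    fig.canvas.draw()
    buf = np.asarray(fig.canvas.buffer_rgba())[:, :, :3].copy()
    plt.close(fig)
    img = Image.fromarray(buf, mode="RGB")
    if img.size != (style.width_px, style.height_px):
        img = img.resize((style.width_px, style.height_px), Image.BILINEAR)
    out = io.BytesIO()
    img.save(out, format="PNG", optimize=False, compress_level=6)
    return out.getvalue()


def render_dataset(curvesets: Sequence[CurveSet], out_dir: str | Path,
                   style: RenderStyle,
                   kinds: Iterable[str] = CURVE_KINDS) -> pd.DataFrame:
    """Render every run in every kind; return the image manifest.

    Filenames encode run id and kind only; species labels live solely in the
    returned manifest (image_path, run_id, kind, species_label).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seen_ids = set()
    rows = []
    for cs in curvesets:
        if cs.run_id in seen_ids:
            raise ValueError(f"duplicate run id {cs.run_id!r} in dataset")
        seen_ids.add(cs.run_id)
        for kind in kinds:
            png = render(cs, kind, style)
            path = out_dir / f"{cs.run_id}_{kind}.png"
            path.write_bytes(png)
            rows.append({"image_path": str(path), "run_id": cs.run_id,
                         "kind": kind, "species_label": cs.species_label})
    return pd.DataFrame(rows)


def manifest_hash(manifest: pd.DataFrame) -> str:
    """Stable hash of a manifest's relative content (for regression checks)."""
    df = manifest.copy()
    if "image_path" in df.columns:
        df["image_path"] = df["image_path"].map(lambda p: Path(p).name)
    payload = df.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()
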