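"""Normalization, heatmap overlay rendering and animation encoding.

Two complementary normalizations give a CAM stack its meaning: *local*
normalization rescales each layer's map by that layer's own min/max (what
matters at this layer?), while *global* normalization rescales every map by
the single min/max over all layers (which layer matters most overall?).
Under global normalization a layer whose activations are weak relative to
the rest of the network appears as an attenuated version of its local map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v2 as imageio
import numpy as np
from matplotlib import colormaps
from PIL import Image, ImageDraw

from .cam_engine import CAMFrame
from .model_graph import LayerRef

logger = logging.getLogger(__name__)


@dataclass
class CAMStack:
    """Ordered CAM frames over a model's target layers, with global extrema."""

    frames: list[CAMFrame]
    method: str = ""
    target_class: int = -1
    image_id: str = ""
    global_min: float = field(init=False)
    global_max: float = field(init=False)

    def __post_init__(self):
        self.frames = sorted(self.frames, key=lambda f: f.layer.index)
        if self.frames:
            self.global_min = float(min(f.raw_map.min() for f in self.frames))
            self.global_max = float(max(f.raw_map.max() for f in self.frames))
        else:
            self.global_min = self.global_max = 0.0

    def __len__(self):
        return len(self.frames)


@dataclass
class RenderedFrame:
    """An RGB overlay frame plus its caption and normalization tag."""

    rgb: np.ndarray  # (H, W, 3) uint8
    caption: str
    normalization: str
    layer: LayerRef


def normalize_local(frame: CAMFrame | np.ndarray) -> np.ndarray:
    """Rescale one map to [0, 1] by its own min/max; constant maps become 0."""
    raw = frame.raw_map if isinstance(frame, CAMFrame) else np.asarray(frame, dtype=float)
    mn, mx = float(raw.min()), float(raw.max())
    if mx == mn:
        name = frame.layer.name if isinstance(frame, CAMFrame) else "<map>"
        logger.warning("degenerate constant CAM frame at %s; normalized to zeros", name)
        return np.zeros_like(raw)
    return (raw - mn) / (mx - mn)


def normalize_global(stack: CAMStack) -> list[np.ndarray]:
    """Rescale every frame by the stack-wide (min, max) pair."""
    if not stack.frames:
        raise ValueError("cannot globally normalize an empty CAM stack")
    gmn, gmx = stack.global_min, stack.global_max
    if gmx == gmn:
        logger.warning("all CAM frames constant and equal; global normalization yields zeros")
        return [np.zeros_like(f.raw_map) for f in stack.frames]
    return [(f.raw_map - gmn) / (gmx - gmn) for f in stack.frames]


def _to_rgb01(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim == 3 and img.shape[0] in (1, 3):  # channel-first
        img = np.moveaxis(img, 0, -1)
    if img.ndim == 2:
        img = img[..., None]
    if img.shape[-1] == 1:
        img = np.repeat(img, 3, axis=-1)
    return np.clip(img, 0.0, 1.0)


def render_overlay(image: np.ndarray, unit_map: np.ndarray, layer: LayerRef,
                   colormap: str = "jet", alpha: float = 0.5,
                   normalization: str = "local") -> RenderedFrame:
    """Alpha-blend a colormapped unit map onto the image and stamp a caption."""
    unit_map = np.asarray(unit_map, dtype=float)
    if unit_map.min() < -1e-9 or unit_map.max() > 1 + 1e-9:
        raise ValueError("unit_map must lie in [0, 1]")
    img = _to_rgb01(image)
    if img.shape[:2] != unit_map.shape:
        raise ValueError(f"image {img.shape[:2]} and map {unit_map.shape} shapes differ")
    heat = colormaps[colormap](np.clip(unit_map, 0.0, 1.0))[..., :3]
    blended = (1.0 - alpha) * img + alpha * heat
    rgb = (np.clip(blended, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    caption = f"[{layer.index}] {layer.name} ({normalization})"
    pil = Image.fromarray(rgb)
    ImageDraw.Draw(pil).text((2, 2), caption, fill=(255, 255, 255))
    return RenderedFrame(rgb=np.asarray(pil), caption=caption,
                         normalization=normalization, layer=layer)


def _frame_filename(i: int, layer_name: str) -> str:
    safe = layer_name.replace("/", "_").replace(" ", "_")
    return f"{i:04d}_{safe}.png"


def encode_animation(frames: list[RenderedFrame], fps: float, out_dir: str | Path,
                     basename: str = "animation", make_gif: bool = False,
                     frame_dirname: str = "frames") -> dict:
    """Write per-frame PNGs and encode the frame sequence into a video.

    Frames are written as zero-padded-index PNGs in layer order and encoded
    to MP4 when an H.264 encoder is available; otherwise the animation falls
    back to GIF with a warning.  Returns paths of everything written.
    """
    if not frames:
        raise ValueError("cannot encode an animation with zero frames")
    shapes = {f.rgb.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"frames have mismatched dimensions: {shapes}")
    out_dir = Path(out_dir)
    frame_dir = out_dir / frame_dirname
    frame_dir.mkdir(parents=True, exist_ok=True)
    png_paths = []
    for i, f in enumerate(frames):
        p = frame_dir / _frame_filename(i, f.layer.name)
        Image.fromarray(f.rgb).save(p)
        png_paths.append(p)

    result = {"frames": png_paths, "video": None, "gif": None}
    mp4_path = out_dir / f"{basename}.mp4"
    try:
        with imageio.get_writer(mp4_path, fps=fps, codec="libx264",
                                pixelformat="yuv420p") as writer:
            for f in frames:
                writer.append_data(f.rgb)
        result["video"] = mp4_path
    except Exception as exc:  # no ffmpeg backend available
        warnings.warn(f"MP4 encoder unavailable ({exc}); falling back to GIF")
        make_gif = True
        if mp4_path.exists():
            mp4_path.unlink()
    if make_gif:
        gif_path = out_dir / f"{basename}.gif"
        imageio.mimsave(gif_path, [f.rgb for f in frames], duration=1000.0 / fps, loop=0)
        result["gif"] = gif_path
    return result
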