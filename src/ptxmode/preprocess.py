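"""Turn raw clips and M-mode captures into fixed-size model-ready segments.

The preprocessing chain mirrors a typical point-of-care ultrasound workflow:
frames are pulled out of B-mode clips, the on-screen settings bar is cropped
away with device-specific coordinates, a long M-mode capture is split into
many overlapping one-second windows (a cheap way to multiply a small number
of captures into a large training set), and every segment is finally resized
to the square input the classifier expects, with the single grayscale
channel replicated three times.

Rolling-window offsets are equally spaced and endpoint-inclusive: window
``i`` of ``n`` starts at ``round(i * (span - w) / (n - 1))``, so the first
window starts at 0 and the last ends flush with the capture span. Splitting
is an exact crop — no resampling happens until the final resize.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage.transform import resize as _sk_resize

from ptxmode.usim import BmodeClip, MmodeImage

__all__ = [
    "CropRegion",
    "RollingWindowConfig",
    "GeometryError",
    "extract_frames",
    "crop_and_resize",
    "rolling_window_split",
    "rolling_offsets",
    "to_three_channel",
]


class GeometryError(ValueError):
    """A crop or window does not fit inside its source image."""


@dataclass(frozen=True)
class CropRegion:
    """Pixel rectangle: top-left corner (x, y), width w, height h (0-based)."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise GeometryError(f"crop corner ({self.x},{self.y}) negative")
        if self.w < 1 or self.h < 1:
            raise GeometryError(f"crop size {self.w}x{self.h} must be >= 1x1")

    def check_inside(self, image: np.ndarray) -> None:
        H, W = image.shape[:2]
        if self.y + self.h > H or self.x + self.w > W:
            raise GeometryError(
                f"crop (x={self.x}, y={self.y}, w={self.w}, h={self.h}) "
                f"exceeds image of size {W}x{H}"
            )


@dataclass(frozen=True)
class RollingWindowConfig:
    """How to split one capture window into overlapping segments.

    ``window`` gives the segment size and vertical extent; ``window.x`` is
    the left edge of the capture span inside the source image and
    ``capture_span_px`` its horizontal extent. The default 100 segments from
    a 5-s capture means consecutive one-second windows overlap heavily.
    """

    n_segments: int = 100
    window: CropRegion = CropRegion(0, 0, 100, 128)
    capture_span_px: int = 500

    def __post_init__(self) -> None:
        if self.n_segments < 2:
            raise GeometryError(f"n_segments={self.n_segments} must be >= 2")
        if self.window.w > self.capture_span_px:
            raise GeometryError(
                f"window width {self.window.w} exceeds capture span "
                f"{self.capture_span_px}"
            )


def extract_frames(clip: BmodeClip | str | Path) -> list[np.ndarray]:
    """Return the ordered frames of a clip (in-memory stack or TIFF file)."""
    if isinstance(clip, BmodeClip):
        frames = [np.asarray(f) for f in clip.frames]
    else:
        path = Path(clip)
        if not path.exists():
            raise IOError(f"clip file not found: {path}")
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        frames = [np.asarray(f) for f in stack]
    if len(frames) == 0:
        raise IOError("clip contains no frames")
    return frames


def crop_and_resize(image: np.ndarray, crop: CropRegion,
                    target_side: int) -> np.ndarray:
    """Crop a rectangle and bilinearly resize it to a square.

    Aspect ratio is *not* preserved — the crop is stretched to
    ``target_side``² exactly as a batch image-resize tool would do it.
    """
    if target_side < 8:
        raise GeometryError(f"target_side={target_side} must be >= 8")
    crop.check_inside(image)
    sub = image[crop.y:crop.y + crop.h, crop.x:crop.x + crop.w]
    if sub.shape[:2] == (target_side, target_side):
        return sub.copy()
    return _sk_resize(sub, (target_side, target_side), order=1,
                      mode="edge", anti_aliasing=False, preserve_range=True)


def rolling_offsets(span: int, width: int, n: int) -> list[int]:
    """Endpoint-inclusive equally spaced offsets: round(i*(span-w)/(n-1))."""
    return [int(round(i * (span - width) / (n - 1))) for i in range(n)]


def rolling_window_split(mmode: MmodeImage | np.ndarray,
                         cfg: RollingWindowConfig) -> list[np.ndarray]:
    """Split a capture into ``cfg.n_segments`` exact-crop windows.

    Each output is the ``window.w`` × ``window.h`` subarray starting at
    horizontal offset ``window.x + offset_i``; offsets are non-decreasing,
    the first is 0 and the last is ``capture_span_px - window.w``.
    """
    pixels = mmode.pixels if isinstance(mmode, MmodeImage) else np.asarray(mmode)
    win = cfg.window
    if win.x + cfg.capture_span_px > pixels.shape[1]:
        raise GeometryError(
            f"capture span [{win.x}, {win.x + cfg.capture_span_px}) exceeds "
            f"image width {pixels.shape[1]}"
        )
    if win.y + win.h > pixels.shape[0]:
        raise GeometryError(
            f"window rows [{win.y}, {win.y + win.h}) exceed image height "
            f"{pixels.shape[0]}"
        )
    offsets = rolling_offsets(cfg.capture_span_px, win.w, cfg.n_segments)
    return [
        pixels[win.y:win.y + win.h, win.x + off:win.x + off + win.w].copy()
        for off in offsets
    ]


def to_three_channel(image: np.ndarray) -> np.ndarray:
    """Replicate a single grayscale channel into an H×W×3 stack."""
    if image.ndim == 3 and image.shape[2] == 3:
        return image
    if image.ndim != 2:
        raise GeometryError(f"expected 2-D grayscale image, got {image.shape}")
    return np.repeat(image[:, :, None], 3, axis=2)


def segment_images(images: list[MmodeImage], cfg: RollingWindowConfig,
                   target_side: int) -> tuple[np.ndarray, np.ndarray]:
    """Full M-mode pipeline: split every capture, resize, stack, label.

    Returns ``(X, y)`` with ``X`` of shape (N, side, side) in [0, 1] and
    ``y`` integer labels (1 = PTX positive).
    """
    segs, labels = [], []
    for im in images:
        lab = 1 if im.spec.ptx_positive else 0
        for seg in rolling_window_split(im, cfg):
            full = CropRegion(0, 0, seg.shape[1], seg.shape[0])
            segs.append(crop_and_resize(seg, full, target_side))
            labels.append(lab)
    return np.stack(segs), np.asarray(labels, dtype=np.int64)
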