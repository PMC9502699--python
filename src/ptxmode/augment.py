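"""Cumulative augmentation levels for closing an appearance domain gap.

Level 0 leaves images untouched. Level 1 adds the conventional geometric
augmentations (random horizontal/vertical reflection and a 0.8–1.2× zoom),
applied to training images only. Level 2 additionally histogram-matches
*every* image — training, validation and test alike — to one fixed reference
image from the target domain using a 64-bin specification; this is a
preprocessing step rather than an augmentation, which is why it touches all
roles. Level 3 finally replaces each training image with one
brightness-jittered copy (offset ~ U(−0.5, 0.5)) and one contrast-jittered
copy (gain ~ U(0.7, 1.4) about mid-gray), doubling the training set.

All operators act on grayscale floats in [0, 1], preserve shape, clip back
into range, and are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "AugmentationPlan",
    "flip",
    "zoom",
    "histogram_match",
    "jitter",
    "build_training_set",
    "histogram_counts",
    "emd_64bin",
]

ZOOM_RANGE = (0.8, 1.2)
BRIGHTNESS_LIMIT = 0.5
CONTRAST_RANGE = (0.7, 1.4)
HISTOGRAM_BINS = 64


class AugmentationError(ValueError):
    pass


@dataclass
class AugmentationPlan:
    """Which cumulative augmentation level applies, and with what knobs.

    Levels are cumulative: level *k* applies every operator of levels ≤ *k*.
    A ``reference`` image (target-domain appearance) is mandatory from
    level 2 upward.
    """

    level: int = 0
    zoom_range: tuple[float, float] = ZOOM_RANGE
    brightness_limit: float = BRIGHTNESS_LIMIT
    contrast_range: tuple[float, float] = CONTRAST_RANGE
    histogram_bins: int = HISTOGRAM_BINS
    reference: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.level not in (0, 1, 2, 3):
            raise AugmentationError(f"level={self.level} not in 0..3")
        if self.histogram_bins < 2:
            raise AugmentationError(
                f"histogram_bins={self.histogram_bins} must be >= 2"
            )
        if self.level >= 2 and self.reference is None:
            raise AugmentationError(
                "augmentation level >= 2 requires a reference image for "
                "histogram matching"
            )


def _check_gray01(image: np.ndarray, what: str = "image") -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise AugmentationError(f"{what} must be 2-D grayscale, got {arr.shape}")
    if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
        raise AugmentationError(f"{what} intensities must lie in [0, 1]")
    return np.clip(arr, 0.0, 1.0)


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

def flip(image: np.ndarray, axis: str) -> np.ndarray:
    """Mirror an image: ``axis='x'`` reverses columns, ``'y'`` reverses rows."""
    if axis == "x":
        return np.asarray(image)[:, ::-1].copy()
    if axis == "y":
        return np.asarray(image)[::-1, :].copy()
    raise AugmentationError(f"unknown flip axis {axis!r} (expected 'x' or 'y')")


def zoom(image: np.ndarray, scale: float | None = None,
         seed: int | None = None,
         scale_range: tuple[float, float] = ZOOM_RANGE) -> np.ndarray:
    """Center-anchored rescale that preserves the output shape.

    ``scale > 1`` enlarges and crops the center back; ``scale < 1`` shrinks
    and pads reflectively (reflection avoids dark borders that would
    correlate with class). If ``scale`` is None it is drawn uniformly from
    ``scale_range`` using ``seed``.
    """
    img = np.asarray(image, dtype=np.float64)
    if scale is None:
        rng = np.random.default_rng(seed)
        scale = float(rng.uniform(*scale_range))
    if not scale_range[0] - 1e-9 <= scale <= scale_range[1] + 1e-9:
        raise AugmentationError(
            f"zoom scale {scale} outside [{scale_range[0]}, {scale_range[1]}]"
        )
    if abs(scale - 1.0) < 1e-12:
        return img.copy()
    H, W = img.shape
    newH, newW = max(1, round(H * scale)), max(1, round(W * scale))
    resized = _sk_resize(img, (newH, newW), order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
    if scale > 1.0:
        top, left = (newH - H) // 2, (newW - W) // 2
        out = resized[top:top + H, left:left + W]
    else:
        pad_t = (H - newH) // 2
        pad_l = (W - newW) // 2
        out = np.pad(resized,
                     ((pad_t, H - newH - pad_t), (pad_l, W - newW - pad_l)),
                     mode="reflect")
    return np.clip(out, 0.0, 1.0)


def histogram_counts(image: np.ndarray, bins: int = HISTOGRAM_BINS) -> np.ndarray:
    """Counts over ``bins`` equal-width intensity bins on [0, 1]."""
    return np.histogram(np.asarray(image).ravel(), bins=bins, range=(0.0, 1.0))[0]


def histogram_match(image: np.ndarray, reference: np.ndarray,
                    bins: int = HISTOGRAM_BINS) -> np.ndarray:
    """Binned histogram specification toward a reference image.

    Both histograms are taken over ``bins`` equal-width bins on [0, 1]. Each
    source bin *j* is mapped, via the monotone CDF-matching rule, to the
    center of the first reference bin whose cumulative mass reaches the
    source CDF at *j*. Matching ``reference == image`` reproduces the input
    up to bin quantization (every pixel moves to its own bin center).
    """
    img = _check_gray01(image, "image")
    ref = _check_gray01(reference, "reference")
    if bins < 2:
        raise AugmentationError(f"bins={bins} must be >= 2")

    edges = np.linspace(0.0, 1.0, bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    cdf_img = np.cumsum(np.histogram(img.ravel(), bins=edges)[0])
    cdf_img = cdf_img / cdf_img[-1]
    cdf_ref = np.cumsum(np.histogram(ref.ravel(), bins=edges)[0])
    cdf_ref = cdf_ref / cdf_ref[-1]

    # monotone lookup: source bin j -> first ref bin k with cdf_ref[k] >= cdf_img[j]
    lut = np.searchsorted(cdf_ref, cdf_img - 1e-12)
    lut = np.minimum(lut, bins - 1)

    src_bins = np.minimum((img * bins).astype(int), bins - 1)
    return np.clip(centers[lut[src_bins]], 0.0, 1.0)


def jitter(image: np.ndarray, kind: str, seed: int | None = None,
           amount: float | None = None) -> np.ndarray:
    """Random brightness or contrast perturbation.

    brightness: ``pixel + b`` with ``b ~ U(-0.5, 0.5)``;
    contrast:   ``0.5 + g * (pixel - 0.5)`` with ``g ~ U(0.7, 1.4)``.
    Pass ``amount`` to fix the draw explicitly. Result clipped to [0, 1].
    """
    img = _check_gray01(image, "image")
    rng = np.random.default_rng(seed)
    if kind == "brightness":
        b = float(rng.uniform(-BRIGHTNESS_LIMIT, BRIGHTNESS_LIMIT)) \
            if amount is None else float(amount)
        out = img + b
    elif kind == "contrast":
        g = float(rng.uniform(*CONTRAST_RANGE)) if amount is None else float(amount)
        out = 0.5 + g * (img - 0.5)
    else:
        raise AugmentationError(
            f"unknown jitter kind {kind!r} (expected 'brightness' or 'contrast')"
        )
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# dataset-level application
# ---------------------------------------------------------------------------

def _random_flip_zoom(image: np.ndarray, rng: np.random.Generator,
                      zoom_range: tuple[float, float]) -> tuple[np.ndarray, dict]:
    """One random draw of the level-1 geometric operators for one image."""
    draws = {
        "flip_x": bool(rng.random() < 0.5),
        "flip_y": bool(rng.random() < 0.5),
        "zoom": float(rng.uniform(*zoom_range)),
    }
    out = image
    if draws["flip_x"]:
        out = flip(out, "x")
    if draws["flip_y"]:
        out = flip(out, "y")
    out = zoom(out, scale=draws["zoom"], scale_range=zoom_range)
    return out, draws


def build_training_set(
    roles: dict[str, tuple[np.ndarray, np.ndarray]],
    plan: AugmentationPlan,
) -> tuple[dict[str, tuple[np.ndarray, np.ndarray]], list[dict]]:
    """Apply a cumulative augmentation level to a role-keyed dataset.

    ``roles`` maps ``'train' | 'validation' | 'test'`` to ``(X, y)`` stacks
    of grayscale images in [0, 1]. Only the training role is geometrically
    augmented or jittered; histogram matching (level ≥ 2) is applied to all
    roles. At level 3 each training image is *replaced* by its brightness-
    and contrast-jittered copies, so the training count exactly doubles.

    Returns the transformed roles plus a manifest of the random draws.
    """
    if "train" not in roles:
        raise AugmentationError("roles must include a 'train' entry")
    rng = np.random.default_rng(plan.seed)
    manifest: list[dict] = []
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    # level 1: random flip/zoom on training images only (count unchanged)
    train_X, train_y = roles["train"]
    train_imgs = [np.asarray(im, dtype=np.float64) for im in train_X]
    if plan.level >= 1:
        geo = []
        for i, im in enumerate(train_imgs):
            aug, draws = _random_flip_zoom(im, rng, plan.zoom_range)
            geo.append(aug)
            manifest.append({"role": "train", "index": i,
                             "operator": "flip_zoom", **draws})
        train_imgs = geo

    # level 2: histogram matching on every image of every role
    def _match_all(imgs: list[np.ndarray], role: str) -> list[np.ndarray]:
        if plan.level < 2:
            return imgs
        matched = [histogram_match(im, plan.reference, plan.histogram_bins)
                   for im in imgs]
        manifest.append({"role": role, "operator": "histogram_match",
                         "bins": plan.histogram_bins, "count": len(imgs)})
        return matched

    train_imgs = _match_all(train_imgs, "train")

    # level 3: replace each training image by its two jittered variants
    if plan.level >= 3:
        doubled, ys = [], []
        for i, im in enumerate(train_imgs):
            b = float(rng.uniform(-plan.brightness_limit, plan.brightness_limit))
            g = float(rng.uniform(*plan.contrast_range))
            doubled.append(jitter(im, "brightness", amount=b))
            doubled.append(jitter(im, "contrast", amount=g))
            ys.extend([train_y[i], train_y[i]])
            manifest.append({"role": "train", "index": i, "operator": "jitter",
                             "brightness": b, "contrast": g})
        out["train"] = (np.stack(doubled), np.asarray(ys))
    else:
        out["train"] = (np.stack(train_imgs), np.asarray(train_y).copy())

    for role in roles:
        if role == "train":
            continue
        X, y = roles[role]
        imgs = [np.asarray(im, dtype=np.float64) for im in X]
        imgs = _match_all(imgs, role)
        out[role] = (np.stack(imgs), np.asarray(y).copy())

    return out, manifest


def emd_64bin(image: np.ndarray, reference: np.ndarray,
              bins: int = HISTOGRAM_BINS) -> float:
    """Earth-mover distance between two images' binned intensity histograms.

    Computed as the L1 distance between normalized bin CDFs (the 1-D
    Wasserstein distance in units of bins).
    """
    h1 = histogram_counts(image, bins).astype(float)
    h2 = histogram_counts(reference, bins).astype(float)
    c1 = np.cumsum(h1 / h1.sum())
    c2 = np.cumsum(h2 / h2.sum())
    return float(np.abs(c1 - c2).sum())
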