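"""Procedural generation of synthetic lung-ultrasound imagery.

This module produces labeled M-mode images and B-mode clip stacks that carry
the sonographic structure clinicians use to read pneumothorax (PTX):

* **M-mode, PTX-negative** — the *seashore* (sandy-beach) sign: laminar
  chest-wall bands above a bright pleural line, granular isotropic speckle
  below it (the moving lung).
* **M-mode, PTX-positive** — the *barcode* (stratosphere) sign: horizontal
  lamination continues below the pleural line because lung sliding is absent.
* **B-mode** — rib shadows flanking an intercostal window, a bright pleural
  line, and (only when the lung slides) B-line streaks plus frame-to-frame
  lateral texture motion below the pleura.

Appearance (global brightness, contrast, speckle grain, sensor noise) is
factored into :class:`DomainParams` so the same underlying anatomy can be
rendered in two imaging *domains* — a bright, fine-grained "phantom" domain
and a darker, higher-contrast, coarser "swine" domain — giving a controlled
appearance-only domain shift for augmentation experiments.

Speckle is modeled as blur-smoothed uniform noise (blob size set by
``speckle_grain_px``), not as a physical scattering simulation: texture-class
separability is the design goal, acoustics are out of scope.

Conventions: row 0 is the shallowest depth, column 0 the earliest time;
intensities are floats in [0, 1] in memory and 8-bit grayscale on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "DomainParams",
    "MmodeSpec",
    "MmodeImage",
    "BmodeClip",
    "PHANTOM_DOMAIN",
    "SWINE_DOMAIN",
    "generate_mmode",
    "generate_bmode_clip",
    "make_dataset",
    "save_dataset",
    "load_dataset",
]


class ParameterError(ValueError):
    """A generator parameter violates its documented range."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainParams:
    """Appearance knobs defining one imaging domain.

    The domain transform is applied as the *last* rendering step::

        pixel <- clip(contrast_gain * (pixel - 0.5) + 0.5
                      + brightness_offset + noise, 0, 1)

    with ``noise ~ N(0, noise_sd)`` per pixel.

    Parameters
    ----------
    name : str
        Domain label recorded in manifests.
    brightness_offset : float
        Additive intensity offset on the [0, 1] scale, in [-0.5, 0.5].
    contrast_gain : float
        Multiplicative gain about mid-gray (0.5); must be positive.
    speckle_grain_px : float
        Characteristic speckle blob size in pixels (Gaussian blur sigma
        applied to the raw scatter noise); at least 1.
    noise_sd : float
        Standard deviation of additive Gaussian sensor noise.
    pleural_depth_frac : float
        Vertical position of the pleural line as a fraction of image
        height, strictly inside (0, 1).
    chest_band_count : int
        Number of laminar muscle-like bands rendered in the chest wall.
    ptx_brightness_bias : float
        Extra brightness offset applied only to PTX-positive renders — a
        class-correlated acquisition confound. Positive and negative
        captures come from different imaging sessions (the lung is halted
        and the apparatus re-adjusted between them), so their global
        brightness can differ systematically. This shortcut is exactly
        what an unaugmented classifier tends to latch onto instead of the
        sonographic texture, and what histogram matching and
        brightness/contrast jitter are meant to neutralize.
    """

    name: str = "phantom"
    brightness_offset: float = 0.0
    contrast_gain: float = 1.0
    speckle_grain_px: float = 1.5
    noise_sd: float = 0.02
    pleural_depth_frac: float = 0.35
    chest_band_count: int = 4
    ptx_brightness_bias: float = 0.0

    def __post_init__(self) -> None:
        if not -0.5 <= self.brightness_offset <= 0.5:
            raise ParameterError(
                f"brightness_offset={self.brightness_offset} outside [-0.5, 0.5]"
            )
        if self.contrast_gain <= 0:
            raise ParameterError(f"contrast_gain={self.contrast_gain} must be > 0")
        if not 0 < self.pleural_depth_frac < 1:
            raise ParameterError(
                f"pleural_depth_frac={self.pleural_depth_frac} outside (0, 1)"
            )
        if self.speckle_grain_px < 1:
            raise ParameterError(
                f"speckle_grain_px={self.speckle_grain_px} must be >= 1"
            )
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd={self.noise_sd} must be >= 0")
        if self.chest_band_count < 0:
            raise ParameterError(f"chest_band_count={self.chest_band_count} < 0")
        if not -0.5 <= self.ptx_brightness_bias <= 0.5:
            raise ParameterError(
                f"ptx_brightness_bias={self.ptx_brightness_bias} outside "
                "[-0.5, 0.5]"
            )


#: Default source domain: bright, fine speckle, mild noise, and a
#: class-correlated brightness confound (positive captures render brighter)
#: emulating the session-to-session acquisition differences between the
#: PTX-negative and PTX-positive collection setups.
PHANTOM_DOMAIN = DomainParams(name="phantom", ptx_brightness_bias=0.15)

#: Default target domain: globally darker, higher contrast, coarser speckle
#: and noisier — an appearance-only shift relative to ``PHANTOM_DOMAIN`` —
#: and no class-brightness confound (one continuous imaging session).
#: Magnitudes are calibrated so a classifier trained on un-augmented phantom
#: images generalizes poorly across the gap (the phenomenon the staged
#: augmentation levels are designed to close).
SWINE_DOMAIN = DomainParams(
    name="swine",
    brightness_offset=-0.30,
    contrast_gain=2.0,
    speckle_grain_px=3.0,
    noise_sd=0.05,
    pleural_depth_frac=0.42,
    chest_band_count=6,
)


@dataclass(frozen=True)
class MmodeSpec:
    """Geometry and physiology of one M-mode capture.

    ``ptx_positive=True`` forces barcode texture below the pleural line
    regardless of ``respiration_rpm`` (an air-filled pleural space decouples
    the lung from the chest wall, so no motion reaches the scan line).
    """

    duration_s: float = 5.0
    px_per_s: float = 100.0
    height_px: int = 128
    ptx_positive: bool = False
    respiration_rpm: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError(f"duration_s={self.duration_s} must be > 0")
        if self.px_per_s < 1:
            raise ParameterError(f"px_per_s={self.px_per_s} must be >= 1")
        if self.height_px < 8:
            raise ParameterError(f"height_px={self.height_px} must be >= 8")
        if self.respiration_rpm < 0:
            raise ParameterError(f"respiration_rpm={self.respiration_rpm} < 0")

    @property
    def width_px(self) -> int:
        return int(round(self.duration_s * self.px_per_s))


@dataclass
class MmodeImage:
    """A labeled M-mode image: rows = depth, columns = time."""

    pixels: np.ndarray
    spec: MmodeSpec
    domain: DomainParams

    @property
    def label(self) -> str:
        return "positive" if self.spec.ptx_positive else "negative"

    @property
    def pleural_row(self) -> int:
        """Row index of the top of the pleural-line band."""
        return int(round(self.domain.pleural_depth_frac * self.spec.height_px))


@dataclass
class BmodeClip:
    """An ordered stack of B-mode frames with rib-shadow geometry metadata."""

    frames: list[np.ndarray]
    fps: float
    duration_s: float
    ptx_positive: bool
    domain: DomainParams
    rib_positions: tuple[int, ...]


# ---------------------------------------------------------------------------
# rendering helpers
# ---------------------------------------------------------------------------

def _apply_domain(field: np.ndarray, domain: DomainParams,
                  rng: np.random.Generator,
                  ptx_positive: bool = False) -> np.ndarray:
    """Contrast about mid-gray, brightness offset, sensor noise, clip.

    The class-correlated ``ptx_brightness_bias`` is folded into the
    brightness term for positive renders.
    """
    offset = domain.brightness_offset
    if ptx_positive:
        offset += domain.ptx_brightness_bias
    out = domain.contrast_gain * (field - 0.5) + 0.5 + offset
    if domain.noise_sd > 0:
        out = out + rng.normal(0.0, domain.noise_sd, size=field.shape)
    return np.clip(out, 0.0, 1.0)


def _speckle_field(shape: tuple[int, int], grain_px: float,
                   rng: np.random.Generator,
                   lo: float = 0.05, hi: float = 0.80) -> np.ndarray:
    """Granular isotropic speckle: blurred uniform noise rescaled to [lo, hi]."""
    raw = rng.uniform(0.0, 1.0, size=shape)
    blurred = ndimage.gaussian_filter(raw, sigma=grain_px / 2.0, mode="reflect")
    span = blurred.max() - blurred.min()
    if span < 1e-12:
        return np.full(shape, (lo + hi) / 2.0)
    return lo + (hi - lo) * (blurred - blurred.min()) / span


def _laminar_profile(n_rows: int, n_bands: int, rng: np.random.Generator,
                     lo: float = 0.05, hi: float = 0.75) -> np.ndarray:
    """Depth-only intensity profile with smooth quasi-periodic bands.

    Broadcasting this across columns gives perfectly horizontal lamination —
    the building block of both the chest wall and the barcode sign.
    """
    depth = np.linspace(0.0, 1.0, n_rows)
    profile = np.zeros(n_rows)
    if n_bands > 0:
        phases = rng.uniform(0, 2 * np.pi, size=n_bands)
        weights = rng.uniform(0.5, 1.0, size=n_bands)
        for k in range(n_bands):
            profile += weights[k] * np.sin(
                2 * np.pi * (k + 1) * depth * 0.9 + phases[k]
            )
    else:
        profile = rng.uniform(-1, 1, size=n_rows)
    profile = ndimage.gaussian_filter1d(profile, sigma=1.0, mode="reflect")
    span = profile.max() - profile.min()
    if span < 1e-12:
        return np.full(n_rows, (lo + hi) / 2.0)
    return lo + (hi - lo) * (profile - profile.min()) / span


# ---------------------------------------------------------------------------
# M-mode generation
# ---------------------------------------------------------------------------

def generate_mmode(spec: MmodeSpec, domain: DomainParams) -> MmodeImage:
    """Render one M-mode image.

    Layout, top to bottom:

    1. chest wall (rows above the pleural line): laminar bands, nearly
       constant along time;
    2. a bright pleural-line band (2–3 rows at the image's top intensities);
    3. the sub-pleural region: granular speckle when PTX-negative (seashore),
       with a gentle periodic column-intensity modulation at the respiratory
       rate; perfectly laminar when PTX-positive (barcode).

    The domain appearance transform (contrast, brightness, noise) is applied
    last, so phantom- and swine-rendered images of the same ``spec.seed``
    share identical texture labels and differ only in intensity mapping.
    Deterministic for a fixed ``spec.seed``.
    """
    if not isinstance(spec, MmodeSpec):
        raise ParameterError("spec must be an MmodeSpec")
    if not isinstance(domain, DomainParams):
        raise ParameterError("domain must be a DomainParams")

    h, w = spec.height_px, spec.width_px
    rng = np.random.default_rng(spec.seed)
    img = np.zeros((h, w), dtype=np.float64)

    pleural_top = int(round(domain.pleural_depth_frac * h))
    pleural_h = max(2, h // 48)
    pleural_bot = min(h - 1, pleural_top + pleural_h)

    # 1. chest wall: laminar profile broadcast along time
    chest = _laminar_profile(pleural_top, domain.chest_band_count, rng)
    img[:pleural_top, :] = chest[:, None]

    # 2. pleural line: the brightest structure in the image
    img[pleural_top:pleural_bot, :] = 0.97

    # 3. sub-pleural region
    sub_rows = h - pleural_bot
    if spec.ptx_positive:
        # barcode: depth-only lamination, zero column-to-column variation
        lung = _laminar_profile(sub_rows, max(3, domain.chest_band_count), rng)
        img[pleural_bot:, :] = lung[:, None]
    else:
        # seashore: isotropic granular speckle
        lung = _speckle_field((sub_rows, w), domain.speckle_grain_px, rng)
        if spec.respiration_rpm > 0:
            t = np.arange(w) / spec.px_per_s
            breath = 1.0 + 0.12 * np.sin(
                2 * np.pi * (spec.respiration_rpm / 60.0) * t
            )
            lung = lung * breath[None, :]
        img[pleural_bot:, :] = np.clip(lung, 0.0, 1.0)

    pixels = _apply_domain(img, domain, rng, ptx_positive=spec.ptx_positive)
    return MmodeImage(pixels=pixels, spec=spec, domain=domain)


# ---------------------------------------------------------------------------
# B-mode generation
# ---------------------------------------------------------------------------

def generate_bmode_clip(duration_s: float, fps: float, ptx_positive: bool,
                        domain: DomainParams, seed: int = 0,
                        height_px: int = 128, width_px: int = 128,
                        n_ribs: int = 2) -> BmodeClip:
    """Render a B-mode clip of one intercostal window.

    Static anatomy: laminar superficial tissue, a bright pleural line, and
    ``n_ribs`` dark vertical rib shadows. When ``ptx_positive`` is False the
    sub-pleural speckle slides laterally frame to frame (lung sliding) and
    bright B-line streaks radiate downward from the pleura; when True the
    sub-pleural texture is frozen and B-lines are absent. Per-frame sensor
    noise is drawn independently, so only the noiseless anatomy is static.
    """
    if duration_s <= 0:
        raise ParameterError(f"duration_s={duration_s} must be > 0")
    if fps < 1:
        raise ParameterError(f"fps={fps} must be >= 1")
    n_frames = int(round(fps * duration_s))
    rng = np.random.default_rng(seed)

    h, w = height_px, width_px
    pleural_top = int(round(domain.pleural_depth_frac * h))
    pleural_h = max(2, h // 48)
    pleural_bot = min(h - 1, pleural_top + pleural_h)
    sub_rows = h - pleural_bot

    chest = _laminar_profile(pleural_top, domain.chest_band_count, rng)
    base = np.zeros((h, w))
    base[:pleural_top, :] = chest[:, None]
    base[pleural_top:pleural_bot, :] = 0.97

    # wide sub-pleural texture strip to sample sliding windows from
    max_shift = max(2, w // 16)
    strip = _speckle_field((sub_rows, w + 2 * max_shift),
                           domain.speckle_grain_px, rng)

    # B-lines: bright vertical streaks below the pleura (negative only),
    # anchored to the sliding texture so they move with the lung
    n_blines = 3
    bline_cols = rng.integers(max_shift, w + max_shift, size=n_blines)
    bline_strip = np.zeros_like(strip)
    for c in bline_cols:
        width_b = 2
        lo, hi_ = max(0, c - width_b), min(strip.shape[1], c + width_b + 1)
        bline_strip[:, lo:hi_] = 0.35

    # rib shadows: dark attenuation columns below the superficial layer
    rib_margin = w // (n_ribs + 2)
    rib_positions = tuple(
        int(round((k + 1) * w / (n_ribs + 1))) for k in range(n_ribs)
    )
    shadow = np.ones((h, w))
    rib_half = max(3, w // 12)
    rib_top = max(1, pleural_top // 2)
    for c in rib_positions:
        lo, hi_ = max(0, c - rib_half), min(w, c + rib_half + 1)
        shadow[rib_top:, lo:hi_] = 0.12
    del rib_margin

    frames: list[np.ndarray] = []
    breath_hz = 20.0 / 60.0
    for i in range(n_frames):
        frame = base.copy()
        if ptx_positive:
            shift = 0
            sub = strip[:, max_shift:max_shift + w]
        else:
            phase = np.sin(2 * np.pi * breath_hz * (i / fps))
            shift = int(round(max_shift * phase))
            sub = (strip + bline_strip)[:, max_shift + shift:max_shift + shift + w]
        frame[pleural_bot:, :] = np.clip(sub, 0.0, 1.0)
        frame *= shadow
        frames.append(_apply_domain(frame, domain, rng,
                                    ptx_positive=ptx_positive))

    return BmodeClip(frames=frames, fps=fps, duration_s=duration_s,
                     ptx_positive=ptx_positive, domain=domain,
                     rib_positions=rib_positions)


# ---------------------------------------------------------------------------
# dataset assembly and I/O
# ---------------------------------------------------------------------------

def make_dataset(n_per_class: int, spec_template: MmodeSpec,
                 domain: DomainParams, seed: int = 0,
                 out_dir: str | Path | None = None) -> list[MmodeImage]:
    """Generate a balanced labeled M-mode collection.

    Image ``i`` of each class receives the derived seed ``seed + 2*i``
    (negative) or ``seed + 2*i + 1`` (positive), so enlarging ``n_per_class``
    extends a dataset without re-rendering earlier images.
    """
    if n_per_class < 1:
        raise ParameterError(f"n_per_class={n_per_class} must be >= 1")
    images: list[MmodeImage] = []
    for i in range(n_per_class):
        for positive in (False, True):
            sub_seed = seed + 2 * i + int(positive)
            spec = MmodeSpec(
                duration_s=spec_template.duration_s,
                px_per_s=spec_template.px_per_s,
                height_px=spec_template.height_px,
                ptx_positive=positive,
                respiration_rpm=spec_template.respiration_rpm,
                seed=sub_seed,
            )
            images.append(generate_mmode(spec, domain))
    if out_dir is not None:
        save_dataset(images, out_dir, dataset_seed=seed)
    return images


def to_uint8(pixels: np.ndarray) -> np.ndarray:
    """Quantize a [0, 1] float image to 8-bit grayscale."""
    return np.clip(np.round(pixels * 255.0), 0, 255).astype(np.uint8)


def save_dataset(images: list[MmodeImage], out_dir: str | Path,
                 dataset_seed: int | None = None) -> Path:
    """Write ``<root>/<positive|negative>/<name>.png`` plus a JSON sidecar."""
    root = Path(out_dir)
    records = []
    for idx, im in enumerate(images):
        sub = root / im.label
        sub.mkdir(parents=True, exist_ok=True)
        name = f"mmode_{idx:05d}.png"
        iio.imwrite(sub / name, to_uint8(im.pixels))
        records.append({
            "file": f"{im.label}/{name}",
            "label": im.label,
            "spec": asdict(im.spec),
            "domain": asdict(im.domain),
        })
    manifest = {"dataset_seed": dataset_seed, "n_images": len(images),
                "images": records}
    (root / "dataset.json").write_text(json.dumps(manifest, indent=2))
    return root


def load_dataset(root: str | Path) -> tuple[list[np.ndarray], list[str]]:
    """Read a class-subdirectory PNG layout back into float [0, 1] arrays."""
    root = Path(root)
    images, labels = [], []
    for label in ("negative", "positive"):
        sub = root / label
        if not sub.is_dir():
            continue
        for path in sorted(sub.glob("*.png")):
            images.append(iio.imread(path).astype(np.float64) / 255.0)
            labels.append(label)
    if not images:
        raise IOError(f"no images found under {root}")
    return images, labels


def save_clip(clip: BmodeClip, path: str | Path) -> Path:
    """Write a clip as a multi-page 8-bit grayscale TIFF."""
    stack = np.stack([to_uint8(f) for f in clip.frames])
    tifffile.imwrite(Path(path), stack)
    return Path(path)
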