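"""Image containers, grayscale conversion, quantization and patch sampling.

The pipeline treats a dermoscopy image as an 8-bit RGB array from which
small square windows ("keypoints", default 6x6 px) are sampled at uniform
random positions.  Each window carries both an RGB view (for per-channel
color statistics) and a normalized grayscale view (for first-order and
co-occurrence texture features).  Sampling positions are drawn inside an
optional region of interest so feature content does not depend on where
the lesion sits in the frame.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, UnidentifiedImageError

#: ITU-R BT.601 luma weights, the conventional RGB -> gray projection.
DEFAULT_GRAY_WEIGHTS = (0.299, 0.587, 0.114)

#: Default number of gray levels used when quantizing for co-occurrence
#: matrices.  A 6x6 window holds only 30 horizontal pixel pairs, so a
#: coarse level set keeps the co-occurrence matrix well populated.
DEFAULT_LEVELS = 8

#: Default side length of a sampled window, in pixels.
DEFAULT_PATCH_SIZE = 6


class ImageDecodeError(RuntimeError):
    """Raised when a file cannot be decoded as an image."""


class PatchSamplingError(ValueError):
    """Raised when an image (or ROI) cannot accommodate the requested window."""


@dataclass(frozen=True)
class RGBImage:
    """8-bit three-channel image.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` integer array with values in 0..255.
    id
        Identifier used for provenance and seed derivation.
    """

    pixels: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) pixel array, got shape {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("RGB channel values must lie in 0..255")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GrayImage:
    """Single-channel image, either normalized to [0, 1] or integer-leveled.

    ``levels`` counts the distinct representable intensities; ``normalized``
    distinguishes the continuous [0, 1] representation (used for first-order
    moments) from the integer 0..L-1 representation (used for co-occurrence
    matrices).
    """

    pixels: np.ndarray
    levels: int
    normalized: bool

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected 2-D pixel array, got shape {px.shape}")
        if self.normalized:
            if px.min() < 0.0 or px.max() > 1.0:
                raise ValueError("normalized gray values must lie in [0, 1]")
            object.__setattr__(self, "pixels", px.astype(np.float64))
        else:
            if not np.issubdtype(px.dtype, np.integer):
                raise ValueError("integer-leveled gray image requires integer dtype")
            if px.min() < 0 or px.max() >= self.levels:
                raise ValueError("integer gray values must lie in 0..levels-1")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class Patch:
    """A square window sampled from an image, with provenance.

    Coordinates are 0-based, ``x0`` indexing columns and ``y0`` rows; the
    window spans the half-open ranges ``[x0, x0+size)`` x ``[y0, y0+size)``.
    """

    image_id: str
    x0: int
    y0: int
    size: int
    rgb: RGBImage = field(repr=False)
    gray: GrayImage = field(repr=False)

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("patch size must be >= 2")


def read_image(path) -> RGBImage:
    """Read a JPEG/PNG file into an :class:`RGBImage`.

    Grayscale or palette files are expanded to three identical channels.
    """
    try:
        with Image.open(path) as im:
            rgb = im.convert("RGB")
            pixels = np.asarray(rgb, dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise ImageDecodeError(f"cannot decode image file: {path}") from exc
    return RGBImage(pixels=pixels, id=str(path))


def write_image(img: RGBImage, path) -> None:
    """Write an :class:`RGBImage` to disk (format inferred from extension)."""
    Image.fromarray(img.pixels, mode="RGB").save(path)


def to_gray(img: RGBImage, weights=DEFAULT_GRAY_WEIGHTS) -> GrayImage:
    """Project RGB onto a normalized grayscale channel.

    ``gray = (w_r*R + w_g*G + w_b*B) / 255`` per pixel, with nonnegative
    weights summing to 1, so the output lies in [0, 1].
    """
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (3,) or (w < 0).any():
        raise ValueError("gray weights must be 3 nonnegative reals")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"gray weights must sum to 1 (got {w.sum()!r})")
    gray = img.pixels.astype(np.float64) @ w / 255.0
    # Guard against rounding a hair past the endpoints.
    gray = np.clip(gray, 0.0, 1.0)
    return GrayImage(pixels=gray, levels=256, normalized=True)


def quantize(img: GrayImage, levels: int = DEFAULT_LEVELS) -> GrayImage:
    """Map a normalized gray image onto integer levels 0..L-1.

    Value ``v`` maps to ``min(floor(v*L), L-1)``; the top of the range is
    clamped so v=1.0 falls in the last bin.
    """
    if levels < 2:
        raise ValueError("level count must be >= 2")
    if not img.normalized:
        raise ValueError("quantize expects a normalized [0, 1] gray image")
    q = np.minimum(np.floor(img.pixels * levels), levels - 1).astype(np.int64)
    return GrayImage(pixels=q, levels=levels, normalized=False)


def _resolve_roi(img: RGBImage, roi) -> tuple[int, int, int, int]:
    if roi is None:
        return 0, 0, img.width, img.height
    x0, y0, x1, y1 = (int(v) for v in roi)
    if not (0 <= x0 < x1 <= img.width and 0 <= y0 < y1 <= img.height):
        raise ValueError(f"ROI {roi} does not fit inside image '{img.id}' "
                         f"({img.width}x{img.height})")
    return x0, y0, x1, y1


def derive_seed(master_seed: int, *keys) -> int:
    """Deterministic 31-bit sub-seed keyed by arbitrary string components.

    Keyed by content (e.g. an image id), not by position, so processing
    order does not change per-item randomness.
    """
    payload = ":".join([str(master_seed), *map(str, keys)]).encode()
    return int.from_bytes(hashlib.sha256(payload).digest()[:4], "big") % (2**31)


def extract_patches(
    img: RGBImage,
    n: int,
    size: int = DEFAULT_PATCH_SIZE,
    seed: int = 0,
    roi=None,
    gray_weights=DEFAULT_GRAY_WEIGHTS,
) -> list[Patch]:
    """Sample ``n`` square windows uniformly at random (with replacement).

    Top-left corners are drawn uniformly over all admissible positions in
    the ROI (full image by default).  Windows may overlap.  Deterministic
    for a fixed seed.
    """
    rx0, ry0, rx1, ry1 = _resolve_roi(img, roi)
    max_x = rx1 - size
    max_y = ry1 - size
    if max_x < rx0 or max_y < ry0:
        raise PatchSamplingError(
            f"image '{img.id}': ROI {rx1 - rx0}x{ry1 - ry0} cannot hold a "
            f"{size}x{size} window")
    rng = np.random.default_rng(seed)
    xs = rng.integers(rx0, max_x + 1, size=n)
    ys = rng.integers(ry0, max_y + 1, size=n)
    gray_full = to_gray(img, gray_weights)
    patches = []
    for x0, y0 in zip(xs.tolist(), ys.tolist()):
        rgb_view = RGBImage(pixels=img.pixels[y0:y0 + size, x0:x0 + size],
                            id=img.id)
        gray_view = GrayImage(pixels=gray_full.pixels[y0:y0 + size, x0:x0 + size],
                              levels=256, normalized=True)
        patches.append(Patch(image_id=img.id, x0=x0, y0=y0, size=size,
                             rgb=rgb_view, gray=gray_view))
    return patches
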