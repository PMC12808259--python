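"""Image loading, calibration and colour-space views.

All images are carried as floating-point intensity grids in [0, 1],
independent of the bit depth of the file they came from.  A
:class:`CalibratedImage` additionally records the physical length of one
pixel (``l_pixel``, in millimetres) when known, which downstream code uses
to convert pixel counts into physical areas.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "Modality",
    "Fabric",
    "CalibratedImage",
    "RGBImage",
    "load_image",
    "save_image",
    "to_grayscale",
    "value_channel",
]

# Rec. 601 luma weights, used for RGB -> greyscale conversion.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


class Modality(enum.Enum):
    """Acquisition modality of a photograph."""

    VL = "vl"          # visible light
    IR = "ir"          # infrared (700 nm long-pass)
    TAPE_SCAN = "tape_scan"


class Fabric(enum.Enum):
    """Trace carrier the residues were deposited on."""

    WHITE_COTTON = "white_cotton"
    DENIM = "denim"
    TAPE = "tape"
    UNKNOWN = "unknown"


def _validate_l_pixel(l_pixel: float | None) -> None:
    if l_pixel is not None:
        if not math.isfinite(l_pixel) or l_pixel <= 0:
            raise ValueError(
                f"l_pixel must be a finite positive length in mm/pixel, got {l_pixel!r}"
            )


@dataclass(frozen=True)
class CalibratedImage:
    """Single-channel intensity image with acquisition metadata.

    Parameters
    ----------
    pixels:
        2-D float array with values in [0, 1].
    l_pixel:
        Physical length of one pixel in millimetres, or ``None`` if the
        image is uncalibrated.
    modality, fabric:
        Acquisition metadata used to select processing presets.
    """

    pixels: np.ndarray
    l_pixel: float | None = None
    modality: Modality = Modality.VL
    fabric: Fabric = Fabric.UNKNOWN

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"expected a 2-D intensity grid, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite intensities")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError(
                f"intensities must lie in [0, 1], got range "
                f"[{px.min():.4g}, {px.max():.4g}]"
            )
        _validate_l_pixel(self.l_pixel)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "CalibratedImage":
        """Same metadata, new pixel grid."""
        return replace(self, pixels=pixels)


@dataclass(frozen=True)
class RGBImage:
    """Colour image with channels in [0, 1], e.g. a developed-tape scan."""

    pixels: np.ndarray
    l_pixel: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected an (H, W, 3) RGB grid, got shape {px.shape}")
        if not np.all(np.isfinite(px)) or px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("RGB channels must be finite and lie in [0, 1]")
        _validate_l_pixel(self.l_pixel)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _rescale_to_unit(raw: np.ndarray) -> np.ndarray:
    """Map integer sample depths to [0, 1]; pass floats through clipped."""
    if np.issubdtype(raw.dtype, np.integer):
        info = np.iinfo(raw.dtype)
        return raw.astype(np.float64) / float(info.max)
    out = raw.astype(np.float64)
    return np.clip(out, 0.0, 1.0)


def load_image(
    path: str | Path,
    l_pixel: float | None = None,
    modality: Modality = Modality.VL,
    fabric: Fabric = Fabric.UNKNOWN,
) -> CalibratedImage | RGBImage:
    """Read a PNG/TIFF/JPEG file into a calibrated unit-interval image.

    Colour files yield an :class:`RGBImage` (alpha channels are dropped);
    single-channel files yield a :class:`CalibratedImage` with the given
    metadata attached.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the file cannot be decoded or ``l_pixel`` is not positive.
    """
    path = Path(path)
    _validate_l_pixel(l_pixel)
    if not path.is_file():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        raw = iio.imread(path)
    except Exception as exc:  # decoder errors vary by backend
        raise ValueError(f"could not decode image file {path}: {exc}") from exc
    scaled = _rescale_to_unit(np.asarray(raw))
    if scaled.ndim == 3:
        if scaled.shape[2] >= 3:
            return RGBImage(scaled[:, :, :3], l_pixel=l_pixel)
        scaled = scaled[:, :, 0]
    return CalibratedImage(scaled, l_pixel=l_pixel, modality=modality, fabric=fabric)


def save_image(img: CalibratedImage | RGBImage | np.ndarray, path: str | Path) -> None:
    """Write an image as 16-bit PNG (greyscale) or 8-bit PNG (RGB)."""
    path = Path(path)
    arr = img.pixels if isinstance(img, (CalibratedImage, RGBImage)) else np.asarray(img)
    if arr.ndim == 2:
        iio.imwrite(path, np.round(arr * 65535).astype(np.uint16))
    else:
        iio.imwrite(path, np.round(arr * 255).astype(np.uint8))


def to_grayscale(img: RGBImage) -> CalibratedImage:
    """Rec. 601 luma conversion: Y = 0.299 R + 0.587 G + 0.114 B."""
    if not isinstance(img, RGBImage):
        raise TypeError("to_grayscale expects an RGBImage")
    luma = img.pixels @ _LUMA_WEIGHTS
    # weights sum to 1 so the result is a convex combination, but guard
    # against float round-off pushing a pixel marginally past the bounds
    return CalibratedImage(np.clip(luma, 0.0, 1.0), l_pixel=img.l_pixel)


def value_channel(img: RGBImage) -> CalibratedImage:
    """HSV value channel V = max(R, G, B) of a tape scan.

    The value channel gives the strongest contrast between dark developed
    residue spots and the pale tape background, and is independent of hue.
    """
    if not isinstance(img, RGBImage):
        raise TypeError("value_channel expects an RGBImage")
    v = img.pixels.max(axis=2)
    return CalibratedImage(v, l_pixel=img.l_pixel, modality=Modality.TAPE_SCAN)
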