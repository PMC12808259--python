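"""Fourier-domain suppression of fabric texture.

GSR particles are small, high-contrast blobs; the fabric they sit on
contributes structured background at characteristic spatial frequencies —
slow illumination gradients at the lowest frequencies, and the periodic
weave (e.g. a denim twill) at a narrow high-frequency band.  A radial
high-pass filter removes the former; a band-pass additionally removes the
weave band while keeping the particle-scale frequencies in between.

Cutoffs are expressed in cycles per image width so a preset transfers
across image resolutions.  Transitions are Gaussian-edged (an erf profile)
by default to limit ringing; ``transition_width=0`` gives an ideal hard
edge, which is convenient for analytic tests.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .imaging import CalibratedImage

__all__ = ["FilterKind", "FilterSpec", "make_filter_mask", "apply_filter_raw",
           "apply_frequency_filter", "normalize_unit"]


class FilterKind(enum.Enum):
    HIGH_PASS = "high_pass"
    BAND_PASS = "band_pass"


@dataclass(frozen=True)
class FilterSpec:
    """Radial frequency filter description.

    Parameters
    ----------
    kind:
        ``HIGH_PASS`` (pass everything above ``low_cut``) or ``BAND_PASS``
        (pass the open band between ``low_cut`` and ``high_cut``).
    low_cut, high_cut:
        Radial cutoffs in cycles per image width.  ``high_cut`` is only
        meaningful for band-pass filters.
    transition_width:
        Width of the Gaussian-edged transition in the same frequency
        units; 0 means an ideal (hard) edge.
    """

    kind: FilterKind
    low_cut: float
    high_cut: float | None = None
    transition_width: float = 0.0

    def __post_init__(self) -> None:
        if self.kind is FilterKind.HIGH_PASS:
            if not self.low_cut > 0:
                raise ValueError("HIGH_PASS requires low_cut > 0")
            if self.high_cut is not None:
                raise ValueError("high_cut is only valid for BAND_PASS")
        elif self.kind is FilterKind.BAND_PASS:
            if self.high_cut is None or not (0 < self.low_cut < self.high_cut):
                raise ValueError("BAND_PASS requires 0 < low_cut < high_cut")
        else:
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.transition_width < 0:
            raise ValueError("transition_width must be >= 0")


def _radial_frequency(height: int, width: int) -> np.ndarray:
    """Radial frequency of every FFT bin, in cycles per image width.

    Normalized per-axis frequencies are both scaled by the image width, so
    the radius is isotropic in cycles-per-pixel-pitch terms (square pixels
    assumed).
    """
    fy = np.fft.fftfreq(height)[:, None] * width
    fx = np.fft.fftfreq(width)[None, :] * width
    return np.hypot(fy, fx)


def _soft_step(r: np.ndarray, cut: float, width: float) -> np.ndarray:
    """Smooth 0 -> 1 step centred at ``cut``; hard step when width == 0."""
    if width == 0:
        return (r >= cut).astype(np.float64)
    return 0.5 * (1.0 + erf((r - cut) / (width * np.sqrt(2.0))))


def make_filter_mask(height: int, width: int, spec: FilterSpec) -> np.ndarray:
    """Real-valued frequency mask in [0, 1], in FFT bin layout.

    The mask is radially symmetric in centred-frequency coordinates.  For
    a high-pass filter the DC bin is exactly zero, so a constant image is
    annihilated and filtered outputs are zero-mean.
    """
    if height < 2 or width < 2:
        raise ValueError(f"mask needs height, width >= 2, got {height}x{width}")
    r = _radial_frequency(height, width)
    rise = _soft_step(r, spec.low_cut, spec.transition_width)
    if spec.kind is FilterKind.HIGH_PASS:
        mask = rise
    else:
        fall = _soft_step(r, spec.high_cut, spec.transition_width)
        if spec.transition_width == 0:
            # hard band edge: pass the closed band [low_cut, high_cut]
            mask = rise * (r <= spec.high_cut)
        else:
            mask = rise * (1.0 - fall)
    mask[0, 0] = 0.0  # DC always removed: background mean carries no particles
    return mask


def apply_filter_raw(pixels: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Filter a 2-D array in the Fourier domain; no re-normalization.

    Returns the real part of IFFT(FFT(x) * mask).  Useful for tests that
    rely on linearity and the zero-mean property of high-pass output.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 2 or min(pixels.shape) < 2:
        raise ValueError(f"expected a 2-D image of at least 2x2, got shape {pixels.shape}")
    mask = make_filter_mask(*pixels.shape, spec)
    return np.fft.ifft2(np.fft.fft2(pixels) * mask).real


def normalize_unit(pixels: np.ndarray) -> np.ndarray:
    """Affine map of an array to [0, 1]; a constant array maps to zeros."""
    lo = pixels.min()
    span = pixels.max() - lo
    if span == 0:
        return np.zeros_like(pixels)
    return (pixels - lo) / span


def apply_frequency_filter(img: CalibratedImage, spec: FilterSpec) -> CalibratedImage:
    """Suppress fabric texture and re-normalize to the unit interval.

    The filtered real part is affinely rescaled so that its minimum maps
    to 0 and its maximum to 1, giving downstream thresholds a common
    scale.  Image metadata (calibration, modality, fabric) is preserved.
    """
    filtered = apply_filter_raw(img.pixels, spec)
    return img.with_pixels(normalize_unit(filtered))
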