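"""Colorimetric decomposition of scintillator fluorescence photographs.

A camera JPG of the glowing scintillator encodes the 2D dose distribution
in its brightness.  This module converts sRGB-encoded images to linear
light, decomposes them into CIE XYZ tristimulus / xyz chromaticity planes
and into HSV, histograms the V (value) channel, segments signal from
container reflections with a V threshold ("V-cut"), and turns the masked V
plane into a relative 2D dose map on physical coordinates.

Convention: pixel (0, 0) is the top-left corner, rows run down the beam
axis (the beam enters at the top of the frame), and HSV is computed on the
gamma-encoded channel values as consumer image pipelines do; pass
``linear_light`` flags where a linear-light V is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from skimage import color as skcolor

from .transport import DoseGrid2D

__all__ = [
    "RGBImage",
    "XYZDecomposition",
    "HSVImage",
    "VMask",
    "srgb_decode",
    "srgb_encode",
    "rgb_to_xyz",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "v_histogram",
    "v_threshold",
    "dose_map_from_image",
    "SRGB_TO_XYZ",
]

# IEC 61966-2-1 sRGB → CIE XYZ (D65 white), the matrix consumer cameras target
SRGB_TO_XYZ = np.array(
    [
        [0.41239080, 0.35758434, 0.18048079],
        [0.21263901, 0.71516868, 0.07219232],
        [0.01933082, 0.11919478, 0.95053215],
    ]
)


@dataclass
class RGBImage:
    """H×W×3 float pixels in [0, 1] with an encoding tag."""

    pixels: np.ndarray
    colorspace: str = "srgb"  # "srgb" (gamma-encoded) | "linear"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("expected an H×W×3 array")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("pixel values must lie in [0, 1]")
        if self.colorspace not in ("srgb", "linear"):
            raise ValueError(f"unknown colorspace {self.colorspace!r}")

    @classmethod
    def from_file(cls, path) -> "RGBImage":
        arr = iio.imread(path)
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.dtype == np.uint8:
            arr = arr.astype(float) / 255.0
        elif arr.dtype == np.uint16:
            arr = arr.astype(float) / 65535.0
        return cls(arr, "srgb")

    def to_file(self, path) -> None:
        iio.imwrite(path, (np.clip(self.pixels, 0, 1) * 255).round().astype(np.uint8))


@dataclass
class XYZDecomposition:
    """Tristimulus planes X, Y, Z and normalised chromaticity x, y, z."""

    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray


@dataclass
class HSVImage:
    """Hexcone HSV planes: H in degrees [0, 360), S and V in [0, 1]."""

    H: np.ndarray
    S: np.ndarray
    V: np.ndarray


@dataclass
class VMask:
    """Boolean V-threshold mask; ``masked_V`` keeps V on selected pixels."""

    v_cut: float
    mask: np.ndarray
    masked_V: np.ndarray


def srgb_decode(img: RGBImage) -> RGBImage:
    """Apply the sRGB electro-optical transfer (gamma removal) per channel."""
    if img.colorspace == "linear":
        import warnings

        warnings.warn("image already linear; srgb_decode is a no-op", stacklevel=2)
        return RGBImage(img.pixels.copy(), "linear")
    p = img.pixels
    lin = np.where(p <= 0.04045, p / 12.92, ((p + 0.055) / 1.055) ** 2.4)
    return RGBImage(lin, "linear")


def srgb_encode(linear: np.ndarray) -> np.ndarray:
    """Inverse transfer: linear light → sRGB-encoded values."""
    p = np.clip(np.asarray(linear, dtype=float), 0.0, 1.0)
    return np.where(p <= 0.0031308, 12.92 * p, 1.055 * p ** (1.0 / 2.4) - 0.055)


def rgb_to_xyz(img: RGBImage) -> XYZDecomposition:
    """Per-pixel sRGB/D65 matrix transform plus chromaticity normalisation.

    Requires linear-light input (run :func:`srgb_decode` first on camera
    files).  Where X+Y+Z = 0 the chromaticities are defined as 0.
    """
    if img.colorspace != "linear":
        raise ValueError("rgb_to_xyz expects linear RGB; apply srgb_decode first")
    xyz = img.pixels @ SRGB_TO_XYZ.T
    X, Y, Z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    total = X + Y + Z
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(total > 0, X / total, 0.0)
        y = np.where(total > 0, Y / total, 0.0)
        z = np.where(total > 0, Z / total, 0.0)
    return XYZDecomposition(X, Y, Z, x, y, z)


def rgb_to_hsv(img: RGBImage) -> HSVImage:
    """Hexcone HSV: V = max(R,G,B), S = (max−min)/max, H by sextant rule.

    Computed on the channel values as stored (normally gamma-encoded, the
    common image-processing convention).  H is 0 where S = 0.
    """
    hsv = skcolor.rgb2hsv(img.pixels)
    return HSVImage(hsv[..., 0] * 360.0, hsv[..., 1], hsv[..., 2])


def hsv_to_rgb(hsv: HSVImage, colorspace: str = "srgb") -> RGBImage:
    arr = np.stack([hsv.H / 360.0, hsv.S, hsv.V], axis=-1)
    return RGBImage(skcolor.hsv2rgb(arr), colorspace)


def v_histogram(img: HSVImage, n_bins: int = 100):
    """Histogram of the V plane over [0, 1]; counts sum to the pixel count."""
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    counts, edges = np.histogram(img.V, bins=n_bins, range=(0.0, 1.0))
    return counts, edges


def v_threshold(img: HSVImage, v_cut: float) -> VMask:
    """Keep pixels with V ≥ v_cut (the paper-style V-cut segmentation)."""
    if not 0.0 <= v_cut <= 1.0:
        raise ValueError("v_cut must lie in [0, 1]")
    mask = img.V >= v_cut
    return VMask(v_cut, mask, np.where(mask, img.V, 0.0))


def dose_map_from_image(
    img: RGBImage,
    v_cut: float = 0.3,
    calibration: float = 1.0,
    linear_light: bool = True,
) -> DoseGrid2D:
    """Relative 2D dose map from a fluorescence photograph.

    The V-cut is applied on the encoded (display-space) V plane, matching
    how the threshold is chosen by eye on the photograph; the retained dose
    values are taken from the linear-light V plane (``linear_light=True``)
    so that pixel value is proportional to emitted light, then rescaled to
    max = 100%.  ``calibration`` is the pixel pitch in cm/pixel.

    The result is a relative :class:`DoseGrid2D`: ``deposited`` holds
    percentages, not MeV, and no escaped-energy accounting applies.
    """
    if calibration <= 0:
        raise ValueError("calibration must be positive")
    encoded = img if img.colorspace == "srgb" else RGBImage(srgb_encode(img.pixels), "srgb")
    sel = v_threshold(rgb_to_hsv(encoded), v_cut)
    if not sel.mask.any():
        raise ValueError("V-cut removed every pixel")
    if linear_light:
        v_vals = srgb_decode(encoded).pixels.max(axis=2)
    else:
        v_vals = rgb_to_hsv(encoded).V
    kept = np.where(sel.mask, v_vals, 0.0)
    dose = kept * (100.0 / kept.max())
    return DoseGrid2D(
        dose,
        cell_size=calibration,
        beam=None,
        escaped_energy=0.0,
        relative=True,
        meta={"v_cut": v_cut},
    )
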