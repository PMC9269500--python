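"""Optical tomography: sinograms, Radon projection and filtered back-projection.

A vial containing a T-shaped bar rotates on a turntable while a camera
films it.  One fixed pixel row of every frame is a parallel-beam projection
of the slice at that height; stacking the rows over a revolution forms a
sinogram, and filtered back-projection (inverse Radon transform) recovers
the slice.  Forward/inverse Radon transforms delegate to
``skimage.transform`` with the conventions fixed here: angle 0° at the
first frame, counter-clockwise positive, detector axis along image columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import iradon, radon

__all__ = [
    "FrameStack",
    "Sinogram",
    "ReconstructedSlice",
    "TBarPhantomSpec",
    "InsufficientCoverageError",
    "sinogram_from_frames",
    "attenuation_sinogram",
    "forward_radon",
    "inverse_radon_fbp",
    "phantom_slice_truth",
    "estimate_rotation_period",
]

_LUMA = np.array([0.2126, 0.7152, 0.0722])  # Rec. 709


class InsufficientCoverageError(ValueError):
    """The sinogram spans less than 180° of rotation."""


@dataclass
class FrameStack:
    """Frames from a rotating-sample video plus the rotation metadata."""

    frames: np.ndarray  # (N, H, W) grayscale or (N, H, W, 3) RGB
    rotation_period: int  # frames per revolution
    baseline_row: int  # pixel row used to build the sinogram

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (N, H, W) or (N, H, W, 3)")
        if self.frames.shape[0] < self.rotation_period:
            raise ValueError("need at least one full revolution of frames")
        if not 0 <= self.baseline_row < self.frames.shape[1]:
            raise ValueError("baseline_row outside the image height")

    @classmethod
    def from_directory(cls, directory, rotation_period: int, baseline_row: int) -> "FrameStack":
        """Load sorted JPG/PNG frames extracted from a rotation video."""
        import pathlib

        import imageio.v3 as iio

        paths = sorted(
            p
            for p in pathlib.Path(directory).iterdir()
            if p.suffix.lower() in (".jpg", ".jpeg", ".png", ".tif", ".tiff")
        )
        if not paths:
            raise FileNotFoundError(f"no frames found in {directory}")
        shapes = set()
        frames = []
        for p in paths:
            arr = iio.imread(p)
            shapes.add(arr.shape)
            frames.append(arr)
        if len(shapes) > 1:
            raise ValueError("frames have mixed dimensions")
        stack = np.stack(frames).astype(float)
        if stack.dtype != float:
            stack = stack.astype(float)
        if stack.max() > 1.0:
            stack = stack / 255.0
        return cls(stack, rotation_period, baseline_row)


@dataclass
class Sinogram:
    """Angle × detector-bin intensity array."""

    intensities: np.ndarray  # (n_angles, n_detector)
    angles: np.ndarray  # degrees, strictly increasing
    detector_spacing: float = 1.0  # pixel (or cm) per bin

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.intensities.shape[0] != self.angles.size:
            raise ValueError("one angle per sinogram row is required")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("sinogram intensities must be finite")

    @property
    def span(self) -> float:
        """Angular coverage in degrees including one trailing step."""
        if self.angles.size < 2:
            return 0.0
        step = np.median(np.diff(self.angles))
        return float(self.angles[-1] - self.angles[0] + step)


@dataclass
class ReconstructedSlice:
    image: np.ndarray
    pixel_size: float
    filter_name: str


def sinogram_from_frames(stack: FrameStack) -> Sinogram:
    """Extract the baseline row of every frame and stack rows by angle.

    The frame index modulo the rotation period assigns the angle
    (index × 360°/period); rows from repeated revolutions at the same angle
    are averaged, which suppresses frame noise.
    """
    frames = stack.frames
    rows = frames[:, stack.baseline_row]  # (N, W) or (N, W, 3)
    if rows.ndim == 3:
        rows = rows @ _LUMA
    period = stack.rotation_period
    n = rows.shape[0]
    acc = np.zeros((period, rows.shape[1]))
    cnt = np.zeros(period)
    idx = np.arange(n) % period
    np.add.at(acc, idx, rows)
    np.add.at(cnt, idx, 1.0)
    acc /= cnt[:, None]
    angles = np.arange(period) * 360.0 / period
    return Sinogram(acc, angles)


def attenuation_sinogram(sino: Sinogram, i0: float | None = None) -> Sinogram:
    """Convert transmitted intensity to optical depth: p = −ln(I / I0).

    ``i0`` defaults to the brightest sinogram value (unobstructed backlight).
    Use this before reconstruction when the frames record transmitted light
    rather than line integrals.
    """
    i0 = float(sino.intensities.max()) if i0 is None else i0
    if i0 <= 0:
        raise ValueError("reference intensity must be positive")
    p = -np.log(np.clip(sino.intensities / i0, 1e-9, None))
    return Sinogram(p, sino.angles.copy(), sino.detector_spacing)


def forward_radon(image: np.ndarray, angles) -> Sinogram:
    """Parallel-beam line integrals of a square image at the given angles."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("forward_radon expects a square 2D image")
    angles = np.asarray(angles, dtype=float)
    sino = radon(image, theta=angles, circle=True)  # (n_det, n_angles)
    return Sinogram(sino.T, angles)


def inverse_radon_fbp(
    sino: Sinogram,
    filter_name: str = "ramp",
    output_size: int | None = None,
    fold_360: bool = False,
) -> ReconstructedSlice:
    """Filtered back-projection reconstruction of a sinogram.

    ``filter_name`` is one of ``ramp`` (Ram-Lak), ``shepp-logan``, ``hann``
    (Hann-apodised ramp) or ``none`` (plain, blurred back-projection).  A
    360° sinogram may either be used directly (every projection back-
    projected, the default) or folded onto 180° by averaging conjugate rays
    (``fold_360=True``).  Raises if the angular coverage is below 180°.
    """
    if sino.span < 180.0 - 1e-6:
        raise InsufficientCoverageError(
            f"angular span {sino.span:.1f}° < 180°; cannot reconstruct"
        )
    intensities, angles = sino.intensities, sino.angles
    if fold_360 and sino.span > 180.0 + 1e-6:
        half = angles < 180.0
        upper = angles >= 180.0
        folded = intensities[half].copy()
        n_det = intensities.shape[1]
        # conjugate ray: p(θ+180°, s) = p(θ, −s); with an even detector count
        # the centre sits between bins, so the flip needs a one-bin roll
        for a_up, row in zip(angles[upper], intensities[upper]):
            j = int(np.argmin(np.abs(angles[half] - (a_up - 180.0))))
            flipped = row[::-1] if n_det % 2 else np.roll(row[::-1], 1)
            folded[j] = 0.5 * (folded[j] + flipped)
        intensities, angles = folded, angles[half]

    name_map = {"ramp": "ramp", "shepp-logan": "shepp-logan", "hann": "hann", "none": None}
    if filter_name not in name_map:
        raise ValueError(f"unknown filter {filter_name!r}")
    img = iradon(
        intensities.T,
        theta=angles,
        filter_name=name_map[filter_name],
        circle=True,
        output_size=output_size,
    )
    return ReconstructedSlice(img, sino.detector_spacing, filter_name)


@dataclass
class TBarPhantomSpec:
    """Geometry of the rotating vial + T-bar phantom at the baseline slice.

    All lengths in pixels of the reconstruction grid.  The two drilled
    cylindrical holes cross the bar horizontally, so in the slice they
    appear as rectangular strips through the bar centre.  Attenuation
    levels are linear coefficients per pixel; shapes are painted outermost
    first, so the bar overrides the liquid and holes override the bar.
    An odd ``image_size`` keeps the geometric centre on a pixel, aligned
    with the projection/back-projection detector-centre convention.
    """

    image_size: int = 161
    vial_radius: float = 70.0
    vial_wall: float = 4.0
    bar_radius: float = 28.0
    hole_half_width: float = 5.0
    hole_offsets: tuple[float, ...] = (-14.0, 14.0)  # strip centres along y
    mu_wall: float = 0.004
    mu_liquid: float = 0.0012
    mu_bar: float = 0.006
    mu_hole: float = 0.0012  # holes are flooded by the liquid
    bar_row_range: tuple[float, float] = (0.35, 0.75)  # bar extent as height fractions

    def __post_init__(self) -> None:
        if self.bar_radius > self.vial_radius - self.vial_wall + 1e-9:
            raise ValueError("bar must fit inside the vial")
        if (
            self.bar_radius > 0
            and self.hole_offsets
            and max(abs(o) for o in self.hole_offsets) + self.hole_half_width > self.bar_radius
        ):
            raise ValueError("holes must lie inside the bar")


def phantom_slice_truth(
    spec: TBarPhantomSpec, with_bar: bool = True, supersample: int = 4
) -> np.ndarray:
    """Ground-truth attenuation image of the baseline slice.

    Rendered on a ``supersample``× finer grid and block-averaged down, so
    shape edges carry proper partial-pixel coverage instead of aliased
    steps.
    """
    n = spec.image_size * supersample
    c = (n - 1) / 2.0
    s = float(supersample)
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(xx - c, yy - c)
    img = np.zeros((n, n))
    if spec.vial_radius <= 0:
        return img[::supersample, ::supersample] * 0.0
    img[r <= spec.vial_radius * s] = spec.mu_wall
    inner = (spec.vial_radius - spec.vial_wall) * s
    img[r <= inner] = spec.mu_liquid
    if with_bar and spec.bar_radius > 0:
        img[r <= spec.bar_radius * s] = spec.mu_bar
        for off in spec.hole_offsets:
            strip = (
                (np.abs(yy - c - off * s) <= spec.hole_half_width * s)
                & (r <= spec.bar_radius * s)
            )
            img[strip] = spec.mu_hole
    img = np.clip(img, 0.0, None)
    m = spec.image_size
    return img.reshape(m, supersample, m, supersample).mean(axis=(1, 3))


def phantom_projection(
    spec: TBarPhantomSpec, angles, with_bar: bool = True
) -> Sinogram:
    """Exact parallel-beam line integrals of the T-bar phantom.

    The phantom is a composition of disks (vial, wall, bar) and bar-fixed
    rectangular strips (the drilled holes), all of which have closed-form
    chord lengths, so the projections carry no interpolation error.  Angle
    convention matches :func:`forward_radon` on :func:`phantom_slice_truth`.
    """
    n = spec.image_size
    s = np.arange(n) - (n - 1) / 2.0  # detector coordinate, pixels

    def chord(radius):
        return 2.0 * np.sqrt(np.clip(radius**2 - s**2, 0.0, None))

    base = (
        spec.mu_wall * chord(spec.vial_radius)
        + (spec.mu_liquid - spec.mu_wall) * chord(spec.vial_radius - spec.vial_wall)
    )
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    out = np.tile(base, (angles.size, 1))
    if with_bar and spec.bar_radius > 0:
        out += (spec.mu_bar - spec.mu_liquid) * chord(spec.bar_radius)[None, :]
        half_len = np.sqrt(np.clip(spec.bar_radius**2 - s**2, 0.0, None))
        for i, theta in enumerate(angles):
            t = np.deg2rad(theta)
            sin_t, cos_t = np.sin(t), np.cos(t)
            for off in spec.hole_offsets:
                if abs(cos_t) < 1e-9:
                    inside = np.abs(s * sin_t - off) <= spec.hole_half_width
                    length = np.where(inside, 2.0 * half_len, 0.0)
                else:
                    t1 = (off - spec.hole_half_width - s * sin_t) / cos_t
                    t2 = (off + spec.hole_half_width - s * sin_t) / cos_t
                    lo = np.minimum(t1, t2)
                    hi = np.maximum(t1, t2)
                    length = np.clip(
                        np.minimum(hi, half_len) - np.maximum(lo, -half_len), 0.0, None
                    )
                out[i] += (spec.mu_hole - spec.mu_bar) * length
    return Sinogram(out, angles)


def estimate_rotation_period(signal: np.ndarray, min_lag: int = 2) -> int:
    """Frames per revolution from the autocorrelation of a frame-wise signal.

    ``signal`` is any per-frame scalar or row trace (2D arrays are reduced
    to their row mean).  Returns the lag of the first autocorrelation peak
    past ``min_lag``.
    """
    sig = np.asarray(signal, dtype=float)
    if sig.ndim == 2:
        sig = sig.mean(axis=1)
    sig = sig - sig.mean()
    n = sig.size
    ac = np.correlate(sig, sig, mode="full")[n - 1 :]
    ac /= ac[0] if ac[0] != 0 else 1.0
    # first local maximum after min_lag
    for lag in range(min_lag, n - 1):
        if ac[lag] >= ac[lag - 1] and ac[lag] > ac[lag + 1] and ac[lag] > 0.2:
            return lag
    return int(np.argmax(ac[min_lag:]) + min_lag)
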