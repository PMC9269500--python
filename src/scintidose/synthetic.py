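"""Synthetic stand-ins for the camera, LINAC and rotation rig.

Everything the real experiment would photograph is emulated here so the
whole analysis chain runs offline: fluorescence photographs rendered from a
dose grid through a simple camera model (blue emission, point-spread blur,
container-reflection bands, sensor noise, sRGB encoding, 8-bit
quantisation), frame stacks of the rotating T-bar vial, and analytic toy
depth-dose curves with known practical ranges.  All generators take a seed
and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .colorimetry import RGBImage, srgb_decode, srgb_encode
from .ranges import DepthDoseCurve
from .tomography import FrameStack, TBarPhantomSpec, phantom_projection
from .transport import DoseGrid2D

__all__ = [
    "CameraModel",
    "RotPhantomSpec",
    "render_fluorescence_image",
    "render_rotation_frames",
    "render_rotating_point",
    "make_toy_pdd",
    "gamma_style_scene",
    "electron_camera",
]


@dataclass
class CameraModel:
    """A consumer camera photographing the glowing scintillator.

    ``emission_color`` is the linear-RGB direction of the scintillation
    light (blue-dominant for PPO/bis-MSB fluors).  ``gain`` scales dose →
    linear brightness; ``psf_sigma`` is the optical blur in pixels;
    ``reflection_bands`` are (row_start_frac, row_stop_frac, v_level)
    triples — the glimmer from the container walls, placed so the band's
    encoded V value equals ``v_level``.  ``depth_stretch`` emulates the
    apparent depth-axis distortion from viewing through the container wall.
    Noise is Gaussian in linear light plus optional scaled-Poisson shot
    noise; the final image is sRGB-encoded and quantised to 8 bits.
    """

    emission_color: tuple[float, float, float] = (0.10, 0.25, 0.90)
    gain: float = 1.0
    psf_sigma: float = 1.5
    noise_gauss: float = 0.01
    noise_poisson: float = 0.0  # photons per unit linear intensity; 0 = off
    reflection_bands: tuple = ()
    depth_stretch: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.psf_sigma < 0:
            raise ValueError("gain must be positive and psf_sigma non-negative")
        for band in self.reflection_bands:
            if not 0.0 <= band[2] <= 1.0:
                raise ValueError("reflection V levels must lie in [0, 1]")


def render_fluorescence_image(dose: DoseGrid2D, cam: CameraModel) -> RGBImage:
    """Render a camera-like sRGB photograph of a dose distribution.

    Pipeline: normalise dose → linear RGB along the emission color → PSF
    blur → reflection bands → noise → sRGB encode → 8-bit quantise.  Image
    rows follow dose depth (beam enters at the top of the frame).
    """
    d = np.asarray(dose.deposited, dtype=float)
    if d.min() < 0:
        raise ValueError("dose must be non-negative")
    rng = np.random.default_rng(cam.seed)
    peak = d.max()
    brightness = np.zeros_like(d) if peak == 0 else d / peak
    brightness = np.clip(brightness * cam.gain, 0.0, 1.0)

    if cam.depth_stretch != 1.0:
        # apparent (photographed) depth axis is stretched; resample rows
        n_rows = d.shape[0]
        src_rows = np.arange(n_rows) / cam.depth_stretch
        coords = np.meshgrid(src_rows, np.arange(d.shape[1]), indexing="ij")
        brightness = ndimage.map_coordinates(brightness, coords, order=1, cval=0.0)

    emission = np.asarray(cam.emission_color, dtype=float)
    linear = brightness[:, :, None] * emission[None, None, :]

    if cam.psf_sigma > 0:
        linear = ndimage.gaussian_filter(linear, (cam.psf_sigma, cam.psf_sigma, 0))

    n_rows = linear.shape[0]
    for r0, r1, v_level in cam.reflection_bands:
        rows = slice(int(round(r0 * n_rows)), int(round(r1 * n_rows)))
        # linear level chosen so the band's encoded V equals v_level
        lin_peak = float(srgb_decode(RGBImage(np.full((1, 1, 3), v_level))).pixels[0, 0, 0])
        band = emission / emission.max() * lin_peak
        linear[rows] = np.maximum(linear[rows], band[None, None, :])

    if cam.noise_poisson > 0:
        scale = cam.noise_poisson
        linear = rng.poisson(np.clip(linear, 0, 1) * scale) / scale
    if cam.noise_gauss > 0:
        linear = linear + rng.normal(0.0, cam.noise_gauss, linear.shape)
    linear = np.clip(linear, 0.0, 1.0)

    encoded = srgb_encode(linear)
    quantised = np.round(encoded * 255.0) / 255.0
    return RGBImage(quantised, "srgb")


def gamma_style_scene(
    image_shape: tuple[int, int] = (200, 200),
    signal_v: float = 0.63,
    reflection_v: float = 0.30,
    noise_gauss: float = 0.008,
    seed: int = 0,
) -> tuple[DoseGrid2D, CameraModel]:
    """Dose grid + camera reproducing the photon-beam photograph's V makeup.

    High-energy photons traverse the whole container, so the dose (and the
    fluorescence) is nearly uniform over the frame; the container walls add
    reflection bands at the top and bottom.  Defaults put the direct-light
    population near V = 0.6 and the reflections near V = 0.3, giving the
    characteristic double-peaked V histogram.
    """
    field_arr = np.ones(image_shape)
    # the reflections sit above and below the liquid, where there is no signal
    band = int(round(0.10 * image_shape[0]))
    field_arr[:band] = 0.0
    field_arr[-band:] = 0.0
    dose = DoseGrid2D(field_arr, cell_size=0.05, beam=None, relative=True)
    lin_signal = float(srgb_decode(RGBImage(np.full((1, 1, 3), signal_v))).pixels[0, 0, 0])
    emission = (0.10, 0.25, 0.90)
    gain = lin_signal / max(emission)
    cam = CameraModel(
        emission_color=emission,
        gain=gain,
        psf_sigma=0.0,
        noise_gauss=noise_gauss,
        reflection_bands=((0.0, 0.10, reflection_v), (0.90, 1.0, reflection_v)),
        seed=seed,
    )
    return dose, cam


def electron_camera(seed: int = 0, depth_stretch: float = 1.0) -> CameraModel:
    """Default camera for electron-beam photographs.

    Container-wall reflections are rendered at V = 0.25, just below the
    0.3 V-cut used for electron images, so the documented threshold removes
    them; blur and noise are modest consumer-camera levels.
    """
    return CameraModel(
        psf_sigma=1.5,
        noise_gauss=0.01,
        reflection_bands=((0.0, 0.05, 0.25), (0.95, 1.0, 0.25)),
        depth_stretch=depth_stretch,
        seed=seed,
    )


@dataclass
class RotPhantomSpec:
    """A rotating vial + T-bar video acquisition."""

    phantom: TBarPhantomSpec = field(default_factory=TBarPhantomSpec)
    frames_per_rev: int = 120
    n_frames: int = 240
    noise_sigma: float = 0.004
    refraction_amp: float = 0.0  # apparent detector displacement in pixels
    i0: float = 1.0  # unobstructed backlight intensity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < self.frames_per_rev:
            raise ValueError("need at least one full revolution")

    @property
    def frame_height(self) -> int:
        return self.phantom.image_size

    @property
    def baseline_row(self) -> int:
        lo, hi = self.phantom.bar_row_range
        return int(round(0.5 * (lo + hi) * self.frame_height))


def render_rotation_frames(spec: RotPhantomSpec) -> FrameStack:
    """Film the rotating vial: transmitted backlight through the phantom.

    Each frame records I = I0·exp(−∫μ dl) per pixel column: rows within the
    bar's vertical extent see the full slice (bar + holes), rows outside see
    the vial and liquid only.  ``refraction_amp`` displaces every projection
    by a fixed amount in the camera frame, emulating the apparent shift that
    refraction through the curved vial wall (or a miscentred rotation axis)
    imprints on the recorded rays; because the shift is fixed on the
    detector, conjugate views at θ and θ+180° disagree, and 360° sampling
    averages the inconsistency away while a 180° sinogram cannot.  Gaussian
    sensor noise is added per frame.
    """
    n_det = spec.phantom.image_size
    # exact line integrals of the phantom geometry (no interpolation error)
    proj_vial = phantom_projection(spec.phantom, [0.0], with_bar=False).intensities[0]
    thetas = np.arange(spec.frames_per_rev) * 360.0 / spec.frames_per_rev
    proj_bar_all = phantom_projection(spec.phantom, thetas).intensities

    h = spec.frame_height
    lo = int(round(spec.phantom.bar_row_range[0] * h))
    hi = int(round(spec.phantom.bar_row_range[1] * h))
    rng = np.random.default_rng(spec.seed)
    det = np.arange(n_det, dtype=float)

    frames = np.empty((spec.n_frames, h, n_det))
    for i in range(spec.n_frames):
        proj_bar = proj_bar_all[i % spec.frames_per_rev]
        if spec.refraction_amp:
            proj_bar = np.interp(det - spec.refraction_amp, det, proj_bar)
        frame = np.empty((h, n_det))
        frame[:] = spec.i0 * np.exp(-proj_vial)[None, :]
        frame[lo:hi] = spec.i0 * np.exp(-proj_bar)[None, :]
        if spec.noise_sigma > 0:
            frame = frame + rng.normal(0.0, spec.noise_sigma, frame.shape)
        frames[i] = np.clip(frame, 0.0, 1.0)

    return FrameStack(frames, spec.frames_per_rev, spec.baseline_row)


def render_rotating_point(
    radius_px: float,
    frames_per_rev: int = 90,
    n_frames: int = 90,
    image_size: int = 128,
    blob_sigma: float = 1.5,
    phase_deg: float = 0.0,
    seed: int = 0,
) -> FrameStack:
    """A bright point at radius r on the turntable, filmed from the side.

    The point's apparent column oscillates as c + r·cos(θ + φ) while its
    row stays fixed, so the sinogram trace is a sinusoid of amplitude r
    detector bins — the geometric sanity check for the rotation rig.
    """
    rng = np.random.default_rng(seed)
    c = (image_size - 1) / 2.0
    row0 = image_size // 2
    cols = np.arange(image_size)
    frames = np.zeros((n_frames, image_size, image_size))
    for i in range(n_frames):
        theta = np.deg2rad((i % frames_per_rev) * 360.0 / frames_per_rev + phase_deg)
        cx = c + radius_px * np.cos(theta)
        profile = np.exp(-0.5 * ((cols - cx) / blob_sigma) ** 2)
        frames[i, row0] = profile
        frames[i, row0 - 1] = 0.6 * profile
        frames[i, row0 + 1] = 0.6 * profile
    frames += rng.normal(0.0, 1e-4, frames.shape)
    return FrameStack(np.clip(frames, 0, 1), frames_per_rev, row0)


def make_toy_pdd(
    shape: str = "trapezoid",
    plateau_end: float = 3.0,
    fall_end: float = 4.0,
    background: float = 2.0,
    depth_max: float = 5.0,
    sigma: float = 0.4,
    n: int = 501,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> DepthDoseCurve:
    """Analytic depth-dose fixtures with a known practical range.

    ``trapezoid``: 100% plateau to ``plateau_end``, linear fall to
    ``background`` % at ``fall_end``, flat tail — the tangent/background
    intersection is exactly ``fall_end`` (for background > 0).
    ``gaussian-falloff``: plateau followed by a Gaussian distal edge of
    width ``sigma`` on a flat background.  Optional Gaussian noise (percent,
    seeded) for robustness studies.
    """
    depth = np.linspace(0.0, depth_max, n)
    if shape == "trapezoid":
        fall = 100.0 + (background - 100.0) * (depth - plateau_end) / (fall_end - plateau_end)
        dose = np.where(
            depth <= plateau_end, 100.0, np.where(depth <= fall_end, fall, background)
        )
    elif shape == "gaussian-falloff":
        tail = (100.0 - background) * np.exp(
            -0.5 * ((depth - plateau_end) / sigma) ** 2
        ) + background
        dose = np.where(depth <= plateau_end, 100.0, tail)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        dose = np.clip(dose + rng.normal(0.0, noise_sigma, dose.shape), 0.0, None)
    return DepthDoseCurve.from_raw(depth, dose, provenance="synthetic")
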