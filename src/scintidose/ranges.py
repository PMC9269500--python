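"""Practical-range extraction from depth-dose curves.

The practical range R_p of an electron beam is read off the percent-depth-
dose (PDD) curve as the depth where the tangent at the steepest point of the
distal falloff intersects the horizontal bremsstrahlung-background line.
This module also extracts R_50 (distal 50% depth) and z_max (depth of dose
maximum), converts pixel coordinates to centimetres, and applies a
refraction correction to camera-derived curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DepthDoseCurve",
    "RangeResult",
    "NoFiniteRangeError",
    "practical_range",
    "pixel_calibration",
    "refraction_correct",
]


class NoFiniteRangeError(ValueError):
    """The curve has no distal falloff inside the grid (photon-like PDD)."""


@dataclass
class DepthDoseCurve:
    """Relative dose (%) versus depth (cm), normalised to max = 100."""

    depth: np.ndarray  # cm, strictly increasing
    dose: np.ndarray  # percent, max = 100
    provenance: str = "synthetic"  # mc | image | synthetic

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        if self.depth.ndim != 1 or self.depth.shape != self.dose.shape:
            raise ValueError("depth and dose must be matching 1D arrays")
        if np.any(np.diff(self.depth) <= 0):
            raise ValueError("depth must be strictly increasing")
        if abs(self.dose.max() - 100.0) > 1e-6:
            raise ValueError("dose must be normalised to max 100")

    @classmethod
    def from_raw(cls, depth, dose, provenance="synthetic") -> "DepthDoseCurve":
        """Normalise an arbitrary non-negative dose profile to max = 100%."""
        dose = np.asarray(dose, dtype=float)
        m = dose.max()
        if m <= 0:
            raise ValueError("dose profile is identically zero")
        return cls(np.asarray(depth, dtype=float), dose * (100.0 / m), provenance)

    def to_csv(self, path) -> None:
        pd.DataFrame({"depth_cm": self.depth, "dose_percent": self.dose}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, provenance="image") -> "DepthDoseCurve":
        df = pd.read_csv(path)
        return cls.from_raw(df["depth_cm"].to_numpy(), df["dose_percent"].to_numpy(), provenance)


@dataclass
class RangeResult:
    """Range metrics extracted from one depth-dose curve.  All depths in cm."""

    r_p: float
    r_50: float
    z_max: float
    tangent_slope: float  # %/cm, negative on the falloff
    tangent_anchor: tuple[float, float]  # (depth, dose) at the steepest point
    background: float  # % level of the distal tail
    uncertainty: float  # cm, from the tangent-window sensitivity scan

    def __post_init__(self) -> None:
        if not (self.z_max <= self.r_50 + 1e-9 and self.r_50 <= self.r_p + 1e-9):
            raise ValueError("expected z_max <= r_50 <= r_p")

    def as_dict(self) -> dict:
        return {
            "r_p_cm": self.r_p,
            "r_50_cm": self.r_50,
            "z_max_cm": self.z_max,
            "tangent_slope_pct_per_cm": self.tangent_slope,
            "background_pct": self.background,
            "uncertainty_cm": self.uncertainty,
        }


def _moving_average(y: np.ndarray, window: int = 3) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(y, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def _distal_crossing(depth, dose, level, start):
    """First depth at/after index ``start`` where dose falls through ``level``."""
    d = dose[start:]
    below = np.nonzero(d <= level)[0]
    if below.size == 0:
        return None
    j = below[0]
    if j == 0:
        return depth[start]
    x0, x1 = depth[start + j - 1], depth[start + j]
    y0, y1 = d[j - 1], d[j]
    if y1 == y0:
        return x1
    return x0 + (level - y0) * (x1 - x0) / (y1 - y0)


def _default_window(depth, dose, i_max, z_max):
    z80 = _distal_crossing(depth, dose, 80.0, i_max)
    z20 = _distal_crossing(depth, dose, 20.0, i_max)
    if z80 is not None and z20 is not None and z20 > z80:
        return 0.2 * (z20 - z80) / 0.6
    return 0.2 * (depth[-1] - z_max)


def _extract(depth, dose, tangent_window, tail_window):
    i_max = int(np.argmax(dose))
    z_max = depth[i_max]

    # bremsstrahlung background: mean over the distal tail of the grid
    n_tail = max(2, int(round(tail_window * len(depth))))
    background = float(np.mean(dose[-n_tail:]))

    # steepest descent on a lightly smoothed curve, restricted distal to max
    smooth = _moving_average(dose, 3)
    grad = np.gradient(smooth, depth)
    grad[: i_max + 1] = 0.0
    g_min = grad.min()
    if g_min >= 0:
        raise NoFiniteRangeError("no distal falloff inside the grid")
    # a linear falloff has a plateau of equally steep samples; take its
    # middle so the fit window stays clear of the corners
    near = np.nonzero(grad <= g_min * (1.0 - 1e-9))[0]
    i_steep = int(near[len(near) // 2])

    if tangent_window is None:
        tangent_window = _default_window(depth, dose, i_max, z_max)

    z_s = depth[i_steep]
    sel = (depth >= z_s - tangent_window / 2) & (depth <= z_s + tangent_window / 2)
    if sel.sum() < 2:  # widen to the three nearest samples
        order = np.argsort(np.abs(depth - z_s))
        sel = np.zeros_like(sel)
        sel[order[:3]] = True
    slope, intercept = np.polyfit(depth[sel], dose[sel], 1)
    if slope >= 0:
        raise NoFiniteRangeError("distal tangent is not decreasing")

    r_p = (background - intercept) / slope
    return r_p, z_max, i_max, background, slope, (z_s, float(np.interp(z_s, depth, dose)))


def practical_range(
    curve: DepthDoseCurve,
    tangent_window: float | None = None,
    tail_window: float = 0.1,
) -> RangeResult:
    """Extract R_p, R_50 and z_max by the tangent/background construction.

    Parameters
    ----------
    tangent_window
        Width (cm) of the straight-line fit centred on the steepest distal
        point.  Defaults to 20% of the falloff extent.  The tangent is fitted
        to the unsmoothed data; only the location of the steepest point uses
        a 3-sample moving average.
    tail_window
        Fraction of the depth grid (distal end) averaged into the
        bremsstrahlung-background level.

    The quoted uncertainty is half the spread of R_p when the tangent window
    is varied by ±50% — a documented convention, since the falloff of a
    measured curve is never exactly linear.
    """
    depth, dose = curve.depth, curve.dose
    if int(np.argmax(dose)) >= len(dose) - 1:
        raise NoFiniteRangeError("dose is still rising at the end of the grid")

    r_p, z_max, i_max, background, slope, anchor = _extract(
        depth, dose, tangent_window, tail_window
    )

    r_50 = _distal_crossing(depth, dose, 50.0, i_max)
    if r_50 is None:
        raise NoFiniteRangeError("dose never falls through 50% distal to the maximum")

    base_w = tangent_window if tangent_window is not None else _default_window(
        depth, dose, i_max, z_max
    )
    variants = []
    for w in (0.5 * base_w, 1.5 * base_w):
        try:
            variants.append(_extract(depth, dose, w, tail_window)[0])
        except NoFiniteRangeError:
            pass
    spread = (max(variants + [r_p]) - min(variants + [r_p])) / 2 if variants else 0.0

    return RangeResult(
        r_p=float(r_p),
        r_50=float(r_50),
        z_max=float(z_max),
        tangent_slope=float(slope),
        tangent_anchor=anchor,
        background=background,
        uncertainty=float(spread),
    )


def pixel_calibration(image_extent_px: float, container_extent_cm: float) -> float:
    """cm per pixel from a container of known physical size in the frame."""
    if image_extent_px <= 0 or container_extent_cm <= 0:
        raise ValueError("extents must be positive")
    return container_extent_cm / image_extent_px


def refraction_correct(
    curve: DepthDoseCurve,
    n_medium: float = 1.0,
    n_air: float = 1.0,
    depth_scale: float | None = None,
) -> DepthDoseCurve:
    """Rescale apparent depths of a camera-derived curve.

    Viewing the scintillator through the container wall stretches or
    compresses the apparent depth axis.  The correction is a single
    multiplicative factor on depth; with ``depth_scale=None`` it defaults to
    1.0 (no correction), since the appropriate factor depends on the
    camera/container geometry and must be supplied by the user.  ``n_medium``
    and ``n_air`` are recorded for provenance only; equal indices with no
    explicit factor give the identity.
    """
    if n_medium < 1.0:
        raise ValueError("n_medium must be >= 1")
    factor = 1.0 if depth_scale is None else float(depth_scale)
    return DepthDoseCurve(curve.depth * factor, curve.dose.copy(), curve.provenance)
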