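"""Deterministic geometry of the image-acquisition protocols.

Two diver-rig trajectories are modelled:

* the "Reef Record" spiral — a line coiled round a central drum unwinds one
  drum circumference per turn, so the track is an Archimedean spiral with
  inter-turn spacing pi * drum_diameter; the swept plot diameter is twice the
  tether length;
* the "Mow-the-lawn" boustrophedon — straight passes of fixed length offset
  cross-track by a constant spacing.

Plus the pinhole footprint / ground-sampling-distance (GSD) geometry of the
downward-looking camera at constant range above the substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = [
    "CameraModel",
    "DIVER_RIG_CAMERA",
    "SpiralPlan",
    "LawnmowerPlan",
    "footprint",
    "spiral_plan",
    "lawnmower_plan",
]


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera: full fields of view (degrees) and pixel counts."""

    fov_h: float
    fov_v: float
    pixels_h: int
    pixels_v: int

    def __post_init__(self) -> None:
        for f in (self.fov_h, self.fov_v):
            if not 0 < f < 180:
                raise ParameterError("fields of view must lie in (0, 180) degrees")
        if self.pixels_h < 1 or self.pixels_v < 1:
            raise ParameterError("pixel counts must be >= 1")


#: the stereo-rig camera: 1360 x 1024 px, 42 x 34 degree in-water FOV
DIVER_RIG_CAMERA = CameraModel(fov_h=42.0, fov_v=34.0, pixels_h=1360, pixels_v=1024)


def footprint(cam: CameraModel, range_m: float) -> tuple[float, float, float]:
    """(width m, height m, gsd mm/px) of the image footprint at a given range.

    width = 2 * range * tan(fov_h / 2), height analogous;
    gsd = width / pixels_h, in millimetres per pixel. Flat substrate at
    constant range is assumed.
    """
    if not range_m > 0:
        raise ParameterError("range must be positive")
    width = 2.0 * range_m * np.tan(np.radians(cam.fov_h) / 2.0)
    height = 2.0 * range_m * np.tan(np.radians(cam.fov_v) / 2.0)
    gsd_mm = 1000.0 * width / cam.pixels_h
    return float(width), float(height), float(gsd_mm)


@dataclass
class SpiralPlan:
    """Archimedean spiral survey: r(theta) = pitch * theta / (2 pi)."""

    drum_diameter: float
    tether_length: float
    waypoints: np.ndarray = field(repr=False)

    @property
    def track_spacing(self) -> float:
        """Inter-turn spacing: one drum circumference unwinds per turn."""
        return float(np.pi * self.drum_diameter)

    @property
    def plot_diameter(self) -> float:
        return 2.0 * self.tether_length

    @property
    def swept_area(self) -> float:
        return float(np.pi * self.tether_length**2)


@dataclass
class LawnmowerPlan:
    """Boustrophedon survey: n_passes lines of line_length, cross_spacing apart."""

    line_length: float
    n_passes: int
    cross_spacing: float
    waypoints: np.ndarray = field(repr=False)

    @property
    def area(self) -> float:
        return self.line_length * self.n_passes * self.cross_spacing


def spiral_plan(
    drum_diameter: float, tether_length: float, step: float = 0.1
) -> SpiralPlan:
    """Waypoints of the Reef Record spiral, sampled every ``step`` metres of
    arc length, from the centre out to radius = tether_length.

    The pitch (radial gain per turn) is pi * drum_diameter, the circumference
    of the drum the line unwinds from. The final waypoint lies exactly at the
    tether radius, so the plot diameter is exactly twice the tether length.
    """
    if drum_diameter <= 0 or tether_length <= 0:
        raise ParameterError("drum_diameter and tether_length must be positive")
    if step <= 0:
        raise ParameterError("step must be positive")
    pitch = np.pi * drum_diameter
    a = pitch / (2.0 * np.pi)  # r = a * theta
    theta_max = tether_length / a
    # arc length of r = a*theta is s(theta) = a/2 * (theta*sqrt(1+theta^2) + asinh(theta))
    def arclen(theta):
        return 0.5 * a * (theta * np.hypot(1.0, theta) + np.arcsinh(theta))

    total = arclen(theta_max)
    targets = np.arange(0.0, total, step)
    # invert s(theta) by Newton iteration; ds/dtheta = a*sqrt(1+theta^2)
    theta = np.sqrt(2.0 * targets / a)  # small-theta initial guess
    for _ in range(30):
        theta = theta - (arclen(theta) - targets) / (a * np.hypot(1.0, theta))
        theta = np.clip(theta, 0.0, theta_max)
    theta = np.append(theta, theta_max)
    r = a * theta
    waypoints = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return SpiralPlan(drum_diameter, tether_length, waypoints)


def lawnmower_plan(
    line_length: float, n_passes: int, cross_spacing: float
) -> LawnmowerPlan:
    """Waypoints of a Mow-the-lawn survey.

    Pass k runs along x at y = k * cross_spacing, alternating direction;
    covered area is line_length * n_passes * cross_spacing. Zero passes give
    an empty plan.
    """
    if line_length <= 0 or cross_spacing <= 0:
        raise ParameterError("line_length and cross_spacing must be positive")
    if n_passes < 0:
        raise ParameterError("n_passes must be >= 0")
    pts = []
    for k in range(n_passes):
        y = k * cross_spacing
        ends = [(0.0, y), (line_length, y)]
        if k % 2 == 1:
            ends.reverse()
        pts.extend(ends)
    waypoints = np.array(pts, dtype=float).reshape(-1, 2)
    return LawnmowerPlan(line_length, n_passes, cross_spacing, waypoints)
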