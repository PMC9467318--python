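"""Screen geometry and pixel <-> visual-angle conversion.

Gaze positions arrive in screen pixels (origin top-left, y growing
downward). All event detection and scoring operates in degrees of
visual angle (deg va) about the screen center, computed per axis with
an exact arctangent given the monitor's physical size and the viewing
distance. The conversion is exact at all eccentricities and invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScreenGeometry", "px_to_deg", "deg_to_px", "PAPER_GEOMETRY"]


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical and pixel dimensions of the display plus viewing distance.

    Parameters
    ----------
    width_cm, height_cm : float
        Physical size of the display area in centimetres.
    res_x_px, res_y_px : int
        Display resolution in pixels.
    distance_cm : float
        Eye-to-screen distance in centimetres.
    """

    width_cm: float
    height_cm: float
    res_x_px: int
    res_y_px: int
    distance_cm: float

    def __post_init__(self) -> None:
        for name in ("width_cm", "height_cm", "res_x_px", "res_y_px", "distance_cm"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be strictly positive, got {v!r}")

    @property
    def pitch_x_cm(self) -> float:
        """Width of one pixel in cm."""
        return self.width_cm / self.res_x_px

    @property
    def pitch_y_cm(self) -> float:
        """Height of one pixel in cm."""
        return self.height_cm / self.res_y_px

    @property
    def center_px(self) -> tuple[float, float]:
        return (self.res_x_px / 2.0, self.res_y_px / 2.0)


#: 19-inch CRT at 1024x768 (36 x 27 cm) viewed from 71 cm — the standard
#: desktop eye-tracking setup this package's defaults assume.
PAPER_GEOMETRY = ScreenGeometry(
    width_cm=36.0, height_cm=27.0, res_x_px=1024, res_y_px=768, distance_cm=71.0
)


def px_to_deg(p, geom: ScreenGeometry) -> np.ndarray:
    """Convert pixel positions to degrees of visual angle about screen center.

    Per axis: theta = atan((p - center_px) * pixel_pitch_cm / distance_cm),
    in degrees. The screen center maps to (0, 0); x grows rightward and
    y downward, matching the pixel convention.

    Parameters
    ----------
    p : array_like, shape (2,) or (n, 2)
        Pixel coordinates.
    geom : ScreenGeometry

    Returns
    -------
    ndarray with the same shape as ``p``: angular position(s) in deg va.
    """
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite pixel coordinate")
    cx, cy = geom.center_px
    off = p - np.array([cx, cy])
    scale = np.array([geom.pitch_x_cm, geom.pitch_y_cm]) / geom.distance_cm
    return np.degrees(np.arctan(off * scale))


def deg_to_px(theta, geom: ScreenGeometry) -> np.ndarray:
    """Inverse of :func:`px_to_deg` (exact round-trip)."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite angular coordinate")
    cx, cy = geom.center_px
    scale = np.array([geom.pitch_x_cm, geom.pitch_y_cm]) / geom.distance_cm
    off = np.tan(np.radians(theta)) / scale
    return off + np.array([cx, cy])


def angular_distance(a, b) -> np.ndarray:
    """Euclidean distance in (theta_x, theta_y) space, in deg va."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return np.linalg.norm(a - b, axis=-1)
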