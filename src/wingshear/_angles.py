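"""Axial (nematic) angle arithmetic.

All angles in this package follow one convention: positions are stored in
image coordinates (x rightward, y downward, in micrometres), but every
reported angle is mathematical — counterclockwise from +x after flipping the
y-axis.  Orientations of junctions, polarity axes and flow directions are
axial quantities (defined modulo 180 degrees) and live in [-90, 90).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_axial",
    "axial_deg",
    "axial_diff",
    "nematic_mean",
]


def wrap_axial(angle_deg):
    """Map an angle in degrees to the axial range [-90, 90)."""
    return (np.asarray(angle_deg, dtype=float) + 90.0) % 180.0 - 90.0


def axial_deg(dx, dy):
    """Axial orientation in degrees of the segment (dx, dy) given in image
    coordinates (y downward).  The y-flip converts to the mathematical
    convention before wrapping to [-90, 90)."""
    return wrap_axial(np.degrees(np.arctan2(-np.asarray(dy, float), np.asarray(dx, float))))


def axial_diff(a_deg, b_deg):
    """Smallest axial difference a - b, in [-90, 90)."""
    return wrap_axial(np.asarray(a_deg, float) - np.asarray(b_deg, float))


def nematic_mean(angles_deg, weights=None):
    """Weighted nematic (doubled-angle) mean.

    Returns (magnitude, angle_deg) where magnitude is the resultant length of
    the doubled-angle unit vectors (1 = perfectly aligned, 0 = isotropic) and
    angle_deg is the mean axis in [-90, 90).
    """
    phi2 = 2.0 * np.radians(np.asarray(angles_deg, float))
    if weights is None:
        weights = np.ones_like(phi2)
    w = np.asarray(weights, float)
    if w.sum() <= 0:
        raise ValueError("nematic_mean requires positive total weight")
    cx = np.sum(w * np.cos(phi2)) / w.sum()
    sx = np.sum(w * np.sin(phi2)) / w.sum()
    mag = float(np.hypot(cx, sx))
    ang = float(wrap_axial(np.degrees(0.5 * np.arctan2(sx, cx))))
    return mag, ang
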