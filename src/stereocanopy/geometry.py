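"""Stereo rig geometry and metric conversions between disparity, depth and height.

The rig is a fixed overhead pair of pinhole cameras with vertical optical
axes, separated horizontally by a baseline ``G`` and mounted a height ``H``
above the ground reference.  For such a rig the depth of a scene point is
``P = f*G / (d*S_c)`` where ``d`` is its disparity in pixels, ``f`` the focal
length and ``S_c`` the sensor pixel pitch.  Plant height above ground is most
robustly recovered from the *normalized* disparity ``eta = d - d_g`` (``d_g``
being the disparity of the ground plane), because any rig-vibration offset
common to a frame cancels in the subtraction:

    h = H**2 * eta * S_c / (f*G + eta * S_c * H)

All lengths are handled internally in millimetres; disparities in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CameraRig",
    "disparity_to_depth",
    "depth_to_height",
    "normalize_disparity",
    "height_from_normalized_disparity",
    "pixel_footprint_area",
]


@dataclass(frozen=True)
class CameraRig:
    """Fixed overhead stereo rig geometry.

    Parameters
    ----------
    focal_length : float
        Effective focal length ``f`` in mm.
    baseline : float
        Distance ``G`` between the camera apertures in mm.
    camera_height : float
        Height ``H`` of the apertures above the ground reference in mm.
    pixel_pitch : float
        Sensor pixel pitch ``S_c`` in mm per pixel.
    """

    focal_length: float
    baseline: float
    camera_height: float
    pixel_pitch: float

    def __post_init__(self) -> None:
        for name in ("focal_length", "baseline", "camera_height", "pixel_pitch"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"CameraRig.{name} must be finite and positive, got {v!r}")

    @property
    def ground_disparity(self) -> float:
        """Disparity of the ground plane, ``d_g = f*G / (H*S_c)`` (pixels)."""
        return self.focal_length * self.baseline / (self.camera_height * self.pixel_pitch)

    @property
    def ground_footprint(self) -> float:
        """Side length of one pixel's footprint on the ground, ``H*S_c/f`` (mm)."""
        return self.camera_height * self.pixel_pitch / self.focal_length

    @classmethod
    def from_dict(cls, d: dict) -> "CameraRig":
        """Build a rig from config keys ``focal_length_mm`` etc."""
        return cls(
            focal_length=float(d["focal_length_mm"]),
            baseline=float(d["baseline_mm"]),
            camera_height=float(d["camera_height_mm"]),
            pixel_pitch=float(d["pixel_pitch_mm"]),
        )

    def to_dict(self) -> dict:
        return {
            "focal_length_mm": self.focal_length,
            "baseline_mm": self.baseline,
            "camera_height_mm": self.camera_height,
            "pixel_pitch_mm": self.pixel_pitch,
        }


def disparity_to_depth(rig: CameraRig, d):
    """Convert disparity (pixels) to depth below the cameras (mm).

    ``P = f*G / (d*S_c)``; strictly decreasing in ``d``.  Raises for
    non-positive disparities (a point at infinity or behind the camera).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("disparity must be positive for a finite depth")
    out = rig.focal_length * rig.baseline / (d * rig.pixel_pitch)
    return out if out.ndim else float(out)


def depth_to_height(rig: CameraRig, depth):
    """Height above the ground reference, ``h = H - P`` (mm).

    Negative results indicate points below the ground plane (e.g. furrows);
    clamping is left to the caller.
    """
    depth = np.asarray(depth, dtype=float)
    if np.any(depth <= 0):
        raise ValueError("depth must be positive")
    out = rig.camera_height - depth
    return out if out.ndim else float(out)


def normalize_disparity(d, d_g: float):
    """Normalized disparity ``eta = d - d_g``.

    ``d_g`` is the disparity of the ground level.  Because any constant
    offset (rig vibration) shifts ``d`` and ``d_g`` identically, ``eta`` is
    invariant to it.
    """
    if d_g <= 0:
        raise ValueError("ground disparity d_g must be positive")
    d = np.asarray(d, dtype=float)
    out = d - d_g
    return out if out.ndim else float(out)


def height_from_normalized_disparity(rig: CameraRig, eta):
    """Height above ground from normalized disparity (mm).

    ``h = H**2 * eta * S_c / (f*G + eta*S_c*H)``.  At ``eta = 0`` the point is
    on the ground; as ``eta`` grows the height approaches ``H``.  Equals the
    composition depth->height at disparity ``d_g + eta`` when ``d_g`` is the
    rig-implied ground disparity.
    """
    eta = np.asarray(eta, dtype=float)
    f, G, H, S_c = rig.focal_length, rig.baseline, rig.camera_height, rig.pixel_pitch
    denom = f * G + eta * S_c * H
    if np.any(denom <= 0):
        raise ValueError("f*G + eta*S_c*H must be positive (point behind camera)")
    out = H * H * eta * S_c / denom
    return out if out.ndim else float(out)


def pixel_footprint_area(rig: CameraRig, depth):
    """Physical area imaged by one pixel at depth ``P``: ``(P*S_c/f)**2`` (mm^2).

    The basis of normalizing pixel-count height histograms to leaf area:
    pixels imaging surfaces closer to the camera cover less physical area.
    """
    depth = np.asarray(depth, dtype=float)
    if np.any(depth <= 0):
        raise ValueError("depth must be positive")
    side = depth * rig.pixel_pitch / rig.focal_length
    out = side * side
    return out if out.ndim else float(out)
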