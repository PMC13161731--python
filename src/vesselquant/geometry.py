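"""Physical calibration and per-object geometry.

All downstream analysis works in physical units (micrometres).  A
:class:`PixelCalibration` converts pixel measurements to µm; an
:class:`InstanceRecord` carries the calibrated morphometry of one vessel
object (area, centroid, perimeter, equivalent radius).

Conventions used throughout the package:

* image coordinates are 0-based, row-major, with y increasing downward;
* a pixel with index ``(i, j)`` contributes its centre at
  ``((j + 0.5) * s, (i + 0.5) * s)`` in µm, where ``s`` is the pixel size;
* the *equivalent radius* of an object of area ``A`` is the radius of the
  circle with the same area, ``r = sqrt(A / pi)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InputError

#: Pixel size of the slide scanner used for the reference datasets (µm/px).
DEFAULT_MICRONS_PER_PIXEL = 0.137


@dataclass(frozen=True)
class PixelCalibration:
    """Physical pixel size of a raster image.

    Parameters
    ----------
    microns_per_pixel :
        Edge length of one pixel in µm. Must be positive.
    """

    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL

    def __post_init__(self) -> None:
        if not (self.microns_per_pixel > 0 and math.isfinite(self.microns_per_pixel)):
            raise InputError(
                f"microns_per_pixel must be a positive finite number, "
                f"got {self.microns_per_pixel!r}"
            )

    @property
    def area_scale(self) -> float:
        """µm² per pixel (the square of the linear scale)."""
        return self.microns_per_pixel**2


@dataclass(frozen=True)
class InstanceRecord:
    """One vessel object with calibrated morphometry.

    ``eq_radius_um`` is derived from ``area_um2`` unless supplied explicitly;
    when supplied it must agree with ``sqrt(area_um2 / pi)`` to 1e-9 relative.
    """

    id: int
    centroid_x_um: float
    centroid_y_um: float
    area_um2: float
    perimeter_um: float = float("nan")
    eq_radius_um: float = field(default=None)  # type: ignore[assignment]
    area_px: int = 0

    def __post_init__(self) -> None:
        if not (self.area_um2 > 0 and math.isfinite(self.area_um2)):
            raise InputError(f"area_um2 must be positive, got {self.area_um2!r}")
        if not (math.isfinite(self.centroid_x_um) and math.isfinite(self.centroid_y_um)):
            raise InputError("instance centroid must be finite")
        expected = equivalent_radius(self.area_um2)
        if self.eq_radius_um is None:
            object.__setattr__(self, "eq_radius_um", expected)
        elif abs(self.eq_radius_um - expected) > 1e-9 * expected:
            raise InputError(
                f"eq_radius_um={self.eq_radius_um} inconsistent with "
                f"area_um2={self.area_um2} (expected {expected})"
            )

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.centroid_x_um, self.centroid_y_um)


def area_px_to_um2(area_px: int, calib: PixelCalibration) -> float:
    """Convert a pixel count to a physical area in µm².

    No rounding is applied: 10 px at 0.137 µm/px is exactly
    ``10 * 0.137**2 = 0.18769`` µm².
    """
    if area_px < 0:
        raise InputError(f"pixel area must be non-negative, got {area_px}")
    return float(area_px) * calib.area_scale


def equivalent_radius(area_um2: float) -> float:
    """Radius (µm) of the circle whose area equals ``area_um2``."""
    if not (area_um2 > 0):
        raise InputError(f"area must be positive, got {area_um2!r}")
    return math.sqrt(area_um2 / math.pi)


def centroid_distance(p: InstanceRecord, g: InstanceRecord) -> float:
    """Euclidean distance (µm) between the centroids of two instances."""
    return math.hypot(
        p.centroid_x_um - g.centroid_x_um, p.centroid_y_um - g.centroid_y_um
    )


def circle_iou(r1: float, r2: float, d: float) -> float:
    """Intersection-over-union of two discs of radii ``r1``, ``r2`` whose
    centres are ``d`` apart.

    Uses the closed-form circular-lens intersection area with an explicit
    containment branch; exact up to floating point, no numerical integration.
    The result is symmetric in the radii and non-increasing in ``d``.
    """
    if not (r1 > 0 and r2 > 0):
        raise InputError(f"radii must be positive, got r1={r1!r}, r2={r2!r}")
    if d < 0:
        raise InputError(f"distance must be non-negative, got {d!r}")

    a1 = math.pi * r1 * r1
    a2 = math.pi * r2 * r2
    if d >= r1 + r2:
        return 0.0
    r_min, r_max = (r1, r2) if r1 <= r2 else (r2, r1)
    if d + r_min <= r_max:
        # one disc inside the other: intersection is the smaller disc
        inter = math.pi * r_min * r_min
    else:
        # circular lens: sum of the two circular-segment areas
        d1 = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
        d2 = d - d1
        seg1 = r1 * r1 * math.acos(max(-1.0, min(1.0, d1 / r1)))
        seg2 = r2 * r2 * math.acos(max(-1.0, min(1.0, d2 / r2)))
        tri = 0.5 * math.sqrt(
            max(0.0, (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2))
        )
        inter = seg1 + seg2 - tri
    union = a1 + a2 - inter
    return inter / union
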