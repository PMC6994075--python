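"""Length, volume, surface area and curvature from the width profile.

The worm body is modelled as a chain of circular truncated cones
(frusta) between consecutive width samples:

    V = (1/3) * pi * (r1^2 + r1*r2 + r2^2) * h
    S = pi * (r1 + r2) * sqrt((r1 - r2)^2 + h^2)

Summing V over the chain gives the volume, summing S the lateral
surface area; the solid is closed by the zero-width tip samples, so no
end caps are added.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .preprocess import BinaryWormMask
from .radii import WidthProfile, to_frustum_series
from .spine import SpinePath


@dataclasses.dataclass
class TruncatedConeSegment:
    r1: float  # radius at near face, physical units
    r2: float  # radius at far face
    h: float  # axial height

    def __post_init__(self) -> None:
        if self.r1 < 0 or self.r2 < 0:
            raise ValueError("radii must be >= 0")
        if self.h <= 0:
            raise ValueError("height must be > 0")


@dataclasses.dataclass
class Morphometrics:
    """One worm's measurements: length, volume, surface area, curvature."""

    length: float
    volume: float
    surface_area: float
    curvature: np.ndarray | None = None  # radians per physical length unit
    worm_id: str = ""


def frustum_volume(seg: TruncatedConeSegment) -> float:
    """Volume of one truncated cone; r1 == r2 gives the cylinder pi r^2 h."""
    return (np.pi / 3.0) * (seg.r1**2 + seg.r1 * seg.r2 + seg.r2**2) * seg.h


def frustum_lateral_area(seg: TruncatedConeSegment) -> float:
    """Lateral (slant) surface of one truncated cone; r1 == r2 gives 2 pi r h."""
    return np.pi * (seg.r1 + seg.r2) * np.sqrt((seg.r1 - seg.r2) ** 2 + seg.h**2)


def _series_sums(series: np.ndarray) -> tuple[float, float]:
    r1, r2, h = series[:, 0], series[:, 1], series[:, 2]
    vol = float(np.sum((np.pi / 3.0) * (r1**2 + r1 * r2 + r2**2) * h))
    area = float(np.sum(np.pi * (r1 + r2) * np.sqrt((r1 - r2) ** 2 + h**2)))
    return vol, area


def curvature(spine: SpinePath, smooth_sigma: float = 0.0) -> np.ndarray:
    """Per-point curvature k = d(phi)/ds in radians per pixel.

    Central differences on the unwrapped tangent angle (one-sided at the
    ends). ``smooth_sigma`` > 0 applies a Gaussian filter to the angle
    series first — off by default so nothing is hidden from the caller.
    """
    if len(spine.points) < 3:
        raise ValueError("need at least 3 spine points for curvature")
    phi = spine.tangent_angle
    if smooth_sigma > 0:
        phi = gaussian_filter1d(phi, smooth_sigma, mode="nearest")
    return np.gradient(phi, spine.arc_length)


def total_morphometrics(
    wp: WidthProfile,
    spine: SpinePath,
    worm_id: str = "",
    with_curvature: bool = False,
    curvature_smooth_sigma: float = 0.0,
) -> Morphometrics:
    """Length, frustum-sum volume and surface area in physical units."""
    if len(wp.s_px) != len(spine.points):
        raise ValueError("width profile and spine path are inconsistent")
    series = to_frustum_series(wp)
    vol, area = _series_sums(series)
    k = None
    if with_curvature:
        # curvature comes out per pixel; rescale to per physical unit
        k = curvature(spine, curvature_smooth_sigma) / wp.scale
    return Morphometrics(
        length=spine.length_px * wp.scale,
        volume=vol,
        surface_area=area,
        curvature=k,
        worm_id=worm_id,
    )


def straighten(
    mask: BinaryWormMask, spine: SpinePath, wp: WidthProfile, margin: int = 2
) -> np.ndarray:
    """Rebuild the silhouette on a straight axis from (s, width) pairs.

    Column x of the output corresponds to arc position s = x; the rows
    within width(s)/2 of the centre row are foreground. This is a
    reconstruction from the width profile, not an image resampling, so
    the result is symmetric about its axis.
    """
    length = int(np.ceil(spine.length_px))
    if length < 1 or not np.any(wp.width_px > 0):
        return np.zeros((1, max(length + 1, 1)), dtype=bool)
    half = int(np.ceil(np.nanmax(wp.width_px) / 2.0)) + margin
    xs = np.arange(length + 1, dtype=np.float64)
    w = np.interp(xs, wp.s_px, wp.width_px)
    # axis sits between the two centre rows; half-open band so a column
    # of width w fills round(w) rows, matching pixel-centre rasterization
    offsets = np.arange(2 * half) - half + 0.5
    return (offsets[:, None] > -w[None, :] / 2.0) & (
        offsets[:, None] <= w[None, :] / 2.0
    )
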