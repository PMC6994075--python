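"""Diameter of the worm along its midline.

At every spine point a probe line normal to the midline is intersected
with the worm boundary on either side; the distance between the two
sub-pixel crossings is the local diameter. The per-point (position,
width) pairs feed the truncated-cone integration and the per-worm
output table.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as ndi

from .errors import RadiiFailureError
from .spine import OutlineImage, SpinePath, _first_outside_crossing

DEFAULT_PROBE_HALF_PX = 30.0
#: maximum tolerated fraction of spine points with no width measurement
MAX_MISSING_FRACTION = 0.05


@dataclasses.dataclass
class WidthProfile:
    """Per-spine-point diameter plus the boundary points on each side.

    ``s_px`` / ``width_px`` are in pixels; ``s`` and ``width`` apply the
    calibration scale. ``missing`` flags points whose width had to be
    interpolated from neighbours.
    """

    s_px: np.ndarray
    width_px: np.ndarray
    edge_left: np.ndarray  # (N, 2) sub-pixel (x, y)
    edge_right: np.ndarray  # (N, 2)
    scale: float
    missing: np.ndarray  # (N,) bool

    @property
    def s(self) -> np.ndarray:
        return self.s_px * self.scale

    @property
    def width(self) -> np.ndarray:
        return self.width_px * self.scale

    @property
    def missing_fraction(self) -> float:
        return float(self.missing.mean())


def measure_widths(
    path: SpinePath,
    edge: OutlineImage,
    probe_half_length: float = DEFAULT_PROBE_HALF_PX,
) -> WidthProfile:
    """Diameter at every spine point from normal-probe boundary crossings.

    The first crossing on each side is used; anything beyond it (e.g.
    the far limb of a curled worm re-entering the probe) is ignored.
    The appended tip points get width 0 by construction, closing the
    solid for the volume/surface integration. A side with no crossing
    within the probe's reach is recorded as missing and interpolated
    linearly in arc length afterwards; more than
    ``MAX_MISSING_FRACTION`` missing points aborts the measurement.
    """
    if not path.extended:
        raise ValueError("measure_widths requires an end-extended spine path")
    filled_f = edge.filled().astype(np.float32)
    n = len(path.points)
    width = np.full(n, np.nan)
    missing = np.zeros(n, dtype=bool)
    e_left = np.full((n, 2), np.nan)
    e_right = np.full((n, 2), np.nan)
    normals = path.normals()
    for i, (p, nrm) in enumerate(zip(path.points, normals)):
        if i == 0 or i == n - 1:
            width[i] = 0.0
            e_left[i] = e_right[i] = p
            continue
        left = _first_outside_crossing(filled_f, p, nrm, probe_half_length)
        right = _first_outside_crossing(filled_f, p, -nrm, probe_half_length)
        if left is None or right is None:
            missing[i] = True
            continue
        e_left[i] = left
        e_right[i] = right
        width[i] = np.hypot(*(left - right))
    if missing.mean() > MAX_MISSING_FRACTION:
        raise RadiiFailureError(
            f"radii failure: {missing.sum()} of {n} spine points "
            f"({100 * missing.mean():.1f}%) had no boundary crossing within "
            f"{probe_half_length} px"
        )
    if missing.any():
        ok = ~missing
        width[missing] = np.interp(
            path.arc_length[missing], path.arc_length[ok], width[ok]
        )
    return WidthProfile(
        s_px=path.arc_length.copy(),
        width_px=width,
        edge_left=e_left,
        edge_right=e_right,
        scale=edge.scale,
        missing=missing,
    )


def to_frustum_series(wp: WidthProfile) -> np.ndarray:
    """Consecutive width samples -> (r1, r2, h) rows in physical units.

    Row i spans samples i..i+1: radii are the half-widths at each end,
    h the arc-length gap. The heights telescope to the full spine span.
    """
    if len(wp.s_px) < 2:
        raise ValueError("need at least 2 width samples")
    if np.any(np.diff(wp.s_px) <= 0):
        raise ValueError("arc-length positions must be strictly increasing")
    r = wp.width / 2.0
    h = np.diff(wp.s)
    return np.column_stack([r[:-1], r[1:], h])


def write_width_table(
    path, wp: WidthProfile, unit: str = "mm", header: bool = True
) -> None:
    """Two tab-separated columns: arc position and width, physical units."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"Position ({unit})\tWidth ({unit})\n")
        for s, w in zip(wp.s, wp.width):
            fh.write(f"{s:.4f}\t{w:.4f}\n")
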