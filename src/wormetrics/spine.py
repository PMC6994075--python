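"""Midline ("spine line") extraction and tracing.

The worm mask is thinned to a one-pixel skeleton, the skeleton is traced
end to end with a moving perpendicular profile line that re-centres at
every step, and finally the traced path is extended to the worm's true
tips using the one-pixel outline of the mask (thinning always stops a
little short of the ends).

Coordinates are (x, y) = (column, row), origin at the top-left pixel
centre, sub-pixel positions are real-valued.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize as _sk_skeletonize

from .errors import (
    DegenerateWormError,
    EndExtensionError,
    SelfOverlapError,
    SelfProximityError,
)
from .preprocess import STRUCT8, BinaryWormMask

DEFAULT_STEP_PX = 4.0
DEFAULT_PROFILE_HALF_PX = 20.0
DEFAULT_MIN_SPINE_LEN_PX = 10.0
DEFAULT_PRUNE_LEN_PX = 10.0
#: second profile cluster farther than this from the accepted one means
#: another part of the worm entered the profile line
PROXIMITY_TOL_PX = 5.0
#: window of terminal points used to estimate an end's direction
END_SLOPE_POINTS = 5

STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclasses.dataclass
class SpinePath:
    """Ordered sub-pixel midline with tangent angles and arc length.

    ``tangent_angle`` is unwrapped so consecutive differences stay below
    pi/2; ``arc_length`` is the cumulative point-to-point distance in
    pixels, starting at 0.
    """

    points: np.ndarray  # (N, 2) float, columns (x, y)
    tangent_angle: np.ndarray  # (N,) radians, unwrapped
    arc_length: np.ndarray  # (N,) pixels, arc_length[0] == 0
    extended: bool = False

    @classmethod
    def from_points(cls, points: np.ndarray, extended: bool = False) -> "SpinePath":
        points = np.asarray(points, dtype=np.float64)
        if points.ndim != 2 or points.shape[1] != 2 or len(points) < 2:
            raise ValueError("need an (N>=2, 2) point array")
        seg = np.diff(points, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        if np.any(seglen == 0):
            raise ValueError("duplicate consecutive points")
        arc = np.concatenate([[0.0], np.cumsum(seglen)])
        # central-difference tangents, one-sided at the ends
        fwd = np.vstack([seg, seg[-1]])
        bwd = np.vstack([seg[0], seg])
        mid = fwd + bwd
        angle = np.unwrap(np.arctan2(mid[:, 1], mid[:, 0]))
        return cls(points, angle, arc, extended)

    @property
    def length_px(self) -> float:
        return float(self.arc_length[-1])

    def normals(self) -> np.ndarray:
        """Unit normals (left of travel) at every point."""
        return np.column_stack(
            [-np.sin(self.tangent_angle), np.cos(self.tangent_angle)]
        )


@dataclasses.dataclass
class OutlineImage:
    """One-pixel-wide closed boundary of the worm mask."""

    pixels: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)

    def filled(self) -> np.ndarray:
        return ndi.binary_fill_holes(self.pixels)


@dataclasses.dataclass
class ProfileLine:
    """Intensity samples along a short line at unit spacing."""

    center: np.ndarray  # (2,) sub-pixel (x, y)
    angle: float  # radians
    half_length: int
    samples: np.ndarray  # (2*half_length + 1,)

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.half_length, self.half_length + 1, dtype=np.float64)

    def coords(self) -> np.ndarray:
        d = np.array([np.cos(self.angle), np.sin(self.angle)])
        return self.center[None, :] + self.offsets[:, None] * d[None, :]


def sample_profile(
    raster: np.ndarray, center: np.ndarray, angle: float, half_length: int
) -> ProfileLine:
    """Bilinear samples of ``raster`` along a line through ``center``."""
    center = np.asarray(center, dtype=np.float64)
    offsets = np.arange(-half_length, half_length + 1, dtype=np.float64)
    xs = center[0] + offsets * np.cos(angle)
    ys = center[1] + offsets * np.sin(angle)
    samples = ndi.map_coordinates(
        raster.astype(np.float32), [ys, xs], order=1, mode="constant", cval=0.0
    )
    return ProfileLine(center, angle, half_length, samples)


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    ys, xs = np.nonzero(skel)
    pix = set(zip(ys.tolist(), xs.tolist()))
    for y, x in pix:
        g.add_node((y, x))
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == 0 and dx == 0:
                    continue
                if (y + dy, x + dx) in pix:
                    g.add_edge((y, x), (y + dy, x + dx), weight=np.hypot(dy, dx))
    return g


def _longest_geodesic(g: nx.Graph) -> list:
    """Longest weighted shortest path between skeleton endpoints.

    Two Dijkstra sweeps from the farthest endpoint pair; exact on trees,
    which is what a pruned skeleton is.
    """
    ends = [n for n, d in g.degree() if d == 1]
    if len(ends) < 2:
        raise SelfOverlapError("self-overlapping worm: skeleton forms a closed loop")
    dist = nx.single_source_dijkstra_path_length(g, ends[0], weight="weight")
    a = max(ends, key=lambda n: dist.get(n, -1.0))
    dist_a, paths_a = nx.single_source_dijkstra(g, a, weight="weight")
    b = max(ends, key=lambda n: dist_a.get(n, -1.0))
    return paths_a[b]


def skeletonize(
    mask: BinaryWormMask,
    prune_len: float = DEFAULT_PRUNE_LEN_PX,
    min_spine_len: float = DEFAULT_MIN_SPINE_LEN_PX,
) -> np.ndarray:
    """Thin the mask to a one-pixel line and keep its longest branch.

    Thinning real masks sprouts short side branches; those shorter than
    ``prune_len`` are irrelevant and the longest endpoint-to-endpoint
    geodesic through the skeleton graph is returned as the spine, which
    removes them all in one step.
    """
    skel = _sk_skeletonize(mask.pixels)
    if not skel.any():
        raise DegenerateWormError("skeleton is empty")
    g = _skeleton_graph(skel)
    if g.number_of_nodes() == 1:
        raise DegenerateWormError("skeleton collapsed to a single pixel")
    path = _longest_geodesic(g)
    length = sum(
        np.hypot(a[0] - b[0], a[1] - b[1]) for a, b in zip(path, path[1:])
    )
    if length < max(min_spine_len, prune_len):
        raise DegenerateWormError(
            f"spine too short ({length:.1f} px < {min_spine_len} px)"
        )
    out = np.zeros_like(skel)
    for y, x in path:
        out[y, x] = True
    return out


def _column_hits(skel: np.ndarray, col: int) -> np.ndarray:
    return np.nonzero(skel[:, col])[0]


def find_start(skel: np.ndarray) -> tuple[np.ndarray, float]:
    """Seed point and slope from two vertical profile lines.

    A vertical line through the image's horizontal centre is sampled and
    the first (topmost) skeleton crossing is taken; a second line a few
    pixels to the right gives a paired crossing from which the local
    slope follows. If the centre column misses the skeleton, adjacent
    columns are scanned outward.
    """
    h, w = skel.shape
    cx = w // 2
    col1 = None
    for off in range(w // 2 + 1):
        for c in ({cx + off, cx - off}):
            if 0 <= c < w and _column_hits(skel, c).size:
                col1 = c
                break
        if col1 is not None:
            break
    if col1 is None:
        raise DegenerateWormError("no skeleton pixel in any column")
    row1 = int(_column_hits(skel, col1)[0])  # first = topmost crossing
    for off in (5, 4, 6, 3, 7, 2, 8, -5, -4, -6, -3, -7, -2, -8, 1, -1):
        col2 = col1 + off
        if not (0 <= col2 < w):
            continue
        hits = _column_hits(skel, col2)
        if hits.size:
            row2 = int(hits[np.argmin(np.abs(hits - row1))])
            slope = (row2 - row1) / (col2 - col1)
            return np.array([col1, row1], dtype=np.float64), float(slope)
    raise DegenerateWormError("could not find a second spine point near the start")


def _profile_clusters(
    profile: ProfileLine, rel_threshold: float = 0.5, gap: int = 2
) -> list[np.ndarray]:
    """Indices of above-half-max runs, split at gaps > ``gap`` samples."""
    m = float(profile.samples.max())
    if m < 0.2:
        return []
    idx = np.nonzero(profile.samples >= rel_threshold * m)[0]
    clusters: list[list[int]] = [[int(idx[0])]]
    for i in idx[1:]:
        if i - clusters[-1][-1] <= gap:
            clusters[-1].append(int(i))
        else:
            clusters.append([int(i)])
    return [np.array(c) for c in clusters]


def _recenter(
    skel_f: np.ndarray,
    cand: np.ndarray,
    perp_angle: float,
    half: int,
    proximity_tol: float,
) -> np.ndarray | None:
    """Re-centre ``cand`` on the skeleton along the perpendicular.

    Returns ``None`` when the profile no longer touches the skeleton
    (the end was passed). A second skeleton cluster on the profile means
    another part of the spine is within the profile's reach.
    """
    profile = sample_profile(skel_f, cand, perp_angle, half)
    clusters = _profile_clusters(profile)
    if not clusters:
        return None
    offsets = profile.offsets
    centroids = []
    for c in clusters:
        w = profile.samples[c]
        centroids.append(float(np.sum(offsets[c] * w) / np.sum(w)))
    order = np.argsort(np.abs(centroids))
    main = int(order[0])
    for other in order[1:]:
        if abs(centroids[int(other)] - centroids[main]) > proximity_tol:
            raise SelfProximityError(
                "spine self-proximity: perpendicular profile crossed the "
                "spine line in two places "
                f"({abs(centroids[int(other)] - centroids[main]):.1f} px apart)"
            )
    d = np.array([np.cos(perp_angle), np.sin(perp_angle)])
    return cand + centroids[main] * d


def trace_from(
    skel: np.ndarray,
    seed: np.ndarray,
    seed_slope: float,
    direction: int,
    step: float = DEFAULT_STEP_PX,
    profile_half: float = DEFAULT_PROFILE_HALF_PX,
    proximity_tol: float = PROXIMITY_TOL_PX,
) -> np.ndarray:
    """March along the skeleton from ``seed`` in one direction.

    Each iteration advances ``step`` pixels along the current tangent,
    re-centres on the skeleton via a perpendicular profile line, and
    updates the tangent from the last two centres. Stops when the
    profile finds no skeleton pixel.
    """
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    skel_f = skel.astype(np.float32)
    h, w = skel.shape
    half = int(round(profile_half))
    theta = np.arctan(seed_slope)
    if direction < 0:
        theta += np.pi
    cur = np.asarray(seed, dtype=np.float64).copy()
    points = [cur.copy()]
    max_iter = int(4 * (h + w) / step) + 10
    for _ in range(max_iter):
        cand = cur + step * np.array([np.cos(theta), np.sin(theta)])
        if not (0 <= cand[0] < w and 0 <= cand[1] < h):
            break
        new = _recenter(skel_f, cand, theta + np.pi / 2, half, proximity_tol)
        if new is None:
            break
        delta = new - cur
        norm = np.hypot(*delta)
        if norm < 0.25 * step:  # stalled at the skeleton's end
            break
        new_theta = np.arctan2(delta[1], delta[0])
        turn = (new_theta - theta + np.pi) % (2 * np.pi) - np.pi
        if abs(turn) > np.pi / 2:  # profile snapped backwards: end reached
            break
        points.append(new)
        cur = new
        theta = new_theta
    return np.array(points)


def trace_full(
    skel: np.ndarray,
    step: float = DEFAULT_STEP_PX,
    profile_half: float = DEFAULT_PROFILE_HALF_PX,
    proximity_tol: float = PROXIMITY_TOL_PX,
) -> SpinePath:
    """Trace the whole spine: both directions from the seed, concatenated."""
    seed, slope = find_start(skel)
    fwd = trace_from(skel, seed, slope, +1, step, profile_half, proximity_tol)
    bwd = trace_from(skel, seed, slope, -1, step, profile_half, proximity_tol)
    pts = np.vstack([bwd[::-1][:-1], fwd]) if len(bwd) > 1 else fwd
    if len(pts) < 2:
        raise DegenerateWormError("trace produced fewer than 2 points")
    return SpinePath.from_points(pts)


def outline(mask: BinaryWormMask) -> OutlineImage:
    """One-pixel boundary: foreground pixels with a background 4-neighbour."""
    fg = mask.pixels
    inner = ndi.binary_erosion(fg, structure=STRUCT4, border_value=0)
    return OutlineImage(fg & ~inner, mask.scale)


def _end_direction(points: np.ndarray) -> np.ndarray:
    """Unit outward direction of a path end from its last few points."""
    k = min(END_SLOPE_POINTS, len(points))
    tail = points[-k:]
    centered = tail - tail.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt[0]
    if np.dot(v, tail[-1] - tail[0]) < 0:
        v = -v
    return v / np.hypot(*v)


def _first_outside_crossing(
    filled_f: np.ndarray,
    start: np.ndarray,
    direction: np.ndarray,
    max_reach: float,
    dt: float = 0.25,
) -> np.ndarray | None:
    """Sub-pixel point where a ray first leaves the filled worm."""
    h, w = filled_f.shape
    ts = np.arange(0.0, max_reach + dt, dt)
    xs = start[0] + ts * direction[0]
    ys = start[1] + ts * direction[1]
    inside = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
    vals = np.full(len(ts), 0.0, dtype=np.float64)
    vals[inside] = ndi.map_coordinates(
        filled_f, [ys[inside], xs[inside]], order=1, mode="constant", cval=0.0
    )
    if vals[0] < 0.5:
        return start.copy()  # already on/outside the boundary
    below = np.nonzero(vals < 0.5)[0]
    if below.size == 0:
        return None
    j = int(below[0])
    v0, v1 = vals[j - 1], vals[j]
    frac = (v0 - 0.5) / (v0 - v1) if v1 != v0 else 0.5
    t_star = ts[j - 1] + frac * dt
    return start + t_star * direction


def extend_ends(
    path: SpinePath, edge: OutlineImage, max_reach: float = 60.0
) -> SpinePath:
    """Extend the traced spine to the worm's true tips.

    Thinning stops short of the ends, so at each end a ray at the
    terminal slope (least-squares over the last few points) is cast
    outward until it crosses the outline; the sub-pixel crossing is
    appended and arc length recomputed.
    """
    if path.extended:
        raise ValueError("path is already extended")
    filled_f = edge.filled().astype(np.float32)
    pts = path.points
    parts: list[np.ndarray] = [pts]
    for endside in ("last", "first"):
        p = pts if endside == "last" else pts[::-1]
        direction = _end_direction(p)
        hit = _first_outside_crossing(filled_f, p[-1], direction, max_reach)
        if hit is None:
            raise EndExtensionError(
                f"end extension failed: ray from the {endside} end never "
                "crossed the outline"
            )
        if np.hypot(*(hit - p[-1])) > 1e-3:
            if endside == "last":
                parts.append(hit[None, :])
            else:
                parts.insert(0, hit[None, :])
    stacked = np.vstack(parts)
    return SpinePath.from_points(stacked, extended=True)
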