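"""Parametric worm phantoms with analytic ground truth.

A worm is a tube swept along a parametric centerline (straight,
circular-arc, sine or hairpin) with a radius profile given as a function
of normalized arc position. Because centerline and radius profile are
known in closed form, length, volume (solid of revolution along arc
length), lateral surface area and curvature are computed by
high-resolution quadrature at construction time — these serve as the
oracle for every measuring module.

Default proportions follow an adult C. elegans: length-to-diameter
around 20:1.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .errors import WormetricsError
from .preprocess import BinaryWormMask, write_mask

#: ground-truth quadrature density, samples per pixel of arc length
GT_SAMPLES_PER_PX = 20
#: polygon vertex density for rasterization, samples per pixel
RENDER_SAMPLES_PER_PX = 2
DEFAULT_TAPER_FRACTION = 0.05


class SpecSelfIntersectsError(WormetricsError):
    """Centerline limbs come closer than the tube diameter allows."""


@dataclasses.dataclass
class WormSpec:
    """Parameters of one synthetic worm.

    ``length_px`` is the centerline arc length for the straight and arc
    families, the x-extent for the sine family, and the limb length for
    the hairpin; the realized arc length is always reported exactly in
    the ground truth.
    """

    kind: str = "sine"  # straight | arc | sine | hairpin
    length_px: float = 1000.0
    radius_px: float = 25.0
    radius_profile: str = "constant"  # constant | linear
    radius_end_px: float | None = None  # far-end radius for "linear"
    taper_frac: float = DEFAULT_TAPER_FRACTION
    arc_radius_px: float = 400.0
    sine_amplitude_px: float = 80.0
    sine_wavelength_px: float = 700.0
    hairpin_gap_px: float = 60.0
    rotation_deg: float = 0.0
    noise_px: float = 0.0
    seed: int = 0
    pad_px: int = 60
    allow_self_proximity: bool = False

    def radius_at(self, t: np.ndarray) -> np.ndarray:
        """Radius at normalized arc position t in [0, 1], tips tapered to 0."""
        t = np.asarray(t, dtype=np.float64)
        if self.radius_profile == "constant":
            base = np.full_like(t, self.radius_px)
        elif self.radius_profile == "linear":
            r_end = self.radius_end_px if self.radius_end_px is not None else self.radius_px
            base = self.radius_px + (r_end - self.radius_px) * t
        else:
            raise ValueError(f"unknown radius_profile {self.radius_profile!r}")
        f = self.taper_frac
        m = np.ones_like(t)
        lo = t < f
        hi = t > 1 - f
        # quadratic taper: radius hits 0 exactly at the tips
        m[lo] = 1.0 - ((f - t[lo]) / f) ** 2
        m[hi] = 1.0 - ((t[hi] - (1 - f)) / f) ** 2
        return base * m


@dataclasses.dataclass
class GroundTruth:
    """Exact geometry of a rendered worm, all in pixel units."""

    length_px: float
    volume_px3: float
    area_px2: float
    s_px: np.ndarray  # dense arc-length grid
    kappa_px: np.ndarray  # curvature on that grid, 1/px
    tip_a: np.ndarray  # (x, y) of the first tip in the rendered raster
    tip_b: np.ndarray
    max_radius_px: float

    def to_jsonable(self) -> dict:
        return {
            "length_px": self.length_px,
            "volume_px3": self.volume_px3,
            "area_px2": self.area_px2,
            "max_radius_px": self.max_radius_px,
            "tip_a": self.tip_a.tolist(),
            "tip_b": self.tip_b.tolist(),
        }


def _centerline(spec: WormSpec, n: int) -> np.ndarray:
    """(n, 2) points (x, y) of the raw (unrotated) centerline."""
    u = np.linspace(0.0, 1.0, n)
    if spec.kind == "straight":
        return np.column_stack([u * spec.length_px, np.zeros(n)])
    if spec.kind == "arc":
        alpha = spec.length_px / spec.arc_radius_px
        phi = (u - 0.5) * alpha
        return spec.arc_radius_px * np.column_stack([np.sin(phi), 1.0 - np.cos(phi)])
    if spec.kind == "sine":
        x = u * spec.length_px
        y = spec.sine_amplitude_px * np.sin(2 * np.pi * x / spec.sine_wavelength_px)
        return np.column_stack([x, y])
    if spec.kind == "hairpin":
        turn_r = spec.hairpin_gap_px / 2.0
        limb = spec.length_px
        turn_len = np.pi * turn_r
        total = 2 * limb + turn_len
        s = u * total
        pts = np.empty((n, 2))
        lower = s <= limb
        pts[lower] = np.column_stack([s[lower], np.zeros(lower.sum())])
        in_turn = (s > limb) & (s <= limb + turn_len)
        ang = (s[in_turn] - limb) / turn_r  # 0..pi around the bend
        pts[in_turn] = np.column_stack(
            [limb + turn_r * np.sin(ang), turn_r * (1 - np.cos(ang))]
        )
        upper = s > limb + turn_len
        back = s[upper] - limb - turn_len
        pts[upper] = np.column_stack([limb - back, np.full(upper.sum(), 2 * turn_r)])
        return pts
    raise ValueError(f"unknown centerline kind {spec.kind!r}")


def _arc_length(pts: np.ndarray) -> np.ndarray:
    seg = np.diff(pts, axis=0)
    return np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])


def _unit_normals(pts: np.ndarray) -> np.ndarray:
    grad = np.gradient(pts, axis=0)
    norm = np.hypot(grad[:, 0], grad[:, 1])
    tang = grad / norm[:, None]
    return np.column_stack([-tang[:, 1], tang[:, 0]])


def _check_clearance(spec: WormSpec, pts: np.ndarray, s: np.ndarray) -> None:
    """Refuse tubes whose limbs would merge when rasterized."""
    if spec.allow_self_proximity:
        return
    keep = np.linspace(0, len(pts) - 1, min(len(pts), 256)).astype(int)
    p = pts[keep]
    ss = s[keep]
    d = np.hypot(*(p[:, None, :] - p[None, :, :]).transpose(2, 0, 1))
    ds = np.abs(ss[:, None] - ss[None, :])
    far = ds > 4 * spec.radius_px
    if far.any() and d[far].min() < 2 * spec.radius_px + 2:
        raise SpecSelfIntersectsError(
            "spec self-intersects: limb clearance "
            f"{d[far].min():.1f} px < tube diameter; pass "
            "allow_self_proximity=True to build a failure fixture"
        )


def _fill_polygon(poly: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd scanline fill: pixels whose centre lies inside ``poly``.

    Equivalent to point-in-polygon over the whole canvas but runs in
    O(perimeter + filled area), which matters for the thousands of
    vertices a jittered tube outline has.
    """
    h, w = shape
    x0, y0 = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    out = np.zeros(shape, dtype=bool)
    rows_all: list[np.ndarray] = []
    xs_all: list[np.ndarray] = []
    for xa, ya, xb, yb in zip(x0, y0, x1, y1):
        if ya == yb:
            continue
        lo, hi = (ya, yb) if ya < yb else (yb, ya)
        # half-open [lo, hi) so shared vertices are counted once
        rows = np.arange(max(0, int(np.ceil(lo))), min(h - 1, int(np.ceil(hi)) - 1) + 1)
        if rows.size == 0:
            continue
        rows_all.append(rows)
        xs_all.append(xa + (rows - ya) * (xb - xa) / (yb - ya))
    if not rows_all:
        return out
    rows = np.concatenate(rows_all)
    xs = np.concatenate(xs_all)
    order = np.lexsort((xs, rows))
    rows, xs = rows[order], xs[order]
    starts = np.searchsorted(rows, np.arange(h), side="left")
    ends = np.searchsorted(rows, np.arange(h), side="right")
    for y in range(h):
        cross = xs[starts[y] : ends[y]]
        for i in range(0, len(cross) - 1, 2):
            a = max(0, int(np.ceil(cross[i])))
            b = min(w - 1, int(np.floor(cross[i + 1])))
            if cross[i + 1] == np.floor(cross[i + 1]):
                b -= 1  # right edge is exclusive, matching the left ceil
            if b >= a:
                out[y, a : b + 1] = True
    return out


def ground_truth_geometry(spec: WormSpec) -> tuple[float, float, float, np.ndarray, np.ndarray]:
    """(length, volume, area, s, kappa) by dense quadrature, pixel units."""
    n = max(2049, int(GT_SAMPLES_PER_PX * spec.length_px) | 1)
    pts = _centerline(spec, n)
    s = _arc_length(pts)
    length = float(s[-1])
    r = spec.radius_at(s / length)
    volume = float(np.pi * np.trapezoid(r**2, s))
    drds = np.gradient(r, s)
    area = float(2 * np.pi * np.trapezoid(r * np.sqrt(1 + drds**2), s))
    grad = np.gradient(pts, axis=0)
    phi = np.unwrap(np.arctan2(grad[:, 1], grad[:, 0]))
    kappa = np.gradient(phi, s)
    return length, volume, area, s, kappa


def render(spec: WormSpec) -> tuple[BinaryWormMask, GroundTruth]:
    """Rasterize the tube as a filled polygon; return mask + ground truth.

    The tube outline {p(s) +/- n(s) r(s)} is sampled densely, optionally
    jittered along the normals (seeded Gaussian, emulating focus and
    threshold variability), rotated about its centroid and drawn on a
    padded canvas. Determinism: identical (spec, seed) gives an
    identical mask.
    """
    length, volume, area, s_dense, kappa = ground_truth_geometry(spec)
    n = max(257, int(RENDER_SAMPLES_PER_PX * length))
    pts = _centerline(spec, n)
    s = _arc_length(pts)
    _check_clearance(spec, pts, s)
    r = spec.radius_at(s / s[-1])
    normals = _unit_normals(pts)
    left = pts + r[:, None] * normals
    right = pts - r[:, None] * normals
    if spec.noise_px > 0:
        rng = np.random.default_rng(spec.seed)
        left += normals * rng.normal(0.0, spec.noise_px, n)[:, None]
        right -= normals * rng.normal(0.0, spec.noise_px, n)[:, None]
    poly = np.vstack([left, right[::-1]])

    theta = np.radians(spec.rotation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    centroid = poly.mean(axis=0)
    poly = (poly - centroid) @ rot.T
    tips = (np.vstack([pts[0], pts[-1]]) - centroid) @ rot.T

    shift = spec.pad_px - poly.min(axis=0)
    poly += shift
    tips += shift
    w = int(np.ceil(poly[:, 0].max())) + spec.pad_px + 1
    h = int(np.ceil(poly[:, 1].max())) + spec.pad_px + 1
    canvas = _fill_polygon(poly, (h, w))

    gt = GroundTruth(
        length_px=length,
        volume_px3=volume,
        area_px2=area,
        s_px=s_dense,
        kappa_px=kappa,
        tip_a=tips[0],
        tip_b=tips[1],
        max_radius_px=float(r.max()),
    )
    mask = BinaryWormMask(canvas, 1.0, [f"synthetic[{spec.kind},seed={spec.seed}]"])
    return mask, gt


def replicate_experiment(
    spec: WormSpec, n: int, seed: int
) -> list[tuple[BinaryWormMask, GroundTruth]]:
    """n renders of one worm under independent rotations and jitter.

    Re-creates, synthetically, the repeated-photograph experiment: the
    underlying worm (and so its true length/volume/area) is identical
    across renders; only orientation and boundary noise vary.
    Deterministic given (spec, n, seed).
    """
    if n < 2:
        raise ValueError("need n >= 2 replicates")
    rng = np.random.default_rng(seed)
    rotations = rng.uniform(0.0, 360.0, n)
    child_seeds = rng.integers(0, 2**31 - 1, n)
    out = []
    for rot, child in zip(rotations, child_seeds):
        rep = dataclasses.replace(spec, rotation_deg=float(rot), seed=int(child))
        out.append(render(rep))
    return out


def write_fixture_folder(
    root: str | Path, specs: list[WormSpec], names: list[str] | None = None
) -> Path:
    """Write masks to a ``photos/``-style folder plus a ground-truth sidecar."""
    root = Path(root)
    photos = root / "photos"
    photos.mkdir(parents=True, exist_ok=True)
    names = names or [f"{i + 1}.png" for i in range(len(specs))]
    truth = {}
    for name, spec in zip(names, specs):
        mask, gt = render(spec)
        write_mask(photos / name, mask)
        truth[name] = gt.to_jsonable()
    (root / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return photos


def preset(name: str, **overrides) -> WormSpec:
    """Named worm specs at realistic proportions (~20:1 length/diameter)."""
    presets = {
        "straight": WormSpec(kind="straight", length_px=1000, radius_px=25),
        "arc": WormSpec(kind="arc", length_px=1000, radius_px=25, arc_radius_px=400),
        "sine": WormSpec(
            kind="sine",
            length_px=1000,
            radius_px=25,
            sine_amplitude_px=80,
            sine_wavelength_px=700,
        ),
        # limbs 16 px apart: masks stay separate (diameter 12) but the
        # midlines are inside the 20 px profile reach -> tracing must fail
        "hairpin": WormSpec(
            kind="hairpin",
            length_px=400,
            radius_px=6,
            hairpin_gap_px=16,
            allow_self_proximity=True,
        ),
    }
    try:
        spec = presets[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}") from None
    return dataclasses.replace(spec, **overrides)
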