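"""Raw micrograph -> clean, horizontal binary worm mask.

The chain mirrors the classic interactive recipe for single-worm images:
pick the highest-contrast colour channel, stretch contrast, threshold,
fill holes, smooth / de-speckle with binary morphology, then expand the
canvas and rotate the worm so its longest dimension is horizontal.

Internally the worm is ``True`` (foreground) regardless of the display
convention; mask writers re-encode black-on-white.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_isodata, threshold_otsu

from .errors import (
    NoContrastError,
    NoObjectError,
    ObjectEliminatedError,
    UnsupportedChannelsError,
)

# 8-connected structuring element used by all binary morphology here.
STRUCT8 = np.ones((3, 3), dtype=bool)

#: fraction of pixels saturated per tail by the contrast stretch
STRETCH_CLIP_FRACTION = 0.0035

DEFAULT_MIN_AREA_PX = 200
DEFAULT_PAD_PX = 60

_THRESHOLDERS = {"otsu": threshold_otsu, "isodata": threshold_isodata}


@dataclasses.dataclass
class CalibratedImage:
    """A raster plus its spatial calibration.

    Parameters
    ----------
    pixels:
        ``(H, W)`` greyscale or ``(H, W, 3)`` colour array.
    scale:
        Physical length per pixel (e.g. mm/px). Must be positive.
    """

    pixels: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if self.pixels.ndim not in (2, 3):
            raise UnsupportedChannelsError(self.pixels.ndim)
        h, w = self.pixels.shape[:2]
        if h < 8 or w < 8:
            raise ValueError(f"image too small: {w}x{h} (minimum 8x8)")

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]


@dataclasses.dataclass
class BinaryWormMask:
    """Boolean raster with worm = ``True`` plus calibration and provenance."""

    pixels: np.ndarray
    scale: float
    provenance: list = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    def with_pixels(self, pixels: np.ndarray, step: str) -> "BinaryWormMask":
        return BinaryWormMask(pixels, self.scale, self.provenance + [step])

    def n_components(self) -> int:
        _, n = ndi.label(self.pixels, structure=STRUCT8)
        return n

    def touches_border(self) -> bool:
        p = self.pixels
        return bool(p[0].any() or p[-1].any() or p[:, 0].any() or p[:, -1].any())


def select_channel(img: CalibratedImage) -> CalibratedImage:
    """Return the single channel with the greatest contrast.

    Contrast is measured as the standard deviation of intensities.
    Greyscale input is returned unchanged.
    """
    if img.n_channels == 1:
        return img
    if img.n_channels != 3:
        raise UnsupportedChannelsError(img.n_channels)
    stds = img.pixels.reshape(-1, 3).astype(np.float64).std(axis=0)
    if np.max(stds) == 0:
        raise NoContrastError("no contrast: all channels are constant")
    best = int(np.argmax(stds))
    return CalibratedImage(img.pixels[:, :, best], img.scale)


def _stretch_contrast(pixels: np.ndarray) -> np.ndarray:
    lo, hi = np.percentile(
        pixels, [100 * STRETCH_CLIP_FRACTION, 100 * (1 - STRETCH_CLIP_FRACTION)]
    )
    if hi <= lo:
        lo, hi = pixels.min(), pixels.max()
    out = np.clip((pixels.astype(np.float64) - lo) / (hi - lo), 0.0, 1.0)
    return out


def binarize(img: CalibratedImage, method: str = "otsu") -> BinaryWormMask:
    """Contrast-stretch and threshold a single-channel image.

    Polarity is resolved by the minority-area rule: whichever side of the
    threshold covers less area is taken to be the worm, so dark-on-bright
    and bright-on-dark images give the same mask.
    """
    if img.n_channels != 1:
        raise UnsupportedChannelsError(img.n_channels)
    pixels = img.pixels
    if pixels.max() == pixels.min():
        raise NoContrastError("no contrast: image is constant")
    try:
        thresholder = _THRESHOLDERS[method]
    except KeyError:
        raise ValueError(
            f"unknown threshold method {method!r}; choose from {sorted(_THRESHOLDERS)}"
        ) from None
    stretched = _stretch_contrast(pixels)
    t = thresholder(stretched)
    above = stretched > t
    fg = above if above.mean() <= 0.5 else ~above
    if not fg.any():
        raise NoObjectError("no object found after thresholding")
    return BinaryWormMask(fg, img.scale, [f"binarize[{method}]"])


def fill_holes(mask: BinaryWormMask) -> BinaryWormMask:
    """Fill every background region not connected to the image border."""
    return mask.with_pixels(ndi.binary_fill_holes(mask.pixels), "fill_holes")


def _largest_component(pixels: np.ndarray) -> np.ndarray:
    """Keep the largest 8-connected component.

    Ties are broken deterministically by topmost, then leftmost centroid.
    """
    labels, n = ndi.label(pixels, structure=STRUCT8)
    if n == 0:
        raise ObjectEliminatedError("object eliminated by cleanup")
    if n == 1:
        return pixels
    areas = ndi.sum_labels(pixels, labels, index=range(1, n + 1))
    centroids = ndi.center_of_mass(pixels, labels, index=range(1, n + 1))
    order = sorted(
        range(n), key=lambda i: (-areas[i], centroids[i][0], centroids[i][1])
    )
    return labels == order[0] + 1


def morphological_cleanup(
    mask: BinaryWormMask, close_iters: int = 0, open_iters: int = 0
) -> BinaryWormMask:
    """Closing to smooth ragged edges, opening to drop small artefacts.

    Afterwards only the largest connected component is kept so the
    one-worm invariant holds even if opening leaves debris.
    """
    if close_iters < 0 or open_iters < 0:
        raise ValueError("iteration counts must be >= 0")
    pixels = mask.pixels
    if close_iters:
        pixels = ndi.binary_closing(pixels, structure=STRUCT8, iterations=close_iters)
    if open_iters:
        pixels = ndi.binary_opening(pixels, structure=STRUCT8, iterations=open_iters)
    if not pixels.any():
        raise ObjectEliminatedError("object eliminated by cleanup")
    pixels = _largest_component(pixels)
    return mask.with_pixels(
        pixels, f"cleanup[close={close_iters},open={open_iters}]"
    )


def _principal_axis_angle(pixels: np.ndarray) -> float:
    """Angle (radians) of the foreground's principal axis w.r.t. the x axis."""
    ys, xs = np.nonzero(pixels)
    x = xs - xs.mean()
    y = ys - ys.mean()
    mxx = np.mean(x * x)
    myy = np.mean(y * y)
    mxy = np.mean(x * y)
    return 0.5 * np.arctan2(2 * mxy, mxx - myy)


def _crop_and_pad(pixels: np.ndarray, pad: int) -> np.ndarray:
    ys, xs = np.nonzero(pixels)
    cropped = pixels[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]
    return np.pad(cropped, pad)


def orient_horizontal(mask: BinaryWormMask, pad: int = DEFAULT_PAD_PX) -> BinaryWormMask:
    """Rotate the worm so its longest dimension is horizontal.

    The rotation angle is the orientation of the principal axis of the
    foreground's second central moments. The rotated raster is
    re-thresholded at 0.5 to stay binary; the result is cropped to the
    foreground bounding box and padded by ``pad`` pixels on every side so
    later profile lines cannot leave the image.
    """
    if not mask.pixels.any():
        raise NoObjectError("empty mask")
    angle = _principal_axis_angle(mask.pixels)
    # ndi.rotate with a positive angle rotates rows toward columns in
    # array space; rotating by +angle (degrees) maps the principal axis
    # onto the horizontal.
    rotated = (
        ndi.rotate(
            mask.pixels.astype(np.float32),
            np.degrees(angle),
            reshape=True,
            order=1,
            mode="constant",
            cval=0.0,
        )
        > 0.5
    )
    if not rotated.any():
        raise ObjectEliminatedError("rotation eliminated foreground")
    rotated = _largest_component(rotated)
    ys, xs = np.nonzero(rotated)
    if (ys.max() - ys.min()) > (xs.max() - xs.min()):
        rotated = rotated.T[:, ::-1]  # extra 90 degree turn
    out = _crop_and_pad(rotated, pad)
    return mask.with_pixels(out, f"orient_horizontal[pad={pad}]")


def preprocess_image(
    img: CalibratedImage,
    threshold_method: str = "otsu",
    close_iters: int = 1,
    open_iters: int = 0,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    pad_px: int = DEFAULT_PAD_PX,
) -> BinaryWormMask:
    """Full chain: channel -> threshold -> fill holes -> cleanup -> orient."""
    mask = binarize(select_channel(img), threshold_method)
    mask = fill_holes(mask)
    mask = morphological_cleanup(mask, close_iters, open_iters)
    mask = orient_horizontal(mask, pad_px)
    if mask.area_px < min_area_px:
        raise NoObjectError(
            f"object too small: {mask.area_px} px < minimum {min_area_px} px"
        )
    return mask


def read_image(path: str | Path, scale: float) -> CalibratedImage:
    """Read a TIFF/PNG/JPEG raster and attach the calibration scale."""
    pixels = np.asarray(iio.imread(path))
    if pixels.ndim == 3 and pixels.shape[2] == 4:  # drop alpha
        pixels = pixels[:, :, :3]
    return CalibratedImage(pixels, scale)


def read_mask(path: str | Path, scale: float) -> BinaryWormMask:
    """Read a binary mask image; the minority-area side is the worm."""
    pixels = np.asarray(iio.imread(path))
    if pixels.ndim == 3:
        pixels = pixels[..., :3].mean(axis=2)
    mid = (pixels.max() + pixels.min()) / 2
    above = pixels > mid
    fg = above if above.mean() <= 0.5 else ~above
    if not fg.any():
        raise NoObjectError(f"no object found in {path}")
    return BinaryWormMask(fg, scale, [f"read_mask[{Path(path).name}]"])


def write_mask(path: str | Path, mask: BinaryWormMask) -> None:
    """Write the mask with the worm black (0) on a white (255) background."""
    out = np.where(mask.pixels, 0, 255).astype(np.uint8)
    iio.imwrite(path, out)
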