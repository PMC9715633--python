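"""Canopy greenness and the mini-rhizotron scan-processing chain.

The rhizotron chain mirrors scanner practice: remove vertical stripe
artifacts, normalize brightness/contrast, align repeat scans of the same
tube by phase correlation, split into tiles, segment roots and convert
masks to areas and diameters.  Segmentation is a deterministic classical
operator (multi-scale ridge filter + hysteresis) behind a small parameter
object, so a learned segmenter can be substituted without touching the
rest of the chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import apply_hysteresis_threshold, sato
from skimage.morphology import medial_axis, remove_small_objects

from .errors import DegenerateSeriesError, InvalidInputError, UndefinedIndexError

__all__ = [
    "RGBImage",
    "RhizotronStack",
    "SegmenterParams",
    "DiameterSummary",
    "canopy_greenness",
    "destripe",
    "normalize",
    "phase_correlation",
    "translate",
    "align_stack",
    "tile",
    "segment_roots",
    "root_area",
    "root_diameters",
]

MM_PER_INCH = 25.4


@dataclass
class RGBImage:
    """An RGB raster with optional resolution and region-of-interest mask."""

    pixels: np.ndarray  # H x W x 3
    dpi: float | None = None
    roi_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InvalidInputError("pixels must be H x W x 3")
        if self.roi_mask is not None:
            self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
            if self.roi_mask.shape != self.pixels.shape[:2]:
                raise InvalidInputError("roi_mask must match image H x W")


@dataclass
class RhizotronStack:
    """Time-ordered greyscale scans of one tube, plus derived products."""

    images: list[np.ndarray]
    doys: list[float]
    dpi: float = 1200.0
    shifts: list[tuple[int, int]] | None = None  # (dx, dy) vs first image
    masks: list[np.ndarray] | None = None
    root_area: list[float] | None = None  # mm^2 cm^-2 per image

    def __post_init__(self) -> None:
        shapes = {im.shape for im in self.images}
        if len(shapes) > 1:
            raise InvalidInputError("all stack images must share dimensions")
        if len(self.images) != len(self.doys):
            raise InvalidInputError("one acquisition doy per image required")


@dataclass
class SegmenterParams:
    """Settings for the classical root segmenter."""

    ridge_scales: tuple[float, ...] = (2.0, 4.0, 6.0)
    threshold_low: float = 5.5  # robust-z units of the ridge response
    threshold_high: float = 11.0
    min_object_px: int = 64

    def __post_init__(self) -> None:
        if not self.threshold_low < self.threshold_high:
            raise InvalidInputError("threshold_low must be < threshold_high")
        if self.min_object_px < 1:
            raise InvalidInputError("min_object_px must be >= 1")


@dataclass
class DiameterSummary:
    mean_mm: float
    max_mm: float
    values_mm: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))

    @property
    def empty(self) -> bool:
        return self.values_mm.size == 0


def canopy_greenness(img: RGBImage, per_pixel: bool = False) -> float:
    """Green chromatic coordinate G/(R+G+B) over the region of interest.

    Default convention is the ratio of ROI channel means (robust to
    exposure noise); ``per_pixel=True`` averages the per-pixel ratio
    instead.
    """
    px = img.pixels.astype(float)
    if img.roi_mask is not None:
        px = px[img.roi_mask]
    else:
        px = px.reshape(-1, 3)
    if px.shape[0] == 0:
        raise UndefinedIndexError("empty region of interest")
    if per_pixel:
        sums = px.sum(axis=1)
        valid = sums > 0
        if not valid.any():
            raise UndefinedIndexError("greenness undefined: all ROI pixels are black")
        return float(np.mean(px[valid, 1] / sums[valid]))
    means = px.mean(axis=0)
    total = means.sum()
    if total <= 0:
        raise UndefinedIndexError("greenness undefined: all ROI pixels are black")
    return float(means[1] / total)


def destripe(img: np.ndarray, strength: float = 0.5) -> np.ndarray:
    """Attenuate strictly vertical (column-constant) stripe artifacts.

    Fourier notch: coefficients near the horizontal-frequency axis
    (vertical frequency ~ 0) are damped by ``1 - exp(-ky^2 / (2*strength^2))``
    for all non-zero horizontal frequencies; the DC/row-mean column is left
    untouched.  Output is float64 of the same shape.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape[1] < 16:
        raise InvalidInputError("destripe expects a 2-D image at least 16 px wide")
    H, W = img.shape
    F = np.fft.fft2(img)
    ky = np.fft.fftfreq(H) * H
    damp = 1.0 - np.exp(-(ky**2) / (2.0 * strength**2))
    gain = np.ones((H, W))
    gain[:, 1:] = damp[:, None]  # keep kx = 0 column (row means, DC)
    out = np.fft.ifft2(F * gain).real
    return out


def normalize(
    img: np.ndarray,
    target_mean: float = 0.5,
    target_sd: float = 0.15,
    clip_percentiles: tuple[float, float] = (0.5, 99.5),
) -> np.ndarray:
    """Percentile-clipped linear rescale to a fixed mean and SD.

    Monotone (non-strict, because of the clip) and invariant to affine
    intensity changes of the input.  Raises on constant images.
    """
    img = np.asarray(img, dtype=float)
    # pure order statistics keep the operation exactly idempotent
    lo, hi = np.quantile(img, np.asarray(clip_percentiles) / 100.0, method="inverted_cdf")
    if hi <= lo:
        lo, hi = img.min(), img.max()
        if hi <= lo:
            raise DegenerateSeriesError("cannot normalize a constant image")
    z = np.clip((img - lo) / (hi - lo), 0.0, 1.0)
    sd = z.std()
    if sd == 0:
        raise DegenerateSeriesError("cannot normalize a constant image")
    return target_mean + target_sd * (z - z.mean()) / sd


def phase_correlation(ref: np.ndarray, mov: np.ndarray) -> tuple[tuple[int, int], float]:
    """Integer (dx, dy) displacement of ``mov`` relative to ``ref``.

    Returns the shift maximizing the normalized cross-power spectrum
    surface and the peak value (1.0 for identical images, near 0 for
    unrelated ones).
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape:
        raise InvalidInputError("images must share dimensions")
    F1 = np.fft.fft2(ref - ref.mean())
    F2 = np.fft.fft2(mov - mov.mean())
    cross = F1 * np.conj(F2)
    mag = np.abs(cross)
    cross /= np.where(mag > 1e-12, mag, 1.0)
    surface = np.fft.ifft2(cross).real
    iy, ix = np.unravel_index(np.argmax(surface), surface.shape)
    peak = float(surface[iy, ix])
    H, W = ref.shape
    dy = -(iy - H if iy > H // 2 else iy)
    dx = -(ix - W if ix > W // 2 else ix)
    return (int(dx), int(dy)), peak


def translate(img: np.ndarray, dx: int, dy: int, fill: float = 0.0) -> np.ndarray:
    """Pure integer translation by (+dx columns, +dy rows), edge-filled."""
    out = np.full_like(img, fill)
    H, W = img.shape[:2]
    ys = slice(max(dy, 0), H + min(dy, 0))
    xs = slice(max(dx, 0), W + min(dx, 0))
    ys_src = slice(max(-dy, 0), H + min(-dy, 0))
    xs_src = slice(max(-dx, 0), W + min(-dx, 0))
    out[ys, xs] = img[ys_src, xs_src]
    return out


def align_stack(stack: RhizotronStack, peak_floor: float = 0.03) -> RhizotronStack:
    """Register every scan to the first by integer phase-correlation shifts.

    Shifts below the confidence floor are zeroed with a warning.  Images
    are resampled by pure translation (no interpolation).
    """
    if len(stack.images) < 2:
        raise InvalidInputError("alignment needs at least 2 images")
    ref = stack.images[0]
    shifts: list[tuple[int, int]] = [(0, 0)]
    aligned = [ref.copy()]
    for k, img in enumerate(stack.images[1:], start=1):
        (dx, dy), peak = phase_correlation(ref, img)
        if peak < peak_floor:
            warnings.warn(
                f"image {k}: phase-correlation peak {peak:.4f} below floor "
                f"{peak_floor}; shift set to (0, 0)",
                stacklevel=2,
            )
            dx = dy = 0
        shifts.append((dx, dy))
        aligned.append(translate(img, -dx, -dy))
    return RhizotronStack(
        images=aligned,
        doys=list(stack.doys),
        dpi=stack.dpi,
        shifts=shifts,
        masks=stack.masks,
        root_area=stack.root_area,
    )


def tile(img: np.ndarray, n_cols: int, n_rows: int) -> list[np.ndarray]:
    """Split an image into a row-major grid of equal tiles.

    Dimensions must be divisible by the grid, allowing a trailing remainder
    of at most 1 px (cropped).
    """
    H, W = img.shape[:2]
    if n_rows > H or n_cols > W or n_rows < 1 or n_cols < 1:
        raise InvalidInputError("grid larger than image")
    if H % n_rows > 1 or W % n_cols > 1:
        raise InvalidInputError("dimensions not divisible by grid (remainder > 1 px)")
    th, tw = H // n_rows, W // n_cols
    return [
        img[r * th : (r + 1) * th, c * tw : (c + 1) * tw]
        for r in range(n_rows)
        for c in range(n_cols)
    ]


def common_window(shifts: list[tuple[int, int]], shape: tuple[int, int]) -> tuple[slice, slice]:
    """Slices of the region valid in every aligned image of a stack.

    After registering by pure translation, a margin of each image is
    edge-fill; cropping to the common window removes the fill seams before
    segmentation.
    """
    H, W = shape[:2]
    dxs = [dx for dx, _ in shifts]
    dys = [dy for _, dy in shifts]
    x0, x1 = max(0, *(-d for d in dxs), 0), W + min(0, *( -d for d in dxs), 0)
    y0, y1 = max(0, *(-d for d in dys), 0), H + min(0, *( -d for d in dys), 0)
    if x1 <= x0 or y1 <= y0:
        raise InvalidInputError("shifts leave no common region")
    return slice(y0, y1), slice(x0, x1)


def segment_roots(img: np.ndarray, params: SegmenterParams | None = None) -> np.ndarray:
    """Classical root segmentation: ridge enhancement + hysteresis.

    Expects a normalized greyscale image with bright roots.  The multiscale
    ridge response is standardized against the image's background (robust
    z-score via median/MAD, which the soil dominates), thresholded with
    hysteresis at ``threshold_low``/``threshold_high`` robust-z units and
    cleaned of components smaller than ``min_object_px``.  Deterministic
    and symmetric under 180-degree rotation.
    """
    params = params or SegmenterParams()
    img = np.asarray(img, dtype=float)
    response = sato(img, sigmas=params.ridge_scales, black_ridges=False)
    med = np.median(response)
    mad = np.median(np.abs(response - med))
    if mad <= 0:
        return np.zeros(img.shape, dtype=bool)
    rz = (response - med) / (1.4826 * mad)
    mask = apply_hysteresis_threshold(rz, params.threshold_low, params.threshold_high)
    # drop components strictly smaller than min_object_px
    return remove_small_objects(mask, max_size=params.min_object_px - 1)


def root_area(mask: np.ndarray, dpi: float) -> tuple[float, float]:
    """(root area per image area in mm^2 cm^-2, absolute root area in mm^2)."""
    if dpi <= 0:
        raise InvalidInputError("dpi must be positive")
    mask = np.asarray(mask, dtype=bool)
    px_mm = MM_PER_INCH / dpi
    area_mm2 = float(mask.sum()) * px_mm**2
    image_area_cm2 = mask.shape[0] * mask.shape[1] * px_mm**2 / 100.0
    return area_mm2 / image_area_cm2, area_mm2


def root_diameters(mask: np.ndarray, dpi: float) -> DiameterSummary:
    """Root diameters from the medial-axis distance transform, in mm.

    Diameter at each skeleton pixel is twice the distance-transform value
    times the pixel size.  An empty mask yields an empty summary.
    """
    if dpi <= 0:
        raise InvalidInputError("dpi must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return DiameterSummary(mean_mm=float("nan"), max_mm=float("nan"))
    skel, dist = medial_axis(mask, return_distance=True)
    diam_px = 2.0 * dist[skel]
    diam_mm = diam_px * MM_PER_INCH / dpi
    return DiameterSummary(
        mean_mm=float(diam_mm.mean()), max_mm=float(diam_mm.max()), values_mm=diam_mm
    )
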