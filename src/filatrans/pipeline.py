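"""Edge-bounded color-profile extraction from filament photographs.

The pipeline mirrors the standard quantification workflow for two-ink
filaments: convert the crop to black and white, delimit the filament with
Canny edge detection (high threshold 0.3 by default), then average the RGB
values of the pixels that lie between the detected edges, column by column,
and smooth the per-column means with a centered 20-px moving average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import canny
from skimage.filters import threshold_otsu

from .errors import FilamentTooShortError, InvalidInputError, NoFilamentError

if TYPE_CHECKING:  # pragma: no cover
    from .report import PrintCondition

__all__ = [
    "RasterImage",
    "FilamentMask",
    "ColorProfile",
    "read_image",
    "to_binary",
    "detect_edges",
    "build_mask",
    "extract_profile",
    "analyze_image",
    "moving_average",
]

#: Minimum end-to-end red difference (intensity units) to call a direction.
_DIRECTION_TOL = 0.02


@dataclass
class RasterImage:
    """An RGB image with its physical scale and capture metadata.

    ``pixels`` is an (H, W, 3) float array of intensities in [0, 1];
    ``mm_per_px`` converts axial pixel distances to millimetres;
    ``elapsed_s`` is the time from filament deposition to image capture,
    needed later for diffusion correction.
    """

    pixels: np.ndarray
    mm_per_px: float
    elapsed_s: float | None = None
    condition: Optional["PrintCondition"] = None
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InvalidInputError("pixels must be an (H, W, 3) RGB array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise InvalidInputError("image must be at least 1x1")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise InvalidInputError("intensities must lie in [0, 1]")
        if self.mm_per_px <= 0:
            raise InvalidInputError("mm_per_px must be > 0")
        if self.elapsed_s is not None and self.elapsed_s < 0:
            raise InvalidInputError("elapsed_s must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    def crop(self, x0: int, y0: int, x1: int, y1: int) -> "RasterImage":
        """Return the axial crop [x0, x1) x [y0, y1) with metadata kept."""
        return RasterImage(
            pixels=self.pixels[y0:y1, x0:x1],
            mm_per_px=self.mm_per_px,
            elapsed_s=self.elapsed_s,
            condition=self.condition,
            id=self.id,
        )


@dataclass
class FilamentMask:
    """Filament interior and the Canny edge map it was derived from.

    Per column, ``mask`` marks the rows strictly between the outermost edge
    pixels; ``columns_covered`` lists (sorted) the columns with a nonempty
    interior.
    """

    mask: np.ndarray
    edge_map: np.ndarray
    columns_covered: np.ndarray


@dataclass
class ColorProfile:
    """Along-filament mean color values, raw and smoothed.

    ``positions_px`` are 0-based column indices of the analyzed crop (unit
    spacing assumed between consecutive entries for smoothing purposes).
    ``direction`` is 'a_to_b' when the red channel falls along the scan,
    'b_to_a' when it rises, None when no clear gradient exists.
    """

    positions_px: np.ndarray
    mean_rgb: np.ndarray
    smoothed_rgb: np.ndarray
    window_px: int
    mm_per_px: float
    direction: str | None = None
    image_id: str = ""
    elapsed_s: float | None = None
    condition: Optional["PrintCondition"] = None

    def __len__(self) -> int:
        return len(self.positions_px)


def read_image(
    path: str | Path,
    mm_per_px: float,
    elapsed_s: float | None = None,
    condition: Optional["PrintCondition"] = None,
) -> RasterImage:
    """Read a PNG/TIFF/JPEG photograph into [0, 1] RGB intensities.

    8- and 16-bit integer images are rescaled by their dtype maximum; an
    alpha channel is dropped; single-channel images are replicated to RGB.
    """
    import imageio.v3 as iio

    data = np.asarray(iio.imread(Path(path)))
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    else:
        data = data.astype(float)
    if data.ndim == 2:
        data = np.stack([data] * 3, axis=-1)
    if data.shape[-1] == 4:
        data = data[..., :3]
    return RasterImage(
        pixels=np.clip(data, 0.0, 1.0),
        mm_per_px=mm_per_px,
        elapsed_s=elapsed_s,
        condition=condition,
        id=Path(path).name,
    )


def to_binary(
    image: RasterImage,
    method: str = "otsu",
    threshold: float | None = None,
) -> np.ndarray:
    """Binarize the image into filament (True) vs background (False).

    Luminance is thresholded globally (Otsu by default, or a fixed value),
    and the minority class is taken as the filament, which makes the result
    independent of whether the inks are darker or lighter than the
    background. The Otsu threshold is refined to the midpoint between the
    two class means (isodata iteration): the raw Otsu value is a histogram
    bin center and can fall on the wrong side of a luminance value that
    occupies that bin, which matters for near-noiseless images whose
    histogram is a few spikes.
    """
    lum = rgb2gray(image.pixels)
    if method == "fixed":
        if threshold is None:
            raise InvalidInputError("fixed binarization needs a threshold")
        thr = float(threshold)
    elif method == "otsu":
        if np.ptp(lum) == 0:
            raise NoFilamentError("uniform image: nothing to separate")
        thr = float(threshold_otsu(lum))
        for _ in range(100):
            low_px, high_px = lum[lum <= thr], lum[lum > thr]
            if low_px.size == 0 or high_px.size == 0:
                break
            new_thr = (low_px.mean() + high_px.mean()) / 2.0
            if new_thr == thr:
                break
            thr = new_thr
    else:
        raise InvalidInputError(f"unknown binarization method {method!r}")

    low = lum <= thr
    n_low = int(low.sum())
    if n_low == 0 or n_low == low.size:
        raise NoFilamentError("binarization produced a single class")
    binary = low if n_low <= low.size - n_low else ~low
    return binary


def detect_edges(
    binary: np.ndarray,
    threshold: float = 0.3,
    low_ratio: float = 0.4,
    sigma: float = 1.0,
) -> np.ndarray:
    """Canny edge map of the binarized (or grayscale) image.

    ``threshold`` is the high hysteresis threshold; the low threshold is
    ``low_ratio * threshold`` (the common dual-threshold convention).
    """
    arr = np.asarray(binary, dtype=float)
    edge_map = canny(
        arr,
        sigma=sigma,
        low_threshold=low_ratio * threshold,
        high_threshold=threshold,
    )
    if not edge_map.any():
        raise NoFilamentError("empty Canny edge map")
    return edge_map


def build_mask(edge_map: np.ndarray, min_columns: int = 20) -> FilamentMask:
    """Mask of pixels strictly between each column's outermost edge pixels.

    Columns with fewer than two edge pixels, or no interior row between
    them, are excluded from coverage. Fewer than ``min_columns`` covered
    columns raises :class:`FilamentTooShortError`.
    """
    edge_map = np.asarray(edge_map, dtype=bool)
    if not edge_map.any():
        raise NoFilamentError("empty edge map")
    h, w = edge_map.shape
    has_edge = edge_map.any(axis=0)
    first = np.where(has_edge, edge_map.argmax(axis=0), h)
    last = np.where(has_edge, h - 1 - edge_map[::-1, :].argmax(axis=0), -1)

    rows = np.arange(h)[:, None]
    mask = (rows > first[None, :]) & (rows < last[None, :])
    covered = np.flatnonzero(mask.any(axis=0))
    if len(covered) < min_columns:
        raise FilamentTooShortError(
            f"only {len(covered)} covered columns (minimum {min_columns})"
        )
    return FilamentMask(mask=mask, edge_map=edge_map, columns_covered=covered)


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with symmetric truncation at the ends.

    Odd windows use a plain box kernel of length ``window``. Even windows
    use the symmetric trapezoidal kernel of support ``window + 1`` with
    half-weight endpoints, which keeps the filter centered (no half-pixel
    positional bias) and mean-preserving on linear segments while its
    equivalent width remains ``window``. Near the profile ends the kernel
    is truncated symmetrically and renormalized, so the output length
    equals the input length.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if window < 1:
        raise InvalidInputError("window must be >= 1")
    if window == 1 or n == 1:
        return values.copy()

    if window % 2:
        h = window // 2
        kernel = np.full(window, 1.0 / window)
    else:
        h = window // 2
        kernel = np.full(window + 1, 1.0 / window)
        kernel[0] = kernel[-1] = 0.5 / window

    out = np.convolve(values, kernel, mode="same") if n >= len(kernel) else np.empty(n)
    # symmetric truncation where the full kernel overhangs an end
    edge = min(h, n - 1)
    for i in range(edge):
        for j in (i, n - 1 - i):
            k = min(j, n - 1 - j)
            sub = kernel[h - k : h + k + 1]
            out[j] = values[j - k : j + k + 1] @ sub / sub.sum()
    return out


def extract_profile(
    image: RasterImage, mask: FilamentMask, window_px: int = 20
) -> ColorProfile:
    """Per-column mean RGB over the filament interior, then smoothed.

    The smoothed profile is the centered ``window_px`` moving average of the
    raw per-column means; the transition direction is inferred from whether
    the red channel falls (a_to_b) or rises (b_to_a) between profile ends.
    """
    cols = mask.columns_covered
    if len(cols) < window_px:
        raise FilamentTooShortError(
            f"{len(cols)} covered columns < window of {window_px}"
        )
    m = mask.mask[:, cols]
    counts = m.sum(axis=0)
    sums = np.einsum("hc,hcd->cd", m.astype(float), image.pixels[:, cols, :])
    mean_rgb = sums / counts[:, None]

    smoothed = np.column_stack(
        [moving_average(mean_rgb[:, ch], window_px) for ch in range(3)]
    )

    red_drop = smoothed[0, 0] - smoothed[-1, 0]
    if red_drop > _DIRECTION_TOL:
        direction: str | None = "a_to_b"
    elif red_drop < -_DIRECTION_TOL:
        direction = "b_to_a"
    else:
        direction = None

    return ColorProfile(
        positions_px=cols.astype(float),
        mean_rgb=mean_rgb,
        smoothed_rgb=smoothed,
        window_px=window_px,
        mm_per_px=image.mm_per_px,
        direction=direction,
        image_id=image.id,
        elapsed_s=image.elapsed_s,
        condition=image.condition,
    )


def analyze_image(
    image: RasterImage,
    window_px: int = 20,
    canny_high: float = 0.3,
    canny_low_ratio: float = 0.4,
    min_columns: int | None = None,
    binarize: str = "otsu",
    binarize_threshold: float | None = None,
    canny_on: str = "binary",
    crop: tuple[int, int, int, int] | None = None,
    rotate_deg: float = 0.0,
) -> ColorProfile:
    """Run the full crop-to-profile pipeline on one image.

    ``canny_on='gray'`` applies Canny to the grayscale image instead of the
    binarized one (both give identical band boundaries on clean crops).
    ``rotate_deg`` pre-rotates a slightly tilted filament to horizontal.
    """
    if rotate_deg:
        from skimage.transform import rotate as _rotate

        image = RasterImage(
            pixels=np.clip(
                _rotate(image.pixels, rotate_deg, mode="edge"), 0.0, 1.0
            ),
            mm_per_px=image.mm_per_px,
            elapsed_s=image.elapsed_s,
            condition=image.condition,
            id=image.id,
        )
    if crop is not None:
        x0, y0, x1, y1 = crop
        image = image.crop(x0, y0, x1, y1)

    binary = to_binary(image, method=binarize, threshold=binarize_threshold)
    source = binary if canny_on == "binary" else rgb2gray(image.pixels)
    edges = detect_edges(source, threshold=canny_high, low_ratio=canny_low_ratio)
    mask = build_mask(edges, min_columns=window_px if min_columns is None else min_columns)
    return extract_profile(image, mask, window_px=window_px)
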