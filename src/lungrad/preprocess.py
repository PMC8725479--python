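"""Reading images/masks and producing the discretized, normalized ROI.

All feature extraction downstream operates on a :class:`DiscretizedROI`:
in-mask intensities clipped at ``mean ± k·std``, min–max mapped onto the
integer range 0..255 with bin width 1.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from . import dicomio

N_LEVELS = 256
DEFAULT_OUTLIER_SIGMA = 3.0
DEFAULT_MIN_ROI_PIXELS = 32


class ShapeMismatchError(ValueError):
    """Image and mask grids do not have the same shape."""


class UnsupportedFormatError(ValueError):
    """Input file is not a supported greyscale image format."""


@dataclasses.dataclass(frozen=True)
class MaskedImage:
    """A greyscale pixel grid with a boolean region-of-interest mask.

    Coordinates are row-major and 0-based.  ``pixels`` may be in any input
    scale (8-bit PNG, rescaled DICOM stored values, float synthetic field);
    the mask marks the pixels on which features are computed.
    """

    pixels: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels, dtype=np.float64)
        mask = np.asarray(self.mask, dtype=bool)
        if pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {pixels.shape}")
        if pixels.shape != mask.shape:
            raise ShapeMismatchError(
                f"pixel grid {pixels.shape} and mask {mask.shape} differ"
            )
        object.__setattr__(self, "pixels", pixels)
        object.__setattr__(self, "mask", mask)

    @property
    def n_roi_pixels(self) -> int:
        return int(self.mask.sum())

    def roi_values(self) -> np.ndarray:
        return self.pixels[self.mask]


@dataclasses.dataclass(frozen=True)
class DiscretizedROI:
    """Integer grey levels in 0..255 inside the mask; undefined outside.

    ``degenerate`` is set when the ROI was constant (all levels forced to 0)
    so that batch extraction never aborts; flagged subjects are reported and
    excluded from modelling by default.
    """

    levels: np.ndarray
    mask: np.ndarray
    degenerate: bool = False
    n_levels: int = N_LEVELS

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels)
        mask = np.asarray(self.mask, dtype=bool)
        if levels.shape != mask.shape:
            raise ShapeMismatchError(
                f"level grid {levels.shape} and mask {mask.shape} differ"
            )
        inside = levels[mask]
        if inside.size and (inside.min() < 0 or inside.max() >= self.n_levels):
            raise ValueError("in-mask levels outside [0, n_levels)")
        object.__setattr__(self, "levels", levels.astype(np.int64))
        object.__setattr__(self, "mask", mask)

    def roi_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def normalize_roi(
    img: MaskedImage,
    outlier_sigma: float = DEFAULT_OUTLIER_SIGMA,
    min_roi_pixels: int = 1,
) -> DiscretizedROI:
    """Clip in-mask values at ``mean ± outlier_sigma·std`` and discretize.

    The clipped values are mapped linearly so clip-min -> 0, clip-max -> 255,
    and floored to bin width 1; the maximum value is assigned bin 255 so bin
    edges are bit-exact.  A constant ROI yields all-zero levels with the
    ``degenerate`` flag raised rather than an exception.

    Parameters
    ----------
    img:
        Image plus boolean ROI mask.
    outlier_sigma:
        Clipping half-width ``k`` in units of the in-mask standard deviation.
        ``np.inf`` disables outlier removal (plain min–max).
    min_roi_pixels:
        Minimum number of in-mask pixels required.
    """
    if outlier_sigma <= 0:
        raise ValueError("outlier_sigma must be positive")
    values = img.roi_values()
    if values.size < max(1, min_roi_pixels):
        raise ValueError(
            f"ROI has {values.size} pixels, fewer than required {min_roi_pixels}"
        )
    mu = float(values.mean())
    sigma = float(values.std())
    if sigma == 0.0:
        levels = np.zeros(img.pixels.shape, dtype=np.int64)
        return DiscretizedROI(levels=levels, mask=img.mask, degenerate=True)

    if np.isinf(outlier_sigma):
        lo, hi = float(values.min()), float(values.max())
    else:
        lo = max(float(values.min()), mu - outlier_sigma * sigma)
        hi = min(float(values.max()), mu + outlier_sigma * sigma)
    if hi <= lo:
        levels = np.zeros(img.pixels.shape, dtype=np.int64)
        return DiscretizedROI(levels=levels, mask=img.mask, degenerate=True)

    clipped = np.clip(img.pixels, lo, hi)
    scaled = (clipped - lo) * (N_LEVELS / (hi - lo))
    levels = np.floor(scaled).astype(np.int64)
    levels[levels >= N_LEVELS] = N_LEVELS - 1  # the max value lands in bin 255
    levels[~img.mask] = 0
    return DiscretizedROI(levels=levels, mask=img.mask, degenerate=False)


def _read_grey_array(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        # accept greyscale stored with redundant channels
        if arr.shape[2] in (3, 4) and np.all(arr[..., 0] == arr[..., 1]) and np.all(
            arr[..., 0] == arr[..., 2]
        ):
            arr = arr[..., 0]
        else:
            raise UnsupportedFormatError(f"{path}: expected greyscale, got shape {arr.shape}")
    return np.asarray(arr)


def read_image_and_mask(image_path: str | Path, mask_path: str | Path) -> MaskedImage:
    """Load an image (PNG/TIFF or single-frame monochrome DICOM) and its mask.

    The mask is any raster image where nonzero means in-ROI.  DICOM rescale
    slope/intercept are applied when present.
    """
    image_path = Path(image_path)
    mask_path = Path(mask_path)
    if image_path.suffix.lower() in (".dcm", ".dicom"):
        pixels = dicomio.read_dicom_image(image_path)
    else:
        pixels = _read_grey_array(image_path).astype(np.float64)
    mask = _read_grey_array(mask_path) != 0
    if pixels.shape != mask.shape:
        raise ShapeMismatchError(
            f"image {pixels.shape} vs mask {mask.shape} ({image_path}, {mask_path})"
        )
    return MaskedImage(pixels=pixels, mask=mask)
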